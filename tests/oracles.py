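"""Independent brute-force implementations of the F-statistic estimators.

These transcribe the published definitions directly over nested Python lists
of genotype tuples — no numpy, no shared code with the package — and serve
as the golden reference for the vectorized estimators on small tables.
"""

from __future__ import annotations


def wc_theta(pop_a, pop_b) -> float:
    """Weir & Cockerham (1984) theta for two samples, ratio of summed components.

    ``pop_a``/``pop_b`` are lists of individuals; an individual is a list of
    ``(allele1, allele2)`` tuples, one per locus.
    """
    pops = [pop_a, pop_b]
    r = 2
    n_loci = len(pops[0][0])
    num = 0.0
    den = 0.0
    ns = [len(pop) for pop in pops]
    nbar = sum(ns) / r
    nc = (r * nbar - sum(n * n for n in ns) / (r * nbar)) / (r - 1)
    for locus in range(n_loci):
        alleles = sorted({a for pop in pops for ind in pop for a in ind[locus]})
        for u in alleles:
            ps = [
                sum(ind[locus].count(u) for ind in pop) / (2 * n)
                for pop, n in zip(pops, ns)
            ]
            hs = [
                sum(1 for ind in pop if ind[locus][0] != ind[locus][1] and u in ind[locus]) / n
                for pop, n in zip(pops, ns)
            ]
            pbar = sum(n * p for n, p in zip(ns, ps)) / (r * nbar)
            s2 = sum(n * (p - pbar) ** 2 for n, p in zip(ns, ps)) / ((r - 1) * nbar)
            hbar = sum(n * h for n, h in zip(ns, hs)) / (r * nbar)
            inner = pbar * (1 - pbar) - (r - 1) / r * s2
            a = nbar / nc * (s2 - (inner - hbar / 4) / (nbar - 1))
            b = nbar / (nbar - 1) * (inner - (2 * nbar - 1) / (4 * nbar) * hbar)
            c = hbar / 2
            num += a
            den += a + b + c
    if den == 0.0:
        return float("nan")
    return num / den


def nei_fis(pop) -> float:
    """Nei's within-population F_IS = 1 - sum(Ho) / sum(Hs) over polymorphic loci.

    Hs carries the n/(n-1) small-sample correction
    ``Hs = n/(n-1) * (1 - sum_u p_u^2 - Ho/(2n))``.
    """
    n = len(pop)
    n_loci = len(pop[0])
    sum_ho = 0.0
    sum_hs = 0.0
    any_poly = False
    for locus in range(n_loci):
        alleles = sorted({a for ind in pop for a in ind[locus]})
        if len(alleles) < 2:
            continue
        any_poly = True
        ho = sum(1 for ind in pop if ind[locus][0] != ind[locus][1]) / n
        freqs = [sum(ind[locus].count(u) for ind in pop) / (2 * n) for u in alleles]
        hs = n / (n - 1) * (1 - sum(p * p for p in freqs) - ho / (2 * n))
        sum_ho += ho
        sum_hs += hs
    if not any_poly or sum_hs == 0.0:
        return float("nan")
    return 1.0 - sum_ho / sum_hs


def random_toy_table(rng, n_ind, n_loci, n_alleles=3):
    """Random genotype table as nested tuples (plus a guaranteed-polymorphic locus)."""
    table = [
        [
            (int(rng.integers(0, n_alleles)), int(rng.integers(0, n_alleles)))
            for _ in range(n_loci)
        ]
        for _ in range(n_ind)
    ]
    # force polymorphism at locus 0 so the estimators are defined
    table[0][0] = (0, 1)
    return table
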