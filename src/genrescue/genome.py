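"""Diploid SNP genome layout, founding genotypes, mutation, and Mendelian transmission.

The genome is a fixed panel of biallelic-at-founding SNP loci split into three
classes laid out contiguously along the locus axis:

* **neutral** loci seed standing variation (founding minor allele frequency
  drawn per locus from a configured interval) and drive every diversity
  statistic;
* **migrant-associated** loci are population-diagnostic markers: founders of
  each population are homozygous for their own diagnostic allele, so the
  source-diagnostic allele fraction measures migrant ancestry;
* **conserved** loci start monomorphic reference and acquire a fitness cost
  only through mutation (homozygous-mutant = deleterious).

Genotypes are stored as a dense ``uint8`` array of shape ``(n_individuals,
n_loci, 2)`` holding one of three allele states.  The mutant state is a third,
absorbing allele distinct from reference/alternate so that conserved-site
mutation counting never collides with standing variation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .errors import ConfigurationError

# Allele state codes used throughout the package.
REF: int = 0
ALT: int = 1
MUT: int = 2

#: Diagnostic allele carried by founders at migrant-associated loci.
RECIPIENT_ALLELE: int = REF
SOURCE_ALLELE: int = ALT

# Low / high founding minor-allele-frequency intervals.
MAF_LOW: tuple[float, float] = (0.05, 0.15)
MAF_HIGH: tuple[float, float] = (0.40, 0.50)


@dataclass(frozen=True)
class GenomeSpec:
    """Locus-class layout, founding frequency ranges, and mutation rates.

    Parameters
    ----------
    n_neutral, n_migrant, n_conserved
        Locus counts per class (defaults 1000 / 100 / 100).
    maf_range_recipient, maf_range_source
        Closed intervals for the founding minor allele frequency ``p`` of the
        neutral loci in each population.  Bounds must lie in (0, 0.5).
    mu_neutral
        Per-allele, per-year mutation probability for neutral and
        migrant-associated loci.
    constraint_u
        Selective-constraint multiplier applied to the conserved class; the
        conserved rate is ``mu_neutral * constraint_u``.
    """

    n_neutral: int = 1000
    n_migrant: int = 100
    n_conserved: int = 100
    maf_range_recipient: tuple[float, float] = MAF_LOW
    maf_range_source: tuple[float, float] = MAF_LOW
    mu_neutral: float = 2.2e-9
    constraint_u: float = 2.2

    def __post_init__(self) -> None:
        for name in ("n_neutral", "n_migrant", "n_conserved"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        for name in ("maf_range_recipient", "maf_range_source"):
            lo, hi = getattr(self, name)
            if not (0.0 < lo <= hi <= 0.5):
                raise ConfigurationError(
                    f"{name}={getattr(self, name)!r}: bounds must satisfy 0 < lo <= hi <= 0.5"
                )
        if self.mu_neutral < 0 or self.constraint_u < 0:
            raise ConfigurationError("mutation parameters must be non-negative")

    @property
    def mu_conserved(self) -> float:
        return self.mu_neutral * self.constraint_u

    @property
    def n_loci(self) -> int:
        return self.n_neutral + self.n_migrant + self.n_conserved

    @property
    def neutral_slice(self) -> slice:
        return slice(0, self.n_neutral)

    @property
    def migrant_slice(self) -> slice:
        return slice(self.n_neutral, self.n_neutral + self.n_migrant)

    @property
    def conserved_slice(self) -> slice:
        return slice(self.n_neutral + self.n_migrant, self.n_loci)

    @property
    def stat_slice(self) -> slice:
        """Neutral + migrant-associated loci (the divergence-statistic panel)."""
        return slice(0, self.n_neutral + self.n_migrant)


class FoundingFrequencies(NamedTuple):
    """Per-locus founding alternate-allele frequencies for both populations.

    At migrant-associated loci the value is the frequency of the population's
    own diagnostic allele (always 1.0); at conserved loci it is the frequency
    of non-reference alleles (always 0.0).
    """

    recipient: np.ndarray
    source: np.ndarray
    shared: bool


def _as_rng(rng: np.random.Generator | int | None) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def draw_founding_frequencies(
    spec: GenomeSpec, rng: np.random.Generator | int | None = None
) -> FoundingFrequencies:
    """Draw founding allele frequencies for every locus.

    Neutral frequencies are uniform on the configured interval.  When the two
    populations use the same interval a single draw per locus is shared by
    both (the founding alternate allele is the same allele in both
    populations); when the intervals differ each population draws
    independently.
    """
    rng = _as_rng(rng)
    shared = spec.maf_range_recipient == spec.maf_range_source

    def _draw(bounds: tuple[float, float]) -> np.ndarray:
        lo, hi = bounds
        return rng.uniform(lo, hi, size=spec.n_neutral)

    neutral_r = _draw(spec.maf_range_recipient)
    neutral_s = neutral_r if shared else _draw(spec.maf_range_source)

    def _full(neutral: np.ndarray) -> np.ndarray:
        freqs = np.empty(spec.n_loci, dtype=float)
        freqs[spec.neutral_slice] = neutral
        freqs[spec.migrant_slice] = 1.0
        freqs[spec.conserved_slice] = 0.0
        return freqs

    return FoundingFrequencies(_full(neutral_r), _full(neutral_s), shared)


def init_genotypes(
    spec: GenomeSpec,
    n_individuals: int,
    population_label: str,
    frequencies: np.ndarray,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Create founder genotypes of shape ``(n_individuals, n_loci, 2)``.

    Neutral allele copies are alternate with probability ``p`` independently
    (Hardy-Weinberg founding), migrant-associated loci are homozygous for the
    population's diagnostic allele, conserved loci are homozygous reference.
    """
    if n_individuals <= 0:
        raise ConfigurationError("n_individuals must be positive")
    if population_label not in ("recipient", "source"):
        raise ConfigurationError(f"unknown population label {population_label!r}")
    rng = _as_rng(rng)

    geno = np.zeros((n_individuals, spec.n_loci, 2), dtype=np.uint8)
    p = np.asarray(frequencies, dtype=np.float32)[spec.neutral_slice]
    draws = rng.random((n_individuals, spec.n_neutral, 2), dtype=np.float32)
    geno[:, spec.neutral_slice, :] = (draws < p[None, :, None]).astype(np.uint8)
    diag = SOURCE_ALLELE if population_label == "source" else RECIPIENT_ALLELE
    geno[:, spec.migrant_slice, :] = diag
    # conserved loci stay homozygous reference
    return geno


class MutationEvents(NamedTuple):
    """Indices of allele copies newly flipped to the mutant state."""

    rows: np.ndarray  # individual row index
    loci: np.ndarray  # locus column index (absolute)
    copies: np.ndarray  # 0 or 1


def mutate(
    genotypes: np.ndarray,
    spec: GenomeSpec,
    rng: np.random.Generator | int | None = None,
) -> MutationEvents:
    """Flip allele copies to the absorbing mutant state, in place.

    Neutral and migrant-associated copies mutate at ``mu_neutral``; conserved
    copies at ``mu_conserved``.  At realistic rates mutations are drawn
    sparsely (a binomial event count and uniform placement) rather than by
    masking every allele copy; with elevated rates (>= 1 %) a dense Bernoulli
    mask is used so that test-only settings such as ``mu = 1`` behave exactly.

    Returns the positions of copies that changed state (already-mutant copies
    hit again do not recur in the result).
    """
    rng = _as_rng(rng)
    n = genotypes.shape[0]
    out_rows: list[np.ndarray] = []
    out_loci: list[np.ndarray] = []
    out_copies: list[np.ndarray] = []
    if n == 0:
        empty = np.empty(0, dtype=np.int64)
        return MutationEvents(empty, empty.copy(), empty.copy())

    for sl, mu in ((spec.stat_slice, spec.mu_neutral), (spec.conserved_slice, spec.mu_conserved)):
        if mu <= 0.0:
            continue
        width = sl.stop - sl.start
        block = genotypes[:, sl, :]
        n_slots = n * width * 2
        if mu >= 0.01:
            hits = rng.random(block.shape) < mu
            hits &= block != MUT
            rows, loci, copies = np.nonzero(hits)
        else:
            k = rng.binomial(n_slots, mu)
            if k == 0:
                continue
            # duplicate draws are harmless (absorbing state); collision
            # probability is negligible at these rates
            flat = rng.integers(0, n_slots, size=k)
            rows, rem = np.divmod(flat, width * 2)
            loci, copies = np.divmod(rem, 2)
            fresh = block[rows, loci, copies] != MUT
            rows, loci, copies = rows[fresh], loci[fresh], copies[fresh]
        block[rows, loci, copies] = MUT
        out_rows.append(rows)
        out_loci.append(loci + sl.start)
        out_copies.append(copies)

    if not out_rows:
        empty = np.empty(0, dtype=np.int64)
        return MutationEvents(empty, empty.copy(), empty.copy())
    return MutationEvents(
        np.concatenate(out_rows), np.concatenate(out_loci), np.concatenate(out_copies)
    )


def count_conserved(genotypes: np.ndarray, spec: GenomeSpec) -> tuple[np.ndarray, np.ndarray]:
    """Per-individual conserved-site mutation counts.

    Returns ``(m, d)`` where ``m`` counts mutant allele copies across the
    conserved loci (either copy) and ``d`` counts loci homozygous for the
    mutant state (the deleterious configuration).
    """
    block = genotypes[:, spec.conserved_slice, :]
    is_mut = block == MUT
    m = is_mut.sum(axis=(1, 2))
    d = (is_mut[:, :, 0] & is_mut[:, :, 1]).sum(axis=1)
    return m.astype(np.int64), d.astype(np.int64)


def count_deleterious(genotypes: np.ndarray, spec: GenomeSpec, individual: int) -> tuple[int, int]:
    """Deleterious-locus and total conserved-mutation counts for one individual."""
    m, d = count_conserved(genotypes[individual : individual + 1], spec)
    return int(d[0]), int(m[0])


def mendelian_offspring(
    genotypes: np.ndarray,
    parents_a: np.ndarray,
    parents_b: np.ndarray,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Create offspring genotypes by independent Mendelian segregation.

    At every locus each offspring receives one uniformly chosen allele copy
    from each parent, independently across loci.  ``parents_a``/``parents_b``
    are row indices into ``genotypes``; one offspring is produced per pair of
    entries.  Mutation is *not* applied here.
    """
    rng = _as_rng(rng)
    parents_a = np.atleast_1d(np.asarray(parents_a, dtype=np.intp))
    parents_b = np.atleast_1d(np.asarray(parents_b, dtype=np.intp))
    if parents_a.shape != parents_b.shape:
        raise ValueError("parent index arrays must have equal length")
    from ._kernels import mendel_pick

    k = parents_a.size
    n_loci = genotypes.shape[1]
    genotypes = np.ascontiguousarray(genotypes)
    off = np.empty((k, n_loci, 2), dtype=np.uint8)
    n_words = (k * n_loci + 63) // 64
    for j, parents in enumerate((parents_a, parents_b)):
        words = rng.integers(0, 2**64, size=n_words, dtype=np.uint64)
        mendel_pick(genotypes, parents, words, off, j)
    return off


def write_genotypes_csv(path, genotypes: np.ndarray, ids=None) -> None:
    """Write a wide CSV: one row per (individual, locus) with both allele codes.

    Columns: ``individual_id, locus, allele1, allele2`` with allele states
    coded 0 = reference, 1 = alternate, 2 = mutant.
    """
    import pandas as pd

    n, n_loci, _ = genotypes.shape
    if ids is None:
        ids = np.arange(n)
    df = pd.DataFrame(
        {
            "individual_id": np.repeat(np.asarray(ids), n_loci),
            "locus": np.tile(np.arange(n_loci), n),
            "allele1": genotypes[:, :, 0].ravel(),
            "allele2": genotypes[:, :, 1].ravel(),
        }
    )
    df.to_csv(path, index=False)


def write_vcf(path, genotypes: np.ndarray, spec: GenomeSpec, ids=None) -> None:
    """Write diploid genotypes as a minimal VCF 4.2 text file.

    Each locus becomes one record on contig ``1`` at position ``locus + 1``
    with ``REF=A`` and ``ALT=C,T``: GT allele index 1 is the standing
    alternate allele and index 2 the mutant state.  Locus class is recorded
    in the ID column (``neu``/``mig``/``con`` prefix).  Unphased genotypes.
    """
    n, n_loci, _ = genotypes.shape
    if ids is None:
        ids = [f"ind{i}" for i in range(n)]
    classes = np.empty(n_loci, dtype=object)
    classes[spec.neutral_slice] = "neu"
    classes[spec.migrant_slice] = "mig"
    classes[spec.conserved_slice] = "con"
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##contig=<ID=1>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(str(s) for s in ids)
            + "\n"
        )
        for locus in range(n_loci):
            gts = "\t".join(
                f"{genotypes[i, locus, 0]}/{genotypes[i, locus, 1]}" for i in range(n)
            )
            fh.write(f"1\t{locus + 1}\t{classes[locus]}_{locus}\tA\tC,T\t.\t.\t.\tGT\t{gts}\n")
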