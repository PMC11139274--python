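"""Monitored population-genetic statistics.

Heterozygosities, migrant ancestry, Nei F_IS, Weir & Cockerham (1984) F_ST,
and across-replicate quantile summaries.  All estimators consume per-locus
genotype-count tables (:class:`CountTable`) built in a single pass over the
genotype array, so a year-0 "historical" snapshot can be reduced to counts
once and compared against every subsequent year cheaply.

Conventions
-----------
* Observed/expected heterozygosity and F_IS use the neutral loci only.
* F_ST uses neutral + migrant-associated loci; the 100 fixed-difference
  diagnostic loci are what place two freshly founded populations at
  theta ~ 0.36 under the low founding-frequency regime.
* F_ST aggregates variance components as a ratio of sums across loci and
  alleles (sum of a over sum of a + b + c), the convention of the standard
  hierarchical F-statistics packages; loci monomorphic in the pooled sample
  contribute zero to both sums.
* F_IS is ``1 - sum(Ho) / sum(Hs)`` over polymorphic loci with Nei's
  small-sample correction ``Hs = n/(n-1) * (1 - sum p_u^2 - Ho/(2n))``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genome import GenomeSpec, SOURCE_ALLELE

_N_STATES = 3

# genotype code = 3 * allele1 + allele2 -> dosage of each allele state
_DOSE = np.zeros((9, _N_STATES), dtype=np.float64)
_HET = np.zeros(9, dtype=bool)
for _a in range(_N_STATES):
    for _b in range(_N_STATES):
        _code = 3 * _a + _b
        _DOSE[_code, _a] += 1
        _DOSE[_code, _b] += 1
        _HET[_code] = _a != _b
# heterozygous genotypes containing each allele state
_HET_CARRIER = _DOSE.astype(bool) & _HET[:, None]


@dataclass(frozen=True)
class CountTable:
    """Per-locus genotype summaries for one population sample.

    Attributes
    ----------
    n : int
        Number of diploid individuals.
    allele_counts : (L, 3) float array
        Copies of each allele state per locus.
    het : (L,) float array
        Heterozygous individuals per locus.
    het_carrier : (L, 3) float array
        Heterozygous individuals whose genotype contains each allele state.
    """

    n: int
    allele_counts: np.ndarray
    het: np.ndarray
    het_carrier: np.ndarray

    @property
    def freqs(self) -> np.ndarray:
        return self.allele_counts / (2.0 * self.n)


def count_table(geno: np.ndarray, loci: slice | None = None) -> CountTable:
    """Tabulate genotype counts per locus in one pass over the array."""
    from ._kernels import genotype_counts

    n = geno.shape[0]
    start, stop, _ = (loci or slice(None)).indices(geno.shape[1])
    cnt = genotype_counts(np.ascontiguousarray(geno), start, stop).astype(np.float64)
    return CountTable(
        n=n,
        allele_counts=cnt @ _DOSE,
        het=cnt[:, _HET].sum(axis=1),
        het_carrier=cnt @ _HET_CARRIER,
    )


# ---------------------------------------------------------------------------
# diversity and ancestry


def observed_heterozygosity(geno: np.ndarray, spec: GenomeSpec) -> float:
    """Mean per-individual fraction of heterozygous neutral loci."""
    if geno.shape[0] == 0:
        return float("nan")
    block = geno[:, spec.neutral_slice, :]
    return float((block[:, :, 0] != block[:, :, 1]).mean())


def expected_heterozygosity(geno: np.ndarray, spec: GenomeSpec) -> float:
    """Mean neutral-locus gene diversity ``1 - sum_u p_u^2`` (uncorrected)."""
    if geno.shape[0] == 0:
        return float("nan")
    ct = count_table(geno, spec.neutral_slice)
    return _expected_het_from_counts(ct)


def _expected_het_from_counts(ct: CountTable) -> float:
    p = ct.freqs
    return float((1.0 - (p**2).sum(axis=1)).mean())


def migrant_ancestry(geno: np.ndarray, spec: GenomeSpec) -> float:
    """Fraction of source-diagnostic allele copies at migrant-associated loci."""
    if geno.shape[0] == 0:
        return float("nan")
    block = geno[:, spec.migrant_slice, :]
    return float((block == SOURCE_ALLELE).mean())


# ---------------------------------------------------------------------------
# F-statistics


def _fis_from_counts(ct: CountTable) -> float:
    n = ct.n
    if n < 2:
        return float("nan")
    polymorphic = (ct.allele_counts > 0).sum(axis=1) >= 2
    if not polymorphic.any():
        return float("nan")
    ho = ct.het[polymorphic] / n
    p = ct.freqs[polymorphic]
    hs = (n / (n - 1.0)) * (1.0 - (p**2).sum(axis=1) - ho / (2.0 * n))
    denom = hs.sum()
    if denom == 0.0:
        return float("nan")
    return float(1.0 - ho.sum() / denom)


def f_is(geno: np.ndarray, spec: GenomeSpec) -> float:
    """Within-population inbreeding coefficient over polymorphic neutral loci.

    ``1 - Ho/Hs`` aggregated as a ratio of locus sums, with Nei's
    small-sample correction inside Hs.  Undefined (NaN) when every neutral
    locus is monomorphic or fewer than two individuals are present.
    """
    return _fis_from_counts(count_table(geno, spec.neutral_slice))


def wc_fst_from_counts(ct_a: CountTable, ct_b: CountTable) -> float:
    """Weir & Cockerham (1984) theta for two population samples.

    Variance components a (among populations), b (among individuals within
    populations), and c (within individuals) are computed per locus and
    allele and aggregated as ``sum(a) / sum(a + b + c)``.  Loci monomorphic
    in the pooled sample contribute zero to both sums; if nothing is
    polymorphic the estimator is undefined (NaN).
    """
    n1, n2 = float(ct_a.n), float(ct_b.n)
    if n1 < 2 or n2 < 2:
        return float("nan")
    r = 2.0
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
    p1, p2 = ct_a.freqs, ct_b.freqs  # (L, 3)
    h1 = ct_a.het_carrier / n1
    h2 = ct_b.het_carrier / n2
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    inner = pbar * (1.0 - pbar) - s2 * (r - 1.0) / r
    a = (nbar / nc) * (s2 - (inner - hbar / 4.0) / (nbar - 1.0))
    b = (nbar / (nbar - 1.0)) * (inner - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar)
    c = hbar / 2.0
    denom = (a + b + c).sum()
    if denom == 0.0:
        return float("nan")
    return float(a.sum() / denom)


def f_st(
    geno_a: np.ndarray,
    geno_b: np.ndarray,
    spec: GenomeSpec | None = None,
    loci: slice | None = None,
) -> float:
    """Weir-Cockerham theta between two genotype tables.

    When a :class:`GenomeSpec` is given the neutral + migrant-associated
    panel is used; an explicit ``loci`` slice overrides, and with neither
    every locus enters.
    """
    if loci is None and spec is not None:
        loci = spec.stat_slice
    return wc_fst_from_counts(count_table(geno_a, loci), count_table(geno_b, loci))


# ---------------------------------------------------------------------------
# per-year metric capture and replicate summaries

#: Metric columns summarized across replicates.
METRIC_COLUMNS = (
    "census",
    "n_adults",
    "sex_ratio",
    "ho_neutral",
    "he_neutral",
    "migrant_ancestry",
    "f_is",
    "fst_vs_recipient0",
    "fst_vs_source0",
    "n_effective_migrants",
    "n_effective_parents",
    "births",
    "deaths",
)


def recipient_metrics(
    pop,
    snapshot_recipient: CountTable,
    snapshot_source: CountTable,
) -> dict:
    """Genetic metric block for one recipient population census.

    One count table over the neutral + migrant panel feeds Ho, He, F_IS,
    migrant ancestry, and both divergence statistics against the year-0
    snapshots.
    """
    spec: GenomeSpec = pop.spec
    if pop.size == 0:
        return {name: float("nan") for name in (
            "ho_neutral", "he_neutral", "migrant_ancestry",
            "f_is", "fst_vs_recipient0", "fst_vs_source0",
        )}
    ct = count_table(pop.geno, spec.stat_slice)
    neutral = slice(0, spec.n_neutral)
    migrant = slice(spec.n_neutral, spec.n_neutral + spec.n_migrant)
    ct_neutral = CountTable(
        ct.n, ct.allele_counts[neutral], ct.het[neutral], ct.het_carrier[neutral]
    )
    ho = float(ct.het[neutral].sum() / (ct.n * spec.n_neutral))
    he = _expected_het_from_counts(ct_neutral)
    ancestry = float(
        ct.allele_counts[migrant, SOURCE_ALLELE].sum() / (2.0 * ct.n * spec.n_migrant)
    )
    return {
        "ho_neutral": ho,
        "he_neutral": he,
        "migrant_ancestry": ancestry,
        "f_is": _fis_from_counts(ct_neutral),
        "fst_vs_recipient0": wc_fst_from_counts(snapshot_recipient, ct),
        "fst_vs_source0": wc_fst_from_counts(snapshot_source, ct),
    }


def summarize_replicates(
    tables: Iterable[pd.DataFrame],
    quantile_pair: tuple[float, float] = (0.08, 0.92),
) -> pd.DataFrame:
    """Across-replicate per-year mean and central quantile band of each metric.

    Replicates contribute to a year only while extant (an extirpated
    replicate's table simply ends), so no zero-imputation occurs.  The band
    defaults to the central 84 % quantiles, the interval whose overlap
    behaviour approximates an alpha = 0.05 test between scenario means.

    Returns a tidy frame indexed by year with ``<metric>_mean``,
    ``<metric>_lo``, ``<metric>_hi`` columns plus ``n_replicates``.
    """
    tables = list(tables)
    if len(tables) < 2:
        raise ValueError("need at least two replicates to summarize")
    lo_q, hi_q = quantile_pair
    if not 0.0 <= lo_q < hi_q <= 1.0:
        raise ValueError("quantile_pair must be an increasing pair in [0, 1]")
    stacked = pd.concat(tables, keys=range(len(tables)), names=["replicate"])
    grouped = stacked.groupby("year")
    out = pd.DataFrame(index=grouped.size().index)
    out["n_replicates"] = grouped.size()
    for col in METRIC_COLUMNS:
        if col not in stacked.columns:
            continue
        series = grouped[col]
        out[f"{col}_mean"] = series.mean()
        out[f"{col}_lo"] = series.quantile(lo_q)
        out[f"{col}_hi"] = series.quantile(hi_q)
    return out


def extirpation_years(tables: Sequence[pd.DataFrame]) -> list[int | None]:
    """Per-replicate extirpation year (None when the replicate ran to the end)."""
    years: list[int | None] = []
    for df in tables:
        if len(df) and bool(df["extirpated"].iloc[-1]):
            years.append(int(df["year"].iloc[-1]))
        else:
            years.append(None)
    return years
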