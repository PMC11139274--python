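"""The canonical scenario grid and its headline measurements.

This module names the simulation cells of the full-scale study design —
extinction-risk category x connectivity regime x migration timing x founding
minor-allele-frequency regime — and provides the scalar summaries used to
describe their outcomes: percent change in observed heterozygosity between
two census years, divergence from the year-0 snapshots at the end of the
run, and migrant ancestry averaged over the post-migration window.

Cells are referred to by descriptive keys such as
``crash_ce_unconnected`` (critically endangered crash, no migration) or
``crash_end_pulse_during`` (endangered crash, four 25-individual pulses
while habitat is still being restored).
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .engine import ScenarioResult, make_scenario, run_scenario

#: Full-scale study cells, keyed by a descriptive name.  Each value is the
#: keyword set handed to :func:`genrescue.make_scenario`.
STUDY_CELLS: Mapping[str, dict] = {
    "control_unconnected": dict(crash_category="none", regime="none"),
    "crash_ce_unconnected": dict(crash_category="critically_endangered", regime="none"),
    "crash_vuln_unconnected": dict(crash_category="vulnerable", regime="none"),
    "crash_end_unconnected_highmaf": dict(
        crash_category="endangered", regime="none", maf_regime="high/high"
    ),
    "crash_end_opg_highmaf": dict(
        crash_category="endangered", regime="one_per_generation", maf_regime="high/high"
    ),
    "crash_end_opg_high_to_low": dict(
        crash_category="endangered",
        regime="one_per_generation",
        maf_regime="high_source/low_recipient",
    ),
    "crash_end_opg_low_to_high": dict(
        crash_category="endangered",
        regime="one_per_generation",
        maf_regime="low_source/high_recipient",
    ),
    "crash_ce_opg": dict(crash_category="critically_endangered", regime="one_per_generation"),
    "crash_end_opg": dict(crash_category="endangered", regime="one_per_generation"),
    "crash_vuln_opg": dict(crash_category="vulnerable", regime="one_per_generation"),
    "crash_end_burst_after": dict(
        crash_category="endangered", regime="burst", timing="after_restoration"
    ),
    "crash_end_pulse_during": dict(
        crash_category="endangered", regime="pulse", timing="during_restoration"
    ),
}


def run_cell(
    name: str,
    replicates: int = 30,
    base_seed: int = 0,
    progress: bool = False,
) -> ScenarioResult:
    """Run one named study cell.

    The cell's seed is offset by its (stable) position in the grid so that
    different cells never share random streams under one base seed.
    """
    offset = list(STUDY_CELLS).index(name)
    cfg = make_scenario(
        **STUDY_CELLS[name], replicates=replicates, base_seed=base_seed, track_lrs=False
    )
    return run_scenario(cfg, base_seed=base_seed + 1000 * offset, progress=progress)


# ---------------------------------------------------------------------------
# scalar summaries of a cell


def percent_reduction(
    summary: pd.DataFrame, metric: str, year0: int, year1: int
) -> float:
    """Percent drop in a replicate-mean metric between two census years."""
    v0 = float(summary.loc[year0, f"{metric}_mean"])
    v1 = float(summary.loc[year1, f"{metric}_mean"])
    return 100.0 * (v0 - v1) / v0


def level_at(summary: pd.DataFrame, metric: str, year: int) -> float:
    """Replicate-mean metric at one census year."""
    return float(summary.loc[year, f"{metric}_mean"])


def window_mean(
    summary: pd.DataFrame, metric: str, year0: int, year1: int
) -> float:
    """Replicate-mean metric averaged over an inclusive year window."""
    rows = summary.loc[year0:year1, f"{metric}_mean"]
    return float(rows.mean())


# per-replicate versions of the same scalars, for uncertainty bands


def _at_year(df: pd.DataFrame, metric: str, year: int) -> float:
    row = df.loc[df["year"] == year, metric]
    return float(row.iloc[0]) if len(row) else float("nan")


def replicate_percent_reductions(
    result: ScenarioResult, metric: str, year0: int, year1: int
) -> np.ndarray:
    vals = []
    for df in result.replicates:
        v0, v1 = _at_year(df, metric, year0), _at_year(df, metric, year1)
        vals.append(100.0 * (v0 - v1) / v0)
    return np.asarray(vals)


def replicate_levels(result: ScenarioResult, metric: str, year: int) -> np.ndarray:
    return np.asarray([_at_year(df, metric, year) for df in result.replicates])


def replicate_window_means(
    result: ScenarioResult, metric: str, year0: int, year1: int
) -> np.ndarray:
    vals = []
    for df in result.replicates:
        window = df.loc[(df["year"] >= year0) & (df["year"] <= year1), metric]
        vals.append(float(window.mean()) if len(window) else float("nan"))
    return np.asarray(vals)


def band_half_width(values: np.ndarray, quantiles=(0.08, 0.92)) -> float:
    """Half-width of the central 84% quantile band of per-replicate scalars."""
    values = values[np.isfinite(values)]
    lo, hi = np.quantile(values, quantiles)
    return float((hi - lo) / 2.0)
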