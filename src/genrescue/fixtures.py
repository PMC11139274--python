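"""Miniature scenarios and hand-checkable genotype tables for tests and demos.

The mini scenarios keep the full structure of a study cell — three locus
classes, both populations, crash schedule, migration, snapshots — at a scale
that runs in seconds, so every code path is exercised without the cost of a
full 350-year, 1200-locus run.  They are *not* calibrated to reproduce any
published quantity; full-scale configurations do that.
"""

from __future__ import annotations

from types import MappingProxyType
from typing import Sequence

import numpy as np

from .demography import CrashSchedule
from .engine import ScenarioConfig
from .errors import ConfigurationError
from .genome import GenomeSpec
from .migration import MigrationSchedule, build_schedule

PROFILES = ("smoke", "crash", "rescue")

_MINI_GENOME = dict(n_neutral=20, n_migrant=10, n_conserved=10)


def make_mini_scenario(profile: str, seed: int = 0) -> ScenarioConfig:
    """Deterministic down-scaled scenario config.

    ``smoke``   — control run: no crash, no migration, 60 years.
    ``crash``   — severe crash (K 60 -> 6, years 20-35) without migration;
                  at this severity some replicates extirpate.
    ``rescue``  — a survivable crash (K 60 -> 20) supported by four
                  post-restoration migrant pulses.
    """
    if profile not in PROFILES:
        raise ConfigurationError(f"unknown mini profile {profile!r}")
    genome = GenomeSpec(**_MINI_GENOME)
    years = 60
    common = dict(
        years=years,
        genome=genome,
        k_source=200,
        replicates=10,
        base_seed=int(seed),
        extirpation_threshold=3,
    )
    if profile == "smoke":
        return ScenarioConfig(
            name="mini_smoke",
            crash=CrashSchedule(k_historic=60),
            migration=build_schedule("none"),
            **common,
        )
    if profile == "crash":
        crash = CrashSchedule(
            k_historic=60, k_crash=6, decline_start=20, decline_years=5, minima_end=35
        )
        return ScenarioConfig(
            name="mini_crash", crash=crash, migration=build_schedule("none"), **common
        )
    crash = CrashSchedule(
        k_historic=60, k_crash=20, decline_start=20, decline_years=5, minima_end=35
    )
    pulses = MigrationSchedule(
        "pulse", "after_restoration", MappingProxyType({36: 5, 42: 5, 48: 5, 54: 5})
    )
    return ScenarioConfig(
        name="mini_rescue", crash=crash, migration=pulses, **common
    )


def make_toy_genotypes(layout: Sequence[Sequence[tuple[int, int]]]) -> np.ndarray:
    """Build a genotype array verbatim from nested (allele1, allele2) pairs.

    ``layout[i][l]`` is the genotype of individual ``i`` at locus ``l``.
    Rows must all have the same number of loci.
    """
    n = len(layout)
    if n == 0:
        raise ConfigurationError("layout must contain at least one individual")
    widths = {len(row) for row in layout}
    if len(widths) != 1:
        raise ConfigurationError("ragged genotype table")
    arr = np.asarray(layout, dtype=np.uint8)
    if arr.ndim != 3 or arr.shape[2] != 2:
        raise ConfigurationError("each entry must be an (allele1, allele2) pair")
    return arr
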