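"""Migration schedules and source-to-recipient individual transfer.

Four connectivity regimes are supported:

* ``none`` — no movement ever;
* ``one_per_generation`` — one migrant every year of the run (the age of
  maturity, one year, is the model's generation convention);
* ``burst`` — a single translocation of 100 individuals;
* ``pulse`` — four translocations of 25 individuals.

Burst and pulse events can be timed either *during* habitat restoration
(while the population is still held at the crash minima: year 125, or years
125/140/155/170) or *after* restoration has completed (year 151, or years
151/165/181/195).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Mapping

import numpy as np

from .errors import ConfigurationError
from .population import Population

log = logging.getLogger(__name__)

REGIMES = ("none", "one_per_generation", "burst", "pulse")
TIMINGS = ("during_restoration", "after_restoration")

_EVENT_YEARS = {
    ("burst", "during_restoration"): {125: 100},
    ("burst", "after_restoration"): {151: 100},
    ("pulse", "during_restoration"): {125: 25, 140: 25, 155: 25, 170: 25},
    ("pulse", "after_restoration"): {151: 25, 165: 25, 181: 25, 195: 25},
}


@dataclass(frozen=True)
class MigrationSchedule:
    """Mapping of simulation year to migrant count for one regime/timing."""

    regime: str
    timing: str | None
    events: Mapping[int, int]

    @property
    def total_migrants(self) -> int:
        return sum(self.events.values())

    def migrants_at(self, year: int) -> int:
        return self.events.get(year, 0)


def build_schedule(
    regime: str, timing: str | None = None, run_years: int = 350
) -> MigrationSchedule:
    """Construct the year -> migrant-count map for a regime/timing choice.

    ``timing`` is required for burst/pulse and must be absent otherwise.
    """
    if regime not in REGIMES:
        raise ConfigurationError(f"unknown migration regime {regime!r}")
    if regime in ("none", "one_per_generation"):
        if timing is not None:
            raise ConfigurationError(f"timing is not applicable to regime {regime!r}")
        if regime == "none":
            events: dict[int, int] = {}
        else:
            events = {year: 1 for year in range(1, run_years + 1)}
    else:
        if timing not in TIMINGS:
            raise ConfigurationError(
                f"regime {regime!r} requires timing in {TIMINGS}, got {timing!r}"
            )
        events = dict(_EVENT_YEARS[(regime, timing)])
    return MigrationSchedule(regime, timing, MappingProxyType(events))


def transfer_migrants(
    source: Population,
    recipient: Population,
    n: int,
    rng: np.random.Generator,
    year: int,
) -> np.ndarray:
    """Move ``n`` uniformly sampled mature individuals between populations.

    Genotype rows move verbatim (a transfer, not a re-draw); arrivals are
    flagged ``origin = migrant`` with the arrival year recorded.  If fewer
    than ``n`` mature source individuals exist, all available are moved and a
    warning is logged; an extirpated source contributes nothing.

    Returns the ids of the transferred individuals.
    """
    if n < 0:
        raise ConfigurationError("migrant count must be non-negative")
    if n == 0:
        return np.empty(0, dtype=np.int64)
    if source.extirpated:
        log.warning("year %d: source population extirpated, no migrants moved", year)
        return np.empty(0, dtype=np.int64)
    mature = np.flatnonzero(source.mature_mask())
    k = min(n, mature.size)
    if k < n:
        log.warning(
            "year %d: only %d mature source individuals for %d requested migrants",
            year,
            mature.size,
            n,
        )
    if k == 0:
        return np.empty(0, dtype=np.int64)
    rows = rng.choice(mature, size=k, replace=False)
    fields = source.take_rows(rows)
    geno = source.geno[rows].copy()
    fields["origin_migrant"] = np.ones(k, dtype=bool)
    fields["arrival_year"] = np.full(k, year, dtype=np.int32)
    moved_ids = fields["ids"]
    dead = np.zeros(source.size, dtype=bool)
    dead[rows] = True
    source.remove(dead)
    recipient.append(geno, **fields)
    return moved_ids
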