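"""Yearly reproduction pipeline: carrying-capacity schedule, logistic quota,
Allee-limited pairing, migrant-preferential breeder selection, and offspring
creation.

The habitat crash is expressed purely through the carrying capacity ``K``:
a linear decline from the historic capacity to a crash floor over the decline
decade, a hold at the floor through the minima, and an instant return to the
historic capacity once restoration completes.  Offspring numbers follow the
discrete logistic map

    N_{t+1} = (1 + r (1 - N_t / K)) N_t

perturbed by density-independent Normal(0, sigma) noise; the yearly birth
quota is ``max(0, round(N_{t+1}) - N_t)`` (reductions are left to the
mortality processes, never to culling).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .errors import ConfigurationError
from .genome import count_conserved, mendelian_offspring, mutate
from .population import FEMALE, MALE, Population, _LABEL_CODE

#: Crash-floor carrying capacities by extinction-risk category.
CRASH_CAPACITY = {
    "none": None,
    "vulnerable": 700,
    "endangered": 300,
    "critically_endangered": 100,
}

MAX_FECUNDITY: int = 2


@dataclass(frozen=True)
class CrashSchedule:
    """Piecewise carrying-capacity trajectory of a habitat crash.

    ``k_crash=None`` means no crash: the capacity is ``k_historic`` forever.
    Otherwise K declines linearly from ``k_historic`` to ``k_crash`` over
    ``decline_years`` starting at ``decline_start``, holds at the floor until
    ``minima_end``, and is restored to ``k_historic`` afterwards.
    """

    k_historic: int = 1000
    k_crash: int | None = None
    decline_start: int = 100
    decline_years: int = 10
    minima_end: int = 150

    def __post_init__(self) -> None:
        if self.k_historic <= 0:
            raise ConfigurationError("k_historic must be positive")
        if self.k_crash is not None:
            if not (0 < self.k_crash < self.k_historic):
                raise ConfigurationError("k_crash must lie in (0, k_historic)")
            if self.decline_years <= 0 or self.minima_end < self.decline_start + self.decline_years:
                raise ConfigurationError("invalid crash timing")

    @classmethod
    def from_category(cls, category: str, **kwargs) -> "CrashSchedule":
        if category not in CRASH_CAPACITY:
            raise ConfigurationError(f"unknown extinction-risk category {category!r}")
        return cls(k_crash=CRASH_CAPACITY[category], **kwargs)


def carrying_capacity_at(year: int, schedule: CrashSchedule) -> int:
    """Carrying capacity in force at ``year`` (rounded to whole individuals)."""
    k0 = schedule.k_historic
    kb = schedule.k_crash
    if kb is None or year < schedule.decline_start or year > schedule.minima_end:
        return k0
    frac = min((year - schedule.decline_start) / schedule.decline_years, 1.0)
    return int(round(k0 + (kb - k0) * frac))


def offspring_quota(
    n_t: int,
    k: int,
    r: float = 1.0,
    noise_sd: float = 1.0,
    rng: np.random.Generator | None = None,
) -> int:
    """Number of offspring to create this year from the logistic map.

    The projected ``N_{t+1}`` is perturbed by Normal(0, ``noise_sd``) when a
    generator is supplied and the sd is positive, floored at zero, and
    rounded; the quota is the positive part of the projected increment.
    """
    if n_t < 0 or k <= 0:
        raise ConfigurationError("require n_t >= 0 and k > 0")
    if n_t == 0:
        return 0
    projected = (1.0 + r * (1.0 - n_t / k)) * n_t
    if noise_sd > 0 and rng is not None:
        projected += rng.normal(0.0, noise_sd)
    projected = max(projected, 0.0)
    return max(int(round(projected)) - n_t, 0)


class BreedingPairs(NamedTuple):
    """Row indices of paired mates plus per-pair annotations."""

    females: np.ndarray  # row indices into the population
    males: np.ndarray
    has_migrant: np.ndarray  # bool
    n_offspring: np.ndarray  # int, filled by select_breeders (0 before)

    @property
    def n_pairs(self) -> int:
        return self.females.size


def _empty_pairs() -> BreedingPairs:
    z = np.empty(0, dtype=np.intp)
    return BreedingPairs(z, z.copy(), np.empty(0, dtype=bool), np.empty(0, dtype=np.int64))


def form_pairs(pop: Population, rng: np.random.Generator) -> BreedingPairs:
    """Randomly pair mature individuals across sexes with an Allee penalty.

    The candidate pair count ``P`` is the minority mature sex count; each
    candidate pair is retained independently with probability ``1 - 1/P``,
    so a lone pair can never breed and mate-finding improves with density.
    """
    mature = pop.mature_mask()
    f_idx = np.flatnonzero(mature & (pop.sex == FEMALE))
    m_idx = np.flatnonzero(mature & (pop.sex == MALE))
    p = min(f_idx.size, m_idx.size)
    if p == 0:
        return _empty_pairs()
    f_idx = rng.permutation(f_idx)[:p]
    m_idx = rng.permutation(m_idx)[:p]
    retained = rng.random(p) < (1.0 - 1.0 / p)
    f_idx, m_idx = f_idx[retained], m_idx[retained]
    has_migrant = pop.origin_migrant[f_idx] | pop.origin_migrant[m_idx]
    return BreedingPairs(
        f_idx, m_idx, has_migrant, np.zeros(f_idx.size, dtype=np.int64)
    )


def select_breeders(
    pairs: BreedingPairs,
    quota: int,
    migrant_bias: bool,
    rng: np.random.Generator,
) -> BreedingPairs:
    """Assign offspring (max 2 per pair) down a priority order until the quota runs out.

    With ``migrant_bias`` pairs containing at least one migrant come first
    (random order within each tier); otherwise the order is fully random.
    The final funded pair may receive a single offspring; quota beyond
    ``2 * n_pairs`` is dropped.
    """
    if quota < 0:
        raise ConfigurationError("quota must be non-negative")
    n = pairs.n_pairs
    if n == 0 or quota == 0:
        return pairs._replace(n_offspring=np.zeros(n, dtype=np.int64))
    if migrant_bias:
        mig = np.flatnonzero(pairs.has_migrant)
        res = np.flatnonzero(~pairs.has_migrant)
        order = np.concatenate((rng.permutation(mig), rng.permutation(res)))
    else:
        order = rng.permutation(n)
    total = min(quota, MAX_FECUNDITY * n)
    counts = np.zeros(n, dtype=np.int64)
    n_full, rem = divmod(total, MAX_FECUNDITY)
    counts[order[:n_full]] = MAX_FECUNDITY
    if rem:
        counts[order[n_full]] = rem
    return pairs._replace(n_offspring=counts)


class ReproductionOutcome(NamedTuple):
    births: int
    n_effective_parents: int
    n_effective_migrants: int


def reproduce(
    pop: Population,
    breeders: BreedingPairs,
    rng: np.random.Generator,
    id_source,
    lrs=None,
) -> ReproductionOutcome:
    """Create the assigned offspring and append them to the population.

    Newborns get Mendelian genotypes (mutation applied at creation), a fair
    coin sex, age 0, and resident origin.  Parent lifetime-reproductive-
    success counters are updated through the optional ``lrs`` ledger.
    Violates loudly on same-sex pairings or immature parents.
    """
    active = breeders.n_offspring > 0
    f_rows = breeders.females[active]
    m_rows = breeders.males[active]
    counts = breeders.n_offspring[active]
    if f_rows.size == 0:
        return ReproductionOutcome(0, 0, 0)
    if (pop.sex[f_rows] != FEMALE).any() or (pop.sex[m_rows] != MALE).any():
        raise ValueError("breeding pairs must be female x male")
    if (pop.age[f_rows] < 1).any() or (pop.age[m_rows] < 1).any():
        raise ValueError("breeding pairs must be mature")

    n_births = int(counts.sum())
    rep_f = np.repeat(f_rows, counts)
    rep_m = np.repeat(m_rows, counts)
    kids = mendelian_offspring(pop.geno, rep_f, rep_m, rng)
    mutate(kids, pop.spec, rng)  # newborn mutation at creation
    # conserved counts of newborns (inherited plus de novo)
    m, d = count_conserved(kids, pop.spec)

    n_eff_parents = 2 * f_rows.size
    n_eff_migrants = int(
        pop.origin_migrant[f_rows].sum() + pop.origin_migrant[m_rows].sum()
    )
    if lrs is not None:
        lrs.record_breeding(
            pop.ids[f_rows], pop.ids[m_rows], counts
        )
    kid_ids = id_source.take(n_births)
    if lrs is not None:
        lrs.register(kid_ids)
    pop.append(
        kids,
        ids=kid_ids,
        sex=rng.integers(0, 2, size=n_births, dtype=np.uint8),
        age=np.zeros(n_births, dtype=np.int16),
        origin_migrant=np.zeros(n_births, dtype=bool),
        natal=np.full(n_births, _LABEL_CODE[pop.label], dtype=np.uint8),
        parent_f=pop.ids[rep_f],
        parent_m=pop.ids[rep_m],
        arrival_year=np.full(n_births, -1, dtype=np.int32),
        maturity_checked=np.zeros(n_births, dtype=bool),
        cons_mut=m,
        cons_del=d,
    )
    return ReproductionOutcome(n_births, n_eff_parents, n_eff_migrants)
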