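"""Population state: individual records, aging, and the three mortality processes.

Individuals are stored struct-of-arrays style: every per-individual attribute
is a numpy array aligned with the genotype table, and only live individuals
are kept (deaths compact all arrays together).  This keeps the yearly cycle
fully vectorized.

Mortality has three channels, applied in this order each year:

1. **maturity viability** — once in a lifetime, in the year an individual's
   age reaches maturity (1), it dies with probability ``1 - 1/(d + 1)`` where
   ``d`` is its count of deleterious (homozygous-mutant) conserved loci;
2. **yearly mutation cost** — every year, death with probability
   ``1 - 1/(m + 1)`` where ``m`` is its total count of mutant allele copies
   at conserved loci;
3. **age hazard** — death with probability ``age / max_lifespan``; at
   ``age >= max_lifespan`` this is 1, so no individual older than the
   lifespan ever appears in a census.

The mutation-cost hazards are zero at zero mutations and strictly increasing
in the mutation count.  At the default mutation rates these two channels
essentially never fire; the age hazard alone sets the demographic
quasi-equilibrium near 0.7 K.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError
from .genome import GenomeSpec, count_conserved, init_genotypes, mutate

FEMALE: int = 0
MALE: int = 1

MATURITY_AGE: int = 1
MAX_LIFESPAN: int = 10
MAX_FOUNDER_AGE: int = 9

_LABEL_CODE = {"recipient": 0, "source": 1}


class IdSource:
    """Replicate-wide allocator of unique individual ids."""

    __slots__ = ("next_id",)

    def __init__(self, start: int = 0) -> None:
        self.next_id = start

    def take(self, n: int) -> np.ndarray:
        ids = np.arange(self.next_id, self.next_id + n, dtype=np.int64)
        self.next_id += n
        return ids


@dataclass
class Population:
    """Live individuals of one population plus their diploid genotype table."""

    label: str
    spec: GenomeSpec
    geno: np.ndarray  # (N, L, 2) uint8
    ids: np.ndarray  # int64
    sex: np.ndarray  # uint8, FEMALE/MALE
    age: np.ndarray  # int16
    origin_migrant: np.ndarray  # bool: True iff transferred by a migration event
    natal: np.ndarray  # uint8 population code at birth
    parent_f: np.ndarray  # int64 mother id, -1 for founders
    parent_m: np.ndarray  # int64 father id, -1 for founders
    arrival_year: np.ndarray  # int32, -1 unless migrant
    maturity_checked: np.ndarray  # bool
    cons_mut: np.ndarray  # int64, mutant conserved allele copies (m)
    cons_del: np.ndarray  # int64, homozygous-mutant conserved loci (d)
    year: int = 0
    extirpated: bool = False

    _ARRAYS = (
        "ids",
        "sex",
        "age",
        "origin_migrant",
        "natal",
        "parent_f",
        "parent_m",
        "arrival_year",
        "maturity_checked",
        "cons_mut",
        "cons_del",
    )

    @property
    def size(self) -> int:
        return self.geno.shape[0]

    @property
    def n_mature(self) -> int:
        return int((self.age >= MATURITY_AGE).sum())

    def mature_mask(self) -> np.ndarray:
        return self.age >= MATURITY_AGE

    def remove(self, dead: np.ndarray) -> int:
        """Drop individuals flagged in the boolean mask; returns the count."""
        n_dead = int(dead.sum())
        if n_dead == 0:
            return 0
        keep = ~dead
        self.geno = self.geno[keep]
        for name in self._ARRAYS:
            setattr(self, name, getattr(self, name)[keep])
        return n_dead

    def append(self, geno: np.ndarray, **fields: np.ndarray) -> None:
        """Append a block of individuals (newborns or arriving migrants)."""
        self.geno = np.concatenate((self.geno, geno))
        for name in self._ARRAYS:
            setattr(
                self,
                name,
                np.concatenate((getattr(self, name), fields[name])),
            )

    def take_rows(self, idx: np.ndarray) -> dict[str, np.ndarray]:
        """Copy out per-individual fields for the given rows (for transfer)."""
        return {name: getattr(self, name)[idx].copy() for name in self._ARRAYS}

    def mutate_rows(self, rng: np.random.Generator, stop: int | None = None) -> int:
        """Apply one year of mutation to rows ``[0, stop)`` (default: all).

        Conserved-site bookkeeping (``cons_mut``/``cons_del``) is updated
        incrementally from the event list so the full genotype table never
        needs rescanning.
        """
        view = self.geno if stop is None else self.geno[:stop]
        events = mutate(view, self.spec, rng)
        if events.rows.size:
            sl = self.spec.conserved_slice
            in_cons = (events.loci >= sl.start) & (events.loci < sl.stop)
            rows = events.rows[in_cons]
            if rows.size:
                np.add.at(self.cons_mut, rows, 1)
                affected = np.unique(rows)
                _, d = count_conserved(self.geno[affected], self.spec)
                self.cons_del[affected] = d
        return int(events.rows.size)

    def to_frame(self):
        """Snapshot of the individual records as a pandas DataFrame."""
        import pandas as pd

        return pd.DataFrame(
            {
                "id": self.ids,
                "sex": np.where(self.sex == FEMALE, "F", "M"),
                "age": self.age,
                "origin": np.where(self.origin_migrant, "migrant", "resident"),
                "natal": np.where(self.natal == _LABEL_CODE["source"], "source", "recipient"),
                "parent_f": self.parent_f,
                "parent_m": self.parent_m,
                "arrival_year": self.arrival_year,
                "conserved_mutations": self.cons_mut,
                "deleterious_loci": self.cons_del,
            }
        )


def initialize_population(
    spec: GenomeSpec,
    label: str,
    n: int,
    frequencies: np.ndarray,
    rng: np.random.Generator,
    id_source: IdSource | None = None,
) -> Population:
    """Found a population of ``n`` individuals at carrying capacity.

    Sex is a fair coin; age is Poisson with mean at the age of maturity
    (1 year), truncated to ``[0, 9]`` so no founder is immediately removed by
    the lifespan rule.  Genotypes come from :func:`genome.init_genotypes`.
    """
    if n <= 0:
        raise ConfigurationError("population size must be positive")
    if id_source is None:
        id_source = IdSource()
    geno = init_genotypes(spec, n, label, frequencies, rng)
    age = np.minimum(rng.poisson(float(MATURITY_AGE), size=n), MAX_FOUNDER_AGE)
    neg1 = np.full(n, -1, dtype=np.int64)
    return Population(
        label=label,
        spec=spec,
        geno=geno,
        ids=id_source.take(n),
        sex=rng.integers(0, 2, size=n, dtype=np.uint8),
        age=age.astype(np.int16),
        origin_migrant=np.zeros(n, dtype=bool),
        natal=np.full(n, _LABEL_CODE[label], dtype=np.uint8),
        parent_f=neg1,
        parent_m=neg1.copy(),
        arrival_year=np.full(n, -1, dtype=np.int32),
        # founders already past maturity never face the maturity check;
        # they carry no mutations, so the check would be a no-op anyway
        maturity_checked=age >= MATURITY_AGE,
        cons_mut=np.zeros(n, dtype=np.int64),
        cons_del=np.zeros(n, dtype=np.int64),
    )


def age_population(pop: Population) -> Population:
    """Advance every live individual's age by one year (in place)."""
    pop.age += 1
    return pop


def _hazard_from_count(count: np.ndarray) -> np.ndarray:
    """Death probability ``1 - 1/(c + 1)``: zero at c = 0, increasing in c."""
    return 1.0 - 1.0 / (count + 1.0)


def age_death_mask(
    pop: Population, rng: np.random.Generator, max_lifespan: int = MAX_LIFESPAN
) -> np.ndarray:
    """Bernoulli deaths at probability ``age / max_lifespan`` (1 at the cap)."""
    p = np.minimum(pop.age / float(max_lifespan), 1.0)
    return rng.random(pop.size) < p


def mutation_cost_mask(pop: Population, rng: np.random.Generator) -> np.ndarray:
    """Yearly fitness cost of carrying mutant conserved alleles."""
    if not pop.cons_mut.any():
        return np.zeros(pop.size, dtype=bool)
    p = _hazard_from_count(pop.cons_mut)
    return rng.random(pop.size) < p


def maturity_viability_mask(pop: Population, rng: np.random.Generator) -> np.ndarray:
    """Once-per-lifetime viability check in the year age reaches maturity.

    Also marks the cohort as checked; callers must apply the returned mask.
    """
    due = (pop.age >= MATURITY_AGE) & ~pop.maturity_checked
    pop.maturity_checked |= due
    if not (due & (pop.cons_del > 0)).any():
        return np.zeros(pop.size, dtype=bool)
    p = np.where(due, _hazard_from_count(pop.cons_del), 0.0)
    return rng.random(pop.size) < p


def apply_age_mortality(
    pop: Population, rng: np.random.Generator, max_lifespan: int = MAX_LIFESPAN
) -> int:
    """Apply the age hazard and remove the dead; returns the death count."""
    return pop.remove(age_death_mask(pop, rng, max_lifespan))


def apply_mutation_mortality(pop: Population, rng: np.random.Generator) -> int:
    return pop.remove(mutation_cost_mask(pop, rng))


def apply_maturity_viability(pop: Population, rng: np.random.Generator) -> int:
    return pop.remove(maturity_viability_mask(pop, rng))
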