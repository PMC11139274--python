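"""Simulation engine: the yearly cycle, replicates, and the scenario grid.

One replicate simulates a migrant-recipient population (historic carrying
capacity 1000) and, whenever the connectivity regime can move individuals, a
migrant source population (carrying capacity 5000, never crashed, never
receiving) forward through 350 years:

* years 1-100: stabilization at the historic capacity;
* years 100-110: linear carrying-capacity decline to the crash floor;
* years 110-150: hold at the minima;
* years 151-350: restoration at the historic capacity.

Within a year the recipient executes, in order: aging, scheduled migrant
arrival, pair formation (Allee-limited), logistic offspring quota (census
after immigration, before births), migrant-biased breeder selection and
reproduction with newborn mutation, yearly mutation of standing individuals,
the three mortality processes, metric capture, and the extirpation check
(census <= 10 ends the replicate).  The source population runs the identical
cycle against its own capacity with no immigration.

Every replicate owns independent random streams derived from
``(base_seed, replicate_index)``, so results are reproducible and
independent of execution order.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .demography import (
    CrashSchedule,
    carrying_capacity_at,
    form_pairs,
    offspring_quota,
    reproduce,
    select_breeders,
)
from .errors import ConfigurationError
from .genome import MAF_HIGH, MAF_LOW, GenomeSpec, draw_founding_frequencies
from .migration import MigrationSchedule, build_schedule, transfer_migrants
from .population import (
    FEMALE,
    MALE,
    IdSource,
    Population,
    age_death_mask,
    age_population,
    initialize_population,
    maturity_viability_mask,
    mutation_cost_mask,
)
from .stats import (
    CountTable,
    count_table,
    extirpation_years,
    recipient_metrics,
    summarize_replicates,
)

log = logging.getLogger(__name__)

#: Founding minor-allele-frequency regimes: (recipient range, source range).
MAF_REGIMES = {
    "low/low": (MAF_LOW, MAF_LOW),
    "high/high": (MAF_HIGH, MAF_HIGH),
    "high_source/low_recipient": (MAF_LOW, MAF_HIGH),
    "low_source/high_recipient": (MAF_HIGH, MAF_LOW),
}


@dataclass(frozen=True)
class ScenarioConfig:
    """Full parameter set of one simulation cell.

    The defaults reproduce the study conditions: a 1000-individual recipient
    and 5000-individual source, 350 years, 100-year stabilization, growth
    rate 1, unit demographic noise, migrant-biased breeding, and extirpation
    at a census of 10 or fewer.
    """

    name: str = "scenario"
    years: int = 350
    genome: GenomeSpec = field(default_factory=GenomeSpec)
    crash: CrashSchedule = field(default_factory=CrashSchedule)
    migration: MigrationSchedule = field(
        default_factory=lambda: build_schedule("none")
    )
    k_source: int = 5000
    r: float = 1.0
    noise_sd: float = 1.0
    migrant_bias: bool = True
    extirpation_threshold: int = 10
    max_lifespan: int = 10
    replicates: int = 100
    base_seed: int = 0
    track_lrs: bool = True

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ConfigurationError("replicates must be >= 1")
        if self.crash.k_crash is not None and self.years < self.crash.minima_end:
            raise ConfigurationError("run must extend past the crash minima")

    @property
    def needs_source(self) -> bool:
        """The source only has to be simulated forward when it can send migrants."""
        return len(self.migration.events) > 0


def make_scenario(
    crash_category: str = "none",
    regime: str = "none",
    timing: str | None = None,
    maf_regime: str = "low/low",
    **overrides,
) -> ScenarioConfig:
    """Convenience constructor from the scenario-grid vocabulary.

    ``crash_category`` is one of none / vulnerable / endangered /
    critically_endangered; ``maf_regime`` one of the keys of
    :data:`MAF_REGIMES`.  Remaining keyword arguments override
    :class:`ScenarioConfig` fields.
    """
    if maf_regime not in MAF_REGIMES:
        raise ConfigurationError(f"unknown MAF regime {maf_regime!r}")
    recip_range, source_range = MAF_REGIMES[maf_regime]
    years = int(overrides.pop("years", 350))
    genome = overrides.pop("genome", None)
    if genome is None:
        genome = GenomeSpec(
            maf_range_recipient=recip_range, maf_range_source=source_range
        )
    crash = overrides.pop("crash", None)
    if crash is None:
        crash = CrashSchedule.from_category(crash_category)
    name = overrides.pop(
        "name",
        f"{crash_category}__{regime}" + (f"__{timing}" if timing else "") + f"__{maf_regime.replace('/', '-')}",
    )
    return ScenarioConfig(
        name=name,
        years=years,
        genome=genome,
        crash=crash,
        migration=build_schedule(regime, timing, run_years=years),
        **overrides,
    )


class LrsLedger:
    """Lifetime-reproductive-success counters indexed by individual id."""

    def __init__(self) -> None:
        self._mates = np.zeros(0, dtype=np.int32)
        self._offspring = np.zeros(0, dtype=np.int32)
        self._matured = np.zeros(0, dtype=np.int32)

    def _ensure(self, max_id: int) -> None:
        if max_id >= self._mates.size:
            new = max(max_id + 1, 2 * self._mates.size, 1024)
            for name in ("_mates", "_offspring", "_matured"):
                arr = getattr(self, name)
                grown = np.zeros(new, dtype=np.int32)
                grown[: arr.size] = arr
                setattr(self, name, grown)

    def register(self, ids: np.ndarray) -> None:
        if ids.size:
            self._ensure(int(ids.max()))

    def record_breeding(
        self, female_ids: np.ndarray, male_ids: np.ndarray, counts: np.ndarray
    ) -> None:
        """One mating partnership and ``counts`` offspring per pair."""
        if female_ids.size == 0:
            return
        self._ensure(int(max(female_ids.max(), male_ids.max())))
        for ids in (female_ids, male_ids):
            np.add.at(self._mates, ids, 1)
            np.add.at(self._offspring, ids, counts.astype(np.int32))

    def record_matured(self, parent_f: np.ndarray, parent_m: np.ndarray) -> None:
        """Credit parents of individuals that just reached maturity."""
        for ids in (parent_f, parent_m):
            ids = ids[ids >= 0]
            if ids.size:
                self._ensure(int(ids.max()))
                np.add.at(self._matured, ids, 1)

    def to_frame(self, ids: np.ndarray) -> pd.DataFrame:
        self.register(np.asarray(ids))
        ids = np.asarray(ids)
        return pd.DataFrame(
            {
                "id": ids,
                "lrs_mates": self._mates[ids],
                "lrs_offspring": self._offspring[ids],
                "lrs_offspring_matured": self._matured[ids],
            }
        )


@dataclass
class ReplicateResult:
    """Per-year metric table plus bookkeeping for one replicate."""

    metrics: pd.DataFrame
    extirpation_year: int | None
    lrs: pd.DataFrame | None = None


def _replicate_rngs(base_seed: int, replicate_index: int) -> dict[str, np.random.Generator]:
    ss = np.random.SeedSequence(entropy=int(base_seed), spawn_key=(int(replicate_index),))
    names = ("founding", "init_recipient", "init_source", "recipient", "source", "migration")
    children = ss.spawn(len(names))
    return {name: np.random.default_rng(child) for name, child in zip(names, children)}


def _cycle(
    pop: Population,
    k: int,
    cfg: ScenarioConfig,
    rng: np.random.Generator,
    id_source: IdSource,
    lrs: LrsLedger | None,
) -> dict:
    """Reproduction, mutation, and mortality for one population-year."""
    n_before = pop.size
    pairs = form_pairs(pop, rng)
    quota = offspring_quota(n_before, k, cfg.r, cfg.noise_sd, rng)
    breeders = select_breeders(pairs, quota, cfg.migrant_bias, rng)
    outcome = reproduce(pop, breeders, rng, id_source, lrs)
    pop.mutate_rows(rng, stop=n_before)

    dead = maturity_viability_mask(pop, rng)
    if lrs is not None:
        reached = (pop.age == 1) & ~dead  # survived the year they matured
        lrs.record_matured(pop.parent_f[reached], pop.parent_m[reached])
    alive = ~dead
    mut = mutation_cost_mask(pop, rng)
    dead |= mut & alive
    alive &= ~mut
    age = age_death_mask(pop, rng, cfg.max_lifespan)
    dead |= age & alive
    deaths = pop.remove(dead)
    return {
        "births": outcome.births,
        "deaths": deaths,
        "n_effective_parents": outcome.n_effective_parents,
        "n_effective_migrants": outcome.n_effective_migrants,
    }


def run_year(
    recipient: Population,
    source: Population | None,
    cfg: ScenarioConfig,
    year: int,
    rngs: dict[str, np.random.Generator],
    id_source: IdSource,
    snapshots: tuple[CountTable, CountTable],
    lrs: LrsLedger | None = None,
) -> dict:
    """Advance both populations one year and capture recipient metrics."""
    age_population(recipient)
    if source is not None:
        age_population(source)

    n_arrivals = cfg.migration.migrants_at(year)
    if n_arrivals and source is not None:
        transfer_migrants(source, recipient, n_arrivals, rngs["migration"], year)

    k_recipient = carrying_capacity_at(year, cfg.crash)
    flows = _cycle(recipient, k_recipient, cfg, rngs["recipient"], id_source, lrs)
    if source is not None:
        _cycle(source, cfg.k_source, cfg, rngs["source"], id_source, None)
        if source.size <= cfg.extirpation_threshold:
            source.extirpated = True

    n_females = int((recipient.sex == FEMALE).sum())
    n_males = recipient.size - n_females
    row = {
        "year": year,
        "census": recipient.size,
        "n_adults": recipient.n_mature,
        "sex_ratio": (n_females / n_males) if n_males else float("nan"),
        **recipient_metrics(recipient, *snapshots),
        **flows,
        "extirpated": recipient.size <= cfg.extirpation_threshold,
    }
    if row["extirpated"]:
        recipient.extirpated = True
    recipient.year = year
    if source is not None:
        source.year = year
    return row


def run_replicate(
    cfg: ScenarioConfig, replicate_index: int = 0, base_seed: int | None = None
) -> ReplicateResult:
    """Run one replicate to year ``cfg.years`` or extirpation.

    Fully deterministic given ``(base_seed, replicate_index)``; the year-0
    genotype snapshots of both founding populations are reduced to count
    tables immediately after initialization and held fixed for every
    divergence comparison.
    """
    seed = cfg.base_seed if base_seed is None else base_seed
    rngs = _replicate_rngs(seed, replicate_index)
    freqs = draw_founding_frequencies(cfg.genome, rngs["founding"])
    id_source = IdSource()
    recipient = initialize_population(
        cfg.genome, "recipient", cfg.crash.k_historic, freqs.recipient,
        rngs["init_recipient"], id_source,
    )
    source_pop = initialize_population(
        cfg.genome, "source", cfg.k_source, freqs.source,
        rngs["init_source"], id_source,
    )
    snapshots = (
        count_table(recipient.geno, cfg.genome.stat_slice),
        count_table(source_pop.geno, cfg.genome.stat_slice),
    )
    # An empty migration schedule decouples the recipient from the
    # contemporary source entirely (comparisons use the year-0 snapshot), so
    # the source needs no forward simulation in that case.
    source = source_pop if cfg.needs_source else None
    lrs = LrsLedger() if cfg.track_lrs else None
    if lrs is not None:
        lrs.register(recipient.ids)
        lrs.register(source_pop.ids)

    rows = []
    for year in range(1, cfg.years + 1):
        row = run_year(recipient, source, cfg, year, rngs, id_source, snapshots, lrs)
        rows.append(row)
        if row["extirpated"]:
            break
    metrics = pd.DataFrame(rows)
    ext_year = int(metrics["year"].iloc[-1]) if bool(metrics["extirpated"].iloc[-1]) else None
    lrs_frame = None
    if lrs is not None:
        lrs_frame = lrs.to_frame(np.arange(id_source.next_id))
    return ReplicateResult(metrics=metrics, extirpation_year=ext_year, lrs=lrs_frame)


@dataclass
class ScenarioResult:
    """Replicate tables and their across-replicate summary for one scenario."""

    config: ScenarioConfig
    replicates: list[pd.DataFrame]
    summary: pd.DataFrame
    extirpation_years: list[int | None]

    def replicate_mean(self, metric: str, year: int) -> float:
        """Across-replicate mean of a metric at one year (extant replicates)."""
        return float(self.summary.loc[year, f"{metric}_mean"])


def run_scenario(
    cfg: ScenarioConfig,
    replicates: int | None = None,
    base_seed: int | None = None,
    progress: bool = False,
    keep_lrs: bool = False,
) -> ScenarioResult:
    """Run all replicates of one scenario and summarize them."""
    n_rep = cfg.replicates if replicates is None else replicates
    seed = cfg.base_seed if base_seed is None else base_seed
    iterator = range(n_rep)
    if progress:
        try:
            from tqdm import tqdm

            iterator = tqdm(iterator, desc=cfg.name, unit="rep")
        except ImportError:  # pragma: no cover
            pass
    tables = []
    run_cfg = cfg if keep_lrs else replace(cfg, track_lrs=False)
    for idx in iterator:
        try:
            tables.append(run_replicate(run_cfg, idx, base_seed=seed).metrics)
        except Exception:  # partial failures must not sink the grid
            log.exception("scenario %s replicate %d failed", cfg.name, idx)
    summary = summarize_replicates(tables)
    return ScenarioResult(
        config=cfg,
        replicates=tables,
        summary=summary,
        extirpation_years=extirpation_years(tables),
    )


def run_scenario_grid(
    configs: list[ScenarioConfig],
    replicates: int | None = None,
    base_seed: int | None = None,
    out_dir: str | Path | None = None,
    progress: bool = False,
) -> dict[str, ScenarioResult]:
    """Run a list of scenarios; results are independent of scenario order.

    When ``out_dir`` is given, per-replicate yearly metrics, the summary, and
    a config echo are written per scenario (tidy CSV plus JSON metadata).
    """
    if not configs:
        raise ConfigurationError("need at least one scenario")
    results: dict[str, ScenarioResult] = {}
    for i, cfg in enumerate(configs):
        seed = cfg.base_seed if base_seed is None else base_seed
        results[cfg.name] = run_scenario(
            cfg, replicates=replicates, base_seed=seed + i, progress=progress
        )
        if out_dir is not None:
            write_scenario_outputs(results[cfg.name], out_dir)
    return results


def write_scenario_outputs(result: ScenarioResult, out_dir: str | Path) -> None:
    """Write tidy per-replicate CSV, summary CSV, and JSON metadata."""
    out = Path(out_dir) / result.config.name
    out.mkdir(parents=True, exist_ok=True)
    tidy = pd.concat(
        result.replicates, keys=range(len(result.replicates)), names=["replicate"]
    ).reset_index(level="replicate")
    tidy.insert(0, "scenario", result.config.name)
    tidy.to_csv(out / "yearly_metrics.csv", index=False)
    result.summary.to_csv(out / "summary.csv")
    cfg = result.config
    meta = {
        "scenario": cfg.name,
        "years": cfg.years,
        "replicates": len(result.replicates),
        "base_seed": cfg.base_seed,
        "k_historic": cfg.crash.k_historic,
        "k_crash": cfg.crash.k_crash,
        "k_source": cfg.k_source,
        "migration_regime": cfg.migration.regime,
        "migration_timing": cfg.migration.timing,
        "migration_events": {str(k): v for k, v in sorted(cfg.migration.events.items())},
        "maf_range_recipient": list(cfg.genome.maf_range_recipient),
        "maf_range_source": list(cfg.genome.maf_range_source),
        "migrant_bias": cfg.migrant_bias,
        "quantile_band": [0.08, 0.92],
        "extirpation_years": result.extirpation_years,
    }
    with open(out / "scenario.json", "w") as fh:
        json.dump(meta, fh, indent=2)
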