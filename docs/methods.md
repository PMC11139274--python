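# Methods

## Model overview

`genrescue` is a forward-time, individual-based model of two diploid,
age-structured populations: a migrant-**recipient** population (historic
carrying capacity K = 1000) that experiences a habitat crash and
restoration, and a migrant **source** population (K = 5000) that never
crashes and never receives immigrants. Time advances in yearly steps for
350 years. Within a year the recipient executes, in order:

1. aging (+1 year to every survivor; newborns enter at age 0 and are first
   aged the following year);
2. scheduled migrant arrival (individuals sampled uniformly from the mature
   source, moved with their genotypes intact);
3. random pairing of mature individuals (age ≥ 1) across sexes with an
   Allee penalty;
4. the logistic offspring quota, computed from the post-immigration census
   and the year's carrying capacity;
5. breeder selection (migrant-containing pairs first, by default) and
   offspring creation with Mendelian transmission and newborn mutation;
6. yearly mutation of standing individuals;
7. mortality: the once-per-lifetime maturity viability check, the yearly
   conserved-mutation cost, then the age hazard;
8. metric capture;
9. the extirpation check (census ≤ 10 ends the replicate).

The source population runs the identical cycle against its own capacity.
When the migration regime is `none` the source cannot influence the
recipient (divergence is always measured against its year-0 snapshot), so
the engine skips its forward simulation; per-population random streams make
this output-identical to simulating it.

## Demography

**Offspring quota.** The yearly number of offspring is
`max(0, round(N' + ε) − N)` with `N' = (1 + r (1 − N/K)) N`, r = 1 and
ε ~ Normal(0, 1). The quota is an *increment*: when the logistic map points
downward (N > K) no culling occurs — the mortality processes do all
shrinking. This reading is fixed by the observed equilibrium: logistic
births balancing the age hazard stabilize the census near 0.71 K (≈ 715 at
K = 1000, which the reference design also reports), whereas a
"total-offspring" reading has no equilibrium below ~1.7 K.

**Pairing and the Allee effect.** Mature females and males are shuffled and
paired; the candidate pair count P is the minority-sex count, and each
candidate pair is retained independently with probability 1 − 1/P (a lone
pair can never breed). Pairing is monogamous within a year and reshuffled
every year. Breeding pairs receive 2 offspring each down a priority order
until the quota is spent (the last funded pair may get 1); with
`migrant_bias` on (default), pairs containing at least one migrant are
funded first, which keeps the number of effective migrants close to the
number of arrivals.

**Mortality.** Three channels, in the order listed above:

* *maturity viability* — in the year an individual's age reaches 1 it dies
  with probability 1 − 1/(d + 1), d = count of homozygous-mutant conserved
  loci; the check fires once per lifetime;
* *yearly mutation cost* — death with probability 1 − 1/(m + 1), m = count
  of mutant allele copies across conserved loci;
* *age hazard* — death with probability age/10, certain from age 10.

The 1 − 1/(c + 1) form is a deliberate regularization: a literal
"reciprocal of the mutation count" is undefined at zero and decreases with
the count, the opposite of the intended fitness cost. The form used is zero
for a clean genome, 0.5 at one mutation, and increasing. At the default
mutation rates (below) both mutation channels are essentially inert —
fewer than one death per hundred replicates — so the age hazard alone sets
the demographic equilibrium; the channels matter only under elevated rates.

**Crash schedule.** A crash is a carrying-capacity trajectory: K declines
linearly from 1000 over years 100–110 to a floor of 700 (vulnerable), 300
(endangered), or 100 (critically endangered), holds through year 150, and
snaps back to 1000. The linear ramp is a modeling choice (only the decline
duration is specified by the design); because the census tracks ~0.7 K from
below, ramp shape has little effect on the realized trajectory.

## Genome

1200 independent loci (no linkage or recombination map), three classes:

* **neutral** (1000): founded under Hardy–Weinberg with per-locus alternate
  allele frequency drawn uniformly from the configured interval — low
  (0.05–0.15) or high (0.40–0.50). When both populations use the same
  interval they share a single draw per locus (the "same allele in both
  populations"); crossed regimes draw independently. HWE founding makes the
  configured p the realized frequency and gives initial observed
  heterozygosity ≈ E[2p(1−p)] (≈ 0.178 for the low range), the value the
  full model reproduces at year 1. A literal per-individual
  homozygous/heterozygous coin flip was considered and rejected: it breaks
  the correspondence between configured p and realized allele frequency.
* **migrant-associated** (100): fixed differences between the founders of
  the two populations; no fitness effect; the source-diagnostic allele
  fraction is the migrant-ancestry measure. These loci mutate at the
  neutral rate (a negligible channel, ~1 event per full run).
* **conserved** (100): monomorphic reference at founding; mutation feeds
  the viability costs above.

Mutation flips an allele copy to a third, absorbing *mutant* state at
μ = 2.2 × 10⁻⁹ per copy per year (neutral and migrant-associated) and
μ × u with u = 2.2 (conserved). Modeling the mutant as a distinct state
keeps conserved-site counting unambiguous and leaves neutral diversity
untouched at realistic rates. Offspring receive one uniformly chosen allele
copy per parent per locus, independently across loci.

## Monitoring statistics

All estimators run on per-locus genotype-count tables so the year-0
"historical" snapshots can be compared against every later year cheaply.

* **Observed heterozygosity** — mean per-individual fraction of
  heterozygous neutral loci. **Expected heterozygosity** — mean neutral
  gene diversity 1 − Σ p² (uncorrected).
* **F_IS** — 1 − ΣH_O/ΣH_S over polymorphic neutral loci, with Nei's
  small-sample correction H_S = n/(n−1) (1 − Σp² − H_O/2n). The correction
  is applied inside F_IS only; reported H_E stays uncorrected.
* **F_ST** — Weir & Cockerham's θ, variance components summed over loci and
  allele states (ratio of sums, the convention of the standard hierarchical
  F-statistics packages), computed over the neutral + migrant-associated
  panel. The 100 fixed-difference loci dominate the initial between-
  population divergence: two freshly founded populations sit at θ ≈ 0.357
  under the low-frequency regime (the package's founding-divergence test
  checks this closed-form value). Heterozygosity and F_IS deliberately use
  neutral loci only, paralleling the diversity definitions.
* **Migrant ancestry** — fraction of source-diagnostic allele copies at the
  marker loci, population-wide.
* **Counts** — effective migrants (migrants among a year's breeders),
  effective parents (distinct breeders), births, deaths, sex ratio
  (females:males; undefined when no males remain), lifetime reproductive
  success per individual (mating partnerships, offspring, offspring that
  reached age 1; partnerships are counted per breeding year, not
  deduplicated across years).

Replicate summaries are per-year means with central 84 % quantile bands
(0.08/0.92), the interval whose overlap behaviour approximates an α = 0.05
comparison between scenario means. Extirpated replicates simply stop
contributing from their extirpation year (no imputation); extirpation years
are reported separately.

## Migration regimes

`none`; `one_per_generation` (1 migrant every year 1–350 — the age of
maturity, 1 year, is the model's generation convention, and schedules are
expressed in years); `burst` (100 individuals once); `pulse` (25
individuals four times). Burst and pulse are timed either *during*
restoration (years 125 / 125–170) or *after* it (151 / 151–195). Migrants
are drawn from the contemporary, forward-simulated source — not a static
pool — so source drift is part of the model; removing ≤ 100 individuals
from ~3500 is demographically negligible for the source.

## Randomness and reproducibility

Every replicate derives six named streams (founding frequencies, two
initializations, per-population dynamics, migration) from
`SeedSequence(base_seed, spawn_key=(replicate,))`, so a replicate is fully
reproducible from `(scenario, replicate index, base seed)` and independent
of execution order; scenario cells in the study grid additionally offset
their seeds by grid position. The two inner loops (Mendelian allele picking
and genotype tabulation) are numba kernels fed by pre-drawn 64-bit words
from the owning numpy generator.

## Problem sizes and what the tests show

Unit and property tests run on miniature configurations (40-locus genomes,
K ≈ 60, 60-year runs) that keep all three locus classes and both
populations so every code path executes; estimator golden tests compare
against brute-force transcriptions of the published formulas on ≤ 10-
individual tables. The full-scale outcome checks and `scripts/acceptance.py`
use 30 replicates per cell (the across-replicate quantile bands are stable
at this count, and a cell completes in 1–2 minutes on one CPU).

The synthetic populations emulate the study design's arbitrary
small-rodent-like agent: yearly breeding, maturity at 1, lifespan 10,
logistic density dependence. They do not emulate linkage, selection on
standing variation, environmental stochasticity beyond the unit-variance
demographic noise, or behaviour (dispersal choice, mate choice); passing
tests therefore validate the drift/migration/demography machinery, not
predictions for any particular real species.

## Known limitations

* Drift intensity at very small census sizes is sensitive to breeding
  micro-structure (how families are packed into the yearly quota, parental
  age distribution). The design text pins the demographic equilibrium and
  the migration-dominated outcomes tightly, but leaves this micro-structure
  open; outcomes that are pure small-N drift (deep-crash heterozygosity
  loss without migration) carry the largest structural uncertainty.
* No recombination, linkage, or selection coefficients on neutral or
  marker loci; no return migration; no checkpoint/restart mid-replicate.
* F_ST is reported genome-wide (no per-locus or sliding-window output),
  and no effective-population-size estimation is attempted.
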