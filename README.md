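# genrescue

Forward-time, individual-based simulation of **genetic rescue under managed
connectivity**: what happens to the genome of a small, crashing population
when managers restore its habitat and then reconnect it to a large source
population — continuously (one migrant per generation), in a single burst
translocation, or in repeated pulses?

The package is aimed at conservation-genetics modelers who want to compare
management interventions *in silico* before committing to translocations:
it simulates a migrant-recipient population through a habitat crash and
restoration against a 5000-individual migrant source population, tracking
every individual's diploid genotype at 1200 SNPs, and monitors the
population-genetic quantities a manager would assay in the field.

## Model

Two populations evolve under a yearly cycle of aging, migration, Allee-limited
random pairing, logistic reproduction, mutation, and mortality:

* **Demography.** Yearly offspring numbers follow the discrete logistic map
  *N*<sub>t+1</sub> = (1 + *r*(1 − *N*<sub>t</sub>/*K*)) *N*<sub>t</sub>
  (growth rate *r* = 1, Normal(0, 1) density-independent noise), with a
  maximum fecundity of 2 per breeding pair. Mate finding carries an Allee
  penalty — each candidate pair is retained with probability 1 − 1/*P*,
  where *P* is the candidate pair count — and each individual dies with
  yearly probability age/10 (removal is certain past age 9). A habitat crash
  is a carrying-capacity trajectory: linear decline from *K* = 1000 to a
  floor of 700 / 300 / 100 (vulnerable / endangered / critically endangered)
  over 10 years, a 40-year hold, then restoration.
* **Genome.** 1000 neutral SNPs founded at Hardy–Weinberg with per-locus
  minor allele frequencies drawn from a low (0.05–0.15) or high (0.40–0.50)
  interval; 100 population-diagnostic marker SNPs (fixed differences between
  the populations) that measure migrant ancestry; 100 conserved SNPs,
  monomorphic at founding, whose mutations (μ = 2.2 × 10⁻⁹ neutral,
  ×2.2 constraint for conserved sites) impose viability costs when they
  accumulate.
* **Monitoring.** Every year the recipient reports census, adults, sex
  ratio, observed/expected neutral heterozygosity (*H*<sub>O</sub>,
  *H*<sub>E</sub>), Nei's *F*<sub>IS</sub>, migrant ancestry, effective
  migrants and parents, and Weir–Cockerham *F*<sub>ST</sub> against frozen
  year-0 snapshots of both the recipient and the source ("how far has the
  population moved from its own history, and how close has it drifted to
  the source?"). Replicates are summarized by per-year means with central
  84 % quantile bands.

## Worked example

A seconds-scale miniature crash-and-rescue (60 years, 40-locus genome,
*K* = 60 → 20, four 5-individual pulses after restoration):

```
$ genrescue demo --seed 3
demo scenario: mini_rescue (60 years, 10 replicates)
  year   1: census   47.9  Ho 0.171  ancestry 0.000
  year  35: census   13.9  Ho 0.103  ancestry 0.000
  year  60: census   43.3  Ho 0.149  ancestry 0.820
  extirpated replicates: 0/10
```

Reading the three lines: the population equilibrates below carrying capacity
(census ≈ 0.7 K, here ~48 of 60) because logistic births balance the age
hazard; the crash strips ~40 % of observed heterozygosity by the end of the
minima (0.171 → 0.103); after restoration plus migrant pulses the census and
part of the diversity recover (0.149), but 82 % of marker-allele copies now
trace to the source population — the rescued population is no longer the
population that crashed.

Full-scale cells run from the same CLI, e.g. the endangered crash reconnected
by one migrant per year:

```bash
genrescue run --crash endangered --regime one_per_generation \
              --replicates 30 --seed 1 --out results/
```

which writes per-replicate yearly metrics (`yearly_metrics.csv`), the
across-replicate summary with 84 % bands (`summary.csv`), and a config echo
(`scenario.json`). `genrescue grid` runs a whole scenario grid from a YAML
list, and the `genrescue.study` module exposes the named full-scale cells
programmatically.

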