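# Methods

## Scope

`gdsim` models a single-locus autonomous CRISPR/Cas9 homing gene drive
segregating in a closed *Aedes aegypti* population, with all drive-blocking
resistance products merged into a single cost-free allele class.  The
package covers the full path from bench counts to population forecasts:
inheritance-rate analysis of single-generation outcrosses, estimation of
cutting/homing/resistance/deposition rates, amplicon-level GDBI
summaries, inheritance-cube construction, and a stochastic daily-time-step
population model with single-release scenarios.

## Genetics

**State space.**  Unordered genotypes over alleles {W, H, R}, in fixed
order (WW, WH, WR, HH, HR, RR).  A fourth allele code `E` (the eCFP
"blocked drive" balancer — a marker-only insertion that destroys the
protospacer) exists only in the cross-synthesis/analysis layer; it is
uncleavable, transmits Mendelianly, and never enters the population cube.

**Germline homing.**  Cutting requires an `H` allele in the same genotype
(Cas9 and the U6-driven sgRNA are encoded on the construct) and acts only
on `W` alleles, so `WH` is the single non-Mendelian germline.  Conversion
is modelled pre-meiotically: with sex-specific probability *c* the `W` is
cut, resolving to `H` (probability *ch*) or to `R` (*cr* = 1 − *ch*).

**Maternal deposition.**  If the mother carries `H`, every `W` allele of
the zygote is independently cut with probability *dF* after gamete union,
resolving to `H` with *dhF* and `R` with *drF*.  The modelled configuration
is *dhF* = 0, *drF* = 1 (no homology template in the embryo).  Deposition
is maternal-only; a paternal analogue is not modelled.  Note a deliberate
generalization: deposition also acts on a *maternally* inherited `W` that
escaped germline cutting.  The underlying assay could only measure editing
of the paternal allele (the maternal allele was a balancer), but deposited
RNP in the embryo has no way to distinguish allele origin.  The practical
effect is a slightly higher resistance influx from `WH` mothers than a
paternal-only reading would give.

**Cube.**  `build_cube` evaluates the zygote distribution for all 36
parental pairs; every row is validated to sum to 1 within 1e-12.  The
construction is cross-checked in the test suite against an independent
event-tree enumerator over (conversion, segregation, deposition) outcomes.

## Parameter estimation

**Cutting rates (`estimate_cut_params`).**  Two estimators:

* `method="table"` (default) reproduces the published count arithmetic.
  Marker-positive offspring of the "low" and "high" pools are summed
  (*P*); GDBI carriers among marker-negatives are estimated per pool as
  (pool negatives) × (tested-positive fraction), with a pooled-fraction
  fallback for untested pools (*G*); then *c* = (*P*+*G*)/*N*,
  *ch* = *P*/(*P*+*G*), *cr* = 1 − *ch*.  When only percentages are
  available, positives are reconstructed as round(rate × n), which
  reproduces the printed tables at their printed precision.
* `method="cube"` inverts the cube expectations (marker rate
  m = (1+*c·ch*)/2, resistance rate r = *c·cr*/2):
  *c* = 2(*P*+*G*)/*N* − 1, *ch* = (2*P*/*N* − 1)/*c*, clipped to [0, 1].

The table arithmetic counts *every* marker-positive offspring as a homing
event, including the Mendelian half that inherits `H` without any cutting;
it therefore converges to (1+*c*)/2 rather than *c* under the cube model
and overstates drive strength when plugged back into the cube.  The
default remains `"table"` so that simulation parameterization matches the
published pipeline; `"cube"` is the consistent estimator and is the one
that recovers the generating parameters of synthetic data (the round-trip
recovery tests use it).  This tension is inherent to the source arithmetic
and is surfaced rather than hidden.

**Deposition (`estimate_deposition`).**  *dF* is the mean over replicates
of the fraction of balancer-inheriting (eCFP) larvae with Cas9 activity at
the drive locus; only the paternal `W` is editable in those larvae, and
only by deposited RNP.

**Lifecycle (`derive_lifecycle`).**  From a per-line life-parameter table:
betaK = fecundity × 4 / 11 (eggs/female/day: four blood meals over an
11-day urban adult lifespan), tLarva = rounded larva-to-pupa days,
ξF = ξM = 1 + Δ where Δ = viability(drive line) − viability(wild-type) when
Δ < 0 *and* the difference is flagged significant (the flag is an input,
not an internal test), else 1; fertility multiplier 0.9 on drive-carrying
genotypes.  The functional form "ξ multiplies larva→pupa success" is a
design choice: the derivation rule pins down only that the viability
difference enters ξ, not the functional form.

## Bundled data and defaults

The OX-1 pool counts, trans-heterozygous assay counts, and injection
survivor counts ship as package CSVs.  The per-line drive-locus deposition
rates (Nos 0.19, Zpg 0.14) ship as constants.  The life-parameter table
(`fitness_defaults_synthetic.csv`) is **synthetic but representative**,
chosen once: wild-type fecundity 75 eggs/female/cycle → betaK = 27.27,
larva-to-pupa 6 d → tLarva = 6, a significant −0.10 viability deficit for
the Nos line (ξ = 0.90) and none for the Zpg line (ξ = 1).  The measured
values behind these quantities are not public; every simulation result
that depends on them should be read as conditional on these documented
defaults.  Entomological defaults muAD = 0.123/day and popGrowth = 1.175
per generation follow the modelling framework's documented defaults.

## Population model

Daily update order: (1) adult mortality, binomial with p = 1 − muAD;
(2) oviposition — each mated-female cell (female genotype × stored mate
genotype) lays Poisson(count × betaK × fertility) eggs, genotypes
multinomial from the cube row; females never lay on their emergence day;
(3) aquatic aging — eggs/larvae/pupae survive their daily rates and
advance one day; larvae additionally face γ/(γ + L_total); graduating
larvae are split 50:50 by sex and thinned by ξ of their genotype and sex
(sex is assigned at pupation so the sex-specific modifier can act there);
(4) emergence and mating — new females mate once, mate genotype multinomial
proportional to current adult males, retrying the next day if no males
exist; (5) releases join the adult pool (and hence the mating market from
the following day).  Deterministic mode replaces every draw with its
expectation on a real-valued state.

**Calibration.**  One shared density-independent daily aquatic survival
s0 is fixed by the intrinsic growth condition
0.5 · betaK · (1 − muAD)/muAD · s0^(tEgg+tLarva+tPupa) = popGrowth.
Under the update order above the equilibrium density factor then has the
closed form f\* = popGrowth^(−1/tLarva) (density must cancel exactly the
per-generation surplus), giving γ = f\*·L\*/(1 − f\*) with L\* the
equilibrium larval total — no numerical root solve is needed.  The
contract (wild-type deterministic run holds adults within 2% of N_eq for
365 days) is verified by simulation; with the closed form it holds to
machine precision.  Calibration fails with a diagnostic when muAD → 1
(no female survives to her first laying day), when popGrowth ≤ 1, or when
the required s0 ≥ 1.

**Randomness.**  One root seed per run; replicate *i* uses the stream
`default_rng([seed, i])`, so replicates are reproducible and independent.
All stochastic state is integer-valued and non-negative at every step (an
internal guard raises otherwise).

**Summaries.**  `effector_coverage` is the daily fraction of adult females
carrying ≥ 1 drive allele (the proxy for a drive-linked antiviral
effector).  First-passage summaries are reported post-release (day −
release day); absent events are reported as absent, never 0.  Drive
elimination requires the `H` allele to be gone from *every* life stage,
including the stored-sperm genotype of once-mated females — a female
inseminated by a drive male can otherwise re-introduce the drive after the
last living carrier dies.

## Synthetic data

The generators emulate the statistical structure the estimators assume:
multinomial offspring from the cube row of a hemizygous × wild-type cross
(female-parental crosses include deposition; male-parental cannot),
hypergeometric GDBI subsampling of marker-negatives with "carries ≥ 1 R" as
indel-positivity, Bernoulli(½) balancer/drive classes with Bernoulli(dF)
drive-locus activity in the trans-het assay, and per-read amplicon
classifications with apparent indel proportion f + (1 − f) × chimera_rate.
Family sizes follow a truncated negative binomial (dispersion 5) matched to
the observed ranges/means (female-parental 20–142, mean 59; male-parental
21–415, mean 91).  What the generators do **not** emulate: family-level
rate heterogeneity beyond multinomial sampling (real crosses show
overdispersion up to 100% inheritance), linkage between deposition and
germline activity within mothers, PCR amplification bias other than the
single chimera parameter, and any fitness effect on the synthetic family
sizes.  Passing round-trip tests therefore demonstrates estimator
consistency under the assumed sampling model, not robustness to every
source of real-data overdispersion.

## Numerical choices

Cube rows validated to 1e-12; cube CSV written with 15 significant digits;
quantiles use the inclusive linear-interpolation convention so box-plot
statistics are reproducible; the chi-square test of 1:1 inheritance is the
standard 1-df Pearson statistic; ties in the synthetic low/high pool split
go to "low" (families at the median rate).  Percentages are stored as
fractions internally and rendered as percentages only at report
boundaries.

## Known limitations

* Single panmictic patch: no migration, spatial structure, or seasonality.
* No parent-of-origin effects beyond the deposition step; no multi-locus
  or split drives; no sex-linked loci.
* The fertility multiplier applies to the egg output of drive-carrying
  females only (the 10% decrease is stated as overall, without sex
  attribution); applying it to both sexes requires routing it through the
  mating step and is not implemented.
* Simulated release outcomes are conditional on the synthetic
  life-parameter defaults above; in particular the *time to drive
  elimination* scales inversely with the drive's fitness deficit, so that
  quantity carries the largest parametric uncertainty of anything the
  package computes.  The qualitative outcome — transient replacement, a
  window of high female drive coverage, then exhaustion by cost-free
  resistance — is insensitive to those defaults and is what the property
  tests pin down.
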