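# Methods

## The drive model

The deterministic core tracks the adult genotype distribution (+/+, +/t) of
a population segregating a recessive-lethal sperm-killing driver across
discrete, non-overlapping generations. Three probabilities parameterise it:

| parameter | meaning | default | source of the default |
|---|---|---|---|
| d | t-transmission of a +/t sire within his own paternity share | 0.9 | classic transmission measurements in +/t males |
| c | expected paternity share of a +/t male against one +/+ male | 0.113 | laboratory sperm-competition trials |
| P | probability a litter has two mates rather than one | 0.609 | the corrected behavioural polyandry rate |

Assumptions: random mating (sires drawn independently, with replacement,
from the adult genotype distribution; sexes have identical genotype
composition); polyandry means exactly two mates (the minimal model with a
single parameter P — observed litters have up to four sires, but a
two-mate model is what a scalar polyandry rate identifies); competition
rescales paternity shares while d acts at full strength within a share;
equal pre-selection fecundity across union types; t/t conceptions removed
in utero and no later viability differences, so the viable newborn
distribution is simultaneously the newborn cohort and the next adult
generation.

Because each conceptus takes its maternal and paternal gametes
independently, the newborn distribution is bilinear in the parental
t-gamete probabilities and the whole population mixes through their means:
a = H/2 and b = d[(1−P)H + P(H² + 2cH(1−H))], giving
pre-selection {ww, wt, tt} = {(1−a)(1−b), a+b−2ab, ab} and viable newborn
+/t proportion H′ = (a+b−2ab)/(1−ab). This aggregation is exact, not an
approximation.

Two closed forms were derived independently before implementation and are
used by the test suite as oracles while the package computes both
quantities numerically:

* monandry fixed point, solving H′ = H with P = 0:
  **H\* = 1 − √((1−d)/d)** (2/3 at d = 0.9);
* invasion threshold, linearising at H → 0 where the growth factor is
  λ = 1/2 + d(1 − P + 2cP): **P\* = (d − ½)/(d(1 − 2c))**
  (0.5742 at d = 0.9, c = 0.113). For c ≥ 1/2 no polyandry rate stops
  invasion.

Numerical choices: fixed-point iteration tolerance 1e-10 (equilibria
reported once |ΔH| falls below it); threshold bisection to width 1e-6 on
the growth factor evaluated at H = 1e-8; trajectories stop on |ΔH| < 1e-10
or `max_generations` (default 1000); extinction declared below H = 1e-6;
the phase surface starts every cell from H = 0.5 and allows 5000
generations so near-threshold cells settle. At d = 1 the boundary
equilibrium H\* = 1 is approached sublinearly and the iteration reports a
value ~1e-5 short of it; interior d are unaffected.

## The misclassification correction

Paternity-based polyandry scoring is blind to matings that yield no
offspring. Within a two-mate litter of size k whose first mate has expected
share s, all pups share one sire with probability s^k + (1−s)^k, assuming
pup paternities are independent draws with a fixed share — the simplest
exchangeable model consistent with defining c as an expected share. Shares
follow the sire-pair genotypes under random mating at adult +/t frequency
y: equal-genotype pairs split 1/2, mixed pairs give the +/t male c. The
population mean m̄ of this quantity over the litter-size distribution
(sizes ≥ 2 only; singletons cannot reveal two sires and are excluded
throughout) converts the genetic rate G to the behavioural rate
B = G/(1−m̄), with the misclassified fraction M = B·m̄ satisfying
B = G + M.

On data, `estimate_behavioural_polyandry` takes the litter-size
distribution from the observed eligible litters and accepts per-cohort
adult male +/t frequencies: the sire-pair mixture is frequency dependent,
so when the carrier frequency drifts over a study the cohort-weighted m̄ is
the right average. Known limits of the correction: it ignores the dam's
genotype, yet in +/t-mother litters the in-utero loss of t/t conceptions
falls more heavily on the +/t sire's pups, skewing realised shares beyond
c. At carrier frequencies near the ~12% typical of the study system this
bias is negligible (verified by simulation); at 20%+ it becomes visible as
a slight underestimate of B. Mating order, timing and copulatory plugs are
not modelled.

## The individual-based simulator

`popsim.simulate` generates the data the estimators consume, with the full
causal chain: founders (default 12 animals, 4 carriers — the study
population's founding), discrete generations, 50:50 sexes, each female
having a truncated-Poisson number (mean 3, support 1–8) of reproductive
events per generation — roughly the study's three litters per breeding
female — with mates drawn anew per event: one mate with probability 1−P,
two distinct males otherwise. Litter sizes are truncated Poisson on 1–8
with mean 3.1 (matching ~3,100 pups over ~1,000 litters); conceptions are
drawn at that size and thinned by t/t loss, so recessive lethality shrinks
realised litters rather than being resampled away. The next generation's
breeders are sampled uniformly from the viable pups up to a carrying
capacity (default 200 adults). Output is deterministic given (seed,
config).

The simulator intentionally omits: overlapping generations and lifespan
variation, spatial/nest structure, immigration and emigration, mate
choice, temperature and density covariates, and post-birth pup mortality.
Passing tests therefore demonstrate internal consistency of model +
estimators under the stated mating system, not fidelity to every feature
of field data. It also emits a `matings` table recording mates that
achieved no paternity — information real paternity studies lack — which is
what allows unconditional estimation of c in simulation.

## Estimation stages

* **Polyandry rate**: multi-sire fraction among litters of realised size
  ≥ 2, with a 95% Wilson score interval (closed form, well behaved near the
  boundaries; the choice of interval is a convention).
* **Competition intensity**: per male, the arithmetic mean of co-sire
  counts over litters where he sired ≥ 1 pup, plus a harmonic-style
  summary computed as hmean(1 + co-sires) − 1 so uncontested litters do
  not zero the mean (a plain harmonic mean is undefined with zeros; this
  is an interpretation, flagged as such). Males with no offspring never
  enter — they are invisible to paternity data — and this conditioning is
  logged.
* **Male fitness GLM**: offspring count ~ genotype + competitors +
  n_litters and their two-way interactions, Poisson log link with
  Pearson-χ²/df dispersion (quasi-Poisson). Model selection enumerates all
  18 marginality-respecting submodels and ranks by qAIC computed with the
  largest model's dispersion. Sequential deviance fractions for
  competition, genotype and their interaction are reported after first
  accounting for the number of reproductive events. Degenerate designs
  (constant covariates, a single genotype class, < 10 males) raise a
  `FitError` naming the offending terms.
* **Drive parameters**: d̂ is the +/t fraction among pups of
  +/t sire × +/+ dam single-sire litters (mixed litters would confound
  transmission with shares; +/t dams would confound it with t/t loss).
  ĉ is the +/t male's pooled paternity share in two-mate mixed-genotype
  litters, restricted to +/+ dams for the same lethality reason — without
  the restriction even c = 0.5 data yield ĉ ≈ 0.35 among +/t-mother
  litters. With mating records every mixed litter counts; with paternity
  data alone the estimate conditions on both males siring and is flagged
  `conditional` (it necessarily overstates c).
* **Selection gradient**: relative fitness (offspring/mean) regressed on
  the per-female genetic polyandry proportion, pooled, per genotype, and
  with a genotype × polyandry contrast. Mean litter size enters as a
  covariate whenever available: multiple paternity is detected more easily
  in large litters and large litters mean high fitness, so the raw
  regression has a built-in positive artifact (null-data calibration:
  mean z ≈ +1.3 unadjusted, ≈ 0.1 adjusted). This is the same reason the
  polyandry analysis itself must condition on litter size. Without a
  `mean_litter_size` column the function falls back to the bare
  regression.

## Problem sizes

The test suite validates parameter recovery on a single simulated study of
~6,000 litters (seconds to generate) and calibrates null behaviour of the
GLM interaction and the selection gradient on 100 seeded replicates of
~600-litter populations each; these sizes give binomial standard errors
small enough to detect the biases of interest while keeping the whole
suite under a few minutes. The acceptance script computes only
deterministic model quantities.

## Known limitations

* The misclassification correction assumes two mates; litters with three
  or four sires are counted as polyandrous when scored but their extra
  mates do not enter m̄.
* The correction's m̄ cannot reproduce a published misclassified fraction
  without the originating study's litter-size distribution; its validation
  here is self-consistency (B = G + M) and recovery of the generating
  behavioural rate in simulation.
* ĉ and d̂ discard informative but confounded litters (+/t dams, mixed
  single-sire litters) rather than modelling the confounds.
* The deterministic model has no drift; stochastic fate near the threshold
  is the simulator's domain.
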