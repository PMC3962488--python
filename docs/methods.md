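# Methods

## The 2+1 pairing model

Meiosis I in an *XYY* male must move three sex chromosomes to two poles.  The
model assumes that exactly two chromosomes pair and disjoin faithfully while
the third segregates independently, with the three possible pairs occurring
at frequencies `p_L` (X–Y1), `p_M` (X–Y2) and `p_N` (Y1–Y2) on the
probability simplex.  Each configuration produces four equiprobable sperm
karyotypes (the paired chromosomes separate; the free chromosome joins either
pole with probability 1/2), closing the outcome space at six classes:
`X, 12, X1, 2, X2, 1` in the canonical order used for every table.  Nullo-XY
sperm, chromosome loss, meiosis-II errors and trivalent pairing are outside
the model; the control crosses bound such events below ~1% of progeny, so
their omission cannot move class frequencies at the resolution of the data.
Partial pairing failure of the "2" pair is likewise not parameterised: the
model is the extreme case of 100% disjunction of whichever pair forms.

Zygote classes inherit the sperm-class probabilities (every scored offspring
comes from an X-bearing egg) and may be re-weighted by a per-class relative
viability `v_c ≥ 0` (canonicalised to max 1) with renormalisation.  Viability
acts multiplicatively after meiosis, reflecting the reading that class
deficits in such crosses arise from postmeiotic embryonic inviability rather
than segregation itself.  Two structural consequences carry all the
diagnostics: under unit viability the complementary class pairs (X/12, X1/2,
X2/1) are exactly equal, and the expected sex ratio is exactly 1/2 for every
mixture.

## Estimation

The forward map from mixture to class frequencies is linear and invertible
on the simplex: `p_L = 1 − 2(f_X1 + f_2)`, `p_M = 1 − 2(f_X2 + f_1)`,
`p_N = 1 − 2(f_X + f_12)`.  The moments estimator applies this inversion to
pooled frequencies (summed counts, never averaged ratios).  Sampling noise
can push components outside [0, 1]; such estimates are projected (negatives
clipped, renormalised) and flagged `projected` rather than silently accepted.
Six frequencies cannot identify a mixture and five free viabilities jointly,
so no joint fit is offered: the estimator states its unit-viability
assumption in its output, and the complementary-pair differences
(`f_X − f_12`, …) are reported as the viability diagnostic.  Simulation with
a 0.6-viable XYY-son class confirms the expected bias of the unit-viability
estimator and that the X~12 asymmetry flags it.

Uncertainty comes from a vial bootstrap (resample vials with replacement,
re-pool, re-invert; percentile intervals).  Vials, not flies, are the
exchangeable unit because progeny within a vial share parents and culture
conditions.  Measured coverage at 50 vials × 150 flies is near the 95%
nominal level (within ~3 binomial SE over 100 replicates in the test suite).

Cross summaries follow the published table conventions: pooled statistics
from summed counts; per-vial means and SDs treating each vial as an
independent subpopulation (n−1 denominator); percent female from the
X-bearing-sperm classes; percent aneuploid as XXY daughters plus XYY sons
(classes X1, X2, 12) for XYY crosses and the two exceptional classes for
four-class control crosses.  Control-cross exceptional rates get exact
Clopper–Pearson intervals.  One-decimal rounding is applied only at
presentation time.

## Difference-of-means intervals

Replicate-vial subsets are compared through the posterior of a difference of
normal means under noninformative priors, summarised from (mean, SD, n).
Two readings are implemented:

* **Common variance (default).**  The posterior of the difference is an
  exact shifted/scaled Student t with `df = n_a + n_b − 2` and scale
  `s_p · sqrt(1/n_a + 1/n_b)`.  With equal group sizes this interval is also
  exactly calibrated in the frequentist sense: measured null exclusion at
  n = 3 per group is 2.5% at the 97.5% level (10,000 simulated pairs).
* **Separate variances (`equal_var=False`).**  The Behrens–Fisher posterior
  approximated by a Welch t with Satterthwaite degrees of freedom.  At n = 3
  this is measurably conservative (~1.6% null exclusion at the 97.5% level),
  which is why it is not the default for the three-vial subsets this package
  targets; at equal n its scale is identical and only the df differ.

Both readings flag exactly the same single comparison in the packaged
72-comparison subset scan; a plain normal-quantile interval flags four and
is rejected as anticonservative at these group sizes.  "Level 0.975" means a
two-sided 97.5% interval (0.9875 quantile).  No multiple-testing correction
is applied across the scan — one hit in 72 comparisons at the 2.5% level is
itself the expected chance outcome, which is the scientific point.

The required-sample-size calculation is the detectability criterion
`n = ceil(t²(1−α/2, df=1000) · (sd_a² + sd_b²) / (mean_a − mean_b)²)` with
separate variances summed and no power term beyond the α threshold.  Because
the packaged summary statistics are printed rounded to one decimal,
recomputed vial numbers are expected to agree with previously reported ones
only to within a few percent.

## Synthetic data

The generators produce every input the pipeline consumes, under one global
seed with deterministic substreams per generator.

* **XYY vials.**  Vial sizes come from a mean/SD-parameterised integer model
  (constant, Poisson, or negative binomial as the requested SD grows);
  defaults of 10 vials × 120 ± 45 flies match the observed range of ~80–200
  flies per vial with super-Poisson spread.  Class counts are multinomial
  per vial around the model's zygote distribution, optionally perturbed by a
  symmetric-mean Dirichlet draw with total concentration κ — the simplest
  exchangeable model of between-vial overdispersion, with the closed-form
  frequency variance `p(1−p)(n+κ)/(n(1+κ))` used as the test oracle.
* **Control crosses.**  Exceptional progeny binomial at `ndj_rate`
  (default 0.005, the magnitude seen in the control tables), split evenly
  between XXY-like daughters and X0-like sons since counts cannot
  distinguish nondisjunction from loss; normals split 1:1.
* **qPCR.**  `Ct = baseline − log2(template)/log2(1+efficiency) + N(0, σ)`
  per well, with σ = 0.2 cycles and triplicates by default, for an rDNA
  amplicon and a tRNA normaliser in a sample and a reference genotype.

What the generators do not emulate: viability differences correlated across
vials of one sire, variegation expressivity, gynandromorphs, larval-timing
effects, or plate-specific qPCR artefacts beyond an additive offset (which
the ΔΔCt estimator cancels by construction).  Passing tests therefore show
correctness of the estimators under the stated stochastic model, not
robustness to every failure mode of real fly crosses.

## qPCR quantification

Relative rDNA copy number is comparative 2^−ΔΔCt at assumed 100%
amplification efficiency: per-replicate ΔCt = Ct_rDNA − Ct_tRNA, means
compared between sample and reference, result expressed as a percentage of
the reference.  Mean-ΔCt-first (not averaging per-replicate ratios) keeps
the estimator unbiased on the log2 scale.  SEMs are pooled by
root-sum-of-squares on the ΔCt scale and transferred to the percent scale by
the delta method (`SEM_% = ln2 · value_% · SEM_ΔCt`); Monte-Carlo simulation
confirms the delta-method SEM tracks the true sampling SD within ~30% at
realistic noise.  Replicate outliers are kept; absolute copy numbers are out
of scope.

## Numerical choices and problem sizes

* Simplex tolerance 1e-9 for mixtures (renormalise within, reject beyond);
  moments-estimator input must sum to 1 within 1e-6; packaged percentage
  rows are renormalised at parse time since printed values sum to 99.8–100.1.
* Degenerate intervals: zero scale with equal means yields [0, 0]
  (not significant).  Constant regression response yields slope 0, r² = 0;
  constant abscissa is an error.
* Zero-size simulated vials are redrawn; zero-variance classes make
  complementary correlations NaN with a flag rather than raising.
* Test-suite simulation sizes (2,000 vials for variance oracles, 10,000 null
  pairs, 100 coverage replicates × 400 bootstrap draws, 500 qPCR
  repetitions, 20 mixtures × 30 vials for recovery) were chosen so each
  check's Monte-Carlo error is several times smaller than the tolerance it
  enforces while the whole suite stays fast on one CPU.

## Known limitations

* The mixture estimator is only as good as the unit-viability assumption;
  with strong class-specific inviability it returns a biased "effective"
  mixture, and only the complementary-pair diagnostic reveals this.
* The 2+1 model cannot represent trivalent pairing or partial disjunction;
  if those occur, estimated frequencies are projections onto the model.
* Percentile bootstrap intervals undercover slightly for small vial counts
  (< ~15 vials) and are reported without correction.
* The qPCR model assumes equal efficiency for target and normaliser; a real
  efficiency gap shifts estimates multiplicatively and is not corrected.
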