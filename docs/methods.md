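# Methods

This note documents the models behind each stage, the defaults and why they
were chosen, what the synthetic-data generator does and does not emulate,
and the numerical choices a maintainer would otherwise have to reverse-
engineer from the code.

## Synthetic trial generator

The generator emulates a three-arm cluster-randomised ECD trial: 31 village
clusters in two subdistrict strata (allocated group : combined : control as
5:5:8 and 3:3:7), 20 caregiver-child dyads per village (n = 620), children
aged 4–26 months at endline, and 7.6% loss to follow-up, applied completely
at random. Arm is constant within village by construction.

Continuous endpoints follow the random-intercept model

    y_ij = μ + effect[arm_j] + β_age (age_ij − age_mid) + u_j + e_ij,
    u_j ~ N(0, ρσ²),  e_ij ~ N(0, (1 − ρ)σ²),

so the marginal SD is σ and the age-conditional intracluster correlation is
ρ (default 0.20). Marginal means and SDs default to realistic control-arm
endline values for each instrument (e.g. play activities 3.2 ± 1.5 on 0–6,
depressive symptoms 15 ± 8.5 on 0–60, milestone domains ≈45 ± 11 on 0–60);
age slopes give development scores a monthly growth gradient (≈0.8–2
points/month) and leave the maternal scales age-flat. Binary household
outcomes use a logistic model with a normal village intercept whose variance
σ_b² = ρ/(1 − ρ)·π²/3 puts the *latent-scale* ICC at ρ; the observed-scale
ICC of a binary outcome is necessarily smaller, which is documented rather
than corrected because the design calculation that motivates ρ = 0.20 is for
a continuous endpoint.

Bounded integer scales are produced by clipping and rounding the latent
score to the instrument's support (thresholding preserves the ICC machinery
while matching the integer support); item-level responses are then derived
from the bounded score so that re-scoring the items reproduces it exactly —
e.g. a play-activities count of k endorses k of the 6 items uniformly at
random, a milestone domain raw of s (a multiple of 5) becomes ⌊s/10⌋ "yes"
items plus one "sometimes" when s mod 10 = 5.

Two consequences worth knowing:

- **Attenuation.** An additive effect injected on the latent scale is
  partly absorbed by the scale bounds (ceiling for the activities count,
  floor for low-prevalence scores). `clip_scores=False` switches the
  generator into a calibration mode that exposes the unbounded continuous
  scores as columns, making additive effects exact estimands; the
  effect-recovery experiments use it.
- **ICC dilution.** The marginal ICC of an outcome with a strong age slope
  is below ρ, because uniform within-village age variation adds
  individual-level variance. ICC calibration checks therefore use the
  age-flat depressive-symptom score.

Development scores receive a 2% rate of gross outliers (extra N(0, (6σ)²)
measurement error), emulating the handful of implausible assessments real
data contain; without them the |z| > 4 exclusion rule would never fire at
n ≈ 600. Baseline versions of two outcomes share the village effect and
half the individual signal of their endline counterparts (arm effects
removed — baselines predate the intervention), so the covariate prescreen
has something real to find. Attrition is MCAR by default; covariates match
realistic marginal frequencies (57% maternal primary education, 85%
electricity, 20% brick walls, lognormal income, Poisson(3) assets) but
their mutual correlations are invented — the generator makes no claim about
the covariance structure of real baseline tables.

What passing tests on these data do **not** show: robustness to informative
attrition, to cluster-size variation, to non-normal village effects, or to
instrument misclassification. The generator is a fidelity harness for the
estimation machinery, not a behavioural model of households.

ICC estimation uses the one-way ANOVA estimator with the unbalanced-design
average cluster size n₀; it errors on a single cluster or zero total
variance.

## Scoring

Scoring is a pure function of the item dictionaries shipped as versioned
YAML (`ecdtrial/data/instruments.yaml`). Milestone items are mapped through
the conventional yes = 10 / sometimes = 5 / not yet = 0 scheme; the scheme
is a parameter because adapted inventories sometimes rescale it. The
activities subscale counts the primary caregiver's stimulating activities;
the total milestone score is the sum of the five domain raws computed
before any standardisation. The depressive-symptom score reverse-codes the
four positively worded items of the standard key. Missing items are never
imputed or pro-rated: any missing required item makes the affected score
(and any total built on it) missing. The expressive-vocabulary count is
defined only for children over 9 months and child dietary diversity only
over 6 months; the generator leaves them missing below those ages.

## Internal age-standardisation

Norms come from the trial's own control arm (followed-up records only):
z = (raw − mean(age)) / sd(age). The default estimator bins age into
3-month bins and takes the within-bin control mean and SD, merging any bin
below 15 records into its smaller neighbour; bins are transparent, easy to
audit (they serialise to YAML) and make no shape assumption. A
quadratic-mean / linear-SD regression method is available for small control
arms; its SD model rescales mean absolute residuals by √(π/2). Ages outside
the fitted range clamp to the boundary bin. Scores with |z| > 4 are flagged
for exclusion — two-sided, applied per outcome independently, which is why
analysed n varies across development outcomes. Standardizers are fitted
once on the original sample and reused inside bootstrap replicates
(refitting per replicate would change the estimand; the fixed-norms choice
keeps it stable and is configurable).

Self-standardisation is an identity check: applying a binned standardizer
to its own fitting sample gives mean exactly 0 and variance
(N − k)/(N − 1) ≈ 0.97–0.99, i.e. SD within 0.02 of 1 at the control-arm
sizes used here.

## Effect estimation

G-computation proceeds per outcome and per comparison (each intervention
arm versus control; two comparisons per outcome, no multiplicity
adjustment): complete cases on the outcome and retained covariates, model
fit by OLS (continuous) or maximum-likelihood logistic (binary) with an
intercept, arm indicator and covariate block (categorical covariates
dummy-coded, first level dropped), then the mean counterfactual prediction
under each arm is differenced. Non-convergence or separation raises with
the fitter's diagnostics. Design matrices are assembled directly with
numpy/pandas rather than a formula engine: the bootstrap re-runs the
estimator hundreds of thousands of times in the calibration experiments
and per-call formula parsing would dominate the runtime.

Covariate prescreening adds each candidate singly to the arm-only base
model and keeps it when the likelihood-ratio p < 0.20 (χ² df = number of
encoded columns). The base model includes the arm indicators; candidates
are screened singly and the retained set is frozen before the bootstrap —
re-screening inside replicates would mix selection noise into the interval.
A candidate that fails to fit, or is constant, is dropped with a logged
warning.

The bootstrap resamples villages with replacement *within arm* (each arm
keeps its village count), stacks the records, and re-runs the estimator;
CIs are the 2.5th/97.5th percentiles of B = 1000 replicates (percentile,
not BCa — the simplest method consistent with a plain clustered bootstrap).
Replicates that fail are redrawn up to 5% of B, then the run errors. A
single run-level seed fans out to per-comparison streams through
`numpy.random.SeedSequence`, so a manifest (seed, B, retained covariates)
reproduces every interval bit-for-bit.

Known limitation — small-cluster undercoverage. With 8 villages in an
intervention arm and 15 in control, the percentile village bootstrap is
anti-conservative: resampling k of k clusters understates the cluster-mean
variance by roughly (k − 1)/k per arm, and the percentile interval also
ignores the t-like tails of a mean over ~21 effective units. At the default
design (ρ = 0.20, m = 20) the package's own 500-trial calibration
experiment measures 92.8% coverage of a nominal 95% interval under a
simulated null, i.e. a type-I error of 7.2% rather than 5%; a companion
diagnostic shows the mean bootstrap-implied SE running ≈7% below the
empirical sampling SD, matching the (k − 1)/k account. This is a property
of the interval
method at this cluster count, not of the point estimator (which the
recovery experiments show unbiased); analysts who need calibrated tests at
these cluster counts should treat the percentile CIs as approximate, or
enlarge the design. The cluster-df t option in the design module is the
conservative counterpart on the planning side.

Cohen's d uses the pooled SD over (n₁ − 1) + (n₂ − 1) degrees of freedom
and the normal-approximation CI with
var(d) = (n₁ + n₂)/(n₁ n₂) + d²/(2(n₁ + n₂)).

## Design calculations

Power uses the design-effect normal approximation:
SE = σ √(DE (1/(k_t m) + 1/(k_c m))) with DE = 1 + (m − 1)ρ, and
power = Φ(|δ|/SE − z₀.₉₇₅). With δ = 2.0, σ = 3.3, ρ = 0.20, m = 20 and 8
treatment vs 15 control clusters this gives 0.807, which is why the normal
(rather than cluster-df t) approximation is the default: it reproduces the
planned 8/15 design from its stated inputs. The t variant is provided and
documented as more conservative. `required_clusters` walks integer
multiples of the allocation ratio until the target power is reached.
Randomisation permutes villages within stratum under the plan's counts,
reproducibly from a seed. The village screen keeps villages whose every
screened demographic lies within 1.5 district SDs of the district mean.

## Reporting

Flow accounting stores only counts; every percentage is recomputed on
access (half-up rounding, one decimal — display only, computation is never
rounded). Results tables print unadjusted mean ± SD or n (%) per arm next
to adjusted differences with CIs to two decimals. The run manifest (seeds,
B, α_screen, retained covariates, per-comparison ns) is emitted as JSON and
suffices to reproduce every table cell.

## Experiment sizes

The calibration experiments use: 50 random small trials for the
g-computation/oracle agreement; 500 simulated null trials at the default
design with B = 400 for bootstrap coverage; 30 replicates of a 200-village
trial for effect recovery; 250 replicates for the prescreen retention rate.
These sizes put Monte-Carlo error comfortably below the bands being
checked while keeping the default test run fast enough for routine use.
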