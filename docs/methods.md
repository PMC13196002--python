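# Methods

This note documents the statistical machinery, the synthetic-data model
behind the test suite, the numerical choices, and the design decisions
taken where the underlying procedure was open to interpretation.

## Tabular group comparisons

Continuous variables are compared with two-sample tests gated by
Shapiro–Wilk normality (per group) and Levene's test centred at the
median: non-normality in either group routes to Mann–Whitney U;
normality with unequal variances to Welch's t; otherwise the pooled t.
Cohen's *d* always uses the pooled SD — including alongside a Welch
t — so one effect-size convention covers the whole results table.
Because published tables print only (mean, SD, n), a summary-statistic
entry point (`independent_t_from_stats`) mirrors the raw-data path;
statistics recomputed from two-decimal summaries can disagree with the
originals by up to ~1% (e.g. gait speed: −10.30 recomputed vs −10.351
printed), which is the tolerance the tests use for such checks.

Sex distributions use Fisher's exact test (two-sided by the standard
small-*p* summation rule; a doubling rule is available), the odds ratio
ad/bc, and the Woolf logit interval exp(ln OR ± z₀.₉₇₅·√(1/a+1/b+1/c+1/d)).
Cramér's V comes from the uncorrected χ². For the bundled 18:5 vs 4:14
table this yields V ≈ 0.56; the value 0.601 circulated with the original
table is not reproducible from those counts by any standard formula and
is therefore not asserted anywhere.

The bundled per-patient clinical table reproduces all printed cohort
summaries (mean age 77.26, mRS 2.39, iNPH scale 51 after rounding,
Evans index 0.38, Radscale 9.26). Two internal inconsistencies in the
printed source are flagged rather than corrected: the Evans-index SD
(printed 0.34 in the text, 0.04 in the table; the per-patient column
gives 0.044) and the printed Evans minimum 0.30 (the column's minimum
is 0.31).

## 1D statistical parametric mapping

A comparison treats the whole 101-node gait-cycle waveform as the unit
of inference. Each participant contributes one curve — the mean across
strides and sides — keeping observations independent (whether analyses
of this kind should pool left/right cycles as independent observations
is generally ambiguous; per-side analysis is available via the
`sides` argument). The node-wise pooled-variance two-sample t with
ν = n₁+n₂−2 forms the t-continuum. Published analyses of this design
sometimes print t(40) for n = 23+18; this package reports the pooled
convention ν = 39.

Residual smoothness is estimated from the node-wise-standardised
residual field: FWHM = √(4 ln 2 / v̄) with v̄ the mean squared
node-to-node derivative, clipped to [1, Q]. For a Gaussian-kernel field
this estimator is consistent (the generator round trip recovers a
15-node FWHM within a few percent); for white node noise it returns the
resolution floor ≈ 1.18.

The two-tailed critical threshold t* solves the expected Euler
characteristic equation at α/2,

    α/2 = P(T_ν > u) + R·ρ₁(u; ν),
    ρ₁(u; ν) = √(4 ln 2)/(2π) · (1 + u²/ν)^(−(ν−1)/2),

with R = (Q−1)/FWHM resels, by bracketed Brent root finding
(|Δu| < 1e−8) starting at the uncorrected quantile. The solution is
capped at the Bonferroni-over-nodes quantile: for rough fields the EC
approximation over-corrects, and Bonferroni is always valid at discrete
nodes, so the smaller of the two thresholds is used (standard SPM
practice). Calibration on smooth simulated nulls (n = 20+20, FWHM 15)
gives a family-wise rejection rate of ~0.03–0.06 at α = 0.05, and the
threshold agrees with the permutation max-|t| 95th percentile within a
few percent.

Suprathreshold clusters are maximal runs of |t| > t*. Cluster p-values
use the 1D Poisson clumping heuristic: with expected cluster count
m = R·ρ₁(t*) and expected suprathreshold extent (Q−1)·P(T>t*), cluster
extents are taken as exponential with mean extent/m, giving
p = 1 − exp(−m·e^(−k/mean)) (doubled for two tails, capped at 1). Where
this closed form is in doubt the permutation oracle is the fallback.
Extents are reported in % gait cycle as end − start node widths (nodes
are integer percent), and the persistence filter keeps clusters whose
extent is *strictly greater* than 5 %GC — a 10–15-node cluster (5 %GC)
is dropped, 10–16 (6 %GC) kept. Clusters touching node 0 or node 100
are annotated as adjacent to the cycle boundary but never merged, which
would change reported extents.

## Signature classifier

Each persistence-filtered region is scalarised as the mean of the
participant's mean curve over the region's node span (the scalarisation
is a documented default — peak or integral would be alternatives; the
region mean is the least noise-sensitive of the three). The nested
cross-validation then runs, per repeat × outer fold (defaults: 10
repeats, 5 stratified outer folds):

1. *z*-transform fitted on the training rows only;
2. SMOTE on the standardised training rows (k = 5 nearest minority
   neighbours, auto-reduced for small minorities; applied after the
   z-transform so neighbour distances are scale-free, and only inside
   training folds);
3. L2-penalised logistic regression (λ = 1 in standardised space,
   intercept unpenalised) by Newton iteration to gradient norm < 1e−8;
4. feature ranking by mean |SHAP| — exact for a linear model:
   φᵢⱼ = βⱼ(xᵢⱼ − x̄ⱼ) on the log-odds scale, additive to machine
   precision;
5. ablation over nested subsets of the ranking scored by inner
   stratified 3-fold CV (pooled OOF AUC/F1), selecting the plateau
   onset: the last subset size that improves the running best inner AUC
   by more than 0.01 (the "smallest size within tolerance of the best"
   alternative collapses to one feature whenever a single feature is
   strong, which defeats stability selection of complementary pairs);
6. refit on the selected subset and score the held-out fold.

Per-participant OOF probabilities are averaged across repeats before
thresholding at 0.5 (majority vote is available); sensitivity is recall
on the case class and specificity comes from the control row of the
confusion matrix. AUC is pairwise concordance with ties counted half;
confidence intervals are percentile bootstrap over participants.
Features selected in at least 50% of outer splits (inclusive) form the
consensus set.

## Synthetic cohort generator

The generator emulates the structure of a two-group 3D gait study, with
defaults pinned to the reference cohort: 23 cases vs 18 controls, sex
composition 18:5 vs 4:14, age 77.26 ± 5.8 vs 73.78 ± 6.1 years, and
spatiotemporal summaries (cases 0.48 ± 0.25 m/s speed, 1.35 ± 0.23 s
cycle, 0.63 ± 0.30 m stride length, 0.18 ± 0.04 m width; controls
1.20 ± 0.18, 1.08 ± 0.08, 1.31 ± 0.15, 0.11 ± 0.03).

* **Templates.** Normative mean curves per joint-plane are truncated
  (5-harmonic) Fourier series of hand-sketched adult gait curves; the
  coefficients live in the configuration, not the code, and are free
  parameters.
* **Between-subject variability.** White Gaussian node noise convolved
  with a Gaussian kernel of configurable FWHM (default 15 nodes) and
  rescaled to a target SD (default 3°) — a stationary smooth Gaussian
  random field, the regime random field theory assumes. Padding well
  beyond the kernel support avoids edge effects.
* **Stride-to-stride noise.** Independent smooth fields per recorded
  stride (default SD 1°, 4 strides per participant; the number of
  analysed strides per participant is typically small in overground
  protocols, and 4 is a choice, not a datum).
* **Group effects.** Additive raised-cosine bumps (zero at the region
  edges, preserving smoothness) or boxcars on configured %GC regions;
  the preset regions are the twelve the reference study reported, with
  a default 3° amplitude which reproduces peak t statistics near 3 at
  the study's group sizes. Effects apply to both sides by default.
* **Raw trials.** Vertical GRF per foot is zero in swing and the smooth
  double bump BW·(1.2 sin πτ + 0.3 sin 3πτ) over a 60%-of-cycle stance;
  the steep initial slope puts the 5%-BW crossing within ~6 ms of the
  true contact so threshold detection is accurate to one sample at
  100 Hz. Heels hold position in stance and advance one stride length
  per cycle via a smoothstep; medio-lateral positions sit at ± half the
  stride width.
* **Seeding.** One master seed; every participant draws from substreams
  keyed (seed, participant index, stream), so enlarging the cohort
  never reshuffles existing subjects.

What the generator does **not** emulate: marker-level artefacts and
soft-tissue noise, walking aids, turning, asymmetric or non-stationary
effects, kinetic waveforms beyond the vertical GRF pulse, and
correlations between demographics and gait (draws are independent).
Passing tests therefore demonstrate correctness of the machinery under
the stated statistical model, not performance on real capture data.

## Benchmark experiments

The classifier benchmark (`make_benchmark_cohort`) simulates the
study-sized cohort with effects at the two consensus regions the
reference analysis identified — pelvic obliquity 6–35 %GC and hip
ab/adduction 0–53 %GC — and extracts those two features plus ten region
features from unaffected joint-planes. The effect amplitude (6.5° at
the bump peak, ≈ 2.2× the subject noise SD) is chosen so the pair is
*complementary*: each feature alone discriminates only partially, while
together they nearly separate the groups. At larger amplitudes a single
feature suffices statistically and a parsimonious selector correctly
stops at one feature, which is a different regime from the two-feature
consensus being modelled. Under the defaults the two informative
features enter the ≥50% consensus in ≥ 90% of seeds with OOF AUC ≥ 0.9.

Null calibration shuffles labels on the amplitude-zero cohort. On a
41-participant cohort a null OOF AUC has a sampling SD near 0.09, so
single-seed values roam roughly 0.3–0.6; the across-seed mean sits near
0.5 (slightly below, a known consequence of feature selection inside CV
at small n, which can anti-generalise). Shuffling labels while leaving
strong bimodal effect features in place amplifies that anti-learning —
occasionally to AUC ≈ 0.2 — and is deliberately not used as the null
condition.

## Numerical choices and degenerate inputs

* Butterworth filtering uses `filtfilt` with reflective padding of
  three filter lengths; the `order` argument is the single-pass order,
  so the dual-pass magnitude is its square (−6 dB at f_c for order 4).
* Cycle normalization interpolates with a cubic spline, falling back to
  linear below 4 samples per cycle; events outside the series raise.
* Event detection bridges sub-threshold gaps shorter than 50 ms,
  discards bursts shorter than the minimum stance (100 ms default), and
  refines crossings by linear interpolation. All-zero GRF returns empty
  events with no provenance flag; the caller supplies manual events
  (external fallback criteria are not modelled).
* Stride width is measured between heel positions at each foot's own
  heel strike within the cycle (a definition choice; configurable by
  replacing the routine); cycles missing a contralateral strike report
  width as missing rather than failing.
* Zero pooled variance at a node, constant residual fields,
  zero-variance training features, minorities below 2 samples, and
  single-class label vectors all raise informative errors rather than
  propagating NaNs.
* The logistic Newton solver declines the line search once the gradient
  norm is below 1e−4 (the objective decrease is below float resolution
  there) and errors with the iteration count if the gradient norm
  cannot reach 1e−8.

## Problem sizes

The test suite and the acceptance script use simulation sizes chosen for
single-CPU runs: 500 null cohorts for family-wise calibration, 100
replicates for region recovery, 2000 permutations for the threshold
cross-check, and 10–12 seeds × (5–10 repeats × 5 folds) for the
classifier experiments. All are comfortably beyond the Monte-Carlo
resolution the asserted tolerances require.

## Known limitations

* Cluster p-values rest on the Poisson clumping heuristic; they are
  approximate for wide clusters near the threshold. The permutation
  oracle is the reference when exactness matters.
* RFT assumes stationary smoothness; the estimator pools a single FWHM
  per comparison across both groups' residuals.
* The SMOTE implementation computes exact pairwise distances (fine for
  cohort-sized minorities; not intended for thousands of samples).
* Joint angles are consumed, not computed: marker-set biomechanics,
  inverse kinematics/dynamics and GRF waveform analysis beyond event
  detection are out of scope.
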