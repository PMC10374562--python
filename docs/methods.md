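# Methods

This note records the models, conventions and numerical choices behind
the package, and what the synthetic-data tests do and do not establish
about real data.

## Assay and data model

A sample is one plasma draw from one animal on one study day, assayed on
one plate; an analyte is one aptamer reagent with a positive RFU
readout. The measurement model the whole package is built around is
multiplicative:

    RFU_obs = RFU_true · hybScale(sample) · plateScale(plate, analyte) · 10^ε

with ε ~ N(0, σ_log) on the log10 scale, and a biology layer in which an
analyte's expected signal responds to tumor volume V through a
saturating exponential, RFU_true = C + A·(1 − e^(−B·V)): C is the
baseline abundance (RFU), A the maximal increment at saturation (RFU),
and B (1/mm³) the rate at which the signal approaches it. Null analytes
have A = 0 exactly; "shared" responders react to every tumor line,
line-specific responders to one.

## Normalization

Stage order follows the measurement chain: hybridization → plate
calibration → median-signal. Each stage estimates and divides out one
artifact layer; all factors are positive, so dimensions and positivity
are preserved, and re-running any stage immediately after itself returns
factors of 1.

Two numerical conventions make the median-signal stage a well-defined
fixed point rather than a heuristic pass:

* **Log-scale medians.** Medians of positive signals are taken on the
  log scale — identical to the ordinary median for odd counts, the
  geometric mean of the two middle values for even counts. This makes
  the median reciprocal-symmetric (median(1/y) = 1/median(y)), which is
  what lets "scale by the median ratio" have an exact fixed point.
* **Gauge fixing.** Multiplying every sample of a plate-bin by a common
  factor leaves all intra-plate ratios unchanged, so that mode is not
  identifiable; each pass's scales are therefore divided by their
  per-plate median over study samples before being applied. Without
  this the iteration can drift along the unidentifiable direction.

The stage iterates (recompute intra-plate medians over study samples →
compute per-sample-bin scales → gauge-fix → apply) to a tolerance of
1e-12, typically converging in well under 100 passes; after convergence
the normalized matrix satisfies median_a(x_sa / intraPlateMedian(a)) = 1
for every sample and bin. Intra-plate medians use study samples only:
calibrators and buffers are plate-QC artifacts, not biology, though they
receive scales of their own. Hybridization controls are excluded from
all downstream statistics. Single-dilution datasets are treated as one
bin. The reference values for hybridization controls and plate
calibration ship with the dataset (the synthetic generator emits them);
median normalization uses the post-calibration plate medians (stage
order), an interpretation the data do not pin down.

## Screening

Inference is on log10 signal. The repeated-measures ANOVA is the
classical univariate within-subject F (SS partitioned into subject, time
and error; df (k−1), (k−1)(n−1)) without sphericity correction — the
simplest model consistent with using each animal as its own control.
Animals missing a timepoint are dropped for that analyte
(complete-case); fewer than two complete animals flags the analyte
undefined and it fails selection. BH adjustment is the step-up procedure
with monotonicity enforcement; NaN p-values propagate and do not count
toward the number of tests.

Fold changes pair each animal to its own day-0 sample and take the
per-day median across animals; the maximum absolute value over days is
the filter statistic. The Pearson filter correlates log10 signal with
tumor volume over all samples of the group (computed per group, not
pooled across lines). Control exclusion applies the same q and
fold-change thresholds to the control-group screen. Selection is
monotone in all three thresholds by construction.

## Volume and type models

Features are log10 RFU, centered and scaled with training-set parameters
frozen into the model; the response is cube-root volume (linearizes the
diameter–volume geometry and tempers heteroskedasticity at large
volumes). Predictions invert the cube root, clamping negative linear
scores to 0 mm³ — volumes cannot be negative.

Cross-validation is grouped by animal (all of an animal's timepoints in
one fold), as is the train/holdout split (whole animals per group held
out), so longitudinal correlation cannot leak. The λ grid is log-spaced
over [λ_max·1e-4, λ_max] with 50 points (λ_max the smallest λ that zeros
all slopes), the mixing grid has 7 points over [0.1, 1]; the chosen grid
point is the most-penalized one within one standard error of the CV-MSE
minimum (the glmnet `lambda.1se` convention). The 1SE rule is what keeps
panels parsimonious: with the CV-minimum rule the same problems select
2–3× more markers at negligible CV gain. The holdout fraction defaults
to 27%; the explained variance R² is evaluated on the cube-root
(fitting) scale.

Operating points: candidate thresholds are the holdout's own predicted
volumes; a sample is called tumor-bearing iff its prediction exceeds the
threshold. The default selection maximizes specificity subject to
sensitivity = 1 (falling back to Youden's J when no threshold reaches
full sensitivity); ties prefer the larger threshold. Line-specific
models impute the volumes of other tumor lines to zero before training.
The type classifier is multinomial logistic regression (saga solver)
with an elastic-net penalty, grid-searched by grouped-CV accuracy;
one-vs-rest ROC curves and argmax accuracy are computed on the holdout.

## MDTV

The saturation fit is plain (unweighted) nonlinear least squares, per
the constant-variance assumption; initialization uses C₀ = mean of the
low-volume signals, A₀ = data span, B₀ = ln2 / (volume at half rise),
with multiplicative restarts on B₀. The covariance comes from the
Jacobian at the optimum and σ from the residuals with n−3 df. A fit with
amplitude below max(2σ, a vanishing fraction of the data span) or a
non-positive rate is a non-responder; non-convergence is flagged and
propagates.

The detection limit inverts the band construction in closed form:
MDTV = −ln(1 − 2zσ/A)/B with z = 1.96 (a normal quantile, configurable;
the df behind the 95% bands are not otherwise specified), "not
detectable" when 2zσ ≥ A. A delta-method band using the parameter
covariance exists as an alternative method tag for the baseline
interval; the constant-variance closed form is the default and is what
the acceptance checks exercise. Blood-volume scaling defaults to a
70 kg × 70 mL/kg human (4900 mL) against a 25 g × 58.5 mL/kg mouse
(1.4625 mL), ratio ≈ 3350 — an inference from standard physiological
values, exposed in the config; the human-equivalent diameter is
(6·V·ratio/π)^(1/3), reported in cm to one decimal.

Estimator performance at the generator's noise level (σ_log = 0.05,
i.e. ≈12% CV per observation, 30 points per fit, log-spaced volumes as
exponential growth produces): A and C are recovered to ≈4% median
relative error; B's information limit is much looser — the Cramér–Rao
relative sd of B is ≈17% under these conditions for any unbiased
estimator (≈12% even for a D-optimal replicated design), and the fit
attains ≈12% median error, i.e. it is near-efficient but B simply
cannot be pinned to a few percent at this noise and sample size. MDTV
estimates land within a factor of 2 of the closed-form truth (evaluated
at the pooled residual sd the constant-variance estimator targets under
multiplicative noise, σ = RMS(mean)·ln10·σ_log) in ≈98% of fits.

## Enrichment

Over-representation is the one-sided upper-tail hypergeometric test,
with gene sets intersected with the declared universe first; the default
background is the assay's unique protein menu (n = 4132 for the full
platform; the simulated menu's size for synthetic runs). Enriched sets
(BH q < 0.25) enter a similarity graph with edges where
(Jaccard + overlap)/2 ≥ 0.375; clusters are connected components;
isolated nodes supported by a single model are dropped, isolated nodes
supported by several models stay as singleton clusters. Gene sets are
read from GMT files; the pipeline's `enrich` stage builds a small
synthetic collection from the truth ledger when no GMT is supplied, and
emits clusters only — functional labels are left to the analyst.

## Synthetic cohorts: what they emulate, and what they do not

Tumor volume grows as V(t) = min(cap, V0·e^(r·t)) with per-animal
lognormal jitter on r (sd 0.1 on the log scale — a free parameter, no
published per-animal variance to match); the cap (2000 mm³ ≈ 2 g at
unit density) mirrors a humane-endpoint size. Day-0 samples are drawn
before implantation, so their volume is 0. Treated sensitive arms decay
exponentially during the treatment window and regrow afterwards;
resistant arms grow through it. Each volume is also expressed as a
caliper (length, width) pair with length·width²/2 = V at a fixed aspect
ratio of 1.6. Defaults mirror the study structure the package targets:
5–12 animals per group, 4–6 bleeds including day 0, 12 hybridization
controls, 5 calibrators per plate, and a few hundred analytes (300 by
default — enough for the multiplicity structure without slowing tests;
configurable upward toward the platform's ~5000).

Responder amplitudes default to A = 2C and noise to σ_log = 0.05, a
high-signal regime in which the screen's planted-marker recovery is
exact and the volume model's holdout R² exceeds 0.8. Passing those tests
therefore demonstrates that the machinery is correct and leak-free — not
that real cohorts, with correlated analytes, drifting baselines,
cross-reactive reagents and biology that is not a clean saturating
curve, would yield the same operating characteristics. The generator
also does not model pharmacokinetics of the treatment, immune or
stromal compartments, or mouse-protein cross-reactivity of the
reagents.

## Degenerate inputs and tie-breaks

Flat data give F = 0, p = 1; zero-variance signals fail the Pearson
filter rather than erroring; a bin with fewer than 3 analytes is skipped
with a warning; a plate without calibrators, a missing hybridization
control, duplicate sample ids, and non-positive RFU are hard errors
naming the offender. Operating-point ties prefer the larger threshold;
enrichment clusters sort by size then name so output order is
deterministic. All randomness flows from a single integer seed; pipeline
stages derive their own seeds from it and the stage name, and identical
(config, seed) runs produce byte-identical artifacts.
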