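# Methods

`ctrval` implements the statistical machinery of a multi-reader validation
study for an automatic cardiothoracic-ratio (CTR) reader: geometric CTR
extraction from segmentation masks, agreement statistics against expert
radiologists, a probabilistic consensus reference for cardiomegaly,
pooled-reader non-inferiority testing, and the agreement-study sample-size
design. This note records the models, the numerical choices, and the
places where the design was genuinely open.

## CTR geometry from binary masks

On a posteroanterior chest radiograph the CTR is `(MLD + MRD) / GT`: the
maximum horizontal reach of the cardiac silhouette to the patient's left
(MLD) and right (MRD) of the body midline, over the greatest transverse
diameter of the thoracic cavity (GT). Given binary lung and heart masks on
a shared grid, `ctr_geometry` measures:

* **midline** — the column `floor((leftmost + rightmost)/2)` over the lung
  mask's foreground columns. Radiologists anchor the midline on the
  vertebral bodies, which lung/heart masks cannot supply; the lung-field
  midpoint is the deterministic convention available from the declared
  inputs. This is a documented convention difference, not an approximation
  claim.
* **MLD / MRD** — per-row signed distances from the midline to the heart's
  row-wise extreme columns, maximized independently over rows (the two
  maxima typically occur at different heights), each clamped at zero when
  the heart does not cross the midline.
* **GT** — from the global column range of the lung mask (not per-row),
  matching the "greatest transverse dimension" convention. Whether the
  commercial systems measure at the inner rib margin or the lung-field
  edge is unstated in the literature we target; we use the lung-field
  edge.

Widths are inclusive pixel counts; all connected components count as
foreground (a pneumothorax may split a lung field); ties in the
maximum-width row break to the topmost row. The implementation is
vectorized but is required by test to agree *exactly* with an exhaustive
per-pixel scan on random irregular masks.

## Bland–Altman agreement

Differences are `y − x` (comparison minus reference) on the absolute
scale, or `100·(y − x)/((x + y)/2)` percent on the relative scale (the
standard percentage convention; the denominator is the pair mean). Limits
of agreement are `mean ± 1.96·sd`. Parametric LOA confidence intervals
use the standard-error approximation

    se(LOA) = sd · sqrt(1/n + 1.96² / (2(n−1)))

with a t(n−1) quantile; a seeded case-resampling percentile bootstrap is
available (`ci_method="bootstrap"`). Coverage of the parametric interval
is verified by simulation to sit in the 93–97% band at n = 160.

Model-versus-experts pairing: the default pairs the model CTR with the
per-case mean of the four expert datasets (2 radiologists × 2 sessions),
one pair per case; a stacked mode (4 pairs per case) is available by flag.

## ICC(2,1) and the bootstrap ICC comparison

All ICCs are two-way random effects, absolute agreement, single measures
(ICC(2,1)), computed from the two-way ANOVA mean squares with the
McGraw–Wong F-based confidence interval (Satterthwaite denominator df).
The implementation is cross-checked against `pingouin.intraclass_corr`.
A constant ratings matrix is perfect agreement by convention (estimate 1,
degenerate CI, warning).

Constructions for the study's coefficients:

* intra-observer: per radiologist, session-1 vs session-2 columns;
* inter-observer (radiologists): session means per radiologist, two
  columns;
* model vs radiologists: the model column paired with each of the four
  expert datasets and stacked (4n × 2). This yields a single coefficient
  comparable to the radiologist–radiologist ICC; the construction behind
  published model-vs-readers ICCs is rarely stated, so this is a
  documented package convention.

Two ICCs are compared with a paired case bootstrap: each resample draws
cases with replacement and is applied to both matrices (for the stacked
matrix, all rows of a drawn case move together). The two-sided p-value is
`2·min(P(Δ* ≤ 0), P(Δ* ≥ 0))`, floored at `1/n_boot` so that 0 is never
reported. Cases are the exchangeable unit; 1000 resamples by default.

## Consensus reference standards

Cardiomegaly is CTR **strictly greater than** the cutoff (0.50 primary,
0.55 for "significant cardiomegaly"); a CTR exactly at the cutoff is
negative. Table-level reproducibility depends on this strictness, so it
is pinned by test.

The primary reference fuses the four expert label sets with the
two-class Dawid–Skene model fitted by EM: per-case posteriors of the
latent true label, a class prevalence, and one 2×2 row-stochastic
confusion matrix per annotation set, under conditional independence of
sets given the truth. Numerical choices:

* initialization from the per-case vote fraction (soft majority) — the
  standard choice; no random restarts, so the fit is deterministic;
* M-step Laplace smoothing of +1 pseudo-count per confusion cell and on
  the prevalence, preventing zero-probability lock-in with only four
  annotation sets; `smoothing=0` restores the classical unsmoothed
  estimator;
* convergence when the maximum posterior change falls below `tol = 1e-6`,
  capped at 100 iterations;
* a posterior of exactly 0.5 labels positive, favouring sensitivity in a
  screening context (configurable by construction: labels are
  `posterior >= 0.5`).

Treating the four datasets (2 radiologists × 2 sessions) as four
conditionally independent annotators ignores within-radiologist
correlation; this is the modelling simplification implied by using the
four sets as separate voters, and it is stated rather than corrected.

The sensitivity-analysis reference takes the per-case median of the four
CTR measurements (even count → mean of the two middle values) and
binarizes at the cutoff.

## Reader test and non-inferiority

Sensitivity, specificity, PPV, NPV and accuracy are computed from 2×2
counts with Wilson score intervals (Clopper–Pearson by flag). A measure
with a zero denominator is *undefined* (NaN plus a warning), never 0.
The five readers are pooled at the decision level (n_cases × n_readers
decisions against the per-case reference).

The non-inferiority comparison of `θ_model − θ_readers` uses a cluster
(case-level) bootstrap Wald test: resampling cases preserves the
model/reader pairing and the within-case correlation of pooled reader
decisions without parametric correlation assumptions. With margin δ = 0.10
(absolute percentage points) the hypotheses are H0: Δ ≤ −δ vs
H1: Δ > −δ, and

    p = P( Z ≤ −(Δ̂ + δ) / SE* ),

with SE* the bootstrap SD of Δ* (2000 resamples by default), declared
non-inferior at p < 0.025 one-sided. A percentile variant
(`method="percentile"`) reports the bootstrap mass at or below −δ. If the
metric is undefined in more than 20% of resamples the subgroup is too
degenerate and an `unstable-metric` error names it. Degenerate zero-SE
cases floor the p-value at `1/n_boot`.

Simulation places the test's type-I error at the boundary (Δ = −0.10,
n = 160, prevalence 0.5, reader sensitivity 0.978) in [0.01, 0.05]
against the nominal 0.025, and its power at Δ = 0 above 0.95.

The reference standard is built exclusively from the expert annotation
sets — never from the five readers or the model. The pipeline's
provenance log records the annotator ids that entered consensus so the
firewall is auditable, and a test perturbs reader/model data to confirm
the reference does not move.

## Agreement-study sample size

Design question: the smallest n such that, with probability ≥ 1 − β, the
two-sided (1 − α) confidence intervals of both 95% limits of agreement
fall inside the maximum allowed difference ±δ_max, for differences
N(μ_d, σ_d²). Since the sample mean and SD are independent
(d̄ ~ N(μ_d, σ_d²/n), s ~ σ_d·χ_{n−1}/√(n−1)), the containment
probability is computed exactly by Gauss–Legendre quadrature over the χ
density of s, with a seeded Monte-Carlo oracle as an independent
cross-check (the two agree to ±0.005 across the tested grid).

Two conventions for allocating the type II error across the two limits
are implemented and both reported:

* **per-limit** (default): each limit's CI contained with probability
  ≥ 1 − β/2. On the canonical inputs (μ_d = 0.00175, σ_d = 0.04108,
  δ_max = 0.15, α = β = 0.05) this yields **n = 23**, matching the
  sample sizes produced by the medical-statistics calculators in common
  use for this design.
* **joint**: both CIs contained simultaneously with probability ≥ 1 − β;
  one case smaller (n = 22) on the same inputs.

The returned minimum is floored at n = 3. If
δ_max ≤ |μ_d| + 1.96·σ_d the true limits already violate the allowed
band and no n achieves the goal; this raises `goal-unachievable` rather
than returning a huge n. On the α convention (whether it is the CI level
of the limits themselves or of their confidence bounds): the LOA
multiplier is fixed at 1.96 (95% limits) and α sets the two-sided level
of the bounds' CIs, which is the combination that reproduces the
canonical n.

## Synthetic study generator

The generator emulates the *structure* of a 160-case validation study so
every stage runs without patient data; it does not emulate radiograph
appearance, and passing tests say nothing about segmentation quality on
real images.

* **Population** — four pathology strata (normal, pneumothorax, pleural
  effusion, consolidation) of 40 cases; true CTR from a truncated normal
  with mean 0.522 and SD 0.095, truncated to (0.2, 0.9) to keep thorax
  geometry feasible. Each case carries a lognormal difficulty multiplier
  (log-SD 0.25, normalized to unit mean square): hard films are hard for
  every observer, concentrating disagreement in a few cases as in real
  reading studies without changing the average noise power.
* **Observers** — a measurement is
  `true + b_o + u_{o,s} + m(category)·d_i·e`. Observer offsets `b_o` are
  fixed calibration constants (experts ∓0.009; readers −0.008…+0.008;
  model +0.0074), not per-study draws: a case-level bootstrap cannot see
  study-level random offsets, so redrawing them each study would make the
  bootstrap p-values incompatible with their own sampling distribution.
  Per-measurement noise: experts and readers SD 0.012, model SD 0.0085,
  inflated ×1.3 (experts/readers) and ×2.0 (model) in the effusion and
  consolidation strata where fluid or airspace opacity obscures the
  relevant borders. Observed CTRs truncate to (0.1, 1.0); MLD/MRD/GT are
  back-filled consistently (fixed GT per case, ~60:40 left:right heart
  split with jitter).
  With this calibration the expected intra-observer ICC is ≈0.979, the
  radiologist inter-observer ICC ≈0.972, the model-vs-radiologists ICC
  ≈0.973, and the model-vs-experts MAE ≈0.012 with the
  effusion/consolidation strata roughly 1.8× noisier than
  normal/pneumothorax — the agreement structure the pipeline is designed
  to detect. A 60-study sweep under these defaults reproduced the
  stratum-MAE ordering in 93% of replicates and a non-significant ICC
  difference in 98%.
* **Masks** — two half-ellipse lung fields and an elliptical heart,
  rasterized so the analytic `(MLD+MRD)/GT` equals the requested CTR to
  within rounding (the heart-center row is snapped to an integer so one
  raster row realizes the full span). Pathology perturbations are
  stylized mechanisms reproducing the *direction* of real measurement
  biases, not anatomy: pneumothorax collapses one apex (GT unchanged),
  effusion truncates one base and can clip the lateral costophrenic
  extent (shrinking measured GT, hence inflating measured CTR),
  consolidation erodes blobs along the heart-adjacent border.
* **Label matrices** — drawn from explicit row-stochastic confusion
  matrices per annotation set, for consensus-recovery experiments.

All generators are deterministic given a seed; a master seed spawns
independent child streams per stage, and report files are byte-identical
across reruns.

## Problem sizes and runtimes

The default study is 160 cases (the published design), with 1000
bootstrap resamples for ICC comparisons and 2000 for non-inferiority
tests. Simulation-based checks use 200 replicates (ICC CI coverage,
n = 500 each), 1000 replicates (LOA CI coverage, n = 160), and 500
replicates per arm (non-inferiority operating characteristics); these
sizes put the binomial noise of the estimated rates well inside the
asserted bands. The full test suite runs in well under a minute on one
CPU.

## Known limitations

* The lung-field midline is a convention, not the vertebral midline a
  radiologist would use; absolute MLD/MRD values are therefore not
  comparable across conventions even when the CTR is.
* The Dawid–Skene fit treats repeated sessions of one radiologist as
  independent annotators.
* The non-inferiority test is asymptotic (bootstrap Wald); its type-I
  error is verified by simulation at the published design point, not
  proven in general, and percentile p-values are offered for small
  subgroups.
* The generator produces measurement *tables* whose agreement structure
  matches the published ranges; it does not model reader drift over
  time, correlated model/expert errors on the same case beyond shared
  difficulty, or prevalence shift.
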