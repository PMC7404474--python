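# Methods

This note documents the models, algorithms and numerical choices behind
`olivegrade`, and what its synthetic data can and cannot say about real
instruments.

## Signal model (synthetic_data)

A flash-GC sample is modelled as, per column,

    x(t) = b(t) + Σ_c  h_c · exp(−(t − τ(rt_c))² / 2σ_c²) + ε(t)

on a 10,000-point grid at dt = 0.01 s (100 s run), with

- baseline `b(t) = L + D·(t/T)² + W·sin(2πt/T)` (defaults L = 50, D = 8,
  W = 3 intensity units) — a gentle ramp plus curvature, small relative to
  peaks;
- 14 marker compounds spanning 8.5–92.5 s on the non-polar column, each
  with a Gaussian peak of σ = 0.25–0.45 s and height
  `h_c = concentration_c × response_factor_c`; ethanol (21.8 s), hexanal
  (55.6 s) and (E)-2-hexenal (62.0 s) sit at the retention times used for
  the standard-solution sensitivity check, and no compound elutes in the
  43–50 s blank window on either column (that window is the noise
  reference);
- per-sample concentrations drawn lognormal with grade-dependent means
  (C6 "green" markers high in EVOO; ethanol, ethyl acetate, acetic acid,
  octane, (E)-2-heptenal, 1-octen-3-ol rising from VOO to LOO) and CV
  0.50–0.65;
- a shared warp `τ(t) = t + δ + s·4u(1−u)`, `u = t/T`, with global shift
  δ ~ N(0, 0.06 s) and mid-run stretch s ~ N(0, 0.03 s), identical for both
  columns (this is what COW must undo);
- white detector noise ε ~ N(0, 5).

Grade spacing was calibrated once against the full pipeline so that binary
stage external accuracy lands in the realistic 70–95% band — the overlap of
adjacent grades is what produces borderline samples — and then frozen; the
concentrations are *not* measured chemistry, only a statistical stand-in
with the right difficulty. Consequences: passing tests demonstrate the
correctness and calibration behaviour of the *algorithms*, not field
performance on real oils. The generator also omits co-elution structure,
peak tailing, detector drift within a run, and correlated compound
chemistry (defect markers rise independently rather than along defect
axes).

QC machinery: a pooled QC sample is the arithmetic mean of three component
traces (equal-volume ideal mixing) plus fresh noise. Intra-day replicates
apply a global lognormal amplification (CV 0.05) and small injection jitter
(0.02 s); inter-day replicates add a larger global day factor (CV 0.06), a
smooth retention-dependent multiplicative gain field (CV 0.08, six-term
Fourier basis — different chromatogram regions drift differently across
days) and larger jitter (0.05 s). These values are calibrated so the
intra-day run passes the intra-day acceptance rules with margin while the
inter-day run fails them but passes the (weaker) inter-day rules — i.e. the
generator reproduces the qualitative verdict structure of a real
validation campaign — and are frozen. With only seven replicates the
realized day-to-day spread is itself noisy (the sample SD of the global day
factor has ~29% relative error at six degrees of freedom), so the inter-day
verdict can flip from seed to seed near the threshold — exactly as a real
seven-replicate campaign can; the intra-day verdict has wide margin and is
stable.

Randomness: every generator takes a seed; datasets derive per-sample
streams as `default_rng([seed, index])` so any single sample is
reproducible in isolation.

## COW alignment (preprocess)

The reference (the sample with the highest mean raw-trace correlation to
all others — a medoid; chosen over all samples because the calibration
split itself is computed on aligned data) is divided into segments of
`segment_length` = 100 points (1 s). For each segment, candidate source
segments of length 100 ± `slack` (= 15) points are linearly interpolated to
the reference segment length and scored by Pearson correlation; a dynamic
program over boundary positions maximizes the summed correlation with both
ends pinned. Ties resolve toward the smallest source position. Degenerate
segments: a segment whose variance is below 10⁻¹⁴ of its raw sum of squares
(i.e. coefficient of variation ≲ 10⁻⁷) contributes correlation 0 — this
relative rule also guards the one-pass variance against catastrophic
cancellation; computed correlations are clamped to [−1, 1].

`band` (default 40 points = 0.4 s in the pipeline) optionally bounds each
boundary's absolute displacement. It is purely a performance device for
10,000-point traces — an order of magnitude above the generator's jitter
scale — and `band=None` gives the textbook unbounded search, which is what
the exhaustive-enumeration equivalence tests exercise. The inner loop is
compiled with numba; a full trace aligns in well under 0.1 s.

Known limitation: COW is not exactly idempotent. A second pass on an
aligned signal can recover residual piecewise-linear interpolation error,
mostly in the end segments where pinning forbids a clean shift; the test
suite asserts the true properties (no objective loss, re-warp within a few
points of identity) rather than exact idempotence.

## Fingerprints, signal region, autoscaling

The two aligned traces are concatenated after trimming 50 trailing points
per column (19,900 points for a full run; the trim is configurable). Per
instrument column, the retained region is the contiguous run between the
first and last point where the cross-sample maximum of baseline-subtracted
intensity exceeds k = 10 × the blank-window noise SD of the reference
(baseline per sample = median of its own blank window). k = 10 sits well
above the S/N = 3 detection bar, so retained points carry real signal.
Autoscaling (mean 0 / SD 1, n−1 denominator) is fit on calibration rows
only and applied everywhere; zero-variance columns are centered, left
undivided and flagged. Fitting scaling on the full matrix would leak
external-set statistics into the model, so the split-aware order is
enforced by the API.

## Validation protocol (validate)

RSD% is computed per retained point across aligned, **raw** (never
autoscaled — the RSD of a mean-centered variable is undefined; the
autoscaling step in the published-style processing order is read as
belonging to the classification branch, and a config switch for any other
convention is deliberately not provided) QC replicates, with points whose
replicate mean falls below the noise floor (blank baseline + k·σ, the same
rule as region selection) excluded. Bands follow the standard reporting
layout (≤10, 10–15, 15–20, then decades to 100, plus an overflow band so
counts always conserve). Acceptance: intra-day >90% below 15% and >95%
below 20%; inter-day >85% / >90%; identical replicates yield exactly 0
(enforced against floating-point dust). The Horwitz-style check is a trend
test — Spearman ρ(log mean intensity, RSD%) < 0 with p < 0.05 — because in
fingerprint mode no concentration scale exists for the numeric Horwitz
curve; the classical curve `RSD% = 2^(1−0.5·log10 C)` is available for
plots only and never gated on.

S/N: S is the baseline-subtracted apex of a lightly smoothed trace (boxcar
of ~σ/2, so white noise cannot masquerade as a peak on a blank injection)
within ±3σ of the compound's retention time; N is the mean absolute
baseline-subtracted intensity in the 43–50 s window; pass requires S/N > 3
strictly.

## PLS-DA (plsda)

NIPALS PLS1 on autoscaled X and a centered {0,1} dummy: per component,
w ∝ Xᵀy, t = Xw, p = Xᵀt/tᵀt, q = yᵀt/tᵀt, deflate X and y; the regression
vector accumulates through R = W(PᵀW)⁻¹ computed incrementally, so cost per
component is O(n·p) and nothing p×p is ever formed. At n_lv = rank(X) the
fit reproduces OLS (tested against `lstsq` and cross-checked against
scikit-learn's PLSRegression); requesting more components than the data
support raises an error naming the achievable maximum.

Threshold: Gaussians are fitted to each class's calibration ŷ and the
decision value solves π₀N(y; μ₀, σ₀) = π₁N(y; μ₁, σ₁) (quadratic; the root
between the class means is taken, the midpoint with a warning if none
exists; with equal priors and SDs this is exactly the midpoint). Priors
default to equal — matching a fixed 0.5 probability threshold —
with class-frequency priors available. Posterior probabilities come from
the same two-Gaussian model, computed in log space and clipped to
[10⁻¹², 1−10⁻¹²] (never certain).

Model selection: venetian blinds (fold f = index mod n_blinds over
calibration manifest order, default 10 folds) with scaling, fit and
threshold re-estimated inside every fold; all candidate LV counts are
scored from one incremental NIPALS pass per fold; the count minimizing CV
misclassification wins, ties to fewer. `max_lv` defaults to 20, capped at
min(n − n_blinds, 50) and by the rank available in every fold. Note the
rule tracks the empirical minimum: on structureless data the selected count
is whatever the noise minimum happens to be, which is why the parsimony
tie-break is verified on exact-tie (separable) instances.

Kennard–Stone split: greedy max–min Euclidean selection of the 75%
calibration subset starting from the mutually most distant pair, ties to
the smallest index, |external| = round(0.25·n) half-up; deterministic, run
on the unscaled region-selected matrix.

## Cascades and evaluation (cascade)

S1 = EVOO vs no-EVOO then VOO vs LOO; S2 = LOO vs no-LOO then VOO vs EVOO.
Stage 1 trains on all calibration samples (one-vs-rest relabeling), stage 2
only on the calibration samples of its pair; LV counts are selected
independently per stage. Prediction routes stage-1 negatives to stage 2;
each sample gets exactly one grade and the deciding stage's assigned-class
posterior (no probability chaining across stages). Evaluation:
cross-validation tables come from per-fold refits (scaling and threshold
re-fit per fold, LV count fixed — so CV denominators equal the calibration
counts); external tables from the untouched 25%; stage-2 tables condition
on true pair membership. ROC sweeps the unique decision scores (ties
grouped into one step) with trapezoid AUC, which equals the normalized
Mann–Whitney U statistic; AUC is invariant to whether scores or posterior
probabilities are swept, so scores are used. Integer percentages round
half-up in the printed style; raw fractions are also emitted. Triage lists
external samples whose assigned-class probability falls below the chosen
level (default 0.5; at level 1.0 every sample is triaged because
probabilities are clipped below 1).

## Problem sizes and determinism

The default study conditions are 333 samples (123 EVOO / 129 VOO / 81 LOO),
10,000 points per column, 75/25 split, 10 CV folds. The acceptance suite
runs this full size over ten seeds for the classification-recovery check;
the chance-level (zero effect size) check uses 120-sample datasets over two
seeds, which already bounds accuracy within a few percent of 50%; the
byte-identical determinism check uses a 44-sample run, since determinism is
size-independent. The acceptance script reports a single full-size study
per seed. All pipeline randomness flows from one seed; reports serialize
with sorted keys and shortest-round-trip floats, so a fixed seed reproduces
byte-identical JSON.
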