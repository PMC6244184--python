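# Methods

## Scope and model

`lipidqc` processes targeted extracted-ion chromatograms (EICs) from a
QC-bracketed, multi-batch LC-MS lipidomics acquisition into a final
samples × lipids peak-height matrix. The observation model behind both the
simulator and the correction is multiplicative:

    height(s, i) = conc(s, lipid(i)) · response(i) · drift_b(i)(x_s) · ε(s, i)

for sample s at injection order x_s in batch b, ion i, with lognormal
measurement noise ε and a smooth per-(ion, batch) drift curve. Retention
times are distorted per sample by a quadratic map t_obs = a·t_e² + b·t_e + c
with b near 1. Chromatographic peaks are Gaussian on a constant baseline
with Gaussian point noise, clipped at zero.

## Mass arithmetic

Atomic monoisotopic masses (C, H, N, O, P, S, Na) are hard-coded from the
IUPAC values to nine decimals for bit-exact reproducibility across
platforms. Adduct m/z values include the electron mass (subtracted for
cations, added for anions); without that correction the conventional
reference values for ammoniated TG(58:8) (948.8015 Th) and protonated
purine (121.0509 Th) are not reproduced at 4-decimal display precision.
Display rounding is half-even to 4 decimals; full precision is used
internally. Only singly charged adducts ([M+H]+, [M+NH4]+, [M+Na]+,
[M−H]−, [M+OAc]−) are supported — the lipid classes in scope need nothing
else. Triacylglycerol shorthand TG(n:d) maps to C(n+3) H(2n+2−2d) O6.

## Synthetic acquisition design

The generator emulates a four-batch cohort acquisition: study samples are
shuffled, chunked into blocks of `qc_interval` (default 10), and each block
is closed by one pooled-QC injection; one blank follows per
`blank_interval` study samples, immediately after the block's QC (so every
blank has a preceding QC for the carryover check). Batches are built from
whole blocks, so batch study counts are multiples of the QC interval and no
QC block straddles a batch boundary; a partial final block still receives a
closing QC. Replicate pairs re-inject a randomly chosen study sample under
a linked id and share its true concentrations exactly.

Generator defaults (the study conditions every stochastic test runs under):

| parameter | default | meaning |
|---|---|---|
| drift_amplitude | 0.20 | peak fractional within-batch drift |
| drift_shape | linear | drift curve in injection order (quadratic available) |
| batch_scale_sigma | 0.15 | lognormal σ of the constant per-(ion, batch) response factor |
| noise_cv | 0.08 | lognormal measurement CV per (sample, ion) |
| biological_cv | 0.35 | lognormal spread of study-sample lipid levels |
| rt_quad_sd / rt_slope_sd / rt_shift_sd | 3e-5 / 1e-3 / 0.008 | sd of the per-sample quadratic RT coefficients (a, b−1, c) |
| peak_width_sd | 0.02 min | chromatographic Gaussian σ |
| baseline_level / baseline_noise | 50 / 5 counts | EIC baseline and its point noise |
| carryover_fraction | 0.02 | blank peak as a fraction of the preceding QC |
| rt_grid_step | 0.005 min | EIC sampling (≈ 2 spectra/s) |

Drift is multiplicative because the correction divides by a fitted response
curve; an additive drift model would not be removed by a ratio. The default
drift shape is linear in injection order so that the local-linear LOESS
model class nests the truth: noise-free runs are then corrected to
numerical zero QC RSD, which turns "the correction works" into an exact,
testable property rather than an approximation. The quadratic shape is
available for stress tests. RT distortion is quadratic because the
recalibration model is quadratic — exact recovery is again a testable
property. Typical per-sample RT shifts under the default coefficient sds
are a few hundredths of a minute, comfortably inside the 0.20-min
standard-search window.

All randomness flows from one master seed through named substreams (plan,
database, concentrations, responses, drift, retention times, noise,
baseline), so each stage is independently reproducible and the whole
pipeline is byte-deterministic under a fixed seed.

**What the generator does not emulate:** real lipid class structure in the
concentration covariance (lipids are independent), missing peaks and
detector saturation, isotope envelopes and profile-mode m/z, co-eluting
isobars, non-Gaussian peak shapes (tailing), and a QC pool offset from the
study-sample centroid — the QC pool sits at each lipid's mean level, so the
PCA overview shows a tight QC cluster inside the study cloud rather than a
separated one. Passing tests therefore demonstrate correctness of the
algorithms under the stated noise model, not robustness to every real-data
pathology.

## Extraction

Internal-standard apexes are grid argmaxima within expected RT ± 0.10 min
(ties to the earliest point; apexes on a window boundary are used but
flagged — silently excluding them would bias the fit). The apex location is
refined by a three-point parabolic interpolation in log intensity after
subtracting the trace median as a baseline estimate; for a Gaussian peak
this is exact, and it removes the half-grid-step quantization that would
otherwise dominate the recalibration residuals. Peak heights are *not*
refined: the reported height is the raw grid maximum, and no smoothing or
integration is applied anywhere.

The recalibration is one quadratic per sample fitted to the standards of
both polarities jointly (the simulator draws one distortion per injection;
a two-instrument acquisition would fit per polarity). The fit requires ≥ 3
usable standards and ≥ 3 distinct expected RTs; otherwise the sample falls
back to the identity calibration, flagged. Blanks carry no spiked standards
and always use the identity map. The two windows are distinct by design:
± 1.0 min of EIC context for the noise median, 0.20 min total for the peak
search, interpreted as calibrated RT ± 0.10 min (a 10.167-min target is
searched in 10.067–10.267, displayed floored to 10.06–10.26). Missing
measurements are explicit NaN markers — zero is a legitimate intensity.

## Normalization

LOESS is local-linear with tricube weights over the `ceil(span·n)` (≥ 3)
nearest neighbours; predictions beyond the QC order range clamp to the
boundary fit. Local-linear degree was chosen over local-constant for
unbiasedness at the batch edges with the ~5–20 QCs a batch provides, and
over local-quadratic for variance. The span grid is 0.3–1.0 in steps of
0.1; leave-one-out CV selects the span, with ties (within floating-point
jitter) resolved toward the smoothest span so exact fits never chase noise.

The correction is `corrected = (raw / pred) · anchor` with
`anchor = median_QC(raw) / median_QC(raw / pred)`, which preserves the
within-batch QC median exactly — the re-anchored form of dividing by the
prediction and rescaling to the batch QC median. Fallbacks (fewer than 4
usable QCs, non-positive QC values or predictions) leave the batch
unchanged and are recorded in the audit table, as are chosen spans, pre/post
QC RSDs and correction-factor ranges. Median normalization then scales each
batch so its per-ion QC median equals the pooled QC median; ions with a
non-positive batch median are left unscaled and flagged. Blanks pass
through every stage untouched. The k-fold CV RSD deals QCs (ordered by
injection) into interleaved folds, refits drift and median anchors on the
training QCs only, corrects the held-out QCs and reports the RSD of the
pooled held-out values; k equal to the QC count gives leave-one-out.
Whether the original workflow anchored its median step on QC or all-sample
medians is ambiguous; QC medians were chosen as consistent with the
QC-anchored design.

## Filtering

QC RSDs for selection are computed on the normalized matrix (selection
happens after normalization in the processing order). RSD ties break by
mode (positive first), then adduct label, then ion id — any deterministic
rule works; this one is stable across runs. "More than 25% RSD" is strict:
a 25.0% ion is retained. The ρ ≥ 0.80 cross-mode concordance flag is
reporting-only. Internal standards are removed from the final matrix
regardless of RSD: they are calibration devices, not analytes. Lipids whose
members all have undefined RSD (zero QC mean or < 2 QC values) are dropped
and logged.

## Validation suite

Replicate t-tests run on log10 heights because the noise model is
multiplicative (log differences are approximately normal); no
multiple-testing correction is applied since the summary of interest is the
descriptive fraction of non-significant ions. PCA uses log10, column-
centered, unscaled data (autoscaling would equalize ion variances and hide
the intensity structure); non-positive cells are floored at half the
smallest positive value before the log, and a constant matrix reports zero
variance rather than erroring. Carryover is the baseline-subtracted total
ion signal of each blank over that of its preceding QC, flagged above 5% by
default. Fold change is max/min of two positive group means with a
direction label.

## Problem sizes

The default verification run is 4 batches × 200 study samples (20 QCs, 20
blanks, 20 replicate pairs) against a 30-lipid / 65-ion database on a
0.005-min grid — large enough for 5 QCs per batch (the minimum for LOO span
selection) and stable RSD estimates, small enough that the full suite and
the end-to-end examples run in well under a minute each. The t-test
calibration check uses 500 ions × 20 pairs simulated at the matrix level.

## Known limitations

- The per-sample recalibration assumes the standards' distortion
  generalizes to all targets; systematic, compound-specific RT shifts are
  out of model.
- With only 4 usable QCs in a batch the span is fixed at 1.0; with fewer,
  drift in that batch is not corrected (audited, not imputed).
- The Spearman concordance and duplicate t-tests require complete pairs;
  no imputation is attempted.
- Counts of lipids surviving filtering depend on the synthetic database
  composition; the pipeline reports its own audited counts.
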