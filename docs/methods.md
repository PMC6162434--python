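# Methods

## Two-site exchange simulator

Dynamic HP ¹³C acquisitions are modeled as unidirectional two-pool
exchange with longitudinal relaxation:

    dP/dt = u(t) − (kPL + R1P)·P
    dL/dt = kPL·P − R1L·L

with P, L the longitudinal magnetization of pyruvate and lactate. Back-flux
(lactate → pyruvate) is omitted: the analysis quantifies only forward
conversion, and at physiological lactate pool sizes the apparent reverse
rate is not identifiable from these acquisitions. No vascular/perfusion
compartment is modeled, and there is no k-space, B₀/B₁ or spectral-spatial
RF simulation — the simulator produces the tumor-ROI signal curves the
analysis consumes, nothing upstream of them.

Parameters (units, defaults, rationale):

| parameter | default | meaning |
|---|---|---|
| `kpl` | 0.02 s⁻¹ | apparent pyruvate→lactate conversion rate; mid-range for glycolytic tumors, and the value at which the simulated lactate peak lags pyruvate by ~3 s |
| `r1p`, `r1l` | 1/25 s⁻¹ | longitudinal relaxation; a typical [1-¹³C]pyruvate T₁ of ~25 s at high field |
| `input_start`, `input_duration` | 0 s, 13 s | rectangular venous bolus; 13 s is the mid-range of a 12–14 s tail-vein injection |
| `input_amplitude` | 1 a.u./s | arbitrary magnetization scale (all conversion metrics are scale invariant) |

The bolus is rectangular rather than gamma-variate: the conversion metric
is an AUC ratio and is insensitive to the input's exact shape, and a
rectangle makes the piecewise-analytic checks exact.

**Sampling.** Acquisition uses 20 time points, TR 3 s, first excitation
6 s after injection start. Lactate is excited at a constant 90°, so each
time point reads the lactate formed during the preceding TR. Pyruvate uses
a variable-flip-angle (VFA) schedule; the default is the constant-signal
progression θₙ = arctan(1/√(N−n)) (12.92° → 90° for N = 20), which
equalizes per-pulse transverse signal for a non-replenished pool. The
acquisition protocol being emulated states only a 3–90° range, so the
schedule is configurable (`scheme="custom"`) and the arctan default is a
documented choice, not a claim about the original schedule. Excitations
are instantaneous: signal = M_z·sin θ, then M_z ← M_z·cos θ.

**Integration.** Adaptive RK45 (`scipy.integrate.solve_ivp`,
rtol 10⁻⁸/atol 10⁻¹²) between RF events, with integration segments split
at the bolus edges so the input discontinuity never sits inside a solver
step. Against the closed-form impulse solution the trajectories agree to
better than 10⁻⁶ relative; with relaxation off, total magnetization after
bolus completion is conserved to ~10⁻⁸ relative.

**Noise.** Optional Rician corruption (magnitude MRI):
S ← √((S+n₁)² + n₂²), n᷈ ~ N(0, σ²). Tests default to noiseless.

## Flip-angle correction

Per time point, M̂ₙ = Sₙ/sin θₙ; for a VFA channel this is additionally
divided by Π_{m<n} cos θₘ to undo the magnetization spent by earlier
pulses (skipped for the constant-90° lactate channel, where cos 90° = 0
makes it singular and each sample is newly formed magnetization anyway).
Both conventions (cumulative and sin-only) are implemented; cumulative is
the default for pyruvate.

A caveat the tests make explicit: cumulative-cos compensation
reconstructs the RF-free trajectory exactly only while no new
magnetization is flowing in. With the default bolus (0–13 s) overlapping
the sampling window (from 6 s), magnetization that arrives *after* early
pulses gets divided by cos factors it never experienced, biasing the
corrected curve high by up to ~3% at late time points. The round-trip
test therefore uses a bolus that completes before the first excitation,
where the identity is exact; under the default overlap the corrected
curve is still the standard estimator, just not an unbiased one. The AUC
ratio inherits a small, deterministic, kPL-monotone bias that cancels in
the cohort generator because it inverts the full
simulate-correct-measure map rather than an idealized formula.

## Conversion metrics

`Lac_AUC = Σₙ lacₙ·TR` (rectangle rule — with uniform sampling and 90°
lactate sampling each point already represents one TR of accumulation;
the trapezoid alternative differs only in endpoint weights and is
available). `Pyr_max` is the maximum of the *corrected* pyruvate curve;
correction precedes the max because the raw VFA pyruvate curve peaks
wherever sin θ, not magnetization, is largest. The ratio has units of
seconds; `nLac = ratio × mean tumor ¹H ADC` is an exact product. Pyruvate
signal duration is operationalized as FWHM of the corrected curve with
linear interpolation at half maximum (boundary-clipped when the curve is
truncated). ROI handling averages voxel signals before metric computation
(mean-then-metric).

## ADC fitting

`S(b) = S₀·e^(−b·ADC)` by nonlinear least squares initialized from the
log-linear OLS solution (default), or pure log-linear. Neither b-set
contains b = 0, so S₀ is always a fitted parameter. Negative fitted ADCs
(noise) clamp to 0 with a `clipped` flag — enforcing physical
non-negativity and keeping ROI means free of sign cancellation. Fits are
permutation invariant in b (the interleaved ¹³C ordering is metadata, not
mathematics). Voxelwise maps are fit-then-average inside the mask
(map-then-mean) for both nuclei; a mean-then-fit ROI path is provided for
low-SNR ¹³C use. Noiseless recovery is exact to ≥9 significant digits
over ADC ∈ [10⁻⁵, 3×10⁻³] mm²/s; the nonlinear loss matches a dense
grid-search oracle within 10⁻¹⁰.

## Histology

**Cellularity.** 8-bit RGB → Beer–Lambert optical density → projection on
the hematoxylin vector of the standard H&E deconvolution basis
(`skimage.color.rgb2hed`) → Gaussian smoothing (σ = 1 px) → global Otsu →
distance-transform watershed with seeds at distance maxima ≥ d_min/2
apart → objects with equivalent diameter outside 8–30 px discarded.
Cellularity is labeled pixels as % of *total image* pixels (the metric's
verbatim definition), not of tissue area. Diameter-filtered labels are
renumbered directly; relabeling by connectivity would re-merge de-clumped
touching objects. Physical pixel size (0.15 µm at 40×) is carried as
configuration only; the pipeline operates in pixel units.

**MCT4 / DAB.** RGB → HSV in [0,1]³; stained = hue ∈ [0, 0.169] AND
saturation ∈ [0.189, 1.0] AND value in the lower tail V ≤ P₁₆(V over
tissue pixels), computed per image to absorb illumination differences.
"Within the 16th percentile" is read as the lower tail because DAB is
dark; the absolute-band alternative (V ∈ [0, 0.16]) is available via
configuration. Tissue = pixels with S > 0.05 or V < 0.95 (excludes bare
slide). The hue window does not wrap through red (configurable). Output
is stained pixels as % of tissue area; multi-region sampling averages
per-region percentages. Note the percentile rule imposes a ceiling: the
detected fraction cannot exceed ~16% of tissue, so quantification is
meaningful only below that — all emulated group means (≤ 9.87%) are.

## Phantoms and what they establish

H&E phantoms place random non-overlapping (touching allowed) ellipses,
diameters 8–30 px, rendered through the same stain basis the analysis
inverts, over a uniform eosin background with per-nucleus chromatin
texture. DAB phantoms place in-window brown blobs (hue 0.055–0.105,
S 0.40–0.70, V 0.31–0.41) on jittered pink tissue (hue ≈ 0.93,
V 0.66–0.90) inside a white border; stain V sits strictly below tissue V
so the percentile rule is exercised away from its ceiling. Both
generators stop when the achieved fraction — an exact pixel count of the
emitted mask, recorded as the ground truth — is within 0.5 points of
target, and raise if packing stalls.

These phantoms validate the *computational* chain (deconvolution,
thresholding, de-clumping, bookkeeping), recovering nuclear fractions
over 5–40% and stain fractions over 2–12% with mean absolute error below
1 point. They do not emulate chromatin texture variation, stain
batch-to-batch variability, out-of-focus blur, folds or necrosis, so
passing them bounds algorithmic error, not biological robustness.

## Statistics

One-way fixed-effects ANOVA (F with k−1, N−k df; zero within-group
variance raises rather than returning an undefined F — except inside the
pipeline driver, where degenerate noiseless cohorts report NaN and skip
the post-hocs). Post-hoc: all pairwise two-sided t tests on the pooled
within-group mean square with N−k df, consistent with ANOVA's
homoscedasticity assumption (Welch per-pair available). The pairwise
family per metric is controlled by the BKY two-stage step-up at q = 0.05,
implemented from the published definition (stage 1: BH at q/(1+q); m̂₀ =
m − r₁; stage 2: BH at q·m/m̂₀; r₁ = 0 → reject none, r₁ = m → reject
all) and cross-checked against an independent implementation. Pearson r
with two-sided t-based p (n−2 df). Summaries are mean ± SD/√n.

## Cohort generator

Per subject, ground-truth nLac, lactate/pyruvate ADC, cellularity % and
MCT4 % are drawn from group normals truncated at 0 (SD reconstructed from
reported SEM as SD = SEM·√n). The tumor ¹H ADC is not an
independent draw: ADC₁H = 1.35×10⁻³ − 0.0357×10⁻³·(cellularity − 16) +
N(0, 0.14×10⁻³) mm²/s, floored at 0.4×10⁻³ — anchored so a
16%-cellularity tumor averages 1.35×10⁻³ and a 23% tumor ≈ 1.10×10⁻³,
with scatter sized to give a cellularity–ADC correlation near −0.7,
matching the inverse relation the metric normalization relies on. The
conversion target ratio = nLac/ADC₁H is mapped to a kPL by Brent
inversion of the monotone simulate→correct→measure composition (bracket
[0, 0.5] s⁻¹, xtol 10⁻⁷), so noiseless analysis of the synthesized raw
data recovers the drawn nLac by construction — that closure is what the
end-to-end tests check. Default cohort: three groups of n = 8/7/8
emulating a high-conversion, high-MCT4, low-cellularity line against two
lower-conversion lines.

## Problem sizes and determinism

Default validation sizes: 1024² histology phantoms for single-image
recovery, 256² and 8×8 diffusion grids inside cohort runs, n = 8 per
cohort group, 10⁴-replicate Monte-Carlo for ANOVA calibration and
3000-replicate Rician-bias checks — each chosen as the smallest size at
which the quantity under test is statistically stable. All randomness
flows through `numpy.random.default_rng` seeds carried in the specs;
identical spec + seed reproduces outputs bit for bit, and pipeline CSVs
embed the seed and a configuration hash so reruns can be verified byte
for byte.

## Known limitations

* The exchange model has no vascular compartment and a rectangular input;
  absolute kPL values are therefore simulator-relative even though the
  AUC-ratio metric is robust to this.
* Cumulative flip-angle correction is biased during bolus inflow (above).
* The VFA schedule of the emulated protocol is not known beyond its 3–90°
  range; the arctan default is one member of that family.
* The MCT4 percentile rule saturates at 16% of tissue.
* Group statistics assume homoscedastic normal groups; no nonparametric
  fallback is provided.
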