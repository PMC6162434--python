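# hpcmri

Quantitative analysis of hyperpolarized (HP) ¹³C pyruvate MRI in orthotopic
renal-cell-carcinoma (RCC) models — with a synthetic-data module that makes
the whole pipeline verifiable against known ground truth.

## The problem

Localized renal tumors are hard to risk-stratify non-invasively. Aggressive
RCCs are strongly glycolytic: they convert pyruvate to lactate (via LDHA)
and export the lactate (via the MCT4 transporter). Dynamic HP ¹³C pyruvate
MRI can watch this conversion happen in vivo, and diffusion-weighted ¹³C
MRI can probe where the lactate sits (intra- vs extracellular). This
package implements the full measurement chain used to quantify those
effects in mouse models bearing human RCC lines (A-498, UOK262, 786-O),
for imaging scientists who want a tested, reusable reference
implementation:

* **dynamics** — flip-angle correction of dynamic ¹³C series and the
  conversion metric
  `Lac_AUC / Pyr_max` (lactate area-under-the-curve over maximal corrected
  pyruvate signal), normalized by the tumor ¹H ADC to adjust for
  cellularity: `nLac = (Lac_AUC / Pyr_max) × ADC_1H`.
* **diffusion** — mono-exponential ADC estimation,
  `S_b / S_0 = e^(−b·ADC)`, fitted voxelwise for ¹H
  (b = 25, 180, 323, 508 s/mm²) and HP ¹³C pyruvate/lactate
  (interleaved b = 50, 300, 600, 1500, 1000, 2000 s/mm²), with ROI means.
* **histo** — cellularity from H&E sections (hematoxylin color
  deconvolution → Otsu → watershed de-clumping → % image area covered by
  nuclei) and % MCT4 staining from DAB IHC (HSV thresholding: hue ∈
  [0, 0.169], saturation ∈ [0.189, 1.0], value within the per-image 16th
  percentile, as % of tissue area).
* **group_stats** — one-way ANOVA with pooled-t post-hoc tests under
  Benjamini–Krieger–Yekutieli two-stage step-up FDR control (q = 0.05),
  Pearson correlation, mean ± SEM summaries.
* **simulate / phantoms / cohort** — generators for every input: a
  unidirectional two-site exchange model (dP/dt = input − (kPL+R1P)·P,
  dL/dt = kPL·P − R1L·L) sampled by a variable-flip-angle pulse train,
  mono-exponential diffusion phantoms with Rician noise, H&E/DAB histology
  phantoms with exact ground-truth masks, and multi-subject cohorts whose
  drawn metrics the pipeline provably recovers.

Estimator-style components (`MonoExponentialADC`, `FlipAngleCorrector`,
`NucleiSegmenter`, `Mct4Quantifier`) follow scikit-learn conventions
(`fit`/`predict`/`transform`, `get_params`); module-level functions wrap
them for script use.

## Worked example

```python
from hpcmri import (
    ExchangeParams, make_vfa_schedule, simulate_hp_dynamics,
    flip_angle_correct, conversion_metrics, normalize_by_adc,
    DiffusionPhantomSpec, simulate_diffusion_signal, fit_monoexp_adc,
)
from hpcmri.simulate import B_VALUES_C13

schedule = make_vfa_schedule()            # 20 pts, TR 3 s, arctan VFA, start 6 s
series = simulate_hp_dynamics(ExchangeParams(kpl=0.02), schedule)
metrics = conversion_metrics(flip_angle_correct(series))
print(f"Lac_AUC/Pyr_max = {metrics.ratio:.3f} s")
print(f"pyruvate peak at {metrics.pyr_peak_time:.0f} s, lactate peak at {metrics.lac_peak_time:.0f} s")
print(f"nLac = {normalize_by_adc(metrics.ratio, 1.35e-3):.3e}")

sig = simulate_diffusion_signal(DiffusionPhantomSpec(adc_true=0.495e-3, b_values=B_VALUES_C13))
fit = fit_monoexp_adc(B_VALUES_C13, sig)
print(f"fitted lactate ADC = {fit.adc_hat*1e3:.3f} x 10^-3 mm^2/s (R^2 = {fit.r_squared:.4f})")
```

prints

```
Lac_AUC/Pyr_max = 1.152 s
pyruvate peak at 12 s, lactate peak at 15 s
nLac = 1.556e-03
fitted lactate ADC = 0.495 x 10^-3 mm^2/s (R^2 = 1.0000)
```

i.e. at kPL = 0.02 s⁻¹ the simulated pyruvate peaks 12 s after injection
and lactate 3 s later; the conversion ratio times a typical low-cellularity
tumor ¹H ADC gives the normalized conversion; and a noiseless diffusion
decay generated at 0.495×10⁻³ mm²/s is recovered exactly by the
mono-exponential fit.

A command-line interface mirrors the stages
(`hpcmri simulate|analyze-dynamics|analyze-diffusion|analyze-histo|stats|run`),
reading/writing NIfTI + JSON sidecars, PNG/TIFF and CSV; `hpcmri run`
executes the whole chain and writes per-subject tables, group summaries
and a text report.

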