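# visoct — visible-light OCT parafoveal oximetry

`visoct` implements a complete analysis chain for measuring hemoglobin
oxygen saturation (sO₂) in small parafoveal retinal vessels from
visible-light optical coherence tomography (VIS-OCT) volumes, together
with a fully ground-truthed synthetic phantom that stands in for patient
scans. It is aimed at researchers developing or validating spectroscopic
OCT oximetry pipelines: every stage — spectral reconstruction, retinal
layer segmentation, sub-band spectrum extraction, Beer–Lambert
inversion, vessel morphometry and cohort statistics — is a tested,
importable module.

## The measurement

Visible light is absorbed strongly enough by hemoglobin that the
reflectance spectrum at the *bottom* of a vessel encodes the oxygen
saturation of the blood the light traversed twice. The model fitted to
each vessel is

```
I(sO₂ | λ, z) = I₀(λ) R₀ · A λ^{-α} · exp(-[sO₂·μ_HbO₂(λ) + (1-sO₂)·μ_Hb(λ)] · z)
```

where `A λ^{-α}` is a power-law vessel-wall reflectance, `μ = μ_a + W·μ_s`
(W = 0.2) is the whole-blood attenuation per hemoglobin species, and `z`
is the round-trip optical path through blood. After normalization by the
averaged spectrum of non-vascular nerve-fiber layer (RNFL), `I₀R₀` drops
out and the three free parameters (sO₂ ∈ [0,1], A > 0, α) are estimated
by bounded least squares on log-intensity.

The pipeline around the fit follows a clinical VIS-OCT protocol:

1. **recon** — DC removal, Hann apodization, FFT per A-line; a short-time
   Fourier transform with 11 Gaussian windows swept across the spectrum
   yields the 4-D sub-band intensity I(x, y, z, λ).
2. **layers** — RPE detected as the blurred per-A-line intensity maximum
   (σ = 7), repaired by iterative third-order polynomial fitting with
   mean ± 1.8·SD outlier deletion; failed B-scans screened by the
   coefficient of variation of the fitted curves; retina flattened; ILM
   found by the maximum axial gradient; en-face image from a 20-px band
   above the RPE; vessel mask by adaptive thresholding.
3. **oximetry** — per-vessel ROI averaging with ILM flattening, RNFL
   normalization, vessel-bottom detection as the second reflective peak
   below the ILM, spectrum extraction 5 px above / 10 px below the
   bottom, least-squares sO₂ inversion (`OximetryModel.fit()` →
   `OximetryResults` with standard errors and a `summary()` table).
4. **vesseltopo** — centerline length, mask area, axial diameter and
   min/max distance to the fovea per segment.
5. **stats_report** — Pearson correlations with t-based p-values,
   unpaired t-tests, and per-eye / per-segment summary tables.
6. **phantom** — synthesizes spectral interferograms of a layered retina
   (ILM, diffuse scatter band, RPE) with vessels of 20–40 µm caliber,
   Beer–Lambert attenuated bottom reflections, vessel shadows, shot
   noise, corrupted B-scans and saturated glint artifacts — with every
   ground-truth quantity recorded for validation.

## Worked example

```python
import numpy as np
from visoct import OximetryModel, load_default_extinction, model_spectrum

table = load_default_extinction()
lam = np.linspace(525, 595, 11)           # sub-band centers, nm
z = 0.05                                  # round-trip blood path, mm

# a noiseless spectrum generated at arterial saturation, then inverted
spectrum = model_spectrum(0.921, 1.0, 1.0, z, table, lam)
result = OximetryModel(spectrum, lam, z, table).fit()
print(result.summary())
```

```
Beer-Lambert vessel oximetry fit
============================================
n sub-bands     : 11
z path (mm)     : 0.0500
sO2 (vol %)     :    92.10  (SE 0.00, 95% CI [92.10, 92.10])
A_refl          :          1
alpha           :    1.000  (SE 0.000)
residual norm   : 3.859e-08
converged       : True
```

The fitted saturation (92.10 vol %) recovers the generating value
exactly; on noisy or phantom-extracted spectra the standard error and
confidence interval become informative.

The full pipeline runs from the command line:

```sh
visoct run --seed 11 --out out/          # phantom → tables, ~12 s
```

which writes `segments.csv` (per-vessel sO₂, diameter, length, area,
fovea distances), `segment_summary.csv` (arteriole vs venule comparison
with t-test p-values), surface maps and en-face images. On the default
two-vessel phantom the recovered saturations land within ~1 vol % of
the buried truths. Each stage (`phantom`, `segment`, `oximetry`,
`topo`, `report`) is also runnable alone on saved intermediates.

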