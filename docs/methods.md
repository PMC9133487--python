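# Methods

This note documents the models, the synthetic data, the numerical
choices and the limitations of `visoct`, in enough detail to judge what
a passing test suite does and does not demonstrate about real data.

## 1. Spectroscopic model and inversion

The vessel-bottom reflectance after RNFL normalization is modelled as

    I(sO₂ | λ, z) = A λ^(-α) · exp(-[sO₂·μ_HbO₂(λ) + (1-sO₂)·μ_Hb(λ)] z)

with λ in nm and the blood path z in mm. `μ = μ_a + W·μ_s` per
hemoglobin species, with the scattering scale `W = 0.2` — scattering by
red cells attenuates the ballistic beam only partially, and 0.2 is the
conventional weighting for whole blood in the visible band. The path
convention is `z = 2 × lumen diameter` (round trip through blood to the
back wall); forward and inverse use the same convention, so saturation
recovery is convention-independent, but absolute `z` matters on real
data and is exposed everywhere as a parameter.

The fit minimizes squared *log*-intensity residuals: the exponential
attenuation becomes linear, the power law becomes linear in log λ, and
multiplicative noise becomes approximately additive. Parameters and
bounds: sO₂ ∈ [0, 1], log A ∈ [-30, 30], α ∈ [-4, 4]; `scipy`'s
trust-region-reflective bounded least squares, restarted from
sO₂ ∈ {0.25, 0.5, 0.75} (the problem is benign, but restarts make
boundary solutions robust), ties broken by lower residual then lower
sO₂. The fit is fully deterministic. Standard errors come from the
Gauss–Newton covariance `σ² (JᵀJ)⁻¹` in log space; they are indicative
only when the solution is interior to the bounds.

### Spectral instrument response

A sub-band value is *not* a point sample of the reflectance spectrum:
it is the magnitude of a Gaussian-windowed Fourier transform of the
reflectance-weighted fringes, box-averaged around the depth peak. Where
μ(λ) has steep structure (the oxyhemoglobin edge near 585–600 nm), the
window average differs from the center-wavelength sample by up to ~10%,
enough to bias sO₂ by several vol %. Fitting a plain Gaussian-in-λ
average of the model over-corrects, because the transform magnitude is
not a linear λ-average. `SubbandResponse` therefore simulates the
actual operator — synthesize a single-reflector fringe for the candidate
reflectance, window, transform, box-average — and the fit runs the model
through it. `set_baseline(reference)` additionally carries the measured
RNFL reference through the operator, cancelling the second-order bias
from source/RNFL coloring varying *within* a window (~+2.4 vol %
otherwise). With both, phantom-level recovery is within ~0.6 vol %
noiseless. Pure model-generated spectra (no windows) are fitted without
a response, and recover exactly.

## 2. Hemoglobin coefficients

`data/hb_extinction_synthetic.csv` holds whole-blood μ_a and μ_s per
species, 450–650 nm at 1 nm. It is a **synthetic reconstruction**:
pchip interpolation of hand-set anchors reproducing the landmark
features of standard compilations (HbO₂ α/β bands at 577/542 nm, the
single deoxy band near 556 nm, isosbestic-like crossings near 500, 525,
548, 571 and 587 nm, strong deoxy excess beyond 600 nm) at magnitudes
appropriate for ~150 g/L hemoglobin. It is *not* metrologically
traceable; since the phantom and the inversion share the table, all
recovery results are exact by construction, but absolute saturations on
real data would inherit the table's errors. Replace via
`ExtinctionTable.from_csv` for quantitative work.

## 3. Reconstruction

Fringes are sampled in linear k; a reflector at depth pixel `d`
contributes `R(λ_n)·cos(2π d n/N)`. Full-band reconstruction: per-A-line
mean subtraction (DC), Hann apodization, FFT magnitude, positive-depth
half (N/2 pixels; index 0 = zero delay, 0-based throughout). The Hann
window is standard spectral shaping: without it the rectangular-window
sinc sidelobes of the bright RPE dominate weak structures several pixels
away, and their subpixel-phase dependence imprints artificial texture on
the en-face projection.

The STFT uses Gaussian windows equally spaced in k, inset by half a
window at both ends; default FWHM is one eighth of the source support
(10 nm on the default 520–600 nm band), giving ~50% overlap and an
axial PSF of σ ≈ 3 px. The spectral/axial widths trade off as
σ_λ·σ_z ≈ span/2π; both choices are exposed.

## 4. Layer segmentation

* RPE: per-B-scan 2-D Gaussian blur (σ = 7 px) then per-A-line argmax.
  All-zero A-lines are flagged missing, never assigned a depth.
* Per-B-scan repair: iterate {fit cubic to inliers → delete residuals
  outside mean ± 1.8·SD → refit} until no new outlier or `max_iter`;
  statistics are recomputed over current inliers each round; deleted
  points take fitted values. A numerical floor on the residual SD
  (10⁻⁸ of the data scale) keeps exact fits from flagging float noise.
  Fewer than `poly_order + 2` inliers is an error naming the B-scan.
* Across B-scans: the coefficient of variation (SD/mean) of each fitted
  curve is screened once with the same mean ± 1.8·SD rule; flagged
  curves are replaced by the previous valid one (the next valid one at
  the volume start). The screen is deliberately *not* iterated:
  iterating cascades on smooth anatomical depth variation and discards
  healthy B-scans, while a single pass reliably isolates saturated
  frames.
* Flattening: integer circular shifts to a common RPE row (exactly
  invertible); ILM as the maximum axial gradient of the lightly
  smoothed (σ = 1) profile above the flattened RPE row. Gradient-edge
  detection carries a systematic ≈ -1 px offset on discrete bright
  interfaces; it cancels in all ILM-relative quantities (bottom depth,
  diameter).
* En face: mean over the half-open band [RPE-20, RPE-guard) with a
  3-px guard keeping the RPE peak's own PSF shoulder (whose strength
  swings with subpixel surface position) out of the average; rows of
  COV-flagged B-scans are replaced by their nearest valid row before
  thresholding.
* Vessel mask: a pixel is vessel when it falls below its local mean
  (block ≈ image width / 8) by more than 0.30 × the median brightness —
  a robust offset that saturated B-scans cannot distort; objects under
  10 px are removed as unresolvable children vessels.

## 5. Vessel spectra, bottom detection, morphometry

ROI A-lines are flattened to the detected ILM (integer shifts) and
averaged per sub-band; A-lines whose ILM deviates > 4 px from the ROI
median are dropped as misdetections (glint artifacts). The RNFL
normalization spectrum is measured over non-vascular A-lines in the
band [ILM-5, ILM+10) — the *same* depth box as the vessel-bottom
extraction, so the per-window PSF capture fraction (different for
edge-truncated windows) cancels exactly — aggregated by median for
robustness.

The vessel bottom is the second reflective peak below the ILM: peaks of
the lightly smoothed wavelength-averaged profile, excluding a 3-px ILM
guard and anything deeper than 48 px (parafoveal lumina stay under
40 µm, so deeper peaks are outer retina, not vessel); the deepest
qualifying peak is returned, which equals the "second peak" even when
the weak top reflection degenerates into a shoulder. No qualifying peak
⇒ the vessel is excluded, mirroring clinical practice. The bottom
spectrum is the column mean over rows [bottom-5, bottom+10), clipped at
edges without error.

Morphometry: centerline length along the longest skeleton geodesic
(8-connected, steps 1 or √2 px; branch ties broken by scan order); area
as pixel count × pitch²; axial diameter as the top-to-bottom peak
separation with parabolic subpixel refinement × axial pitch (the
lateral mask width is only a diagnostic); fovea distances as min/max
Euclidean distance from the (manually annotated or phantom-truth) fovea
to mask pixel centers.

## 6. Cohort statistics

Pearson r with the two-sided p from `t = r√((n-2)/(1-r²))` against
t(n-2); two-sample t-tests pooled by default (Welch by flag);
significance at p < 0.05 with *no* multiple-testing correction — the
report footer states this. Per-eye arteriovenous difference is computed
per eye, never as a difference of group means.

The module embeds a published baseline cohort's per-eye correlation
table (21 (r, p) pairs over 7 covariates × 3 saturation columns, 16
eyes) as reference data for a consistency validation. A data-forensics
note: the cylinder row's printed p-values are inconsistent with n = 16
(off by up to 0.055) but reproduce to within 0.002 at n = 13 — three
eyes evidently lacked a refraction cylinder measurement — so the
validator carries per-covariate effective sample sizes.

## 7. The phantom: what it emulates and what it does not

Emulated: linear-k spectral fringes of a layered retina (ILM with a
power-law RNFL reflectance over a Gaussian or flat source; a diffuse
24-layer scatter band from mid inner retina to just above the RPE; a
bright RPE); vessels of 20–40 µm caliber between ILM and RPE with a
circular lumen, a weak top-wall reflection, a Beer–Lambert attenuated
back-wall reflection and wavelength-dependent shadowing of everything
beneath; relative shot noise; saturated-noise corrupt B-scans; and
saturated superficial glints (~40 × RPE brightness, drawn at rate/30
per pixel so the configured rate approximates the fraction of corrupted
A-lines after the σ = 7 blur spreads each glint over ~30 columns).
Every quantity is recorded in `PhantomTruth`.

Deliberate simplifications, and their consequences for what the tests
show: fringes carry no dispersion and no k-resampling error (the
real-spectrometer path is a pass-through hook); the DC term is
spectrally flat so scalar mean subtraction removes it exactly; there is
no eye motion, no choroid, and no speckle beyond optional multiplicative
noise; interfaces are sharp (a physically diffuse axial extent would
suppress exactly the high-k fringes sub-band spectroscopy reads, so
peak widths come from the PSF instead); at desk-scale grids vessels are
rasterized with a 1-px minimum lateral half-width (a 25 µm vessel is
sub-pixel at 39 µm lateral pitch) while the axial geometry — what
oximetry and diameter actually measure — is exact. Passing tests
therefore demonstrate the *algorithm chain*, not robustness to motion,
speckle decorrelation or spectrometer miscalibration.

Key defaults: grid 64 × 128 × 512 px (device raster 512 × 256 over
5 × 5 mm reachable by config); source support 520–600 nm; axial pitch
1.5 µm/px — typical VIS-OCT axial sampling, and necessary so the fixed
5-px-above extraction window clears the vessel top: at 3 µm/px an 8-px
lumen puts the top's PSF tail inside the window and biases sO₂ low by
~10 vol % (the diameter measurement is unaffected, and the diameter
validation deliberately runs at 3.1 µm/px where 8 px × 3.1 µm = 24.8 µm).
Vessel clearance below the ILM defaults to 8 px so the top remains a
resolvable peak. Reflectivities (ILM 0.5, RPE 1.0, wall 0.25, back-wall
2.0 pre-attenuation, scatter 0.015) were chosen once so that every
detection the chain relies on — RPE argmax, ILM gradient, en-face
shadow contrast, top/bottom peaks — is realistic-looking and
unambiguous in the noiseless limit.

## 8. Problem sizes and determinism

The test suite generates phantoms at 16–48 B-scans × 32–256 A-lines ×
256 spectral samples; the end-to-end pipeline check uses the full
default 64 × 128 × 1024 grid (≈ 12 s). All randomness flows through
`numpy.random.default_rng(seed)` with seeds fixed in configs; identical
config + seed reproduces volumes bit-exactly and pipeline CSVs
byte-exactly. The Monte-Carlo noise study (200 fits at 3% multiplicative
spectrum noise per endpoint) and the grid-search cross-check (sO₂ step
0.001, amplitude and exponent profiled out linearly) each run in a few
seconds.

## 9. Known limitations

* Absolute sO₂ accuracy on real data depends on the extinction table,
  the path-length convention and the unmodelled pigment/media spectra;
  the package validates the *pipeline*, not the absolute calibration.
* The mean ± 1.8·SD outlier rule has a breakdown point: a cluster of
  coherent outliers covering ≳ 20% of a B-scan can drag the cubic fit
  (especially near edges) instead of being deleted; such frames are the
  COV screen's job, and genuinely ambiguous frames can occasionally
  evade both.
* sO₂ in vessels whose lumen spans ≲ 10 axial px is biased by
  top-reflection contamination of the fixed extraction window; use
  finer axial sampling or a narrower above-window.
* The skeleton length follows the pixel geodesic, not a smoothed
  centerline; for very tortuous vessels it underestimates slightly.
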