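"""Beer-Lambert inversion of sub-band vessel spectra for oxygen saturation.

The reflectance spectrum extracted at the bottom of a retinal vessel is
modelled as

    I(sO2 | lambda, z) = A * lambda**(-alpha)
                         * exp(-[sO2*mu_HbO2(lambda) + (1-sO2)*mu_Hb(lambda)] * z)

after normalization by a non-vascular nerve-fiber-layer (RNFL) reference
spectrum, which cancels the source spectrum and system response (the
source and reference-arm terms are assumed unity post-normalization).
``A * lambda**(-alpha)`` is a power-law model of the vessel-wall
reflectance; ``mu = mu_a + W*mu_s`` is the whole-blood attenuation
coefficient per hemoglobin species with the scattering term scaled by
``W = 0.2``; ``z`` is the optical path through blood in mm.

The only free parameters are the saturation ``sO2`` (a fraction, reported
in vol % = 100 x fraction), the amplitude ``A`` and the scattering
exponent ``alpha``.  The fit is a bounded least squares on log-intensity,
which linearizes the exponent and makes the problem numerically benign.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize, signal

__all__ = [
    "ExtinctionTable",
    "DepthSpectrum",
    "OximetryFit",
    "OximetryModel",
    "OximetryResults",
    "SubbandResponse",
    "load_default_extinction",
    "model_spectrum",
    "extract_roi_spectra",
    "normalize_by_rnfl",
    "measure_rnfl_reference",
    "find_vessel_bottom",
    "extract_bottom_spectrum",
    "fit_so2",
]

DEFAULT_W = 0.2
ALPHA_BOUNDS = (-4.0, 4.0)
_LOG_A_BOUNDS = (-30.0, 30.0)


@dataclass
class ExtinctionTable:
    """Whole-blood absorption and scattering coefficients vs wavelength.

    All coefficients in mm^-1 on a wavelength grid in nm.  The effective
    attenuation per species is ``mu = mu_a + W * mu_s`` with the
    scattering scale ``W`` defaulting to 0.2.  Interpolation is linear in
    wavelength.
    """

    lambda_nm: np.ndarray
    mu_a_hbo2: np.ndarray
    mu_a_hb: np.ndarray
    mu_s_hbo2: np.ndarray
    mu_s_hb: np.ndarray
    W: float = DEFAULT_W

    def __post_init__(self):
        for name in ("lambda_nm", "mu_a_hbo2", "mu_a_hb", "mu_s_hbo2", "mu_s_hb"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if np.any(np.diff(self.lambda_nm) <= 0):
            raise ValueError("lambda_nm grid must be strictly increasing")
        for name in ("mu_a_hbo2", "mu_a_hb", "mu_s_hbo2", "mu_s_hb"):
            if np.any(getattr(self, name) < 0):
                raise ValueError(f"{name} must be non-negative")

    def _check_cover(self, lam):
        lam = np.asarray(lam, dtype=float)
        if lam.min() < self.lambda_nm[0] or lam.max() > self.lambda_nm[-1]:
            raise ValueError(
                f"wavelengths [{lam.min():.1f}, {lam.max():.1f}] nm outside the "
                f"tabulated range [{self.lambda_nm[0]:.0f}, {self.lambda_nm[-1]:.0f}] nm"
            )
        return lam

    def mu_hbo2(self, lam) -> np.ndarray:
        """Effective attenuation of fully oxygenated blood, mm^-1."""
        lam = self._check_cover(lam)
        return np.interp(lam, self.lambda_nm, self.mu_a_hbo2) + self.W * np.interp(
            lam, self.lambda_nm, self.mu_s_hbo2
        )

    def mu_hb(self, lam) -> np.ndarray:
        """Effective attenuation of fully deoxygenated blood, mm^-1."""
        lam = self._check_cover(lam)
        return np.interp(lam, self.lambda_nm, self.mu_a_hb) + self.W * np.interp(
            lam, self.lambda_nm, self.mu_s_hb
        )

    def mu(self, so2: float, lam) -> np.ndarray:
        """Attenuation of blood at saturation ``so2`` (linear mixture)."""
        return so2 * self.mu_hbo2(lam) + (1.0 - so2) * self.mu_hb(lam)

    @classmethod
    def from_csv(cls, path, W: float = DEFAULT_W) -> "ExtinctionTable":
        import pandas as pd

        data = pd.read_csv(path, comment="#")
        return cls(
            lambda_nm=data["lambda_nm"],
            mu_a_hbo2=data["mu_a_hbo2"],
            mu_a_hb=data["mu_a_hb"],
            mu_s_hbo2=data["mu_s_hbo2"],
            mu_s_hb=data["mu_s_hb"],
            W=W,
        )


def load_default_extinction(W: float = DEFAULT_W) -> ExtinctionTable:
    """Load the packaged hemoglobin extinction table (450-650 nm, 1 nm).

    The packaged table is a synthetic reconstruction of standard
    whole-blood Hb/HbO2 compilations (see the CSV header for details);
    magnitudes are realistic but not metrologically traceable.
    """
    ref = importlib.resources.files("visoct.data") / "hb_extinction_synthetic.csv"
    with importlib.resources.as_file(ref) as path:
        return ExtinctionTable.from_csv(path, W=W)


def model_spectrum(
    so2: float,
    A_refl: float,
    alpha: float,
    z_path_mm: float,
    table: ExtinctionTable,
    lambda_centers,
) -> np.ndarray:
    """Forward model of the normalized vessel-bottom spectrum.

    ``A_refl * lambda**(-alpha) * exp(-mu(so2, lambda) * z)`` with
    wavelengths in nm and ``z`` in mm.  The source spectrum and
    reference-arm reflectance are unity after RNFL normalization.
    """
    if not 0.0 <= so2 <= 1.0:
        raise ValueError("so2 must be a fraction in [0, 1]")
    if z_path_mm <= 0:
        raise ValueError("z_path_mm must be positive")
    lam = np.asarray(lambda_centers, dtype=float)
    return A_refl * lam ** (-alpha) * np.exp(-table.mu(so2, lam) * z_path_mm)


# ---------------------------------------------------------------------------
# ROI spectrum extraction
# ---------------------------------------------------------------------------


@dataclass
class DepthSpectrum:
    """Depth-resolved spectrum of one vessel ROI, ILM-flattened.

    ``I_z_lambda`` has one row per depth pixel (row 0 = ILM) and one
    column per spectral sub-band.  ``mean_aline`` is the wavelength
    average, used for peak (vessel top/bottom) detection.
    """

    I_z_lambda: np.ndarray
    lambda_centers: np.ndarray
    bottom_idx: int | None = None
    z_path_mm: float | None = None
    mean_aline: np.ndarray = field(default=None)

    def __post_init__(self):
        self.I_z_lambda = np.asarray(self.I_z_lambda, dtype=float)
        self.lambda_centers = np.asarray(self.lambda_centers, dtype=float)
        if self.I_z_lambda.ndim != 2:
            raise ValueError("I_z_lambda must be (depth, n_subbands)")
        if self.I_z_lambda.shape[1] != self.lambda_centers.size:
            raise ValueError("one column per sub-band center required")
        if self.mean_aline is None:
            self.mean_aline = self.I_z_lambda.mean(axis=1)
        if self.bottom_idx is not None and not (
            0 <= self.bottom_idx < self.I_z_lambda.shape[0]
        ):
            raise ValueError("bottom_idx outside the depth range")

    @property
    def n_depth(self) -> int:
        return self.I_z_lambda.shape[0]


def extract_roi_spectra(stack, roi_mask, ilm, max_ilm_dev_px: float = 4.0) -> DepthSpectrum:
    """Average all A-lines of a vessel ROI after flattening to the ILM.

    Each masked A-line of every sub-band volume is shifted so its ILM
    depth lands on row 0, then all A-lines are averaged; the wavelength
    average of the result is stored as ``mean_aline``.  A-lines whose
    ILM depth deviates from the ROI median by more than
    ``max_ilm_dev_px`` are dropped as misdetections (bright spike
    artifacts derail the gradient search on isolated A-lines); they
    would otherwise smear the averaged peaks.
    """
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if not roi_mask.any():
        raise ValueError("ROI mask is empty")
    ilm = np.asarray(ilm, dtype=float)
    if roi_mask.shape != ilm.shape or roi_mask.shape != stack.subbands.shape[1:3]:
        raise ValueError("mask / ILM / volume lateral shapes disagree")
    if not np.all(np.isfinite(ilm[roi_mask])):
        raise ValueError("ILM undefined under the ROI mask")

    xs, ys = np.nonzero(roi_mask)
    med = np.median(ilm[xs, ys])
    keep = np.abs(ilm[xs, ys] - med) <= max_ilm_dev_px
    if keep.any():
        xs, ys = xs[keep], ys[keep]
    shifts = np.rint(ilm[xs, ys]).astype(int)
    n_depth = stack.subbands.shape[-1]
    length = n_depth - shifts.max()
    if length < 2:
        raise ValueError("ILM too deep: no depth samples left after flattening")
    acc = np.zeros((length, stack.n_windows), dtype=float)
    for x, y, s in zip(xs, ys, shifts):
        acc += stack.subbands[:, x, y, s : s + length].T
    acc /= xs.size
    return DepthSpectrum(I_z_lambda=acc, lambda_centers=stack.lambda_centers)


def normalize_by_rnfl(ds: DepthSpectrum, ref) -> DepthSpectrum:
    """Divide each sub-band column by the RNFL reference spectrum.

    ``ref`` is the averaged non-vascular RNFL spectrum sampled at the
    sub-band centers (one value per column).
    """
    ref = np.asarray(ref, dtype=float)
    if ref.shape != (ds.I_z_lambda.shape[1],):
        raise ValueError("reference must have one value per sub-band")
    if np.any(ref <= 0):
        raise ValueError("reference spectrum must be strictly positive")
    return DepthSpectrum(
        I_z_lambda=ds.I_z_lambda / ref[None, :],
        lambda_centers=ds.lambda_centers,
        bottom_idx=ds.bottom_idx,
        z_path_mm=ds.z_path_mm,
    )


def measure_rnfl_reference(
    stack, ilm, exclude_mask=None, above: int = 5, below: int = 10
) -> np.ndarray:
    """Measure the RNFL normalization spectrum from the volume itself.

    Averages each sub-band over a band around the ILM/RNFL reflection
    (rows ``[ilm-above, ilm+below)``) across all non-vascular A-lines.
    The band deliberately matches the vessel-bottom extraction window:
    using the same depth box on both makes the per-window axial-PSF
    capture fraction (which differs between edge-truncated and mid-band
    spectral windows) cancel exactly in the normalization, along with
    the source spectrum and window gains.
    """
    ilm = np.asarray(ilm, dtype=float)
    keep = np.isfinite(ilm)
    if exclude_mask is not None:
        keep &= ~np.asarray(exclude_mask, dtype=bool)
    if not keep.any():
        raise ValueError("no non-vascular A-lines available for the reference")
    xs, ys = np.nonzero(keep)
    n_depth = stack.subbands.shape[-1]
    vals = np.empty((xs.size, stack.n_windows), dtype=float)
    for j, (x, y) in enumerate(zip(xs, ys)):
        z0 = max(int(round(ilm[x, y])) - above, 0)
        z1 = min(int(round(ilm[x, y])) + below, n_depth)
        vals[j] = stack.subbands[:, x, y, z0:z1].mean(axis=-1)
    # median across A-lines: robust to spike artifacts and saturated
    # (corrupt) B-scans that survive the exclusion mask
    ref = np.median(vals, axis=0)
    if np.any(ref <= 0):
        raise ValueError("measured reference spectrum is not strictly positive")
    return ref


def find_vessel_bottom(
    ds: DepthSpectrum,
    smooth_sigma: float = 1.0,
    prominence_frac: float = 0.015,
    ilm_guard_px: int = 3,
    max_depth_px: int = 48,
) -> int:
    """Locate the vessel bottom as the second reflective peak below the ILM.

    Peaks are detected on the lightly smoothed wavelength-averaged
    profile.  The ILM complex occupies the first few rows (row 0 plus a
    small guard band absorbing the +/- 1 px ILM-detection jitter) and is
    not a candidate.  The search is restricted to the anatomically
    plausible vessel band ``(ilm_guard_px, max_depth_px]`` — parafoveal
    lumina stay under 40 um, so deeper peaks (outer retina, RPE) cannot
    be a vessel bottom — and the deepest qualifying peak is returned:
    the top and bottom reflections are the only peaks in that band, so
    this is the second reflective peak even when the weaker top
    reflection degenerates into a shoulder of the ILM complex.  No
    qualifying peak means the bottom cannot be identified and the vessel
    should be excluded.
    """
    prof = ndimage.gaussian_filter1d(ds.mean_aline.astype(float), smooth_sigma)
    prom = prominence_frac * float(prof.max()) if prof.max() > 0 else None
    peaks, _ = signal.find_peaks(prof, prominence=prom)
    peaks = peaks[(peaks > ilm_guard_px) & (peaks <= max_depth_px)]
    if peaks.size < 1 or (peaks.size < 2 and peaks[0] <= ilm_guard_px + 2):
        raise ValueError("vessel bottom not found (no reflective peak in the vessel band)")
    return int(peaks[-1])


def extract_bottom_spectrum(
    ds: DepthSpectrum, bottom_idx: int, above: int = 5, below: int = 10
) -> np.ndarray:
    """Average the depth-spectrum rows around the vessel bottom.

    The window is the half-open row range ``[bottom-above, bottom+below)``,
    clipped at the matrix edges without error.
    """
    lo = max(bottom_idx - above, 0)
    hi = min(bottom_idx + below, ds.n_depth)
    if hi <= lo:
        raise ValueError("extraction window is empty")
    return ds.I_z_lambda[lo:hi].mean(axis=0)


# ---------------------------------------------------------------------------
# Least-squares inversion
# ---------------------------------------------------------------------------


@dataclass
class OximetryFit:
    """Result of one Beer-Lambert saturation fit."""

    so2: float
    A_refl: float
    alpha: float
    residual_norm: float
    success: bool

    @property
    def so2_volpct(self) -> float:
        """Saturation in vol % (fraction x 100)."""
        return 100.0 * self.so2


class SubbandResponse:
    """Spectral instrument response of the sub-band extraction chain.

    A sub-band value is not a point sample of the reflectance spectrum:
    it is the magnitude of a Gaussian-windowed Fourier transform of the
    reflectance-weighted fringes, box-averaged around the peak.  This
    operator reproduces that chain for a single reflector — synthesize
    the fringe for a candidate reflectance spectrum, window it exactly
    as the reconstruction does, transform, and box-average — and
    normalizes by the response to a flat reflector (which is what RNFL
    normalization does to first order).  Fitting through it removes the
    bias that steep hemoglobin absorption edges otherwise incur.
    """

    def __init__(
        self,
        lambda_range_nm,
        n_spectral: int = 1024,
        n_windows: int = 11,
        fwhm_nm: float | None = None,
        box_above: int = 5,
        box_below: int = 10,
        depth_px: float | None = None,
    ):
        from .recon import gaussian_window_grid, spectral_axes

        self.lambda_range_nm = tuple(lambda_range_nm)
        span = abs(self.lambda_range_nm[1] - self.lambda_range_nm[0])
        self.fwhm_nm = span / 8.0 if fwhm_nm is None else float(fwhm_nm)
        _, self.lambda_axis = spectral_axes(self.lambda_range_nm, n_spectral)
        fwhm_samples = self.fwhm_nm / span * n_spectral
        centers, self.windows = gaussian_window_grid(
            n_spectral, n_windows, fwhm_samples
        )
        lam_c = np.interp(centers, np.arange(n_spectral), self.lambda_axis)
        self.order = np.argsort(lam_c)
        self.lambda_centers = lam_c[self.order]
        n = n_spectral
        z0 = (n // 4) + 0.37 if depth_px is None else depth_px
        self._phase = np.cos(2.0 * np.pi * z0 * np.arange(n) / n)
        lo = int(round(z0)) - box_above
        hi = int(round(z0)) + box_below
        self._box = slice(max(lo, 0), min(hi, n // 2))
        self._baseline = np.ones(n)
        self._flat = self._apply(self._baseline)

    def _apply(self, R: np.ndarray) -> np.ndarray:
        fr = R * self._phase
        fr = fr - fr.mean()
        spec = np.fft.rfft(self.windows * fr[None, :], axis=-1)
        n_depth = self._phase.size // 2
        out = np.abs(spec[:, :n_depth])[:, self._box].mean(axis=-1)
        return out[self.order]

    def set_baseline(self, reference) -> "SubbandResponse":
        """Use a measured RNFL reference as the spectral baseline.

        The source spectrum and RNFL coloring vary *within* each window,
        so dividing the data by the reference does not cancel them
        exactly; interpolating the measured reference onto the spectral
        axis and carrying it through the operator (numerator and
        denominator alike) removes this second-order bias.
        """
        ref = np.asarray(reference, dtype=float)
        if ref.shape != self.lambda_centers.shape or np.any(ref <= 0):
            raise ValueError("reference must be one positive value per sub-band")
        self._baseline = np.interp(self.lambda_axis, self.lambda_centers, ref)
        self._flat = self._apply(self._baseline)
        return self

    def __call__(self, R_lambda) -> np.ndarray:
        """Sub-band spectrum of reflectance ``R(lambda)``, baseline-normalized."""
        R = np.asarray(R_lambda(self.lambda_axis), dtype=float)
        return self._apply(self._baseline * R) / self._flat


def _make_log_model(lam, z, table, response: "SubbandResponse | None"):
    """Log forward model, optionally through the instrument response."""
    if response is None:
        log_lam = np.log(lam)
        mu_hb = table.mu_hb(lam)
        dmu = table.mu_hbo2(lam) - mu_hb

        def log_model(so2, log_A, alpha):
            return log_A - alpha * log_lam - z * (mu_hb + so2 * dmu)

        return log_model

    lam_ax = response.lambda_axis
    log_lam_ax = np.log(lam_ax)
    mu_hb = table.mu_hb(lam_ax)
    dmu = table.mu_hbo2(lam_ax) - mu_hb

    base = response._baseline

    def log_model(so2, log_A, alpha):
        R = np.exp(log_A - alpha * log_lam_ax - z * (mu_hb + so2 * dmu))
        return np.log(response._apply(base * R) / response._flat)

    return log_model


def fit_so2(
    spectrum,
    lambda_centers,
    z_path_mm: float,
    table: ExtinctionTable,
    starts=(0.25, 0.5, 0.75),
    response: SubbandResponse | None = None,
) -> OximetryFit:
    """Bounded least-squares inversion of the vessel-bottom spectrum.

    Minimizes the squared log-intensity residual over
    ``sO2 in [0, 1]``, ``A > 0`` (parametrized as log A) and
    ``alpha in [-4, 4]``, restarting from several initial saturations and
    keeping the solution with the lowest residual (ties broken by lower
    sO2).  Deterministic: no randomness is involved.  When the spectrum
    comes from finite-width spectral windows, pass the matching
    :class:`SubbandResponse` so the model carries the same spectral
    instrument response.
    """
    spectrum = np.asarray(spectrum, dtype=float)
    lam = np.asarray(lambda_centers, dtype=float)
    if spectrum.shape != lam.shape:
        raise ValueError("spectrum and lambda_centers must have equal length")
    if np.any(spectrum <= 0) or not np.all(np.isfinite(spectrum)):
        raise ValueError("spectrum must be strictly positive and finite")
    if z_path_mm <= 0:
        raise ValueError("z_path_mm must be positive")

    log_I = np.log(spectrum)
    log_lam = np.log(lam)
    log_model = _make_log_model(lam, z_path_mm, table, response)

    def residual(params):
        return log_model(*params) - log_I

    lower = [0.0, _LOG_A_BOUNDS[0], ALPHA_BOUNDS[0]]
    upper = [1.0, _LOG_A_BOUNDS[1], ALPHA_BOUNDS[1]]
    best = None
    for s0 in starts:
        x0 = np.clip([s0, float(np.mean(log_I + log_lam)), 1.0], lower, upper)
        sol = optimize.least_squares(
            residual, x0, bounds=(lower, upper), method="trf"
        )
        key = (round(float(sol.cost), 12), round(float(sol.x[0]), 9))
        if best is None or key < best[0]:
            best = (key, sol)
    sol = best[1]
    so2, log_A, alpha = sol.x
    return OximetryFit(
        so2=float(so2),
        A_refl=float(np.exp(log_A)),
        alpha=float(alpha),
        residual_norm=float(np.linalg.norm(sol.fun)),
        success=bool(sol.success),
    )


class OximetryModel:
    """Beer-Lambert saturation model for one extracted vessel spectrum.

    Parameters
    ----------
    spectrum : array-like
        Normalized vessel-bottom spectrum, one positive value per
        sub-band.
    lambda_centers : array-like
        Sub-band center wavelengths in nm.
    z_path_mm : float
        Optical path through blood (round trip), mm.
    table : ExtinctionTable, optional
        Defaults to the packaged extinction table.

    Examples
    --------
    >>> table = load_default_extinction()
    >>> lam = np.linspace(525, 595, 11)
    >>> y = model_spectrum(0.9, 1.0, 1.0, 0.05, table, lam)
    >>> res = OximetryModel(y, lam, 0.05, table).fit()
    >>> round(res.so2_volpct, 1)
    90.0
    """

    def __init__(self, spectrum, lambda_centers, z_path_mm, table=None,
                 response: SubbandResponse | None = None):
        self.spectrum = np.asarray(spectrum, dtype=float)
        self.lambda_centers = np.asarray(lambda_centers, dtype=float)
        self.z_path_mm = float(z_path_mm)
        self.table = table if table is not None else load_default_extinction()
        self.response = response

    @classmethod
    def from_depth_spectrum(cls, ds: DepthSpectrum, table=None,
                            response: SubbandResponse | None = None, **window):
        """Build the model from a bottom-located :class:`DepthSpectrum`."""
        if ds.bottom_idx is None or ds.z_path_mm is None:
            raise ValueError("DepthSpectrum needs bottom_idx and z_path_mm")
        spec = extract_bottom_spectrum(ds, ds.bottom_idx, **window)
        return cls(spec, ds.lambda_centers, ds.z_path_mm, table=table,
                   response=response)

    def predict(self, so2, A_refl, alpha):
        """Model spectrum at the sub-band centers (through the spectral
        instrument response when one was configured)."""
        log_model = _make_log_model(
            self.lambda_centers, self.z_path_mm, self.table, self.response
        )
        return np.exp(log_model(so2, np.log(A_refl), alpha))

    def fit(self, starts=(0.25, 0.5, 0.75)) -> "OximetryResults":
        fit = fit_so2(
            self.spectrum, self.lambda_centers, self.z_path_mm, self.table,
            starts, response=self.response,
        )
        return OximetryResults(self, fit)


class OximetryResults:
    """Fitted saturation with uncertainties and diagnostics.

    Standard errors come from the Gauss-Newton covariance of the
    log-space regression, ``sigma^2 (J^T J)^-1`` with ``sigma^2`` the
    residual variance; they are indicative only when the fit is interior
    to the bounds.
    """

    param_names = ("so2", "log_A", "alpha")

    def __init__(self, model: OximetryModel, fit: OximetryFit):
        self.model = model
        self.fit = fit
        self.params = np.array([fit.so2, np.log(fit.A_refl), fit.alpha])
        self._bse = self._compute_bse()

    def _compute_bse(self):
        lam = self.model.lambda_centers
        n, p = lam.size, 3
        # Jacobian of the log-model: d/d so2 = -z*dmu; d/d logA = 1; d/d alpha = -log lam
        dmu = self.model.table.mu_hbo2(lam) - self.model.table.mu_hb(lam)
        J = np.column_stack(
            [-self.model.z_path_mm * dmu, np.ones(n), -np.log(lam)]
        )
        resid = np.log(self.model.predict(self.fit.so2, self.fit.A_refl, self.fit.alpha)) - np.log(
            self.model.spectrum
        )
        dof = max(n - p, 1)
        sigma2 = float(resid @ resid) / dof
        try:
            cov = sigma2 * np.linalg.inv(J.T @ J)
            return np.sqrt(np.clip(np.diag(cov), 0, None))
        except np.linalg.LinAlgError:
            return np.full(p, np.nan)

    @property
    def so2(self) -> float:
        return self.fit.so2

    @property
    def so2_volpct(self) -> float:
        return self.fit.so2_volpct

    @property
    def bse(self) -> np.ndarray:
        """Standard errors of (so2, log_A, alpha)."""
        return self._bse

    @property
    def so2_se_volpct(self) -> float:
        return 100.0 * self._bse[0]

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.model.predict(self.fit.so2, self.fit.A_refl, self.fit.alpha)

    @property
    def resid(self) -> np.ndarray:
        return np.log(self.model.spectrum) - np.log(self.fittedvalues)

    def conf_int_so2(self, alpha: float = 0.05):
        from scipy import stats

        dof = max(self.model.lambda_centers.size - 3, 1)
        q = stats.t.ppf(1 - alpha / 2, dof)
        lo = max(self.fit.so2 - q * self._bse[0], 0.0)
        hi = min(self.fit.so2 + q * self._bse[0], 1.0)
        return lo, hi

    def summary(self) -> str:
        f = self.fit
        lo, hi = self.conf_int_so2()
        lines = [
            "Beer-Lambert vessel oximetry fit",
            "=" * 44,
            f"n sub-bands     : {self.model.lambda_centers.size}",
            f"z path (mm)     : {self.model.z_path_mm:.4f}",
            f"sO2 (vol %)     : {f.so2_volpct:8.2f}  (SE {self.so2_se_volpct:.2f},"
            f" 95% CI [{100*lo:.2f}, {100*hi:.2f}])",
            f"A_refl          : {f.A_refl:10.4g}",
            f"alpha           : {f.alpha:8.3f}  (SE {self._bse[2]:.3f})",
            f"residual norm   : {f.residual_norm:.3e}",
            f"converged       : {f.success}",
        ]
        return "\n".join(lines)
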