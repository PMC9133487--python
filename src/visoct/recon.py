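"""Depth reconstruction of spectral-domain OCT interferograms.

A-lines are reconstructed by DC removal followed by a Fourier transform of
the spectral fringes sampled in linear wavenumber (k).  Wavelength-resolved
("sub-band") volumes come from a short-time Fourier transform: a set of
Gaussian windows swept across the spectral support, each windowed fringe
transformed independently.  Sub-band spectroscopy trades axial resolution
for spectral resolution: each sub-band's axial point-spread function is
wider than the full-band one by the ratio of spectral supports.

Conventions
-----------
* Fringe arrays are ``(n_bscans, n_alines, n_spectral)``; reconstructed
  volumes are ``(n_bscans, n_alines, n_depth)`` with ``n_depth =
  n_spectral // 2``.
* Depth index 0 is the zero-delay line (top of the image); indices are
  0-based everywhere.
* Windows are equally spaced in k.  Magnitude (not log) volumes are the
  working representation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "InterferogramVolume",
    "SubbandStack",
    "spectral_axes",
    "reconstruct_fullband",
    "stft_subbands",
]

TWO_PI = 2.0 * np.pi


def spectral_axes(lambda_range_nm: tuple[float, float], n_spectral: int):
    """Linear-in-k sampling grid covering ``lambda_range_nm``.

    Returns ``(k_axis, lambda_axis)`` where ``k = 2*pi/lambda`` (1/nm) is
    strictly increasing and ``lambda_axis`` is therefore strictly
    decreasing, as on a spectrometer resampled to linear k.
    """
    lo, hi = float(lambda_range_nm[0]), float(lambda_range_nm[1])
    if not 0 < lo < hi:
        raise ValueError(f"invalid wavelength range {lambda_range_nm}")
    k = np.linspace(TWO_PI / hi, TWO_PI / lo, n_spectral)
    return k, TWO_PI / k


@dataclass
class InterferogramVolume:
    """Raw spectral fringes for every A-line of a raster scan.

    Attributes
    ----------
    fringes : ndarray, shape (n_bscans, n_alines, n_spectral)
    k_axis : ndarray, shape (n_spectral,)
        Wavenumber of each spectral sample; strictly monotonic.
    lambda_axis : ndarray, shape (n_spectral,)
        Wavelength in nm of each spectral sample.
    """

    fringes: np.ndarray
    k_axis: np.ndarray
    lambda_axis: np.ndarray

    def __post_init__(self):
        self.fringes = np.asarray(self.fringes)
        self.k_axis = np.asarray(self.k_axis, dtype=float)
        self.lambda_axis = np.asarray(self.lambda_axis, dtype=float)
        if self.fringes.ndim != 3:
            raise ValueError("fringes must be (n_bscans, n_alines, n_spectral)")
        n = self.fringes.shape[-1]
        if self.k_axis.shape != (n,) or self.lambda_axis.shape != (n,):
            raise ValueError("spectral axes inconsistent with fringe length")
        dk = np.diff(self.k_axis)
        if not (np.all(dk > 0) or np.all(dk < 0)):
            raise ValueError("k_axis must be strictly monotonic")

    @property
    def n_bscans(self) -> int:
        return self.fringes.shape[0]

    @property
    def n_alines(self) -> int:
        return self.fringes.shape[1]

    @property
    def n_spectral(self) -> int:
        return self.fringes.shape[2]

    def save(self, path) -> None:
        np.savez_compressed(
            path, fringes=self.fringes, k_axis=self.k_axis, lambda_axis=self.lambda_axis
        )

    @classmethod
    def load(cls, path) -> "InterferogramVolume":
        with np.load(path) as z:
            return cls(z["fringes"], z["k_axis"], z["lambda_axis"])


@dataclass
class SubbandStack:
    """Full-band volume plus wavelength-resolved sub-band volumes.

    ``subbands`` holds the 4-D intensity I(x, y, z, lambda) as
    ``(n_windows, n_bscans, n_alines, n_depth)``; ``lambda_centers`` are
    the window-center wavelengths in nm, sorted ascending.
    """

    fullband: np.ndarray
    subbands: np.ndarray
    lambda_centers: np.ndarray
    window_fwhm_nm: float = field(default=np.nan)

    def __post_init__(self):
        self.lambda_centers = np.asarray(self.lambda_centers, dtype=float)
        if self.subbands.shape[0] != self.lambda_centers.size:
            raise ValueError("one center wavelength per sub-band required")
        if np.any(np.diff(self.lambda_centers) <= 0):
            raise ValueError("lambda_centers must be sorted ascending")

    @property
    def n_windows(self) -> int:
        return self.subbands.shape[0]

    def save(self, path) -> None:
        np.savez_compressed(
            path,
            fullband=self.fullband,
            subbands=self.subbands,
            lambda_centers=self.lambda_centers,
            window_fwhm_nm=np.array(self.window_fwhm_nm),
        )

    @classmethod
    def load(cls, path) -> "SubbandStack":
        with np.load(path) as z:
            return cls(
                z["fullband"],
                z["subbands"],
                z["lambda_centers"],
                float(z["window_fwhm_nm"]),
            )


def _dc_removed(fringes: np.ndarray) -> np.ndarray:
    return fringes - fringes.mean(axis=-1, keepdims=True)


def reconstruct_fullband(volume: InterferogramVolume, apodize: bool = True) -> np.ndarray:
    """Full-band magnitude reconstruction of every A-line.

    Per A-line: subtract the spectral mean (DC), apodize with a Hann
    window (standard spectral shaping — suppresses the sinc sidelobes a
    rectangular window would put around bright reflectors), transform,
    keep the magnitude of the positive-depth half.  Output depth length
    is ``n_spectral // 2``.
    """
    if not np.all(np.isfinite(volume.fringes)):
        raise ValueError("fringes contain non-finite values")
    n = volume.n_spectral
    fr = _dc_removed(volume.fringes)
    if apodize:
        fr = fr * np.hanning(n)
    spec = np.fft.rfft(fr, axis=-1)
    return np.abs(spec[..., : n // 2]).astype(np.float32)


def gaussian_window_grid(
    n_spectral: int, n_windows: int, fwhm_samples: float
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian windows equally spaced in k, inset by half a window.

    Returns ``(centers, windows)`` with ``centers`` the (float) sample
    indices of the window maxima and ``windows`` of shape
    ``(n_windows, n_spectral)``.
    """
    half = fwhm_samples / 2.0
    centers = np.linspace(half, n_spectral - 1 - half, n_windows)
    sigma = fwhm_samples / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    n = np.arange(n_spectral)
    windows = np.exp(-0.5 * ((n[None, :] - centers[:, None]) / sigma) ** 2)
    return centers, windows


def stft_subbands(
    volume: InterferogramVolume,
    n_windows: int = 11,
    fwhm_nm: float | None = None,
) -> SubbandStack:
    """Short-time Fourier transform with Gaussian spectral windows.

    Window centers are equally spaced in k across the support, the first
    and last inset by half a window so every window fits inside the
    recorded spectrum.  ``fwhm_nm`` defaults to one eighth of the source
    support, giving roughly 50% overlap between neighbours.
    """
    if n_windows < 2:
        raise ValueError("n_windows must be >= 2")
    lam = volume.lambda_axis
    span_nm = float(abs(lam[0] - lam[-1]))
    if fwhm_nm is None:
        fwhm_nm = span_nm / 8.0
    if fwhm_nm >= span_nm:
        raise ValueError(
            f"window FWHM {fwhm_nm} nm does not fit in the {span_nm} nm support"
        )
    n = volume.n_spectral
    # k is sampled linearly, so a wavelength width maps to a sample width
    # through the mean nm-per-sample (exact to first order over the band).
    fwhm_samples = fwhm_nm / span_nm * n
    centers, windows = gaussian_window_grid(n, n_windows, fwhm_samples)

    fr = _dc_removed(volume.fringes)
    n_depth = n // 2
    sub = np.empty((n_windows, *fr.shape[:2], n_depth), dtype=np.float32)
    for i in range(n_windows):
        spec = np.fft.rfft(fr * windows[i], axis=-1)
        sub[i] = np.abs(spec[..., :n_depth])

    lambda_centers = np.interp(centers, np.arange(n), lam)
    order = np.argsort(lambda_centers)
    return SubbandStack(
        fullband=reconstruct_fullband(volume),
        subbands=sub[order],
        lambda_centers=lambda_centers[order],
        window_fwhm_nm=float(fwhm_nm),
    )
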