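"""Retinal surface segmentation, flattening, en-face projection and masks.

The RPE is detected per A-line as the brightest pixel of a Gaussian-blurred
B-scan, then corrected by a two-step outlier procedure:

1. within each B-scan, a third-order polynomial is fitted to the detected
   curve; points whose residual falls outside mean +/- k*SD (k = 1.8) are
   deleted and the fit repeated until no outlier remains, deleted points
   taking the fitted value;
2. across B-scans, the coefficient of variation (SD/mean) of each final
   fitted curve is screened with the same mean +/- k*SD rule; a flagged
   B-scan's curve is replaced by the previous valid one (the next valid
   one if the first B-scan is flagged).

The retina is then flattened on the fitted RPE, the ILM found as the
greatest axial intensity gradient above the RPE, the en-face image formed
by averaging a 20-pixel band above the RPE, and the vessel mask obtained
by adaptive thresholding of the en-face image (vessel shadows are dark)
with small objects removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_local
from skimage.morphology import remove_small_objects

__all__ = [
    "SegmentationConfig",
    "LayerSurfaces",
    "detect_rpe_raw",
    "refine_curve",
    "segment_rpe",
    "reject_bscan_outliers",
    "flatten",
    "unflatten",
    "detect_ilm",
    "make_enface",
    "repair_enface_rows",
    "vessel_mask",
]


@dataclass
class SegmentationConfig:
    blur_sigma: float = 7.0
    poly_order: int = 3
    outlier_k: float = 1.8
    enface_band_px: int = 20
    max_iter: int = 50
    # adaptive vessel-mask parameters (block size as a fraction of image
    # width; offset as a fraction of the dynamic range; objects below
    # min_object_px are discarded as unresolvable children vessels)
    adaptive_block_frac: float = 0.125
    adaptive_offset_frac: float = 0.30
    min_object_px: int = 10
    enface_guard_px: int = 3
    ilm_smooth_sigma: float = 1.0
    ilm_margin_px: int = 8

    def __post_init__(self):
        if self.outlier_k <= 0:
            raise ValueError("outlier_k must be positive")
        if self.poly_order < 1:
            raise ValueError("poly_order must be >= 1")


@dataclass
class LayerSurfaces:
    """Segmented surfaces with per-B-scan diagnostics."""

    rpe_raw: np.ndarray
    rpe_fit: np.ndarray
    ilm: np.ndarray | None = None
    outlier_mask: np.ndarray | None = None
    cov_trace: np.ndarray | None = None
    replaced_bscans: tuple = ()

    @property
    def n_bscans(self) -> int:
        return self.rpe_fit.shape[0]

    def validate(self) -> None:
        if self.ilm is not None and not np.all(self.ilm < self.rpe_fit):
            raise ValueError("ILM must lie above the fitted RPE everywhere")


def detect_rpe_raw(volume: np.ndarray, cfg: SegmentationConfig | None = None) -> np.ndarray:
    """Per-A-line depth of maximum intensity after Gaussian blurring.

    Each B-scan is blurred with a 2-D Gaussian of ``blur_sigma`` pixels
    before the argmax, suppressing speckle-like structure.  All-zero
    A-lines are flagged missing (NaN), never assigned a depth.
    """
    cfg = cfg or SegmentationConfig()
    volume = np.asarray(volume, dtype=float)
    B, A, D = volume.shape
    raw = np.empty((B, A), dtype=float)
    for x in range(B):
        img = ndimage.gaussian_filter(volume[x], cfg.blur_sigma)
        raw[x] = np.argmax(img, axis=-1)
        dead = ~np.any(volume[x] != 0, axis=-1)
        raw[x, dead] = np.nan
    return raw


def refine_curve(
    raw_curve: np.ndarray,
    cfg: SegmentationConfig | None = None,
    bscan_index: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Iterative polynomial fit with mean +/- k*SD residual rejection.

    Fits a polynomial of ``poly_order`` to the current inliers, deletes
    points whose residual leaves the mean +/- ``outlier_k`` * SD band
    (statistics recomputed over the current inliers each iteration), and
    repeats until no new outlier appears or ``max_iter`` is reached.
    Returns the fitted curve evaluated everywhere (deleted points thereby
    replaced by fitted values) and the outlier flags.
    """
    cfg = cfg or SegmentationConfig()
    y = np.asarray(raw_curve, dtype=float)
    x = np.arange(y.size, dtype=float)
    inliers = np.isfinite(y)
    where = f" in B-scan {bscan_index}" if bscan_index is not None else ""
    min_pts = cfg.poly_order + 2

    coeffs = None
    for _ in range(cfg.max_iter):
        if inliers.sum() < min_pts:
            raise ValueError(
                f"too few inlier points ({int(inliers.sum())} < {min_pts}) for a "
                f"degree-{cfg.poly_order} fit{where}"
            )
        coeffs = np.polyfit(x[inliers], y[inliers], cfg.poly_order)
        res = y[inliers] - np.polyval(coeffs, x[inliers])
        m, s = res.mean(), res.std()
        # numerically-exact fits must not flag floating-point noise
        if s <= 1e-8 * max(1.0, float(np.abs(y[inliers]).max())):
            break
        bad = np.abs(res - m) > cfg.outlier_k * s
        if not bad.any():
            break
        idx = np.nonzero(inliers)[0][bad]
        inliers[idx] = False
    fitted = np.polyval(coeffs, x)
    return fitted, ~inliers


def segment_rpe(volume: np.ndarray, cfg: SegmentationConfig | None = None) -> LayerSurfaces:
    """Detect and refine the RPE over a whole volume.

    Runs :func:`detect_rpe_raw`, refines every B-scan's curve and records
    the per-B-scan coefficient of variation of the fitted curves.
    """
    cfg = cfg or SegmentationConfig()
    raw = detect_rpe_raw(volume, cfg)
    B, A = raw.shape
    fit = np.empty_like(raw)
    outliers = np.zeros((B, A), dtype=bool)
    cov = np.empty(B)
    for x in range(B):
        fit[x], outliers[x] = refine_curve(raw[x], cfg, bscan_index=x)
        cov[x] = fit[x].std() / fit[x].mean() if fit[x].mean() != 0 else np.inf
    return LayerSurfaces(
        rpe_raw=raw, rpe_fit=fit, outlier_mask=outliers, cov_trace=cov
    )


def _screen_flags(values: np.ndarray, k: float) -> np.ndarray:
    """Single-pass mean +/- k*SD screening of a 1-D sequence."""
    finite = np.isfinite(values)
    flags = ~finite
    v = values[finite]
    if v.size >= 3 and v.std() > 0:
        flags |= np.abs(values - v.mean()) > k * v.std()
    return flags


def reject_bscan_outliers(
    surfaces: LayerSurfaces, cfg: SegmentationConfig | None = None
) -> LayerSurfaces:
    """Screen the COV trace across B-scans and replace failed curves.

    A B-scan whose fitted-curve COV leaves the mean +/- k*SD band of the
    COV trace is considered a failed segmentation; its curve is replaced
    by the previous valid curve, or the next valid one when the first
    B-scans are flagged.  The screen is applied once (the delete-refit
    iteration belongs to the within-B-scan polynomial stage; iterating
    the COV screen cascades on smooth anatomical variation and discards
    healthy B-scans).  The B-scan count is preserved.
    """
    cfg = cfg or SegmentationConfig()
    cov = np.asarray(surfaces.cov_trace, dtype=float)
    flagged = _screen_flags(cov, cfg.outlier_k)
    fit = surfaces.rpe_fit.copy()
    valid = np.nonzero(~flagged)[0]
    if valid.size == 0:
        raise ValueError("every B-scan flagged by the COV rule; nothing to keep")
    replaced = []
    for x in np.nonzero(flagged)[0]:
        prev = valid[valid < x]
        donor = prev[-1] if prev.size else valid[valid > x][0]
        fit[x] = fit[donor]
        replaced.append(int(x))
    return LayerSurfaces(
        rpe_raw=surfaces.rpe_raw,
        rpe_fit=fit,
        ilm=surfaces.ilm,
        outlier_mask=surfaces.outlier_mask,
        cov_trace=cov,
        replaced_bscans=tuple(replaced),
    )


def flatten(
    volume: np.ndarray, rpe_fit: np.ndarray, target_row: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Circularly shift every A-line so the RPE sits on a common row.

    Returns the flattened volume and the integer shift map (kept for
    inversion by :func:`unflatten`).
    """
    volume = np.asarray(volume)
    if target_row is None:
        target_row = int(round(float(np.median(rpe_fit))))
    shifts = target_row - np.rint(rpe_fit).astype(int)
    out = np.empty_like(volume)
    B, A, _ = volume.shape
    for x in range(B):
        for y in range(A):
            out[x, y] = np.roll(volume[x, y], shifts[x, y])
    return out, shifts


def unflatten(flattened: np.ndarray, shifts: np.ndarray) -> np.ndarray:
    """Invert :func:`flatten` exactly (circular shifts are bijective)."""
    out = np.empty_like(flattened)
    B, A, _ = flattened.shape
    for x in range(B):
        for y in range(A):
            out[x, y] = np.roll(flattened[x, y], -shifts[x, y])
    return out


def detect_ilm(
    flattened: np.ndarray,
    rpe_row: int,
    cfg: SegmentationConfig | None = None,
    shifts: np.ndarray | None = None,
) -> np.ndarray:
    """ILM depth as the greatest intensity-gradient above the RPE.

    Operates on the flattened volume: per A-line the axial profile is
    lightly smoothed (sigma = ``ilm_smooth_sigma``, stabilizing ties) and
    the maximum of its axial gradient within ``[1, rpe_row -
    ilm_margin_px)`` taken.  If ``shifts`` is given the map is returned
    in the original (unflattened) depth frame.
    """
    cfg = cfg or SegmentationConfig()
    vol = np.asarray(flattened, dtype=float)
    hi = rpe_row - cfg.ilm_margin_px
    if hi <= 2:
        raise ValueError("no room above the RPE row to search for the ILM")
    smooth = ndimage.gaussian_filter1d(vol[..., :hi], cfg.ilm_smooth_sigma, axis=-1)
    grad = np.gradient(smooth, axis=-1)
    ilm = np.argmax(grad[..., 1:], axis=-1) + 1.0
    if shifts is not None:
        ilm = ilm - shifts
    return ilm


def make_enface(
    volume: np.ndarray, rpe_fit: np.ndarray, cfg: SegmentationConfig | None = None
) -> np.ndarray:
    """Mean intensity over the band ``enface_band_px`` pixels above the RPE.

    The band is half-open, ``[rpe - enface_band_px, rpe - enface_guard_px)``:
    a small guard keeps the bright RPE reflection's own point-spread
    shoulder (whose strength swings with the sub-pixel surface position)
    out of the average.  The band is clipped at the volume top without
    error.
    """
    cfg = cfg or SegmentationConfig()
    volume = np.asarray(volume, dtype=float)
    B, A, D = volume.shape
    hi = np.clip(np.rint(rpe_fit).astype(int) - cfg.enface_guard_px, 1, D)
    lo = np.clip(np.rint(rpe_fit).astype(int) - cfg.enface_band_px, 0, None)
    enface = np.empty((B, A))
    for x in range(B):
        for y in range(A):
            enface[x, y] = volume[x, y, lo[x, y] : hi[x, y]].mean()
    return enface


def repair_enface_rows(enface: np.ndarray, replaced_bscans) -> np.ndarray:
    """Replace failed B-scans' en-face rows by the nearest valid row.

    Extends the COV-based curve replacement to the projection image:
    a corrupt B-scan contributes saturated garbage to the en-face image
    and would distort the adaptive threshold's local means.
    """
    out = np.asarray(enface, dtype=float).copy()
    bad = sorted(int(i) for i in replaced_bscans)
    valid = [i for i in range(out.shape[0]) if i not in set(bad)]
    if not valid:
        return out
    for i in bad:
        donor = min(valid, key=lambda v: abs(v - i))
        out[i] = out[donor]
    return out


def vessel_mask(enface: np.ndarray, cfg: SegmentationConfig | None = None) -> np.ndarray:
    """Binary vessel mask by adaptive thresholding of the en-face image.

    Vessels cast shadows, so a pixel is vessel when it falls below its
    local mean (block = width * ``adaptive_block_frac``) by more than
    ``adaptive_offset_frac`` of the median brightness — a robust scale
    that a few saturated (corrupt) B-scans cannot distort.  Objects
    smaller than ``min_object_px`` — unresolvable children vessels — are
    removed.  A blank image yields an empty mask.
    """
    cfg = cfg or SegmentationConfig()
    img = np.asarray(enface, dtype=float)
    if img.max() == img.min():
        return np.zeros(img.shape, dtype=bool)
    block = int(max(img.shape) * cfg.adaptive_block_frac)
    block = max(block | 1, 3)  # odd, >= 3
    offset = cfg.adaptive_offset_frac * float(np.median(img))
    thr = threshold_local(img, block_size=block, method="mean", offset=offset)
    mask = img < thr
    # skimage >= 0.26: max_size removes objects <= its value
    return remove_small_objects(mask, max_size=cfg.min_object_px - 1)
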