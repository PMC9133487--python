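"""Topographic features of vessel segments: L, A, D, rho_min, rho_max.

Length is measured along the skeleton centerline (longest geodesic path,
8-connected steps weighted 1 or sqrt(2) pixels), area as the pixel count
of the en-face mask, diameter axially from the vessel top and bottom
peaks of the ROI-averaged A-line, and rho_min / rho_max as the extreme
Euclidean distances from the fovea to the mask pixels.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import ndimage, signal
from skimage.morphology import skeletonize

from .oximetry import DepthSpectrum

__all__ = [
    "TopoFeatures",
    "centerline_length",
    "mask_area",
    "vessel_diameter",
    "fovea_distances",
    "compute_features",
]

_SQRT2 = float(np.sqrt(2.0))


def _subpixel(prof: np.ndarray, p: int) -> float:
    """Parabolic sub-pixel refinement of a peak position."""
    if not 0 < p < prof.size - 1:
        return float(p)
    denom = prof[p - 1] - 2.0 * prof[p] + prof[p + 1]
    if denom == 0:
        return float(p)
    return float(p + 0.5 * (prof[p - 1] - prof[p + 1]) / denom)


@dataclass
class TopoFeatures:
    L_mm: float
    A_mm2: float
    D_um: float
    rho_min_mm: float
    rho_max_mm: float
    label: str

    def __post_init__(self):
        if self.rho_min_mm > self.rho_max_mm:
            raise ValueError("rho_min must not exceed rho_max")

    @property
    def A_1e3_mm2(self) -> float:
        """Area in 10^-3 mm^2, the unit used for cohort tables."""
        return 1e3 * self.A_mm2


def _skeleton_graph(skel: np.ndarray) -> nx.Graph:
    g = nx.Graph()
    pix = np.argwhere(skel)
    coords = set(map(tuple, pix))
    for x, y in map(tuple, pix):
        g.add_node((x, y))
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                if dx == dy == 0:
                    continue
                nb = (x + dx, y + dy)
                if nb in coords:
                    g.add_edge((x, y), nb, weight=_SQRT2 if dx and dy else 1.0)
    return g


def centerline_length(mask: np.ndarray, lateral_pitch_mm: float) -> float:
    """Centerline length in mm along the longest skeleton path.

    The mask is skeletonized; inter-pixel steps count 1 (axial moves) or
    sqrt(2) (diagonal moves) pixels.  Branches are resolved by taking
    the longest geodesic between skeleton endpoints, ties broken by
    first-found in scan order.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return 0.0
    skel = skeletonize(mask)
    g = _skeleton_graph(skel)
    if g.number_of_nodes() < 2:
        return 0.0
    ends = sorted(n for n, d in g.degree() if d <= 1)
    sources = ends if ends else sorted(g.nodes())
    best = 0.0
    for src in sources:
        dist = nx.single_source_dijkstra_path_length(g, src, weight="weight")
        far = max(dist.values())
        if far > best:
            best = far
    return best * lateral_pitch_mm


def mask_area(mask: np.ndarray, lateral_pitch_mm: float) -> float:
    """Mask area in mm^2: pixel count times the squared lateral pitch."""
    return int(np.count_nonzero(mask)) * lateral_pitch_mm**2


def vessel_diameter(
    ds: DepthSpectrum,
    axial_pitch_um: float,
    smooth_sigma: float = 1.0,
    prominence_frac: float = 0.015,
    ilm_guard_px: int = 3,
    max_depth_px: int = 48,
) -> float:
    """Axial vessel diameter in um from the ROI-averaged A-line.

    The top of the vessel is the first reflective peak below the ILM row
    and the bottom the second (``ds.bottom_idx`` when already located);
    the diameter is their separation times the axial pixel pitch.  The
    search is restricted to the plausible vessel band below the ILM
    complex.  Note this is an axial measurement, not the lateral mask
    width.
    """
    prof = ndimage.gaussian_filter1d(ds.mean_aline.astype(float), smooth_sigma)
    prom = prominence_frac * float(prof.max()) if prof.max() > 0 else None
    peaks, _ = signal.find_peaks(prof, prominence=prom)
    peaks = peaks[(peaks > ilm_guard_px) & (peaks <= max_depth_px)]
    if peaks.size < 2:
        raise ValueError("vessel top/bottom peaks not found in the averaged A-line")
    top = int(peaks[0])
    bottom = int(ds.bottom_idx) if ds.bottom_idx is not None else int(peaks[-1])
    if bottom <= top:
        raise ValueError("vessel bottom does not lie below the top peak")
    return (_subpixel(prof, bottom) - _subpixel(prof, top)) * axial_pitch_um


def fovea_distances(
    mask: np.ndarray, fovea_xy: tuple[float, float], lateral_pitch_mm: float
) -> tuple[float, float]:
    """Minimum and maximum Euclidean distance from the fovea to the mask.

    Distances are taken to pixel centers, in mm.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask has no fovea distances")
    xs, ys = np.nonzero(mask)
    d = np.hypot(xs - fovea_xy[0], ys - fovea_xy[1]) * lateral_pitch_mm
    return float(d.min()), float(d.max())


def compute_features(
    mask: np.ndarray,
    ds: DepthSpectrum,
    fovea_xy: tuple[float, float],
    lateral_pitch_mm: float,
    axial_pitch_um: float,
    label: str,
) -> TopoFeatures:
    """All topographic features of one vessel segment."""
    rho_min, rho_max = fovea_distances(mask, fovea_xy, lateral_pitch_mm)
    return TopoFeatures(
        L_mm=centerline_length(mask, lateral_pitch_mm),
        A_mm2=mask_area(mask, lateral_pitch_mm),
        D_um=vessel_diameter(ds, axial_pitch_um),
        rho_min_mm=rho_min,
        rho_max_mm=rho_max,
        label=label,
    )
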