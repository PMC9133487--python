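"""Synthetic VIS-OCT volumes with known layers, vessels and saturation.

The phantom emulates the structures the analysis pipeline must handle on
a real parafoveal raster scan — a layered retina bounded by the ILM and
the bright RPE, a diffuse inner-retina scatter band, small vessels
(20-40 um caliber) lying between the two surfaces, wavelength-dependent
attenuation of everything beneath a vessel, shot-like fringe noise,
occasional corrupted B-scans, and bright spike reflectors that derail a
naive maximum-intensity RPE search — while recording every ground-truth
quantity needed to score the pipeline.

Fringes are synthesized directly in linear k with no dispersion: a
reflector at depth pixel ``z`` contributes ``R(lambda_n) *
cos(2*pi*z*n/N)`` to the A-line's spectral samples ``n = 0..N-1``, so the
Fourier reconstruction places it exactly at depth bin ``z``.  The
vessel-bottom reflectance follows the same Beer-Lambert forward model the
inversion fits (see :mod:`visoct.oximetry`), with a power-law vessel-wall
term and a round-trip blood path of twice the lumen diameter.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .oximetry import ExtinctionTable, load_default_extinction
from .recon import InterferogramVolume, spectral_axes

__all__ = [
    "VesselSpec",
    "PhantomConfig",
    "PhantomTruth",
    "make_phantom",
    "make_reference_rnfl_spectrum",
    "source_spectrum",
]

TWO_PI = 2.0 * np.pi


@dataclass
class VesselSpec:
    """One synthetic vessel: en-face centerline plus optical truth.

    ``polyline`` is a (K, 2) array of en-face pixel coordinates
    (x = B-scan index, y = A-line index).  The lumen is circular in
    cross-section: its axial extent equals ``diameter_um``.  The vessel
    top sits ``clearance_px`` beneath the local ILM.
    """

    polyline: np.ndarray
    diameter_um: float
    so2: float
    label: str
    A_refl: float = 1.0
    alpha: float = 1.0
    clearance_px: float = 8.0

    def __post_init__(self):
        self.polyline = np.atleast_2d(np.asarray(self.polyline, dtype=float))
        if self.polyline.shape[1] != 2:
            raise ValueError("polyline must be (K, 2) en-face pixel coordinates")
        if not 0.0 <= self.so2 <= 1.0:
            raise ValueError("vessel so2 must be a fraction in [0, 1]")
        if self.label not in ("artery", "vein"):
            raise ValueError("label must be 'artery' or 'vein'")

    @property
    def z_path_mm(self) -> float:
        """Round-trip optical path through blood: twice the lumen diameter."""
        return 2.0 * self.diameter_um / 1000.0


@dataclass
class PhantomConfig:
    """Geometry, optics and degradation settings of one phantom volume.

    The default grid (64 B-scans x 128 A-lines x 512 depth px) is a
    desk-scale version of the device's 512 x 256 raster over a 5 x 5 mm
    field; the full raster is reachable through the same fields.
    """

    n_bscans: int = 64
    n_alines: int = 128
    n_depth: int = 512
    n_spectral: int = 1024
    fov_mm: float = 5.0
    depth_pitch_um: float = 1.5
    lambda_range_nm: tuple[float, float] = (520.0, 600.0)
    vessels: tuple[VesselSpec, ...] = ()
    # layered-retina geometry (fractions of the depth axis / pixels)
    ilm_frac: float = 0.25
    thickness_frac: float = 0.40
    surface_tilt_px: float = 4.0
    surface_curve_px: float = 6.0
    n_scatter_layers: int = 24
    # degradations
    rpe_outlier_rate: float = 0.0
    corrupt_bscan_indices: tuple[int, ...] = ()
    noise_sigma: float = 0.0
    seed: int = 0
    # optics
    source: str = "gaussian"  # or "flat"
    rnfl_alpha: float = 1.2
    diameter_band_um: tuple[float, float] = (20.0, 40.0)
    fovea_xy: tuple[float, float] | None = None
    # interface reflectivities (relative)
    ilm_refl: float = 0.5
    rpe_refl: float = 1.0
    vessel_wall_refl: float = 0.25
    # back-wall specular reflection is strong; after round-trip blood
    # attenuation the bottom peak stays comparable to the top one
    bottom_refl: float = 2.0
    scatter_refl: float = 0.015
    spike_refl: float = 40.0
    dc_level: float = 20.0

    def __post_init__(self):
        self.vessels = tuple(self.vessels)
        self.corrupt_bscan_indices = tuple(int(i) for i in self.corrupt_bscan_indices)
        if self.n_depth > self.n_spectral // 2:
            raise ValueError("n_depth must be <= n_spectral // 2")
        if any(not 0 <= i < self.n_bscans for i in self.corrupt_bscan_indices):
            raise ValueError("corrupt_bscan_indices outside the B-scan range")
        lo, hi = self.diameter_band_um
        for v in self.vessels:
            if not lo <= v.diameter_um <= hi:
                raise ValueError(
                    f"vessel diameter {v.diameter_um} um outside the allowed "
                    f"band [{lo}, {hi}] um"
                )

    @property
    def lateral_pitch_mm(self) -> float:
        return self.fov_mm / self.n_alines

    @property
    def axial_pitch_um(self) -> float:
        return self.depth_pitch_um


@dataclass
class PhantomTruth:
    """Every ground-truth quantity the phantom buries in the volume."""

    rpe_depth: np.ndarray
    ilm_depth: np.ndarray
    vessel_masks: list
    vessel_top_depth: list
    vessel_bottom_depth: list
    true_so2: list
    labels: list
    z_path_mm: list
    fovea_xy: tuple
    pixel_pitches: tuple
    corrupt_bscans: tuple = ()
    spike_mask: np.ndarray | None = None

    def __post_init__(self):
        if not np.all(self.ilm_depth < self.rpe_depth):
            raise ValueError("truth violated: ILM must be above the RPE everywhere")
        for m in self.vessel_masks:
            if np.asarray(m)[list(self.corrupt_bscans), :].any():
                raise ValueError("vessel masks must not overlap corrupt B-scans")

    def to_json(self, path) -> None:
        payload = {
            "rpe_depth": np.asarray(self.rpe_depth).tolist(),
            "ilm_depth": np.asarray(self.ilm_depth).tolist(),
            "vessel_masks": [np.asarray(m).astype(int).tolist() for m in self.vessel_masks],
            "vessel_top_depth": list(map(float, self.vessel_top_depth)),
            "vessel_bottom_depth": list(map(float, self.vessel_bottom_depth)),
            "true_so2": list(map(float, self.true_so2)),
            "labels": list(self.labels),
            "z_path_mm": list(map(float, self.z_path_mm)),
            "fovea_xy": list(map(float, self.fovea_xy)),
            "pixel_pitches": list(map(float, self.pixel_pitches)),
            "corrupt_bscans": list(map(int, self.corrupt_bscans)),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "PhantomTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            rpe_depth=np.array(d["rpe_depth"], dtype=float),
            ilm_depth=np.array(d["ilm_depth"], dtype=float),
            vessel_masks=[np.array(m, dtype=bool) for m in d["vessel_masks"]],
            vessel_top_depth=d["vessel_top_depth"],
            vessel_bottom_depth=d["vessel_bottom_depth"],
            true_so2=d["true_so2"],
            labels=d["labels"],
            z_path_mm=d["z_path_mm"],
            fovea_xy=tuple(d["fovea_xy"]),
            pixel_pitches=tuple(d["pixel_pitches"]),
            corrupt_bscans=tuple(d["corrupt_bscans"]),
        )


# ---------------------------------------------------------------------------
# Optics helpers
# ---------------------------------------------------------------------------


def source_spectrum(config: PhantomConfig, lambda_nm) -> np.ndarray:
    """Source power spectral density I0(lambda), strictly positive."""
    lam = np.asarray(lambda_nm, dtype=float)
    if config.source == "flat":
        return np.ones_like(lam)
    lo, hi = config.lambda_range_nm
    center, width = 0.5 * (lo + hi), (hi - lo) / 3.0
    return 0.25 + np.exp(-0.5 * ((lam - center) / width) ** 2)


def make_reference_rnfl_spectrum(config: PhantomConfig, lambda_nm=None) -> np.ndarray:
    """The phantom's non-vascular RNFL reflectance spectrum.

    The RNFL reflects with a smooth power law ``(lambda/lambda_ref)**
    (-rnfl_alpha)`` on top of the source spectrum; this is the ground
    truth for the normalization step.  Evaluated on ``lambda_nm``
    (defaults to the phantom's spectral axis).
    """
    if lambda_nm is None:
        _, lambda_nm = spectral_axes(config.lambda_range_nm, config.n_spectral)
    lam = np.asarray(lambda_nm, dtype=float)
    lam_ref = 0.5 * (config.lambda_range_nm[0] + config.lambda_range_nm[1])
    return source_spectrum(config, lam) * (lam / lam_ref) ** (-config.rnfl_alpha)


def _surfaces(config: PhantomConfig):
    """Smooth ILM and RPE depth maps (B-scans x A-lines), cubic-friendly."""
    B, A, D = config.n_bscans, config.n_alines, config.n_depth
    xb = np.arange(B) / max(B - 1, 1)
    ya = (np.arange(A) / max(A - 1, 1)) - 0.5
    t, c = config.surface_tilt_px, config.surface_curve_px
    ilm = (
        config.ilm_frac * D
        + t * ya[None, :]
        + c * (ya**2)[None, :]
        + 2.0 * np.sin(TWO_PI * xb)[:, None]
    )
    rpe = (
        (config.ilm_frac + config.thickness_frac) * D
        - t * ya[None, :]
        - c * (ya**2)[None, :]
        + 2.0 * np.cos(TWO_PI * xb)[:, None]
    )
    return ilm, rpe


def _rasterize_vessel(spec: VesselSpec, config: PhantomConfig) -> np.ndarray:
    """En-face mask of a vessel polyline with its physical half-width.

    At desk-scale grids the physical half-width can fall below one
    pixel; a 1 px floor keeps the vessel detectable en face (the axial
    geometry, which oximetry and diameter use, stays exact).
    """
    B, A = config.n_bscans, config.n_alines
    lateral_pitch_um = config.lateral_pitch_mm * 1000.0
    half_px = max(spec.diameter_um / 2.0 / lateral_pitch_um, 1.0)
    xs, ys = np.meshgrid(np.arange(B), np.arange(A), indexing="ij")
    pts = np.stack([xs.ravel(), ys.ravel()], axis=1).astype(float)
    dmin = np.full(pts.shape[0], np.inf)
    poly = spec.polyline
    for p0, p1 in zip(poly[:-1], poly[1:]):
        seg = p1 - p0
        L2 = float(seg @ seg)
        if L2 == 0:
            d = np.linalg.norm(pts - p0, axis=1)
        else:
            tt = np.clip((pts - p0) @ seg / L2, 0.0, 1.0)
            d = np.linalg.norm(pts - (p0 + tt[:, None] * seg), axis=1)
        dmin = np.minimum(dmin, d)
    if poly.shape[0] == 1:
        dmin = np.linalg.norm(pts - poly[0], axis=1)
    return (dmin <= half_px).reshape(B, A)


def _add_reflector(out, depth_y, amp, rows, n_grid):
    """Accumulate cos fringes of one interface into a B-scan's fringes."""
    if rows.size == 0:
        return
    phase = (TWO_PI / n_grid.size) * depth_y[rows, None] * n_grid[None, :]
    out[rows] += amp[rows] * np.cos(phase)


# ---------------------------------------------------------------------------
# Main generator
# ---------------------------------------------------------------------------


def make_phantom(
    config: PhantomConfig, table: ExtinctionTable | None = None
) -> tuple[InterferogramVolume, PhantomTruth]:
    """Synthesize one phantom interferogram volume and its ground truth.

    Interfaces per A-line: ILM, ``n_scatter_layers`` diffuse inner-retina
    layers, per-vessel top and bottom (the bottom with finite Gaussian
    axial extent and Beer-Lambert attenuated reflectance at the vessel's
    true saturation), and the RPE.  Everything lying beneath a vessel is
    shadowed by the vessel's round-trip blood transmission.  Corrupt
    B-scans are replaced by saturated noise; a bright spike reflector is
    planted just below the ILM at randomly chosen A-lines to create RPE
    detection outliers.
    """
    cfg = config
    if table is None:
        table = load_default_extinction()
    rng = np.random.default_rng(cfg.seed)
    B, A, N = cfg.n_bscans, cfg.n_alines, cfg.n_spectral
    k_axis, lam = spectral_axes(cfg.lambda_range_nm, N)
    n_grid = np.arange(N, dtype=float)

    I0 = source_spectrum(cfg, lam)
    base = make_reference_rnfl_spectrum(cfg, lam)  # I0 * RNFL power law
    lam_ref = 0.5 * (cfg.lambda_range_nm[0] + cfg.lambda_range_nm[1])

    ilm, rpe = _surfaces(cfg)
    if cfg.n_scatter_layers > 0:
        # diffuse band from the mid inner retina down to just above the
        # RPE, so the en-face projection band always contains scatter
        fracs = np.linspace(0.30, 0.97, cfg.n_scatter_layers)
        fracs = fracs + rng.uniform(-0.01, 0.01, size=fracs.size)
    else:
        fracs = np.empty(0)

    # Spike artifacts: isolated saturated glints just below the ILM,
    # bright enough (spike_refl ~40x the RPE) that they outshine the RPE
    # after the sigma-7 2-D detection blur dilutes them laterally.  Each
    # glint corrupts the raw detection over its blurred footprint
    # (~30 A-lines at the default brightness), so glints are drawn at
    # rate/30 per pixel to make ``rpe_outlier_rate`` approximate the
    # fraction of corrupted A-lines.  Meaningful only at realistic
    # lateral widths (hundreds of A-lines per B-scan).
    spike_mask = rng.random((B, A)) < cfg.rpe_outlier_rate / 30.0

    # vessel geometry and optics
    masks, tops, bottoms, T_list = [], [], [], []
    for v in cfg.vessels:
        mask = _rasterize_vessel(v, cfg)
        mask[list(cfg.corrupt_bscan_indices), :] = False
        lumen_px = v.diameter_um / cfg.depth_pitch_um
        top = ilm + v.clearance_px
        bottom = top + lumen_px
        under = mask & (bottom >= rpe - 2.0)
        if under.any():
            raise ValueError(
                f"vessel '{v.label}' (d={v.diameter_um} um) extends below the "
                "RPE: lumen must lie strictly between ILM and RPE"
            )
        # round-trip transmission through the blood column
        T = np.exp(-table.mu(v.so2, lam) * v.z_path_mm)
        masks.append(mask)
        tops.append(top)
        bottoms.append(bottom)
        T_list.append(T)

    # bottom reflectance spectrum per vessel: Beer-Lambert forward model on
    # top of the shared source x RNFL baseline, power-law wall reflectance
    # referenced to the band center so amplitudes stay O(bottom_refl).
    bottom_amp = [
        cfg.bottom_refl * v.A_refl * base * (lam / lam_ref) ** (-v.alpha) * T_list[i]
        for i, v in enumerate(cfg.vessels)
    ]

    fringes = np.empty((B, A, N), dtype=float)
    all_rows = np.arange(A)
    for x in range(B):
        # Spectrally flat DC so per-A-line mean subtraction removes it
        # exactly; structured-DC estimation belongs to real-spectrometer
        # preprocessing, which the phantom deliberately sidesteps.
        out = np.full((A, N), cfg.dc_level, dtype=float)

        vx = [
            (masks[i][x], tops[i][x], bottoms[i][x], T_list[i], bottom_amp[i])
            for i in range(len(cfg.vessels))
        ]

        def shadowed(amp, depth_y):
            """Apply each vessel's transmission to interfaces beneath it."""
            for m, _t, bot, T, _ba in vx:
                sel = m & (depth_y > bot)
                if sel.any():
                    amp[sel] *= T[None, :]
            return amp

        # ILM
        _add_reflector(out, ilm[x], np.tile(cfg.ilm_refl * base, (A, 1)), all_rows, n_grid)

        # diffuse scatter layers (zeroed inside a lumen, shadowed below it)
        for f in fracs:
            depth_y = ilm[x] + f * (rpe[x] - ilm[x])
            amp = np.tile(cfg.scatter_refl * base, (A, 1))
            for m, top, bot, _T, _ba in vx:
                inside = m & (depth_y > top) & (depth_y < bot)
                amp[inside] = 0.0
            amp = shadowed(amp, depth_y)
            _add_reflector(out, depth_y, amp, all_rows, n_grid)

        # RPE (no RNFL coloring; always beneath every vessel)
        amp = np.tile(cfg.rpe_refl * I0, (A, 1))
        for m, _t, _b, T, _ba in vx:
            amp[m] *= T[None, :]
        _add_reflector(out, rpe[x], amp, all_rows, n_grid)

        # spike outliers just below the ILM, brighter than the RPE
        rows = np.nonzero(spike_mask[x])[0]
        _add_reflector(out, ilm[x] + 2.0, np.tile(cfg.spike_refl * I0, (A, 1)), rows, n_grid)

        # vessels: top and bottom interfaces.  Both are sharp reflectors:
        # the realistic finite width of the reconstructed bottom peak
        # comes from the sub-band axial PSF, and a physically diffuse
        # axial extent would damp exactly the high-k fringe components
        # the sub-band spectroscopy relies on.
        for m, top, bot, _T, ba in vx:
            rows = np.nonzero(m)[0]
            _add_reflector(out, top, np.tile(cfg.vessel_wall_refl * base, (A, 1)), rows, n_grid)
            _add_reflector(out, bot, np.tile(ba, (A, 1)), rows, n_grid)

        fringes[x] = out

    rms = float(np.sqrt(np.mean((fringes - fringes.mean(axis=-1, keepdims=True)) ** 2)))
    if cfg.noise_sigma > 0:
        fringes += cfg.noise_sigma * rms * rng.standard_normal(fringes.shape)
    for idx in cfg.corrupt_bscan_indices:
        # saturated noise: heavy clipping drives half the samples to the rails
        raw = 3.0 * rng.uniform(-1.0, 1.0, size=(A, N))
        fringes[idx] = (3.0 * rms if rms > 0 else 1.0) * np.clip(raw, -1.0, 1.0)

    volume = InterferogramVolume(fringes=fringes, k_axis=k_axis, lambda_axis=lam)
    truth = PhantomTruth(
        rpe_depth=rpe,
        ilm_depth=ilm,
        vessel_masks=masks,
        vessel_top_depth=[float(tops[i][masks[i]].mean()) if masks[i].any() else float("nan") for i in range(len(masks))],
        vessel_bottom_depth=[float(bottoms[i][masks[i]].mean()) if masks[i].any() else float("nan") for i in range(len(masks))],
        true_so2=[v.so2 for v in cfg.vessels],
        labels=[v.label for v in cfg.vessels],
        z_path_mm=[v.z_path_mm for v in cfg.vessels],
        fovea_xy=cfg.fovea_xy
        if cfg.fovea_xy is not None
        else (cfg.n_bscans / 2.0, cfg.n_alines / 2.0),
        pixel_pitches=(cfg.lateral_pitch_mm, cfg.depth_pitch_um),
        corrupt_bscans=cfg.corrupt_bscan_indices,
        spike_mask=spike_mask,
    )
    return volume, truth
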