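"""Shared fixtures: small phantoms and their processed artifacts.

Phantom volumes are generated at desk scale (16-64 B-scans, 256-sample
spectra) so the whole suite stays fast; the geometry, optics and
processing chain are identical to full-size runs.
"""

import numpy as np
import pytest

from visoct.layers import (
    SegmentationConfig,
    detect_ilm,
    flatten,
    make_enface,
    reject_bscan_outliers,
    repair_enface_rows,
    segment_rpe,
    vessel_mask,
)
from visoct.oximetry import (
    SubbandResponse,
    load_default_extinction,
    measure_rnfl_reference,
)
from visoct.phantom import PhantomConfig, VesselSpec, make_phantom
from visoct.recon import stft_subbands


@pytest.fixture(scope="session")
def table():
    return load_default_extinction()


@pytest.fixture(scope="session")
def lam11():
    """Eleven sub-band centers spanning the visible oximetry band."""
    return np.linspace(525.0, 595.0, 11)


def _process(cfg):
    """Run the full segmentation chain on a phantom and bundle artifacts."""
    volume, truth = make_phantom(cfg)
    stack = stft_subbands(volume)
    seg = SegmentationConfig()
    surfaces = reject_bscan_outliers(segment_rpe(stack.fullband, seg), seg)
    target = int(round(float(np.median(surfaces.rpe_fit))))
    flattened, shifts = flatten(stack.fullband, surfaces.rpe_fit, target)
    ilm = detect_ilm(flattened, target, seg, shifts=shifts)
    enface = repair_enface_rows(
        make_enface(stack.fullband, surfaces.rpe_fit, seg), surfaces.replaced_bscans
    )
    detected = vessel_mask(enface, seg)
    any_vessel = np.zeros(enface.shape, dtype=bool)
    for m in truth.vessel_masks:
        any_vessel |= m
    exclude = any_vessel | detected
    if surfaces.replaced_bscans:
        exclude[list(surfaces.replaced_bscans), :] = True
    reference = measure_rnfl_reference(stack, ilm, exclude_mask=exclude)
    response = SubbandResponse(
        cfg.lambda_range_nm, n_spectral=cfg.n_spectral, fwhm_nm=stack.window_fwhm_nm
    ).set_baseline(reference)
    return {
        "cfg": cfg,
        "volume": volume,
        "truth": truth,
        "stack": stack,
        "seg": seg,
        "surfaces": surfaces,
        "ilm": ilm,
        "enface": enface,
        "detected_mask": detected,
        "reference": reference,
        "response": response,
    }


@pytest.fixture(scope="session")
def process_phantom():
    """Factory running the full segmentation chain on a config."""
    return _process


@pytest.fixture(scope="session")
def clean_artery():
    """Noiseless single-arteriole phantom (24.8 um, sO2 0.921)."""
    cfg = PhantomConfig(
        n_bscans=16,
        n_alines=32,
        n_depth=128,
        n_spectral=256,
        vessels=(
            VesselSpec(
                polyline=[[2, 16], [13, 16]], diameter_um=24.8, so2=0.921, label="artery"
            ),
        ),
        depth_pitch_um=1.55,
        seed=7,
    )
    return _process(cfg)


@pytest.fixture(scope="session")
def two_vessel():
    """Noiseless two-vessel phantom at the cohort's mean calibers."""
    cfg = PhantomConfig(
        vessels=(
            VesselSpec(polyline=[[10, 20], [50, 90]], diameter_um=24.8, so2=0.921, label="artery"),
            VesselSpec(polyline=[[10, 100], [55, 30]], diameter_um=28.4, so2=0.484, label="vein"),
        ),
        seed=3,
    )
    return _process(cfg)


@pytest.fixture(scope="session")
def degraded():
    """Phantom with 5% RPE spike outliers and two corrupt B-scans."""
    cfg = PhantomConfig(
        n_bscans=48,
        n_alines=256,
        n_depth=128,
        n_spectral=256,
        vessels=(
            VesselSpec(polyline=[[8, 64], [40, 192]], diameter_um=24.8, so2=0.921, label="artery"),
        ),
        rpe_outlier_rate=0.05,
        corrupt_bscan_indices=(20, 40),
        seed=3,
    )
    return _process(cfg)
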