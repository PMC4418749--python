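import numpy as np
import pytest

from octcornea import CorneaTruth, OpticalGeometry, generate_bscan


def scaled_geometry(width_px=640, depth_px=900):
    """Reduced raster that preserves the default axial/lateral pitches."""
    base = OpticalGeometry()
    return OpticalGeometry(
        depth_px=depth_px,
        width_px=width_px,
        depth_extent_mm=base.depth_extent_mm * depth_px / base.depth_px,
        width_extent_mm=base.width_extent_mm * width_px / base.width_px,
    )


@pytest.fixture(scope="session")
def small_geometry():
    return scaled_geometry()


@pytest.fixture(scope="session")
def flat_truth():
    return CorneaTruth(anterior_radius_mm=float("inf"))


@pytest.fixture(scope="session")
def postop_truth():
    return CorneaTruth(
        epi_um=53.1, bowman_um=17.0, stroma_to_flap_um=95.8 - 53.1 - 17.0, total_um=439.5
    )


@pytest.fixture(scope="session")
def clean_flat_scan(flat_truth, small_geometry):
    """Noiseless, artifact-free flat-cornea B-scan with its truth."""
    return generate_bscan(
        flat_truth, geometry=small_geometry, noise_level=0.0, artifact_flags=set(), seed=7
    )


@pytest.fixture(scope="session")
def clean_curved_scan(small_geometry):
    truth = CorneaTruth()
    return generate_bscan(
        truth, geometry=small_geometry, noise_level=0.0, artifact_flags=set(), seed=7
    )


def brute_force_ridge_positions(pixels, column):
    """Independent oracle: argmax + analytic parabola per ridge of one A-scan."""
    from scipy.signal import find_peaks

    col = np.asarray(pixels[:, column], dtype=float)
    peaks, _ = find_peaks(col, prominence=0.05 * col.max())
    out = []
    for p in peaks:
        denom = col[p - 1] - 2 * col[p] + col[p + 1]
        out.append(p + 0.5 * (col[p - 1] - col[p + 1]) / denom if denom < 0 else float(p))
    return out
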