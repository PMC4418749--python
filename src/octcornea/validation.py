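"""Accuracy evaluation of the segmentation against generator truth."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .geometry import OpticalGeometry
from .segmentation import SegmentationParams, segment_bscan
from .simulate import DEFAULT_ARTIFACTS, BScanMeta, CorneaTruth, generate_bscan
from .thickness import interfaces_to_thickness


def _draw_truth(rng: np.random.Generator, post_op: bool) -> CorneaTruth:
    """Sample a study-plausible cornea (pre- or post-op)."""
    epi = float(np.clip(rng.normal(54.0, 3.5), 42.0, 68.0))
    bowman = float(np.clip(rng.normal(17.0, 1.5), 10.0, 25.0))
    if post_op:
        flap = float(np.clip(rng.normal(100.0, 8.0), epi + bowman + 10.0, 135.0))
        total = float(np.clip(rng.normal(440.0, 30.0), flap + 150.0, 620.0))
        stroma_to_flap = flap - epi - bowman
    else:
        stroma_to_flap = None
        total = float(np.clip(rng.normal(524.0, 26.0), 400.0, 620.0))
    return CorneaTruth(
        epi_um=epi, bowman_um=bowman, stroma_to_flap_um=stroma_to_flap, total_um=total
    )


def evaluate_segmentation_accuracy(
    n_images: int = 50,
    seed: int = 0,
    geometry: OpticalGeometry | None = None,
    noise_level: float = 1.0,
    artifact_flags=DEFAULT_ARTIFACTS,
    params: SegmentationParams | None = None,
) -> pd.DataFrame:
    """Generate, segment, and score ``n_images`` seeded B-scans.

    Images alternate pre-/post-operative corneas with study-plausible
    randomized thicknesses.  Returns one row per image x layer with the
    true and estimated thickness and their absolute error (um).
    """
    geometry = geometry or OpticalGeometry()
    rng = np.random.default_rng(seed)
    image_seeds = rng.integers(0, 2**31 - 1, size=n_images)
    rows = []
    for i in range(n_images):
        post_op = i % 2 == 1
        truth = _draw_truth(rng, post_op)
        meta = BScanMeta(
            subject_id=f"V{i:03d}", visit="1W" if post_op else "PRE",
            scan_rep=1, seed=int(image_seeds[i]),
        )
        image, btruth = generate_bscan(
            truth, geometry=geometry, noise_level=noise_level,
            artifact_flags=artifact_flags, seed=int(image_seeds[i]), meta=meta,
        )
        iset = segment_bscan(image, params=params, post_op=post_op)
        est = interfaces_to_thickness(iset, geometry, meta=meta)
        for layer, true_um in btruth.thickness_um.items():
            est_um = est.as_dict()[layer]
            rows.append(
                {
                    "image": i,
                    "post_op": post_op,
                    "layer": layer,
                    "true_um": true_um,
                    "estimated_um": est_um,
                    "abs_error_um": abs(est_um - true_um),
                }
            )
    return pd.DataFrame(rows)


def mean_absolute_error(errors: pd.DataFrame) -> float:
    """Pooled MAE (um) over all images and layers."""
    return float(errors["abs_error_um"].mean())
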