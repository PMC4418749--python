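"""Reading and writing B-scans, ground-truth sidecars, and manifests.

Images are stored as 16-bit grayscale TIFF (or PNG); reflectivity is
mapped linearly from [0, INTENSITY_FULL_SCALE] to the uint16 range.
Each image may carry a JSON sidecar with acquisition metadata, raster
geometry, and (for synthetic data) the exact per-column interface
depths and true sublayer thicknesses.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .geometry import OpticalGeometry
from .simulate import BScanImage, BScanMeta, BScanTruth, CorneaTruth

#: Reflectivity value mapped to uint16 full scale on write.
INTENSITY_FULL_SCALE = 4.0

MANIFEST_COLUMNS = ("subject_id", "group", "visit", "scan_rep", "image_path", "truth_path")


def _encode(pixels: np.ndarray) -> np.ndarray:
    scaled = np.clip(pixels / INTENSITY_FULL_SCALE, 0.0, 1.0) * 65535.0
    return np.round(scaled).astype(np.uint16)


def _decode(raw: np.ndarray) -> np.ndarray:
    return raw.astype(float) * (INTENSITY_FULL_SCALE / 65535.0)


def write_bscan(image: BScanImage, path, truth: BScanTruth | None = None, truth_path=None):
    """Write a B-scan as 16-bit TIFF/PNG, optionally with its JSON sidecar."""
    path = Path(path)
    raw = _encode(image.pixels)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, raw)
    elif path.suffix.lower() == ".png":
        import imageio.v3 as iio

        iio.imwrite(path, raw)
    else:
        raise ValidationError(f"unsupported image format: {path.suffix}")
    if truth_path is not None:
        write_sidecar(image, Path(truth_path), truth)
    return path


def write_sidecar(image: BScanImage, path: Path, truth: BScanTruth | None):
    doc = {
        "meta": asdict(image.meta),
        "geometry": asdict(image.geometry),
    }
    if truth is not None:
        params = asdict(truth.params)
        params.pop("interface_reflectivities", None)
        doc["truth"] = {
            "params": params,
            "thickness_um": dict(truth.thickness_um),
            "reflex_column": truth.reflex_column,
            "interface_depth_px": {
                k: np.round(np.asarray(v), 4).tolist()
                for k, v in truth.interface_depth_px.items()
            },
        }
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(doc))


def read_bscan(path, truth_path=None):
    """Read a B-scan (and optional sidecar) back from disk.

    Returns ``(BScanImage, BScanTruth | None)``.  Without a sidecar the
    default geometry is assumed and metadata is minimal.
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        raw = tifffile.imread(path)
    elif path.suffix.lower() == ".png":
        import imageio.v3 as iio

        raw = iio.imread(path)
    else:
        raise ValidationError(f"unsupported image format: {path.suffix}")
    pixels = _decode(np.asarray(raw))

    geometry = OpticalGeometry(depth_px=pixels.shape[0], width_px=pixels.shape[1])
    meta = BScanMeta()
    truth = None
    if truth_path is not None and Path(truth_path).exists():
        doc = json.loads(Path(truth_path).read_text())
        geometry = OpticalGeometry(**doc["geometry"])
        meta = BScanMeta(**doc["meta"])
        if "truth" in doc:
            t = doc["truth"]
            truth = BScanTruth(
                params=CorneaTruth(**t["params"]),
                interface_depth_px={
                    k: np.asarray(v, dtype=float)
                    for k, v in t["interface_depth_px"].items()
                },
                thickness_um=t["thickness_um"],
                reflex_column=t.get("reflex_column"),
            )
    return BScanImage(pixels=pixels, geometry=geometry, meta=meta), truth


def write_manifest(manifest: pd.DataFrame, path):
    missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise ValidationError(f"manifest missing columns: {missing}")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    manifest.to_csv(path, index=False)
    return Path(path)


def read_manifest(path) -> pd.DataFrame:
    manifest = pd.read_csv(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise ValidationError(f"manifest missing columns: {missing}")
    return manifest
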