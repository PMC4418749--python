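"""Synthetic corneal B-scan generator with known ground truth.

Emulates anterior-segment UHR-OCT images of the central cornea before
and after thin-flap (sub-Bowman's) keratomileusis: four reflective
interfaces pre-operatively (air-epithelium, epithelium-Bowman's,
Bowman's-stroma, endothelium-aqueous) plus a flap interface
post-operatively, a central vertical specular reflex, horizontal
artifact bands, and multiplicative speckle.  Every generated image
carries exact per-column interface depths so downstream segmentation is
testable without any real acquisition.

Cohort-level generation reproduces a two-group (mechanical
microkeratome "Moria" vs femtosecond laser "FEMTO") five-visit study
design with two scan repetitions per visit: per-subject random
intercepts, per-visit biological variation, and independent per-scan
repeatability noise whose scan-pair difference SD matches a configured
target.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import GeometryError, ValidationError
from .geometry import OpticalGeometry

VISITS = ("PRE", "1D", "1W", "2W", "1M")
GROUPS = ("Moria", "FEMTO")
LAYERS = ("epithelium", "bowman", "flap", "total")
INTERFACES = ("air_epi", "epi_bowman", "bowman_stroma", "flap", "endo_aqueous")

#: Relative peak reflectivities of the corneal interfaces.  The
#: air-epithelium interface carries the largest index step and is the
#: brightest; intrastromal interfaces (flap) are the faintest.
DEFAULT_REFLECTIVITIES = {
    "air_epi": 1.0,
    "epi_bowman": 0.5,
    "bowman_stroma": 0.4,
    "flap": 0.35,
    "endo_aqueous": 0.7,
}

DEFAULT_ARTIFACTS = frozenset({"specular_reflex", "horizontal_bands"})

#: Lateral half-span (um from apex) over which all interfaces must stay
#: inside the raster; covers the reflex exclusion plus both flanking
#: analysis regions with margin.
_CENTRAL_SPAN_UM = 900.0

# Specular reflex model: a bright vertical streak with a Gaussian
# lateral footprint at the apex column.
_REFLEX_AMPLITUDE = 1.2
_REFLEX_SIGMA_COLS = 4.0
# Horizontal artifact bands: thin constant rows.
_N_HBANDS = 3
_HBAND_AMPLITUDE = 0.15
_HBAND_ROWS = 2
# Additive detector background noise sigma at noise_level = 1.
_BACKGROUND_SIGMA = 0.02


@dataclass(frozen=True)
class CorneaTruth:
    """Ground-truth description of one cornea (geometric thicknesses, um).

    ``stroma_to_flap_um`` is the anterior-stromal portion of the flap,
    i.e. flap thickness = epithelium + Bowman's + stroma_to_flap; it is
    ``None`` pre-operatively (no flap).  Microdistortion is a sinusoidal
    lateral perturbation of the Bowman's layer boundaries (amplitude 0
    disables it).
    """

    epi_um: float = 53.1
    bowman_um: float = 17.0
    stroma_to_flap_um: float | None = None
    total_um: float = 525.8
    anterior_radius_mm: float = 7.8
    apex_depth_um: float = 150.0
    apex_offset_px: float = 0.0
    microdistortion_amp_um: float = 0.0
    microdistortion_period_um: float = 150.0
    interface_reflectivities: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_REFLECTIVITIES)
    )

    def __post_init__(self):
        for name in ("epi_um", "bowman_um", "total_um", "apex_depth_um"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.anterior_radius_mm <= 0:
            raise ValidationError("anterior_radius_mm must be positive (use inf for flat)")
        if self.microdistortion_amp_um < 0:
            raise ValidationError("microdistortion_amp_um must be >= 0")
        if self.microdistortion_period_um <= 0:
            raise ValidationError("microdistortion_period_um must be positive")
        if self.stroma_to_flap_um is not None:
            if self.stroma_to_flap_um <= 0:
                raise ValidationError("stroma_to_flap_um must be positive")
            if not (self.epi_um + self.bowman_um < self.flap_um < self.total_um):
                raise ValidationError(
                    "flap must lie between epithelium+Bowman's and total thickness"
                )
        elif self.epi_um + self.bowman_um >= self.total_um:
            raise ValidationError("epithelium + Bowman's must be less than total")

    @property
    def flap_um(self) -> float | None:
        """Flap thickness (surface to flap interface), None pre-op."""
        if self.stroma_to_flap_um is None:
            return None
        return self.epi_um + self.bowman_um + self.stroma_to_flap_um

    def thickness_um(self) -> dict:
        out = {
            "epithelium": self.epi_um,
            "bowman": self.bowman_um,
            "total": self.total_um,
        }
        if self.stroma_to_flap_um is not None:
            out["flap"] = self.flap_um
        return out

    def interface_depths_um(
        self, geometry: OpticalGeometry, columns: np.ndarray | None = None
    ) -> dict:
        """Per-column optical-path depth (um from image top) of each interface.

        Columns laterally beyond the anterior radius of curvature get NaN.
        The depth axis stores optical path: the anterior surface sits in
        air (index 1), interfaces below it are offset by group_index x
        geometric thickness.  Paraxial model: no refraction bending.
        """
        if columns is None:
            columns = np.arange(geometry.width_px)
        columns = np.asarray(columns, dtype=float)
        x_um = (
            columns - (geometry.width_px - 1) / 2.0 - self.apex_offset_px
        ) * geometry.lateral_pitch_um
        r_um = self.anterior_radius_mm * 1000.0
        if math.isinf(r_um):
            sag = np.zeros_like(x_um)
        else:
            inside = np.abs(x_um) < r_um
            sag = np.full_like(x_um, np.nan)
            sag[inside] = r_um - np.sqrt(r_um**2 - x_um[inside] ** 2)
        n = geometry.group_index
        z0 = self.apex_depth_um + sag
        wiggle = 0.0
        if self.microdistortion_amp_um > 0:
            wiggle = n * self.microdistortion_amp_um * np.sin(
                2.0 * np.pi * x_um / self.microdistortion_period_um
            )
        depths = {
            "air_epi": z0,
            "epi_bowman": z0 + n * self.epi_um + wiggle,
            "bowman_stroma": z0 + n * (self.epi_um + self.bowman_um) + wiggle,
            "endo_aqueous": z0 + n * self.total_um,
        }
        if self.stroma_to_flap_um is not None:
            depths["flap"] = z0 + n * self.flap_um
        return {k: depths[k] for k in INTERFACES if k in depths}


@dataclass(frozen=True)
class BScanMeta:
    """Acquisition metadata attached to each B-scan."""

    subject_id: str = "S000"
    group: str = "Moria"
    visit: str = "PRE"
    scan_rep: int = 1
    seed: int | None = None


@dataclass
class BScanImage:
    """One B-scan: a non-negative reflectivity raster plus calibration."""

    pixels: np.ndarray
    geometry: OpticalGeometry
    meta: BScanMeta = field(default_factory=BScanMeta)

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.shape != (self.geometry.depth_px, self.geometry.width_px):
            raise GeometryError(
                f"raster shape {self.pixels.shape} does not match geometry "
                f"({self.geometry.depth_px}, {self.geometry.width_px})"
            )
        if not np.all(np.isfinite(self.pixels)):
            raise ValidationError("raster contains non-finite intensities")
        if np.any(self.pixels < 0):
            raise ValidationError("raster contains negative intensities")


@dataclass(frozen=True)
class BScanTruth:
    """Ground truth bundled with a generated image.

    ``interface_depth_px`` maps interface name to the exact per-column
    sub-pixel depth (optical-path pixels) after curvature and
    microdistortion; ``thickness_um`` holds geometric sublayer
    thicknesses.
    """

    params: CorneaTruth
    interface_depth_px: Mapping[str, np.ndarray]
    thickness_um: Mapping[str, float]
    reflex_column: int | None = None


def generate_bscan(
    truth: CorneaTruth,
    geometry: OpticalGeometry | None = None,
    noise_level: float = 1.0,
    artifact_flags: Iterable[str] = DEFAULT_ARTIFACTS,
    seed: int = 0,
    meta: BScanMeta | None = None,
) -> tuple[BScanImage, BScanTruth]:
    """Render one synthetic B-scan.

    Each interface is a curved ridge whose axial cross-section is a
    Gaussian with the geometry's PSF width.  ``noise_level`` scales both
    multiplicative speckle (fully developed exponential speckle at 1.0,
    the standard single-look caricature) and the additive background;
    0 gives a noiseless image.  ``artifact_flags`` may contain
    ``"specular_reflex"`` and ``"horizontal_bands"``.

    Returns the image and a :class:`BScanTruth` recording the exact
    per-column interface depths in pixels.
    """
    geometry = geometry or OpticalGeometry()
    flags = set(artifact_flags)
    unknown = flags - {"specular_reflex", "horizontal_bands"}
    if unknown:
        raise ValidationError(f"unknown artifact flags: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    pitch = geometry.axial_pitch_um
    sigma_px = geometry.axial_psf_sigma_px

    depths_um = truth.interface_depths_um(geometry)
    depths_px = {k: v / pitch for k, v in depths_um.items()}

    # The central analysis span must fit entirely inside the raster.
    cols = np.arange(geometry.width_px)
    x_um = (
        cols - (geometry.width_px - 1) / 2.0 - truth.apex_offset_px
    ) * geometry.lateral_pitch_um
    central = np.abs(x_um) <= _CENTRAL_SPAN_UM
    margin = 4.0 * sigma_px
    for name, z in depths_px.items():
        zc = z[central]
        if np.any(~np.isfinite(zc)) or np.any(zc < margin) or np.any(
            zc > geometry.depth_px - 1 - margin
        ):
            raise GeometryError(
                f"interface '{name}' falls outside the raster in the central region"
            )

    img = np.zeros((geometry.depth_px, geometry.width_px), dtype=float)
    rows = np.arange(geometry.depth_px, dtype=float)[:, None]
    refl = dict(DEFAULT_REFLECTIVITIES)
    refl.update(truth.interface_reflectivities)
    for name, z in depths_px.items():
        amp = refl[name]
        valid = np.isfinite(z) & (z > -6 * sigma_px) & (z < geometry.depth_px + 6 * sigma_px)
        if not np.any(valid):
            continue
        d = (rows - z[None, valid]) / sigma_px
        with np.errstate(under="ignore"):
            img[:, valid] += amp * np.exp(-0.5 * d * d)

    reflex_col = None
    if "specular_reflex" in flags:
        reflex_col = int(round((geometry.width_px - 1) / 2.0 + truth.apex_offset_px))
        lat = np.exp(-0.5 * ((cols - reflex_col) / _REFLEX_SIGMA_COLS) ** 2)
        img += _REFLEX_AMPLITUDE * lat[None, :]
    if "horizontal_bands" in flags:
        band_rows = rng.integers(
            int(0.05 * geometry.depth_px), int(0.95 * geometry.depth_px), size=_N_HBANDS
        )
        for r in band_rows:
            img[r : r + _HBAND_ROWS, :] += _HBAND_AMPLITUDE

    if noise_level > 0:
        w = min(float(noise_level), 1.0)
        img *= (1.0 - w) + w * rng.exponential(1.0, size=img.shape)
        img += rng.normal(0.0, _BACKGROUND_SIGMA * noise_level, size=img.shape)
        np.clip(img, 0.0, None, out=img)

    meta = meta or BScanMeta(seed=seed)
    if meta.seed is None:
        meta = replace(meta, seed=seed)
    image = BScanImage(pixels=img, geometry=geometry, meta=meta)
    bt = BScanTruth(
        params=truth,
        interface_depth_px=depths_px,
        thickness_um=truth.thickness_um(),
        reflex_column=reflex_col,
    )
    return image, bt


# ---------------------------------------------------------------------------
# Cohort-level generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortDesign:
    """Statistical design of a simulated two-scan five-visit cohort.

    ``means_um[group][layer][visit]`` are the true population means;
    the flap layer has no PRE entry.  Between-subject variation is split
    into a per-subject random intercept and an independent per-visit
    biological deviation: intercept SD = sqrt(between_sd^2 - visit_sd^2)
    so the cross-sectional SD at any visit matches ``between_sd_um``.
    Per scan repetition an independent measurement error with SD
    ``pair_diff_sd_um / sqrt(2)`` is added, so the difference of the two
    scans of a visit has SD equal to the configured target.
    """

    n_per_group: Mapping[str, int]
    means_um: Mapping[str, Mapping[str, Mapping[str, float]]]
    between_sd_um: Mapping[str, Mapping[str, float]]
    visit_sd_um: Mapping[str, Mapping[str, float]]
    pair_diff_sd_um: Mapping[str, Mapping[str, float]]
    visits: Sequence[str] = VISITS
    max_resample: int = 100

    def __post_init__(self):
        if tuple(self.visits) != VISITS:
            raise ValidationError(f"visits must be exactly {VISITS}")
        for g, n in self.n_per_group.items():
            if n < 1:
                raise ValidationError(f"group {g}: sample size must be >= 1")
            if g not in self.means_um:
                raise ValidationError(f"group {g}: no means configured")
        for table in (self.between_sd_um, self.visit_sd_um, self.pair_diff_sd_um):
            for g, layers in table.items():
                for layer, sd in layers.items():
                    if sd < 0:
                        raise ValidationError(f"{g}/{layer}: SD must be >= 0")


def default_study_design(
    n_per_group: Mapping[str, int] | None = None,
) -> CohortDesign:
    """Study-conditions design: a 20-subject microkeratome group and a
    21-subject femtosecond group, five visits, typical thin-flap SBK
    sublayer trajectories (flap only after surgery, large post-ablation
    drop in total thickness, ~+1.6 um Bowman's thickening at day 1)."""
    means = {
        "Moria": {
            "epithelium": {"PRE": 53.1, "1D": 56.0, "1W": 54.4, "2W": 55.7, "1M": 56.9},
            "bowman": {"PRE": 17.0, "1D": 18.5, "1W": 18.0, "2W": 18.1, "1M": 18.4},
            "flap": {"1D": 95.8, "1W": 95.5, "2W": 96.5, "1M": 98.2},
            "total": {"PRE": 525.8, "1D": 439.5, "1W": 431.6, "2W": 432.0, "1M": 434.2},
        },
        "FEMTO": {
            "epithelium": {"PRE": 51.9, "1D": 54.5, "1W": 53.2, "2W": 53.2, "1M": 55.2},
            "bowman": {"PRE": 15.7, "1D": 17.4, "1W": 17.2, "2W": 17.1, "1M": 17.8},
            "flap": {"1D": 105.6, "1W": 106.3, "2W": 105.7, "1M": 107.5},
            "total": {"PRE": 521.7, "1D": 453.1, "1W": 443.7, "2W": 441.7, "1M": 445.0},
        },
    }
    # Cross-sectional between-subject SDs (taken at the week-1 visit).
    between = {
        "Moria": {"epithelium": 3.6, "bowman": 1.5, "flap": 7.8, "total": 23.6},
        "FEMTO": {"epithelium": 3.1, "bowman": 1.2, "flap": 8.6, "total": 37.8},
    }
    # Within-subject visit-to-visit biological variation.
    visit_sd = {
        "Moria": {"epithelium": 1.8, "bowman": 0.9, "flap": 1.8, "total": 4.0},
        "FEMTO": {"epithelium": 1.8, "bowman": 0.9, "flap": 1.8, "total": 4.0},
    }
    # Target SD of the difference between the two scans of one visit.
    pair_sd = {
        "Moria": {"epithelium": 1.22, "bowman": 0.61, "flap": 1.80, "total": 4.29},
        "FEMTO": {"epithelium": 1.02, "bowman": 0.48, "flap": 2.00, "total": 4.71},
    }
    return CohortDesign(
        n_per_group=dict(n_per_group or {"Moria": 20, "FEMTO": 21}),
        means_um=means,
        between_sd_um=between,
        visit_sd_um=visit_sd,
        pair_diff_sd_um=pair_sd,
    )


def _ordered(epi, bowman, flap, total) -> bool:
    for v in (epi, bowman, flap, total):
        if v is not None and v <= 0:
            return False
    if epi is None or bowman is None or total is None:
        return True  # partial layer sets: positivity is all we can check
    if flap is None:
        return epi + bowman < total
    return epi + bowman < flap < total


def _draw_subject(rng, design, group, subject, layers, intercept, gmeans):
    """Draw all visits and scans for one subject, or None on failure."""
    out = []
    for visit in design.visits:
        present = [l for l in layers if visit in gmeans[l]]
        true = None
        for attempt in range(design.max_resample):
            cand = {
                l: gmeans[l][visit]
                + intercept[l]
                + rng.normal(0.0, design.visit_sd_um[group].get(l, 0.0))
                for l in present
            }
            if _ordered(
                cand.get("epithelium"), cand.get("bowman"),
                cand.get("flap"), cand.get("total"),
            ) and all(v > 0 for v in cand.values()):
                true = cand
                break
        if true is None:
            return None
        for rep in (1, 2):
            meas = None
            for attempt in range(design.max_resample):
                cand = {
                    l: true[l]
                    + rng.normal(
                        0.0,
                        design.pair_diff_sd_um[group].get(l, 0.0) / math.sqrt(2.0),
                    )
                    for l in present
                }
                if _ordered(
                    cand.get("epithelium"), cand.get("bowman"),
                    cand.get("flap"), cand.get("total"),
                ) and all(v > 0 for v in cand.values()):
                    meas = cand
                    break
            if meas is None:
                return None
            out.append(
                {
                    "subject_id": subject,
                    "group": group,
                    "visit": visit,
                    "scan_rep": rep,
                    "epithelium_um": meas.get("epithelium", np.nan),
                    "bowman_um": meas.get("bowman", np.nan),
                    "flap_um": meas.get("flap", np.nan),
                    "total_um": meas.get("total", np.nan),
                }
            )
    return out


def sample_cohort_truth(design: CohortDesign, seed: int = 0) -> pd.DataFrame:
    """Draw per-scan true sublayer thicknesses for a whole cohort.

    Returns a wide table with one row per subject x visit x scan
    repetition and columns ``epithelium_um``, ``bowman_um``, ``flap_um``
    (NaN pre-op) and ``total_um``.  Non-physical draws (non-positive or
    mis-ordered thicknesses) are resampled with a warning, up to
    ``design.max_resample`` attempts.
    """
    rng = np.random.default_rng(seed)
    rows = []
    warned = False
    for group, n in design.n_per_group.items():
        gmeans = design.means_um[group]
        layers = [l for l in LAYERS if l in gmeans]
        isd = {}
        for l in layers:
            b = design.between_sd_um[group].get(l, 0.0)
            v = design.visit_sd_um[group].get(l, 0.0)
            isd[l] = math.sqrt(max(b * b - v * v, 0.0))
        for i in range(n):
            subject = f"{group}-{i:03d}"
            subject_rows = None
            # A pathological random intercept (e.g. flap drawn close to
            # epithelium + Bowman's) can make every visit-level draw
            # non-physical, so the whole subject is redrawn in that case.
            for subject_attempt in range(design.max_resample):
                intercept = {l: rng.normal(0.0, isd[l]) for l in layers}
                subject_rows = _draw_subject(
                    rng, design, group, subject, layers, intercept, gmeans
                )
                if subject_rows is not None:
                    break
                if not warned:
                    warnings.warn("resampled a non-physical thickness draw")
                    warned = True
            if subject_rows is None:
                raise ValidationError(
                    f"could not draw physical thicknesses for {subject}"
                )
            rows.extend(subject_rows)
    return pd.DataFrame(rows)


def truth_from_row(row: Mapping, **kwargs) -> CorneaTruth:
    """Build a renderable :class:`CorneaTruth` from one cohort-truth row."""
    flap = row.get("flap_um")
    stroma_to_flap = None
    if flap is not None and np.isfinite(flap):
        stroma_to_flap = float(flap) - float(row["epithelium_um"]) - float(row["bowman_um"])
    return CorneaTruth(
        epi_um=float(row["epithelium_um"]),
        bowman_um=float(row["bowman_um"]),
        stroma_to_flap_um=stroma_to_flap,
        total_um=float(row["total_um"]),
        **kwargs,
    )


def generate_cohort(
    design: CohortDesign,
    seed: int = 0,
    outdir=None,
    geometry: OpticalGeometry | None = None,
    noise_level: float = 1.0,
    artifact_flags: Iterable[str] = DEFAULT_ARTIFACTS,
    truth_kwargs: Mapping | None = None,
):
    """Generate a full cohort of B-scans plus a manifest table.

    With ``outdir`` set, images (16-bit TIFF) and ground-truth JSON
    sidecars are written to disk one scan at a time and the manifest's
    ``image_path``/``truth_path`` columns point at them; otherwise all
    images are returned in memory (only sensible for small designs).

    Returns ``(images_or_paths, manifest)`` where the manifest has one
    row per scan: subject_id, group, visit, scan_rep, image_path,
    truth_path and the true sublayer thicknesses.
    """
    from . import io as _io  # local import to avoid a cycle

    geometry = geometry or OpticalGeometry()
    truth_kwargs = dict(truth_kwargs or {})
    truth_df = sample_cohort_truth(design, seed=seed)
    image_seeds = np.random.default_rng(seed + 1).integers(
        0, 2**31 - 1, size=len(truth_df)
    )
    images = []
    manifest_rows = []
    if outdir is not None:
        from pathlib import Path

        outdir = Path(outdir)
        (outdir / "images").mkdir(parents=True, exist_ok=True)
        (outdir / "truth").mkdir(parents=True, exist_ok=True)
    for idx, row in truth_df.reset_index(drop=True).iterrows():
        truth = truth_from_row(row, **truth_kwargs)
        meta = BScanMeta(
            subject_id=row["subject_id"],
            group=row["group"],
            visit=row["visit"],
            scan_rep=int(row["scan_rep"]),
            seed=int(image_seeds[idx]),
        )
        image, btruth = generate_bscan(
            truth,
            geometry=geometry,
            noise_level=noise_level,
            artifact_flags=artifact_flags,
            seed=int(image_seeds[idx]),
            meta=meta,
        )
        stem = f"{meta.subject_id}_{meta.visit}_s{meta.scan_rep}"
        if outdir is not None:
            image_path = outdir / "images" / f"{stem}.tif"
            truth_path = outdir / "truth" / f"{stem}.json"
            _io.write_bscan(image, image_path, truth=btruth, truth_path=truth_path)
            images.append(str(image_path))
        else:
            image_path = truth_path = ""
            images.append((image, btruth))
        manifest_rows.append(
            {
                "subject_id": meta.subject_id,
                "group": meta.group,
                "visit": meta.visit,
                "scan_rep": meta.scan_rep,
                "image_path": str(image_path),
                "truth_path": str(truth_path),
                "epithelium_um": row["epithelium_um"],
                "bowman_um": row["bowman_um"],
                "flap_um": row["flap_um"],
                "total_um": row["total_um"],
            }
        )
    manifest = pd.DataFrame(manifest_rows)
    return images, manifest
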