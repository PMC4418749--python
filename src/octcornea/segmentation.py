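"""Automated corneal sublayer segmentation from axial reflectivity peaks.

The processing chain mirrors clinical anterior-segment UHR-OCT
practice:

1. *Preprocess*: light median filtering, removal of horizontal artifact
   bands by row-robust baseline subtraction, location of the central
   specular reflex (or of the corneal apex when no reflex is present),
   exclusion of the 128 A-scans around it, and bookkeeping of two
   0.5-mm flanking analysis regions.
2. *Profiles*: within each flanking region the A-scans are flattened to
   the local air-epithelium ridge and averaged into one longitudinal
   reflectivity profile.
3. *Interfaces*: local maxima of each profile are assigned in depth
   order to the air-epithelium, epithelium-Bowman's, Bowman's-stroma,
   (post-operative) flap, and endothelium-aqueous interfaces, each
   constrained to an anatomical plausibility window, with sub-pixel
   refinement by a parabolic fit through the peak and its neighbours.

Failed assignments raise :class:`~octcornea.errors.SegmentationError`
with QC flags; a manual-override path replaces flagged interfaces with
operator-supplied depths.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.ndimage import median_filter, uniform_filter1d
from scipy.signal import find_peaks
from scipy.stats import median_abs_deviation

from .errors import DetectionError, GeometryError, SegmentationError, ValidationError
from .geometry import OpticalGeometry
from .simulate import INTERFACES, BScanImage, BScanMeta

_INTERFACE_ORDER = INTERFACES  # air_epi, epi_bowman, bowman_stroma, flap, endo_aqueous


@dataclass(frozen=True)
class PlausibilityWindows:
    """Anatomical windows (geometric um) constraining peak assignment.

    Epithelium and Bowman's windows are measured from the previous
    interface; flap and total windows from the anterior surface.
    Defaults bracket published central corneal anatomy (epithelium
    ~50-52 um, Bowman's layer ~8-20 um, thin SBK flaps ~90-110 um).
    """

    epithelium_um: tuple = (35.0, 75.0)
    bowman_um: tuple = (8.0, 30.0)
    flap_from_surface_um: tuple = (70.0, 140.0)
    total_from_surface_um: tuple = (350.0, 700.0)


@dataclass(frozen=True)
class SegmentationParams:
    median_size: int = 3              # lateral median prefilter width (A-scans)
    lateral_smooth_px: int = 25       # lateral smoothing for masks/traces
    support_rel_threshold: float = 0.15
    exclusion_columns: int = 128      # A-scans removed around the reflex
    region_width_um: float = 500.0    # width of each flanking region
    reflex_energy_ratio: float = 5.0  # column-energy ratio flagging a reflex
    peak_prominence_nsigma: float = 3.0
    peak_prominence_rel_floor: float = 0.08  # fraction of profile max
    surface_peak_rel_height: float = 0.4     # air-epi peak vs tallest peak
    windows: PlausibilityWindows = field(default_factory=PlausibilityWindows)


@dataclass
class PreprocessedImage:
    pixels: np.ndarray
    geometry: OpticalGeometry
    meta: BScanMeta
    excluded_columns: range
    analysis_regions: tuple
    reflex_column: int | None


@dataclass
class AxialProfile:
    """Averaged longitudinal reflectivity profile of one flanking region."""

    depth_px: np.ndarray
    reflectivity: np.ndarray
    geometry: OpticalGeometry
    provenance: str = ""
    column_offsets: np.ndarray | None = None

    def __post_init__(self):
        if len(self.depth_px) != len(self.reflectivity):
            raise ValidationError("depth and reflectivity vectors differ in length")
        if not np.all(np.isfinite(self.reflectivity)):
            raise ValidationError("profile reflectivity contains non-finite values")


@dataclass(frozen=True)
class InterfaceSet:
    """Sub-pixel interface depths for one measurement (optical px)."""

    air_epi_px: float
    epi_bowman_px: float
    bowman_stroma_px: float
    endo_aqueous_px: float
    flap_px: float | None = None
    qc_flags: tuple = ()
    provenance: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        d = self.depths()
        vals = [d[k] for k in _INTERFACE_ORDER if k in d]
        if any(b <= a for a, b in zip(vals, vals[1:])):
            raise ValidationError(f"interface depths are not strictly increasing: {d}")

    def depths(self) -> dict:
        out = {
            "air_epi": self.air_epi_px,
            "epi_bowman": self.epi_bowman_px,
            "bowman_stroma": self.bowman_stroma_px,
            "endo_aqueous": self.endo_aqueous_px,
        }
        if self.flap_px is not None:
            out["flap"] = self.flap_px
        return {k: out[k] for k in _INTERFACE_ORDER if k in out}


# ---------------------------------------------------------------------------
# Anterior-surface tracing and apex localisation
# ---------------------------------------------------------------------------

def _anterior_trace(pixels: np.ndarray, smooth_px: int, min_rel: float = 0.3):
    """Per-column anterior-surface row via first half-maximum crossing.

    Lateral smoothing makes the trace robust to speckle; the first
    crossing of half the column maximum always lands on the shallowest
    (air-epithelium) ridge, which is also the brightest.  Column
    validity is judged against the *median* column maximum, which a
    single speckle spike cannot inflate.
    """
    sm = uniform_filter1d(pixels, size=max(smooth_px, 1), axis=1, mode="nearest")
    colmax = sm.max(axis=0)
    valid = colmax > min_rel * np.median(colmax)
    if np.median(colmax) <= 0:
        valid = np.zeros_like(valid)
    trace = np.full(pixels.shape[1], -1, dtype=int)
    if np.any(valid):
        above = sm[:, valid] >= 0.5 * colmax[valid]
        trace[valid] = np.argmax(above, axis=0)
    return trace, valid


def locate_apex(image: BScanImage | np.ndarray, params: SegmentationParams | None = None) -> int:
    """Lateral index where the air-epithelium interface is shallowest.

    Ties (e.g. a flat cornea) resolve to the midmost tied column so the
    result is deterministic.
    """
    params = params or SegmentationParams()
    pixels = image.pixels if isinstance(image, BScanImage) else np.asarray(image)
    trace, valid = _anterior_trace(pixels, params.lateral_smooth_px)
    if not np.any(valid):
        raise DetectionError("no detectable anterior surface")
    vmin = trace[valid].min()
    tied = np.flatnonzero(valid & (trace == vmin))
    return int(tied[len(tied) // 2])


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def _remove_horizontal_baseline(px: np.ndarray, params: SegmentationParams) -> np.ndarray:
    """Subtract a per-row robust baseline estimated outside ridge support.

    Horizontal artifact bands are constant across columns, so the row
    median over non-ridge columns estimates them; rows almost fully
    covered by ridge support (a flat cornea's own ridge) are left
    untouched rather than self-subtracted.
    """
    sm = uniform_filter1d(px, size=params.lateral_smooth_px, axis=1, mode="nearest")
    support = sm > params.support_rel_threshold * sm.max()
    off_support = np.where(support, np.nan, px)
    frac_support = support.mean(axis=1)
    with np.errstate(invalid="ignore"):
        import warnings as _w

        with _w.catch_warnings():
            _w.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
            baseline = np.nanmedian(off_support, axis=1)
    baseline = np.where(np.isnan(baseline) | (frac_support > 0.8), 0.0, baseline)
    return np.clip(px - baseline[:, None], 0.0, None)


def preprocess(image: BScanImage, params: SegmentationParams | None = None) -> PreprocessedImage:
    """Noise/artifact suppression plus reflex exclusion bookkeeping.

    The specular reflex is located as the column of maximal total
    energy when that energy is anomalously high relative to the median
    column; otherwise the exclusion window is centred on the apex.
    Exactly ``exclusion_columns`` A-scans are excluded (left-biased
    centring for even counts) and two ``region_width_um``-wide flanking
    analysis regions are recorded.
    """
    params = params or SegmentationParams()
    geom = image.geometry
    region_cols = int(round(params.region_width_um / geom.lateral_pitch_um))
    needed = params.exclusion_columns + 2 * region_cols
    if geom.width_px < needed:
        raise GeometryError(
            f"image width {geom.width_px} px cannot host the {params.exclusion_columns}-column "
            f"exclusion plus two {region_cols}-column regions ({needed} px needed)"
        )

    # Median filtering runs laterally only (across neighbouring A-scans):
    # the axial PSF is ~2 px wide, so any axial filtering would distort
    # the very peaks being localised.
    px = image.pixels
    if params.median_size > 1:
        px = median_filter(px, size=(1, params.median_size))
    px = _remove_horizontal_baseline(px, params)

    energy = px.sum(axis=0)
    med_energy = np.median(energy)
    reflex_column = None
    if med_energy > 0 and energy.max() > params.reflex_energy_ratio * med_energy:
        reflex_column = int(np.argmax(energy))
    center = reflex_column if reflex_column is not None else locate_apex(px, params)

    start = center - params.exclusion_columns // 2
    start = int(np.clip(start, region_cols, geom.width_px - params.exclusion_columns - region_cols))
    excluded = range(start, start + params.exclusion_columns)
    regions = (
        range(start - region_cols, start),
        range(excluded.stop, excluded.stop + region_cols),
    )
    px = px.copy()
    px[:, excluded.start : excluded.stop] = 0.0
    return PreprocessedImage(
        pixels=px,
        geometry=geom,
        meta=image.meta,
        excluded_columns=excluded,
        analysis_regions=regions,
        reflex_column=reflex_column,
    )


# ---------------------------------------------------------------------------
# Longitudinal profiles
# ---------------------------------------------------------------------------

def build_profiles(pre: PreprocessedImage, params: SegmentationParams | None = None):
    """One depth-aligned averaged profile per flanking region.

    Each region's A-scans are shifted (integer rows) so their
    air-epithelium crossing sits at the region's median surface row,
    then averaged column-wise.  Alignment offsets are recorded on the
    returned profiles.
    """
    params = params or SegmentationParams()
    profiles = []
    for region in pre.analysis_regions:
        sub = pre.pixels[:, region.start : region.stop]
        trace, valid = _anterior_trace(sub, smooth_px=9)
        if valid.mean() < 0.9:
            raise DetectionError(
                f"anterior surface undetectable in region [{region.start}:{region.stop})"
            )
        # Refine the coarse half-max trace to the sub-pixel ridge centre
        # (argmax + parabola near the trace on the laterally smoothed
        # image); rounding that to integer shifts leaves only ~0.3 px of
        # alignment jitter, keeping the averaged peak near PSF width.
        sm = uniform_filter1d(sub, size=9, axis=1, mode="nearest")
        fine = np.full(sub.shape[1], np.nan)
        for c in np.flatnonzero(valid):
            lo = max(int(trace[c]) - 3, 1)
            hi = min(int(trace[c]) + 6, sub.shape[0] - 1)
            p = lo + int(np.argmax(sm[lo:hi, c]))
            fine[c] = _parabolic_refine(sm[:, c], p)
        ref = int(round(np.nanmedian(fine)))
        shifts = np.round(fine[valid] - ref).astype(int)
        cols = np.flatnonzero(valid)
        depth = sub.shape[0]
        acc = np.zeros(depth)
        for c, s in zip(cols, shifts):
            col = sub[:, c]
            if s > 0:
                acc[: depth - s] += col[s:]
            elif s < 0:
                acc[-s:] += col[: depth + s]
            else:
                acc += col
        profile = acc / len(cols)
        profiles.append(
            AxialProfile(
                depth_px=np.arange(depth, dtype=float),
                reflectivity=profile,
                geometry=pre.geometry,
                provenance=f"region[{region.start}:{region.stop})",
                column_offsets=shifts,
            )
        )
    return profiles


# ---------------------------------------------------------------------------
# Peak detection and interface assignment
# ---------------------------------------------------------------------------

def _parabolic_refine(y: np.ndarray, p: int) -> float:
    """Sub-pixel vertex of the parabola through (p-1, p, p+1)."""
    if p <= 0 or p >= len(y) - 1:
        return float(p)
    denom = y[p - 1] - 2.0 * y[p] + y[p + 1]
    if denom >= 0:
        return float(p)
    return p + 0.5 * (y[p - 1] - y[p + 1]) / denom


def _first_in(positions, lo, hi, after=-np.inf):
    for pos in positions:
        if pos > after and lo <= pos <= hi:
            return pos
    return None


def detect_interfaces(
    profile: AxialProfile,
    post_op: bool,
    params: SegmentationParams | None = None,
) -> InterfaceSet:
    """Assign ordered reflectivity peaks to corneal interfaces.

    Local maxima exceeding a prominence of ``peak_prominence_nsigma``
    robust noise SDs are located; the first peak is the air-epithelium
    interface and each subsequent interface is the shallowest remaining
    peak inside its plausibility window.  Sub-pixel positions come from
    a parabolic fit through each peak and its two neighbours.
    """
    params = params or SegmentationParams()
    y = np.asarray(profile.reflectivity, dtype=float)
    if y.max() <= 0:
        raise SegmentationError("profile has no signal", qc_flags=("no_signal",))
    # Noise scale from the deep tail of the profile (below the cornea),
    # with a relative floor so residual speckle shoulders on the ridges
    # never count as interfaces.
    tail = y[int(0.9 * len(y)):]
    noise_sd = median_abs_deviation(tail, scale="normal") if len(tail) > 3 else 0.0
    prominence = max(
        params.peak_prominence_nsigma * noise_sd,
        params.peak_prominence_rel_floor * y.max(),
        1e-9,
    )
    peaks, _ = find_peaks(y, prominence=prominence)
    if len(peaks) == 0:
        raise SegmentationError("no reflectivity peaks found", qc_flags=("no_peaks",))
    positions = [_parabolic_refine(y, int(p)) for p in peaks]
    heights = y[peaks]

    geom = profile.geometry
    to_px = geom.geometric_um_to_optical_px
    w = params.windows
    # The air-epithelium interface is the shallowest *strong* peak (the
    # largest index step in the cornea), not just the first local max.
    strong = heights >= params.surface_peak_rel_height * heights.max()
    if not np.any(strong):
        raise SegmentationError("no surface peak found", qc_flags=("missing:air_epi",))
    air = positions[int(np.flatnonzero(strong)[0])]
    assigned = {"air_epi": air}
    missing = []

    epi = _first_in(positions, air + to_px(w.epithelium_um[0]),
                    air + to_px(w.epithelium_um[1]), after=air)
    if epi is None:
        missing.append("epi_bowman")
    else:
        assigned["epi_bowman"] = epi
        bow = _first_in(positions, epi + to_px(w.bowman_um[0]),
                        epi + to_px(w.bowman_um[1]), after=epi)
        if bow is None:
            missing.append("bowman_stroma")
        else:
            assigned["bowman_stroma"] = bow
    if post_op:
        prev = assigned.get("bowman_stroma", air)
        flap = _first_in(positions, air + to_px(w.flap_from_surface_um[0]),
                         air + to_px(w.flap_from_surface_um[1]), after=prev)
        if flap is None:
            missing.append("flap")
        else:
            assigned["flap"] = flap
    prev = max(assigned.values())
    endo = _first_in(positions, air + to_px(w.total_from_surface_um[0]),
                     air + to_px(w.total_from_surface_um[1]), after=prev)
    if endo is None:
        missing.append("endo_aqueous")
    else:
        assigned["endo_aqueous"] = endo

    if missing:
        raise SegmentationError(
            f"could not assign interfaces: {missing} "
            f"({len(positions)} peaks detected in {profile.provenance or 'profile'})",
            qc_flags=tuple(f"missing:{m}" for m in missing),
        )
    return InterfaceSet(
        air_epi_px=assigned["air_epi"],
        epi_bowman_px=assigned["epi_bowman"],
        bowman_stroma_px=assigned["bowman_stroma"],
        flap_px=assigned.get("flap"),
        endo_aqueous_px=assigned["endo_aqueous"],
        provenance={k: "auto" for k in assigned},
    )


def apply_manual_override(iset: InterfaceSet, override: Mapping[str, float]) -> InterfaceSet:
    """Replace selected interface depths with operator-supplied values.

    Overridden interfaces are marked with provenance ``"manual"``.  The
    merged set must remain strictly increasing in depth.
    """
    if not override:
        return iset
    unknown = set(override) - set(_INTERFACE_ORDER)
    if unknown:
        raise ValidationError(f"unknown interfaces in override: {sorted(unknown)}")
    vals = [override[k] for k in _INTERFACE_ORDER if k in override]
    if any(b <= a for a, b in zip(vals, vals[1:])):
        raise ValidationError("override depths must be strictly increasing")
    depths = iset.depths()
    depths.update(override)
    provenance = dict(iset.provenance)
    provenance.update({k: "manual" for k in override})
    return InterfaceSet(
        air_epi_px=depths["air_epi"],
        epi_bowman_px=depths["epi_bowman"],
        bowman_stroma_px=depths["bowman_stroma"],
        flap_px=depths.get("flap"),
        endo_aqueous_px=depths["endo_aqueous"],
        qc_flags=iset.qc_flags,
        provenance=provenance,
    )


def _average_interface_sets(sets) -> InterfaceSet:
    """Mean of per-region interface depths -> one central measurement."""
    flaps = [s.flap_px for s in sets]
    if any(f is None for f in flaps) != all(f is None for f in flaps):
        raise ValidationError("regions disagree on flap presence")
    provenance = {}
    for s in sets:
        for k, v in s.provenance.items():
            provenance[k] = v if provenance.get(k, v) == v else "mixed"
    return InterfaceSet(
        air_epi_px=float(np.mean([s.air_epi_px for s in sets])),
        epi_bowman_px=float(np.mean([s.epi_bowman_px for s in sets])),
        bowman_stroma_px=float(np.mean([s.bowman_stroma_px for s in sets])),
        flap_px=None if flaps[0] is None else float(np.mean(flaps)),
        endo_aqueous_px=float(np.mean([s.endo_aqueous_px for s in sets])),
        qc_flags=tuple(sorted({f for s in sets for f in s.qc_flags})),
        provenance=provenance,
    )


def segment_bscan(
    image: BScanImage,
    params: SegmentationParams | None = None,
    post_op: bool | None = None,
) -> InterfaceSet:
    """Full single-scan segmentation: preprocess, profile, detect, average.

    The two flanking-region interface sets are averaged into one central
    measurement.  ``post_op`` defaults to ``meta.visit != "PRE"``.
    """
    params = params or SegmentationParams()
    if post_op is None:
        post_op = image.meta.visit != "PRE"
    pre = preprocess(image, params)
    profiles = build_profiles(pre, params)
    sets = [detect_interfaces(p, post_op=post_op, params=params) for p in profiles]
    return _average_interface_sets(sets)
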