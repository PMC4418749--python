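"""Interface depths -> geometric sublayer thicknesses -> cohort table.

Depth-pixel separations are optical path; dividing the optical
distance by the corneal group index (1.376) yields geometric
thickness:  um_geometric = delta_px * axial_pitch_um / group_index.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .geometry import OpticalGeometry
from .segmentation import InterfaceSet
from .simulate import BScanMeta, LAYERS


@dataclass(frozen=True)
class SublayerThickness:
    """Geometric sublayer thicknesses (um) for one scan."""

    epithelium_um: float
    bowman_um: float
    total_um: float
    flap_um: float | None = None
    meta: BScanMeta | None = None

    def __post_init__(self):
        vals = {"epithelium_um": self.epithelium_um, "bowman_um": self.bowman_um,
                "total_um": self.total_um}
        if self.flap_um is not None:
            vals["flap_um"] = self.flap_um
        for name, v in vals.items():
            if not np.isfinite(v) or v <= 0:
                raise ValidationError(f"{name} must be positive and finite, got {v}")
        if self.flap_um is not None:
            if not (self.epithelium_um + self.bowman_um <= self.flap_um <= self.total_um):
                raise ValidationError(
                    "layer-sum invariant violated: epithelium + Bowman's <= flap <= total"
                )
        elif self.epithelium_um + self.bowman_um > self.total_um:
            raise ValidationError("epithelium + Bowman's exceeds total thickness")

    def as_dict(self) -> dict:
        out = {
            "epithelium": self.epithelium_um,
            "bowman": self.bowman_um,
            "total": self.total_um,
        }
        if self.flap_um is not None:
            out["flap"] = self.flap_um
        return out


def interfaces_to_thickness(
    iset: InterfaceSet, geometry: OpticalGeometry, meta: BScanMeta | None = None
) -> SublayerThickness:
    """Convert one interface set to geometric sublayer thicknesses."""
    to_um = geometry.optical_px_to_geometric_um
    flap = None
    if iset.flap_px is not None:
        flap = to_um(iset.flap_px - iset.air_epi_px)
    return SublayerThickness(
        epithelium_um=to_um(iset.epi_bowman_px - iset.air_epi_px),
        bowman_um=to_um(iset.bowman_stroma_px - iset.epi_bowman_px),
        flap_um=flap,
        total_um=to_um(iset.endo_aqueous_px - iset.air_epi_px),
        meta=meta,
    )


def average_scans(s1: SublayerThickness, s2: SublayerThickness) -> SublayerThickness:
    """Element-wise mean of the two scan repetitions of one visit."""
    if (s1.flap_um is None) != (s2.flap_um is None):
        raise ValidationError("scans disagree on flap availability")
    if s1.meta is not None and s2.meta is not None:
        if (s1.meta.subject_id, s1.meta.visit) != (s2.meta.subject_id, s2.meta.visit):
            raise ValidationError("scans belong to different subject/visit")
    meta = s1.meta if s1.meta is None else replace(s1.meta, scan_rep=0)
    return SublayerThickness(
        epithelium_um=(s1.epithelium_um + s2.epithelium_um) / 2.0,
        bowman_um=(s1.bowman_um + s2.bowman_um) / 2.0,
        flap_um=None if s1.flap_um is None else (s1.flap_um + s2.flap_um) / 2.0,
        total_um=(s1.total_um + s2.total_um) / 2.0,
        meta=meta,
    )


COHORT_COLUMNS = ("subject_id", "group", "visit", "scan_rep", "layer", "thickness_um")


def assemble_cohort(
    results: Iterable[SublayerThickness],
    manifest: pd.DataFrame | None = None,
    failures: Sequence[dict] = (),
) -> tuple[pd.DataFrame, dict]:
    """Long-format cohort thickness table plus a QC report.

    One row per subject x visit x scan x layer.  Failed scans are
    excluded from the table and enumerated in the QC report; when a
    manifest is given, every manifest row must be accounted for either
    by a result or by a failure record.
    """
    rows = []
    seen = set()
    for st in results:
        if st.meta is None:
            raise ValidationError("assemble_cohort requires scan metadata")
        m = st.meta
        for layer, value in st.as_dict().items():
            key = (m.subject_id, m.visit, m.scan_rep, layer)
            if key in seen:
                raise ValidationError(f"duplicate measurement for {key}")
            seen.add(key)
            rows.append(
                {
                    "subject_id": m.subject_id,
                    "group": m.group,
                    "visit": m.visit,
                    "scan_rep": m.scan_rep,
                    "layer": layer,
                    "thickness_um": value,
                }
            )
    cohort = pd.DataFrame(rows, columns=list(COHORT_COLUMNS))
    qc = {
        "n_scans": len({(r["subject_id"], r["visit"], r["scan_rep"]) for r in rows}),
        "n_failed": len(failures),
        "failures": [dict(f) for f in failures],
    }
    if manifest is not None:
        accounted = {(r["subject_id"], r["visit"], r["scan_rep"]) for r in rows}
        accounted |= {
            (f.get("subject_id"), f.get("visit"), f.get("scan_rep")) for f in failures
        }
        missing = [
            (r.subject_id, r.visit, int(r.scan_rep))
            for r in manifest.itertuples()
            if (r.subject_id, r.visit, int(r.scan_rep)) not in accounted
        ]
        if missing:
            raise ValidationError(
                f"{len(missing)} manifest scans have neither a result nor a "
                f"failure record, e.g. {missing[:3]}"
            )
        qc["n_manifest"] = len(manifest)
    return cohort, qc


def cohort_from_truth(truth_df: pd.DataFrame) -> pd.DataFrame:
    """Long-format cohort table directly from generator truth (no images).

    Used for statistics-level Monte-Carlo studies where rendering and
    re-segmenting every scan would add nothing but the (separately
    validated) segmentation error.
    """
    value_cols = {f"{layer}_um": layer for layer in LAYERS}
    long = truth_df.melt(
        id_vars=["subject_id", "group", "visit", "scan_rep"],
        value_vars=list(value_cols),
        var_name="layer",
        value_name="thickness_um",
    )
    long["layer"] = long["layer"].map(value_cols)
    return long.dropna(subset=["thickness_um"]).reset_index(drop=True)
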