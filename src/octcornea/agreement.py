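"""Intrasession repeatability and agreement statistics.

Two same-visit scans per subject yield, per group and sublayer:
per-measurement mean +/- SD, paired-difference mean +/- SD, the
intraclass correlation coefficient (two-way random, absolute
agreement, single measures by default), the coefficient of
repeatability CoR = 2 x SD(difference), CoR% = CoR / overall mean x
100, and Bland-Altman 95% limits of agreement = mean difference +/-
1.96 x SD(difference).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, ValidationError
from .simulate import LAYERS

LOA_MULTIPLIER = 1.96  # conventional normal quantile, not a t quantile


def coefficient_of_repeatability(diffs: Sequence[float]) -> float:
    """CoR: twice the sample SD (ddof=1) of paired test-retest differences."""
    diffs = np.asarray(diffs, dtype=float)
    if diffs.size < 2:
        raise InsufficientDataError("CoR needs at least 2 paired differences")
    return 2.0 * float(np.std(diffs, ddof=1))


def cor_percent(cor_um: float, overall_mean_um: float) -> float:
    """CoR as a percentage of the overall mean of both measurements."""
    if overall_mean_um <= 0:
        raise ValidationError("overall mean must be positive")
    return cor_um / overall_mean_um * 100.0


def limits_of_agreement(diffs: Sequence[float]) -> tuple[float, float]:
    """Bland-Altman 95% limits: mean difference +/- 1.96 SD."""
    diffs = np.asarray(diffs, dtype=float)
    if diffs.size < 2:
        raise InsufficientDataError("LoA needs at least 2 paired differences")
    m = float(np.mean(diffs))
    s = float(np.std(diffs, ddof=1))
    return (m - LOA_MULTIPLIER * s, m + LOA_MULTIPLIER * s)


def intraclass_correlation(m1: Sequence[float], m2: Sequence[float], model: str = "icc2") -> float:
    """ICC from the two-way paired-measurement variance decomposition.

    ``model="icc2"`` (default) is two-way random effects, absolute
    agreement, single measures -- bias between the two measurements
    counts against agreement.  ``model="icc3"`` (two-way mixed,
    consistency) is available for comparison.
    """
    x = np.column_stack([np.asarray(m1, float), np.asarray(m2, float)])
    n, k = x.shape
    if n < 3:
        raise InsufficientDataError("ICC needs at least 3 subjects")
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    grand = x.mean()
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    sse = np.sum((x - row_means[:, None] - col_means[None, :] + grand) ** 2)
    mse = sse / ((n - 1) * (k - 1))
    if model == "icc2":
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
    elif model == "icc3":
        denom = msr + (k - 1) * mse
    else:
        raise ValidationError(f"unknown ICC model: {model}")
    if denom <= 0:
        raise InsufficientDataError("ICC undefined: zero total variance")
    return float((msr - mse) / denom)


@dataclass(frozen=True)
class AgreementResult:
    """One group x sublayer row of the repeatability table."""

    group: str
    layer: str
    n: int
    m1_mean_um: float
    m1_sd_um: float
    m2_mean_um: float
    m2_sd_um: float
    dif_mean_um: float
    dif_sd_um: float
    icc: float
    cor_um: float
    cor_pct: float
    loa_low_um: float
    loa_high_um: float


def agreement_from_pairs(m1, m2, group: str = "", layer: str = "",
                         icc_model: str = "icc2") -> AgreementResult:
    """All agreement statistics for one set of paired measurements."""
    m1 = np.asarray(m1, float)
    m2 = np.asarray(m2, float)
    if m1.shape != m2.shape:
        raise ValidationError("m1 and m2 must be paired (equal length)")
    diffs = m2 - m1
    cor = coefficient_of_repeatability(diffs)
    overall = float(np.mean(np.concatenate([m1, m2])))
    loa_low, loa_high = limits_of_agreement(diffs)
    return AgreementResult(
        group=group,
        layer=layer,
        n=len(m1),
        m1_mean_um=float(np.mean(m1)),
        m1_sd_um=float(np.std(m1, ddof=1)),
        m2_mean_um=float(np.mean(m2)),
        m2_sd_um=float(np.std(m2, ddof=1)),
        dif_mean_um=float(np.mean(diffs)),
        dif_sd_um=float(np.std(diffs, ddof=1)),
        icc=intraclass_correlation(m1, m2, model=icc_model),
        cor_um=cor,
        cor_pct=cor_percent(cor, overall),
        loa_low_um=loa_low,
        loa_high_um=loa_high,
    )


def agreement_table(cohort: pd.DataFrame, visit: str = "1W",
                    icc_model: str = "icc2") -> pd.DataFrame:
    """Repeatability table (one row per group x layer) at one visit.

    Only subjects with both scan repetitions of the visit contribute;
    incomplete pairs are dropped pairwise.
    """
    sub = cohort[cohort["visit"] == visit]
    if sub.empty:
        raise InsufficientDataError(f"no data at visit {visit}")
    rows = []
    for group in sub["group"].unique():
        gsub = sub[sub["group"] == group]
        for layer in [l for l in LAYERS if l in set(gsub["layer"])]:
            wide = (
                gsub[gsub["layer"] == layer]
                .pivot_table(index="subject_id", columns="scan_rep",
                             values="thickness_um", aggfunc="first")
            )
            if not {1, 2}.issubset(wide.columns):
                continue
            wide = wide[[1, 2]].dropna()
            res = agreement_from_pairs(
                wide[1].to_numpy(), wide[2].to_numpy(),
                group=group, layer=layer, icc_model=icc_model,
            )
            rows.append(res.__dict__)
    return pd.DataFrame(rows)
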