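"""Between-visit change analysis, group comparison, and power utility.

Visit-level thickness per subject is the mean of the two scan
repetitions.  Changes over the five-visit schedule are tested with a
one-way repeated-measures ANOVA (optionally Greenhouse-Geisser
corrected) plus Bonferroni-corrected paired t-tests on the four
consecutive-visit intervals.  The between-group comparison is a
two-sample t interval (pooled variance by default, Welch optional).
Sample-size planning iterates the exact noncentral-t power.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, ValidationError
from .simulate import LAYERS, VISITS

INTERVALS = (("PRE", "1D"), ("1D", "1W"), ("1W", "2W"), ("2W", "1M"))


def subject_visit_means(cohort: pd.DataFrame) -> pd.DataFrame:
    """Per-subject per-visit thickness: mean of the scan repetitions."""
    return (
        cohort.groupby(["subject_id", "group", "visit", "layer"], as_index=False)[
            "thickness_um"
        ]
        .mean()
    )


@dataclass(frozen=True)
class ChangeResult:
    """Paired change over one consecutive-visit interval."""

    group: str
    layer: str
    interval: str  # e.g. "1D-PRE"
    n: int
    change_mean_um: float
    change_sd_um: float
    p_value: float
    p_corrected: float
    significant: bool


def repeated_measures_anova(
    means: pd.DataFrame, sphericity_correction: bool = False
) -> float:
    """Omnibus p-value of a one-way repeated-measures ANOVA over visits.

    ``means`` is a subject x visit table (columns subject_id, visit,
    thickness_um) restricted to one group and layer; only subjects with
    every visit contribute.
    """
    wide = means.pivot_table(index="subject_id", columns="visit",
                             values="thickness_um", aggfunc="first").dropna()
    if wide.shape[1] < 3:
        raise InsufficientDataError("repeated-measures ANOVA needs >= 3 visits")
    if wide.shape[0] < 3:
        raise InsufficientDataError("repeated-measures ANOVA needs >= 3 complete subjects")
    long = wide.reset_index().melt(
        id_vars="subject_id", var_name="visit", value_name="thickness_um"
    )
    import pingouin as pg

    aov = pg.rm_anova(
        data=long, dv="thickness_um", within="visit", subject="subject_id",
        correction=sphericity_correction,
    )
    cols = {c.replace("-", "_"): c for c in aov.columns}
    col = cols.get("p_GG_corr") if sphericity_correction else None
    col = col or cols.get("p_unc")
    return float(aov[col].iloc[0])


def visit_changes(
    cohort: pd.DataFrame,
    group: str,
    layer: str,
    alpha: float = 0.05,
    sphericity_correction: bool = False,
    omnibus: bool = True,
) -> tuple[list[ChangeResult], float]:
    """Consecutive-visit paired changes plus the omnibus ANOVA p-value.

    Post hoc consecutive-interval paired t-tests are Bonferroni
    corrected over the number of intervals tested for the layer (four,
    or three for the flap which does not exist pre-operatively).  When
    fewer than three visits carry the layer the omnibus p is NaN and
    only the paired changes are returned.  ``omnibus=False`` skips the
    ANOVA (useful in large Monte-Carlo studies of the post hoc test).
    """
    means = subject_visit_means(cohort)
    sub = means[(means["group"] == group) & (means["layer"] == layer)]
    if sub.empty:
        raise InsufficientDataError(f"no data for {group}/{layer}")
    visits_present = [v for v in VISITS if v in set(sub["visit"])]
    intervals = [(a, b) for a, b in INTERVALS if a in visits_present and b in visits_present]
    if not intervals:
        raise InsufficientDataError(f"no consecutive-visit pairs for {group}/{layer}")
    wide = sub.pivot_table(index="subject_id", columns="visit",
                           values="thickness_um", aggfunc="first")
    results = []
    m = len(intervals)
    for a, b in intervals:
        pair = wide[[a, b]].dropna()
        if len(pair) < 3:
            raise InsufficientDataError(
                f"fewer than 3 complete pairs for {group}/{layer} {b}-{a}"
            )
        delta = pair[b] - pair[a]
        tstat, p = stats.ttest_rel(pair[b], pair[a])
        p_corr = min(1.0, float(p) * m)
        results.append(
            ChangeResult(
                group=group,
                layer=layer,
                interval=f"{b}-{a}",
                n=len(pair),
                change_mean_um=float(delta.mean()),
                change_sd_um=float(delta.std(ddof=1)),
                p_value=float(p),
                p_corrected=p_corr,
                significant=p_corr < alpha,
            )
        )
    anova_p = float("nan")
    if omnibus:
        try:
            anova_p = repeated_measures_anova(
                sub[sub["visit"].isin(visits_present)], sphericity_correction
            )
        except InsufficientDataError:
            pass
    return results, anova_p


def changes_table(cohort: pd.DataFrame, alpha: float = 0.05,
                  sphericity_correction: bool = False) -> pd.DataFrame:
    """Interval-change table over all groups and layers."""
    rows = []
    for group in cohort["group"].unique():
        layers = [l for l in LAYERS
                  if l in set(cohort.loc[cohort["group"] == group, "layer"])]
        for layer in layers:
            changes, anova_p = visit_changes(
                cohort, group, layer, alpha=alpha,
                sphericity_correction=sphericity_correction,
            )
            for c in changes:
                row = c.__dict__.copy()
                row["anova_p"] = anova_p
                rows.append(row)
    return pd.DataFrame(rows)


def visit_table(cohort: pd.DataFrame) -> pd.DataFrame:
    """Per-visit mean +/- SD of subject-level (scan-averaged) thickness."""
    means = subject_visit_means(cohort)
    out = (
        means.groupby(["group", "layer", "visit"])["thickness_um"]
        .agg(n="count", mean_um="mean", sd_um=lambda s: s.std(ddof=1))
        .reset_index()
    )
    out["visit"] = pd.Categorical(out["visit"], categories=list(VISITS), ordered=True)
    return out.sort_values(["group", "layer", "visit"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Between-group comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupDiffResult:
    """Two-sample mean difference (group2 - group1) with 95% CI."""

    layer: str
    visit: str
    n1: int
    n2: int
    diff_mean_um: float
    ci_low_um: float
    ci_high_um: float
    p_value: float


def group_difference_ci(
    n1: int, mean1: float, sd1: float,
    n2: int, mean2: float, sd2: float,
    confidence: float = 0.95,
    method: str = "pooled",
    layer: str = "",
    visit: str = "",
) -> GroupDiffResult:
    """t-based CI for the difference of two independent group means.

    ``method="pooled"`` uses the classic equal-variance Student
    interval; ``"welch"`` uses the Welch-Satterthwaite approximation.
    The difference reported is mean2 - mean1.
    """
    if n1 < 2 or n2 < 2:
        raise InsufficientDataError("each group needs at least 2 subjects")
    if sd1 <= 0 or sd2 <= 0:
        raise ValidationError("group SDs must be positive")
    if not 0 < confidence < 1:
        raise ValidationError("confidence must be in (0, 1)")
    diff = mean2 - mean1
    if method == "pooled":
        df = n1 + n2 - 2
        sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
        se = math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    elif method == "welch":
        v1, v2 = sd1**2 / n1, sd2**2 / n2
        se = math.sqrt(v1 + v2)
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    else:
        raise ValidationError(f"unknown CI method: {method}")
    tcrit = stats.t.ppf(0.5 + confidence / 2.0, df)
    half = tcrit * se
    p = 2.0 * stats.t.sf(abs(diff) / se, df)
    return GroupDiffResult(
        layer=layer, visit=visit, n1=n1, n2=n2,
        diff_mean_um=diff, ci_low_um=diff - half, ci_high_um=diff + half,
        p_value=float(p),
    )


def group_difference_from_cohort(
    cohort: pd.DataFrame, layer: str, visit: str,
    group1: str, group2: str, confidence: float = 0.95, method: str = "pooled",
) -> GroupDiffResult:
    means = subject_visit_means(cohort)
    sel = means[(means["layer"] == layer) & (means["visit"] == visit)]
    x1 = sel.loc[sel["group"] == group1, "thickness_um"].to_numpy()
    x2 = sel.loc[sel["group"] == group2, "thickness_um"].to_numpy()
    if len(x1) < 2 or len(x2) < 2:
        raise InsufficientDataError(f"too few subjects for {layer}/{visit}")
    return group_difference_ci(
        len(x1), float(np.mean(x1)), float(np.std(x1, ddof=1)),
        len(x2), float(np.mean(x2)), float(np.std(x2, ddof=1)),
        confidence=confidence, method=method, layer=layer, visit=visit,
    )


# ---------------------------------------------------------------------------
# Sample-size planning
# ---------------------------------------------------------------------------

def achieved_power(
    n: int, effect_size_d: float, alpha: float = 0.05,
    family: str = "two_sample", tails: int = 2,
) -> float:
    """Exact noncentral-t power of a t-test at per-group size ``n``."""
    if family in ("one_sample", "paired"):
        if n < 2:
            return 0.0
        df = n - 1
        delta = effect_size_d * math.sqrt(n)
    elif family == "two_sample":
        if n < 2:
            return 0.0
        df = 2 * n - 2
        delta = effect_size_d * math.sqrt(n / 2.0)
    else:
        raise ValidationError(f"unknown test family: {family}")
    if tails == 2:
        tc = stats.t.ppf(1.0 - alpha / 2.0, df)
    elif tails == 1:
        tc = stats.t.ppf(1.0 - alpha, df)
    else:
        raise ValidationError("tails must be 1 or 2")
    # scipy's noncentral t underflows for very large noncentrality; the
    # rejection probability is 1 to far beyond double precision there.
    if delta - tc > 10.0:
        return 1.0
    power = stats.nct.sf(tc, df, delta)
    if tails == 2:
        power += stats.nct.cdf(-tc, df, delta)
    return float(power)


def required_sample_size(
    effect_size_d: float, alpha: float = 0.05, power: float = 0.95,
    family: str = "two_sample", tails: int = 2, max_n: int = 1_000_000,
) -> int:
    """Smallest n (per group) whose achieved power reaches the target."""
    if effect_size_d <= 0:
        raise ValidationError("effect size must be positive")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValidationError("alpha and power must be in (0, 1)")
    n = 2
    while n <= max_n:
        if achieved_power(n, effect_size_d, alpha, family, tails) >= power:
            return n
        n += 1
    raise ValidationError(f"target power not attainable below n = {max_n}")
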