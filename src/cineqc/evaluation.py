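"""Agreement and validation statistics between two segmentation/biomarker sources.

Implements the field's standard validation battery for automated vs manual
cardiac analysis: per-label Dice overlap (reported in %, median with
interquartile range), Bland-Altman bias and +/-1.96 SD limits of agreement
with Pearson correlation, median absolute errors, and nonparametric group
comparisons (Mann-Whitney U between groups, Wilcoxon signed-rank within)
with tiered Bonferroni-adjusted significance, stratifiable by disease
group, scanner vendor, or field strength.

Conventions: Dice over an empty-in-both label is *missing* (excluded from
medians), not 100%; Pearson r on constant input is missing; IQR is the
75th - 25th percentile with linear interpolation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import LabelStack
from .errors import ConsistencyError, InsufficientDataError

__all__ = [
    "dice",
    "BlandAltman",
    "bland_altman",
    "error_summary",
    "GroupComparison",
    "group_compare",
    "stratified_report",
    "DEFAULT_ALPHAS",
]

#: significance tiers of the star convention (each divided by the test count)
DEFAULT_ALPHAS = (0.01, 0.001, 0.0001)


def dice(a: LabelStack, b: LabelStack, label: int) -> float:
    """Dice overlap of one label between congruent stacks, in %.

    100 is perfect agreement, 0 no agreement; NaN (missing) when the label
    is empty in both stacks.
    """
    if a.voxels.shape != b.voxels.shape:
        raise ConsistencyError(
            f"stack shapes differ: {a.voxels.shape} vs {b.voxels.shape}"
        )
    ma = a.voxels == label
    mb = b.voxels == label
    denom = int(ma.sum()) + int(mb.sum())
    if denom == 0:
        return float("nan")
    return 100.0 * 2.0 * int((ma & mb).sum()) / denom


@dataclass(frozen=True)
class BlandAltman:
    """Bias, +/-1.96 SD limits of agreement, and Pearson correlation."""

    bias: float
    loa_lower: float
    loa_upper: float
    r: float  # NaN for constant input
    r_pvalue: float
    n: int


def bland_altman(auto, manual) -> BlandAltman:
    """Bland-Altman agreement between paired measurements.

    ``bias = mean(auto - manual)``, limits ``bias +/- 1.96 * SD(auto -
    manual)`` (sample SD), plus Pearson r of auto vs manual.  Requires at
    least 3 pairs.
    """
    auto = np.asarray(auto, dtype=float)
    manual = np.asarray(manual, dtype=float)
    if auto.shape != manual.shape or auto.ndim != 1:
        raise InsufficientDataError("auto and manual must be equal-length 1D arrays")
    n = len(auto)
    if n < 3:
        raise InsufficientDataError(f"Bland-Altman needs >= 3 pairs, got {n}")
    diff = auto - manual
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    if np.ptp(auto) == 0 or np.ptp(manual) == 0:
        r, p = float("nan"), float("nan")
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r, p = stats.pearsonr(auto, manual)
    return BlandAltman(
        bias=bias,
        loa_lower=bias - 1.96 * sd,
        loa_upper=bias + 1.96 * sd,
        r=float(r),
        r_pvalue=float(p),
        n=n,
    )


def error_summary(auto, manual) -> tuple[float, float]:
    """(median, IQR) of the absolute errors ``|auto - manual|``."""
    auto = np.asarray(auto, dtype=float)
    manual = np.asarray(manual, dtype=float)
    if auto.size == 0:
        raise InsufficientDataError("error_summary needs at least 1 pair")
    err = np.abs(auto - manual)
    q25, q50, q75 = np.percentile(err, [25, 50, 75])  # linear interpolation
    return float(q50), float(q75 - q25)


@dataclass(frozen=True)
class GroupComparison:
    """A rank test with tiered Bonferroni-adjusted significance."""

    design: str
    statistic: float
    p_value: float
    n_tests: int
    alphas: tuple[float, ...] = DEFAULT_ALPHAS
    adjusted_thresholds: tuple[float, ...] = ()
    stars: int = 0  # number of tiers passed (0 = not significant)

    def significant(self, tier: int = 1) -> bool:
        return self.stars >= tier


def group_compare(
    a,
    b=None,
    design: str = "between",
    n_tests: int = 1,
    alphas: tuple[float, ...] = DEFAULT_ALPHAS,
) -> GroupComparison:
    """Nonparametric comparison with Bonferroni-adjusted significance tiers.

    ``design="between"``: two-sided Mann-Whitney U between samples `a` and
    `b`.  ``design="within_vs_zero"``: Wilcoxon signed-rank of the paired
    differences `a` against zero (all-zero differences => p = 1).
    Significance stars count the tiers ``p < alpha / n_tests`` passed.
    """
    a = np.asarray(a, dtype=float)
    if design == "between":
        b = np.asarray(b, dtype=float)
        if len(a) < 2 or len(b) < 2:
            raise InsufficientDataError("between-group test needs n >= 2 per group")
        stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    elif design == "within_vs_zero":
        if len(a) < 1:
            raise InsufficientDataError("within test needs >= 1 difference")
        if np.all(a == 0):
            stat, p = 0.0, 1.0
        else:
            stat, p = stats.wilcoxon(a)
    else:
        raise ValueError(f"unknown design {design!r}")
    thresholds = tuple(alpha / n_tests for alpha in alphas)
    stars = sum(p < t for t in thresholds)
    return GroupComparison(
        design=design,
        statistic=float(stat),
        p_value=float(p),
        n_tests=n_tests,
        alphas=tuple(alphas),
        adjusted_thresholds=thresholds,
        stars=int(stars),
    )


def _summaries_for(df: pd.DataFrame, metrics: list[str]) -> dict:
    out = {}
    for metric in metrics:
        auto = df[f"{metric}_auto"].to_numpy(dtype=float)
        manual = df[f"{metric}_ref"].to_numpy(dtype=float)
        med, iqr = error_summary(auto, manual)
        entry = {"n": len(df), "median_abs_error": med, "iqr_abs_error": iqr}
        try:
            ba = bland_altman(auto, manual)
            entry.update(
                bias=ba.bias, loa_lower=ba.loa_lower, loa_upper=ba.loa_upper,
                pearson_r=ba.r,
            )
        except InsufficientDataError:
            entry.update(bias=np.nan, loa_lower=np.nan, loa_upper=np.nan, pearson_r=np.nan)
        out[metric] = entry
    return out


def stratified_report(
    results: pd.DataFrame,
    metadata: pd.DataFrame | None = None,
    stratum: str | None = None,
    metrics: list[str] | None = None,
    min_n: int = 3,
    n_tests: int | None = None,
) -> dict:
    """Per-stratum agreement summaries plus between-stratum comparisons.

    `results` has one row per study with ``<metric>_auto`` / ``<metric>_ref``
    column pairs and a ``study_id`` column; `metadata` carries the stratum
    column (e.g. ``disease_group``, ``vendor``, ``field_T``).  Strata with
    fewer than `min_n` studies are reported as insufficient, never dropped
    silently.  With ``stratum=None`` the report is the unstratified summary
    under the single key ``"all"``.
    """
    if metrics is None:
        metrics = sorted(
            c[: -len("_auto")] for c in results.columns if c.endswith("_auto")
        )
    table = results
    if stratum is not None:
        if metadata is None:
            raise InsufficientDataError("stratified report needs metadata")
        table = results.merge(
            metadata[["study_id", stratum]], on="study_id", how="left"
        )
        table[stratum] = table[stratum].fillna("__missing__")
    report: dict = {"strata": {}, "comparisons": {}}
    groups = (
        {"all": table} if stratum is None
        else {str(k): g for k, g in table.groupby(stratum, sort=True)}
    )
    for name, g in groups.items():
        if len(g) < min_n:
            report["strata"][name] = {"n": len(g), "insufficient": True}
        else:
            report["strata"][name] = {"n": len(g), "insufficient": False,
                                      "metrics": _summaries_for(g, metrics)}
    usable = [k for k, v in report["strata"].items() if not v.get("insufficient")]
    if len(usable) >= 2:
        pairs = [
            (a, b) for i, a in enumerate(usable) for b in usable[i + 1:]
        ]
        total_tests = n_tests if n_tests is not None else len(pairs) * len(metrics)
        for a, b in pairs:
            for metric in metrics:
                ga = groups[a]
                gb = groups[b]
                err_a = np.abs(ga[f"{metric}_auto"] - ga[f"{metric}_ref"])
                err_b = np.abs(gb[f"{metric}_auto"] - gb[f"{metric}_ref"])
                cmp = group_compare(err_a, err_b, design="between", n_tests=total_tests)
                report["comparisons"][f"{metric}:{a}|{b}"] = {
                    "statistic": cmp.statistic,
                    "p_value": cmp.p_value,
                    "stars": cmp.stars,
                }
    return report
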