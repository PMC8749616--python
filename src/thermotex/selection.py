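"""Three-criterion screening cascade over color/feature combinations.

Every (component, approach, feature) combination — 350 under the full
configuration — is screened in order:

1. **Homogeneity** of the non-pregnant group across its imaging
   sessions: an omnibus test (one-way ANOVA for Gaussian series,
   Kruskal–Wallis otherwise, gated by Shapiro–Wilk) must NOT reject at
   α; survivors get a pooled mean ± SD over all non-pregnant values.
2. **Separation**: the pooled non-pregnant values are compared with the
   pregnant series of each gestation month; a combination survives when
   the contrast is significant from some month through the end of
   pregnancy, and that earliest month is recorded.  After this stage
   the asymmetric (GLCH) branch is dropped — its selections duplicate
   the symmetric (GLCM) branch — and only HS + GLCM go forward.
3. **Monotone trend**: the pregnant per-month means must rise (In) or
   fall (De) strictly across the scheduled months (Spearman rank
   correlation of mean vs month equal to ±1 with non-zero total
   change); combinations with a trend form the final indicator set.

No multiplicity correction is applied across combinations; mares
contributing several sessions are treated as independent observations
per month.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SelectionConfig",
    "StageCounts",
    "normality_gate",
    "criterion1_homogeneity",
    "criterion2_separation",
    "criterion3_trend",
    "build_series",
    "run_selection",
]

_APPROACHES = ("HS", "GLCM", "GLCH")


@dataclass(frozen=True)
class SelectionConfig:
    """Significance levels and comparison structure of the cascade.

    ``comparison``: ``"omnibus"`` (default) runs one omnibus test over
    pooled non-pregnant + all pregnant months followed by post-hoc
    control-vs-month contrasts (Tukey HSD for Gaussian data, Dunn's
    rank test with Bonferroni adjustment otherwise); ``"pairwise"``
    tests each month against the pooled non-pregnant values separately
    (Welch t / Mann–Whitney), unadjusted.
    """

    alpha: float = 0.05
    normality_alpha: float = 0.05
    comparison: str = "omnibus"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.normality_alpha < 1:
            raise ValueError("normality_alpha must be in (0, 1)")
        if self.comparison not in ("omnibus", "pairwise"):
            raise ValueError(f"unknown comparison mode {self.comparison!r}")


DEFAULT_SELECTION_CONFIG = SelectionConfig()


@dataclass(frozen=True)
class StageCounts:
    """Per-approach survivor counts at each cascade stage."""

    enumerated: dict[str, int]
    after_c1: dict[str, int]
    after_c2: dict[str, int]
    after_glch_drop: dict[str, int]
    final: dict[str, int]
    glch_duplicates_glcm: bool | None = None

    @staticmethod
    def total(per_approach: dict[str, int]) -> int:
        """Total survivor count across approaches at one stage."""
        return int(sum(per_approach.values()))

    def totals(self) -> dict[str, int]:
        return {
            "enumerated": self.total(self.enumerated),
            "after_c1": self.total(self.after_c1),
            "after_c2": self.total(self.after_c2),
            "after_glch_drop": self.total(self.after_glch_drop),
            "final": self.total(self.final),
        }


def _clean(values) -> np.ndarray:
    arr = np.asarray(values, dtype=np.float64)
    if arr.ndim != 1:
        raise ValueError("each series must be one-dimensional")
    if not np.all(np.isfinite(arr)):
        raise ValueError("series contain non-finite values")
    return arr


def normality_gate(series_lists, alpha: float = 0.05) -> str:
    """Choose the test family for a comparison.

    Returns ``"parametric"`` iff every series passes Shapiro–Wilk at
    ``alpha``; constant series count as non-Gaussian.  Series must have
    at least 3 observations.
    """
    family = "parametric"
    for values in series_lists:
        arr = _clean(values)
        if len(arr) < 3:
            raise ValueError(f"series of length {len(arr)} too short for normality test")
        if np.ptp(arr) == 0:
            family = "nonparametric"
            continue
        if stats.shapiro(arr).pvalue < alpha:
            family = "nonparametric"
    return family


def _omnibus_pvalue(groups, family: str) -> float:
    flat = np.concatenate(groups)
    if np.ptp(flat) == 0:  # all observations identical: no evidence of differences
        return 1.0
    if family == "parametric":
        return float(stats.f_oneway(*groups).pvalue)
    return float(stats.kruskal(*groups).pvalue)


def criterion1_homogeneity(
    session_lists, cfg: SelectionConfig = DEFAULT_SELECTION_CONFIG
) -> tuple[bool, float | None, float | None]:
    """Stage 1: stability of a feature across non-pregnant sessions.

    Passes when the omnibus test does not reject (p ≥ α); on a pass the
    pooled mean and SD over the concatenated sessions are returned.
    """
    groups = [_clean(g) for g in session_lists]
    if len(groups) < 2:
        raise ValueError("need at least two sessions")
    family = normality_gate(groups, cfg.normality_alpha)
    p = _omnibus_pvalue(groups, family)
    if p < cfg.alpha:
        return False, None, None
    pooled = np.concatenate(groups)
    return True, float(pooled.mean()), float(pooled.std(ddof=1))


def _dunn_pvalues(groups, control_index: int) -> np.ndarray:
    """Dunn's rank-based multiple comparisons of each group vs a control.

    z statistics on mean ranks of the joint ranking with tie
    correction; two-sided p-values Bonferroni-adjusted for the number
    of control contrasts.
    """
    sizes = np.array([len(g) for g in groups])
    flat = np.concatenate(groups)
    n = len(flat)
    ranks = stats.rankdata(flat)
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    mean_ranks = np.array([ranks[a:b].mean() for a, b in zip(bounds[:-1], bounds[1:])])
    _, tie_counts = np.unique(flat, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (12 * (n - 1))
    variance = n * (n + 1) / 12 - tie_term
    others = [i for i in range(len(groups)) if i != control_index]
    pvals = np.empty(len(others))
    for j, i in enumerate(others):
        se = np.sqrt(variance * (1 / sizes[control_index] + 1 / sizes[i]))
        z = abs(mean_ranks[i] - mean_ranks[control_index]) / se if se > 0 else 0.0
        pvals[j] = 2 * stats.norm.sf(z)
    return np.minimum(pvals * len(others), 1.0)


def _control_contrast_pvalues(pooled, month_lists, family: str, mode: str) -> np.ndarray:
    """p-value of the non-pregnant-vs-month contrast for every month."""
    if mode == "pairwise":
        out = []
        for values in month_lists:
            if family == "parametric":
                out.append(stats.ttest_ind(pooled, values, equal_var=False).pvalue)
            else:
                out.append(stats.mannwhitneyu(pooled, values, alternative="two-sided").pvalue)
        return np.asarray(out, dtype=np.float64)

    groups = [pooled] + list(month_lists)
    if family == "parametric":
        res = stats.tukey_hsd(*groups)
        return np.asarray([res.pvalue[0, i + 1] for i in range(len(month_lists))])
    return _dunn_pvalues(groups, control_index=0)


def criterion2_separation(
    pooled_nonpregnant,
    pregnant_by_month: dict[int, np.ndarray],
    cfg: SelectionConfig = DEFAULT_SELECTION_CONFIG,
) -> int | None:
    """Stage 2: earliest month from which the groups separate for good.

    Returns the smallest scheduled month m whose non-pregnant-vs-month
    contrast is significant for m and every later month; None when no
    such month exists (including when the omnibus test does not
    reject).
    """
    pooled = _clean(pooled_nonpregnant)
    months = sorted(pregnant_by_month)
    if not months:
        raise ValueError("no pregnant months supplied")
    month_lists = [_clean(pregnant_by_month[m]) for m in months]
    family = normality_gate([pooled] + month_lists, cfg.normality_alpha)

    if cfg.comparison == "omnibus":
        if _omnibus_pvalue([pooled] + month_lists, family) >= cfg.alpha:
            return None
    pvals = _control_contrast_pvalues(pooled, month_lists, family, cfg.comparison)
    significant = pvals < cfg.alpha

    first_sep = None
    for month, sig in zip(reversed(months), reversed(significant)):
        if not sig:
            break
        first_sep = month
    return first_sep


def criterion3_trend(per_month_means: dict[int, float]) -> str:
    """Stage 3: 'In', 'De' or 'none' for the pregnant per-month means.

    A trend requires a perfect Spearman rank correlation (±1) between
    mean and month together with a non-zero total change — i.e. the
    means move strictly monotonically across the scheduled months.
    """
    months = sorted(per_month_means)
    if len(months) < 3:
        raise ValueError("need means for at least 3 months")
    means = np.array([per_month_means[m] for m in months], dtype=np.float64)
    total_change = means[-1] - means[0]
    if total_change == 0 or np.ptp(means) == 0:
        return "none"
    rho = stats.spearmanr(months, means).statistic
    if rho >= 1.0 - 1e-12:
        return "In"
    if rho <= -1.0 + 1e-12:
        return "De"
    return "none"


def build_series(table: pd.DataFrame):
    """Group a tidy feature table into per-combination series.

    Yields ((component, approach, feature), np_sessions, pregnant_months)
    where np_sessions maps session → values of the non-pregnant group
    and pregnant_months maps gestation month → values.
    """
    for (component, approach, feature), sub in table.groupby(
        ["component", "approach", "feature"], sort=True
    ):
        np_rows = sub[sub["group"] == "NP"]
        p_rows = sub[sub["group"] == "P"]
        np_sessions = {
            int(s): g["value"].to_numpy(dtype=np.float64)
            for s, g in np_rows.groupby("session")
        }
        pregnant_months = {
            int(m): g["value"].to_numpy(dtype=np.float64)
            for m, g in p_rows.groupby("month")
        }
        yield (component, approach, feature), np_sessions, pregnant_months


def run_selection(
    table: pd.DataFrame, cfg: SelectionConfig = DEFAULT_SELECTION_CONFIG
) -> tuple[pd.DataFrame, StageCounts]:
    """Apply the full cascade to a feature table.

    Returns the per-combination selection table (pass_c1, pooled mean ±
    SD, first separating month, trend) and the per-stage survivor
    counts.  The cascade is monotone: each stage only removes
    combinations.
    """
    records = []
    for (component, approach, feature), np_sessions, pregnant_months in build_series(table):
        session_lists = [np_sessions[s] for s in sorted(np_sessions)]
        pass_c1, pooled_mean, pooled_sd = criterion1_homogeneity(session_lists, cfg)
        first_sep: int | None = None
        trend = "none"
        if pass_c1 and pregnant_months:
            pooled = np.concatenate(session_lists)
            first_sep = criterion2_separation(pooled, pregnant_months, cfg)
            if first_sep is not None and approach != "GLCH":
                means = {m: float(np.mean(v)) for m, v in pregnant_months.items()}
                trend = criterion3_trend(means)
        records.append(
            {
                "component": component,
                "approach": approach,
                "feature": feature,
                "pass_c1": pass_c1,
                "pooled_mean": pooled_mean,
                "pooled_sd": pooled_sd,
                "first_sep_month": first_sep,
                "trend": trend,
            }
        )
    result = pd.DataFrame.from_records(records)
    result["first_sep_month"] = result["first_sep_month"].astype("Int64")

    def _by_approach(mask: pd.Series) -> dict[str, int]:
        counts = result.loc[mask, "approach"].value_counts()
        return {a: int(counts.get(a, 0)) for a in _APPROACHES if (result["approach"] == a).any()}

    enumerated = _by_approach(pd.Series(True, index=result.index))
    after_c1 = _by_approach(result["pass_c1"])
    survived_c2 = result["pass_c1"] & result["first_sep_month"].notna()
    after_c2 = _by_approach(survived_c2)
    after_drop = {a: n for a, n in after_c2.items() if a != "GLCH"}
    final = _by_approach(survived_c2 & (result["trend"] != "none"))
    final.pop("GLCH", None)

    glch_dup: bool | None = None
    if "GLCH" in after_c2 and "GLCM" in after_c2:
        sel = result[survived_c2]
        glcm_set = set(map(tuple, sel.loc[sel["approach"] == "GLCM", ["component", "feature"]].to_numpy()))
        glch_set = set(map(tuple, sel.loc[sel["approach"] == "GLCH", ["component", "feature"]].to_numpy()))
        glch_dup = glcm_set == glch_set

    counts = StageCounts(
        enumerated=enumerated,
        after_c1=after_c1,
        after_c2=after_c2,
        after_glch_drop=after_drop,
        final=final,
        glch_duplicates_glcm=glch_dup,
    )
    return result, counts
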