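"""Threshold-based pregnancy annotation and diagnostic accuracy.

For every selected combination, each mare is annotated pregnant (1) or
non-pregnant (0) by comparing her feature value with a threshold derived
from the pooled non-pregnant mean ± SD.  Three thresholds are evaluated
per combination and month: k = 0, 1, 2 with

* increasing indicators: t_k = mean − k·SD, positive when value > t_k;
* decreasing indicators: t_k = mean + k·SD, positive when value < t_k.

Moving from k = 0 to k = 2 relaxes the rule, so sensitivity is
non-decreasing and specificity non-increasing in k.  Ties at the
threshold are annotated non-pregnant.  Confusion counts give Se, Sp,
PPV and NPV (0/0 ratios are reported as 1.00, and all four metrics are
rounded half away from zero to two decimals at reporting); predictive
values can also be recomputed across a sweep of pregnancy prevalences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ThresholdSet",
    "ConfusionCounts",
    "compute_thresholds",
    "annotate",
    "accuracy_metrics",
    "counts_from_rounded_rates",
    "prevalence_adjusted",
    "evaluate",
    "prevalence_sweep",
]


def _round2(x: float) -> float:
    """Round half away from zero to 2 decimals."""
    return float(np.floor(abs(x) * 100 + 0.5) * np.sign(x) / 100)


@dataclass(frozen=True)
class ThresholdSet:
    """The three decision thresholds for one combination."""

    pooled_mean: float
    pooled_sd: float
    direction: str  # "In" or "De"
    thresholds: tuple[float, float, float]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n_pos(self) -> int:
        return self.tp + self.fn

    @property
    def n_neg(self) -> int:
        return self.tn + self.fp


def compute_thresholds(pooled_mean: float, pooled_sd: float, direction: str) -> ThresholdSet:
    """Thresholds mean ∓ k·SD, k = 0, 1, 2.

    For increasing (In) indicators the threshold moves *down* with k
    (mean, mean − SD, mean − 2SD) and for decreasing (De) indicators it
    moves *up*, so that larger k always relaxes the positivity rule.
    """
    if pooled_sd < 0:
        raise ValueError("pooled SD must be non-negative")
    if direction not in ("In", "De"):
        raise ValueError(f"direction must be 'In' or 'De', got {direction!r}")
    sign = -1.0 if direction == "In" else 1.0
    ts = tuple(pooled_mean + sign * k * pooled_sd for k in range(3))
    return ThresholdSet(pooled_mean, pooled_sd, direction, ts)


def annotate(value: float, threshold: float, direction: str) -> int:
    """1 = pregnant, 0 = non-pregnant; equality counts as non-pregnant."""
    if not (np.isfinite(value) and np.isfinite(threshold)):
        raise ValueError("value and threshold must be finite")
    if direction == "In":
        return int(value > threshold)
    if direction == "De":
        return int(value < threshold)
    raise ValueError(f"direction must be 'In' or 'De', got {direction!r}")


def accuracy_metrics(counts: ConfusionCounts) -> dict[str, float]:
    """Se, Sp, PPV, NPV rounded to two decimals; 0/0 ratios are 1.00."""
    if counts.n_pos < 1 or counts.n_neg < 1:
        raise ValueError("need at least one positive and one negative subject")

    def ratio(num: int, den: int) -> float:
        return 1.0 if den == 0 else num / den

    return {
        "Se": _round2(counts.tp / counts.n_pos),
        "Sp": _round2(counts.tn / counts.n_neg),
        "PPV": _round2(ratio(counts.tp, counts.tp + counts.fp)),
        "NPV": _round2(ratio(counts.tn, counts.tn + counts.fn)),
    }


def counts_from_rounded_rates(rate: float, denominator: int) -> int:
    """Invert a 2-decimal rate back to its integer numerator.

    Returns the unique c in 0..denominator with round(c/denominator, 2)
    == rate; raises when no or several candidates match.
    """
    if not 0 <= rate <= 1:
        raise ValueError("rate must lie in [0, 1]")
    if denominator < 1:
        raise ValueError("denominator must be >= 1")
    matches = [c for c in range(denominator + 1) if _round2(c / denominator) == _round2(rate)]
    if len(matches) != 1:
        raise ValueError(
            f"rate {rate} over {denominator} has {len(matches)} integer solutions"
        )
    return matches[0]


def prevalence_adjusted(se: float, sp: float, p: float) -> tuple[float, float]:
    """PPV and NPV at an assumed pregnancy prevalence p (Bayes' rule).

    PPV = se·p / (se·p + (1−sp)(1−p)); NPV = sp(1−p) / ((1−se)p +
    sp(1−p)); indeterminate 0/0 ratios are 1.0 by convention.
    """
    for name, val in (("se", se), ("sp", sp), ("p", p)):
        if not 0 <= val <= 1:
            raise ValueError(f"{name} must lie in [0, 1]")
    ppv_den = se * p + (1 - sp) * (1 - p)
    npv_den = (1 - se) * p + sp * (1 - p)
    ppv = 1.0 if ppv_den == 0 else se * p / ppv_den
    npv = 1.0 if npv_den == 0 else sp * (1 - p) / npv_den
    return ppv, npv


def _session_for_month(month: int) -> int:
    # Gestation months (4,5)->session 1, (6,7)->2, (8,9)->3, (10,11)->4.
    return (month - 4) // 2 + 1


def evaluate(
    table: pd.DataFrame,
    selection: pd.DataFrame,
    months: tuple[int, ...] | None = None,
) -> pd.DataFrame:
    """Accuracy records for every final combination × month × threshold.

    ``selection`` is the output of :func:`thermotex.selection.run_selection`;
    only rows with a trend (the stage-3 survivors) are evaluated.  For a
    given month, positives are the pregnant mares imaged that month and
    negatives are the non-pregnant mares at the concurrent session.
    """
    chosen = selection[selection["trend"].isin(["In", "De"])]
    if chosen.empty:
        raise ValueError("selection contains no combinations with a trend")
    records = []
    for row in chosen.itertuples(index=False):
        sub = table[
            (table["component"] == row.component)
            & (table["approach"] == row.approach)
            & (table["feature"] == row.feature)
        ]
        if sub.empty:
            raise ValueError(
                f"feature table lacks combination {(row.component, row.approach, row.feature)}"
            )
        tset = compute_thresholds(row.pooled_mean, row.pooled_sd, row.trend)
        p_rows = sub[sub["group"] == "P"]
        np_rows = sub[sub["group"] == "NP"]
        month_list = months or tuple(sorted(p_rows["month"].dropna().unique()))
        for month in month_list:
            month = int(month)
            pos_values = p_rows.loc[p_rows["month"] == month, "value"].to_numpy()
            neg_values = np_rows.loc[
                np_rows["session"] == _session_for_month(month), "value"
            ].to_numpy()
            if len(pos_values) == 0 or len(neg_values) == 0:
                raise ValueError(f"no observations for month {month}")
            for k, threshold in enumerate(tset.thresholds):
                pos_calls = np.array([annotate(v, threshold, row.trend) for v in pos_values])
                neg_calls = np.array([annotate(v, threshold, row.trend) for v in neg_values])
                counts = ConfusionCounts(
                    tp=int(pos_calls.sum()),
                    fn=int(len(pos_calls) - pos_calls.sum()),
                    fp=int(neg_calls.sum()),
                    tn=int(len(neg_calls) - neg_calls.sum()),
                )
                metrics = accuracy_metrics(counts)
                records.append(
                    {
                        "component": row.component,
                        "approach": row.approach,
                        "feature": row.feature,
                        "month": month,
                        "threshold_k": k,
                        "TP": counts.tp,
                        "FP": counts.fp,
                        "TN": counts.tn,
                        "FN": counts.fn,
                        **metrics,
                    }
                )
    return pd.DataFrame.from_records(records)


def prevalence_sweep(
    accuracy: pd.DataFrame, prevalences=tuple(np.round(np.arange(0.1, 1.01, 0.1), 1))
) -> pd.DataFrame:
    """Predictive values of each accuracy record across prevalences."""
    records = []
    for row in accuracy.itertuples(index=False):
        for p in prevalences:
            ppv, npv = prevalence_adjusted(row.Se, row.Sp, float(p))
            records.append(
                {
                    "component": row.component,
                    "approach": row.approach,
                    "feature": row.feature,
                    "month": row.month,
                    "threshold_k": row.threshold_k,
                    "prevalence": float(p),
                    "PPV": _round2(ppv),
                    "NPV": _round2(npv),
                }
            )
    return pd.DataFrame.from_records(records)
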