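"""Two-cohort comparison of per-image metrics.

The comparison a fundus-synthesis evaluation reports for each metric
(vessel amount, mean zone-B SNR): group means +- sd, an unpaired t-test,
Cohen's d on the pooled standard deviation, and two relative-difference
summaries — the mean difference as a percentage of the image size (total
pixel count of the standardized frame) and of the grand mean of the two
cohorts.  Effect sizes below 0.2 are conventionally "small"; the package
computes, it does not adjudicate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CohortComparison",
    "StatisticsError",
    "unpaired_t_test",
    "cohens_d",
    "cohens_d_from_samples",
    "comparison_from_summary",
    "compare_cohorts",
    "comparisons_to_frame",
]


class StatisticsError(ValueError):
    """Inputs too degenerate for the requested statistic."""


@dataclass
class CohortComparison:
    metric: str
    group1: str
    group2: str
    n1: int
    n2: int
    mean1: float
    sd1: float
    mean2: float
    sd2: float
    mean_difference: float          # mean1 - mean2 (sign preserved)
    t: float
    df: float
    p: float
    cohens_d: float                 # sign follows mean1 - mean2
    pct_of_image_size: float | None  # 100 |diff| / total pixels (counts only)
    pct_of_grand_mean: float        # 100 |diff| / ((mean1 + mean2) / 2)


def unpaired_t_test(
    sample1, sample2, variant: str = "pooled"
) -> tuple[float, float, float]:
    """Two-sided unpaired t-test; classical pooled-variance Student's t by
    default, Welch via ``variant="welch"``.  Returns ``(t, df, p)``."""
    x1 = np.asarray(sample1, dtype=float)
    x2 = np.asarray(sample2, dtype=float)
    if x1.size < 2 or x2.size < 2:
        raise StatisticsError("each sample needs n >= 2")
    if not (np.isfinite(x1).all() and np.isfinite(x2).all()):
        raise StatisticsError("samples must be finite")
    if x1.std(ddof=1) == 0.0 and x2.std(ddof=1) == 0.0:
        raise StatisticsError("zero variance in both samples")
    if variant not in ("pooled", "welch"):
        raise ValueError(f"unknown t-test variant {variant!r}")
    res = stats.ttest_ind(x1, x2, equal_var=(variant == "pooled"))
    return float(res.statistic), float(res.df), float(res.pvalue)


def cohens_d(
    mean_difference: float, sd1: float, sd2: float, n1: int, n2: int
) -> float:
    """Standardized mean difference on the pooled standard deviation.

    ``d = diff / sqrt(((n1-1) sd1^2 + (n2-1) sd2^2) / (n1 + n2 - 2))``;
    for equal n this reduces to ``diff / sqrt((sd1^2 + sd2^2) / 2)``.
    """
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be >= 0")
    if sd1 == 0.0 and sd2 == 0.0:
        raise StatisticsError("Cohen's d undefined: both sds are zero")
    if n1 < 2 or n2 < 2:
        raise StatisticsError("Cohen's d needs n >= 2 per group")
    pooled = math.sqrt(((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2))
    return float(mean_difference / pooled)


def cohens_d_from_samples(sample1, sample2) -> float:
    x1 = np.asarray(sample1, dtype=float)
    x2 = np.asarray(sample2, dtype=float)
    return cohens_d(
        float(x1.mean() - x2.mean()),
        float(x1.std(ddof=1)), float(x2.std(ddof=1)),
        x1.size, x2.size,
    )


def comparison_from_summary(
    metric: str,
    n1: int, mean1: float, sd1: float,
    n2: int, mean2: float, sd2: float,
    image_size: int | None = None,
    group1: str = "real", group2: str = "synthesized",
    mean_difference: float | None = None,
) -> CohortComparison:
    """Build the full comparison from summary statistics alone.

    Useful when only published summary rows (n, mean, sd, and possibly a
    separately printed mean difference) are available.  The pooled t is
    recomputed from the summaries.
    """
    diff = (mean1 - mean2) if mean_difference is None else mean_difference
    d = cohens_d(diff, sd1, sd2, n1, n2)
    pooled = math.sqrt(((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2))
    se = pooled * math.sqrt(1.0 / n1 + 1.0 / n2)
    df = n1 + n2 - 2
    t = diff / se if se > 0 else float("nan")
    p = float(2.0 * stats.t.sf(abs(t), df)) if np.isfinite(t) else float("nan")
    grand = (mean1 + mean2) / 2.0
    return CohortComparison(
        metric=metric, group1=group1, group2=group2,
        n1=n1, n2=n2, mean1=mean1, sd1=sd1, mean2=mean2, sd2=sd2,
        mean_difference=diff, t=float(t), df=float(df), p=p, cohens_d=d,
        pct_of_image_size=(
            100.0 * abs(diff) / float(image_size) ** 2
            if image_size is not None else None
        ),
        pct_of_grand_mean=100.0 * abs(diff) / grand if grand != 0 else float("nan"),
    )


def compare_cohorts(
    metrics_table: pd.DataFrame,
    metric_name: str,
    image_size: int | None = 1024,
    variant: str = "pooled",
) -> CohortComparison:
    """Compare the two cohorts of a per-image metrics table on one metric.

    ``metrics_table`` needs columns ``cohort`` and ``metric_name``; rows
    with non-finite metric values are ignored.  Cohort order (hence the
    sign of the difference) is the sorted label order, so the result is
    invariant to row order.  ``pct_of_image_size`` is reported only for
    the pixel-count metric ``vessel_amount``.
    """
    if metric_name not in metrics_table.columns:
        raise ValueError(f"unknown metric {metric_name!r}")
    if "cohort" not in metrics_table.columns:
        raise ValueError("metrics table needs a 'cohort' column")
    labels = sorted(metrics_table["cohort"].unique())
    if len(labels) != 2:
        raise ValueError(f"expected exactly 2 cohorts, found {labels}")
    g1, g2 = labels
    vals = metrics_table[np.isfinite(metrics_table[metric_name].astype(float))]
    # sorted values make the result exactly invariant to input row order
    x1 = np.sort(vals.loc[vals["cohort"] == g1, metric_name].to_numpy(dtype=float))
    x2 = np.sort(vals.loc[vals["cohort"] == g2, metric_name].to_numpy(dtype=float))
    if x1.size < 2 or x2.size < 2:
        raise StatisticsError("each cohort needs >= 2 finite rows")
    t, df, p = unpaired_t_test(x1, x2, variant=variant)
    comp = comparison_from_summary(
        metric_name,
        x1.size, float(x1.mean()), float(x1.std(ddof=1)),
        x2.size, float(x2.mean()), float(x2.std(ddof=1)),
        image_size=image_size if metric_name == "vessel_amount" else None,
        group1=str(g1), group2=str(g2),
    )
    comp.t, comp.df, comp.p = t, df, p  # use the sample-level test
    comp.cohens_d = cohens_d_from_samples(x1, x2)
    return comp


def comparisons_to_frame(comparisons) -> pd.DataFrame:
    """One row per metric with all CohortComparison fields."""
    return pd.DataFrame([vars(c) for c in comparisons])
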