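"""Weekly series assembly, baseline change records, trend and response
classification, and cohort box-plot summaries.

Percent change is always relative to the week-0 (pretreatment) value:
``100 * (v_w - v_0) / v_0``.  Weeks are aligned by index; scan days are
carried as metadata only.  Missing weeks are never interpolated.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .roi import HistogramSummary

logger = logging.getLogger(__name__)

#: metric name -> HistogramSummary attribute ("gtv_volume" is special-cased)
_SUMMARY_METRICS = {
    "median_adc": "median",
    "mean_adc": "mean",
    "sd_adc": "sd",
    "p10_adc": "p10",
    "p25_adc": "p25",
    "p75_adc": "p75",
    "p90_adc": "p90",
    "skewness": "skewness",
    "kurtosis": "kurtosis",
}

TREND_INCREASE = "increase"
TREND_PLATEAU = "plateau"
TREND_DECREASE = "decrease"

FLAGGED = "flagged_poor_response"
NOT_FLAGGED = "not_flagged"


@dataclass
class TimePoint:
    """One weekly observation: viable-tumor ADC summary + whole-GTV volume."""

    week: int
    adc_summary: HistogramSummary
    gtv_volume_cm3: float
    days_from_rt_start: int | None = None

    def __post_init__(self):
        if self.week < 0:
            raise ValueError("week must be >= 0")


@dataclass
class ChangeRecord:
    week: int
    metric: str
    absolute_change: float
    percent_change: float


@dataclass
class ResponseCall:
    """Outcome of the early-ADC-change rule.

    ``label`` is fully determined by the rule: flagged iff the observed
    percent change at the decision week is strictly below the threshold.
    """

    label: str
    threshold_pct: float
    decision_week: int
    observed_week: int
    observed_percent_change: float


@dataclass
class LongitudinalSeries:
    """Ordered weekly timepoints for one lesion (GTV)."""

    gtv_id: str
    timepoints: list[TimePoint]
    trend: list[tuple[int, int, str]] = field(default_factory=list)
    changes: list[ChangeRecord] = field(default_factory=list)
    response: ResponseCall | None = None

    def __post_init__(self):
        weeks = [tp.week for tp in self.timepoints]
        if weeks.count(0) != 1:
            raise ValueError(f"series {self.gtv_id}: exactly one week-0 entry required")
        if any(b <= a for a, b in zip(weeks, weeks[1:])):
            raise ValueError(f"series {self.gtv_id}: weeks must be strictly increasing")

    @property
    def weeks(self) -> list[int]:
        return [tp.week for tp in self.timepoints]

    def timepoint(self, week: int) -> TimePoint:
        for tp in self.timepoints:
            if tp.week == week:
                return tp
        raise KeyError(f"series {self.gtv_id}: no timepoint at week {week}")


def metric_value(tp: TimePoint, metric: str) -> float:
    if metric == "gtv_volume":
        return tp.gtv_volume_cm3
    try:
        return getattr(tp.adc_summary, _SUMMARY_METRICS[metric])
    except KeyError:
        raise ValueError(
            f"unknown metric {metric!r}; expected gtv_volume or one of "
            f"{sorted(_SUMMARY_METRICS)}"
        ) from None


def percent_change(series: LongitudinalSeries, metric: str) -> list[ChangeRecord]:
    """Absolute and percent change of ``metric`` vs the week-0 baseline.

    The week-0 record carries both changes equal to 0.  A zero baseline is
    an error.
    """
    baseline = metric_value(series.timepoint(0), metric)
    if baseline == 0 or not math.isfinite(baseline):
        raise ValueError(
            f"series {series.gtv_id}: baseline {metric} is {baseline}; percent change undefined"
        )
    records = []
    for tp in series.timepoints:
        v = metric_value(tp, metric)
        records.append(
            ChangeRecord(
                week=tp.week,
                metric=metric,
                absolute_change=v - baseline,
                percent_change=100.0 * (v - baseline) / baseline,
            )
        )
    return records


def classify_trend(
    series: LongitudinalSeries, metric: str, plateau_tol: float = 5.0
) -> list[tuple[int, int, str]]:
    """Label each week-over-week interval increase/plateau/decrease.

    An interval is a plateau when the step, expressed in percent of the
    baseline value, is within ``plateau_tol`` in magnitude; otherwise the
    sign decides.  The tolerance is a convention of this pipeline, not a
    published rule.
    """
    if len(series.timepoints) < 2:
        raise ValueError("classify_trend needs at least two timepoints")
    baseline = metric_value(series.timepoint(0), metric)
    if baseline == 0:
        raise ValueError("zero baseline: trend in percent of baseline undefined")
    labels = []
    for a, b in zip(series.timepoints, series.timepoints[1:]):
        step_pct = 100.0 * (metric_value(b, metric) - metric_value(a, metric)) / baseline
        if abs(step_pct) <= plateau_tol:
            lab = TREND_PLATEAU
        elif step_pct > 0:
            lab = TREND_INCREASE
        else:
            lab = TREND_DECREASE
        labels.append((a.week, b.week, lab))
    return labels


def classify_response(
    series: LongitudinalSeries,
    threshold_pct: float = 25.0,
    decision_week: int = 3,
    metric: str = "median_adc",
) -> ResponseCall:
    """Early-change response rule: flag poor response when the percent
    change at the decision week is strictly below the threshold.

    If the decision week is missing, the nearest earlier non-baseline week
    is used (logged).  Defaults: threshold 25 %, decision week 3.
    """
    candidates = [tp.week for tp in series.timepoints if 0 < tp.week <= decision_week]
    if not candidates:
        raise ValueError(
            f"series {series.gtv_id}: no timepoint at or before week {decision_week} "
            "besides baseline"
        )
    observed_week = max(candidates)
    if observed_week != decision_week:
        logger.warning(
            "series %s: decision week %d missing, using week %d",
            series.gtv_id,
            decision_week,
            observed_week,
        )
    changes = {r.week: r.percent_change for r in percent_change(series, metric)}
    observed = changes[observed_week]
    label = FLAGGED if observed < threshold_pct else NOT_FLAGGED
    return ResponseCall(
        label=label,
        threshold_pct=threshold_pct,
        decision_week=decision_week,
        observed_week=observed_week,
        observed_percent_change=observed,
    )


def cohort_summary(
    series_list: list[LongitudinalSeries],
    metric: str,
    use_percent_change: bool = True,
) -> pd.DataFrame:
    """Per-week box-plot statistics across lesions.

    Whiskers follow the Tukey 1.5 x IQR convention; values beyond them are
    listed as outliers.  Lesions missing a week are excluded from that week
    only.  Columns: week, n, median, p25, p75, whisker_low, whisker_high,
    outliers (semicolon-joined reprs).
    """
    if not series_list:
        raise ValueError("cohort_summary requires at least one series")
    per_week: dict[int, list[float]] = {}
    for s in series_list:
        if use_percent_change:
            values = {r.week: r.percent_change for r in percent_change(s, metric)}
        else:
            values = {tp.week: metric_value(tp, metric) for tp in s.timepoints}
        for wk, v in values.items():
            per_week.setdefault(wk, []).append(v)

    rows = []
    for wk in sorted(per_week):
        x = np.asarray(per_week[wk], dtype=np.float64)
        p25, med, p75 = np.percentile(x, [25, 50, 75])
        iqr = p75 - p25
        lo_fence, hi_fence = p25 - 1.5 * iqr, p75 + 1.5 * iqr
        inside = x[(x >= lo_fence) & (x <= hi_fence)]
        outliers = sorted(x[(x < lo_fence) | (x > hi_fence)].tolist())
        rows.append(
            {
                "week": wk,
                "n": int(x.size),
                "median": float(med),
                "p25": float(p25),
                "p75": float(p75),
                "whisker_low": float(inside.min()),
                "whisker_high": float(inside.max()),
                "outliers": ";".join(repr(v) for v in outliers),
            }
        )
    return pd.DataFrame(rows)


def percent_change_of_cohort_median(
    series_list: list[LongitudinalSeries], metric: str
) -> pd.DataFrame:
    """Percent change of the per-week cohort median raw value vs week 0.

    Complements :func:`cohort_summary` (median of per-lesion percent
    changes); the two aggregations differ in general and both are reported.
    """
    per_week: dict[int, list[float]] = {}
    for s in series_list:
        for tp in s.timepoints:
            per_week.setdefault(tp.week, []).append(metric_value(tp, metric))
    medians = {wk: float(np.median(v)) for wk, v in per_week.items()}
    if 0 not in medians or medians[0] == 0:
        raise ValueError("cohort median baseline missing or zero")
    base = medians[0]
    rows = [
        {"week": wk, "percent_change_of_median": 100.0 * (medians[wk] - base) / base}
        for wk in sorted(medians)
    ]
    return pd.DataFrame(rows)
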