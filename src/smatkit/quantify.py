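"""Ratiometric decay analysis of probe time-lapse series (SMAT).

Field-level mean gray value per frame -> first-timepoint normalization per
field trace -> replicate x field aggregation into a per-condition decay curve
(ratiometric mean +/- SEM) -> per-timepoint condition-vs-reference statistics
(two-way ANOVA, then Bonferroni-corrected posttests across timepoints).

Each field-of-view trace is one statistical observation, normalized
individually before aggregation, so every curve starts at exactly 1 and the
t0 SEM is 0.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ImageSeries",
    "IntensityTrace",
    "NormalizedDecayCurve",
    "ConditionComparison",
    "mean_gray_value",
    "series_to_trace",
    "normalize_trace",
    "aggregate_condition",
    "compare_conditions",
    "segment_switch_analysis",
    "stars",
    "traces_to_frame",
]

STAR_THRESHOLDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def stars(p: float) -> str:
    """Significance annotation: *** p<0.001, ** p<0.01, * p<0.05, else 'ns'."""
    for thr, s in STAR_THRESHOLDS:
        if p < thr:
            return s
    return "ns"


@dataclass
class ImageSeries:
    """One field's time-lapse: frames acquired at ``times`` minutes."""

    condition: str
    replicate: int
    field: int
    times: np.ndarray
    frames: list

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if len(self.frames) != len(self.times):
            raise ValueError("one frame per timepoint required")
        if len(self.times) >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        shapes = {np.asarray(f).shape for f in self.frames}
        if len(shapes) > 1:
            raise ValueError(f"frames have mismatched shapes: {shapes}")


@dataclass
class IntensityTrace:
    """Mean-gray-value time series of one field."""

    condition: str
    replicate: int
    field: int
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have the same length")
        if np.any(self.values < 0):
            raise ValueError("intensity values must be non-negative")


@dataclass
class NormalizedDecayCurve:
    """Per-condition ratiometric mean +/- SEM over replicate x field traces."""

    condition: str
    times: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    n: int


@dataclass
class ConditionComparison:
    """Per-timepoint condition-vs-reference tests, Bonferroni adjusted.

    ``p_adj`` and ``stars`` map each non-reference condition to arrays/lists
    aligned with ``times``; ``anova`` holds the two-way ANOVA p-values for
    the condition, time, and interaction terms.
    """

    reference: str
    times: np.ndarray
    p_adj: dict = dc_field(default_factory=dict)
    stars: dict = dc_field(default_factory=dict)
    anova: dict = dc_field(default_factory=dict)


def mean_gray_value(frame: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Arithmetic mean pixel intensity of a frame (optionally within a mask)."""
    frame = np.asarray(frame, dtype=float)
    if frame.size == 0:
        raise ValueError("empty frame")
    if mask is None:
        return float(frame.mean())
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != frame.shape:
        raise ValueError("mask shape must match frame shape")
    if not mask.any():
        raise ValueError("empty mask")
    return float(frame[mask].mean())


def series_to_trace(series: ImageSeries, mask: np.ndarray | None = None,
                    background: float = 0.0) -> IntensityTrace:
    """Reduce a time-lapse series to its per-frame mean-gray-value trace.

    ``background`` is an optional constant subtracted from each frame mean
    (clipped at 0); by default the raw mean is used.
    """
    values = np.array([mean_gray_value(f, mask) for f in series.frames])
    if background:
        values = np.clip(values - background, 0.0, None)
    return IntensityTrace(series.condition, series.replicate, series.field,
                          series.times, values)


def normalize_trace(trace: IntensityTrace) -> IntensityTrace:
    """Divide a trace by its first (t0) value; output starts at exactly 1."""
    ref = trace.values[0]
    if ref <= 0:
        raise ValueError(
            f"cannot normalize: t0 value {ref} <= 0 "
            f"(condition={trace.condition!r}, replicate={trace.replicate}, "
            f"field={trace.field})"
        )
    values = trace.values / ref
    values[0] = 1.0
    return IntensityTrace(trace.condition, trace.replicate, trace.field,
                          trace.times, values)


def aggregate_condition(traces: list) -> NormalizedDecayCurve:
    """Pointwise mean and SEM across a condition's normalized traces."""
    if len(traces) < 2:
        raise ValueError("need at least 2 traces to aggregate")
    conds = {t.condition for t in traces}
    if len(conds) > 1:
        raise ValueError(f"traces from multiple conditions: {conds}")
    t0 = traces[0].times
    for tr in traces[1:]:
        if not np.array_equal(tr.times, t0):
            raise ValueError("traces have mismatched time grids")
    mat = np.vstack([tr.values for tr in traces])
    mean = mat.mean(axis=0)
    sem = mat.std(axis=0, ddof=1) / np.sqrt(mat.shape[0])
    return NormalizedDecayCurve(traces[0].condition, t0, mean, sem, mat.shape[0])


def traces_to_frame(traces: list) -> pd.DataFrame:
    """Long-format DataFrame (condition, replicate, field, time_min, value)."""
    rows = []
    for tr in traces:
        for t, v in zip(tr.times, tr.values):
            rows.append((tr.condition, tr.replicate, tr.field, t, v))
    return pd.DataFrame(rows, columns=["condition", "replicate", "field",
                                       "time_min", "value"])


def _two_way_anova(df: pd.DataFrame) -> dict:
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    model = ols("value ~ C(condition) + C(time_min) + C(condition):C(time_min)",
                data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    return {
        "p_condition": float(table.loc["C(condition)", "PR(>F)"]),
        "p_time": float(table.loc["C(time_min)", "PR(>F)"]),
        "p_interaction": float(table.loc["C(condition):C(time_min)", "PR(>F)"]),
    }


def compare_conditions(traces: list, reference: str,
                       run_anova: bool = True) -> ConditionComparison:
    """Two-way ANOVA plus per-timepoint Bonferroni-corrected posttests.

    Factors are condition and time with each field trace as an observation;
    each non-reference condition is compared with the reference at every
    timepoint by a pooled-variance two-sample t-test, and p-values are
    Bonferroni-multiplied by the number of timepoints.
    """
    by_cond: dict[str, list] = {}
    for tr in traces:
        by_cond.setdefault(tr.condition, []).append(tr)
    if reference not in by_cond:
        raise ValueError(f"reference condition {reference!r} not in traces")
    if len(by_cond) < 2:
        raise ValueError("need at least 2 conditions to compare")
    for cond, trs in by_cond.items():
        if len(trs) < 2:
            raise ValueError(f"condition {cond!r} has fewer than 2 traces")

    times = by_cond[reference][0].times
    n_t = len(times)
    ref_mat = np.vstack([tr.values for tr in by_cond[reference]])

    out = ConditionComparison(reference=reference, times=times)
    for cond in sorted(c for c in by_cond if c != reference):
        mat = np.vstack([tr.values for tr in by_cond[cond]])
        if mat.shape[1] != n_t:
            raise ValueError(f"condition {cond!r} is on a different time grid")
        p_adj = np.ones(n_t)
        for k in range(n_t):
            a, b = ref_mat[:, k], mat[:, k]
            if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
                p = 1.0  # identical constant columns (e.g. the t0 = 1 anchor)
            else:
                p = stats.ttest_ind(a, b, equal_var=True).pvalue
                p = 1.0 if np.isnan(p) else float(p)
            p_adj[k] = min(1.0, p * n_t)
        out.p_adj[cond] = p_adj
        out.stars[cond] = [stars(p) for p in p_adj]

    if run_anova:
        out.anova = _two_way_anova(traces_to_frame(traces))
    return out


def _renormalize_at(trace: IntensityTrace, idx: int) -> IntensityTrace:
    sub = IntensityTrace(trace.condition, trace.replicate, trace.field,
                         trace.times[idx:] - trace.times[idx],
                         trace.values[idx:])
    return normalize_trace(sub)


def segment_switch_analysis(traces: list, switch_time: float, reference: str,
                            run_anova: bool = True) -> dict:
    """Condition comparisons split at a media-switch timepoint.

    The post-switch window is re-normalized to the frame at ``switch_time``
    (curves have typically already decayed by the switch, and the question is
    how decay proceeds *after* the cue changes).  Returns ``{"pre": ...,
    "post": ...}``; ``pre`` is None when the switch is at t0.
    """
    times = traces[0].times
    if switch_time < times[0] or switch_time >= times[-1]:
        raise ValueError(
            f"switch_time {switch_time} outside the time grid "
            f"[{times[0]}, {times[-1]})"
        )
    idx = int(np.searchsorted(times, switch_time))
    if times[idx] != switch_time:
        raise ValueError(f"switch_time {switch_time} is not a grid timepoint")

    post = [_renormalize_at(tr, idx) for tr in traces]
    result = {"pre": None,
              "post": compare_conditions(post, reference, run_anova=run_anova)}
    if idx > 0:
        pre = [IntensityTrace(tr.condition, tr.replicate, tr.field,
                              tr.times[: idx + 1], tr.values[: idx + 1])
               for tr in traces]
        result["pre"] = compare_conditions(pre, reference, run_anova=run_anova)
    return result
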