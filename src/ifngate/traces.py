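"""Quantification of single-cell reporter time traces.

Per-cell quantities: the activation time of each reporter (first
sustained rise of the smoothed time derivative after treatment onset),
the delay time (difference of the two activation times), the percentage
of cell-cycle progression at treatment onset (from the bracketing
division annotations), group classification by delay threshold, and
baseline-subtracted induction amounts.

The activation-time detector is a derivative-threshold rule with a
persistence requirement.  Its thresholds are configuration, not biology:
the rule is validated against synthetic ground truth, where it recovers
activation times to within one sampling interval on noiseless traces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import uniform_filter1d

from .synthetic import IRF9_CHANNEL, USP18_CHANNEL

__all__ = [
    "ActivationCall",
    "ProgressionRecord",
    "smoothed_derivative",
    "call_activation_time",
    "delay_time",
    "percent_progression",
    "classify_delay_groups",
    "induction_amount",
    "normalized_inductions",
    "cohort_summary",
    "quantify_cohort",
]


@dataclass(frozen=True)
class ActivationCall:
    """Result of the activation-time detector for one trace."""

    time: float | None          # hours since treatment onset, None if censored
    censored: bool
    threshold: float
    smooth_window: int
    persistence: int

    @property
    def called(self) -> bool:
        return not self.censored


@dataclass(frozen=True)
class ProgressionRecord:
    """% of the current cell cycle elapsed at treatment onset."""

    percent: float | None
    cycle_start: float | None
    cycle_end: float | None
    censored: bool
    reason: str = ""


def _check_uniform(times: np.ndarray) -> float:
    diffs = np.diff(times)
    if diffs.size == 0:
        raise ValueError("trace needs at least two samples")
    dt = float(diffs[0])
    if not np.allclose(diffs, dt, rtol=1e-6, atol=1e-9):
        raise ValueError("trace must be uniformly sampled")
    return dt


def smoothed_derivative(times, values, window: int = 5) -> np.ndarray:
    """Centered moving-average smoothing followed by central differences
    (one-sided at the endpoints).  ``window`` must be odd and >= 3."""
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    if window > values.size:
        raise ValueError("window longer than trace")
    dt = _check_uniform(times)
    smooth = uniform_filter1d(values, size=window, mode="nearest")
    return np.gradient(smooth, dt)


def call_activation_time(
    times,
    values,
    onset: float = 0.0,
    smooth_window: int = 5,
    threshold_sd: float = 3.0,
    persistence: int = 3,
    rel_floor: float = 0.4,
) -> ActivationCall:
    """First time after ``onset`` at which the smoothed derivative exceeds
    a threshold for at least ``persistence`` consecutive samples.

    The threshold is the pre-onset baseline derivative mean plus
    ``threshold_sd`` baseline SDs, floored at ``rel_floor`` times the
    post-onset derivative maximum (the floor keeps the smeared foot of
    the smoothing kernel from triggering early on clean traces).
    Censored when no such run exists.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    deriv = smoothed_derivative(times, values, smooth_window)
    pre = times < onset
    if pre.sum() < 2:
        raise ValueError("no pre-onset baseline samples to set the threshold")
    base = deriv[pre]
    post = times >= onset
    dmax = float(deriv[post].max()) if post.any() else 0.0
    threshold = max(
        float(base.mean() + threshold_sd * base.std(ddof=1)), rel_floor * dmax
    )
    above = (deriv > threshold) & post
    idx = np.flatnonzero(above)
    # first run of `persistence` consecutive indices
    call_t = None
    run = 1
    for j in range(idx.size):
        run = run + 1 if j > 0 and idx[j] == idx[j - 1] + 1 else 1
        if run >= persistence:
            call_t = float(times[idx[j - persistence + 1]] - onset)
            break
    return ActivationCall(
        time=call_t,
        censored=call_t is None,
        threshold=threshold,
        smooth_window=smooth_window,
        persistence=persistence,
    )


def delay_time(act_irf9: ActivationCall, act_usp18: ActivationCall) -> float | None:
    """USP18 activation minus IRF9 activation, raw (negative values under
    noise are retained); None when either call is censored."""
    if act_irf9.censored or act_usp18.censored:
        return None
    return act_usp18.time - act_irf9.time


def percent_progression(onset: float, divisions) -> ProgressionRecord:
    """Percentage of the current cell cycle elapsed at treatment onset,
    from the two consecutive observed divisions bracketing the onset."""
    divs = np.sort(np.asarray(divisions, dtype=float))
    if divs.size < 2:
        return ProgressionRecord(None, None, None, True, "fewer than two divisions")
    k = int(np.searchsorted(divs, onset, side="right")) - 1
    if k < 0 or k >= divs.size - 1:
        return ProgressionRecord(
            None, None, None, True, "onset outside any observed full cycle"
        )
    a, b = float(divs[k]), float(divs[k + 1])
    return ProgressionRecord(100.0 * (onset - a) / (b - a), a, b, False)


def classify_delay_groups(delays, threshold: float = 10.0):
    """Split delays at ``threshold``: Group 1 (<= threshold, includes any
    negative measured delays) vs Group 2 (> threshold).

    Returns ``(labels, fractions)`` with labels in {1, 2}.
    """
    delays = np.asarray(delays, dtype=float)
    if delays.size == 0:
        raise ValueError("empty delay list")
    labels = np.where(delays > threshold, 2, 1)
    fractions = {
        1: float(np.mean(labels == 1)),
        2: float(np.mean(labels == 2)),
    }
    return labels, fractions


def induction_amount(times, values, window_start: float, window_end: float) -> float:
    """Baseline-subtracted induction: trace value at ``window_end`` minus
    value at ``window_start`` (linear interpolation between samples)."""
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if window_start < times[0] or window_end > times[-1]:
        raise ValueError("induction window lies outside the trace")
    return float(
        np.interp(window_end, times, values) - np.interp(window_start, times, values)
    )


def normalized_inductions(amounts: dict, control_key) -> dict:
    """Divide each condition's induction amount by the control's."""
    control = amounts[control_key]
    if control == 0:
        raise ValueError("control induction is zero; cannot normalize")
    return {k: v / control for k, v in amounts.items()}


def cohort_summary(
    records: pd.DataFrame,
    columns=None,
    correlation_pairs=(),
    delay_column: str | None = None,
    delay_threshold: float = 10.0,
) -> dict:
    """Means (with normal-approximation 95% CI), CVs, requested Pearson
    correlations, and the Group-2 fraction of a per-cell record table."""
    if records.empty:
        raise ValueError("empty records")
    if columns is None:
        columns = [c for c in records.columns if records[c].dtype.kind in "fi"]
    out: dict = {"n": int(len(records)), "columns": {}}
    for col in columns:
        x = records[col].dropna().to_numpy(dtype=float)
        entry: dict = {"n": int(x.size)}
        if x.size >= 2:
            m = float(x.mean())
            sd = float(x.std(ddof=1))
            half = 1.959963984540054 * sd / np.sqrt(x.size)
            entry.update(
                mean=m, sd=sd, ci95=(m - half, m + half),
                cv=(sd / m if m > 0 else None),
            )
        else:
            entry.update(mean=float(x.mean()) if x.size else None, sd=None,
                         ci95=None, cv=None, flagged="n < 2")
        out["columns"][col] = entry
    out["correlations"] = {}
    for a, b in correlation_pairs:
        sub = records[[a, b]].dropna()
        if len(sub) >= 2 and sub[a].std() > 0 and sub[b].std() > 0:
            r, p = stats.pearsonr(sub[a], sub[b])
            out["correlations"][f"{a}~{b}"] = {"r": float(r), "p": float(p)}
        else:
            out["correlations"][f"{a}~{b}"] = {"r": None, "p": None}
    if delay_column is not None:
        delays = records[delay_column].dropna().to_numpy(dtype=float)
        if delays.size:
            _, fractions = classify_delay_groups(delays, delay_threshold)
            out["group2_fraction"] = fractions[2]
    return out


def quantify_cohort(
    traces: pd.DataFrame,
    divisions: pd.DataFrame,
    onset: float = 0.0,
    irf9_channel: str = IRF9_CHANNEL,
    usp18_channel: str = USP18_CHANNEL,
    delay_threshold: float = 10.0,
    **call_kwargs,
) -> pd.DataFrame:
    """Per-cell quantification of a tidy trace table.

    Returns one row per cell: activation times of both reporters, delay,
    % cell-cycle progression at onset, and the delay-group label (NaN
    where censored).
    """
    rows = []
    div_by_cell = {
        cid: grp["division_time_h"].to_numpy()
        for cid, grp in divisions.groupby("cell_id")
    }
    for cid, grp in traces.groupby("cell_id"):
        calls = {}
        for channel in (irf9_channel, usp18_channel):
            sub = grp[grp["channel"] == channel].sort_values("time_h")
            if sub.empty:
                calls[channel] = None
                continue
            calls[channel] = call_activation_time(
                sub["time_h"].to_numpy(), sub["value"].to_numpy(),
                onset=onset, **call_kwargs,
            )
        ci, cu = calls[irf9_channel], calls[usp18_channel]
        delay = delay_time(ci, cu) if ci is not None and cu is not None else None
        prog = percent_progression(onset, div_by_cell.get(cid, []))
        rows.append(
            {
                "cell_id": cid,
                "act_irf9_h": ci.time if ci is not None else None,
                "act_usp18_h": cu.time if cu is not None else None,
                "delay_h": delay,
                "pct_progression": prog.percent,
                "group": (
                    (2 if delay > delay_threshold else 1) if delay is not None else None
                ),
            }
        )
    return pd.DataFrame(rows)
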