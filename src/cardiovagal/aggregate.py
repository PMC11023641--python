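"""Daily, binned, and event-locked aggregation surfaces.

Three analysis surfaces are produced from cleaned beats and vitals:

* per-day 24-hour metrics with change-from-Day-1 (Day 1 = each subject's
  first recording day, used as their own baseline),
* three-day bins {Day 2-4, 5-7, 8-10, 11-13} of those changes, each
  subject-day treated as one observation,
* treatment-session series: 6-minute sliding windows stepped by 3 minutes
  bi-directionally from the session onset/offset, z-normalized against a
  daily reference built with the same sliding-window procedure over the
  whole day, summarized into pre / during / post period means and deltas.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .metrics import compute_metrics
from .types import HrvMetrics, RrSeries

logger = logging.getLogger(__name__)

DAY_BINS = (
    ("Day 2-4", 2, 4),
    ("Day 5-7", 5, 7),
    ("Day 8-10", 8, 10),
    ("Day 11-13", 11, 13),
)

WINDOW_S = 360.0   # 6-minute sliding window
STEP_S = 180.0     # 3-minute step
PERIOD_S = 1200.0  # 20-minute pre / during / post periods
MIN_COVERAGE_H = 4.0

#: metric columns summarized per window in the event-locked analysis
WINDOW_METRICS = ("hr", "rmssd", "sdnn", "qtc_mean")


def daily_summary(
    rr: RrSeries,
    qt_ms: Optional[np.ndarray],
    vitals: Optional[pd.DataFrame],
    subject: str,
    day: int,
    min_coverage_h: float = MIN_COVERAGE_H,
) -> Optional[dict]:
    """Metrics for one subject-day, or None when ECG coverage is too short.

    Coverage is the summed duration of valid RR intervals.  Vitals are
    averaged over the day (columns other than ``time_s`` are taken as vitals
    streams).
    """
    coverage_h = float(np.sum(rr.valid_rr)) / 1000.0 / 3600.0
    if coverage_h < min_coverage_h:
        logger.info("%s day %d: %.2f h valid ECG < %.1f h minimum; day absent",
                    subject, day, coverage_h, min_coverage_h)
        return None
    m = compute_metrics(rr, qt_ms)
    row = {"subject": subject, "day": day, "coverage_h": coverage_h}
    row.update(m.as_dict())
    if vitals is not None:
        for col in vitals.columns:
            if col != "time_s":
                row[col] = float(vitals[col].mean())
    return row


def add_change_from_day1(table: pd.DataFrame, metric_cols=None) -> pd.DataFrame:
    """Append ``<metric>_change`` columns: value minus the subject's Day-1
    value (zero on Day 1 by construction; NaN when Day 1 is absent)."""
    df = table.copy()
    if metric_cols is None:
        metric_cols = [c for c in df.columns
                       if c not in ("subject", "day", "arm", "coverage_h")
                       and pd.api.types.is_numeric_dtype(df[c])
                       and not c.endswith("_change")]
    day1 = df[df.day == 1].set_index("subject")
    for c in metric_cols:
        base = df.subject.map(day1[c]) if c in day1.columns else np.nan
        df[f"{c}_change"] = df[c] - base
    return df


def bin_days(table: pd.DataFrame) -> pd.DataFrame:
    """Attach the three-day bin label; Day 1 (baseline) and days past 13 are
    excluded from the result."""
    df = table[table.day >= 2].copy()
    labels = pd.Series(pd.NA, index=df.index, dtype="object")
    for name, lo, hi in DAY_BINS:
        labels[(df.day >= lo) & (df.day <= hi)] = name
    df["day_bin"] = labels
    return df[df.day_bin.notna()].copy()


def _window_covered(rr: RrSeries, t0: float, t1: float,
                    max_beat_gap_s: float = 3.0) -> bool:
    """True when beats cover [t0, t1) without an internal gap."""
    w = rr.restrict(t0, t1)
    if len(w) < 10:
        return False
    t = w.times
    edges = np.concatenate([[t[0] - t0], np.diff(t), [t1 - t[-1]]])
    return bool(np.max(edges) <= max_beat_gap_s)


def _window_metrics(rr: RrSeries, qt_ms, t0: float, t1: float) -> dict:
    mask = (rr.times >= t0) & (rr.times < t1)
    sub = RrSeries(rr.times[mask], rr.rr[mask], rr.flags[mask])
    q = qt_ms[mask] if qt_ms is not None else None
    return compute_metrics(sub, q).as_dict()


def sliding_windows(
    rr: RrSeries,
    qt_ms: Optional[np.ndarray],
    t_start: float,
    t_stop: float,
    window_s: float = WINDOW_S,
    step_s: float = STEP_S,
) -> pd.DataFrame:
    """Metric values over 6-minute windows stepped by 3 minutes.

    Windows not fully covered by gap-free beats are dropped.  Returns one row
    per emitted window with its start time.
    """
    starts = np.arange(t_start, t_stop - window_s + 1e-9, step_s)
    rows = []
    for s in starts:
        if not _window_covered(rr, s, s + window_s):
            continue
        row = {"window_start_s": float(s)}
        row.update(_window_metrics(rr, qt_ms, s, s + window_s))
        rows.append(row)
    return pd.DataFrame(rows)


def daily_reference(windows: pd.DataFrame,
                    metric_cols=WINDOW_METRICS) -> pd.DataFrame:
    """Per-metric mean and SD of the day's sliding-window values."""
    rows = []
    for c in metric_cols:
        v = windows[c].dropna() if c in windows else pd.Series(dtype=float)
        rows.append({
            "metric": c,
            "mean": float(v.mean()) if len(v) else np.nan,
            "sd": float(v.std(ddof=1)) if len(v) > 1 else np.nan,
        })
    return pd.DataFrame(rows).set_index("metric")


@dataclass
class SessionWindowSeries:
    """Event-locked normalized windows and period summaries for one session."""

    windows: pd.DataFrame          # offset_min, <metric>, <metric>_z
    period_means: pd.DataFrame     # period x metric (normalized units)
    deltas: pd.DataFrame           # metric -> during_minus_pre, post_minus_pre
    alignment: str = "onset"


def event_locked(
    rr: RrSeries,
    qt_ms: Optional[np.ndarray],
    onset_s: float,
    offset_s: float,
    reference: pd.DataFrame,
    window_s: float = WINDOW_S,
    step_s: float = STEP_S,
    period_s: float = PERIOD_S,
    span_s: Optional[float] = None,
) -> SessionWindowSeries:
    """Normalized metric series around one treatment session.

    Windows start at ``onset + k*step`` for integer k (bi-directional) and
    are z-scored with the daily reference: (value - daily mean) / daily SD;
    metrics whose daily SD is zero come out absent.  Period means use only
    windows fully contained in the 20-minute pre ([onset-period, onset]),
    during ([onset, offset]) and post ([offset, offset+period]) spans.
    """
    if span_s is None:
        span_s = period_s + 240.0
    k_min = -int(np.floor((span_s) / step_s))
    k_max = int(np.floor((offset_s - onset_s + span_s) / step_s))
    rows = []
    for k in range(k_min, k_max + 1):
        s = onset_s + k * step_s
        if not _window_covered(rr, s, s + window_s):
            continue
        row = {"offset_min": (s - onset_s) / 60.0, "window_start_s": s}
        row.update(_window_metrics(rr, qt_ms, s, s + window_s))
        rows.append(row)
    win = pd.DataFrame(rows)

    for c in WINDOW_METRICS:
        if c not in win.columns or c not in reference.index:
            continue
        mu, sd = reference.loc[c, "mean"], reference.loc[c, "sd"]
        if not np.isfinite(sd) or sd == 0:
            win[f"{c}_z"] = np.nan
        else:
            win[f"{c}_z"] = (win[c] - mu) / sd

    periods = {
        "pre": (onset_s - period_s, onset_s),
        "during": (onset_s, offset_s),
        "post": (offset_s, offset_s + period_s),
    }
    pm, deltas = {}, {}
    if len(win):
        for name, (a, b) in periods.items():
            inside = (win.window_start_s >= a - 1e-9) & \
                     (win.window_start_s + window_s <= b + 1e-9)
            pm[name] = {
                c: float(win.loc[inside, f"{c}_z"].mean())
                for c in WINDOW_METRICS if f"{c}_z" in win
            }
        for c in WINDOW_METRICS:
            if f"{c}_z" not in win:
                continue
            deltas[c] = {
                "during_minus_pre": pm["during"].get(c, np.nan)
                - pm["pre"].get(c, np.nan),
                "post_minus_pre": pm["post"].get(c, np.nan)
                - pm["pre"].get(c, np.nan),
            }
    return SessionWindowSeries(
        windows=win,
        period_means=pd.DataFrame(pm).T,
        deltas=pd.DataFrame(deltas).T,
    )
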