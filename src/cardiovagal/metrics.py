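"""RR-interval cleaning and cardiac metrics.

Cleaning follows the trial's preprocessing rules: intervals above 2 s or below
300 ms are outliers; an interval differing by more than 20% from the previous
*retained* (valid) interval is an ectopic beat.  Flags are annotations only —
interval values are never mutated, and every metric below uses only the
intervals flagged valid.

Time-domain HRV (RMSSD, SDNN, pNNI_50), frequency-domain power (total power
below 0.4 Hz, normalized high-frequency power 0.15–0.4 Hz), Lorenz-plot
autonomic indices (CVI/CSI, Toichi convention) and Bazett-corrected QT are the
metric set entering the downstream factor analysis and group statistics.
"""
from __future__ import annotations

import logging

import numpy as np
from scipy import interpolate, signal

from .types import ECTOPIC, OUTLIER, VALID, HrvMetrics, RrSeries

logger = logging.getLogger(__name__)

RR_MAX_MS = 2000.0
RR_MIN_MS = 300.0
ECTOPIC_REL_DIFF = 0.20
PROLONGED_QTC_MS = 500.0
NN50_THRESHOLD_MS = 50.0

LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.40)
TOTAL_BAND_MAX = 0.40


def clean_rr(
    rr: RrSeries,
    rr_max_ms: float = RR_MAX_MS,
    rr_min_ms: float = RR_MIN_MS,
    ectopic_rel_diff: float = ECTOPIC_REL_DIFF,
) -> RrSeries:
    """Flag outlier and ectopic intervals; values are left untouched.

    The outlier rule is applied first; the ectopic rule then compares each
    remaining interval to the previous interval that survived both rules, so
    a single outlier cannot poison its successor.
    """
    if len(rr) == 0:
        raise ValueError("empty RR series")
    flags = np.full(len(rr), VALID, dtype=np.int8)
    flags[(rr.rr > rr_max_ms) | (rr.rr < rr_min_ms)] = OUTLIER
    prev = None  # last retained interval, ms
    for i in range(len(rr)):
        if flags[i] == OUTLIER:
            continue
        if prev is not None and abs(rr.rr[i] - prev) / prev > ectopic_rel_diff:
            flags[i] = ECTOPIC
            continue
        prev = rr.rr[i]
    out = RrSeries(rr.times.copy(), rr.rr.copy(), flags)
    if not out.valid_mask.any():
        logger.warning("all %d RR intervals flagged; metrics will be absent", len(rr))
    return out


def heart_rate(rr: RrSeries) -> float:
    """Mean heart rate in bpm over valid intervals (60000 / mean RR ms)."""
    v = rr.valid_rr
    if v.size == 0:
        return np.nan
    return 60000.0 / float(np.mean(v))


def qtc_bazett(qt_ms, rr_s):
    """Bazett heart-rate correction: QTc = QT / sqrt(RR), RR in seconds.

    Estimates the QT interval at a standard heart rate of 60 bpm (RR = 1 s,
    where the correction is the identity).
    """
    qt_ms = np.asarray(qt_ms, dtype=float)
    rr_s = np.asarray(rr_s, dtype=float)
    if np.any(rr_s <= 0):
        raise ValueError("RR must be positive for Bazett correction")
    out = qt_ms / np.sqrt(rr_s)
    return float(out) if out.ndim == 0 else out


def prolonged_qtc_fraction(qtc_ms, threshold_ms: float = PROLONGED_QTC_MS) -> float:
    """Percentage of beats with QTc >= 500 ms (threshold inclusive)."""
    qtc_ms = np.asarray(qtc_ms, dtype=float)
    qtc_ms = qtc_ms[~np.isnan(qtc_ms)]
    if qtc_ms.size == 0:
        raise ValueError("no QTc values")
    return 100.0 * float(np.count_nonzero(qtc_ms >= threshold_ms)) / qtc_ms.size


def _valid_successive_diffs(rr: RrSeries) -> np.ndarray:
    """Differences between adjacent intervals where both are valid.

    Pairs spanning a flagged beat are excluded rather than bridged.
    """
    m = rr.valid_mask
    pair = m[1:] & m[:-1]
    return np.diff(rr.rr)[pair]


def hrv_time(rr: RrSeries) -> tuple:
    """Return (rmssd, sdnn, pnni50) over valid intervals.

    SDNN uses the n-1 sample standard deviation; pNNI_50 counts successive
    differences strictly greater than 50 ms.
    """
    v = rr.valid_rr
    if v.size < 3:
        return np.nan, np.nan, np.nan
    sdnn = float(np.std(v, ddof=1))
    d = _valid_successive_diffs(rr)
    if d.size < 2:
        logger.warning("fewer than 2 usable successive pairs; RMSSD/pNNI_50 absent")
        return np.nan, sdnn, np.nan
    rmssd = float(np.sqrt(np.mean(d**2)))
    pnni50 = 100.0 * float(np.count_nonzero(np.abs(d) > NN50_THRESHOLD_MS)) / d.size
    return rmssd, sdnn, pnni50


def hrv_freq(
    rr: RrSeries,
    resample_hz: float = 4.0,
    welch_segment_s: float = 120.0,
) -> tuple:
    """Return (total_power, nhf_power) from the Welch PSD of the tachogram.

    Valid intervals are resampled to an even grid at ``resample_hz`` with
    cubic interpolation across flagged beats; total power integrates the PSD
    below 0.4 Hz (DC excluded) and nhf_power is the 0.15–0.4 Hz share of it.
    """
    m = rr.valid_mask
    t, y = rr.times[m], rr.rr[m]
    if t.size < 4 or t[-1] - t[0] < 120.0:
        return np.nan, np.nan
    grid = np.arange(t[0], t[-1], 1.0 / resample_hz)
    f_interp = interpolate.interp1d(t, y, kind="cubic", assume_sorted=True)
    even = f_interp(grid)
    nperseg = min(int(welch_segment_s * resample_hz), even.size)
    freqs, psd = signal.welch(
        even, fs=resample_hz, nperseg=nperseg, noverlap=nperseg // 2,
        detrend="constant",
    )
    band = (freqs > 0) & (freqs <= TOTAL_BAND_MAX)
    total = float(np.trapezoid(psd[band], freqs[band]))
    hf = (freqs >= HF_BAND[0]) & (freqs <= HF_BAND[1])
    hf_power = float(np.trapezoid(psd[hf], freqs[hf]))
    if total <= 0:
        return total, np.nan
    return total, hf_power / total


def lorenz_indices(rr: RrSeries) -> tuple:
    """Return (cvi, csi) from the Lorenz (Poincaré) plot of valid intervals.

    SD1 = sqrt(var(ΔRR)/2) is beat-to-beat (vagal) scatter; SD2 completes the
    ellipse via 2·SDNN² = SD1² + SD2².  With transverse axis T = 4·SD1 and
    longitudinal axis L = 4·SD2: CSI = L/T, CVI = log10(L·T).
    """
    d = _valid_successive_diffs(rr)
    if d.size < 10:
        return np.nan, np.nan
    sd1_sq = float(np.var(d, ddof=1)) / 2.0
    sdnn = float(np.std(rr.valid_rr, ddof=1))
    sd2_sq = max(2.0 * sdnn**2 - sd1_sq, 0.0)
    if sd1_sq <= 0 or sd2_sq <= 0:
        return np.nan, np.nan
    sd1, sd2 = np.sqrt(sd1_sq), np.sqrt(sd2_sq)
    csi = sd2 / sd1
    cvi = float(np.log10(16.0 * sd1 * sd2))
    return cvi, csi


def compute_metrics(rr: RrSeries, qt_ms=None) -> HrvMetrics:
    """All cardiac metrics for one window of (cleaned) RR intervals.

    ``qt_ms`` is an optional per-interval QT array aligned with ``rr``; QTc is
    computed per beat with Bazett's formula over valid intervals with a
    measured QT.
    """
    rmssd, sdnn, pnni50 = hrv_time(rr)
    total_power, nhf = hrv_freq(rr)
    cvi, csi = lorenz_indices(rr)
    out = HrvMetrics(
        hr=heart_rate(rr), rmssd=rmssd, sdnn=sdnn, pnni50=pnni50,
        total_power=total_power, nhf_power=nhf, cvi=cvi, csi=csi,
    )
    if qt_ms is not None:
        qt_ms = np.asarray(qt_ms, dtype=float)
        ok = rr.valid_mask & ~np.isnan(qt_ms)
        if ok.any():
            qtc = qtc_bazett(qt_ms[ok], rr.rr[ok] / 1000.0)
            out.qtc_mean = float(np.mean(qtc))
            out.qtc_median = float(np.median(qtc))
            out.prolonged_qtc_pct = prolonged_qtc_fraction(qtc)
    return out
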