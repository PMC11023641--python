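"""Template-based synthetic ECG with analytically known fiducials.

Each beat is a sum of raised-cosine (Hann) bumps for the P wave, the Q/R/S
deflections and the T wave.  Hann bumps have compact support, so every wave
onset and offset is an exact sample index, not an asymptotic tail — exactness
of the ground truth is preferred over morphological realism, because the
point of the signal is to score the delineator.

Geometry (defaults, ms relative to the R peak):

    p_onset  p_peak  p_offset   qrs_onset   r_peak   qrs_offset
     -210     -160     -110        -50         0         +50

The T wave is placed so that the true QT (qrs_onset → t_offset) equals the
per-beat value returned by ``qt_model(rr_s)``; its support is the final
``t_width`` ms of that interval with the peak at the support midpoint.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd

from ..types import BeatFiducials, EcgRecord, RrSeries


def bazett_constant_qt(qtc_ms: float = 400.0) -> Callable[[float], float]:
    """QT rule QT = qtc·sqrt(RR s): every beat has Bazett QTc == qtc_ms."""

    def qt_model(rr_s: float) -> float:
        return qtc_ms * np.sqrt(rr_s)

    return qt_model


# per-wave (center offset ms, half-width ms, amplitude mV); T handled separately
_TEMPLATE = {
    "p": (-160.0, 50.0, 0.15),
    "q": (-35.0, 15.0, -0.12),
    "r": (0.0, 25.0, 1.0),
    "s": (35.0, 15.0, -0.25),
}
_QRS_ON_MS = -50.0
_QRS_OFF_MS = 50.0
_P_ON_MS = -210.0
_P_OFF_MS = -110.0
_T_WIDTH_MS = 160.0
_T_AMP = 0.30


@dataclass
class GroundTruth:
    """Exact beat-level truth attached to a synthetic record."""

    fiducials: BeatFiducials
    qt_ms: np.ndarray            # true QT per beat (NaN where no T wave)
    qtc_ms: np.ndarray           # true Bazett QTc per beat
    session_intervals: list = field(default_factory=list)  # (onset, offset) samples
    daily_metrics: Optional[pd.DataFrame] = None


def _hann_bump(x: np.ndarray, fs: float, center: int, half_width_ms: float,
               amp: float) -> None:
    hw = int(round(half_width_ms * fs / 1000.0))
    if hw < 1:
        return
    lo, hi = center - hw, center + hw
    a, b = max(lo, 0), min(hi + 1, x.size)
    if a >= b:
        return
    k = np.arange(a, b) - lo
    x[a:b] += amp * 0.5 * (1 - np.cos(2 * np.pi * k / (2 * hw)))


def synthesize_ecg(
    rr: RrSeries,
    qt_model: Optional[Callable[[float], float]] = None,
    fs: float = 500.0,
    noise_sd: float = 0.0,
    powerline_amp: float = 0.0,
    powerline_hz: float = 60.0,
    seed: int = 0,
    include_t: bool = True,
) -> tuple:
    """Render an RR series into an ECG trace with exact fiducials.

    Returns ``(EcgRecord, GroundTruth)``.  Beat *i* is the beat at
    ``rr.times[i]``; its QT is driven by the interval ``rr.rr[i]`` that ends
    at that beat.  Raises if any beat's QT would reach the next R wave.
    """
    if fs < 250:
        raise ValueError("fs must be >= 250 Hz for T-wave delineation")
    if qt_model is None:
        qt_model = bazett_constant_qt(400.0)
    rng = np.random.default_rng(seed)

    pad_s = 0.6
    r_samples = np.round((rr.times - rr.times[0] + pad_s) * fs).astype(int)
    n_samples = r_samples[-1] + int(pad_s * fs)
    x = np.zeros(n_samples)

    ms = fs / 1000.0
    rows = []
    qt_true = np.full(len(rr), np.nan)
    for i, r in enumerate(r_samples):
        rr_s = rr.rr[i] / 1000.0
        for _, (c, hw, amp) in _TEMPLATE.items():
            _hann_bump(x, fs, r + int(round(c * ms)), hw, amp)
        row = {
            "p_onset": r + int(round(_P_ON_MS * ms)),
            "p_peak": r + int(round(_TEMPLATE["p"][0] * ms)),
            "p_offset": r + int(round(_P_OFF_MS * ms)),
            "qrs_onset": r + int(round(_QRS_ON_MS * ms)),
            "r_peak": r,
            "qrs_offset": r + int(round(_QRS_OFF_MS * ms)),
            "t_peak": pd.NA,
            "t_offset": pd.NA,
        }
        if include_t:
            qt = float(qt_model(rr_s))
            if qt >= rr.rr[i]:
                raise ValueError(
                    f"beat {i}: QT {qt:.0f} ms >= RR {rr.rr[i]:.0f} ms "
                    "(T wave would overlap the next beat)"
                )
            t_off = row["qrs_onset"] + int(round(qt * ms))
            t_center = t_off - int(round(_T_WIDTH_MS / 2 * ms))
            _hann_bump(x, fs, t_center, _T_WIDTH_MS / 2, _T_AMP)
            row["t_peak"] = t_center
            row["t_offset"] = t_off
            qt_true[i] = (t_off - row["qrs_onset"]) / ms
        rows.append(row)

    if noise_sd > 0:
        x = x + rng.normal(0.0, noise_sd, x.size)
    if powerline_amp > 0:
        t = np.arange(x.size) / fs
        x = x + powerline_amp * np.sin(2 * np.pi * powerline_hz * t)

    fid = BeatFiducials(pd.DataFrame(rows))
    with np.errstate(invalid="ignore"):
        qtc_true = qt_true / np.sqrt(rr.rr / 1000.0)
    record = EcgRecord(samples=x, fs=fs, t0=rr.times[0] - pad_s)
    return record, GroundTruth(fiducials=fid, qt_ms=qt_true, qtc_ms=qtc_true)
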