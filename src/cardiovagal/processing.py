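"""ECG preprocessing, R-peak detection, wavelet delineation, event binarization.

Filtering: zero-phase (forward-backward) 0.5 Hz fifth-order high-pass
Butterworth plus a 60 Hz notch (second-order IIR, Q = 30).  Zero-phase
application preserves fiducial timing.

R-peak detection rides on the steepness of the absolute gradient of the
filtered signal: a smoothed absolute-gradient envelope is thresholded
adaptively, and each supra-threshold QRS region contributes the local maximum
of the signal as the R peak, with a 200 ms physiological refractory period.

Delineation follows the dyadic-scale wavelet scheme of the classic
modulus-maxima delineator: the signal is decomposed with the quadratic-spline
wavelet (a-trous algorithm, derivative-of-smoothing filters), QRS boundaries
are read off the modulus-maxima pattern around the R pair at a fine scale,
and the T wave is found as the dominant modulus-maxima pair at a coarse scale
inside a post-QRS search window, with its offset located by threshold
crossing after the last T modulus maximum.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import signal

from .types import BeatFiducials, EcgRecord, EventIntervals

logger = logging.getLogger(__name__)

HIGHPASS_HZ = 0.5
HIGHPASS_ORDER = 5
NOTCH_HZ = 60.0
NOTCH_Q = 30.0
REFRACTORY_S = 0.200


def preprocess(ecg: EcgRecord) -> EcgRecord:
    """Zero-phase high-pass then powerline notch; gaps propagated, never
    interpolated."""
    if ecg.fs < 250:
        raise ValueError("fs must be >= 250 Hz")
    if ecg.duration < 10.0:
        raise ValueError("record shorter than 10 s")
    sos = signal.butter(HIGHPASS_ORDER, HIGHPASS_HZ, "highpass", fs=ecg.fs,
                        output="sos")
    y = signal.sosfiltfilt(sos, ecg.samples)
    if NOTCH_HZ < ecg.fs / 2:
        b, a = signal.iirnotch(NOTCH_HZ, NOTCH_Q, fs=ecg.fs)
        y = signal.filtfilt(b, a, y)
    out = ecg.with_samples(y)
    out.gap_mask = ecg.gap_mask.copy()
    return out


def detect_r_peaks(ecg: EcgRecord, min_height_frac: float = 0.4) -> np.ndarray:
    """R-peak sample indices from the gradient-steepness envelope.

    The signal is restricted to the QRS energy band (5-22 Hz), its squared
    gradient is averaged over 100 ms, and the envelope is thresholded at
    ``min_height_frac`` of a high percentile of its own peak heights — an
    adaptive, amplitude-scale-invariant criterion.  Each supra-threshold
    region contributes the local signal maximum as the R peak; peaks closer
    than the 200 ms refractory period are pruned, keeping the larger, and
    peaks whose neighborhood touches a gap are dropped.
    """
    x = ecg.samples
    if x.size == 0 or np.ptp(x) == 0:
        return np.array([], dtype=int)
    fs = ecg.fs
    # restrict to the QRS energy band before taking the gradient so wideband
    # noise does not lift the steepness envelope
    sos = signal.butter(3, (5.0, 22.0), "bandpass", fs=fs, output="sos")
    xb = signal.sosfiltfilt(sos, x)
    grad = np.gradient(xb) ** 2
    win = max(int(0.10 * fs), 1)
    env = signal.convolve(grad, np.ones(win) / win, mode="same")
    env = env - np.median(env)

    cand, _ = signal.find_peaks(env, distance=int(REFRACTORY_S * fs))
    if cand.size == 0:
        logger.warning("no QRS candidates found in a non-empty window")
        return np.array([], dtype=int)
    # QRS envelope peaks dominate the top of the candidate-height
    # distribution even when noise peaks outnumber them (heart rate bounds
    # the QRS count from below at ~1 per 2 s); anchor the threshold there.
    ref = np.percentile(env[cand], 95)
    thr = min_height_frac * ref
    regions, _ = signal.find_peaks(env, height=thr,
                                   distance=int(REFRACTORY_S * fs))
    if regions.size == 0:
        logger.warning("no QRS regions above threshold")
        return np.array([], dtype=int)

    # refine each envelope peak to the local signal maximum (the R wave)
    half = int(0.06 * fs)
    peaks = []
    for c in regions:
        a, b = max(c - half, 0), min(c + half + 1, x.size)
        peaks.append(a + int(np.argmax(x[a:b])))
    peaks = np.array(sorted(set(peaks)), dtype=int)

    # enforce refractory on the refined peaks, keep the taller
    keep = []
    for p in peaks:
        if keep and (p - keep[-1]) < REFRACTORY_S * fs:
            if x[p] > x[keep[-1]]:
                keep[-1] = p
        else:
            keep.append(p)
    peaks = np.array(keep, dtype=int)

    if ecg.gap_mask.any():
        pad = int(0.3 * fs)
        gm = ecg.gap_mask
        ok = [
            p for p in peaks
            if not gm[max(p - pad, 0):min(p + pad, gm.size)].any()
        ]
        peaks = np.array(ok, dtype=int)
    return peaks


def _quadratic_spline_wt(x: np.ndarray, levels: int = 5) -> list:
    """Dyadic wavelet transform with the quadratic-spline wavelet (a-trous).

    Smoothing filter h = [1,3,3,1]/8 and derivative filter g = [2,-2],
    upsampled by 2**(k-1) at level k; each band is re-aligned by its
    accumulated group delay so modulus-maxima positions sit on the waveform
    features that caused them.  Returns [w1 .. w_levels].
    """
    h = np.array([1.0, 3.0, 3.0, 1.0]) / 8.0
    g = np.array([2.0, -2.0])
    n = x.size
    a = x.astype(float)
    delay_a = 0.0
    out = []
    for k in range(1, levels + 1):
        up = 2 ** (k - 1)
        gk = np.zeros((g.size - 1) * up + 1)
        gk[::up] = g
        hk = np.zeros((h.size - 1) * up + 1)
        hk[::up] = h
        w_full = np.convolve(a, gk, mode="full")
        shift = int(round(delay_a + 0.5 * up))
        w = w_full[shift:shift + n]
        out.append(w)
        a_full = np.convolve(a, hk, mode="full")
        # a's delay accounted incrementally; crop back to n each level
        a = a_full[int(round(1.5 * up)):int(round(1.5 * up)) + n]
        delay_a = 0.0  # already compensated by cropping
    return out


def _modulus_maxima(w: np.ndarray, lo: int, hi: int, thr: float) -> np.ndarray:
    """Indices of local maxima of |w| above thr inside [lo, hi)."""
    lo, hi = max(lo, 1), min(hi, w.size - 1)
    if hi <= lo:
        return np.array([], dtype=int)
    seg = np.abs(w[lo:hi])
    pk, _ = signal.find_peaks(seg, height=thr)
    return pk + lo


def _walk_below(w: np.ndarray, start: int, frac: float, direction: int,
                limit: int) -> int:
    """First sample from ``start`` (exclusive) where |w| < frac*|w[start]|."""
    target = frac * abs(w[start])
    i = start
    while 0 < i < w.size - 1 and abs(i - start) < limit:
        i += direction
        if abs(w[i]) < target:
            return i
    return i


def delineate(ecg: EcgRecord, r_peaks: np.ndarray) -> BeatFiducials:
    """Per-beat P/QRS/T landmarks via wavelet modulus maxima.

    Beats whose fiducials come out in unphysiological order are dropped (and
    counted in a log message); beats where no T wave clears the threshold
    carry absent T fields.
    """
    r_peaks = np.asarray(r_peaks, dtype=int)
    if r_peaks.size == 0:
        raise ValueError("r_peaks must be nonempty")
    fs = ecg.fs
    ms = fs / 1000.0
    w = _quadratic_spline_wt(ecg.samples, levels=5)
    w_qrs = w[3]   # scale 2^4: fine structure, QRS slopes
    w_t = w[4]     # scale 2^5: smooth structure, T/P slopes
    x = ecg.samples

    rows, dropped = [], 0
    for j, r in enumerate(r_peaks):
        lo = r - int(90 * ms)
        hi = r + int(90 * ms)
        if lo < 0 or hi >= x.size:
            continue
        # main modulus-maxima pair around the R wave
        pre_seg = np.abs(w_qrs[lo:r])
        post_seg = np.abs(w_qrs[r:hi])
        if pre_seg.size == 0 or post_seg.size == 0:
            continue
        n_pre = lo + int(np.argmax(pre_seg))
        n_post = r + int(np.argmax(post_seg))
        pair_amp = min(abs(w_qrs[n_pre]), abs(w_qrs[n_post]))
        if pair_amp == 0:
            continue

        # QRS onset: the first modulus maximum before the R pair marks the
        # leading wave of the complex (Q); at this fine scale its location
        # sits on the complex boundary.  Without one, walk down from the pair.
        mm_left = _modulus_maxima(w_qrs, n_pre - int(70 * ms), n_pre,
                                  0.06 * pair_amp)
        if mm_left.size:
            qrs_on = int(mm_left[0])
        else:
            qrs_on = _walk_below(w_qrs, n_pre, 0.25, -1, int(80 * ms))
        # QRS offset: symmetric rule on the trailing (S) wave
        mm_right = _modulus_maxima(w_qrs, n_post + 1, n_post + int(70 * ms),
                                   0.06 * pair_amp)
        if mm_right.size:
            qrs_off = int(mm_right[-1])
        else:
            qrs_off = _walk_below(w_qrs, n_post, 0.25, +1, int(80 * ms))

        # T wave: dominant modulus-maxima pair at the coarse scale in a
        # window after the QRS, bounded by the next beat
        next_r = r_peaks[j + 1] if j + 1 < r_peaks.size else x.size
        t_lo = qrs_off + int(60 * ms)
        t_hi = min(r + int(600 * ms), next_r - int(150 * ms))
        t_peak, t_off = None, None
        if t_hi - t_lo > int(80 * ms):
            seg = np.abs(w_t[t_lo:t_hi])
            thr_t = max(0.10 * np.max(np.abs(w_t[lo:hi])), 1e-12)
            mm = _modulus_maxima(w_t, t_lo, t_hi, thr_t)
            if mm.size >= 2:
                # dominant *adjacent* opposite-signed pair: the two slopes of
                # one wave; scored by the smaller member so both must be real
                best, score = None, 0.0
                for a, b in zip(mm[:-1], mm[1:]):
                    if np.sign(w_t[a]) == np.sign(w_t[b]):
                        continue
                    s = min(abs(w_t[a]), abs(w_t[b]))
                    if s > score:
                        best, score = (int(a), int(b)), s
                if best is not None:
                    first, last = best
                    # T peak: zero crossing of w between the pair
                    zc = first + np.where(
                        np.diff(np.sign(w_t[first:last + 1])) != 0
                    )[0]
                    t_peak = int(zc[0]) + 1 if zc.size else (first + last) // 2
                    # T offset: threshold crossing after the last maximum
                    t_off = _walk_below(w_t, last, 0.30, +1, int(160 * ms))

        # gap handling: drop beats whose search windows touch missing data
        if ecg.gap_mask.any():
            wlo = min(lo, qrs_on)
            whi = max(hi, t_off or hi)
            if ecg.gap_mask[max(wlo, 0):min(whi + 1, x.size)].any():
                continue

        # P wave: modulus-maxima pair at the coarse scale before QRS onset
        p_on = p_peak = p_off = None
        p_lo, p_hi = qrs_on - int(220 * ms), qrs_on - int(20 * ms)
        if p_lo > 0:
            thr_p = max(0.05 * np.max(np.abs(w_t[lo:hi])), 1e-12)
            mm = _modulus_maxima(w_t, p_lo, p_hi, thr_p)
            if mm.size >= 2:
                m1, m2 = mm[0], mm[-1]
                if np.sign(w_t[m1]) != np.sign(w_t[m2]):
                    zc = m1 + np.where(
                        np.diff(np.sign(w_t[m1:m2 + 1])) != 0
                    )[0]
                    if zc.size:
                        p_peak = int(zc[0]) + 1
                        p_on = _walk_below(w_t, m1, 0.45, -1, int(80 * ms))
                        p_off = _walk_below(w_t, m2, 0.45, +1, int(80 * ms))

        row = {
            "p_onset": p_on, "p_peak": p_peak, "p_offset": p_off,
            "qrs_onset": qrs_on, "r_peak": int(r), "qrs_offset": qrs_off,
            "t_peak": t_peak, "t_offset": t_off,
        }
        vals = [v for v in row.values() if v is not None]
        if not np.all(np.diff(vals) > 0):
            dropped += 1
            continue
        rows.append({k: (pd.NA if v is None else int(v))
                     for k, v in row.items()})
    if dropped:
        logger.info("delineate: dropped %d beats with unphysiological order",
                    dropped)
    return BeatFiducials(pd.DataFrame(rows, columns=list(
        ("p_onset", "p_peak", "p_offset", "qrs_onset", "r_peak",
         "qrs_offset", "t_peak", "t_offset"))))


def qt_from_fiducials(fid: BeatFiducials, fs: float) -> np.ndarray:
    """Per-beat QT in ms (qrs_onset -> t_offset); NaN where T is absent."""
    on = fid.table["qrs_onset"].to_numpy(dtype=float, na_value=np.nan)
    off = fid.table["t_offset"].to_numpy(dtype=float, na_value=np.nan)
    return (off - on) / fs * 1000.0


def binarize_events(trace: np.ndarray, fs: float,
                    min_duration_s: float = 60.0) -> EventIntervals:
    """Rectify and binarize the treatment marker at half its maximum.

    Contiguous supra-threshold runs become (onset, offset) intervals; runs
    shorter than ``min_duration_s`` are discarded.
    """
    trace = np.abs(np.asarray(trace, dtype=float))
    if trace.size == 0 or trace.max() <= 0:
        return EventIntervals([], fs=fs)
    above = trace >= trace.max() / 2.0
    edges = np.diff(above.astype(int))
    onsets = list(np.where(edges == 1)[0] + 1)
    offsets = list(np.where(edges == -1)[0] + 1)
    if above[0]:
        onsets.insert(0, 0)
    if above[-1]:
        offsets.append(trace.size)
    intervals = [
        (a, b) for a, b in zip(onsets, offsets)
        if (b - a) / fs >= min_duration_s
    ]
    return EventIntervals(intervals, fs=fs)
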