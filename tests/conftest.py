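"""Shared fixtures: synthetic signals with known ground truth."""
import numpy as np
import pytest

from cardiovagal.processing import delineate, detect_r_peaks, preprocess
from cardiovagal.synth import (RrGenParams, bazett_constant_qt,
                               generate_rr_series, synthesize_ecg)

FS = 500.0


@pytest.fixture(scope="session")
def clean_rr_series():
    """10 minutes of anomaly-free RR intervals with known targets."""
    params = RrGenParams(mean_rr=800.0, sdnn_target=50.0, rmssd_target=30.0,
                         seed=11)
    return generate_rr_series(params, 600.0)


@pytest.fixture(scope="session")
def clean_ecg_600s():
    """600 s clean synthetic ECG at 500 Hz with Bazett-constant QTc 400 ms."""
    params = RrGenParams(mean_rr=800.0, sdnn_target=40.0, rmssd_target=25.0,
                         seed=21)
    rr, _ = generate_rr_series(params, 600.0)
    ecg, truth = synthesize_ecg(rr, qt_model=bazett_constant_qt(400.0), fs=FS)
    return ecg, truth


@pytest.fixture(scope="session")
def delineated_clean(clean_ecg_600s):
    """Preprocessed record, detected R peaks and fiducials for the clean ECG."""
    ecg, truth = clean_ecg_600s
    filtered = preprocess(ecg)
    peaks = detect_r_peaks(filtered)
    fiducials = delineate(filtered, peaks)
    return filtered, peaks, fiducials, truth


def match_r_peaks(detected, true_r, fs=FS, tol_s=0.05):
    """Greedy one-to-one matching of detected to true R peaks within +-tol.

    Returns (sensitivity, precision, mean absolute error in ms).
    """
    detected = np.asarray(detected)
    true_r = np.asarray(true_r)
    tol = int(tol_s * fs)
    used, errs = set(), []
    for p in detected:
        d = np.abs(true_r - p)
        i = int(np.argmin(d))
        if d[i] <= tol and i not in used:
            used.add(i)
            errs.append((p - true_r[i]) / fs * 1000.0)
    sens = len(used) / true_r.size
    prec = len(used) / max(detected.size, 1)
    mae = float(np.mean(np.abs(errs))) if errs else np.nan
    return sens, prec, mae
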