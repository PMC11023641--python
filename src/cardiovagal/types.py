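"""Core containers shared across the pipeline.

Conventions: ECG sample indices are 0-based; beat times are seconds from the
start of the record; RR intervals are milliseconds; QT/QTc are milliseconds.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

# RR interval flag codes
VALID = 0
OUTLIER = 1
ECTOPIC = 2

FLAG_NAMES = {VALID: "valid", OUTLIER: "outlier", ECTOPIC: "ectopic"}

#: the seven autonomic variables entering the factor analysis
FACTOR_VARIABLES = (
    "rmssd",
    "sdnn",
    "pnni50",
    "total_power",
    "nhf_power",
    "cvi",
    "csi",
)


@dataclass
class EcgRecord:
    """A single-channel ECG trace.

    Parameters
    ----------
    samples : voltage in mV.
    fs : sampling rate in Hz.
    t0 : absolute start time in seconds (trial clock).
    subject : subject identifier.
    day : 1-based recording-day index.
    gap_mask : boolean array, True where the sample is missing (monitor
        restart); same length as ``samples``.
    """

    samples: np.ndarray
    fs: float
    t0: float = 0.0
    subject: str = ""
    day: int = 1
    gap_mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.gap_mask is None:
            self.gap_mask = np.zeros(self.samples.size, dtype=bool)
        else:
            self.gap_mask = np.asarray(self.gap_mask, dtype=bool)
            if self.gap_mask.size != self.samples.size:
                raise ValueError("gap mask must match sample count")

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs

    def with_samples(self, samples: np.ndarray) -> "EcgRecord":
        return replace(self, samples=np.asarray(samples, dtype=float))


# order in which fiducials must appear within one beat
FIDUCIAL_ORDER = (
    "p_onset",
    "p_peak",
    "p_offset",
    "qrs_onset",
    "r_peak",
    "qrs_offset",
    "t_peak",
    "t_offset",
)


@dataclass
class BeatFiducials:
    """Per-beat wave landmarks as sample indices.

    Stored as a DataFrame with one row per beat and one (nullable integer)
    column per fiducial.  ``r_peak`` is always present; any other landmark may
    be absent (pd.NA) when delineation could not locate it.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in FIDUCIAL_ORDER if c not in self.table.columns]
        for c in missing:
            self.table[c] = pd.array([pd.NA] * len(self.table), dtype="Int64")
        self.table = self.table[list(FIDUCIAL_ORDER)].astype("Int64")
        if self.table["r_peak"].isna().any():
            raise ValueError("r_peak must be present for every beat")

    def __len__(self) -> int:
        return len(self.table)

    def check_ordering(self) -> bool:
        """True iff present fiducials strictly increase within every beat."""
        vals = self.table.to_numpy(dtype=float, na_value=np.nan)
        for row in vals:
            present = row[~np.isnan(row)]
            if present.size > 1 and not np.all(np.diff(present) > 0):
                return False
        return True


@dataclass
class EventIntervals:
    """Treatment-session intervals recovered from the analog marker trace."""

    intervals: list  # of (onset_sample, offset_sample)
    fs: float
    source: str = ""

    def __post_init__(self) -> None:
        iv = sorted(tuple(map(int, p)) for p in self.intervals)
        for a, b in iv:
            if a >= b:
                raise ValueError("interval onset must precede offset")
        for (a0, b0), (a1, b1) in zip(iv, iv[1:]):
            if a1 < b0:
                raise ValueError("intervals must be disjoint")
        self.intervals = iv

    def __len__(self) -> int:
        return len(self.intervals)

    def to_seconds(self) -> list:
        return [(a / self.fs, b / self.fs) for a, b in self.intervals]


@dataclass
class RrSeries:
    """Timestamped RR intervals with validity flags.

    ``times[i]`` is the time (s) of the beat that *ends* interval ``rr[i]``
    (ms).  Flags are exhaustive and exclusive: valid / outlier / ectopic.
    """

    times: np.ndarray
    rr: np.ndarray
    flags: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.rr = np.asarray(self.rr, dtype=float)
        if self.times.size != self.rr.size:
            raise ValueError("times and rr must have equal length")
        if np.any(self.rr <= 0):
            raise ValueError("RR intervals must be positive")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("beat times must be strictly increasing")
        if self.flags is None:
            self.flags = np.full(self.rr.size, VALID, dtype=np.int8)
        else:
            self.flags = np.asarray(self.flags, dtype=np.int8)
            if self.flags.size != self.rr.size:
                raise ValueError("flags must match rr length")

    def __len__(self) -> int:
        return self.rr.size

    @property
    def valid_mask(self) -> np.ndarray:
        return self.flags == VALID

    @property
    def valid_rr(self) -> np.ndarray:
        return self.rr[self.valid_mask]

    def restrict(self, t_start: float, t_stop: float) -> "RrSeries":
        """Sub-series of intervals whose end-beat falls in [t_start, t_stop)."""
        m = (self.times >= t_start) & (self.times < t_stop)
        return RrSeries(self.times[m], self.rr[m], self.flags[m])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.times,
                "rr_ms": self.rr,
                "flag": [FLAG_NAMES[f] for f in self.flags],
            }
        )


@dataclass
class HrvMetrics:
    """One window's worth of cardiac metrics; absent values are NaN."""

    hr: float = np.nan                 # bpm
    rmssd: float = np.nan              # ms
    sdnn: float = np.nan               # ms
    pnni50: float = np.nan             # %
    total_power: float = np.nan        # ms^2
    nhf_power: float = np.nan          # fraction in [0, 1]
    cvi: float = np.nan
    csi: float = np.nan
    qtc_mean: float = np.nan           # ms
    qtc_median: float = np.nan         # ms
    prolonged_qtc_pct: float = np.nan  # %

    def as_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class FactorModel:
    """Fitted two-factor model of the autonomic variable set."""

    variables: list
    loadings: np.ndarray        # (n_vars, n_factors), rotated
    communalities: np.ndarray   # (n_vars,)
    uniquenesses: np.ndarray    # (n_vars,)
    rotation: str
    scores: Optional[np.ndarray] = None   # (n_obs, n_factors)
    labels: dict = field(default_factory=dict)
    n_iter: int = 0

    @property
    def n_factors(self) -> int:
        return self.loadings.shape[1]

    def loadings_frame(self) -> pd.DataFrame:
        cols = [self.labels.get(j, f"factor{j + 1}") for j in range(self.n_factors)]
        return pd.DataFrame(self.loadings, index=self.variables, columns=cols)
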