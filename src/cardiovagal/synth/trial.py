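"""Synthetic two-arm ICU trial: subjects, daily metric truth, sessions, signals.

The generator has two tiers sharing one root seed:

* **Metric tier** (cheap, always produced): per-subject metadata, treatment
  sessions, and true daily values of every cardiovascular metric.  Arm
  effects are standardized (Cohen's d units) and applied to the
  *change-from-day-1* of each metric: for days >= 2 the change is drawn as
  ``N(mu_arm, sd_m)`` with ``mu_taVNS - mu_sham = d_m * sd_m``, so the
  realized between-arm effect size over subject-days matches the requested
  ``arm_effects`` in expectation.

* **Signal tier** (expensive, rendered on demand): 500 Hz ECG around each
  treatment session (pre/during/post block), 1 Hz vitals as AR(1) processes
  around the arm-specific daily means, and the analog treatment-marker
  trace.  Rendering a full multi-day 500 Hz trial is deliberately avoided;
  signals exist to exercise the delineation and event-locking stages, and
  the block length around sessions is configurable.

All randomness flows from ``spec.seed`` through ``numpy.random.SeedSequence``
spawns keyed by subject and day, so a fixed seed gives a bit-identical trial.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import signal as sps

from .ecg import GroundTruth, bazett_constant_qt, synthesize_ecg
from .rr import RrGenParams, generate_rr_series

#: default arm effects (Cohen's d on change-from-day-1, taVNS minus Sham)
DEFAULT_ARM_EFFECTS = {
    "hr": -0.01,
    "rmssd": 0.42,
    "sdnn": 0.10,
    "qtc_mean": -0.57,
    "ppi": -0.49,
    "resp": 0.37,
}

#: (baseline mean, baseline SD, daily change SD) per metric
_METRIC_MODEL = {
    "hr": (76.0, 8.0, 8.0),
    "rmssd": (28.0, 8.0, 10.0),
    "sdnn": (48.0, 10.0, 12.0),
    "pnni50": (8.0, 4.0, 5.0),
    "total_power": (2400.0, 700.0, 800.0),
    "nhf_power": (0.35, 0.08, 0.10),
    "cvi": (3.6, 0.3, 0.35),
    "csi": (2.6, 0.7, 0.8),
    "qtc_mean": (430.0, 20.0, 15.0),
    "bp": (85.0, 8.0, 6.0),
    "icp": (12.0, 3.0, 2.0),
    "ppi": (2.5, 0.8, 0.6),
    "resp": (18.0, 2.5, 2.5),
}

_VITALS = ("bp", "icp", "ppi", "resp")

#: latent two-factor loading structure of the daily HRV-metric changes:
#: factor 1 = overall variability, factor 2 = parasympathetic tone.  Shared
#: latent variation makes the seven variables genuinely correlated, which is
#: what the downstream factor analysis is built to recover.
_FACTOR_LOADINGS = {
    "rmssd": (0.60, 0.50),
    "sdnn": (0.85, 0.00),
    "pnni50": (0.80, 0.00),
    "total_power": (0.75, 0.00),
    "nhf_power": (0.00, 0.80),
    "cvi": (0.40, 0.30),
    "csi": (0.00, -0.75),
}

#: acute-response model for per-session heart-rate deltas (post minus pre,
#: normalized units): intercept, arm shift, mRS-change slope, arm x mRS
#: interaction, subject random-intercept SD, residual SD
DEFAULT_ACUTE_MODEL = {
    "beta0": 0.73,
    "beta_tavns": -0.29,
    "beta_mrs": 1.47,
    "beta_interaction": -1.85,
    "subject_sd": 1.0,
    "residual_sd": 2.0,
}


@dataclass
class SynthTrialSpec:
    """Configuration of one synthetic trial; defaults mirror the study design
    (two arms of 11 and 13, ~11 recording days, two 20-minute sessions/day,
    500 Hz ECG, 1 Hz vitals)."""

    n_tavns: int = 11
    n_sham: int = 13
    days_mean: float = 11.1
    days_sd: float = 6.8
    sessions_per_day: int = 2
    session_minutes: float = 20.0
    fs_ecg: float = 500.0
    fs_vitals: float = 1.0
    arm_effects: dict = field(default_factory=lambda: dict(DEFAULT_ARM_EFFECTS))
    acute_hr_shift: float = 0.02   # fractional post-onset HR rise, taVNS only
    gap_fraction: float = 0.03     # fraction of each ECG block masked as missing
    ectopic_rate: float = 0.0
    outlier_rate: float = 0.0
    acute_model: dict = field(default_factory=lambda: dict(DEFAULT_ACUTE_MODEL))
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_tavns, self.n_sham, self.sessions_per_day) <= 0:
            raise ValueError("counts must be positive")
        if self.fs_ecg < 250:
            raise ValueError("fs_ecg must be >= 250 Hz")
        if self.days_mean <= 0 or self.session_minutes <= 0:
            raise ValueError("days_mean and session_minutes must be positive")
        if not 0 <= self.gap_fraction < 1:
            raise ValueError("gap_fraction must be in [0, 1)")


@dataclass
class TrialData:
    """Generated trial: metadata + daily truth + sessions, with lazy signals."""

    spec: SynthTrialSpec
    subjects: pd.DataFrame       # subject, arm, age_decade, mrs_admission/discharge
    daily_truth: pd.DataFrame    # subject, arm, day, <metric>, <metric>_change
    sessions: pd.DataFrame       # subject, day, session, onset_s, offset_s (day clock)

    def render_session_block(self, subject: str, day: int, session: int):
        """Synthesize the ECG / vitals / event-trace block around one session.

        The block spans pre (one session length), during, and post (one
        session length) plus a 2-minute margin on each side.  Returns a dict
        with ``ecg`` (EcgRecord), ``truth`` (GroundTruth), ``vitals``
        (DataFrame at fs_vitals), ``event_trace`` (ndarray at fs_vitals) and
        ``block_start_s`` (day-clock time of the first sample).
        """
        spec = self.spec
        row = self.sessions[
            (self.sessions.subject == subject)
            & (self.sessions.day == day)
            & (self.sessions.session == session)
        ]
        if row.empty:
            raise KeyError(f"no session {session} for {subject} day {day}")
        onset_s = float(row.onset_s.iloc[0])
        offset_s = float(row.offset_s.iloc[0])
        truth_row = self.daily_truth[
            (self.daily_truth.subject == subject) & (self.daily_truth.day == day)
        ].iloc[0]
        arm = truth_row["arm"]

        margin = 120.0
        sess_len = spec.session_minutes * 60.0
        block_start = onset_s - sess_len - margin
        block_len = 3 * sess_len + 2 * margin

        ss = np.random.SeedSequence(
            [spec.seed, _subject_index(subject), day, session, 7]
        )
        child = ss.generate_state(4)
        rr_params = RrGenParams(
            mean_rr=60000.0 / truth_row["hr"],
            sdnn_target=max(truth_row["sdnn"], 5.0),
            rmssd_target=min(
                max(truth_row["rmssd"], 3.0), 1.9 * max(truth_row["sdnn"], 5.0)
            ),
            ectopic_rate=spec.ectopic_rate,
            outlier_rate=spec.outlier_rate,
            seed=int(child[0] % (2**31)),
        )
        rr, _ = generate_rr_series(rr_params, block_len)
        rr = dataclasses.replace(rr, times=rr.times + block_start)
        if arm == "taVNS" and spec.acute_hr_shift > 0:
            post = (rr.times >= offset_s) & (rr.times < offset_s + sess_len)
            rr.rr[post] /= 1.0 + spec.acute_hr_shift

        qt_model = bazett_constant_qt(truth_row["qtc_mean"])
        ecg, truth = synthesize_ecg(
            rr, qt_model=qt_model, fs=spec.fs_ecg, noise_sd=0.02,
            seed=int(child[1] % (2**31)),
        )
        ecg = dataclasses.replace(ecg, subject=subject, day=day)
        if spec.gap_fraction > 0:
            rng = np.random.default_rng(child[2])
            gap_len = int(spec.gap_fraction * ecg.samples.size)
            if gap_len > 0:
                start = rng.integers(0, ecg.samples.size - gap_len)
                ecg.gap_mask[start:start + gap_len] = True
                ecg.samples[start:start + gap_len] = 0.0

        n_v = int(block_len * spec.fs_vitals)
        t_v = block_start + np.arange(n_v) / spec.fs_vitals
        rng_v = np.random.default_rng(child[3])
        vit = {"time_s": t_v}
        for name in _VITALS:
            vit[name] = _ar1(truth_row[name], _METRIC_MODEL[name][1] * 0.3, n_v, rng_v)
        event = np.zeros(n_v)
        on_i = int(round((onset_s - block_start) * spec.fs_vitals))
        off_i = int(round((offset_s - block_start) * spec.fs_vitals))
        event[on_i:off_i] = 1.0
        event += rng_v.uniform(0.0, 0.2, n_v)  # noise below half-maximum
        truth.session_intervals = [(on_i, off_i)]
        return {
            "ecg": ecg,
            "truth": truth,
            "vitals": pd.DataFrame(vit),
            "event_trace": event,
            "block_start_s": block_start,
            "onset_s": onset_s,
            "offset_s": offset_s,
        }

    def write(self, out_dir) -> None:
        """Write the metric tier as plain CSV (deterministic byte content)."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        kw = dict(index=False, float_format="%.6f", lineterminator="\n")
        self.subjects.to_csv(out / "subjects.csv", **kw)
        self.daily_truth.to_csv(out / "daily_truth.csv", **kw)
        self.sessions.to_csv(out / "sessions.csv", **kw)


def _subject_index(subject: str) -> int:
    return int(subject.split("-")[-1])


def _ar1(mean: float, sd: float, n: int, rng, phi: float = 0.98) -> np.ndarray:
    eps = rng.normal(0.0, sd * np.sqrt(1 - phi**2), n)
    x = sps.lfilter([1.0], [1.0, -phi], eps)
    return mean + x


def generate_trial(spec: SynthTrialSpec, out_dir: Optional[str] = None) -> TrialData:
    """Generate the metric tier of a synthetic trial (signals render lazily).

    Reproducible for a fixed ``spec.seed``; see ``TrialData`` for layout.
    """
    root = np.random.default_rng(np.random.SeedSequence([spec.seed, 11]))
    n_total = spec.n_tavns + spec.n_sham
    arms = np.array(["taVNS"] * spec.n_tavns + ["Sham"] * spec.n_sham)
    root.shuffle(arms)

    subj_rows, daily_rows, sess_rows = [], [], []
    for idx in range(n_total):
        subject = f"S-{idx:02d}"
        arm = arms[idx]
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 13, idx]))
        n_days = int(np.clip(round(rng.normal(spec.days_mean, spec.days_sd)), 2, 13))
        age_decade = int(rng.choice([30, 40, 50, 60, 70, 80],
                                    p=[0.05, 0.15, 0.2, 0.3, 0.2, 0.1]))
        mrs_adm = int(rng.integers(1, 6))
        shift = -1.0 if arm == "taVNS" else -0.4
        mrs_dis = int(np.clip(mrs_adm + round(rng.normal(shift, 1.2)), 0, 6))
        subj_rows.append(
            dict(subject=subject, arm=arm, age_decade=age_decade,
                 mrs_admission=mrs_adm, mrs_discharge=mrs_dis, n_days=n_days)
        )

        u_subj = rng.normal(0.0, spec.acute_model["subject_sd"])
        base = {
            m: rng.normal(mu, sd) for m, (mu, sd, _) in _METRIC_MODEL.items()
        }
        base["nhf_power"] = float(np.clip(base["nhf_power"], 0.05, 0.9))
        base["rmssd"] = max(base["rmssd"], 8.0)
        base["sdnn"] = max(base["sdnn"], max(15.0, base["rmssd"] / 1.9))
        base["ppi"] = max(base["ppi"], 0.3)
        for day in range(1, n_days + 1):
            row = dict(subject=subject, arm=arm, day=day)
            # standardized daily deviation: latent two-factor structure for
            # the HRV variable set, independent noise for the rest
            f = rng.normal(size=2)
            for m, (_, _, chg_sd) in _METRIC_MODEL.items():
                if day == 1:
                    change = 0.0
                else:
                    d_eff = spec.arm_effects.get(m, 0.0) if arm == "taVNS" else 0.0
                    if m in _FACTOR_LOADINGS:
                        l1, l2 = _FACTOR_LOADINGS[m]
                        uniq = np.sqrt(max(1.0 - l1**2 - l2**2, 0.02))
                        z = l1 * f[0] + l2 * f[1] + uniq * rng.normal()
                    else:
                        z = rng.normal()
                    change = chg_sd * (d_eff + z)
                value = base[m] + change
                if m == "nhf_power":
                    value = float(np.clip(value, 0.01, 0.99))
                elif m in ("rmssd", "sdnn", "pnni50", "total_power", "ppi",
                           "csi", "icp"):
                    value = max(value, 0.05 * abs(base[m]) + 1e-3)
                row[m] = value
                row[f"{m}_change"] = value - base[m] if day > 1 else 0.0
            row["rmssd"] = min(row["rmssd"], 1.9 * row["sdnn"])
            daily_rows.append(row)

            for k in range(spec.sessions_per_day):
                # nominal 09:00 / 17:00 day-clock times with +-30 min jitter
                nominal = (9.0 + 8.0 * k) * 3600.0
                onset = nominal + rng.uniform(-1800.0, 1800.0)
                am = spec.acute_model
                treat = 1.0 if arm == "taVNS" else 0.0
                mrs_change = mrs_dis - mrs_adm
                hr_delta = (
                    am["beta0"] + am["beta_tavns"] * treat
                    + am["beta_mrs"] * mrs_change
                    + am["beta_interaction"] * treat * mrs_change
                    + u_subj + rng.normal(0.0, am["residual_sd"])
                )
                sess_rows.append(
                    dict(subject=subject, day=day, session=k,
                         onset_s=onset,
                         offset_s=onset + spec.session_minutes * 60.0,
                         mrs_change=mrs_change, hr_delta=hr_delta)
                )

    trial = TrialData(
        spec=spec,
        subjects=pd.DataFrame(subj_rows),
        daily_truth=pd.DataFrame(daily_rows),
        sessions=pd.DataFrame(sess_rows),
    )
    if out_dir is not None:
        trial.write(out_dir)
    return trial
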