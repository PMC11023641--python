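"""End-to-end orchestration: simulate -> process -> aggregate -> factors -> stats.

``run`` executes the full analysis on a synthetic trial and returns a result
bundle mirroring the study's reporting surfaces: daily/binned group
comparisons, the factor model, event-locked session summaries, equivalence
and power reports, the RMSSD-decay interaction regression, the acute
heart-rate mixed model, age-adjusted comparisons, and a delineation quality
check against the generator's ground truth.  Every number in the bundle is
deterministic given the root seed.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import stats as st
from .aggregate import bin_days, daily_reference, event_locked, sliding_windows
from .factors import fit_factors
from .metrics import clean_rr
from .processing import (binarize_events, delineate, detect_r_peaks,
                         preprocess, qt_from_fiducials)
from .synth import SynthTrialSpec, generate_trial
from .types import FACTOR_VARIABLES, RrSeries

logger = logging.getLogger(__name__)

CARDIAC_FAMILY = ("hr", "qtc_mean", "rmssd", "sdnn")  # + the two factors = 6
VITALS_FAMILY = ("bp", "icp", "ppi", "resp")


@dataclass
class RunConfig:
    """All tunables of one pipeline run; defaults are the trial's values."""

    spec: SynthTrialSpec = field(default_factory=SynthTrialSpec)
    alpha: float = 0.05
    cardiac_bonferroni: int = 6
    vitals_bonferroni: int = 4
    margins: dict = field(default_factory=lambda: dict(st.EQUIV_MARGINS))
    n_render_blocks: int = 2   # session blocks pushed through the signal path
    out_dir: Optional[str] = None


def _zscore_by_subject(df: pd.DataFrame, cols) -> pd.DataFrame:
    out = df.copy()
    g = out.groupby("subject")
    for c in cols:
        mu, sd = g[c].transform("mean"), g[c].transform("std")
        out[c] = ((out[c] - mu) / sd).where(sd > 0)
    return out


def run(config: RunConfig) -> dict:
    """Execute all stages; on a stage failure later stages are skipped and
    the bundle records which stage failed."""
    t_start = time.time()
    bundle: dict = {"config": dataclasses.asdict(config), "failed_stage": None,
                    "log": []}

    def note(msg):
        bundle["log"].append(f"[{time.time() - t_start:8.1f}s] {msg}")
        logger.info(msg)

    stages = [
        ("simulate", _stage_simulate),
        ("daily_groups", _stage_daily_groups),
        ("factors", _stage_factors),
        ("equivalence_power", _stage_equivalence_power),
        ("interaction_mixed", _stage_models),
        ("signal_qa", _stage_signal_qa),
    ]
    state: dict = {"config": config}
    for name, fn in stages:
        try:
            note(f"stage {name} start")
            fn(state, bundle)
            note(f"stage {name} done")
        except Exception as exc:  # pragma: no cover - defensive
            logger.exception("stage %s failed", name)
            bundle["failed_stage"] = name
            bundle["log"].append(f"stage {name} FAILED: {exc}")
            break
    if config.out_dir:
        write_bundle(bundle, config.out_dir)
    return bundle


def _stage_simulate(state, bundle):
    config = state["config"]
    trial = generate_trial(config.spec)
    state["trial"] = trial
    daily = trial.daily_truth.copy()
    state["daily"] = daily
    bundle["n_subjects"] = len(trial.subjects)
    bundle["n_subject_days"] = int((daily.day >= 2).sum())


def _stage_daily_groups(state, bundle):
    config, daily = state["config"], state["daily"]
    post = daily[daily.day >= 2]
    rows = []
    for fam, metrics, bonf in (
        ("cardiac", CARDIAC_FAMILY, config.cardiac_bonferroni),
        ("vitals", VITALS_FAMILY, config.vitals_bonferroni),
    ):
        for m in metrics:
            a = post.loc[post.arm == "taVNS", f"{m}_change"].dropna()
            b = post.loc[post.arm == "Sham", f"{m}_change"].dropna()
            r = st.compare_groups(a, b, config.alpha, bonferroni_factor=bonf)
            rows.append(dict(family=fam, metric=m, test=r.test, n_tavns=r.n1,
                             n_sham=r.n2, statistic=r.statistic, p=r.p,
                             p_corrected=r.p_corrected, cohens_d=r.cohens_d,
                             power=r.power))
    bundle["daily_comparisons"] = pd.DataFrame(rows)

    binned = bin_days(post)
    brows = []
    for (label, m), grp in (
        (key, g) for key in
        [(lbl, mm) for lbl in binned.day_bin.unique()
         for mm in CARDIAC_FAMILY]
        for g in [binned[binned.day_bin == key[0]]]
    ):
        a = grp.loc[grp.arm == "taVNS", f"{m}_change"].dropna()
        b = grp.loc[grp.arm == "Sham", f"{m}_change"].dropna()
        if len(a) >= 3 and len(b) >= 3:
            brows.append(dict(day_bin=label, metric=m,
                              cohens_d=st.cohens_d(a, b),
                              n_tavns=len(a), n_sham=len(b)))
    bundle["binned_effects"] = pd.DataFrame(brows)


def _stage_factors(state, bundle):
    config, daily = state["config"], state["daily"]
    z = _zscore_by_subject(daily, [c for c in FACTOR_VARIABLES])
    model = fit_factors(z)
    state["factor_model"] = model
    bundle["factor_loadings"] = model.loadings_frame()
    bundle["factor_labels"] = dict(model.labels)

    fit_rows = z[list(model.variables)].dropna()
    scored = daily.loc[fit_rows.index, ["subject", "arm", "day"]].copy()
    for j in range(model.n_factors):
        scored[model.labels.get(j, f"factor{j+1}")] = model.scores[:, j]
    # factor change from each subject's Day-1 score
    rows = []
    for j in range(model.n_factors):
        name = model.labels.get(j, f"factor{j+1}")
        day1 = scored[scored.day == 1].set_index("subject")[name]
        change = scored[name] - scored.subject.map(day1)
        post = scored.day >= 2
        a = change[post & (scored.arm == "taVNS")].dropna()
        b = change[post & (scored.arm == "Sham")].dropna()
        r = st.compare_groups(a, b, config.alpha,
                              bonferroni_factor=config.cardiac_bonferroni)
        rows.append(dict(factor=name, test=r.test, p=r.p,
                         p_corrected=r.p_corrected, cohens_d=r.cohens_d))
    bundle["factor_comparisons"] = pd.DataFrame(rows)


def _stage_equivalence_power(state, bundle):
    config, daily = state["config"], state["daily"]
    post = daily[daily.day >= 2]
    eq = {}
    for metric, margin_key in (("hr", "hr"), ("qtc_mean", "qt"), ("bp", "bp")):
        a = post.loc[post.arm == "taVNS", f"{metric}_change"].dropna()
        b = post.loc[post.arm == "Sham", f"{metric}_change"].dropna()
        r = st.tost_equivalence(a, b, config.margins[margin_key], config.alpha)
        eq[metric] = dict(margin=r.margin, t_lower=r.t_lower, p_lower=r.p_lower,
                          t_upper=r.t_upper, p_upper=r.p_upper,
                          equivalent=r.equivalent)
    bundle["equivalence"] = eq
    n1 = int((post.arm == "taVNS").sum())
    n2 = int((post.arm == "Sham").sum())
    bundle["power_report"] = dict(
        n_tavns_days=n1, n_sham_days=n2,
        achieved_power_d05=st.power_two_sample_t(n1, n2, 0.5, config.alpha),
        required_n_per_group_80pct=st.required_n(0.80, 0.5, config.alpha),
    )


def _stage_models(state, bundle):
    config, daily, trial = state["config"], state["daily"], state["trial"]
    post = daily[daily.day >= 2]
    coef = st.interaction_regression(post, response="rmssd_change")
    bundle["interaction_regression"] = coef

    sess = trial.sessions.merge(trial.subjects[["subject", "arm"]], on="subject")
    mm = st.fit_mixed_model(sess, response="hr_delta")
    bundle["mixed_model"] = dict(
        params=mm.params.to_dict(), pvalues=mm.pvalues.to_dict(),
        random_intercept_var=mm.random_intercept_var,
        fell_back_to_ols=mm.fell_back_to_ols,
    )

    ages = trial.subjects.set_index("subject").age_decade + 5.0
    anc_rows = {}
    for m in ("rmssd", "sdnn", "qtc_mean"):
        t = post[["subject", "arm", f"{m}_change"]].copy()
        t["age"] = t.subject.map(ages)
        r = st.ancova_age(t, response=f"{m}_change")
        anc_rows[m] = dict(arm_coef=r.loc["treat", "coef"],
                           arm_p=r.loc["treat", "p"],
                           age_coef=r.loc["age", "coef"] if "age" in r.index
                           else np.nan)
    bundle["ancova_age"] = anc_rows

    corr = {}
    for arm in ("taVNS", "Sham"):
        g = post[post.arm == arm]
        r, p = st.pearson_corr(g.ppi_change, g.resp_change)
        corr[arm] = dict(r=r, p=p, n=len(g))
    bundle["ppi_resp_correlation"] = corr


def _stage_signal_qa(state, bundle):
    """Push a few session blocks through the full signal path and score the
    delineation and event-locking against generator ground truth."""
    config, trial = state["config"], state["trial"]
    blocks = []
    subjects = trial.subjects.subject.tolist()
    for i in range(config.n_render_blocks):
        subject = subjects[i % len(subjects)]
        day = 2
        blk = trial.render_session_block(subject, day, i % trial.spec.sessions_per_day)
        blocks.append((subject, blk))

    qa_rows, deltas = [], []
    for subject, blk in blocks:
        ecg = preprocess(blk["ecg"])
        peaks = detect_r_peaks(ecg)
        fid = delineate(ecg, peaks)
        truth = blk["truth"]
        true_r = truth.fiducials.table.r_peak.to_numpy(int)
        det_r = fid.table.r_peak.to_numpy(int)
        tol = int(0.05 * ecg.fs)
        used, errs = set(), []
        for p in det_r:
            d = np.abs(true_r - p)
            i = int(np.argmin(d))
            if d[i] <= tol and i not in used:
                used.add(i)
                errs.append((p - true_r[i]) / ecg.fs * 1000.0)
        merged = fid.table.merge(truth.fiducials.table, on="r_peak",
                                 suffixes=("_d", "_t"))
        qt_d = (merged.t_offset_d.astype(float)
                - merged.qrs_onset_d.astype(float)) / ecg.fs * 1000.0
        qt_t = (merged.t_offset_t.astype(float)
                - merged.qrs_onset_t.astype(float)) / ecg.fs * 1000.0
        qa_rows.append(dict(
            subject=subject,
            sensitivity=len(used) / true_r.size,
            precision=len(used) / max(det_r.size, 1),
            mean_abs_r_error_ms=float(np.mean(np.abs(errs))) if errs else np.nan,
            mean_qt_error_ms=float(np.nanmean(qt_d - qt_t)),
        ))

        ev = binarize_events(blk["event_trace"], fs=trial.spec.fs_vitals)
        if len(ev) == 0:
            continue
        onset = blk["block_start_s"] + ev.intervals[0][0] / trial.spec.fs_vitals
        offset = blk["block_start_s"] + ev.intervals[0][1] / trial.spec.fs_vitals
        r_times = fid.table.r_peak.to_numpy(float) / ecg.fs + ecg.t0
        rr = clean_rr(RrSeries(r_times[1:], np.diff(r_times) * 1000.0))
        qt = qt_from_fiducials(fid, ecg.fs)[1:]
        win = sliding_windows(rr, qt, rr.times[0], rr.times[-1])
        if len(win) < 4:
            continue
        s = event_locked(rr, qt, onset, offset, daily_reference(win))
        if "hr" in s.deltas.index:
            deltas.append(dict(subject=subject,
                               hr_during_minus_pre=s.deltas.loc["hr",
                                                                "during_minus_pre"],
                               hr_post_minus_pre=s.deltas.loc["hr",
                                                              "post_minus_pre"]))
    bundle["signal_qa"] = pd.DataFrame(qa_rows)
    bundle["session_deltas_signal"] = pd.DataFrame(deltas)


def _to_jsonable(obj):
    if isinstance(obj, pd.DataFrame):
        return json.loads(obj.to_json(orient="split"))
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.bool_):
        return bool(obj)
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    return obj


def write_bundle(bundle: dict, out_dir) -> None:
    """Persist the bundle: CSV per table, one JSON for scalars, plain log."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scalars = {}
    for key, val in bundle.items():
        if isinstance(val, pd.DataFrame):
            val.to_csv(out / f"{key}.csv", index=True,
                       float_format="%.6g", lineterminator="\n")
        elif key == "log":
            (out / "run.log").write_text("\n".join(val) + "\n")
        else:
            scalars[key] = _to_jsonable(val)
    (out / "results.json").write_text(
        json.dumps(scalars, indent=2, sort_keys=True, default=str) + "\n")
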