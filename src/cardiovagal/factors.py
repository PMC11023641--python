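"""Exploratory factor analysis of the autonomic metric set.

Seven HRV-derived variables (RMSSD, SDNN, pNNI_50, total power, normalized
HF power, CVI, CSI) are z-scored per subject-day and decomposed into two
factors: an *Overall HRV* factor loading on the variability magnitudes and a
*Parasympathetic Activity* factor loading positively on RMSSD and normalized
HF power and negatively on the cardiac sympathetic index.

Extraction is minimum-residual (minres/ULS): uniquenesses are optimized so
the rank-2 factor solution reproduces the off-diagonal correlations with the
least squared residual.  A varimax rotation follows for interpretability,
and factor scores use the regression (Thurstone) estimator.  Factor labels
are assigned by loading pattern, not position, because factor order out of
the optimizer is arbitrary.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .types import FACTOR_VARIABLES, FactorModel

logger = logging.getLogger(__name__)

OVERALL_HRV = "Overall HRV"
PARASYMPATHETIC = "Parasympathetic Activity"


def zscore_daily(table: pd.DataFrame, metric_cols=None,
                 group_cols=("subject", "day")) -> pd.DataFrame:
    """Z-score metrics within each subject-day.

    Groups with zero SD (constant metric) come out absent for that metric.
    Designed for window-level tables where each subject-day contributes many
    rows; a one-row group has no SD and is absent.
    """
    df = table.copy()
    if metric_cols is None:
        metric_cols = [c for c in df.columns if c in FACTOR_VARIABLES]
    g = df.groupby(list(group_cols))
    for c in metric_cols:
        mu = g[c].transform("mean")
        sd = g[c].transform("std")
        z = (df[c] - mu) / sd
        df[c] = z.where((sd > 0) & np.isfinite(sd))
    return df


def bartlett_sphericity(table: pd.DataFrame) -> tuple:
    """Bartlett's test that the correlation matrix is an identity.

    chi2 = -(n - 1 - (2p + 5)/6) * ln det(R) with df = p(p-1)/2.
    Returns (statistic, p_value).
    """
    x = table.dropna().to_numpy(dtype=float)
    n, p = x.shape
    if n <= p:
        raise ValueError("need more observations than variables")
    r = np.corrcoef(x, rowvar=False)
    sign, logdet = np.linalg.slogdet(r)
    if sign <= 0:
        raise ValueError("correlation matrix is singular")
    chi2 = -(n - 1 - (2 * p + 5) / 6.0) * logdet
    df = p * (p - 1) // 2
    return float(chi2), float(stats.chi2.sf(chi2, df))


def scree_eigenvalues(table: pd.DataFrame) -> np.ndarray:
    """Descending eigenvalues of the correlation matrix (sum = n variables)."""
    x = table.dropna().to_numpy(dtype=float)
    r = np.corrcoef(x, rowvar=False)
    ev = np.linalg.eigvalsh(r)[::-1]
    return ev


def _minres_loadings(r: np.ndarray, n_factors: int) -> tuple:
    """Minimum-residual extraction: optimize uniquenesses, return loadings.

    For given uniquenesses psi the best rank-k approximation of R - diag(psi)
    comes from its top-k eigenpairs; the objective is the sum of squared
    off-diagonal residuals.
    """
    p = r.shape[0]

    def loadings_for(psi):
        rr = r.copy()
        np.fill_diagonal(rr, 1.0 - psi)
        vals, vecs = linalg.eigh(rr)
        idx = np.argsort(vals)[::-1][:n_factors]
        lam = np.clip(vals[idx], 0.0, None)
        return vecs[:, idx] * np.sqrt(lam)

    mask = ~np.eye(p, dtype=bool)

    def objective(psi):
        lo = loadings_for(psi)
        resid = r - lo @ lo.T
        return float(np.sum(resid[mask] ** 2))

    # start from SMC-based uniquenesses: 1/diag(R^-1) = 1 - R^2 of each
    # variable on the others
    start = np.clip(1.0 / np.diag(np.linalg.pinv(r)), 0.05, 0.95)
    res = optimize.minimize(
        objective, start, method="L-BFGS-B",
        bounds=[(0.005, 1.0)] * p,
        options=dict(maxiter=1000, ftol=1e-12),
    )
    if not res.success and res.nit >= 1000:
        raise RuntimeError(
            f"minres did not converge after {res.nit} iterations: {res.message}"
        )
    return loadings_for(res.x), res.nit


def varimax(loadings: np.ndarray, max_iter: int = 500,
            tol: float = 1e-8) -> np.ndarray:
    """Orthogonal varimax rotation (Kaiser), SVD-based iteration."""
    lam = loadings.copy()
    p, k = lam.shape
    rot = np.eye(k)
    d_old = 0.0
    for _ in range(max_iter):
        basis = loadings @ rot
        u, s, vt = np.linalg.svd(
            loadings.T @ (basis**3 - basis @ np.diag(
                np.sum(basis**2, axis=0)) / p)
        )
        rot = u @ vt
        d = np.sum(s)
        if d_old != 0 and d / d_old < 1 + tol:
            break
        d_old = d
    return loadings @ rot


def _label_factors(loadings: np.ndarray, variables) -> dict:
    """Assign factor names from the loading pattern.

    The Overall-HRV factor has its largest loadings on the variability
    magnitudes (rmssd, sdnn, pnni50, total_power); the parasympathetic
    factor loads positively on rmssd and nhf_power and negatively on csi.
    """
    v = {name: i for i, name in enumerate(variables)}
    labels = {}
    overall_set = [v[m] for m in ("rmssd", "sdnn", "pnni50", "total_power")
                   if m in v]
    scores = []
    for j in range(loadings.shape[1]):
        col = loadings[:, j]
        # sign convention: flip so the overall/parasympathetic pattern is
        # positive (factor sign is arbitrary)
        if np.sum(col[overall_set]) < 0:
            col = -col
            loadings[:, j] = col
        scores.append(np.mean(np.abs(col[overall_set])))
    j_overall = int(np.argmax(scores))
    labels[j_overall] = OVERALL_HRV
    for j in range(loadings.shape[1]):
        if j in labels:
            continue
        col = loadings[:, j]
        para = 0.0
        if "nhf_power" in v:
            if col[v["nhf_power"]] < 0:
                col = -col
                loadings[:, j] = col
            para = col[v["nhf_power"]] + col.take(v.get("rmssd", 0))
        if para > 0 and ("csi" not in v or col[v["csi"]] < para):
            labels[j] = PARASYMPATHETIC
        else:
            labels[j] = f"factor{j + 1}"
    return labels


def fit_factors(table: pd.DataFrame, n_factors: int = 2) -> FactorModel:
    """Fit the two-factor minres + varimax model and score observations.

    Rows with any absent variable are dropped listwise.  A failed Bartlett
    sphericity gate (p >= 0.05) logs a warning but does not stop the fit.
    """
    cols = [c for c in FACTOR_VARIABLES if c in table.columns]
    data = table[cols].dropna()
    x = data.to_numpy(dtype=float)
    try:
        _, p_sphericity = bartlett_sphericity(data)
        if p_sphericity >= 0.05:
            logger.warning(
                "Bartlett sphericity not rejected (p=%.3f); variables may be "
                "uncorrelated", p_sphericity)
    except ValueError:
        pass
    r = np.corrcoef(x, rowvar=False)
    raw, n_iter = _minres_loadings(r, n_factors)
    rotated = varimax(raw)
    labels = _label_factors(rotated, cols)
    communalities = np.sum(rotated**2, axis=1)
    uniquenesses = 1.0 - communalities
    # regression (Thurstone) scores on standardized data
    z = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
    weights = np.linalg.solve(r, rotated)
    scores = z @ weights
    return FactorModel(
        variables=cols,
        loadings=rotated,
        communalities=communalities,
        uniquenesses=uniquenesses,
        rotation="varimax",
        scores=scores,
        labels=labels,
        n_iter=n_iter,
    )


def tucker_congruence(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Congruence matrix between two loading sets (columns = factors)."""
    num = a.T @ b
    den = np.sqrt(np.outer(np.sum(a**2, axis=0), np.sum(b**2, axis=0)))
    return num / den


def align_factors(est: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """Resolve sign/permutation indeterminacy: reorder and re-sign the
    estimated loading columns to best match the reference."""
    c = tucker_congruence(est, truth)
    k = est.shape[1]
    out = np.zeros_like(est)
    used = set()
    for j in range(k):
        order = np.argsort(-np.abs(c[:, j]))
        for i in order:
            if i not in used:
                used.add(i)
                out[:, j] = est[:, i] * np.sign(c[i, j])
                break
    return out
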