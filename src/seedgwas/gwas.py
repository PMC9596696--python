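"""Single-marker mixed-linear-model association scan (MLM Q+K).

The model is y = X b + g + eps with g ~ N(0, s2_g K) a polygenic random
effect over the kinship matrix K and eps ~ N(0, s2_e I).  Writing
delta = s2_e / s2_g, the covariance is s2_g (K + delta I): one spectral
decomposition K = U S U' rotates the data so the covariance is diagonal,
and restricted maximum likelihood profiles out s2_g leaving a
one-dimensional search over log delta (EMMA).  Per-marker tests are then
weighted least squares in the rotated space with a 1-df Wald F.

``p3d=True`` (population parameters previously determined) reuses the
null model's delta for every marker — the default, and the only mode that
is vectorised; ``p3d=False`` re-optimises delta per marker.

The QTN-by-environment interaction scan stacks the per-environment
phenotypes, rotates each environment block by U with a shared delta, and
F-tests the marker x environment term — a fixed-effect analogue of
multi-environment QTN models, labelled as such.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .popgen import GenotypePanel, natural_chrom_key

__all__ = [
    "MixedModelFit",
    "fit_null_mlm",
    "mlm_scan",
    "qei_scan",
    "bonferroni_threshold",
    "manhattan_qq_export",
]

_LOG_DELTA_BOUNDS = (-10.0, 10.0)


@dataclass
class MixedModelFit:
    """Null-model REML fit: spectral data, variance ratio and likelihood."""

    delta: float            # s2_e / s2_g at the REML optimum
    sigma2_g: float
    sigma2_e: float
    h2: float               # 1 / (1 + delta)
    reml_loglik: float
    eigenvalues: np.ndarray     # of K, descending
    rotation: np.ndarray        # U with K = U diag(S) U'
    y_rot: np.ndarray
    X_rot: np.ndarray           # rotated fixed covariates (incl. intercept)
    beta_null: np.ndarray


def _design(y: np.ndarray, Q: np.ndarray | None) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, float).ravel()
    n = len(y)
    X = np.ones((n, 1))
    if Q is not None:
        Q = np.atleast_2d(np.asarray(Q, float))
        if Q.shape[0] != n:
            Q = Q.T
        X = np.column_stack([X, Q])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("covariate matrix is singular")
    return y, X


def _reml_neg_loglik(log_delta: float, S: np.ndarray, ys: np.ndarray,
                     Xs: np.ndarray) -> float:
    n, p = Xs.shape
    w = S + np.exp(log_delta)
    sw = np.sqrt(w)
    Xw = Xs / sw[:, None]
    yw = ys / sw
    beta, _, _, _ = np.linalg.lstsq(Xw, yw, rcond=None)
    resid = yw - Xw @ beta
    rss = float(resid @ resid)
    sigma2 = rss / (n - p)
    _, logdet_xwx = np.linalg.slogdet(Xw.T @ Xw)
    _, logdet_xx = np.linalg.slogdet(Xs.T @ Xs)
    ll = -0.5 * ((n - p) * (np.log(2 * np.pi * sigma2) + 1)
                 + np.sum(np.log(w)) + logdet_xwx - logdet_xx)
    return -ll


def fit_null_mlm(y: np.ndarray, Q: np.ndarray | None,
                 K: np.ndarray) -> MixedModelFit:
    """REML fit of the covariates-only mixed model.

    One eigendecomposition of K, then a grid + Brent search of the REML
    profile over log delta on [-10, 10] (tolerance 1e-6).
    """
    y, X = _design(y, Q)
    K = np.asarray(K, float)
    if K.shape != (len(y), len(y)):
        raise ValueError("K must be n x n matching y")
    S, U = np.linalg.eigh((K + K.T) / 2.0)
    if S.min() < -1e-6 * max(1.0, S.max()):
        raise ValueError("K is not positive semidefinite")
    S = np.clip(S, 0.0, None)
    order = np.argsort(S)[::-1]
    S, U = S[order], U[:, order]
    ys = U.T @ y
    Xs = U.T @ X

    grid = np.linspace(*_LOG_DELTA_BOUNDS, 61)
    vals = [_reml_neg_loglik(g, S, ys, Xs) for g in grid]
    i = int(np.argmin(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        _reml_neg_loglik, bounds=(lo, hi), args=(S, ys, Xs),
        method="bounded", options={"xatol": 1e-6})
    log_delta = float(res.x)
    delta = float(np.exp(log_delta))

    n, p = Xs.shape
    w = S + delta
    Xw = Xs / np.sqrt(w)[:, None]
    yw = ys / np.sqrt(w)
    beta, _, _, _ = np.linalg.lstsq(Xw, yw, rcond=None)
    rss = float(np.sum((yw - Xw @ beta) ** 2))
    sigma2_g = rss / (n - p)
    return MixedModelFit(
        delta=delta,
        sigma2_g=sigma2_g,
        sigma2_e=sigma2_g * delta,
        h2=1.0 / (1.0 + delta),
        reml_loglik=-float(res.fun),
        eigenvalues=S,
        rotation=U,
        y_rot=ys,
        X_rot=Xs,
        beta_null=beta,
    )


def _scan_rotated(yw: np.ndarray, Xw: np.ndarray,
                  Gw: np.ndarray) -> tuple[np.ndarray, ...]:
    """Per-marker weighted LS given whitened y, covariates and markers."""
    n, p = Xw.shape
    Qx, _ = np.linalg.qr(Xw)
    my = yw - Qx @ (Qx.T @ yw)
    MG = Gw - Qx @ (Qx.T @ Gw)
    den = np.einsum("ij,ij->j", MG, MG)
    num = MG.T @ my
    ok = den > 1e-12
    beta = np.where(ok, num / np.where(ok, den, 1.0), np.nan)
    rss0 = float(my @ my)
    rss = rss0 - np.where(ok, beta**2 * den, 0.0)
    dof = n - p - 1
    se = np.sqrt(rss / dof / np.where(ok, den, np.nan))
    F = (beta / se) ** 2
    pval = stats.f.sf(F, 1, dof)
    return beta, se, F, pval, ok


def mlm_scan(y: np.ndarray, Q: np.ndarray | None, panel: GenotypePanel,
             K: np.ndarray, p3d: bool = True, alpha: float = 0.05,
             null_fit: MixedModelFit | None = None) -> pd.DataFrame:
    """Association scan of every marker against one trait.

    Returns one row per marker: effect, se, F, p, -log10 p, and a
    Bonferroni flag at ``alpha / (number of testable markers)``.
    Monomorphic markers get NaN statistics and ``tested=False``.
    """
    fit = null_fit if null_fit is not None else fit_null_mlm(y, Q, K)
    G = panel.dosages.astype(float)
    G[G < 0] = np.nan
    col_mean = np.nanmean(G, axis=0)
    G = np.where(np.isnan(G), col_mean, G)
    poly = G.std(axis=0) > 0

    m = panel.n_markers
    beta = np.full(m, np.nan)
    se = np.full(m, np.nan)
    F = np.full(m, np.nan)
    pval = np.full(m, np.nan)

    if p3d:
        w = fit.eigenvalues + fit.delta
        sw = np.sqrt(w)
        yw = fit.y_rot / sw
        Xw = fit.X_rot / sw[:, None]
        Gw = (fit.rotation.T @ G[:, poly]) / sw[:, None]
        b, s, f, p, ok = _scan_rotated(yw, Xw, Gw)
        idx = np.flatnonzero(poly)
        beta[idx], se[idx], F[idx], pval[idx] = b, s, f, p
    else:
        yv, X = _design(y, Q)
        for j in np.flatnonzero(poly):
            fit_j = fit_null_mlm(yv, np.column_stack(
                [X[:, 1:], G[:, j]]) if X.shape[1] > 1 else G[:, [j]], K)
            w = fit_j.eigenvalues + fit_j.delta
            sw = np.sqrt(w)
            yw = fit_j.y_rot / sw
            Xw = fit_j.X_rot / sw[:, None]
            # marker is the last fixed-effect column
            b, s, f, p, ok = _scan_rotated(yw, Xw[:, :-1],
                                           Xw[:, -1:])
            beta[j], se[j], F[j], pval[j] = b[0], s[0], f[0], p[0]

    n_tested = int(poly.sum())
    thr = bonferroni_threshold(n_tested, alpha) if n_tested else np.nan
    out = pd.DataFrame({
        "marker": panel.markers["id"],
        "chrom": panel.markers["chrom"],
        "cm": panel.markers["cm"],
        "effect": beta,
        "se": se,
        "F": F,
        "p": pval,
        "neglog10p": -np.log10(np.clip(pval, np.finfo(float).tiny, None)),
        "tested": poly,
    })
    out["significant"] = out["p"] < thr
    out.attrs["bonferroni_threshold"] = thr
    out.attrs["delta"] = fit.delta
    out.attrs["h2"] = fit.h2
    return out


def bonferroni_threshold(m: int, alpha: float = 0.05) -> float:
    """Per-test threshold alpha / m for m markers."""
    if m < 1:
        raise ValueError("need at least one marker")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    return alpha / m


def qei_scan(y_by_env: dict, Q: np.ndarray | None, panel: GenotypePanel,
             K: np.ndarray, alpha: float = 0.05) -> pd.DataFrame:
    """Fixed-effect marker x environment interaction F-test per marker.

    ``y_by_env`` maps environment label -> phenotype vector over the same
    accessions (same order as the panel).  The stacked model has an
    environment main effect, shared covariates, a marker main effect and a
    marker x environment term; kinship is handled by rotating each
    environment block with the null model's U and a shared delta (the mean
    of the per-environment REML log-deltas).  This is a simplified QEI
    analogue, not a multi-locus variance-component model.
    """
    envs = list(y_by_env)
    if len(envs) < 2:
        raise ValueError("QEI needs at least two environments")
    n = panel.n_accessions
    for env in envs:
        if len(np.asarray(y_by_env[env]).ravel()) != n:
            raise ValueError(f"environment {env!r} has mismatched accessions")

    fits = [fit_null_mlm(y_by_env[env], Q, K) for env in envs]
    delta = float(np.exp(np.mean([np.log(f.delta) for f in fits])))
    U, S = fits[0].rotation, fits[0].eigenvalues
    sw = np.sqrt(S + delta)

    G = panel.dosages.astype(float)
    G[G < 0] = np.nan
    G = np.where(np.isnan(G), np.nanmean(G, axis=0), G)
    poly = G.std(axis=0) > 0

    # rotated, whitened blocks
    yws, Xws, Gws = [], [], []
    _, X = _design(np.zeros(n), Q)
    for idx, env in enumerate(envs):
        yv = np.asarray(y_by_env[env], float).ravel()
        yws.append((U.T @ yv) / sw)
        env_cols = np.zeros((n, len(envs)))
        env_cols[:, idx] = 1.0
        Xb = np.column_stack([env_cols, X[:, 1:]])
        Xws.append((U.T @ Xb) / sw[:, None])
        Gws.append((U.T @ G) / sw[:, None])
    yw = np.concatenate(yws)
    Xw = np.vstack(Xws)

    n_env = len(envs)
    dof_int = n_env - 1
    rows = []
    contrasts = np.eye(n_env)[:, 1:] - 1.0 / n_env  # sum-to-zero env coding
    for j in range(panel.n_markers):
        if not poly[j]:
            rows.append((np.nan, np.nan, np.nan))
            continue
        gmain = np.concatenate([Gws[b][:, j] for b in range(n_env)])
        ginter = np.vstack([
            np.outer(Gws[b][:, j], contrasts[b]) for b in range(n_env)])
        X_red = np.column_stack([Xw, gmain])
        X_full = np.column_stack([X_red, ginter])
        rss_red = _rss(X_red, yw)
        rss_full = _rss(X_full, yw)
        dof_full = len(yw) - X_full.shape[1]
        F = ((rss_red - rss_full) / dof_int) / (rss_full / dof_full)
        p = stats.f.sf(F, dof_int, dof_full)
        rows.append((F, p, dof_full))
    F_arr, p_arr, _ = map(np.array, zip(*rows))
    thr = bonferroni_threshold(int(poly.sum()), alpha)
    out = pd.DataFrame({
        "marker": panel.markers["id"],
        "chrom": panel.markers["chrom"],
        "cm": panel.markers["cm"],
        "F_interaction": F_arr,
        "p_interaction": p_arr,
        "neglog10p": -np.log10(np.clip(p_arr, np.finfo(float).tiny, None)),
        "tested": poly,
    })
    out["significant"] = out["p_interaction"] < thr
    out.attrs["bonferroni_threshold"] = thr
    out.attrs["delta"] = delta
    return out


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def manhattan_qq_export(results: pd.DataFrame,
                        chrom_lengths: dict | None = None,
                        p_col: str = "p") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Plot-coordinate tables for Manhattan and QQ plots.

    The Manhattan table adds a cumulative genome coordinate (chromosome
    offsets are the running sum of chromosome lengths, by natural
    chromosome order); the QQ table pairs sorted observed -log10 p with
    expected quantiles -log10((i - 0.5) / m).  Output ordering is
    independent of the input marker order.
    """
    res = results.dropna(subset=[p_col]).copy()
    chroms = sorted(res["chrom"].unique(), key=natural_chrom_key)
    if chrom_lengths is None:
        chrom_lengths = {c: float(res.loc[res["chrom"] == c, "cm"].max())
                         for c in chroms}
    offset = {}
    run = 0.0
    for c in chroms:
        offset[c] = run
        run += float(chrom_lengths[c])
    res["genome_cm"] = res["chrom"].map(offset) + res["cm"]
    res["neglog10p"] = -np.log10(np.clip(res[p_col], np.finfo(float).tiny,
                                         None))
    manhattan = res.sort_values(
        ["genome_cm", "marker"], kind="mergesort").reset_index(drop=True)[
        ["marker", "chrom", "cm", "genome_cm", p_col, "neglog10p"]]

    obs = np.sort(res[p_col].to_numpy())
    m = len(obs)
    expected = (np.arange(1, m + 1) - 0.5) / m
    qq = pd.DataFrame({
        "expected_neglog10p": -np.log10(expected),
        "observed_neglog10p": -np.log10(np.clip(obs, np.finfo(float).tiny,
                                                None)),
    })
    return manhattan, qq
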