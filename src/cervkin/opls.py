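"""Orthogonal projections to latent structures (O-PLS) regression with VIP.

O-PLS regresses a single response (here a kinematic variable such as Peak
Speed) on a wide, collinear predictor block (the 44 self-rated items).
Variation in X orthogonal to y is first removed by one or more orthogonal
components; a single predictive PLS component is then fitted.  The model is
summarised by R²Y (explained variation), Q² (predicted variation from
k-fold cross-validation; the model counts as significant when Q² > 0.05),
and per-predictor VIP values (variable importance in the projection, with
mean squared VIP equal to 1).  A predictor is called significant when its
VIP exceeds 1 and the jack-knife confidence interval of the VIP stays above
0.5.

All computations are on mean-centred, unit-variance (UV) scaled columns;
missing predictor cells are handled by the NIPALS convention of forming
inner products over present cells only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "OplsModel",
    "fit_opls",
    "vip",
    "significant_predictors",
    "Q2_SIGNIFICANCE",
    "VIP_INFLUENTIAL",
    "VIP_CI_FLOOR",
]

Q2_SIGNIFICANCE = 0.05
VIP_INFLUENTIAL = 1.0
VIP_CI_FLOOR = 0.5


@dataclass
class OplsModel:
    predictor_names: list[str]
    w: np.ndarray  # predictive weights (unit norm)
    p: np.ndarray  # predictive X-loadings
    c: float  # y-loading of the predictive score
    w_ortho: np.ndarray  # (n_ortho, p)
    p_ortho: np.ndarray  # (n_ortho, p)
    t_scores: np.ndarray
    t_ortho_scores: np.ndarray  # (n_ortho, n)
    r2y: float
    q2: float
    vip: np.ndarray
    vip_ci: np.ndarray  # (p, 2)
    n_ortho: int
    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: float
    y_sd: float
    log_transformed_columns: list[str] = field(default_factory=list)


def _uv_scale(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = np.nanmean(X, axis=0)
    sd = np.nanstd(X, axis=0, ddof=1)
    if np.any(sd == 0) or np.any(np.isnan(sd)):
        bad = np.where((sd == 0) | np.isnan(sd))[0]
        raise ValueError(f"constant or empty predictor column(s) at index {bad.tolist()}")
    return (X - mean) / sd, mean, sd


def _masked_weights(X: np.ndarray, u: np.ndarray) -> np.ndarray:
    """wⱼ = Σ_present xᵢⱼ uᵢ / Σ_present uᵢ², per column (NIPALS convention)."""
    present = ~np.isnan(X)
    Xz = np.where(present, X, 0.0)
    num = Xz.T @ u
    den = present.T.astype(float) @ (u * u)
    den = np.where(den == 0, np.nan, den)
    return num / den


def _masked_scores(X: np.ndarray, w: np.ndarray) -> np.ndarray:
    """tᵢ = Σ_present xᵢⱼ wⱼ / Σ_present wⱼ², per row."""
    present = ~np.isnan(X)
    Xz = np.where(present, X, 0.0)
    num = Xz @ w
    den = present.astype(float) @ (w * w)
    den = np.where(den == 0, np.nan, den)
    return num / den


def _deflate(X: np.ndarray, t: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Subtract the rank-one component t pᵀ, leaving NaN cells NaN."""
    return X - np.outer(t, p)


def _fit_core(
    Xs: np.ndarray, ys: np.ndarray, n_ortho: int
) -> tuple[np.ndarray, np.ndarray, float, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """O-PLS on pre-scaled data; returns (w, p, c, t, w_o, p_o, t_o)."""
    X = Xs.copy()
    w_o_list, p_o_list, t_o_list = [], [], []
    for _ in range(n_ortho):
        w = _masked_weights(X, ys)
        nw = np.linalg.norm(w)
        if nw < 1e-12:
            break
        w = w / nw
        t = _masked_scores(X, w)
        p_load = _masked_weights(X, t)
        w_o = p_load - (w @ p_load) * w
        n_wo = np.linalg.norm(w_o)
        if n_wo < 1e-12:
            break  # no orthogonal variation left
        w_o = w_o / n_wo
        t_o = _masked_scores(X, w_o)
        p_o = _masked_weights(X, t_o)
        X = _deflate(X, t_o, p_o)
        w_o_list.append(w_o)
        p_o_list.append(p_o)
        t_o_list.append(t_o)
    w = _masked_weights(X, ys)
    nw = np.linalg.norm(w)
    if nw < 1e-12:
        raise ValueError("degenerate model: X carries no covariance with y")
    w = w / nw
    t = _masked_scores(X, w)
    p_load = _masked_weights(X, t)
    c = float((ys @ t) / (t @ t))
    pdim = Xs.shape[1]
    w_o = np.array(w_o_list).reshape(-1, pdim)
    p_o = np.array(p_o_list).reshape(-1, pdim)
    t_o = np.array(t_o_list).reshape(-1, Xs.shape[0])
    return w, p_load, c, t, w_o, p_o, t_o


def _vip_from_weights(w: np.ndarray) -> np.ndarray:
    """Single-predictive-component VIP: √p · |wⱼ| / ‖w‖ (so mean VIP² = 1)."""
    p = w.size
    return np.sqrt(p) * np.abs(w) / np.linalg.norm(w)


def _predict(
    X_new: np.ndarray, w: np.ndarray, c: float, w_o: np.ndarray, p_o: np.ndarray
) -> np.ndarray:
    X = X_new.copy()
    for k in range(w_o.shape[0]):
        t_o = _masked_scores(X, w_o[k])
        X = _deflate(X, t_o, p_o[k])
    t = _masked_scores(X, w)
    return c * t


def fit_opls(
    X: np.ndarray,
    y: np.ndarray,
    predictor_names: list[str] | None = None,
    n_ortho: int | str = "auto",
    cv_folds: int = 7,
    seed: int = 0,
    log_skewed: bool = True,
    skew_threshold: float = 1.0,
    max_ortho: int = 2,
) -> OplsModel:
    """Fit an O-PLS model of y on X.

    Columns with |skewness| above ``skew_threshold`` (and strictly positive
    values) are log-transformed before UV scaling when ``log_skewed`` is set.
    Q² = 1 − PRESS/SS from ``cv_folds``-fold cross-validation with a seeded
    shuffled fold assignment; each fold's model is refitted (including the
    scaling) on the training part only.

    With ``n_ortho="auto"`` (the default) orthogonal components are added
    one at a time and kept only while they improve Q² by more than 0.01 —
    the cross-validated component rule of the standard chemometrics
    workflow; a forced fixed count can overfit weak-signal data.  Pass an
    integer to fix the count.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, p = X.shape
    if y.shape != (n,):
        raise ValueError("y must be a vector matching X's rows")
    if n < cv_folds:
        raise ValueError(f"need at least cv_folds={cv_folds} observations, got {n}")
    if np.isnan(y).any():
        raise ValueError("missing responses are not supported")
    names = list(predictor_names) if predictor_names is not None else [
        f"x{j}" for j in range(p)
    ]
    if len(names) != p:
        raise ValueError("predictor_names length must match X's columns")

    logged: list[str] = []
    X = X.copy()
    if log_skewed:
        for j in range(p):
            col = X[:, j]
            ok = ~np.isnan(col)
            if ok.sum() > 2 and np.all(col[ok] > 0):
                if abs(stats.skew(col[ok], bias=False)) > skew_threshold:
                    X[:, j] = np.where(ok, np.log(np.where(ok, col, 1.0)), np.nan)
                    logged.append(names[j])

    if n_ortho == "auto":
        model = _fit_scaled(X, y, names, 0, cv_folds, seed, logged)
        for k in range(1, max_ortho + 1):
            candidate = _fit_scaled(X, y, names, k, cv_folds, seed, logged)
            if np.isnan(candidate.q2) or candidate.q2 <= model.q2 + 0.01:
                break
            model = candidate
        return model
    return _fit_scaled(X, y, names, int(n_ortho), cv_folds, seed, logged)


def _fit_scaled(
    X: np.ndarray,
    y: np.ndarray,
    names: list[str],
    n_ortho: int,
    cv_folds: int,
    seed: int,
    logged: list[str],
) -> OplsModel:
    n, p = X.shape
    Xs, x_mean, x_sd = _uv_scale(X)
    y_mean, y_sd = float(y.mean()), float(y.std(ddof=1))
    if y_sd == 0:
        raise ValueError("constant response")
    ys = (y - y_mean) / y_sd

    w, p_load, c, t, w_o, p_o, t_o = _fit_core(Xs, ys, n_ortho)
    y_hat = c * t
    ss_y = float(ys @ ys)
    r2y = 1.0 - float((ys - y_hat) @ (ys - y_hat)) / ss_y

    # --- cross-validation: Q² and fold-deleted VIPs for the jack-knife CI
    rng = np.random.default_rng(seed)
    fold_of = np.repeat(np.arange(cv_folds), int(np.ceil(n / cv_folds)))[:n]
    rng.shuffle(fold_of)
    press = 0.0
    ss = 0.0
    fold_vips = []
    for fold in range(cv_folds):
        test = fold_of == fold
        train = ~test
        if test.sum() == 0 or train.sum() < 3:
            continue
        Xtr, mtr, sdtr = _uv_scale(X[train])
        ytr = y[train]
        ytr_mean = ytr.mean()
        ytr_sd = ytr.std(ddof=1)
        ys_tr = (ytr - ytr_mean) / ytr_sd
        try:
            w_f, _, c_f, _, wo_f, po_f, _ = _fit_core(Xtr, ys_tr, n_ortho)
        except ValueError:
            continue
        Xte = (X[test] - mtr) / sdtr
        pred = ytr_mean + ytr_sd * _predict(Xte, w_f, c_f, wo_f, po_f)
        press += float(np.nansum((y[test] - pred) ** 2))
        ss += float(np.sum((y[test] - ytr_mean) ** 2))
        fold_vips.append(_vip_from_weights(w_f))
    q2 = 1.0 - press / ss if ss > 0 else np.nan

    vips = _vip_from_weights(w)
    if fold_vips:
        V = np.array(fold_vips)
        m = V.shape[0]
        vmean = V.mean(axis=0)
        se = np.sqrt((m - 1) / m * np.sum((V - vmean) ** 2, axis=0))
        tcrit = stats.t.ppf(0.975, m - 1)
        ci = np.column_stack([vips - tcrit * se, vips + tcrit * se])
    else:
        ci = np.column_stack([np.full(p, np.nan), np.full(p, np.nan)])

    return OplsModel(
        predictor_names=names,
        w=w,
        p=p_load,
        c=c,
        w_ortho=w_o,
        p_ortho=p_o,
        t_scores=t,
        t_ortho_scores=t_o,
        r2y=float(r2y),
        q2=float(q2),
        vip=vips,
        vip_ci=ci,
        n_ortho=int(w_o.shape[0]),
        x_mean=x_mean,
        x_sd=x_sd,
        y_mean=y_mean,
        y_sd=y_sd,
        log_transformed_columns=logged,
    )


def vip(model: OplsModel) -> tuple[np.ndarray, np.ndarray]:
    """VIP vector and jack-knife confidence intervals of a fitted model."""
    if not np.any(model.vip > 0):
        raise ValueError("degenerate model: VIP undefined")
    return model.vip, model.vip_ci


def significant_predictors(model: OplsModel) -> list[tuple[str, float]]:
    """Predictors called significant: model Q² > 0.05, VIP > 1 and VIP CI
    lower bound above 0.5; ordered by descending VIP."""
    if not model.q2 > Q2_SIGNIFICANCE:
        return []
    hits = [
        (name, float(v))
        for name, v, (lo, _) in zip(model.predictor_names, model.vip, model.vip_ci)
        if v > VIP_INFLUENTIAL and lo > VIP_CI_FLOOR
    ]
    return sorted(hits, key=lambda kv: -kv[1])
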