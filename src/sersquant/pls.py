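"""Partial least squares calibration: PLS-1/PLS-2, nested (double)
cross-validation with leave-one-concentration-out folds, bootstrap
out-of-bag validation, quality metrics and the pseudo-univariate
(capability-of-detection) multivariate LoD.

The core is a NIPALS decomposition with X and Y deflation; a single-column Y
(PLS-1) and a multi-column Y (PLS-2) share the same code path.  Coefficients
are available for every nested model size 1..A from one fit, which makes
cross-validated latent-variable selection cheap.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .lod import LoDEstimate

__all__ = [
    "PLSModel",
    "ValidationMetrics",
    "DoubleCVResult",
    "BootstrapResult",
    "fit_pls",
    "predict",
    "predict_all",
    "compute_metrics",
    "double_cv_loco",
    "bootstrap_validate",
    "pls_lod",
    "save_model",
    "load_model",
]


@dataclass
class PLSModel:
    n_lv: int
    x_mean: np.ndarray            # (p,)
    y_mean: np.ndarray            # (m,)
    weights: np.ndarray           # W, p x A
    x_loadings: np.ndarray        # P, p x A
    y_loadings: np.ndarray        # C, m x A (regression of Y on each score)
    coefficients: np.ndarray      # A x p x m, nested models 1..A
    analytes: list[str] = field(default_factory=list)
    chain: str | None = None

    @property
    def n_channels(self) -> int:
        return self.x_mean.size

    @property
    def n_responses(self) -> int:
        return self.y_mean.size

    def coefs(self, n_lv: int | None = None) -> np.ndarray:
        a = self.n_lv if n_lv is None else n_lv
        if not 1 <= a <= self.coefficients.shape[0]:
            raise ValueError(f"n_lv must be in 1..{self.coefficients.shape[0]}")
        return self.coefficients[a - 1]


def _as_2d(Y: np.ndarray) -> np.ndarray:
    Y = np.asarray(Y, dtype=float)
    return Y[:, None] if Y.ndim == 1 else Y


def fit_pls(
    X: np.ndarray,
    Y: np.ndarray,
    n_lv: int,
    analytes: list[str] | None = None,
) -> PLSModel:
    """PLS with mean centering and X/Y deflation (NIPALS family).

    Each weight vector is the fixed point of the NIPALS inner loop, computed
    exactly as the dominant eigenvector of the small (n_responses x
    n_responses) matrix (Y^T X)(X^T Y) — identical to fully converged
    iterative NIPALS, but deterministic and independent of a convergence
    tolerance.  Stops early (with fewer components) if a score collapses
    numerically.
    """
    X = np.asarray(X, dtype=float)
    Y2 = _as_2d(Y)
    n, p = X.shape
    if Y2.shape[0] != n:
        raise ValueError("X and Y row counts differ")
    bound = min(n - 1, p)
    if not 1 <= n_lv <= bound:
        raise ValueError(f"n_lv must be in 1..{bound} (min(n - 1, n_channels))")
    m = Y2.shape[1]
    x_mean = X.mean(axis=0)
    y_mean = Y2.mean(axis=0)
    Xc = X - x_mean
    Yc = Y2 - y_mean
    x_scale = float(np.linalg.norm(Xc)) or 1.0

    W = np.zeros((p, n_lv))
    P = np.zeros((p, n_lv))
    C = np.zeros((m, n_lv))
    a_used = 0
    for a in range(n_lv):
        M = Xc.T @ Yc  # p x m cross-covariance
        if m == 1:
            w = M[:, 0]
        else:
            small = M.T @ M  # m x m
            evals, evecs = np.linalg.eigh(small)
            q = evecs[:, -1]
            if q[int(np.argmax(np.abs(q)))] < 0:
                q = -q  # deterministic sign (B is invariant either way)
            w = M @ q
        nw = np.linalg.norm(w)
        if nw <= 1e-14 * x_scale:
            break  # Y fully explained / no covariance left
        w = w / nw
        t = Xc @ w
        tt = float(t @ t)
        if tt <= (1e-12 * x_scale) ** 2:
            break  # rank exhausted
        p_a = Xc.T @ t / tt
        c_a = Yc.T @ t / tt
        Xc = Xc - np.outer(t, p_a)
        Yc = Yc - np.outer(t, c_a)
        W[:, a], P[:, a], C[:, a] = w, p_a, c_a
        a_used += 1

    if a_used == 0:
        raise ValueError("PLS found no usable component (X has no variance)")
    W, P, C = W[:, :a_used], P[:, :a_used], C[:, :a_used]
    # nested coefficients B_a = W_a (P_a^T W_a)^-1 C_a^T for a = 1..A
    coefs = np.zeros((a_used, p, m))
    PtW = P.T @ W
    for a in range(1, a_used + 1):
        R = W[:, :a] @ np.linalg.solve(PtW[:a, :a], np.eye(a))
        coefs[a - 1] = R @ C[:, :a].T
    return PLSModel(
        n_lv=a_used,
        x_mean=x_mean,
        y_mean=y_mean,
        weights=W,
        x_loadings=P,
        y_loadings=C,
        coefficients=coefs,
        analytes=list(analytes) if analytes is not None else [f"y{j}" for j in range(m)],
    )


def predict(model: PLSModel, X_new: np.ndarray, n_lv: int | None = None) -> np.ndarray:
    """Predicted concentrations (ppm); negative predictions are reported,
    never clipped."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != model.n_channels:
        raise ValueError(
            f"channel count {X_new.shape[1]} does not match training ({model.n_channels})"
        )
    return (X_new - model.x_mean) @ model.coefs(n_lv) + model.y_mean


def predict_all(model: PLSModel, X_new: np.ndarray) -> np.ndarray:
    """(A, n, m) predictions for every nested model size from one fit."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    Xc = X_new - model.x_mean
    return np.einsum("np,apm->anm", Xc, model.coefficients) + model.y_mean


@dataclass
class ValidationMetrics:
    """Per-analyte goodness-of-fit and error summaries (ppm).  Fields are
    None where the corresponding context was not evaluated."""

    analytes: list[str]
    r2: np.ndarray | None = None       # training
    q2_cv: np.ndarray | None = None
    q2_test: np.ndarray | None = None
    rmsec: np.ndarray | None = None
    rmsecv: np.ndarray | None = None
    rmsep: np.ndarray | None = None


def compute_metrics(known: np.ndarray, predicted: np.ndarray, context: str = "test"):
    """Per-column R^2/Q^2 = 1 - RSS/TSS (TSS centred on the known values of
    this context) and RMSE = sqrt(mean squared error).

    Returns ``(r2, rmse)`` arrays, one entry per response column.
    """
    if context not in ("train", "cv", "test"):
        raise ValueError(f"unknown context {context!r}")
    yk = _as_2d(known)
    yp = _as_2d(predicted)
    if yk.shape != yp.shape:
        raise ValueError("known and predicted shapes differ")
    if yk.shape[0] < 2:
        raise ValueError("need at least 2 observations")
    resid = yp - yk
    rss = (resid**2).sum(axis=0)
    tss = ((yk - yk.mean(axis=0)) ** 2).sum(axis=0)
    if np.any(tss == 0):
        raise ValueError("zero variance in known values")
    r2 = 1.0 - rss / tss
    rmse = np.sqrt((resid**2).mean(axis=0))
    return r2, rmse


# ---------------------------------------------------------------------------
# cross-validation

def _level_groups(Y: np.ndarray) -> np.ndarray:
    """Group index per row: one group per distinct concentration level
    (distinct row of Y); replicates of a level always travel together."""
    _, inv = np.unique(_as_2d(Y), axis=0, return_inverse=True)
    return inv


def _fold_of_level(n_levels: int, max_folds: int | None, seed: int) -> np.ndarray:
    """Map each level to a fold: identity (leave-one-level-out) or, when
    capped, a seeded balanced grouping of levels into ``max_folds`` folds."""
    if max_folds is None or n_levels <= max_folds:
        return np.arange(n_levels)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_levels)
    folds = np.empty(n_levels, dtype=int)
    folds[perm] = np.arange(n_levels) % max_folds
    return folds


@dataclass
class DoubleCVResult:
    selected_lv: int                 # consensus (median of per-fold choices)
    per_fold_lv: list[int]
    q2_cv: np.ndarray                # per analyte
    rmsecv: np.ndarray               # per analyte, ppm
    predictions: np.ndarray          # pooled outer predictions, n x m
    groups: np.ndarray               # level index per row
    n_outer_folds: int


def double_cv_loco(
    X: np.ndarray,
    Y: np.ndarray,
    candidate_lvs,
    analytes: list[str] | None = None,
    max_outer_folds: int | None = None,
    max_inner_folds: int | None = None,
    one_se: bool = True,
    seed: int = 0,
) -> DoubleCVResult:
    """Nested cross-validation with concentration-level folds.

    The outer loop holds out all replicates of one concentration level (or a
    seeded group of levels when ``max_outer_folds`` caps the count); the
    inner loop repeats the scheme on the outer-training levels to pick the
    number of latent variables (minimum inner RMSECV, with a one-standard-
    error parsimony tie-break toward fewer LVs).  Outer predictions are
    pooled into Q^2_cv and RMSECV.
    """
    X = np.asarray(X, dtype=float)
    Y2 = _as_2d(Y)
    candidate_lvs = sorted(int(a) for a in candidate_lvs)
    if not candidate_lvs or candidate_lvs[0] < 1:
        raise ValueError("candidate_lvs must contain integers >= 1")
    groups = _level_groups(Y2)
    n_levels = groups.max() + 1
    if n_levels < 3:
        raise ValueError("need at least 3 distinct concentration levels")
    outer_folds = _fold_of_level(n_levels, max_outer_folds, seed)
    n_outer = outer_folds.max() + 1
    if n_outer == 1:
        raise ValueError("a single level holds all samples; cannot cross-validate")

    preds = np.full_like(Y2, np.nan)
    per_fold_lv: list[int] = []
    for of in range(n_outer):
        test_rows = np.flatnonzero(np.isin(outer_folds[groups], of))
        train_rows = np.flatnonzero(~np.isin(outer_folds[groups], of))
        Xtr, Ytr = X[train_rows], Y2[train_rows]
        tr_groups = groups[train_rows]
        tr_levels, tr_inv = np.unique(tr_groups, return_inverse=True)
        inner_folds = _fold_of_level(tr_levels.size, max_inner_folds, seed + 1)
        n_inner = inner_folds.max() + 1
        max_cand = min(candidate_lvs[-1], min(Xtr.shape[0] - 1, Xtr.shape[1]))
        cands = [a for a in candidate_lvs if a <= max_cand]
        # inner CV: one fit per inner fold yields predictions at every size
        sq_err = np.zeros((len(cands), n_inner))
        counts = np.zeros(n_inner)
        for inf in range(n_inner):
            it_rows = np.flatnonzero(np.isin(inner_folds[tr_inv], inf))
            il_rows = np.flatnonzero(~np.isin(inner_folds[tr_inv], inf))
            mdl = fit_pls(Xtr[il_rows], Ytr[il_rows], max(cands))
            all_pred = predict_all(mdl, Xtr[it_rows])  # A x nt x m
            for ci, a in enumerate(cands):
                aa = min(a, mdl.n_lv)
                sq_err[ci, inf] = ((all_pred[aa - 1] - Ytr[it_rows]) ** 2).sum()
            counts[inf] = it_rows.size * Y2.shape[1]
        pooled_rmse = np.sqrt(sq_err.sum(axis=1) / counts.sum())
        best = int(np.argmin(pooled_rmse))
        chosen = cands[best]
        if one_se and n_inner > 1:
            fold_rmse = np.sqrt(sq_err[best] / counts)
            se = fold_rmse.std(ddof=1) / np.sqrt(n_inner)
            for ci, a in enumerate(cands):
                if pooled_rmse[ci] <= pooled_rmse[best] + se:
                    chosen = a
                    break
        per_fold_lv.append(chosen)
        mdl = fit_pls(Xtr, Ytr, chosen)
        preds[test_rows] = predict(mdl, X[test_rows], min(chosen, mdl.n_lv))

    q2, rmse = compute_metrics(Y2, preds, context="cv")
    selected = int(np.median(per_fold_lv))
    return DoubleCVResult(
        selected_lv=selected,
        per_fold_lv=per_fold_lv,
        q2_cv=q2,
        rmsecv=rmse,
        predictions=preds,
        groups=groups,
        n_outer_folds=int(n_outer),
    )


# ---------------------------------------------------------------------------
# bootstrap validation

@dataclass
class BootstrapResult:
    n_resamples: int
    n_skipped: int                  # iterations with an empty out-of-bag set
    oob_mean: np.ndarray            # n x m per-sample OOB prediction mean
    oob_sd: np.ndarray              # n x m per-sample OOB prediction sd
    oob_count: np.ndarray           # times each sample was out-of-bag
    q2_test: np.ndarray             # pooled over all (sample, iteration) pairs
    rmsep: np.ndarray               # ppm, pooled
    mean_oob_fraction: float
    seed: int
    all_oob: bool = True            # every sample out-of-bag at least once


def bootstrap_validate(
    X: np.ndarray,
    Y: np.ndarray,
    n_lv: int,
    n_resamples: int = 1000,
    seed: int = 0,
) -> BootstrapResult:
    """Bootstrap out-of-bag validation at a fixed number of latent variables.

    Each iteration draws n rows with replacement as the training set, fits,
    and predicts the out-of-bag rows.  Q^2_test and RMSEP are pooled over
    every (sample, iteration) out-of-bag prediction; per-sample means and SDs
    summarise the prediction clouds.
    """
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    X = np.asarray(X, dtype=float)
    Y2 = _as_2d(Y)
    n, m = Y2.shape
    rng = np.random.default_rng(seed)
    s1 = np.zeros((n, m))
    s2 = np.zeros((n, m))
    cnt = np.zeros(n)
    rss = np.zeros(m)
    k_sum = np.zeros(m)
    k_sumsq = np.zeros(m)
    total = 0
    skipped = 0
    oob_frac = 0.0
    for _ in range(n_resamples):
        idx = rng.integers(0, n, n)
        mask = np.ones(n, dtype=bool)
        mask[idx] = False
        oob = np.flatnonzero(mask)
        if oob.size == 0:
            skipped += 1
            continue
        oob_frac += oob.size / n
        mdl = fit_pls(X[idx], Y2[idx], n_lv)
        pred = predict(mdl, X[oob], min(n_lv, mdl.n_lv))
        s1[oob] += pred
        s2[oob] += pred**2
        cnt[oob] += 1
        rss += ((pred - Y2[oob]) ** 2).sum(axis=0)
        k_sum += Y2[oob].sum(axis=0)
        k_sumsq += (Y2[oob] ** 2).sum(axis=0)
        total += oob.size
    done = n_resamples - skipped
    if done == 0 or total == 0:
        raise ValueError("every bootstrap iteration had an empty out-of-bag set")
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = s1 / cnt[:, None]
        var = np.maximum(s2 / cnt[:, None] - mean**2, 0.0)
    tss = k_sumsq - k_sum**2 / total  # centred on the pooled known values
    return BootstrapResult(
        n_resamples=n_resamples,
        n_skipped=skipped,
        oob_mean=mean,
        oob_sd=np.sqrt(var),
        oob_count=cnt,
        q2_test=1.0 - rss / tss,
        rmsep=np.sqrt(rss / total),
        mean_oob_fraction=oob_frac / done,
        seed=seed,
        all_oob=bool(np.all(cnt > 0)),
    )


# ---------------------------------------------------------------------------
# multivariate (pseudo-univariate) LoD

def pls_lod(
    known: np.ndarray,
    predicted: np.ndarray,
    alpha: float = 0.05,
    beta: float = 0.05,
    delta_method: str = "normal",
    analyte: str | None = None,
) -> LoDEstimate:
    """Capability-of-detection LoD from the predicted-vs-known regression.

    Fits OLS ``predicted = b * known + a`` over the calibration levels and
    returns ``LoD = Delta(alpha, beta) * (s/b) * sqrt(1 + 1/n + xbar^2/Sxx)``
    where s is the residual SD.  ``Delta`` is the normal approximation
    3.29 at alpha = beta = 0.05 (default), or the sum of one-sided t
    quantiles when ``delta_method="t"``.
    """
    x = np.asarray(known, dtype=float)
    y = np.asarray(predicted, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("known and predicted must be equal-length 1-D arrays")
    n = x.size
    if np.unique(x).size < 5:
        raise ValueError("PLS LoD needs at least 5 distinct calibration levels")
    res = stats.linregress(x, y)
    b = float(res.slope)
    if b <= 0:
        raise ValueError("non-positive predicted-vs-known slope")
    resid = y - (b * x + res.intercept)
    s = np.sqrt(float(resid @ resid) / (n - 2))
    xbar = x.mean()
    sxx = float(((x - xbar) ** 2).sum())
    if delta_method == "normal":
        delta = stats.norm.ppf(1 - alpha) + stats.norm.ppf(1 - beta)  # ~3.29
    elif delta_method == "t":
        delta = stats.t.ppf(1 - alpha, n - 2) + stats.t.ppf(1 - beta, n - 2)
    else:
        raise ValueError(f"unknown delta_method {delta_method!r}")
    value = delta * (s / b) * np.sqrt(1.0 + 1.0 / n + xbar**2 / sxx)
    return LoDEstimate(
        value=float(value),
        method="pls_ortiz",
        analyte=analyte,
        details={"alpha": alpha, "beta": beta, "delta": float(delta),
                 "slope": b, "residual_sd": float(s), "n": n},
    )


# ---------------------------------------------------------------------------
# model persistence (JSON)

def save_model(model: PLSModel, path) -> None:
    payload = {
        "format": "sersquant-pls-model",
        "version": 1,
        "n_lv": model.n_lv,
        "x_mean": model.x_mean.tolist(),
        "y_mean": model.y_mean.tolist(),
        "weights": model.weights.tolist(),
        "x_loadings": model.x_loadings.tolist(),
        "y_loadings": model.y_loadings.tolist(),
        "coefficients": model.coefficients.tolist(),
        "analytes": model.analytes,
        "chain": model.chain,
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path) -> PLSModel:
    d = json.loads(Path(path).read_text())
    if d.get("format") != "sersquant-pls-model":
        raise ValueError(f"{path} is not a sersquant PLS model file")
    return PLSModel(
        n_lv=int(d["n_lv"]),
        x_mean=np.array(d["x_mean"]),
        y_mean=np.array(d["y_mean"]),
        weights=np.array(d["weights"]),
        x_loadings=np.array(d["x_loadings"]),
        y_loadings=np.array(d["y_loadings"]),
        coefficients=np.array(d["coefficients"]),
        analytes=list(d["analytes"]),
        chain=d.get("chain"),
    )
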