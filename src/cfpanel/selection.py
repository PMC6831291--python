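"""Penalized regression marker selection with bootstrap confidence bands.

The disease label (0 = nontumor, 1 = tumor) is regressed linearly on
candidate-probe beta values under an elastic-net penalty

    (1/2n) ||y - b - X w||^2 + lambda * (mix |w|_1 + (1 - mix)/2 |w|_2^2),

solved by cyclic coordinate descent with soft-thresholding on an
internally standardized design; coefficients are returned on the
original beta scale.  ``mix`` is the elastic-net mixing parameter
(1 = pure Lasso); the pipeline default is 0.05, a mostly-ridge penalty
read off glmnet's ``alpha`` convention.  The penalty weight is chosen as
``lambda_min``, the value minimizing stratified k-fold cross-validated
squared error over a 100-point log-spaced grid from ``lambda_max``
(smallest penalty with an all-zero solution) down by four decades.

Markers are then selected by sign-definite bootstrap confidence
intervals: B stratified case resamples, lambda re-chosen within each
replicate (a fast mode freezes it at the full-data lambda_min), and the
95% percentile interval per coefficient.  A probe is selected when its
lower bound is > 0 (hypermethylation runs) or its upper bound is < 0
(hypomethylation runs).
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._solver import enet_path_gram

__all__ = ["ElasticNetFit", "SelectionResult", "fit_elastic_net",
           "make_lambda_grid", "choose_lambda_min", "bootstrap_select",
           "ConvergenceError"]

log = logging.getLogger(__name__)

DEFAULT_TOL = 1e-7
CV_TOL = 1e-4  # looser tolerance inside cross-validation path solves
MAX_SWEEPS = 100_000
N_LAMBDA = 100
LAMBDA_EPS = 1e-4


class ConvergenceError(RuntimeError):
    """Coordinate descent failed to reach the tolerance."""

    def __init__(self, last_delta: float):
        super().__init__(f"coordinate descent did not converge "
                         f"(last max coefficient change {last_delta:.3e})")
        self.last_delta = last_delta


@dataclass
class ElasticNetFit:
    """Original-scale coefficients of one elastic-net solve."""

    coefficients: pd.Series
    intercept: float
    lam: float
    mixing: float


@dataclass
class SelectionResult:
    """Bootstrap selection output for one direction.

    ``table`` is indexed by probe id with columns ``coefficient`` (full-
    data fit at the full-data lambda_min), ``ci_lower``/``ci_upper``
    (percentile bootstrap bounds) and ``selected``.
    """

    table: pd.DataFrame
    direction: str
    n_bootstraps: int
    ci_level: float
    mixing: float
    lambda_full: float
    boot_coefficients: np.ndarray | None = field(default=None, repr=False)

    @property
    def selected_probes(self) -> list[str]:
        return list(self.table.index[self.table["selected"]])

    def weights(self) -> pd.Series:
        """Point coefficients of the selected probes (panel weights)."""
        return self.table.loc[self.table["selected"], "coefficient"]


def _as_xy(X, y):
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        Xa = X.to_numpy(dtype=float)
    else:
        Xa = np.asarray(X, dtype=float)
        names = [f"x{j}" for j in range(Xa.shape[1])]
    ya = np.asarray(y, dtype=float).ravel()
    if Xa.shape[0] != ya.shape[0]:
        raise ValueError("X and y disagree on sample count")
    return Xa, ya, names


def _standardize(Xa, ya):
    """Center/scale columns (population sd); drop constant columns."""
    mx = Xa.mean(axis=0)
    sx = Xa.std(axis=0)
    # a numerically constant column has sd at rounding-error scale
    keep = sx > 1e-10 * np.maximum(1.0, np.abs(mx))
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} zero-variance columns",
                      stacklevel=3)
    Xs = (Xa[:, keep] - mx[keep]) / sx[keep]
    my = ya.mean()
    return Xs, ya - my, mx, sx, keep, my


def _solve_path(Xs, yc, lambdas, mixing, tol=DEFAULT_TOL):
    n = Xs.shape[0]
    G = Xs.T @ Xs / n
    c = Xs.T @ yc / n
    W, sweeps, last_delta = enet_path_gram(
        G, c, np.asarray(lambdas, dtype=float), float(mixing), tol, MAX_SWEEPS)
    bad = sweeps >= MAX_SWEEPS
    if bad.any():
        raise ConvergenceError(float(last_delta[bad][0]))
    return W


def fit_elastic_net(X, y, lam: float, mixing: float = 0.05,
                    tol: float = DEFAULT_TOL) -> ElasticNetFit:
    """One elastic-net solve; coefficients on the original beta scale."""
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    if not 0.0 <= mixing <= 1.0:
        raise ValueError("mixing must be in [0, 1]")
    Xa, ya, names = _as_xy(X, y)
    if Xa.shape[0] < 3:
        raise ValueError("need at least 3 samples")
    Xs, yc, mx, sx, keep, my = _standardize(Xa, ya)
    # pathwise warm start down to the requested lambda (cold starts on
    # near-singular p > n problems converge too slowly)
    n = Xs.shape[0]
    lam_max = float(np.max(np.abs(Xs.T @ yc / n))) / max(mixing, 1e-3)
    if lam > 0 and lam < lam_max:
        path = np.r_[np.logspace(np.log10(lam_max), np.log10(lam), 20)[:-1],
                     lam]
    else:
        path = np.array([lam])
    W = _solve_path(Xs, yc, path, mixing, tol)
    w_std = W[-1]
    coef = np.zeros(Xa.shape[1])
    coef[keep] = w_std / sx[keep]
    intercept = my - float(coef @ mx)
    return ElasticNetFit(pd.Series(coef, index=names, name="coefficient"),
                         intercept, lam, mixing)


def make_lambda_grid(X, y, mixing: float = 0.05, n_lambda: int = N_LAMBDA,
                     eps: float = LAMBDA_EPS) -> np.ndarray:
    """Descending log-spaced grid from lambda_max (all-zero solution)
    down to eps * lambda_max, glmnet-style."""
    Xa, ya, _ = _as_xy(X, y)
    Xs, yc, *_ = _standardize(Xa, ya)
    n = Xs.shape[0]
    cmax = float(np.max(np.abs(Xs.T @ yc / n)))
    lam_max = cmax / max(mixing, 1e-3)
    if lam_max <= 0:
        lam_max = 1.0
    return np.logspace(np.log10(lam_max), np.log10(lam_max * eps), n_lambda)


def _stratified_folds(y, k_folds, rng):
    """Fold index per sample, stratified by label; a response with many
    distinct values (continuous y) falls back to plain shuffled folds."""
    y = np.asarray(y)
    n = y.shape[0]
    levels = np.unique(y)
    if levels.size > max(2, n // (2 * k_folds)):
        idx = rng.permutation(n)
        fold = np.empty(n, dtype=int)
        fold[idx] = np.arange(n) % k_folds
        return fold
    fold = np.empty(n, dtype=int)
    for lab in levels:
        idx = np.flatnonzero(y == lab)
        rng.shuffle(idx)
        fold[idx] = np.arange(idx.size) % k_folds
    return fold


def choose_lambda_min(X, y, mixing: float = 0.05, k_folds: int = 5,
                      lambda_grid=None, seed: int = 0) -> float:
    """lambda minimizing mean stratified k-fold CV squared error; ties
    resolve to the larger lambda (grid is descending)."""
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    Xa, ya, _ = _as_xy(X, y)
    if Xa.shape[0] < k_folds:
        raise ValueError("fewer samples than folds")
    if lambda_grid is None:
        lambda_grid = make_lambda_grid(Xa, ya, mixing)
    lambda_grid = np.asarray(lambda_grid, dtype=float)
    if lambda_grid.size > 1 and np.any(np.diff(lambda_grid) > 0):
        raise ValueError("lambda grid must be descending")

    rng = np.random.default_rng(seed)
    fold = _stratified_folds(ya, k_folds, rng)
    cv_err = np.zeros(lambda_grid.size)
    for f in range(k_folds):
        tr, te = fold != f, fold == f
        Xs, yc, mx, sx, keep, my = _standardize(Xa[tr], ya[tr])
        W = _solve_path(Xs, yc, lambda_grid, mixing, tol=CV_TOL)
        coef = np.zeros((lambda_grid.size, Xa.shape[1]))
        coef[:, keep] = W / sx[keep]
        pred = Xa[te] @ coef.T + (my - coef @ mx)
        cv_err += ((ya[te, None] - pred) ** 2).sum(axis=0)
    cv_err /= Xa.shape[0]
    return float(lambda_grid[int(np.argmin(cv_err))])


def _stratified_resample(y, rng):
    y = np.asarray(y)
    idx = []
    for lab in np.unique(y):
        pool = np.flatnonzero(y == lab)
        idx.append(rng.choice(pool, size=pool.size, replace=True))
    return np.concatenate(idx)


def bootstrap_select(X, y, direction: str, mixing: float = 0.05,
                     B: int = 100, ci_level: float = 0.95, seed: int = 0,
                     reselect_lambda: bool = True, k_folds: int = 5,
                     keep_boot: bool = False) -> SelectionResult:
    """Sign-definite bootstrap-CI marker selection.

    B stratified case resamples; within each, lambda_min is re-chosen by
    CV (set ``reselect_lambda=False`` to freeze it at the full-data
    value) and the elastic net refit.  The per-coefficient percentile
    interval at ``ci_level`` drives selection: hyper runs keep probes
    with lower bound > 0, hypo runs keep probes with upper bound < 0.
    """
    if direction not in ("hyper", "hypo"):
        raise ValueError(f"direction must be hyper or hypo, got {direction!r}")
    if B < 2:
        raise ValueError("need at least 2 bootstraps")
    Xa, ya, names = _as_xy(X, y)
    rng = np.random.default_rng(seed)
    grid = make_lambda_grid(Xa, ya, mixing)

    lam_full = choose_lambda_min(Xa, ya, mixing, k_folds, grid,
                                 seed=int(rng.integers(2 ** 31)))
    full_fit = fit_elastic_net(Xa, ya, lam_full, mixing)

    boot = np.zeros((B, Xa.shape[1]))
    for b in range(B):
        for _ in range(10):
            idx = _stratified_resample(ya, rng)
            Xb = Xa[idx]
            if not np.all(Xb == Xb[0]):  # degenerate all-identical rows
                break
        else:
            raise RuntimeError("could not draw a non-degenerate bootstrap "
                               "replicate in 10 tries")
        yb = ya[idx]
        if reselect_lambda:
            lam_b = choose_lambda_min(Xb, yb, mixing, k_folds, grid,
                                      seed=int(rng.integers(2 ** 31)))
        else:
            lam_b = lam_full
        boot[b] = fit_elastic_net(Xb, yb, lam_b, mixing).coefficients.to_numpy()

    alpha = 1.0 - ci_level
    lo = np.percentile(boot, 100 * alpha / 2, axis=0)
    hi = np.percentile(boot, 100 * (1 - alpha / 2), axis=0)
    if direction == "hyper":
        selected = lo > 0.0
    else:
        selected = hi < 0.0

    table = pd.DataFrame({
        "coefficient": full_fit.coefficients.to_numpy(),
        "ci_lower": lo,
        "ci_upper": hi,
        "selected": selected,
    }, index=pd.Index(names, name="probe_id"))
    return SelectionResult(table, direction, B, ci_level, mixing, lam_full,
                           boot if keep_boot else None)
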