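"""Cyclic coordinate descent for the elastic net, Gram formulation.

Solves, for a descending sequence of penalties ``lam`` with warm starts,

    (1/2n) * ||y - X w||^2 + lam * (mix * ||w||_1 + (1 - mix)/2 * ||w||_2^2)

given the Gram matrix G = X'X / n and covariance c = X'y / n of a
column-standardized design and centered response.  The coordinate update
is the classic soft-threshold step

    w_j <- S(c_j - sum_{k != j} G_jk w_k, lam * mix) / (G_jj + lam * (1 - mix)).

The kernel is JIT-compiled; it is the hot path of the bootstrap x CV x
lambda-path selection loop.
"""
from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["enet_path_gram"]


@njit(cache=True)
def enet_path_gram(G, c, lambdas, mix, tol, max_sweeps):
    """Solve the elastic net along a lambda path.

    Returns (W, sweeps, last_delta): coefficient matrix of shape
    (n_lambda, p) on the standardized scale, sweep counts, and the final
    max coefficient change per lambda (for convergence diagnostics).
    """
    p = c.shape[0]
    n_lam = lambdas.shape[0]
    W = np.zeros((n_lam, p))
    sweeps = np.zeros(n_lam, dtype=np.int64)
    last_delta = np.zeros(n_lam)
    w = np.zeros(p)
    # running gradient helper: g = G @ w, updated incrementally
    g = np.zeros(p)
    for li in range(n_lam):
        lam = lambdas[li]
        l1 = lam * mix
        l2 = lam * (1.0 - mix)
        delta = 0.0
        for sweep in range(max_sweeps):
            delta = 0.0
            for j in range(p):
                wj = w[j]
                rho = c[j] - g[j] + G[j, j] * wj
                az = abs(rho) - l1
                if az > 0.0:
                    wn = np.sign(rho) * az / (G[j, j] + l2)
                else:
                    wn = 0.0
                if wn != wj:
                    diff = wn - wj
                    w[j] = wn
                    for k in range(p):
                        g[k] += G[k, j] * diff
                    ad = abs(diff)
                    if ad > delta:
                        delta = ad
            if delta < tol:
                break
        sweeps[li] = sweep + 1
        last_delta[li] = delta
        W[li, :] = w
    return W, sweeps, last_delta
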