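"""Independent dense evaluator of the restricted log-likelihood.

Used as a brute-force oracle against the REML optimizer: builds V explicitly
for batches of variance-component vectors and evaluates

    l_R(theta) = -1/2 [ log|V| + log|X'V^-1 X| + y'Py ] - (n-p)/2 log(2 pi)

with plain slogdet/inv calls, sharing no code with the package's fitting
routines.
"""

import numpy as np


def batch_reml_loglik(thetas, y, X, kernels, chunk=2000):
    thetas = np.atleast_2d(np.asarray(thetas, dtype=float))
    K = np.stack([np.asarray(k, dtype=float) for k in kernels])
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    const = -0.5 * (n - p) * np.log(2 * np.pi)
    out = np.full(len(thetas), -np.inf)
    for start in range(0, len(thetas), chunk):
        th = thetas[start : start + chunk]
        V = np.tensordot(th, K, axes=(1, 0))  # (B, n, n)
        sign_v, logdet_v = np.linalg.slogdet(V)
        ok = sign_v > 0
        if not ok.any():
            continue
        Vinv = np.linalg.inv(V[ok])
        vinv_x = Vinv @ X
        vinv_y = np.einsum("bij,j->bi", Vinv, y)
        xtvx = np.einsum("ip,biq->bpq", X, vinv_x)
        sign_x, logdet_x = np.linalg.slogdet(xtvx)
        xtvy = np.einsum("ip,bi->bp", X, vinv_y)
        beta = np.linalg.solve(xtvx, xtvy[..., None])[..., 0]
        quad = y @ vinv_y.T - np.einsum("bp,bp->b", xtvy, beta)
        vals = -0.5 * (logdet_v[ok] + logdet_x + quad) + const
        vals[sign_x <= 0] = -np.inf
        idx = np.where(ok)[0] + start
        out[idx] = vals
    return out


def grid_search_reml(y, X, kernels, bounds, n_points, n_zooms=2):
    """Coarsened exhaustive grid: broad sweep, then zooms around the incumbent.

    Returns (best_theta, best_loglik). Each zoom re-grids a window of +/- 1.5
    grid steps around the current best, so the effective per-axis resolution
    multiplies with every stage.
    """
    bounds = [list(b) for b in bounds]
    best_theta, best_logl = None, -np.inf
    for _ in range(n_zooms + 1):
        axes = [np.linspace(lo, hi, n_points) for lo, hi in bounds]
        mesh = np.meshgrid(*axes, indexing="ij")
        thetas = np.column_stack([m.ravel() for m in mesh])
        logls = batch_reml_loglik(thetas, y, X, kernels)
        i = int(np.argmax(logls))
        if logls[i] > best_logl:
            best_logl = float(logls[i])
            best_theta = thetas[i].copy()
        for d, (lo, hi) in enumerate(bounds):
            step = (hi - lo) / (n_points - 1)
            bounds[d] = [max(lo, best_theta[d] - 1.5 * step),
                         best_theta[d] + 1.5 * step]
    return best_theta, best_logl
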