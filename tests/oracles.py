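"""Independent oracles used to cross-check the implementation.

These deliberately take different computational routes from the package:
the generalized-eigenvalue formulation of CCA, per-pair Pearson
correlations, covariance eigendecomposition for PCA, and random-search
lower bounds.  They are slow and simple on purpose.
"""

import numpy as np
from scipy import linalg, stats


def gev_canonical_correlations(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Canonical correlations via the symmetric generalized eigenproblem

        [0   Sxy] w = rho [Sxx  0 ] w
        [Syx  0 ]         [0   Syy]

    whose positive eigenvalues are the canonical correlations.
    """
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    n = x.shape[0]
    sxx = xc.T @ xc / (n - 1)
    syy = yc.T @ yc / (n - 1)
    sxy = xc.T @ yc / (n - 1)
    dx, dy = sxx.shape[0], syy.shape[0]
    a = np.zeros((dx + dy, dx + dy))
    a[:dx, dx:] = sxy
    a[dx:, :dx] = sxy.T
    b = np.zeros_like(a)
    b[:dx, :dx] = sxx
    b[dx:, dx:] = syy
    vals = linalg.eigh(a, b, eigvals_only=True)
    rho = np.sort(vals[vals > 1e-12])[::-1]
    return rho[: min(dx, dy)]


def pairwise_pearson(ts: np.ndarray) -> np.ndarray:
    """r x r correlation matrix from per-pair scipy.stats.pearsonr calls."""
    r = ts.shape[1]
    out = np.eye(r)
    for i in range(r):
        for j in range(i + 1, r):
            c = stats.pearsonr(ts[:, i], ts[:, j]).statistic
            out[i, j] = out[j, i] = c
    return out


def covariance_eig_fractions(x: np.ndarray) -> np.ndarray:
    """PCA explained-variance fractions from the covariance eigenvalues."""
    xc = x - x.mean(axis=0)
    cov = xc.T @ xc / (x.shape[0] - 1)
    vals = np.sort(linalg.eigh(cov, eigvals_only=True))[::-1]
    return vals / vals.sum()


def best_random_correlation(
    x: np.ndarray, y: np.ndarray, n_draws: int, rng: np.random.Generator
) -> float:
    """Best correlation over random unit weight pairs; a lower bound on the
    first canonical correlation."""
    best = 0.0
    for _ in range(n_draws):
        u = rng.standard_normal(x.shape[1])
        v = rng.standard_normal(y.shape[1])
        c = abs(np.corrcoef(x @ u, y @ v)[0, 1])
        best = max(best, c)
    return best
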