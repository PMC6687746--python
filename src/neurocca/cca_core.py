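"""PCA reduction and canonical correlation analysis of the two views.

The brain and behaviour matrices have far more variables than subjects, so
each view is first reduced to its top ``d`` principal components (X_d,
Y_d).  CCA then finds, per mode, a pair of canonical basis vectors (u, v)
whose projections -- the canonical variates (P_X, P_Y) -- are maximally
correlated.  Variables are interpreted through loadings: the Pearson
correlation of each preprocessed variable with the corresponding variate
(structure coefficients).

Numerics: PCA uses the SVD of the column-centred matrix; the sign of each
component is fixed so its largest-magnitude weight is positive.  CCA uses
the SVD of the whitened cross-covariance (via thin QR of each centred
view), which is numerically stable and exact for full-rank inputs.
Canonical signs are arbitrary; modes can be re-signed against the
behaviour loadings with :func:`fix_mode_signs`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg

from .dataio import DataMatrix


@dataclass
class PcaModel:
    """Principal-component reduction of one view.

    Attributes
    ----------
    basis : (m, d) orthonormal variable-space directions (columns).
    means : (m,) column means removed before projection.
    component_scores : (n, d) projections of the training data.
    explained_variance_fractions : (d,) non-increasing fractions in [0, 1].
    total_variance : total variance of the training data (sum over columns).
    """

    variable_ids: list[str]
    basis: np.ndarray
    means: np.ndarray
    component_scores: np.ndarray
    explained_variance_fractions: np.ndarray
    total_variance: float

    @property
    def d(self) -> int:
        return self.basis.shape[1]

    def project(self, view: DataMatrix) -> np.ndarray:
        """Project new subjects onto the training components (no refit)."""
        if view.variable_ids != self.variable_ids:
            raise ValueError("variables differ from the PCA training view")
        return (view.values - self.means) @ self.basis


def pca_reduce(view: DataMatrix, d: int) -> PcaModel:
    """Reduce ``view`` to its top-``d`` principal components.

    Requires ``1 <= d <= min(n - 1, m)``.  Components are ordered by
    explained variance; each basis vector's largest-magnitude element is
    made positive so the decomposition is reproducible.
    """
    x = view.values
    n, m = x.shape
    if not 1 <= d <= min(n - 1, m):
        raise ValueError(f"d={d} out of range for n={n}, m={m}")
    means = x.mean(axis=0)
    xc = x - means
    # SVD of the centred matrix: singular values give component variances.
    u, s, vt = linalg.svd(xc, full_matrices=False)
    basis = vt[:d].T
    # Deterministic sign: largest |weight| positive per component.
    flip = np.sign(basis[np.abs(basis).argmax(axis=0), np.arange(d)])
    flip[flip == 0] = 1.0
    basis = basis * flip
    scores = xc @ basis
    var = s**2 / (n - 1)
    total = var.sum()
    fractions = var[:d] / total if total > 0 else np.zeros(d)
    return PcaModel(list(view.variable_ids), basis, means, scores,
                    fractions, float(total))


@dataclass
class CcaModel:
    """Fitted CCA between two reduced views.

    ``u_weights`` / ``v_weights`` map centred reduced data to variates with
    unit sample variance; ``correlations`` holds the canonical correlations
    in non-increasing order; ``variates_x`` / ``variates_y`` are the
    training-sample scores (P_X, P_Y).
    """

    d: int
    u_weights: np.ndarray  # (d, d): column k = basis vector for mode k
    v_weights: np.ndarray
    correlations: np.ndarray
    variates_x: np.ndarray  # (n, d)
    variates_y: np.ndarray
    x_means: np.ndarray
    y_means: np.ndarray

    def transform(self, xd: np.ndarray, yd: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Variates for new reduced data using the training weights/centring."""
        xd = np.asarray(xd, dtype=float)
        yd = np.asarray(yd, dtype=float)
        if xd.shape[1] != self.d or yd.shape[1] != self.d:
            raise ValueError("reduced dimension differs from the fitted model")
        return (xd - self.x_means) @ self.u_weights, (yd - self.y_means) @ self.v_weights

    def flip_modes(self, signs: np.ndarray) -> "CcaModel":
        """Flip u, v, P_X and P_Y jointly per mode (signs in {-1, +1})."""
        s = np.asarray(signs, dtype=float)
        return CcaModel(
            self.d, self.u_weights * s, self.v_weights * s, self.correlations,
            self.variates_x * s, self.variates_y * s, self.x_means, self.y_means,
        )


def canonical_correlations(xd: np.ndarray, yd: np.ndarray) -> np.ndarray:
    """Canonical correlations only (no weights); fast path for permutations."""
    xc = xd - xd.mean(axis=0)
    yc = yd - yd.mean(axis=0)
    qx, _ = linalg.qr(xc, mode="economic")
    qy, _ = linalg.qr(yc, mode="economic")
    s = linalg.svd(qx.T @ qy, compute_uv=False)
    return np.clip(s, 0.0, 1.0)


def fit_cca(xd: np.ndarray, yd: np.ndarray) -> CcaModel:
    """Fit CCA on two n x d reduced views of the same subjects.

    Both views must have full column rank and n > d.  Variates are scaled
    to unit sample variance; within each view they are mutually
    uncorrelated, and the per-mode Pearson correlation between paired
    variates equals the canonical correlation.
    """
    xd = np.asarray(xd, dtype=float)
    yd = np.asarray(yd, dtype=float)
    if xd.ndim != 2 or yd.ndim != 2 or xd.shape[0] != yd.shape[0]:
        raise ValueError("views must be 2-D with equal subject counts")
    n, d = xd.shape
    if yd.shape[1] != d:
        raise ValueError("views must share the reduced dimension d")
    if n <= d:
        raise ValueError(f"need n > d (n={n}, d={d})")
    x_means = xd.mean(axis=0)
    y_means = yd.mean(axis=0)
    xc = xd - x_means
    yc = yd - y_means
    qx, rx = linalg.qr(xc, mode="economic")
    qy, ry = linalg.qr(yc, mode="economic")
    if np.abs(np.diag(rx)).min() < 1e-10 * max(np.abs(np.diag(rx)).max(), 1.0):
        raise ValueError("x view is rank deficient")
    if np.abs(np.diag(ry)).min() < 1e-10 * max(np.abs(np.diag(ry)).max(), 1.0):
        raise ValueError("y view is rank deficient")
    u, s, vt = linalg.svd(qx.T @ qy)
    corr = np.clip(s, 0.0, 1.0)
    # Weights solving R w = U give unit-norm Q-space variates; rescale to
    # unit sample variance.
    scale = np.sqrt(n - 1)
    u_w = linalg.solve_triangular(rx, u * scale)
    v_w = linalg.solve_triangular(ry, vt.T * scale)
    px = xc @ u_w
    py = yc @ v_w
    # Deterministic baseline sign: largest |v weight| positive per mode.
    flip = np.sign(v_w[np.abs(v_w).argmax(axis=0), np.arange(d)])
    flip[flip == 0] = 1.0
    model = CcaModel(d, u_w, v_w, corr, px, py, x_means, y_means)
    return model.flip_modes(flip)


def project(
    model: CcaModel,
    pca_x: PcaModel,
    pca_y: PcaModel,
    brain: DataMatrix,
    behaviour: DataMatrix,
) -> tuple[np.ndarray, np.ndarray]:
    """Out-of-sample variates: training PCA bases then training canonical
    weights, with no refitting.  Inputs must already be preprocessed with
    training-derived parameters."""
    if brain.subject_ids != behaviour.subject_ids:
        raise ValueError("views list different subjects")
    return model.transform(pca_x.project(brain), pca_y.project(behaviour))


def variable_loadings(view: DataMatrix, variates: np.ndarray) -> pd.DataFrame:
    """Pearson correlation of every (preprocessed) variable with each variate.

    Returns a variables x modes DataFrame of structure coefficients in
    [-1, 1]; columns are labelled ``mode1`` .. ``modeK``.
    """
    variates = np.asarray(variates, dtype=float)
    if variates.ndim == 1:
        variates = variates[:, None]
    if variates.shape[0] != view.n_subjects:
        raise ValueError("variates and view list different subject counts")
    x = view.values
    sd = x.std(axis=0, ddof=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        names = [view.variable_ids[i] for i in zero]
        raise ValueError(f"zero-variance variables have undefined loadings: {names}")
    xc = (x - x.mean(axis=0)) / sd
    vc = variates - variates.mean(axis=0)
    vsd = vc.std(axis=0, ddof=1)
    if (vsd == 0).any():
        raise ValueError("zero-variance variate")
    vc = vc / vsd
    load = xc.T @ vc / (x.shape[0] - 1)
    return pd.DataFrame(
        np.clip(load, -1.0, 1.0),
        index=view.variable_ids,
        columns=[f"mode{k + 1}" for k in range(variates.shape[1])],
    )


def fix_mode_signs(
    model: CcaModel, behaviour: DataMatrix
) -> tuple[CcaModel, np.ndarray]:
    """Re-sign each mode so the behavioural variable with the largest
    absolute loading has a positive loading (u/P_X flipped jointly with
    v/P_Y).  Returns the re-signed model and the signs applied."""
    loadings = variable_loadings(behaviour, model.variates_y).to_numpy()
    top = np.abs(loadings).argmax(axis=0)
    signs = np.sign(loadings[top, np.arange(loadings.shape[1])])
    signs[signs == 0] = 1.0
    return model.flip_modes(signs), signs
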