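"""Permutation inference for CCA modes and PCA dimensionality selection.

For a candidate dimensionality ``d``, both views are PCA-reduced once, CCA
is fit on the unpermuted data to obtain the true canonical correlations
``q``, and the rows of the reduced behaviour matrix are randomly permuted
``n_perm`` times, refitting CCA each time, to build the null matrix ``Q*``
(d x n_perm).  Mode ``i`` receives a family-wise-error corrected p-value by
the maximum-statistic rule: the true ``q_i`` is compared against the null
distribution of the FIRST (largest) permuted canonical correlation,

    p_fwe[i] = (1 + #{permutations: max q* >= q_i}) / (1 + n_perm),

which makes p_fwe non-decreasing across modes and controls the FWE over
modes.  With the add-one convention the smallest reportable p is
1/(n_perm + 1) -- "p < 0.0001" at 10000 permutations means zero
exceedances.

Model selection repeats this over a grid of candidate dimensionalities
(default {5, 10, 25, 50, 75, 100, 125, 150, 200}) and applies Bonferroni
correction over the grid to the first-mode p-values (0.05 / 9 = 0.0056 at
the default grid); the chosen ``d`` minimises the first-mode p among
significant candidates, ties broken by the smallest ``d``.

Because row permutation commutes with a fixed PCA projection, permuting
the reduced behaviour rows is equivalent to permuting the raw behaviour
rows before projection.

Nuisance handling.  When the same confound design has been regressed out
of both views, their residuals share the design's null space, which makes
naive row shuffling slightly liberal: the unpermuted views are aligned
within an (n - k)-dimensional subspace while permuted ones are not.  With
``design`` supplied, the permutation is therefore carried out in an
orthonormal basis of the design's null space (a Huh-Jhun-style
projection): the reduced views are mapped to (n - k)-row matrices whose
rows are exchangeable under the null, leaving the true canonical
correlations mathematically unchanged while restoring exact
family-wise-error control.  ``design=None`` gives the plain row shuffle
of the residualized behaviour matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .cca_core import PcaModel, fit_cca, pca_reduce
from .dataio import DataMatrix, DatasetBundle

#: Default candidate PCA dimensionalities (9 values; Bonferroni 0.05/9).
DEFAULT_CANDIDATE_DS = (5, 10, 25, 50, 75, 100, 125, 150, 200)
DEFAULT_N_PERM = 10000
DEFAULT_ALPHA = 0.05


@dataclass
class PermutationResult:
    """True canonical correlations, null matrix and FWE p-values at one d."""

    d: int
    true_correlations: np.ndarray  # (d,) the vector q
    null_matrix: np.ndarray        # (d, n_perm) the matrix Q*
    p_fwe: np.ndarray              # (d,)
    n_perm: int
    seed: int | None
    permutations: np.ndarray | None = None  # (n_perm, n) row-shuffle log

    def display_p(self, i: int) -> str:
        """Human-readable p for mode i: '< 1/(N+1)' when no exceedance."""
        floor = 1.0 / (self.n_perm + 1)
        if self.p_fwe[i] <= floor:
            return f"< {floor:.4g}"
        return f"{self.p_fwe[i]:.4g}"


@dataclass
class ModelSelectionResult:
    """Per-candidate first-mode p-values and the Bonferroni-selected d."""

    candidate_ds: list[int]
    first_mode_p: dict[int, float]
    bonferroni_alpha: float       # per-candidate threshold alpha/len(grid)
    chosen_d: int | None          # None when no candidate is significant
    results: dict[int, PermutationResult] = field(default_factory=dict)

    @property
    def any_significant(self) -> bool:
        return self.chosen_d is not None


def nuisance_null_basis(design: np.ndarray) -> np.ndarray:
    """Orthonormal basis (n x (n - k)) of the null space of an intercept-
    augmented confound design, for permutation in the exchangeable
    residual space."""
    design = np.asarray(design, dtype=float)
    if design.ndim != 2:
        raise ValueError("design must be 2-D (subjects x confounds)")
    full = np.column_stack([np.ones(len(design)), design])
    basis = linalg.null_space(full.T)
    if basis.shape[1] == 0:
        raise ValueError("confound design leaves no residual degrees of freedom")
    return basis


def permutation_pvalues(
    x: DataMatrix | np.ndarray,
    y: DataMatrix | np.ndarray,
    d: int,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    keep_permutations: bool = False,
    design: np.ndarray | None = None,
) -> PermutationResult:
    """Max-statistic FWE p-values for the d CCA modes of two views.

    ``x`` and ``y`` are preprocessed views (or already-reduced arrays with
    exactly d columns).  PCA is computed once on the unpermuted data; each
    permutation uniformly shuffles the rows of the reduced behaviour
    matrix only (the brain view stays fixed) and CCA is refit.

    ``design`` (subjects x confounds, no intercept column) switches the
    shuffle to the confound null space, which is exact when the same
    design was regressed out of both views; the true correlations are
    identical either way (see the module docstring).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    xd = _reduce(x, d)
    yd = _reduce(y, d)
    n = xd.shape[0]
    model = fit_cca(xd, yd)
    q = model.correlations

    if rng is None:
        rng = np.random.default_rng(seed)
    if design is None:
        # Permuting Y's rows permutes the rows of its centred QR factor, so
        # the permuted canonical correlations are singular values of
        # Qx' P Qy.
        xc = xd - xd.mean(axis=0)
        yc = yd - yd.mean(axis=0)
        qx, _ = linalg.qr(xc, mode="economic")
        qy, _ = linalg.qr(yc, mode="economic")
    else:
        # Residual-space (Huh-Jhun style) shuffle: map both reduced views
        # into the (n - k)-dimensional null space of the design.  The
        # reduced views already live in that space column-wise (they were
        # residualized), so the uncentred canonical correlations of the
        # transformed views equal the centred ones of the originals.
        basis = nuisance_null_basis(design)
        if basis.shape[0] != n:
            raise ValueError("design rows do not match the number of subjects")
        n = basis.shape[1]
        if n <= d:
            raise ValueError(
                f"only {n} residual degrees of freedom for d={d} modes"
            )
        qx, _ = linalg.qr(basis.T @ xd, mode="economic")
        qy, _ = linalg.qr(basis.T @ yd, mode="economic")
    null = np.empty((d, n_perm))
    perms = np.empty((n_perm, n), dtype=np.int64) if keep_permutations else None
    for b in range(n_perm):
        perm = rng.permutation(n)
        if perms is not None:
            perms[b] = perm
        s = linalg.svd(qx.T @ qy[perm], compute_uv=False)
        null[:, b] = np.clip(s, 0.0, 1.0)
    max_null = null[0]  # ordered: row 0 is each permutation's largest
    exceed = (max_null[None, :] >= q[:, None]).sum(axis=1)
    p_fwe = (1.0 + exceed) / (1.0 + n_perm)
    return PermutationResult(d, q, null, p_fwe, n_perm, seed, perms)


def _reduce(view: DataMatrix | np.ndarray, d: int) -> np.ndarray:
    if isinstance(view, DataMatrix):
        return pca_reduce(view, d).component_scores
    arr = np.asarray(view, dtype=float)
    if arr.shape[1] != d:
        raise ValueError(f"pre-reduced view has {arr.shape[1]} columns, expected d={d}")
    return arr


def significant_modes(
    result: PermutationResult, alpha: float = DEFAULT_ALPHA
) -> list[int]:
    """0-based indices of modes with p_fwe < alpha.

    Because p_fwe is non-decreasing in the mode index, the output is
    always a contiguous prefix of the modes.
    """
    return [i for i, p in enumerate(result.p_fwe) if p < alpha]


def select_pca_dimension(
    bundle: DatasetBundle,
    candidate_ds: tuple[int, ...] | list[int] = DEFAULT_CANDIDATE_DS,
    n_perm: int = DEFAULT_N_PERM,
    alpha: float = DEFAULT_ALPHA,
    seed: int | None = None,
    keep_null: bool = True,
    nuisance: str = "project",
) -> ModelSelectionResult:
    """Choose the PCA dimensionality by Bonferroni-corrected permutation tests.

    For each candidate d the first-mode FWE p-value is computed with
    :func:`permutation_pvalues`; candidates with p <= alpha/len(grid) are
    significant, and the chosen d attains the minimal p (smallest d on
    ties).  A result with no significant candidate sets ``chosen_d`` to
    None rather than raising.

    ``nuisance="project"`` (default) permutes in the null space of the
    bundle's confound design, which keeps the test exact after confound
    regression; ``nuisance="naive"`` shuffles residualized rows directly.
    """
    candidate_ds = sorted(int(d) for d in candidate_ds)
    if not candidate_ds:
        raise ValueError("empty candidate grid")
    if nuisance not in ("project", "naive"):
        raise ValueError("nuisance must be 'project' or 'naive'")
    n = bundle.n_subjects
    for d in candidate_ds:
        if d >= n or d > min(bundle.brain.n_variables, bundle.behaviour.n_variables):
            raise ValueError(f"candidate d={d} invalid for data of size n={n}")
    design = None
    if nuisance == "project":
        from .preprocess import confound_design

        design = confound_design(bundle.confounds).to_numpy(dtype=float)
    threshold = alpha / len(candidate_ds)
    ss = np.random.SeedSequence(seed) if seed is not None else np.random.SeedSequence()
    children = ss.spawn(len(candidate_ds))
    first_p: dict[int, float] = {}
    results: dict[int, PermutationResult] = {}
    for d, child in zip(candidate_ds, children):
        res = permutation_pvalues(
            bundle.brain, bundle.behaviour, d, n_perm,
            rng=np.random.default_rng(child),
            design=design,
        )
        res.seed = seed
        first_p[d] = float(res.p_fwe[0])
        if keep_null:
            results[d] = res
    significant = [d for d in candidate_ds if first_p[d] <= threshold]
    chosen = min(significant, key=lambda d: (first_p[d], d)) if significant else None
    return ModelSelectionResult(candidate_ds, first_p, threshold, chosen, results)
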