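"""Multiple hold-out validation of CCA modes.

The permutation framework assesses significance in-sample; the hold-out
framework asks whether a mode generalises.  Subjects are repeatedly split
into training and test sets.  Per split, every data-dependent parameter
-- near-constant filtering, imputation medians, confound betas,
standardization, the PCA bases and the canonical weights -- is estimated
on training subjects only; test subjects are pushed through those frozen
transforms, and the out-of-sample canonical correlation of the first mode
is tested by permuting the test-set behaviour scores.  The omnibus
decision Bonferroni-corrects over splits: the model generalises iff the
minimal per-split p-value is below alpha / n_splits.

Split count, test fraction and the per-split permutation count are
configurable; the defaults (10 splits, 20% test, 1000 permutations)
follow the structure of the multiple hold-out framework for two-view
latent-variable models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cca_core import fit_cca, pca_reduce, project
from .dataio import DatasetBundle
from .perm_inference import select_pca_dimension
from .preprocess import PreprocessConfig, exclude_high_motion_subjects, fit_preprocess

DEFAULT_N_SPLITS = 10
DEFAULT_TEST_FRACTION = 0.2
DEFAULT_N_PERM = 1000


@dataclass
class SplitPlan:
    """Reproducible train/test subject assignments."""

    n_splits: int
    test_fraction: float
    seed: int | None
    train_ids: list[list[str]]
    test_ids: list[list[str]]

    def test_membership_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for ids in self.test_ids:
            for s in ids:
                counts[s] = counts.get(s, 0) + 1
        return counts


@dataclass
class SplitResult:
    split: int
    chosen_d: int
    train_correlation: float
    test_correlation: float
    p_value: float
    n_train: int
    n_test: int


@dataclass
class HoldoutResult:
    """Per-split results and the Bonferroni omnibus decision."""

    splits: list[SplitResult]
    alpha: float
    omnibus_p: float        # min per-split p times n_splits, capped at 1
    significant: bool       # min p < alpha / n_splits
    plan: SplitPlan | None = None
    extras: dict = field(default_factory=dict)

    @property
    def test_correlations(self) -> np.ndarray:
        return np.array([s.test_correlation for s in self.splits])


def make_splits(
    subject_ids: list[str],
    n_splits: int = DEFAULT_N_SPLITS,
    test_fraction: float = DEFAULT_TEST_FRACTION,
    seed: int | None = None,
) -> SplitPlan:
    """Draw ``n_splits`` independent random train/test splits.

    ``test_fraction`` must lie in (0, 0.5); each split holds out
    round(test_fraction * n) subjects.  Same seed, same plan.
    """
    if not 0 < test_fraction < 0.5:
        raise ValueError("test_fraction must be in (0, 0.5)")
    if n_splits < 1:
        raise ValueError("n_splits must be >= 1")
    n = len(subject_ids)
    n_test = int(round(test_fraction * n))
    if n_test < 1 or n - n_test < 2:
        raise ValueError(f"too few subjects (n={n}) for test_fraction={test_fraction}")
    rng = np.random.default_rng(seed)
    train_ids, test_ids = [], []
    ids = np.array(subject_ids)
    for _ in range(n_splits):
        perm = rng.permutation(n)
        test = sorted(ids[perm[:n_test]].tolist())
        train = sorted(ids[perm[n_test:]].tolist())
        train_ids.append(train)
        test_ids.append(test)
    return SplitPlan(n_splits, test_fraction, seed, train_ids, test_ids)


def holdout_run(
    bundle: DatasetBundle,
    candidate_ds: list[int] | tuple[int, ...],
    split_plan: SplitPlan | None = None,
    n_perm: int = DEFAULT_N_PERM,
    alpha: float = 0.05,
    seed: int | None = None,
    n_splits: int = DEFAULT_N_SPLITS,
    test_fraction: float = DEFAULT_TEST_FRACTION,
    selection_n_perm: int | None = None,
    preprocess_config: PreprocessConfig | None = None,
) -> HoldoutResult:
    """Run the multiple hold-out validation on a raw bundle.

    Motion QC (a pure per-subject rule) is applied once up front; splits
    are drawn over retained subjects.  Per split the remaining
    preprocessing, the candidate-d selection (training-data permutation
    test; skipped for a single candidate) and the CCA fit all see training
    subjects only.  The per-split p-value permutes the TEST behaviour
    scores ``n_perm`` times and compares the permuted first-mode
    correlation against the observed one (add-one convention).
    """
    candidate_ds = [int(d) for d in candidate_ds]
    if not candidate_ds:
        raise ValueError("need at least one candidate d")
    ss = np.random.SeedSequence(seed) if seed is not None else np.random.SeedSequence()
    plan_seed_ss, *rest = ss.spawn(1 + 2)
    sel_ss, perm_ss = rest

    mask, _ = exclude_high_motion_subjects(
        bundle.confounds,
        preprocess_config.max_fd_cut if preprocess_config else 1.3,
        preprocess_config.mean_fd_cut if preprocess_config else 0.3,
    )
    retained = [s for s, ok in zip(bundle.subject_ids, mask) if ok]
    bundle = bundle.subset_subjects(retained)

    if split_plan is None:
        split_plan = make_splits(
            bundle.subject_ids, n_splits, test_fraction,
            seed=int(plan_seed_ss.generate_state(1)[0] % (2**31)),
        )
    sel_children = sel_ss.spawn(split_plan.n_splits)
    perm_children = perm_ss.spawn(split_plan.n_splits)

    results: list[SplitResult] = []
    for k, (train, test) in enumerate(zip(split_plan.train_ids, split_plan.test_ids)):
        train_bundle = bundle.subset_subjects(train)
        test_bundle = bundle.subset_subjects(test)
        processed_train, model, _ = fit_preprocess(train_bundle, preprocess_config)
        processed_test = model.transform(test_bundle)

        if len(candidate_ds) > 1:
            sel = select_pca_dimension(
                processed_train, candidate_ds,
                n_perm=selection_n_perm or max(n_perm // 2, 100),
                alpha=alpha,
                seed=int(sel_children[k].generate_state(1)[0] % (2**31)),
                keep_null=False,
            )
            d = sel.chosen_d if sel.chosen_d is not None else min(
                sel.candidate_ds, key=lambda dd: (sel.first_mode_p[dd], dd)
            )
        else:
            d = candidate_ds[0]

        pca_x = pca_reduce(processed_train.brain, d)
        pca_y = pca_reduce(processed_train.behaviour, d)
        cca = fit_cca(pca_x.component_scores, pca_y.component_scores)
        px_t, py_t = project(
            cca, pca_x, pca_y, processed_test.brain, processed_test.behaviour
        )
        obs = float(np.corrcoef(px_t[:, 0], py_t[:, 0])[0, 1])

        rng = np.random.default_rng(perm_children[k])
        n_test_subj = px_t.shape[0]
        exceed = 0
        for _ in range(n_perm):
            perm = rng.permutation(n_test_subj)
            if np.corrcoef(px_t[:, 0], py_t[perm, 0])[0, 1] >= obs:
                exceed += 1
        p = (1.0 + exceed) / (1.0 + n_perm)

        results.append(
            SplitResult(
                k, d,
                float(cca.correlations[0]), obs, p,
                len(train), len(test),
            )
        )

    min_p = min(r.p_value for r in results)
    omnibus_p = min(min_p * split_plan.n_splits, 1.0)
    significant = min_p < alpha / split_plan.n_splits
    return HoldoutResult(results, alpha, omnibus_p, significant, split_plan)
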