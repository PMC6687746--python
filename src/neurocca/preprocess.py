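"""Quality control and preprocessing of the two views.

Implements the study's stated rules:

* regional time-series -> Pearson connectivity;
* exclusion of regions with low mean signal in at least one subject
  (within-subject z-score across regions, z < -1.96);
* exclusion of high-motion subjects (max FD > 1.3 mm or mean FD > 0.3 mm);
* removal of near-constant behaviour items (modal value shared by more
  than 95% of subjects);
* median imputation of missing behaviour entries;
* one-hot site coding, OLS confound regression (mean FD + site) and
  per-variable standardization (mu = 0, sigma = 1).

The pipeline order is: subject motion exclusion, near-constant filtering
on observed values, median imputation, confound regression,
standardization.  ``PreprocessModel`` separates parameter estimation
(fit, training subjects only) from application (transform), so the
hold-out workflow never leaks test-set statistics into training.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dataclass_field
from pathlib import Path

import numpy as np
import pandas as pd

from .dataio import ConfoundTable, ConnectivityProfile, DataMatrix, DatasetBundle

# Default thresholds (configurable; these are the study's values).
Z_CUT = -1.96          # within-subject z-score below which a region is excluded
MAX_FD_CUT = 1.3       # mm, maximum framewise displacement
MEAN_FD_CUT = 0.3      # mm, mean framewise displacement
MODAL_SHARE_CUT = 0.95  # modal share above which an item is near-constant


@dataclass
class QcReport:
    """Machine-readable record of every exclusion and imputation."""

    excluded_regions: list[str] = dataclass_field(default_factory=list)
    excluded_subjects: list[dict] = dataclass_field(default_factory=list)
    removed_variables: list[str] = dataclass_field(default_factory=list)
    imputation_counts: dict[str, int] = dataclass_field(default_factory=dict)
    notes: list[str] = dataclass_field(default_factory=list)

    def merge(self, other: "QcReport") -> "QcReport":
        return QcReport(
            self.excluded_regions + other.excluded_regions,
            self.excluded_subjects + other.excluded_subjects,
            self.removed_variables + other.removed_variables,
            {**self.imputation_counts, **other.imputation_counts},
            self.notes + other.notes,
        )

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(self.__dict__, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(payload + "\n")
        return payload


# ---------------------------------------------------------------------------
# Connectivity from time-series


def compute_connectivity(
    timeseries: np.ndarray, region_ids: list[str] | None = None
) -> ConnectivityProfile:
    """Pairwise Pearson correlation between regional time-series.

    Parameters
    ----------
    timeseries : ndarray of shape (T, r)
        T time points for r regions; T >= 3 and no region constant in time.
    """
    ts = np.asarray(timeseries, dtype=float)
    if ts.ndim != 2 or ts.shape[0] < 3:
        raise ValueError("timeseries must be T x r with T >= 3")
    r = ts.shape[1]
    if region_ids is None:
        region_ids = [f"region{i + 1}" for i in range(r)]
    sd = ts.std(axis=0)
    constant = np.flatnonzero(sd == 0)
    if constant.size:
        names = [region_ids[i] for i in constant]
        raise ValueError(f"constant time-series (undefined correlation): {names}")
    corr = np.corrcoef(ts, rowvar=False)
    np.fill_diagonal(corr, 1.0)
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)  # round-off hygiene only
    return ConnectivityProfile(corr, region_ids)


# ---------------------------------------------------------------------------
# Exclusion rules


def exclude_low_signal_regions(
    mean_signals: DataMatrix, z_cut: float = Z_CUT
) -> tuple[np.ndarray, QcReport]:
    """Flag regions whose within-subject z-score falls below ``z_cut``.

    For each subject the regional mean signals are z-scored across regions
    (sample SD, ddof=1); a region is excluded iff its z-score is strictly
    below ``z_cut`` for at least one subject.  Subjects with zero variance
    across regions contribute no exclusions (logged).

    Returns
    -------
    keep : boolean mask over regions (True = retained)
    report : QcReport
    """
    x = mean_signals.values
    if x.shape[1] < 2:
        raise ValueError("need at least 2 regions")
    report = QcReport()
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    degenerate = sd[:, 0] == 0
    if degenerate.any():
        for sid in np.array(mean_signals.subject_ids)[degenerate]:
            report.notes.append(
                f"subject {sid}: zero variance across regions; no exclusions contributed"
            )
    sd_safe = np.where(sd == 0, 1.0, sd)
    z = (x - mu) / sd_safe
    z[degenerate, :] = 0.0
    flagged = (z < z_cut).any(axis=0)
    report.excluded_regions = [
        v for v, f in zip(mean_signals.variable_ids, flagged) if f
    ]
    return ~flagged, report


def exclude_high_motion_subjects(
    confounds: ConfoundTable,
    max_cut: float = MAX_FD_CUT,
    mean_cut: float = MEAN_FD_CUT,
) -> tuple[np.ndarray, QcReport]:
    """Flag subjects with max FD > ``max_cut`` or mean FD > ``mean_cut``.

    Both comparisons are strict ("larger than"), so a subject at exactly
    the threshold is retained.
    """
    report = QcReport()
    max_bad = confounds.max_fd > max_cut
    mean_bad = confounds.mean_fd > mean_cut
    for i, sid in enumerate(confounds.subject_ids):
        if max_bad[i] or mean_bad[i]:
            reasons = []
            if max_bad[i]:
                reasons.append(f"max_fd {confounds.max_fd[i]:g} > {max_cut:g} mm")
            if mean_bad[i]:
                reasons.append(f"mean_fd {confounds.mean_fd[i]:g} > {mean_cut:g} mm")
            report.excluded_subjects.append(
                {"subject_id": sid, "reason": "high_motion", "detail": "; ".join(reasons)}
            )
    return ~(max_bad | mean_bad), report


# ---------------------------------------------------------------------------
# Behaviour-table preparation


def _modal_share(col: np.ndarray) -> float:
    """Share of the most common value among non-missing entries."""
    observed = col[~np.isnan(col)]
    if observed.size == 0:
        return 1.0
    _, counts = np.unique(observed, return_counts=True)
    return counts.max() / observed.size


def filter_near_constant(
    table: DataMatrix, share_cut: float = MODAL_SHARE_CUT
) -> tuple[DataMatrix, QcReport]:
    """Drop variables whose modal value's share strictly exceeds ``share_cut``.

    The share is computed over non-missing entries; a column with exactly
    95 of 100 identical values is retained at the default cut.
    """
    if table.n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    report = QcReport()
    keep: list[str] = []
    for j, vid in enumerate(table.variable_ids):
        if _modal_share(table.values[:, j]) > share_cut:
            report.removed_variables.append(vid)
        else:
            keep.append(vid)
    return table.subset_variables(keep), report


def impute_median(table: DataMatrix) -> tuple[DataMatrix, QcReport]:
    """Replace missing entries with the per-variable median of observed values.

    The even-count median is the mean of the two middle values.  A fully
    missing variable is an error.
    """
    values = table.values.copy()
    report = QcReport()
    for j, vid in enumerate(table.variable_ids):
        col = values[:, j]
        missing = np.isnan(col)
        if missing.all():
            raise ValueError(f"variable {vid} has no observed values to impute from")
        if missing.any():
            col[missing] = np.median(col[~missing])
            report.imputation_counts[vid] = int(missing.sum())
    return (
        DataMatrix(values, table.subject_ids, table.variable_ids, allow_missing=False),
        report,
    )


# ---------------------------------------------------------------------------
# Confounds


def one_hot_site(
    confounds: ConfoundTable, label_order: list[str] | None = None
) -> pd.DataFrame:
    """One-hot encode the site label, one column per level in ``label_order``.

    With order [CBU, WBIC, UCL] a London/UCL subject becomes [0, 0, 1].
    """
    if label_order is None:
        label_order = list(confounds.site_levels)
    unseen = set(confounds.site) - set(label_order)
    if unseen:
        raise ValueError(f"site labels not in label_order: {sorted(unseen)}")
    cols = {
        f"site_{lab}": (np.array(confounds.site) == lab).astype(float)
        for lab in label_order
    }
    return pd.DataFrame(cols, index=confounds.subject_ids)


def confound_design(
    confounds: ConfoundTable,
    label_order: list[str] | None = None,
    drop_last_site: bool = True,
) -> pd.DataFrame:
    """Mean-FD plus one-hot site design matrix (no intercept column).

    The last one-hot column is dropped by default so the design stays
    full-rank once the regression adds an intercept.
    """
    sites = one_hot_site(confounds, label_order)
    if drop_last_site and sites.shape[1] > 1:
        sites = sites.iloc[:, :-1]
    design = pd.concat(
        [pd.DataFrame({"mean_fd": confounds.mean_fd}, index=confounds.subject_ids), sites],
        axis=1,
    )
    return design


@dataclass
class ConfoundRegression:
    """OLS confound removal with an intercept; fit on train, apply anywhere."""

    confound_ids: list[str]
    betas: np.ndarray  # (n_confounds + 1) x n_variables, row 0 = intercept

    @classmethod
    def fit(cls, data: DataMatrix, design: pd.DataFrame) -> "ConfoundRegression":
        if list(design.index) != data.subject_ids:
            raise ValueError("design subjects do not match data subjects")
        c = design.to_numpy(dtype=float)
        design_mat = np.column_stack([np.ones(len(c)), c])
        rank = np.linalg.matrix_rank(design_mat)
        if rank < design_mat.shape[1]:
            raise ValueError(
                "confound design is rank-deficient with an intercept; "
                "drop a redundant one-hot column"
            )
        betas, *_ = np.linalg.lstsq(design_mat, data.values, rcond=None)
        return cls(list(design.columns), betas)

    def transform(self, data: DataMatrix, design: pd.DataFrame) -> DataMatrix:
        if list(design.columns) != self.confound_ids:
            raise ValueError("design columns differ from the fitted confounds")
        if list(design.index) != data.subject_ids:
            raise ValueError("design subjects do not match data subjects")
        c = design.to_numpy(dtype=float)
        design_mat = np.column_stack([np.ones(len(c)), c])
        resid = data.values - design_mat @ self.betas
        return DataMatrix(resid, data.subject_ids, data.variable_ids)


def regress_confounds(data: DataMatrix, design: pd.DataFrame) -> DataMatrix:
    """Per-variable OLS residuals after regressing out the confound design
    (with intercept).  Residuals are orthogonal to every confound column."""
    return ConfoundRegression.fit(data, design).transform(data, design)


# ---------------------------------------------------------------------------
# Standardization


@dataclass
class Standardizer:
    """Column-wise mean-centring and unit-variance scaling (sample SD)."""

    variable_ids: list[str]
    means: np.ndarray
    sds: np.ndarray

    @classmethod
    def fit(cls, data: DataMatrix) -> "Standardizer":
        if np.isnan(data.values).any():
            raise ValueError("standardize requires complete data")
        means = data.values.mean(axis=0)
        sds = data.values.std(axis=0, ddof=1)
        zero = np.flatnonzero(sds == 0)
        if zero.size:
            names = [data.variable_ids[i] for i in zero]
            raise ValueError(f"zero-variance variables cannot be standardized: {names}")
        return cls(list(data.variable_ids), means, sds)

    def transform(self, data: DataMatrix) -> DataMatrix:
        if data.variable_ids != self.variable_ids:
            raise ValueError("variables differ from the fitted standardizer")
        return DataMatrix(
            (data.values - self.means) / self.sds, data.subject_ids, data.variable_ids
        )


def standardize(data: DataMatrix) -> DataMatrix:
    """Mean-centre and scale every column to unit sample variance."""
    return Standardizer.fit(data).transform(data)


# ---------------------------------------------------------------------------
# Full pipeline


@dataclass
class PreprocessConfig:
    z_cut: float = Z_CUT
    max_fd_cut: float = MAX_FD_CUT
    mean_fd_cut: float = MEAN_FD_CUT
    modal_share_cut: float = MODAL_SHARE_CUT
    site_label_order: list[str] | None = None


@dataclass
class PreprocessModel:
    """All training-derived preprocessing parameters, applied as one transform."""

    config: PreprocessConfig
    behaviour_variables: list[str]
    behaviour_medians: dict[str, float]
    brain_regression: ConfoundRegression
    behaviour_regression: ConfoundRegression
    brain_standardizer: Standardizer
    behaviour_standardizer: Standardizer

    def transform(self, bundle: DatasetBundle) -> DatasetBundle:
        """Apply training-derived filtering, imputation, confound betas and
        scaling to new subjects (no refitting)."""
        behaviour = bundle.behaviour.subset_variables(self.behaviour_variables)
        values = behaviour.values.copy()
        for j, vid in enumerate(behaviour.variable_ids):
            missing = np.isnan(values[:, j])
            if missing.any():
                values[missing, j] = self.behaviour_medians[vid]
        behaviour = DataMatrix(values, behaviour.subject_ids, behaviour.variable_ids)
        design = confound_design(bundle.confounds, self.config.site_label_order)
        brain = self.brain_regression.transform(bundle.brain, design)
        behaviour = self.behaviour_regression.transform(behaviour, design)
        brain = self.brain_standardizer.transform(brain)
        behaviour = self.behaviour_standardizer.transform(behaviour)
        return DatasetBundle(brain, behaviour, bundle.confounds)


def fit_preprocess(
    bundle: DatasetBundle, config: PreprocessConfig | None = None
) -> tuple[DatasetBundle, PreprocessModel, QcReport]:
    """Fit the preprocessing pipeline on ``bundle`` and return its transform
    of the same subjects, the fitted parameters, and the QC report.

    Order: motion subject exclusion -> near-constant filtering (observed
    values) -> median imputation -> confound regression -> standardization.
    """
    if config is None:
        config = PreprocessConfig()
    subj_mask, motion_report = exclude_high_motion_subjects(
        bundle.confounds, config.max_fd_cut, config.mean_fd_cut
    )
    kept = [s for s, ok in zip(bundle.subject_ids, subj_mask) if ok]
    if not kept:
        raise ValueError("all subjects excluded for motion")
    bundle = bundle.subset_subjects(kept)

    behaviour, filter_report = filter_near_constant(
        bundle.behaviour, config.modal_share_cut
    )
    behaviour, impute_report = impute_median(behaviour)
    medians = {
        vid: float(np.median(behaviour.values[:, j]))
        for j, vid in enumerate(behaviour.variable_ids)
    }

    design = confound_design(bundle.confounds, config.site_label_order)
    brain_reg = ConfoundRegression.fit(bundle.brain, design)
    behav_reg = ConfoundRegression.fit(behaviour, design)
    brain = brain_reg.transform(bundle.brain, design)
    behaviour_r = behav_reg.transform(behaviour, design)

    brain_std = Standardizer.fit(brain)
    behav_std = Standardizer.fit(behaviour_r)
    processed = DatasetBundle(
        brain_std.transform(brain),
        behav_std.transform(behaviour_r),
        bundle.confounds,
    )
    model = PreprocessModel(
        config, list(behaviour.variable_ids), medians,
        brain_reg, behav_reg, brain_std, behav_std,
    )
    report = motion_report.merge(filter_report).merge(impute_report)
    return processed, model, report


def preprocess_pipeline(
    bundle: DatasetBundle, config: PreprocessConfig | None = None
) -> tuple[DatasetBundle, QcReport]:
    """Convenience wrapper around :func:`fit_preprocess` returning only the
    processed bundle and QC report (parameters fit on the full sample, as in
    the permutation workflow)."""
    processed, _, report = fit_preprocess(bundle, config)
    return processed, report
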