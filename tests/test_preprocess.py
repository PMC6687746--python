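import numpy as np
import pandas as pd
import pytest
from oracles import pairwise_pearson

from neurocca import (
    ConfoundTable,
    DataMatrix,
    compute_connectivity,
    exclude_high_motion_subjects,
    exclude_low_signal_regions,
    filter_near_constant,
    impute_median,
    one_hot_site,
    preprocess_pipeline,
    regress_confounds,
    standardize,
)
from neurocca.preprocess import confound_design


def dm(values, prefix="v", allow_missing=False):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    return DataMatrix(
        values,
        [f"s{i+1}" for i in range(values.shape[0])],
        [f"{prefix}{j+1}" for j in range(values.shape[1])],
        allow_missing=allow_missing,
    )


class TestComputeConnectivity:
    def test_identical_and_negated_series(self, rng):
        base = rng.standard_normal(50)
        ts = np.column_stack([base, base, -base])
        prof = compute_connectivity(ts)
        assert prof.matrix[0, 1] == pytest.approx(1.0)
        assert prof.matrix[0, 2] == pytest.approx(-1.0)

    def test_matches_per_pair_pearson_oracle(self, rng):
        ts = rng.standard_normal((40, 5))
        prof = compute_connectivity(ts)
        assert np.allclose(prof.matrix, pairwise_pearson(ts), atol=1e-12)

    def test_constant_series_names_region(self, rng):
        ts = rng.standard_normal((20, 3))
        ts[:, 1] = 2.5
        with pytest.raises(ValueError, match="region2"):
            compute_connectivity(ts)

    def test_too_few_timepoints(self, rng):
        with pytest.raises(ValueError, match="T >= 3"):
            compute_connectivity(rng.standard_normal((2, 4)))


class TestLowSignalRegions:
    def test_hand_computed_outlier_region(self):
        # z of the low region is (0 - 50/6) / sd ~ -2.04 < -1.96 (sample SD)
        signals = dm([[10, 10, 10, 10, 10, 0]], prefix="r")
        keep, report = exclude_low_signal_regions(signals)
        assert report.excluded_regions == ["r6"]
        assert keep.sum() == 5

    def test_flag_requires_single_subject_only(self, rng):
        # region dips below the cut for one subject out of many
        signals = np.full((5, 10), 100.0) + rng.normal(0, 1, (5, 10))
        signals[2, 7] = 0.0
        keep, report = exclude_low_signal_regions(dm(signals, prefix="r"))
        assert "r8" in report.excluded_regions

    def test_degenerate_subject_contributes_nothing(self):
        signals = dm([[5.0, 5.0, 5.0]], prefix="r")
        keep, report = exclude_low_signal_regions(signals)
        assert keep.all()
        assert any("zero variance" in n for n in report.notes)

    def test_parcellation_scale_accounting(self, rng):
        # 376 regions; exactly 28 planted low-signal regions -> 348 retained
        # uniform signals keep natural z-scores above -sqrt(3) ~ -1.73, so
        # only the planted regions can cross -1.96
        n_subj, n_reg = 20, 376
        signals = rng.uniform(90, 110, (n_subj, n_reg))
        low = rng.choice(n_reg, size=28, replace=False)
        for k, r in enumerate(low):
            signals[k % n_subj, r] = 0.0  # far below -1.96 SDs
        keep, report = exclude_low_signal_regions(dm(signals, prefix="r"))
        assert keep.sum() == 348
        assert len(report.excluded_regions) == 28


class TestMotionExclusion:
    @pytest.mark.parametrize(
        "mean_fd,max_fd,excluded",
        [
            (0.1, 1.4, True),    # max above 1.3 mm
            (0.1, 1.3, False),   # exactly at threshold: retained (strict >)
            (0.31, 0.5, True),   # mean above 0.3 mm
            (0.3, 0.5, False),   # exactly at threshold: retained
        ],
    )
    def test_strict_thresholds(self, mean_fd, max_fd, excluded):
        table = ConfoundTable(["s1"], [mean_fd], [max_fd], ["A"])
        keep, report = exclude_high_motion_subjects(table)
        assert keep[0] != excluded
        assert bool(report.excluded_subjects) == excluded

    def test_reason_codes_recorded(self):
        table = ConfoundTable(["s1", "s2"], [0.5, 0.1], [0.6, 2.0], ["A", "A"])
        _, report = exclude_high_motion_subjects(table)
        reasons = {e["subject_id"]: e["detail"] for e in report.excluded_subjects}
        assert "mean_fd" in reasons["s1"] and "max_fd" in reasons["s2"]


class TestNearConstantFilter:
    def test_strictly_greater_than_cut(self):
        col_at_cut = np.r_[np.zeros(95), np.arange(1, 6)]      # share exactly 0.95
        col_above = np.r_[np.zeros(96), np.arange(1, 5)]       # share 0.96
        table = dm(np.column_stack([col_at_cut, col_above]))
        filtered, report = filter_near_constant(table)
        assert filtered.variable_ids == ["v1"]
        assert report.removed_variables == ["v2"]

    def test_all_constant_column_removed(self):
        table = dm(np.column_stack([np.arange(10), np.full(10, 3.0)]))
        filtered, report = filter_near_constant(table)
        assert report.removed_variables == ["v2"]

    def test_share_uses_observed_values_only(self):
        # 19 identical of 20 observed (0.95, kept) vs 20 of 21 (>0.95 among
        # observed once the missing entry is ignored)
        col = np.r_[np.zeros(20), 1.0, np.nan]
        table = dm(np.column_stack([col]), allow_missing=True)
        _, report = filter_near_constant(table)
        assert report.removed_variables == ["v1"]

    def test_study_scale_counts(self, rng):
        n = 306
        cols = [rng.normal(size=n) for _ in range(364)]
        for _ in range(8):
            c = np.zeros(n)
            c[rng.choice(n, 3, replace=False)] = 1.0
            cols.append(c)
        table = dm(np.column_stack(cols))
        filtered, report = filter_near_constant(table)
        assert table.n_variables == 372
        assert filtered.n_variables == 364
        assert len(report.removed_variables) == 8


class TestImputeMedian:
    def test_odd_count_median(self):
        table = dm(np.array([[1.0], [2.0], [np.nan], [4.0]]), allow_missing=True)
        out, report = impute_median(table)
        assert out.values[2, 0] == 2.0
        assert report.imputation_counts == {"v1": 1}

    def test_even_count_mean_of_middle_two(self):
        col = np.r_[1.0, 2.0, 3.0, 4.0, np.nan]
        out, _ = impute_median(dm(col[:, None], allow_missing=True))
        assert out.values[4, 0] == 2.5

    def test_complete_column_unchanged(self):
        table = dm(np.arange(6.0)[:, None])
        out, report = impute_median(table)
        assert np.array_equal(out.values, table.values)
        assert report.imputation_counts == {}

    def test_fully_missing_column_error(self):
        table = dm(np.full((3, 1), np.nan), allow_missing=True)
        with pytest.raises(ValueError, match="no observed values"):
            impute_median(table)


class TestOneHotSite:
    def test_london_encoding(self):
        table = ConfoundTable(
            ["s1"], [0.1], [0.2], ["UCL"], site_levels=["CBU", "WBIC", "UCL"]
        )
        cols = one_hot_site(table, ["CBU", "WBIC", "UCL"])
        assert cols.loc["s1"].tolist() == [0.0, 0.0, 1.0]

    def test_rows_sum_to_one(self, rng):
        sites = list(rng.choice(["A", "B", "C"], size=30))
        table = ConfoundTable([f"s{i}" for i in range(30)], np.full(30, 0.1),
                              np.full(30, 0.2), sites)
        cols = one_hot_site(table, ["A", "B", "C"])
        assert (cols.sum(axis=1) == 1.0).all()

    def test_unseen_label_error(self):
        table = ConfoundTable(["s1"], [0.1], [0.2], ["Oxford"])
        with pytest.raises(ValueError, match="Oxford"):
            one_hot_site(table, ["CBU", "WBIC", "UCL"])


class TestConfoundRegression:
    @staticmethod
    def _table(n, rng):
        return ConfoundTable(
            [f"s{i+1}" for i in range(n)],
            rng.lognormal(-2, 0.3, n),
            rng.lognormal(-1, 0.3, n),
            list(rng.choice(["A", "B", "C"], size=n)),
        )

    def test_variable_linear_in_fd_zeroed(self, rng):
        table = self._table(50, rng)
        design = confound_design(table)
        data = dm((3.0 * table.mean_fd + 1.0)[:, None])
        resid = regress_confounds(data, design)
        assert np.allclose(resid.values, 0.0, atol=1e-10)

    def test_residuals_orthogonal_to_design(self, rng):
        table = self._table(80, rng)
        design = confound_design(table)
        data = dm(rng.standard_normal((80, 6)))
        resid = regress_confounds(data, design)
        assert np.allclose(resid.values.sum(axis=0), 0.0, atol=1e-8)
        assert np.allclose(design.to_numpy().T @ resid.values, 0.0, atol=1e-7)

    def test_rank_deficient_design_rejected(self, rng):
        table = self._table(40, rng)
        design = confound_design(table, drop_last_site=False)  # full one-hot
        data = dm(rng.standard_normal((40, 2)))
        with pytest.raises(ValueError, match="rank-deficient"):
            regress_confounds(data, design)


class TestStandardize:
    def test_unit_moments_and_idempotence(self, rng):
        data = dm(rng.normal(5, 3, (30, 4)))
        out = standardize(data)
        assert np.allclose(out.values.mean(axis=0), 0.0, atol=1e-12)
        assert np.allclose(out.values.std(axis=0, ddof=1), 1.0)
        again = standardize(out)
        assert np.allclose(again.values, out.values, atol=1e-12)

    def test_constant_column_error(self):
        with pytest.raises(ValueError, match="zero-variance"):
            standardize(dm(np.column_stack([np.arange(5.0), np.full(5, 2.0)])))


class TestPipeline:
    def test_output_invariants(self, planted_bundle):
        _, bundle, _ = planted_bundle
        processed, report = preprocess_pipeline(bundle)
        for view in (processed.brain, processed.behaviour):
            assert np.abs(view.values.mean(axis=0)).max() < 1e-8
            assert np.abs(view.values.std(axis=0, ddof=1) - 1).max() < 1e-6
            design = confound_design(processed.confounds)
            dc = design.to_numpy() - design.to_numpy().mean(axis=0)
            corr = dc.T @ view.values / len(view.values)
            assert np.abs(corr).max() < 1e-8

    def test_planted_artifacts_removed_and_reported(self, planted_bundle):
        _, bundle, truth = planted_bundle
        processed, report = preprocess_pipeline(bundle)
        assert sorted(report.removed_variables) == sorted(truth.near_constant_ids)
        assert not set(truth.near_constant_ids) & set(processed.behaviour.variable_ids)
        assert np.isfinite(processed.behaviour.values).all()
        assert sum(report.imputation_counts.values()) > 0

    def test_rerun_on_own_output_is_noop(self, planted_bundle):
        _, bundle, _ = planted_bundle
        processed, _ = preprocess_pipeline(bundle)
        again, report = preprocess_pipeline(processed)
        assert report.removed_variables == []
        assert report.excluded_subjects == []
        # residual-of-residual and re-standardization change nothing
        assert np.allclose(again.brain.values, processed.brain.values, atol=1e-8)

    def test_exclusion_masks_deterministic(self, planted_bundle):
        _, bundle, _ = planted_bundle
        m1, _ = exclude_high_motion_subjects(bundle.confounds)
        m2, _ = exclude_high_motion_subjects(bundle.confounds)
        assert np.array_equal(m1, m2)
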