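import numpy as np
import pandas as pd
import pytest

from mirmine.panel import (ExpressionMatrix, FilterReport, filter_features,
                           log2_transform, match_cohort_samples,
                           quantile_normalize, read_expression)
from conftest import EXPECTED_RETAINED


def _toy(values, kind="miR", features=None, samples=None):
    values = np.asarray(values, dtype=float)
    features = features or [f"f{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=features,
                                         columns=samples), kind)


class TestReadExpression:
    def test_toy_roundtrip(self, tmp_path):
        m = _toy([[1.123456789, 2.0], [3.0, 4.0], [5.0, 6.5]])
        path = tmp_path / "m.tsv"
        m.write_tsv(path)
        back = read_expression(path, "miR")
        assert back.feature_ids == m.feature_ids
        assert back.sample_ids == m.sample_ids
        np.testing.assert_allclose(back.values, m.values, atol=5e-7)

    def test_missing_and_empty_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_expression(tmp_path / "nope.tsv", "miR")
        empty = tmp_path / "empty.tsv"
        empty.write_text("")
        with pytest.raises(Exception):
            read_expression(empty, "miR")

    def test_non_numeric_cell_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("feature_id\ts1\ts2\nf1\t1.0\toops\n")
        with pytest.raises(ValueError):
            read_expression(path, "miR")

    def test_duplicate_feature_ids_suffixed(self, tmp_path):
        path = tmp_path / "dup.tsv"
        path.write_text("feature_id\ts1\nf1\t1.0\nf1\t2.0\n")
        with pytest.warns(UserWarning):
            m = read_expression(path, "miR")
        assert m.feature_ids == ["f1", "f1.1"]

    def test_duplicate_sample_ids_rejected(self):
        df = pd.DataFrame([[1.0, 2.0]], index=["f"], columns=["s", "s"])
        with pytest.raises(ValueError):
            ExpressionMatrix(df, "miR")


class TestQuantileNormalize:
    def test_hand_computed_rank_means(self):
        m = _toy([[1.0, 2.0], [3.0, 4.0]])
        out = quantile_normalize(m)
        np.testing.assert_allclose(out.values, [[1.5, 1.5], [3.5, 3.5]])

    def test_identical_columns_fixed_point(self):
        m = _toy([[1.0, 1.0], [5.0, 5.0], [3.0, 3.0]])
        out = quantile_normalize(m)
        np.testing.assert_allclose(out.values, m.values)

    def test_columns_share_multiset_and_ranks(self):
        rng = np.random.default_rng(7)
        m = _toy(rng.normal(size=(30, 6)))
        out = quantile_normalize(m)
        sorted_cols = np.sort(out.values, axis=0)
        for j in range(1, 6):
            np.testing.assert_array_equal(sorted_cols[:, 0], sorted_cols[:, j])
        # within-column ordering preserved
        for j in range(6):
            assert (np.argsort(out.values[:, j], kind="stable")
                    == np.argsort(m.values[:, j], kind="stable")).all()
        np.testing.assert_allclose(out.values.mean(axis=0),
                                   out.values.mean(axis=0)[0])

    def test_single_sample_identity_with_warning(self):
        m = _toy([[1.0], [2.0]])
        with pytest.warns(UserWarning):
            out = quantile_normalize(m)
        np.testing.assert_array_equal(out.values, m.values)


class TestLog2Transform:
    def test_values(self):
        m = _toy([[0.0, 7.0, 1.0]])
        out = log2_transform(m, offset=1.0)
        np.testing.assert_allclose(out.values, [[0.0, 3.0, 1.0]])

    def test_monotonicity_preserved(self):
        rng = np.random.default_rng(3)
        v = rng.uniform(0, 100, size=(1, 20))
        out = log2_transform(_toy(v), offset=1.0)
        assert (np.argsort(out.values[0]) == np.argsort(v[0])).all()

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            log2_transform(_toy([[0.0, 1.0]]), offset=0.0)


class TestFilterFeatures:
    def test_hand_enumerated_fixture(self, preprocessing_fixture):
        """The 20-feature/57-sample fixture retains exactly the 7 wide features."""
        out, report = filter_features(preprocessing_fixture)
        assert sorted(out.feature_ids) == sorted(EXPECTED_RETAINED)
        assert report.n_input == 20
        assert report.n_dropped_abundance == 5      # 3 all-zero + 2 with 13 above
        assert report.n_dropped_range == 8
        assert report.n_retained == 7

    def test_independent_rule_enumeration(self, preprocessing_fixture):
        """filter_features agrees with a plain-loop application of both rules."""
        m = preprocessing_fixture
        x = m.values
        abund_thr = np.percentile(x, 10.0)
        range_thr = np.percentile(x, 90.0)
        expected = []
        for i, fid in enumerate(m.feature_ids):
            n_above = sum(1 for v in x[i] if v > abund_thr)
            rng_i = x[i].max() - x[i].min()
            if n_above >= 14 and rng_i > range_thr:
                expected.append(fid)
        out, report = filter_features(m)
        assert out.feature_ids == expected
        assert report.thresholds_used["abundance_threshold"] == abund_thr
        assert report.thresholds_used["range_threshold"] == range_thr

    def test_thirteen_above_dropped_fourteen_passes_abundance(
            self, preprocessing_fixture):
        out, report = filter_features(preprocessing_fixture)
        assert "low13_1" not in out.feature_ids          # 13/57 above: dropped
        # low14 features pass the abundance rule (they fail only on range)
        assert report.n_dropped_abundance == 5

    def test_retained_features_still_pass_original_thresholds(
            self, preprocessing_fixture):
        """Idempotence: every retained feature passes the recorded thresholds."""
        out, report = filter_features(preprocessing_fixture)
        thr = report.thresholds_used
        x = out.values
        assert ((x > thr["abundance_threshold"]).sum(axis=1)
                >= thr["min_count_above"]).all()
        assert (np.ptp(x, axis=1) > thr["range_threshold"]).all()

    def test_mrna_fraction_of_total_rule(self):
        # global range 0..20; threshold 2.0; ranges 20, 1.4, 4
        vals = np.vstack([np.linspace(0, 20, 10),
                          10 + np.linspace(0, 1.4, 10),
                          np.linspace(5, 9, 10)])
        m = _toy(vals, kind="mRNA-probe")
        out, rep = filter_features(m, min_count_above=1)
        assert out.feature_ids == ["f0", "f2"]
        assert rep.thresholds_used["range_threshold"] == pytest.approx(2.0)

    def test_all_dropped_raises(self):
        m = _toy(np.zeros((3, 8)))
        with pytest.raises(ValueError):
            filter_features(m)

    def test_report_must_reconcile(self):
        with pytest.raises(ValueError):
            FilterReport(n_input=5, n_dropped_abundance=1, n_dropped_range=1,
                         n_retained=1)


class TestMatchCohortSamples:
    def test_partial_overlap(self):
        mir = pd.DataFrame(np.ones((2, 5)), index=["a", "b"],
                           columns=[f"BC{i}" for i in range(5)])
        mrna = pd.DataFrame(np.ones((3, 5)), index=["x", "y", "z"],
                            columns=[f"BC{i}" for i in range(2, 7)])
        m1, m2 = match_cohort_samples(mir, mrna)
        assert m1.sample_ids == m2.sample_ids == ["BC2", "BC3", "BC4"]

    def test_disjoint_barcodes_error(self):
        mir = pd.DataFrame(np.ones((1, 2)), columns=["A1", "A2"])
        mrna = pd.DataFrame(np.ones((1, 2)), columns=["B1", "B2"])
        with pytest.raises(ValueError):
            match_cohort_samples(mir, mrna)

    def test_patient_with_two_samples_kept_distinct(self):
        cols = ["SIM-01-1000-01A", "SIM-01-1000-06A", "SIM-02-1001-01A"]
        mir = pd.DataFrame(np.ones((1, 3)), columns=cols)
        mrna = pd.DataFrame(np.ones((1, 3)), columns=cols)
        m1, _ = match_cohort_samples(mir, mrna)
        assert m1.sample_ids == sorted(cols)
        assert len(m1.sample_ids) == 3
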