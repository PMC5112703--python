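import numpy as np
import pandas as pd
import pytest
from scipy.special import digamma

from mirmine.association import (MiEstimatorParams, _ksg_mi_block, ksg_mi,
                                 pairwise_associations, pearson)
from mirmine.panel import ExpressionMatrix


def naive_ksg2(x, y, k):
    """Independent O(N^2) reference of KSG algorithm 2: plain Python loops,
    no spatial indexing, same formula."""
    n = len(x)
    terms = []
    for i in range(n):
        others = [j for j in range(n) if j != i]
        joint = [max(abs(x[i] - x[j]), abs(y[i] - y[j])) for j in others]
        order = sorted(range(n - 1), key=lambda t: joint[t])
        knn = [others[t] for t in order[:k]]
        eps_x = max(abs(x[i] - x[j]) for j in knn)
        eps_y = max(abs(y[i] - y[j]) for j in knn)
        n_x = sum(1 for j in others if abs(x[j] - x[i]) <= eps_x)
        n_y = sum(1 for j in others if abs(y[j] - y[i]) <= eps_y)
        terms.append(digamma(n_x) + digamma(n_y))
    return float(digamma(k) - 1.0 / k + digamma(n)
                 - np.mean(np.asarray(terms)))


def _matrix(values, kind, prefix):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(
        pd.DataFrame(values,
                     index=[f"{prefix}{i}" for i in range(values.shape[0])],
                     columns=[f"s{j}" for j in range(values.shape[1])]),
        kind)


class TestPearson:
    def test_exact_anticorrelation(self):
        assert pearson([1, 2, 3], [6, 4, 2]) == pytest.approx(-1.0)

    def test_hand_computed_half(self):
        assert pearson([1, 2, 3], [2, 1, 3]) == pytest.approx(0.5)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            pearson([1.0, 2.0], [2.0, 1.0])


class TestKsgMi:
    def test_matches_naive_oracle_bitwise(self):
        """Production estimator equals the plain-loop reference exactly on
        pre-jittered data (identical noise realisation)."""
        rng = np.random.default_rng(42)
        for _ in range(50):
            x = rng.uniform(size=20)
            y = 0.5 * x + rng.normal(size=20)
            got = ksg_mi(x, y, MiEstimatorParams(k=4, noise_amplitude=0.0))
            assert got == naive_ksg2(list(x), list(y), 4)

    def test_symmetric_on_jitter_free_input(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=50), rng.normal(size=50)
        p = MiEstimatorParams(noise_amplitude=0.0)
        assert ksg_mi(x, y, p) == ksg_mi(y, x, p)

    def test_gaussian_closed_form_moderate_n(self):
        rho = 0.6
        errs = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            xy = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=500)
            mi = ksg_mi(xy[:, 0], xy[:, 1], MiEstimatorParams(rng_seed=seed))
            errs.append(mi + 0.5 * np.log(1 - rho ** 2))
        assert abs(np.mean(errs)) < 0.05

    def test_monotone_transform_invariance(self):
        rho = 0.6
        rng = np.random.default_rng(11)
        xy = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=500)
        p = MiEstimatorParams(noise_amplitude=0.0)
        base = ksg_mi(xy[:, 0], xy[:, 1], p)
        transformed = ksg_mi(np.exp(xy[:, 0]), xy[:, 1], p)
        assert transformed == pytest.approx(base, abs=0.1)

    def test_tied_values_handled_by_jitter(self):
        x = np.repeat([0.0, 1.0, 2.0], 10)
        y = np.repeat([2.0, 1.0, 0.0], 10)
        mi = ksg_mi(x, y, MiEstimatorParams(rng_seed=1))
        assert np.isfinite(mi) and mi > 0.3

    def test_input_validation(self):
        p = MiEstimatorParams(k=4)
        with pytest.raises(ValueError):
            ksg_mi([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], p)          # N <= k
        with pytest.raises(ValueError):
            ksg_mi(np.ones(10), np.arange(10.0),
                   MiEstimatorParams(noise_amplitude=0.0))        # zero variance
        with pytest.raises(ValueError):
            MiEstimatorParams(k=0)


class TestPairwiseAssociations:
    def test_row_count_and_columns(self):
        rng = np.random.default_rng(0)
        mir = _matrix(rng.normal(size=(2, 30)), "miR", "m")
        mrna = _matrix(rng.normal(size=(3, 30)), "mRNA-probe", "p")
        out = pairwise_associations(mir, mrna)
        assert len(out) == 6
        assert list(out.columns) == ["mir_id", "probe_id", "pearson_r", "mi_nats"]

    def test_sample_permutation_invariance(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(2, 25))
        Y = rng.normal(size=(3, 25))
        params = MiEstimatorParams(noise_amplitude=0.0)
        base = pairwise_associations(_matrix(X, "miR", "m"),
                                     _matrix(Y, "mRNA-probe", "p"), params)
        perm = rng.permutation(25)
        shuf = pairwise_associations(_matrix(X[:, perm], "miR", "m"),
                                     _matrix(Y[:, perm], "mRNA-probe", "p"),
                                     params)
        # identical up to float summation order under the permutation
        np.testing.assert_allclose(base["pearson_r"], shuf["pearson_r"],
                                   rtol=1e-12)
        np.testing.assert_allclose(base["mi_nats"], shuf["mi_nats"],
                                   rtol=1e-12, atol=1e-14)

    def test_matches_single_pair_estimator(self):
        """Block kernel and single-pair path agree exactly on jitter-free data."""
        rng = np.random.default_rng(2)
        X = rng.normal(size=(3, 40))
        Y = rng.normal(size=(5, 40))
        params = MiEstimatorParams(noise_amplitude=0.0)
        out = pairwise_associations(_matrix(X, "miR", "m"),
                                    _matrix(Y, "mRNA-probe", "p"), params)
        for row in out.itertuples(index=False):
            i = int(row.mir_id[1:])
            j = int(row.probe_id[1:])
            assert row.mi_nats == ksg_mi(X[i], Y[j], params)
            assert row.pearson_r == pytest.approx(pearson(X[i], Y[j]), abs=1e-12)

    def test_block_size_does_not_change_results(self):
        rng = np.random.default_rng(3)
        mir = _matrix(rng.normal(size=(2, 30)), "miR", "m")
        mrna = _matrix(rng.normal(size=(7, 30)), "mRNA-probe", "p")
        a = pairwise_associations(mir, mrna, block_size=2)
        b = pairwise_associations(mir, mrna, block_size=100)
        np.testing.assert_array_equal(a["mi_nats"], b["mi_nats"])

    def test_sample_mismatch_rejected(self):
        rng = np.random.default_rng(4)
        mir = _matrix(rng.normal(size=(1, 10)), "miR", "m")
        mrna = ExpressionMatrix(
            pd.DataFrame(rng.normal(size=(1, 10)),
                         columns=[f"t{j}" for j in range(10)]), "mRNA-probe")
        with pytest.raises(ValueError):
            pairwise_associations(mir, mrna)

    def test_seeded_determinism(self):
        rng = np.random.default_rng(6)
        mir = _matrix(rng.normal(size=(2, 20)), "miR", "m")
        mrna = _matrix(rng.normal(size=(2, 20)), "mRNA-probe", "p")
        p = MiEstimatorParams(rng_seed=9)
        a = pairwise_associations(mir, mrna, p)
        b = pairwise_associations(mir, mrna, p)
        pd.testing.assert_frame_equal(a, b)

    def test_block_kernel_shape(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=25)
        Y = rng.normal(size=(4, 25))
        assert _ksg_mi_block(x, Y, 4).shape == (4,)
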