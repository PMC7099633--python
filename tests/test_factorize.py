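import numpy as np
import pytest
from scipy.optimize import minimize
from sklearn.linear_model import Lasso
from sklearn.metrics import rand_score

from sparsebin.factorize import (
    CodeMatrix,
    _dict_constraint,
    assign_buckets,
    code_columns,
    coding_kkt_residual,
    learn_dictionary,
    objective_value,
)


def qp_oracle(D, x, l1, l2):
    """Independent oracle for the non-negative elastic-net code: smooth
    bound-constrained QP solved by L-BFGS-B."""

    def f(a):
        r = x - D @ a
        return 0.5 * r @ r + l1 * a.sum() + 0.5 * l2 * a @ a

    def grad(a):
        return D.T @ (D @ a - x) + l1 + l2 * a

    best = None
    for start in (np.zeros(D.shape[1]), np.full(D.shape[1], 0.5)):
        res = minimize(f, start, jac=grad, method="L-BFGS-B",
                       bounds=[(0, None)] * D.shape[1],
                       options={"ftol": 1e-15, "gtol": 1e-12})
        if best is None or res.fun < best.fun:
            best = res
    return best.x


class TestCodeColumns:
    def test_zero_input_zero_code(self):
        D = np.array([[1.0, 0.0], [0.0, 1.0], [0.0, 0.0]])
        A = code_columns(np.zeros((3, 2)), D, l1=0.1, l2=0.01)
        assert not A.any()

    def test_large_l1_kills_code(self, rng):
        D = np.abs(rng.standard_normal((4, 3)))
        D /= np.linalg.norm(D, axis=0)
        x = np.abs(rng.standard_normal((4, 1)))
        l1 = float((D.T @ (x / np.linalg.norm(x))).max()) + 1e-9
        A = code_columns(x, D, l1=l1, l2=0.0, nonneg=True)
        assert not A.any()

    def test_matches_qp_oracle_3x2(self, rng):
        for _ in range(20):
            D = np.abs(rng.standard_normal((3, 2)))
            D /= np.linalg.norm(D, axis=0)
            x = np.abs(rng.standard_normal(3))
            x /= np.linalg.norm(x)
            A = code_columns(x[:, None], D, l1=0.1, l2=0.01,
                             normalize_columns=False)
            expected = qp_oracle(D, x, 0.1, 0.01)
            np.testing.assert_allclose(A.ravel(), expected, atol=1e-4)

    def test_kkt_residual_small(self, rng):
        D = np.abs(rng.standard_normal((6, 4)))
        D /= np.linalg.norm(D, axis=0)
        X = np.abs(rng.standard_normal((6, 30)))
        A = code_columns(X, D, l1=0.05, l2=0.01)
        Xn = X / np.linalg.norm(X, axis=0)
        assert coding_kkt_residual(Xn, D, A, 0.05, 0.01, nonneg=True) <= 1e-6

    def test_lasso_agreement_without_positivity(self, rng):
        # l2=0, no sign constraint: must match a reference LASSO solver
        m, p = 8, 5
        D = rng.standard_normal((m, p))
        D /= np.linalg.norm(D, axis=0)
        x = rng.standard_normal(m)
        x /= np.linalg.norm(x)
        l1 = 0.05
        A = code_columns(x[:, None], D, l1=l1, l2=0.0, nonneg=False,
                         normalize_columns=False)
        ref = Lasso(alpha=l1 / m, fit_intercept=False, tol=1e-12, max_iter=100000)
        ref.fit(D, x)
        np.testing.assert_allclose(A.ravel(), ref.coef_, atol=1e-4)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="incompatible"):
            code_columns(np.zeros((3, 1)), np.zeros((4, 2)), l1=0.1, l2=0.0)


class TestObjective:
    def test_exact_factorization_zero(self, rng):
        D = rng.random((5, 2))
        A = rng.random((2, 10))
        assert objective_value(D @ A, D, A, 0.0, 0.0) == pytest.approx(0.0, abs=1e-12)

    def test_zero_code(self, rng):
        X = rng.random((4, 6))
        val = objective_value(X, np.zeros((4, 2)), np.zeros((2, 6)), 0.3, 0.1)
        assert val == pytest.approx(0.5 * (X**2).sum() / 6)

    def test_direct_summation_oracle(self, rng):
        X = rng.random((4, 7))
        D = rng.random((4, 3))
        A = rng.random((3, 7))
        expected = np.mean(
            [
                0.5 * np.sum((X[:, i] - D @ A[:, i]) ** 2)
                + 0.2 * np.abs(A[:, i]).sum()
                + 0.5 * 0.05 * np.sum(A[:, i] ** 2)
                for i in range(7)
            ]
        )
        assert objective_value(X, D, A, 0.2, 0.05) == pytest.approx(expected)


class TestLearnDictionary:
    def test_rank_one_limit(self, rng):
        v = np.abs(rng.standard_normal(6))
        v /= np.linalg.norm(v)
        X = np.tile(v[:, None], (1, 40))
        d = learn_dictionary(X, p=1, l1=0.01, l2=0.0, batch_size=40, epochs=5, seed=0)
        cos = abs(d.D[:, 0] @ v) / np.linalg.norm(d.D[:, 0])
        assert cos >= 0.99

    def test_full_batch_objective_monotone(self, rng):
        X = np.abs(rng.standard_normal((10, 50)))
        d = learn_dictionary(X, p=4, batch_size=50, epochs=8, seed=1)
        h = np.array(d.objective_history)
        assert np.all(np.diff(h) <= 1e-8)

    def test_planted_partition_recovered(self, rng):
        # X = D* A* with disjoint non-negative supports + small noise
        m, n, p = 10, 200, 4
        D_true = np.abs(rng.standard_normal((m, p)))
        D_true /= np.linalg.norm(D_true, axis=0)
        labels_true = rng.integers(0, p, size=n)
        A_true = np.zeros((p, n))
        A_true[labels_true, np.arange(n)] = 0.5 + rng.random(n)
        X = D_true @ A_true + 0.01 * rng.standard_normal((m, n))
        X = np.abs(X)
        d = learn_dictionary(X, p=p, l1=0.05, l2=0.01, batch_size=64, epochs=10, seed=3)
        A = code_columns(X, d)
        found = assign_buckets(CodeMatrix(coeffs=A, bucket_ids=np.arange(n)))
        assert rand_score(labels_true, found.labels) >= 0.95

    def test_feasibility_with_gamma_terms(self, rng):
        X = np.abs(rng.standard_normal((8, 60)))
        d = learn_dictionary(X, p=3, gamma1=0.2, gamma2=0.1, batch_size=20,
                             epochs=3, seed=2)
        for j in range(3):
            assert _dict_constraint(d.D[:, j], 0.2, 0.1) <= 1 + 1e-6
        assert (d.D >= 0).all()

    def test_seeded_determinism(self, rng):
        X = np.abs(rng.standard_normal((6, 80)))
        kw = dict(p=3, batch_size=16, epochs=3, seed=11)
        d1 = learn_dictionary(X, **kw)
        d2 = learn_dictionary(X, **kw)
        np.testing.assert_array_equal(d1.D, d2.D)
        A1, A2 = code_columns(X, d1), code_columns(X, d2)
        np.testing.assert_array_equal(A1, A2)

    def test_errors(self, rng):
        X = np.abs(rng.standard_normal((4, 5)))
        with pytest.raises(ValueError, match="exceeds"):
            learn_dictionary(X, p=6)
        bad = X.copy()
        bad[0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            learn_dictionary(bad, p=2)


class TestModelPersistence:
    def test_roundtrip(self, tmp_path, rng):
        from sparsebin.factorize import CodeMatrix, load_model, save_model

        X = np.abs(rng.standard_normal((6, 40)))
        d = learn_dictionary(X, p=3, batch_size=40, epochs=3, seed=5)
        A = code_columns(X, d)
        code = CodeMatrix(coeffs=A, bucket_ids=np.arange(40) * 7)
        assignment = assign_buckets(code)
        save_model(tmp_path / "model", d, code, assignment)
        d2, code2, assignment2 = load_model(tmp_path / "model")
        np.testing.assert_allclose(d2.D, d.D)
        np.testing.assert_allclose(code2.coeffs, A)
        np.testing.assert_array_equal(code2.bucket_ids, code.bucket_ids)
        np.testing.assert_array_equal(assignment2.labels, assignment.labels)
        assert d2.l1 == d.l1 and d2.nonneg_code == d.nonneg_code


class TestAssignBuckets:
    def test_argmax(self):
        A = np.array([[0.2, 0.0], [0.7, 0.0], [0.1, 0.3]])
        out = assign_buckets(A)
        assert out.labels[0] == out.component_map[1]
        assert out.labels[1] == out.component_map[2]

    def test_zero_column_unassigned(self):
        A = np.array([[0.0, 1.0], [0.0, 0.5]])
        out = assign_buckets(A)
        assert out.labels.tolist() == [-1, 0]

    def test_tie_breaks_to_smaller_component(self):
        A = np.array([[0.5], [0.5]])
        out = assign_buckets(A)
        assert out.labels[0] == out.component_map[0]

    def test_empty_components_dropped_stable(self):
        # components 0 and 3 never win: clusters renumbered 1->0, 2->1
        A = np.array(
            [[0.1, 0.1], [0.9, 0.2], [0.0, 0.8], [0.0, 0.0]]
        )
        out = assign_buckets(A)
        assert out.n_clusters == 2
        assert out.component_map == {1: 0, 2: 1}
        assert out.labels.tolist() == [0, 1]
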