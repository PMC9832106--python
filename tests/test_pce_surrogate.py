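"""Stieltjes orthonormal bases, least-squares PCE, analytic Sobol
indices and held-out validation."""

import numpy as np
import pytest

from hepasens import pce_surrogate as ps


class TestStieltjesRecurrence:
    def test_normal_samples_recover_hermite(self):
        """On standard-normal samples the recurrence approaches the
        probabilists' Hermite one: a_k = 0, b_k = sqrt(k)."""
        x = np.random.default_rng(0).normal(size=200_000)
        basis = ps.stieltjes_recurrence(x, 4, "norm")
        assert np.allclose(basis.a, 0.0, atol=0.05)
        assert np.allclose(basis.b[1:], np.sqrt(np.arange(1, 5)), atol=0.05)

    def test_uniform_samples_recover_legendre(self):
        x = np.random.default_rng(1).uniform(-1, 1, 200_000)
        basis = ps.stieltjes_recurrence(x, 5, "leg")
        expected = np.array([k / np.sqrt(4 * k * k - 1) for k in range(1, 6)])
        assert np.allclose(basis.a, 0.0, atol=0.05)
        assert np.allclose(basis.b[1:], expected, atol=0.05)

    def test_degree_zero_is_the_unit_constant(self):
        x = np.random.default_rng(2).exponential(size=5000)
        basis = ps.stieltjes_recurrence(x, 3)
        vals = basis.evaluate(x)
        assert np.all(vals[:, 0] == 1.0)
        assert np.mean(vals[:, 0] ** 2) == pytest.approx(1.0)

    @pytest.mark.parametrize("maker", [
        lambda rng: rng.lognormal(0.0, 0.5, 20_000),
        lambda rng: rng.beta(0.7, 2.0, 20_000),
        lambda rng: np.concatenate([rng.normal(-2, 0.5, 10_000),
                                    rng.normal(2, 0.5, 10_000)]),
    ])
    def test_gram_identity_on_arbitrary_measures(self, maker):
        x = maker(np.random.default_rng(3))
        basis = ps.stieltjes_recurrence(x, 6)
        assert basis.gram_deviation(x) < ps.GRAM_TOL

    def test_preconditions(self):
        with pytest.raises(ValueError, match="samples"):
            ps.stieltjes_recurrence(np.arange(50.0), 4)   # < 50*q
        with pytest.raises(ValueError, match="degenerate"):
            ps.stieltjes_recurrence(np.full(1000, 2.0), 3)


class TestMultiIndexSet:
    @pytest.mark.parametrize("d,q,count", [(10, 4, 1001), (1, 4, 5), (2, 2, 6)])
    def test_total_degree_cardinality(self, d, q, count):
        mset = ps.MultiIndexSet.total_degree(d, q)
        assert len(mset) == count

    def test_graded_order_with_zero_first(self):
        mset = ps.MultiIndexSet.total_degree(3, 3)
        deg = mset.indices.sum(axis=1)
        assert np.all(np.diff(deg) >= 0)
        assert np.all(mset.indices[0] == 0)
        assert len(np.unique(mset.indices, axis=0)) == len(mset)


def _uniform_basis(d, q, n, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.uniform(-1.0, 1.0, size=(n, d))
    mset, bases = ps.build_basis({f"x{j}": X[:, j] for j in range(d)}, q=q)
    return X, mset, bases


class TestFit:
    def test_polynomial_reproduced_exactly(self):
        X, mset, bases = _uniform_basis(3, 3, 2000)
        y = 1.0 + X[:, 0] - 2.0 * X[:, 1] ** 2 + X[:, 0] * X[:, 2] ** 2
        sur = ps.fit_pce(X, y, mset, bases)
        assert sur.residual_rms[0] < 1e-10
        pred = ps.fit_pce(X, y, mset, bases).predict(X)[:, 0]
        assert np.allclose(pred, y, atol=1e-8)

    def test_duplicate_rows_leave_coefficients_unchanged(self):
        X, mset, bases = _uniform_basis(2, 2, 500)
        y = X[:, 0] + X[:, 1] ** 2
        b1 = ps.fit_pce(X, y, mset, bases).beta
        X2 = np.vstack([X, X])
        b2 = ps.fit_pce(X2, np.concatenate([y, y]), mset, bases).beta
        assert np.allclose(b1, b2, atol=1e-10)

    def test_underdetermined_rejected_with_requirement(self):
        X, mset, bases = _uniform_basis(3, 3, 2000)
        with pytest.raises(ValueError, match=str(2 * len(mset))):
            ps.fit_pce(X[:30], np.zeros(30), mset, bases)

    def test_parseval_total_variance(self):
        """Variance from squared coefficients matches the empirical
        output variance for a polynomial response."""
        X, mset, bases = _uniform_basis(2, 4, 5000, seed=5)
        y = 2 * X[:, 0] + X[:, 1] ** 3
        sur = ps.fit_pce(X, y, mset, bases)
        assert sur.total_variance()[0] == pytest.approx(y.var(), rel=0.05)


class TestAnalyticSobol:
    def test_single_active_input(self):
        X, mset, bases = _uniform_basis(3, 2, 1000, seed=6)
        y = 0.5 + 3.0 * X[:, 0] + X[:, 0] ** 2
        est = ps.sobol_from_pce(ps.fit_pce(X, y, mset, bases))
        assert est.S[0, 0] == pytest.approx(1.0, abs=1e-6)
        assert est.ST[0, 0] == pytest.approx(1.0, abs=1e-6)
        assert np.allclose(est.S[0, 1:], 0.0, atol=1e-10)

    def test_first_order_shares_bounded_by_total_variance(self):
        X, mset, bases = _uniform_basis(3, 4, 4000, seed=7)
        y = X[:, 0] * X[:, 1] + X[:, 2]
        est = ps.sobol_from_pce(ps.fit_pce(X, y, mset, bases))
        assert est.S[0].sum() <= 1.0 + 1e-8
        assert np.all(est.ST[0] >= est.S[0] - 1e-10)

    def test_zero_variance_rejected(self):
        X, mset, bases = _uniform_basis(2, 2, 500, seed=8)
        sur = ps.fit_pce(X, np.ones(len(X)), mset, bases)
        with pytest.raises(ValueError, match="variance"):
            ps.sobol_from_pce(sur)


class TestQ2:
    @pytest.fixture(scope="class")
    def fitted(self):
        X, mset, bases = _uniform_basis(2, 3, 3000, seed=9)
        y = X[:, 0] + X[:, 1] ** 2
        return ps.fit_pce(X, y, mset, bases)

    def test_perfect_predictions_score_one(self, fitted):
        Xt = np.random.default_rng(10).uniform(-1, 1, (500, 2))
        yt = Xt[:, 0] + Xt[:, 1] ** 2
        rep = ps.q2_score(fitted, Xt, yt)
        assert rep.q2["y0"] == pytest.approx(1.0, abs=1e-8)

    def test_direct_formula_evaluation(self, fitted):
        """Q2 of predictions (1,2,3) against truth (1,2,4) equals
        1 - 1/(3 var), by the definition."""
        yt = np.array([1.0, 2.0, 4.0])
        pred = np.array([1.0, 2.0, 3.0])
        var = yt.var()
        expected = 1.0 - 1.0 / (3.0 * var)
        q2 = 1.0 - np.sum((yt - pred) ** 2) / (len(yt) * var)
        assert q2 == pytest.approx(expected)

    def test_train_test_overlap_rejected(self, fitted):
        rng = np.random.default_rng(11)
        Xt = rng.uniform(-1, 1, (50, 2))
        # smuggle one training row into the test set
        X_train_row = np.array(sorted(fitted._train_registry))  # noqa: F841
        X, _, _ = _uniform_basis(2, 3, 3000, seed=9)
        Xt[0] = X[0]
        with pytest.raises(ValueError, match="overlap"):
            ps.q2_score(fitted, Xt, Xt[:, 0])

    def test_degenerate_test_outputs_rejected(self, fitted):
        Xt = np.random.default_rng(12).uniform(-1, 1, (50, 2))
        with pytest.raises(ValueError, match="variance"):
            ps.q2_score(fitted, Xt, np.ones(50))
        with pytest.raises(ValueError, match="2 test rows"):
            ps.q2_score(fitted, Xt[:1], np.ones(1))


class TestSerialization:
    def test_round_trip_preserves_predictions(self, tmp_path):
        X, mset, bases = _uniform_basis(3, 3, 2000, seed=13)
        y = np.column_stack([X[:, 0] ** 2, X.sum(axis=1)])
        sur = ps.fit_pce(X, y, mset, bases, output_names=("a", "b"))
        sur.save(tmp_path / "sur.json")
        again = ps.PCESurrogate.load(tmp_path / "sur.json")
        Xt = np.random.default_rng(14).uniform(-1, 1, (100, 3))
        assert np.allclose(sur.predict(Xt), again.predict(Xt), atol=1e-12)
        est1, est2 = ps.sobol_from_pce(sur), ps.sobol_from_pce(again)
        assert np.allclose(est1.S, est2.S)
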