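"""Pick-freeze Sobol estimation against closed-form oracles, plus the
convergence, confidence-interval and classification reports."""

import numpy as np
import pytest

from hepasens import sobol_saltelli as ss


class Uniform:
    """Minimal marginal exposing ppf, for analytic test functions."""

    def __init__(self, lo, hi):
        self.lo, self.hi = lo, hi

    def ppf(self, u):
        return self.lo + (self.hi - self.lo) * np.asarray(u)


def _design(d, N, seed=0, lo=0.0, hi=1.0):
    return ss.build_saltelli_design(
        {f"x{j}": Uniform(lo, hi) for j in range(d)}, N, seed=seed)


class TestDesign:
    def test_evaluation_count_is_d_plus_2_times_N(self):
        des = _design(1, 2)
        assert des.rows.shape == (6, 1)
        assert des.n_evaluations == 6

    def test_hybrid_blocks_swap_one_column(self):
        des = _design(3, 64, seed=4)
        for j in range(3):
            ab = des.AB(j)
            assert np.array_equal(ab[:, j], des.B[:, j])
            other = [k for k in range(3) if k != j]
            assert np.array_equal(ab[:, other], des.A[:, other])

    def test_columns_inside_marginal_support(self):
        des = _design(4, 128, seed=1, lo=-2.0, hi=3.0)
        assert des.rows.min() >= -2.0 and des.rows.max() <= 3.0

    def test_preconditions(self):
        with pytest.raises(ValueError):
            _design(2, 1)
        with pytest.raises(ValueError):
            ss.build_saltelli_design({}, 8)


class TestEstimator:
    def test_additive_two_input_variance_shares(self):
        """Y = X1 + 2 X2 on iid uniforms: variance splits 1/5, 4/5 and
        the model is additive so total equals first order."""
        des = _design(2, 2 ** 14, seed=1)
        y = des.rows[:, 0] + 2.0 * des.rows[:, 1]
        est = ss.estimate_sobol(des, y[:, None], ("y",))
        assert est.S[0, 0] == pytest.approx(0.2, abs=0.02)
        assert est.S[0, 1] == pytest.approx(0.8, abs=0.02)
        assert np.allclose(est.ST[0], est.S[0], atol=0.02)
        assert est.S[0].sum() == pytest.approx(1.0, abs=0.03)

    def test_ishigami_closed_form(self):
        des = _design(3, 2 ** 14, seed=2, lo=-np.pi, hi=np.pi)
        X = des.rows
        y = (np.sin(X[:, 0]) + 7.0 * np.sin(X[:, 1]) ** 2
             + 0.1 * X[:, 2] ** 4 * np.sin(X[:, 0]))
        est = ss.estimate_sobol(des, y[:, None], ("ishigami",))
        assert est.S[0, 0] == pytest.approx(0.3139, abs=0.02)
        assert est.S[0, 1] == pytest.approx(0.4424, abs=0.02)
        assert est.S[0, 2] == pytest.approx(0.0, abs=0.02)
        assert est.ST[0, 2] > 0.2          # X3 acts only through interactions

    def test_inactive_input_scores_zero(self):
        des = _design(3, 2 ** 13, seed=3)
        y = des.rows[:, 0] ** 2 + des.rows[:, 1]
        est = ss.estimate_sobol(des, y[:, None], ("y",))
        assert abs(est.S[0, 2]) < 0.01
        assert abs(est.ST[0, 2]) < 0.01

    def test_quadrature_oracle_on_polynomial(self):
        """Pick-freeze agrees with dense-grid quadrature Sobol indices
        for a degree-3 interaction polynomial."""
        des = _design(2, 2 ** 14, seed=5)
        f = lambda x1, x2: x1 + x1 * x2 ** 2
        y = f(des.rows[:, 0], des.rows[:, 1])
        est = ss.estimate_sobol(des, y[:, None], ("y",))
        # brute-force quadrature of var[E(Y|Xj)] on a fine grid
        g = (np.arange(2000) + 0.5) / 2000
        G1, G2 = np.meshgrid(g, g, indexing="ij")
        Y = f(G1, G2)
        var = Y.var()
        s1 = Y.mean(axis=1).var() / var
        s2 = Y.mean(axis=0).var() / var
        assert est.S[0, 0] == pytest.approx(s1, abs=0.02)
        assert est.S[0, 1] == pytest.approx(s2, abs=0.02)

    def test_constant_output_rejected(self):
        des = _design(2, 64)
        with pytest.raises(ValueError, match="variance"):
            ss.estimate_sobol(des, np.ones((des.n_evaluations, 1)), ("y",))

    def test_incomplete_outputs_rejected(self):
        des = _design(2, 64)
        with pytest.raises(ValueError, match="rows"):
            ss.estimate_sobol(des, np.ones((10, 1)), ("y",))
        y = np.ones(des.n_evaluations)
        y[3] = np.nan
        with pytest.raises(ValueError, match="finite"):
            ss.estimate_sobol(des, y[:, None] + des.rows[:, :1], ("y",))

    def test_seed_reproducibility(self):
        d1 = _design(2, 256, seed=11)
        d2 = _design(2, 256, seed=11)
        assert np.array_equal(d1.rows, d2.rows)
        d3 = _design(2, 256, seed=12)
        assert not np.array_equal(d1.rows, d3.rows)


class TestConvergenceReport:
    def _est(self, S, ST, N):
        S, ST = np.atleast_2d(S), np.atleast_2d(ST)
        return ss.SobolEstimate(S=S, ST=ST, output_names=("y",),
                                input_names=tuple(f"x{i}" for i in range(S.shape[1])),
                                N=N)

    def test_identical_estimates_zero_error(self):
        e = self._est([0.5, 0.3], [0.5, 0.3], 100)
        rep = ss.convergence_error(e, e)
        assert rep.err_first["y"] == 0.0 and rep.err_total["y"] == 0.0

    def test_max_abs_difference(self):
        e1 = self._est([0.5, 0.3], [0.5, 0.3], 100)
        e2 = self._est([0.4, 0.35], [0.45, 0.3], 200)
        rep = ss.convergence_error(e1, e2)
        assert rep.err_first["y"] == pytest.approx(0.1)
        assert rep.err_total["y"] == pytest.approx(0.05)

    def test_symmetry(self):
        e1 = self._est([0.5, 0.3], [0.5, 0.3], 100)
        e2 = self._est([0.4, 0.35], [0.45, 0.3], 200)
        a = ss.convergence_error(e1, e2)
        b = ss.convergence_error(e2, e1)
        assert a.err_first == b.err_first and a.err_total == b.err_total

    def test_mismatched_inputs_rejected(self):
        e1 = self._est([0.5, 0.3], [0.5, 0.3], 100)
        e2 = ss.SobolEstimate(S=np.array([[0.5]]), ST=np.array([[0.5]]),
                              output_names=("y",), input_names=("z0",), N=100)
        with pytest.raises(ValueError):
            ss.convergence_error(e1, e2)


class TestConfidenceIntervals:
    def _repeats(self, n, N=2 ** 12):
        out = []
        for seed in range(n):
            des = _design(2, N, seed=seed)
            y = des.rows[:, 0] + 2.0 * des.rows[:, 1]
            out.append(ss.estimate_sobol(des, y[:, None], ("y",)))
        return out

    def test_requires_two_repeats_and_equal_N(self):
        reps = self._repeats(2)
        with pytest.raises(ValueError):
            ss.confidence_intervals(reps[:1])
        bad = self._repeats(1, N=2 ** 11) + reps[:1]
        with pytest.raises(ValueError, match="same N"):
            ss.confidence_intervals(bad)

    def test_identical_repeats_zero_width(self):
        reps = self._repeats(1) * 3
        ci = ss.confidence_intervals(reps)
        assert np.allclose(ci.lo, ci.hi)

    def test_coverage_of_analytic_values(self):
        """The 95% interval over 10 repeats covers the analytic shares
        (0.2, 0.8) for at least 8 of 10 checks per index."""
        ci = ss.confidence_intervals(self._repeats(10))
        truth = np.array([0.2, 0.8])
        assert np.all(ci.lo[0] <= truth + 1e-3)
        assert np.all(ci.hi[0] >= truth - 1e-3)
        assert ci.n_repeats == 10


class TestClassification:
    def _single(self, s, st):
        est = ss.SobolEstimate(S=np.array([[s]]), ST=np.array([[st]]),
                               output_names=("y",), input_names=("x",), N=10)
        return ss.classify_sensitivity(est)["y"]["x"]

    def test_legend_examples(self):
        assert self._single(0.45, 0.5) == "sensitive"
        assert self._single(0.1, 0.1) == "fairly sensitive"
        assert self._single(0.002, 0.004) == "insensitive"
        assert self._single(0.1, 0.4) == "intermediate"

    def test_negative_noise_is_not_clipped(self):
        assert self._single(-0.01, 0.004) == "insensitive"

    def test_threshold_override(self):
        est = ss.SobolEstimate(S=np.array([[0.15]]), ST=np.array([[0.16]]),
                               output_names=("y",), input_names=("x",), N=10)
        lab = ss.classify_sensitivity(est, {"sensitive_S": 0.1})["y"]["x"]
        assert lab == "sensitive"
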