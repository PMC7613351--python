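"""Latin hypercube design, Saltelli scheme and Sobol index estimators.

Closed-form oracles: for the additive model f = x1 + 2*x2 on [0,1]^2 the
variance decomposes as V = (1 + 4)/12 with S1 = 0.2, S2 = 0.8; the Ishigami
and g-function indices use their published closed forms, recomputed in
:mod:`toasense.gsa`.
"""

import numpy as np
import pytest

from toasense.gsa import (
    gfunction,
    gfunction_indices,
    gsa_spectral,
    ishigami,
    ishigami_indices,
    lhs_sample,
    saltelli_design,
    sobol_indices,
)


def _run_gsa(fn, ranges, N, seed=0, **kw):
    return gsa_spectral(fn, ranges, N=N, seed=seed, **kw)


class TestLHS:
    def test_one_sample_per_quartile(self):
        x = lhs_sample(4, 1, seed=0)[:, 0]
        strata = np.floor(x * 4).astype(int)
        assert sorted(strata) == [0, 1, 2, 3]

    def test_deterministic_under_seed(self):
        assert np.array_equal(lhs_sample(16, 3, seed=5), lhs_sample(16, 3, seed=5))

    def test_column_means_within_stratification_bound(self):
        n = 64
        U = lhs_sample(n, 4, seed=1)
        assert np.all(np.abs(U.mean(axis=0) - 0.5) <= 1.0 / (2 * n))

    def test_invalid_sizes_rejected(self):
        with pytest.raises(ValueError):
            lhs_sample(0, 2)


class TestSaltelliDesign:
    def test_evaluation_count(self):
        d = saltelli_design(8, 3, seed=0)
        assert d.n_evaluations == 8 * (3 + 2) == 40

    def test_pq_differs_only_in_substituted_column(self):
        d = saltelli_design(16, 4, seed=2)
        for i, Pi in enumerate(d.PQ):
            for j in range(4):
                if j == i:
                    assert np.array_equal(Pi[:, j], d.Q[:, j])
                else:
                    assert np.array_equal(Pi[:, j], d.P[:, j])

    def test_entries_in_unit_cube(self):
        d = saltelli_design(32, 5, seed=3)
        for M in [d.P, d.Q, *d.PQ]:
            assert np.all(M >= 0) and np.all(M <= 1)


class TestSobolEstimators:
    def test_additive_model_indices(self):
        # S1 = 1/5, S2 = 4/5, no interactions
        fn = lambda X: X[:, 0] + 2.0 * X[:, 1]
        res = _run_gsa(fn, {"x1": (0, 1), "x2": (0, 1)}, N=8192, seed=0)
        assert res.Si[0, 0] == pytest.approx(0.2, abs=0.02)
        assert res.Si[1, 0] == pytest.approx(0.8, abs=0.02)
        assert np.allclose(res.STi[:, 0], res.Si[:, 0], atol=0.02)
        assert abs(res.Si[:, 0].sum() - 1.0) <= 0.03

    def test_ishigami_closed_form_recovered(self):
        # median worst-case error over a fixed seed batch stays within the
        # expected Monte Carlo accuracy at N=4096
        oracle = ishigami_indices()
        ranges = {f"x{i}": (-np.pi, np.pi) for i in (1, 2, 3)}
        si_err, sti_err = [], []
        for seed in range(5):
            res = _run_gsa(ishigami, ranges, N=4096, seed=seed)
            si_err.append(np.abs(res.Si[:, 0] - oracle["Si"]).max())
            sti_err.append(np.abs(res.STi[:, 0] - oracle["STi"]).max())
        assert np.median(si_err) <= 0.03
        assert np.median(sti_err) <= 0.03

    def test_gfunction_closed_form_recovered(self):
        a = np.array([0.0, 1.0, 4.5, 9.0])
        oracle = gfunction_indices(a)
        ranges = {f"x{i}": (0, 1) for i in range(4)}
        res = _run_gsa(lambda X: gfunction(X, a), ranges, N=4096, seed=2)
        assert np.allclose(res.Si[:, 0], oracle["Si"], atol=0.03)

    def test_total_dominates_first_order(self):
        ranges = {f"x{i}": (-np.pi, np.pi) for i in (1, 2, 3)}
        res = _run_gsa(ishigami, ranges, N=4096, seed=3)
        assert np.all(res.STi[:, 0] >= res.Si[:, 0] - 0.02)

    def test_constant_output_flagged_undefined(self):
        fn = lambda X: np.full(X.shape[0], 3.3)
        res = _run_gsa(fn, {"x1": (0, 1), "x2": (0, 1)}, N=64, seed=0)
        assert res.undefined[0]
        assert np.all(np.isnan(res.Si))

    def test_jansen_cross_check_agrees(self):
        ranges = {f"x{i}": (-np.pi, np.pi) for i in (1, 2, 3)}
        rs = _run_gsa(ishigami, ranges, N=4096, seed=4, estimator="saltelli")
        rj = _run_gsa(ishigami, ranges, N=4096, seed=4, estimator="jansen")
        assert np.allclose(rs.Si[:, 0], rj.Si[:, 0], atol=0.05)
        assert np.array_equal(rs.STi, rj.STi)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            sobol_indices(np.zeros(8), np.zeros(8), np.zeros((2, 7)))

    def test_estimates_converge_with_sample_size(self):
        oracle = ishigami_indices()
        ranges = {f"x{i}": (-np.pi, np.pi) for i in (1, 2, 3)}
        errs = {}
        for N in (256, 8192):
            e = []
            for seed in range(10):
                res = _run_gsa(ishigami, ranges, N=N, seed=seed)
                e.append(np.abs(res.Si[:, 0] - oracle["Si"]).max())
            errs[N] = np.median(e)
        assert errs[8192] <= errs[256]


class TestSpectralGSA:
    def test_evaluation_count_n_k_plus_2(self):
        calls = {"n": 0}

        def fn(X):
            calls["n"] += X.shape[0]
            return X.sum(axis=1)

        res = _run_gsa(fn, {f"x{i}": (0, 1) for i in range(12)}, N=100, seed=0)
        assert calls["n"] == 100 * 14 == res.n_evaluations

    def test_vector_output_per_wavelength(self):
        fn = lambda X: np.column_stack([X[:, 0], 2 * X[:, 1], X[:, 0] + X[:, 1]])
        res = _run_gsa(
            fn, {"a": (0, 1), "b": (0, 1)}, N=2048, seed=1,
            wavelengths_nm=[500.0, 600.0, 700.0],
        )
        assert res.Si.shape == (2, 3)
        assert res.Si[0, 0] == pytest.approx(1.0, abs=0.05)
        assert res.Si[1, 1] == pytest.approx(1.0, abs=0.05)
        assert res.mean_sti("a", 690, 710) == pytest.approx(0.5, abs=0.05)

    def test_variable_permutation_permutes_rows(self):
        # permuting the variable order re-assigns design columns, so the
        # permuted estimates agree up to Monte Carlo noise
        fn1 = lambda X: X[:, 0] + 3 * X[:, 1]
        fn2 = lambda X: X[:, 1] + 3 * X[:, 0]
        r1 = _run_gsa(fn1, {"a": (0, 1), "b": (0, 1)}, N=8192, seed=7)
        r2 = _run_gsa(fn2, {"b": (0, 1), "a": (0, 1)}, N=8192, seed=7)
        assert r1.Si[0, 0] == pytest.approx(r2.Si[1, 0], abs=0.03)
        assert r1.Si[1, 0] == pytest.approx(r2.Si[0, 0], abs=0.03)

    def test_sti_shares_sum_to_one(self):
        fn = lambda X: np.sin(X[:, 0]) + X[:, 1] ** 2
        res = _run_gsa(fn, {"a": (0, 2), "b": (0, 2)}, N=1024, seed=0)
        assert res.sti_shares[:, 0].sum() == pytest.approx(1.0)


class TestAnalyticOracles:
    def test_ishigami_at_origin(self):
        assert ishigami(np.zeros((1, 3)))[0] == 0.0

    def test_gfunction_degenerate_constant(self):
        a = np.full(3, 1e12)
        X = np.random.default_rng(0).uniform(size=(100, 3))
        assert np.allclose(gfunction(X, a), 1.0, atol=1e-9)
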