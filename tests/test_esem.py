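import numpy as np
import pytest
from scipy.stats import ncx2

from vawmi.esem import (
    baseline_chi_square,
    extract_unrotated,
    fit_esem,
    fit_indices,
    geomin_criterion,
    rotate_geomin,
)
from vawmi.tetrachoric import TetrachoricResult, estimate_matrix


def _tet_from_rho(R, n=10_000, var=1e-4):
    k = R.shape[0]
    return TetrachoricResult(
        rho=R,
        tau=np.zeros(k),
        rho_var=np.full((k, k), var),
        n=n,
        converged=np.ones((k, k), bool),
        near_boundary=np.zeros((k, k), bool),
        corrected=np.zeros((k, k), bool),
        psd_repaired=False,
        rho_raw=R,
    )


class TestGeominCriterion:
    def test_zero_matrix_value(self):
        assert np.isclose(geomin_criterion(np.zeros((15, 3)), 0.001), 15 * 0.001)

    def test_invariance_under_permutation_and_sign(self):
        rng = np.random.default_rng(0)
        L = rng.normal(size=(8, 3))
        base = geomin_criterion(L)
        assert np.isclose(geomin_criterion(L[:, [2, 0, 1]]), base)
        assert np.isclose(geomin_criterion(L * np.array([1, -1, 1])), base)

    def test_matches_direct_formula_oracle(self):
        rng = np.random.default_rng(7)
        L = rng.normal(size=(4, 2))
        eps = 0.001
        # independent scripted evaluation of sum_j prod_k (l^2+eps)^(1/m)
        oracle = sum(
            ((L[j, 0] ** 2 + eps) * (L[j, 1] ** 2 + eps)) ** 0.5 for j in range(4)
        )
        assert abs(geomin_criterion(L, eps) - oracle) < 1e-12

    def test_positive_epsilon_required(self):
        with pytest.raises(ValueError):
            geomin_criterion(np.zeros((3, 2)), 0.0)


class TestExtractUnrotated:
    def test_exact_factor_structure_recovered(self):
        rng = np.random.default_rng(4)
        L0 = rng.uniform(-0.8, 0.8, size=(15, 3)) * np.array([1, 0.6, 0.4])
        L0 = L0 * (0.9 / np.abs(L0).max())
        R = L0 @ L0.T
        np.fill_diagonal(R, 1.0)
        tet = _tet_from_rho(R)
        sol = extract_unrotated(tet, 3)
        assert sol.chi_square < 1e-8
        # recovered loadings span the same subspace: Procrustes residual
        Q, _, _ = np.linalg.svd(sol.Lambda, full_matrices=False)
        proj = Q @ Q.T
        assert np.max(np.abs(proj @ L0 - L0)) < 1e-5

    def test_identity_rho_gives_zero_loadings(self):
        sol = extract_unrotated(_tet_from_rho(np.eye(15)), 3)
        assert sol.F_min < 1e-12
        assert np.max(np.abs(sol.Lambda)) < 1e-4

    def test_nesting_more_factors_never_fit_worse(self, measurement_params):
        from vawmi import generate_survey

        s = generate_survey(measurement_params, 5_000, seed=6)
        tet = estimate_matrix(s.responses)
        f = [extract_unrotated(tet, m).F_min for m in (1, 2, 3)]
        assert f[0] >= f[1] >= f[2]
        assert f[0] > f[2]  # 3-factor truth: 1-factor strictly worse

    def test_inadmissible_factor_count_rejected(self):
        with pytest.raises(ValueError):
            extract_unrotated(_tet_from_rho(np.eye(15)), 12)


class TestRotateGeomin:
    def test_rotation_preserves_model_implied_correlations(self, measurement_params):
        from vawmi import generate_survey

        s = generate_survey(measurement_params, 20_000, seed=8)
        tet = estimate_matrix(s.responses)
        unrot = extract_unrotated(tet, 3)
        L, Phi, diag = rotate_geomin(unrot.Lambda, seed=0)
        before = unrot.Lambda @ unrot.Lambda.T
        after = L @ Phi @ L.T
        assert np.max(np.abs(before - after)) < 1e-8
        assert diag.converged

    def test_phi_is_correlation_matrix(self, measurement_params):
        from vawmi import generate_survey

        s = generate_survey(measurement_params, 20_000, seed=8)
        tet = estimate_matrix(s.responses)
        L, Phi, _ = rotate_geomin(extract_unrotated(tet, 3).Lambda, seed=0)
        assert np.allclose(np.diag(Phi), 1.0)
        assert np.linalg.eigvalsh(Phi).min() > 0

    def test_majors_aligned_to_who_domains_and_positive(self, measurement_params):
        from vawmi import generate_survey
        from vawmi._instrument import MAJOR_FACTOR

        s = generate_survey(measurement_params, 50_000, seed=10)
        sol = fit_esem(estimate_matrix(s.responses), 3, seed=0)
        L = sol.Lambda_rotated
        for j in range(15):
            assert np.argmax(np.abs(L[j])) == MAJOR_FACTOR[j]
            assert L[j, MAJOR_FACTOR[j]] > 0


class TestFitIndices:
    def test_boundary_identities(self):
        fit = fit_indices(63.0, 63, 1000.0, 105, 1000, np.zeros(105), np.ones(105))
        assert fit["RMSEA"] == 0.0
        fit = fit_indices(0.0, 63, 1000.0, 105, 1000, np.zeros(105), np.ones(105))
        assert fit["CFI"] == 1.0

    @pytest.mark.parametrize(
        "T,df,n", [(120.0, 63, 500), (80.0, 63, 2000), (300.0, 105, 1081)]
    )
    def test_rmsea_ci_matches_bisection_oracle(self, T, df, n):
        def bisect(q):
            lo, hi = 0.0, 1e6
            if ncx2.cdf(T, df, 1e-12) < q:
                return 0.0
            for _ in range(200):
                mid = 0.5 * (lo + hi)
                if ncx2.cdf(T, df, mid) > q:
                    lo = mid
                else:
                    hi = mid
            return 0.5 * (lo + hi)

        fit = fit_indices(T, df, 10 * T, df + 5, n, np.zeros(3), np.ones(3))
        lo_expect = np.sqrt(bisect(0.95) / (df * n))
        hi_expect = np.sqrt(bisect(0.05) / (df * n))
        assert abs(fit["RMSEA_90CI"][0] - lo_expect) < 1e-6
        assert abs(fit["RMSEA_90CI"][1] - hi_expect) < 1e-6
        assert fit["RMSEA_90CI"][0] <= fit["RMSEA"] <= fit["RMSEA_90CI"][1]

    def test_wrmr_definition(self):
        resid = np.array([0.01, -0.02, 0.005])
        var = np.array([1e-4, 4e-4, 2.5e-5])
        fit = fit_indices(10.0, 5, 100.0, 10, 500, resid, var)
        expected = np.sqrt(np.mean(resid**2 / var))
        assert np.isclose(fit["WRMR"], expected)

    def test_misconstructed_baseline_fatal(self):
        with pytest.raises(ValueError, match="baseline"):
            fit_indices(10.0, 63, 5.0, 63, 100, np.zeros(3), np.ones(3))

    def test_indices_bounded(self):
        fit = fit_indices(500.0, 63, 520.0, 105, 200, np.zeros(3), np.ones(3))
        assert 0.0 <= fit["CFI"] <= 1.0
        assert 0.0 <= fit["TLI"] <= 1.0


class TestEndToEnd:
    def test_three_factor_beats_one_factor_on_simulated_data(self, measurement_params):
        from vawmi import generate_survey

        s = generate_survey(measurement_params, 5_000, seed=13)
        tet = estimate_matrix(s.responses)
        sol3 = fit_esem(tet, 3, seed=0)
        sol1 = fit_esem(tet, 1, seed=0)
        assert sol3.fit["CFI"] > 0.95
        assert sol1.fit["CFI"] < sol3.fit["CFI"]

    def test_fit_invariant_to_rotation_seed(self, measurement_params):
        from vawmi import generate_survey

        s = generate_survey(measurement_params, 5_000, seed=13)
        tet = estimate_matrix(s.responses)
        a = fit_esem(tet, 3, seed=0)
        b = fit_esem(tet, 3, seed=99)
        assert np.isclose(a.fit["chi_square"], b.fit["chi_square"])
        assert np.isclose(a.fit["CFI"], b.fit["CFI"])
        assert np.max(np.abs(a.Lambda_rotated - b.Lambda_rotated)) < 1e-4

    def test_communalities_within_unit_interval(self, measurement_params):
        from vawmi import generate_survey

        s = generate_survey(measurement_params, 5_000, seed=13)
        sol = fit_esem(estimate_matrix(s.responses), 3, seed=0)
        assert (sol.communalities > 0).all()
        assert (sol.communalities <= 1.0 + 1e-8).all()


class TestGeominProperties:
    """Derandomized property checks of the rotation criterion."""

    def test_criterion_invariances_hold_for_arbitrary_matrices(self):
        from hypothesis import given, settings
        from hypothesis import strategies as st
        from hypothesis.extra.numpy import arrays

        @settings(max_examples=50, deadline=None, derandomize=True)
        @given(
            arrays(np.float64, (6, 3), elements=st.floats(-2, 2, allow_nan=False)),
            st.permutations([0, 1, 2]),
            st.tuples(*[st.sampled_from([-1.0, 1.0])] * 3),
        )
        def check(L, perm, signs):
            base = geomin_criterion(L)
            assert geomin_criterion(L[:, list(perm)]) == pytest.approx(base, rel=1e-12)
            assert geomin_criterion(L * np.array(signs)) == pytest.approx(base, rel=1e-12)
            assert base >= 6 * 0.001 - 1e-15  # zero matrix is the minimum

        check()
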