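import numpy as np
import pytest
from scipy.integrate import dblquad
from scipy.optimize import minimize_scalar
from scipy.special import ndtri

from vawmi.tetrachoric import (
    bvn_cdf,
    estimate_matrix,
    estimate_pair,
    nearest_psd,
)


# --------------------------------------------------------------------------
# independent oracle: orthant probabilities by 2-D numeric integration and
# a brute-force 1-D likelihood scan over rho
# --------------------------------------------------------------------------

def _orthant_quadrature(tau1, tau2, rho):
    """P(Z1 > tau1, Z2 > tau2) by direct 2-D quadrature of the density."""
    s = 1.0 - rho * rho

    def density(y, x):
        return np.exp(-(x * x - 2 * rho * x * y + y * y) / (2 * s)) / (
            2 * np.pi * np.sqrt(s)
        )

    val, _ = dblquad(density, tau1, 8.5, tau2, 8.5, epsabs=1e-11, epsrel=1e-11)
    return val


def _oracle_rho(counts):
    """Profile-likelihood rho by scan + refinement, quadrature orthants."""
    from scipy.special import ndtr

    n = counts.sum()
    p1 = (counts[0, 0] + counts[0, 1]) / n
    p2 = (counts[0, 0] + counts[1, 0]) / n
    t1, t2 = ndtri(1 - p1), ndtri(1 - p2)

    def nll(r):
        p11 = _orthant_quadrature(t1, t2, r)
        p10 = ndtr(-t1) - p11
        p01 = ndtr(-t2) - p11
        p00 = 1 - ndtr(-t1) - ndtr(-t2) + p11
        probs = np.clip([p11, p10, p01, p00], 1e-300, 1)
        cts = [counts[0, 0], counts[0, 1], counts[1, 0], counts[1, 1]]
        return -sum(c * np.log(p) for c, p in zip(cts, probs))

    grid = np.linspace(-0.998, 0.998, 81)
    best = grid[np.argmin([nll(r) for r in grid])]
    res = minimize_scalar(
        nll,
        bounds=(max(best - 0.05, -0.999), min(best + 0.05, 0.999)),
        method="bounded",
        options={"xatol": 1e-9},
    )
    return float(res.x)


class TestBvnCdf:
    def test_against_scipy_multivariate_normal(self):
        from scipy.stats import multivariate_normal

        rng = np.random.default_rng(1)
        for _ in range(50):
            h, k = rng.normal(size=2) * 1.5
            r = rng.uniform(-0.995, 0.995)
            ref = multivariate_normal(cov=[[1, r], [r, 1]]).cdf([h, k])
            assert abs(bvn_cdf(h, k, r) - ref) < 1e-10

    def test_independence_factorizes(self):
        from scipy.special import ndtr

        assert abs(bvn_cdf(0.3, -0.7, 0.0) - ndtr(0.3) * ndtr(-0.7)) < 1e-12


class TestEstimatePair:
    def test_independence_table_gives_exact_zero(self):
        est = estimate_pair(np.array([[25, 25], [25, 25]]))
        assert est.rho == 0.0
        assert est.tau1 == 0.0 and est.tau2 == 0.0

    def test_symmetric_table_matches_quadrature_oracle(self):
        counts = np.array([[40.0, 10.0], [10.0, 40.0]])
        est = estimate_pair(counts)
        assert abs(est.rho - _oracle_rho(counts)) < 1e-6

    def test_perfect_table_with_correction_near_boundary(self):
        est = estimate_pair(np.array([[50, 0], [0, 50]]), correction=0.5)
        assert est.rho > 0.95
        assert est.near_boundary and est.corrected
        oracle = _oracle_rho(np.array([[50.5, 0.5], [0.5, 50.5]]))
        assert abs(est.rho - oracle) < 1e-5

    def test_zero_margin_without_correction_is_fatal(self):
        with pytest.raises(ValueError, match="continuity"):
            estimate_pair(np.array([[0, 0], [30, 70]]))

    def test_transpose_symmetry(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            t = rng.integers(2, 60, size=(2, 2)).astype(float)
            a = estimate_pair(t)
            b = estimate_pair(t.T)
            assert abs(a.rho - b.rho) < 1e-6

    def test_relabel_flips_sign_and_threshold(self):
        t = np.array([[45.0, 12.0], [8.0, 35.0]])
        a = estimate_pair(t)
        flipped = t[::-1]  # 0<->1 on item 1
        b = estimate_pair(flipped)
        assert abs(a.rho + b.rho) < 1e-7
        assert abs(a.tau1 + b.tau1) < 1e-12

    def test_ml_close_to_two_step_on_balanced_table(self):
        t = np.array([[40.0, 15.0], [12.0, 33.0]])
        a = estimate_pair(t, method="two-step")
        b = estimate_pair(t, method="ml")
        assert abs(a.rho - b.rho) < 0.05

    def test_thresholds_are_inverse_normal_of_margins(self):
        t = np.array([[30.0, 20.0], [10.0, 40.0]])
        est = estimate_pair(t)
        assert np.isclose(est.tau1, ndtri(1 - 0.5))
        assert np.isclose(est.tau2, ndtri(1 - 0.4))


class TestEstimateMatrix:
    def test_matrix_close_to_implied_correlations(self, measurement_params):
        from vawmi import generate_survey, implied_tetrachoric

        s = generate_survey(measurement_params, 60_000, seed=2)
        tet = estimate_matrix(s.responses)
        implied = np.array(
            [
                [implied_tetrachoric(measurement_params, i + 1, j + 1) for j in range(15)]
                for i in range(15)
            ]
        )
        np.fill_diagonal(implied, 1.0)
        assert np.max(np.abs(tet.rho - implied)) < 0.05
        # thresholds follow the y* > 0 convention
        prev = s.responses.values.mean(axis=0)
        assert np.allclose(tet.tau, ndtri(1 - prev), atol=1e-10)

    def test_duplicate_item_capped_and_flagged(self, small_survey):
        vals = small_survey.responses.values
        extended = np.column_stack([vals, vals[:, 0]])
        tet = estimate_matrix(extended)
        assert tet.rho_raw[0, 15] >= 0.999 - 1e-6
        assert tet.near_boundary[0, 15]

    def test_repaired_matrix_is_psd(self, small_survey):
        tet = estimate_matrix(small_survey.responses)
        assert np.linalg.eigvalsh(tet.rho).min() >= -1e-10

    def test_degenerate_item_without_correction_fatal(self):
        vals = np.zeros((50, 15), dtype=int)
        vals[:25, 1:] = 1
        with pytest.raises(ValueError, match="item 1"):
            estimate_matrix(vals, correction=0.0)


class TestNearestPsd:
    def test_indefinite_matrix_repaired_with_unit_diagonal(self):
        m = np.array([[1.0, 0.9, 0.9], [0.9, 1.0, -0.9], [0.9, -0.9, 1.0]])
        fixed, repaired = nearest_psd(m)
        assert repaired
        assert np.linalg.eigvalsh(fixed).min() >= 0
        assert np.allclose(np.diag(fixed), 1.0)

    def test_psd_input_untouched(self):
        m = np.eye(4)
        fixed, repaired = nearest_psd(m)
        assert not repaired and np.array_equal(fixed, m)
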