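import numpy as np
import pytest

from vawmi import generate_survey
from vawmi.mimic import (
    PosteriorDraws,
    SamplerConfig,
    build_direct_map,
    compute_ppp,
    flag_noninvariance,
    gibbs_sample,
    standardize,
)

from conftest import make_params


def _short_cfg(iterations=240, chains=2):
    return SamplerConfig(chains=chains, iterations=iterations, thin=1)


@pytest.fixture(scope="module")
def short_run(study_params):
    survey = generate_survey(study_params, 400, seed=31)
    draws = gibbs_sample(
        survey.responses, survey.covariates, None, _short_cfg(), seed=5
    )
    return survey, draws


class TestGibbsSampler:
    def test_seed_reproducibility(self, study_params):
        survey = generate_survey(study_params, 200, seed=2)
        cfg = _short_cfg(iterations=80)
        a = gibbs_sample(survey.responses, survey.covariates, None, cfg, seed=9)
        b = gibbs_sample(survey.responses, survey.covariates, None, cfg, seed=9)
        assert np.array_equal(a.Lambda, b.Lambda)
        assert np.array_equal(a.Psi, b.Psi)
        assert np.array_equal(a.d_rep, b.d_rep)
        c = gibbs_sample(survey.responses, survey.covariates, None, cfg, seed=10)
        assert not np.array_equal(a.Lambda, c.Lambda)

    def test_identification_every_draw(self, short_run):
        _, draws = short_run
        psi = draws.stack(draws.Psi)
        diag = psi[:, np.arange(3), np.arange(3)]
        assert np.all(diag == 1.0)
        assert np.all(np.abs(psi) <= 1.0 + 1e-12)
        assert min(np.linalg.eigvalsh(m).min() for m in psi) > -1e-10

    def test_direct_effects_zero_outside_map(self, short_run):
        survey, draws = short_run
        cols = list(draws.design_columns)
        active = {
            (item, cols.index(c))
            for item, cc in draws.direct_columns.items()
            for c in cc
        }
        A = draws.stack(draws.A)
        for j in range(15):
            for c in range(len(cols)):
                if (j + 1, c) not in active:
                    assert np.all(A[:, j, c] == 0.0)

    def test_realized_discrepancy_recomputable_from_stored_draws(self, short_run):
        # independent re-derivation: scipy bivariate-normal CDF and explicit
        # loops instead of the sampler's vectorized Owen's-T path
        from scipy.special import ndtr, ndtri
        from scipy.stats import multivariate_normal

        survey, draws = short_run
        Y = survey.responses.values.astype(float)
        n = Y.shape[0]
        c, k = 1, draws.n_kept - 1
        nu, L = draws.nu[c, k], draws.Lambda[c, k]
        A, B, Psi = draws.A[c, k], draws.B[c, k], draws.Psi[c, k]
        X = draws.X
        s = np.sqrt(np.array([L[j] @ Psi @ L[j] + 1.0 for j in range(15)]))
        P = ndtr((nu[None, :] + X @ (B.T @ L.T + A.T)) / s[None, :])
        p = np.clip(P.mean(axis=0), 1e-10, 1 - 1e-10)
        h = ndtri(p)
        d = np.sum((Y.mean(0) - p) ** 2 / (p * (1 - p) / n))
        for i in range(15):
            for j in range(i + 1, 15):
                rho = L[i] @ Psi @ L[j] / (s[i] * s[j])
                pi = multivariate_normal(cov=[[1, rho], [rho, 1]]).cdf([h[i], h[j]])
                pi = np.clip(pi, 1e-10, 1 - 1e-10)
                phat = (Y[:, i] * Y[:, j]).mean()
                d += (phat - pi) ** 2 / (pi * (1 - pi) / n)
        assert abs(d - draws.d_obs[c, k]) < 1e-6

    def test_single_chain_rejected(self, study_params):
        survey = generate_survey(study_params, 100, seed=3)
        with pytest.raises(ValueError, match="chains"):
            gibbs_sample(
                survey.responses, survey.covariates, None,
                SamplerConfig(chains=1, iterations=50), seed=1,
            )

    def test_cross_loading_prior_domination(self, study_params):
        # shrinking the cross-loading prior variance toward zero must drive
        # posterior cross-loadings monotonically toward zero
        survey = generate_survey(study_params, 400, seed=13)
        from vawmi._instrument import MAJOR_FACTOR

        means = []
        for var in (1.0, 0.01, 1e-4):
            cfg = SamplerConfig(chains=2, iterations=300, thin=1, cross_prior_var=var)
            draws = gibbs_sample(survey.responses, survey.covariates, None, cfg, seed=3)
            L = draws.stack(draws.Lambda).mean(axis=0)
            crosses = [
                abs(L[j, f]) for j in range(15) for f in range(3) if f != MAJOR_FACTOR[j]
            ]
            means.append(np.mean(crosses))
        assert means[0] > means[1] > means[2]
        assert means[2] < 0.05


class TestComputePpp:
    def test_requires_100_retained_iterations(self, study_params):
        survey = generate_survey(study_params, 100, seed=3)
        draws = gibbs_sample(
            survey.responses, survey.covariates, None,
            SamplerConfig(chains=2, iterations=80, thin=1), seed=1,
        )
        with pytest.raises(ValueError, match="100"):
            compute_ppp(draws)

    def test_ppp_is_exceedance_fraction(self, short_run):
        _, draws = short_run
        expected = np.mean(draws.d_rep >= draws.d_obs)
        assert compute_ppp(draws) == pytest.approx(expected)


def _manual_draws(study_params, survey, Lambda, *, A=None, B=None, Psi=None, kept=60):
    """Hand-built PosteriorDraws with constant parameter values."""
    p = survey.covariates.matrix.shape[1]
    shape = (2, kept)
    A = np.zeros((15, p)) if A is None else A
    B = np.zeros((3, p)) if B is None else B
    Psi = np.eye(3) if Psi is None else Psi
    return PosteriorDraws(
        nu=np.zeros(shape + (15,)),
        Lambda=np.broadcast_to(Lambda, shape + (15, 3)).copy(),
        A=np.broadcast_to(A, shape + (15, p)).copy(),
        B=np.broadcast_to(B, shape + (3, p)).copy(),
        Psi=np.broadcast_to(Psi, shape + (3, 3)).copy(),
        d_obs=np.zeros(shape),
        d_rep=np.ones(shape),
        direct_columns={1: [survey.covariates.columns[0]]},
        design_columns=tuple(survey.covariates.columns),
        X=survey.covariates.matrix,
    )


class TestStandardize:
    def test_closed_form_with_identity_psi_and_no_covariates(self, study_params):
        survey = generate_survey(study_params, 300, seed=8)
        rng = np.random.default_rng(0)
        Lambda = rng.normal(size=(15, 3))
        draws = _manual_draws(study_params, survey, Lambda)
        summ = standardize(draws, survey.covariates)
        expected = Lambda / np.sqrt((Lambda**2).sum(axis=1) + 1.0)[:, None]
        got = (
            summ.loadings.pivot(index="item", columns="factor", values="mean")
            .loc[range(1, 16), ["psychological", "physical", "sexual"]]
            .to_numpy()
        )
        assert np.max(np.abs(got - expected)) < 1e-10

    def test_all_zero_direct_effect_draws_give_zero_flags(self, study_params):
        survey = generate_survey(study_params, 300, seed=8)
        draws = _manual_draws(study_params, survey, np.zeros((15, 3)))
        summ = standardize(draws, survey.covariates)
        flags = flag_noninvariance(summ, force=True)
        assert len(flags) == 0

    def test_chain_permutation_leaves_summaries_unchanged(self, short_run):
        survey, draws = short_run
        swapped = PosteriorDraws(
            nu=draws.nu[::-1].copy(),
            Lambda=draws.Lambda[::-1].copy(),
            A=draws.A[::-1].copy(),
            B=draws.B[::-1].copy(),
            Psi=draws.Psi[::-1].copy(),
            d_obs=draws.d_obs[::-1].copy(),
            d_rep=draws.d_rep[::-1].copy(),
            direct_columns=draws.direct_columns,
            design_columns=draws.design_columns,
            X=draws.X,
            config=draws.config,
        )
        a = standardize(draws, survey.covariates)
        b = standardize(swapped, survey.covariates)
        assert np.allclose(a.loadings["mean"], b.loadings["mean"])
        assert np.allclose(a.b_effects["ci_lower"], b.b_effects["ci_lower"])
        assert a.ppp == b.ppp


class TestFlagging:
    def test_unconverged_summary_refuses_flags_without_force(self, study_params):
        survey = generate_survey(study_params, 300, seed=8)
        draws = _manual_draws(study_params, survey, np.zeros((15, 3)))
        summ = standardize(draws, survey.covariates)
        summ.converged = False
        with pytest.raises(RuntimeError, match="PSR|converge"):
            flag_noninvariance(summ)
        flag_noninvariance(summ, force=True)

    def test_flag_rule_is_ci_excluding_zero(self, study_params):
        survey = generate_survey(study_params, 300, seed=8)
        kept = 60
        draws = _manual_draws(study_params, survey, np.zeros((15, 3)), kept=kept)
        # inject a positive direct effect for item 1 on the first column
        rng = np.random.default_rng(1)
        draws.A[:, :, 0, 0] = 1.0 + 0.05 * rng.standard_normal((2, kept))
        summ = standardize(draws, survey.covariates)
        flags = flag_noninvariance(summ, force=True)
        assert len(flags) == 1
        assert flags.iloc[0]["item"] == 1 and flags.iloc[0]["sign"] == 1


class TestBuildDirectMap:
    def test_blanket_effects_shrunk_screened_diffuse(self, small_survey):
        dm = build_direct_map(
            small_survey.covariates, screened={5: ["educ"], 10: ["site"]}
        )
        assert dm.prior_var[(3, "site:viwandani")] == 0.01
        assert dm.prior_var[(10, "site:viwandani")] == 25.0  # screen overrides
        assert dm.prior_var[(5, "educ:tertiary")] == 25.0
        assert set(dm.items_with("site:viwandani")) == set(range(1, 16))
        assert dm.items_with("educ:tertiary") == [5]
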