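"""Synthetic survey generator for the probit MIMIC model.

Draws covariates from stated categorical marginals (independently across
covariates), factor scores eta_i = B x_i + zeta_i with zeta ~ N(0, Psi),
latent responses y*_ij = nu_j + lambda_j' eta_i + a_j' x_i + eps_ij with
standard-normal residuals, and observed items y_ij = 1 iff y*_ij > 0.

A 12-item binary asset battery is generated from a latent wealth score via
a logistic ownership model; the "wealth" covariate, when present in the
spec, is the tercile of that same latent score so the asset block and the
wealth covariate are mutually consistent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, ndtr

from ._instrument import N_ITEMS
from .containers import CovariateDesign, ItemResponseMatrix, dummy_code
from .params import CovariateSpec, MimicParameters

__all__ = [
    "SyntheticSurvey",
    "generate_survey",
    "marginal_item_probability",
    "population_item_prevalence",
    "implied_tetrachoric",
    "solve_intercepts",
    "N_ASSETS",
]

N_ASSETS = 12
_ASSET_SLOPE = 1.5
# ownership log-odds intercepts spread so that marginal ownership spans
# roughly 10%-90% across the battery at wealth = 0
_ASSET_INTERCEPTS = np.linspace(-2.2, 2.2, N_ASSETS)
_WEALTH_TERCILE_CUTS = (-0.43072729929545756, 0.43072729929545756)  # Phi^-1(1/3), Phi^-1(2/3)


@dataclass
class SyntheticSurvey:
    """One generated survey: items, covariates, assets, and the truth."""

    responses: ItemResponseMatrix
    covariates: CovariateDesign
    assets: np.ndarray  # (n, q) 0/1 ownership indicators
    truth: MimicParameters
    seed: int

    @property
    def n(self) -> int:
        return self.responses.n

    def to_frame(self) -> pd.DataFrame:
        """Single flat table: items, raw covariates, assets."""
        parts = [self.responses.to_frame()]
        if self.covariates.raw is not None:
            parts.append(self.covariates.raw.reset_index(drop=True))
        assets = pd.DataFrame(
            self.assets, columns=[f"asset{q + 1:02d}" for q in range(self.assets.shape[1])]
        )
        parts.append(assets)
        return pd.concat(parts, axis=1)


def _draw_covariates(
    spec: CovariateSpec, n: int, rng: np.random.Generator
) -> tuple[pd.DataFrame, np.ndarray]:
    """Draw raw categorical covariates; wealth terciles come from a latent
    normal wealth score (returned for the asset battery)."""
    raw = {}
    wealth_latent = rng.standard_normal(n)
    for cov in spec:
        if cov.name == "wealth" and len(cov.categories) == 3:
            cats = np.asarray(cov.categories, dtype=object)
            idx = np.searchsorted(_WEALTH_TERCILE_CUTS, wealth_latent)
            raw[cov.name] = cats[idx]
        else:
            raw[cov.name] = rng.choice(cov.categories, size=n, p=cov.probs)
    return pd.DataFrame(raw), wealth_latent


def generate_survey(params: MimicParameters, n: int, seed: int) -> SyntheticSurvey:
    """Simulate n respondents from the probit MIMIC model."""
    if n < 1:
        raise ValueError("n must be a positive integer")
    rng = np.random.default_rng(seed)
    spec = params.covariate_spec

    raw, wealth_latent = _draw_covariates(spec, n, rng)
    design = dummy_code(raw, spec)
    X = design.matrix

    chol = np.linalg.cholesky(params.Psi)
    zeta = rng.standard_normal((n, 3)) @ chol.T
    eta = X @ params.B.T + zeta

    ystar = (
        params.nu[None, :]
        + eta @ params.Lambda.T
        + X @ params.A.T
        + rng.standard_normal((n, N_ITEMS))
    )
    responses = ItemResponseMatrix((ystar > 0).astype(np.int8))

    ownership = expit(_ASSET_INTERCEPTS[None, :] + _ASSET_SLOPE * wealth_latent[:, None])
    assets = (rng.random((n, N_ASSETS)) < ownership).astype(np.int8)

    return SyntheticSurvey(
        responses=responses, covariates=design, assets=assets, truth=params, seed=seed
    )


def marginal_item_probability(params: MimicParameters, x: np.ndarray, item: int) -> float:
    """P(y_j = 1 | x) = Phi((nu_j + lambda_j'Bx + a_j'x) / sqrt(l'Psi l + 1)).

    ``item`` is 1-based (1..15) to match the instrument numbering.
    """
    if not 1 <= item <= N_ITEMS:
        raise ValueError(f"item must be in 1..{N_ITEMS}")
    j = item - 1
    x = np.asarray(x, dtype=float)
    lam = params.Lambda[j]
    num = params.nu[j] + lam @ params.B @ x + params.A[j] @ x
    denom = np.sqrt(lam @ params.Psi @ lam + 1.0)
    return float(ndtr(num / denom))


def population_item_prevalence(params: MimicParameters) -> np.ndarray:
    """Exact P(y_j = 1) under the spec's independent covariate marginals.

    Averages the closed-form conditional probability over the exact discrete
    distribution of the linear predictor lambda_j'Bx + a_j'x.
    """
    spec = params.covariate_spec
    sd = params.ystar_sd()
    out = np.empty(N_ITEMS)
    for j in range(N_ITEMS):
        coef = params.Lambda[j] @ params.B + params.A[j]
        values, probs = spec.linear_predictor_distribution(coef)
        out[j] = float(probs @ ndtr((params.nu[j] + values) / sd[j]))
    return out


def implied_tetrachoric(params: MimicParameters, i: int, j: int) -> float:
    """Model-implied correlation of (y*_i, y*_j) ignoring covariate effects.

    corr = lambda_i' Psi lambda_j / (SD(y*_i) SD(y*_j)); items 1-based.
    """
    li, lj = params.Lambda[i - 1], params.Lambda[j - 1]
    sd = params.ystar_sd()
    return float(li @ params.Psi @ lj / (sd[i - 1] * sd[j - 1]))


def solve_intercepts(
    params_wo_nu: MimicParameters, target_prevalence: np.ndarray, tol: float = 1e-8
) -> np.ndarray:
    """Solve for nu so the population prevalence matches the target.

    The marginal prevalence is monotone increasing in nu_j, so each item is
    a scalar root-finding problem; solved by Brent's method to ``tol`` on
    the prevalence scale.
    """
    target = np.asarray(target_prevalence, dtype=float)
    if target.shape != (N_ITEMS,) or np.any((target <= 0) | (target >= 1)):
        raise ValueError("target prevalences must be 15 values strictly inside (0,1)")
    spec = params_wo_nu.covariate_spec
    sd = params_wo_nu.ystar_sd()
    nu = np.empty(N_ITEMS)
    for j in range(N_ITEMS):
        coef = params_wo_nu.Lambda[j] @ params_wo_nu.B + params_wo_nu.A[j]
        values, probs = spec.linear_predictor_distribution(coef)

        def f(v: float, j: int = j) -> float:
            return float(probs @ ndtr((v + values) / sd[j])) - target[j]

        lo, hi = -10.0 * sd[j], 10.0 * sd[j]
        nu[j] = brentq(f, lo, hi, xtol=tol, rtol=8.9e-16)
    return nu
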