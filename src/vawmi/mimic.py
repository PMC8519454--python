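"""Bayesian MIMIC probit model by Gibbs sampling.

Measurement model: y*_ij = nu_j + lambda_j' eta_i + a_j' x_i + eps_ij with
eps ~ N(0,1) and y_ij = 1 iff y*_ij > 0.  Structural model:
eta_i = B x_i + zeta_i, zeta ~ N(0, Psi) with Psi a correlation matrix.

Every item loads on all three factors in the BSEM spirit: the major
loading (WHO domain) gets a diffuse N(0, 25) prior while cross-loadings
get informative small-variance N(0, 0.01) priors instead of exact zeros.
Intercepts, direct effects and B coefficients are N(0, 25).  Psi is
updated by a parameter-expanded inverse-Wishart step: an unconstrained
covariance is drawn from its conjugate full conditional and the draw is
mapped back to the identified space (correlation Psi, rescaled Lambda, B,
eta) through the scale-invariance group of the model.

Data augmentation follows Albert & Chib: y* are univariate truncated
normals given everything else, and eta has a multivariate-normal full
conditional shared across respondents up to its mean.

Model fit is assessed with a posterior predictive p-value whose
discrepancy is a limited-information chi-square: standardized residuals of
the 15 item margins and the 105 pairwise both-yes proportions against the
model-implied values (factors integrated out analytically via the probit
structure).  A purely marginal discrepancy cannot see misfit in the
dependence structure; the pairwise moments can.  Replicated data are drawn
from the model at each retained iteration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from ._instrument import MAJOR_FACTOR, N_FACTORS, N_ITEMS
from .containers import CovariateDesign, ItemResponseMatrix

__all__ = [
    "SamplerConfig",
    "PosteriorDraws",
    "MimicSummary",
    "build_direct_map",
    "gibbs_sample",
    "compute_ppp",
    "standardize",
    "flag_noninvariance",
    "marginal_response_probability",
    "bernoulli_deviance",
    "sample_moments",
    "implied_moments",
    "moment_discrepancy",
]


@dataclass
class SamplerConfig:
    chains: int = 2
    iterations: int = 20_000
    burn_in: int | None = None  # default: first half
    thin: int = 2
    major_prior_var: float = 25.0
    cross_prior_var: float = 0.01
    intercept_prior_var: float = 25.0
    direct_prior_var: float = 25.0
    b_prior_var: float = 25.0
    psr_threshold: float = 1.1

    def resolved_burn_in(self) -> int:
        return self.iterations // 2 if self.burn_in is None else self.burn_in


@dataclass
class DirectEffectSpec:
    """Which direct effects are free per item, and their prior variances.

    A covariate whose direct effects are free on *every* item is not
    identified jointly with its factor effect (only lambda_j'B + a_j is);
    such blanket effects therefore carry informative small-variance priors
    (the BSEM device), while screened-in effects — free on a strict subset
    of items — keep the diffuse prior.
    """

    columns: dict[int, list[str]]  # 1-based item -> dummy columns
    prior_var: dict[tuple[int, str], float]

    def items_with(self, column: str) -> list[int]:
        return [it for it, cols in self.columns.items() if column in cols]


def build_direct_map(
    design: CovariateDesign,
    screened: dict[int, list[str]] | None = None,
    always: tuple[str, ...] = ("invited", "site", "agegrp"),
    *,
    stage2_p=None,
    diffuse_var: float = 25.0,
    shrink_var: float = 0.01,
) -> DirectEffectSpec:
    """Item (1-based) -> dummy columns with free direct effects.

    Every item keeps the always-retained adjustment covariates (with
    small-variance priors, see DirectEffectSpec); screened-in covariate
    names (from the two-stage LRT screen) are added per item with diffuse
    priors.

    Anchoring: if a covariate's screened items cover *every* item of one
    factor, that factor's regression on the covariate is no longer
    separable from the direct effects.  Only the screened effect with the
    strongest evidence (smallest stage-2 p-value when ``stage2_p`` is
    given, else the lowest item number) keeps the diffuse prior; the rest
    of that factor's items are demoted to the small-variance
    identification prior, restoring a majority of anchor items.
    """
    spec = design.spec
    columns: dict[int, list[str]] = {}
    prior_var: dict[tuple[int, str], float] = {}
    screened = screened or {}
    for item in range(1, N_ITEMS + 1):
        cols: list[str] = []
        for cov in always:
            if cov in spec.names:
                for col in spec[cov].dummy_columns:
                    cols.append(col)
                    prior_var[(item, col)] = shrink_var
        for cov in screened.get(item, []):
            for col in spec[cov].dummy_columns:
                if col not in cols:
                    cols.append(col)
                prior_var[(item, col)] = diffuse_var  # screen overrides shrink
        columns[item] = cols

    factor_items = {
        k: [j + 1 for j in range(N_ITEMS) if MAJOR_FACTOR[j] == k] for k in range(N_FACTORS)
    }
    cov_items: dict[str, set[int]] = {}
    for item, covs in screened.items():
        for cov in covs:
            cov_items.setdefault(cov, set()).add(item)
    for cov, items in cov_items.items():
        for k, majors in factor_items.items():
            if set(majors) <= items:
                if stage2_p is not None:
                    keep = min(majors, key=lambda it: stage2_p.loc[it, cov])
                else:
                    keep = min(majors)
                for it in majors:
                    if it != keep:
                        for col in spec[cov].dummy_columns:
                            prior_var[(it, col)] = shrink_var
    return DirectEffectSpec(columns=columns, prior_var=prior_var)


# --------------------------------------------------------------------------
# building blocks
# --------------------------------------------------------------------------

def _truncated_normal(mean: np.ndarray, positive: np.ndarray, rng) -> np.ndarray:
    """Draws of N(mean,1) truncated to (0,inf) where positive else (-inf,0]."""
    u = rng.random(mean.shape)
    p0 = ndtr(-mean)  # P(z <= 0)
    p = np.where(positive, p0 + u * (1.0 - p0), u * p0)
    p = np.clip(p, 1e-300, 1.0 - 1e-16)
    return mean + ndtri(p)


def marginal_response_probability(
    nu: np.ndarray, Lambda: np.ndarray, A: np.ndarray, B: np.ndarray, Psi: np.ndarray, X: np.ndarray
) -> np.ndarray:
    """P(y_ij = 1 | x_i) with the factors integrated out, (n, 15)."""
    s = np.sqrt(np.einsum("jk,kl,jl->j", Lambda, Psi, Lambda) + 1.0)
    M = nu[None, :] + X @ (B.T @ Lambda.T + A.T)
    return ndtr(M / s[None, :])


def bernoulli_deviance(y: np.ndarray, p: np.ndarray) -> float:
    """-2 * Bernoulli log-likelihood of binary y under probabilities p."""
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    return float(-2.0 * np.sum(np.where(y > 0, np.log(p), np.log1p(-p))))


def sample_moments(Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Item proportions and pairwise both-yes proportions of a binary matrix."""
    n = Y.shape[0]
    pbar = Y.mean(axis=0)
    p11 = (Y.T @ Y) / n
    return pbar, p11


def implied_moments(
    nu: np.ndarray, Lambda: np.ndarray, A: np.ndarray, B: np.ndarray, Psi: np.ndarray, X: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Model-implied item and pairwise both-yes probabilities.

    Marginals are exact (averaged over the sample covariates); pairwise
    probabilities use the latent-response correlations
    rho_ij = lambda_i' Psi lambda_j / (s_i s_j) with effective thresholds
    matched to the implied marginals (covariate heterogeneity beyond the
    margins is ignored, the same approximation for observed and
    replicated data).
    """
    from .tetrachoric import bvn_cdf_vec

    s = np.sqrt(np.einsum("jk,kl,jl->j", Lambda, Psi, Lambda) + 1.0)
    P = ndtr((nu[None, :] + X @ (B.T @ Lambda.T + A.T)) / s[None, :])
    p = np.clip(P.mean(axis=0), 1e-10, 1 - 1e-10)
    h = ndtri(p)
    rho = (Lambda @ Psi @ Lambda.T) / np.outer(s, s)
    iu, ju = np.triu_indices(N_ITEMS, 1)
    pi11 = np.zeros((N_ITEMS, N_ITEMS))
    pi11[iu, ju] = bvn_cdf_vec(h[iu], h[ju], rho[iu, ju])
    pi11 = pi11 + pi11.T
    np.fill_diagonal(pi11, p)
    return p, pi11


def moment_discrepancy(
    observed: tuple[np.ndarray, np.ndarray],
    implied: tuple[np.ndarray, np.ndarray],
    n: int,
) -> float:
    """Limited-information chi-square discrepancy.

    Sum of squared standardized residuals of the 15 item margins and the
    105 pairwise both-yes proportions against their model-implied values
    — sensitive to misfit in the dependence structure, which a marginal
    likelihood cannot see.
    """
    pbar, p11 = observed
    p, pi11 = implied
    z_marg = (pbar - p) / np.sqrt(p * (1 - p) / n)
    iu, ju = np.triu_indices(N_ITEMS, 1)
    pi = np.clip(pi11[iu, ju], 1e-10, 1 - 1e-10)
    z_pair = (p11[iu, ju] - pi) / np.sqrt(pi * (1 - pi) / n)
    return float(np.sum(z_marg**2) + np.sum(z_pair**2))


# --------------------------------------------------------------------------
# posterior containers
# --------------------------------------------------------------------------

@dataclass
class PosteriorDraws:
    """Post-burn-in, thinned MCMC draws (chains x kept x ...)."""

    nu: np.ndarray  # (c, k, 15)
    Lambda: np.ndarray  # (c, k, 15, 3)
    A: np.ndarray  # (c, k, 15, p) zero outside the direct map
    B: np.ndarray  # (c, k, 3, p)
    Psi: np.ndarray  # (c, k, 3, 3)
    d_obs: np.ndarray  # (c, k) realized discrepancies
    d_rep: np.ndarray  # (c, k) replicated discrepancies
    direct_columns: dict[int, list[str]]
    design_columns: tuple[str, ...]
    X: np.ndarray = field(repr=False)
    seed: int = 0
    config: SamplerConfig = field(default_factory=SamplerConfig)

    @property
    def n_chains(self) -> int:
        return self.nu.shape[0]

    @property
    def n_kept(self) -> int:
        return self.nu.shape[1]

    def stack(self, arr: np.ndarray) -> np.ndarray:
        """Merge chain and draw axes."""
        return arr.reshape(-1, *arr.shape[2:])


def _split_rhat(x: np.ndarray) -> float:
    """Split potential-scale-reduction of one scalar chain array (c, k)."""
    c, k = x.shape
    half = k // 2
    if half < 2:
        return np.nan
    halves = np.concatenate([x[:, :half], x[:, half : 2 * half]], axis=0)
    m, l = halves.shape
    means = halves.mean(axis=1)
    W = halves.var(axis=1, ddof=1).mean()
    Bv = l * means.var(ddof=1)
    if W <= 0:
        return 1.0
    var_hat = (l - 1) / l * W + Bv / l
    return float(np.sqrt(var_hat / W))


def _align_chain(out: dict, chain: int) -> None:
    """Resolve factor label/sign switching within one chain's draws.

    The posterior is invariant under column permutations and sign flips of
    the factors (up to the small-variance prior's soft anchoring); chains
    can settle in different labelings.  Align each chain to the WHO domain
    pattern using the chain-mean loadings.
    """
    import itertools

    Lbar = out["Lambda"][chain].mean(axis=0)  # (15, 3)
    target = np.zeros((N_ITEMS, N_FACTORS))
    for j in range(N_ITEMS):
        target[j, MAJOR_FACTOR[j]] = 1.0
    absL = np.abs(Lbar)
    congr = (absL / np.clip(np.linalg.norm(absL, axis=0), 1e-12, None)).T @ (
        target / np.linalg.norm(target, axis=0)
    )
    order = list(
        max(
            itertools.permutations(range(N_FACTORS)),
            key=lambda perm: sum(congr[perm[l], l] for l in range(N_FACTORS)),
        )
    )
    signs = np.array(
        [np.sign(np.sum(Lbar[:, order[l]] * target[:, l])) or 1.0 for l in range(N_FACTORS)]
    )
    if order == list(range(N_FACTORS)) and np.all(signs == 1.0):
        return
    out["Lambda"][chain] = out["Lambda"][chain][:, :, order] * signs[None, None, :]
    out["B"][chain] = out["B"][chain][:, order, :] * signs[None, :, None]
    out["Psi"][chain] = (
        out["Psi"][chain][:, order][:, :, order] * np.outer(signs, signs)[None, :, :]
    )


# --------------------------------------------------------------------------
# the sampler
# --------------------------------------------------------------------------

def gibbs_sample(
    responses: ItemResponseMatrix,
    covariates: CovariateDesign,
    direct_map: DirectEffectSpec | dict[int, list[str]] | None = None,
    config: SamplerConfig | None = None,
    seed: int = 0,
) -> PosteriorDraws:
    """Run the Gibbs sampler; returns post-burn-in, thinned draws.

    A potential-scale-reduction above the configured threshold on any
    monitored parameter raises a warning and marks the result; it is not
    fatal (downstream reporting refuses unconverged flags unless forced).
    """
    cfg = config or SamplerConfig()
    if cfg.chains < 2:
        raise ValueError("at least 2 chains are required for convergence checks")
    Y = responses.values.astype(float)
    X = covariates.matrix
    n, p = X.shape
    if Y.shape[0] != n:
        raise ValueError("responses and covariates disagree on n")
    cols = list(covariates.columns)
    col_index = {c: i for i, c in enumerate(cols)}

    # The config's prior variances are meant on the standardized scale.
    # Internally the sampler works on the probit scale with unit-variance
    # design columns, so priors are rescaled by fixed empirical factors:
    # per-item y* scale from tetrachoric squared multiple correlations
    # (1/(1-SMC_j), the classic communality estimate) and per-column
    # design SDs.  Draws are mapped back to the original design scale.
    from .tetrachoric import estimate_matrix

    sd_xc = X.std(axis=0, ddof=1)
    sd_xc = np.where(sd_xc > 0, sd_xc, 1.0)
    Xs = X / sd_xc[None, :]
    R = estimate_matrix(responses).rho
    smc = 1.0 - 1.0 / np.diag(np.linalg.inv(R + 1e-6 * np.eye(N_ITEMS)))
    item_scale2 = np.clip(1.0 / np.clip(1.0 - smc, 1e-3, 1.0), 1.0, 400.0)
    if direct_map is None:
        direct_map = build_direct_map(covariates)
    if isinstance(direct_map, DirectEffectSpec):
        columns_map = direct_map.columns
        prior_var_map = direct_map.prior_var
    else:
        columns_map = {it: list(direct_map.get(it, [])) for it in range(1, N_ITEMS + 1)}
        prior_var_map = {}
    active = {
        item: np.array([col_index[c] for c in columns_map.get(item, [])], dtype=int)
        for item in range(1, N_ITEMS + 1)
    }

    burn = cfg.resolved_burn_in()
    kept = (cfg.iterations - burn) // cfg.thin
    if kept < 1:
        raise ValueError("no draws retained; increase iterations or reduce burn-in/thin")

    # per-item prior precisions for (nu, lambda_1..3, a_active), all scaled
    # to the item's probit scale via item_scale2
    prior_prec: dict[int, np.ndarray] = {}
    for item in range(1, N_ITEMS + 1):
        j = item - 1
        # cross-loadings anchor the factor rotation: their small variance
        # stays on the probit scale (not item-rescaled).  Rescaling it to
        # the standardized scale loosens the anchor enough that the
        # rotation wanders between chains for high-communality items.
        lam_prec = np.full(N_FACTORS, 1.0 / cfg.cross_prior_var)
        lam_prec[MAJOR_FACTOR[j]] = 1.0 / (cfg.major_prior_var * item_scale2[j])
        # identification-shrink direct effects (var <= 1) stay on the probit
        # scale like the cross-loadings; diffuse ones scale with the item
        a_prec = []
        for c in columns_map.get(item, []):
            v = prior_var_map.get((item, c), cfg.direct_prior_var)
            a_prec.append(1.0 / (v * item_scale2[j] if v > 1.0 else v))
        prior_prec[item] = np.concatenate(
            [[1.0 / (cfg.intercept_prior_var * item_scale2[j])], lam_prec, a_prec]
        )

    XtX = Xs.T @ Xs
    sX, UX = np.linalg.eigh(XtX)  # fixed design: precompute for the B step
    sX = np.clip(sX, 0.0, None)
    # group items with equal direct-effect counts for batched linear algebra
    groups: dict[int, list[int]] = {}
    for item in range(1, N_ITEMS + 1):
        groups.setdefault(len(active[item]), []).append(item)
    out = {
        "nu": np.empty((cfg.chains, kept, N_ITEMS)),
        "Lambda": np.empty((cfg.chains, kept, N_ITEMS, N_FACTORS)),
        "A": np.zeros((cfg.chains, kept, N_ITEMS, p)),
        "B": np.empty((cfg.chains, kept, N_FACTORS, p)),
        "Psi": np.empty((cfg.chains, kept, N_FACTORS, N_FACTORS)),
        "d_obs": np.empty((cfg.chains, kept)),
        "d_rep": np.empty((cfg.chains, kept)),
    }

    positive = Y > 0
    obs_moments = sample_moments(Y)
    for chain in range(cfg.chains):
        rng = np.random.default_rng(np.random.SeedSequence([seed, chain]))
        # dispersed but sane initial values
        nu = ndtri(np.clip(Y.mean(axis=0), 1e-3, 1 - 1e-3)) + 0.1 * rng.standard_normal(N_ITEMS)
        Lambda = 0.1 * rng.standard_normal((N_ITEMS, N_FACTORS))
        for j in range(N_ITEMS):
            Lambda[j, MAJOR_FACTOR[j]] = 1.0 + 0.2 * rng.standard_normal()
        A = np.zeros((N_ITEMS, p))
        B = np.zeros((N_FACTORS, p))
        Psi = np.eye(N_FACTORS)
        eta = rng.standard_normal((n, N_FACTORS))

        # per-group index stacks for batched measurement updates
        group_idx = {
            d: np.stack(
                [np.concatenate([np.arange(4), 4 + active[item]]) for item in items]
            ).astype(int)
            for d, items in groups.items()
        }
        group_items = {d: np.array(items) - 1 for d, items in groups.items()}
        group_prior = {
            d: np.stack([prior_prec[item] for item in items])
            for d, items in groups.items()
        }

        keep_idx = 0
        for it in range(cfg.iterations):
            # (i) latent responses
            M = nu[None, :] + eta @ Lambda.T + Xs @ A.T
            ystar = _truncated_normal(M, positive, rng)

            # (ii) factor scores
            ePsi, VPsi = np.linalg.eigh(Psi)
            ePsi = np.clip(ePsi, 1e-12, None)
            Psi_inv = (VPsi / ePsi) @ VPsi.T
            prec = Lambda.T @ Lambda + Psi_inv
            cov = np.linalg.inv(prec)
            cov = 0.5 * (cov + cov.T)
            R = ystar - nu[None, :] - Xs @ A.T
            mean = (R @ Lambda + Xs @ B.T @ Psi_inv) @ cov
            eta = mean + rng.standard_normal((n, N_FACTORS)) @ np.linalg.cholesky(cov).T

            # (iii) measurement rows (nu_j, lambda_j, a_j), batched by size
            Z = np.concatenate([np.ones((n, 1)), eta, Xs], axis=1)
            C = Z.T @ Z
            Zty = Z.T @ ystar  # (1+3+p, 15)
            for d, items0 in group_items.items():
                idx = group_idx[d]  # (g, 4+d)
                Cg = C[idx[:, :, None], idx[:, None, :]]
                w = 4 + d
                Cg[:, np.arange(w), np.arange(w)] += group_prior[d]
                bg = Zty.T[items0[:, None], idx]  # (g, w)
                Lg = np.linalg.cholesky(Cg)
                meang = np.linalg.solve(Cg, bg[:, :, None])[:, :, 0]
                zg = rng.standard_normal((len(items0), w, 1))
                noise = np.linalg.solve(np.transpose(Lg, (0, 2, 1)), zg)[:, :, 0]
                draw = meang + noise
                nu[items0] = draw[:, 0]
                Lambda[items0] = draw[:, 1:4]
                for r, item in enumerate(items0 + 1):
                    A[item - 1, :] = 0.0
                    if d:
                        A[item - 1, active[item]] = draw[r, 4:]

            # (iv) factor regressions B: the prior is iid N(0, v), so the
            # vec-posterior precision kron(X'X, Psi^-1) + I/v diagonalizes
            # in the fixed kron(U_X, V_Psi) eigenbasis
            dP = 1.0 / ePsi  # eigenvalues of Psi_inv (eigvecs VPsi)
            Rmat = VPsi.T @ (Psi_inv @ (eta.T @ Xs)) @ UX  # (3, p) transformed rhs
            Evals = np.outer(dP, sX) + 1.0 / cfg.b_prior_var
            mean_t = Rmat / Evals
            draw_t = mean_t + rng.standard_normal((N_FACTORS, p)) / np.sqrt(Evals)
            B = VPsi @ draw_t @ UX.T

            # (v) parameter-expanded inverse-Wishart step for Psi (Bartlett)
            Zres = eta - Xs @ B.T
            scale = np.eye(N_FACTORS) + Zres.T @ Zres
            dfw = N_FACTORS + 2 + n
            Cw = np.linalg.cholesky(np.linalg.inv(scale))
            T = np.zeros((N_FACTORS, N_FACTORS))
            T[np.tril_indices(N_FACTORS, -1)] = rng.standard_normal(
                N_FACTORS * (N_FACTORS - 1) // 2
            )
            T[np.diag_indices(N_FACTORS)] = np.sqrt(
                rng.chisquare(dfw - np.arange(N_FACTORS))
            )
            Mw = Cw @ T
            W = np.linalg.inv(Mw @ Mw.T)  # ~ InvWishart(dfw, scale)
            dscale = np.sqrt(np.diag(W))
            Psi = W / np.outer(dscale, dscale)
            np.fill_diagonal(Psi, 1.0)
            # map back to the identified space via the scale group
            Lambda = Lambda * dscale[None, :]
            B = B / dscale[:, None]
            eta = eta / dscale[None, :]

            if it >= burn and (it - burn) % cfg.thin == 0 and keep_idx < kept:
                implied = implied_moments(nu, Lambda, A, B, Psi, Xs)
                d_obs = moment_discrepancy(obs_moments, implied, n)
                eta_rep = Xs @ B.T + rng.standard_normal((n, N_FACTORS)) @ np.linalg.cholesky(Psi).T
                ystar_rep = (
                    nu[None, :]
                    + eta_rep @ Lambda.T
                    + Xs @ A.T
                    + rng.standard_normal((n, N_ITEMS))
                )
                d_rep = moment_discrepancy(
                    sample_moments((ystar_rep > 0).astype(float)), implied, n
                )
                out["nu"][chain, keep_idx] = nu
                out["Lambda"][chain, keep_idx] = Lambda
                out["A"][chain, keep_idx] = A / sd_xc[None, :]
                out["B"][chain, keep_idx] = B / sd_xc[None, :]
                out["Psi"][chain, keep_idx] = Psi
                out["d_obs"][chain, keep_idx] = d_obs
                out["d_rep"][chain, keep_idx] = d_rep
                keep_idx += 1

        _align_chain(out, chain)

    return PosteriorDraws(
        nu=out["nu"],
        Lambda=out["Lambda"],
        A=out["A"],
        B=out["B"],
        Psi=out["Psi"],
        d_obs=out["d_obs"],
        d_rep=out["d_rep"],
        direct_columns=columns_map,
        design_columns=tuple(cols),
        X=X,
        seed=seed,
        config=cfg,
    )


def compute_ppp(draws: PosteriorDraws) -> float:
    """Posterior predictive p-value: P(D(y_rep, theta) >= D(y_obs, theta))."""
    total = draws.n_chains * draws.n_kept
    if total < 100:
        raise ValueError(f"only {total} retained iterations; need at least 100 for a PPP")
    return float(np.mean(draws.d_rep >= draws.d_obs))


# --------------------------------------------------------------------------
# standardized summaries, convergence, flags
# --------------------------------------------------------------------------

@dataclass
class MimicSummary:
    loadings: pd.DataFrame  # standardized loading summaries per (item, factor)
    b_effects: pd.DataFrame  # standardized B summaries per (factor, column)
    a_effects: pd.DataFrame  # standardized A summaries per (item, column)
    factor_correlations: pd.DataFrame
    ppp: float
    psr: pd.DataFrame
    converged: bool
    flags: pd.DataFrame = None  # filled by flag_noninvariance

    def max_psr(self) -> float:
        return float(self.psr["psr"].max())


def _summarize(draws_2d: np.ndarray) -> tuple[float, float, float, float]:
    """mean, median, 2.5%, 97.5% of a flat draw vector."""
    return (
        float(np.mean(draws_2d)),
        float(np.median(draws_2d)),
        float(np.percentile(draws_2d, 2.5)),
        float(np.percentile(draws_2d, 97.5)),
    )


def standardize(draws: PosteriorDraws, covariates: CovariateDesign) -> MimicSummary:
    """STDYX standardization per draw, then posterior summaries.

    SD(y*_j) uses the full model-implied variance (loadings, Psi, B and
    the empirical covariate covariance, residual 1); SD(eta_k) likewise
    includes the covariate contribution; binary covariates standardize by
    their sample SD.
    """
    X = covariates.matrix
    Sx = np.cov(X.T, ddof=1) if X.shape[1] > 1 else np.atleast_2d(np.var(X, ddof=1))
    sd_x = np.sqrt(np.clip(np.diag(Sx), 1e-12, None))

    c, k = draws.n_chains, draws.n_kept
    Lam = draws.Lambda
    A = draws.A
    B = draws.B
    Psi = draws.Psi

    var_eta = np.einsum("ckfp,pq,ckgq->ckfg", B, Sx, B) + Psi
    sd_eta = np.sqrt(np.einsum("ckff->ckf", var_eta))
    V = np.einsum("ckjf,ckfp->ckjp", Lam, B) + A  # reduced-form item x covariate
    var_y = (
        np.einsum("ckjp,pq,ckjq->ckj", V, Sx, V)
        + np.einsum("ckjf,ckfg,ckjg->ckj", Lam, Psi, Lam)
        + 1.0
    )
    sd_y = np.sqrt(var_y)

    lam_std = Lam * sd_eta[:, :, None, :] / sd_y[:, :, :, None]
    a_std = A * sd_x[None, None, None, :] / sd_y[:, :, :, None]
    b_std = B * sd_x[None, None, None, :] / sd_eta[:, :, :, None]
    corr_eta = var_eta / (sd_eta[:, :, :, None] * sd_eta[:, :, None, :])

    from ._instrument import FACTOR_NAMES

    rows = []
    psr_rows = []
    for j in range(N_ITEMS):
        for f in range(N_FACTORS):
            mean, med, lo, hi = _summarize(lam_std[:, :, j, f])
            rows.append(
                {
                    "item": j + 1,
                    "factor": FACTOR_NAMES[f],
                    "major": MAJOR_FACTOR[j] == f,
                    "mean": mean,
                    "median": med,
                    "ci_lower": lo,
                    "ci_upper": hi,
                }
            )
            psr_rows.append(
                {"parameter": f"lambda[{j + 1},{FACTOR_NAMES[f]}]", "psr": _split_rhat(lam_std[:, :, j, f])}
            )
    loadings = pd.DataFrame(rows)

    cols = draws.design_columns
    rows = []
    for f in range(N_FACTORS):
        for ci, col in enumerate(cols):
            mean, med, lo, hi = _summarize(b_std[:, :, f, ci])
            rows.append(
                {
                    "factor": FACTOR_NAMES[f],
                    "column": col,
                    "mean": mean,
                    "median": med,
                    "ci_lower": lo,
                    "ci_upper": hi,
                    "significant": (lo > 0) or (hi < 0),
                }
            )
            psr_rows.append({"parameter": f"b[{FACTOR_NAMES[f]},{col}]", "psr": _split_rhat(b_std[:, :, f, ci])})
    b_effects = pd.DataFrame(rows)

    col_index = {cname: i for i, cname in enumerate(cols)}
    rows = []
    for item in range(1, N_ITEMS + 1):
        for cname in draws.direct_columns.get(item, []):
            ci = col_index[cname]
            mean, med, lo, hi = _summarize(a_std[:, :, item - 1, ci])
            rows.append(
                {
                    "item": item,
                    "column": cname,
                    "mean": mean,
                    "median": med,
                    "ci_lower": lo,
                    "ci_upper": hi,
                    "noninvariant": (lo > 0) or (hi < 0),
                }
            )
            psr_rows.append({"parameter": f"a[{item},{cname}]", "psr": _split_rhat(a_std[:, :, item - 1, ci])})
    a_effects = pd.DataFrame(rows)

    rows = []
    for f in range(N_FACTORS):
        for g in range(f + 1, N_FACTORS):
            mean, med, lo, hi = _summarize(corr_eta[:, :, f, g])
            rows.append(
                {
                    "factor_1": FACTOR_NAMES[f],
                    "factor_2": FACTOR_NAMES[g],
                    "mean": mean,
                    "median": med,
                    "ci_lower": lo,
                    "ci_upper": hi,
                }
            )
    factor_correlations = pd.DataFrame(rows)

    psr = pd.DataFrame(psr_rows)
    ppp = compute_ppp(draws)
    converged = bool(psr["psr"].max() <= draws.config.psr_threshold)
    if not converged:
        warnings.warn(
            f"maximum PSR {psr['psr'].max():.3f} exceeds "
            f"{draws.config.psr_threshold}; treat flags with caution",
            stacklevel=2,
        )
    return MimicSummary(
        loadings=loadings,
        b_effects=b_effects,
        a_effects=a_effects,
        factor_correlations=factor_correlations,
        ppp=ppp,
        psr=psr,
        converged=converged,
    )


def flag_noninvariance(summary: MimicSummary, *, force: bool = False) -> pd.DataFrame:
    """Items x covariate-levels whose standardized direct-effect 95%
    credible interval excludes zero.

    Refuses to report flags from an unconverged run unless ``force``.
    """
    if not summary.converged and not force:
        raise RuntimeError(
            "sampler did not converge (PSR above threshold); rerun longer "
            "or pass force=True"
        )
    a = summary.a_effects
    flags = a.loc[a["noninvariant"]].copy()
    flags["sign"] = np.sign(flags["mean"]).astype(int)
    summary.flags = flags.reset_index(drop=True)
    return summary.flags
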