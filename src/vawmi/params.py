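"""Parameter containers for the probit MIMIC measurement model.

The model for respondent i and item j is

    eta_i   = B x_i + zeta_i,          zeta_i ~ N(0, Psi)
    y*_ij   = nu_j + lambda_j' eta_i + a_j' x_i + eps_ij,   eps_ij ~ N(0, 1)
    y_ij    = 1  iff  y*_ij > 0

with three correlated violence factors (psychological, physical, sexual),
covariate effects on the factors (B, "population heterogeneity") and
item-level direct covariate effects (A, scalar noninvariance / DIF).
Identification fixes diag(Psi) = 1 and the residual variance of y* at 1.

Parameters live on the unstandardized probit scale; reported estimates are
standardized.  Standardization here is conditional on the covariates:
SD(eta_k) = 1 (because diag(Psi) = 1) and
SD(y*_j) = sqrt(lambda_j' Psi lambda_j + 1), so that

    lambda*_j = lambda_j / SD(y*_j)
    a*_jc     = a_jc  * SD(x_c) / SD(y*_j)
    b*_kc     = b_kc  * SD(x_c)

which is exactly invertible given Psi and the covariate marginals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._instrument import MAJOR_FACTOR, N_FACTORS, N_ITEMS

__all__ = [
    "Covariate",
    "CovariateSpec",
    "MimicParameters",
    "standardized_to_probit_loadings",
]


@dataclass(frozen=True)
class Covariate:
    """A categorical survey covariate with known marginal distribution.

    ``categories`` are ordered as coded in the questionnaire; ``reference``
    must be one of them and is omitted from the dummy coding.
    """

    name: str
    categories: tuple[str, ...]
    probs: tuple[float, ...]
    reference: str

    def __post_init__(self) -> None:
        if len(self.categories) != len(self.probs):
            raise ValueError(f"{self.name}: categories/probs length mismatch")
        if self.reference not in self.categories:
            raise ValueError(f"{self.name}: reference {self.reference!r} not a category")
        total = float(np.sum(self.probs))
        if not np.isclose(total, 1.0, atol=1e-8):
            raise ValueError(f"{self.name}: marginal probabilities sum to {total}")
        if np.any(np.asarray(self.probs) < 0):
            raise ValueError(f"{self.name}: negative marginal probability")

    @property
    def dummy_levels(self) -> tuple[str, ...]:
        """Non-reference categories, in coded order."""
        return tuple(c for c in self.categories if c != self.reference)

    @property
    def dummy_columns(self) -> tuple[str, ...]:
        return tuple(f"{self.name}:{c}" for c in self.dummy_levels)


class CovariateSpec:
    """An ordered collection of categorical covariates.

    Provides the dummy-coded design layout (k-1 indicator columns per
    covariate, reference omitted) shared by the generator, the reader and
    the models.
    """

    def __init__(self, covariates: list[Covariate] | tuple[Covariate, ...]):
        self.covariates = tuple(covariates)
        names = [c.name for c in self.covariates]
        if len(set(names)) != len(names):
            raise ValueError("duplicate covariate names")

    def __iter__(self):
        return iter(self.covariates)

    def __len__(self) -> int:
        return len(self.covariates)

    def __getitem__(self, name: str) -> Covariate:
        for c in self.covariates:
            if c.name == name:
                return c
        raise KeyError(name)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.covariates)

    @property
    def dummy_columns(self) -> tuple[str, ...]:
        cols: list[str] = []
        for c in self.covariates:
            cols.extend(c.dummy_columns)
        return tuple(cols)

    @property
    def n_dummies(self) -> int:
        return len(self.dummy_columns)

    def dummy_marginal_probs(self) -> np.ndarray:
        """P(x_c = 1) for each dummy column, under the stated marginals."""
        probs: list[float] = []
        for c in self.covariates:
            for cat, p in zip(c.categories, c.probs):
                if cat != c.reference:
                    probs.append(float(p))
        return np.asarray(probs)

    def dummy_sd(self) -> np.ndarray:
        """Bernoulli SDs sqrt(p(1-p)) of the dummy columns."""
        p = self.dummy_marginal_probs()
        return np.sqrt(p * (1.0 - p))

    def block_slices(self) -> dict[str, slice]:
        """Column slice of each covariate's dummy block in the design."""
        out: dict[str, slice] = {}
        start = 0
        for c in self.covariates:
            k = len(c.dummy_levels)
            out[c.name] = slice(start, start + k)
            start += k
        return out

    def linear_predictor_distribution(self, coef: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Exact distribution of coef'x under independent covariates.

        Returns (values, probabilities) of the discrete random variable
        sum_c coef_c x_c, built by convolving the per-covariate blocks.
        Used for closed-form marginal item prevalences.
        """
        coef = np.asarray(coef, dtype=float)
        if coef.shape != (self.n_dummies,):
            raise ValueError("coefficient length does not match dummy columns")
        values = np.zeros(1)
        probs = np.ones(1)
        for c, sl in zip(self.covariates, self.block_slices().values()):
            block = coef[sl]
            # contribution of this covariate: 0 for the reference level,
            # block[k] for the k-th non-reference level
            contrib, weight = [], []
            k = 0
            for cat, p in zip(c.categories, c.probs):
                if cat == c.reference:
                    contrib.append(0.0)
                else:
                    contrib.append(float(block[k]))
                    k += 1
                weight.append(float(p))
            contrib_a = np.asarray(contrib)
            weight_a = np.asarray(weight)
            if np.allclose(contrib_a, 0.0):
                continue
            values = (values[:, None] + contrib_a[None, :]).ravel()
            probs = (probs[:, None] * weight_a[None, :]).ravel()
            if values.size > 300_000:  # collapse duplicates to keep support small
                values, inv = np.unique(np.round(values, 12), return_inverse=True)
                probs = np.bincount(inv, weights=probs)
        return values, probs


def _check_psd(mat: np.ndarray, name: str) -> None:
    if not np.allclose(mat, mat.T, atol=1e-10):
        raise ValueError(f"{name} is not symmetric")
    eigvals = np.linalg.eigvalsh(mat)
    if eigvals.min() <= 0:
        raise ValueError(
            f"{name} is not positive definite (min eigenvalue {eigvals.min():.3e})"
        )


@dataclass
class MimicParameters:
    """Full parameter set of the probit MIMIC model (probit scale)."""

    nu: np.ndarray  # (15,) item intercepts
    Lambda: np.ndarray  # (15, 3) loadings
    A: np.ndarray  # (15, p) item-level direct effects
    B: np.ndarray  # (3, p) covariate effects on the factors
    Psi: np.ndarray  # (3, 3) factor residual covariance, diag fixed at 1
    covariate_spec: CovariateSpec
    major_factor: tuple[int, ...] = field(default=MAJOR_FACTOR)

    def __post_init__(self) -> None:
        self.nu = np.asarray(self.nu, dtype=float)
        self.Lambda = np.asarray(self.Lambda, dtype=float)
        self.A = np.asarray(self.A, dtype=float)
        self.B = np.asarray(self.B, dtype=float)
        self.Psi = np.asarray(self.Psi, dtype=float)
        p = self.covariate_spec.n_dummies
        if self.nu.shape != (N_ITEMS,):
            raise ValueError(f"nu must have shape ({N_ITEMS},)")
        if self.Lambda.shape != (N_ITEMS, N_FACTORS):
            raise ValueError(f"Lambda must have shape ({N_ITEMS}, {N_FACTORS})")
        if self.A.shape != (N_ITEMS, p):
            raise ValueError(f"A must have shape ({N_ITEMS}, {p})")
        if self.B.shape != (N_FACTORS, p):
            raise ValueError(f"B must have shape ({N_FACTORS}, {p})")
        if self.Psi.shape != (N_FACTORS, N_FACTORS):
            raise ValueError("Psi must be 3x3")
        _check_psd(self.Psi, "Psi")
        if len(self.major_factor) != N_ITEMS:
            raise ValueError("major_factor must designate one factor per item")

    # ----- standardization ------------------------------------------------

    def ystar_sd(self) -> np.ndarray:
        """Model-implied SD of y* conditional on x: sqrt(l'Psi l + 1)."""
        quad = np.einsum("jk,kl,jl->j", self.Lambda, self.Psi, self.Lambda)
        return np.sqrt(quad + 1.0)

    def standardized_loadings(self) -> np.ndarray:
        return self.Lambda / self.ystar_sd()[:, None]

    def standardized_direct_effects(self) -> np.ndarray:
        sx = self.covariate_spec.dummy_sd()
        return self.A * sx[None, :] / self.ystar_sd()[:, None]

    def standardized_factor_effects(self) -> np.ndarray:
        return self.B * self.covariate_spec.dummy_sd()[None, :]

    def communalities(self) -> np.ndarray:
        """Standardized communality h*_j = l*' Psi l* per item."""
        L = self.standardized_loadings()
        return np.einsum("jk,kl,jl->j", L, self.Psi, L)


def standardized_to_probit_loadings(L_std: np.ndarray, Psi: np.ndarray) -> np.ndarray:
    """Invert the loading standardization.

    Given standardized loadings L* and factor correlation matrix Psi, the
    probit-scale row is lambda_j = L*_j / sqrt(1 - h*_j) with
    h*_j = L*_j' Psi L*_j.  Requires h*_j < 1 (communality below one).
    """
    L_std = np.asarray(L_std, dtype=float)
    h = np.einsum("jk,kl,jl->j", L_std, Psi, L_std)
    if np.any(h >= 1.0):
        bad = int(np.argmax(h))
        raise ValueError(
            f"standardized communality >= 1 for item {bad + 1} (h*={h[bad]:.4f})"
        )
    return L_std / np.sqrt(1.0 - h)[:, None]
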