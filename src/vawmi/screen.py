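"""Two-stage frequentist covariate screen for item-level direct effects.

For each of the 15 items, a probit model adjusted for the always-retained
set {invited, site, age} is fit with one candidate covariate at a time;
candidates significant by likelihood-ratio test at p <= 0.10 enter a
per-item multivariable probit, and those still significant at p <= 0.05
(jointly over their k-1 dummy columns) define the item's direct-effect set
in the MIMIC model.  The adjustment covariates are always retained in the
structural part regardless of significance.

No multiple-testing correction is applied across items (a deliberate
mirror of the original screening procedure; treat stage-2 survivors as a
screen, not as confirmatory inference).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import chi2

from ._instrument import N_ITEMS
from .containers import CovariateDesign, ItemResponseMatrix

__all__ = ["ProbitFit", "probit_fit", "lrt", "ScreenResult", "run_screen", "ALWAYS_RETAINED"]

ALWAYS_RETAINED = ("invited", "site", "agegrp")


@dataclass
class ProbitFit:
    params: np.ndarray
    loglik: float
    converged: bool
    separation: bool
    ridge_penalty: float = 0.0


def _ridge_probit(y: np.ndarray, X: np.ndarray, penalty: float) -> tuple[np.ndarray, float]:
    """Newton iterations for a ridge-penalized probit (separation fallback)."""
    from scipy.special import log_ndtr, ndtr

    beta = np.zeros(X.shape[1])
    for _ in range(200):
        xb = X @ beta
        pdf = np.exp(-0.5 * xb**2) / np.sqrt(2 * np.pi)
        cdf = np.clip(ndtr(xb), 1e-12, 1 - 1e-12)
        # score and expected information of the probit log-likelihood
        w = pdf / (cdf * (1 - cdf))
        score = X.T @ (w * (y - cdf)) - penalty * beta
        H = (X * (w * pdf)[:, None]).T @ X + penalty * np.eye(X.shape[1])
        step = np.linalg.solve(H, score)
        beta = beta + step
        if np.linalg.norm(score) < 1e-8:
            break
    xb = X @ beta
    ll = float(np.sum(np.where(y > 0, log_ndtr(xb), log_ndtr(-xb))))
    return beta, ll


def probit_fit(y: np.ndarray, X: np.ndarray, *, add_intercept: bool = True) -> ProbitFit:
    """ML probit regression (Newton); ridge fallback under separation.

    X must be full column rank after adding the intercept; perfect
    separation is flagged and handled with a small ridge penalty (1e-4)
    rather than treated as fatal.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    design = sm.add_constant(X, has_constant="add") if add_intercept else X
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        raise ValueError("design matrix is rank deficient")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Probit(y, design).fit(method="newton", disp=0, maxiter=100, tol=1e-10)
            params = np.asarray(res.params)
            ll = float(res.llf)
            converged = bool(res.mle_retvals.get("converged", True))
            separated = (not converged) or np.any(np.abs(params) > 25)
        except Exception:
            separated, converged = True, False
    if separated:
        params, ll = _ridge_probit(y, design, penalty=1e-4)
        warnings.warn("perfect separation suspected; ridge fallback applied", stacklevel=2)
        return ProbitFit(params=params, loglik=ll, converged=True, separation=True, ridge_penalty=1e-4)
    return ProbitFit(params=params, loglik=ll, converged=converged, separation=False)


def lrt(ll_full: float, ll_reduced: float, df_diff: int) -> tuple[float, float]:
    """Likelihood-ratio statistic 2*(ll_full - ll_reduced) and its p-value."""
    if df_diff < 1:
        raise ValueError("df_diff must be >= 1")
    if ll_full < ll_reduced - 1e-8:
        raise ValueError(
            f"full-model log-likelihood {ll_full:.6f} below reduced "
            f"{ll_reduced:.6f}: models are not nested as assumed"
        )
    stat = max(2.0 * (ll_full - ll_reduced), 0.0)
    return stat, float(chi2.sf(stat, df_diff))


@dataclass
class ScreenResult:
    """Per-item LRT screen results and the final direct-effect map."""

    stage1_p: pd.DataFrame  # items x candidate covariates, LRT p-values
    stage2_p: pd.DataFrame  # items x covariates (NaN if not a stage-2 candidate)
    direct_map: dict[int, list[str]]  # 1-based item -> covariate names
    always_retained: tuple[str, ...] = field(default=ALWAYS_RETAINED)
    dropped: list[str] = field(default_factory=list)

    def direct_map_columns(self, design: CovariateDesign) -> dict[int, list[str]]:
        """Expand covariate names to dummy-column names per item."""
        out: dict[int, list[str]] = {}
        for item, covs in self.direct_map.items():
            cols: list[str] = []
            for cov in covs:
                cols.extend(design.spec[cov].dummy_columns)
            out[item] = cols
        return out


def _fit_blocks(
    y: np.ndarray, design: CovariateDesign, covariates: list[str]
) -> ProbitFit:
    if covariates:
        X = np.hstack([design.block(c) for c in covariates])
    else:
        X = np.empty((design.n, 0))
    return probit_fit(y, X)


def run_screen(
    responses: ItemResponseMatrix,
    covariates: CovariateDesign,
    alpha1: float = 0.10,
    alpha2: float = 0.05,
) -> ScreenResult:
    """The two-stage per-item LRT screen.

    Multi-category covariates are tested as a block (df = k-1).  Constant
    covariates are dropped with a warning and can never be selected.
    Items with very few positive responses are fit anyway, with a warning.
    """
    spec = covariates.spec
    missing = [c for c in ALWAYS_RETAINED if c not in spec.names]
    if missing:
        raise ValueError(f"always-retained covariates missing from design: {missing}")

    dropped = []
    candidates = []
    for cov in spec:
        if cov.name in ALWAYS_RETAINED:
            continue
        block = covariates.block(cov.name)
        if np.all(block.std(axis=0) == 0):
            warnings.warn(f"covariate {cov.name!r} is constant; dropped", stacklevel=2)
            dropped.append(cov.name)
        else:
            candidates.append(cov.name)

    adjust = list(ALWAYS_RETAINED)
    items = range(1, N_ITEMS + 1)
    stage1 = pd.DataFrame(index=list(items), columns=candidates, dtype=float)
    stage2 = pd.DataFrame(index=list(items), columns=candidates, dtype=float)
    direct_map: dict[int, list[str]] = {}

    for item in items:
        y = responses.values[:, item - 1].astype(float)
        if y.sum() < 5 or (1 - y).sum() < 5:
            warnings.warn(
                f"item {item} has fewer than 5 responses in one outcome; "
                "screen attempted anyway",
                stacklevel=2,
            )
        base = _fit_blocks(y, covariates, adjust)
        for cov in candidates:
            aug = _fit_blocks(y, covariates, adjust + [cov])
            df_diff = covariates.block(cov).shape[1]
            try:
                _, p = lrt(aug.loglik, base.loglik, df_diff)
            except ValueError:
                p = 1.0  # numerically degenerate fit: treat as no evidence
            stage1.loc[item, cov] = p

        survivors = [c for c in candidates if stage1.loc[item, c] <= alpha1]
        kept: list[str] = []
        if survivors:
            full = _fit_blocks(y, covariates, adjust + survivors)
            for cov in survivors:
                others = [c for c in survivors if c != cov]
                reduced = _fit_blocks(y, covariates, adjust + others)
                df_diff = covariates.block(cov).shape[1]
                try:
                    _, p = lrt(full.loglik, reduced.loglik, df_diff)
                except ValueError:
                    p = 1.0
                stage2.loc[item, cov] = p
                if p <= alpha2:
                    kept.append(cov)
        direct_map[item] = kept

    return ScreenResult(
        stage1_p=stage1, stage2_p=stage2, direct_map=direct_map, dropped=dropped
    )
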