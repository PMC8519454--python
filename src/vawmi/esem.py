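"""Exploratory 3-factor model on tetrachoric correlations.

Estimation is diagonally-weighted least squares (DWLS): the non-redundant
tetrachoric correlations s are fit by the factor-implied correlations
sigma(Lambda) minimizing

    F = sum_r (s_r - sigma_r)^2 / v_r,

with v_r the asymptotic variance of each tetrachoric estimate.  The
unrotated solution (orthogonal factors) is then obliquely rotated with the
Geomin criterion (epsilon = 0.001) by gradient projection, with multiple
seeded random starts because Geomin has local minima.  Fit indices follow
the categorical-data conventions: chi-square T = n * F_min (an unadjusted
DWLS statistic; the mean-and-variance adjusted statistic used by
commercial software is proprietary and is approximated only up to this
unadjusted form), CFI/TLI against the independence baseline, RMSEA with a
90% CI from inverting the noncentral chi-square CDF, and WRMR.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, minimize
from scipy.stats import ncx2

from ._instrument import MAJOR_FACTOR, N_FACTORS, N_ITEMS
from .tetrachoric import TetrachoricResult

__all__ = [
    "UnrotatedSolution",
    "EsemSolution",
    "extract_unrotated",
    "geomin_criterion",
    "rotate_geomin",
    "fit_indices",
    "fit_esem",
]

UNIQUENESS_FLOOR = 1e-3


# --------------------------------------------------------------------------
# DWLS extraction
# --------------------------------------------------------------------------

@dataclass
class UnrotatedSolution:
    Lambda: np.ndarray  # (p, m), orthogonal factors
    F_min: float  # DWLS discrepancy on the chi-square scale basis
    n: int
    weights: np.ndarray  # (p, p) Var(s_r) used in the weighting
    s: np.ndarray  # (p, p) sample correlation matrix fitted
    converged: bool
    heywood: np.ndarray  # (p,) items whose uniqueness hit the floor
    grad_norm: float

    @property
    def df(self) -> int:
        p, m = self.Lambda.shape
        return p * (p - 1) // 2 - (p * m - m * (m - 1) // 2)

    @property
    def chi_square(self) -> float:
        return self.n * self.F_min


def _offdiag_mask(p: int) -> np.ndarray:
    return ~np.eye(p, dtype=bool)


def _dwls_objective(L_flat: np.ndarray, S: np.ndarray, W: np.ndarray, p: int, m: int):
    """F and gradient; W = 1/v elementwise (zero diagonal)."""
    L = L_flat.reshape(p, m)
    R = L @ L.T - S
    E = R * W  # symmetric, zero diagonal
    f = 0.5 * float(np.sum(E * R))  # counts each pair once
    g = 2.0 * E @ L
    return f, g.ravel()


def extract_unrotated(
    tet: TetrachoricResult,
    n_factors: int,
    n: int | None = None,
) -> UnrotatedSolution:
    """Minimize the DWLS discrepancy over an unrotated p x m loading matrix.

    Weights are the asymptotic variances of the tetrachoric estimates; the
    discrepancy is scaled so that T = n * F_min is a chi-square statistic.
    Heywood rows (communality > 1 - floor) are rescaled onto the admissible
    boundary and flagged rather than treated as fatal.
    """
    S = np.asarray(tet.rho, dtype=float)
    p = S.shape[0]
    m = int(n_factors)
    if m < 1 or p * m - m * (m - 1) // 2 > p * (p - 1) // 2:
        raise ValueError(f"{m} factors is inadmissible for {p} items")
    n = int(n if n is not None else tet.n)

    var_s = np.asarray(tet.rho_var, dtype=float) * n  # unit-level variances
    var_s = np.where(_offdiag_mask(p), np.clip(var_s, 1e-12, None), np.inf)
    W = np.where(_offdiag_mask(p), 1.0 / var_s, 0.0)

    # principal-factor start: reduced correlation matrix with squared
    # multiple correlations on the diagonal (keeps degenerate inputs, e.g.
    # identity rho, at the zero-loading solution)
    smc = 1.0 - 1.0 / np.diag(np.linalg.inv(S + 1e-8 * np.eye(p)))
    S_red = S.copy()
    np.fill_diagonal(S_red, np.clip(smc, 0.0, 1.0))
    eigvals, eigvecs = np.linalg.eigh(S_red)
    order = np.argsort(eigvals)[::-1]
    L0 = eigvecs[:, order[:m]] * np.sqrt(np.clip(eigvals[order[:m]], 0.0, None))

    res = minimize(
        _dwls_objective,
        L0.ravel(),
        args=(S, W, p, m),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": 5000, "gtol": 1e-10, "ftol": 1e-15},
    )
    L = res.x.reshape(p, m)

    h = np.sum(L**2, axis=1)
    heywood = h > 1.0 - UNIQUENESS_FLOOR
    if heywood.any():
        scale = np.sqrt((1.0 - UNIQUENESS_FLOOR) / h[heywood])
        L[heywood] *= scale[:, None]
    f, g = _dwls_objective(L.ravel(), S, W, p, m)
    # F uses unit-level weights n*Var(s_r), so T = n * F is the chi-square
    return UnrotatedSolution(
        Lambda=L,
        F_min=f,
        n=n,
        weights=var_s / n,  # actual Var(s_r) at this sample size
        s=S,
        converged=bool(res.success),
        heywood=heywood,
        grad_norm=float(np.linalg.norm(g)),
    )


def baseline_chi_square(tet: TetrachoricResult, n: int | None = None) -> tuple[float, int]:
    """Independence baseline (all correlations zero, thresholds free)."""
    n = int(n if n is not None else tet.n)
    p = tet.rho.shape[0]
    mask = np.triu(_offdiag_mask(p))
    var_s = np.clip(tet.rho_var[mask], 1e-12, None)
    T_B = float(np.sum(tet.rho[mask] ** 2 / var_s))
    return T_B, p * (p - 1) // 2


# --------------------------------------------------------------------------
# Geomin rotation
# --------------------------------------------------------------------------

def geomin_criterion(Lambda: np.ndarray, epsilon: float = 0.001) -> float:
    """sum_j ( prod_k (lambda_jk^2 + eps) )^(1/m)."""
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    L2 = np.asarray(Lambda, dtype=float) ** 2 + epsilon
    m = L2.shape[1]
    return float(np.sum(np.exp(np.mean(np.log(L2), axis=1))))


def _geomin_grad(Lambda: np.ndarray, epsilon: float) -> tuple[float, np.ndarray]:
    L2 = Lambda**2 + epsilon
    m = L2.shape[1]
    row = np.exp(np.mean(np.log(L2), axis=1))
    f = float(np.sum(row))
    G = (2.0 / m) * row[:, None] * Lambda / L2
    return f, G


def _gpa_oblique(
    A: np.ndarray, T0: np.ndarray, epsilon: float, tol: float = 1e-6, maxiter: int = 2000
) -> tuple[np.ndarray, np.ndarray, float, bool]:
    """Oblique gradient-projection rotation (Jennrich 2002) of A by T0.

    Stops when the projected gradient norm falls below ``tol`` or when the
    line search can no longer improve the criterion within float precision
    (stagnation with a small gradient also counts as converged).
    """
    T = T0.copy()
    Ti = np.linalg.inv(T)
    L = A @ Ti.T
    f, Gq = _geomin_grad(L, epsilon)
    G = -(L.T @ Gq @ Ti).T
    al = 1.0
    converged = False
    for _ in range(maxiter):
        Gp = G - T * (T * G).sum(axis=0)
        s = np.linalg.norm(Gp)
        if s < tol:
            converged = True
            break
        al *= 2.0
        improved = False
        for _ in range(60):
            X = T - al * Gp
            v = 1.0 / np.sqrt((X**2).sum(axis=0))
            Tt = X * v
            Ti = np.linalg.inv(Tt)
            L = A @ Ti.T
            ft, Gqt = _geomin_grad(L, epsilon)
            if ft < f - 0.5 * s**2 * al:
                improved = True
                break
            al /= 2.0
        if not improved:
            converged = s < 1e-3  # stagnated at float precision near optimum
            L = A @ np.linalg.inv(T).T
            break
        T, f = Tt, ft
        G = -(L.T @ Gqt @ Ti).T
    Phi = T.T @ T
    return L, Phi, f, converged


def _align_to_pattern(L: np.ndarray, Phi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Permute/sign-flip columns to the WHO domain order (psych, phys, sex).

    Permutation by maximal absolute column congruence with the WHO major
    pattern; each column's sign set so its largest-magnitude loading is
    positive.
    """
    p, m = L.shape
    if m > 1:
        target = np.zeros((p, m))
        for j in range(min(p, N_ITEMS)):
            k = MAJOR_FACTOR[j]
            if k < m:
                target[j, k] = 1.0
        absL = np.abs(L)
        congr = (absL / np.linalg.norm(absL, axis=0)).T @ (
            target / np.clip(np.linalg.norm(target, axis=0), 1e-12, None)
        )  # (m, m): rotated column x target column
        # perm[l] = rotated column assigned to target position l
        best_perm = max(
            itertools.permutations(range(m)),
            key=lambda perm: sum(congr[perm[l], l] for l in range(m)),
        )
        order = list(best_perm)
        L = L[:, order]
        Phi = Phi[np.ix_(order, order)]
    signs = np.sign(L[np.argmax(np.abs(L), axis=0), np.arange(m)])
    signs[signs == 0] = 1.0
    L = L * signs
    Phi = Phi * np.outer(signs, signs)
    return L, Phi


@dataclass
class RotationDiagnostics:
    criterion: float
    n_starts: int
    chosen_start: int
    start_criteria: np.ndarray
    converged: bool


def rotate_geomin(
    unrotated: np.ndarray,
    epsilon: float = 0.001,
    n_starts: int = 30,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, RotationDiagnostics]:
    """Oblique Geomin rotation with seeded random orthonormal starts.

    The identity start is always included; the best converged criterion
    wins, ties within 1e-8 broken by lexicographic loading order.
    """
    A = np.asarray(unrotated, dtype=float)
    m = A.shape[1]
    rng = np.random.default_rng(seed)
    starts = [np.eye(m)]
    for _ in range(max(n_starts - 1, 0)):
        Q, _ = np.linalg.qr(rng.standard_normal((m, m)))
        starts.append(Q)

    results = []
    for T0 in starts:
        try:
            results.append(_gpa_oblique(A, T0, epsilon))
        except np.linalg.LinAlgError:
            continue
    if not any(r[3] for r in results):
        raise RuntimeError(
            "Geomin rotation failed to converge from any start; criteria: "
            + ", ".join(f"{r[2]:.6g}" for r in results)
        )
    crit = np.array([r[2] if r[3] else np.inf for r in results])
    best = int(np.argmin(crit))
    # tie-break within 1e-8 by lexicographic order of the aligned loadings
    tied = np.flatnonzero(crit <= crit[best] + 1e-8)
    if len(tied) > 1:
        aligned = {i: _align_to_pattern(results[i][0], results[i][1]) for i in tied}
        best = int(min(tied, key=lambda i: tuple(np.round(aligned[i][0].ravel(), 10))))
    L, Phi, f, _ = results[best]
    L, Phi = _align_to_pattern(L, Phi)
    diag = RotationDiagnostics(
        criterion=float(f),
        n_starts=len(starts),
        chosen_start=best,
        start_criteria=crit,
        converged=True,
    )
    return L, Phi, diag


# --------------------------------------------------------------------------
# fit indices
# --------------------------------------------------------------------------

def _rmsea_ci(T: float, df: int, n: int, level: float = 0.90) -> tuple[float, float]:
    """Invert the noncentral chi-square CDF in the noncentrality parameter."""
    lo_q, hi_q = (1.0 + level) / 2.0, (1.0 - level) / 2.0  # 0.95, 0.05

    def nc_solving(q: float) -> float:
        # find nc with ncx2.cdf(T; df, nc) = q; cdf decreases in nc
        f = lambda nc: ncx2.cdf(T, df, nc) - q
        if f(0.0) < 0:  # even nc=0 puts too little mass below T
            return 0.0
        hi = max(T, 1.0)
        while f(hi) > 0:
            hi *= 2.0
            if hi > 1e8:
                return hi
        return brentq(f, 0.0, hi, xtol=1e-10)

    nc_lo = nc_solving(lo_q)
    nc_hi = nc_solving(hi_q)
    return (
        float(np.sqrt(nc_lo / (df * n))),
        float(np.sqrt(nc_hi / (df * n))),
    )


def fit_indices(
    T: float,
    df: int,
    T_B: float,
    df_B: int,
    n: int,
    residuals: np.ndarray,
    weights: np.ndarray,
) -> dict:
    """CFI, TLI, RMSEA (+90% CI) and WRMR.

    ``residuals`` are the e non-redundant (s_r - sigma_r) values and
    ``weights`` their asymptotic variances Var(s_r).
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    if df_B <= df:
        raise ValueError("baseline df must exceed model df (misconstructed baseline)")
    num = max(T - df, 0.0)
    den = max(T_B - df_B, 0.0)
    cfi = 1.0 if den == 0 else 1.0 - num / max(den, num)
    ratio_b = T_B / df_B
    tli = 1.0 if ratio_b <= 1.0 else (ratio_b - T / df) / (ratio_b - 1.0)
    tli = float(np.clip(tli, 0.0, 1.0))
    cfi = float(np.clip(cfi, 0.0, 1.0))
    rmsea = float(np.sqrt(num / (df * n)))
    ci = _rmsea_ci(T, df, n)
    residuals = np.asarray(residuals, dtype=float)
    weights = np.clip(np.asarray(weights, dtype=float), 1e-12, None)
    wrmr = float(np.sqrt(np.mean(residuals**2 / weights)))
    return {
        "chi_square": float(T),
        "df": int(df),
        "baseline_chi_square": float(T_B),
        "baseline_df": int(df_B),
        "CFI": cfi,
        "TLI": tli,
        "RMSEA": rmsea,
        "RMSEA_90CI": (min(ci), max(max(ci[0], rmsea), ci[1])),
        "WRMR": wrmr,
    }


# --------------------------------------------------------------------------
# one-call front end
# --------------------------------------------------------------------------

@dataclass
class EsemSolution:
    Lambda_rotated: np.ndarray
    Phi: np.ndarray
    communalities: np.ndarray
    F_min: float
    fit: dict
    rotation: RotationDiagnostics
    unrotated: UnrotatedSolution = field(repr=False)

    def implied_correlations(self) -> np.ndarray:
        R = self.Lambda_rotated @ self.Phi @ self.Lambda_rotated.T
        np.fill_diagonal(R, 1.0)
        return R


def fit_esem(
    tet: TetrachoricResult,
    n_factors: int = N_FACTORS,
    *,
    n: int | None = None,
    epsilon: float = 0.001,
    n_starts: int = 30,
    seed: int = 0,
) -> EsemSolution:
    """DWLS extraction + Geomin rotation + fit indices, end to end."""
    unrot = extract_unrotated(tet, n_factors, n=n)
    L, Phi, diag = rotate_geomin(unrot.Lambda, epsilon=epsilon, n_starts=n_starts, seed=seed)
    T = unrot.chi_square
    T_B, df_B = baseline_chi_square(tet, n=unrot.n)
    p = L.shape[0]
    mask = np.triu(_offdiag_mask(p))
    implied = L @ Phi @ L.T
    resid = (tet.rho - implied)[mask]
    fit = fit_indices(T, unrot.df, T_B, df_B, unrot.n, resid, unrot.weights[mask])
    comm = np.einsum("jk,kl,jl->j", L, Phi, L)
    return EsemSolution(
        Lambda_rotated=L,
        Phi=Phi,
        communalities=comm,
        F_min=unrot.F_min,
        fit=fit,
        rotation=diag,
        unrotated=unrot,
    )
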