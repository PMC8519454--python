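"""Descriptive surface of the survey: per-item prevalence, the
acts-of-violence distribution (overall and stratified), sample summaries,
and the PCA wealth index.

"At least half" of the 15 acts is interpreted as >= 8 (the smallest
integer no less than 7.5).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._instrument import DOMAIN_MAP, ITEM_LABELS, N_ITEMS
from .containers import CovariateDesign, ItemResponseMatrix

__all__ = [
    "item_prevalence",
    "acts_distribution",
    "wealth_index",
    "summarize_sample",
    "HALF_OF_ITEMS",
]

HALF_OF_ITEMS = 8  # smallest integer >= 15/2


def item_prevalence(
    responses: ItemResponseMatrix, by: pd.Series | np.ndarray | None = None
) -> pd.DataFrame:
    """Percent reporting "yes" per item, optionally per stratum.

    Returns a tidy frame: item, label, domain, (stratum,) n, n_yes, percent.
    """
    if responses.n == 0:
        raise ValueError("empty response matrix")
    vals = responses.values

    def _one(block: np.ndarray, stratum=None) -> pd.DataFrame:
        out = pd.DataFrame(
            {
                "item": np.arange(1, N_ITEMS + 1),
                "label": list(ITEM_LABELS),
                "domain": [DOMAIN_MAP[j] for j in range(N_ITEMS)],
                "n": block.shape[0],
                "n_yes": block.sum(axis=0),
                "percent": 100.0 * block.mean(axis=0),
            }
        )
        if stratum is not None:
            out.insert(0, "stratum", stratum)
        return out

    if by is None:
        return _one(vals)
    by = pd.Series(np.asarray(by), name="stratum")
    frames = [_one(vals[(by == s).to_numpy()], s) for s in by.unique()]
    return pd.concat(frames, ignore_index=True)


@dataclass
class ActsDistribution:
    """Per-respondent act counts and the cumulative >=k table."""

    counts: np.ndarray  # per-respondent number of acts (0..15)
    table: pd.DataFrame  # threshold k, n_at_least, pct_at_least (x stratum)

    @property
    def n_at_least_one(self) -> int:
        return int((self.counts >= 1).sum())

    @property
    def n_at_least_half(self) -> int:
        return int((self.counts >= HALF_OF_ITEMS).sum())


def acts_distribution(
    responses: ItemResponseMatrix, by: pd.Series | np.ndarray | None = None
) -> ActsDistribution:
    """Cumulative counts/percentages of respondents with >= k acts, k=1..15."""
    if responses.n == 0:
        raise ValueError("empty response matrix")
    counts = responses.values.sum(axis=1)
    ks = np.arange(1, N_ITEMS + 1)

    def _one(c: np.ndarray, stratum=None) -> pd.DataFrame:
        at_least = np.array([(c >= k).sum() for k in ks])
        out = pd.DataFrame(
            {
                "threshold": ks,
                "n_at_least": at_least,
                "pct_at_least": 100.0 * at_least / max(len(c), 1),
            }
        )
        if stratum is not None:
            out.insert(0, "stratum", stratum)
        return out

    if by is None:
        table = _one(counts)
    else:
        by = pd.Series(np.asarray(by), name="stratum")
        table = pd.concat(
            [_one(counts[(by == s).to_numpy()], s) for s in by.unique()],
            ignore_index=True,
        )
    return ActsDistribution(counts=counts, table=table)


def wealth_index(assets: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """First-principal-component wealth score and tercile assignment.

    PCA is on the correlation matrix of the binary asset indicators (the
    standard survey-wealth convention).  The component is oriented so the
    score correlates positively with the total number of assets owned.
    Terciles cut at the 33.33/66.67 percentiles; ties go to the lower
    group (respondents with equal scores always share a tercile).

    Returns (score, tercile in {1,2,3}, component loadings over kept columns).
    """
    assets = np.asarray(assets, dtype=float)
    if assets.ndim != 2:
        raise ValueError("assets must be a 2-D matrix")
    sd = assets.std(axis=0, ddof=1)
    keep = sd > 0
    if keep.sum() < 2:
        raise ValueError("need at least 2 asset columns with nonzero variance")
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} zero-variance asset column(s)",
            stacklevel=2,
        )
    Z = (assets[:, keep] - assets[:, keep].mean(axis=0)) / sd[keep]
    corr = np.corrcoef(Z, rowvar=False)
    eigvals, eigvecs = np.linalg.eigh(corr)
    pc1 = eigvecs[:, -1]
    score = Z @ pc1
    total = assets.sum(axis=1)
    if np.corrcoef(score, total)[0, 1] < 0:
        pc1, score = -pc1, -score
    lo, hi = np.percentile(score, [100 / 3, 200 / 3])
    tercile = np.where(score <= lo, 1, np.where(score <= hi, 2, 3))
    return score, tercile, pc1


def plot_prevalence(table: pd.DataFrame, path) -> None:
    """Horizontal bar chart of per-item prevalence (PNG). Optional: needs
    matplotlib."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 5))
    t = table.sort_values("item", ascending=False)
    ax.barh([f"item {i}" for i in t["item"]], t["percent"], color="#4878a8")
    ax.set_xlabel("% reporting the act (past 12 months)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_acts_curves(dist: ActsDistribution, path) -> None:
    """Cumulative >=k curves, one line per stratum if stratified (PNG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    t = dist.table
    if "stratum" in t.columns:
        for s, g in t.groupby("stratum"):
            ax.plot(g["threshold"], g["pct_at_least"], marker="o", label=str(s))
        ax.legend()
    else:
        ax.plot(t["threshold"], t["pct_at_least"], marker="o")
    ax.set_xlabel("number of acts k")
    ax.set_ylabel("% with >= k acts")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def summarize_sample(covariates: CovariateDesign) -> pd.DataFrame:
    """Counts and percentages per category per covariate (raw columns)."""
    if covariates.raw is None:
        raise ValueError("design carries no raw categorical columns")
    raw = covariates.raw
    rows = []
    for cov in covariates.spec:
        counts = raw[cov.name].astype(str).value_counts()
        for cat in cov.categories:
            c = int(counts.get(cat, 0))
            rows.append(
                {
                    "covariate": cov.name,
                    "category": cat,
                    "reference": cat == cov.reference,
                    "n": c,
                    "percent": 100.0 * c / len(raw),
                }
            )
    return pd.DataFrame(rows)
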