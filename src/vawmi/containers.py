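"""In-memory containers shared by the generator, IO and the models."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._instrument import DOMAIN_MAP, ITEM_COLUMNS, ITEM_LABELS, N_ITEMS
from .params import CovariateSpec

__all__ = ["ItemResponseMatrix", "CovariateDesign", "dummy_code"]


@dataclass
class ItemResponseMatrix:
    """n x 15 binary responses to the WHO VAW items."""

    values: np.ndarray
    item_labels: tuple[str, ...] = field(default=ITEM_LABELS)
    domain_map: dict[int, str] = field(default_factory=lambda: dict(DOMAIN_MAP))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2 or self.values.shape[1] != N_ITEMS:
            raise ValueError(f"expected an n x {N_ITEMS} matrix, got {self.values.shape}")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("item responses must be 0/1")
        self.values = self.values.astype(np.int8)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=list(ITEM_COLUMNS))


@dataclass
class CovariateDesign:
    """Dummy-coded covariate design plus the raw categorical columns."""

    matrix: np.ndarray  # (n, p) 0/1 indicators
    spec: CovariateSpec
    raw: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != self.spec.n_dummies:
            raise ValueError(
                f"design has {self.matrix.shape[1]} columns, spec expects "
                f"{self.spec.n_dummies}"
            )

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def columns(self) -> tuple[str, ...]:
        return self.spec.dummy_columns

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, columns=list(self.columns))

    def block(self, covariate: str) -> np.ndarray:
        """The dummy columns belonging to one covariate."""
        return self.matrix[:, self.spec.block_slices()[covariate]]


def dummy_code(raw: pd.DataFrame, spec: CovariateSpec) -> CovariateDesign:
    """Dummy-code raw categorical columns against the spec's references.

    Raises on unknown category labels, naming the column and first bad row.
    """
    n = len(raw)
    mat = np.zeros((n, spec.n_dummies))
    slices = spec.block_slices()
    for cov in spec:
        if cov.name not in raw.columns:
            raise ValueError(f"missing covariate column {cov.name!r}")
        col = raw[cov.name].astype(str)
        known = set(cov.categories)
        bad = ~col.isin(known)
        if bad.any():
            row = int(np.argmax(bad.to_numpy()))
            raise ValueError(
                f"covariate {cov.name!r}: unknown category {col.iloc[row]!r} "
                f"at row {row}"
            )
        sl = slices[cov.name]
        for k, level in enumerate(cov.dummy_levels):
            mat[:, sl.start + k] = (col == level).to_numpy(dtype=float)
    return CovariateDesign(matrix=mat, spec=spec, raw=raw.copy())
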