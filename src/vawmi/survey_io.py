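"""Read/validate/write respondent-level survey tables.

Single entry point for both synthetic surveys and external deposits.  The
on-disk dialect is plain CSV (UTF-8, header row): item columns item01..15
coded 0/1, raw categorical covariate columns named as in the codebook, and
optional asset columns asset01..assetQ.  An optional column-mapping YAML
renames external columns/category labels into this dialect, so unknown
deposit layouts can be adapted without code changes.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._instrument import ITEM_COLUMNS, N_ITEMS
from .containers import CovariateDesign, ItemResponseMatrix, dummy_code
from .params import Covariate, CovariateSpec
from .synthetic import SyntheticSurvey

__all__ = [
    "read_survey",
    "write_survey",
    "write_results",
    "load_codebook",
    "save_codebook",
    "apply_column_mapping",
]


def save_codebook(spec: CovariateSpec, path: str | Path) -> None:
    doc = {
        c.name: {
            "categories": list(c.categories),
            "probs": [float(p) for p in c.probs],
            "reference": c.reference,
        }
        for c in spec
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_codebook(path: str | Path) -> CovariateSpec:
    doc = yaml.safe_load(Path(path).read_text())
    return CovariateSpec(
        [
            Covariate(
                name=name,
                categories=tuple(entry["categories"]),
                probs=tuple(entry["probs"]),
                reference=entry["reference"],
            )
            for name, entry in doc.items()
        ]
    )


def apply_column_mapping(df: pd.DataFrame, mapping: dict) -> pd.DataFrame:
    """Rename columns and recode category labels per a mapping document.

    mapping = {"columns": {external: internal}, "values": {column: {ext: int}}}
    """
    df = df.rename(columns=mapping.get("columns", {}))
    for col, recode in mapping.get("values", {}).items():
        if col in df.columns:
            df[col] = df[col].map(lambda v: recode.get(v, v))
    return df


def read_survey(
    path: str | Path,
    codebook: CovariateSpec,
    *,
    mapping: dict | str | Path | None = None,
    on_missing: str = "fail",
) -> tuple[ItemResponseMatrix, CovariateDesign]:
    """Read a survey CSV and dummy-code its covariates.

    on_missing: "fail" (default) or "drop" (listwise deletion of rows with
    any missing item/covariate value).
    """
    if on_missing not in ("fail", "drop"):
        raise ValueError("on_missing must be 'fail' or 'drop'")
    df = pd.read_csv(path)
    if mapping is not None:
        if not isinstance(mapping, dict):
            mapping = yaml.safe_load(Path(mapping).read_text())
        df = apply_column_mapping(df, mapping)

    missing_cols = [c for c in ITEM_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"missing item columns: {missing_cols}")

    used = list(ITEM_COLUMNS) + [c.name for c in codebook]
    absent = [c for c in used if c not in df.columns]
    if absent:
        raise ValueError(f"missing columns: {absent}")

    na_rows = df[used].isna().any(axis=1)
    if na_rows.any():
        if on_missing == "fail":
            row = int(np.argmax(na_rows.to_numpy()))
            raise ValueError(f"missing value at row {row}; pass on_missing='drop' to listwise-delete")
        df = df.loc[~na_rows].reset_index(drop=True)

    items = df[list(ITEM_COLUMNS)].to_numpy()
    bad = ~np.isin(items, (0, 1))
    if bad.any():
        j = int(np.argwhere(bad)[0][1])
        i = int(np.argwhere(bad)[0][0])
        raise ValueError(
            f"item column {ITEM_COLUMNS[j]!r} has out-of-range value "
            f"{items[i, j]!r} at row {i}"
        )
    responses = ItemResponseMatrix(items)
    if "wealth" in codebook.names and any(c.startswith("asset") for c in df.columns):
        logging.getLogger("vawmi").warning(
            "both an explicit wealth column and asset columns are present; "
            "the explicit wealth column is used (recompute via "
            "descriptives.wealth_index to override)"
        )
    design = dummy_code(df[[c.name for c in codebook]], codebook)
    return responses, design


def write_survey(survey: SyntheticSurvey, path: str | Path) -> Path:
    """Write a synthetic survey CSV plus a sidecar YAML with the truth."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    survey.to_frame().to_csv(path, index=False)
    truth = survey.truth
    sidecar = {
        "seed": int(survey.seed),
        "n": int(survey.n),
        "nu": truth.nu.tolist(),
        "Lambda": truth.Lambda.tolist(),
        "A": truth.A.tolist(),
        "B": truth.B.tolist(),
        "Psi": truth.Psi.tolist(),
        "dummy_columns": list(truth.covariate_spec.dummy_columns),
    }
    side_path = path.with_suffix(".truth.yaml")
    side_path.write_text(yaml.safe_dump(sidecar, sort_keys=False))
    return path


@dataclass
class Manifest:
    files: list[str]
    meta: dict

    def to_json(self) -> str:
        return json.dumps({"files": self.files, "meta": self.meta}, indent=2)


def write_results(
    tables: dict[str, pd.DataFrame | dict],
    out_dir: str | Path,
    *,
    meta: dict | None = None,
) -> Manifest:
    """Write result tables (DataFrames -> CSV, dicts -> JSON) with a manifest.

    The manifest records every file written plus run metadata (timestamp,
    content hash of each artifact, caller-supplied seed/config info).
    """
    if not tables:
        raise ValueError("no tables to write")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: list[str] = []
    hashes: dict[str, str] = {}
    for name, obj in tables.items():
        if isinstance(obj, pd.DataFrame):
            fp = out / f"{name}.csv"
            obj.to_csv(fp, index=False)
        elif isinstance(obj, dict):
            fp = out / f"{name}.json"
            fp.write_text(json.dumps(obj, indent=2, default=_json_default))
        else:
            raise TypeError(f"table {name!r} must be a DataFrame or dict, got {type(obj)}")
        files.append(fp.name)
        hashes[fp.name] = hashlib.sha256(fp.read_bytes()).hexdigest()[:16]
    manifest = Manifest(
        files=files,
        meta={
            "written_at": datetime.now(timezone.utc).isoformat(),
            "hashes": hashes,
            **(meta or {}),
        },
    )
    (out / "manifest.json").write_text(manifest.to_json())
    return manifest


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
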