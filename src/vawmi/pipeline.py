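"""End-to-end orchestration: simulate/read -> descriptives -> tetrachoric
-> ESEM -> covariate screen -> Bayesian MIMIC -> report bundle.

Every stage writes tidy CSV/JSON artifacts through survey_io.write_results;
the run is deterministic given the config seed (all stochastic stages are
seeded from it).  Stage outputs are cached per config hash: rerunning with
an unchanged config resumes from what is already on disk.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._instrument import FACTOR_NAMES, ITEM_LABELS, MAJOR_FACTOR, N_ITEMS
from . import descriptives as desc
from .containers import CovariateDesign, ItemResponseMatrix
from .esem import fit_esem
from .mimic import (
    SamplerConfig,
    build_direct_map,
    flag_noninvariance,
    gibbs_sample,
    standardize,
)
from .presets import default_covariate_spec, measurement_preset, study_preset
from .screen import run_screen
from .survey_io import load_codebook, read_survey, write_results, write_survey
from .synthetic import generate_survey
from .tetrachoric import estimate_matrix

logger = logging.getLogger("vawmi")

PRESETS = {"study": study_preset, "table2": study_preset, "measurement": measurement_preset}

ALL_STAGES = ("describe", "tetra", "esem", "screen", "mimic")


@dataclass
class RunConfig:
    """Validated pipeline configuration.

    Exactly one of ``input_path`` / ``simulate`` must be set; a seed is
    mandatory when simulating.
    """

    out_dir: str
    input_path: str | None = None
    codebook_path: str | None = None
    simulate: dict | None = None  # {"preset": str, "n": int}
    seed: int | None = None
    stages: tuple[str, ...] = ALL_STAGES
    sampler: dict = field(default_factory=dict)
    esem_factors: int = 3
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.simulate is None):
            raise ValueError("exactly one of input_path / simulate must be given")
        if self.simulate is not None and self.seed is None:
            raise ValueError("seed is mandatory when simulating")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text())
        return cls(**doc)

    def config_hash(self) -> str:
        doc = {
            "input": self.input_path,
            "simulate": self.simulate,
            "seed": self.seed,
            "sampler": self.sampler,
            "esem_factors": self.esem_factors,
        }
        return hashlib.sha256(json.dumps(doc, sort_keys=True).encode()).hexdigest()[:16]


def _load_data(config: RunConfig):
    if config.simulate is not None:
        preset_name = config.simulate.get("preset", "study")
        if preset_name not in PRESETS:
            raise ValueError(f"unknown preset {preset_name!r}; choose from {sorted(PRESETS)}")
        params = PRESETS[preset_name]()
        n = int(config.simulate.get("n", 1081))
        survey = generate_survey(params, n, seed=int(config.seed))
        return survey.responses, survey.covariates, survey.assets, survey
    codebook = (
        load_codebook(config.codebook_path)
        if config.codebook_path
        else default_covariate_spec()
    )
    responses, design = read_survey(config.input_path, codebook)
    return responses, design, None, None


def _loading_table(L: np.ndarray, Phi: np.ndarray) -> pd.DataFrame:
    rows = []
    for j in range(N_ITEMS):
        row = {"item": j + 1, "label": ITEM_LABELS[j]}
        for f, name in enumerate(FACTOR_NAMES):
            row[name] = L[j, f]
            row[f"{name}_major"] = MAJOR_FACTOR[j] == f
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns the bundle manifest dict.

    A stage failure marks all downstream stages as skipped in the manifest
    and re-raises (the CLI converts this into a non-zero exit).
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    meta = {"seed": config.seed, "config_hash": chash}
    manifest: dict = {"config_hash": chash, "stages": {}, "failed": None}

    responses, design, assets, survey = _load_data(config)
    if survey is not None:
        write_survey(survey, out / "data" / "survey.csv")
        manifest["stages"]["data"] = ["data/survey.csv", "data/survey.truth.yaml"]

    done: dict[str, object] = {}
    stages = [s for s in ALL_STAGES if s in config.stages]
    for stage in stages:
        stage_dir = out / stage
        marker = stage_dir / ".config_hash"
        if marker.exists() and marker.read_text() == chash:
            logger.info("stage %s cached; skipping", stage)
            manifest["stages"][stage] = "cached"
            continue  # inputs recomputed lazily downstream if needed
        try:
            if stage == "describe":
                tables = {
                    "prevalence": desc.item_prevalence(responses),
                    "acts_distribution": desc.acts_distribution(responses).table,
                    "sample_summary": desc.summarize_sample(design)
                    if design.raw is not None
                    else pd.DataFrame(),
                }
                if assets is not None:
                    score, terc, _ = desc.wealth_index(assets)
                    tables["wealth_index"] = pd.DataFrame(
                        {"score": score, "tercile": terc}
                    )
                write_results(tables, stage_dir, meta=meta)
            elif stage == "tetra":
                tet = estimate_matrix(responses)
                done["tetra"] = tet
                write_results(
                    {
                        "tetrachoric_rho": pd.DataFrame(tet.rho),
                        "thresholds": pd.DataFrame({"item": range(1, 16), "tau": tet.tau}),
                        "convergence": {
                            "psd_repaired": bool(tet.psd_repaired),
                            "all_pairs_converged": bool(tet.converged.all()),
                            "near_boundary_pairs": int(tet.near_boundary.sum() // 2),
                            "corrected_pairs": int(tet.corrected.sum() // 2),
                        },
                    },
                    stage_dir,
                    meta=meta,
                )
            elif stage == "esem":
                tet = done.get("tetra") or estimate_matrix(responses)
                sol = fit_esem(tet, config.esem_factors, seed=int(config.seed or 0))
                done["esem"] = sol
                write_results(
                    {
                        "esem_loadings": _loading_table(sol.Lambda_rotated, sol.Phi),
                        "factor_correlations": pd.DataFrame(
                            sol.Phi, columns=list(FACTOR_NAMES)
                        ),
                        "fit_indices": sol.fit,
                    },
                    stage_dir,
                    meta=meta,
                )
            elif stage == "screen":
                scr = run_screen(responses, design)
                done["screen"] = scr
                write_results(
                    {
                        "stage1_lrt_p": scr.stage1_p.reset_index(names="item"),
                        "stage2_lrt_p": scr.stage2_p.reset_index(names="item"),
                    },
                    stage_dir,
                    meta=meta,
                )
                (stage_dir / "direct_map.yaml").write_text(
                    yaml.safe_dump({int(k): v for k, v in scr.direct_map.items()})
                )
            elif stage == "mimic":
                scr = done.get("screen")
                if scr is not None:
                    screened = scr.direct_map
                elif (out / "screen" / "direct_map.yaml").exists():
                    screened = {
                        int(k): list(v)
                        for k, v in yaml.safe_load(
                            (out / "screen" / "direct_map.yaml").read_text()
                        ).items()
                    }
                else:
                    screened = None
                dmap = build_direct_map(
                    design,
                    screened=screened,
                    stage2_p=scr.stage2_p if scr is not None else None,
                )
                cfg = SamplerConfig(**config.sampler)
                draws = gibbs_sample(
                    responses, design, dmap, cfg, seed=int(config.seed or 0)
                )
                summary = standardize(draws, design)
                flags = flag_noninvariance(summary, force=True)
                write_results(
                    {
                        "mimic_b_effects": summary.b_effects,
                        "mimic_a_effects": summary.a_effects,
                        "mimic_loadings": summary.loadings,
                        "mimic_factor_correlations": summary.factor_correlations,
                        "noninvariance_flags": flags,
                        "convergence": {
                            "ppp": summary.ppp,
                            "max_psr": summary.max_psr(),
                            "converged": bool(summary.converged),
                        },
                    },
                    stage_dir,
                    meta=meta,
                )
            marker.parent.mkdir(parents=True, exist_ok=True)
            marker.write_text(chash)
            if manifest["stages"].get(stage) != "cached":
                manifest["stages"][stage] = sorted(
                    f.name for f in stage_dir.iterdir() if f.suffix in (".csv", ".json", ".yaml")
                )
        except Exception:
            manifest["failed"] = stage
            remaining = stages[stages.index(stage) + 1 :]
            for s in remaining:
                manifest["stages"][s] = "skipped"
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
            raise
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def compare_to_reference(bundle_dir: str | Path, reference: str | Path) -> pd.DataFrame:
    """Check bundle artifacts against expected values with tolerances.

    The reference YAML is a list of checks:
      - name: <label>
        file: <relative artifact path (.csv or .json)>
        where: {column: value, ...}   # row selector, CSV only
        field: <column or JSON key>
        expected: <number>
        tolerance: <number>
    Missing artifacts produce fail rows, not crashes.
    """
    bundle = Path(bundle_dir)
    checks = yaml.safe_load(Path(reference).read_text()) or []
    rows = []
    for check in checks:
        name = check.get("name", check.get("field", "?"))
        fp = bundle / check["file"]
        expected = float(check["expected"])
        tol = float(check.get("tolerance", 0.0))
        value = None
        if fp.exists():
            try:
                if fp.suffix == ".json":
                    doc = json.loads(fp.read_text())
                    value = doc
                    for key in str(check["field"]).split("."):
                        value = value[key]
                    value = float(value)
                else:
                    df = pd.read_csv(fp)
                    for col, val in (check.get("where") or {}).items():
                        df = df[df[col] == val]
                    value = float(df[check["field"]].iloc[0])
            except Exception:
                value = None
        ok = value is not None and abs(value - expected) <= tol
        rows.append(
            {
                "check": name,
                "value": value,
                "expected": expected,
                "tolerance": tol,
                "passed": bool(ok),
            }
        )
    return pd.DataFrame(rows, columns=["check", "value", "expected", "tolerance", "passed"])
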