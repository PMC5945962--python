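"""Canonical CSV/YAML formats and the end-to-end pipeline runner.

The canonical cohort CSV is long format: one row per subject-visit with
``subject_id, visit_months, diagnosis, age, site, tiv`` followed by one
column per biomarker and optional phenotype / converter columns.  Every run
writes a manifest (config hash, seed, library versions) sufficient to
reproduce each artifact bit-exactly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .simulate import DIAGNOSES, PHENOTYPES

__all__ = ["PipelineConfig", "read_cohort", "write_cohort", "run_pipeline"]

REQUIRED_COLS = ("subject_id", "visit_months", "diagnosis", "age", "site", "tiv")
OPTIONAL_COLS = tuple(PHENOTYPES) + ("converter",)


def read_cohort(path) -> pd.DataFrame:
    """Read and validate a canonical cohort CSV.

    Checks required columns, the diagnosis vocabulary, numeric biomarker
    columns without missing values, and subject-visit key uniqueness.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort CSV {path.name} is missing columns: {missing}")
    bad = sorted(set(df["diagnosis"].unique()) - set(DIAGNOSES))
    if bad:
        raise ValueError(f"unknown diagnosis labels {bad}; expected {DIAGNOSES}")
    dup = df.duplicated(subset=["subject_id", "visit_months"])
    if dup.any():
        keys = df.loc[dup, ["subject_id", "visit_months"]].iloc[0].tolist()
        raise ValueError(f"duplicate subject-visit key, e.g. {keys}")
    biomarkers = biomarker_columns(df)
    for col in biomarkers + ["age", "tiv"]:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            raise ValueError(f"column {col!r} has missing or non-numeric values")
        df[col] = vals
    return df


def biomarker_columns(df: pd.DataFrame) -> list[str]:
    return [c for c in df.columns if c not in REQUIRED_COLS and c not in OPTIONAL_COLS]


def write_cohort(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


@dataclass
class PipelineConfig:
    """Every tunable the pipeline uses; no unseeded runs.

    Defaults carry the study constants: selection at corrected p < 0.001 with
    |t| > 8, 5-sigma outlier removal, 100 bootstrap resamples.
    """

    seed: int = 0
    p_threshold: float = 0.001
    t_threshold: float = 8.0
    outlier_sigma: float = 5.0
    select: bool = False
    fit_group: str = "HC"
    em_tol: float = 1e-6
    em_max_iter: int = 500
    n_restarts: int = 10
    mcmc_samples: int = 100_000
    mcmc_burn_in: int = 10_000
    n_bootstrap: int = 100
    bootstrap_restarts: int = 5
    lower_half_max: int | None = None
    bilateral_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed must be set; unseeded runs are not allowed")
        for name in ("p_threshold", "t_threshold", "outlier_sigma", "em_tol"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("em_max_iter", "n_restarts", "mcmc_samples", "n_bootstrap"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: PipelineConfig, input_path, out_dir) -> dict:
    """Run prep -> distribution fits -> sequence -> staging -> validations.

    Writes all artifacts under ``out_dir`` and returns them in memory.
    Identical (input, config, seed) produce byte-identical CSV outputs.
    """
    from .model import EventBasedModel
    from .prep import select_biomarkers
    from .staging import (longitudinal_consistency, phenotype_regression,
                          predict_conversion, stage_distribution)

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    df = read_cohort(input_path)
    stage_name = "prep"
    try:
        model = EventBasedModel.from_dataframe(
            df, select=config.select, p_threshold=config.p_threshold,
            t_threshold=config.t_threshold,
            bilateral_map=config.bilateral_map or None,
            outlier_sigma=config.outlier_sigma, fit_group=config.fit_group)
        select_biomarkers(model.matrix, config.p_threshold, config.t_threshold,
                          config.bilateral_map or None).table.to_csv(
            out / "selection_report.csv", index=False)

        stage_name = "fit"
        results = model.fit(n_restarts=config.n_restarts,
                            mcmc_samples=config.mcmc_samples,
                            mcmc_burn_in=config.mcmc_burn_in,
                            seed=config.seed,
                            tol=config.em_tol, max_iter=config.em_max_iter)
        results.fit_table().to_csv(out / "distribution_fits.csv")
        pd.DataFrame({"position": np.arange(1, results.n_events + 1),
                      "biomarker": results.ordered_biomarkers}
                     ).to_csv(out / "ml_sequence.csv", index=False)
        if results.pvd is not None:
            pd.DataFrame(results.pvd.matrix,
                         index=results.biomarker_names,
                         columns=[f"pos_{p+1}" for p in range(results.n_events)]
                         ).to_csv(out / "positional_variance.csv")
            _save_pvd_plot(results, out / "positional_variance.png")

        stage_name = "staging"
        assignments = results.stage_cohort(df)
        assignments.to_csv(out / "stages.csv")
        dist = stage_distribution(
            _baseline(assignments), df.set_index("subject_id")["diagnosis"][
                lambda s: ~s.index.duplicated()],
            n_stages=results.n_events, lower_half_max=config.lower_half_max)
        dist.to_csv(out / "stage_distribution.csv")

        stage_name = "validation"
        report: dict = {}
        if (df["visit_months"] > 0).any():
            report["longitudinal"] = _jsonable(
                longitudinal_consistency(assignments))
        if "converter" in df.columns:
            base = df[df["visit_months"] == 0].set_index("subject_id")
            conv = base["converter"].astype(bool)
            pre = conv.index[base["diagnosis"] == "preHD"]
            res = predict_conversion(_baseline(assignments).stages[pre],
                                     conv[pre], results.n_events)
            report["conversion"] = {
                "threshold_stage": res.threshold_stage,
                "sensitivity": res.sensitivity,
                "specificity": res.specificity,
                "balanced_accuracy": res.balanced_accuracy,
            }
        pheno_cols = [c for c in PHENOTYPES if c in df.columns]
        if pheno_cols:
            base = df[df["visit_months"] == 0].set_index("subject_id")
            reg = phenotype_regression(_baseline(assignments), base[pheno_cols])
            reg.to_csv(out / "phenotype_regression.csv")
            report["phenotype_regression"] = reg.reset_index().to_dict("records")
        with open(out / "validation_report.json", "w") as fh:
            json.dump(report, fh, indent=2)

        manifest = {
            "config": asdict(config),
            "config_digest": config.digest(),
            "seed": config.seed,
            "input": str(input_path),
            "versions": {"hdebm": __version__, "numpy": np.__version__,
                         "pandas": pd.__version__},
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage_name!r} failed: {exc}") from exc
    return {"model": model, "results": results, "stages": assignments,
            "report": report, "manifest": manifest}


def _baseline(assignments):
    from .staging import StageAssignments

    tab = assignments.table
    mask = (tab["visit_months"] == 0).to_numpy()
    return StageAssignments(tab[mask].reset_index(drop=True),
                            assignments.log_likelihood_by_stage[mask])


def _jsonable(report: dict) -> dict:
    return {k: v for k, v in report.items()
            if isinstance(v, (int, float, str, bool))}


def _save_pvd_plot(results, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ax = results.plot_positional_variance()
    ax.figure.tight_layout()
    ax.figure.savefig(path, dpi=150)
    plt.close(ax.figure)
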