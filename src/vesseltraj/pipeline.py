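"""End-to-end pipeline: simulate -> measure -> fit -> compare -> report.

One :class:`RunConfig` (YAML-loadable) drives all stages; a single top-level
seed is fanned out to per-stage streams, every table is written with a fixed
float format, and a run manifest records the config hash, seed and a checksum
per output so that identical config+seed reruns are bitwise reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as vio
from .atlas import AtlasConfig, SubjectShapeSeries, estimate_atlas
from .curves import GENERATOR_LABELS, to_point_set
from .morphometrics import first_last_table, measure_scans
from .reporting import build_report
from .synthetic import ArteryTrend, CohortConfig, CovariateSpec, generate_cohort


class PipelineError(RuntimeError):
    """Stage-labeled pipeline failure."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    out_dir: str = "run"
    seed: int = 0
    fmt: str = "vtk"
    points_per_artery: int = 12
    cohort: CohortConfig = field(default_factory=CohortConfig)
    atlas: AtlasConfig = field(default_factory=AtlasConfig)
    factors: list[str] | None = None
    plots: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        cohort_raw = dict(raw.pop("cohort", {}))
        if "trends" in cohort_raw:
            cohort_raw["trends"] = {
                k: ArteryTrend(**v) for k, v in cohort_raw["trends"].items()
            }
        if "covariates" in cohort_raw:
            cohort_raw["covariates"] = tuple(
                CovariateSpec(**c) for c in cohort_raw["covariates"]
            )
        atlas_raw = dict(raw.pop("atlas", {}))
        cfg = cls(**raw)
        merged = {**_as_dict(cfg.cohort), **cohort_raw}
        merged["trends"] = {
            k: v if isinstance(v, ArteryTrend) else ArteryTrend(**v)
            for k, v in merged.get("trends", {}).items()
        }
        merged["covariates"] = tuple(
            c if isinstance(c, CovariateSpec) else CovariateSpec(**c)
            for c in merged.get("covariates", ())
        )
        cfg.cohort = CohortConfig(**merged)
        cfg.atlas = AtlasConfig(**{**dataclasses.asdict(cfg.atlas), **atlas_raw})
        return cfg

    def config_hash(self) -> str:
        blob = json.dumps(
            {
                "seed": self.seed,
                "fmt": self.fmt,
                "points_per_artery": self.points_per_artery,
                "cohort": _as_dict(self.cohort),
                "atlas": dataclasses.asdict(self.atlas),
                "factors": self.factors,
            },
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _as_dict(cfg) -> dict:
    d = {}
    for f in dataclasses.fields(cfg):
        v = getattr(cfg, f.name)
        if isinstance(v, dict):
            v = {k: dataclasses.asdict(x) if dataclasses.is_dataclass(x) else x for k, x in v.items()}
        elif isinstance(v, tuple) and v and dataclasses.is_dataclass(v[0]):
            v = [dataclasses.asdict(x) for x in v]
        d[f.name] = v
    return d


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages into ``config.out_dir``; returns the run directory.

    Any stage failure raises :class:`PipelineError` naming the stage, after
    writing a partial-results manifest.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
        "checksums": {},
    }

    def finish_stage(stage: str, *paths: Path) -> None:
        manifest["stages"][stage] = "ok"
        for p in paths:
            manifest["checksums"][str(p.relative_to(out))] = _checksum(p)
        (out / "run_manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))

    def fail(stage: str, exc: Exception):
        manifest["stages"][stage] = f"failed: {exc}"
        (out / "run_manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
        raise PipelineError(stage, str(exc)) from exc

    # ------------------------------------------------------------- simulate
    try:
        cohort_cfg = dataclasses.replace(config.cohort, seed=config.seed)
        cohort, truth = generate_cohort(cohort_cfg)
        cohort_dir = out / "cohort"
        manifest_path = vio.write_cohort(cohort, cohort_dir, fmt=config.fmt)
        vio.write_ground_truth(truth, cohort_dir / "ground_truth.json")
    except PipelineError:
        raise
    except Exception as exc:
        fail("simulate", exc)
    finish_stage(
        "simulate", manifest_path, cohort_dir / "covariates.csv", cohort_dir / "ground_truth.json"
    )

    # -------------------------------------------------------------- measure
    try:
        scans = vio.read_manifest(manifest_path)
        records = measure_scans(scans)
        records_path = out / "morphometry.csv"
        records.to_csv(records_path, index=False, float_format="%.9g")
        table = first_last_table(records)
        table_path = out / "first_last_table.csv"
        table.to_csv(table_path, index=False, float_format="%.9g")
    except Exception as exc:
        fail("measure", exc)
    finish_stage("measure", records_path, table_path)

    # ------------------------------------------------------------------ fit
    try:
        by_subject: dict[str, list] = {}
        for scan in scans:
            by_subject.setdefault(scan.subject_id, []).append(scan)
        series = [
            SubjectShapeSeries(
                sid,
                [s.age for s in ss],
                [to_point_set(s, config.points_per_artery, GENERATOR_LABELS) for s in ss],
            )
            for sid, ss in sorted(by_subject.items())
        ]
        atlas_cfg = dataclasses.replace(config.atlas, seed=config.seed)
        atlas, fit_report = estimate_atlas(series, atlas_cfg)
        params = atlas.params_frame()
        params_path = out / "subject_params.csv"
        params.to_csv(params_path, index=False, float_format="%.9g")
        atlas_path = out / "atlas.json"
        atlas_path.write_text(
            json.dumps(
                {
                    "t0": atlas.t0,
                    "sigma_eps": atlas.sigma_eps,
                    "n_sources": atlas.n_sources,
                    "n_control_points": fit_report.n_control_points,
                    "log_posterior": fit_report.log_posterior,
                    "residual_rms": fit_report.residual_rms,
                    "converged": fit_report.converged,
                    "template_points": np.round(atlas.template.points, 9).tolist(),
                    "momenta": np.round(atlas.momenta.momenta, 9).tolist(),
                    "control_points": np.round(atlas.momenta.control_points, 9).tolist(),
                },
                indent=1,
                sort_keys=True,
            )
        )
    except Exception as exc:
        fail("fit", exc)
    finish_stage("fit", params_path, atlas_path)

    # -------------------------------------------------------------- compare
    try:
        covariates = pd.read_csv(cohort_dir / "covariates.csv")
        if config.factors:
            keep = ["subject_id"] + [f for f in config.factors if f in covariates.columns]
            covariates = covariates[keep]
        report = build_report(
            params,
            covariates,
            records,
            table,
            meta={"config_hash": config.config_hash(), "seed": config.seed},
        )
        report_json = report.write(out / "report", plots=config.plots)
    except Exception as exc:
        fail("compare", exc)
    finish_stage(
        "compare",
        report_json,
        *(p for p in sorted((out / "report").glob("*.csv"))),
    )
    return out
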