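"""End-to-end pipeline: generate -> position -> measure -> analyze.

Every stage writes plain files (STL / JSON / CSV) so any stage can be
re-run independently, and the whole run is deterministic under the seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bow_roc import measure_bone_roc, measure_plate_roc
from .cohort_analysis import make_tables
from .fit_protocol import DEFAULT_THRESHOLDS, cohort_fit_run
from .plate_positioning import PositioningConfig
from .synthetic_anatomy import (
    CohortSpec,
    PlateParams,
    default_cohort_spec,
    make_femur_from_row,
    make_plate_set,
    sample_cohort_table,
    write_femur,
)

log = logging.getLogger("platefit")



@dataclass
class RunConfig:
    """Configuration for a full pipeline run."""

    seed: int = 0
    out_dir: str = "platefit_run"
    cohort_spec: CohortSpec | None = None     # default: published-cohort spec
    cohort_fraction: float = 1.0              # proportional down-scaling
    plate_params: PlateParams | None = None
    thresholds: dict = field(default_factory=lambda: dict(DEFAULT_THRESHOLDS))
    contact_threshold: float = 0.2
    resolution: float = 1.0
    write_meshes: bool = True
    measure_roc: bool = True
    fixed_holes: int | None = None            # force one plate length
    log_level: str = "INFO"

    def resolved_cohort_spec(self) -> CohortSpec:
        spec = self.cohort_spec or default_cohort_spec()
        if self.cohort_fraction != 1.0:
            spec = spec.scaled(self.cohort_fraction)
        return spec


def load_config(path) -> RunConfig:
    """Read a RunConfig from YAML (flat keys; nested specs optional)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = RunConfig()
    for key, value in raw.items():
        if key == "plate_params":
            value = PlateParams(**value)
        if not hasattr(cfg, key):
            raise KeyError(f"unknown config key {key!r}")
        setattr(cfg, key, value)
    return cfg


def _config_hash(config: RunConfig) -> str:
    def default(o):
        if isinstance(o, np.generic):
            return o.item()
        return str(o)
    blob = json.dumps(asdict(config), sort_keys=True, default=default)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    # default float formatting is the shortest round-trippable repr
    df.to_csv(path, index=False)


def read_table(path) -> pd.DataFrame:
    """Read a stage CSV with exact float round-tripping, so a stage
    re-run from saved intermediates reproduces downstream tables
    bit-for-bit."""
    return pd.read_csv(path, float_precision="round_trip")


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def stage_generate(config: RunConfig, out: Path) -> pd.DataFrame:
    """Sample the cohort table (and optionally write femur meshes)."""
    spec = config.resolved_cohort_spec()
    table = sample_cohort_table(spec, seed=config.seed)
    _write_csv(table, out / "cohort.csv")
    if config.write_meshes:
        mesh_dir = out / "meshes"
        for _, row in table.iterrows():
            model = make_femur_from_row(row, resolution=config.resolution)
            write_femur(model, mesh_dir, stem=row["id"])
    return table


def stage_roc(config: RunConfig, table: pd.DataFrame, out: Path) -> pd.DataFrame:
    """Measured anterior-bow ROC per bone (protocol measurement, not the
    generator's ground truth)."""
    rows = []
    for _, row in table.iterrows():
        model = make_femur_from_row(row, resolution=config.resolution)
        res = measure_bone_roc(model)
        rows.append({"id": row["id"], "roc_mm": res.radius,
                     "rms_mm": res.rms_residual,
                     "true_R_bow_mm": row["true_R_bow_mm"]})
    df = pd.DataFrame(rows)
    _write_csv(df, out / "roc.csv")
    return df


def stage_measure(config: RunConfig, table: pd.DataFrame, out: Path
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Position plates and measure fit for every bone in the cohort."""
    plates = make_plate_set(config.plate_params)
    pos_config = PositioningConfig(contact_threshold=config.contact_threshold)
    long_df, summary, failures = cohort_fit_run(
        table, plates, config=pos_config, thresholds=config.thresholds,
        resolution=config.resolution, holes=config.fixed_holes)
    _write_csv(long_df, out / "distances.csv")
    _write_csv(summary, out / "fit_summary.csv")
    with open(out / "failures.json", "w") as fh:
        json.dump(failures, fh, indent=1)
    reports_dir = out / "reports"
    reports_dir.mkdir(exist_ok=True)
    for _, srow in summary.iterrows():
        with open(reports_dir / f"{srow['id']}.json", "w") as fh:
            json.dump({k: (v.item() if isinstance(v, np.generic) else v)
                       for k, v in srow.items()}, fh, indent=1)
    plate_rocs = {str(h): measure_plate_roc(p).radius
                  for h, p in plates.items()}
    with open(out / "plate_roc.json", "w") as fh:
        json.dump(plate_rocs, fh, indent=1)
    return long_df, summary


def stage_analyze(summary: pd.DataFrame, out: Path) -> dict:
    """Descriptive and inferential tables from the fit summary."""
    tables = make_tables(summary)
    tables_dir = out / "tables"
    tables_dir.mkdir(exist_ok=True)
    for name, df in tables.items():
        _write_csv(df, tables_dir / f"{name}.csv")
    return tables


def run_pipeline(config: RunConfig) -> Path:
    """Run all stages; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    handler = logging.FileHandler(out / "run.log")
    log.addHandler(handler)
    try:
        log.info("pipeline start (seed=%d)", config.seed)
        table = stage_generate(config, out)
        log.info("generated cohort of %d subjects", len(table))
        if config.measure_roc:
            stage_roc(config, table, out)
        _, summary = stage_measure(config, table, out)
        log.info("measured fit for %d/%d bones", len(summary), len(table))
        if len(summary):
            stage_analyze(summary, out)
        manifest = {
            "version": __version__,
            "seed": config.seed,
            "config_hash": _config_hash(config),
            "n_subjects": int(len(table)),
            "n_measured": int(len(summary)),
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)
        log.info("pipeline done")
    finally:
        log.removeHandler(handler)
        handler.close()
    return out
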