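"""Cohort I/O, pipeline configuration, and the end-to-end driver.

The cohort CSV schema (UTF-8, comma-separated, header required):

    id, group, his_vis_pct, his_morph_frac, alpha_s1, alpha_s2, alpha_s3,
    alpha, lic, metavir, bmi, diagnosis

Fractions are stored as decimals (e.g. 0.029) in ``*_frac`` columns and
percentages (e.g. 5.0) in ``*_pct`` columns.  Unknown columns are preserved.
``run_pipeline`` chains simulation, morphometry, calibration and diagnostics
and emits a manifest with per-stage output checksums so a rerun with the same
seed is verifiably identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field, asdict
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .calibration import fit_k, fit_linear_link, derive_morph_cutoffs
from .cohort_sim import SubjectRecord, generate_cohort, cohort_to_frame
from .diagnostics import diagnostic_report
from .morphometry import MorphometryConfig, areal_fat_fraction
from .phantom import HistologyPhantomSpec, generate_histology_phantom

log = logging.getLogger(__name__)

__all__ = [
    "CohortSchemaError",
    "read_cohort",
    "write_cohort",
    "PipelineConfig",
    "RunManifest",
    "run_pipeline",
    "child_seed",
]

MANDATORY_COLUMNS = (
    "id", "group", "his_vis_pct", "his_morph_frac",
    "alpha_s1", "alpha_s2", "alpha_s3", "alpha",
)


class CohortSchemaError(ValueError):
    """Cohort CSV violates the documented schema."""


def write_cohort(records, path) -> None:
    cohort_to_frame(records).to_csv(path, index=False)


def read_cohort(path) -> list:
    """Read and validate a cohort CSV into typed subject records.

    Raises :class:`CohortSchemaError` naming the offending column or row
    (1-based data row numbers) on missing columns, non-numeric cells, or
    out-of-range values.
    """
    df = pd.read_csv(path)
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise CohortSchemaError(f"missing mandatory column(s): {missing}")
    numeric = ["his_vis_pct", "his_morph_frac", "alpha_s1", "alpha_s2", "alpha_s3", "alpha"]
    for col in numeric:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            raise CohortSchemaError(f"non-numeric value in {col!r} on row {bad[0] + 1}")
        df[col] = coerced
    for col, lo, hi in (
        ("alpha", 0.0, 1.0),
        ("alpha_s1", 0.0, 1.0),
        ("alpha_s2", 0.0, 1.0),
        ("alpha_s3", 0.0, 1.0),
        ("his_morph_frac", 0.0, 1.0),
        ("his_vis_pct", 0.0, 100.0),
    ):
        vals = df[col]
        bad = df.index[vals.notna() & ((vals < lo) | (vals > hi))]
        if len(bad):
            raise CohortSchemaError(
                f"{col!r} outside [{lo}, {hi}] on row {bad[0] + 1}: {vals[bad[0]]}"
            )
    records = []
    known = set(MANDATORY_COLUMNS) | {"lic", "metavir", "bmi", "diagnosis"}
    for i, row in df.iterrows():
        records.append(
            SubjectRecord(
                id=str(row["id"]),
                group=str(row["group"]),
                his_vis=float(row["his_vis_pct"]),
                his_morph=float(row["his_morph_frac"]),
                alpha_slices=(float(row["alpha_s1"]), float(row["alpha_s2"]), float(row["alpha_s3"])),
                alpha=float(row["alpha"]),
                lic=float(row.get("lic", float("nan"))),
                metavir=int(row.get("metavir", -1)),
                bmi=float(row.get("bmi", float("nan"))),
                diagnosis=str(row.get("diagnosis", "")),
            )
        )
    extra = [c for c in df.columns if c not in known]
    if extra:
        log.info("read_cohort: preserved %d unknown column(s): %s", len(extra), extra)
    return records


@dataclass(frozen=True)
class PipelineConfig:
    out_dir: str = "results/pipeline"
    seed: int = 0
    n_patients: int = 59
    n_controls: int = 10
    k_true: float = 3.0
    tes: tuple = (2.38, 4.76, 7.14)
    vis_cutoffs: tuple = (5.0, 33.0, 66.0)
    phantom_fat_fraction: float = 0.10
    morphometry: MorphometryConfig = field(default_factory=MorphometryConfig)
    log_level: str = "INFO"

    def validate(self) -> None:
        if len(self.tes) != 3 or not (self.tes[0] < self.tes[1] < self.tes[2]):
            raise ValueError("tes must be three increasing echo times")
        if self.n_patients < 3:
            raise ValueError("n_patients must be >= 3")
        if not 0 <= self.phantom_fat_fraction <= 0.5:
            raise ValueError("phantom_fat_fraction must lie in [0, 0.5]")


@dataclass
class RunManifest:
    config: dict
    version: str
    seeds: dict
    checksums: dict
    started: str
    finished: str = ""

    def write(self, path) -> None:
        tmp = Path(str(path) + ".tmp")
        tmp.write_text(json.dumps(dataclasses.asdict(self), indent=2, default=str))
        tmp.replace(path)  # atomic on POSIX


def child_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Simulate -> morphometry -> calibrate -> diagnose, with a manifest."""
    config.validate()
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = {s: child_seed(config.seed, s) for s in ("cohort", "phantom")}
    manifest = RunManifest(
        config=dataclasses.asdict(config),
        version=__version__,
        seeds=seeds,
        checksums={},
        started=datetime.now(timezone.utc).isoformat(),
    )

    # 1. cohort simulation
    records = generate_cohort(
        n_patients=config.n_patients,
        n_controls=config.n_controls,
        k=config.k_true,
        seed=seeds["cohort"],
    )
    cohort_path = out / "cohort.csv"
    write_cohort(records, cohort_path)
    df = cohort_to_frame(records)

    # 2. histology phantom + morphometry
    spec = HistologyPhantomSpec(
        target_fat_fraction=config.phantom_fat_fraction, seed=seeds["phantom"]
    )
    ph = generate_histology_phantom(spec)
    morph = areal_fat_fraction(ph.image, config.morphometry)
    morph_summary = {
        "true_areal_fat_fraction": ph.true_areal_fat_fraction,
        "measured_areal_fat_fraction": morph.areal_fat_fraction,
        "fat_area_px": morph.fat_area,
        "tissue_area_px": morph.tissue_area,
    }
    (out / "morphometry.json").write_text(json.dumps(morph_summary, indent=2))
    morph.particle_table().to_csv(out / "particles.csv", index=False)

    # 3. calibration
    patients = df[df["group"] == "patient"]
    model = fit_k(patients["alpha"], patients["his_morph_frac"])
    model.to_json(out / "calibration.json")
    link = fit_linear_link(patients["his_vis_pct"], patients["his_morph_frac"])
    cutoffs = derive_morph_cutoffs(link, config.vis_cutoffs)
    pd.DataFrame(
        {"vis_cutoff_pct": config.vis_cutoffs, "morph_cutoff_frac": cutoffs}
    ).to_csv(out / "morph_cutoffs.csv", index=False)

    # 4. diagnostics
    report = diagnostic_report(
        df, calibration=model, link=link, vis_cutoffs=config.vis_cutoffs
    )
    report.roc_table().to_csv(out / "roc.csv", index=False)
    summary = {
        "k": model.k,
        "k_r_squared": model.r_squared,
        "link_slope": link.slope,
        "link_intercept": link.intercept,
        "morph_cutoffs": list(map(float, cutoffs)),
    }
    if report.agreement is not None:
        summary["agreement"] = dataclasses.asdict(report.agreement)
    if report.control_interval is not None:
        summary["control_interval"] = dataclasses.asdict(report.control_interval)
    (out / "report.json").write_text(json.dumps(summary, indent=2))

    for p in sorted(out.iterdir()):
        if p.is_file() and not p.name.endswith(".tmp") and p.name != "manifest.json":
            manifest.checksums[p.name] = _sha256(p)
    manifest.finished = datetime.now(timezone.utc).isoformat()
    manifest.write(out / "manifest.json")
    return manifest
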