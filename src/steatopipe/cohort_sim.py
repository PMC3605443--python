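"""Synthetic study cohorts emulating the clinical distributions.

Generates per-subject records for a liver-disease cohort plus healthy
controls, matching the study conditions this pipeline targets:

* 59 patients, visual fat percent (HIS-VIS) right-skewed with median ~5%
  and range up to ~98%, drawn from a two-component mixture (a low-fat bulk
  plus a fatty-liver subgroup) and quantized the way a pathologist reports
  (integers at low fat, steps of five above ~10%, a cluster at zero);
* morphometric areal fraction (HIS-MORPH) linked to HIS-VIS through the
  regression line implied by the grade cutoffs (5% -> 0.014, 33% -> 0.043,
  66% -> 0.077), with multiplicative log-normal scatter;
* MRI alpha produced from HIS-MORPH through the calibration model
  alpha = k f / (k f + 1 - f) with k = 3 by default, after multiplicative
  dispersion on the effective fat fraction plus per-slice Gaussian noise,
  clamped to [0, 1];
* 10 controls with low alpha (median ~0.024, all below 0.2), no biopsy.

The default noise levels are set so that alpha discriminates the steatosis
grade boundaries strongly (ROC areas above 0.9 at every cutoff), emulating
the diagnostic regime of the target study; the inter-method scatter is
milder than real biopsy/MRI comparisons exhibit.

Clinical metadata (BMI, liver iron, fibrosis stage, diagnosis) is drawn to
match the printed cohort table; it is carried as metadata only and feeds no
computation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .calibration import alpha_model

__all__ = ["SubjectRecord", "CohortNoise", "generate_cohort", "cohort_to_frame"]

# HIS-MORPH ~ HIS-VIS regression line implied by the printed grade cutoffs
# (collinear at 5/33/66% -> 0.014/0.043/0.077).
MORPH_LINK_SLOPE = 0.00103
MORPH_LINK_INTERCEPT = 0.0088

DIAGNOSES = ("AIH", "ALD", "HBV-HCV", "NAFLD", "NASH", "NORM", "PSC", "OTHER")
DIAGNOSIS_WEIGHTS = (3, 2, 16, 10, 17, 3, 4, 4)  # patient counts in the cohort table


@dataclass(frozen=True)
class SubjectRecord:
    """One subject's histology, MRI and clinical values.

    Histology fields are NaN for controls (not biopsied).  ``alpha`` is the
    arithmetic mean of the three per-slice values.
    """

    id: str
    group: str  # "control" | "patient"
    his_vis: float  # percent, 0-100
    his_morph: float  # areal fraction, 0-1
    alpha_slices: tuple  # three per-slice alpha values
    alpha: float
    lic: float  # mg Fe / g dry tissue
    metavir: int  # 0-4; -1 for controls (not staged)
    bmi: float
    diagnosis: str

    def __post_init__(self) -> None:
        if self.group not in ("control", "patient"):
            raise ValueError(f"unknown group {self.group!r}")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if not math.isnan(self.his_morph) and not 0.0 <= self.his_morph <= 1.0:
            raise ValueError("his_morph must lie in [0, 1]")
        if not math.isnan(self.his_vis) and not 0.0 <= self.his_vis <= 100.0:
            raise ValueError("his_vis must lie in [0, 100]")
        if abs(self.alpha - float(np.mean(self.alpha_slices))) > 1e-9:
            raise ValueError("alpha must equal the mean of alpha_slices")


@dataclass(frozen=True)
class CohortNoise:
    """Scatter parameters of the generative links."""

    # HIS-VIS is a two-component mixture: most aetiologies carry little fat,
    # while the fatty-liver subgroup (~30% of patients, NAFLD/NASH) sits high.
    vis_log_median: float = math.log(2.5)  # non-steatotic component (percent)
    vis_log_sd: float = 1.1
    fatty_prob: float = 0.27  # 27 of the 59 patients are NAFLD/NASH
    fatty_log_median: float = math.log(45.0)
    fatty_log_sd: float = 0.55
    vis_max: float = 98.0
    morph_log_sd: float = 0.10  # multiplicative scatter on the VIS->MORPH link
    alpha_disp_log_sd: float = 0.10  # dispersion of effective fat fraction
    alpha_slice_sd: float = 0.01  # per-slice Gaussian noise on alpha
    control_alpha_log_median: float = math.log(0.024)
    control_alpha_log_sd: float = 0.42


def quantize_vis(vis):
    """Round a continuous fat percentage the way a pathologist reports it."""
    v = np.asarray(vis, dtype=float)
    v = np.where(v < 0.75, 0.0, v)
    v = np.where(v < 12, np.round(v), np.round(v / 5.0) * 5.0)
    return v


def generate_cohort(
    n_patients: int = 59,
    n_controls: int = 10,
    k: float = 3.0,
    noise: CohortNoise | None = None,
    seed: int = 0,
) -> list:
    """Draw a full synthetic cohort; deterministic for a fixed seed."""
    if n_patients < 1 or n_controls < 0:
        raise ValueError("need n_patients >= 1 and n_controls >= 0")
    noise = noise or CohortNoise()
    rng = np.random.default_rng(seed)
    records = []

    for i in range(n_patients):
        if rng.random() < noise.fatty_prob:
            raw = rng.lognormal(noise.fatty_log_median, noise.fatty_log_sd)
        else:
            raw = rng.lognormal(noise.vis_log_median, noise.vis_log_sd)
        vis = float(np.clip(quantize_vis(raw), 0.0, noise.vis_max))
        link = MORPH_LINK_SLOPE * vis + MORPH_LINK_INTERCEPT
        morph = float(np.clip(link * rng.lognormal(0.0, noise.morph_log_sd), 1e-3, 0.30))
        f_eff = float(np.clip(morph * rng.lognormal(0.0, noise.alpha_disp_log_sd), 1e-4, 0.5))
        a_true = alpha_model(f_eff, k)
        slices = tuple(
            float(np.clip(a_true + rng.normal(0.0, noise.alpha_slice_sd), 0.0, 1.0))
            for _ in range(3)
        )
        metavir = int(rng.choice(5, p=(0.24, 0.30, 0.20, 0.16, 0.10)))
        records.append(
            SubjectRecord(
                id=f"P{i + 1:03d}",
                group="patient",
                his_vis=vis,
                his_morph=morph,
                alpha_slices=slices,
                alpha=float(np.mean(slices)),
                lic=float(np.clip(rng.lognormal(math.log(0.9), 0.5), 0.3, 4.8)),
                metavir=metavir,
                bmi=float(np.clip(rng.normal(29.0, 5.1), 18.0, 48.0)),
                diagnosis=str(
                    rng.choice(DIAGNOSES, p=np.asarray(DIAGNOSIS_WEIGHTS) / sum(DIAGNOSIS_WEIGHTS))
                ),
            )
        )

    for i in range(n_controls):
        a = float(
            np.clip(
                rng.lognormal(noise.control_alpha_log_median, noise.control_alpha_log_sd),
                0.005,
                0.18,
            )
        )
        slices = tuple(
            float(np.clip(a + rng.normal(0.0, noise.alpha_slice_sd / 2), 0.0, 1.0))
            for _ in range(3)
        )
        records.append(
            SubjectRecord(
                id=f"C{i + 1:03d}",
                group="control",
                his_vis=float("nan"),
                his_morph=float("nan"),
                alpha_slices=slices,
                alpha=float(np.mean(slices)),
                lic=float(np.clip(rng.lognormal(math.log(1.2), 0.3), 0.4, 1.8)),
                metavir=-1,
                bmi=float(np.clip(rng.normal(22.6, 1.8), 18.0, 24.9)),
                diagnosis="CONTROL",
            )
        )
    return records


def cohort_to_frame(records: Sequence[SubjectRecord]) -> pd.DataFrame:
    """Tabulate records with the documented CSV column schema."""
    rows = []
    for r in records:
        rows.append(
            {
                "id": r.id,
                "group": r.group,
                "his_vis_pct": r.his_vis,
                "his_morph_frac": r.his_morph,
                "alpha_s1": r.alpha_slices[0],
                "alpha_s2": r.alpha_slices[1],
                "alpha_s3": r.alpha_slices[2],
                "alpha": r.alpha,
                "lic": r.lic,
                "metavir": r.metavir,
                "bmi": r.bmi,
                "diagnosis": r.diagnosis,
            }
        )
    return pd.DataFrame(rows)
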