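"""Diagnostic-performance statistics for the MRI fat parameter.

Implements the statistical surface of the study design this pipeline
reproduces:

* ROC analysis of alpha against dichotomised histology references, with the
  operating cutoff chosen to maximise sensitivity + specificity (Youden) and
  exact Clopper-Pearson confidence intervals on sensitivity and specificity;
* Bland-Altman limits of agreement on the natural-log scale, with confidence
  intervals and back-transformation to multiplicative ratio bounds — the
  difference variance grows with fat level, so agreement is assessed on
  ratios;
* a 95% prediction interval for control-subject alpha on the log scale,
  interpretable as a healthy reference range.

AUC uses the Mann-Whitney pairwise formulation (ties count 1/2), identical to
trapezoidal integration of the empirical ROC curve.  Positive calls follow
the convention score > cutoff.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

from .calibration import CalibrationModel, LinearLink, derive_morph_cutoffs, invert_alpha

__all__ = [
    "RocResult",
    "AgreementResult",
    "PredictionInterval",
    "DiagnosticReport",
    "roc_auc",
    "optimal_cutoff",
    "proportion_ci",
    "bland_altman_log",
    "bland_altman_from_moments",
    "prediction_interval_log",
    "diagnostic_report",
]


@dataclass(frozen=True)
class RocResult:
    threshold_label: str
    cutoff: float
    auc: float
    p_value: float
    sensitivity: float  # percent
    specificity: float  # percent
    ci_sens: tuple  # percent
    ci_spec: tuple  # percent
    n_pos: int
    n_neg: int


@dataclass(frozen=True)
class AgreementResult:
    mean_diff_log: float
    sd_diff_log: float
    loa_low: float
    loa_high: float
    ci_loa_low: tuple
    ci_loa_high: tuple
    ratio_low: float
    ratio_high: float
    ci_ratio_low: tuple
    ci_ratio_high: tuple
    n: int


@dataclass(frozen=True)
class PredictionInterval:
    low: float
    high: float
    n: int


@dataclass(frozen=True)
class DiagnosticReport:
    roc_visual: list  # RocResult per visual-reference cutoff
    roc_morph: list  # RocResult per morphometric-reference cutoff
    agreement: AgreementResult | None
    control_interval: PredictionInterval | None

    def roc_table(self) -> pd.DataFrame:
        rows = []
        for ref, results in (("HIS-VIS", self.roc_visual), ("HIS-MORPH", self.roc_morph)):
            for r in results:
                rows.append(
                    {
                        "reference": ref,
                        "cutoff_label": r.threshold_label,
                        "alpha_cutoff": r.cutoff,
                        "auc": r.auc,
                        "p_value": r.p_value,
                        "sensitivity_pct": r.sensitivity,
                        "sens_ci_low": r.ci_sens[0],
                        "sens_ci_high": r.ci_sens[1],
                        "specificity_pct": r.specificity,
                        "spec_ci_low": r.ci_spec[0],
                        "spec_ci_high": r.ci_spec[1],
                        "n_pos": r.n_pos,
                        "n_neg": r.n_neg,
                    }
                )
        return pd.DataFrame(rows)


def _check_labels(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-D of equal length")
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present")
    return scores, labels


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the empirical ROC curve, Mann-Whitney formulation.

    Equals P(score_pos > score_neg) + 0.5 * P(tie) over all positive/negative
    pairs, computed via midranks so it is O(n log n).
    """
    scores, labels = _check_labels(scores, labels)
    ranks = stats.rankdata(scores)  # midranks handle ties
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def auc_p_value(scores, labels) -> float:
    """Two-sided p for AUC != 0.5, normal approximation to Mann-Whitney."""
    scores, labels = _check_labels(scores, labels)
    pos = scores[labels]
    neg = scores[~labels]
    res = stats.mannwhitneyu(pos, neg, alternative="two-sided", method="asymptotic")
    return float(res.pvalue)


def optimal_cutoff(scores: Sequence[float], labels: Sequence[int]) -> tuple:
    """Cutoff maximising sensitivity + specificity with positives score > cutoff.

    Candidate cutoffs are the midpoints between consecutive sorted unique
    scores, plus sentinels below/above all scores.  Among Youden-sum ties the
    lowest cutoff is returned (maximises sensitivity).

    Returns ``(cutoff, sensitivity_pct, specificity_pct)``.
    """
    scores, labels = _check_labels(scores, labels)
    uniq = np.unique(scores)
    candidates = [uniq[0] - 1.0]
    candidates += list((uniq[:-1] + uniq[1:]) / 2.0)
    candidates.append(uniq[-1] + 1.0)
    n_pos = labels.sum()
    n_neg = labels.size - n_pos
    best = None
    for c in candidates:
        pred = scores > c
        sens = (pred & labels).sum() / n_pos
        spec = (~pred & ~labels).sum() / n_neg
        youden = sens + spec
        if best is None or youden > best[0] + 1e-12:
            best = (youden, c, sens, spec)
    _, c, sens, spec = best
    return float(c), float(100.0 * sens), float(100.0 * spec)


def proportion_ci(successes: int, n: int, level: float = 0.95) -> tuple:
    """Exact Clopper-Pearson interval for a binomial proportion, in percent."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= successes <= n:
        raise ValueError("successes must lie in [0, n]")
    a = (1.0 - level) / 2.0
    lo = 0.0 if successes == 0 else float(stats.beta.ppf(a, successes, n - successes + 1))
    hi = 1.0 if successes == n else float(stats.beta.ppf(1 - a, successes + 1, n - successes))
    return (100.0 * lo, 100.0 * hi)


def bland_altman_from_moments(mean_diff: float, sd_diff: float, n: int) -> AgreementResult:
    """Limits of agreement from precomputed log-difference moments.

    limits = mean +/- 1.96 sd; limit CIs use SE = sd * sqrt(3/n) with the
    t(n-1) quantile; ratio bounds are the exponentials.
    """
    if n < 3:
        raise ValueError("need n >= 3")
    if sd_diff < 0:
        raise ValueError("sd must be non-negative")
    loa_low = mean_diff - 1.96 * sd_diff
    loa_high = mean_diff + 1.96 * sd_diff
    se = sd_diff * math.sqrt(3.0 / n)
    t = float(stats.t.ppf(0.975, n - 1))
    ci_low = (loa_low - t * se, loa_low + t * se)
    ci_high = (loa_high - t * se, loa_high + t * se)
    return AgreementResult(
        mean_diff_log=mean_diff,
        sd_diff_log=sd_diff,
        loa_low=loa_low,
        loa_high=loa_high,
        ci_loa_low=ci_low,
        ci_loa_high=ci_high,
        ratio_low=math.exp(loa_low),
        ratio_high=math.exp(loa_high),
        ci_ratio_low=(math.exp(ci_low[0]), math.exp(ci_low[1])),
        ci_ratio_high=(math.exp(ci_high[0]), math.exp(ci_high[1])),
        n=n,
    )


def bland_altman_log(x: Sequence[float], y: Sequence[float]) -> AgreementResult:
    """Log-scale Bland-Altman agreement between two positive measurements.

    Differences are d_i = ln x_i - ln y_i, so the back-transformed limits
    bound the ratio x/y for 95% of pairs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    for name, v in (("x", x), ("y", y)):
        bad = np.nonzero(v <= 0)[0]
        if bad.size:
            raise ValueError(
                f"nonpositive value in {name} at index {bad[0]}: log undefined"
            )
    d = np.log(x) - np.log(y)
    return bland_altman_from_moments(float(d.mean()), float(d.std(ddof=1)), int(d.size))


def prediction_interval_log(values: Sequence[float], level: float = 0.95) -> PredictionInterval:
    """Prediction interval for a new observation, computed on the ln scale.

    mean +/- t_{(1+level)/2}(n-1) * sd * sqrt(1 + 1/n), exponentiated.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size < 3:
        raise ValueError("need at least 3 values")
    if np.any(v <= 0):
        raise ValueError("values must be strictly positive for the log transform")
    logs = np.log(v)
    m = logs.mean()
    sd = logs.std(ddof=1)
    t = float(stats.t.ppf((1 + level) / 2.0, v.size - 1))
    half = t * sd * math.sqrt(1.0 + 1.0 / v.size)
    return PredictionInterval(low=math.exp(m - half), high=math.exp(m + half), n=int(v.size))


def _roc_row(scores, positive, label) -> RocResult:
    auc = roc_auc(scores, positive)
    p = auc_p_value(scores, positive)
    cutoff, sens, spec = optimal_cutoff(scores, positive)
    n_pos = int(np.asarray(positive).astype(bool).sum())
    n_neg = len(scores) - n_pos
    tp = round(sens / 100.0 * n_pos)
    tn = round(spec / 100.0 * n_neg)
    return RocResult(
        threshold_label=label,
        cutoff=cutoff,
        auc=auc,
        p_value=p,
        sensitivity=sens,
        specificity=spec,
        ci_sens=proportion_ci(int(tp), n_pos),
        ci_spec=proportion_ci(int(tn), n_neg),
        n_pos=n_pos,
        n_neg=n_neg,
    )


def diagnostic_report(
    cohort: pd.DataFrame,
    calibration: CalibrationModel | None = None,
    link: LinearLink | None = None,
    vis_cutoffs: Sequence[float] = (5.0, 33.0, 66.0),
    morph_cutoffs: Sequence[float] | None = None,
) -> DiagnosticReport:
    """Full diagnostic summary of a cohort table.

    Expects the documented cohort schema (``alpha``, ``his_vis_pct``,
    ``his_morph_frac``, ``group``).  Patients feed the ROC analyses; the first
    visual cutoff dichotomises with >= on the reference side (any steatosis),
    subsequent ones with >; morphometric cutoffs come from ``morph_cutoffs``
    or are derived from ``link``.  When a calibration model is given, alpha is
    inverted to an equivalent areal fraction and compared to the morphometric
    measurement by log-scale Bland-Altman.  Controls, when present, yield the
    alpha prediction interval.
    """
    required = {"alpha", "group"}
    missing = required - set(cohort.columns)
    if missing:
        raise ValueError(f"cohort table missing columns: {sorted(missing)}")
    patients = cohort[cohort["group"] == "patient"]
    controls = cohort[cohort["group"] == "control"]

    roc_visual = []
    if "his_vis_pct" in cohort.columns and len(patients):
        scores = patients["alpha"].to_numpy()
        vis = patients["his_vis_pct"].to_numpy()
        for i, c in enumerate(vis_cutoffs):
            positive = vis >= c if i == 0 else vis > c
            label = (">=" if i == 0 else ">") + f"{c:g}%"
            if positive.all() or not positive.any():
                log.warning("skipping visual cutoff %s: only one class present", label)
                continue
            roc_visual.append(_roc_row(scores, positive, label))

    roc_morph = []
    if "his_morph_frac" in cohort.columns and len(patients):
        if morph_cutoffs is None and link is not None:
            morph_cutoffs = derive_morph_cutoffs(link, vis_cutoffs)
        if morph_cutoffs is not None:
            scores = patients["alpha"].to_numpy()
            morph = patients["his_morph_frac"].to_numpy()
            for i, c in enumerate(morph_cutoffs):
                positive = morph >= c if i == 0 else morph > c
                label = (">=" if i == 0 else ">") + f"{c:g}"
                if positive.all() or not positive.any():
                    log.warning("skipping morph cutoff %s: only one class present", label)
                    continue
                roc_morph.append(_roc_row(scores, positive, label))

    agreement = None
    if calibration is not None and "his_morph_frac" in cohort.columns and len(patients) >= 3:
        mri_morph = invert_alpha(patients["alpha"].to_numpy(), calibration.k)
        morph = patients["his_morph_frac"].to_numpy()
        ok = (mri_morph > 0) & (morph > 0)
        if ok.sum() >= 3:
            agreement = bland_altman_log(morph[ok], mri_morph[ok])

    control_interval = None
    if len(controls) >= 3 and (controls["alpha"] > 0).all():
        control_interval = prediction_interval_log(controls["alpha"].to_numpy())

    return DiagnosticReport(
        roc_visual=roc_visual,
        roc_morph=roc_morph,
        agreement=agreement,
        control_interval=control_interval,
    )


# Thin wrappers over routine descriptive tests, for report completeness only.
def compare_groups_t(a, b):
    return stats.ttest_ind(a, b, equal_var=False)


def compare_groups_mannwhitney(a, b):
    return stats.mannwhitneyu(a, b, alternative="two-sided")


def compare_groups_chi2(table):
    return stats.chi2_contingency(table)


def normality_ks(a):
    a = np.asarray(a, dtype=float)
    return stats.kstest((a - a.mean()) / a.std(ddof=1), "norm")
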