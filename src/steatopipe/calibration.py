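"""Calibration between the MRI fat parameter alpha and tissue fat fraction.

The T1-weighted Dixon parameter alpha is related to the fat volume fraction
``f`` through a one-parameter rational model

    alpha = k * f / (k * f + (1 - f))

where ``k`` lumps the proton-density and T1-weighting differences between fat
and water signal.  ``k`` equals the slope d(alpha)/df at f = 0, so k > 1
amplifies contrast at low fat fractions.  The model is a strictly increasing
bijection of [0, 1] onto itself for every k > 0 and reduces to the identity at
k = 1.

This module fits k by least squares to paired (fat fraction, alpha)
observations, inverts the model to map alpha back to an equivalent areal fat
fraction, and derives morphometric grade cutoffs from the regression of the
morphometric fat fraction on the pathologist's visual percentage.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
import json
import warnings
from typing import Sequence

import numpy as np
from scipy import optimize

__all__ = [
    "CalibrationModel",
    "LinearLink",
    "alpha_model",
    "invert_alpha",
    "fit_k",
    "fit_linear_link",
    "derive_morph_cutoffs",
]


@dataclass(frozen=True)
class CalibrationModel:
    """Fitted calibration constant with goodness of fit."""

    k: float
    r_squared: float
    n: int

    def __post_init__(self) -> None:
        if not self.k > 0:
            raise ValueError(f"k must be positive, got {self.k}")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "CalibrationModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(k=d["k"], r_squared=d["r_squared"], n=d["n"])


@dataclass(frozen=True)
class LinearLink:
    """OLS regression line of morphometric fraction on visual percent."""

    slope: float
    intercept: float
    r_squared: float

    def predict(self, vis_percent):
        return self.slope * np.asarray(vis_percent, dtype=float) + self.intercept


def alpha_model(f, k: float):
    """Map fat volume fraction to the expected alpha value.

    Parameters
    ----------
    f : array_like
        Fat volume fraction(s) in [0, 1].
    k : float
        Positive calibration constant.
    """
    if not k > 0:
        raise ValueError(f"k must be positive, got {k}")
    f = np.asarray(f, dtype=float)
    if np.any(f < 0) or np.any(f > 1):
        raise ValueError("fat fraction must lie in [0, 1]")
    out = k * f / (k * f + (1.0 - f))
    return float(out) if out.ndim == 0 else out


def invert_alpha(alpha, k: float):
    """Exact inverse of :func:`alpha_model`: f = alpha / (k - alpha*(k-1))."""
    if not k > 0:
        raise ValueError(f"k must be positive, got {k}")
    alpha = np.asarray(alpha, dtype=float)
    if np.any(alpha < 0) or np.any(alpha > 1):
        raise ValueError("alpha must lie in [0, 1]")
    out = alpha / (k - alpha * (k - 1.0))
    return float(out) if out.ndim == 0 else out


def fit_k(
    alphas: Sequence[float],
    fractions: Sequence[float],
    k_max: float = 100.0,
    xatol: float = 1e-9,
) -> CalibrationModel:
    """Least-squares fit of the calibration constant k.

    Minimises sum((alpha_i - alpha_model(f_i, k))^2) over k in (0, k_max] by
    bounded scalar minimisation (Brent-style); deterministic, no random
    initialisation.  Reports r^2 = 1 - SS_res / SS_tot.

    Raises
    ------
    ValueError
        On fewer than 3 pairs, fractions outside [0, 1], or all-zero
        fractions (k is unidentifiable when no fat is present).
    """
    a = np.asarray(alphas, dtype=float)
    f = np.asarray(fractions, dtype=float)
    if a.shape != f.shape or a.ndim != 1:
        raise ValueError("alphas and fractions must be 1-D of equal length")
    if a.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.any(f < 0) or np.any(f > 1):
        raise ValueError("fractions must lie in [0, 1]")
    if np.all(f == 0):
        raise ValueError("all fractions are zero: k is unidentifiable")
    if np.all(f == f[0]):
        warnings.warn(
            "all fractions identical: the fit has no leverage over the model's shape",
            UserWarning,
            stacklevel=2,
        )

    def sse(k: float) -> float:
        r = a - alpha_model(f, k)
        return float(r @ r)

    res = optimize.minimize_scalar(
        sse, bounds=(xatol, k_max), method="bounded", options={"xatol": xatol}
    )
    k_hat = float(res.x)
    ss_res = sse(k_hat)
    ss_tot = float(np.sum((a - a.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return CalibrationModel(k=k_hat, r_squared=r2, n=int(a.size))


def fit_linear_link(
    vis_percent: Sequence[float],
    morph_fraction: Sequence[float],
    through_origin: bool = False,
) -> LinearLink:
    """OLS fit of morphometric fraction against visual fat percent.

    Default includes an intercept; ``through_origin=True`` forces the line
    through zero.
    """
    x = np.asarray(vis_percent, dtype=float)
    y = np.asarray(morph_fraction, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("need >= 2 paired observations of equal length")
    if through_origin:
        X = x[:, None]
    else:
        X = np.column_stack([x, np.ones_like(x)])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    slope = float(coef[0])
    intercept = 0.0 if through_origin else float(coef[1])
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else float("nan")
    return LinearLink(slope=slope, intercept=intercept, r_squared=r2)


def derive_morph_cutoffs(
    link: LinearLink, vis_cutoffs: Sequence[float] = (5.0, 33.0, 66.0)
) -> np.ndarray:
    """Morphometric fraction cutoffs at the visual grade boundaries.

    Evaluates the fitted regression line at each visual cutoff (percent),
    mirroring how grade boundaries on the visual scale translate to the
    morphometric scale.
    """
    return np.asarray(link.predict(vis_cutoffs), dtype=float)
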