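"""T2*-corrected Dixon alpha estimation from triple-echo ROI intensities.

A single breath-hold gradient-echo acquisition yields three echoes: opposed
phase at TE1, in phase at TE2, opposed phase at TE3.  The effective transverse
decay T2* is estimated from the two opposed-phase echoes,

    T2* = (TE3 - TE1) / ln(OP1 / OP2),

and the first opposed-phase intensity is decay-corrected forward to the
in-phase echo time before forming the standard Dixon fraction

    alpha = (IP - OP1 * exp(-(TE2 - TE1)/T2*)) / (2 * IP),

clamped to [0, 1].  alpha is computed per slice and averaged across slices.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

log = logging.getLogger(__name__)

#: Sentinel T2* meaning "no measurable decay" (decay factor exactly 1).
NO_CORRECTION = math.inf

#: Echo times (ms) of the acquisition protocol this pipeline targets.
DEFAULT_TES = (2.38, 4.76, 7.14)

__all__ = [
    "EchoTriple",
    "AlphaResult",
    "NO_CORRECTION",
    "DEFAULT_TES",
    "estimate_t2star",
    "compute_alpha",
    "alpha_from_slices",
    "roi_mean",
]


@dataclass(frozen=True)
class EchoTriple:
    """ROI mean intensities at the opposed/in/opposed-phase echoes."""

    op1: float
    ip: float
    op2: float
    te1: float = DEFAULT_TES[0]
    te2: float = DEFAULT_TES[1]
    te3: float = DEFAULT_TES[2]

    def __post_init__(self) -> None:
        if min(self.op1, self.ip, self.op2) < 0:
            raise ValueError("echo intensities must be non-negative")
        if not (self.te1 < self.te2 < self.te3):
            raise ValueError("echo times must satisfy te1 < te2 < te3")


@dataclass(frozen=True)
class AlphaResult:
    alpha_per_slice: tuple
    alpha: float
    t2star_per_slice: tuple
    correction_applied: tuple  # False where the no-decay fallback fired


def estimate_t2star(triple: EchoTriple) -> float:
    """T2* (ms) from the two opposed-phase echoes.

    Returns the :data:`NO_CORRECTION` sentinel (infinite T2*, decay factor 1)
    when OP1 <= OP2, i.e. when noise has inverted the expected monotonic decay
    and no physical T2* exists.  Zero intensities are an error: the log ratio
    is undefined.
    """
    if triple.op1 == 0 or triple.op2 == 0:
        raise ValueError("opposed-phase intensity of 0: T2* undefined")
    if triple.op1 <= triple.op2:
        return NO_CORRECTION
    return (triple.te3 - triple.te1) / math.log(triple.op1 / triple.op2)


def compute_alpha(triple: EchoTriple, t2star: float) -> float:
    """Decay-corrected Dixon fraction for one slice, clamped to [0, 1]."""
    if triple.ip == 0:
        raise ValueError("in-phase intensity of 0: alpha undefined")
    decay = math.exp(-(triple.te2 - triple.te1) / t2star)
    raw = (triple.ip - triple.op1 * decay) / (2.0 * triple.ip)
    return min(max(raw, 0.0), 1.0)


def alpha_from_slices(triples: Sequence[EchoTriple]) -> AlphaResult:
    """Per-slice T2* and alpha, averaged at the alpha level.

    The protocol acquires three axial slices; fewer are accepted with a
    warning so partially-acquired subjects are not dropped.
    """
    if len(triples) == 0:
        raise ValueError("no slices provided")
    if len(triples) < 3:
        log.warning("alpha_from_slices: only %d slice(s), expected 3", len(triples))
    t2stars, alphas, corrected = [], [], []
    for t in triples:
        t2 = estimate_t2star(t)
        t2stars.append(t2)
        alphas.append(compute_alpha(t, t2))
        corrected.append(t2 is not NO_CORRECTION and math.isfinite(t2))
    return AlphaResult(
        alpha_per_slice=tuple(alphas),
        alpha=float(np.mean(alphas)),
        t2star_per_slice=tuple(t2stars),
        correction_applied=tuple(corrected),
    )


def roi_radius_mm(area_mm2: float) -> float:
    """Radius of a circular ROI of the given area (mm)."""
    if area_mm2 <= 0:
        raise ValueError("ROI area must be positive")
    return math.sqrt(area_mm2 / math.pi)


def roi_mean(
    image: np.ndarray,
    center: tuple,
    area_mm2: float,
    pixel_spacing: tuple,
) -> float:
    """Mean intensity over a circular ROI.

    Parameters
    ----------
    image : 2-D array
        Magnitude image.
    center : (row, col)
        ROI centre in pixel coordinates.
    area_mm2 : float
        ROI area; the radius is sqrt(area / pi).
    pixel_spacing : (row_mm, col_mm)
        Physical pixel size.

    A pixel contributes iff its centre falls inside the circle.  The ROI must
    lie fully inside the image.
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("image must be 2-D")
    r_mm = roi_radius_mm(area_mm2)
    cy, cx = center
    sy, sx = pixel_spacing
    ry, rx = r_mm / sy, r_mm / sx
    if cy - ry < -0.5 or cx - rx < -0.5 or cy + ry > image.shape[0] - 0.5 or cx + rx > image.shape[1] - 0.5:
        raise ValueError("ROI extends outside the image")
    yy, xx = np.mgrid[0 : image.shape[0], 0 : image.shape[1]]
    inside = ((yy - cy) * sy) ** 2 + ((xx - cx) * sx) ** 2 < r_mm**2
    if not inside.any():
        raise ValueError("ROI contains no pixel centres")
    return float(image[inside].mean())
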