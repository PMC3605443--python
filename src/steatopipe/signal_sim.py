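"""Two-compartment water/fat simulator for triple-echo ROI signals.

Produces the ROI-mean intensities a spoiled gradient-echo sequence would see
for a voxel population containing water and fat proton pools.  Each pool's
steady-state weight is

    w = rho * sin(theta) * (1 - E1) / (1 - cos(theta) * E1),   E1 = exp(-TR/T1)

and the observed magnitude at echo time TE is

    S(TE) = |W -/+ F| * exp(-TE / T2*)

with "-" at the opposed-phase echoes (TE1, TE3) and "+" at the in-phase echo
(TE2).  Optional Gaussian noise of a given sd is added independently per echo.

The simulator refuses fat fractions above 0.5: with magnitude-only dual-echo
data, water and fat are interchangeable and the water-dominant branch is
assumed throughout the pipeline.

This is a ROI-level simulator only: no k-space, phase maps, or field
inhomogeneity, and no iron-dependent T2* shortening.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .alpha import DEFAULT_TES, EchoTriple

__all__ = ["MRISignalParams", "steady_state_weight", "simulate_roi_signals"]


@dataclass(frozen=True)
class MRISignalParams:
    """Acquisition and tissue parameters for the ROI signal model.

    Echo/repetition times and flip angle default to the targeted protocol
    (TEs 2.38/4.76/7.14 ms, TR 88 ms, 70 degrees).  The T1 defaults are
    literature-typical 1.5 T values for liver water (~586 ms) and fat
    (~343 ms) and are package defaults, not protocol constants.
    """

    te1: float = DEFAULT_TES[0]
    te2: float = DEFAULT_TES[1]
    te3: float = DEFAULT_TES[2]
    tr: float = 88.0
    flip_angle: float = 70.0  # degrees
    t1_water: float = 586.0
    t1_fat: float = 343.0
    t2star: float = 20.0
    proton_density_water: float = 100.0
    proton_density_fat: float = 100.0
    noise_sd: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (self.te1 < self.te2 < self.te3):
            raise ValueError("echo times must satisfy te1 < te2 < te3")
        if self.t2star <= 0:
            raise ValueError("t2star must be positive")
        if self.proton_density_water < 0 or self.proton_density_fat < 0:
            raise ValueError("proton densities must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @property
    def weight_ratio(self) -> float:
        """Per-proton fat/water signal weight ratio (the calibration k)."""
        ww = steady_state_weight(1.0, self.flip_angle, self.tr, self.t1_water)
        wf = steady_state_weight(1.0, self.flip_angle, self.tr, self.t1_fat)
        return wf / ww


def steady_state_weight(rho: float, flip_angle_deg: float, tr: float, t1: float) -> float:
    """Spoiled gradient-echo steady-state magnetization weight."""
    theta = math.radians(flip_angle_deg)
    e1 = math.exp(-tr / t1)
    return rho * math.sin(theta) * (1.0 - e1) / (1.0 - math.cos(theta) * e1)


def simulate_roi_signals(fat_fraction: float, params: MRISignalParams) -> EchoTriple:
    """Simulate the three ROI-mean echo intensities for a fat proton fraction.

    ``fat_fraction`` is the fraction of tissue protons residing in fat,
    restricted to [0, 0.5] (water dominance).  With zero noise the output is a
    closed-form function of the inputs; with noise, draws come from a
    generator seeded by ``params.seed``.
    """
    if not 0.0 <= fat_fraction <= 0.5:
        raise ValueError(
            f"fat_fraction {fat_fraction} outside [0, 0.5]: magnitude Dixon "
            "signals are water/fat ambiguous above 0.5"
        )
    rho_total = params.proton_density_water + params.proton_density_fat
    w = steady_state_weight(
        (1.0 - fat_fraction) * rho_total, params.flip_angle, params.tr, params.t1_water
    )
    f = steady_state_weight(
        fat_fraction * rho_total, params.flip_angle, params.tr, params.t1_fat
    )
    signals = []
    for te, sign in ((params.te1, -1.0), (params.te2, +1.0), (params.te3, -1.0)):
        signals.append(abs(w + sign * f) * math.exp(-te / params.t2star))
    if params.noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        signals = [max(s + rng.normal(0.0, params.noise_sd), 0.0) for s in signals]
    op1, ip, op2 = signals
    return EchoTriple(op1=op1, ip=ip, op2=op2, te1=params.te1, te2=params.te2, te3=params.te3)
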