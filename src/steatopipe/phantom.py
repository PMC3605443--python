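"""Synthetic trichrome-like histology sections with known areal fat fraction.

A phantom emulates a scanned, stained biopsy section: dark textured tissue on
a white slide background, with three kinds of bright (near-white) voids inside
the tissue:

* **fat vacuoles** — near-circular holes with diameters drawn from a
  configurable range; these constitute the ground-truth fat mask;
* **vessels** — large elongated bright structures (above the morphometric
  size bound and/or below the circularity bound);
* **tears** — long thin cracks with very low circularity.

Vacuoles never overlap each other, vessels, tears, or the tissue boundary, so
the ground-truth areal fat fraction is exactly (fat pixels)/(tissue pixels) by
construction.  Placement is rejection-resampled until the achieved fraction is
within +/-10% relative of the target; an unreachable target raises instead of
silently under-filling.

All randomness flows from the single seed in the spec.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict, field

import numpy as np
import tifffile
from skimage import draw

__all__ = [
    "HistologyPhantomSpec",
    "HistologyPhantom",
    "PhantomPlacementError",
    "generate_histology_phantom",
    "equivalent_circle_diameter_um",
    "DEFAULT_PIXEL_SIZE_UM",
]

#: Default scan resolution, back-inferred from the morphometric size filter's
#: pixel/micron anchor (a 100 px circle has diameter 5.6 um).
DEFAULT_PIXEL_SIZE_UM = 0.5

FRACTION_RTOL = 0.10  # relative tolerance on the achieved fat fraction
SEPARATION_PX = 2  # minimum gap between bright structures and boundaries


class PhantomPlacementError(RuntimeError):
    """Raised when the target fat fraction cannot be realised in the image."""


@dataclass(frozen=True)
class HistologyPhantomSpec:
    image_width: int = 512
    image_height: int = 512
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM  # um / pixel
    target_fat_fraction: float = 0.05
    vacuole_diameter_range: tuple = (8.0, 45.0)  # um
    n_vessels: int = 1
    n_tears: int = 1
    tissue_color_mean: tuple = (150, 105, 160)  # trichrome-ish RGB
    tissue_color_std: float = 10.0
    background_value: int = 255
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.target_fat_fraction <= 0.5:
            raise ValueError("target_fat_fraction must lie in [0, 0.5]")
        lo, hi = self.vacuole_diameter_range
        if lo <= 0 or hi < lo:
            raise ValueError("vacuole diameters must be positive and ordered")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.image_width < 64 or self.image_height < 64:
            raise ValueError("image must be at least 64x64 pixels")


@dataclass(frozen=True)
class HistologyPhantom:
    image: np.ndarray  # (H, W, 3) uint8
    fat_mask: np.ndarray  # (H, W) bool, ground-truth vacuoles
    tissue_mask: np.ndarray  # (H, W) bool, filled biopsy outline
    vessel_mask: np.ndarray  # (H, W) bool, vessels and tears
    true_areal_fat_fraction: float
    spec: HistologyPhantomSpec

    def save(self, image_path, mask_prefix=None) -> None:
        """Write the RGB image as TIFF plus a sidecar JSON with ground truth."""
        tifffile.imwrite(image_path, self.image)
        meta = asdict(self.spec)
        meta["true_areal_fat_fraction"] = self.true_areal_fat_fraction
        with open(str(image_path) + ".json", "w") as fh:
            json.dump(meta, fh, indent=2)
        if mask_prefix is not None:
            tifffile.imwrite(f"{mask_prefix}_fat.tif", self.fat_mask.astype(np.uint8) * 255)
            tifffile.imwrite(f"{mask_prefix}_tissue.tif", self.tissue_mask.astype(np.uint8) * 255)


def equivalent_circle_diameter_um(area_px: float, pixel_size: float = DEFAULT_PIXEL_SIZE_UM) -> float:
    """Diameter (um) of a circle with the given pixel area: d = 2*sqrt(A/pi)*s."""
    if area_px < 0:
        raise ValueError("area must be non-negative")
    return 2.0 * math.sqrt(area_px / math.pi) * pixel_size


def pixel_size_from_anchor(area_px: float, diameter_um: float) -> float:
    """Pixel size (um/px) implied by one (area, equivalent diameter) anchor."""
    return diameter_um / (2.0 * math.sqrt(area_px / math.pi))


def _tissue_ellipse(h: int, w: int) -> np.ndarray:
    mask = np.zeros((h, w), dtype=bool)
    rr, cc = draw.ellipse(h / 2 - 0.5, w / 2 - 0.5, 0.38 * h, 0.44 * w, shape=(h, w))
    mask[rr, cc] = True
    return mask


def _disk_mask(h, w, cy, cx, radius):
    rr, cc = draw.disk((cy, cx), radius, shape=(h, w))
    m = np.zeros((h, w), dtype=bool)
    m[rr, cc] = True
    return m


def _rot_ellipse_mask(h, w, cy, cx, a, b, angle):
    rr, cc = draw.ellipse(cy, cx, a, b, shape=(h, w), rotation=angle)
    m = np.zeros((h, w), dtype=bool)
    m[rr, cc] = True
    return m


def _place(
    rng, proposal, allowed: np.ndarray, occupied: np.ndarray, max_tries: int = 200
):
    """Find a placement whose mask fits inside `allowed` avoiding `occupied`."""
    h, w = allowed.shape
    for _ in range(max_tries):
        cy = rng.uniform(0, h)
        cx = rng.uniform(0, w)
        m = proposal(cy, cx)
        if not m.any():
            continue
        if np.all(allowed[m]) and not np.any(occupied[m]):
            return m
    return None


def generate_histology_phantom(spec: HistologyPhantomSpec) -> HistologyPhantom:
    """Render a phantom section realising the spec's target fat fraction.

    Raises
    ------
    PhantomPlacementError
        If non-overlapping vacuoles cannot reach the target fraction within
        +/-10% relative (image too small or too crowded).
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_height, spec.image_width
    tissue = _tissue_ellipse(h, w)
    tissue_area = int(tissue.sum())

    # Bright structures must stay clear of the tissue border so hole-filling
    # of the inverted threshold image recovers the full tissue outline.
    from scipy import ndimage

    interior = ndimage.binary_erosion(tissue, iterations=SEPARATION_PX + 1)
    occupied = np.zeros((h, w), dtype=bool)  # structures + separation halo

    vessel_mask = np.zeros((h, w), dtype=bool)
    for _ in range(spec.n_vessels):
        # elongated, oversized: rejected by both size and circularity filters
        area = rng.uniform(12000, 22000)
        ratio = rng.uniform(3.5, 5.0)
        b = math.sqrt(area / (math.pi * ratio))
        a = ratio * b
        angle = rng.uniform(0, math.pi)
        m = _place(rng, lambda cy, cx: _rot_ellipse_mask(h, w, cy, cx, a, b, angle),
                   interior, occupied)
        if m is None:
            raise PhantomPlacementError("could not place a vessel")
        vessel_mask |= m
        occupied |= ndimage.binary_dilation(m, iterations=SEPARATION_PX)

    for _ in range(spec.n_tears):
        # thin crack: in-bounds area but circularity far below 0.5
        length = rng.uniform(150, 260)
        thick = rng.uniform(3.0, 5.0)
        angle = rng.uniform(0, math.pi)
        m = _place(rng, lambda cy, cx: _rot_ellipse_mask(h, w, cy, cx, thick, length / 2, angle),
                   interior, occupied)
        if m is None:
            raise PhantomPlacementError("could not place a tear")
        vessel_mask |= m
        occupied |= ndimage.binary_dilation(m, iterations=SEPARATION_PX)

    # --- vacuoles: rejection-resample until the fraction lands in band -----
    fat_mask = np.zeros((h, w), dtype=bool)
    target_px = spec.target_fat_fraction * tissue_area
    tol_px = FRACTION_RTOL * target_px
    lo_um, hi_um = spec.vacuole_diameter_range
    placed = 0
    failures = 0
    while target_px > 0 and placed < target_px - tol_px:
        d_um = rng.uniform(lo_um, hi_um)
        r_px = d_um / 2.0 / spec.pixel_size
        est_area = math.pi * r_px**2
        if placed + est_area > target_px + tol_px:
            # would overshoot: cap the diameter so the vacuole can still fit
            max_area = target_px + tol_px - placed
            r_cap = math.sqrt(max_area / math.pi)
            if 2 * r_cap * spec.pixel_size < lo_um:
                break  # smallest admissible vacuole overshoots; check band below
            r_px = rng.uniform(lo_um / 2.0 / spec.pixel_size, r_cap)
        m = _place(rng, lambda cy, cx: _disk_mask(h, w, cy, cx, r_px), interior, occupied)
        if m is None:
            failures += 1
            if failures > 50:
                raise PhantomPlacementError(
                    f"target fat fraction {spec.target_fat_fraction} unreachable: "
                    f"placed {placed / tissue_area:.4f} before running out of room"
                )
            continue
        fat_mask |= m
        placed = int(fat_mask.sum())
        occupied |= ndimage.binary_dilation(m, iterations=SEPARATION_PX)

    achieved = placed / tissue_area
    if target_px > 0 and abs(achieved - spec.target_fat_fraction) > FRACTION_RTOL * spec.target_fat_fraction:
        raise PhantomPlacementError(
            f"achieved fraction {achieved:.4f} outside +/-10% of target "
            f"{spec.target_fat_fraction:.4f}"
        )

    # --- render ------------------------------------------------------------
    img = np.empty((h, w, 3), dtype=np.uint8)
    img[:] = spec.background_value
    tissue_px = int(tissue.sum())
    for c, mean in enumerate(spec.tissue_color_mean):
        vals = rng.normal(mean, spec.tissue_color_std, size=tissue_px)
        # keep tissue safely below the bright-void intensity range
        img[..., c][tissue] = np.clip(vals, 0, 219).astype(np.uint8)
    bright = fat_mask | vessel_mask
    n_bright = int(bright.sum())
    for c in range(3):
        vals = rng.normal(250, 2.0, size=n_bright)
        img[..., c][bright] = np.clip(vals, 235, 255).astype(np.uint8)

    return HistologyPhantom(
        image=img,
        fat_mask=fat_mask,
        tissue_mask=tissue,
        vessel_mask=vessel_mask,
        true_areal_fat_fraction=achieved,
        spec=spec,
    )
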