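"""Infarct-area quantification from binary masks.

The percentage infarct area (PIA) of a stained brain section is the
lesion's pixel count over the ipsilateral hemisphere's pixel count,
times 100.  Segmentation of raw histology is out of scope: this module
operates on already-binarized lesion/hemisphere mask pairs, exchanged as
8-bit PNGs (0 background, 255 foreground) or 0/1 text grids, and ships a
synthetic mask generator for fixtures and worked examples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from PIL import Image
from scipy import ndimage

from .errors import ParameterError


@dataclass
class LesionMaskPair:
    """Binary lesion and hemisphere masks of identical shape.

    The lesion must be contained in the hemisphere; ``pixel_size`` (µm/px)
    is carried for provenance only — it cancels out of the area ratio.
    """

    lesion: np.ndarray
    hemisphere: np.ndarray
    pixel_size: float | None = None

    def __post_init__(self) -> None:
        self.lesion = np.asarray(self.lesion, dtype=bool)
        self.hemisphere = np.asarray(self.hemisphere, dtype=bool)
        if self.lesion.shape != self.hemisphere.shape:
            raise ParameterError(
                f"mask shapes differ: {self.lesion.shape} vs {self.hemisphere.shape}")
        if not self.hemisphere.any():
            raise ParameterError("empty hemisphere mask")
        if np.any(self.lesion & ~self.hemisphere):
            raise ParameterError("lesion pixels found outside the hemisphere mask")


def percent_infarct_area(m: LesionMaskPair) -> float:
    """PIA = 100 x lesion pixels / hemisphere pixels."""
    return 100.0 * int(m.lesion.sum()) / int(m.hemisphere.sum())


def generate_lesion_mask(hemisphere_shape: tuple[int, int], target_pia: float,
                         seed: int = 0) -> LesionMaskPair:
    """Synthetic mask pair hitting *target_pia* percent.

    The hemisphere is the filled ellipse inscribed in ``hemisphere_shape``.
    The lesion grows from a random interior point by repeated dilation
    clipped to the hemisphere; the final ring is trimmed in fixed raster
    order so the pixel count equals round(target_pia% of hemisphere).
    """
    if not 0 <= target_pia <= 100:
        raise ParameterError(f"target_pia must be in [0, 100], got {target_pia}")
    h, w = hemisphere_shape
    if h < 3 or w < 3:
        raise ParameterError(f"shape {hemisphere_shape} too small for an elliptical mask")
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    ry, rx = h / 2.0, w / 2.0
    hemisphere = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
    hemi_px = int(hemisphere.sum())
    target_px = int(round(target_pia / 100.0 * hemi_px))

    lesion = np.zeros_like(hemisphere)
    if target_px > 0:
        rng = np.random.default_rng(seed)
        interior = np.argwhere(hemisphere)
        sy, sx = interior[rng.integers(interior.shape[0])]
        lesion[sy, sx] = True
        while int(lesion.sum()) < target_px:
            grown = ndimage.binary_dilation(lesion) & hemisphere
            if grown.sum() == lesion.sum():  # hemisphere saturated
                break
            excess = int(grown.sum()) - target_px
            if excess > 0:
                ring = np.argwhere(grown & ~lesion)
                for y, x in ring[: excess]:  # trim in raster order
                    grown[y, x] = False
            lesion = grown
    return LesionMaskPair(lesion=lesion, hemisphere=hemisphere)


def write_mask_png(mask: np.ndarray, path: str) -> str:
    """Write a binary mask as an 8-bit PNG (0 background, 255 foreground)."""
    img = Image.fromarray(np.where(np.asarray(mask, dtype=bool), 255, 0).astype(np.uint8))
    img.save(path, format="PNG")
    return path


def read_mask_png(path: str) -> np.ndarray:
    """Read a binary mask PNG; any nonzero pixel is foreground."""
    return np.asarray(Image.open(path).convert("L")) > 0


def write_mask_text(mask: np.ndarray, path: str) -> str:
    """Write a binary mask as a 0/1 text grid."""
    np.savetxt(path, np.asarray(mask, dtype=int), fmt="%d")
    return path


def read_mask_text(path: str) -> np.ndarray:
    return np.loadtxt(path, ndmin=2).astype(bool)
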