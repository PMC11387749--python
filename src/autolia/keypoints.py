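"""Morphological vein extraction and leaf root/tip key-point localisation.

Each segmented leaf region is processed with the binary open operation
``A o B = (A erode B) dilate B``, which strips boundary protrusions and leaves
the central vein support of the blade. The key points are then the vein pixels
nearest the top and bottom of the image: the leaf root and the leaf tip.
"""

from __future__ import annotations

from dataclasses import dataclass
import logging

import numpy as np
from scipy import ndimage as ndi
from skimage import morphology as skmorph

from .depthseg import DepthMap
from .errors import InvalidInputError, KeypointDepthError

logger = logging.getLogger(__name__)

__all__ = [
    "StructuringElement",
    "Keypoint",
    "LeafKeypoints",
    "erode",
    "dilate",
    "open_mask",
    "extract_vein",
    "locate_keypoints",
]


@dataclass(frozen=True)
class StructuringElement:
    """Flat structuring element: a disk or square of the given pixel radius."""

    shape: str = "disk"
    radius: int = 2

    def __post_init__(self) -> None:
        if self.shape not in ("disk", "square"):
            raise InvalidInputError(f"unknown structuring element shape {self.shape!r}")
        if not (isinstance(self.radius, (int, np.integer)) and self.radius >= 1):
            raise InvalidInputError(f"radius must be an integer >= 1, got {self.radius}")

    def footprint(self) -> np.ndarray:
        if self.shape == "disk":
            return skmorph.disk(self.radius).astype(bool)
        side = 2 * self.radius + 1
        return np.ones((side, side), dtype=bool)


def _as_mask(mask) -> np.ndarray:
    m = np.asarray(mask, dtype=bool)
    if m.ndim != 2:
        raise InvalidInputError("mask must be 2-D")
    return m


def erode(mask, se: StructuringElement) -> np.ndarray:
    """Binary erosion: pixels whose translated SE fits inside the mask."""
    return ndi.binary_erosion(_as_mask(mask), structure=se.footprint())


def dilate(mask, se: StructuringElement) -> np.ndarray:
    """Binary dilation (Minkowski sum with the SE)."""
    return ndi.binary_dilation(_as_mask(mask), structure=se.footprint())


def open_mask(mask, se: StructuringElement) -> np.ndarray:
    """Binary opening: erosion followed by dilation (anti-extensive, idempotent)."""
    return dilate(erode(mask, se), se)


def extract_vein(region, se: StructuringElement, skeletonize: bool = False) -> np.ndarray:
    """Vein support of one leaf region via the open operation.

    If the region is thinner than the SE (opening empty) the radius falls back
    to 1, and finally to the raw region, so a nonempty region always yields a
    nonempty vein. With ``skeletonize=True`` the opened mask is additionally
    thinned to its medial line (useful for strongly curved leaves).
    """
    region = _as_mask(region)
    if not region.any():
        raise InvalidInputError("empty leaf region")
    vein = open_mask(region, se)
    if not vein.any() and se.radius > 1:
        vein = open_mask(region, StructuringElement(se.shape, 1))
    if not vein.any():
        vein = region.copy()
    if skeletonize:
        skel = skmorph.skeletonize(vein)
        if skel.any():
            vein = skel
    return vein


@dataclass(frozen=True)
class Keypoint:
    row: int
    col: int
    depth_m: float


@dataclass(frozen=True)
class LeafKeypoints:
    """Leaf root (topmost vein pixel) and tip (bottommost vein pixel)."""

    root: Keypoint
    tip: Keypoint

    def __post_init__(self) -> None:
        if self.root.row > self.tip.row:
            raise InvalidInputError("root must not lie below tip")


def _depth_at(depth: DepthMap, row: int, col: int) -> float:
    """Depth at a pixel, repaired by the 5x5 neighbourhood median if invalid."""
    if depth.valid_mask[row, col]:
        return float(depth.values[row, col])
    h, w = depth.shape
    r0, r1 = max(0, row - 2), min(h, row + 3)
    c0, c1 = max(0, col - 2), min(w, col + 3)
    window = depth.values[r0:r1, c0:c1]
    ok = depth.valid_mask[r0:r1, c0:c1]
    if not ok.any():
        raise KeypointDepthError(f"no valid depth near key point ({row}, {col})")
    return float(np.median(window[ok]))


def locate_keypoints(vein, depth: DepthMap) -> LeafKeypoints:
    """Root/tip key points of a vein mask with depths attached.

    Root is the vein pixel with minimum row, tip the one with maximum row;
    ties break toward the smaller column. Missing depths are repaired by the
    median of valid depths in the 5x5 neighbourhood; if none exists a
    :class:`KeypointDepthError` is raised and the caller skips the leaf.
    """
    vein = _as_mask(vein)
    rows, cols = np.nonzero(vein)
    if rows.size == 0:
        raise InvalidInputError("empty vein mask")
    if vein.shape != depth.shape:
        raise InvalidInputError("vein/depth shapes disagree")
    r_root = int(rows.min())
    c_root = int(cols[rows == r_root].min())
    r_tip = int(rows.max())
    c_tip = int(cols[rows == r_tip].min())
    root = Keypoint(r_root, c_root, _depth_at(depth, r_root, c_root))
    tip = Keypoint(r_tip, c_tip, _depth_at(depth, r_tip, c_tip))
    return LeafKeypoints(root, tip)
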