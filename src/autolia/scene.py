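"""Acquisition front-end: plant detection/selection, box alignment and
cropping, and disparity-to-depth conversion.

The deep detector and stereo network the full system would use are pluggable
backends behind small callable contracts; the package ships deterministic
fixture backends (full-frame detection, sidecar-file detections, precomputed
disparity) so the geometry pipeline can be exercised without any model.

Coordinates are 0-based; boxes are half-open ``(x0, y0, x1, y1)``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Protocol, runtime_checkable

import numpy as np

from .depthseg import DepthMap
from .errors import EmptyDepthError, InvalidInputError, NoPlantError
from .geometry import CameraModel

logger = logging.getLogger(__name__)

__all__ = [
    "Detection",
    "DetectorBackend",
    "FullFrameDetector",
    "SidecarDetector",
    "CropPair",
    "select_plant",
    "align_boxes",
    "crop",
    "disparity_to_depth",
    "PrecomputedDisparity",
]


@dataclass(frozen=True)
class Detection:
    """One detector output: half-open pixel box, confidence, class name."""

    box: tuple[int, int, int, int]
    confidence: float
    class_name: str = "plant"

    def __post_init__(self) -> None:
        x0, y0, x1, y1 = self.box
        if not (x0 < x1 and y0 < y1):
            raise InvalidInputError(f"degenerate box {self.box}")
        if not 0.0 <= self.confidence <= 1.0:
            raise InvalidInputError(f"confidence must lie in [0, 1], got {self.confidence}")

    @property
    def width(self) -> int:
        return self.box[2] - self.box[0]

    @property
    def height(self) -> int:
        return self.box[3] - self.box[1]

    @property
    def area(self) -> int:
        return self.width * self.height


@runtime_checkable
class DetectorBackend(Protocol):
    """Callable contract: image -> list of detections, deterministic."""

    def __call__(self, image: np.ndarray) -> list[Detection]: ...


class FullFrameDetector:
    """Fixture backend: the whole frame is one plant at full confidence."""

    def __init__(self, confidence: float = 1.0):
        self.confidence = confidence

    def __call__(self, image: np.ndarray) -> list[Detection]:
        h, w = image.shape[:2]
        return [Detection((0, 0, w, h), self.confidence)]


class SidecarDetector:
    """Fixture backend reading detections from a JSON sidecar file.

    The file holds a list of objects with keys ``box`` (``[x0, y0, x1, y1]``),
    ``confidence`` and optional ``class_name``; boxes are clipped to the image.
    """

    def __init__(self, path):
        with open(path) as fh:
            self._records = json.load(fh)

    def __call__(self, image: np.ndarray) -> list[Detection]:
        h, w = image.shape[:2]
        out = []
        for rec in self._records:
            x0, y0, x1, y1 = rec["box"]
            x0, x1 = max(0, int(x0)), min(w, int(x1))
            y0, y1 = max(0, int(y0)), min(h, int(y1))
            if x0 >= x1 or y0 >= y1:
                continue
            out.append(
                Detection((x0, y0, x1, y1), float(rec["confidence"]), rec.get("class_name", "plant"))
            )
        return out


@dataclass
class CropPair:
    """Left/right crops of identical size with their source-image offsets."""

    left: np.ndarray
    right: np.ndarray
    offset_left: tuple[int, int]  # (x0, y0)
    offset_right: tuple[int, int]

    def __post_init__(self) -> None:
        if self.left.shape[:2] != self.right.shape[:2]:
            raise InvalidInputError("stereo crops must have equal dimensions")


def select_plant(dets: list[Detection], conf_th: float = 0.6) -> Detection:
    """Pick the best plant: highest confidence at or above the threshold.

    Ties break toward the larger box area, then the smaller x0. With no
    detection at or above ``conf_th`` a :class:`NoPlantError` is raised and the
    caller aborts the frame.
    """
    if not 0.0 <= conf_th <= 1.0:
        raise InvalidInputError(f"conf_th must lie in [0, 1], got {conf_th}")
    eligible = [d for d in dets if d.confidence >= conf_th]
    if not eligible:
        raise NoPlantError(
            f"no detection with confidence >= {conf_th} among {len(dets)} candidates"
        )
    return min(eligible, key=lambda d: (-d.confidence, -d.area, d.box[0]))


def _expand_to(box: tuple[int, int, int, int], tw: int, th: int, image_size) -> tuple[int, int, int, int]:
    """Symmetrically expand a box about its centre to (tw, th), shift to fit."""
    W, H = image_size
    x0, y0, x1, y1 = box
    cx = (x0 + x1) / 2.0
    cy = (y0 + y1) / 2.0
    nx0 = int(round(cx - tw / 2.0))
    ny0 = int(round(cy - th / 2.0))
    nx0 = min(max(nx0, 0), max(W - tw, 0))
    ny0 = min(max(ny0, 0), max(H - th, 0))
    return (nx0, ny0, nx0 + min(tw, W), ny0 + min(th, H))


def align_boxes(
    left: Detection, right: Detection, image_size: tuple[int, int]
) -> tuple[tuple[int, int, int, int], tuple[int, int, int, int]]:
    """Expand the two plant boxes to a common size.

    Each box grows symmetrically about its centre to the element-wise maximum
    width and height of the pair, then is shifted (never shrunk) to fit inside
    the image. If the target exceeds the image, both boxes clip to the full
    image extent with a logged warning.
    """
    W, H = image_size
    tw = max(left.width, right.width)
    th = max(left.height, right.height)
    if tw > W or th > H:
        logger.warning("aligned box %dx%d exceeds image %dx%d; clipping", tw, th, W, H)
        tw, th = min(tw, W), min(th, H)
    return (_expand_to(left.box, tw, th, image_size), _expand_to(right.box, tw, th, image_size))


def crop(image: np.ndarray, box: tuple[int, int, int, int]) -> np.ndarray:
    """Crop with half-open box semantics; the box must lie inside the image."""
    x0, y0, x1, y1 = box
    h, w = image.shape[:2]
    if not (0 <= x0 < x1 <= w and 0 <= y0 < y1 <= h):
        raise InvalidInputError(f"box {box} outside image of size {(w, h)}")
    return image[y0:y1, x0:x1].copy()


def disparity_to_depth(disp: np.ndarray, cam: CameraModel, min_disp: float = 0.1) -> DepthMap:
    """Rectified-stereo conversion ``z = focal_px * baseline_m / disparity``.

    Pixels with disparity at or below ``min_disp`` (or non-finite) are marked
    invalid rather than mapped to huge depths. Raises
    :class:`EmptyDepthError` when no pixel survives.
    """
    disp = np.asarray(disp, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        valid = np.isfinite(disp) & (disp > min_disp)
        z = np.where(valid, cam.focal_px * cam.baseline_m / disp, np.nan)
    if not valid.any():
        raise EmptyDepthError("all disparities at or below the minimum")
    return DepthMap(z, ~valid)


class PrecomputedDisparity:
    """Fixture stereo backend: serves crops of a stored full-frame disparity.

    Stands in for a stereo-matching network during testing; the call contract
    is ``(left_crop, right_crop, left_box) -> disparity grid`` matching the
    crop size.
    """

    def __init__(self, disparity: np.ndarray):
        self.disparity = np.asarray(disparity, dtype=float)

    @classmethod
    def from_file(cls, path) -> "PrecomputedDisparity":
        from .io import read_depth_array

        return cls(read_depth_array(Path(path)))

    def __call__(
        self, left_crop: np.ndarray, right_crop: np.ndarray, left_box: tuple[int, int, int, int]
    ) -> np.ndarray:
        x0, y0, x1, y1 = left_box
        out = self.disparity[y0:y1, x0:x1]
        if out.shape[:2] != left_crop.shape[:2]:
            raise InvalidInputError("stored disparity does not cover the crop")
        return out
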