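"""File I/O: depth maps (TIFF/PFM/NPY), label maps (16-bit PNG), overlays,
measurement CSVs and ground-truth JSON."""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .depthseg import DepthMap, RegionTable
from .errors import InvalidInputError
from .synth import GroundTruth, LeafTruth
from .geometry import Point3

__all__ = [
    "read_depth_array",
    "read_depth",
    "write_depth",
    "read_pfm",
    "write_pfm",
    "write_label_png",
    "write_overlay_png",
    "write_ground_truth",
    "read_ground_truth",
    "rle_encode",
    "rle_decode",
]


def read_pfm(path) -> np.ndarray:
    """Read a (grayscale) PFM file into a float array, top row first."""
    with open(path, "rb") as fh:
        header = fh.readline().strip()
        if header not in (b"Pf", b"PF"):
            raise InvalidInputError(f"{path}: not a PFM file")
        dims = fh.readline().split()
        w, h = int(dims[0]), int(dims[1])
        scale = float(fh.readline().strip())
        endian = "<" if scale < 0 else ">"
        count = w * h * (3 if header == b"PF" else 1)
        data = np.fromfile(fh, dtype=endian + "f4", count=count)
    if header == b"PF":
        data = data.reshape(h, w, 3)[..., 0]
    else:
        data = data.reshape(h, w)
    return np.flipud(data).astype(np.float32)  # PFM stores bottom row first


def write_pfm(path, arr: np.ndarray) -> None:
    """Write a float array as a little-endian grayscale PFM file."""
    arr = np.asarray(arr, dtype=np.float32)
    if arr.ndim != 2:
        raise InvalidInputError("PFM writer expects a 2-D array")
    with open(path, "wb") as fh:
        fh.write(b"Pf\n")
        fh.write(f"{arr.shape[1]} {arr.shape[0]}\n".encode())
        fh.write(b"-1.0\n")
        np.flipud(arr).astype("<f4").tofile(fh)


def read_depth_array(path) -> np.ndarray:
    """Read a raw float grid from .tif/.tiff, .pfm or .npy by extension."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        return np.asarray(tifffile.imread(path), dtype=float)
    if suffix == ".pfm":
        return np.asarray(read_pfm(path), dtype=float)
    if suffix == ".npy":
        return np.asarray(np.load(path), dtype=float)
    raise InvalidInputError(f"unsupported depth format: {path.name}")


def read_depth(path) -> DepthMap:
    """Read a depth map; non-finite and non-positive pixels become invalid."""
    return DepthMap.from_array(read_depth_array(path))


def write_depth(path, depth: DepthMap | np.ndarray) -> None:
    """Write a depth map (invalid pixels as NaN) as 32-bit TIFF, PFM or NPY."""
    arr = depth.values if isinstance(depth, DepthMap) else np.asarray(depth, dtype=float)
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, arr.astype(np.float32))
    elif suffix == ".pfm":
        write_pfm(path, np.nan_to_num(arr, nan=0.0))
    elif suffix == ".npy":
        np.save(path, arr.astype(np.float32))
    else:
        raise InvalidInputError(f"unsupported depth format: {path.name}")


def write_label_png(path, label_map: np.ndarray) -> None:
    """Write an integer label map as a 16-bit grayscale PNG."""
    lm = np.asarray(label_map)
    if lm.min() < 0 or lm.max() > np.iinfo(np.uint16).max:
        raise InvalidInputError("label map does not fit uint16")
    iio.imwrite(Path(path), lm.astype(np.uint16))


_PALETTE = np.array(
    [
        [60, 60, 60],
        [46, 204, 113],
        [52, 152, 219],
        [231, 76, 60],
        [241, 196, 15],
        [155, 89, 182],
        [26, 188, 156],
        [230, 126, 34],
    ],
    dtype=np.uint8,
)


def write_overlay_png(path, regions: RegionTable, keypoints=None) -> None:
    """Inspection overlay: colored regions, white key-point dots."""
    lm = regions.label_map
    rgb = _PALETTE[lm % len(_PALETTE)]
    rgb[lm == 0] = (20, 20, 20)
    if keypoints:
        for kp in keypoints:
            for pt in (kp.root, kp.tip):
                r0, r1 = max(0, pt.row - 1), min(lm.shape[0], pt.row + 2)
                c0, c1 = max(0, pt.col - 1), min(lm.shape[1], pt.col + 2)
                rgb[r0:r1, c0:c1] = (255, 255, 255)
    iio.imwrite(Path(path), rgb)


def rle_encode(mask: np.ndarray) -> dict:
    """Run-length encode a boolean mask (row-major, starts-with-False runs)."""
    flat = np.asarray(mask, dtype=bool).ravel()
    n = flat.size
    changes = np.nonzero(np.diff(flat))[0] + 1
    bounds = np.concatenate(([0], changes, [n]))
    runs = np.diff(bounds)
    if flat[0]:  # canonical form starts with a (possibly zero) False run
        runs = np.concatenate(([0], runs))
    return {"shape": list(mask.shape), "runs": runs.tolist()}


def rle_decode(rec: dict) -> np.ndarray:
    shape = tuple(rec["shape"])
    runs = rec["runs"]
    flat = np.zeros(int(np.prod(shape)), dtype=bool)
    pos = 0
    val = False
    for run in runs:
        if val:
            flat[pos : pos + run] = True
        pos += run
        val = not val
    return flat.reshape(shape)


def write_ground_truth(path, gt: GroundTruth) -> None:
    """Serialise scene ground truth as JSON (masks run-length encoded)."""
    rec = {
        "theta_deg": gt.theta_deg,
        "leaves": [
            {
                "mask": rle_encode(leaf.mask),
                "root_px": list(leaf.root_px),
                "tip_px": list(leaf.tip_px),
                "root_xyz": list(leaf.root_xyz.as_array()),
                "tip_xyz": list(leaf.tip_xyz.as_array()),
                "phi_true_deg": leaf.phi_true_deg,
            }
            for leaf in gt.leaves
        ],
    }
    with open(path, "w") as fh:
        json.dump(rec, fh)


def read_ground_truth(path) -> GroundTruth:
    with open(path) as fh:
        rec = json.load(fh)
    leaves = [
        LeafTruth(
            mask=rle_decode(leaf["mask"]),
            root_px=tuple(leaf["root_px"]),
            tip_px=tuple(leaf["tip_px"]),
            root_xyz=Point3.from_array(leaf["root_xyz"]),
            tip_xyz=Point3.from_array(leaf["tip_xyz"]),
            phi_true_deg=leaf["phi_true_deg"],
        )
        for leaf in rec["leaves"]
    ]
    depth = np.zeros((1, 1)) if not leaves else np.zeros(leaves[0].mask.shape)
    return GroundTruth(leaves, rec["theta_deg"], depth)
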