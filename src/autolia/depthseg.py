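"""Spatial-continuity leaf segmentation on depth maps.

The chain transforms a depth map through four stages:

``depth -> per-axis gradients -> per-axis local surface angles ->
per-axis angle differences -> edge/surface classification -> two-pass
connected-component labelling -> region-size filtering``

A pixel pair on one continuous (possibly bent) leaf surface shows a small
second-order depth signal: the *angle difference* between neighbouring pixels.
Where the difference exceeds the global threshold ``seg_th * 90`` degrees the
pixel is classified as a leaf-edge point; edge points fence off leaf-surface
regions, which are then labelled with a classic two-pass union-find pass and
filtered by area.

Noise handling ("jump pixels"): a run of up to ``n_th`` corrupted depth pixels
produces a run of up to ``n_th + 2`` consecutive edge flags along a scan line
(the corruption propagates through one forward difference and one second
difference). Such a run is healed back to SURFACE when the flanking surface
pixels are mutually consistent: their local angles agree within the tolerance
*and* the depth chord bridging the gap agrees with both flank angles. The
second condition keeps genuine depth steps (leaf floating in front of the
background, both sides locally parallel) from being healed away.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import logging

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .errors import InvalidInputError
from .geometry import CameraModel

logger = logging.getLogger(__name__)

__all__ = [
    "DepthMap",
    "SegParams",
    "GradientMaps",
    "AngleMap",
    "AngleDiff",
    "PixelClassMap",
    "RegionTable",
    "SURFACE",
    "EDGE",
    "INVALID",
    "depth_to_gradient",
    "gradient_to_angle",
    "angle_difference",
    "classify_pixels",
    "label_regions",
    "filter_regions",
    "segment",
    "denoise_depth",
]

# pixel classes
INVALID = 0
SURFACE = 1
EDGE = 2


@dataclass
class DepthMap:
    """Dense per-pixel depth grid (metres) with an invalid-pixel mask."""

    values: np.ndarray
    invalid_mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.invalid_mask = np.asarray(self.invalid_mask, dtype=bool)
        if self.values.ndim != 2:
            raise InvalidInputError("depth values must be a 2-D grid")
        if self.values.shape != self.invalid_mask.shape:
            raise InvalidInputError("depth/invalid-mask shapes disagree")
        valid = ~self.invalid_mask
        vals = self.values[valid]
        if vals.size and not np.all(np.isfinite(vals) & (vals > 0)):
            raise InvalidInputError("valid depths must be finite and > 0")

    @classmethod
    def from_array(cls, arr, invalid_mask=None) -> "DepthMap":
        """Wrap an array; non-finite or non-positive entries are marked invalid."""
        arr = np.asarray(arr, dtype=float)
        bad = ~np.isfinite(arr) | (arr <= 0)
        if invalid_mask is not None:
            bad |= np.asarray(invalid_mask, dtype=bool)
        return cls(np.where(bad, np.nan, arr), bad)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def valid_mask(self) -> np.ndarray:
        return ~self.invalid_mask

    def copy(self) -> "DepthMap":
        return DepthMap(self.values.copy(), self.invalid_mask.copy())


@dataclass(frozen=True)
class SegParams:
    """Global segmentation thresholds.

    ``seg_th`` is a dimensionless fraction of a right angle: neighbouring
    pixels whose local surface angles differ by more than ``seg_th * 90``
    degrees belong to different surfaces. ``n_th`` is the jump-pixel count: the
    maximum run of corrupted depth pixels that may be skipped without declaring
    a surface break. Region areas are bounded as fractions of the crop area.
    ``steep_cut_deg`` classifies pixels whose local slope is nearly parallel to
    the viewing ray as edges (such surfaces are unmeasurable and arise mainly
    from smoothing ramps across depth steps).
    """

    seg_th: float = 0.5
    n_th: int = 2
    min_area_frac: float = 0.002
    max_area_frac: float = 0.5
    steep_cut_deg: float = 80.0

    def __post_init__(self) -> None:
        if not 0 < self.seg_th <= 1:
            raise InvalidInputError(f"seg_th must lie in (0, 1], got {self.seg_th}")
        if not (isinstance(self.n_th, (int, np.integer)) and self.n_th >= 0):
            raise InvalidInputError(f"n_th must be a non-negative integer, got {self.n_th}")
        if not 0 <= self.min_area_frac < self.max_area_frac <= 1:
            raise InvalidInputError(
                f"need 0 <= min_area_frac < max_area_frac <= 1, got "
                f"{self.min_area_frac}, {self.max_area_frac}"
            )
        if not 0 < self.steep_cut_deg <= 90:
            raise InvalidInputError(f"steep_cut_deg must lie in (0, 90], got {self.steep_cut_deg}")

    @property
    def tol_deg(self) -> float:
        """Angular-difference tolerance in degrees (= seg_th * 90)."""
        return self.seg_th * 90.0


@dataclass
class GradientMaps:
    """Forward depth differences per axis, metres per pixel step."""

    down: np.ndarray  # z[v+1, u] - z[v, u]
    right: np.ndarray  # z[v, u+1] - z[v, u]
    valid_down: np.ndarray
    valid_right: np.ndarray


@dataclass
class AngleMap:
    """Local surface inclination vs the imaging plane, degrees, per axis."""

    down: np.ndarray
    right: np.ndarray
    valid_down: np.ndarray
    valid_right: np.ndarray


@dataclass
class AngleDiff:
    """Forward differences of the angle maps (second-order depth signal)."""

    down: np.ndarray
    right: np.ndarray
    valid_down: np.ndarray
    valid_right: np.ndarray


@dataclass
class PixelClassMap:
    """Per-pixel class over {INVALID, SURFACE, EDGE}."""

    labels: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape


@dataclass
class RegionTable:
    """Labelled regions: 0 = background/edge, 1..k = regions (largest first
    after filtering)."""

    label_map: np.ndarray
    table: pd.DataFrame = field(default_factory=lambda: _empty_table())

    def __len__(self) -> int:
        return len(self.table)

    def mask(self, label: int) -> np.ndarray:
        return self.label_map == label

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


_TABLE_COLUMNS = [
    "label",
    "area_px",
    "row_min",
    "col_min",
    "row_max",
    "col_max",
    "centroid_row",
    "centroid_col",
]


def _empty_table() -> pd.DataFrame:
    return pd.DataFrame(columns=_TABLE_COLUMNS)


def depth_to_gradient(depth: DepthMap) -> GradientMaps:
    """Forward depth differences toward the right/down neighbour.

    The last column (row) of the right (down) gradient is undefined; a
    difference is valid only where both participating pixels are valid.
    """
    h, w = depth.shape
    if h < 2 or w < 2:
        raise InvalidInputError("depth map needs at least 2 pixels per axis")
    z = depth.values
    ok = depth.valid_mask
    down = np.full((h, w), np.nan)
    right = np.full((h, w), np.nan)
    vdown = np.zeros((h, w), dtype=bool)
    vright = np.zeros((h, w), dtype=bool)
    down[:-1, :] = z[1:, :] - z[:-1, :]
    right[:, :-1] = z[:, 1:] - z[:, :-1]
    vdown[:-1, :] = ok[1:, :] & ok[:-1, :]
    vright[:, :-1] = ok[:, 1:] & ok[:, :-1]
    down[~vdown] = np.nan
    right[~vright] = np.nan
    return GradientMaps(down, right, vdown, vright)


def gradient_to_angle(grad: GradientMaps, depth: DepthMap, cam: CameraModel) -> AngleMap:
    """Convert depth gradients to local surface angles vs the imaging plane.

    The metric footprint of one pixel step at depth ``z`` is ``z / focal_px``;
    the local angle is ``arctan(dz / footprint)`` in degrees, in (-90, 90).
    """
    if grad.down.shape != depth.shape:
        raise InvalidInputError("gradient/depth shapes disagree")
    with np.errstate(invalid="ignore"):
        ds = depth.values / cam.focal_px
        down = np.degrees(np.arctan2(grad.down, ds))
        right = np.degrees(np.arctan2(grad.right, ds))
    down[~grad.valid_down] = np.nan
    right[~grad.valid_right] = np.nan
    return AngleMap(down, right, grad.valid_down.copy(), grad.valid_right.copy())


def angle_difference(angles: AngleMap) -> AngleDiff:
    """Forward differences of the per-axis angle maps, degrees."""
    h, w = angles.down.shape
    down = np.full((h, w), np.nan)
    right = np.full((h, w), np.nan)
    vdown = np.zeros((h, w), dtype=bool)
    vright = np.zeros((h, w), dtype=bool)
    down[:-1, :] = angles.down[1:, :] - angles.down[:-1, :]
    right[:, :-1] = angles.right[:, 1:] - angles.right[:, :-1]
    vdown[:-1, :] = angles.valid_down[1:, :] & angles.valid_down[:-1, :]
    vright[:, :-1] = angles.valid_right[:, 1:] & angles.valid_right[:, :-1]
    down[~vdown] = np.nan
    right[~vright] = np.nan
    return AngleDiff(down, right, vdown, vright)


def _find_runs(flags: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True in a 1-D boolean array as (start, stop) inclusive."""
    if not flags.any():
        return []
    padded = np.concatenate(([False], flags, [False]))
    d = np.diff(padded.astype(np.int8))
    starts = np.nonzero(d == 1)[0]
    stops = np.nonzero(d == -1)[0] - 1
    return list(zip(starts.tolist(), stops.tolist()))


def _heal_axis(
    flags: np.ndarray,
    angle: np.ndarray,
    z: np.ndarray,
    valid: np.ndarray,
    params: SegParams,
    focal_px: float,
) -> np.ndarray:
    """Jump-pixel healing along axis 1 of ``flags``.

    Returns the boolean mask of flag pixels cleared back to SURFACE. A run of
    at most ``n_th + 2`` flags is cleared when its flanking surface pixels are
    mutually consistent: flank angles agree within tolerance and the depth
    chord across the gap agrees with both flank angles within tolerance.
    """
    tol = params.tol_deg
    max_run = params.n_th + 2
    n_rows, n_cols = flags.shape
    healed = np.zeros_like(flags)
    for r in range(n_rows):
        row_flags = flags[r]
        if not row_flags.any():
            continue
        for i, j in _find_runs(row_flags):
            if j - i + 1 > max_run:
                continue
            before, after = i - 1, j + 1
            if before < 0 or after >= n_cols:
                continue
            if row_flags[before] or row_flags[after]:
                continue  # runs are maximal, but flanks may be invalid
            if not (valid[r, before] and valid[r, after]):
                continue
            a1 = angle[r, before]
            a2 = angle[r, after]
            if not (np.isfinite(a1) and np.isfinite(a2)):
                continue
            if abs(a1 - a2) > tol:
                continue
            gap = after - before
            z1, z2 = z[r, before], z[r, after]
            footprint = gap * 0.5 * (z1 + z2) / focal_px
            chord = np.degrees(np.arctan2(z2 - z1, footprint))
            if abs(chord) >= params.steep_cut_deg:
                continue  # a bridge nearly parallel to the ray is a step, not a surface
            if abs(chord - a1) > tol or abs(chord - a2) > tol:
                continue
            healed[r, i : j + 1] = True
    return healed


def classify_pixels(
    diff: AngleDiff,
    params: SegParams,
    angles: AngleMap | None = None,
    depth: DepthMap | None = None,
    cam: CameraModel | None = None,
) -> PixelClassMap:
    """Classify every pixel as SURFACE, EDGE or INVALID.

    A pixel is flagged as an edge when its angle difference on either axis
    exceeds ``seg_th * 90`` degrees (or its local angle exceeds the steep-angle
    cut). With ``n_th > 0`` jump-pixel healing requires ``angles``, ``depth``
    and ``cam``; each axis heals only its own flags, so a genuine break seen
    by one axis survives whatever the other axis concludes.
    """
    tol = params.tol_deg
    with np.errstate(invalid="ignore"):
        flag_right = diff.valid_right & (np.abs(diff.right) > tol)
        flag_down = diff.valid_down & (np.abs(diff.down) > tol)
        if angles is not None:
            flag_right |= angles.valid_right & (np.abs(angles.right) >= params.steep_cut_deg)
            flag_down |= angles.valid_down & (np.abs(angles.down) >= params.steep_cut_deg)

    if flag_right.any() or flag_down.any():
        if angles is None or depth is None or cam is None:
            if params.n_th > 0:
                raise InvalidInputError(
                    "jump-pixel healing (n_th > 0) needs angles, depth and cam"
                )
        else:
            z = depth.values
            flag_right &= ~_heal_axis(
                flag_right, angles.right, z, depth.valid_mask, params, cam.focal_px
            )
            flag_down &= ~_heal_axis(
                flag_down.T, angles.down.T, z.T, depth.valid_mask.T, params, cam.focal_px
            ).T

    edge = flag_right | flag_down
    labels = np.full(diff.right.shape, SURFACE, dtype=np.uint8)
    labels[edge] = EDGE
    if depth is not None:
        labels[depth.invalid_mask] = INVALID
    return PixelClassMap(labels)


class _UnionFind:
    """Union-find over provisional labels (label 0 unused)."""

    def __init__(self) -> None:
        self.parent = [0]

    def make(self) -> int:
        self.parent.append(len(self.parent))
        return len(self.parent) - 1

    def find(self, x: int) -> int:
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:  # path compression
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            if ra < rb:
                self.parent[rb] = ra
            else:
                self.parent[ra] = rb


def label_regions(classes: PixelClassMap) -> RegionTable:
    """Two-pass 4-connected component labelling of SURFACE pixels.

    First traversal assigns provisional labels row by row (runs of SURFACE
    pixels share one label) and records equivalences with labels overlapping
    in the previous row; the second traversal resolves equivalences and
    relabels contiguously. EDGE and INVALID pixels get label 0.
    """
    surface = classes.labels == SURFACE
    h, w = surface.shape
    provisional = np.zeros((h, w), dtype=np.int32)
    uf = _UnionFind()
    prev_runs: list[tuple[int, int, int]] = []  # (start, stop, label) in previous row
    for r in range(h):
        runs = _find_runs(surface[r])
        cur_runs: list[tuple[int, int, int]] = []
        for i, j in runs:
            label = 0
            for pi, pj, plabel in prev_runs:
                if pi <= j and i <= pj:  # 4-connected vertical overlap
                    if label == 0:
                        label = plabel
                    else:
                        uf.union(label, plabel)
            if label == 0:
                label = uf.make()
            provisional[r, i : j + 1] = label
            cur_runs.append((i, j, label))
        prev_runs = cur_runs
    # second traversal: resolve equivalences, relabel contiguously
    n_prov = len(uf.parent)
    roots = np.array([uf.find(k) for k in range(n_prov)], dtype=np.int32)
    remap = np.zeros(n_prov, dtype=np.int32)
    next_label = 0
    for k in range(1, n_prov):
        if roots[k] == k:
            next_label += 1
            remap[k] = next_label
    label_map = remap[roots[provisional]]
    return RegionTable(label_map, _region_stats(label_map))


def _region_stats(label_map: np.ndarray) -> pd.DataFrame:
    labels = np.unique(label_map)
    labels = labels[labels > 0]
    if labels.size == 0:
        return _empty_table()
    rows, cols = np.nonzero(label_map)
    lab = label_map[rows, cols]
    df = pd.DataFrame({"label": lab, "row": rows, "col": cols})
    g = df.groupby("label")
    out = pd.DataFrame(
        {
            "label": labels,
            "area_px": g.size().reindex(labels).to_numpy(),
            "row_min": g["row"].min().reindex(labels).to_numpy(),
            "col_min": g["col"].min().reindex(labels).to_numpy(),
            "row_max": g["row"].max().reindex(labels).to_numpy(),
            "col_max": g["col"].max().reindex(labels).to_numpy(),
            "centroid_row": g["row"].mean().reindex(labels).to_numpy(),
            "centroid_col": g["col"].mean().reindex(labels).to_numpy(),
        }
    )
    return out.reset_index(drop=True)


def filter_regions(regions: RegionTable, params: SegParams) -> RegionTable:
    """Keep regions whose pixel count lies within the area-fraction bounds.

    Survivors are relabelled contiguously in decreasing size order (largest
    region becomes label 1); removed regions fall back to label 0.
    """
    h, w = regions.label_map.shape
    total = h * w
    lo = params.min_area_frac * total
    hi = params.max_area_frac * total
    tab = regions.table
    keep = tab[(tab["area_px"] >= lo) & (tab["area_px"] <= hi)]
    if len(keep) == 0:
        return RegionTable(np.zeros_like(regions.label_map), _empty_table())
    keep = keep.sort_values(["area_px", "label"], ascending=[False, True])
    old_labels = keep["label"].to_numpy()
    remap = np.zeros(int(regions.table["label"].max()) + 1, dtype=np.int32)
    remap[old_labels] = np.arange(1, len(old_labels) + 1)
    label_map = remap[regions.label_map]
    new_tab = keep.copy()
    new_tab["label"] = np.arange(1, len(old_labels) + 1)
    return RegionTable(label_map, new_tab.reset_index(drop=True))


def segment(depth: DepthMap, cam: CameraModel, params: SegParams | None = None) -> RegionTable:
    """Run the full segmentation chain on a depth map (no denoising)."""
    params = params or SegParams()
    grad = depth_to_gradient(depth)
    angles = gradient_to_angle(grad, depth, cam)
    diff = angle_difference(angles)
    classes = classify_pixels(diff, params, angles=angles, depth=depth, cam=cam)
    regions = label_regions(classes)
    filtered = filter_regions(regions, params)
    logger.debug(
        "segment: %d raw regions, %d after size filtering", len(regions), len(filtered)
    )
    return filtered


def denoise_depth(
    depth: DepthMap, median_radius: int = 1, gaussian_sigma: float = 0.8
) -> DepthMap:
    """Depth-map denoising: median filter (kills isolated mismatch outliers)
    followed by a light Gaussian blur (tames per-pixel matching jitter).

    Invalid pixels are filled from their nearest valid neighbour before
    filtering and re-marked invalid afterwards, so the mask is preserved.
    Either stage can be disabled by passing 0.
    """
    z = depth.values.copy()
    bad = depth.invalid_mask
    if bad.all():
        return depth.copy()
    if bad.any():
        idx = ndi.distance_transform_edt(bad, return_distances=False, return_indices=True)
        z = z[tuple(idx)]
    if median_radius > 0:
        z = ndi.median_filter(z, size=2 * median_radius + 1, mode="nearest")
    if gaussian_sigma > 0:
        z = ndi.gaussian_filter(z, sigma=gaussian_sigma, mode="nearest")
    z[bad] = np.nan
    return DepthMap(z, bad.copy())
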