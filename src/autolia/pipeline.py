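"""Pipeline orchestration, configuration, metrics and evaluation.

``run_on_depth`` runs the measurement chain on a depth map:
denoise -> gradient/angle/angle-difference -> edge classification -> two-pass
labelling -> size filtering -> per-region vein + key points -> angle
decomposition, returning one :class:`Measurement` per surviving leaf.
``run_on_stereo`` prepends the acquisition front-end (detection, selection,
box alignment, cropping, disparity-to-depth).

Evaluation against synthetic ground truth follows the recognition-rate /
signed-deviation scheme: ``rate = 100 * n_eva / n_gt`` (capped at 100 with
over-segmentation logged) and ``dist = LIA_gt - LIA_m`` per matched leaf, with
the *average error* reported as the mean of per-leaf ``|dist|``.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from . import depthseg
from .depthseg import DepthMap, RegionTable, SegParams
from .errors import InvalidInputError
from .geometry import CameraModel, RigPose, backproject, measure_lia
from .keypoints import LeafKeypoints, StructuringElement, extract_vein, locate_keypoints
from .errors import KeypointDepthError
from .scene import align_boxes, crop, disparity_to_depth, select_plant
from .synth import GroundTruth

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "Measurement",
    "run_on_depth",
    "run_on_stereo",
    "run_pipeline",
    "recognition_rate",
    "dist",
    "match_predictions",
    "evaluate",
    "EvaluationReport",
    "measurements_to_frame",
    "summarize_groups",
]


@dataclass(frozen=True)
class PipelineConfig:
    """All tunables of the measurement pipeline; YAML round-trippable."""

    # segmentation
    seg_th: float = 0.5
    n_th: int = 2
    min_area_frac: float = 0.002
    max_area_frac: float = 0.5
    steep_cut_deg: float = 80.0
    # depth denoising (0 disables a stage); the median is edge-preserving,
    # so the default smoothing adds no ramps at depth steps
    median_radius: int = 2
    gaussian_sigma: float = 0.0
    # key points
    se_shape: str = "disk"
    se_radius: int = 2
    vein_skeletonize: bool = False
    # acquisition
    conf_th: float = 0.6
    min_disp: float = 0.1
    input_mode: str = "depth"  # "depth" | "stereo"
    # rig
    theta_deg: float = 32.5
    focal_px: float = 300.0
    cx: float = 159.5
    cy: float = 119.5
    baseline_m: float = 0.12
    image_width: int = 320
    image_height: int = 240

    def __post_init__(self) -> None:
        if self.input_mode not in ("depth", "stereo"):
            raise InvalidInputError(f"unknown input_mode {self.input_mode!r}")
        self.seg_params()  # validates the segmentation block
        self.pose()
        StructuringElement(self.se_shape, self.se_radius)

    def seg_params(self) -> SegParams:
        return SegParams(
            seg_th=self.seg_th,
            n_th=self.n_th,
            min_area_frac=self.min_area_frac,
            max_area_frac=self.max_area_frac,
            steep_cut_deg=self.steep_cut_deg,
        )

    def camera(self) -> CameraModel:
        return CameraModel(
            focal_px=self.focal_px,
            principal_point=(self.cx, self.cy),
            baseline_m=self.baseline_m,
            image_size=(self.image_width, self.image_height),
        )

    def pose(self) -> RigPose:
        return RigPose(self.theta_deg)

    def structuring_element(self) -> StructuringElement:
        return StructuringElement(self.se_shape, self.se_radius)

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        data = yaml.safe_load(text) or {}
        return cls(**data)


@dataclass(frozen=True)
class Measurement:
    """One measured leaf: key points, decomposition angles, region area.

    Every record satisfies ``theta + alpha + phi + 90 = 180`` exactly.
    """

    plant_id: str
    leaf_id: int
    root_row: int
    root_col: int
    root_depth_m: float
    tip_row: int
    tip_col: int
    tip_depth_m: float
    theta_deg: float
    alpha_deg: float
    phi_deg: float
    area_px: int


def measurements_to_frame(measurements: list[Measurement]) -> pd.DataFrame:
    cols = [f.name for f in Measurement.__dataclass_fields__.values()]
    return pd.DataFrame([asdict(m) for m in measurements], columns=cols)


def _measure_regions(
    depth: DepthMap,
    regions: RegionTable,
    config: PipelineConfig,
    plant_id: str,
) -> tuple[list[Measurement], list[np.ndarray]]:
    cam = config.camera()
    pose = config.pose()
    se = config.structuring_element()
    measurements: list[Measurement] = []
    masks: list[np.ndarray] = []
    for row in regions.table.itertuples():
        mask = regions.mask(row.label)
        vein = extract_vein(mask, se, skeletonize=config.vein_skeletonize)
        try:
            kp = locate_keypoints(vein, depth)
        except KeypointDepthError as exc:
            logger.warning("plant %s region %d skipped: %s", plant_id, row.label, exc)
            continue
        A = backproject(kp.root.col, kp.root.row, kp.root.depth_m, cam)
        B = backproject(kp.tip.col, kp.tip.row, kp.tip.depth_m, cam)
        dec = measure_lia(A, B, pose)
        measurements.append(
            Measurement(
                plant_id=plant_id,
                leaf_id=int(row.label),
                root_row=kp.root.row,
                root_col=kp.root.col,
                root_depth_m=kp.root.depth_m,
                tip_row=kp.tip.row,
                tip_col=kp.tip.col,
                tip_depth_m=kp.tip.depth_m,
                theta_deg=dec.theta_deg,
                alpha_deg=dec.alpha_deg,
                phi_deg=dec.phi_deg,
                area_px=int(row.area_px),
            )
        )
        masks.append(mask)
    return measurements, masks


def run_on_depth(
    depth: DepthMap,
    config: PipelineConfig | None = None,
    plant_id: str = "plant0",
    return_masks: bool = False,
):
    """Measure every leaf in a depth map.

    Returns the list of :class:`Measurement` sorted by region size (largest
    first); with ``return_masks=True`` also the per-leaf masks, aligned with
    the measurement list. An empty result (no region survives) is returned
    with a logged reason, not raised.
    """
    config = config or PipelineConfig()
    t0 = time.perf_counter()
    cam = config.camera()
    if depth.shape != (config.image_height, config.image_width):
        # crops may be smaller than the nominal frame: re-centre the intrinsics
        h, w = depth.shape
        cam = CameraModel(cam.focal_px, ((w - 1) / 2, (h - 1) / 2), cam.baseline_m, (w, h))
    work = depth
    if config.median_radius > 0 or config.gaussian_sigma > 0:
        work = depthseg.denoise_depth(depth, config.median_radius, config.gaussian_sigma)
    regions = depthseg.segment(work, cam, config.seg_params())
    if len(regions) == 0:
        logger.info("plant %s: 0 regions after filtering", plant_id)
        measurements, masks = [], []
    else:
        measurements, masks = _measure_regions(work, regions, config, plant_id)
    logger.info(
        "plant %s: %d regions -> %d measurements in %.2f s",
        plant_id,
        len(regions),
        len(measurements),
        time.perf_counter() - t0,
    )
    if return_masks:
        return measurements, masks
    return measurements


def run_on_stereo(
    left: np.ndarray,
    right: np.ndarray,
    detector,
    disparity_backend,
    config: PipelineConfig | None = None,
    plant_id: str = "plant0",
    return_masks: bool = False,
):
    """Full acquisition chain: detect -> select -> align -> crop -> disparity
    -> depth -> leaf measurement.

    ``detector`` maps an image to detections; ``disparity_backend`` maps
    ``(left_crop, right_crop, left_box)`` to a disparity grid. A
    :class:`NoPlantError` from selection propagates (the frame is unusable).
    """
    config = config or PipelineConfig()
    det_l = select_plant(detector(left), config.conf_th)
    det_r = select_plant(detector(right), config.conf_th)
    h, w = left.shape[:2]
    box_l, box_r = align_boxes(det_l, det_r, (w, h))
    crop_l = crop(left, box_l)
    crop_r = crop(right, box_r)
    disp = disparity_backend(crop_l, crop_r, box_l)
    depth = disparity_to_depth(disp, config.camera(), config.min_disp)
    return run_on_depth(depth, config, plant_id=plant_id, return_masks=return_masks)


def run_pipeline(inputs: dict, config: PipelineConfig | None = None, **kwargs):
    """Dispatch on ``config.input_mode``: ``{"depth": DepthMap}`` or
    ``{"left", "right", "detector", "disparity_backend"}``."""
    config = config or PipelineConfig()
    if config.input_mode == "depth":
        return run_on_depth(inputs["depth"], config, **kwargs)
    return run_on_stereo(
        inputs["left"], inputs["right"], inputs["detector"], inputs["disparity_backend"],
        config, **kwargs,
    )


# ---------------------------------------------------------------------------
# metrics


def recognition_rate(n_eva: int, n_gt: int) -> float:
    """Leaf recognition rate in percent: ``100 * n_eva / n_gt``, capped at 100."""
    if n_gt <= 0:
        raise InvalidInputError("n_gt must be > 0")
    if n_eva < 0:
        raise InvalidInputError("n_eva must be >= 0")
    if n_eva > n_gt:
        logger.info("over-segmentation: %d predictions for %d true leaves", n_eva, n_gt)
        return 100.0
    return 100.0 * n_eva / n_gt


def dist(lia_gt_deg: float, lia_m_deg: float) -> float:
    """Signed deviation of the measured LIA from truth: ``LIA_gt - LIA_m``."""
    if not (np.isfinite(lia_gt_deg) and np.isfinite(lia_m_deg)):
        raise InvalidInputError("dist needs finite angles")
    return float(lia_gt_deg) - float(lia_m_deg)


def match_predictions(
    pred_masks: list[np.ndarray], truth_masks: list[np.ndarray]
) -> list[tuple[int, int, float]]:
    """Greedy one-to-one pairing by descending mask overlap (IoU).

    Returns ``(pred_index, truth_index, iou)`` triples; predictions and truths
    with no overlapping partner stay unmatched.
    """
    if not pred_masks or not truth_masks:
        return []
    iou = np.zeros((len(pred_masks), len(truth_masks)))
    for i, pm in enumerate(pred_masks):
        for j, tm in enumerate(truth_masks):
            inter = np.logical_and(pm, tm).sum()
            if inter:
                union = np.logical_or(pm, tm).sum()
                iou[i, j] = inter / union
    pairs: list[tuple[int, int, float]] = []
    used_i: set[int] = set()
    used_j: set[int] = set()
    order = np.dstack(np.unravel_index(np.argsort(-iou, axis=None), iou.shape))[0]
    for i, j in order:
        if iou[i, j] <= 0:
            break
        if i in used_i or j in used_j:
            continue
        pairs.append((int(i), int(j), float(iou[i, j])))
        used_i.add(int(i))
        used_j.add(int(j))
    return pairs


@dataclass
class EvaluationReport:
    """Scene-level evaluation: recognition, deviations, LIA summary."""

    recognition_rate_pct: float
    dists_deg: list[float]
    mean_abs_error_deg: float
    mean_lia_deg: float
    var_lia_deg2: float
    n_predicted: int
    n_truth: int
    group_key: str | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def evaluate(
    measurements: list[Measurement],
    pred_masks: list[np.ndarray],
    truth: GroundTruth,
    group_key: str | None = None,
) -> EvaluationReport:
    """Score measurements against scene ground truth.

    Recognition follows the capped rate; ``dist`` is computed per matched
    leaf; the mean absolute error averages per-leaf ``|dist|``. The LIA
    summary (mean and population variance of the measured angles) mirrors the
    per-time-point physiology aggregation.
    """
    if truth.n_leaves == 0:
        raise InvalidInputError("ground truth holds no leaves")
    pairs = match_predictions(pred_masks, [leaf.mask for leaf in truth.leaves])
    dists = [
        dist(truth.leaves[j].phi_true_deg, measurements[i].phi_deg) for i, j, _ in pairs
    ]
    phis = [m.phi_deg for m in measurements]
    return EvaluationReport(
        recognition_rate_pct=recognition_rate(len(measurements), truth.n_leaves),
        dists_deg=dists,
        mean_abs_error_deg=float(np.mean(np.abs(dists))) if dists else float("nan"),
        mean_lia_deg=float(np.mean(phis)) if phis else float("nan"),
        var_lia_deg2=float(np.var(phis)) if phis else float("nan"),
        n_predicted=len(measurements),
        n_truth=truth.n_leaves,
        group_key=group_key,
    )


def summarize_groups(records: pd.DataFrame, by: str = "theta_deg") -> pd.DataFrame:
    """Group measured LIAs (e.g. by shooting angle or time point): mean/Var.

    ``records`` is a measurement frame (see :func:`measurements_to_frame`)
    with a ``phi_deg`` column.
    """
    g = records.groupby(by)["phi_deg"]
    out = pd.DataFrame(
        {"mean_lia_deg": g.mean(), "var_lia_deg2": g.var(ddof=0), "n_leaves": g.size()}
    )
    return out.reset_index()
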