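"""Synthetic-scene generator: planar elliptical leaves over a background plane.

Each leaf is a planar elliptical patch whose root-to-tip chord makes a
prescribed leaf inclination angle ``phi_true`` with the horizontal plane given
the camera pitch ``theta``. The patch is rasterised by per-pixel ray-plane
intersection, leaves compose under the painter's rule (nearest depth wins) and
a constant-depth background plane fills the rest. The generator returns exact
ground truth (per-leaf masks, key points with 3-D coordinates, true LIA) and
can add Gaussian depth noise, salt outliers (isolated double-depth pixels, the
"discrete mutant mismatch points" of stereo matching) and mismatch streaks
(thin double-depth runs, the continuous variant).

Azimuth is the rotation of the chord about the *world vertical*: azimuth 0
puts the chord in the vertical plane through the optical axis (tip down-image,
tip nearer the camera — the configuration in which the imaging-plane angle
decomposition is exact). The chord's angle to the horizontal plane equals
``phi_true`` exactly for every azimuth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .depthseg import DepthMap
from .errors import InvalidInputError, InvalidSpecError
from .geometry import CameraModel, Point3, RigPose, project, up_vector_cam

__all__ = [
    "LeafSpec",
    "SceneSpec",
    "LeafTruth",
    "GroundTruth",
    "default_camera",
    "render_depth",
    "render_disparity",
    "add_noise",
    "add_streaks",
    "standard_scene",
]


def default_camera(width: int = 320, height: int = 240) -> CameraModel:
    """The study's reference rig: 320x240 crop, 300 px focal, 12 cm baseline.

    At the 3 m shooting distance one pixel spans 10 mm on the scene, so a
    35 cm leaf blade covers ~35 px — the scale at which the segmentation
    thresholds of the pipeline defaults were chosen.
    """
    return CameraModel(
        focal_px=300.0,
        principal_point=((width - 1) / 2.0, (height - 1) / 2.0),
        baseline_m=0.12,
        image_size=(width, height),
    )


@dataclass(frozen=True)
class LeafSpec:
    """One planar elliptical leaf.

    ``length_px``/``width_px`` are the blade's major/minor axes in pixels as
    they would appear face-on at the leaf's centre depth; ``phi_true_deg`` is
    the true LIA of the root-to-tip chord; ``azimuth_deg`` rotates the chord
    about the world vertical (0 = down-image); ``depth_offset_m`` lifts the
    leaf centre off the background plane toward the camera.
    """

    center: tuple[float, float]  # (row, col)
    length_px: float = 44.0
    width_px: float = 24.0
    phi_true_deg: float = 40.0
    azimuth_deg: float = 0.0
    depth_offset_m: float = 0.45

    def __post_init__(self) -> None:
        if not self.length_px > self.width_px > 0:
            raise InvalidInputError(
                f"need length_px > width_px > 0, got {self.length_px}, {self.width_px}"
            )
        if not 0 <= self.phi_true_deg < 90:
            raise InvalidInputError(f"phi_true_deg must lie in [0, 90), got {self.phi_true_deg}")


@dataclass(frozen=True)
class SceneSpec:
    """A full synthetic scene: camera, rig pose, leaves, background, noise."""

    camera: CameraModel
    pose: RigPose
    leaves: tuple[LeafSpec, ...]
    background_depth_m: float = 3.0
    noise_sigma_m: float = 0.0
    salt_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "leaves", tuple(self.leaves))
        if not self.background_depth_m > 0:
            raise InvalidInputError("background depth must be > 0")
        if self.noise_sigma_m < 0:
            raise InvalidInputError("noise_sigma_m must be >= 0")
        if not 0 <= self.salt_rate < 1:
            raise InvalidInputError("salt_rate must lie in [0, 1)")


@dataclass
class LeafTruth:
    """Exact per-leaf ground truth from the renderer."""

    mask: np.ndarray
    root_px: tuple[int, int]  # (row, col)
    tip_px: tuple[int, int]
    root_xyz: Point3
    tip_xyz: Point3
    phi_true_deg: float


@dataclass
class GroundTruth:
    """Scene-level truth: per-leaf records plus the noiseless depth field."""

    leaves: list[LeafTruth]
    theta_deg: float
    depth_true: np.ndarray = field(repr=False)

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)


def _rotate_about(v: np.ndarray, axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rodrigues rotation of ``v`` about the unit ``axis``."""
    a = math.radians(angle_deg)
    return (
        v * math.cos(a)
        + np.cross(axis, v) * math.sin(a)
        + axis * (axis @ v) * (1.0 - math.cos(a))
    )


def leaf_chord_direction(phi_deg: float, azimuth_deg: float, theta_deg: float) -> np.ndarray:
    """Unit root->tip chord direction in the camera frame.

    Built so the chord makes exactly ``phi_deg`` with the horizontal plane for
    any azimuth. Azimuth 0 reproduces the in-slice near-side configuration
    ``(0, cos(theta + phi - 90), sin(theta + phi - 90))``.
    """
    up = up_vector_cam(theta_deg)
    psi = math.radians(theta_deg + phi_deg - 90.0)
    t0 = np.array([0.0, math.cos(psi), math.sin(psi)])
    cphi = math.cos(math.radians(phi_deg))
    # horizontal component of the in-slice chord (phi < 90 guarantees cphi > 0)
    h0 = (t0 + math.sin(math.radians(phi_deg)) * up) / cphi
    h = _rotate_about(h0, up, azimuth_deg)
    return cphi * h - math.sin(math.radians(phi_deg)) * up


def render_depth(spec: SceneSpec) -> tuple[DepthMap, GroundTruth]:
    """Rasterise the scene; returns the (optionally noisy) depth map + truth.

    Leaves are intersected per pixel with their supporting plane; the nearest
    leaf owns each pixel (painter's rule) and the background plane fills the
    rest. Truth masks are disjoint by construction and recorded before noise.
    """
    cam = spec.camera
    w, h = cam.image_size
    f = cam.focal_px
    up = up_vector_cam(spec.pose.theta_deg)

    us, vs = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
    rays = np.stack([(us - cam.cx) / f, (vs - cam.cy) / f, np.ones_like(us)], axis=-1)

    depth = np.full((h, w), spec.background_depth_m)
    owner = np.full((h, w), -1, dtype=np.int32)
    truths: list[LeafTruth] = []

    for k, leaf in enumerate(spec.leaves):
        r0, c0 = leaf.center
        z_c = spec.background_depth_m - leaf.depth_offset_m
        if z_c <= 0:
            raise InvalidSpecError(f"leaf {k} centre behind the camera (z = {z_c:.3f})")
        center = np.array([(c0 - cam.cx) * z_c / f, (r0 - cam.cy) * z_c / f, z_c])
        t_dir = leaf_chord_direction(leaf.phi_true_deg, leaf.azimuth_deg, spec.pose.theta_deg)
        w_dir = np.cross(t_dir, up)
        nw = np.linalg.norm(w_dir)
        if nw < 1e-12:  # chord vertical: any horizontal width direction works
            w_dir = np.array([1.0, 0.0, 0.0])
        else:
            w_dir = w_dir / nw
        normal = np.cross(t_dir, w_dir)

        px_m = z_c / f  # metres per pixel at the leaf centre depth
        semi_major = 0.5 * leaf.length_px * px_m
        semi_minor = 0.5 * leaf.width_px * px_m

        denom = rays @ normal
        cn = center @ normal
        with np.errstate(divide="ignore", invalid="ignore"):
            lam = np.where(np.abs(denom) > 1e-12, cn / denom, np.inf)
        pts = rays * lam[..., None]
        rel = pts - center
        s = rel @ t_dir
        q = rel @ w_dir
        inside = (
            np.isfinite(lam)
            & (lam > 0)
            & ((s / semi_major) ** 2 + (q / semi_minor) ** 2 <= 1.0)
        )
        leaf_z = np.where(inside, lam, np.inf)
        if inside.any():
            if float(leaf_z[inside].min()) <= 0:
                raise InvalidSpecError(f"leaf {k} intersects the camera")
            if float(leaf_z[inside].max()) >= spec.background_depth_m:
                raise InvalidSpecError(f"leaf {k} passes behind the background plane")
        closer = leaf_z < depth
        depth[closer] = leaf_z[closer]
        owner[closer] = k

        root3 = Point3.from_array(center - semi_major * t_dir)
        tip3 = Point3.from_array(center + semi_major * t_dir)
        # orient root toward the image top
        ur, vr = project(root3, cam)
        ut, vt = project(tip3, cam)
        if vr > vt:
            root3, tip3 = tip3, root3
            (ur, vr), (ut, vt) = (ut, vt), (ur, vr)
        truths.append(
            LeafTruth(
                mask=np.zeros((h, w), dtype=bool),  # filled after occlusion
                root_px=(int(round(vr)), int(round(ur))),
                tip_px=(int(round(vt)), int(round(ut))),
                root_xyz=root3,
                tip_xyz=tip3,
                phi_true_deg=leaf.phi_true_deg,
            )
        )

    for k, truth in enumerate(truths):
        truth.mask = owner == k

    gt = GroundTruth(truths, spec.pose.theta_deg, depth.copy())
    out = DepthMap(depth, np.zeros_like(depth, dtype=bool))
    if spec.noise_sigma_m > 0 or spec.salt_rate > 0:
        out = add_noise(out, spec.noise_sigma_m, spec.salt_rate, spec.seed)
    return out, gt


def render_disparity(depth: DepthMap, cam: CameraModel) -> np.ndarray:
    """Disparity ``d = focal_px * baseline_m / z`` per pixel; invalid -> 0."""
    with np.errstate(divide="ignore", invalid="ignore"):
        d = cam.focal_px * cam.baseline_m / depth.values
    d[depth.invalid_mask] = 0.0
    return d


def add_noise(depth: DepthMap, sigma_m: float, salt_rate: float, seed: int) -> DepthMap:
    """Gaussian depth noise plus salt outliers.

    Zero-mean Gaussian noise of standard deviation ``sigma_m`` is added to
    every valid pixel; then exactly ``round(salt_rate * n_pixels)`` pixels
    (drawn without replacement) are replaced by double-depth outliers, the
    signature of an isolated stereo mismatch.
    """
    if sigma_m < 0:
        raise InvalidInputError("sigma_m must be >= 0")
    if not 0 <= salt_rate < 1:
        raise InvalidInputError("salt_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    z = depth.values.copy()
    ok = depth.valid_mask
    if sigma_m > 0:
        z[ok] = z[ok] + rng.normal(0.0, sigma_m, size=int(ok.sum()))
        np.clip(z, 1e-6, None, out=z)
    n_salt = int(round(salt_rate * z.size))
    if n_salt > 0:
        flat = rng.choice(z.size, size=n_salt, replace=False)
        rr, cc = np.unravel_index(flat, z.shape)
        z[rr, cc] = np.where(ok[rr, cc], z[rr, cc] * 2.0, z[rr, cc])
    z[~ok] = np.nan
    return DepthMap(z, ~ok)


def add_streaks(
    depth: DepthMap, streaks: list[tuple[int, int, int]], factor: float = 2.0
) -> DepthMap:
    """Continuous-mismatch noise: 1-px-high horizontal double-depth runs.

    Each streak is ``(row, col_start, col_stop)`` (half-open); affected valid
    pixels are multiplied by ``factor``. Models the contiguous mismatch bands
    a stereo matcher produces on textureless or occluded strips.
    """
    z = depth.values.copy()
    ok = depth.valid_mask
    for row, c0, c1 in streaks:
        if not (0 <= row < z.shape[0] and 0 <= c0 < c1 <= z.shape[1]):
            raise InvalidInputError(f"streak {(row, c0, c1)} outside the map")
        sel = ok[row, c0:c1]
        z[row, c0:c1][sel] *= factor
    z[~ok] = np.nan
    return DepthMap(z, ~ok)


def standard_scene(
    theta_deg: float,
    phi_deg: float,
    n_leaves: int = 3,
    noise_sigma_frac: float = 0.0,
    salt_rate: float = 0.0,
    seed: int = 0,
) -> SceneSpec:
    """The study's canonical test scene: ``n_leaves`` in-slice leaves at one LIA.

    Leaves sit ~half a metre in front of a 3 m background, laterally
    separated, all at azimuth 0 (the configuration in which the angle decomposition is
    exact). ``noise_sigma_frac`` scales the Gaussian sigma as a fraction of
    the background depth (0.005 = 0.5 % of depth).
    """
    cam = default_camera()
    if not 1 <= n_leaves <= 4:
        raise InvalidInputError("standard scene supports 1-4 leaves")
    # the first leaf sits on the principal column, i.e. exactly in the vertical
    # plane through the optical axis, where the angle decomposition is exact
    cols = [cam.cx, 70.0, 255.0, 115.0][:n_leaves]
    rows = [120.0, 126.0, 112.0, 60.0][:n_leaves]
    offsets = [0.45, 0.50, 0.55, 0.60][:n_leaves]
    leaves = tuple(
        LeafSpec(center=(r, c), phi_true_deg=phi_deg, depth_offset_m=off)
        for r, c, off in zip(rows, cols, offsets)
    )
    return SceneSpec(
        camera=cam,
        pose=RigPose(theta_deg),
        leaves=leaves,
        background_depth_m=3.0,
        noise_sigma_m=noise_sigma_frac * 3.0,
        salt_rate=salt_rate,
        seed=seed,
    )
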