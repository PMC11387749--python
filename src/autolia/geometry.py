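"""Pinhole camera geometry and leaf inclination angle (LIA) recovery.

The camera frame is right-handed with x right, y down along image rows and z
forward along the optical axis; depth is the z coordinate. The rig is pitched
down by the inclinometer angle ``theta_deg``, so the world up direction seen in
the camera frame is ``u_c = (0, -cos theta, -sin theta)``.

Two routes to the LIA ``phi`` of a leaf chord (root ``A`` -> tip ``B``) are
provided:

* the imaging-plane construction (:func:`alpha_law_of_cosines` followed by
  :func:`lia_from_decomposition`), which projects ``A`` and ``B`` through the
  optical centre onto the imaging plane and applies the law of cosines in the
  auxiliary triangle ``ABC``, then closes the decomposition
  ``theta + alpha + phi + 90 = 180``; exact for chords lying in the vertical
  plane through the optical axis, on the near-side branch (``phi`` in
  ``[0, 90]``);
* the general 3D oracle (:func:`lia_3d_oracle`), valid for any chord
  orientation, which measures the chord against ``u_c`` directly.

Sign convention: ``alpha`` (the chord's angle to the imaging plane) is
*positive when the tip is nearer the camera than the root*. This is the unique
convention under which the closure identity reproduces the 3D oracle; see
``alpha_closed_form``.

Angles are degrees at every public interface.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError

__all__ = [
    "CameraModel",
    "RigPose",
    "Point3",
    "AngleDecomposition",
    "backproject",
    "project",
    "alpha_closed_form",
    "alpha_law_of_cosines",
    "lia_from_decomposition",
    "lia_3d_oracle",
    "up_vector_cam",
    "measure_lia",
]


@dataclass(frozen=True)
class CameraModel:
    """Pinhole intrinsics plus the stereo baseline.

    Parameters
    ----------
    focal_px : float
        Focal length in pixels (square pixels assumed), > 0.
    principal_point : tuple of float
        ``(cx, cy)`` in pixel coordinates, inside the image.
    baseline_m : float
        Stereo baseline in metres, > 0.
    image_size : tuple of int
        ``(width, height)`` in pixels.
    """

    focal_px: float
    principal_point: tuple[float, float]
    baseline_m: float
    image_size: tuple[int, int]

    def __post_init__(self) -> None:
        cx, cy = self.principal_point
        w, h = self.image_size
        if not self.focal_px > 0:
            raise InvalidInputError(f"focal_px must be > 0, got {self.focal_px}")
        if not self.baseline_m > 0:
            raise InvalidInputError(f"baseline_m must be > 0, got {self.baseline_m}")
        if not (w > 0 and h > 0):
            raise InvalidInputError(f"image_size must be positive, got {self.image_size}")
        if not (0 <= cx < w and 0 <= cy < h):
            raise InvalidInputError(
                f"principal point {self.principal_point} outside image {self.image_size}"
            )

    @property
    def cx(self) -> float:
        return self.principal_point[0]

    @property
    def cy(self) -> float:
        return self.principal_point[1]

    @property
    def width(self) -> int:
        return self.image_size[0]

    @property
    def height(self) -> int:
        return self.image_size[1]


@dataclass(frozen=True)
class RigPose:
    """Inclinometer reading: downward pitch of the optical axis, degrees."""

    theta_deg: float

    def __post_init__(self) -> None:
        if not 0 <= self.theta_deg < 90:
            raise InvalidInputError(f"theta_deg must lie in [0, 90), got {self.theta_deg}")


@dataclass(frozen=True)
class Point3:
    """A point in the camera frame, metres (x right, y down, z = depth)."""

    x: float
    y: float
    z: float

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)

    @classmethod
    def from_array(cls, a) -> "Point3":
        return cls(float(a[0]), float(a[1]), float(a[2]))


@dataclass(frozen=True)
class AngleDecomposition:
    """The (theta, alpha, phi) triple obeying theta + alpha + phi + 90 = 180."""

    theta_deg: float
    alpha_deg: float
    phi_deg: float

    @property
    def closure_residual_deg(self) -> float:
        """Deviation of theta + alpha + phi + 90 from 180 degrees."""
        return self.theta_deg + self.alpha_deg + self.phi_deg + 90.0 - 180.0

    @classmethod
    def from_alpha(cls, alpha_deg: float, theta_deg: float) -> "AngleDecomposition":
        return cls(theta_deg, alpha_deg, lia_from_decomposition(alpha_deg, theta_deg))

    @classmethod
    def from_phi(cls, phi_deg: float, theta_deg: float) -> "AngleDecomposition":
        return cls(theta_deg, 90.0 - theta_deg - phi_deg, phi_deg)


def backproject(u: float, v: float, z: float, cam: CameraModel) -> Point3:
    """Back-project pixel ``(u, v)`` at depth ``z`` (metres) into the camera frame."""
    if not z > 0:
        raise InvalidInputError(f"depth must be > 0, got {z}")
    f = cam.focal_px
    return Point3((u - cam.cx) * z / f, (v - cam.cy) * z / f, float(z))


def project(p: Point3, cam: CameraModel) -> tuple[float, float]:
    """Forward pinhole projection of a camera-frame point to pixel coordinates."""
    if not p.z > 0:
        raise InvalidInputError(f"cannot project point with z = {p.z}")
    return (cam.cx + cam.focal_px * p.x / p.z, cam.cy + cam.focal_px * p.y / p.z)


def alpha_closed_form(A: Point3, B: Point3) -> float:
    """Closed-form angle between the chord ``A -> B`` and the imaging plane.

    Returns ``arcsin((z_A - z_B) / |AB|)`` in degrees: positive when the tip
    ``B`` is nearer the camera than the root ``A``. Under this convention the
    decomposition ``phi = 90 - theta - alpha`` reproduces the general 3D oracle
    for in-slice chords on the near-side branch.
    """
    d = B.as_array() - A.as_array()
    n = float(np.linalg.norm(d))
    if n == 0.0:
        raise InvalidInputError("coincident key points")
    s = (A.z - B.z) / n
    return math.degrees(math.asin(max(-1.0, min(1.0, s))))


def alpha_law_of_cosines(A: Point3, B: Point3, cam: CameraModel) -> float:
    """Chord-to-imaging-plane angle via the projective triangle construction.

    ``A`` and ``B`` are projected through the optical centre onto the (unit
    focal) imaging plane, giving ``A'`` and ``B'``. ``C`` is placed on the ray
    from ``A`` parallel to ``A'B'`` at distance ``d_A * |A'B'|`` (the
    similar-triangles scaling), and the angle at ``A`` in triangle ``ABC`` is
    recovered from the law of cosines. The magnitude equals
    :func:`alpha_closed_form` for chords in the vertical plane through the
    optical axis; the sign follows the tip-nearer-positive convention.
    """
    if not (A.z > 0 and B.z > 0):
        raise InvalidInputError("key points must lie in front of the camera")
    a = A.as_array()
    b = B.as_array()
    ab = b - a
    norm_ab = float(np.linalg.norm(ab))
    if norm_ab == 0.0:
        raise InvalidInputError("coincident key points")
    # Perspective projections onto the z = 1 plane (the plane offset cancels
    # out of the angle, so unit focal distance is used).
    a_proj = a / A.z
    b_proj = b / B.z
    u = b_proj - a_proj
    if float(np.linalg.norm(u)) < 1e-12:
        # A and B on the same optical ray: the construction degenerates; the
        # closed form still defines the angle.
        return alpha_closed_form(A, B)
    c = a + A.z * u  # |AC| = d_A * |A'B'|, AC parallel to A'B'
    ac = float(np.linalg.norm(c - a))
    bc = float(np.linalg.norm(c - b))
    cos_gamma = (ac * ac + norm_ab * norm_ab - bc * bc) / (2.0 * ac * norm_ab)
    gamma = math.degrees(math.acos(max(-1.0, min(1.0, cos_gamma))))
    # gamma is the angle between AB and the A'B' direction; depending on the
    # orientation of A'B' it is either |alpha| or 180 - |alpha|.
    mag = min(gamma, 180.0 - gamma)
    if A.z > B.z:
        return mag
    if A.z < B.z:
        return -mag
    return 0.0


def lia_from_decomposition(alpha_deg: float, theta_deg: float) -> float:
    """LIA from the closure identity: ``phi = 90 - theta - alpha`` (degrees)."""
    if not abs(alpha_deg) <= 90:
        raise InvalidInputError(f"|alpha_deg| must be <= 90, got {alpha_deg}")
    if not 0 <= theta_deg < 90:
        raise InvalidInputError(f"theta_deg must lie in [0, 90), got {theta_deg}")
    return 90.0 - theta_deg - alpha_deg


def up_vector_cam(theta_deg: float) -> np.ndarray:
    """World up direction expressed in the camera frame (unit vector)."""
    t = math.radians(theta_deg)
    return np.array([0.0, -math.cos(t), -math.sin(t)])


def lia_3d_oracle(A: Point3, B: Point3, pose: RigPose) -> float:
    """General 3D ground-truth LIA of the chord ``A -> B`` in degrees.

    ``arcsin(|(B - A) . u_c| / |B - A|)`` with ``u_c`` the world up vector in
    the camera frame; valid for chords of any orientation, always in [0, 90].
    """
    d = B.as_array() - A.as_array()
    n = float(np.linalg.norm(d))
    if n == 0.0:
        raise InvalidInputError("coincident key points")
    s = abs(float(d @ up_vector_cam(pose.theta_deg))) / n
    return math.degrees(math.asin(min(1.0, s)))


def measure_lia(A: Point3, B: Point3, pose: RigPose) -> AngleDecomposition:
    """Measure a leaf chord: phi from the 3D oracle, alpha back-filled from Eq. closure.

    The returned decomposition satisfies ``theta + alpha + phi + 90 = 180``
    exactly; for in-slice near-side chords ``alpha`` coincides with
    :func:`alpha_closed_form`.
    """
    phi = lia_3d_oracle(A, B, pose)
    return AngleDecomposition.from_phi(phi, pose.theta_deg)
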