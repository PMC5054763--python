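"""Canonical 3D face model, camera model, pose representation and projection.

Clinical head posture is described by three Euler angles, named as in the
ophthalmic literature:

* **yaw** — face turn; positive = face turned toward the subject's left;
* **pitch** — chin up/down; positive = chin up;
* **roll** — head tilt; positive = tilt toward the subject's right shoulder.

The rotation is intrinsic yaw → pitch → roll. The camera frame follows the
dominant imaging convention: x right, y down, z forward (into the scene),
image origin at the top-left corner, pixel centres on integer coordinates.
The face model frame coincides with the camera frame at the null pose, so a
subject facing the camera squarely has yaw = pitch = roll = 0; the model +z
axis points out of the back of the head (the nose tip has negative z).

Metric scale is anchored by a standard adult interpupillary distance of
65 mm: the distance between the centroids of the two lid-margin point sets
of the canonical model is exactly 65 mm, which lets a monocular camera
report head position in millimetres.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .exceptions import BehindCameraError, InvalidRotationError

__all__ = [
    "N_LANDMARKS",
    "MIRROR_PAIRS",
    "FaceModel",
    "HeadPose",
    "CameraModel",
    "LandmarkObservation",
    "canonical_model",
    "default_camera",
    "euler_to_rotation",
    "rotation_to_euler",
    "project",
    "wrap_angle_deg",
]

N_LANDMARKS = 68

#: Left-right landmark index pairing of the standard 68-point annotation
#: scheme (jaw 0-16, brows 17-26, nose 27-35, eyes 36-47, lips 48-67).
#: (a, b) means a and b swap under mirroring about the midsagittal plane.
MIRROR_PAIRS: tuple[tuple[int, int], ...] = tuple(
    [(i, 16 - i) for i in range(9)]
    + [(17 + i, 26 - i) for i in range(5)]
    + [(27 + i, 27 + i) for i in range(4)]
    + [(31, 35), (32, 34), (33, 33)]
    + [(36, 45), (37, 44), (38, 43), (39, 42), (40, 47), (41, 46)]
    + [(48, 54), (49, 53), (50, 52), (51, 51), (55, 59), (56, 58), (57, 57)]
    + [(60, 64), (61, 63), (62, 62), (65, 67), (66, 66)]
)

_REGION_COUNTS = {
    "jawline": 17,
    "eyebrow_right": 5,
    "eyebrow_left": 5,
    "nose": 9,
    "eye_right": 6,
    "eye_left": 6,
    "lips": 20,
}


def wrap_angle_deg(a):
    """Wrap angles (degrees) into (-180, 180]."""
    a = np.asarray(a, dtype=float)
    wrapped = -((-a + 180.0) % 360.0 - 180.0)
    return wrapped if wrapped.ndim else float(wrapped)


@dataclass(frozen=True)
class FaceModel:
    """A rigid 68-point 3D face shape in millimetres (model frame).

    Attributes
    ----------
    points
        (68, 3) array of landmark coordinates, mm. Origin at the midpoint
        of the two pupil centres.
    region_labels
        Per-point anatomical region, one of jawline, eyebrow_left,
        eyebrow_right, nose, eye_left, eye_right, lips.
    pupil_left_index_set, pupil_right_index_set
        Landmark indices (the lid-margin points of each eye) whose
        centroids define the subject's left and right pupil centres.
    """

    points: np.ndarray
    region_labels: tuple[str, ...]
    pupil_left_index_set: tuple[int, ...] = tuple(range(42, 48))
    pupil_right_index_set: tuple[int, ...] = tuple(range(36, 42))

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.shape != (N_LANDMARKS, 3):
            raise ValueError(f"expected ({N_LANDMARKS}, 3) points, got {pts.shape}")
        object.__setattr__(self, "points", pts)

    @property
    def pupil_left(self) -> np.ndarray:
        """Centroid of the subject's left lid-margin landmarks, mm."""
        return self.points[list(self.pupil_left_index_set)].mean(axis=0)

    @property
    def pupil_right(self) -> np.ndarray:
        return self.points[list(self.pupil_right_index_set)].mean(axis=0)

    @property
    def interpupillary_distance_mm(self) -> float:
        return float(np.linalg.norm(self.pupil_left - self.pupil_right))

    def mirrored(self) -> "FaceModel":
        """The model reflected about the midsagittal (x = 0) plane, with the
        left-right index pairing applied so a symmetric model round-trips."""
        out = np.empty_like(self.points)
        for a, b in MIRROR_PAIRS:
            out[a] = self.points[b] * np.array([-1.0, 1.0, 1.0])
            out[b] = self.points[a] * np.array([-1.0, 1.0, 1.0])
        return FaceModel(out, self.region_labels,
                         self.pupil_left_index_set, self.pupil_right_index_set)


@dataclass(frozen=True)
class HeadPose:
    """Clinical head pose: Euler angles in degrees plus metric translation.

    ``(tx_mm, ty_mm, tz_mm)`` is the position of the face-model origin (the
    pupil midpoint) in the camera frame; tz is depth along the optical axis
    and must be positive for the head to be in front of the camera.
    """

    yaw_deg: float = 0.0
    pitch_deg: float = 0.0
    roll_deg: float = 0.0
    tx_mm: float = 0.0
    ty_mm: float = 0.0
    tz_mm: float = 0.0

    @property
    def angles_deg(self) -> np.ndarray:
        return np.array([self.yaw_deg, self.pitch_deg, self.roll_deg])

    @property
    def translation_mm(self) -> np.ndarray:
        return np.array([self.tx_mm, self.ty_mm, self.tz_mm])

    @property
    def distance_mm(self) -> float:
        """Euclidean camera-to-head distance, mm."""
        return float(np.linalg.norm(self.translation_mm))

    def rotation_matrix(self) -> np.ndarray:
        return euler_to_rotation(self)

    def is_finite(self) -> bool:
        return bool(np.all(np.isfinite(self.angles_deg))
                    and np.all(np.isfinite(self.translation_mm)))


@dataclass(frozen=True)
class CameraModel:
    """Pinhole camera intrinsics (no lens distortion)."""

    focal_px: float
    principal_point_px: tuple[float, float]
    image_size_px: tuple[int, int]

    def __post_init__(self):
        if not self.focal_px > 0:
            raise ValueError("focal_px must be positive")
        cx, cy = self.principal_point_px
        w, h = self.image_size_px
        if not (0 <= cx <= w and 0 <= cy <= h):
            raise ValueError("principal point outside image bounds")


def default_camera(width: int = 1920, height: int = 1080) -> CameraModel:
    """Typical consumer-webcam intrinsics: focal length = image width
    (about a 53 degree horizontal field of view), principal point centred."""
    return CameraModel(focal_px=float(width),
                       principal_point_px=(width / 2.0, height / 2.0),
                       image_size_px=(width, height))


@dataclass(frozen=True)
class LandmarkObservation:
    """One frame of observed 2D landmarks (pixels) with a visibility mask.

    Fully occluded frames (zero visible points) are legal input; hidden
    points may carry NaN coordinates.
    """

    frame_id: int
    points_px: np.ndarray
    visible: np.ndarray

    def __post_init__(self):
        pts = np.asarray(self.points_px, dtype=float)
        vis = np.asarray(self.visible, dtype=bool)
        if pts.shape != (N_LANDMARKS, 2):
            raise ValueError(f"expected ({N_LANDMARKS}, 2) points, got {pts.shape}")
        if vis.shape != (N_LANDMARKS,):
            raise ValueError("visible mask must have length 68")
        if not np.all(np.isfinite(pts[vis])):
            raise ValueError("visible landmark coordinates must be finite")
        object.__setattr__(self, "points_px", pts)
        object.__setattr__(self, "visible", vis)

    @property
    def n_visible(self) -> int:
        return int(self.visible.sum())


_CANONICAL_CACHE: FaceModel | None = None


def canonical_model() -> FaceModel:
    """The fixed, versioned canonical 68-point face shape.

    Loaded from a CSV resource holding exact decimal coordinates; the table
    is mirror-symmetric, has a pupil-centroid separation of exactly 65 mm,
    and is centred on the pupil midpoint. Deterministic across calls and
    platforms.
    """
    global _CANONICAL_CACHE
    if _CANONICAL_CACHE is None:
        path = resources.files("headposture.data") / "canonical_face_68.csv"
        pts = np.zeros((N_LANDMARKS, 3))
        labels: list[str] = [""] * N_LANDMARKS
        with path.open("r", encoding="utf-8") as fh:
            header = fh.readline().strip().split(",")
            assert header == ["index", "region", "x_mm", "y_mm", "z_mm"]
            for line in fh:
                idx, region, x, y, z = line.strip().split(",")
                i = int(idx)
                pts[i] = (float(x), float(y), float(z))
                labels[i] = region
        _CANONICAL_CACHE = FaceModel(pts, tuple(labels))
    return _CANONICAL_CACHE


def euler_to_rotation(pose: HeadPose | Sequence[float]) -> np.ndarray:
    """Rotation matrix (model frame -> camera frame) for a clinical pose.

    Intrinsic yaw → pitch → roll. Because the camera frame has y down and
    z forward, the anatomical "up" and "out of the face" axes are -y and
    -z, so each clinical angle is the negative of the right-handed rotation
    about the corresponding frame axis: R = Ry(-yaw) Rx(-pitch) Rz(-roll).
    """
    if isinstance(pose, HeadPose):
        angles = pose.angles_deg
    else:
        angles = np.asarray(pose, dtype=float)
    if not np.all(np.isfinite(angles)):
        raise ValueError("angles must be finite")
    yaw, pitch, roll = angles
    return Rotation.from_euler("YXZ", [-yaw, -pitch, -roll], degrees=True).as_matrix()


def rotation_to_euler(R: np.ndarray) -> tuple[float, float, float]:
    """Decompose a rotation matrix into (yaw, pitch, roll) degrees.

    Inverse of :func:`euler_to_rotation`. At gimbal lock (|pitch| = 90°)
    the representative with roll = 0 is returned and the ambiguity is
    folded into yaw.

    Raises
    ------
    InvalidRotationError
        If R is not orthonormal within 1e-6 or has negative determinant.
    """
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3):
        raise InvalidRotationError(f"expected 3x3 matrix, got {R.shape}")
    defect = np.linalg.norm(R.T @ R - np.eye(3))
    if not defect < 1e-6:
        raise InvalidRotationError(f"matrix not orthonormal (defect {defect:.3g})")
    if np.linalg.det(R) < 0:
        raise InvalidRotationError("matrix has negative determinant (reflection)")
    with warnings.catch_warnings():
        # scipy warns at gimbal lock; its convention (third angle set to 0)
        # is exactly the tie-break documented here.
        warnings.simplefilter("ignore", UserWarning)
        a, b, c = Rotation.from_matrix(R).as_euler("YXZ", degrees=True)
    yaw, pitch, roll = -a, -b, -c
    return (wrap_angle_deg(yaw), wrap_angle_deg(pitch), wrap_angle_deg(roll))


def project(model: FaceModel, pose: HeadPose, camera: CameraModel,
            frame_id: int = 0) -> LandmarkObservation:
    """Project the model at a pose through the pinhole camera.

    u = cx + f·X/Z, v = cy + f·Y/Z per landmark, with (X, Y, Z) the
    camera-frame coordinates R·p + t. All points are marked visible.

    Raises
    ------
    BehindCameraError
        If any transformed point has non-positive depth.
    """
    if not pose.tz_mm > 0:
        raise BehindCameraError(f"tz_mm must be positive, got {pose.tz_mm}")
    R = euler_to_rotation(pose)
    cam_pts = model.points @ R.T + pose.translation_mm
    Z = cam_pts[:, 2]
    if np.any(Z <= 0):
        raise BehindCameraError("a model point has non-positive camera depth")
    cx, cy = camera.principal_point_px
    u = cx + camera.focal_px * cam_pts[:, 0] / Z
    v = cy + camera.focal_px * cam_pts[:, 1] / Z
    return LandmarkObservation(frame_id=frame_id,
                               points_px=np.column_stack([u, v]),
                               visible=np.ones(N_LANDMARKS, dtype=bool))
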