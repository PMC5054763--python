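"""Per-frame head-pose estimation from 2D landmarks.

Inverts the pinhole projection of the rigid canonical face model: given one
frame of observed 68-point landmarks, recovers the clinical Euler angles
(yaw, pitch, roll), the metric translation of the head in the camera frame
(anchored by the 65 mm model interpupillary distance), and a goodness-of-fit
confidence in [0, 1].

The fit is a two-stage perspective-n-point solve:

1. a closed-form weak-perspective (scaled orthographic) initialisation —
   a least-squares affine fit of the model to the pixels, orthonormalised
   to the nearest rotation, with depth recovered from the affine scale;
2. damped Gauss–Newton (Levenberg–Marquardt) refinement of the six pose
   parameters minimising the sum of squared reprojection errors.

Confidence is a linear function of the RMS reprojection error normalised by
the projected inter-pupillary pixel distance, so the same threshold is
meaningful across cameras, resolutions and subject distances. It is a
goodness-of-fit surrogate: occlusion, noise and extreme pose all push it
down, and pure-noise frames score 0.

The public entry points are :class:`LandmarkPoseModel` (statsmodels-style
model object; ``fit()`` returns :class:`PoseFitResults`) and the functional
wrapper :func:`estimate_pose`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .exceptions import DegenerateConfigurationError, NotTrackedError
from .facemodel import (
    CameraModel,
    FaceModel,
    HeadPose,
    LandmarkObservation,
    canonical_model,
    default_camera,
    euler_to_rotation,
    rotation_to_euler,
    wrap_angle_deg,
)

__all__ = [
    "EstimatorConfig",
    "PoseEstimate",
    "PoseFitResults",
    "LandmarkPoseModel",
    "initialize_weak_perspective",
    "refine_pose",
    "compute_confidence",
    "estimate_distance",
    "estimate_pose",
]


@dataclass(frozen=True)
class EstimatorConfig:
    """Tunables of the pose fit.

    max_iterations
        Cap on Gauss–Newton iterations (50 is far beyond what a clean
        frame needs; the fit is quadratically convergent near the optimum).
    convergence_tol_deg, convergence_tol_mm
        Declare convergence when successive parameter updates fall below
        both (degrees for the angles, millimetres for the translation).
    min_visible_landmarks
        Fewer visible points than this and the frame is untracked; 6 is the
        minimum that over-determines the 6 pose degrees of freedom.
    confidence_threshold
        Estimates below this confidence are reported as not tracked.
    residual_scale
        Normalised RMS reprojection error at which confidence reaches 0;
        0.10 means "10% of the inter-pupil pixel distance".
    """

    max_iterations: int = 50
    convergence_tol_deg: float = 1e-6
    convergence_tol_mm: float = 1e-4
    min_visible_landmarks: int = 6
    confidence_threshold: float = 0.75
    residual_scale: float = 0.10

    def __post_init__(self):
        if self.min_visible_landmarks < 6:
            raise ValueError("min_visible_landmarks must be >= 6")
        for name in ("max_iterations", "convergence_tol_deg", "convergence_tol_mm",
                     "confidence_threshold", "residual_scale"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class PoseEstimate:
    """Result of a single-frame pose fit.

    ``tracked = False`` means the frame could not be fitted confidently;
    its pose fields are NaN. ``residual_rms_norm`` is the RMS reprojection
    error divided by the projected inter-pupil pixel distance.
    """

    pose: HeadPose
    confidence: float
    residual_rms_norm: float
    tracked: bool
    n_visible: int


_UNTRACKED_POSE = HeadPose(*([float("nan")] * 6))


@dataclass(frozen=True)
class PoseFitResults(PoseEstimate):
    """A :class:`PoseEstimate` with fit diagnostics.

    ``resid_px`` holds the per-landmark reprojection distance in pixels
    (NaN for invisible landmarks).
    """

    converged: bool = False
    n_iterations: int = 0
    resid_px: np.ndarray = field(default_factory=lambda: np.full(68, np.nan))

    @property
    def distance_mm(self) -> float:
        """Metric camera-to-head distance (requires ``tracked``)."""
        return estimate_distance(self)

    def summary(self) -> str:
        """Human-readable report of the fitted pose and diagnostics."""
        p = self.pose
        lines = [
            "Head pose fit",
            "=" * 46,
            f"tracked              {self.tracked}",
            f"yaw (face turn)      {p.yaw_deg:10.3f} deg",
            f"pitch (chin up/down) {p.pitch_deg:10.3f} deg",
            f"roll (head tilt)     {p.roll_deg:10.3f} deg",
            f"tx, ty, tz           {p.tx_mm:8.1f}, {p.ty_mm:8.1f}, {p.tz_mm:8.1f} mm",
            f"distance             {p.distance_mm:10.1f} mm" if self.tracked
            else "distance                    n/a",
            f"confidence           {self.confidence:10.1%}",
            f"residual (norm. RMS) {self.residual_rms_norm:10.4f}",
            f"landmarks used       {self.n_visible:6d}",
            f"iterations           {self.n_iterations:6d} (converged: {self.converged})",
        ]
        return "\n".join(lines)


def initialize_weak_perspective(obs: LandmarkObservation, model: FaceModel,
                                camera: CameraModel,
                                min_visible: int = 6) -> HeadPose:
    """Closed-form scaled-orthographic pose estimate.

    Fits pixels = A·X + b in least squares over the visible landmarks,
    orthonormalises the two rows of A to the nearest rotation and reads the
    depth off the affine scale (tz = focal / s). Deliberately biased (weak
    perspective ignores within-face depth variation) but always within the
    refinement basin on face-like geometry.

    Raises
    ------
    DegenerateConfigurationError
        Fewer than ``min_visible`` visible landmarks, or a rank-deficient
        (e.g. collinear) visible configuration.
    """
    vis = obs.visible
    if obs.n_visible < min_visible:
        raise DegenerateConfigurationError(
            f"{obs.n_visible} visible landmarks < minimum {min_visible}")
    X = model.points[vis]
    U = obs.points_px[vis]
    G = np.column_stack([X, np.ones(len(X))])
    W, _, rank, _ = np.linalg.lstsq(G, U, rcond=None)
    if rank < 4:
        raise DegenerateConfigurationError(
            "visible landmarks are geometrically degenerate (rank "
            f"{rank} < 4 affine fit)")
    A = W[:3].T                       # (2, 3): scaled first two rotation rows
    b = W[3]
    s1 = float(np.linalg.norm(A[0]))
    s2 = float(np.linalg.norm(A[1]))
    s = 0.5 * (s1 + s2)
    if not (s > 1e-12 and np.isfinite(s)):
        raise DegenerateConfigurationError("degenerate affine scale")
    r1 = A[0] / s1
    r2 = A[1] / s2
    M = np.vstack([r1, r2, np.cross(r1, r2)])
    Um, _, Vt = np.linalg.svd(M)
    R = Um @ Vt
    if np.linalg.det(R) < 0:
        Um[:, -1] *= -1
        R = Um @ Vt
    yaw, pitch, roll = rotation_to_euler(R)
    cx, cy = camera.principal_point_px
    tz = camera.focal_px / s
    tx = (float(b[0]) - cx) / s
    ty = (float(b[1]) - cy) / s
    return HeadPose(yaw, pitch, roll, tx, ty, abs(tz))


def _reprojection_residuals(params: np.ndarray, X: np.ndarray, U: np.ndarray,
                            camera: CameraModel) -> np.ndarray:
    """Stacked (u, v) reprojection errors for the visible landmarks."""
    R = euler_to_rotation(params[:3])
    cam = X @ R.T + params[3:]
    Z = np.maximum(cam[:, 2], 1.0)    # keep gradients finite behind camera
    cx, cy = camera.principal_point_px
    proj = np.column_stack([cx + camera.focal_px * cam[:, 0] / Z,
                            cy + camera.focal_px * cam[:, 1] / Z])
    return (proj - U).ravel()


def _projected_ipd_px(model: FaceModel, pose: HeadPose,
                      camera: CameraModel) -> float:
    R = euler_to_rotation(pose)
    px = []
    for pupil in (model.pupil_left, model.pupil_right):
        cam = R @ pupil + pose.translation_mm
        z = max(cam[2], 1.0)
        px.append(camera.focal_px * cam[:2] / z)
    return float(np.linalg.norm(px[0] - px[1]))


def compute_confidence(residual_rms_norm: float, cfg: EstimatorConfig) -> float:
    """Map the normalised residual to a confidence fraction.

    confidence = clamp(1 − residual / residual_scale, 0, 1): 1 for a
    perfect fit, 0 once the RMS reprojection error reaches
    ``residual_scale`` times the inter-pupil pixel distance.
    """
    if residual_rms_norm < 0:
        raise ValueError("residual must be non-negative")
    if not np.isfinite(residual_rms_norm):
        return 0.0
    return float(np.clip(1.0 - residual_rms_norm / cfg.residual_scale, 0.0, 1.0))


def _untracked(n_visible: int, residual: float = float("nan")) -> PoseFitResults:
    return PoseFitResults(pose=_UNTRACKED_POSE, confidence=0.0,
                          residual_rms_norm=residual, tracked=False,
                          n_visible=n_visible)


def refine_pose(obs: LandmarkObservation, model: FaceModel, camera: CameraModel,
                init: HeadPose, cfg: EstimatorConfig | None = None) -> PoseFitResults:
    """Levenberg–Marquardt refinement of all six pose parameters.

    Minimises the sum of squared reprojection errors from ``init``;
    divergence or non-convergence is reported through ``tracked = False``,
    never as an exception.
    """
    cfg = cfg or EstimatorConfig()
    if obs.n_visible < cfg.min_visible_landmarks:
        return _untracked(obs.n_visible)
    if not init.is_finite():
        return _untracked(obs.n_visible)
    vis = obs.visible
    X = model.points[vis]
    U = obs.points_px[vis]
    x0 = np.array([init.yaw_deg, init.pitch_deg, init.roll_deg,
                   init.tx_mm, init.ty_mm, max(init.tz_mm, 10.0)])
    try:
        res = least_squares(
            _reprojection_residuals, x0, args=(X, U, camera), method="lm",
            xtol=1e-14, ftol=1e-14, gtol=1e-14,
            max_nfev=cfg.max_iterations * (len(x0) + 2))
    except Exception:
        return _untracked(obs.n_visible)
    p = res.x
    pose = HeadPose(wrap_angle_deg(p[0]), wrap_angle_deg(p[1]),
                    wrap_angle_deg(p[2]), p[3], p[4], p[5])
    if not (pose.is_finite() and pose.tz_mm > 0):
        return _untracked(obs.n_visible)
    per_point = res.fun.reshape(-1, 2)
    dists = np.linalg.norm(per_point, axis=1)
    ipd_px = _projected_ipd_px(model, pose, camera)
    residual_norm = (float(np.sqrt(np.mean(dists ** 2))) / ipd_px
                     if ipd_px > 1e-9 else float("inf"))
    confidence = compute_confidence(residual_norm, cfg)
    converged = res.status > 0
    n_iter = int(math.ceil(res.nfev / (len(x0) + 1)))
    resid_full = np.full(68, np.nan)
    resid_full[vis] = dists
    return PoseFitResults(pose=pose, confidence=confidence,
                          residual_rms_norm=residual_norm,
                          tracked=bool(converged
                                       and confidence >= cfg.confidence_threshold),
                          n_visible=obs.n_visible,
                          converged=converged, n_iterations=n_iter,
                          resid_px=resid_full)


def estimate_distance(estimate: PoseEstimate) -> float:
    """Euclidean camera-to-head distance in mm (scale anchored by the
    65 mm model interpupillary distance).

    Raises
    ------
    NotTrackedError
        If the estimate is not tracked.
    """
    if not estimate.tracked:
        raise NotTrackedError("distance undefined for an untracked frame")
    return estimate.pose.distance_mm


def estimate_pose(obs: LandmarkObservation, model: FaceModel | None = None,
                  camera: CameraModel | None = None,
                  cfg: EstimatorConfig | None = None) -> PoseFitResults:
    """Single public per-frame entry point: initialise then refine.

    Never raises on bad data — empty, occluded or nonsensical frames come
    back with ``tracked = False`` and NaN pose.
    """
    model = model or canonical_model()
    camera = camera or default_camera()
    cfg = cfg or EstimatorConfig()
    if obs.n_visible < cfg.min_visible_landmarks:
        return _untracked(obs.n_visible)
    try:
        init = initialize_weak_perspective(obs, model, camera,
                                           cfg.min_visible_landmarks)
    except DegenerateConfigurationError:
        return _untracked(obs.n_visible)
    return refine_pose(obs, model, camera, init, cfg)


class LandmarkPoseModel:
    """Pose-fitting model for one frame of landmarks (statsmodels-style).

    Parameters
    ----------
    obs
        The observed landmarks.
    face_model, camera, config
        Default to the canonical 65 mm-IPD face, the default webcam
        intrinsics, and the default :class:`EstimatorConfig`.

    Examples
    --------
    >>> from headposture import canonical_model, default_camera, project, HeadPose
    >>> cam = default_camera()
    >>> obs = project(canonical_model(), HeadPose(10, -5, 2, 0, 0, 1200), cam)
    >>> res = LandmarkPoseModel(obs, camera=cam).fit()
    >>> round(res.pose.yaw_deg, 3)
    10.0
    """

    def __init__(self, obs: LandmarkObservation,
                 face_model: FaceModel | None = None,
                 camera: CameraModel | None = None,
                 config: EstimatorConfig | None = None):
        self.obs = obs
        self.face_model = face_model or canonical_model()
        self.camera = camera or default_camera()
        self.config = config or EstimatorConfig()

    @classmethod
    def from_dataframe(cls, df, frame_id: int | None = None, **kwargs):
        """Build from a landmark table with columns
        frame_id, landmark_index, u_px, v_px, visible."""
        from .io import observations_from_dataframe
        frames = observations_from_dataframe(df)
        if frame_id is not None:
            frames = [f for f in frames if f.frame_id == frame_id]
        if len(frames) != 1:
            raise ValueError("need exactly one frame; pass frame_id to select")
        return cls(frames[0], **kwargs)

    def fit(self, start_pose: HeadPose | None = None) -> PoseFitResults:
        """Fit the pose; ``start_pose`` overrides the weak-perspective
        initialisation."""
        if start_pose is None:
            return estimate_pose(self.obs, self.face_model, self.camera,
                                 self.config)
        return refine_pose(self.obs, self.face_model, self.camera,
                           start_pose, self.config)
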