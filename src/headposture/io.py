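"""File formats and run configuration.

All interchange formats are plain text: comma-separated CSV with a header
row, '.' decimal separator and LF line endings, angles always in degrees
and positions in millimetres; landmark indices are 0-based (0–67) in the
standard 68-point region order. The ``matrix_text`` pose-annotation
dialect mirrors the per-frame ground-truth files shipped with public
head-pose video datasets: a 3×3 row-major rotation matrix (three lines of
three whitespace-separated floats) followed by one translation line
(three floats, mm), repeated per frame, blank lines ignored.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .estimator import EstimatorConfig, PoseEstimate
from .exceptions import ConfigError, InvalidRotationError, ParseError
from .facemodel import (
    N_LANDMARKS,
    CameraModel,
    HeadPose,
    LandmarkObservation,
    euler_to_rotation,
    rotation_to_euler,
)
from .synthetic import AnnotatedFrame

__all__ = [
    "write_landmarks_csv",
    "read_landmarks_csv",
    "observations_from_dataframe",
    "write_ground_truth_csv",
    "read_ground_truth_csv",
    "write_pose_annotation",
    "read_pose_annotation",
    "write_estimates_csv",
    "read_estimates_csv",
    "RunConfig",
    "load_config",
]

LANDMARK_COLUMNS = ["frame_id", "landmark_index", "u_px", "v_px", "visible"]
TRUTH_COLUMNS = ["frame_id", "yaw_deg", "pitch_deg", "roll_deg",
                 "tx_mm", "ty_mm", "tz_mm", "dropped"]
ESTIMATE_COLUMNS = ["frame_id", "yaw_deg", "pitch_deg", "roll_deg",
                    "tx_mm", "ty_mm", "tz_mm", "distance_mm",
                    "confidence", "tracked"]


def _frames_to_obs(frames) -> list[LandmarkObservation]:
    return [f.obs if isinstance(f, AnnotatedFrame) else f for f in frames]


def write_landmarks_csv(frames: Sequence, path) -> None:
    """Write per-frame landmarks (one row per visible landmark)."""
    obs_list = _frames_to_obs(frames)
    rows = []
    for obs in obs_list:
        for i in np.flatnonzero(obs.visible):
            rows.append((obs.frame_id, int(i),
                         obs.points_px[i, 0], obs.points_px[i, 1], 1))
    df = pd.DataFrame(rows, columns=LANDMARK_COLUMNS)
    df.to_csv(path, index=False, lineterminator="\n")


def observations_from_dataframe(df: pd.DataFrame) -> list[LandmarkObservation]:
    """Landmark table -> per-frame observations (grouped and ordered by
    frame_id; landmarks missing from a frame are marked invisible)."""
    missing = [c for c in LANDMARK_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"landmark table missing columns {missing}")
    idx = df["landmark_index"].to_numpy()
    if len(df) and (idx.min() < 0 or idx.max() >= N_LANDMARKS):
        bad = idx[(idx < 0) | (idx >= N_LANDMARKS)][0]
        raise ParseError(f"landmark index {bad} outside 0-{N_LANDMARKS - 1}")
    dup = df.duplicated(subset=["frame_id", "landmark_index"])
    if dup.any():
        f, i = df.loc[dup.idxmax(), ["frame_id", "landmark_index"]]
        raise ParseError(f"duplicate row for frame {f}, landmark {i}")
    frames = []
    for fid, grp in df.groupby("frame_id", sort=True):
        pts = np.full((N_LANDMARKS, 2), np.nan)
        vis = np.zeros(N_LANDMARKS, dtype=bool)
        li = grp["landmark_index"].to_numpy(dtype=int)
        flagged = grp["visible"].to_numpy().astype(bool)
        pts[li[flagged], 0] = grp["u_px"].to_numpy()[flagged]
        pts[li[flagged], 1] = grp["v_px"].to_numpy()[flagged]
        vis[li[flagged]] = True
        frames.append(LandmarkObservation(frame_id=int(fid), points_px=pts,
                                          visible=vis))
    return frames


def read_landmarks_csv(path) -> list[LandmarkObservation]:
    """Read a landmark CSV into per-frame observations."""
    df = pd.read_csv(path)
    return observations_from_dataframe(df)


def write_ground_truth_csv(frames: Sequence[AnnotatedFrame], path) -> None:
    rows = [(f.obs.frame_id, f.truth.yaw_deg, f.truth.pitch_deg,
             f.truth.roll_deg, f.truth.tx_mm, f.truth.ty_mm, f.truth.tz_mm,
             int(f.dropped)) for f in frames]
    pd.DataFrame(rows, columns=TRUTH_COLUMNS).to_csv(
        path, index=False, lineterminator="\n")


def read_ground_truth_csv(path) -> tuple[list[HeadPose], list[bool], list[int]]:
    """Read a ground-truth CSV -> (poses, dropped flags, frame ids)."""
    df = pd.read_csv(path)
    missing = [c for c in TRUTH_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"ground-truth table missing columns {missing}")
    poses = [HeadPose(r.yaw_deg, r.pitch_deg, r.roll_deg,
                      r.tx_mm, r.ty_mm, r.tz_mm) for r in df.itertuples()]
    return poses, [bool(d) for d in df["dropped"]], [int(f) for f in df["frame_id"]]


def write_pose_annotation(poses: Sequence[HeadPose], path,
                          dialect: str = "matrix_text") -> None:
    """Write per-frame poses, either as matrix_text blocks or as the
    ground-truth CSV dialect (dropped column all zero)."""
    if dialect == "csv":
        frames = [AnnotatedFrame(
            obs=LandmarkObservation(i, np.full((N_LANDMARKS, 2), np.nan),
                                    np.zeros(N_LANDMARKS, bool)),
            truth=p) for i, p in enumerate(poses)]
        write_ground_truth_csv(frames, path)
        return
    if dialect != "matrix_text":
        raise ValueError(f"unknown dialect {dialect!r}")
    with open(path, "w", encoding="utf-8") as fh:
        for p in poses:
            R = euler_to_rotation(p)
            for row in R:
                fh.write(" ".join(f"{v:.12f}" for v in row) + "\n")
            fh.write(" ".join(f"{v:.6f}" for v in p.translation_mm) + "\n")
            fh.write("\n")


def read_pose_annotation(path, dialect: str = "matrix_text") -> list[HeadPose]:
    """Read per-frame poses from a matrix_text or CSV annotation file.

    matrix_text rotation matrices are converted to clinical Euler angles;
    matrices whose orthonormality defect exceeds 1e-3 are rejected, milder
    numerical defects are projected to the nearest rotation first.

    Raises
    ------
    ParseError
        Malformed or truncated input, with the offending line number.
    InvalidRotationError
        A rotation block that is not orthonormal within 1e-3.
    """
    if dialect == "csv":
        poses, _, _ = read_ground_truth_csv(path)
        return poses
    if dialect != "matrix_text":
        raise ValueError(f"unknown dialect {dialect!r}")
    numbered: list[tuple[int, list[float]]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            stripped = raw.strip()
            if not stripped:
                continue
            try:
                vals = [float(tok) for tok in stripped.split()]
            except ValueError:
                raise ParseError("not a numeric line", line=lineno) from None
            if len(vals) != 3:
                raise ParseError(f"expected 3 floats, found {len(vals)}",
                                 line=lineno)
            numbered.append((lineno, vals))
    if len(numbered) % 4 != 0:
        last = numbered[-1][0] if numbered else 0
        raise ParseError("truncated pose block (need 4 lines per frame)",
                         line=last)
    poses = []
    for b in range(0, len(numbered), 4):
        R = np.array([numbered[b][1], numbered[b + 1][1], numbered[b + 2][1]])
        t = numbered[b + 3][1]
        defect = np.linalg.norm(R.T @ R - np.eye(3))
        if defect > 1e-3:
            raise InvalidRotationError(
                f"rotation block starting at line {numbered[b][0]} is not "
                f"orthonormal (defect {defect:.3g})")
        U, _, Vt = np.linalg.svd(R)
        Rn = U @ Vt
        if np.linalg.det(Rn) < 0:
            U[:, -1] *= -1
            Rn = U @ Vt
        yaw, pitch, roll = rotation_to_euler(Rn)
        poses.append(HeadPose(yaw, pitch, roll, t[0], t[1], t[2]))
    return poses


def write_estimates_csv(estimates: Sequence[PoseEstimate], path,
                        frame_ids: Sequence[int] | None = None) -> None:
    """Write per-frame estimates (NaN pose fields for untracked frames)."""
    ids = frame_ids if frame_ids is not None else range(len(estimates))
    rows = []
    for fid, e in zip(ids, estimates):
        p = e.pose
        dist = p.distance_mm if e.tracked else float("nan")
        rows.append((fid, p.yaw_deg, p.pitch_deg, p.roll_deg,
                     p.tx_mm, p.ty_mm, p.tz_mm, dist,
                     e.confidence, int(e.tracked)))
    pd.DataFrame(rows, columns=ESTIMATE_COLUMNS).to_csv(
        path, index=False, lineterminator="\n")


def read_estimates_csv(path) -> tuple[list[PoseEstimate], list[int]]:
    """Read an estimate CSV back into PoseEstimate objects + frame ids."""
    df = pd.read_csv(path)
    missing = [c for c in ESTIMATE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"estimate table missing columns {missing}")
    ests, ids = [], []
    for r in df.itertuples():
        pose = HeadPose(r.yaw_deg, r.pitch_deg, r.roll_deg,
                        r.tx_mm, r.ty_mm, r.tz_mm)
        ests.append(PoseEstimate(pose=pose, confidence=float(r.confidence),
                                 residual_rms_norm=float("nan"),
                                 tracked=bool(r.tracked), n_visible=-1))
        ids.append(int(r.frame_id))
    return ests, ids


@dataclass(frozen=True)
class RunConfig:
    """Validated flat run configuration (see ``load_config``).

    Camera fields default to the standard webcam model (focal = image
    width); estimator fields mirror :class:`EstimatorConfig`; the
    remaining fields parameterise evaluation and agreement analysis.
    """

    image_width_px: int = 1920
    image_height_px: int = 1080
    focal_px: float | None = None
    max_iterations: int = 50
    convergence_tol_deg: float = 1e-6
    convergence_tol_mm: float = 1e-4
    min_visible_landmarks: int = 6
    confidence_threshold: float = 0.75
    residual_scale: float = 0.10
    min_confidence: float | None = None
    threshold_deg: float = 5.0
    bin_width_deg: float = 5.0
    dominance_threshold_deg: float = 10.0
    loa_multiplier: float = 1.96
    icc_mode: str = "average"
    seed: int = 0

    def camera(self) -> CameraModel:
        f = self.focal_px if self.focal_px is not None else float(self.image_width_px)
        return CameraModel(focal_px=float(f),
                           principal_point_px=(self.image_width_px / 2.0,
                                               self.image_height_px / 2.0),
                           image_size_px=(self.image_width_px,
                                          self.image_height_px))

    def estimator(self) -> EstimatorConfig:
        return EstimatorConfig(
            max_iterations=self.max_iterations,
            convergence_tol_deg=self.convergence_tol_deg,
            convergence_tol_mm=self.convergence_tol_mm,
            min_visible_landmarks=self.min_visible_landmarks,
            confidence_threshold=self.confidence_threshold,
            residual_scale=self.residual_scale)


def load_config(path) -> RunConfig:
    """Load a flat key-value YAML config, rejecting unknown keys.

    A typo in a threshold silently falling back to a default could corrupt
    a clinical-style analysis, so unknown keys are a named error rather
    than a warning.
    """
    text = Path(path).read_text(encoding="utf-8")
    data = yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError("config must be a flat key: value mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = sorted(set(data) - known)
    if unknown:
        raise ConfigError(f"unknown config key(s): {', '.join(unknown)}")
    for key, val in data.items():
        if isinstance(val, (dict, list)):
            raise ConfigError(f"config key {key!r} must be a scalar")
    try:
        cfg = RunConfig(**data)
        cfg.camera()
        cfg.estimator()
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc
    return cfg
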