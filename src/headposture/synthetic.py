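"""Synthetic-data generators: annotated landmark sequences and the
fixation-target protocol.

Everything the rest of the package needs for validation is generated here,
with no external downloads: subjects (perturbed copies of the canonical
face with a controllable true interpupillary distance), annotated frame
sequences under the stressors seen in real head-pose video (pixel noise,
partial occlusion, dropped frames), and the 43-posture fixation-target
protocol used for comparing the tracker against a mechanical inclinometer
device (yaw and pitch targets every 5° out to ±40°, roll lines every 10°
from −40° to +40°).

All generators are deterministic per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import BehindCameraError
from .facemodel import (
    N_LANDMARKS,
    CameraModel,
    FaceModel,
    HeadPose,
    LandmarkObservation,
    canonical_model,
    default_camera,
    project,
)

__all__ = [
    "SyntheticSubject",
    "AnnotatedFrame",
    "SequenceSpec",
    "make_subject",
    "render_sequence",
    "crom_protocol_poses",
    "ProtocolTrial",
    "simulate_protocol_study",
    "DEFAULT_STANDOFF_MM",
]

#: Default subject-to-camera distance, mm (seated subject ~1.2 m from the
#: webcam, the geometry of a typical clinic set-up).
DEFAULT_STANDOFF_MM = 1200.0


@dataclass(frozen=True)
class SyntheticSubject:
    """A randomised face shape: canonical model + seeded Gaussian
    per-point perturbation, rescaled to the subject's true IPD."""

    model: FaceModel
    shape_sd_mm: float
    ipd_mm: float
    seed: int


@dataclass(frozen=True)
class AnnotatedFrame:
    """An observation paired with its ground-truth pose."""

    obs: LandmarkObservation
    truth: HeadPose
    dropped: bool = False


@dataclass(frozen=True)
class SequenceSpec:
    """Recipe for a rendered sequence.

    noise_sd_px
        i.i.d. Gaussian pixel noise added to every visible landmark.
    noise_sd_px_per_deg
        Optional pose-dependent degradation: extra noise SD per degree of
        pose eccentricity (the largest absolute Euler angle), emulating
        the empirical pattern that tracking accuracy decays with more
        extreme head posture.
    occlusion_rate
        Fraction of landmarks hidden (independently) per frame.
    drop_rate
        Fraction of frames dropped entirely (zero visible landmarks).
    """

    poses: tuple[HeadPose, ...]
    noise_sd_px: float = 0.0
    occlusion_rate: float = 0.0
    drop_rate: float = 0.0
    camera: CameraModel = field(default_factory=default_camera)
    seed: int = 0
    noise_sd_px_per_deg: float = 0.0

    def __post_init__(self):
        if len(self.poses) < 1:
            raise ValueError("need at least one pose")
        for name in ("occlusion_rate", "drop_rate"):
            r = getattr(self, name)
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.noise_sd_px < 0 or self.noise_sd_px_per_deg < 0:
            raise ValueError("noise SDs must be non-negative")

    @property
    def n_frames(self) -> int:
        return len(self.poses)


def make_subject(seed: int = 0, shape_sd_mm: float = 0.0,
                 ipd_mm: float = 65.0) -> SyntheticSubject:
    """Draw a synthetic subject.

    Adds isotropic Gaussian noise (SD ``shape_sd_mm``) to every canonical
    landmark, then rescales uniformly so the pupil-centroid distance equals
    ``ipd_mm`` exactly. ``shape_sd_mm = 0, ipd_mm = 65`` reproduces the
    canonical model bit for bit.
    """
    if shape_sd_mm < 0:
        raise ValueError("shape_sd_mm must be >= 0")
    if not ipd_mm > 0:
        raise ValueError("ipd_mm must be positive")
    base = canonical_model()
    pts = base.points.copy()
    if shape_sd_mm > 0:
        rng = np.random.default_rng(seed)
        pts = pts + rng.normal(0.0, shape_sd_mm, size=pts.shape)
    interim = FaceModel(pts, base.region_labels,
                        base.pupil_left_index_set, base.pupil_right_index_set)
    scale = ipd_mm / interim.interpupillary_distance_mm
    if scale != 1.0:
        centre = 0.5 * (interim.pupil_left + interim.pupil_right)
        pts = (pts - centre) * scale
    model = FaceModel(pts, base.region_labels,
                      base.pupil_left_index_set, base.pupil_right_index_set)
    return SyntheticSubject(model=model, shape_sd_mm=shape_sd_mm,
                            ipd_mm=ipd_mm, seed=seed)


def render_sequence(subject: SyntheticSubject,
                    spec: SequenceSpec) -> list[AnnotatedFrame]:
    """Render an annotated frame sequence.

    Per frame: project the subject at the trajectory pose, add pixel noise,
    hide a random landmark subset, and possibly drop the frame (empty
    observation). Ground truth is always recorded, dropped or not.

    Raises
    ------
    BehindCameraError
        If any trajectory pose puts the face behind the camera.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_frames
    drop = rng.random(n) < spec.drop_rate
    frames: list[AnnotatedFrame] = []
    for i, pose in enumerate(spec.poses):
        clean = project(subject.model, pose, spec.camera, frame_id=i)
        if drop[i]:
            frames.append(AnnotatedFrame(
                obs=LandmarkObservation(
                    frame_id=i,
                    points_px=np.full((N_LANDMARKS, 2), np.nan),
                    visible=np.zeros(N_LANDMARKS, dtype=bool)),
                truth=pose, dropped=True))
            # burn the per-frame draws so dropping frames does not shift
            # the noise stream of later frames
            rng.normal(size=(N_LANDMARKS, 2))
            rng.random(N_LANDMARKS)
            continue
        sd = spec.noise_sd_px + spec.noise_sd_px_per_deg * float(
            np.max(np.abs(pose.angles_deg)))
        pts = clean.points_px + sd * rng.normal(size=(N_LANDMARKS, 2))
        hidden = rng.random(N_LANDMARKS) < spec.occlusion_rate
        pts[hidden] = np.nan
        frames.append(AnnotatedFrame(
            obs=LandmarkObservation(frame_id=i, points_px=pts,
                                    visible=~hidden),
            truth=pose, dropped=False))
    return frames


@dataclass(frozen=True)
class ProtocolTrial:
    """One fixation target of the protocol: which axis it probes and the
    target eccentricity in degrees."""

    axis: str
    target_deg: float

    def to_pose(self, tz_mm: float = DEFAULT_STANDOFF_MM) -> HeadPose:
        kw = {"yaw": "yaw_deg", "pitch": "pitch_deg", "roll": "roll_deg"}
        return HeadPose(**{kw[self.axis]: self.target_deg}, tz_mm=tz_mm)


def crom_protocol_poses(max_yaw_deg: float = 40.0, yaw_step: float = 5.0,
                        max_pitch_deg: float = 40.0, pitch_step: float = 5.0,
                        max_roll_deg: float = 40.0, roll_step: float = 10.0,
                        ) -> list[ProtocolTrial]:
    """Enumerate the fixation-target protocol.

    Yaw and pitch series run 0, ±step … ±max with the other axes at zero
    (the null target appears once per series); the roll series runs −max …
    +max in ``roll_step`` increments. Defaults give 17 + 17 + 9 = 43
    distinct postures per subject.
    """
    def series(maximum: float, step: float) -> list[float]:
        if step <= 0 or maximum < 0:
            raise ValueError("steps must be positive, ranges non-negative")
        k = maximum / step
        if abs(k - round(k)) > 1e-9:
            raise ValueError("step must divide the range")
        vals = [i * step for i in range(-int(round(k)), int(round(k)) + 1)]
        return vals

    trials = [ProtocolTrial("yaw", v) for v in series(max_yaw_deg, yaw_step)]
    trials += [ProtocolTrial("pitch", v) for v in series(max_pitch_deg, pitch_step)]
    trials += [ProtocolTrial("roll", v) for v in series(max_roll_deg, roll_step)]
    return trials


def simulate_protocol_study(n_subjects: int = 4,
                            pose_execution_sd_deg: float = 3.0,
                            instrument_noise_a_sd: float = 1.0,
                            instrument_noise_b_sd: float = 1.0,
                            seed: int = 0,
                            trials: Sequence[ProtocolTrial] | None = None,
                            ) -> pd.DataFrame:
    """Simulate the two-instrument comparison study.

    For each subject × trial a true executed pose is drawn (target plus
    Gaussian execution error — subjects fixate targets with their heads,
    they are not clamped to the target angle), then each instrument reads
    the true pose plus its own independent Gaussian noise.

    Returns a table with columns subject, axis, target_deg,
    instrument_a_deg (comparator, e.g. the mechanical device) and
    instrument_b_deg (the tracker). Defaults give 4 × 43 = 172 rows.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    for v in (pose_execution_sd_deg, instrument_noise_a_sd, instrument_noise_b_sd):
        if v < 0:
            raise ValueError("all SDs must be >= 0")
    trials = list(trials) if trials is not None else crom_protocol_poses()
    rng = np.random.default_rng(seed)
    rows = []
    for subject in range(n_subjects):
        for trial in trials:
            true = trial.target_deg + rng.normal(0.0, pose_execution_sd_deg)
            a = true + rng.normal(0.0, instrument_noise_a_sd)
            b = true + rng.normal(0.0, instrument_noise_b_sd)
            rows.append((subject, trial.axis, trial.target_deg, a, b))
    return pd.DataFrame(rows, columns=["subject", "axis", "target_deg",
                                       "instrument_a_deg", "instrument_b_deg"])
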