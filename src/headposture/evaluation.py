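"""Accuracy evaluation of per-frame pose estimates against ground truth.

Implements the validation machinery used when benchmarking a tracker
against annotated head-pose video: per-frame absolute angular errors (with
wrap-around), confidence-filtered mean/median summaries, derivation of the
symmetric operational range within which mean combined error stays under a
clinical threshold, single-axis subanalysis, predicted-vs-actual heat-map
binning, and extraction of repeated-pose matrices for reliability (ICC)
analysis.

Conventions: the *combined* error of a frame is the mean of its three
per-axis absolute errors, so the combined mean over frames equals the
grand mean of all per-axis errors. Untracked frames are excluded from the
error statistics but counted, mirroring the practice of reporting a
confident-recognition rate separately from accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .estimator import PoseEstimate
from .exceptions import (
    AlignmentError,
    EmptySummaryError,
    InsufficientRepeatsError,
)
from .facemodel import HeadPose, wrap_angle_deg

__all__ = [
    "AXES",
    "ErrorSummary",
    "RangeBin",
    "OperationalRange",
    "absolute_errors",
    "summarize_errors",
    "operational_range",
    "single_axis_subset",
    "heatmap_bins",
    "repeated_pose_icc_prep",
]

AXES = ("yaw", "pitch", "roll")


@dataclass(frozen=True)
class ErrorSummary:
    """Mean/median absolute errors in degrees, per axis and combined."""

    mean_deg: dict
    median_deg: dict
    combined_mean_deg: float
    combined_median_deg: float
    n_frames_used: int
    n_frames_total: int
    filter_description: str

    @property
    def fraction_used(self) -> float:
        return self.n_frames_used / self.n_frames_total

    def summary(self) -> str:
        lines = [
            "Absolute head-posture error (degrees)",
            "=" * 45,
            f"{'':10s}{'mean':>10s}{'median':>10s}",
        ]
        for ax in AXES:
            lines.append(f"{ax:10s}{self.mean_deg[ax]:10.3f}"
                         f"{self.median_deg[ax]:10.3f}")
        lines.append(f"{'combined':10s}{self.combined_mean_deg:10.3f}"
                     f"{self.combined_median_deg:10.3f}")
        lines.append(f"frames used: {self.n_frames_used}/{self.n_frames_total}"
                     f" ({self.fraction_used:.1%}); filter: "
                     f"{self.filter_description}")
        return "\n".join(lines)


@dataclass(frozen=True)
class RangeBin:
    """One bin of the per-axis error profile."""

    axis: str
    center_deg: float
    width_deg: float
    mean_combined_error_deg: float
    n_frames: int


@dataclass(frozen=True)
class OperationalRange:
    """Largest symmetric per-axis ranges with sub-threshold mean error."""

    limits_deg: dict
    threshold_deg: float
    bin_width_deg: float
    bins: tuple[RangeBin, ...]
    warning: dict

    def summary(self) -> str:
        parts = [f"±{self.limits_deg[ax]:.0f}° {ax}" for ax in AXES]
        return (f"operational range (< {self.threshold_deg:g}° mean combined "
                f"error): " + ", ".join(parts))


def absolute_errors(estimates: Sequence[PoseEstimate],
                    truths: Sequence[HeadPose],
                    frame_ids: Sequence[int] | None = None) -> pd.DataFrame:
    """Per-frame per-axis absolute angular errors.

    Differences are taken on the circle (wrapped into (−180, 180]) before
    the absolute value. Returns one row per frame with columns yaw, pitch,
    roll (NaN for untracked frames), confidence and tracked, indexed by
    frame_id.

    Raises
    ------
    AlignmentError
        If the two series differ in length (they must align frame by frame).
    """
    if len(estimates) != len(truths):
        raise AlignmentError(
            f"{len(estimates)} estimates vs {len(truths)} ground-truth poses")
    if frame_ids is not None and len(frame_ids) != len(truths):
        raise AlignmentError("frame_ids length mismatch")
    idx = list(frame_ids) if frame_ids is not None else list(range(len(truths)))
    rows = []
    for est, truth in zip(estimates, truths):
        if est.tracked:
            err = np.abs(wrap_angle_deg(est.pose.angles_deg - truth.angles_deg))
            rows.append([*err, est.confidence, True])
        else:
            rows.append([np.nan, np.nan, np.nan, est.confidence, False])
    df = pd.DataFrame(rows, columns=[*AXES, "confidence", "tracked"],
                      index=pd.Index(idx, name="frame_id"))
    df["tracked"] = df["tracked"].astype(bool)
    return df


def summarize_errors(errors: pd.DataFrame,
                     min_confidence: float | None = None) -> ErrorSummary:
    """Mean/median summary over frames passing the confidence filter.

    ``min_confidence = None`` keeps every tracked frame. The combined
    error of a frame is the mean of its three axis errors; the combined
    mean/median are taken over frames.

    Raises
    ------
    EmptySummaryError
        If no frame survives the filter.
    """
    total = len(errors)
    kept = errors[errors["tracked"]]
    desc = "tracked frames"
    if min_confidence is not None:
        kept = kept[kept["confidence"] >= min_confidence]
        desc = f"tracked frames with confidence >= {min_confidence:g}"
    if len(kept) == 0:
        raise EmptySummaryError("no frames pass the filter: " + desc)
    per_axis = kept[list(AXES)]
    combined = per_axis.mean(axis=1)
    return ErrorSummary(
        mean_deg={ax: float(per_axis[ax].mean()) for ax in AXES},
        median_deg={ax: float(per_axis[ax].median()) for ax in AXES},
        combined_mean_deg=float(combined.mean()),
        combined_median_deg=float(combined.median()),
        n_frames_used=int(len(kept)),
        n_frames_total=int(total),
        filter_description=desc,
    )


def _bin_center(values: np.ndarray, width: float) -> np.ndarray:
    return np.round(values / width) * width


def operational_range(errors: pd.DataFrame, truths: Sequence[HeadPose],
                      threshold_deg: float = 5.0,
                      bin_width_deg: float = 5.0) -> OperationalRange:
    """Largest symmetric ±L per axis with sub-threshold binned error.

    Frames are binned by the true value of each axis (bins centred on
    multiples of the bin width); L is the largest multiple of the width
    such that every populated bin with |centre| ≤ L has mean combined
    absolute error below the threshold. If even the central bin fails the
    axis gets range 0 and a warning flag.
    """
    if not threshold_deg > 0:
        raise ValueError("threshold_deg must be positive")
    kept = errors[errors["tracked"]]
    combined = kept[list(AXES)].mean(axis=1)
    truth_arr = np.array([t.angles_deg for t in truths])
    truth_df = pd.DataFrame(truth_arr, columns=AXES,
                            index=errors.index)[errors["tracked"]]
    limits: dict = {}
    warning: dict = {}
    bins: list[RangeBin] = []
    for k, ax in enumerate(AXES):
        centers = _bin_center(truth_df[ax].to_numpy(), bin_width_deg)
        prof = pd.DataFrame({"center": centers, "err": combined.to_numpy()})
        grouped = prof.groupby("center")["err"].agg(["mean", "size"])
        for c, row in grouped.iterrows():
            bins.append(RangeBin(ax, float(c), bin_width_deg,
                                 float(row["mean"]), int(row["size"])))
        max_extent = float(np.max(np.abs(grouped.index.to_numpy())))
        L = 0.0
        failed = False
        n_steps = int(round(max_extent / bin_width_deg))
        for step in range(0, n_steps + 1):
            cand = step * bin_width_deg
            sel = grouped[np.abs(grouped.index.to_numpy()) <= cand + 1e-9]
            if len(sel) == 0:
                L = cand          # no populated bin inside: vacuously fine
            elif np.all(sel["mean"] < threshold_deg):
                L = cand
            else:
                failed = True
                break
        limits[ax] = L
        warning[ax] = failed and L == 0.0
    return OperationalRange(limits_deg=limits, threshold_deg=threshold_deg,
                            bin_width_deg=bin_width_deg, bins=tuple(bins),
                            warning=warning)


def single_axis_subset(truths: Sequence[HeadPose],
                       dominance_threshold_deg: float = 10.0) -> dict:
    """Partition frames by the axis on which the pose predominantly deviates.

    A frame belongs to axis A iff |A| strictly exceeds the magnitudes of
    both other axes and those two magnitudes are at most the dominance
    threshold. Frames that match no axis (near-primary position, ties, or
    two large axes) are left unassigned.

    Returns a dict axis -> list of frame indices, plus key "unassigned".
    """
    out: dict = {ax: [] for ax in AXES}
    out["unassigned"] = []
    for i, t in enumerate(truths):
        mags = np.abs(t.angles_deg)
        order = np.argsort(mags)[::-1]
        dominant, second, third = order[0], order[1], order[2]
        if (mags[dominant] > mags[second]
                and mags[second] <= dominance_threshold_deg
                and mags[third] <= dominance_threshold_deg):
            out[AXES[dominant]].append(i)
        else:
            out["unassigned"].append(i)
    return out


def heatmap_bins(predicted: Sequence[HeadPose], actual: Sequence[HeadPose],
                 bin_width_deg: float = 5.0) -> dict:
    """Joint (actual, predicted) histograms per axis.

    Returns a dict axis -> (counts, edges) where counts[i, j] is the
    number of frames whose actual value falls in edge bin i and predicted
    value in edge bin j; counts sum to the number of frames.
    """
    if len(predicted) != len(actual):
        raise AlignmentError("predicted/actual length mismatch")
    pred = np.array([p.angles_deg for p in predicted])
    act = np.array([a.angles_deg for a in actual])
    out = {}
    for k, ax in enumerate(AXES):
        lo = np.floor(min(pred[:, k].min(), act[:, k].min())
                      / bin_width_deg) * bin_width_deg
        hi = np.ceil(max(pred[:, k].max(), act[:, k].max())
                     / bin_width_deg) * bin_width_deg
        if hi <= lo:
            hi = lo + bin_width_deg
        edges = np.arange(lo, hi + bin_width_deg / 2, bin_width_deg)
        counts, _, _ = np.histogram2d(act[:, k], pred[:, k],
                                      bins=[edges, edges])
        out[ax] = (counts.astype(int), edges)
    return out


def repeated_pose_icc_prep(truths: Sequence[HeadPose],
                           estimates: Sequence[PoseEstimate],
                           axis: str,
                           pose_values: Sequence[float],
                           tolerance_deg: float = 2.5,
                           n_required: int = 8) -> np.ndarray:
    """Collect a (poses × repeats) matrix of repeated estimates.

    For each requested pose value, gathers tracked estimates whose true
    pose deviates from the primary position only on ``axis`` (the other
    axes within ``tolerance_deg``) and whose true value on the axis is
    within ``tolerance_deg`` of the requested value; keeps the first
    ``n_required`` per pose. The matrix feeds the ICC computation.

    Raises
    ------
    InsufficientRepeatsError
        Naming the first pose with fewer than ``n_required`` repeats.
    """
    k = AXES.index(axis)
    others = [j for j in range(3) if j != k]
    matrix = np.zeros((len(pose_values), n_required))
    for row, target in enumerate(pose_values):
        found = []
        for truth, est in zip(truths, estimates):
            if not est.tracked:
                continue
            ang = truth.angles_deg
            if (abs(ang[k] - target) <= tolerance_deg
                    and all(abs(ang[j]) <= tolerance_deg for j in others)):
                found.append(est.pose.angles_deg[k])
                if len(found) == n_required:
                    break
        if len(found) < n_required:
            raise InsufficientRepeatsError(
                f"{axis} = {target}°: {len(found)} repeats < required "
                f"{n_required}")
        matrix[row] = found
    return matrix
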