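"""Segmentation scoring: per-frame IoU and per-video average IoU.

Model quality is judged per video: the intersection-over-union (Jaccard
index) of predicted vs. ground-truth nerve masks is computed for every
sampled frame and averaged over the video.  Frames where the model
predicted nothing (empty masks) count as IoU 0 by default so that failed
frames penalize the average; ``skip_invalid=True`` excludes them instead.
Two empty masks score 1 — nothing to segment and nothing segmented — so
the contract is total.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import MaskFrame, MaskSequence

__all__ = ["IoUReport", "compute_iou", "evaluate_video"]


@dataclass
class IoUReport:
    """Per-frame IoUs plus the per-video average."""

    per_frame: list[tuple[int, float, bool]]  # (frame_index, iou, valid)
    video_average_iou: float
    n_frames: int
    policy: str  # invalid frames "counted" as 0 or "skipped"


def compute_iou(a: MaskFrame | np.ndarray, b: MaskFrame | np.ndarray) -> float:
    """Intersection over union of two same-size binary masks."""
    pa = (a.pixels if isinstance(a, MaskFrame) else np.asarray(a)) > 0
    pb = (b.pixels if isinstance(b, MaskFrame) else np.asarray(b)) > 0
    if pa.shape != pb.shape:
        raise ValueError(f"mask dimensions differ: {pa.shape} vs {pb.shape}")
    union = np.count_nonzero(pa | pb)
    if union == 0:
        return 1.0
    return np.count_nonzero(pa & pb) / union


def evaluate_video(
    pred: MaskSequence, truth: MaskSequence, skip_invalid: bool = False
) -> IoUReport:
    """Score a predicted sequence against ground truth, frame by frame.

    A prediction frame is invalid when it is empty while the truth frame
    is not.  With ``skip_invalid`` those frames are excluded from the
    average (and from ``n_frames``); otherwise they contribute IoU 0.
    """
    if len(pred) != len(truth):
        raise ValueError(
            f"sequence lengths differ: {len(pred)} predicted vs {len(truth)} truth"
        )
    if pred.shape != truth.shape:
        raise ValueError(f"mask dimensions differ: {pred.shape} vs {truth.shape}")
    per_frame: list[tuple[int, float, bool]] = []
    scores: list[float] = []
    for p, t in zip(pred.frames, truth.frames):
        valid = not (p.is_empty() and not t.is_empty())
        iou = compute_iou(p, t)
        per_frame.append((t.frame_index, iou, valid))
        if valid or not skip_invalid:
            scores.append(iou)
    if not scores:
        raise ValueError("no frames left to average after skipping invalid ones")
    return IoUReport(
        per_frame=per_frame,
        video_average_iou=float(np.mean(scores)),
        n_frames=len(scores),
        policy="skipped" if skip_invalid else "counted",
    )
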