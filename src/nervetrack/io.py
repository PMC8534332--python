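"""Domain containers and file I/O for mask sequences, candidates and tables.

Coordinate convention used throughout the package: ``x`` is the column index
increasing rightward, ``y`` is the row index increasing downward, both
0-based.  The anatomical meaning of the axes (e.g. +x toward the scaphoid
side, +y toward the palmar side) is carried only as free-text
``axis_labels`` metadata and never interpreted by the geometry code, so the
pipeline stays device- and probe-orientation independent.

Mask sequences are stored either as a directory of per-frame 8-bit
single-channel images (PNG, lexicographic name order) or as a multipage
TIFF stack; any source pixel value > 0 maps to foreground.  Acquisition
metadata lives in a small YAML sidecar (``px_per_cm`` mandatory; ``fps``
defaults to 38 frames/s and ``frame_step`` to 4, the usual acquisition and
frame-picking settings for dynamic wrist ultrasound).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

__all__ = [
    "MaskFrame",
    "SequenceMeta",
    "MaskSequence",
    "CandidateSet",
    "PhaseAnnotation",
    "MetadataError",
    "SequenceError",
    "read_mask_sequence",
    "write_mask_sequence",
    "read_meta",
    "write_meta",
    "write_metrics_table",
    "read_metrics_table",
    "write_candidates",
    "read_candidates",
    "read_phase_annotation",
    "write_phase_annotation",
]

#: Image file suffixes accepted when reading a directory of per-frame masks.
_FRAME_SUFFIXES = (".png", ".tif", ".tiff", ".bmp")

#: Columns of the per-frame metrics table, in file order.
METRICS_COLUMNS = [
    "frame_index",
    "time_s",
    "csa_px",
    "csa_cm2",
    "cx_px",
    "cy_px",
    "cx_cm",
    "cy_cm",
    "perimeter_px",
    "perimeter_cm",
    "circularity",
    "step_displacement_cm",
]


class MetadataError(ValueError):
    """Missing or inconsistent sidecar metadata."""


class SequenceError(ValueError):
    """Structurally invalid mask sequence (empty, ragged dimensions, ...)."""


def _as_binary(pixels: np.ndarray) -> np.ndarray:
    arr = np.asarray(pixels)
    if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] < 1:
        raise SequenceError(f"mask must be a 2-D grid, got shape {arr.shape}")
    return (arr > 0).astype(np.uint8)


@dataclass(frozen=True)
class MaskFrame:
    """One binary segmentation mask on an ``h x w`` pixel grid.

    ``pixels`` holds exactly 0/1 values; any positive source value is
    treated as foreground on construction.  An all-zero frame is allowed
    (a failed prediction) and is reported by :meth:`is_empty`.
    """

    pixels: np.ndarray
    frame_index: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "pixels", _as_binary(self.pixels))
        if self.frame_index < 0:
            raise ValueError("frame_index must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def is_empty(self) -> bool:
        return not bool(self.pixels.any())

    def area(self) -> int:
        return int(self.pixels.sum())


@dataclass(frozen=True)
class SequenceMeta:
    """Acquisition metadata for a mask sequence.

    Parameters
    ----------
    px_per_cm:
        Image scale, pixels per centimeter (> 0).  There is no universal
        default: it depends on the ultrasound depth setting, so it must be
        supplied with the data.
    fps:
        Acquisition frame rate of the source video in frames/s (default 38).
    frame_step:
        Every ``frame_step``-th acquired frame is present in the sequence
        (default 4), so the effective sampling interval is
        ``dt = frame_step / fps`` seconds.
    axis_labels:
        Optional ``(label_for_+x, label_for_+y)`` anatomical annotation.
    """

    px_per_cm: float
    fps: float = 38.0
    frame_step: int = 4
    axis_labels: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        if not self.px_per_cm > 0:
            raise MetadataError("px_per_cm must be positive")
        if not self.fps > 0:
            raise MetadataError("fps must be positive")
        if int(self.frame_step) != self.frame_step or self.frame_step < 1:
            raise MetadataError("frame_step must be an integer >= 1")

    @property
    def dt(self) -> float:
        """Effective sampling interval in seconds."""
        return self.frame_step / self.fps


@dataclass
class MaskSequence:
    """Ordered mask frames sharing one grid, plus acquisition metadata."""

    meta: SequenceMeta
    frames: list[MaskFrame]

    def __post_init__(self) -> None:
        if not self.frames:
            raise SequenceError("mask sequence must contain at least one frame")
        shape = self.frames[0].shape
        for f in self.frames[1:]:
            if f.shape != shape:
                raise SequenceError(
                    f"inconsistent frame dimensions: {f.shape} != {shape} "
                    f"(frame_index {f.frame_index})"
                )
        idx = [f.frame_index for f in self.frames]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise SequenceError("frame_index must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames[0].shape

    def times(self) -> np.ndarray:
        """Frame times in seconds, ``position * dt`` from the first frame."""
        return np.arange(len(self.frames)) * self.meta.dt

    @classmethod
    def from_array(cls, stack: np.ndarray, meta: SequenceMeta) -> "MaskSequence":
        """Build a sequence from an ``(n, h, w)`` array of masks."""
        stack = np.asarray(stack)
        if stack.ndim != 3:
            raise SequenceError("stack must be 3-D (frames, rows, cols)")
        frames = [MaskFrame(stack[i], frame_index=i) for i in range(stack.shape[0])]
        return cls(meta=meta, frames=frames)

    def to_array(self) -> np.ndarray:
        return np.stack([f.pixels for f in self.frames])


@dataclass
class CandidateSet:
    """Scored candidate masks for one frame (instance-segmentation output)."""

    frame_index: int
    candidates: list[tuple[np.ndarray, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        checked = []
        for mask, score in self.candidates:
            if not (0.0 <= score <= 1.0):
                raise ValueError(f"candidate score {score} outside [0, 1]")
            checked.append((_as_binary(mask), float(score)))
        self.candidates = checked


@dataclass
class PhaseAnnotation:
    """Manually annotated flexion/extension intervals.

    ``intervals`` is an ordered list of ``(start_frame_pos, end_frame_pos,
    label)`` with labels alternating between ``"flexion"`` and
    ``"extension"`` and half-open touching allowed (an interval may start
    where the previous one ends).
    """

    intervals: list[tuple[int, int, str]]

    def __post_init__(self) -> None:
        prev_end = None
        prev_label = None
        for start, end, label in self.intervals:
            if label not in ("flexion", "extension"):
                raise ValueError(f"unknown phase label {label!r}")
            if end <= start:
                raise ValueError(f"interval ({start}, {end}) has no extent")
            if prev_end is not None and start < prev_end:
                raise ValueError("annotation intervals overlap")
            if prev_label is not None and label == prev_label:
                raise ValueError("annotation labels must alternate")
            prev_end, prev_label = end, label


# ---------------------------------------------------------------------------
# metadata sidecar


def read_meta(path: str | Path) -> SequenceMeta:
    """Read a YAML/key:value metadata sidecar into :class:`SequenceMeta`."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise MetadataError(f"metadata file {path} is not a key:value mapping")
    if "px_per_cm" not in raw:
        raise MetadataError(f"metadata file {path} lacks mandatory key 'px_per_cm'")
    labels = raw.get("axis_labels")
    if labels is not None:
        labels = tuple(str(v) for v in labels)
        if len(labels) != 2:
            raise MetadataError("axis_labels must name the +x and +y senses")
    return SequenceMeta(
        px_per_cm=float(raw["px_per_cm"]),
        fps=float(raw.get("fps", 38.0)),
        frame_step=int(raw.get("frame_step", 4)),
        axis_labels=labels,
    )


def write_meta(meta: SequenceMeta, path: str | Path) -> None:
    data = dataclasses.asdict(meta)
    if data["axis_labels"] is not None:
        data["axis_labels"] = list(data["axis_labels"])
    else:
        del data["axis_labels"]
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


# ---------------------------------------------------------------------------
# mask sequences


def _read_stack(path: Path) -> np.ndarray:
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in _FRAME_SUFFIXES
        )
        if not files:
            raise SequenceError(f"no frame images found in directory {path}")
        frames = [np.atleast_2d(np.squeeze(iio.imread(p))) for p in files]
        shapes = {f.shape for f in frames}
        if len(shapes) > 1:
            raise SequenceError(f"inconsistent frame dimensions in {path}: {shapes}")
        return np.stack(frames)
    arr = tifffile.imread(path) if path.suffix.lower() in (".tif", ".tiff") else iio.imread(path)
    arr = np.squeeze(np.asarray(arr))
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise SequenceError(f"cannot interpret {path} as a stack of 2-D masks")
    return arr


def read_mask_sequence(path: str | Path, meta_path: str | Path) -> MaskSequence:
    """Read a mask sequence (image directory or multipage TIFF) + sidecar."""
    meta = read_meta(meta_path)
    stack = _read_stack(Path(path))
    return MaskSequence.from_array(stack, meta)


def write_mask_sequence(
    seq: MaskSequence, path: str | Path, meta_path: str | Path | None = None
) -> None:
    """Write a sequence as a multipage TIFF (``.tif``) or a PNG directory."""
    path = Path(path)
    stack = (seq.to_array() * 255).astype(np.uint8)
    if path.suffix.lower() in (".tif", ".tiff"):
        path.parent.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(path, stack, photometric="minisblack")
    else:
        path.mkdir(parents=True, exist_ok=True)
        for i, frame in enumerate(stack):
            iio.imwrite(path / f"frame_{i:05d}.png", frame)
    if meta_path is not None:
        write_meta(seq.meta, meta_path)


# ---------------------------------------------------------------------------
# metrics tables


def write_metrics_table(records: Sequence, path: str | Path) -> None:
    """Write per-frame morphology records as CSV (header + one row/frame).

    Floats are printed with 17 significant digits so a read-back reproduces
    them bit-exactly; invalid frames carry empty metric cells.
    """
    if not records:
        raise ValueError("no records to write")
    rows = []
    for r in records:
        rows.append(
            {
                "frame_index": r.frame_index,
                "time_s": r.time_s,
                "csa_px": r.csa_px if r.valid else np.nan,
                "csa_cm2": r.csa_cm2,
                "cx_px": r.centroid_px[0] if r.valid else np.nan,
                "cy_px": r.centroid_px[1] if r.valid else np.nan,
                "cx_cm": r.centroid_cm[0] if r.valid else np.nan,
                "cy_cm": r.centroid_cm[1] if r.valid else np.nan,
                "perimeter_px": r.perimeter_px,
                "perimeter_cm": r.perimeter_cm,
                "circularity": r.circularity,
                "step_displacement_cm": r.step_displacement_cm,
            }
        )
    df = pd.DataFrame(rows, columns=METRICS_COLUMNS)
    df.to_csv(path, index=False, float_format="%.17g")


def read_metrics_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(METRICS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"metrics table {path} lacks columns {sorted(missing)}")
    return df


def records_from_table(df: pd.DataFrame) -> list:
    """Rebuild per-frame morphology records from a metrics table."""
    from .morphology import MorphRecord

    records = []
    for row in df.itertuples(index=False):
        valid = bool(np.isfinite(row.circularity))
        records.append(
            MorphRecord(
                frame_index=int(row.frame_index),
                time_s=float(row.time_s),
                csa_px=int(row.csa_px) if np.isfinite(row.csa_px) else 0,
                csa_cm2=float(row.csa_cm2),
                centroid_px=(float(row.cx_px), float(row.cy_px)),
                centroid_cm=(float(row.cx_cm), float(row.cy_cm)),
                perimeter_px=float(row.perimeter_px),
                perimeter_cm=float(row.perimeter_cm),
                circularity=float(row.circularity),
                step_displacement_cm=float(row.step_displacement_cm),
                valid=valid,
            )
        )
    return records


# ---------------------------------------------------------------------------
# candidate sets


def write_candidates(
    candidate_sets: Sequence[CandidateSet], out_dir: str | Path
) -> None:
    """Serialize candidate sets: one mask stack per frame + a score table."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for cs in candidate_sets:
        if cs.candidates:
            stack = np.stack([m for m, _ in cs.candidates]).astype(np.uint8) * 255
            tifffile.imwrite(
                out_dir / f"candidates_{cs.frame_index:05d}.tif",
                stack,
                photometric="minisblack",
            )
        for ci, (_, score) in enumerate(cs.candidates):
            rows.append(
                {"frame_index": cs.frame_index, "candidate_index": ci, "score": score}
            )
    pd.DataFrame(
        rows, columns=["frame_index", "candidate_index", "score"]
    ).to_csv(out_dir / "scores.csv", index=False, float_format="%.17g")


def read_candidates(in_dir: str | Path) -> list[CandidateSet]:
    in_dir = Path(in_dir)
    scores = pd.read_csv(in_dir / "scores.csv")
    sets: list[CandidateSet] = []
    for frame_index, grp in scores.groupby("frame_index", sort=True):
        stack_path = in_dir / f"candidates_{int(frame_index):05d}.tif"
        stack = tifffile.imread(stack_path)
        if stack.ndim == 2:
            stack = stack[None]
        grp = grp.sort_values("candidate_index")
        cands = [
            (stack[int(ci)], float(s))
            for ci, s in zip(grp["candidate_index"], grp["score"])
        ]
        sets.append(CandidateSet(frame_index=int(frame_index), candidates=cands))
    return sets


# ---------------------------------------------------------------------------
# phase annotations


def read_phase_annotation(path: str | Path) -> PhaseAnnotation:
    """Read a ``start,end,label`` CSV into a :class:`PhaseAnnotation`."""
    df = pd.read_csv(path)
    for col in ("start", "end", "label"):
        if col not in df.columns:
            raise ValueError(f"annotation file {path} lacks column {col!r}")
    intervals = [
        (int(s), int(e), str(l).strip().lower())
        for s, e, l in zip(df["start"], df["end"], df["label"])
    ]
    return PhaseAnnotation(intervals)


def write_phase_annotation(ann: PhaseAnnotation, path: str | Path) -> None:
    pd.DataFrame(ann.intervals, columns=["start", "end", "label"]).to_csv(
        path, index=False
    )
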