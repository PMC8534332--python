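"""Flexion/extension cycle analysis of per-frame morphology traces.

During a finger flexion/extension cycle the nerve centroid's x coordinate
follows a biphasic (roughly triangular) waveform: it drifts toward the
ulnar side while the fingers flex and returns while they extend.  This
module

* splits a metric trace into alternating flexion/extension phases —
  either from a manual annotation or automatically from the smoothed
  centroid-x waveform (alternating local extrema with a prominence
  threshold; the turning points are the phase boundaries);
* histograms phase durations and extracts the D90/D50 ranges — the
  contiguous duration band around the modal bin whose counts reach 90%
  resp. 50% of the modal count — used to pool phases of similar length;
* resamples each phase onto a common 30-point normalized-time grid
  ``u_k = k/29`` by linear interpolation, so phases of different duration
  can be averaged point-wise into mean ± SD profiles.

Phases are labeled ``flexion`` when the net centroid-x change over the
phase is negative (ulnar drift with the package's x-rightward image
convention and the usual probe orientation) and ``extension`` otherwise;
the labels strictly alternate.  The per-frame centroid offset is the
Euclidean deviation from the centroid at the start of the enclosing
flexion phase, so an extension phase is referenced to the flexion phase
that opened its cycle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .io import PhaseAnnotation
from .morphology import MorphRecord

__all__ = [
    "N_POINTS",
    "Phase",
    "DurationHistogram",
    "NormalizedProfile",
    "PhaseError",
    "NoPhasesError",
    "PhaseDisqualifiedError",
    "segment_phases",
    "duration_histogram",
    "modal_range",
    "resample_normalized",
    "pool_profiles",
    "compare_profiles",
]

#: Number of normalized-time samples per phase (interval 1/29 on [0, 1]).
N_POINTS = 30

#: Metric names resolvable by :meth:`Phase.metric_values`.
_METRIC_FIELDS = {
    "csa_px": lambda r: r.csa_px if r.valid else np.nan,
    "csa_cm2": lambda r: r.csa_cm2,
    "cx_px": lambda r: r.centroid_px[0],
    "cy_px": lambda r: r.centroid_px[1],
    "cx_cm": lambda r: r.centroid_cm[0],
    "cy_cm": lambda r: r.centroid_cm[1],
    "perimeter_px": lambda r: r.perimeter_px,
    "perimeter_cm": lambda r: r.perimeter_cm,
    "circularity": lambda r: r.circularity,
    "step_displacement_cm": lambda r: r.step_displacement_cm,
}


class PhaseError(ValueError):
    """Invalid phase-analysis input."""


class NoPhasesError(PhaseError):
    """The trace contains no detectable motion phases."""


class PhaseDisqualifiedError(PhaseError):
    """Phase has too many missing frames to be resampled reliably."""


@dataclass
class Phase:
    """One flexion or extension interval of a metric trace.

    ``start``/``end`` are inclusive positions into the record list;
    consecutive phases share their boundary frame (the turning point).
    """

    label: str
    start: int
    end: int
    duration_s: float
    trace: list[MorphRecord]
    centroid_offset_cm: np.ndarray

    def __post_init__(self) -> None:
        if self.label not in ("flexion", "extension"):
            raise PhaseError(f"unknown phase label {self.label!r}")
        if len(self.trace) < 2 or not self.duration_s > 0:
            raise PhaseError("a phase needs at least 2 frames and positive duration")

    @property
    def n_frames(self) -> int:
        return len(self.trace)

    def times(self) -> np.ndarray:
        return np.asarray([r.time_s for r in self.trace])

    def metric_values(self, metric: str) -> np.ndarray:
        """Per-frame values of ``metric`` (NaN for invalid frames)."""
        if metric == "centroid_offset_cm":
            return np.asarray(self.centroid_offset_cm, dtype=float)
        try:
            getter = _METRIC_FIELDS[metric]
        except KeyError:
            raise KeyError(
                f"unknown metric {metric!r}; choose from "
                f"{sorted(_METRIC_FIELDS) + ['centroid_offset_cm']}"
            ) from None
        return np.asarray([getter(r) for r in self.trace], dtype=float)


@dataclass
class DurationHistogram:
    """Histogram of phase durations with the D90/D50 modal ranges."""

    label: str
    bin_width_s: float
    bin_edges: np.ndarray
    counts: np.ndarray
    d90_range_s: tuple[float, float]
    d50_range_s: tuple[float, float]


@dataclass
class NormalizedProfile:
    """Pooled mean ± SD of a metric on the 30-point normalized-time grid."""

    metric: str
    label: str
    grid: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    n_phases: int


# ---------------------------------------------------------------------------
# phase segmentation


def _smooth(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average; the window shrinks near the edges."""
    if window < 1 or window % 2 == 0:
        raise PhaseError("smoothing window must be a positive odd integer")
    half = window // 2
    out = np.empty_like(x, dtype=float)
    for i in range(len(x)):
        lo, hi = max(0, i - half), min(len(x), i + half + 1)
        out[i] = x[lo:hi].mean()
    return out


def _bridge_nan(x: np.ndarray) -> np.ndarray:
    """Linear interpolation over missing samples (edges: nearest valid)."""
    x = np.asarray(x, dtype=float)
    bad = np.isnan(x)
    if bad.all():
        raise PhaseError("trace has no valid samples")
    if bad.any():
        idx = np.arange(len(x))
        x = x.copy()
        x[bad] = np.interp(idx[bad], idx[~bad], x[~bad])
    return x


def _alternating_extrema(x: np.ndarray, prominence: float) -> list[tuple[int, str]]:
    """Interior maxima/minima plus both endpoints, alternation enforced."""
    maxima, _ = find_peaks(x, prominence=prominence)
    minima, _ = find_peaks(-x, prominence=prominence)
    ext = [(int(i), "max") for i in maxima] + [(int(i), "min") for i in minima]
    ext.sort()
    if not ext:
        return []
    # Endpoints are turning points too when a recording starts/ends at a
    # cycle boundary; kind is the opposite of the nearest interior extremum.
    first_i, first_k = ext[0]
    if first_i > 0:
        ext.insert(0, (0, "min" if first_k == "max" else "max"))
    last_i, last_k = ext[-1]
    n = len(x)
    if last_i < n - 1:
        ext.append((n - 1, "min" if last_k == "max" else "max"))
    return _enforce_alternation(x, ext)


def _enforce_alternation(x: np.ndarray, ext: list[tuple[int, str]]) -> list[tuple[int, str]]:
    out: list[tuple[int, str]] = []
    for i, kind in ext:
        if out and out[-1][1] == kind:
            j, _ = out[-1]
            better = (x[i] > x[j]) if kind == "max" else (x[i] < x[j])
            if better:
                out[-1] = (i, kind)
        else:
            out.append((i, kind))
    return out


def _merge_short_runs(
    x: np.ndarray, ext: list[tuple[int, str]], dt: float, min_phase_s: float
) -> list[tuple[int, str]]:
    """Drop extrema bounding runs shorter than ``min_phase_s``."""
    while len(ext) >= 2:
        durations = [(ext[k + 1][0] - ext[k][0]) * dt for k in range(len(ext) - 1)]
        short = [k for k, d in enumerate(durations) if d < min_phase_s]
        if not short:
            break
        k = min(short, key=lambda kk: durations[kk])
        if k == 0:
            del ext[0]
        elif k == len(ext) - 2:
            del ext[-1]
        else:
            # drop the less salient of the two interior bounding extrema
            def salience(pos: int) -> float:
                i = ext[pos][0]
                left = x[ext[pos - 1][0]] if pos > 0 else x[i]
                right = x[ext[pos + 1][0]] if pos < len(ext) - 1 else x[i]
                return abs(x[i] - (left + right) / 2.0)

            del ext[k if salience(k) <= salience(k + 1) else k + 1]
        ext = _enforce_alternation(x, ext)
    return ext


def _attach_offsets(phases: list[Phase]) -> None:
    """Fill centroid offsets relative to the enclosing flexion start."""
    ref: tuple[float, float] | None = None
    for ph in phases:
        if ph.label == "flexion" or ref is None:
            ref = ph.trace[0].centroid_cm
        cx = np.asarray([r.centroid_cm[0] for r in ph.trace], dtype=float)
        cy = np.asarray([r.centroid_cm[1] for r in ph.trace], dtype=float)
        ph.centroid_offset_cm = np.hypot(cx - ref[0], cy - ref[1])


def segment_phases(
    records: list[MorphRecord],
    mode: str = "automatic",
    annotation: PhaseAnnotation | None = None,
    window_frames: int = 5,
    prominence_frac: float = 0.10,
    min_phase_s: float = 0.2,
) -> list[Phase]:
    """Split a morphology trace into alternating flexion/extension phases.

    Automatic mode smooths centroid-x with a centered moving average
    (``window_frames``), finds alternating local extrema whose prominence
    is at least ``prominence_frac`` of the total centroid-x range, and
    makes each inter-extremum run one phase; runs shorter than
    ``min_phase_s`` are merged into their neighbors.  Annotated mode
    returns the phases exactly as annotated.
    """
    if len(records) < 2:
        raise PhaseError("need at least 2 records to segment phases")
    times = np.asarray([r.time_s for r in records])
    dt = float(np.median(np.diff(times)))

    if mode == "annotated":
        if annotation is None:
            raise PhaseError("annotated mode requires a PhaseAnnotation")
        phases = []
        for start, end, label in annotation.intervals:
            if not (0 <= start < end < len(records)):
                raise PhaseError(
                    f"annotation interval ({start}, {end}) outside the sequence"
                )
            trace = records[start : end + 1]
            phases.append(
                Phase(
                    label=label,
                    start=start,
                    end=end,
                    duration_s=float(times[end] - times[start]),
                    trace=trace,
                    centroid_offset_cm=np.empty(0),
                )
            )
        _attach_offsets(phases)
        return phases
    if mode != "automatic":
        raise PhaseError("mode must be 'automatic' or 'annotated'")

    cx = _bridge_nan(np.asarray([r.centroid_cm[0] for r in records], dtype=float))
    smooth = _smooth(cx, window_frames)
    span = float(smooth.max() - smooth.min())
    if span == 0.0:
        raise NoPhasesError("centroid trace is constant; no motion phases")
    ext = _alternating_extrema(smooth, prominence=prominence_frac * span)
    ext = _merge_short_runs(smooth, ext, dt, min_phase_s)
    # Smoothing rounds the waveform vertices and can shift each turning
    # point by a frame, which systematically clips the ramps; snap every
    # extremum to the extremum of a lightly (3-point) smoothed trace within
    # half a smoothing window.  The light smoothing keeps the snap from
    # chasing single-frame measurement noise.
    fine = _smooth(cx, 3) if window_frames > 3 else cx
    half = window_frames // 2
    snapped: list[tuple[int, str]] = []
    for i, kind in ext:
        lo, hi = max(0, i - half), min(len(cx), i + half + 1)
        j = lo + int(np.argmax(fine[lo:hi]) if kind == "max" else np.argmin(fine[lo:hi]))
        snapped.append((j, kind))
    snapped.sort()
    ext = _enforce_alternation(fine, [e for k, e in enumerate(snapped)
                                      if k == 0 or snapped[k][0] != snapped[k - 1][0]])
    if len(ext) < 2:
        raise NoPhasesError("fewer than two turning points found")

    phases = []
    for (i0, _), (i1, _) in zip(ext, ext[1:]):
        label = "flexion" if cx[i1] < cx[i0] else "extension"
        phases.append(
            Phase(
                label=label,
                start=i0,
                end=i1,
                duration_s=float(times[i1] - times[i0]),
                trace=records[i0 : i1 + 1],
                centroid_offset_cm=np.empty(0),
            )
        )
    _attach_offsets(phases)
    return phases


# ---------------------------------------------------------------------------
# duration histogram


def modal_range(
    counts: np.ndarray, edges: np.ndarray, frac: float
) -> tuple[float, float]:
    """Duration range of the contiguous bin run, containing the modal bin,
    whose counts are >= ``frac`` times the modal count.

    Isolated distant bins above the threshold are excluded; the range is
    reported as (low edge of the first bin, high edge of the last bin).
    """
    counts = np.asarray(counts)
    threshold = frac * counts.max()
    mode = int(np.argmax(counts))
    lo = mode
    while lo > 0 and counts[lo - 1] >= threshold:
        lo -= 1
    hi = mode
    while hi < len(counts) - 1 and counts[hi + 1] >= threshold:
        hi += 1
    return float(edges[lo]), float(edges[hi + 1])


def duration_histogram(
    phases: list[Phase], label: str, bin_width_s: float = 0.03
) -> DurationHistogram:
    """Histogram of phase durations for one label, with D90/D50 ranges.

    Bins have fixed width and start at 0 s; D90 and D50 are the modal
    ranges at 90% and 50% of the maximum count, so D90 is always contained
    in D50 and both contain the modal bin.
    """
    durations = np.asarray([p.duration_s for p in phases if p.label == label])
    if durations.size == 0:
        raise PhaseError(f"no phases labeled {label!r}")
    n_bins = max(1, int(np.ceil(durations.max() / bin_width_s - 1e-12)))
    edges = bin_width_s * np.arange(n_bins + 1)
    counts, _ = np.histogram(durations, bins=edges)
    return DurationHistogram(
        label=label,
        bin_width_s=bin_width_s,
        bin_edges=edges,
        counts=counts,
        d90_range_s=modal_range(counts, edges, 0.9),
        d50_range_s=modal_range(counts, edges, 0.5),
    )


# ---------------------------------------------------------------------------
# normalized-time resampling and pooling


def _bridge_phase_values(values: np.ndarray, max_gap: int = 2) -> np.ndarray:
    """Bridge short invalid gaps inside a phase trace.

    Interior NaN runs of at most ``max_gap`` consecutive frames are
    linearly interpolated; longer runs, or missing endpoint values,
    disqualify the phase.
    """
    values = np.asarray(values, dtype=float)
    bad = np.isnan(values)
    if not bad.any():
        return values
    if bad[0] or bad[-1]:
        raise PhaseDisqualifiedError("phase endpoints have no valid value")
    run = 0
    for b in bad:
        run = run + 1 if b else 0
        if run > max_gap:
            raise PhaseDisqualifiedError(
                f"more than {max_gap} consecutive invalid frames in phase"
            )
    return _bridge_nan(values)


def resample_normalized(phase: Phase, metric: str) -> np.ndarray:
    """Resample a phase's metric onto the 30-point normalized-time grid.

    Timestamps map affinely onto [0, 1]; values are linearly interpolated
    at ``u_k = k/29``, so the first and last outputs equal the first and
    last inputs exactly and affine traces are reproduced exactly.
    """
    values = _bridge_phase_values(phase.metric_values(metric))
    if len(values) < 2:
        raise PhaseError("resampling needs at least 2 values")
    t = phase.times()
    u = (t - t[0]) / (t[-1] - t[0])
    grid = np.arange(N_POINTS) / (N_POINTS - 1)
    out = np.interp(grid, u, values)
    out[0], out[-1] = values[0], values[-1]
    return out


def pool_profiles(
    phases: list[Phase],
    metric: str,
    duration_filter: tuple[float, float] | None = None,
) -> NormalizedProfile:
    """Pool same-label phases into a mean ± SD normalized-time profile.

    ``duration_filter=(low_s, high_s)`` keeps only phases whose duration
    lies in the closed interval — typically a D90 or D50 range.  Phases
    with too many invalid frames are skipped.  At least two phases must
    qualify; the SD uses the n−1 denominator.
    """
    if not phases:
        raise PhaseError("no phases to pool")
    labels = {p.label for p in phases}
    if len(labels) > 1:
        raise PhaseError(f"phases mix labels {sorted(labels)}; pool one label at a time")
    rows = []
    for p in phases:
        if duration_filter is not None:
            lo, hi = duration_filter
            if not (lo <= p.duration_s <= hi):
                continue
        try:
            rows.append(resample_normalized(p, metric))
        except PhaseDisqualifiedError:
            continue
    if len(rows) < 2:
        raise PhaseError(
            f"only {len(rows)} phase(s) qualify for pooling; need at least 2"
        )
    data = np.vstack(rows)
    return NormalizedProfile(
        metric=metric,
        label=labels.pop(),
        grid=np.arange(N_POINTS) / (N_POINTS - 1),
        mean=data.mean(axis=0),
        sd=data.std(axis=0, ddof=1),
        n_phases=len(rows),
    )


def compare_profiles(
    a: NormalizedProfile, b: NormalizedProfile, eps: float = 1e-9
) -> tuple[np.ndarray, float]:
    """Per-point and average relative discrepancy between two profiles.

    The per-point discrepancy is ``|mean_a - mean_b| / max(|mean_b|, eps)``
    (``b`` is the reference); the summary is its average over the grid.
    """
    if a.metric != b.metric or a.label != b.label:
        raise PhaseError("profiles measure different things; cannot compare")
    if a.grid.shape != b.grid.shape or not np.allclose(a.grid, b.grid):
        raise PhaseError("profile grids differ")
    denom = np.maximum(np.abs(b.mean), eps)
    per_point = np.abs(a.mean - b.mean) / denom
    return per_point, float(per_point.mean())
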