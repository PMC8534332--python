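"""Synthetic dynamic-ultrasound mask sequences with known morphology.

The clinical videos behind this kind of analysis are generally not
shareable, so the pipeline is exercised on a generator that emulates
their statistical structure: a single convex-ish nerve cross-section
whose area, position and roundness vary cyclically over ~1 s finger
flexion/extension cycles, sampled at 38 frames/s with every 4th frame
kept, plus the failure modes segmentation models actually produce
(boundary jitter, distractor blobs, region splits, scored candidate
lists).

Shape family.  Each frame's nerve is a star-convex region with polar
radius ``r(theta) = r0 * (1 + m * cos(3*(theta - theta0)))``; the
three-fold term interpolates between a circle (m = 0, circularity 1) and
a rounded triangle (circularity ~0.6, the shape the nerve takes most of
the time).  ``(r0, m)`` are solved per frame so the continuous shape hits
the programmed cross-sectional area and circularity exactly; the mask is
the set of pixel centers inside the curve.

Kinematics.  A normalized activation ``s(t)`` ramps 0 -> 1 linearly over
each flexion phase and 1 -> 0 over each extension phase.  Area scales as
``base * (1 + amplitude * s)`` (default amplitude -0.12: a 12% shrink at
peak flexion), the centroid translates by the programmed excursion
(default 1 mm, predominantly along -x, the ulnar direction), and the
circularity shifts by its own signed amplitude.  Phase durations are
drawn per cycle from truncated normals centered on the typical modal
durations (flexion 0.68 s, extension 0.48 s).

Everything is a pure function of (spec, seed): identical inputs give
bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy import ndimage

from .evaluation import compute_iou
from .io import CandidateSet, MaskFrame, MaskSequence, PhaseAnnotation, SequenceMeta

__all__ = [
    "SimSpec",
    "NoiseSpec",
    "SyntheticTruth",
    "generate_truth",
    "degrade",
    "shape_circularity",
    "solve_shape",
    "render_shape",
]


@dataclass(frozen=True)
class SimSpec:
    """Parameters of the ground-truth motion sequence.

    Defaults encode the study conditions this generator emulates: 38 fps
    acquisition with every 4th frame kept, 5 motion cycles, flexion lasting
    0.68 +/- 0.08 s and extension 0.48 +/- 0.04 s (truncated at 0.3 s), a
    0.12 cm^2 nerve shrinking 12% at peak flexion, a 0.10 cm centroid
    excursion along -x (plus 0.02 cm along y), and circularity near 0.62.
    """

    height: int = 128
    width: int = 160
    px_per_cm: float = 100.0
    fps: float = 38.0
    frame_step: int = 4
    n_cycles: int = 5
    flexion_duration_mean_s: float = 0.68
    flexion_duration_sd_s: float = 0.08
    extension_duration_mean_s: float = 0.48
    extension_duration_sd_s: float = 0.04
    min_duration_s: float = 0.3
    base_csa_cm2: float = 0.12
    csa_amplitude: float = -0.12
    centroid_excursion_cm: float = 0.10
    y_excursion_cm: float = 0.02
    base_circularity: float = 0.62
    circularity_amplitude: float = -0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.base_csa_cm2 > 0:
            raise ValueError("base_csa_cm2 must be positive")
        if not abs(self.csa_amplitude) < 1:
            raise ValueError("|csa_amplitude| must be < 1")
        if self.min_duration_s <= 0:
            raise ValueError("durations must stay positive")

    @property
    def meta(self) -> SequenceMeta:
        return SequenceMeta(
            px_per_cm=self.px_per_cm,
            fps=self.fps,
            frame_step=self.frame_step,
            axis_labels=("scaphoid(+x)/ulnar(-x)", "palmar(+y)"),
        )


@dataclass(frozen=True)
class NoiseSpec:
    """Degradation model applied to ground truth.

    ``boundary_jitter_px`` displaces the nerve boundary by a smooth random
    field of that RMS amplitude; a ``blur_frames_frac`` fraction of frames
    get triple jitter (emulating motion-blurred frames).  With probability
    ``distractor_prob`` per frame a distractor blob of
    ``distractor_area_frac`` times the nerve area (strictly < 1) appears
    at least 3 px away from the nerve.  ``split_prob`` cuts the nerve mask
    in two.  Instance-style output carries ``candidate_count`` scored
    candidates per frame; scores are the candidate's true IoU against
    ground truth plus Gaussian noise of SD ``score_noise_sd``, clipped to
    [0, 1].
    """

    boundary_jitter_px: float = 2.0
    distractor_prob: float = 0.1
    distractor_area_frac: float = 0.15
    split_prob: float = 0.02
    blur_frames_frac: float = 0.05
    candidate_count: int = 3
    score_noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.distractor_area_frac < 1:
            raise ValueError("distractor_area_frac must be in [0, 1)")
        if self.candidate_count < 1:
            raise ValueError("candidate_count must be at least 1")


# ---------------------------------------------------------------------------
# shape family


_THETA = np.linspace(0.0, 2.0 * np.pi, 4096, endpoint=False)
_M_MAX = 0.6


def _perimeter_factor(m: float) -> float:
    """Arc length of r(theta) = 1 + m cos 3theta (unit r0)."""
    r = 1.0 + m * np.cos(3.0 * _THETA)
    dr = -3.0 * m * np.sin(3.0 * _THETA)
    integrand = np.sqrt(r * r + dr * dr)
    return float(integrand.mean() * 2.0 * np.pi)


def shape_circularity(m: float) -> float:
    """Analytic circularity of the three-lobed shape as a function of m."""
    area = np.pi * (1.0 + m * m / 2.0)
    return float(4.0 * np.pi * area / _perimeter_factor(m) ** 2)


def solve_shape(area_px2: float, circularity: float) -> tuple[float, float]:
    """Solve (r0, m) so the continuous shape has the given area and circularity."""
    from scipy.optimize import brentq

    lo = shape_circularity(_M_MAX)
    if not (lo <= circularity <= 1.0 + 1e-12):
        raise ValueError(
            f"target circularity {circularity:.3f} outside the shape family's "
            f"reachable range [{lo:.3f}, 1.0]"
        )
    if circularity >= 1.0:
        m = 0.0
    else:
        m = brentq(lambda mm: shape_circularity(mm) - circularity, 0.0, _M_MAX)
    r0 = np.sqrt(area_px2 / (np.pi * (1.0 + m * m / 2.0)))
    return float(r0), float(m)


def render_shape(
    shape: tuple[int, int],
    center_px: tuple[float, float],
    r0: float,
    m: float,
    theta0: float = 0.0,
) -> np.ndarray:
    """Rasterize the star-convex shape: pixel centers inside the polar curve."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    dx = xx - center_px[0]
    dy = yy - center_px[1]
    rho = np.hypot(dx, dy)
    theta = np.arctan2(dy, dx)
    radius = r0 * (1.0 + m * np.cos(3.0 * (theta - theta0)))
    return (rho <= radius).astype(np.uint8)


# ---------------------------------------------------------------------------
# ground truth


@dataclass
class SyntheticTruth:
    """Ground-truth sequence plus full per-frame bookkeeping.

    ``table`` holds one row per frame with the programmed (continuous)
    CSA, centroid, circularity, activation s and phase label; ``phases``
    lists ``(start_frame, end_frame, label)`` with inclusive, shared
    turning-point frames; ``boundaries_s`` are the exact programmed phase
    boundary times.
    """

    sequence: MaskSequence
    table: pd.DataFrame
    phases: list[tuple[int, int, str]]
    boundaries_s: list[float]
    spec: SimSpec = field(repr=False, default=None)  # type: ignore[assignment]

    def annotation(self) -> PhaseAnnotation:
        """The programmed phases as a manual-style annotation."""
        return PhaseAnnotation([(s, e, l) for s, e, l in self.phases])


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, lo: float) -> float:
    if sd == 0:
        return max(mean, lo)
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if v >= lo:
            return float(v)
    return lo


def generate_truth(spec: SimSpec) -> SyntheticTruth:
    """Render the ground-truth mask sequence programmed by ``spec``."""
    rng = np.random.default_rng(spec.seed)
    dt = spec.frame_step / spec.fps

    # Programmed phase boundaries, in seconds.  Durations are drawn from the
    # truncated normals and then rounded to the frame grid (multiples of dt)
    # so every boundary — and hence the activation extremes s = 0 and s = 1 —
    # is actually sampled by a frame; the sampled centroid range then spans
    # exactly the programmed excursion.
    min_frames = max(2, int(round(spec.min_duration_s / dt)))
    boundary_frames = [0]
    labels: list[str] = []
    for _ in range(spec.n_cycles):
        for mean, sd, label in (
            (spec.flexion_duration_mean_s, spec.flexion_duration_sd_s, "flexion"),
            (spec.extension_duration_mean_s, spec.extension_duration_sd_s, "extension"),
        ):
            dur = _truncated_normal(rng, mean, sd, spec.min_duration_s)
            boundary_frames.append(boundary_frames[-1] + max(min_frames, round(dur / dt)))
            labels.append(label)
    boundaries = [k * dt for k in boundary_frames]
    n_frames = boundary_frames[-1] + 1
    times = np.arange(n_frames) * dt

    def activation(t: float) -> tuple[float, str]:
        k = min(int(np.searchsorted(boundaries, t, side="right")) - 1, len(labels) - 1)
        a, b = boundaries[k], boundaries[k + 1]
        frac = (t - a) / (b - a)
        return (frac, "flexion") if labels[k] == "flexion" else (1.0 - frac, "extension")

    theta0 = float(rng.uniform(0.0, 2.0 * np.pi / 3.0))
    scale = spec.px_per_cm
    # start position: motion span centered on the image center
    cx0 = spec.width / 2.0 + spec.centroid_excursion_cm * scale / 2.0
    cy0 = spec.height / 2.0 - spec.y_excursion_cm * scale / 2.0

    frames: list[MaskFrame] = []
    rows = []
    for j, t in enumerate(times):
        s, label = activation(float(t))
        csa_cm2 = spec.base_csa_cm2 * (1.0 + spec.csa_amplitude * s)
        circ = spec.base_circularity + spec.circularity_amplitude * s
        cx = cx0 - spec.centroid_excursion_cm * scale * s
        cy = cy0 + spec.y_excursion_cm * scale * s
        r0, m = solve_shape(csa_cm2 * scale**2, circ)
        frames.append(
            MaskFrame(render_shape((spec.height, spec.width), (cx, cy), r0, m, theta0), j)
        )
        rows.append(
            {
                "frame_index": j,
                "time_s": float(t),
                "s": s,
                "phase_label": label,
                "csa_cm2_true": csa_cm2,
                "csa_px_true": csa_cm2 * scale**2,
                "cx_px_true": cx,
                "cy_px_true": cy,
                "cx_cm_true": cx / scale,
                "cy_cm_true": cy / scale,
                "circularity_true": circ,
            }
        )

    # phase frame ranges: boundary frames are shared turning points
    phases = [
        (a, b, lab) for a, b, lab in zip(boundary_frames, boundary_frames[1:], labels)
    ]
    seq = MaskSequence(meta=spec.meta, frames=frames)
    return SyntheticTruth(
        sequence=seq,
        table=pd.DataFrame(rows),
        phases=phases,
        boundaries_s=boundaries,
        spec=spec,
    )


# ---------------------------------------------------------------------------
# degradation


def _jitter_mask(
    pixels: np.ndarray, amplitude: float, rng: np.random.Generator
) -> np.ndarray:
    """Displace the mask boundary by a smooth random field (RMS ~amplitude px)."""
    if amplitude <= 0:
        return pixels.copy()
    signed = ndimage.distance_transform_edt(pixels) - ndimage.distance_transform_edt(
        1 - pixels
    )
    g = ndimage.gaussian_filter(rng.standard_normal(pixels.shape), sigma=3.0)
    g /= g.std() or 1.0
    return ((signed + amplitude * g) > 0).astype(np.uint8)


def _split_mask(pixels: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Cut the mask along a random line through its centroid (width ~2 px)."""
    rows, cols = np.nonzero(pixels)
    if rows.size == 0:
        return pixels
    cy, cx = rows.mean(), cols.mean()
    phi = rng.uniform(0.0, np.pi)
    yy, xx = np.mgrid[0 : pixels.shape[0], 0 : pixels.shape[1]]
    dist = np.abs((xx - cx) * np.sin(phi) - (yy - cy) * np.cos(phi))
    out = pixels.copy()
    out[dist <= 1.0] = 0
    return out


def _place_distractor(
    pixels: np.ndarray,
    area_px: float,
    rng: np.random.Generator,
    min_gap_px: float = 3.0,
    tries: int = 100,
) -> np.ndarray | None:
    """A disc of the requested area placed >= min_gap_px from the nerve."""
    h, w = pixels.shape
    r_d = float(np.sqrt(max(area_px, 1.0) / np.pi))
    dist_to_nerve = ndimage.distance_transform_edt(1 - pixels)
    for _ in range(tries):
        cy = rng.uniform(r_d, h - 1 - r_d)
        cx = rng.uniform(r_d, w - 1 - r_d)
        if dist_to_nerve[int(round(cy)), int(round(cx))] >= min_gap_px + r_d:
            yy, xx = np.mgrid[0:h, 0:w]
            return ((xx - cx) ** 2 + (yy - cy) ** 2 <= r_d**2).astype(np.uint8)
    return None


def degrade(
    truth: MaskSequence, noise: NoiseSpec
) -> tuple[MaskSequence, list[CandidateSet]]:
    """Produce semantic-style predictions and scored candidate sets.

    The semantic sequence is the jittered nerve, optionally split, with an
    occasional disjoint distractor blob strictly smaller than the nerve.
    The candidate list holds the jittered nerve plus
    ``candidate_count - 1`` distractor candidates, each scored by its true
    IoU against ground truth plus clipped Gaussian noise.
    """
    rng = np.random.default_rng(noise.seed)
    n = len(truth)
    blur = rng.random(n) < noise.blur_frames_frac
    semantic_frames: list[MaskFrame] = []
    candidate_sets: list[CandidateSet] = []
    for pos, frame in enumerate(truth.frames):
        amp = noise.boundary_jitter_px * (3.0 if blur[pos] else 1.0)
        nerve = _jitter_mask(frame.pixels, amp, rng)
        if rng.random() < noise.split_prob:
            nerve = _split_mask(nerve, rng)
        nerve_area = frame.area()

        distractor = None
        if rng.random() < noise.distractor_prob and noise.distractor_area_frac > 0:
            distractor = _place_distractor(
                frame.pixels, noise.distractor_area_frac * nerve_area, rng
            )
        semantic = nerve | distractor if distractor is not None else nerve
        semantic_frames.append(MaskFrame(semantic, frame.frame_index))

        def scored(mask: np.ndarray) -> tuple[np.ndarray, float]:
            score = compute_iou(mask, frame.pixels)
            if not mask.any():
                score = 0.0
            score += rng.normal(0.0, noise.score_noise_sd) if noise.score_noise_sd else 0.0
            return mask, float(np.clip(score, 0.0, 1.0))

        cands = [scored(nerve)]
        for _ in range(noise.candidate_count - 1):
            if noise.distractor_area_frac <= 0:
                break
            blob = distractor if distractor is not None else _place_distractor(
                frame.pixels, noise.distractor_area_frac * nerve_area, rng
            )
            distractor = None  # reuse the semantic distractor only once
            if blob is not None:
                cands.append(scored(blob))
        candidate_sets.append(CandidateSet(frame_index=frame.frame_index, candidates=cands))
    return (
        MaskSequence(meta=truth.meta, frames=semantic_frames),
        candidate_sets,
    )
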