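"""Resolve multi-region segmentation output into a single nerve mask.

Dynamic-ultrasound segmentation models occasionally emit several
disconnected foreground blocks for one frame (tendon look-alikes, blurred
boundaries) or, for instance-segmentation models, several scored
candidates.  Exactly one median nerve is present per frame, so two simple
rules pick it:

* semantic output — keep the connected region of the largest area;
* instance output — take the candidate with the highest confidence score,
  then keep its largest connected block.

Ties (equal areas, equal scores) break deterministically by the
lexicographically smallest foreground pixel ``(row, col)``.  An empty
prediction yields an empty mask that downstream modules treat as an
invalid frame (NaN metrics row; IoU 0 unless invalid frames are skipped).

The known limitation of the largest-area rule — a frame where the true
nerve is *not* the largest segmented region — is deliberately not
special-cased; the rule is applied as stated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io import CandidateSet, MaskFrame

__all__ = ["Region", "label_regions", "select_semantic_region", "select_instance_candidate"]

_STRUCT8 = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class Region:
    """One 8-connected foreground component."""

    mask: np.ndarray
    area_px: int
    anchor: tuple[int, int]  # lexicographically smallest (row, col) pixel


def label_regions(mask: MaskFrame | np.ndarray) -> list[Region]:
    """8-connected components, sorted by area descending then anchor ascending."""
    pixels = mask.pixels if isinstance(mask, MaskFrame) else np.asarray(mask) > 0
    labels, n = ndimage.label(pixels, structure=_STRUCT8)
    regions: list[Region] = []
    for lab in range(1, n + 1):
        region = labels == lab
        rows, cols = np.nonzero(region)
        order = np.lexsort((cols, rows))
        anchor = (int(rows[order[0]]), int(cols[order[0]]))
        regions.append(
            Region(mask=region.astype(np.uint8), area_px=int(region.sum()), anchor=anchor)
        )
    regions.sort(key=lambda r: (-r.area_px, r.anchor))
    return regions


def select_semantic_region(mask: MaskFrame | np.ndarray) -> MaskFrame:
    """Largest-area rule: keep the biggest 8-connected component.

    An empty input returns an empty mask (invalid-frame marker).
    """
    frame_index = mask.frame_index if isinstance(mask, MaskFrame) else 0
    regions = label_regions(mask)
    if not regions:
        pixels = mask.pixels if isinstance(mask, MaskFrame) else np.asarray(mask)
        return MaskFrame(np.zeros_like(pixels, dtype=np.uint8), frame_index=frame_index)
    return MaskFrame(regions[0].mask, frame_index=frame_index)


def select_instance_candidate(cands: CandidateSet) -> MaskFrame:
    """Highest-confidence rule for instance-segmentation candidates.

    Picks the candidate with the maximal score (ties: larger total area,
    then smaller anchor), then returns the largest connected block inside
    that candidate's mask.  An empty candidate list yields an empty 1x1
    mask (invalid-frame marker); callers that know the grid should prefer
    passing at least one—possibly empty—candidate so the shape is kept.
    """
    if not cands.candidates:
        return MaskFrame(np.zeros((1, 1), dtype=np.uint8), frame_index=cands.frame_index)

    def key(item: tuple[np.ndarray, float]):
        mask, score = item
        area = int(mask.sum())
        if area:
            rows, cols = np.nonzero(mask)
            order = np.lexsort((cols, rows))
            anchor = (int(rows[order[0]]), int(cols[order[0]]))
        else:
            anchor = (np.iinfo(np.intp).max, np.iinfo(np.intp).max)
        # maximize score, then area; minimize anchor
        return (-score, -area, anchor)

    best_mask, _ = min(cands.candidates, key=key)
    if not best_mask.any():
        return MaskFrame(np.zeros_like(best_mask), frame_index=cands.frame_index)
    winner = select_semantic_region(best_mask)
    return MaskFrame(winner.pixels, frame_index=cands.frame_index)
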