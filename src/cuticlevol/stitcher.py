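"""Contig-style merging of per-slice count series from height-step scans.

Specimens taller than the vertical field of view are scanned at several
overlapping heights; each height step is segmented independently, yielding
one count series per step. Because the overlapping slices image the same
anatomy, the true alignment is the suffix/prefix offset where the cuticle
and body count lists vary least between the two series — exactly the way
sequence contigs are assembled from overlapping reads.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .stack_proc import SliceSeries

__all__ = ["OverlapMatch", "find_overlap", "merge_series"]

DEFAULT_MIN_OVERLAP = 3


@dataclass(frozen=True)
class OverlapMatch:
    """Best suffix/prefix alignment between two consecutive series.

    ``offset`` is the index in the first series where the second begins;
    ``score`` is the mean absolute difference over the aligned cuticle and
    body counts jointly (0 for a perfect overlap).
    """

    offset: int
    overlap: int
    score: float

    def __post_init__(self) -> None:
        if self.overlap < 1 or self.score < 0:
            raise ValueError("invalid overlap match")


def find_overlap(
    a: SliceSeries, b: SliceSeries, min_overlap: int = DEFAULT_MIN_OVERLAP
) -> OverlapMatch:
    """Best alignment of a suffix of ``a`` with a prefix of ``b``.

    Scans every overlap length L from ``min_overlap`` to
    ``min(len(a), len(b))`` and scores the alignment by the mean absolute
    difference of the aligned cuticle and body counts (both lists pooled).
    Returns the minimum-score alignment; ties go to the longest overlap.
    """
    if len(a) == 0 or len(b) == 0:
        raise ValueError("series must be nonempty")
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    max_l = min(len(a), len(b))
    if max_l < min_overlap:
        raise ValueError(
            "no alignment satisfies the minimum overlap; if the scans do not "
            "overlap, concatenate the series instead"
        )
    best: OverlapMatch | None = None
    for L in range(min_overlap, max_l + 1):
        da = np.abs(a.cuticle_px[-L:] - b.cuticle_px[:L])
        db = np.abs(a.body_px[-L:] - b.body_px[:L])
        score = float(np.concatenate([da, db]).mean())
        if best is None or score < best.score or (score == best.score and L > best.overlap):
            best = OverlapMatch(offset=len(a) - L, overlap=L, score=score)
    return best


def merge_series(
    parts: list[SliceSeries],
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    combine: str = "first",
) -> SliceSeries:
    """Merge consecutive height-step series into one, counting overlaps once.

    Overlapping slices take their values from the earlier part by default
    (``combine="first"``); ``combine="mean"`` averages the two estimates.
    The merged length is the sum of part lengths minus the sum of overlap
    lengths, and slice indices are renumbered contiguously.
    """
    if combine not in ("first", "mean"):
        raise ValueError("combine must be 'first' or 'mean'")
    if len(parts) == 0:
        raise ValueError("no series to merge")
    merged = parts[0].copy()
    for nxt in parts[1:]:
        m = find_overlap(merged, nxt, min_overlap=min_overlap)
        L = m.overlap
        cut = np.concatenate([merged.cuticle_px, nxt.cuticle_px[L:]])
        body = np.concatenate([merged.body_px, nxt.body_px[L:]])
        if combine == "mean":
            cut[m.offset : m.offset + L] = (
                merged.cuticle_px[m.offset :] + nxt.cuticle_px[:L]
            ) / 2.0
            body[m.offset : m.offset + L] = (
                merged.body_px[m.offset :] + nxt.body_px[:L]
            ) / 2.0
        flags = list(merged.flags) + list(nxt.flags[L:])
        merged = SliceSeries(cuticle_px=cut, body_px=body, flags=flags)
    return merged
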