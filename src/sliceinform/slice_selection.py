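"""Entropy-guided selection of the most informative slice per brain segment.

Each volume axis is partitioned into fifteen equal contiguous segments;
only the nine central segments (1-based indices 4–12) are analyzed, since
edge segments contain only partial brain. Every candidate slice in a
segment is passed through a feature extractor; the Shannon entropy of each
activation channel's intensity histogram is averaged over channels, and
the slice with the highest mean entropy wins the segment::

    A = FE(V)                       (H'×W'×C activation map)
    H(A_c) = -sum_i P_i log2 P_i    (per-channel histogram entropy)
    H_mean(V) = (1/C) sum_c H(A_c)
    V* = argmax_V H_mean(V)

Ties are broken toward the lowest slice index. Entropies are in bits.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .extractors import FeatureExtractor
from .volume_io import Orientation, Slice2D, Volume3D, extract_slice

__all__ = [
    "SegmentPartition",
    "EntropyScore",
    "SelectionResult",
    "partition_segments",
    "central_segments",
    "channel_entropy",
    "mean_entropy",
    "select_slice",
    "select_all",
    "cohort_modal_winners",
]

N_SEGMENTS = 15
CENTRAL_RANGE = range(4, 13)  # 1-based segment indices 4..12 inclusive


@dataclass(frozen=True)
class SegmentPartition:
    """One of the fifteen segments: a half-open slice-index range."""

    orientation: Orientation
    segment_index: int  # 1-based, 1..15
    start: int
    stop: int

    @property
    def slice_range(self) -> range:
        return range(self.start, self.stop)

    def __len__(self) -> int:
        return self.stop - self.start


@dataclass(frozen=True)
class EntropyScore:
    """Per-channel histogram entropies (bits) and their mean."""

    per_channel: tuple[float, ...]
    mean: float


@dataclass
class SelectionResult:
    """Winning slice of one segment plus the full score table."""

    segment: SegmentPartition
    winner_index: int
    winner: Slice2D
    scores: dict[int, EntropyScore] = field(default_factory=dict)


def partition_segments(dim_size: int, orientation: Orientation,
                       n_segments: int = N_SEGMENTS) -> list[SegmentPartition]:
    """Split ``[0, dim_size)`` into ``n_segments`` near-equal ordered ranges.

    When ``dim_size`` is not divisible, the first ``dim_size mod
    n_segments`` ranges are one slice longer, so lengths differ by at
    most one and the ranges tile the axis exactly.
    """
    if dim_size < n_segments:
        raise ValueError(
            f"dim_size {dim_size} < n_segments {n_segments}: axis cannot be "
            "partitioned")
    base, rem = divmod(dim_size, n_segments)
    parts = []
    start = 0
    for i in range(n_segments):
        length = base + (1 if i < rem else 0)
        parts.append(SegmentPartition(orientation, i + 1, start, start + length))
        start += length
    return parts


def central_segments(partitions: list[SegmentPartition]) -> list[SegmentPartition]:
    """Keep the nine central segments (indices 4–12), dropping brain edges."""
    if len(partitions) != N_SEGMENTS:
        raise ValueError(
            f"expected {N_SEGMENTS} partitions, got {len(partitions)}")
    return [p for p in partitions if p.segment_index in CENTRAL_RANGE]


def channel_entropy(channel: np.ndarray, n_bins: int = 256) -> float:
    """Shannon entropy (bits) of one channel's intensity histogram.

    The histogram has ``n_bins`` equal-width bins spanning the channel's
    own [min, max]; empty bins contribute zero; a constant channel has a
    single occupied bin and entropy 0.
    """
    channel = np.asarray(channel, dtype=np.float64)
    if not np.all(np.isfinite(channel)):
        raise ValueError("channel contains non-finite values")
    lo, hi = float(channel.min()), float(channel.max())
    if lo == hi:
        return 0.0
    counts, _ = np.histogram(channel, bins=n_bins, range=(lo, hi))
    p = counts[counts > 0] / channel.size
    return float(-(p * np.log2(p)).sum())


def mean_entropy(activation_map: np.ndarray, n_bins: int = 256) -> EntropyScore:
    """Average :func:`channel_entropy` over the map's C channels."""
    a = np.asarray(activation_map, dtype=np.float64)
    if a.ndim == 2:
        a = a[:, :, None]
    per = tuple(channel_entropy(a[:, :, c], n_bins) for c in range(a.shape[2]))
    return EntropyScore(per_channel=per, mean=float(np.mean(per)))


def select_slice(vol: Volume3D, segment: SegmentPartition,
                 extractor: FeatureExtractor,
                 n_bins: int = 256) -> SelectionResult:
    """Score every slice in ``segment`` and return the entropy argmax.

    Ties go to the lowest slice index. All scores are kept for reporting.
    """
    dim = vol.dims[segment.orientation.axis_index]
    if not (0 <= segment.start < segment.stop <= dim):
        raise ValueError(
            f"segment range [{segment.start}, {segment.stop}) invalid for "
            f"axis length {dim}")
    scores: dict[int, EntropyScore] = {}
    best_idx, best_slice, best_mean = None, None, -np.inf
    for idx in segment.slice_range:
        sl = extract_slice(vol, segment.orientation, idx,
                           segment_index=segment.segment_index)
        try:
            amap = extractor(sl.channels())
        except Exception as exc:  # re-raise with provenance
            raise RuntimeError(
                f"extractor {getattr(extractor, 'name', extractor)!r} failed "
                f"on subject={sl.subject_id} orientation="
                f"{segment.orientation.label} segment={segment.segment_index} "
                f"slice={idx}") from exc
        score = mean_entropy(amap, n_bins)
        scores[idx] = score
        if score.mean > best_mean:  # strict: ties keep the lowest index
            best_idx, best_slice, best_mean = idx, sl, score.mean
    assert best_idx is not None and best_slice is not None
    return SelectionResult(segment=segment, winner_index=best_idx,
                           winner=best_slice, scores=scores)


def select_all(vol: Volume3D, extractor: FeatureExtractor, n_bins: int = 256,
               orientations: tuple[Orientation, ...] = tuple(Orientation),
               segment_indices: tuple[int, ...] = tuple(CENTRAL_RANGE),
               ) -> dict[tuple[str, int], SelectionResult]:
    """Select per-segment winners over every requested orientation.

    With the defaults this yields 3 orientations × 9 central segments =
    27 independent :class:`SelectionResult` entries.
    """
    out: dict[tuple[str, int], SelectionResult] = {}
    for orientation in orientations:
        parts = partition_segments(vol.dims[orientation.axis_index], orientation)
        for part in parts:
            if part.segment_index in segment_indices:
                out[(orientation.label, part.segment_index)] = select_slice(
                    vol, part, extractor, n_bins)
    return out


def cohort_modal_winners(
    per_volume: list[dict[tuple[str, int], SelectionResult]],
) -> dict[tuple[str, int], int]:
    """Fix one slice index per (orientation, segment) across a cohort.

    Cohort mode: the modal winning index over the supplied volumes (ties
    toward the lowest index), for studies wanting one anatomically fixed
    slice position for all subjects instead of per-volume argmax.
    """
    if not per_volume:
        raise ValueError("no selection results supplied")
    keys = per_volume[0].keys()
    fixed: dict[tuple[str, int], int] = {}
    for key in keys:
        counts = Counter(res[key].winner_index for res in per_volume)
        top = max(counts.values())
        fixed[key] = min(i for i, c in counts.items() if c == top)
    return fixed
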