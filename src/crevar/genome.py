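"""Genome layout and half-open interval arithmetic.

Coordinate conventions used throughout the package:

* VCF entities are 1-based; a point variant at VCF position ``p`` occupies
  the 0-based half-open interval ``[p-1, p)`` and an indel with reference
  allele of length ``L`` occupies ``[p-1, p-1+L)``.
* All interval containers (peaks, masks, search spaces) are 0-based
  half-open, BED style. Strand is ignored: accessibility peaks are
  unstranded.

Intervals per contig are stored as ``(n, 2)`` integer arrays. Once merged
they are sorted and non-overlapping, which lets every overlap query reduce
to two ``searchsorted`` calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GenomeLayout",
    "merge_intervals",
    "span_overlaps",
    "count_overlapping",
    "place_nonoverlapping",
]


def merge_intervals(intervals: np.ndarray, gap: int = 0, return_groups: bool = False):
    """Merge overlapping and near-adjacent half-open intervals.

    Intervals closer than or equal to ``gap`` base pairs apart are fused;
    the default ``gap=0`` merges overlapping *and* book-ended intervals
    (``[100,200)`` + ``[200,250)`` -> ``[100,250)``).

    Parameters
    ----------
    intervals
        ``(n, 2)`` array of ``start, end`` pairs with ``start < end``.
    gap
        Maximum separation (bp) at which two intervals are still fused.
    return_groups
        If true, also return an ``(n,)`` array mapping each *input* interval
        (in input order) to the index of the merged interval containing it,
        which is how peak-id back-references are carried.

    Returns
    -------
    merged : ``(m, 2)`` int array, sorted, non-overlapping.
    groups : optional ``(n,)`` int array.
    """
    arr = np.asarray(intervals, dtype=np.int64).reshape(-1, 2)
    if arr.size and np.any(arr[:, 0] >= arr[:, 1]):
        raise ValueError("empty or inverted interval (start >= end)")
    if arr.shape[0] == 0:
        merged = arr.reshape(0, 2)
        return (merged, np.empty(0, dtype=np.int64)) if return_groups else merged
    order = np.argsort(arr[:, 0], kind="stable")
    srt = arr[order]
    groups_sorted = np.empty(len(srt), dtype=np.int64)
    out = []
    cur_start, cur_end = srt[0]
    gi = 0
    groups_sorted[0] = 0
    for i in range(1, len(srt)):
        s, e = srt[i]
        if s <= cur_end + gap:
            cur_end = max(cur_end, e)
        else:
            out.append((cur_start, cur_end))
            cur_start, cur_end = s, e
            gi += 1
        groups_sorted[i] = gi
    out.append((cur_start, cur_end))
    merged = np.asarray(out, dtype=np.int64)
    if not return_groups:
        return merged
    groups = np.empty(len(arr), dtype=np.int64)
    groups[order] = groups_sorted
    return merged, groups


def span_overlaps(starts: np.ndarray, ends: np.ndarray, merged: np.ndarray):
    """Vectorized overlap test of query spans against merged intervals.

    ``merged`` must be sorted and non-overlapping. Returns for each query a
    pair ``(hit, index)`` where ``index`` is the first overlapped merged
    interval (or -1). A span ``[s, e)`` overlaps some interval iff the
    number of intervals ending after ``s`` exceeds the number starting at
    or after ``e``.
    """
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    if merged.shape[0] == 0:
        hit = np.zeros(starts.shape, dtype=bool)
        return hit, np.full(starts.shape, -1, dtype=np.int64)
    lo = np.searchsorted(merged[:, 1], starts, side="right")
    hi = np.searchsorted(merged[:, 0], ends, side="left")
    hit = hi > lo
    idx = np.where(hit, lo, -1)
    return hit, idx


def count_overlapping(starts, ends, merged) -> int:
    """Number of query spans overlapping any merged interval."""
    hit, _ = span_overlaps(starts, ends, merged)
    return int(hit.sum())


@dataclass
class GenomeLayout:
    """Ordered contig sizes plus an optional randomization mask.

    ``mask`` intervals are regions (per contig, 0-based half-open) excluded
    from randomized peak placement, mirroring the use of a hard-masked
    genome to restrict where permuted peaks may land. Masks are normalized
    (sorted, merged) on construction.
    """

    contigs: dict[str, int]
    mask: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.contigs:
            raise ValueError("GenomeLayout needs at least one contig")
        for name, length in self.contigs.items():
            if length <= 0:
                raise ValueError(f"contig {name!r} has non-positive length")
        norm = {}
        for name, iv in self.mask.items():
            if name not in self.contigs:
                raise ValueError(f"mask on unknown contig {name!r}")
            arr = np.asarray(iv, dtype=np.int64).reshape(-1, 2)
            if arr.size:
                if np.any(arr[:, 0] < 0) or np.any(arr[:, 0] >= arr[:, 1]):
                    raise ValueError("mask interval violates 0 <= start < end")
                if np.any(arr[:, 1] > self.contigs[name]):
                    raise ValueError("mask interval exceeds contig length")
                arr = merge_intervals(arr)
            norm[name] = arr
        self.mask = norm

    @property
    def total_length(self) -> int:
        return int(sum(self.contigs.values()))

    @property
    def unmasked_length(self) -> int:
        masked = sum(int((iv[:, 1] - iv[:, 0]).sum()) for iv in self.mask.values())
        return self.total_length - masked

    def validate_interval(self, contig: str, start: int, end: int) -> None:
        if contig not in self.contigs:
            raise ValueError(f"unknown contig {contig!r}")
        if not (0 <= start < end <= self.contigs[contig]):
            raise ValueError(
                f"interval [{start},{end}) out of bounds for {contig} "
                f"(length {self.contigs[contig]})"
            )


class PlacementError(RuntimeError):
    """Raised when rejection sampling cannot place an interval."""


def _overlaps_sorted(starts: list, ends: list, s: int, e: int) -> int:
    """Insertion point if [s,e) is free against disjoint sorted intervals, else -1."""
    import bisect

    j = bisect.bisect_right(ends, s)
    if j < len(starts) and starts[j] < e:
        return -1
    return j


def place_nonoverlapping(
    lengths,
    layout: GenomeLayout,
    rng: np.random.Generator,
    max_attempts: int = 10_000,
):
    """Place intervals of the given lengths uniformly at random, without overlap.

    Placement respects contig boundaries and the layout mask, and returns
    placements aligned with the input order. Longest intervals are placed
    first to keep the rejection rate low; each interval is retried up to
    ``max_attempts`` times before a :class:`PlacementError` naming the
    stuck length is raised.
    """
    lengths = np.asarray(lengths, dtype=np.int64)
    if np.any(lengths <= 0):
        raise ValueError("interval lengths must be positive")
    if int(lengths.sum()) > layout.unmasked_length:
        raise PlacementError(
            f"requested interval mass {int(lengths.sum())} exceeds unmasked "
            f"genome capacity {layout.unmasked_length}"
        )
    names = list(layout.contigs)
    sizes = np.array([layout.contigs[n] for n in names], dtype=np.int64)
    cum = np.cumsum(sizes)
    total = int(cum[-1])
    blocked_s = {n: [] for n in names}
    blocked_e = {n: [] for n in names}
    for n in names:
        iv = layout.mask.get(n)
        if iv is not None and len(iv):
            blocked_s[n] = [int(x) for x in iv[:, 0]]
            blocked_e[n] = [int(x) for x in iv[:, 1]]

    order = np.argsort(-lengths, kind="stable")
    out_contig = np.empty(len(lengths), dtype=object)
    out_start = np.empty(len(lengths), dtype=np.int64)
    for i in order:
        L = int(lengths[i])
        placed = False
        for _ in range(max_attempts):
            g = int(rng.integers(0, total))
            ci = int(np.searchsorted(cum, g, side="right"))
            s = g - (int(cum[ci - 1]) if ci else 0)
            if s + L > int(sizes[ci]):
                continue
            name = names[ci]
            j = _overlaps_sorted(blocked_s[name], blocked_e[name], s, s + L)
            if j < 0:
                continue
            blocked_s[name].insert(j, s)
            blocked_e[name].insert(j, s + L)
            out_contig[i] = name
            out_start[i] = s
            placed = True
            break
        if not placed:
            raise PlacementError(f"could not place interval of length {L} after "
                                 f"{max_attempts} attempts")
    return out_contig, out_start
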