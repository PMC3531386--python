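"""Inversion candidate generation and features.

Inversions flip the strand of one read of any fragment straddling a
breakpoint, producing same-strand (FF or RR) pairs: FF pairs come from
fragments crossing the left breakpoint, RR pairs from the right one.  The
geometry this implies — distances shrinking as pair coordinates advance, FF
pairs sitting left of RR pairs — is used to filter raw orientation clusters.
Reads that straddle a breakpoint themselves fail to map, so their mates pile
up as singletons near the breakpoints; the peak singleton depth over four
windows anchored on each pair is the second feature.
"""
from __future__ import annotations

import dataclasses
from typing import Sequence

from .io_align import DepthIndex, PairRecord
from .pair_model import InsertModel


@dataclasses.dataclass(slots=True)
class Window:
    """A singleton-counting window with its strand rule."""

    start: int
    end: int
    strand_rule: str  # plus_only / minus_only / both


@dataclasses.dataclass(slots=True)
class InversionCandidate:
    chrom: str
    ff_pairs: list[PairRecord]
    rr_pairs: list[PairRecord]
    f1: int | None = None
    f2: int | None = None

    @property
    def n_pairs(self) -> int:
        return len(self.ff_pairs) + len(self.rr_pairs)

    @property
    def region(self) -> tuple[int, int]:
        members = self.ff_pairs + self.rr_pairs
        return (min(p.left_start for p in members),
                max(p.right_end for p in members))


class _OpenCluster:
    __slots__ = ("ff", "rr", "min_right_end")

    def __init__(self, pair: PairRecord):
        self.ff: list[PairRecord] = []
        self.rr: list[PairRecord] = []
        self.min_right_end = pair.right_end
        self.add(pair)

    def add(self, pair: PairRecord) -> None:
        (self.ff if pair.orient == "FF" else self.rr).append(pair)
        self.min_right_end = min(self.min_right_end, pair.right_end)


def cluster_inversions(
    pairs: Sequence[PairRecord],
    min_cluster: int = 3,
) -> list[InversionCandidate]:
    """Group FF/RR pairs whose outer spans mutually overlap.

    Same greedy multi-open sweep as the deletion module, but on outer spans
    [left_start, right_end) — members of an inversion cluster need not share
    an inner gap.  ``pairs`` must be FF/RR records sorted by
    (chrom, left_start); clusters below ``min_cluster`` are dropped.
    """
    candidates: list[InversionCandidate] = []

    def close(cluster: _OpenCluster, chrom: str) -> None:
        if len(cluster.ff) + len(cluster.rr) >= min_cluster:
            candidates.append(InversionCandidate(
                chrom=chrom, ff_pairs=cluster.ff, rr_pairs=cluster.rr))

    open_clusters: list[_OpenCluster] = []
    current_chrom: str | None = None
    for p in pairs:
        if p.chrom_left != current_chrom:
            for c in open_clusters:
                close(c, current_chrom)
            open_clusters = []
            current_chrom = p.chrom_left
        still_open: list[_OpenCluster] = []
        placed = False
        for c in open_clusters:
            if p.left_start >= c.min_right_end:
                close(c, current_chrom)
                continue
            if not placed:
                # sorted input: p.left_start >= every member's left_start,
                # so mutual overlap reduces to this single comparison
                c.add(p)
                placed = True
            still_open.append(c)
        open_clusters = still_open
        if not placed:
            open_clusters.append(_OpenCluster(p))
    for c in open_clusters:
        close(c, current_chrom)
    candidates.sort(key=lambda c: (c.chrom, c.region))
    return candidates


def inversion_geometry_filter(
    cluster: InversionCandidate,
    model: InsertModel,
    distance_slack: float | None = None,
    spread_limit: str = "first_pair",
) -> bool:
    """Accept a raw cluster only if it has inversion geometry.

    Within each orientation group ordered by left-mate start: (a) mapped
    distances are non-increasing up to ``distance_slack`` (default 2*x*sigma
    — insert-size noise makes a strict check reject genuine clusters);
    (b) the left-mate starts of the first and last pair are no further apart
    than the first pair's mapped distance (``spread_limit='first_pair'``) or
    than the mean insert size (``'mean_insert'``).  (c) If both groups are
    present, every FF left-mate start precedes every RR left-mate start, and
    likewise for the right mates.
    """
    if distance_slack is None:
        distance_slack = 2.0 * model.x * model.sigma

    for group in (cluster.ff_pairs, cluster.rr_pairs):
        if not group:
            continue
        ordered = sorted(group, key=lambda p: (p.left_start, p.right_start))
        # (a) later pairs must not have materially larger distances
        running_min = ordered[0].d
        for p in ordered[1:]:
            if p.d > running_min + distance_slack:
                return False
            running_min = min(running_min, p.d)
        # (b) left-mate spread bounded by the first pair's span
        if len(ordered) >= 2:
            spread = ordered[-1].left_start - ordered[0].left_start
            limit = ordered[0].d if spread_limit == "first_pair" else model.mu
            if spread > limit:
                return False
    if cluster.ff_pairs and cluster.rr_pairs:
        if max(p.left_start for p in cluster.ff_pairs) > \
                min(p.left_start for p in cluster.rr_pairs):
            return False
        if max(p.right_start for p in cluster.ff_pairs) > \
                min(p.right_start for p in cluster.rr_pairs):
            return False
    return True


def singleton_windows(
    pair: PairRecord,
    alpha: int = 300,
    chrom_length: int | None = None,
) -> list[Window]:
    """The four breakpoint-flanking windows of an FF or RR pair.

    With L and R the start positions of the left and right mate:
    W1=[L-alpha, L), W2=[L, L+alpha), W3=[R-alpha, R), W4=[R, R+1.5*alpha).
    For FF pairs W1/W3 count forward-strand singletons only and W2/W4 both
    strands; for RR pairs the one-sided rules are mirrored to the reverse
    strand (mates point away from the breakpoint on the other side).
    Windows are clipped to [0, chrom_length).
    """
    if pair.orient not in ("FF", "RR"):
        raise ValueError("singleton windows are defined for FF/RR pairs")
    one_sided = "plus_only" if pair.orient == "FF" else "minus_only"
    left = pair.left_start
    right = pair.right_start
    ext = int(round(1.5 * alpha))
    raw = [
        Window(left - alpha, left, one_sided),
        Window(left, left + alpha, "both"),
        Window(right - alpha, right, one_sided),
        Window(right, right + ext, "both"),
    ]
    windows = []
    for w in raw:
        start = max(w.start, 0)
        end = w.end if chrom_length is None else min(w.end, chrom_length)
        windows.append(Window(start, max(end, start), w.strand_rule))
    return windows


def inversion_features(
    cluster: InversionCandidate,
    singleton_index: DepthIndex,
    alpha: int = 300,
) -> tuple[int, int]:
    """Feature vector (f1, f2) of a geometry-filtered cluster.

    f1 = max(N(FF), N(RR)) — robust to one-sided support, since validated
    inversions may be covered by only one orientation.  f2 = the peak
    per-base singleton depth over all four windows of all member pairs,
    under each window's strand rule.
    """
    f1 = max(len(cluster.ff_pairs), len(cluster.rr_pairs))
    chrom_length = singleton_index.chrom_lengths.get(cluster.chrom)
    f2 = 0
    for p in cluster.ff_pairs + cluster.rr_pairs:
        for w in singleton_windows(p, alpha, chrom_length):
            if w.end > w.start:
                f2 = max(f2, singleton_index.max_singleton(
                    cluster.chrom, w.start, w.end, w.strand_rule))
    cluster.f1 = f1
    cluster.f2 = f2
    return f1, f2
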