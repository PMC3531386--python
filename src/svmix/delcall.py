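"""Deletion candidate generation: clique clustering of stretched FR pairs
and the (discordant count, concordant depth) feature vector.

Pairs supporting one deletion all contain the deleted segment between their
mates, so "overlap" between two pairs is defined on their *inner* intervals
[left_end, right_start); the candidate interval reported for a cluster is
the intersection of its members' inner intervals — the tightest region every
supporting pair implies.
"""
from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .io_align import DepthIndex, PairRecord
from .pair_model import InsertModel, PairClass


@dataclasses.dataclass(slots=True)
class DeletionCandidate:
    """A cluster of mutually overlapping, similar-span deletion pairs."""

    chrom: str
    pairs: list[PairRecord]
    inner_start: int
    inner_end: int
    concordant_depth: float | None = None

    @property
    def n_discordant(self) -> int:
        return len(self.pairs)

    @property
    def inner_region(self) -> tuple[int, int]:
        return (self.inner_start, self.inner_end)


def select_deletion_pairs(
    pairs: Sequence[PairRecord],
    classes: Sequence[PairClass],
    min_quality: int = 30,
    max_span: int = 100_000,
) -> list[PairRecord]:
    """High-quality DELETION-class pairs with span <= max_span, sorted by
    (chrom, left_start)."""
    kept = [
        p for p, cls in zip(pairs, classes)
        if cls == PairClass.DELETION
        and p.pair_quality >= min_quality
        and p.d <= max_span
    ]
    kept.sort(key=lambda p: (p.chrom_left, p.left_start, p.right_start))
    return kept


def _compatible(a: PairRecord, b: PairRecord, tol: float,
                max_insert: float | None) -> bool:
    """Can two pairs support the same deletion?  Their inner intervals must
    intersect, their distances must agree within ``tol``, and (when
    ``max_insert`` is given) their joint inner region must be wide enough to
    hold the deletion the larger stretch implies (d - width <= mu + x*sigma).
    The last condition stops a borderline-stretched pair lying just outside
    a real event from entering its cluster and pinning the intersection to
    a sliver that could not produce the observed distances."""
    width = (min(a.right_start, b.right_start)
             - max(a.left_end, b.left_end))
    if width <= 0:
        return False
    if abs(a.d - b.d) > tol:
        return False
    if max_insert is not None and max(a.d, b.d) - width > max_insert:
        return False
    return True


def _extract_cliques(
    pool: list[PairRecord], tol: float, max_insert: float | None
) -> list[list[PairRecord]]:
    """Split a set of pairs into compatibility cliques by iteratively
    removing the most-conflicted pair — one that, say, overlaps one member
    but not the others — then reprocessing the removed pairs.
    Deterministic; each pair ends up in exactly one clique."""
    cliques: list[list[PairRecord]] = []
    while pool:
        n = len(pool)
        compat = np.ones((n, n), dtype=bool)
        for i in range(n):
            for j in range(i + 1, n):
                ok = _compatible(pool[i], pool[j], tol, max_insert)
                compat[i, j] = compat[j, i] = ok
        active = np.ones(n, dtype=bool)
        removed_idx: list[int] = []
        rank = np.empty(n, dtype=int)
        rank[sorted(range(n),
                    key=lambda k: (pool[k].left_start, pool[k].right_start,
                                   pool[k].d))] = np.arange(n)
        while True:
            conflicts = (~compat[:, active]).sum(axis=1)
            conflicts[~active] = 0
            worst = int(conflicts.max(initial=0))
            if worst == 0:
                break
            # ties: drop the rightmost (latest-sweeping) offender
            idx = max((k for k in np.flatnonzero(active)
                       if conflicts[k] == worst),
                      key=lambda k: int(rank[k]))
            active[idx] = False
            removed_idx.append(idx)
        kept = [pool[k] for k in np.flatnonzero(active)]
        if kept:
            cliques.append(kept)
        pool = [pool[k] for k in removed_idx]
    return cliques


def cluster_deletions(
    pairs: Sequence[PairRecord],
    min_cluster: int = 3,
    span_tolerance: float = 160.0,
    max_insert: float | None = None,
) -> list[DeletionCandidate]:
    """Cluster deletion pairs into mutual-overlap cliques of similar span.

    Pairs are first split into components connected by inner-interval
    overlap (a left-to-right sweep per chromosome); within each component,
    pairs that conflict with the rest — overlapping some members but not
    others, or differing in mapped distance by more than
    ``span_tolerance`` — are iteratively removed and reprocessed, so every
    emitted cluster is a clique under both conditions and each pair belongs
    to at most one cluster.  Clusters with fewer than ``min_cluster``
    members are discarded.

    ``max_insert`` (the concordance upper bound mu + x*sigma), when given,
    additionally requires member pairs to be jointly consistent with a
    *single* deletion (see :func:`_compatible`).

    ``pairs`` must be sorted by (chrom, left_start); the default tolerance
    corresponds to 2*x*sigma at x=4, sigma=20.
    """
    candidates: list[DeletionCandidate] = []

    def flush(component: list[PairRecord], chrom: str) -> None:
        for clique in _extract_cliques(component, span_tolerance,
                                       max_insert):
            if len(clique) < min_cluster:
                continue
            candidates.append(DeletionCandidate(
                chrom=chrom,
                pairs=clique,
                inner_start=max(p.left_end for p in clique),
                inner_end=min(p.right_start for p in clique),
            ))

    component: list[PairRecord] = []
    max_right = 0
    current_chrom: str | None = None
    for p in sorted(pairs, key=lambda p: (p.chrom_left, p.left_end,
                                          p.right_start)):
        if p.chrom_left != current_chrom or p.left_end >= max_right:
            if component:
                flush(component, current_chrom)
            component = []
            max_right = 0
            current_chrom = p.chrom_left
        component.append(p)
        max_right = max(max_right, p.right_start)
    if component:
        flush(component, current_chrom)
    candidates.sort(key=lambda c: (c.chrom, c.inner_start, c.inner_end))
    return candidates


def default_span_tolerance(model: InsertModel) -> float:
    """Distance-similarity tolerance: 2*x*sigma — two pairs from one event
    differ only by insert-size noise, bounded at the same confidence used to
    declare discordance."""
    return 2.0 * model.x * model.sigma


def deletion_features(
    candidate: DeletionCandidate, depth: DepthIndex
) -> tuple[int, float]:
    """Feature vector (number of discordant pairs, mean concordant depth
    over the candidate's inner region)."""
    assert candidate.inner_end > candidate.inner_start, \
        "candidate inner region is empty"
    mean_depth = depth.mean_concordant(
        candidate.chrom, candidate.inner_start, candidate.inner_end)
    candidate.concordant_depth = mean_depth
    return candidate.n_discordant, mean_depth
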