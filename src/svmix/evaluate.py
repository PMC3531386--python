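"""Benchmarking call sets against truth by 50% reciprocal overlap.

Two events are the same when min(|a^b|/|a|, |a^b|/|b|) >= 0.5.  Matching is
one-to-one and greedy in order of decreasing overlap (equal to the optimal
matching whenever overlaps are distinct); precision, recall and the F-score
(harmonic mean) are computed from the matched counts, and genotype
concordance over the matched deletion pairs.
"""
from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np

from .io_align import VariantCall
from .simulate import TruthEvent

logger = logging.getLogger(__name__)


def reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    """min of the two mutual overlap fractions; 0 when disjoint."""
    (a0, a1), (b0, b1) = a, b
    if a1 <= a0 or b1 <= b0:
        logger.warning("zero-length interval in reciprocal_overlap")
        return 0.0
    inter = min(a1, b1) - max(a0, b0)
    if inter <= 0:
        return 0.0
    return min(inter / (a1 - a0), inter / (b1 - b0))


def f_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (0 when both are 0)."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


@dataclasses.dataclass
class MatchResult:
    n_truth: int
    n_pred: int
    n_tp: int
    precision: float
    recall: float
    f_score: float
    matches: list[tuple[int, int, float]]  # (pred index, truth index, RO)
    genotype_confusion: np.ndarray  # rows: predicted HOM/HET; cols: truth

    @property
    def genotype_concordance(self) -> float:
        total = int(self.genotype_confusion.sum())
        if total == 0:
            return float("nan")
        return float(np.trace(self.genotype_confusion)) / total

    def to_dict(self) -> dict:
        return {
            "n_truth": self.n_truth,
            "n_pred": self.n_pred,
            "n_tp": self.n_tp,
            "precision": self.precision,
            "recall": self.recall,
            "f_score": self.f_score,
            "genotype_confusion": self.genotype_confusion.tolist(),
            "genotype_concordance": self.genotype_concordance,
        }


_GT_INDEX = {"HOM": 0, "HET": 1}


def match_calls(
    calls: Sequence[VariantCall],
    truth: Sequence[TruthEvent],
    threshold: float = 0.5,
) -> MatchResult:
    """One-to-one matching of calls to truth events at a reciprocal-overlap
    threshold.

    Candidate pairs on the same chromosome with overlap >= threshold are
    accepted greedily by decreasing overlap (ties broken by genomic order),
    each truth event and each call matching at most once.
    """
    scored: list[tuple[float, int, int]] = []
    for ti, ev in enumerate(truth):
        for ci, call in enumerate(calls):
            if call.chrom != ev.chrom:
                continue
            ro = reciprocal_overlap((call.start, call.end),
                                    (ev.start, ev.end))
            if ro >= threshold:
                scored.append((ro, ti, ci))
    scored.sort(key=lambda t: (-t[0], truth[t[1]].start, calls[t[2]].start,
                               t[1], t[2]))
    used_truth: set[int] = set()
    used_call: set[int] = set()
    matches: list[tuple[int, int, float]] = []
    for ro, ti, ci in scored:
        if ti in used_truth or ci in used_call:
            continue
        used_truth.add(ti)
        used_call.add(ci)
        matches.append((ci, ti, ro))
    n_tp = len(matches)
    n_pred = len(calls)
    n_truth = len(truth)
    precision = n_tp / n_pred if n_pred else 0.0
    recall = n_tp / n_truth if n_truth else 0.0
    confusion = np.zeros((2, 2), dtype=int)
    for ci, ti, _ in matches:
        call, ev = calls[ci], truth[ti]
        if call.sv_type == "DEL" and ev.sv_type == "DEL" \
                and call.genotype in _GT_INDEX and ev.genotype in _GT_INDEX:
            confusion[_GT_INDEX[call.genotype], _GT_INDEX[ev.genotype]] += 1
    return MatchResult(
        n_truth=n_truth, n_pred=n_pred, n_tp=n_tp,
        precision=precision, recall=recall,
        f_score=f_score(precision, recall),
        matches=sorted(matches),
        genotype_confusion=confusion,
    )
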