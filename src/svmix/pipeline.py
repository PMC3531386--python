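"""End-to-end calling pipelines: alignment records in, variant calls out.

Both pipelines share the same front end — estimate the insert-size model,
classify every pair, index concordant/singleton depth — then build
type-specific candidate clusters, extract the 2-D features, fit the
fixed-G Gaussian mixture and keep the candidates whose argmax component is
an event.
"""
from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np

from . import delcall, invcall, mixture
from .evaluate import reciprocal_overlap
from .io_align import DepthIndex, PairRecord, VariantCall, build_depth_index
from .pair_model import (InsertModel, PairClass, classify_pairs,
                         estimate_insert_model)

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class CallerConfig:
    """Caller parameters (defaults follow the published operating point)."""

    min_mapq: int = 30
    x_sd: float = 4.0
    max_del_span: int = 100_000
    max_inv_span: int = 500_000
    alpha: int = 300
    min_cluster: int = 3
    span_tolerance: float | None = None  # default 2*x*sigma
    geometry_slack: float | None = None  # default 2*x*sigma
    geometry_spread_limit: str = "first_pair"
    em_tol: float = 1e-6
    em_max_iter: int = 500
    em_restarts: int = 0
    seed: int | None = None


@dataclasses.dataclass
class CallResult:
    calls: list[VariantCall]
    insert_model: InsertModel
    mixture_model: mixture.MixtureModel | None
    candidates: list
    assignments: list[mixture.Assignment]
    features: np.ndarray


def _dedupe_calls(
    calls: list[VariantCall], threshold: float = 0.5
) -> list[VariantCall]:
    """Collapse calls reporting the same event: when two calls of the same
    type reciprocally overlap by >= threshold, only the better-supported one
    (more discordant pairs, ties by genomic order) is kept.  Occasional
    duplicates arise when insert-size noise splits one event's pairs into
    two clusters."""
    ranked = sorted(calls, key=lambda c: (-c.n_discordant, c.chrom,
                                          c.start, c.end))
    kept: list[VariantCall] = []
    for call in ranked:
        if any(k.chrom == call.chrom
               and reciprocal_overlap((k.start, k.end),
                                      (call.start, call.end)) >= threshold
               for k in kept):
            continue
        kept.append(call)
    kept.sort(key=lambda c: (c.chrom, c.start, c.end))
    return kept


def _prepare(
    pairs: Sequence[PairRecord],
    config: CallerConfig,
    chrom_lengths: dict[str, int] | None,
) -> tuple[InsertModel, list[PairClass], DepthIndex]:
    model = estimate_insert_model(pairs, x=config.x_sd)
    logger.info("insert model: mu=%.2f sigma=%.2f x=%g",
                model.mu, model.sigma, model.x)
    classes = classify_pairs(pairs, model, max_del_span=config.max_del_span)
    depth = build_depth_index(pairs, classes, min_quality=config.min_mapq,
                              chrom_lengths=chrom_lengths)
    return model, classes, depth


def call_deletions(
    pairs: Sequence[PairRecord],
    config: CallerConfig | None = None,
    chrom_lengths: dict[str, int] | None = None,
) -> CallResult:
    """Deletion calling: stretched-FR clique clusters, (discordant count,
    concordant depth) features, G=3 mixture, HOM/HET genotype labels."""
    config = config or CallerConfig()
    model, classes, depth = _prepare(pairs, config, chrom_lengths)
    selected = delcall.select_deletion_pairs(
        pairs, classes, min_quality=config.min_mapq,
        max_span=config.max_del_span)
    tol = (config.span_tolerance if config.span_tolerance is not None
           else delcall.default_span_tolerance(model))
    candidates = delcall.cluster_deletions(
        selected, min_cluster=config.min_cluster, span_tolerance=tol,
        max_insert=model.upper)
    features = np.array(
        [delcall.deletion_features(c, depth) for c in candidates],
        dtype=float).reshape(-1, 2)
    if len(candidates) < 3:
        logger.warning("only %d deletion candidates; mixture not fitted",
                       len(candidates))
        return CallResult([], model, None, candidates, [], features)
    mix = mixture.fit_em(features, G=3, tol=config.em_tol,
                         max_iter=config.em_max_iter, seed=config.seed,
                         restarts=config.em_restarts)
    label_map = mixture.label_components(mix, "DEL")
    assignments = mixture.classify(features, mix, label_map)
    calls = []
    for cand, a in zip(candidates, assignments):
        if a.label == "NORMAL":
            continue
        calls.append(VariantCall(
            chrom=cand.chrom, start=cand.inner_start, end=cand.inner_end,
            sv_type="DEL",
            genotype="HOM" if a.label == "HOM_DEL" else "HET",
            n_discordant=cand.n_discordant,
            feature2=float(cand.concordant_depth),
            probs=tuple(float(p) for p in a.responsibilities),
            uncertainty=a.uncertainty,
        ))
    calls = _dedupe_calls(calls)
    return CallResult(calls, model, mix, candidates, assignments, features)


def call_inversions(
    pairs: Sequence[PairRecord],
    config: CallerConfig | None = None,
    chrom_lengths: dict[str, int] | None = None,
) -> CallResult:
    """Inversion calling: FF/RR outer-span clusters, geometry filtering,
    (f1, f2) features, G=2 mixture."""
    config = config or CallerConfig()
    model, classes, depth = _prepare(pairs, config, chrom_lengths)
    inv_pairs = [
        p for p, cls in zip(pairs, classes)
        if cls in (PairClass.INVERSION_FF, PairClass.INVERSION_RR)
        and p.pair_quality >= config.min_mapq
        and p.same_chrom and p.d <= config.max_inv_span
    ]
    inv_pairs.sort(key=lambda p: (p.chrom_left, p.left_start, p.right_start))
    raw = invcall.cluster_inversions(inv_pairs,
                                     min_cluster=config.min_cluster)
    clusters = [
        c for c in raw
        if invcall.inversion_geometry_filter(
            c, model, distance_slack=config.geometry_slack,
            spread_limit=config.geometry_spread_limit)
    ]
    logger.info("%d raw inversion clusters, %d pass geometry",
                len(raw), len(clusters))
    features = np.array(
        [invcall.inversion_features(c, depth, alpha=config.alpha)
         for c in clusters], dtype=float).reshape(-1, 2)
    if len(clusters) < 2:
        logger.warning("only %d inversion candidates; mixture not fitted",
                       len(clusters))
        return CallResult([], model, None, clusters, [], features)
    mix = mixture.fit_em(features, G=2, tol=config.em_tol,
                         max_iter=config.em_max_iter, seed=config.seed,
                         restarts=config.em_restarts)
    label_map = mixture.label_components(mix, "INV")
    assignments = mixture.classify(features, mix, label_map)
    calls = []
    for cand, a in zip(clusters, assignments):
        if a.label != "INV":
            continue
        start, end = cand.region
        calls.append(VariantCall(
            chrom=cand.chrom, start=start, end=end, sv_type="INV",
            genotype="NA",
            n_discordant=int(cand.f1),
            feature2=float(cand.f2),
            probs=tuple(float(p) for p in a.responsibilities),
            uncertainty=a.uncertainty,
        ))
    calls = _dedupe_calls(calls)
    return CallResult(calls, model, mix, clusters, assignments, features)
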