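"""Truth-annotated paired-end alignment emulation for a diploid genome with
embedded deletions and inversions.

The generator reproduces the read-pair level consequences of mapping a
sheared diploid donor genome back to its reference, without synthesizing
sequence or running an aligner:

* fragments are sampled per haplotype to a target depth with insert lengths
  N(mu, sd), as 36 bp read pairs;
* on a haplotype carrying a deletion, fragments spanning the excised
  junction reappear in reference coordinates as FR pairs stretched by the
  deletion length, and concordant coverage inside the deleted interval
  drops (to zero for homozygous events, to half for heterozygous ones);
* fragments crossing an inversion boundary come back as FF (left boundary)
  or RR (right boundary) pairs whose mapped distances shrink as their
  coordinates advance — the geometry the inversion filter expects;
* reads that straddle a breakpoint by more than a small margin fail to map,
  so their mates are emitted as strand-annotated singletons that pile up
  around the breakpoints;
* point mutations and sequencing errors are modeled through their mapping
  consequences: a per-read chance of a sub-threshold mapping quality
  (reads with two or more altered bases) and a per-read chance of not
  mapping at all (three or more), both derived from the configured rates;
* repeat-driven mismapping artifacts — the clusters of coherent discordant
  pairs over perfectly normal regions that real aligners produce around
  (inverted) segmental duplications — are emulated by low-support "decoy"
  clusters with deletion-like or inversion-like pair geometry but no
  breakpoint singletons and undisturbed concordant depth.  They populate
  the normal-region class that the fixed-G mixture expects to see.
"""
from __future__ import annotations

import dataclasses
import math
from typing import Iterable, Sequence

import numpy as np

from .io_align import PairRecord, gc_paused

DEFAULT_CHROM = "sim1"


@dataclasses.dataclass
class SimConfig:
    """Simulation conditions.

    Defaults reproduce the reference simulation study: a diploid genome with
    190 non-overlapping deletions (94 homozygous, 96 heterozygous, 100 bp to
    75 kb) and 202 inversions, 36 bp reads, insert N(200, 20), ~31x depth,
    0.1% point mutation and 0.5% sequencing error rates.  The genome is a
    20 Mb single chromosome: event counts and densities, not the underlying
    sequence, drive the caller's behavior, and 20 Mb carries the full event
    set at desk scale.
    """

    genome_length: int = 20_000_000
    chrom: str = DEFAULT_CHROM
    n_deletions: int = 190
    n_hom_del: int = 94
    n_het_del: int = 96
    del_size_range: tuple[int, int] = (100, 75_000)
    n_inversions: int = 202
    inv_size_range: tuple[int, int] = (500, 50_000)
    read_length: int = 36
    insert_mu: float = 200.0
    insert_sd: float = 20.0
    depth: float = 31.0
    mutation_rate: float = 0.001
    error_rate: float = 0.005
    n_decoy_deletions: int = 70
    n_decoy_inversions: int = 80
    decoy_support_mean: float = 5.0
    min_event_gap: int = 500
    breakpoint_margin: int = 5
    base_quality: int = 60
    size_distribution: str = "log_uniform"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_hom_del + self.n_het_del != self.n_deletions:
            raise ValueError("n_hom_del + n_het_del must equal n_deletions")
        if self.size_distribution not in ("log_uniform", "uniform"):
            raise ValueError("size_distribution must be log_uniform or uniform")

    @property
    def per_base_alteration(self) -> float:
        return self.mutation_rate + self.error_rate

    @property
    def p_read_degraded(self) -> float:
        """Chance a read maps with quality below threshold: two or more
        altered bases (one mismatch in a short read barely moves MAPQ)."""
        lam = self.per_base_alteration * self.read_length
        return 1.0 - math.exp(-lam) * (1.0 + lam)

    @property
    def p_read_unmapped(self) -> float:
        """Chance a read fails to map at all: three or more altered bases."""
        lam = self.per_base_alteration * self.read_length
        return 1.0 - math.exp(-lam) * (1.0 + lam + lam * lam / 2.0)


@dataclasses.dataclass(slots=True)
class TruthEvent:
    """A planted structural variant."""

    chrom: str
    start: int
    end: int
    sv_type: str  # DEL / INV
    genotype: str  # HOM / HET

    @property
    def size(self) -> int:
        return self.end - self.start


def _draw_sizes(rng: np.random.Generator, n: int,
                size_range: tuple[int, int], how: str) -> np.ndarray:
    lo, hi = size_range
    if how == "log_uniform":
        return np.exp(rng.uniform(np.log(lo), np.log(hi), n)).astype(np.int64)
    return rng.integers(lo, hi + 1, n)


def _place_intervals(
    rng: np.random.Generator,
    sizes: Sequence[int],
    genome_length: int,
    min_gap: int,
    occupied: list[tuple[int, int]],
    max_tries: int = 1000,
) -> list[tuple[int, int]]:
    """Rejection-sample non-overlapping intervals with a minimum gap."""
    placed: list[tuple[int, int]] = []
    taken = sorted(occupied)
    for size in sizes:
        size = int(size)
        for _ in range(max_tries):
            start = int(rng.integers(0, genome_length - size))
            end = start + size
            lo, hi = start - min_gap, end + min_gap
            if all(e <= lo or s >= hi for s, e in taken):
                placed.append((start, end))
                taken.append((start, end))
                break
        else:
            raise RuntimeError(
                "genome too small for event set: placement failed")
    return placed


def plant_events(config: SimConfig) -> list[TruthEvent]:
    """Place the configured deletions and inversions, non-overlapping with
    a minimum gap, sizes log-uniform on the configured ranges; homozygous
    status is assigned to a random subset of the deletions.  Deterministic
    for a fixed config."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))
    total = config.n_deletions + config.n_inversions
    if total == 0:
        return []
    del_sizes = _draw_sizes(rng, config.n_deletions, config.del_size_range,
                            config.size_distribution)
    inv_sizes = _draw_sizes(rng, config.n_inversions, config.inv_size_range,
                            config.size_distribution)
    if (del_sizes.sum() + inv_sizes.sum()) * 3 > config.genome_length:
        raise RuntimeError("genome too small for event set: total event "
                           "span exceeds a third of the genome")
    intervals = _place_intervals(
        rng, np.concatenate([del_sizes, inv_sizes]),
        config.genome_length, config.min_event_gap, [])
    genotypes = np.array(["HET"] * config.n_deletions, dtype=object)
    hom_idx = rng.permutation(config.n_deletions)[:config.n_hom_del]
    genotypes[hom_idx] = "HOM"
    events = [
        TruthEvent(config.chrom, s, e, "DEL", genotypes[i])
        for i, (s, e) in enumerate(intervals[:config.n_deletions])
    ] + [
        TruthEvent(config.chrom, s, e, "INV", "HET")
        for s, e in intervals[config.n_deletions:]
    ]
    events.sort(key=lambda ev: (ev.start, ev.end))
    return events


def _map_through_deletions(
    starts: np.ndarray,
    read_length: int,
    dseg_donor_starts: np.ndarray,
    dseg_ref_starts: np.ndarray,
    dseg_lengths: np.ndarray,
    margin: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Donor read starts -> reference starts across excised deletions.

    Returns (ref_starts, mapped).  Reads straddling a junction by more than
    ``margin`` on the minor side are unmapped; smaller overhangs are
    soft-clip-anchored to the major side.
    """
    seg = np.searchsorted(dseg_donor_starts, starts, side="right") - 1
    off = starts - dseg_donor_starts[seg]
    ref = dseg_ref_starts[seg] + off
    left_part = dseg_lengths[seg] - off
    crossing = left_part < read_length
    mapped = np.ones(starts.shape, dtype=bool)
    if crossing.any():
        right_part = read_length - left_part
        anchor_left = crossing & (right_part <= margin)
        anchor_right = crossing & (left_part <= margin)
        dead = crossing & ~anchor_left & ~anchor_right
        mapped[dead] = False
        nxt = np.minimum(seg + 1, dseg_donor_starts.shape[0] - 1)
        ref_right = dseg_ref_starts[nxt] + right_part - read_length
        ref = np.where(anchor_right, ref_right, ref)
    return ref, mapped


def _apply_inversions(
    ref_starts: np.ndarray,
    reverse: np.ndarray,
    mapped: np.ndarray,
    read_length: int,
    inv_starts: np.ndarray,
    inv_ends: np.ndarray,
    margin: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mirror reads falling inside inversions; unmap breakpoint straddlers.

    Events are separated by more than a read length, so each read overlaps
    at most one inversion.
    """
    if inv_starts.size == 0:
        return ref_starts, reverse, mapped
    r0 = ref_starts
    r1 = ref_starts + read_length
    idx = np.searchsorted(inv_ends, r0, side="right")
    idx = np.minimum(idx, inv_starts.shape[0] - 1)
    s = inv_starts[idx]
    e = inv_ends[idx]
    ov = np.clip(np.minimum(r1, e) - np.maximum(r0, s), 0, None)
    inside = ov == read_length
    partial = (ov > 0) & ~inside
    outside_part = read_length - ov
    # small overhangs are clipped: treat the read as belonging to the side
    # holding all but <= margin of its bases
    as_outside = partial & (ov <= margin)
    as_inside = partial & (outside_part <= margin) & ~as_outside
    dead = partial & ~as_outside & ~as_inside
    flip = inside | as_inside
    new_start = np.maximum(np.where(flip, s + e - r1, r0), 0)
    new_rev = np.where(flip, ~reverse, reverse)
    new_mapped = mapped & ~dead
    return new_start, new_rev, new_mapped


_ORIENTS = np.array(["FF", "FR", "RF", "RR"])


def _orient_codes(left_rev: np.ndarray, right_rev: np.ndarray) -> np.ndarray:
    return _ORIENTS[left_rev.astype(int) * 2 + right_rev.astype(int)]


def _haplotype_pairs(
    config: SimConfig,
    rng: np.random.Generator,
    deletions: list[tuple[int, int]],
    inversions: list[tuple[int, int]],
) -> list[PairRecord]:
    """Emulated alignments of one haplotype's fragments."""
    rl = config.read_length
    margin = config.breakpoint_margin
    chrom = config.chrom

    dels = sorted(deletions)
    del_total = sum(e - s for s, e in dels)
    donor_len = config.genome_length - del_total
    # donor segments between excised deletions
    ref_bounds = [0] + [x for s, e in dels for x in (s, e)] \
        + [config.genome_length]
    ref_seg_starts = np.array(ref_bounds[0::2], dtype=np.int64)
    ref_seg_ends = np.array(ref_bounds[1::2], dtype=np.int64)
    seg_lengths = ref_seg_ends - ref_seg_starts
    donor_seg_starts = np.concatenate(
        [[0], np.cumsum(seg_lengths)[:-1]]).astype(np.int64)

    inv_starts = np.array(sorted(s for s, _ in inversions), dtype=np.int64)
    inv_ends = np.array(sorted(e for _, e in inversions), dtype=np.int64)

    n_frag = int(round(donor_len * (config.depth / 2.0) / (2 * rl)))
    inserts = rng.normal(config.insert_mu, config.insert_sd, n_frag)
    inserts = np.maximum(np.rint(inserts), 2 * rl).astype(np.int64)
    frag_start = np.floor(
        rng.random(n_frag) * (donor_len - inserts)).astype(np.int64)

    a1 = frag_start
    a2 = frag_start + inserts - rl
    rev1 = np.zeros(n_frag, dtype=bool)
    rev2 = np.ones(n_frag, dtype=bool)

    r1, ok1 = _map_through_deletions(
        a1, rl, donor_seg_starts, ref_seg_starts, seg_lengths, margin)
    r2, ok2 = _map_through_deletions(
        a2, rl, donor_seg_starts, ref_seg_starts, seg_lengths, margin)
    r1, rev1, ok1 = _apply_inversions(
        r1, rev1, ok1, rl, inv_starts, inv_ends, margin)
    r2, rev2, ok2 = _apply_inversions(
        r2, rev2, ok2, rl, inv_starts, inv_ends, margin)

    # mapping consequences of mutations / sequencing errors
    ok1 &= rng.random(n_frag) >= config.p_read_unmapped
    ok2 &= rng.random(n_frag) >= config.p_read_unmapped
    p_pair_degraded = 1.0 - (1.0 - config.p_read_degraded) ** 2
    degraded = rng.random(n_frag) < p_pair_degraded
    quality = np.where(degraded, rng.integers(0, 30, n_frag),
                       config.base_quality)

    both = ok1 & ok2
    swap = r2 < r1
    ls = np.where(swap, r2, r1)
    rs = np.where(swap, r1, r2)
    lrev = np.where(swap, rev2, rev1)
    rrev = np.where(swap, rev1, rev2)
    orients = _orient_codes(lrev, rrev)
    records: list[PairRecord] = []
    with gc_paused():
        for l, r, o, q in zip(ls[both].tolist(), rs[both].tolist(),
                              orients[both].tolist(),
                              quality[both].tolist()):
            records.append(PairRecord(
                chrom_left=chrom, chrom_right=chrom,
                left_start=l, left_end=l + rl,
                right_start=r, right_end=r + rl,
                orient=o, pair_quality=q,
            ))
        for keep, rr, rvs in ((ok1 & ~ok2, r1, rev1),
                              (ok2 & ~ok1, r2, rev2)):
            for start, rev, q in zip(rr[keep].tolist(),
                                     rvs[keep].tolist(),
                                     quality[keep].tolist()):
                records.append(PairRecord(
                    chrom_left=chrom, chrom_right=chrom,
                    left_start=start, left_end=start + rl,
                    right_start=start, right_end=start + rl,
                    orient=None, pair_quality=q,
                    is_singleton=True,
                    singleton_strand="-" if rev else "+",
                ))
    return records


def _decoy_pairs(
    config: SimConfig,
    rng: np.random.Generator,
    truth: Sequence[TruthEvent],
) -> list[PairRecord]:
    """Repeat-artifact clusters: coherent discordant pairs over normal
    regions, with no breakpoint singletons and no effect on concordant
    depth."""
    rl = config.read_length
    chrom = config.chrom
    occupied = [(ev.start, ev.end) for ev in truth]
    records: list[PairRecord] = []

    def quality_draw() -> int:
        p = 1.0 - (1.0 - config.p_read_degraded) ** 2
        if rng.random() < p:
            return int(rng.integers(0, 30))
        return config.base_quality

    n_total = config.n_decoy_deletions + config.n_decoy_inversions
    if n_total == 0:
        return records
    del_sizes = _draw_sizes(rng, config.n_decoy_deletions,
                            config.del_size_range, config.size_distribution)
    inv_sizes = _draw_sizes(rng, config.n_decoy_inversions,
                            config.inv_size_range, config.size_distribution)
    intervals = _place_intervals(
        rng, np.concatenate([del_sizes, inv_sizes]),
        config.genome_length, config.min_event_gap, occupied)

    for s, e in intervals[:config.n_decoy_deletions]:
        k = int(rng.poisson(config.decoy_support_mean))
        for _ in range(k):
            ins = int(max(np.rint(rng.normal(config.insert_mu,
                                             config.insert_sd)), 2 * rl))
            lo, hi = max(s - ins + rl, 0), s - rl
            if hi < lo:
                continue
            f = int(rng.integers(lo, hi + 1))
            records.append(PairRecord(
                chrom_left=chrom, chrom_right=chrom,
                left_start=f, left_end=f + rl,
                right_start=f + ins - rl + (e - s),
                right_end=f + ins + (e - s),
                orient="FR", pair_quality=quality_draw(),
            ))
    for s, e in intervals[config.n_decoy_deletions:]:
        k = int(rng.poisson(config.decoy_support_mean))
        orient = "FF" if rng.random() < 0.5 else "RR"
        for _ in range(k):
            ins = int(max(np.rint(rng.normal(config.insert_mu,
                                             config.insert_sd)), 2 * rl))
            if orient == "FF":
                lo, hi = max(s - ins + rl, 0), s - rl
                if hi < lo:
                    continue
                f = int(rng.integers(lo, hi + 1))
                mirror = s + e - (f + ins)
                left, right = sorted((f, mirror))
                records.append(PairRecord(
                    chrom_left=chrom, chrom_right=chrom,
                    left_start=left, left_end=left + rl,
                    right_start=right, right_end=right + rl,
                    orient="FF", pair_quality=quality_draw(),
                ))
            else:
                lo, hi = max(e - ins + rl, 0), e - rl
                if hi < lo:
                    continue
                f = int(rng.integers(lo, hi + 1))
                mirror = s + e - (f + rl)
                left, right = sorted((mirror, f + ins - rl))
                records.append(PairRecord(
                    chrom_left=chrom, chrom_right=chrom,
                    left_start=left, left_end=left + rl,
                    right_start=right, right_end=right + rl,
                    orient="RR", pair_quality=quality_draw(),
                ))
    return records


def emulate_alignment(
    truth: Sequence[TruthEvent],
    config: SimConfig,
) -> list[PairRecord]:
    """Emulated alignment records of the diploid donor implied by
    ``truth``.  Deterministic for a fixed (truth, config)."""
    ss = np.random.SeedSequence([config.seed, 23])
    rng_assign, rng_h0, rng_h1, rng_decoy = (
        np.random.default_rng(c) for c in ss.spawn(4))

    hap_of_het = {
        id(ev): int(rng_assign.integers(0, 2))
        for ev in truth if ev.genotype == "HET"
    }
    records: list[PairRecord] = []
    for hap, rng in ((0, rng_h0), (1, rng_h1)):
        dels = [(ev.start, ev.end) for ev in truth
                if ev.sv_type == "DEL"
                and (ev.genotype == "HOM" or hap_of_het[id(ev)] == hap)]
        invs = [(ev.start, ev.end) for ev in truth
                if ev.sv_type == "INV"
                and (ev.genotype == "HOM" or hap_of_het[id(ev)] == hap)]
        records.extend(_haplotype_pairs(config, rng, dels, invs))
    records.extend(_decoy_pairs(config, rng_decoy, truth))
    return records


def simulate(config: SimConfig) -> tuple[list[TruthEvent], list[PairRecord]]:
    """Plant events and emulate their alignment records."""
    truth = plant_events(config)
    return truth, emulate_alignment(truth, config)


TRUTH_COLUMNS = ("chrom", "start", "end", "sv_type", "genotype", "score")


def write_truth(truth: Iterable[TruthEvent], path) -> None:
    """BED6-style TSV of truth events (header + sorted rows)."""
    rows = sorted(truth, key=lambda ev: (ev.chrom, ev.start, ev.end))
    with open(path, "w") as fh:
        fh.write("\t".join(TRUTH_COLUMNS) + "\n")
        for ev in rows:
            fh.write(f"{ev.chrom}\t{ev.start}\t{ev.end}\t{ev.sv_type}"
                     f"\t{ev.genotype}\t.\n")


def read_truth(path) -> list[TruthEvent]:
    events: list[TruthEvent] = []
    with open(path) as fh:
        fh.readline()  # header
        for line in fh:
            if not line.strip():
                continue
            chrom, start, end, sv_type, genotype = \
                line.rstrip("\n").split("\t")[:5]
            events.append(TruthEvent(chrom, int(start), int(end),
                                     sv_type, genotype))
    return events
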