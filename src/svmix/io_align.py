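"""Alignment I/O: paired-end records, depth indexes, and call output.

The caller consumes coordinate-level information only: for every read pair we
keep the two mapped intervals, the orientation of the pair in coordinate
order (FR/RF/FF/RR), and a single Phred-like pair quality.  Reads whose mate
failed to map (or was split) are carried as *singletons* — they pile up near
breakpoints and feed the inversion features.
"""
from __future__ import annotations

import contextlib
import dataclasses
import gc
import logging
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pysam

logger = logging.getLogger(__name__)

ORIENTATIONS = ("FR", "RF", "FF", "RR")


@contextlib.contextmanager
def gc_paused():
    """Suspend the cyclic collector during bulk allocation; generational GC
    otherwise rescans multi-million-record lists repeatedly."""
    was_enabled = gc.isenabled()
    gc.disable()
    try:
        yield
    finally:
        if was_enabled:
            gc.enable()


@dataclasses.dataclass(slots=True)
class PairRecord:
    """One mapped read pair (or singleton), normalized so 'left' is the
    lower-coordinate mate for same-chromosome pairs.

    Coordinates are 0-based half-open throughout.
    """

    chrom_left: str
    chrom_right: str
    left_start: int
    left_end: int
    right_start: int
    right_end: int
    orient: str | None  # FR/RF/FF/RR; None for singletons
    pair_quality: int
    is_singleton: bool = False
    singleton_strand: str | None = None  # '+'/'-' when is_singleton

    @property
    def d(self) -> int:
        """Separation distance: right end minus left start."""
        return self.right_end - self.left_start

    @property
    def same_chrom(self) -> bool:
        return self.chrom_left == self.chrom_right

    @property
    def inner(self) -> tuple[int, int]:
        """Inner interval between the two mates, [left_end, right_start)."""
        return (self.left_end, self.right_start)

    @property
    def outer(self) -> tuple[int, int]:
        return (self.left_start, self.right_end)


@dataclasses.dataclass(slots=True)
class VariantCall:
    """A predicted structural-variant event with its mixture posteriors."""

    chrom: str
    start: int
    end: int
    sv_type: str  # DEL or INV
    genotype: str  # HOM / HET / NA
    n_discordant: int
    feature2: float
    probs: tuple[float, ...]
    uncertainty: float


_ORIENT_LOOKUP = {
    (False, True): "FR",
    (True, False): "RF",
    (False, False): "FF",
    (True, True): "RR",
}


def pair_from_reads(
    chrom1: str, start1: int, end1: int, reverse1: bool,
    chrom2: str, start2: int, end2: int, reverse2: bool,
    quality: int,
) -> PairRecord:
    """Assemble a normalized PairRecord from two mapped reads."""
    first = (chrom1, start1, end1, reverse1)
    second = (chrom2, start2, end2, reverse2)
    if (chrom2, start2) < (chrom1, start1):
        first, second = second, first
    orient = _ORIENT_LOOKUP[(first[3], second[3])]
    return PairRecord(
        chrom_left=first[0], chrom_right=second[0],
        left_start=first[1], left_end=first[2],
        right_start=second[1], right_end=second[2],
        orient=orient, pair_quality=quality,
    )


def singleton_from_read(
    chrom: str, start: int, end: int, reverse: bool, quality: int
) -> PairRecord:
    return PairRecord(
        chrom_left=chrom, chrom_right=chrom,
        left_start=start, left_end=end,
        right_start=start, right_end=end,
        orient=None, pair_quality=quality,
        is_singleton=True, singleton_strand="-" if reverse else "+",
    )


def read_pairs(
    alignment_path: str | Path,
    min_pair_quality: int = 0,
    quality_mode: str = "min",
) -> Iterator[PairRecord]:
    """Stream PairRecords from a SAM/BAM file.

    Each pair is emitted once; reads whose mate is unmapped become
    singletons; unmapped/secondary/supplementary/duplicate records are
    skipped.  Pairs below ``min_pair_quality`` are *still emitted* — the
    threshold is applied by downstream filters, which see the recorded
    quality.  ``quality_mode='min'`` uses the minimum of the two mates'
    MAPQs as the pair quality (the minimum-of-single-end convention);
    ``'record'`` uses the leftmost mate's own MAPQ.
    """
    if quality_mode not in ("min", "record"):
        raise ValueError(f"unknown quality_mode: {quality_mode!r}")
    path = str(alignment_path)
    mode = "rb" if path.endswith(".bam") else "r"
    pending: dict[str, pysam.AlignedSegment] = {}
    with pysam.AlignmentFile(path, mode, check_sq=False) as fh:
        for read in fh:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if read.is_duplicate:
                continue
            if not read.is_paired or read.mate_is_unmapped:
                yield singleton_from_read(
                    read.reference_name, read.reference_start,
                    read.reference_end, read.is_reverse,
                    read.mapping_quality,
                )
                continue
            mate = pending.pop(read.query_name, None)
            if mate is None:
                pending[read.query_name] = read
                continue
            if quality_mode == "min":
                quality = min(read.mapping_quality, mate.mapping_quality)
            else:
                left = mate if (
                    (mate.reference_name, mate.reference_start)
                    <= (read.reference_name, read.reference_start)
                ) else read
                quality = left.mapping_quality
            yield pair_from_reads(
                mate.reference_name, mate.reference_start,
                mate.reference_end, mate.is_reverse,
                read.reference_name, read.reference_start,
                read.reference_end, read.is_reverse,
                quality,
            )
    n_missing_mate = len(pending)
    if n_missing_mate:
        logger.warning(
            "%d paired reads had no mate record in the file; skipped",
            n_missing_mate,
        )


class DepthIndex:
    """Per-base depth tracks: concordant-pair read depth and strand-resolved
    singleton depth, one set of arrays per chromosome.

    Only reads meeting the quality threshold at build time contribute.
    """

    def __init__(self, chrom_lengths: dict[str, int]):
        self.chrom_lengths = dict(chrom_lengths)
        self._conc: dict[str, np.ndarray] = {}
        self._sing_plus: dict[str, np.ndarray] = {}
        self._sing_minus: dict[str, np.ndarray] = {}
        self._conc_cum: dict[str, np.ndarray] = {}
        for name, length in self.chrom_lengths.items():
            self._conc[name] = np.zeros(length, dtype=np.int32)
            self._sing_plus[name] = np.zeros(length, dtype=np.int32)
            self._sing_minus[name] = np.zeros(length, dtype=np.int32)

    @staticmethod
    def _accumulate(arr: np.ndarray, starts: np.ndarray, ends: np.ndarray) -> None:
        length = arr.shape[0]
        starts = np.clip(starts, 0, length)
        ends = np.clip(ends, 0, length)
        diff = np.bincount(starts, minlength=length + 1).astype(np.int64)
        diff -= np.bincount(ends, minlength=length + 1)
        arr += np.cumsum(diff[:-1]).astype(np.int32)

    def add_concordant(self, chrom: str, starts, ends) -> None:
        self._accumulate(self._conc[chrom], np.asarray(starts, dtype=np.int64),
                         np.asarray(ends, dtype=np.int64))
        self._conc_cum.pop(chrom, None)

    def add_singletons(self, chrom: str, starts, ends, strands) -> None:
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        strands = np.asarray(strands)
        plus = strands == "+"
        self._accumulate(self._sing_plus[chrom], starts[plus], ends[plus])
        self._accumulate(self._sing_minus[chrom], starts[~plus], ends[~plus])

    def concordant_depth(self, chrom: str) -> np.ndarray:
        return self._conc[chrom]

    def singleton_depth(self, chrom: str, strand: str) -> np.ndarray:
        if strand == "+":
            return self._sing_plus[chrom]
        if strand == "-":
            return self._sing_minus[chrom]
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")

    def mean_concordant(self, chrom: str, start: int, end: int) -> float:
        """Mean concordant read depth over [start, end)."""
        if end <= start:
            raise ValueError("empty interval")
        cum = self._conc_cum.get(chrom)
        if cum is None:
            cum = np.concatenate(
                [[0], np.cumsum(self._conc[chrom], dtype=np.int64)])
            self._conc_cum[chrom] = cum
        length = self.chrom_lengths[chrom]
        s = min(max(start, 0), length)
        e = min(max(end, 0), length)
        if e <= s:
            return 0.0
        return float(cum[e] - cum[s]) / (end - start)

    def max_singleton(self, chrom: str, start: int, end: int,
                      strand_rule: str) -> int:
        """Peak per-base singleton depth over [start, end) under a strand
        rule: 'plus_only', 'minus_only', or 'both'."""
        length = self.chrom_lengths[chrom]
        s = min(max(start, 0), length)
        e = min(max(end, 0), length)
        if e <= s:
            return 0
        if strand_rule == "plus_only":
            window = self._sing_plus[chrom][s:e]
        elif strand_rule == "minus_only":
            window = self._sing_minus[chrom][s:e]
        elif strand_rule == "both":
            window = (self._sing_plus[chrom][s:e].astype(np.int64)
                      + self._sing_minus[chrom][s:e])
        else:
            raise ValueError(f"unknown strand_rule: {strand_rule!r}")
        return int(window.max(initial=0))

    def total_concordant_bases(self) -> int:
        return int(sum(int(a.sum()) for a in self._conc.values()))

    def total_singleton_bases(self) -> int:
        return int(sum(int(a.sum()) for a in self._sing_plus.values())
                   + sum(int(a.sum()) for a in self._sing_minus.values()))


def build_depth_index(
    pairs: Sequence[PairRecord],
    classes: Sequence[str],
    min_quality: int = 30,
    chrom_lengths: dict[str, int] | None = None,
) -> DepthIndex:
    """Build concordant and singleton depth tracks from classified pairs.

    Concordant depth counts read bases of pairs classified NORMAL; singleton
    depth counts singleton reads, per strand.  Both respect ``min_quality``.
    """
    if chrom_lengths is None:
        chrom_lengths = {}
        for p in pairs:
            for chrom, end in ((p.chrom_left, p.left_end),
                               (p.chrom_right, p.right_end)):
                if end > chrom_lengths.get(chrom, 0):
                    chrom_lengths[chrom] = end
    index = DepthIndex(chrom_lengths)

    conc: dict[str, tuple[list[int], list[int]]] = {}
    sing: dict[str, tuple[list[int], list[int], list[str]]] = {}
    with gc_paused():
        for p, cls in zip(pairs, classes):
            if p.pair_quality < min_quality:
                continue
            if p.is_singleton:
                starts, ends, strands = sing.setdefault(
                    p.chrom_left, ([], [], []))
                starts.append(p.left_start)
                ends.append(p.left_end)
                strands.append(p.singleton_strand)
            elif cls == "NORMAL":
                starts, ends = conc.setdefault(p.chrom_left, ([], []))
                starts.append(p.left_start)
                ends.append(p.left_end)
                starts.append(p.right_start)
                ends.append(p.right_end)
    for chrom, (starts, ends) in conc.items():
        index.add_concordant(chrom, starts, ends)
    for chrom, (starts, ends, strands) in sing.items():
        index.add_singletons(chrom, starts, ends, strands)
    return index


CALL_COLUMNS = ("chrom", "start", "end", "sv_type", "genotype",
                "n_discordant", "feature2")


def write_calls(calls: Iterable[VariantCall], out_path: str | Path) -> None:
    """Write calls as a BED-like TSV, sorted by (chrom, start).

    Columns: chrom, start, end, sv_type, genotype, n_discordant, feature2,
    p_comp1..p_compG, uncertainty.  Coordinates are 0-based half-open.
    """
    calls = sorted(calls, key=lambda c: (c.chrom, c.start, c.end))
    n_comp = len(calls[0].probs) if calls else 3
    header = list(CALL_COLUMNS) + [f"p_comp{i + 1}" for i in range(n_comp)] \
        + ["uncertainty"]
    with open(out_path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for c in calls:
            row = [c.chrom, str(c.start), str(c.end), c.sv_type, c.genotype,
                   str(c.n_discordant), f"{c.feature2:.6g}"]
            row += [f"{p:.6g}" for p in c.probs]
            row.append(f"{c.uncertainty:.6g}")
            fh.write("\t".join(row) + "\n")


def read_calls(path: str | Path) -> list[VariantCall]:
    calls: list[VariantCall] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        prob_cols = [i for i, name in enumerate(header)
                     if name.startswith("p_comp")]
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            calls.append(VariantCall(
                chrom=parts[0], start=int(parts[1]), end=int(parts[2]),
                sv_type=parts[3], genotype=parts[4],
                n_discordant=int(parts[5]), feature2=float(parts[6]),
                probs=tuple(float(parts[i]) for i in prob_cols),
                uncertainty=float(parts[header.index("uncertainty")]),
            ))
    return calls


def write_sam(
    pairs: Iterable[PairRecord],
    path: str | Path,
    chrom_lengths: dict[str, int],
    read_length: int | None = None,
) -> None:
    """Emit a minimal SAM file from PairRecords (round-trippable through
    :func:`read_pairs`).  CIGARs are full-length matches."""
    names = list(chrom_lengths)
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": n, "LN": int(chrom_lengths[n])} for n in names],
    }
    tid = {n: i for i, n in enumerate(names)}
    records: list[tuple[int, int, pysam.AlignedSegment]] = []
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for i, p in enumerate(sorted(
                pairs, key=lambda r: (r.chrom_left, r.left_start))):
            qname = f"frag{i}"
            if p.is_singleton:
                a = pysam.AlignedSegment()
                a.query_name = qname
                a.reference_id = tid[p.chrom_left]
                a.reference_start = p.left_start
                a.mapping_quality = p.pair_quality
                length = p.left_end - p.left_start
                a.cigarstring = f"{length}M"
                a.query_sequence = "N" * length
                a.flag = 0x1 | 0x8 | 0x40  # paired, mate unmapped, first
                if p.singleton_strand == "-":
                    a.flag |= 0x10
                a.next_reference_id = -1
                a.next_reference_start = -1
                records.append((tid[p.chrom_left], p.left_start, a))
                continue
            left_rev, right_rev = {
                "FR": (False, True), "RF": (True, False),
                "FF": (False, False), "RR": (True, True)}[p.orient]
            specs = [
                (p.chrom_left, p.left_start, p.left_end, left_rev,
                 p.chrom_right, p.right_start, right_rev, 0x40),
                (p.chrom_right, p.right_start, p.right_end, right_rev,
                 p.chrom_left, p.left_start, left_rev, 0x80),
            ]
            for chrom, start, end, rev, mchrom, mstart, mrev, which in specs:
                a = pysam.AlignedSegment()
                a.query_name = qname
                a.reference_id = tid[chrom]
                a.reference_start = start
                a.mapping_quality = p.pair_quality
                a.cigarstring = f"{end - start}M"
                a.query_sequence = "N" * (end - start)
                a.flag = 0x1 | which
                if rev:
                    a.flag |= 0x10
                if mrev:
                    a.flag |= 0x20
                a.next_reference_id = tid[mchrom]
                a.next_reference_start = mstart
                records.append((tid[chrom], start, a))
        for _, _, a in sorted(records, key=lambda t: (t[0], t[1])):
            out.write(a)
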