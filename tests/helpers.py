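"""Small factories for constructing alignment records in tests."""
from __future__ import annotations

from svmix import PairRecord

READ_LEN = 36


def fr_pair(left_start: int, d: int, chrom: str = "c1", quality: int = 60,
            read_len: int = READ_LEN) -> PairRecord:
    """An FR pair with separation distance d starting at left_start."""
    right_end = left_start + d
    return PairRecord(
        chrom_left=chrom, chrom_right=chrom,
        left_start=left_start, left_end=left_start + read_len,
        right_start=right_end - read_len, right_end=right_end,
        orient="FR", pair_quality=quality,
    )


def orient_pair(orient: str, left_start: int, right_start: int,
                chrom: str = "c1", quality: int = 60,
                read_len: int = READ_LEN) -> PairRecord:
    return PairRecord(
        chrom_left=chrom, chrom_right=chrom,
        left_start=left_start, left_end=left_start + read_len,
        right_start=right_start, right_end=right_start + read_len,
        orient=orient, pair_quality=quality,
    )


def singleton(start: int, strand: str = "+", chrom: str = "c1",
              quality: int = 60, read_len: int = READ_LEN) -> PairRecord:
    return PairRecord(
        chrom_left=chrom, chrom_right=chrom,
        left_start=start, left_end=start + read_len,
        right_start=start, right_end=start + read_len,
        orient=None, pair_quality=quality,
        is_singleton=True, singleton_strand=strand,
    )


def inner_pair(inner_start: int, inner_end: int, chrom: str = "c1",
               quality: int = 60, read_len: int = READ_LEN) -> PairRecord:
    """An FR pair whose inner interval is exactly [inner_start, inner_end)."""
    return PairRecord(
        chrom_left=chrom, chrom_right=chrom,
        left_start=inner_start - read_len, left_end=inner_start,
        right_start=inner_end, right_end=inner_end + read_len,
        orient="FR", pair_quality=quality,
    )
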