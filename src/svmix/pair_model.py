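"""Insert-size model estimation and read-pair classification.

A read pair is classified by its orientation and by where its separation
distance d falls relative to the insert-size model mu +/- x*sigma:

====== ==============  ====================  ==============  ===============
orient d < mu - x*s    mu-x*s <= d <= mu+x*s d > mu + x*s    cross-chromosome
====== ==============  ====================  ==============  ===============
FR     INSERTION       NORMAL                DELETION        TRANSLOC_INTER
RF     TANDEM_DUP      TANDEM_DUP            TANDEM_DUP      TRANSLOC_INTER
FF     INVERSION_FF    INVERSION_FF          INVERSION_FF    TRANSLOC_INTER
RR     INVERSION_RR    INVERSION_RR          INVERSION_RR    TRANSLOC_INTER
====== ==============  ====================  ==============  ===============

Boundaries are closed on the NORMAL side.  FR pairs with d beyond an
optional span cutoff are reclassified TRANSLOC_INTRA instead of entering the
deletion pipeline.
"""
from __future__ import annotations

import dataclasses
import enum
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import norm

from .io_align import PairRecord, gc_paused


class PairClass(str, enum.Enum):
    NORMAL = "NORMAL"
    DELETION = "DELETION"
    INSERTION = "INSERTION"
    INVERSION_FF = "INVERSION_FF"
    INVERSION_RR = "INVERSION_RR"
    TANDEM_DUP = "TANDEM_DUP"
    TRANSLOC_INTRA = "TRANSLOC_INTRA"
    TRANSLOC_INTER = "TRANSLOC_INTER"
    COMPLEX = "COMPLEX"

    def __str__(self) -> str:  # so PairClass.NORMAL == "NORMAL" and prints bare
        return self.value


@dataclasses.dataclass(slots=True)
class InsertModel:
    """Insert-size model: mean mu, standard deviation sigma, and the
    concordance multiplier x defining the bounds mu +/- x*sigma."""

    mu: float
    sigma: float
    x: float

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.x <= 0:
            raise ValueError("x must be > 0")

    @property
    def lower(self) -> float:
        return self.mu - self.x * self.sigma

    @property
    def upper(self) -> float:
        return self.mu + self.x * self.sigma


class InsertModelError(ValueError):
    """Raised when the insert-size model cannot be estimated."""


def _trim_sd_factors(trim_percentiles: tuple[float, float]) -> list[float]:
    """Per-stage shrinkage of the sd of a normal sample under percentile
    trimming (truncated-normal variance), used to de-bias sigma.

    Stage one truncates N(0,1) to its [lo, hi] percentile interval; stage
    two truncates that distribution to its own [lo, hi] percentiles.
    Returns the two successive sd ratios.
    """
    lo, hi = trim_percentiles[0] / 100.0, trim_percentiles[1] / 100.0

    def _truncated_sd(p_lo: float, p_hi: float) -> float:
        a, b = norm.ppf(p_lo), norm.ppf(p_hi)
        z = p_hi - p_lo
        mean = (norm.pdf(a) - norm.pdf(b)) / z
        var = 1.0 + (a * norm.pdf(a) - b * norm.pdf(b)) / z - mean ** 2
        return float(np.sqrt(var))

    mass = hi - lo
    s1 = _truncated_sd(lo, hi)
    s2 = _truncated_sd(lo + lo * mass, lo + hi * mass)
    return [s1, s2 / s1]


def estimate_insert_model(
    pairs: Iterable[PairRecord],
    x: float = 4.0,
    trim_percentiles: tuple[float, float] = (1.0, 99.0),
) -> InsertModel:
    """Estimate the insert model from FR same-chromosome pair separations.

    Distances outside the trim percentiles are discarded and the trim is
    applied once more on the surviving distances, so that the small fraction
    of SV-supporting pairs does not inflate sigma; mu is the mean and sigma
    the sample standard deviation of what remains, corrected for the
    shrinkage percentile trimming inflicts on a normal sample (each applied
    trim stage divides sigma by the matching truncated-normal sd ratio).
    """
    d = np.fromiter(
        (p.d for p in pairs
         if not p.is_singleton and p.same_chrom and p.orient == "FR"),
        dtype=np.float64,
    )
    if d.size < 2:
        raise InsertModelError(
            "cannot estimate insert model: fewer than 2 usable FR pairs")
    factors = _trim_sd_factors(trim_percentiles)
    correction = 1.0
    for factor in factors:
        lo, hi = np.percentile(d, trim_percentiles)
        kept = d[(d >= lo) & (d <= hi)]
        if kept.size >= 2 and kept.size < d.size:
            d = kept
            correction *= factor
    mu = float(d.mean())
    sigma = float(d.std(ddof=1)) / correction if d.size > 1 else 0.0
    return InsertModel(mu=mu, sigma=sigma, x=float(x))


def classify_pair(
    pair: PairRecord,
    model: InsertModel,
    max_del_span: int | None = None,
) -> PairClass:
    """Assign the single class label of a read pair.

    ``max_del_span``, when given, reclassifies over-stretched FR pairs as
    intrachromosomal translocations rather than deletion candidates.
    """
    if pair.is_singleton or pair.orient is None:
        return PairClass.COMPLEX
    if not pair.same_chrom:
        return PairClass.TRANSLOC_INTER
    orient = pair.orient
    if orient == "FF":
        return PairClass.INVERSION_FF
    if orient == "RR":
        return PairClass.INVERSION_RR
    if orient == "RF":
        return PairClass.TANDEM_DUP
    d = pair.d
    if d < model.lower:
        return PairClass.INSERTION
    if d <= model.upper:
        return PairClass.NORMAL
    if max_del_span is not None and d > max_del_span:
        return PairClass.TRANSLOC_INTRA
    return PairClass.DELETION


def classify_pairs(
    pairs: Sequence[PairRecord],
    model: InsertModel,
    max_del_span: int | None = None,
) -> list[PairClass]:
    with gc_paused():
        return [classify_pair(p, model, max_del_span) for p in pairs]
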