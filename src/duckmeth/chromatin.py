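"""H3K9me2 peak-set summaries and interval enrichment testing.

Occupancy, element–peak overlap percentages, and a Fisher exact test on a
contingency table constructed the way bedtools' ``fisher`` does: the genome
is divided into slots of the mean interval length and the table counts
overlapping elements, non-overlapping elements, non-overlapping peaks, and
remaining empty slots.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import stats
from scipy.special import logsumexp

from .intervals import covered_bp, merge

log = logging.getLogger(__name__)

__all__ = [
    "occupancy_fraction",
    "element_overlap",
    "build_contingency",
    "fisher_exact",
    "ContingencyTable",
    "FisherResult",
]


@dataclass(frozen=True)
class ContingencyTable:
    """2×2 counts: overlap, element-only, peak-only, neither."""

    n11: int
    n12: int
    n21: int
    n22: int

    def __post_init__(self):
        if min(self.n11, self.n12, self.n21, self.n22) < 0:
            raise ValueError("contingency counts must be nonnegative")


@dataclass(frozen=True)
class FisherResult:
    table: ContingencyTable
    odds_ratio: float  # NaN when a margin is zero
    p_greater: float
    p_two_sided: float


def occupancy_fraction(peaks, genome) -> float:
    """Fraction of the genome covered by the merged peak set."""
    total = genome.total_bp
    if not peaks:
        return 0.0
    return covered_bp(peaks) / total


def _overlap_flags(elements, peaks, min_bp: int) -> np.ndarray:
    """Per-element flag: intersects >= min_bp of the merged peak set."""
    merged = merge(peaks) if peaks else []
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in {iv.chrom for iv in merged}:
        ivs = sorted((iv.start, iv.end) for iv in merged if iv.chrom == chrom)
        by_chrom[chrom] = (
            np.array([s for s, _ in ivs]),
            np.array([e for _, e in ivs]),
        )
    flags = np.zeros(len(elements), dtype=bool)
    for i, el in enumerate(elements):
        got = by_chrom.get(el.chrom)
        if got is None:
            continue
        starts, ends = got
        j0 = np.searchsorted(ends, el.start, side="right")
        j1 = np.searchsorted(starts, el.end, side="left")
        ov = 0
        for j in range(j0, j1):
            ov += min(el.end, ends[j]) - max(el.start, starts[j])
            if ov >= min_bp:
                break
        flags[i] = ov >= min_bp
    return flags


def element_overlap(elements, peaks, min_bp: int = 1) -> tuple[int, int, float]:
    """Count elements intersecting >= min_bp of any peak.

    Returns (n_overlapping, n_total, percent) with percent = 100 * n/total
    rounded half-away-from-zero to 2 decimals.  Half-open semantics: an
    element ending where a peak starts does not overlap it.
    """
    elements = list(elements)
    if not elements:
        raise ValueError("empty element set")
    if min_bp < 1:
        raise ValueError("min_bp must be >= 1")
    n = int(_overlap_flags(elements, peaks, min_bp).sum())
    total = len(elements)
    pct = float(
        (Decimal(100 * n) / Decimal(total)).quantize(
            Decimal("0.01"), rounding=ROUND_HALF_UP
        )
    )
    return n, total, pct


def build_contingency(elements, peaks, genome, min_bp: int = 1) -> ContingencyTable:
    """Genome-slots contingency table for element/peak co-occurrence.

    n11 = elements overlapping >=1 peak; n12 = elements not overlapping;
    n21 = peaks overlapping no element; n22 = round(G / mean-interval-length)
    minus the other three cells, floored at zero (G = total genome bp, mean
    length over elements and peaks combined).  The slot estimate is isolated
    here so alternative constructions can be swapped in.
    """
    elements, peaks = list(elements), list(peaks)
    if not elements or not peaks:
        raise ValueError("both interval sets must be nonempty")
    el_flags = _overlap_flags(elements, peaks, min_bp)
    pk_flags = _overlap_flags(peaks, elements, min_bp)
    n11 = int(el_flags.sum())
    n12 = len(elements) - n11
    n21 = int((~pk_flags).sum())
    g = genome.total_bp if hasattr(genome, "total_bp") else int(genome)
    mean_len = sum(len(iv) for iv in elements + peaks) / (len(elements) + len(peaks))
    slots = round(g / mean_len)
    n22 = slots - n11 - n12 - n21
    if n22 < 0:
        log.warning("genome smaller than interval union; flooring n22 at 0")
        n22 = 0
    return ContingencyTable(n11, n12, n21, n22)


def fisher_exact(table: ContingencyTable) -> FisherResult:
    """Fisher's exact test on a 2×2 table, computed in log space.

    ``p_greater`` sums the hypergeometric tail at or above the observed
    overlap cell (enrichment); ``p_two_sided`` sums all tables with point
    probability <= the observed one (with a 1+1e-7 relative guard against
    float ties), the standard two-sided convention.
    """
    a, b, c, d = table.n11, table.n12, table.n21, table.n22
    n = a + b + c + d
    if n == 0:
        raise ValueError("all-zero contingency table")
    r1, c1 = a + b, a + c
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    support = np.arange(lo, hi + 1)
    logpmf = stats.hypergeom.logpmf(support, n, c1, r1)
    p_greater = float(np.exp(logsumexp(logpmf[support >= a])))
    obs = logpmf[support == a][0]
    keep = logpmf <= obs + math.log1p(1e-7)
    p_two = float(np.exp(logsumexp(logpmf[keep])))
    odds = (a * d) / (b * c) if b * c > 0 else float("nan")
    return FisherResult(table, odds, min(p_greater, 1.0), min(p_two, 1.0))
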