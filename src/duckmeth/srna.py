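"""Small-RNA size-class profiling.

Angiosperm sRNA populations are dominated by 21-nt miRNAs (DCL1/DCL4) and
24-nt heterochromatic siRNAs (DCL3/RdDM); the length histogram of trimmed
reads is therefore a direct functional readout of which dicer pathways are
active.  Reads are counted per occurrence (abundance, not uniqueness).
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field

from Bio import SeqIO

log = logging.getLogger(__name__)

__all__ = ["read_lengths", "size_profile", "SizeProfile"]


def _open_maybe_gz(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def _sniff_format(path) -> str:
    with _open_maybe_gz(path) as fh:
        for line in fh:
            if line.strip():
                return "fastq" if line.startswith("@") else "fasta"
    return "empty"


def read_lengths(path, min_len: int = 15, keep_ids: set[str] | None = None) -> list[int]:
    """Read lengths from a FASTA/FASTQ file (gzip-aware).

    Reads shorter than ``min_len`` are dropped (count logged), mirroring the
    minimum-length option of standard adapter trimmers.  ``keep_ids``, when
    given, restricts counting to those read ids (e.g. ids an external
    aligner reported as genome-matching).
    """
    fmt = _sniff_format(path)
    if fmt == "empty":
        log.warning("read file %s is empty", path)
        return []
    lengths = []
    dropped = 0
    with _open_maybe_gz(path) as fh:
        for i, rec in enumerate(SeqIO.parse(fh, fmt)):
            if keep_ids is not None and rec.id not in keep_ids:
                continue
            n = len(rec.seq)
            if fmt == "fastq" and len(rec.letter_annotations["phred_quality"]) != n:
                raise ValueError(f"truncated FASTQ record at index {i}")
            if n < min_len:
                dropped += 1
                continue
            lengths.append(n)
    if dropped:
        log.info("dropped %d reads shorter than %d nt", dropped, min_len)
    return lengths


@dataclass(frozen=True)
class SizeProfile:
    """Read-length histogram over a window of size classes."""

    counts: dict[int, int]
    total_in_range: int
    total_seen: int
    fractions: dict[int, float] = field(default_factory=dict)


def size_profile(lengths, range_lo: int = 20, range_hi: int = 25) -> SizeProfile:
    """Count and normalise read lengths within [range_lo, range_hi].

    Fractions are of the in-range total, so they sum to 1 when any read
    falls in range; out-of-range reads contribute only to ``total_seen``.
    """
    if range_lo > range_hi:
        raise ValueError("range_lo > range_hi")
    lengths = list(lengths)
    if not lengths:
        raise ValueError("no reads to profile")
    counts = {n: 0 for n in range(range_lo, range_hi + 1)}
    in_range = 0
    for n in lengths:
        if range_lo <= n <= range_hi:
            counts[n] += 1
            in_range += 1
    if in_range == 0:
        log.warning("no reads inside [%d, %d]", range_lo, range_hi)
        fractions = {n: 0.0 for n in counts}
    else:
        fractions = {n: c / in_range for n, c in counts.items()}
    return SizeProfile(counts, in_range, len(lengths), fractions)
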