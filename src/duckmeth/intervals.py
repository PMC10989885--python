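"""Genomic intervals: container type, overlap arithmetic, and readers.

Internal convention is 0-based half-open throughout; GFF3 (1-based closed)
is converted on read, BED passes through unchanged.
"""

from __future__ import annotations

import os
import tempfile
from dataclasses import dataclass

import numpy as np
import pandas as pd
import gffutils

__all__ = [
    "GenomicInterval",
    "overlaps",
    "merge",
    "covered_bp",
    "read_bed",
    "read_gff3",
]


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open stranded interval (gene, exon, TE, peak, window)."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    feature_type: str = ""
    feature_id: str | None = None

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )

    def __len__(self) -> int:
        return self.end - self.start


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """Half-open overlap test: [100,200) and [200,210) do NOT overlap."""
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def merge(intervals) -> list[GenomicInterval]:
    """Union touching or overlapping intervals per chromosome."""
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    out: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda x: (x.start, x.end))
        cur_s, cur_e = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_e:  # touching counts as mergeable
                cur_e = max(cur_e, iv.end)
            else:
                out.append(GenomicInterval(chrom, cur_s, cur_e, feature_type="merged"))
                cur_s, cur_e = iv.start, iv.end
        out.append(GenomicInterval(chrom, cur_s, cur_e, feature_type="merged"))
    return out


def covered_bp(intervals) -> int:
    """Total bases covered by the union of the intervals."""
    ivs = list(intervals)
    if not ivs:
        return 0
    return sum(len(iv) for iv in merge(ivs))


def check_on_genome(intervals, genome) -> None:
    """Raise if any interval names an unknown chromosome or exceeds its length."""
    lengths = genome.lengths
    for iv in intervals:
        if iv.chrom not in lengths:
            raise ValueError(f"interval on unknown chromosome {iv.chrom!r}")
        if iv.end > lengths[iv.chrom]:
            raise ValueError(
                f"interval [{iv.start},{iv.end}) exceeds {iv.chrom} "
                f"length {lengths[iv.chrom]}"
            )


def read_bed(path, feature_type: str = "") -> list[GenomicInterval]:
    """Read BED3/BED6 into intervals (coordinates pass through unchanged)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    if df.shape[1] < 3:
        raise ValueError(f"{path}: BED needs at least 3 columns")
    out = []
    for row in df.itertuples(index=False):
        name = str(row[3]) if df.shape[1] >= 4 else None
        strand = str(row[5]) if df.shape[1] >= 6 else "."
        out.append(
            GenomicInterval(
                str(row[0]), int(row[1]), int(row[2]),
                strand=strand, feature_type=feature_type, feature_id=name,
            )
        )
    return out


def read_gff3(path) -> dict[str, list[GenomicInterval]]:
    """Extract genes, exons and CDS from GFF3 with Parent linkage.

    Coordinates are converted from 1-based closed to 0-based half-open.
    Exon/CDS records carry the id of their ancestral gene in ``feature_id``.
    Returns ``{"gene": [...], "exon": [...], "CDS": [...]}``.
    """
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    out: dict[str, list[GenomicInterval]] = {"gene": [], "exon": [], "CDS": []}

    def gene_of(feat):
        cur = feat
        seen = set()
        while True:
            parents = list(db.parents(cur, level=1))
            if not parents:
                return cur.id if cur.featuretype == "gene" else None
            cur = parents[0]
            if cur.id in seen:
                return None
            seen.add(cur.id)
            if cur.featuretype == "gene":
                return cur.id

    for ftype in ("gene", "exon", "CDS"):
        for feat in db.features_of_type(ftype):
            fid = feat.id if ftype == "gene" else gene_of(feat)
            out[ftype].append(
                GenomicInterval(
                    feat.seqid, feat.start - 1, feat.end,
                    strand=feat.strand, feature_type=ftype, feature_id=fid,
                )
            )
    return out


def write_bed(intervals, path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            name = iv.feature_id or iv.feature_type or "."
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t.\t{iv.strand}\n")


def position_mask(intervals, chrom_lengths: dict[str, int]) -> dict[str, np.ndarray]:
    """Boolean per-base mask of positions covered by the intervals."""
    masks = {c: np.zeros(n, dtype=bool) for c, n in chrom_lengths.items()}
    for iv in intervals:
        if iv.chrom in masks:
            masks[iv.chrom][iv.start : iv.end] = True
    return masks
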