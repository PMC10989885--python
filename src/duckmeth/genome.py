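"""Genome sequences and strand-aware cytosine context classification.

Plant DNA methylation is analysed in three sequence contexts defined by the
two bases 3' of a cytosine on its own strand: CG, CHG and CHH (H = A, C or T).
CHG splits further into the palindromic CWG (CAG/CTG, W = A or T) and the
non-palindromic CCG; CHH splits into CWA and non-CWA.  Because CG and CWG are
(near-)palindromic, each such cytosine has a symmetric partner on the opposite
strand, forming a dyad whose two methylation states are compared to assess
maintenance-methyltransferase fidelity.

All coordinates are 0-based half-open on the Watson (forward) strand; a
Crick-strand cytosine is stored at the Watson coordinate of its complementary
G, matching the methylpy allc convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "GenomeSequence",
    "load_fasta",
    "classify_context",
    "enumerate_cytosines",
    "pair_dyads",
    "tile_windows",
]

_VALID = set("ACGTN")
_COMP = str.maketrans("ACGTN", "TGCAN")


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


@dataclass
class GenomeSequence:
    """An in-memory genome: ordered named chromosomes over {A,C,G,T,N}.

    ``organelle_flags`` marks contigs (chloroplast/mitochondrion) that serve
    as unmethylated controls for bisulfite nonconversion estimation and are
    excluded from nuclear methylation statistics.
    """

    chrom_names: list[str]
    sequences: dict[str, str]
    organelle_flags: dict[str, bool] = field(default_factory=dict)
    softmask: dict[str, np.ndarray] | None = None

    def __post_init__(self):
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise ValueError("duplicate chromosome names")
        for name in self.chrom_names:
            seq = self.sequences[name]
            bad = set(seq) - _VALID
            if bad:
                raise ValueError(
                    f"invalid characters in {name}: {sorted(bad)}"
                )
        for name in self.chrom_names:
            self.organelle_flags.setdefault(name, False)

    @property
    def lengths(self) -> dict[str, int]:
        return {c: len(self.sequences[c]) for c in self.chrom_names}

    @property
    def total_bp(self) -> int:
        return sum(self.lengths.values())

    def nuclear_chroms(self) -> list[str]:
        return [c for c in self.chrom_names if not self.organelle_flags[c]]


def load_fasta(path, organelle_contigs: set[str] | None = None) -> GenomeSequence:
    """Read a (multi-record, line-wrapped) FASTA into a :class:`GenomeSequence`.

    Sequences are uppercased; the original soft-mask (lowercase) is retained
    as a per-base boolean mask but not otherwise used.  Duplicate record names
    and non-IUPAC characters (anything outside A/C/G/T/N after case folding)
    raise ``ValueError``.
    """
    organelle_contigs = organelle_contigs or set()
    names: list[str] = []
    seqs: dict[str, str] = {}
    masks: dict[str, np.ndarray] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate FASTA record name: {rec.id}")
        raw = str(rec.seq)
        upper = raw.upper()
        bad = set(upper) - _VALID
        if bad:
            raise ValueError(
                f"non-IUPAC character(s) {sorted(bad)} in record {rec.id}"
            )
        names.append(rec.id)
        seqs[rec.id] = upper
        masks[rec.id] = np.frombuffer(raw.encode(), dtype="S1") != np.frombuffer(
            upper.encode(), dtype="S1"
        )
    flags = {n: (n in organelle_contigs) for n in names}
    return GenomeSequence(names, seqs, flags, softmask=masks)


def classify_context(triplet: str) -> tuple[str, str]:
    """Classify a 5'→3' trinucleotide starting with C.

    Returns ``(context_class, symmetry_class)`` where context_class is one of
    CG/CHG/CHH/undefined and symmetry_class one of CG-dyad, CWG-dyad, CCG,
    CWA, CHH (non-CWA), or undefined.  CG needs only the dinucleotide, so
    ``CGN`` is still CG; any other N makes the context undefined.
    """
    triplet = triplet.upper()
    if not triplet or triplet[0] != "C":
        raise ValueError(f"triplet must start with C, got {triplet!r}")
    if len(triplet) < 2 or triplet[1] == "N":
        return "undefined", "undefined"
    b2 = triplet[1]
    if b2 == "G":
        return "CG", "CG-dyad"
    if len(triplet) < 3 or triplet[2] == "N":
        return "undefined", "undefined"
    b3 = triplet[2]
    if b3 == "G":  # CHG
        return "CHG", ("CWG-dyad" if b2 in "AT" else "CCG")
    # CHH
    return "CHH", ("CWA" if (b2 in "AT" and b3 == "A") else "CHH")


def enumerate_cytosines(genome: GenomeSequence, chroms=None) -> pd.DataFrame:
    """Enumerate every cytosine on both strands with its context labels.

    Crick-strand sites (a G on the Watson sequence) are reported at the
    Watson coordinate of the G; their trinucleotide is read 5'→3' on the
    reverse complement.  Sites within 2 bp of the relevant sequence end, or
    whose trinucleotide contains N, carry context ``undefined`` and are
    excluded from downstream statistics.

    Returns a DataFrame with columns chrom, pos, strand, subcontext,
    context, symmetry.
    """
    frames = []
    for chrom in chroms or genome.chrom_names:
        seq = genome.sequences[chrom]
        n = len(seq)
        arr = np.frombuffer(seq.encode(), dtype="S1")
        for strand in "+-":
            if strand == "+":
                idx = np.flatnonzero(arr == b"C")
                subs = [seq[i : i + 3] for i in idx]
            else:
                idx = np.flatnonzero(arr == b"G")
                subs = [_revcomp(seq[max(i - 2, 0) : i + 1]) for i in idx]
            if len(idx) == 0:
                continue
            ctx = np.empty(len(idx), dtype=object)
            sym = np.empty(len(idx), dtype=object)
            for k, t in enumerate(subs):
                if len(t) < 3:
                    # CG decidable from the dinucleotide alone
                    if len(t) == 2 and t[1] == "G":
                        ctx[k], sym[k] = "CG", "CG-dyad"
                    else:
                        ctx[k], sym[k] = "undefined", "undefined"
                else:
                    ctx[k], sym[k] = classify_context(t)
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "pos": idx.astype(np.int64),
                        "strand": strand,
                        "subcontext": [t if len(t) == 3 else t + "N" * (3 - len(t)) for t in subs],
                        "context": ctx,
                        "symmetry": sym,
                    }
                )
            )
    if not frames:
        return pd.DataFrame(
            columns=["chrom", "pos", "strand", "subcontext", "context", "symmetry"]
        )
    out = pd.concat(frames, ignore_index=True)
    out.sort_values(["chrom", "pos", "strand"], inplace=True, kind="mergesort")
    out.reset_index(drop=True, inplace=True)
    return out


def pair_dyads(sites: pd.DataFrame) -> pd.DataFrame:
    """Pair symmetric cytosines into CG and CWG dyads.

    A Watson CG at position *i* pairs with the Crick CG at *i+1*; a Watson
    CAG/CTG at *i* pairs with the Crick CTG/CAG at *i+2*.  CCG sites are
    never paired (the opposite-strand C of a CCG is itself a CG-context
    site).  Returns a DataFrame with columns chrom, watson_pos, crick_pos,
    dyad_kind.
    """
    frames = []
    for kind, offset, symclass in (("CG", 1, "CG-dyad"), ("CWG", 2, "CWG-dyad")):
        w = sites[(sites.strand == "+") & (sites.symmetry == symclass)]
        c = sites[(sites.strand == "-") & (sites.symmetry == symclass)]
        if w.empty or c.empty:
            continue
        merged = w[["chrom", "pos"]].merge(
            c[["chrom", "pos"]].assign(pos=c.pos - offset),
            on=["chrom", "pos"],
            how="inner",
        )
        if merged.empty:
            continue
        frames.append(
            pd.DataFrame(
                {
                    "chrom": merged.chrom,
                    "watson_pos": merged.pos,
                    "crick_pos": merged.pos + offset,
                    "dyad_kind": kind,
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=["chrom", "watson_pos", "crick_pos", "dyad_kind"])
    out = pd.concat(frames, ignore_index=True)
    out.sort_values(["chrom", "watson_pos"], inplace=True, kind="mergesort")
    out.reset_index(drop=True, inplace=True)
    return out


def tile_windows(genome: GenomeSequence, width_bp: int, chroms=None) -> pd.DataFrame:
    """Tile chromosomes into consecutive half-open windows of ``width_bp``.

    The final truncated window is retained and flagged ``partial``.
    """
    if width_bp < 1:
        raise ValueError("window width must be >= 1")
    rows = []
    for chrom in chroms or genome.chrom_names:
        n = len(genome.sequences[chrom])
        for start in range(0, n, width_bp):
            end = min(start + width_bp, n)
            rows.append((chrom, start, end, end - start < width_bp))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "partial"])
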