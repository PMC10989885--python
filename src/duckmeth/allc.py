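"""Reader/writer for allc-style per-cytosine methylation tables.

The allc dialect is a TSV with columns chrom, position (1-based), strand,
trinucleotide context, methylated read count, total read count, and an
optional binary call flag; gzip transparently supported.  Positions are
converted to the package's internal 0-based convention on read.
"""

from __future__ import annotations

import logging

import pandas as pd

from .genome import classify_context

log = logging.getLogger(__name__)

_COLUMNS = ["chrom", "pos", "strand", "subcontext", "mc", "cov"]


def _context_of(sub: str) -> str:
    try:
        return classify_context(sub)[0]
    except ValueError:
        return "undefined"


def read_allc(path, genome=None) -> pd.DataFrame:
    """Read an allc table into a DataFrame with 0-based positions.

    Adds a derived ``context`` column (CG/CHG/CHH/undefined).  When
    ``genome`` is given, each record's base is validated: the reference must
    carry a C at ``pos`` on the record's strand (G on Watson for Crick
    records).  Rows with mc > cov, unknown chromosomes, or a wrong column
    count raise ``ValueError`` with the offending 1-based line number.
    """
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            dtype={0: str, 2: str, 3: str},
        )
    except pd.errors.EmptyDataError:
        log.warning("allc file %s is empty", path)
        return pd.DataFrame(columns=_COLUMNS + ["context"])
    if df.shape[1] < 6:
        raise ValueError(f"{path}: expected >=6 tab-separated columns, got {df.shape[1]}")
    df = df.iloc[:, :6].copy()
    df.columns = _COLUMNS
    df["pos"] = df["pos"].astype(int) - 1  # 1-based -> 0-based
    df["mc"] = df["mc"].astype(int)
    df["cov"] = df["cov"].astype(int)

    bad = df.index[(df.mc > df["cov"]) | (df.mc < 0) | (df["cov"] < 0)]
    if len(bad):
        raise ValueError(f"{path}: mc > cov (or negative count) at line {bad[0] + 1}")
    if not df.strand.isin(["+", "-"]).all():
        line = df.index[~df.strand.isin(["+", "-"])][0] + 1
        raise ValueError(f"{path}: bad strand at line {line}")

    if genome is not None:
        known = set(genome.chrom_names)
        unknown = df.index[~df.chrom.isin(known)]
        if len(unknown):
            raise ValueError(
                f"{path}: unknown chromosome {df.chrom.iloc[unknown[0]]!r} "
                f"at line {unknown[0] + 1}"
            )
        for chrom, grp in df.groupby("chrom", sort=False):
            seq = genome.sequences[chrom]
            for row in grp.itertuples():
                expect = "C" if row.strand == "+" else "G"
                if seq[row.pos] != expect:
                    raise ValueError(
                        f"{path}: line {row.Index + 1}: reference base at "
                        f"{chrom}:{row.pos + 1} is {seq[row.pos]}, expected {expect}"
                    )

    df["context"] = df["subcontext"].map(_context_of)
    return df


def write_allc(records: pd.DataFrame, path) -> None:
    """Write records back to allc TSV (positions re-encoded as 1-based)."""
    out = records[_COLUMNS].copy()
    out["pos"] = out["pos"] + 1
    out["flag"] = 1
    out.to_csv(path, sep="\t", header=False, index=False)
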