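"""Shared fixtures and independent oracles for the test-suite."""

from __future__ import annotations

import math
import re
from fractions import Fraction

import pandas as pd
import pytest

from duckmeth.genome import GenomeSequence
from duckmeth.simulate import SynthConfig, generate_dataset

REVCOMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(s: str) -> str:
    return s.translate(REVCOMP)[::-1]


# ---------------------------------------------------------------- oracles --

def oracle_context_scan(seq: str) -> set[tuple[int, str, str]]:
    """Brute-force regex triple-scan over a sequence and its reverse
    complement; independent of the production classifier."""
    seq = seq.upper()
    n = len(seq)
    out = set()
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        for i, base in enumerate(s):
            if base != "C":
                continue
            tri = s[i : i + 3]
            if len(tri) >= 2 and tri[1] == "G":
                ctx = "CG"
            elif re.fullmatch("C[ACT]G", tri):
                ctx = "CHG"
            elif re.fullmatch("C[ACT][ACT]", tri):
                ctx = "CHH"
            else:
                ctx = "undefined"
            pos = i if strand == "+" else n - 1 - i
            out.add((pos, strand, ctx))
    return out


def oracle_binom_tail(k: int, n: int, p: Fraction) -> Fraction:
    """Exact P(X >= k) by direct summation over the binomial pmf."""
    p = Fraction(p)
    return sum(
        Fraction(math.comb(n, j)) * p**j * (1 - p) ** (n - j) for j in range(k, n + 1)
    )


def oracle_fisher(n11: int, n12: int, n21: int, n22: int):
    """Exact Fisher p-values by full enumeration of the hypergeometric
    support with rational arithmetic."""
    n = n11 + n12 + n21 + n22
    r1, c1 = n11 + n12, n11 + n21
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    denom = math.comb(n, c1)
    pmf = {
        k: Fraction(math.comb(r1, k) * math.comb(n - r1, c1 - k), denom)
        for k in range(lo, hi + 1)
    }
    p_greater = sum(v for k, v in pmf.items() if k >= n11)
    obs = pmf[n11]
    p_two = sum(v for v in pmf.values() if v <= obs)
    return p_greater, p_two


# --------------------------------------------------------------- fixtures --

@pytest.fixture(scope="session")
def default_dataset():
    """The default synthetic fixture shared across tests (read-only)."""
    return generate_dataset(SynthConfig(seed=7))


@pytest.fixture()
def toy_genome():
    return GenomeSequence(
        ["chr1", "chrC"],
        {"chr1": "ACGTACCGGTTACGCAGCTGAA", "chrC": "ACGTACGT"},
        {"chr1": False, "chrC": True},
    )


def make_records(rows):
    """Build a site-record frame from (chrom, pos, strand, subcontext, mc, cov)."""
    from duckmeth.allc import _context_of

    df = pd.DataFrame(
        rows, columns=["chrom", "pos", "strand", "subcontext", "mc", "cov"]
    )
    df["context"] = df["subcontext"].map(_context_of)
    return df
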