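"""Weighted methylation statistics, site calling, symmetry and metaplots.

The central statistic is *weighted methylation*: over a set of cytosines, the
total number of methylated read calls divided by the total number of read
calls.  Weighting by coverage avoids the noise amplification of averaging
per-site ratios at low depth.  Sites are filtered per-site by a minimum
coverage before summation (default 5 reads for aggregates; per-site levels
and strand-symmetry comparisons use a 3-read threshold).

Significantly-methylated sites are called with a one-sided binomial test of
each site's methylated count against the bisulfite nonconversion rate
estimated from an unmethylated organelle contig, with Benjamini–Hochberg FDR
control applied within each sequence context.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .intervals import merge as interval_merge
from .intervals import position_mask
from .stats import bh_correct, binomial_tail

log = logging.getLogger(__name__)

__all__ = [
    "WeightedLevel",
    "NonconversionRate",
    "estimate_nonconversion",
    "call_sites",
    "weighted_methylation",
    "windowed_methylation",
    "subcontext_summary",
    "dyad_levels",
    "metaplot",
]


@dataclass(frozen=True)
class WeightedLevel:
    """Aggregated methylation level for one context over one region set."""

    label: str
    mc_sum: int
    cov_sum: int
    n_sites_used: int
    min_cov_applied: int

    @property
    def level(self) -> float:
        """mc_sum / cov_sum; NaN when no read covers a qualifying site."""
        return self.mc_sum / self.cov_sum if self.cov_sum > 0 else float("nan")


@dataclass(frozen=True)
class NonconversionRate:
    """Bisulfite nonconversion probability from an unmethylated control."""

    epsilon: float
    mc_sum: int
    cov_sum: int


def estimate_nonconversion(records: pd.DataFrame, control_contig: str) -> NonconversionRate:
    """Estimate nonconversion as Σmc/Σcov over the control contig, all contexts.

    The control is an organelle contig (chloroplast) carrying no methylation,
    so any apparent methylated calls there measure the failed-conversion rate.
    """
    ctrl = records[records.chrom == control_contig]
    cov_sum = int(ctrl["cov"].sum())
    if cov_sum == 0:
        raise ValueError(
            f"no coverage on control contig {control_contig!r}; "
            "supply the nonconversion rate manually"
        )
    mc_sum = int(ctrl.mc.sum())
    return NonconversionRate(mc_sum / cov_sum, mc_sum, cov_sum)


def call_sites(
    records: pd.DataFrame,
    epsilon: float,
    alpha: float = 0.05,
    min_cov: int = 1,
) -> pd.DataFrame:
    """Binomial site calls against the nonconversion rate.

    For each site with cov >= ``min_cov``, p = P(X >= mc | n=cov, p=epsilon);
    BH correction is applied separately within each context class (site
    counts and effect sizes differ enormously between contexts).  Returns the
    qualifying records with added ``p_value``, ``q_value`` and
    ``is_methylated`` (q < alpha) columns.
    """
    if not 0.0 <= epsilon <= 1.0:
        raise ValueError("epsilon outside [0, 1]")
    df = records[(records["cov"] >= max(min_cov, 1)) & (records.context != "undefined")].copy()
    if df.empty:
        df["p_value"] = df["q_value"] = pd.Series(dtype=float)
        df["is_methylated"] = pd.Series(dtype=bool)
        return df
    df["p_value"] = binomial_tail(df.mc.to_numpy(), df["cov"].to_numpy(), epsilon)
    df["q_value"] = np.nan
    for _, idx in df.groupby("context").groups.items():
        df.loc[idx, "q_value"] = bh_correct(df.loc[idx, "p_value"].to_numpy())
    df["is_methylated"] = df["q_value"] < alpha
    return df


def _restrict(records: pd.DataFrame, regions) -> pd.DataFrame:
    """Subset records to positions inside a region set (list of intervals)."""
    if regions is None:
        return records
    regions = list(regions)
    if not regions:
        return records.iloc[0:0]
    merged = interval_merge(regions)
    keep = np.zeros(len(records), dtype=bool)
    pos = records.pos.to_numpy()
    chroms = records.chrom.to_numpy()
    for chrom in pd.unique(chroms):
        ivs = [(iv.start, iv.end) for iv in merged if iv.chrom == chrom]
        if not ivs:
            continue
        starts = np.array([s for s, _ in ivs])
        ends = np.array([e for _, e in ivs])
        sel = np.flatnonzero(chroms == chrom)
        p = pos[sel]
        j = np.searchsorted(starts, p, side="right") - 1
        inside = (j >= 0) & (p < ends[np.clip(j, 0, None)])
        keep[sel] = inside
    return records[keep]


def weighted_methylation(
    records: pd.DataFrame,
    regions=None,
    contexts=("CG",),
    min_cov: int = 5,
    label: str | None = None,
) -> WeightedLevel:
    """Weighted methylation level over a region set and context filter.

    Sums methylated and total read counts across all sites with coverage
    >= ``min_cov`` whose context is in ``contexts`` (context classes or
    trinucleotide subcontexts both accepted), then divides.
    """
    if min_cov < 1:
        raise ValueError("min_cov must be >= 1")
    contexts = tuple(contexts)
    df = records[records["cov"] >= min_cov]
    df = df[df.context.isin(contexts) | df.subcontext.isin(contexts)]
    df = _restrict(df, regions)
    return WeightedLevel(
        label or "+".join(contexts),
        int(df.mc.sum()),
        int(df["cov"].sum()),
        len(df),
        min_cov,
    )


def windowed_methylation(
    records: pd.DataFrame,
    windows: pd.DataFrame,
    contexts=("CG", "CHG", "CHH"),
    min_cov: int = 5,
) -> pd.DataFrame:
    """Weighted level per (tiling window, context).

    ``windows`` is the tile_windows frame (chrom, start, end, partial).
    Returns one row per window per context with mc_sum, cov_sum, level
    (NaN where no site qualifies) and the partial flag.
    """
    df = records[(records["cov"] >= min_cov) & records.context.isin(contexts)]
    rows = []
    for chrom, grp in df.groupby("chrom"):
        wins = windows[windows.chrom == chrom]
        if wins.empty:
            continue
        starts = wins.start.to_numpy()
        for ctx, sub in grp.groupby("context"):
            p = sub.pos.to_numpy()
            widx = np.searchsorted(starts, p, side="right") - 1
            ok = widx >= 0
            agg = pd.DataFrame(
                {"w": widx[ok], "mc": sub.mc.to_numpy()[ok], "cov": sub["cov"].to_numpy()[ok]}
            ).groupby("w").sum()
            for i, win in enumerate(wins.itertuples(index=False)):
                mc = int(agg.mc.get(i, 0))
                cov = int(agg["cov"].get(i, 0))
                rows.append(
                    (chrom, win.start, win.end, win.partial, ctx, mc, cov,
                     mc / cov if cov else np.nan)
                )
    # windows with no records at all for a context still get a row
    have = {(r[0], r[1], r[4]) for r in rows}
    for win in windows.itertuples(index=False):
        for ctx in contexts:
            if (win.chrom, win.start, ctx) not in have:
                rows.append((win.chrom, win.start, win.end, win.partial, ctx, 0, 0, np.nan))
    out = pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "partial", "context", "mc_sum", "cov_sum", "level"],
    )
    out.sort_values(["chrom", "start", "context"], inplace=True, kind="mergesort")
    out.reset_index(drop=True, inplace=True)
    return out


_CWA = {"CAA", "CTA"}
_CWG = {"CAG", "CTG"}


def subcontext_summary(records: pd.DataFrame, min_cov: int = 5) -> pd.DataFrame:
    """Weighted level per trinucleotide subcontext with biological rollups.

    CG is reported as a single class (the third base is irrelevant to its
    maintenance); CHG splits into CAG/CTG/CCG and CHH into its nine
    trinucleotides.  Rollups are count-weighted merges: CWG (= CAG+CTG), CCG,
    CWA (= CAA+CTA), and non-CWA CHH; CWA enrichment diagnoses CMT2 activity
    and CWG is the palindromic CHG class used for symmetry analysis.
    """
    df = records[(records["cov"] >= min_cov) & (records.context != "undefined")].copy()
    df["class_"] = np.where(df.context == "CG", "CG", df.subcontext)
    rows = []

    def add(label, sub):
        mc, cov = int(sub.mc.sum()), int(sub["cov"].sum())
        rows.append((label, mc, cov, mc / cov if cov else np.nan, len(sub)))

    base_labels = ["CG", "CAG", "CTG", "CCG"] + sorted(
        {f"C{b2}{b3}" for b2 in "ACT" for b3 in "ACT"}
    )
    for label in base_labels:
        add(label, df[df.class_ == label])
    add("CWG", df[df.subcontext.isin(_CWG)])
    add("CWA", df[(df.context == "CHH") & df.subcontext.isin(_CWA)])
    add("non-CWA-CHH", df[(df.context == "CHH") & ~df.subcontext.isin(_CWA)])
    for ctx in ("CG", "CHG", "CHH"):
        if ctx != "CG":
            add(ctx, df[df.context == ctx])
    return pd.DataFrame(rows, columns=["label", "mc_sum", "cov_sum", "level", "n_sites"])


def dyad_levels(
    records: pd.DataFrame,
    dyads: pd.DataFrame,
    min_cov_per_strand: int = 3,
) -> pd.DataFrame:
    """Per-strand methylation levels of symmetric CG / CWG dyads.

    A dyad is reported only when both strands reach ``min_cov_per_strand``
    reads.  Returns chrom, watson_pos, crick_pos, dyad_kind, per-strand
    mc/cov and levels, and ``abs_delta`` = |watson − crick|; the mean of
    that column is the headline symmetry statistic.
    """
    w = records[records.strand == "+"][["chrom", "pos", "mc", "cov"]].rename(
        columns={"pos": "watson_pos", "mc": "watson_mc", "cov": "watson_cov"}
    )
    c = records[records.strand == "-"][["chrom", "pos", "mc", "cov"]].rename(
        columns={"pos": "crick_pos", "mc": "crick_mc", "cov": "crick_cov"}
    )
    out = dyads.merge(w, on=["chrom", "watson_pos"], how="inner").merge(
        c, on=["chrom", "crick_pos"], how="inner"
    )
    out = out[
        (out.watson_cov >= min_cov_per_strand) & (out.crick_cov >= min_cov_per_strand)
    ].copy()
    out["watson_level"] = out.watson_mc / out.watson_cov
    out["crick_level"] = out.crick_mc / out.crick_cov
    out["abs_delta"] = (out.watson_level - out.crick_level).abs()
    out.reset_index(drop=True, inplace=True)
    return out


def metaplot(
    records: pd.DataFrame,
    loci,
    flank_bp: int = 1000,
    n_windows: int = 20,
    exon_intervals=None,
    contexts=("CG", "CHG", "CHH"),
    min_cov: int = 5,
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Pooled methylation profile across loci: flank / body / flank windows.

    Each locus body (start-to-stop for genes, first-to-last bp for
    transposons) is split into ``n_windows`` proportional windows; the
    ``flank_bp`` upstream and downstream regions are split into ``n_windows``
    fixed-width windows each (flank_bp/n_windows bp).  Minus-strand loci are
    reversed so window 0 is always the 5'-most upstream window.  Each of the
    3*n_windows windows gets a single weighted level pooled across all loci
    (ratio of summed counts, not a mean of per-locus ratios).  For gene loci
    with ``exon_intervals`` given, body windows count only positions inside
    the exonic mask.  Loci shorter than ``n_windows`` bp are skipped.

    Returns a DataFrame with window index (0 .. 3*n_windows-1), segment
    (upstream/body/downstream), context, mc_sum, cov_sum, level.
    """
    df = records[(records["cov"] >= min_cov) & records.context.isin(contexts)]
    exon_masks = None
    if exon_intervals is not None:
        lengths = chrom_lengths or {
            c: int(df[df.chrom == c].pos.max()) + 3 for c in df.chrom.unique()
        }
        for iv in exon_intervals:
            lengths[iv.chrom] = max(lengths.get(iv.chrom, 0), iv.end)
        exon_masks = position_mask(exon_intervals, lengths)

    n_total = 3 * n_windows
    flank_w = flank_bp / n_windows
    ctx_list = list(contexts)
    ctx_index = {c: i for i, c in enumerate(ctx_list)}
    mc_acc = np.zeros((n_total, len(ctx_list)), dtype=np.int64)
    cov_acc = np.zeros((n_total, len(ctx_list)), dtype=np.int64)

    by_chrom = {c: g.sort_values("pos") for c, g in df.groupby("chrom")}
    for locus in loci:
        L = locus.end - locus.start
        if L < n_windows:
            log.warning("locus %s shorter than %d bp, skipped", locus.feature_id, n_windows)
            continue
        grp = by_chrom.get(locus.chrom)
        if grp is None:
            continue
        pos = grp.pos.to_numpy()
        lo, hi = locus.start - flank_bp, locus.end + flank_bp
        i0, i1 = np.searchsorted(pos, [lo, hi])
        if i0 == i1:
            continue
        p = pos[i0:i1]
        mc = grp.mc.to_numpy()[i0:i1]
        cov = grp["cov"].to_numpy()[i0:i1]
        ctx = grp.context.to_numpy()[i0:i1]

        gidx = np.empty(len(p), dtype=np.int64)
        up = p < locus.start
        down = p >= locus.end
        body = ~up & ~down
        gidx[up] = np.minimum(
            ((p[up] - lo) / flank_w).astype(np.int64), n_windows - 1
        )
        gidx[body] = n_windows + (p[body] - locus.start) * n_windows // L
        gidx[down] = 2 * n_windows + np.minimum(
            ((p[down] - locus.end) / flank_w).astype(np.int64), n_windows - 1
        )
        keep = np.ones(len(p), dtype=bool)
        if exon_masks is not None and locus.feature_type == "gene":
            mask = exon_masks.get(locus.chrom)
            if mask is not None:
                keep[body] = mask[p[body]]
        if locus.strand == "-":
            gidx = n_total - 1 - gidx
        for k in np.flatnonzero(keep):
            ci = ctx_index[ctx[k]]
            mc_acc[gidx[k], ci] += mc[k]
            cov_acc[gidx[k], ci] += cov[k]

    seg = (["upstream"] * n_windows + ["body"] * n_windows + ["downstream"] * n_windows)
    rows = []
    for wdx in range(n_total):
        for c in ctx_list:
            ci = ctx_index[c]
            covs = int(cov_acc[wdx, ci])
            rows.append(
                (wdx, seg[wdx], c, int(mc_acc[wdx, ci]), covs,
                 mc_acc[wdx, ci] / covs if covs else np.nan)
            )
    return pd.DataFrame(
        rows, columns=["window", "segment", "context", "mc_sum", "cov_sum", "level"]
    )
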