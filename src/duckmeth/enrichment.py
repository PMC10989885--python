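"""Per-feature methylation-enrichment tests and gbM classification.

Gene body methylation (gbM) is CG-only methylation enrichment inside a
gene's coding exons with no accompanying CHG/CHH enrichment.  Each feature
is tested per context with a one-sided binomial test whose success
probability is the genome-wide weighted level over all counted positions of
features of that type (the background), followed by Benjamini–Hochberg FDR
control across features within each context.

Two counting bases are supported: *reads* (successes = methylated read
calls, trials = total read calls) and *sites* (successes = significantly
methylated cytosines, trials = covered cytosines); default reads.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .methylation import _restrict
from .stats import bh_correct, binomial_tail

__all__ = [
    "collect_feature_counts",
    "background_rates",
    "binomial_enrichment",
    "classify_features",
    "enriched_fraction",
    "gbm_set_overlap",
    "expression_filter",
]

CONTEXTS = ("CG", "CHG", "CHH")


def collect_feature_counts(
    records: pd.DataFrame,
    features,
    feature_regions: dict[str, list] | None = None,
    counting_basis: str = "reads",
    min_cov: int = 3,
    site_calls: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-feature, per-context counts over each feature's counted positions.

    ``features`` are gene or TE intervals; for genes, ``feature_regions``
    maps feature_id -> list of coding-exon intervals that restrict the
    counted positions (TEs use their full span).  Sites below ``min_cov``
    are ignored.  With ``counting_basis="sites"`` the significant-site flags
    from ``site_calls`` (output of :func:`duckmeth.methylation.call_sites`)
    define successes.

    Returns one row per (feature, context): feature_id, feature_type,
    context, mc_sum, cov_sum, n_sites, n_methylated_sites, successes,
    trials, insufficient_data.
    """
    if counting_basis not in ("reads", "sites"):
        raise ValueError("counting_basis must be 'reads' or 'sites'")
    if counting_basis == "sites" and site_calls is None:
        raise ValueError("sites basis requires site_calls")

    df = records[(records["cov"] >= min_cov) & records.context.isin(CONTEXTS)]
    if counting_basis == "sites":
        called = site_calls[["chrom", "pos", "strand", "is_methylated"]]
        df = df.merge(called, on=["chrom", "pos", "strand"], how="left")
        df = df.fillna({"is_methylated": False})

    rows = []
    for feat in features:
        regions = None
        if feature_regions is not None and feat.feature_id in feature_regions:
            regions = feature_regions[feat.feature_id]
        if regions is None:
            regions = [feat]
        sub = _restrict(df, regions)
        for ctx in CONTEXTS:
            s = sub[sub.context == ctx]
            mc, cov, n = int(s.mc.sum()), int(s["cov"].sum()), len(s)
            nm = int(s.is_methylated.sum()) if counting_basis == "sites" else 0
            successes, trials = (nm, n) if counting_basis == "sites" else (mc, cov)
            rows.append(
                (feat.feature_id, feat.feature_type, ctx, mc, cov, n, nm,
                 successes, trials, n == 0)
            )
    return pd.DataFrame(
        rows,
        columns=["feature_id", "feature_type", "context", "mc_sum", "cov_sum",
                 "n_sites", "n_methylated_sites", "successes", "trials",
                 "insufficient_data"],
    )


def background_rates(counts: pd.DataFrame) -> dict[str, float]:
    """Per-context success probability: pooled successes/trials over features.

    With the reads basis this is the weighted methylation level over all
    counted positions of all features; with the sites basis it is the
    fraction of covered sites called methylated.
    """
    out = {}
    for ctx in CONTEXTS:
        sub = counts[counts.context == ctx]
        trials = int(sub.trials.sum())
        out[ctx] = int(sub.successes.sum()) / trials if trials else 0.0
    return out


def binomial_enrichment(
    counts: pd.DataFrame,
    background: dict[str, float],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-sided upper-tail binomial enrichment p-values with BH q-values.

    Features with no counted positions in a context are flagged
    insufficient-data and excluded from testing and from the BH batch.
    Returns ``counts`` with p_value, q_value and enriched columns added.
    """
    out = counts.copy()
    out["p_value"] = np.nan
    out["q_value"] = np.nan
    out["enriched"] = False
    for ctx in CONTEXTS:
        sel = (out.context == ctx) & (~out.insufficient_data) & (out.trials > 0)
        if not sel.any():
            continue
        p0 = background[ctx]
        p = binomial_tail(
            out.loc[sel, "successes"].to_numpy(),
            out.loc[sel, "trials"].to_numpy(),
            p0,
        )
        out.loc[sel, "p_value"] = p
        q = bh_correct(np.atleast_1d(p))
        out.loc[sel, "q_value"] = q
        out.loc[sel, "enriched"] = q < alpha
    return out


def classify_features(enrich: pd.DataFrame) -> pd.DataFrame:
    """Collapse per-context enrichment flags into a methylation class.

    gbM requires CG enrichment with neither CHG nor CHH enrichment; any CHG
    or CHH enrichment (regardless of CG) is ``CHG/CHH-enriched``; no
    enrichment anywhere is ``unmethylated``; a feature with no usable CG
    data is ``insufficient-data``.
    """
    rows = []
    for fid, grp in enrich.groupby("feature_id", sort=False):
        flags = {r.context: bool(r.enriched) for r in grp.itertuples()}
        insuff = {r.context: bool(r.insufficient_data) for r in grp.itertuples()}
        if insuff.get("CG", True) and not any(flags.values()):
            cls = "insufficient-data"
        elif flags.get("CHG") or flags.get("CHH"):
            cls = "CHG/CHH-enriched"
        elif flags.get("CG"):
            cls = "gbM"
        else:
            cls = "unmethylated"
        rows.append((fid, flags.get("CG", False), flags.get("CHG", False),
                     flags.get("CHH", False), cls))
    return pd.DataFrame(
        rows, columns=["feature_id", "cg_enriched", "chg_enriched",
                       "chh_enriched", "methylation_class"]
    )


def enriched_fraction(n_enriched: int, n_total: int, decimals: int = 3) -> float:
    """Fraction of enriched features, rounded half-away-from-zero."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_enriched <= n_total:
        raise ValueError("n_enriched outside [0, n_total]")
    frac = Decimal(n_enriched) / Decimal(n_total)
    return float(frac.quantize(Decimal(1).scaleb(-decimals), rounding=ROUND_HALF_UP))


def gbm_set_overlap(
    gbm_a: set[str], gbm_b: set[str], ortholog_map: dict[str, str]
) -> dict:
    """Cross-genotype overlap of gbM gene sets under an ortholog pairing.

    ``ortholog_map`` maps genotype-A ids to genotype-B ids (one-to-one).
    Returns the count of ortholog pairs gbM in both, the Jaccard index over
    mapped gbM genes, and the ids that had no ortholog.
    """
    mapped_a = {a for a in gbm_a if a in ortholog_map}
    unmapped = sorted((gbm_a - mapped_a) | {b for b in gbm_b if b not in set(ortholog_map.values())})
    both = {a for a in mapped_a if ortholog_map[a] in gbm_b}
    union = mapped_a | {a for a, b in ortholog_map.items() if b in gbm_b}
    jaccard = len(both) / len(union) if union else 0.0
    return {
        "overlap": len(both),
        "jaccard": jaccard,
        "n_unmapped": len(unmapped),
        "unmapped_ids": unmapped,
    }


def read_ortholog_map(path) -> dict[str, str]:
    """Read a two-column TSV (id_A, id_B) into a one-to-one id mapping."""
    df = pd.read_csv(path, sep="\t", header=None, names=["id_a", "id_b"], dtype=str)
    if df.id_a.duplicated().any() or df.id_b.duplicated().any():
        raise ValueError(f"{path}: ortholog map must be one-to-one")
    return dict(zip(df.id_a, df.id_b))


def read_expression(path) -> pd.DataFrame:
    """Read a gene-expression TSV (gene_id, fpkm)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "fpkm"],
                     dtype={0: str, 1: float})
    return df


def expression_filter(expression: pd.DataFrame, threshold: float = 1.0) -> pd.DataFrame:
    """Flag genes as expressed when FPKM >= threshold (boundary inclusive)."""
    if (expression.fpkm < 0).any():
        raise ValueError("negative FPKM")
    out = expression.copy()
    out["expressed"] = out.fpkm >= threshold
    return out
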