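"""End-to-end orchestration: contexts → methylation stats → gbM → chromatin → sRNA.

Every stage is a pure function of (inputs, config); the only randomness in
the package lives in the synthetic-data generator, so reruns on the same
inputs produce byte-identical summaries.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import allc as allc_io
from . import chromatin, enrichment, methylation, srna
from .genome import enumerate_cytosines, load_fasta, pair_dyads, tile_windows
from .intervals import read_bed, read_gff3

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_all"]


@dataclass
class RunConfig:
    """Input paths and analysis thresholds for a full pipeline run."""

    fasta: str
    allc: str
    gff3: str | None = None
    ltr_bed: str | None = None
    peaks_bed: str | None = None
    srna_reads: str | None = None
    control_contig: str | None = None
    epsilon: float | None = None        # overrides the control-contig estimate
    out_dir: str = "duckmeth_out"
    min_cov_aggregate: int = 5
    min_cov_site: int = 3
    alpha: float = 0.05
    window_bp: int = 50_000
    flank_bp: int = 1_000
    n_windows: int = 20
    counting_basis: str = "reads"
    srna_range: tuple[int, int] = (20, 25)
    srna_min_len: int = 15
    seed: int = 0

    def __post_init__(self):
        for v in (self.min_cov_aggregate, self.min_cov_site, self.window_bp,
                  self.flank_bp, self.n_windows):
            if v <= 0:
                raise ValueError("thresholds must be positive")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        raw = json.loads(text)
        if "srna_range" in raw:
            raw["srna_range"] = tuple(raw["srna_range"])
        return cls(**raw)


def _round6(x):
    if x is None:
        return None
    if isinstance(x, float):
        return None if np.isnan(x) else round(x, 6)
    return x


def run_all(config: RunConfig) -> dict:
    """Execute every stage and write per-stage TSVs plus a JSON summary.

    Returns the summary dict; files land in ``config.out_dir``.
    """
    os.makedirs(config.out_dir, exist_ok=True)
    summary: dict = {"config": json.loads(config.to_json())}

    organelle = {config.control_contig} if config.control_contig else set()
    genome = load_fasta(config.fasta, organelle_contigs=organelle)
    records = allc_io.read_allc(config.allc, genome)
    nuclear = records[~records.chrom.isin(organelle)]

    # nonconversion
    if config.epsilon is not None:
        eps = config.epsilon
        summary["nonconversion"] = {"epsilon": eps, "source": "manual"}
    elif config.control_contig:
        nc = methylation.estimate_nonconversion(records, config.control_contig)
        eps = nc.epsilon
        summary["nonconversion"] = {
            "epsilon": _round6(eps), "mc_sum": nc.mc_sum, "cov_sum": nc.cov_sum,
            "source": config.control_contig,
        }
    else:
        raise ValueError("need either a control contig or an explicit epsilon")

    # global weighted levels and subcontext decomposition
    summary["global_levels"] = {
        ctx: _round6(
            methylation.weighted_methylation(
                nuclear, contexts=(ctx,), min_cov=config.min_cov_aggregate
            ).level
        )
        for ctx in ("CG", "CHG", "CHH")
    }
    subs = methylation.subcontext_summary(nuclear, min_cov=config.min_cov_aggregate)
    subs.to_csv(os.path.join(config.out_dir, "subcontexts.tsv"), sep="\t", index=False)
    summary["subcontext_levels"] = {
        r.label: _round6(r.level) for r in subs.itertuples()
    }

    # per-site binomial calls
    calls = methylation.call_sites(nuclear, eps, alpha=config.alpha,
                                   min_cov=config.min_cov_site)
    frac = {}
    for ctx in ("CG", "CHG", "CHH"):
        sub = calls[calls.context == ctx]
        frac[ctx] = _round6(float(sub.is_methylated.mean())) if len(sub) else None
    summary["site_call_fraction"] = frac

    # 50-kb windows
    windows = tile_windows(genome, config.window_bp, chroms=genome.nuclear_chroms())
    win = methylation.windowed_methylation(
        nuclear, windows, min_cov=config.min_cov_aggregate
    )
    win.to_csv(os.path.join(config.out_dir, "windows.tsv"), sep="\t", index=False)

    # strand symmetry over CG/CWG dyads
    sites = enumerate_cytosines(genome, chroms=genome.nuclear_chroms())
    dyads = pair_dyads(sites)
    dl = methylation.dyad_levels(nuclear, dyads, min_cov_per_strand=config.min_cov_site)
    dl.to_csv(os.path.join(config.out_dir, "dyads.tsv"), sep="\t", index=False)
    summary["dyad_symmetry"] = {}
    for kind in ("CG", "CWG"):
        sub = dl[dl.dyad_kind == kind]
        entry = {"n_dyads": len(sub)}
        if len(sub):
            # per-dyad |Δ| carries a binomial sampling floor at finite
            # coverage; the aggregate strand difference and the dyad
            # correlation converge to 0 / 1 under symmetric maintenance
            entry["mean_abs_delta"] = _round6(float(sub.abs_delta.mean()))
            entry["strand_level_difference"] = _round6(
                abs(
                    sub.watson_mc.sum() / sub.watson_cov.sum()
                    - sub.crick_mc.sum() / sub.crick_cov.sum()
                )
            )
            if len(sub) > 2 and sub.watson_level.std() > 0 and sub.crick_level.std() > 0:
                entry["pearson_r"] = _round6(
                    float(np.corrcoef(sub.watson_level, sub.crick_level)[0, 1])
                )
        summary["dyad_symmetry"][kind] = entry

    genes = exons = None
    if config.gff3:
        ann = read_gff3(config.gff3)
        genes, exons = ann["gene"], ann["CDS"] or ann["exon"]
        meta = methylation.metaplot(
            nuclear, genes, flank_bp=config.flank_bp, n_windows=config.n_windows,
            exon_intervals=exons, min_cov=config.min_cov_aggregate,
            chrom_lengths=genome.lengths,
        )
        meta.to_csv(os.path.join(config.out_dir, "metaplot_genes.tsv"),
                    sep="\t", index=False)

        # gbM calling over coding-exonic positions
        regions = {}
        for e in exons:
            regions.setdefault(e.feature_id, []).append(e)
        nuclear_genes = [g for g in genes if g.chrom not in organelle]
        counts = enrichment.collect_feature_counts(
            nuclear, nuclear_genes, feature_regions=regions,
            counting_basis=config.counting_basis, min_cov=config.min_cov_site,
            site_calls=calls if config.counting_basis == "sites" else None,
        )
        bg = enrichment.background_rates(counts)
        tested = enrichment.binomial_enrichment(counts, bg, alpha=config.alpha)
        classes = enrichment.classify_features(tested)
        tested.merge(classes, on="feature_id").to_csv(
            os.path.join(config.out_dir, "gene_enrichment.tsv"), sep="\t", index=False
        )
        cc = classes.methylation_class.value_counts()
        summary["gbm"] = {
            "background": {k: _round6(v) for k, v in bg.items()},
            "n_genes_tested": len(classes),
            "n_gbm": int(cc.get("gbM", 0)),
            "n_chg_chh_enriched": int(cc.get("CHG/CHH-enriched", 0)),
            "n_unmethylated": int(cc.get("unmethylated", 0)),
            "n_insufficient": int(cc.get("insufficient-data", 0)),
        }

    ltrs = None
    if config.ltr_bed:
        ltrs = read_bed(config.ltr_bed, feature_type="LTR")
        counts = enrichment.collect_feature_counts(
            nuclear, ltrs, counting_basis=config.counting_basis,
            min_cov=config.min_cov_site,
            site_calls=calls if config.counting_basis == "sites" else None,
        )
        bg = enrichment.background_rates(counts)
        tested = enrichment.binomial_enrichment(counts, bg, alpha=config.alpha)
        chh = tested[tested.context == "CHH"]
        n_enr = int(chh.enriched.sum())
        summary["ltr_chh"] = {
            "n_enriched": n_enr,
            "n_total": len(chh),
            "fraction": enrichment.enriched_fraction(n_enr, len(chh), 3)
            if len(chh) else None,
        }
        tested.to_csv(os.path.join(config.out_dir, "ltr_enrichment.tsv"),
                      sep="\t", index=False)

    if config.peaks_bed:
        peaks = read_bed(config.peaks_bed, feature_type="peak")
        occ = chromatin.occupancy_fraction(peaks, genome)
        summary["h3k9me2"] = {"occupancy_fraction": _round6(occ)}
        if ltrs:
            n, total, pct = chromatin.element_overlap(ltrs, peaks)
            table = chromatin.build_contingency(ltrs, peaks, genome)
            fr = chromatin.fisher_exact(table)
            summary["h3k9me2"].update(
                {
                    "ltr_overlap": {"n": n, "total": total, "percent": pct},
                    "fisher": {
                        "table": [table.n11, table.n12, table.n21, table.n22],
                        "odds_ratio": _round6(fr.odds_ratio),
                        "p_greater": float(f"{fr.p_greater:.6g}"),
                        "p_two_sided": float(f"{fr.p_two_sided:.6g}"),
                    },
                }
            )

    if config.srna_reads:
        lengths = srna.read_lengths(config.srna_reads, min_len=config.srna_min_len)
        prof = srna.size_profile(lengths, *config.srna_range)
        summary["srna"] = {
            "total_reads": prof.total_seen,
            "in_range": prof.total_in_range,
            "fractions": {str(k): _round6(v) for k, v in prof.fractions.items()},
        }
        pd.DataFrame(
            {"length": list(prof.counts), "count": list(prof.counts.values()),
             "fraction": [prof.fractions[k] for k in prof.counts]}
        ).to_csv(os.path.join(config.out_dir, "srna_profile.tsv"), sep="\t", index=False)

    with open(os.path.join(config.out_dir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
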