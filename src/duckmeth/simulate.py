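"""Seeded generator of a miniature duckweed-like test dataset.

Emits a small random genome with gene/exon and LTR-retrotransposon
annotations, an allc-style methylation table with a known per-site truth,
H3K9me2-like peak intervals, and a small-RNA FASTQ — everything the analysis
stages consume, with no downloads.  The defaults emulate the structure of a
compact aquatic-monocot methylome: ~10% of CG dyads methylated at high
level, weak CHG methylation confined to the palindromic CWG subcontext,
essentially absent CHH methylation, symmetric maintenance across strands,
CG-methylated LTR clusters, a single pericentromeric heterochromatin domain
per chromosome, a 21-nt-dominant sRNA population with scarce 24-nt reads,
and an unmethylated chloroplast contig whose apparent methylation measures
bisulfite nonconversion.  Scale is reduced (~200 kb) so the full pipeline
runs in seconds; the structure, not the size, is what is emulated.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GenomeSequence, enumerate_cytosines, pair_dyads, _revcomp
from .intervals import GenomicInterval, position_mask, write_bed

__all__ = ["SynthConfig", "SyntheticDataset", "generate_dataset"]


def _default_srna_weights() -> dict[int, float]:
    # 21-nt miRNAs dominant, 24-nt het-siRNAs nearly absent
    return {20: 0.06, 21: 0.70, 22: 0.12, 23: 0.06, 24: 0.02, 25: 0.04}


@dataclass
class SynthConfig:
    """Knobs of the synthetic methylome; the defaults are the study conditions.

    Probabilities are per-dyad (or per-site when ``symmetric_maintenance``
    is off) chances of being methylated; methylated sites draw their true
    level from a Beta distribution with the stated mean and
    ``beta_concentration``.
    """

    seed: int = 0
    n_chroms: int = 4                 # stands in for the species' 20
    chrom_len_bp: int = 50_000
    gc_fraction: float = 0.40
    n_genes: int = 48
    exons_per_gene: int = 3
    exon_len_bp: int = 300
    intron_len_bp: int = 100
    n_ltr: int = 32
    ltr_len_bp: int = 600
    ltr_peri_fraction: float = 0.5    # fraction of LTRs inside the domain
    gbm_gene_fraction: float = 0.25
    gbm_level_mean: float = 0.85
    p_mcg_background: float = 0.10    # ~10% of CG sites methylated
    p_mcg_ltr: float = 0.30           # CG methylation at LTR clusters
    p_mchg: float = 0.03
    chg_level_mean: float = 0.50      # CHG maintenance is weak
    p_mchh: float = 0.0               # CHH methylation absent
    chh_level_mean: float = 0.30
    beta_concentration: float = 20.0
    symmetric_maintenance: bool = True
    coverage_mean: float = 20.0
    coverage_model: str = "poisson"   # "poisson" or "nb"
    nb_dispersion: float = 0.2
    nonconversion_epsilon: float = 0.005
    peak_domain_bp: int = 4_000       # pericentromeric block, scaled down
    n_scatter_peaks: int = 10         # short euchromatic peaks per chromosome
    scatter_peak_bp: int = 200
    srna_length_weights: dict[int, float] = field(default_factory=_default_srna_weights)
    n_srna_reads: int = 10_000
    srna_min_quality_char: str = "I"
    include_chloroplast: bool = True
    chloroplast_len_bp: int = 10_000
    chloroplast_name: str = "chrC"

    def __post_init__(self):
        for p in (self.gc_fraction, self.p_mcg_background, self.p_mcg_ltr,
                  self.p_mchg, self.p_mchh, self.gbm_gene_fraction,
                  self.ltr_peri_fraction, self.nonconversion_epsilon):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if self.chrom_len_bp <= 0 or self.chloroplast_len_bp <= 0:
            raise ValueError("lengths must be positive")
        wsum = sum(self.srna_length_weights.values())
        if abs(wsum - 1.0) > 1e-9:
            raise ValueError("srna_length_weights must sum to 1")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SynthConfig":
        raw = json.loads(text)
        if "srna_length_weights" in raw:
            raw["srna_length_weights"] = {
                int(k): v for k, v in raw["srna_length_weights"].items()
            }
        return cls(**raw)


@dataclass
class SyntheticDataset:
    """All generated artefacts plus the ground truth behind them."""

    config: SynthConfig
    genome: GenomeSequence
    genes: list[GenomicInterval]
    exons: list[GenomicInterval]          # = CDS (single-transcript genes)
    ltrs: list[GenomicInterval]
    peri_domains: list[GenomicInterval]
    records: pd.DataFrame                 # allc-style site table
    truth: pd.DataFrame                   # per emitted site: true level
    gene_truth: pd.DataFrame              # gene_id, is_gbm
    ltr_truth: pd.DataFrame               # ltr_id, in_peri_domain
    peaks: list[GenomicInterval]
    srna_reads: list[tuple[str, str]]     # (read_id, sequence)


def _random_sequence(rng, n: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=probs)])


def _place_in_slots(rng, region_start, region_end, n, feat_len):
    """Place n non-overlapping features of feat_len inside [start, end)."""
    span = region_end - region_start
    if n == 0:
        return []
    slot = span / n
    if slot < feat_len:
        raise ValueError(
            f"cannot place {n} features of {feat_len} bp in {span} bp; "
            "reduce the feature count or lengthen the chromosome"
        )
    out = []
    for i in range(n):
        lo = region_start + int(i * slot)
        hi = region_start + int((i + 1) * slot) - feat_len
        out.append(int(rng.integers(lo, hi + 1)))
    return out


def _generate_genome(config: SynthConfig, rng):
    names = [f"chr{i + 1:02d}" for i in range(config.n_chroms)]
    seqs = {c: _random_sequence(rng, config.chrom_len_bp, config.gc_fraction) for c in names}
    flags = {c: False for c in names}
    if config.include_chloroplast:
        names.append(config.chloroplast_name)
        seqs[config.chloroplast_name] = _random_sequence(
            rng, config.chloroplast_len_bp, config.gc_fraction
        )
        flags[config.chloroplast_name] = True
    genome = GenomeSequence(list(names), seqs, flags)

    gene_len = config.exons_per_gene * config.exon_len_bp + (
        config.exons_per_gene - 1
    ) * config.intron_len_bp
    nuclear = genome.nuclear_chroms()
    peri = []
    genes, exons, ltrs = [], [], []
    genes_per_chrom = _split_evenly(config.n_genes, len(nuclear))
    ltr_per_chrom = _split_evenly(config.n_ltr, len(nuclear))
    gi = li = 0
    for ci, chrom in enumerate(nuclear):
        L = config.chrom_len_bp
        center = L // 2
        d0, d1 = center - config.peak_domain_bp // 2, center + config.peak_domain_bp // 2
        peri.append(GenomicInterval(chrom, d0, d1, feature_type="peri_domain"))
        # genes on the left arm
        for start in _place_in_slots(rng, 1000, d0 - 1000, genes_per_chrom[ci], gene_len):
            gi += 1
            gid = f"gene{gi:04d}"
            strand = "+" if rng.integers(2) else "-"
            genes.append(
                GenomicInterval(chrom, start, start + gene_len, strand, "gene", gid)
            )
            for e in range(config.exons_per_gene):
                es = start + e * (config.exon_len_bp + config.intron_len_bp)
                exons.append(
                    GenomicInterval(chrom, es, es + config.exon_len_bp, strand, "CDS", gid)
                )
        # LTRs: some inside the pericentromeric domain, the rest on the right arm
        n_peri = int(round(ltr_per_chrom[ci] * config.ltr_peri_fraction))
        n_arm = ltr_per_chrom[ci] - n_peri
        placements = [
            (s, True) for s in _place_in_slots(rng, d0, d1, n_peri, config.ltr_len_bp)
        ] + [
            (s, False)
            for s in _place_in_slots(rng, d1 + 1000, L - 1000, n_arm, config.ltr_len_bp)
        ]
        for start, in_peri in placements:
            li += 1
            lid = f"LTR{li:04d}"
            iv = GenomicInterval(chrom, start, start + config.ltr_len_bp, "+", "LTR", lid)
            ltrs.append(iv)
    return genome, genes, exons, ltrs, peri


def _split_evenly(total: int, k: int) -> list[int]:
    base, rem = divmod(total, k)
    return [base + (1 if i < rem else 0) for i in range(k)]


def _beta_levels(rng, n: int, mean: float, conc: float) -> np.ndarray:
    a, b = mean * conc, (1 - mean) * conc
    return rng.beta(a, b, size=n)


def _generate_methylome(config, genome, genes, exons, ltrs, rng):
    sites = enumerate_cytosines(genome)
    sites = sites[sites.context != "undefined"].reset_index(drop=True)
    n = len(sites)
    level = np.zeros(n, dtype=float)

    lengths = genome.lengths
    # per-gene Bernoulli draw keeps gbM genes unclustered across chromosomes
    gbm_draw = rng.random(len(genes)) < config.gbm_gene_fraction
    gbm_ids = {g.feature_id for g, hit in zip(genes, gbm_draw) if hit}
    gbm_exons = [e for e in exons if e.feature_id in gbm_ids]
    gbm_mask = position_mask(gbm_exons, lengths)
    ltr_mask = position_mask(ltrs, lengths)
    organelle = {c for c, f in genome.organelle_flags.items() if f}

    pos = sites.pos.to_numpy()
    chrom_arr = sites.chrom.to_numpy()
    in_gbm = np.zeros(n, dtype=bool)
    in_ltr = np.zeros(n, dtype=bool)
    is_org = np.zeros(n, dtype=bool)
    for chrom in pd.unique(chrom_arr):
        sel = chrom_arr == chrom
        if chrom in organelle:
            is_org[sel] = True
            continue
        in_gbm[sel] = gbm_mask[chrom][pos[sel]]
        in_ltr[sel] = ltr_mask[chrom][pos[sel]]

    ctx = sites.context.to_numpy()
    sub = sites.subcontext.to_numpy()
    sym = sites.symmetry.to_numpy()

    def p_mcg_for(idx):
        p = np.full(len(idx), config.p_mcg_background)
        p[in_gbm[idx]] = 1.0  # gbM-gene exonic CG sites are methylated
        p[~in_gbm[idx] & in_ltr[idx]] = config.p_mcg_ltr
        return p

    if config.symmetric_maintenance:
        dyads = pair_dyads(sites)
        key = pd.MultiIndex.from_arrays(
            [sites.chrom, sites.pos, sites.strand]
        )
        loc = pd.Series(np.arange(n), index=key)
        for kind, p_base, lmean in (
            ("CG", None, config.gbm_level_mean),
            ("CWG", config.p_mchg, config.chg_level_mean),
        ):
            dd = dyads[dyads.dyad_kind == kind]
            if dd.empty:
                continue
            wi = loc.loc[list(zip(dd.chrom, dd.watson_pos, ["+"] * len(dd)))].to_numpy()
            cidx = loc.loc[list(zip(dd.chrom, dd.crick_pos, ["-"] * len(dd)))].to_numpy()
            nuclear_d = ~is_org[wi]
            p = p_mcg_for(wi) if kind == "CG" else np.full(len(wi), p_base)
            meth = (rng.random(len(wi)) < p) & nuclear_d
            lv = np.zeros(len(wi))
            lv[meth] = _beta_levels(rng, int(meth.sum()), lmean, config.beta_concentration)
            level[wi] = lv
            level[cidx] = lv
        # CHH sites (asymmetric by nature) drawn independently
        chh = np.flatnonzero((ctx == "CHH") & ~is_org)
        meth = rng.random(len(chh)) < config.p_mchh
        lv = np.zeros(len(chh))
        lv[meth] = _beta_levels(rng, int(meth.sum()), config.chh_level_mean,
                                config.beta_concentration)
        level[chh] = lv
        # CCG sites stay unmethylated in symmetric mode (no palindromic partner)
    else:
        for sel, p, lmean in (
            (np.flatnonzero((ctx == "CG") & ~is_org), None, config.gbm_level_mean),
            (np.flatnonzero((ctx == "CHG") & ~is_org),
             config.p_mchg, config.chg_level_mean),
            (np.flatnonzero((ctx == "CHH") & ~is_org),
             config.p_mchh, config.chh_level_mean),
        ):
            pv = p_mcg_for(sel) if p is None else np.full(len(sel), p)
            meth = rng.random(len(sel)) < pv
            lv = np.zeros(len(sel))
            lv[meth] = _beta_levels(rng, int(meth.sum()), lmean, config.beta_concentration)
            level[sel] = lv

    # observed counts: coverage, then nonconversion as false-methylated
    # signal on unmethylated molecules only
    if config.coverage_model == "poisson":
        cov = rng.poisson(config.coverage_mean, size=n)
    elif config.coverage_model == "nb":
        r = 1.0 / config.nb_dispersion
        p_nb = r / (r + config.coverage_mean)
        cov = rng.negative_binomial(r, p_nb, size=n)
    else:
        raise ValueError(f"unknown coverage model {config.coverage_model!r}")
    eps = config.nonconversion_epsilon
    p_obs = level + (1.0 - level) * eps
    mc = rng.binomial(cov, p_obs)

    covered = cov >= 1
    records = pd.DataFrame(
        {
            "chrom": chrom_arr[covered],
            "pos": pos[covered],
            "strand": sites.strand.to_numpy()[covered],
            "subcontext": sub[covered],
            "mc": mc[covered].astype(np.int64),
            "cov": cov[covered].astype(np.int64),
            "context": ctx[covered],
        }
    )
    truth = pd.DataFrame(
        {
            "chrom": chrom_arr[covered],
            "pos": pos[covered],
            "strand": sites.strand.to_numpy()[covered],
            "context": ctx[covered],
            "true_level": level[covered],
            "in_gbm_exon": in_gbm[covered],
            "in_ltr": in_ltr[covered],
        }
    )
    gene_truth = pd.DataFrame(
        {"gene_id": [g.feature_id for g in genes],
         "is_gbm": [g.feature_id in gbm_ids for g in genes]}
    )
    return records, truth, gene_truth


def _generate_peaks(config, genome, peri_domains, rng):
    peaks = [
        GenomicInterval(p.chrom, p.start, p.end, ".", "peak", f"domain_{p.chrom}")
        for p in peri_domains
    ]
    k = 0
    for chrom in genome.nuclear_chroms():
        L = genome.lengths[chrom]
        center = L // 2
        d0 = center - config.peak_domain_bp // 2
        d1 = center + config.peak_domain_bp // 2
        for _ in range(config.n_scatter_peaks):
            while True:
                s = int(rng.integers(0, L - config.scatter_peak_bp))
                if s + config.scatter_peak_bp <= d0 or s >= d1:
                    break
            k += 1
            peaks.append(
                GenomicInterval(chrom, s, s + config.scatter_peak_bp, ".", "peak", f"peak{k:04d}")
            )
    return peaks


def _generate_srna(config, genome, rng):
    lengths = sorted(config.srna_length_weights)
    weights = np.array([config.srna_length_weights[l] for l in lengths])
    nuclear = genome.nuclear_chroms()
    chrom_lens = np.array([genome.lengths[c] for c in nuclear], dtype=float)
    chrom_p = chrom_lens / chrom_lens.sum()
    reads = []
    for i in range(config.n_srna_reads):
        n = lengths[int(rng.choice(len(lengths), p=weights))]
        chrom = nuclear[int(rng.choice(len(nuclear), p=chrom_p))]
        start = int(rng.integers(0, genome.lengths[chrom] - n))
        seq = genome.sequences[chrom][start : start + n]
        if rng.integers(2):
            seq = _revcomp(seq)
        reads.append((f"sr{i:06d}", seq))
    return reads


def generate_dataset(config: SynthConfig | None = None) -> SyntheticDataset:
    """Generate the full synthetic dataset; everything flows from config.seed."""
    config = config or SynthConfig()
    rng = np.random.default_rng(config.seed)
    genome, genes, exons, ltrs, peri = _generate_genome(config, rng)
    records, truth, gene_truth = _generate_methylome(
        config, genome, genes, exons, ltrs, rng
    )
    peaks = _generate_peaks(config, genome, peri, rng)
    srna = _generate_srna(config, genome, rng)
    in_peri = []
    for ltr in ltrs:
        dom = next(d for d in peri if d.chrom == ltr.chrom)
        in_peri.append(ltr.start < dom.end and dom.start < ltr.end)
    ltr_truth = pd.DataFrame(
        {"ltr_id": [l.feature_id for l in ltrs], "in_peri_domain": in_peri}
    )
    return SyntheticDataset(
        config, genome, genes, exons, ltrs, peri,
        records, truth, gene_truth, ltr_truth, peaks, srna,
    )


# -- serialisation ----------------------------------------------------------

def write_fasta(genome: GenomeSequence, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom in genome.chrom_names:
            fh.write(f">{chrom}\n")
            seq = genome.sequences[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_gff3(genes, exons, path) -> None:
    by_gene: dict[str, list] = {}
    for e in exons:
        by_gene.setdefault(e.feature_id, []).append(e)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\tduckmeth\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.feature_id}\n"
            )
            mrna = f"{g.feature_id}.1"
            fh.write(
                f"{g.chrom}\tduckmeth\tmRNA\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={mrna};Parent={g.feature_id}\n"
            )
            for j, e in enumerate(sorted(by_gene.get(g.feature_id, []), key=lambda x: x.start), 1):
                for ftype in ("exon", "CDS"):
                    fh.write(
                        f"{e.chrom}\tduckmeth\t{ftype}\t{e.start + 1}\t{e.end}\t.\t"
                        f"{e.strand}\t{0 if ftype == 'CDS' else '.'}\t"
                        f"ID={mrna}.{ftype}{j};Parent={mrna}\n"
                    )


def write_fastq(reads, path, quality_char: str = "I") -> None:
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{quality_char * len(seq)}\n")


def write_dataset(ds: SyntheticDataset, out_dir) -> dict[str, str]:
    """Write every artefact as plain text; returns the path map."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    from .allc import write_allc

    paths = {
        "fasta": os.path.join(out_dir, "genome.fa"),
        "gff3": os.path.join(out_dir, "genes.gff3"),
        "ltr_bed": os.path.join(out_dir, "ltr.bed"),
        "allc": os.path.join(out_dir, "allc.tsv"),
        "truth": os.path.join(out_dir, "truth.tsv"),
        "gene_truth": os.path.join(out_dir, "gene_truth.tsv"),
        "peaks_bed": os.path.join(out_dir, "peaks.bed"),
        "srna_fastq": os.path.join(out_dir, "srna.fastq"),
        "config": os.path.join(out_dir, "synth_config.json"),
    }
    write_fasta(ds.genome, paths["fasta"])
    write_gff3(ds.genes, ds.exons, paths["gff3"])
    write_bed(ds.ltrs, paths["ltr_bed"])
    write_allc(ds.records, paths["allc"])
    ds.truth.to_csv(paths["truth"], sep="\t", index=False)
    ds.gene_truth.to_csv(paths["gene_truth"], sep="\t", index=False)
    write_bed(ds.peaks, paths["peaks_bed"])
    write_fastq(ds.srna_reads, paths["srna_fastq"], ds.config.srna_min_quality_char)
    with open(paths["config"], "w") as fh:
        fh.write(ds.config.to_json() + "\n")
    return paths
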