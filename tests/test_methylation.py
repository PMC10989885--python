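"""allc parsing, weighted levels, site calls, symmetry and metaplots."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from duckmeth.allc import read_allc, write_allc
from duckmeth.genome import GenomeSequence, enumerate_cytosines, pair_dyads, tile_windows
from duckmeth.intervals import GenomicInterval
from duckmeth.methylation import (
    call_sites,
    dyad_levels,
    estimate_nonconversion,
    metaplot,
    subcontext_summary,
    weighted_methylation,
    windowed_methylation,
)
from duckmeth.stats import bh_correct, binomial_tail

from conftest import make_records, oracle_binom_tail


# ------------------------------------------------------------------ allc --

class TestReadAllc:
    def test_parse_and_coordinate_conversion(self, tmp_path):
        p = tmp_path / "a.tsv"
        p.write_text("Chr01\t100\t+\tCGA\t3\t10\t1\n")
        df = read_allc(p)
        row = df.iloc[0]
        assert (row.pos, row.subcontext, row.context, row.mc, row["cov"]) == (
            99, "CGA", "CG", 3, 10
        )

    def test_mc_exceeding_cov_rejected(self, tmp_path):
        p = tmp_path / "a.tsv"
        p.write_text("Chr01\t100\t+\tCGA\t11\t10\t1\n")
        with pytest.raises(ValueError, match="line 1"):
            read_allc(p)

    def test_empty_file_warns(self, tmp_path, caplog):
        p = tmp_path / "a.tsv"
        p.write_text("")
        with caplog.at_level("WARNING"):
            df = read_allc(p)
        assert df.empty and "empty" in caplog.text

    def test_genome_validation(self, tmp_path, toy_genome):
        p = tmp_path / "a.tsv"
        # chr1 starts ACGT: pos 2 (1-based) is C on Watson
        p.write_text("chr1\t2\t+\tCGT\t1\t4\t1\n")
        assert len(read_allc(p, toy_genome)) == 1
        p.write_text("chr1\t1\t+\tCGT\t1\t4\t1\n")  # ref base A, not C
        with pytest.raises(ValueError, match="expected C"):
            read_allc(p, toy_genome)
        p.write_text("nochrom\t1\t+\tCGT\t1\t4\t1\n")
        with pytest.raises(ValueError, match="unknown chromosome"):
            read_allc(p, toy_genome)

    def test_roundtrip(self, tmp_path):
        recs = make_records([("c", 9, "+", "CGA", 2, 7), ("c", 20, "-", "CAG", 0, 3)])
        p = tmp_path / "a.tsv"
        write_allc(recs, p)
        back = read_allc(p)
        pd.testing.assert_frame_equal(
            back[["chrom", "pos", "strand", "subcontext", "mc", "cov"]],
            recs[["chrom", "pos", "strand", "subcontext", "mc", "cov"]],
        )

    def test_gzip_round_trip(self, tmp_path):
        recs = make_records([("c", 9, "+", "CGA", 2, 7)])
        p = tmp_path / "a.tsv.gz"
        write_allc(recs, p)
        assert read_allc(p).iloc[0].pos == 9


# --------------------------------------------------------- nonconversion --

def test_nonconversion_estimate():
    recs = make_records(
        [("chrC", i, "+", "CGA", m, c) for i, (m, c) in enumerate([(5, 500), (0, 500)])]
        + [("chr1", 0, "+", "CGA", 9, 10)]
    )
    nc = estimate_nonconversion(recs, "chrC")
    assert nc.epsilon == pytest.approx(0.005)
    assert (nc.mc_sum, nc.cov_sum) == (5, 1000)


def test_nonconversion_zero_and_missing_control():
    recs = make_records([("chrC", 0, "+", "CGA", 0, 100)])
    assert estimate_nonconversion(recs, "chrC").epsilon == 0.0
    with pytest.raises(ValueError, match="manually"):
        estimate_nonconversion(recs, "chrM")


# ------------------------------------------------------------ site calls --

def test_binomial_tail_edge_cases():
    assert binomial_tail(3, 3, 0.005) == pytest.approx(0.005**3, rel=1e-12)
    assert binomial_tail(0, 10, 0.3) == 1.0
    assert binomial_tail(1, 5, 0.0) == 0.0
    assert binomial_tail(0, 5, 0.0) == 1.0
    assert binomial_tail(5, 5, 1.0) == 1.0
    with pytest.raises(ValueError):
        binomial_tail(6, 5, 0.1)


@pytest.mark.parametrize("k,n,p", [(2, 10, 0.05), (30, 100, 0.1), (1, 200, 0.005)])
def test_binomial_tail_matches_summation_oracle(k, n, p):
    exact = float(oracle_binom_tail(k, n, Fraction(p).limit_denominator(10**6)))
    assert binomial_tail(k, n, p) == pytest.approx(exact, rel=1e-12)


def test_call_sites_bh_within_context():
    rows = [("c", i, "+", "CGA", 5, 5) for i in range(5)]
    rows += [("c", 100 + i, "+", "CAT", 0, 5) for i in range(5)]
    recs = make_records(rows)
    calls = call_sites(recs, epsilon=0.005, alpha=0.05)
    cg = calls[calls.context == "CG"]
    chh = calls[calls.context == "CHH"]
    assert cg.is_methylated.all()
    assert not chh.is_methylated.any()
    # q >= p everywhere, and q monotone in sorted-p order per context
    assert (calls.q_value >= calls.p_value - 1e-15).all()
    for _, grp in calls.groupby("context"):
        q = grp.sort_values("p_value").q_value.to_numpy()
        assert (np.diff(q) >= -1e-15).all()


def test_bh_step_up_hand_example():
    q = bh_correct([0.01, 0.02, 0.03, 0.04])
    assert q == pytest.approx([0.04, 0.04, 0.04, 0.04])
    assert bh_correct([0.2]) == pytest.approx([0.2])


def test_bh_matches_statsmodels():
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(0)
    p = rng.uniform(size=200) ** 2
    ours = bh_correct(p)
    theirs = multipletests(p, method="fdr_bh")[1]
    assert ours == pytest.approx(theirs, rel=1e-12)


# ------------------------------------------------------- weighted levels --

def test_weighted_methylation_threshold_semantics():
    recs = make_records(
        [("c", 0, "+", "CGA", 2, 4), ("c", 5, "+", "CGT", 0, 6)]
    )
    assert weighted_methylation(recs, min_cov=1).level == pytest.approx(0.2)
    assert weighted_methylation(recs, min_cov=5).level == 0.0
    assert math.isnan(weighted_methylation(recs, min_cov=7).level)


def test_weighted_level_invariant_to_order_and_partition():
    rng = np.random.default_rng(1)
    rows = [
        ("c", int(i), "+", "CGA", int(m), int(c))
        for i, (m, c) in enumerate(zip(rng.integers(0, 5, 50), rng.integers(5, 15, 50)))
    ]
    recs = make_records(rows)
    shuffled = recs.sample(frac=1, random_state=0)
    total = weighted_methylation(recs, min_cov=1)
    assert weighted_methylation(shuffled, min_cov=1).level == total.level
    left = weighted_methylation(recs, regions=[GenomicInterval("c", 0, 25)], min_cov=1)
    right = weighted_methylation(recs, regions=[GenomicInterval("c", 25, 50)], min_cov=1)
    assert left.mc_sum + right.mc_sum == total.mc_sum
    assert left.cov_sum + right.cov_sum == total.cov_sum


def test_windowed_sums_partition_genome(default_dataset):
    ds = default_dataset
    nuclear = ds.records[ds.records.chrom != "chrC"]
    windows = tile_windows(ds.genome, 10_000, chroms=ds.genome.nuclear_chroms())
    win = windowed_methylation(nuclear, windows, contexts=("CG",), min_cov=5)
    total = weighted_methylation(nuclear, contexts=("CG",), min_cov=5)
    assert win.mc_sum.sum() == total.mc_sum
    assert win.cov_sum.sum() == total.cov_sum


def test_window_without_sites_is_na():
    recs = make_records([("c", 3, "+", "CGA", 1, 10)])
    g = GenomeSequence(["c"], {"c": "A" * 200})
    win = windowed_methylation(recs, tile_windows(g, 100), contexts=("CG",), min_cov=5)
    assert math.isnan(win[win.start == 100].level.iloc[0])
    assert win[win.start == 0].level.iloc[0] == pytest.approx(0.1)


# ------------------------------------------------------------ subcontext --

def test_subcontext_rollups():
    recs = make_records(
        [
            ("c", 0, "+", "CAA", 1, 10),
            ("c", 2, "+", "CAT", 2, 10),
            ("c", 4, "+", "CAG", 1, 10),
            ("c", 6, "+", "CTG", 1, 10),
            ("c", 8, "+", "CCG", 2, 10),
        ]
    )
    summ = subcontext_summary(recs, min_cov=1).set_index("label")
    assert summ.loc["CWA"].level == pytest.approx(0.1)       # CAA only
    assert summ.loc["non-CWA-CHH"].level == pytest.approx(0.2)  # CAT only
    assert summ.loc["CWG"].level == pytest.approx(2 / 20)
    assert summ.loc["CCG"].level == pytest.approx(0.2)


def test_subcontext_empty_is_all_na():
    summ = subcontext_summary(make_records([]), min_cov=1)
    assert summ.level.isna().all()


# ----------------------------------------------------------- dyad levels --

def _dyads_for(seq):
    g = GenomeSequence(["c"], {"c": seq})
    return pair_dyads(enumerate_cytosines(g))


def test_dyad_level_pairing_and_threshold():
    dyads = _dyads_for("ACGT")
    recs = make_records(
        [("c", 1, "+", "CGT", 4, 4), ("c", 2, "-", "CGT", 0, 4)]
    )
    dl = dyad_levels(recs, dyads, min_cov_per_strand=3)
    assert len(dl) == 1
    assert (dl.iloc[0].watson_level, dl.iloc[0].crick_level) == (1.0, 0.0)
    assert dl.iloc[0].abs_delta == 1.0
    # strand below the coverage threshold drops the dyad
    recs2 = make_records([("c", 1, "+", "CGT", 2, 2), ("c", 2, "-", "CGT", 0, 4)])
    assert dyad_levels(recs2, dyads, min_cov_per_strand=3).empty


def test_symmetric_maintenance_aggregate_symmetry(default_dataset):
    """Under shared-level maintenance the pooled Watson and Crick levels agree."""
    ds = default_dataset
    sites = enumerate_cytosines(ds.genome, chroms=ds.genome.nuclear_chroms())
    dyads = pair_dyads(sites)
    nuclear = ds.records[ds.records.chrom != "chrC"]
    dl = dyad_levels(nuclear, dyads, min_cov_per_strand=3)
    cg = dl[dl.dyad_kind == "CG"]
    assert len(cg) > 5000
    w = cg.watson_mc.sum() / cg.watson_cov.sum()
    c = cg.crick_mc.sum() / cg.crick_cov.sum()
    assert abs(w - c) < 0.01
    assert np.corrcoef(cg.watson_level, cg.crick_level)[0, 1] > 0.9


def test_independent_strands_are_uncorrelated():
    from duckmeth.simulate import SynthConfig, generate_dataset

    # homogeneous background: no gbM/LTR spatial structure, so any residual
    # correlation could only come from shared per-dyad levels
    ds = generate_dataset(
        SynthConfig(seed=11, symmetric_maintenance=False,
                    gbm_gene_fraction=0.0, p_mcg_ltr=0.10)
    )
    sites = enumerate_cytosines(ds.genome, chroms=ds.genome.nuclear_chroms())
    dyads = pair_dyads(sites)
    nuclear = ds.records[ds.records.chrom != "chrC"]
    dl = dyad_levels(nuclear, dyads, min_cov_per_strand=3)
    cg = dl[dl.dyad_kind == "CG"]
    assert len(cg) > 5000
    assert abs(np.corrcoef(cg.watson_level, cg.crick_level)[0, 1]) < 0.1


# -------------------------------------------------------------- metaplot --

def _uniform_records(seq_len=6000, level=0.5, cov=20):
    """Every 10th position is a CG site at a fixed true level, no noise."""
    rows = []
    for p in range(0, seq_len, 10):
        rows.append(("c", p, "+", "CGA", int(level * cov), cov))
    return make_records(rows)


def test_metaplot_window_arithmetic():
    """A 200-bp gene gets 10-bp body windows and 50-bp flank windows."""
    loci = [GenomicInterval("c", 1000, 1200, "+", "gene", "g1")]
    recs = _uniform_records()
    prof = metaplot(recs, loci, flank_bp=1000, n_windows=20, min_cov=1, contexts=("CG",))
    assert len(prof) == 60
    body = prof[prof.segment == "body"]
    # 10-bp windows catch exactly one of the every-10-bp sites each
    assert (body.cov_sum == 20).all()
    up = prof[prof.segment == "upstream"]
    assert (up.cov_sum == 5 * 20).all()  # 50-bp windows, 5 sites each


def test_metaplot_uniform_is_flat():
    loci = [GenomicInterval("c", 1000, 1200, "+", "gene", "g1"),
            GenomicInterval("c", 3000, 3400, "-", "gene", "g2")]
    prof = metaplot(_uniform_records(), loci, min_cov=1, contexts=("CG",))
    assert prof.level.dropna().to_numpy() == pytest.approx([0.5] * 60)


def test_metaplot_minus_strand_orientation():
    """A minus-strand locus profile equals the mirrored plus-strand profile."""
    rows = [("c", p, "+", "CGA", (3 if p < 2000 else 17), 20) for p in range(0, 6000, 10)]
    recs = make_records(rows)
    plus = metaplot(recs, [GenomicInterval("c", 2000, 2400, "+", "gene", "g")],
                    min_cov=1, contexts=("CG",))
    minus = metaplot(recs, [GenomicInterval("c", 2000, 2400, "-", "gene", "g")],
                     min_cov=1, contexts=("CG",))
    assert plus.level.to_numpy() == pytest.approx(minus.level.to_numpy()[::-1])


def test_metaplot_exonic_mask_restricts_body():
    loci = [GenomicInterval("c", 1000, 1200, "+", "gene", "g1")]
    exons = [GenomicInterval("c", 1000, 1100, "+", "CDS", "g1")]
    prof = metaplot(_uniform_records(), loci, exon_intervals=exons,
                    min_cov=1, contexts=("CG",), chrom_lengths={"c": 6000})
    body = prof[prof.segment == "body"]
    assert (body.cov_sum.iloc[:10] > 0).all()   # exonic half counted
    assert (body.cov_sum.iloc[10:] == 0).all()  # intronic half masked out
    # flanks are unaffected by the mask
    assert (prof[prof.segment == "upstream"].cov_sum > 0).all()


def test_metaplot_short_locus_skipped(caplog):
    with caplog.at_level("WARNING"):
        prof = metaplot(_uniform_records(), [GenomicInterval("c", 100, 110, "+", "gene", "tiny")],
                        min_cov=1, contexts=("CG",))
    assert prof.cov_sum.sum() == 0
    assert "skipped" in caplog.text
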