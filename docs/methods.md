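# Methods

## Coordinates and context classification

All internal coordinates are 0-based half-open on the Watson strand. allc
input positions are treated as 1-based and converted on read; GFF3 (1-based
closed) is converted on read; BED passes through. A Crick-strand cytosine is
stored at the Watson coordinate of its complementary G, matching the
convention of methylpy-style allc files, so dyad partners sit at offsets +1
(CG) and +2 (CWG).

A cytosine's context is the trinucleotide read 5'→3' on its own strand:
CG if the second base is G (decidable from the dinucleotide alone, so a
C G N triplet is still CG), CHG if the third base is G and the second is
A/C/T, CHH otherwise. CHG splits into the palindromic CWG (CAG/CTG) and the
non-palindromic CCG; CHH sites with second base A/T and third base A are
CWA, the diagnostic subcontext of CMT2 activity. Sites whose triplet
contains N, or that lack two downstream bases on their strand (other than
the CG case above), are labelled *undefined* and excluded from every
statistic — exclusion avoids biased denominators, and the count identity
|CG| + |CHG| + |CHH| + |undefined| = #C + #G still holds. Soft-masked
(lowercase) bases are uppercased and retained only as a per-base mask; they
receive no special treatment.

CCG sites are never dyad-paired: the opposite-strand partner of a CCG
cytosine is itself a CG-context site. The strand-symmetry analysis therefore
covers CG and CWG dyads only, which is also why the CHG symmetry default is
CWG-only; CCG can still be summarised separately through the subcontext
table.

## Weighted methylation

Every aggregate level is a ratio of summed counts: Σmc / Σcov over sites
passing a per-site coverage filter. Two thresholds exist because they serve
different purposes: `min_cov_aggregate` (default 5 reads) gates sites
entering region/window/metaplot sums, while `min_cov_site` (default 3
reads) gates per-site levels, dyad comparisons and site calls. The
per-site reading of the "minimum coverage" filter (rather than a per-region
one) follows the convention of the standard weighted-methylation
formulation. Summing counts before dividing makes every level invariant to
record order and to splitting or merging of region partitions, which the
test-suite asserts as a property.

Metaplots divide each locus body — start-to-stop codon for genes,
first-to-last bp for transposons — into 20 proportional windows
(window *w* of a length-*L* body spans [⌊wL/20⌋, ⌊(w+1)L/20⌋)), and each
1,000-bp flank into 20 fixed 50-bp windows; fixed flank widths are the only
self-consistent reading since flanks have constant length. Minus-strand
loci are index-reversed so window 0 is always the 5'-most upstream window.
For genes, body windows count only coding-exonic positions. Each of the 60
windows gets a single pooled level (ratio of sums across loci, not a mean
of per-locus ratios); loci shorter than 20 bp are skipped with a warning,
and windows clipped by a chromosome edge contribute whatever sites remain.

## Nonconversion and site calls

Sodium bisulfite fails to convert a small fraction ε of unmethylated
cytosines, which reads as false methylation. ε is estimated as Σmc/Σcov
over all contexts of an unmethylated organelle (chloroplast) contig;
zero control coverage is an error instructing the user to supply ε
manually. A site is significantly methylated when the one-sided binomial
tail P(X ≥ mc | n = cov, p = ε) survives Benjamini–Hochberg correction at
q < α (default 0.05). BH batches are formed per context class: CG, CHG and
CHH differ by orders of magnitude in site counts and effect sizes, and a
pooled batch would let the strong CG signal distort CHH q-values. The BH
step-up is implemented directly (q_(i) = min over j ≥ i of min(1, m·p_(j)/j))
and cross-checked against statsmodels in the tests.

## Strand symmetry statistics

For each CG/CWG dyad with ≥3 reads on both strands the package reports the
per-strand levels, their absolute difference, and three summaries: the mean
per-dyad |Watson − Crick|, the absolute difference of the pooled
(coverage-weighted) Watson and Crick levels, and the Pearson correlation of
the per-dyad level pairs. The per-dyad mean |Δ| has an irreducible sampling
floor at finite coverage: with a shared true level L per dyad it
concentrates around √(2L(1−L)/cov)·√(2/π) for methylated dyads plus an
ε-driven term for unmethylated ones — about 0.02 under the default
simulation at 20× and still ≈0.012 at 100×. It is reported because it is the
natural per-dyad quantity, but inference about maintenance fidelity should
rest on the pooled strand difference (which converges to 0 under symmetric
maintenance; order 10⁻⁴ on the default fixture) and the dyad correlation
(~0.99 symmetric vs ~0 for independent strands).

## Feature enrichment and gbM classification

Genes are counted over coding-exonic cytosines only; transposons over their
full span. Per feature and context, a one-sided binomial test compares the
feature's counts with the background probability p0, the pooled level over
all counted positions of all features of that type; BH control is applied
across features within each context. Two counting bases are implemented
because both appear in practice and they answer subtly different questions:
*reads* (successes = methylated read calls, trials = read calls; default)
weighs deep sites more, while *sites* (successes = significantly methylated
cytosines, trials = covered cytosines) is robust to a few deep outlier
sites but needs prior site calls. A feature is **gbM** iff CG-enriched and
not CHG- or CHH-enriched; any CHG/CHH enrichment takes precedence; no
enrichment is *unmethylated*; no counted CG positions is
*insufficient-data*. Features on organelle contigs are excluded from
background and testing. α defaults to 0.05.

Note that on structured data the reads-basis binomial is anti-conservative
across features: methylation is assigned per cytosine (or per dyad), so a
feature's read counts are clustered rather than independently drawn at p0,
and overdispersion inflates the discovery fraction above the nominal FDR.
The error-control suite therefore validates FDR on a homogeneous null
(features genuinely drawn at the background rate), which is the regime the
test's guarantee addresses.

The power simulation draws per-gene CDS site counts from the synthetic gene
geometry (three 300-bp exons at 40% GC ≈ Poisson with mean 72 CG sites,
truncated at the ≥50-site eligibility minimum) and evaluates 3×-background
genes against the generating background p0 = 0.10: enrichment is defined
relative to the true background, and estimating p0 by pooling over a
heavily spiked set would conflate signal with background. The FDR-null
simulation, by contrast, keeps pooled estimation, faithful to the actual
procedure.

## Interval overlap and the Fisher exact test

All interval arithmetic is half-open: an element ending where a peak starts
does not overlap it. Occupancy is merged-peak coverage over total genome
length. Element–peak overlap counts an element once if it intersects
≥ `min_bp` (default 1) of the merged peak set and is invariant to peak
merging and element order.

The enrichment contingency table follows the genome-slots construction of
the bedtools fisher tool: n11 = elements overlapping ≥1 peak, n12 =
elements without overlap, n21 = peaks overlapping no element, and n22 =
round(G/ℓ̄) − n11 − n12 − n21 (G = genome length, ℓ̄ = mean interval length
over both sets), floored at 0 with a warning. Published implementations of
this estimate vary between versions, so the construction is isolated in
`build_contingency` and alternatives can be swapped without touching the
test. The Fisher p-values are computed from hypergeometric log-pmfs summed
with log-sum-exp: p_greater is the upper tail at the observed overlap cell,
and the two-sided p sums all tables with point probability ≤ the observed
one (with a 1+1e-7 relative guard against floating-point ties). Both match
full rational-arithmetic enumeration to 1e-10 for margin totals ≤ 40.

## Small-RNA profile

The size profile is a pure length histogram over a configurable window
(default 20–25 nt) of adapter-trimmed reads, counted per occurrence
(abundance); reads shorter than `min_len` (default 15 nt, mirroring the
trimmer's minimum-length option) are dropped and logged, and out-of-range
reads count toward the total seen but not the in-range fractions. Genome
alignment is out of scope; an id-keep hook accepts an external aligner's
read list so alignment-filtered profiles remain computable.

## The synthetic dataset

The generator emulates the *structure* of a compact aquatic-monocot
methylome at ~1/750 scale (4 chromosomes × 50 kb plus a 10-kb chloroplast)
so the full pipeline runs in seconds. Defaults: 10% of background CG dyads
methylated (methylated dyads draw a Beta level with mean 0.85,
concentration 20), gbM genes (25% of 48 genes) fully methylated at CG in
their coding exons, LTR elements CG-methylated at 30%, CHG methylation at
3% confined to CWG dyads, CHH methylation absent (probability 0), one 4-kb
pericentromeric H3K9me2 domain per chromosome plus ten 200-bp scattered
peaks, a 21-nt-dominant sRNA pool (70% 21-nt, 2% 24-nt, 10,000 reads), 20×
Poisson coverage (negative-binomial behind a dispersion knob), and
nonconversion ε = 0.005. Under symmetric maintenance both members of a
CG/CWG dyad share one true level; switching it off draws strands
independently. Nonconversion is modelled as false-methylated signal on
unmethylated molecules only (observed success probability
level + (1 − level)·ε); sequencing error on methylated molecules is folded
into the Beta level. The chloroplast contig is exactly unmethylated.

Every artefact — FASTA, GFF3, BEDs, allc TSV, FASTQ, a truth table mapping
every emitted site to its true level, and the config as JSON — is a pure
function of the single config seed, and the suite asserts byte-identical
regeneration.

What the generator deliberately does not model: realistic transposon
sequence composition, read-level bisulfite simulation (counts are drawn
directly), mappability variation, batch effects, or within-feature
methylation gradients. Passing recovery tests therefore demonstrates the
correctness of the statistics and their estimators under the stated noise
model, not robustness to alignment artefacts in real libraries.

## Numerical choices and degenerate inputs

Binomial tails use the survival function (p = sf(mc − 1)), matching direct
rational summation to 1e-12 relative error for n ≤ 500; p0 = 0 yields p = 1
iff there are no successes, p0 = 1 yields p = 1. Weighted levels with an
empty denominator are NA, never 0. Overlap percentages and enrichment
fractions round half-away-from-zero (decimal arithmetic, not banker's
rounding) to match how such values are conventionally printed. Empty allc
or read files return empty results with a warning; malformed rows,
mc > cov, unknown chromosomes, reference-base mismatches, duplicate FASTA
names and non-IUPAC characters raise errors naming the offending record.
Ties in BH are handled stably; q-values are clipped to [0, 1].

## Pipeline determinism

Analysis stages contain no randomness; the only RNG in the package is the
generator's, seeded from its config. `run-all` writes data to files and
logs to stderr, and its summary JSON (sorted keys, rounded floats, no
timestamps) is byte-identical across reruns on the same inputs.
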