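# Methods

## Scope and model

srnakit quantifies small-RNA accumulation over user-defined genomic regions
from coordinate-level alignment files and makes multi-sample comparisons
possible by correcting library sizes for knockdown-derived reads. It does
not align reads, trim adapters, or remove contaminants: the input contract
is a SAM/BAM file whose records already carry standard flags, CIGAR strings
and sequences. Differential-expression testing and report/plot rendering
are likewise out of scope; the comparison TSVs are the data behind such
plots.

## Regions and coordinates

Regions are named intervals with a strand and a role. `target` regions are
quantified and compared; `knockdown` regions are loci silenced by
introduced siRNAs; `background` regions are any other loci whose reads
should not count toward the effective library size (for example non-insert
vector positions that are transcribed along with the trigger). Reads over
knockdown and background regions define the correction term K.

Region files are BED dialect: 0-based, half-open, tab-separated, with the
role in column 7. All internal coordinates are 0-based half-open; SAM's
1-based positions are converted exactly once, inside the alignment reader.
Whether an upstream tool's region lists are 0- or 1-based varies by
ecosystem; the BED convention was chosen here because the interval tools
this package interoperates with (bedtools and kin) use it, and the
write→parse round trip is tested to be drift-free.

## Read features and counting rules

A counted record is mapped, primary and non-supplementary. Secondary and
supplementary alignments are excluded so that the per-sample total T is
well defined and a multi-mapping read is not counted twice. Records without
a stored sequence cannot contribute clip or composition features; they are
skipped with a warning and reported in a `skipped` tally, never dropped
silently.

Read length is the full query length including soft-clipped bases, because
the clipped bases are the non-templated nucleotide additions of biological
interest — trimming them from the length would hide exactly the signal the
clip profile reports. Hard clips contribute no bases. All sequence-derived
features (5′/3′ clip sequences, first nucleotide, base composition) are
reported in read orientation: for a reverse-strand alignment the stored
sequence is reverse-complemented first, and the CIGAR's leading soft clip
is the read's 3′ clip. This makes the features of a read independent of
which genome strand it happened to align to, a property the test suite
checks directly.

A read is assigned to every region its alignment overlaps by at least one
reference base (half-open interval arithmetic), so a read spanning two
regions counts once in each — but at most once in T and once in K. K is
deduplicated per record: a read overlapping two knockdown regions
increments K by one. Antisense status is read strand ≠ region strand; for
unstranded regions antisense is defined as alignment to the reference
minus strand. Coverage is incremented on reference-consuming aligned
positions (CIGAR M/=/X), clipped to the region interval, in separate plus-
and minus-strand vectors.

"Nucleotide content" is reported both as whole-read base composition and
as the 5′-terminal nucleotide distribution, since both are standard sRNA
diagnostics (e.g. the 5′-U bias of many siRNA classes) and either reading
of the phrase is defensible.

## Normalization

Knockdown-corrected scaling (KDCS): R̂ = R · M/(T − K) with
M = maxₛ(Tₛ − Kₛ). The sample attaining M is returned unscaled; with all
K = 0 the method is exactly total-count scaling (TCS). A sample with
T − K ≤ 0 is a hard error naming the sample. Normalized outputs are
real-valued; rounding would bias the scale-sensitive CoV downstream.

Median-of-ratios size factors: per region the geometric mean of counts
across samples is computed over regions with no zero count; each sample's
factor is the median of its count-to-geometric-mean ratios, and normalized
counts are raw counts divided by the factor. Excluding zero-containing
regions is the standard convention for this estimator; if no region is
all-positive the method refuses with advice to use KDCS/TCS.

In the file-based path the per-sample K follows the sample configuration:
the bundle's deduplicated K when the configured knockdown set covers every
knockdown/background region, zero when the set is empty, and the sum of
the named regions' counts for a proper subset (exact when knockdown
regions do not overlap one another, the practically universal case).

## Comparison metrics

CoV_i = σ_i/μ_i per region over samples, computed on normalized counts
with the sample (n−1) standard deviation — the unbiased-variance
convention appropriate for the n = 4–5 replicate designs this method
targets. ASR_i = AS_i/R_i is computed from raw counts: it is a
within-sample ratio, so per-sample scaling cancels and using normalized
counts would only propagate normalization artifacts. Undefined values
(CoV with n < 2 or zero mean, ASR with R = 0) are NaN in memory and the
explicit marker `NA` in TSVs, never 0.

## Simulator

The generator emulates the structure of knockdown sRNA-seq libraries on a
single random toy contig (multi-contig layouts are supported for
chromosome-dispatch tests). Defaults: read lengths on 21–25 nt with mode
23 (probabilities 0.1/0.2/0.4/0.2/0.1) — the length window and modal
length characteristic of siRNA populations; antisense fraction 0.2; a
non-templated 3′ tail of 1–3 nt added with probability 0.15, drawn from an
A/T-biased alphabet (0.4/0.1/0.1/0.4) reflecting the adenylation/
uridylation typical of such additions; per-region expected read count
1000. Reads are sequence-exact copies of the reference apart from the
tail: the simulator tests statistics extraction and normalization, not
aligner robustness. Tails are encoded as soft clips (trailing for forward,
leading for reverse alignments) so the extraction path is exercised
end-to-end.

A replicate knockdown experiment draws per sample a depth scale from
U(0.5, 2) and a spike fraction f from U(0.3, 0.7); the spike adds
f × (baseline library size) extra reads over the knockdown locus,
exercising the real K-counting path rather than adjusting T
arithmetically. A design whose spike is zero emits a sample configuration
with an empty knockdown set, so downstream KDCS degenerates to TCS
exactly. All randomness flows through `numpy.random.SeedSequence` spawn
keys from one integer seed; output is byte-identical under a fixed seed.

What the simulator does not model: sequencing errors, quality scores,
adapters, multi-mapping reads, and any biological coupling between regions.
Passing tests therefore demonstrate correctness of counting, scaling and
metric arithmetic under the stated generative model, not robustness to
alignment artifacts in real libraries.

## Simulation study of normalization quality

The benchmark simulates, per seed, four replicate libraries (five loci:
four targets plus one knockdown locus, expected 1000 reads each before
depth scaling) with random depths and spikes as above, runs the full
SAM → statistics → normalization pipeline, and scores each method by the
mean per-region CoV of target counts. Replicates of one system should
agree, so lower is better. Over 100 seeds the observed ordering is
KDCS < TCS < raw in every seed, and all three normalizations beat raw
counts; size factors perform on par with KDCS here because the simulated
targets are not differentially expressed between replicates — exactly the
assumption that fails in real knockdown designs with few characterized
loci, which is the case KDCS exists for. These problem sizes (4 × ~10⁴-read
libraries, 100 seeds) keep the study at desk scale while leaving the
Poisson noise floor (CoV ≈ 0.02–0.03 at 1000 reads per region) well below
the method differences being measured.

## Numerical and degenerate-input choices

- Ties in M need no tie-breaking: M is a value, not a sample index.
- Geometric means are computed in log space to avoid overflow.
- Size factors and normalized matrices are written with 10 significant
  digits; re-reading a written table reproduces the matrix to float64
  round-off.
- Empty alignment files are valid input (T = 0, all regions R = 0);
  regions on chromosomes absent from the SAM header produce a warning and
  zero counts, not an error.
- The optional `--min-len/--max-len` read filter removes a read from R, T
  and K alike, keeping the Eq.-level identities between the three
  consistent under filtering.

## File formats

- Region file: BED6+1 (chrom, start, end, name, score, strand, role).
- Sample configuration: 3-column TSV — sample name, path to the sample's
  `region_summary.tsv`, comma-separated knockdown region names (empty ⇒
  K = 0 for that sample).
- Stats bundle: one TSV per table (`region_summary`, `length_hist`,
  `strand_by_length`, `clip_profile`, `first_nt`, `base_composition`,
  `coverage`), each with a single `#` header line carrying the tool
  version, sample name, T, K and the skipped/filtered tallies. Coverage
  rows are emitted only for non-zero depths.
- Normalized counts: region × sample TSV with method and M (or size
  factors) in the `#` header line.
- Comparison tables: `comparison_cov.tsv` (one CoV column per method run)
  and `comparison_asr.tsv` (region × sample, `NA`-capable).
- Every CLI command writes a `manifest.json` with resolved parameters,
  SHA-256 input digests, output paths, version and seed; data files are
  byte-stable across reruns with identical inputs and seed.
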