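# Methods

## Scope and model

`mirmod` analyses single-end small RNA-seq from a paired three-compartment
design — resting cells, activated cells and the extracellular vesicles (EVs)
the activated cells secrete, one triple per donor — to answer three
questions: which miRNAs are differentially carried between compartments,
how the compartments differ in post-transcriptional modifications (PtMs:
non-templated additions and substitutions near the miRNA ends), and whether
EV-enriched miRNAs share short sequence motifs.  Reads are interpreted
against a collection of canonical mature miRNAs only; genome alignment,
novel-miRNA discovery and A-to-I editing are out of scope.

## Synthetic data generator

The generator is first-class code: it defines the conditions under which the
pipeline is validated.

Per sample, reads are drawn from the reference collection with probability
proportional to `exp(b_m + ln2 · lfc_{m,c} + u_{d,m})`: a per-miRNA baseline
`b_m ~ N(0, 1.5²)` (natural-log scale, so abundances span ~3 orders of
magnitude, as in real miRNA libraries), a planted compartment effect
`lfc_{m,c}` in log2 units, and a donor effect `u_{d,m} ~ N(0, 0.2²)` that
makes donor-paired tests meaningful.  Defaults: 5 donors × 3 compartments;
20 % of miRNAs EV-enriched at log2FC = 3 (these are also the carriers of the
planted sorting motif, so enrichment and motif travel together); 10 % of
miRNAs perturbed at ±2 log2 in resting vs activated cells.

Each read is then modified at the 3' end and, with one tenth the rates, at
the 5' end (3' dominance being the empirical norm for miRNA tailing):

* trimming with probability `p_trim = 0.15`, removing `t ≥ 1` bases,
  `t − 1` geometric(0.5);
* a non-templated tail with probability `p_add` (0.10 resting, 0.08
  activated, 0.16 EV — activation lowers tailing, EV sorting raises it),
  of length 1 with probability 0.9 (mono) else 2 + geometric(0.5)−1 extra
  bases (poly), nucleotides i.i.d. with cytosine most frequent
  (C ≈ 0.45–0.50 > A > U > G).  A tail whose first base would re-create the
  canonical base it replaces is redrawn, so tails are non-templated by
  construction;
* per-base substitution error at 0.001 (HiSeq-like);
* the 3' adapter appended; qualities are constant Q40 ('I') — quality
  modelling is out of scope; records are variable-length by default, with a
  fixed-length pad/truncate mode.

Trims are clipped so at least 10 canonical bases survive, keeping every
simulated read classifiable in principle.  What the generator does **not**
emulate: PCR duplication, ligation bias, position-dependent error profiles,
contaminating RNA species, and the large unalignable fraction of real
libraries.  Passing tests therefore demonstrate correctness of the
algorithms under the stated generative model, not robustness to every
artefact of real data — in particular, the synthetic trimming-retention and
alignment rates (~90 % and ~99 %) are far higher than typical real-library
values, because the simulator emits no junk reads.

All randomness flows through `numpy.random.SeedSequence(seed)` children, so
identical seeds give byte-identical FASTQ and truth tables.

## Adapter trimming

Semi-global 3' search: for every read position the overlap with an adapter
prefix anchored at the read suffix is scored, allowing
`floor(rate · overlap)` mismatches (defaults rate 0.1, minimum overlap 3 —
conventional 3'-trimming settings).  The qualifying occurrence with the most
matched bases wins, ties to the leftmost start; the occurrence and
everything 3' of it are removed, and inserts shorter than 20 nt are
discarded.  T and U are equivalent on input; all internal sequences are RNA.

## isomiR classification

Coordinates are end-anchored: position 0 is the canonical terminal
nucleotide of an end, negative positions run into the body, positive beyond
the terminus; events are reported within −4..+4.

A read is decomposed, for every candidate (reference, ungapped shift with
|5' offset| ≤ 4), into a contiguous templated core plus non-templated tails:
core endpoints must match the template; a base adjacent to the core that
matches the template is always consumed as templated (maximal extension /
parsimony); a core mismatch is a substitution only if ≥ 2 templated matches
lie 3'-ward of it within the core (so terminal mismatches become additions),
with at most 1 substitution by default.  Among valid decompositions the call
maximises core length, then minimises non-templated bases (tails +
substitutions), then prefers the smaller |5' offset|, then the
lexicographically smaller miRNA ID with `ambiguous=True`.  Reads whose best
core is under 14 nt or whose tail exceeds 8 nt are unaligned.  Tail runs are
mono (length 1) or poly (≥ 2), with the innermost base flagged as the run
start; positional summaries of mono-additions use only run starts.

This deterministic parsimony rule replaces probabilistic multi-mapping
resolution (EM-based quantifiers): it is exactly reproducible and is checked
against a brute-force oracle that enumerates every decomposition.  Two
consequences are accepted and documented: non-templated bases that
coincidentally match the template are counted as templated (slight
under-count of true additions), and the substitution rule is 3'-ward as
stated, not mirrored.

Candidate references come from an exact k-mer index.  The seed length
defaults to 7, the longest length guaranteed by pigeonhole to occur exactly
inside any valid core (14 nt minimum, ≤ 1 mismatch); longer seeds would be
faster but could miss valid assignments, and the classifier warns when the
configured combination breaks the guarantee.  Classification results are
cached per distinct read sequence, which makes deep libraries cheap (small
RNA reads are highly duplicated).

## Expression and differential expression

Features are kept when CPM ≥ 1 (raw library sizes) in ≥ 3 samples.  TMM
factors follow the published definition: M- and A-values vs a reference
sample (chosen by closest 75th count-fraction percentile to the mean),
double trimming (30 % on M, 5 % on A, rank-based with averaged ties),
precision weights from the binomial delta method, factors rescaled to
geometric mean 1; degenerate trims fall back to factor 1 with a warning.
The implementation reproduces edgeR's `calcNormFactors` to ~1e-6 in the
test suite.

log2-CPM uses a +0.5 count offset on TMM-effective library sizes.  The
moderated t-test fits, per feature, a linear model (intercept + group, plus
optional donor dummies via `--block-donor`; the unpaired two-group model is
the default), then shrinks residual variances toward a fitted prior:
`(d0, s0²)` are obtained by matching the mean and variance of `ln s²` to the
scaled-F marginal, inverting the trigamma function by Newton iteration
(tolerance 1e-8); `d0 ≥ 1e6` is treated as infinite (all posterior variances
equal `s0²`), and `d0 = 0` reduces exactly to the ordinary pooled t-test.
p-values use `d0 + d` degrees of freedom and are BH-adjusted (NaNs propagate
and are excluded from the test count).  Agreement with limma's
`lmFit`/`eBayes` on a shared expression matrix is asserted in the tests.
Enriched sets use adjusted p < 0.05 and |log2FC| > 2; the three-compartment
design is analysed as the two pairwise contrasts (activated vs EV, resting
vs activated), not a joint F-test.  The fold-change threshold is interpreted
in log2 units, the convention of the tooling this stage follows.

qPCR relative quantification: ΔCt = Ct(target) − mean Ct(reference genes)
per sample, ΔΔCt = mean ΔCt(treated) − mean ΔCt(control), RQ = 2^−ΔΔCt,
with per-sample RQs returned for plotting and statistics.

## PtM statistics

A read is "modified" iff it carries ≥ 1 event at either end (an `--end 3p`
restriction is available); per-(miRNA, sample) fractions exclude miRNAs
under 10 reads.  Donor is the test unit: per-miRNA fractions are averaged
within a sample before cross-donor testing (the per-miRNA pooled view is
selectable).  Top-30 sets are ranked by mean within-group CPM (expressed
mode) or by log2FC among significant features (enriched mode), ties broken
by ID.

Signed-rank tests drop zero differences, average tied ranks and compute the
exact two-sided p by dynamic programming over all 2^n sign assignments for
n ≤ 25, else a tie-corrected normal approximation; paired comparisons
across compartments use donor pairing (Mann–Whitney available for unpaired
data).  Kruskal–Wallis uses the tie-corrected H with a chi-square p by
default; an exact full-permutation p is available for small samples, since
a chi-square approximation can never equal an enumerated null exactly.

## Motif discovery

Foreground (EV-enriched miRNA sequences) and background (the full canonical
collection, foreground included — mirroring the use of the complete
annotation as background; `exclude_foreground` is available) are first made
non-redundant by greedy centroid clustering at 80 % identity
(1 − Levenshtein/max length, longest-first processing).  Candidates are
exact k-mers (4–8 nt) present in ≥ 2 foreground sequences; each is tested
ZOOPS-style (a sequence counts once however many occurrences it contains)
with a one-sided Fisher exact test on the presence 2×2 table, and
`E_adj = p × (number of candidates)` — a transparent Bonferroni-style
analogue of a motif-search E-value, reported unclipped.  Motifs with
`E_adj < 0.2` are reported, sorted by E-value.  The search is forward-strand
only; exact k-mers (no IUPAC degeneracy or PWM refinement) suffice because
sorting motifs of interest are short exact strings.

## Problem sizes and numerical choices

The acceptance computations use 10,000 randomized reads for the
caller-vs-oracle comparison; a 5-donor × 3-compartment study with 50 miRNAs
and 50,000 reads/sample for parameter recovery; 20 null replicates of 1000
features (5 vs 5) plus one planted-effect replicate for DE calibration and
power; and 30-sequence foregrounds against 60–80-sequence backgrounds for
motif recovery — sizes chosen so the whole validation runs in about a
minute on one CPU while keeping Monte-Carlo error well inside the 3-SE
bands being checked.  Mono-addition nucleotide frequencies are validated at
position +1 (untrimmed tails), where the generative distribution is exactly
the configured one; at trimmed positions the redraw rule shifts it.

Ties everywhere break deterministically (documented orderings); all stage
randomness derives from a single seed; manifest hashes make whole-run
determinism checkable.

## Known limitations

* Assignment ignores quality scores and allows no indels within the core;
  isomiRs arising from genomic variants or editing are called as
  substitutions.
* The EB moderation assumes a single scaled-F variance prior; no
  mean-variance trend or robustification is fitted.
* The E-value adjustment is Bonferroni-style over candidate k-mers, which is
  conservative for overlapping, correlated k-mers.
* Real-library artefacts (PCR duplicates, ligation bias, UMI collapsing,
  paired-end protocols) are out of scope for both simulator and pipeline.
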