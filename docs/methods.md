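# Methods

This note records the models, algorithmic choices and numerical details
behind each module, the assumptions they make, and what the synthetic-data
tests do and do not demonstrate about real venom-gland data.

## Read merging

A read pair with reads of length R from an insert of length L overlaps over
`min(R, L) − max(0, L − R)` bases once read 2 is reverse-complemented; when
L < R both mates run through the insert into the adapter.  The merger scans
every candidate insert length, scores matches-minus-mismatches over the
overlapping insert region (N counts as a mismatch with quality 0), and
accepts the best candidate iff the overlap is at least `min_overlap`
(default 25 nt) and the mismatch fraction is at most
`max_mismatch_fraction` (default 0.05).  Ties are broken toward the longer
overlap and then the shorter insert, favoring the full read-through
interpretation.  Defaults were chosen to make false merges of unrelated
151-nt reads negligible (a ≥25-nt chance match at ≤5% mismatch has
probability ≪ 1e−6) while still merging a short-insert library in which
most pairs overlap over nearly their entire lengths.  Consensus bases where
the mates agree get quality q1+q2 capped at 93 — the summation rule is the
only simple combination consistent with merged mean phred scores far above
the raw per-base scores — and disagreements keep the higher-quality base at
quality |q1−q2|.  Bases 3' of the inferred insert end are adapter
read-through and are discarded.  Indel sequencing errors are out of scope;
the overlap model is substitution-only.

## Assembly

*Seed extension* requires an exact overlap of ≥100 nt with every base of
the extending read at phred ≥30, and per step appends the eligible read
adding the most new bases (ties broken lexicographically for determinism).
A 30-kb safety cap bounds runaway extension; the longest venom transcripts
are ~5 kb.  *Reference-guided consensus* assigns each read to the reference
it matches best at ≥85% identity (k-mer prefilter, edit-distance infix
alignment on both strands), majority-votes each position, keeps a consensus
only when every CDS position has ≥5× depth, and trims UTR flanks below 5×.
*Deduplication* collapses coding sequences contained verbatim in a longer
transcript.  *Clustering* is single linkage at pairwise divergence
strictly <1% (mismatches over aligned non-gap columns of a global
alignment); single linkage treats clusters as greedily discovered
allele/close-paralog groups, and strict `<` follows the stated threshold
wording.  Clusters are numbered per class by descending total abundance and
members lettered by descending abundance; singleton clusters carry no
letter.  *Chimera screening* combines (a) a coverage-evenness statistic
U = min 100-nt-window mean depth / median depth over the transcript
interior (the terminal read-length ramp is excluded; U < 0.1 flags), and
(b) a mosaic test that looks for a single breakpoint splitting the
candidate into two segments each matching a distinct database parent at
≥95% identity over 60-nt-window-aligned segments.  A chimera call always
requires a two-parent partition; low-but-even coverage never triggers one.
The evenness cutoff and window sizes are package choices calibrated on the
synthetic fusions, not published values.  *Annotation* aligns each
translated CDS locally (BLOSUM62, gap open −11 / extend −1) against a
class-labeled toxin reference; the best hit assigns its class when the
score passes the threshold and the reference description matches a toxin
keyword, otherwise the transcript is a nontoxin.  Coordinates are 0-based
half-open internally and 1-based inclusive in reports.

## Abundance estimation

Merged reads are mapped to CDS-only databases: full-read infix identity
first and, for reads overhanging a CDS end into untranslated sequence, the
best ungapped end-overlap of ≥30 nt with identity computed over the aligned
span.  The read joins the best-identity entry at ≥95% identity; ties across
clusters are broken uniformly at random with a recorded seed (preserving
totals without inventing an expectation-maximization reassignment), and
ties within a cluster count once for the cluster.  Counts and depths are
scaled to 10 million mapped reads; "median coverage" is the median
per-position scaled depth over the representative CDS, the interpretation
that matches the printed column's magnitude.  Percentages use read counts,
not base coverage.  Because mapping is CDS-only, reads wholly within UTRs
never map; the truth-based tests therefore compare mapped counts against
read provenance restricted to CDS-overlapping inserts rather than against
raw expression weights.

## Proteomic evidence

Search databases hold mature proteins (translations with annotated signal
peptides removed — signal-peptide prediction itself is an input, not a
computation) plus reversed-sequence decoys, one per target.  Tryptic
digestion cleaves C-terminal to K/R except before P, with one missed
cleavage and a minimum peptide length of 6 (standard practice; the length
floor is configurable).  Peptides are matched by substring lookup with
isoleucine/leucine collapsed (mass-indistinguishable; a flag disables it)
after stripping modification annotations.  The acceptance rule — ≥3 matched
peptides, ≥20% coverage, score strictly above the highest decoy — is
monotone in all three thresholds and by construction admits zero decoys.
Grouping reconstructs the published tables' shared-unique-peptide
semantics: peptides are processed from most to least specific (ascending
mapped-set size); a peptide whose mapped entries are all unclaimed founds a
group of exactly those entries; entries never claimed have no
distinguishing peptide and no group number.  The original grouping
algorithm is proprietary; this reconstruction reproduces the published
tables' structure but is not claimed identical to it.  Cluster-level
confirmation strips the member letter and counts clusters with ≥1 accepted
identification; report ids outside the naming grammar (contaminants such
as hemoglobin) are excluded with a warning.

## Selection analyses

*Orthologs* are mutual best hits under local BLOSUM62 alignment with
E-values from the classical Karlin–Altschul formula (λ=0.267, K=0.041, the
standard gapped BLOSUM62/11-1 constants) scaled by database length, cutoff
1e−4.  *Codon alignment* back-threads a global protein alignment onto
codons, counts gapped nucleotide positions (a gapped amino-acid column = 3
nucleotide positions), excludes pairs with more than 24, and removes gapped
codon columns before estimation.

*Counting rates* implement Nei–Gojobori (1986): per-codon synonymous site
fractions (changes to stop codons count as nonsynonymous opportunity; stop
codon columns are not sites), pathway-averaged difference counts over all
orderings of the differing positions with stop-crossing pathways discarded,
and the Jukes–Cantor correction d = −3/4 ln(1 − 4p/3), reported as
undefined when p ≥ 0.75.  ω is undefined (never infinity) when dS = 0.
Counting is the default because an exact brute-force pathway oracle exists
for it; the ML mode is the mode matching published codeml-based practice.

*ML rates* maximize the two-sequence GY94 likelihood over divergence t,
transition/transversion ratio κ and ω, with F3x4 codon frequencies (or
caller-supplied frequencies); dN and dS are derived from the fitted flux
split by neutral site opportunity, so dN/dS equals the fitted ω exactly.

*Null-distribution analysis* takes the empirical 95th percentile (linear
interpolation) of the nontoxin dN, dS and ω distributions as thresholds,
counts toxin pairs exceeding each, and compares distributions with
two-sided Wilcoxon rank-sum tests — exact by enumeration of the rank
distribution when the smaller sample has ≤20 tie-free values, otherwise the
normal approximation with tie correction.  Undefined ω values are dropped
with their count reported.

*Trees* come from neighbor joining on pairwise HKY maximum-likelihood
distances (negative branches clamped to zero), or from a user-supplied
newick; a full ML tree search is out of scope.

*Site models* (M0, M1a, M2a, M7, M8) are fit by Felsenstein pruning over
the 61 sense codons with per-node rescaling, GY94 rate matrices sharing a
single clock normalized by the mixture-average rate (so all site classes
share one time scale and high-ω classes evolve faster), and F3x4
frequencies from the data.  The M7/M8 beta is discretized into K = 10
equal-probability categories at category means.  The input tree fixes the
topology and relative branch lengths; a single global scale on those
lengths is optimized jointly with the model parameters.  This keeps fits
fast, deterministic and well-conditioned; it assumes the input tree's
relative branch lengths are adequate, which holds for the NJ trees used
here — per-branch optimization is the main fidelity gap versus codeml.
Optimization is bounded L-BFGS-B from three deterministic starts
(ω ∈ {0.1, 0.5, 2.0}-style grids with κ = 2), run briefly from each start
and then to convergence from the best; the alternative models M2a and M8
additionally warm-start from their fitted nulls (M1a, M7), which guarantees
the nested-likelihood inequality up to optimizer tolerance (1e−4 in the
tests).  LRTs compare 2ΔlnL to χ² with two degrees of freedom (for df = 2
the tail is exactly exp(−Λ/2)); a negative statistic is clamped to zero
with a warning.

## Synthetic data generator

The generator emulates the study conditions: two species whose
transcriptomes contain nontoxins (purifying selection, ω = 0.10) and toxin
gene families (3FTx, SVMPIII, CRISP, CTL by default, with ω > 1),
divergence of 0.15 expected substitutions per codon site between species,
a toxin share of transcription of 0.362 (the measured Brown Treesnake
value), log-normal expression weights rescaled to that share, 151-nt paired
reads with normal insert lengths (mean 150, sd 30), per-cycle phred scores
capped at 41, adapter read-through, substitution errors at 1e−3, and
chimeric (single uniform breakpoint fusions) plus retained-intron
contamination at 2e−3 each.  Within-cluster members carry sprinkled
substitutions bounded so every pair stays below 1% divergence; members
beyond the representative model post-speciation alleles, so only cluster
representatives enter the ortholog map.  Codon evolution is a per-site
Gillespie simulation on the 61 sense codons (stop codons are outside the
state space; start and stop codons are held fixed), with the clock
normalized by the site-ω mixture so branch lengths are expected
substitutions per codon site.  Realized synonymous/nonsynonymous event
counts are returned and serve as the estimation oracle.  Identical configs
give byte-identical outputs; truth provenance is carried in read names
after a reserved separator and can be stripped for blind runs.

What the generator does **not** emulate: indel sequencing errors,
position- and context-dependent error profiles of real flow cells, biased
codon usage (ancestors are uniform over sense codons), alternative
splicing, and allele-frequency structure within clusters.  Passing tests
therefore demonstrate correctness of the algorithms under a clean
substitution-only model, not robustness to every artifact of real
libraries.

## Problem sizes in the test and acceptance runs

The suites run at desk scale as the package's own choice of problem size:
merge round-trip at 1e4 pairs; weight-recovery at 2e4 pairs; counting-
estimator checks at 2,000–5,000 codons; M0 recovery over 20 simulations of
1,000 codons on 6 taxa; M1a-vs-M2a power over 50 replicates of 500 codons
on 8 taxa with 20% of sites at ω = 4 (rejection at α = 0.05 in ≥80% of
replicates); null-threshold calibration at n = 1,000.  Dataset-scale
results (tens of millions of read pairs, thousands of orthologs) require
the archived sequencing deposits and are documented as non-desk checks
only.

## Known limitations

Single-linkage clustering can chain distinct loci through intermediate
alleles if a family is unusually dense; the proprietary assembler the study
used is represented by the defined consensus/extension contracts rather
than reimplemented; E-value constants are fixed rather than fit per scoring
system; site-model fits share one branch-length scale (see above); and the
grouping algorithm is a reconstruction of table structure, not the original
vendor algorithm.
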