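# venomforge

Tools for characterizing venom-gland transcriptomes and proteomes of
rear-fanged (colubrid) snakes, and for testing whether their toxin genes
evolve under diversifying selection.  The package reimplements, as a tested
and reusable pipeline, the workflow used to describe the strongly divergent
venoms of the Brown Treesnake (*Boiga irregularis*, an elapid-like,
three-finger-toxin-dominated venom) and the Desert Night Snake
(*Hypsiglena* sp., a viperid-like, metalloproteinase-dominated venom):

1. **Read merging** (`venomforge.readprep`) — 151-nt paired-end reads whose
   3' ends overlap are merged into consensus fragments; agreeing bases get
   summed phred qualities (capped at 93), disagreements keep the
   higher-quality base with quality |q1 − q2|, and adapter read-through is
   trimmed.
2. **Assembly and curation** (`venomforge.assembly`) — greedy seed extension
   (100-nt exact overlaps, phred ≥ 30) and reference-guided majority-vote
   consensus (identity ≥ 0.85, ≥ 5× coverage across the CDS), duplicate
   collapsing, single-linkage clustering of toxin coding sequences at <1%
   nucleotide divergence, chimera screening (coverage evenness + two-parent
   mosaic test) and keyword-based toxin annotation with cluster-aware names
   (`SVMPIII-2a` = class, cluster number, member letter).
3. **Abundance estimation** (`venomforge.quant`) — merged reads mapped to
   CDS-only databases at ≥ 95% identity, reported per cluster at a
   10-million-mapped-read scale: median coverage, % of toxin reads,
   % of total reads.
4. **Proteomic cross-validation** (`venomforge.protevidence`) — mature-protein
   search databases with reversed-sequence decoys, in-silico tryptic
   digestion (one missed cleavage), peptide-to-protein mapping with I/L
   equivalence, the acceptance rule (≥3 matched peptides, ≥20% coverage,
   score above the best decoy ⇒ 0% false-positive rate), grouping by shared
   unique peptides, and cluster-level confirmation counts.
5. **Selection analyses** (`venomforge.molevol`) — reciprocal-best-hit
   orthologs, codon-aware pairwise alignment (pairs with > 24 gapped
   positions excluded), pairwise dN/dS by Nei–Gojobori counting (pathway
   averaging + Jukes–Cantor correction) or by maximum likelihood under a
   GY94 codon model with F3x4 frequencies, nontoxin null distributions with
   95th-percentile outlier thresholds and Wilcoxon rank-sum comparisons,
   and codon site models (M0, M1a, M2a, M7, M8) fit by Felsenstein pruning
   with χ² (df = 2) likelihood ratio tests for positively selected site
   classes.
6. **Synthetic data with ground truth** (`venomforge.seqsim`) — a two-species
   generator producing toxin gene families (clusters of near-identical
   members), toxin-biased expression, overlapping read pairs with adapter
   read-through and quality scores, chimeric/unspliced contamination, and
   peptide-identification reports with decoys — so every stage above is
   testable without external downloads.

The published expression, identification and site-model tables for the two
study species ship with the package (`venomforge.tables`) and drive the
table-level consistency analyses.

## Worked example

```python
from venomforge.pipeline import PipelineConfig, run_pipeline

cfg = PipelineConfig(out_dir="demo_run", seed=3, n_nontoxins=10,
                     n_read_pairs=4000)
manifest = run_pipeline(cfg)
for stage, info in manifest["stages"].items():
    print(stage, info["counts"])
```

prints (stage counters from the run manifest):

```
simulate {'transcripts': 64, 'read_pairs': 4000, 'report_rows': 395}
merge {'merged': 4000, 'fraction_merged': 1.0}
assemble {'assembled': 14, 'toxin_clusters': 6}
quantify {'clusters_quantified': 6, 'toxin_pct_of_total': 37.004}
proteome {'accepted': 21, 'confirmed_clusters': 10, 'total_clusters': 10}
selection {'orthologs': 20, 'toxin_pairs': 10, 'site_model_tests': 1}
```

Reading the numbers: all 4,000 simulated short-insert pairs merge
(`fraction_merged: 1.0`, as expected when inserts are shorter than twice the
read length); reference-guided assembly keeps the 14 transcripts with ≥ 5×
CDS coverage, whose toxins fall into 6 clusters; the toxin share of mapped
reads (37.0%) recovers the simulated expression bias (36.2% of
transcription was assigned to toxins); peptide evidence confirms 10 of the
10 planted toxin clusters at this detectability; and 10 toxin ortholog
pairs are compared against the 10 nontoxin pairs' null distributions, with
one toxin family large enough for a site-model likelihood ratio test.
`demo_run/` contains the corresponding FASTA/FASTQ/TSV/JSON outputs and a
checksummed `manifest.json`; `venomforge report --manifest
demo_run/manifest.json` collects the study-style tables.

A command-line interface mirrors the stages:
`venomforge simulate|merge|quantify|proteome|selection|run|report`.

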