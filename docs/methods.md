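# Methods

## The genotyping model

The package targets a hemizygous somatic point mutation: an X-linked locus
in male patients, so each cell carries exactly one allele and is purely
mutant (MUT) or purely wild-type (WT). Two routes read the allele:

1. **Targeted amplicon (GoT).** Read 1 of each amplicon pair carries the
   16-nt cell barcode and 12-nt UMI; read 2 spans the locus and is
   classified WT/MUT/OTHER by the base at the variant offset within the
   expected amplicon context.
2. **Transcriptome reads.** Ordinary expression reads overlapping the
   variant, represented as a tagged-read table (cell barcode, UMI, base);
   coverage of any one locus is far sparser than the amplicon's.

### UMI collapsing

PCR amplification replicates each captured molecule, and sequencing errors
in the UMI split one molecule into several apparent UMIs. Within a cell
barcode, UMI pairs at Levenshtein distance ≤ ⌈0.1·L⌉ (2 for L = 12; full
edit distance — substitutions, insertions, deletions — via edlib) are
"matches". Collapsing is greedy: the UMI with the most matches among the
surviving set absorbs its partners; seed and absorbed UMIs leave the pool;
repeat with the next-highest-match UMI until no survivor has a match.
Match counts are unweighted; ties are broken by higher read count, then
lexicographically — deterministic, and favouring the more-sequenced
molecule. Absorbed UMIs cannot seed new clusters; iteration stops only when no
surviving UMI has a match left. The result is a
total map UMI → canonical UMI, idempotent on its own output.

### Consensus and cell calls

Per canonical UMI, WT and MUT reads are tallied (OTHER bases count toward
neither; reads with N in barcode or UMI are dropped before grouping). Equal
nonzero tallies are ambiguous and excluded. A cell with ≥ 1 MUT UMI is
called MUT; otherwise ≥ 1 WT UMI gives WT; otherwise UNASSIGNED. The
one-molecule rule is stated symmetrically for both alleles, which is
contradictory for cells holding both kinds of evidence; MUT takes
precedence here because under hemizygosity a true mutant cell can yield
apparent WT molecules only through error at the amplified locus, whereas
the reverse requires the rarer gain-of-variant error. The number of such
conflicted cells is reported alongside the calls.

Reads may be processed in chunks (default 125,000) for memory bounds;
tallies are re-keyed by cell barcode across chunks before collapsing, so
results are provably invariant to the chunking (tested).

### Transcriptome sniffer

Reads missing either the CB or UB tag are removed. Per (cell, UMI), the
most common base is accepted as the molecule's consensus only when its
share is ≥ 0.75 of the UMI's reads (so 3-of-4 passes); a tied top base or a
sub-threshold majority discards the molecule. Both ≥ and > conventions exist for this rule; ≥ is the default (it admits
the 3-of-4 case) and the operator is a switch (`strict_greater`). Cell calls then follow the same hemizygous
rule as the amplicon route.

## Annotation

- **QC**: retain cells with 500–6,000 detected genes and ≤ 5% mitochondrial
  reads (genes prefixed `MT-` by default, configurable). Idempotent;
  removal counts reported per criterion.
- **Normalization**: counts scaled per cell to a library size of 10,000,
  then ln(1 + x) (natural log, the convention of the surrounding
  ecosystem), via scanpy.
- **Signatures**: per reference subtype, genes ranked by (mean in subtype −
  mean of the rest) descending, ties by gene name; top 250 kept.
- **Cluster assignment**: one-sided (enrichment) Fisher's exact test on the
  2×2 overlap table between a cluster's marker genes and each signature;
  the universe is the genes shared by the expression matrix and the
  reference table (the most common convention). Cluster markers come from the package's own one-vs-rest
  differential expression with the standard thresholds. Ties are broken by
  larger overlap, then name order, and flagged ambiguous.
- **Module scores**: genes are ranked by average expression and split into
  24 equal-frequency bins; for each module gene, up to 100 control genes
  are drawn without replacement from the non-module genes of its bin (a
  module saturating its bin borrows expression-adjacent bins; a module
  covering every gene is its own control and scores exactly 0). Score =
  mean module expression − mean control expression, per cell. Deterministic
  under a seed; invariant to gene order and to adding a constant.
  Controls exclude module genes so a planted module shift is recovered
  unattenuated; scanpy's `score_genes` (same construction) serves as an
  independent cross-check in the tests.
- **Differential expression**: two-sided Wilcoxon rank-sum per gene
  (constant genes get p = 1), Bonferroni adjustment over tested genes, log
  fold change = ln(mean expm1 + 1) difference. The DE flag uses unadjusted
  P < 0.05 with log fold change > 0.1, the standard thresholds for this
  analysis; adjusted p is emitted for volcano-style use.

## Trajectory summaries

Genotype-ratio curves split a lineage's cells into 20 equal-width
pseudotime bins over [0, 1]; per bin the MUT (and WT) ratio is the count
over **all** lineage cells in the bin (unassigned genotypes included in the
denominator, so the MUT and WT curves are ratios to all lineage cells; an
assigned-only mode exists).
SE is binomial √(p(1−p)/n), bands 1.96·SE, bins under 10 cells masked.
Equal-width binning is used rather than a smoother — smoothed display curves
leave the estimator unspecified, while binned means keep the SE bands exact. Score curves use SE = sd/√n per bin and group.

The normalized mutant frequency per cell type averages per-patient
fractions n_MUT/(n_MUT+n_WT) across patients so no patient dominates (a pooled mode is provided and
the mode used is stamped in the output). Only cell types with strictly
more than 100 genotyped cells are analyzed.

## Repertoire statistics

Cells sharing an identical CDR3 nucleotide sequence on their primary chain
(TRB for T cells, IGH for B cells; optionally also identical V/J) form a
clone; only productive chains count, and a cell with several primary-locus
chains is represented by the one with the most supporting UMIs (tie:
lexicographic CDR3). Shannon entropy is computed in bits on clone
frequencies (validated to sum to 1; no silent renormalization); the Gini
index on clone cell counts via the sorted rank formula (a UMI-weighted mode
is available, both framings of molecule- vs cell-level clonality are in use). Clones of
> 20 cells are "expanded"; the interior classes (2–5, 6–20) are plotting
conventions. SHM categories use the conventional boundaries:
0 → germline, (0, 0.03] → low, > 0.03 → high. Isotypes map heavy-chain
constant genes (IGHM→IgM … IGHE→IgE; unknown genes reported as "unknown").
V/J usage tables carry a between-group chi-square test.

## The synthetic cohort generator

`simulate_cohort` produces every input with known ground truth from one
root seed (split per stage, byte-identical reruns). Defaults describe the
emulated cohort: 9 patients × 1,000 cells; cell-type proportions
Mono 0.20, DC 0.05, NK 0.10, T 0.45, B 0.15, plasmablast 0.05; mutant
fractions Mono/DC 0.4, NK 0.2, T/B/plasmablast 0 (myeloid restriction);
amplicon capture 0.17 and transcriptome capture 0.05 per cell; 1% per-base
error; 5% single-edit UMI corruption on PCR duplicates; clone-size zeta
exponent 2.5; marker fold change 4.

Parameters the cohort design leaves open, set once to realistic values:

- **NK decline**: mutant probability at pseudotime t is
  logistic(logit(p₀) − decay·t), decay 2.0 — the logit scale keeps
  probabilities in [0, 1] and gives the observed monotone decline.
- **Molecules per captured cell**: 1 + Poisson(mean − 1), mean 2.0 for the
  amplicon and 1.2 for transcriptome reads (a targeted amplicon recovers
  more molecules of its locus than 5' expression reads do).
- **PCR duplicates per UMI**: 1 + Poisson(3.0), so every UMI has ≥ 1 read
  and the capture rate is exact.
- **Counts**: ~1,500 genes with gamma-distributed baseline rates, 20
  exclusive marker genes per cell type, 13 mitochondrial genes at ~2.4% of
  library; 2% of cells planted low-complexity and 2% high-mitochondrial to
  exercise QC. Read qualities are constant dummies (never consumed).
- **Repertoire**: clone sizes drawn from a zeta(α) distribution truncated
  at the per-patient lineage size; V/J/C calls from a small fixed
  catalogue; SHM beta-distributed per B subtype (naive mean 0, memory
  0.025, plasmablast 0.06, concentration 40); plasmablast isotypes skewed
  to IgG; 97% of chains productive; 2% of transcriptome reads lose a tag.

What the generator does **not** emulate: transcript-level read structure,
doublets and ambient RNA, sequencing-quality variation, per-patient capture
variability (a single global rate is exposed),
batch effects, shared CDR3s between patients, and clustering itself
(cluster labels and pseudotime are inputs throughout, as the upstream
embedding/clustering/trajectory inference is out of scope). Passing tests
therefore demonstrate correctness of the computations under the stated
statistical structure, not robustness to artifacts absent from the model.

## Numerical and design notes

- Levenshtein distance is computed by edlib; tests cross-check a DP oracle.
- Greedy-collapse determinism: survivors are re-scanned after each
  absorption; all tie-breaks are total orders.
- Fisher's exact test via scipy; equivalence to exhaustive hypergeometric
  enumeration is tested for universes ≤ 30.
- Entropy/Gini reject invalid inputs (non-normalized frequencies, sizes
  < 1) rather than renormalizing.
- Degenerate inputs: empty read groups yield empty outputs; an empty count
  matrix, empty lineage, or zero-library cell raises with a message naming
  the problem; configuration errors name the offending field.
- Problem sizes in the test and acceptance runs (9 × 1,000-cell cohorts,
  50–200 replicate seeds for rate-recovery and coverage checks, 500-gene
  null DE panels) are chosen so each statistical property is measured with
  comfortable margin at desk scale.

## Known limitations

- The amplicon simulator flips alleles at the locus only (WT↔MUT); OTHER
  bases arise in real data from indels and off-target priming and are
  exercised in unit tests but not generated by the cohort simulator.
- The sniffer consumes a pre-extracted tagged-read table, not a BAM;
  CB/UB tag extraction from alignments is out of scope.
- Binned trajectory curves are not a smoother; with few cells per bin the
  binomial SE bands are wide and bins below the floor are masked rather
  than interpolated.
- Clone grouping ignores light/alpha chains; convergent CDR3s across V
  genes merge unless the `cdr3nt+VJ` mode is used.
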