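# scgot

Genotype-aware single-cell analysis for a hemizygous somatic mutation, built
around **genotyping of transcriptomes (GoT)**: targeted amplicon
re-sequencing of a variant locus from single-cell cDNA libraries, linked back
to each cell's transcriptome through shared cell barcodes.

The motivating setting is an X-linked somatic missense mutation (as in
VEXAS syndrome, where *UBA1*-mutant cells are restricted to the myeloid
lineage in blood): every cell is purely mutant or purely wild-type, standard
scRNA-seq reads cover the locus in only a few percent of cells, and a
targeted amplicon raises that to ~17%. The package is for computational
biologists who want the complete bespoke analysis of such a study as a
tested, reusable library: genotype calling, genotype-resolved cell-type
composition, pseudotime trajectories, and immune-repertoire clonality —
validated end to end on synthetic cohorts with known ground truth.

## What it computes

- **Amplicon (GoT) genotyping** (`scgot.genotyping`). Within each cell
  barcode, UMIs at Levenshtein distance ≤ ⌈0.1·L⌉ (2 for a 12-base UMI) are
  greedily collapsed, the UMI with the most matches absorbing its partners
  first. Each canonical UMI is called mutant or wild-type by majority of its
  reads; UMIs with equal tallies are removed as ambiguous. Under
  hemizygosity one confident molecule suffices: any mutant UMI makes the
  cell MUT, otherwise any wild-type UMI makes it WT.
- **Transcriptome variant sniffing** (`scgot.sniffer`). Reads lacking cell
  (CB) or molecular (UB) barcode tags are dropped; per (cell, UMI) the most
  common base is accepted only when it reaches ≥ 75% of reads; cells are
  genotyped by the same hemizygous rule.
- **Annotation** (`scgot.annotation`). Cell QC (500–6,000 detected genes,
  ≤ 5% mitochondrial reads), library-size normalization to 10,000 with
  ln(1+x), top-250 reference signatures, one-sided Fisher's-exact
  marker-overlap cluster assignment, expression-bin-matched control module
  scores, and two-sided Wilcoxon rank-sum differential expression with
  Bonferroni correction (DE flag: P < 0.05 and log average fold change > 0.1).
- **Trajectories** (`scgot.trajectory`). Normalized mutant frequency per
  cell type (per-patient fractions averaged across patients; only types with
  > 100 genotyped cells), and binned genotype-ratio / module-score curves
  along a supplied pseudotime with 1.96·SE bands.
- **Repertoire** (`scgot.repertoire`). Clones by identical CDR3 nucleotide
  sequence, Shannon entropy H(P) = −Σ pᵢ log₂ pᵢ, Gini index over clone
  sizes, expansion classes (expanded = > 20 cells), SHM categories
  (germline = 0, low ≤ 3%, high > 3%), isotype and V/J usage tables.
- **Synthetic cohorts** (`scgot.simulate`). A generator that emulates the
  study's statistical structure — lineage-dependent mutant fractions,
  logit-linear mutant decline along NK pseudotime, ~17%/~5% amplicon and
  transcriptome capture, PCR duplicates with single-edit UMI corruption,
  marker-structured counts, zeta-law clone sizes, subtype-dependent SHM —
  with full ground truth for validation.

## Worked example

```python
from scgot import SimulationConfig, simulate_cohort, genotype_cells, AmpliconRead
from scgot.sniffer import TaggedRead, sniff_cells

cohort = simulate_cohort(SimulationConfig(seed=1))   # 9 patients x 1,000 cells
reads = [AmpliconRead(r.cell_barcode, r.umi, r.locus_base)
         for r in cohort.amplicon_reads.itertuples(index=False)]
got = genotype_cells(reads)

genotyped = [c for c in got.cells if c.genotype != "UNASSIGNED"]
truth = cohort.cells.set_index("cell_barcode")["genotype"]
acc = sum(truth[c.cell_barcode] == c.genotype for c in genotyped) / len(genotyped)
print(f"GoT genotyped {len(genotyped)} of {len(cohort.cells)} cells "
      f"({100 * len(genotyped) / len(cohort.cells):.1f}%), accuracy {100 * acc:.1f}%")

sniffed = sniff_cells([TaggedRead(r.cell_barcode, r.umi, r.base_at_variant)
                       for r in cohort.tagged_reads.itertuples(index=False)])
n = sum(c.genotype != "UNASSIGNED" for c in sniffed.cells)
print(f"transcriptome sniffer genotyped {n} cells ({100 * n / 9000:.1f}%)")
```

prints

```
GoT genotyped 1496 of 9000 cells (16.6%), accuracy 100.0%
transcriptome sniffer genotyped 453 cells (5.0%)
```

The amplicon approach genotypes ~17% of cells at essentially perfect
per-cell accuracy, while ordinary transcriptome reads reach only ~5% — the
gap that motivates targeted genotyping in the first place.

The same stages are available from a shell:

```bash
scgot run-all --seed 1 --out-dir out/          # simulate + all stages + manifest
scgot simulate --seed 1 --out-dir sim/
scgot genotype-got --r1 sim/amplicon_R1.fastq --r2 sim/amplicon_R2.fastq --out-prefix got
scgot genotype-sniffer --reads sim/tagged_reads.tsv --out sniffer.tsv
scgot repertoire --chains sim/receptor_chains.tsv --out-dir rep/
```

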