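# ovodiverge

Cross-species comparative analysis of ovarian somatic cells from single-cell
transcriptome and chromatin-accessibility data.

Granulosa (GC), stromal (SC) and theca (TC) cells support folliculogenesis in
every placental mammal, but how much their gene expression programs and
regulatory landscapes have diverged between human and the usual model species
(macaque, mouse, rat, rabbit) determines how far findings transfer between
them. `ovodiverge` implements, as a tested pipeline, the analyses that answer
that question:

* **Expression divergence phylogenies.** Per-group pseudo-bulk profiles over
  1:1 orthologues (counts → CPM → log1p), Spearman correlation distances
  d(i,j) = 1 − ρ(i,j), neighbor-joining trees with gene-resampling bootstrap,
  and a branch-length divergence test: the distribution of total tree length
  L = Σ<sub>e</sub> b<sub>e</sub> over bootstrap replicates is compared
  between cell types by a two-sided Wilcoxon rank-sum test. A longer tree
  means more expression change along the phylogeny.
* **Peak conservation taxonomy.** scATAC peaks are lifted onto the reference
  genome through UCSC chain files (block-walking with a `min_match` mapped-base
  fraction, default 0.95) and classified as *Not alignable*, *Alignable but
  not accessible*, or *Conserved accessible* (≥ 1 bp overlap with a reference
  peak). Conserved-peak sequences feed p-distance NJ trees; accessibility
  pseudo-bulks feed a PCA whose PC2 separations quantify cell-type divergence.
* **Gene-linked cCREs.** Distal peaks co-accessible with a promoter peak are
  candidate cis-regulatory elements; candidates whose metacell accessibility
  correlates with target-gene expression above the empirical 95th percentile
  of all candidate Pearson r values (strict inequality, per species) are
  gene-linked cCREs. At most ~5% of candidates can be retained by
  construction, which is asserted on every run.
* **igHTRs.** Intergenic highly-transcribed regions: duplicate-filtered reads
  (SAM flag bit 0x400) in intergenic repeat-free space are clustered
  left-to-right, merging while the neighbour spacing is < 150 bp and keeping
  clusters with strictly more than 10 reads; regions are quantified
  (reads/kb), located relative to the nearest TSS, profiled for Tn5 insertion
  coverage against length-matched random intergenic controls, and classified
  for conservation against reference igHTRs.
* **NMF pattern projection.** Multiplicative-update NMF learns non-negative
  expression programs in the reference species; other species' cells are
  projected by per-cell non-negative least squares, and each pattern is
  summarized by the correlation of its weights with cell-type indicators —
  conserved programs correlate everywhere, species-specific ones only at home.
* **Motif and TF conservation filters.** Calibrated log-odds PWM scans (MEME
  minimal format; per-position false-positive rate fixed by exact dynamic
  programming over the score distribution), one-sided Fisher enrichment of
  foreground over background sequence sets (p < 0.05), UpSet-style exclusive
  intersections, and the nested TF filter: shared across species → expressed
  (mean log-normalized expression > 0.2 in the reference cell type) →
  conserved (expressed in every species). Wilcoxon rank-sum differential
  expression with Benjamini–Hochberg control and hypergeometric
  over-representation against GMT gene sets round out the toolkit.

Because the analyses are exercised on a **synthetic five-species,
three-cell-type cohort with planted ground truth** (`ovodiverge.synthetic_data`),
every stage has a recoverable answer: planted divergence-rate multipliers,
conservation fractions realized by constructed chain files, igHTR clusters and
decoys, gene–cCRE links, pattern amplitudes and motif occurrences.

## Worked example

Which ovarian cell type changed most during evolution?

```python
import numpy as np
from ovodiverge import synthetic_data as synth
from ovodiverge import phylo_divergence as phylo

tree = synth.SpeciesTree()                      # human..rabbit, 5 species
truth = synth.SimulationTruth(rng_seed=1)       # TC=2.0, SC=1.2, GC=1.0
cohort = synth.simulate_expression(tree, truth, n_genes=600, cells_per_type=60)

counts, meta = phylo.combine_cohort(cohort.counts, cohort.metadata)
totals, trees = phylo.celltype_branch_lengths(counts, meta, cohort.orthologs,
                                              n_boot=100, seed=1)
for ct in ("GC", "SC", "TC"):
    print(f"{ct} mean total branch length: {np.mean(totals[ct]):.3f}")
print(phylo.branch_length_test(totals).to_frame().to_string(index=False))
```

prints

```
GC mean total branch length: 0.376
SC mean total branch length: 0.402
TC mean total branch length: 0.577
group_a group_b      p_value significance
     GC      SC 2.707262e-09         ****
     GC      TC 2.562144e-34         ****
     SC      TC 2.562144e-34         ****
```

The theca-cell tree is the longest — the planted rate order TC > SC > GC is
recovered, with decisive Wilcoxon rank-sum p-values over the 100 bootstrap
replicates. `trees["TC"].to_newick()` shows the species tree with 100%
bootstrap support on both internal edges.

The whole pipeline runs end to end from one command and is byte-identical
per seed:

```sh
ovodiverge run-all --simulate --seed 7 --out out/
```

which writes the synthetic fixture tree (MTX counts, GTF, BED, chain, FASTA,
reads/fragments tables, truth.json), every stage's outputs, and a
`manifest.json` with per-stage seeds and output digests.

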