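# Methods

This note documents the models, rules and numerical choices behind
`ovodiverge`, and what the synthetic cohort does and does not show about
real data.

## Coordinate conventions and I/O

All genomic coordinates are 0-based half-open (BED convention); GTF input
(1-based inclusive) is converted on read and the TSS is derived from the
gene span per strand. Chain files follow UCSC semantics: the `t` fields of
the header describe the source genome, the `q` fields the target, with
block arithmetic (`size dt dq`) verified on load and negative-strand target
coordinates converted to plus-strand on lifting. Alignment input is a
flag-bearing interval table (chrom, start, end, SAM flag, barcode) rather
than BAM, which keeps the pipeline testable with plain-text fixtures; the
duplicate filter drops any read with flag bit 0x400 set, matching the
conventional `-F 1024` semantics.

## Synthetic cohort

The generator emulates a five-species (human, macaque, mouse, rat, rabbit),
three-cell-type (granulosa GC, stromal SC, theca TC) ovarian study with
planted, exactly recoverable ground truth. It is first-class, tested code;
its defaults define the study conditions.

**Expression.** Log-mean expression evolves along the species tree
(topology ((rat,mouse),rabbit),(monkey,human); branch lengths in arbitrary
divergence units, human–rat path ≈ 0.26) by Brownian motion: each branch
adds a Gaussian increment with variance = branch length × cell-type rate
multiplier. Default multipliers GC = 1.0, SC = 1.2, TC = 2.0 plant the
divergence-rate order the branch-length test must recover. Brownian motion
on log-means is the standard phylogenetic comparative model; a generative
model had to be chosen because tree-consistency of pseudo-bulk distances
does not by itself specify one. Cell identity is carried by three disjoint
25-gene marker blocks (+2.5 on the log-mean, constant across species).
Counts are negative-binomial per cell with fixed dispersion 0.5 (variance
μ + 0.5 μ²); only rank and distance structure matter downstream, so the
dispersion is not estimated. Defaults: 1,000 genes, 80 cells per type per
species; the bundled runs use 600 genes × 60 cells to keep a full pipeline
execution in seconds.

**Genomes, peaks and chains.** Per-species single-chromosome genomes carry
an identical entity layout shifted by a species-specific offset, so lifting
is a genuine coordinate translation. Each non-reference species' peaks are
partitioned into the three conservation classes by largest-remainder
apportionment of the planted fractions (exact integer counts); chains are
constructed per alignable interval with a 60 bp flank and a 20 bp
double-sided gap in the first block, so every lift exercises multi-block
arithmetic. Conserved peaks map in index order onto reference peaks, giving
a deterministic cross-species intersection for the sequence trees. Peak
sequences evolve from a common root by per-branch substitution (probability
= branch length × cell-type multiplier × 0.5), so theca-assigned peaks
accumulate the most sequence divergence. Default planted
conserved-accessible fractions fall monotonically with divergence from the
reference (monkey 45% → rabbit 25%).

**Reads and fragments.** Read categories (exon 0.45 / intron 0.20 / ncRNA
0.10 / intergenic-repeat 0.10 / intergenic 0.15) are placed by exact counts
with the read midpoint inside the chosen feature. Planted igHTRs (40 per
species, 500 bp) receive 12–18 reads spanning the interval exactly with all
neighbour gaps < 150 bp; gap-decoys hold two 6-read sub-clusters separated
by exactly 150 bp, count-decoys exactly 10 compliant reads — each decoy
violates exactly one clause of the caller's rule. Background intergenic
reads are rationed ≤ 5 per 400 bp zone so they can never assemble a
spurious igHTR. A planted fraction (default 0.3) of table rows are
duplicate copies of existing reads with flag bit 0x400 set, so the filter's
removal count is exact. Tn5-like fragments are uniform background plus
extra fragments over igHTRs at 3× local density.

**Other cohorts.** The multiome linking cohort gives every gene a promoter
peak and three distal peaks within 100 kb; planted (gene, distal) pairs
share the gene's latent per-cell activity (z ~ Gamma(2,1); expression
Poisson(20z), accessibility Poisson(12z)), giving metacell-level r ≈ 0.9,
while non-planted distals share only an accessibility latent with the
promoter so they form candidates without expression correlation. The
pattern cohort draws counts from five non-negative programs on disjoint
60-gene blocks (one per cell type, one housekeeping, one human-TC-specific)
plus ambient expression confined to non-program tail genes; keeping the
ambient term out of the program blocks is what makes the species-specific
pattern projectable as exactly zero abroad. The motif cohort embeds a
TGACGTCA consensus in 60% of foreground and 12% of background sequences
(5×), with never-embedded decoy PWMs. The TF-filter cohort plants nested
shared (22) / reference-expressed (12) / conserved (7) sets.

## Phylogenetics

Pseudo-bulk = per-group (species or species × cell type) gene sums over 1:1
orthologues → CPM → log1p. Expression distance is 1 − Spearman correlation,
robust to species-specific scale; no distance metric is canonical for
pseudo-bulk trees, and rank correlation is the conservative choice. Trees
are built by neighbor joining (scikit-bio), with negative branch-length
estimates clamped to zero. Bootstrap resamples genes (expression) or
alignment columns (sequence) with replacement; per-edge support is the
bipartition frequency × 100. The divergence statistic is the **total branch
length per bootstrap-replicate tree**; distributions over replicates are
compared per cell-type pair by a two-sided Wilcoxon rank-sum test (exact
when both n ≤ 20 and tie-free, else normal approximation with tie
correction), starred *, **, ***, **** at p ≤ 0.05, 0.01, 0.001, 0.0001.
Taking the distribution over bootstrap replicates is a design choice — a
per-branch or per-subsample distribution would be equally defensible; the
replicate-total version is implemented because it directly measures the
quantity the divergence claim is about.

Sequence distances are concatenated p-distances over peaks conserved
accessible in *all* species (keyed by the reference interval); columns with
a gap or N in either sequence are excluded pairwise, and an optional
Jukes–Cantor transform is available (it errors at p ≥ 0.75 where the
transform saturates).

## Lifting and conservation classes

`lift_interval` walks the aligned blocks of the best-scoring chain
overlapping the query; it succeeds iff the mapped-base fraction is
≥ `min_match` (default 0.95, the conventional liftOver default — the
upstream tool's parameters are not otherwise specified) and returns the
plus-strand span of the mapped bases. Failures are typed: `NO_CHAIN`,
`PARTIAL_BELOW_MIN_MATCH`, or `SPLIT` when other chains also overlap.
Classification: lift failure → *Not alignable*; lifted with ≥ 1 bp overlap
of a reference peak → *Conserved accessible*; otherwise *Alignable but not
accessible*. The ≥ 1 bp overlap rule operationalizes "open in the other
species"; book-ended intervals do not overlap (half-open convention). The
classification is exhaustive and exclusive, asserted on every run, and
raising `min_match` can only move peaks toward *Not alignable*. The
conserved-peak PCA uses log1p CPM-scaled accessibility pseudo-bulks with
feature standardization (the normalization upstream of the original PCA is
unspecified; this is the package's choice).

## Gene-linked cCREs

Cells are partitioned within species × cell type into seeded random
metacells of ~20 cells to stabilize sparse correlations (the correlation
unit is not otherwise defined; exposed in `PipelineConfig`). The
co-accessibility stand-in computes Pearson r between metacell accessibility
profiles for peak pairs within 100 kb, keeping pairs with r ≥ 0.25 — a
documented correlation stand-in for a graphical-lasso co-accessibility
model, whose output table can also be supplied directly. Promoter windows
are 2,000 bp upstream / 500 bp downstream of the TSS, strand-aware (a
common scATAC convention; "promoter element" is otherwise undefined). A
link with exactly one side in a promoter nominates the other side as a
candidate cCRE for that gene; promoter–promoter links contribute both
directions; duplicates keep the maximum link score. Candidates are retained
iff their accessibility–expression Pearson r **strictly exceeds** the
empirical 95th percentile of all candidate r values, computed per species
over candidates only (whether the original percentile was over candidate or
all pairs is ambiguous; candidates-only is implemented and recorded). The
retained fraction is ≤ (1 − quantile) + 1/n by construction and asserted.
Genomic context is assigned at the cCRE midpoint with precedence promoter >
exonic > intronic > intergenic, and distance is midpoint-to-TSS.

## igHTR calling

After duplicate filtering, reads whose midpoint falls in intergenic,
repeat-free space are swept left-to-right per chromosome: a read joins the
open cluster while (read start − cluster's rightmost covered base)
< 150 bp — strictly less, so a 149 bp gap merges and a 150 bp gap splits —
and a cluster is emitted iff it holds **strictly more than 10** reads
("more 10" read as > 10; `ightr_count_inclusive` flips to ≥ 10, and
`ightr_gap_mode` switches to start-to-start spacing, both exposed because
the phrasing is ambiguous). The region is the union of member reads;
reads/kb is raw read count per kilobase with no library-size normalization
(comparisons are within-sample). Emitted regions are re-validated against
the no-gene/no-repeat invariant independently of the sweep. The caller is
verified against an O(n²) brute-force oracle on random instances, and
re-calling the reads of an emitted region returns that region
(idempotence). TSS distances are binned on log-scaled edges (1 kb, 10 kb,
100 kb, 1 Mb). Accessibility profiles scale each region to 20 body bins
plus 2 kb flanks at 100 bp resolution, counting Tn5 insertion endpoints
(both fragment ends); controls are equally many length-matched regions
drawn with a fixed seed from supplied intergenic space. igHTR conservation
mirrors the peak taxonomy: lift failure → *Not conserved*; lifted without
reference-igHTR overlap → *Conserved, but not igHTR*; overlap → *Conserved*.

## Patterns

`fit_patterns` is deterministic multiplicative-update NMF (squared
Frobenius objective, checked non-increasing every 10 iterations; tolerance
1e-9 on the relative decrease, max 2,000 iterations) with 5 seeded restarts
keeping the lowest objective — multiplicative updates can strand a
component at zero from a bad start. Amplitude columns are normalized to
unit L2 with the scale folded into the weights. This replaces a Bayesian
sparse NMF: the downstream analysis consumes only pattern weights and their
cell-type correlations, which this deterministic stand-in reproduces on
synthetic truth. For the synthetic cohort the factorization and projection
run on raw counts, because the planted model is linear on the count scale
and the log1p transform measurably degrades amplitude recovery; for
heavy-tailed real data the log1p route remains available
(`project_cohort(log_normalize=True)`). Projection is per-cell NNLS onto
the fixed amplitudes (all-zero cells get zero weights; fewer than 50%
shared genes is an error), followed by Pearson correlation of each
pattern's weights with cell-type indicator vectors. The default pattern
count for synthetic runs is the planted k = 5; real analyses would choose k
by inspection.

## Enrichment statistics

PWM scanning uses Biopython's PSSM machinery: log-odds against a
configurable background (uniform by default), with the hit threshold set so
a background-random window passes with probability 1e-4, computed by exact
dynamic programming over the discretized score distribution (precision
10³). For sharply peaked PWMs the discrete score atoms make the threshold
conservative — the attainable false-positive rate sits at or below the
target, which the tests verify against exhaustive 8-mer enumeration. Both
strands are scanned; sequences shorter than the motif are skipped and
logged. Motif enrichment is a one-sided Fisher exact test on
sequences-with-hit counts, enriched iff raw p < 0.05 (BH-adjusted q values
are used for DE and ORA, but the enriched flag follows the raw-p
convention, as a flag-switchable documented divergence). The default
background for a real analysis would be dinucleotide-shuffled foreground;
the synthetic cohort supplies its own matched background set.
Over-representation is the hypergeometric upper tail with BH across sets.
Differential expression is a per-gene two-sided Wilcoxon rank-sum on
log-normalized expression (log1p of per-cell counts scaled to 10,000 —
the convention the ">0.2" expression threshold presumes), with log2 fold
change of group means under a pseudocount of 1. The TF filter chain
computes shared = intersection of per-species enriched sets, expressed =
mean normalized expression strictly > 0.2 in the reference species' theca
cells, conserved = expressed in every species; the nesting conserved ⊆
expressed ⊆ shared is asserted.

## Orchestration and determinism

`ovodiverge run-all --simulate` executes simulate → phylo → conserve →
link → ightr → patterns → enrich, writing each stage's outputs and a
manifest (config snapshot, per-stage seeds, SHA-256 digests of all
outputs). One global seed fans out to per-stage seeds by stable SHA-256
hashing of stage names, so stages are decoupled and reruns with the same
seed are byte-identical; manifests contain no timestamps. A full synthetic
run at the bundled sizes (600 genes × 60 cells per type per species, 600
peaks, 20,000 reads per species, 100 bootstrap replicates) completes in
well under a minute on one CPU.

## What the synthetic cohort does not show

The generator plants clean, separable structure: no doublets, ambient RNA,
batch effects, copy-number variation, or annotation errors; genomes are a
single chromosome with non-overlapping features; sequence evolution has no
indels, so "alignments" are trivially columnwise; chain files contain no
inversions or many-to-many mappings (the lifting code supports
negative-strand chains, exercised by hand-built cases). Passing recovery
tests therefore demonstrates that the implementations compute their
definitions correctly and that the planted signals are identifiable at
realistic sizes — not that the pipeline is robust to the full noise
structure of real multi-ome data. Quantities that depend on deposited
sequencing data, external genome builds or a motif database (absolute cell
counts, exact conserved-fraction values, specific TF identities) are
outside what a synthetic cohort can reproduce; the planted defaults mirror
their qualitative structure (e.g. the monotone conserved-accessible
gradient, nested TF filter counts) instead.

## Known limitations

Negative NJ branch lengths are clamped to zero without redistributing the
deficit to the sibling edge. The igHTR caller is strand-agnostic. The
co-accessibility stand-in is a plain correlation, not a sparse graphical
model, and will over-link in dense peak neighbourhoods. PWM threshold
calibration at precision 10³ quantizes scores; extremely low
`per_position_p` values would need a finer distribution. `coaccess_stand_in`
is quadratic in peaks per 100 kb window and intended for peak sets in the
tens of thousands, not millions.
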