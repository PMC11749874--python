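"""Five-species, three-cell-type synthetic cohort with planted ground truth.

The generator emulates the structure of a cross-species ovarian single-cell
multi-omics study: granulosa (GC), stromal (SC) and theca (TC) cells from
human, monkey, mouse, rat and rabbit, with

* expression divergence evolving along a species tree by Brownian motion on
  log-means (cell-type-specific rate multipliers; TC > SC > GC by default),
* per-species peak sets whose conservation classes (not alignable /
  alignable-but-not-accessible / conserved-accessible) are planted exactly
  and realized by constructed UCSC chain files,
* intergenic read clusters satisfying (or deliberately violating) the
  igHTR two-parameter rule,
* promoter-linked candidate cis-regulatory elements with planted
  accessibility-expression correlations,
* planted NMF expression patterns including one reference-species-specific
  theca pattern, and
* motif occurrences planted at elevated foreground rates.

Everything is reproducible bit-identically from (configuration, seed), and
the planted parameters are serialized in :class:`SimulationTruth` so that
downstream recovery tests read only generator outputs plus truth.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

from .core_io import (
    CELL_TYPES,
    CellMetadata,
    Chain,
    ChainBlock,
    ChainMap,
    CountMatrix,
    GeneModel,
    GenomicInterval,
)

DEFAULT_SPECIES = ("human", "monkey", "mouse", "rat", "rabbit")
DEFAULT_NEWICK = (
    "(((rat:0.06,mouse:0.06):0.04,rabbit:0.10):0.03,"
    "(monkey:0.05,human:0.05):0.08);"
)

PEAK_CLASSES = ("NOT_ALIGNABLE", "ALIGNABLE_NOT_ACCESSIBLE", "CONSERVED_ACCESSIBLE")
IGHTR_CLASSES = ("NOT_CONSERVED", "CONSERVED_NOT_IGHTR", "CONSERVED")

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


# ---------------------------------------------------------------------------
# species tree
# ---------------------------------------------------------------------------

@dataclass
class SpeciesTree:
    """Rooted binary tree over the study species, branch lengths in
    arbitrary divergence units."""

    newick: str = DEFAULT_NEWICK

    def __post_init__(self) -> None:
        self._tree = TreeNode.read(io.StringIO(self.newick))
        for node in self._tree.traverse(include_self=False):
            if node.length is None or node.length < 0:
                raise ValueError("all branch lengths must be non-negative")

    @property
    def tree(self) -> TreeNode:
        return self._tree

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(sorted(t.name for t in self._tree.tips()))

    def path_length(self, a: str, b: str) -> float:
        return self._tree.find(a).distance(self._tree.find(b))


# ---------------------------------------------------------------------------
# truth
# ---------------------------------------------------------------------------

def _default_peak_fractions() -> dict[str, dict[str, float]]:
    # conserved-accessible fraction decreases with divergence from the
    # reference, mirroring the observed ~40% -> 20% gradient
    return {
        "monkey": {"NOT_ALIGNABLE": 0.20, "ALIGNABLE_NOT_ACCESSIBLE": 0.35,
                   "CONSERVED_ACCESSIBLE": 0.45},
        "mouse": {"NOT_ALIGNABLE": 0.30, "ALIGNABLE_NOT_ACCESSIBLE": 0.35,
                  "CONSERVED_ACCESSIBLE": 0.35},
        "rat": {"NOT_ALIGNABLE": 0.35, "ALIGNABLE_NOT_ACCESSIBLE": 0.35,
                "CONSERVED_ACCESSIBLE": 0.30},
        "rabbit": {"NOT_ALIGNABLE": 0.40, "ALIGNABLE_NOT_ACCESSIBLE": 0.35,
                   "CONSERVED_ACCESSIBLE": 0.25},
    }


def _default_ightr_fractions() -> dict[str, dict[str, float]]:
    return {
        sp: {"NOT_CONSERVED": 0.35, "CONSERVED_NOT_IGHTR": 0.40, "CONSERVED": 0.25}
        for sp in ("monkey", "mouse", "rat", "rabbit")
    }


def _default_read_props() -> dict[str, float]:
    return {"exon": 0.45, "intron": 0.20, "ncRNA": 0.10,
            "repeat": 0.10, "intergenic": 0.15}


def _default_multipliers() -> dict[str, float]:
    return {"GC": 1.0, "SC": 1.2, "TC": 2.0}


@dataclass
class SimulationTruth:
    """All planted parameters, serialized alongside generator outputs."""

    species: tuple[str, ...] = DEFAULT_SPECIES
    reference: str = "human"
    rate_multipliers: dict[str, float] = field(default_factory=_default_multipliers)
    nb_dispersion: float = 0.5
    peak_class_fractions: dict[str, dict[str, float]] = field(
        default_factory=_default_peak_fractions)
    ightr_class_fractions: dict[str, dict[str, float]] = field(
        default_factory=_default_ightr_fractions)
    read_category_props: dict[str, float] = field(default_factory=_default_read_props)
    duplicate_fraction: float = 0.3
    n_planted_ightrs: int = 40
    n_decoy_gap: int = 20
    n_decoy_count: int = 20
    substitution_scale: float = 0.5
    accessibility_fold: float = 3.0
    motif_fg_rate: float = 0.6
    motif_bg_rate: float = 0.12
    rng_seed: int = 0
    # filled by the generators
    planted_links: list = field(default_factory=list)
    ightr_intervals: dict = field(default_factory=dict)
    pattern_gene_blocks: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(m <= 0 for m in self.rate_multipliers.values()):
            raise ValueError("rate multipliers must be positive")
        if self.nb_dispersion <= 0:
            raise ValueError("negative-binomial dispersion must be positive")
        for table in (self.peak_class_fractions, self.ightr_class_fractions):
            for sp, fr in table.items():
                vals = list(fr.values())
                if any(not 0 <= v <= 1 for v in vals):
                    raise ValueError(f"fractions out of [0,1] for {sp}")
                if abs(sum(vals) - 1.0) > 1e-9:
                    raise ValueError(f"fractions for {sp} do not sum to 1")
        if abs(sum(self.read_category_props.values()) - 1.0) > 1e-9:
            raise ValueError("read category proportions do not sum to 1")
        if not 0 <= self.duplicate_fraction < 1:
            raise ValueError("duplicate fraction out of [0,1)")

    def to_json(self, path: str | Path) -> None:
        payload = asdict(self)
        payload["species"] = list(self.species)
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True,
                                         default=str) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationTruth":
        data = json.loads(Path(path).read_text())
        data["species"] = tuple(data["species"])
        return cls(**data)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def exact_counts(fractions: Sequence[float], n: int) -> list[int]:
    """Integer apportionment of n by the largest-remainder method."""
    raw = np.asarray(fractions, dtype=float) * n
    base = np.floor(raw).astype(int)
    short = n - int(base.sum())
    order = np.argsort(base - raw, kind="stable")  # largest remainder first
    for i in order[:short]:
        base[i] += 1
    return base.tolist()


def _random_seq_array(rng: np.random.Generator, n: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, n, dtype=np.uint8)]


def _arr_to_str(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def _evolve_values(tree: TreeNode, root: np.ndarray, rate: float,
                   rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Brownian motion along the tree: increment variance = branch x rate."""
    values: dict[int, np.ndarray] = {id(tree): root}
    for node in tree.preorder(include_self=False):
        sd = float(np.sqrt((node.length or 0.0) * rate))
        parent = values[id(node.parent)]
        values[id(node)] = parent + rng.normal(0.0, sd, root.size) if sd > 0 else parent.copy()
    return {tip.name: values[id(tip)] for tip in tree.tips()}


def _evolve_sequence(tree: TreeNode, root: np.ndarray, rate: float,
                     rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Per-branch substitution: each base mutates with prob = branch x rate."""
    seqs: dict[int, np.ndarray] = {id(tree): root}
    for node in tree.preorder(include_self=False):
        p = min(0.75, (node.length or 0.0) * rate)
        parent = seqs[id(node.parent)]
        child = parent.copy()
        if p > 0:
            hit = np.nonzero(rng.random(root.size) < p)[0]
            if hit.size:
                # replace with a uniformly chosen *different* base
                shift = rng.integers(1, 4, hit.size)
                idx = (np.searchsorted(_BASES, parent[hit]) + shift) % 4
                child[hit] = _BASES[idx]
        seqs[id(node)] = child
    return {tip.name: seqs[id(tip)] for tip in tree.tips()}


# ---------------------------------------------------------------------------
# expression cohort
# ---------------------------------------------------------------------------

@dataclass
class ExpressionCohort:
    counts: dict[str, CountMatrix]
    metadata: dict[str, CellMetadata]
    orthologs: pd.DataFrame
    leaf_logmeans: dict[str, dict[str, np.ndarray]]  # cell type -> species -> genes


def simulate_expression(tree: SpeciesTree, truth: SimulationTruth,
                        n_genes: int = 1000, cells_per_type: int = 80,
                        seed: int | None = None, n_markers: int = 25,
                        ) -> ExpressionCohort:
    """Simulate per-species single-cell count matrices.

    Log-mean expression evolves along the species tree by Gaussian
    increments with variance = branch length x cell-type rate multiplier;
    counts are drawn negative-binomially per cell (fixed dispersion).
    Cell-type identity is carried by a marker-gene block shared across
    species. A 1:1 orthologue table is emitted.
    """
    if n_genes < 200:
        raise ValueError("n_genes must be >= 200")
    if cells_per_type < 50:
        raise ValueError("cells_per_type must be >= 50")
    rng = np.random.default_rng(truth.rng_seed if seed is None else seed)
    species = truth.species
    gene_ids = [f"g{i:05d}" for i in range(n_genes)]

    root = rng.normal(np.log(3.0), 0.8, n_genes)
    marker_boost = np.zeros((n_genes, len(CELL_TYPES)))
    for t, ct in enumerate(CELL_TYPES):
        marker_boost[t * n_markers:(t + 1) * n_markers, t] = 2.5

    leaf_logmu: dict[str, dict[str, np.ndarray]] = {}
    for ct in CELL_TYPES:
        leaf_logmu[ct] = _evolve_values(tree.tree, root,
                                        truth.rate_multipliers[ct], rng)

    r = 1.0 / truth.nb_dispersion  # NB size parameter; var = mu + disp * mu^2
    counts: dict[str, CountMatrix] = {}
    metadata: dict[str, CellMetadata] = {}
    for sp in species:
        blocks, cell_ids, types = [], [], []
        for t, ct in enumerate(CELL_TYPES):
            mu = np.exp(leaf_logmu[ct][sp] + marker_boost[:, t])
            p = r / (r + mu)
            block = rng.negative_binomial(r, p[:, None],
                                          size=(n_genes, cells_per_type))
            blocks.append(block)
            start = t * cells_per_type
            cell_ids.extend(f"{sp}_c{start + i:05d}" for i in range(cells_per_type))
            types.extend([ct] * cells_per_type)
        mat = np.concatenate(blocks, axis=1)
        features = [f"{sp}_{g}" for g in gene_ids]
        counts[sp] = CountMatrix(features, cell_ids, mat)
        metadata[sp] = CellMetadata(pd.DataFrame({
            "cell_id": cell_ids,
            "species": sp,
            "cell_type": types,
            "library_id": f"{sp}_lib1",
        }))
    orthologs = pd.DataFrame({sp: [f"{sp}_{g}" for g in gene_ids] for sp in species})
    return ExpressionCohort(counts, metadata, orthologs, leaf_logmu)


# ---------------------------------------------------------------------------
# genomes, peaks and chains
# ---------------------------------------------------------------------------

@dataclass
class GenomeAnnotation:
    """Per-species annotation bundle produced by simulate_genomes_and_peaks."""

    species: str
    chrom: str
    chrom_size: int
    genome: dict[str, str]
    peaks: list[GenomicInterval]
    peak_names: list[str]
    peak_classes: list[str] | None       # None for the reference species
    peak_cell_types: list[str]
    genes: list[GeneModel]
    repeats: list[GenomicInterval]
    ightrs: list[GenomicInterval]
    ightr_classes: list[str] | None
    decoy_gap_zones: list[GenomicInterval]
    decoy_count_zones: list[GenomicInterval]
    background_zones: list[GenomicInterval]
    control_zones: list[GenomicInterval]     # free intergenic space for controls
    chain_to_ref: ChainMap | None


class _Layout:
    """Sequential allocator of non-overlapping intervals on one chromosome."""

    def __init__(self, chrom: str, size: int, start: int = 1000, gap: int = 200):
        self.chrom, self.size, self.cursor, self.gap = chrom, size, start, gap

    def take(self, length: int) -> GenomicInterval:
        iv = GenomicInterval(self.chrom, self.cursor, self.cursor + length)
        self.cursor += length + self.gap
        if self.cursor > self.size:
            raise ValueError(
                f"genome_length {self.size} too small for the requested layout"
            )
        return iv


def _make_gene(gid: str, iv: GenomicInterval, biotype: str, strand: str) -> GeneModel:
    if biotype == "protein_coding":
        exons = (
            GenomicInterval(iv.chrom, iv.start, iv.start + 400, strand),
            GenomicInterval(iv.chrom, iv.end - 400, iv.end, strand),
        )
    else:
        exons = (GenomicInterval(iv.chrom, iv.start, iv.end, strand),)
    tss = iv.start if strand == "+" else iv.end - 1
    span = GenomicInterval(iv.chrom, iv.start, iv.end, strand)
    return GeneModel(gid, gid, biotype, strand, tss, exons, span)


def _flanked_chain(src: GenomicInterval, dst_start: int, s_size: int, t_size: int,
                   chrom: str, chain_id: int, score: float) -> Chain:
    """Chain covering src with 60 bp flanks; the interval itself sits fully
    inside the second block so it lifts completely, and the 20 bp flank gap
    exercises multi-block arithmetic."""
    length = src.length
    s0 = src.start - 60
    blocks = (ChainBlock(40, 20, 20), ChainBlock(length + 60, 0, 0))
    return Chain(
        score=score,
        s_chrom=src.chrom, s_size=s_size, s_strand="+",
        s_start=s0, s_end=src.end + 60,
        t_chrom=chrom, t_size=t_size, t_strand="+",
        t_start=dst_start - 60, t_end=dst_start + length + 60,
        chain_id=chain_id, blocks=blocks,
    )


def simulate_genomes_and_peaks(truth: SimulationTruth, tree: SpeciesTree | None = None,
                               n_peaks: int = 600, genome_length: int = 3_000_000,
                               seed: int | None = None, peak_len: int = 400,
                               n_coding: int = 80, n_ncrna: int = 20,
                               n_repeats: int = 60, n_background_zones: int = 1500,
                               ightr_len: int = 500,
                               ) -> dict[str, GenomeAnnotation]:
    """Build per-species genomes, peak sets, gene/repeat annotation, planted
    igHTR slots and chains to the reference realizing the planted
    conservation fractions exactly.

    Layouts are identical across species up to a per-species coordinate
    offset, so lifting is a genuine (multi-block) coordinate translation.
    """
    if n_peaks < 500:
        raise ValueError("n_peaks must be >= 500")
    tree = tree or SpeciesTree()
    rng = np.random.default_rng(truth.rng_seed if seed is None else seed)
    species = truth.species
    ref = truth.reference
    chrom = "chr1"

    # --- shared layout (reference coordinates) ---
    lay = _Layout(chrom, genome_length)
    peak_slots = [lay.take(peak_len) for _ in range(n_peaks)]
    gene_slots = [lay.take(2200) for _ in range(n_coding)]
    nc_slots = [lay.take(600) for _ in range(n_ncrna)]
    repeat_slots = [lay.take(500) for _ in range(n_repeats)]
    ightr_slots = [lay.take(ightr_len) for _ in range(truth.n_planted_ightrs)]
    decoy_gap_slots = [lay.take(900) for _ in range(truth.n_decoy_gap)]
    decoy_count_slots = [lay.take(500) for _ in range(truth.n_decoy_count)]
    bg_slots = [lay.take(400) for _ in range(n_background_zones)]
    control_slots = [lay.take(2 * ightr_len) for _ in range(60)]
    # empty lift targets (alignable but landing on no reference peak)
    align_counts = {
        sp: exact_counts(
            [truth.peak_class_fractions[sp][c] for c in PEAK_CLASSES], n_peaks
        )
        for sp in species if sp != ref
    }
    max_align = max([c[1] for c in align_counts.values()], default=0)
    empty_peak_targets = [lay.take(peak_len) for _ in range(max_align)]
    ightr_counts = {
        sp: exact_counts(
            [truth.ightr_class_fractions[sp][c] for c in IGHTR_CLASSES],
            truth.n_planted_ightrs,
        )
        for sp in species if sp != ref
    }
    max_ightr_empty = max([c[1] for c in ightr_counts.values()], default=0)
    empty_ightr_targets = [lay.take(ightr_len) for _ in range(max_ightr_empty)]

    offsets = {sp: 137 * i for i, sp in enumerate(species)}

    def shift(iv: GenomicInterval, off: int) -> GenomicInterval:
        return GenomicInterval(iv.chrom, iv.start + off, iv.end + off, iv.strand)

    # --- peak conservation assignment ---
    peak_ct = [CELL_TYPES[i % 3] for i in range(n_peaks)]
    per_species_classes: dict[str, list[str]] = {}
    conserved_order: dict[str, list[int]] = {}
    for sp in species:
        if sp == ref:
            continue
        counts = align_counts[sp]
        labels = np.repeat(PEAK_CLASSES, counts)
        perm = rng.permutation(n_peaks)
        cls = np.empty(n_peaks, dtype=object)
        cls[perm] = labels
        per_species_classes[sp] = list(cls)
        conserved_order[sp] = [i for i in range(n_peaks)
                               if cls[i] == "CONSERVED_ACCESSIBLE"]

    # --- evolved sequences for peaks conserved onto the reference ---
    max_cons = max((len(v) for v in conserved_order.values()), default=0)
    evolved: list[dict[str, np.ndarray]] = []
    for j in range(max_cons):
        ct = peak_ct[j]  # keyed by the reference peak the set maps onto
        root_seq = _random_seq_array(rng, peak_len)
        evolved.append(_evolve_sequence(
            tree.tree, root_seq, truth.rate_multipliers[ct] * truth.substitution_scale,
            rng))

    # --- per-species igHTR classes ---
    ightr_cls: dict[str, list[str]] = {}
    for sp in species:
        if sp == ref:
            continue
        counts = ightr_counts[sp]
        labels = np.repeat(IGHTR_CLASSES, counts)
        perm = rng.permutation(truth.n_planted_ightrs)
        cls = np.empty(truth.n_planted_ightrs, dtype=object)
        cls[perm] = labels
        ightr_cls[sp] = list(cls)

    annotations: dict[str, GenomeAnnotation] = {}
    for sp in species:
        off = offsets[sp]
        size = genome_length + off
        genome_arr = _random_seq_array(rng, size)
        peaks = [shift(iv, off) for iv in peak_slots]
        genes = [
            _make_gene(f"{sp}_pc{i:03d}", shift(iv, off), "protein_coding",
                       "+" if i % 2 == 0 else "-")
            for i, iv in enumerate(gene_slots)
        ] + [
            _make_gene(f"{sp}_nc{i:03d}", shift(iv, off), "lncRNA", "+")
            for i, iv in enumerate(nc_slots)
        ]
        repeats = [shift(iv, off) for iv in repeat_slots]
        ightrs = [shift(iv, off) for iv in ightr_slots]

        chains: list[Chain] = []
        classes = per_species_classes.get(sp)
        if sp != ref:
            cid = 1
            n_chains = len(conserved_order[sp]) + align_counts[sp][1] \
                + ightr_counts[sp][2] + ightr_counts[sp][1]
            score = float(1000 + n_chains)
            # conserved peaks: j-th conserved source peak maps onto ref peak j
            for j, i in enumerate(conserved_order[sp]):
                chains.append(_flanked_chain(peaks[i], peak_slots[j].start,
                                             size, genome_length, chrom, cid, score))
                cid += 1
                score -= 1.0
            # alignable-not-accessible: map onto empty target zones
            k = 0
            for i in range(n_peaks):
                if classes[i] == "ALIGNABLE_NOT_ACCESSIBLE":
                    chains.append(_flanked_chain(
                        peaks[i], empty_peak_targets[k].start, size,
                        genome_length, chrom, cid, score))
                    k += 1
                    cid += 1
                    score -= 1.0
            # igHTR conservation chains
            jc = je = 0
            for i, cls in enumerate(ightr_cls[sp]):
                if cls == "CONSERVED":
                    chains.append(_flanked_chain(ightrs[i], ightr_slots[jc].start,
                                                 size, genome_length, chrom, cid, score))
                    jc += 1
                elif cls == "CONSERVED_NOT_IGHTR":
                    chains.append(_flanked_chain(
                        ightrs[i], empty_ightr_targets[je].start, size,
                        genome_length, chrom, cid, score))
                    je += 1
                else:
                    continue
                cid += 1
                score -= 1.0

        # write evolved sequences at the relevant peak coordinates
        if sp == ref:
            for j in range(max_cons):
                s = peak_slots[j].start + off
                genome_arr[s:s + peak_len] = evolved[j][sp]
        else:
            for j, i in enumerate(conserved_order[sp]):
                s = peak_slots[i].start + off
                genome_arr[s:s + peak_len] = evolved[j][sp]

        annotations[sp] = GenomeAnnotation(
            species=sp,
            chrom=chrom,
            chrom_size=size,
            genome={chrom: _arr_to_str(genome_arr)},
            peaks=peaks,
            peak_names=[f"{sp}_peak{i:05d}" for i in range(n_peaks)],
            peak_classes=classes,
            peak_cell_types=list(peak_ct),
            genes=genes,
            repeats=repeats,
            ightrs=ightrs,
            ightr_classes=ightr_cls.get(sp),
            decoy_gap_zones=[shift(iv, off) for iv in decoy_gap_slots],
            decoy_count_zones=[shift(iv, off) for iv in decoy_count_slots],
            background_zones=[shift(iv, off) for iv in bg_slots],
            control_zones=[shift(iv, off) for iv in control_slots],
            chain_to_ref=ChainMap(chains) if sp != ref else None,
        )
        truth.ightr_intervals[sp] = [(iv.chrom, iv.start, iv.end) for iv in ightrs]
    return annotations


# ---------------------------------------------------------------------------
# reads and fragments
# ---------------------------------------------------------------------------

READ_LEN = 100


@dataclass
class ReadSimResult:
    reads: dict[str, pd.DataFrame]
    fragments: dict[str, pd.DataFrame]
    n_duplicates: dict[str, int]
    category_counts: dict[str, dict[str, int]]


def _cluster_starts(s: int, e: int, k: int) -> np.ndarray:
    """k read starts spanning [s, e) exactly, all neighbour gaps < 150 bp."""
    return np.round(np.linspace(s, e - READ_LEN, k)).astype(int)


def simulate_reads_and_fragments(truth: SimulationTruth,
                                 annotations: dict[str, GenomeAnnotation],
                                 n_reads: int = 50_000,
                                 n_background_fragments: int = 30_000,
                                 seed: int | None = None) -> ReadSimResult:
    """Place reads by genomic category with the planted proportions; planted
    igHTR clusters satisfy the two-parameter rule, decoy clusters violate
    exactly one of its clauses, and a planted fraction of rows are duplicate
    copies carrying SAM flag bit 1024. Tn5-like fragments are elevated over
    igHTRs relative to the uniform background."""
    rng = np.random.default_rng(truth.rng_seed if seed is None else seed)
    reads_out, frags_out, dup_out, cat_out = {}, {}, {}, {}
    for sp, ann in annotations.items():
        for iv in ann.ightrs:
            for g in ann.genes:
                if iv.overlaps(g.span):
                    raise ValueError(
                        f"planted igHTR {iv} overlaps gene {g.gene_id}")
        n_dup = int(round(truth.duplicate_fraction * n_reads))
        n_unique = n_reads - n_dup
        cats = list(truth.read_category_props)
        counts = dict(zip(cats, exact_counts(
            [truth.read_category_props[c] for c in cats], n_unique)))

        starts: list[int] = []
        coding = [g for g in ann.genes if g.is_coding]
        ncrna = [g for g in ann.genes if not g.is_coding]

        def midpoint_reads(n: int, pick_interval) -> None:
            for _ in range(n):
                iv = pick_interval()
                m = int(rng.integers(iv.start, iv.end))
                starts.append(max(0, m - READ_LEN // 2))

        midpoint_reads(counts["exon"], lambda: (
            lambda g: g.exons[int(rng.integers(0, len(g.exons)))]
        )(coding[int(rng.integers(0, len(coding)))]))
        midpoint_reads(counts["intron"], lambda: (
            lambda g: GenomicInterval(g.span.chrom, g.exons[0].end,
                                      g.exons[-1].start)
        )(coding[int(rng.integers(0, len(coding)))]))
        midpoint_reads(counts["ncRNA"], lambda: ncrna[
            int(rng.integers(0, len(ncrna)))].exons[0])
        midpoint_reads(counts["repeat"], lambda: ann.repeats[
            int(rng.integers(0, len(ann.repeats)))])

        # intergenic-without-repeat: planted igHTR clusters, decoys, background
        n_intergenic = counts["intergenic"]
        planted_sizes = rng.integers(12, 19, size=len(ann.ightrs))
        used = 0
        for iv, k in zip(ann.ightrs, planted_sizes):
            starts.extend(_cluster_starts(iv.start, iv.end, int(k)).tolist())
            used += int(k)
        for zone in ann.decoy_gap_zones:
            # two 6-read sub-clusters separated by exactly a 150 bp gap
            s = zone.start
            starts.extend(_cluster_starts(s, s + 250, 6).tolist())
            starts.extend(_cluster_starts(s + 400, s + 650, 6).tolist())
            used += 12
        for zone in ann.decoy_count_zones:
            starts.extend(_cluster_starts(zone.start, zone.end, 10).tolist())
            used += 10
        n_bg = n_intergenic - used
        if n_bg < 0:
            raise ValueError("intergenic read budget below planted cluster needs")
        capacity = 5 * len(ann.background_zones)
        if n_bg > capacity:
            raise ValueError(
                f"background zones can host {capacity} reads, need {n_bg}")
        zone_offsets = (0, 60, 120, 180, 240)
        for i in range(n_bg):
            zone = ann.background_zones[i % len(ann.background_zones)]
            starts.append(zone.start + zone_offsets[i // len(ann.background_zones)])

        arr = np.asarray(starts, dtype=int)
        flags = np.zeros(arr.size, dtype=int)
        # duplicate copies of randomly chosen unique reads, flag bit 0x400 set
        dup_src = rng.integers(0, arr.size, size=n_dup)
        arr = np.concatenate([arr, arr[dup_src]])
        flags = np.concatenate([flags, np.full(n_dup, 1024, dtype=int)])
        order = np.argsort(arr, kind="stable")
        barcodes = np.array(
            [f"{sp}_c{i % 200:05d}" for i in range(arr.size)], dtype=object)
        reads = pd.DataFrame({
            "chrom": ann.chrom,
            "start": arr[order],
            "end": arr[order] + READ_LEN,
            "flag": flags[order],
            "barcode": barcodes[order],
        })

        # fragments: uniform background + extra coverage over igHTRs
        frag_len = 200
        lam = n_background_fragments / ann.chrom_size
        fs = rng.integers(0, ann.chrom_size - frag_len,
                          size=n_background_fragments)
        extra = []
        for iv in ann.ightrs:
            n_extra = rng.poisson((truth.accessibility_fold - 1.0)
                                  * lam * iv.length)
            if n_extra:
                extra.append(rng.integers(iv.start, max(iv.start + 1,
                                                        iv.end - frag_len),
                                          size=n_extra))
        fs = np.concatenate([fs] + extra) if extra else fs
        fs.sort(kind="stable")
        frags = pd.DataFrame({
            "chrom": ann.chrom,
            "start": fs,
            "end": fs + frag_len,
            "barcode": [f"{sp}_c{i % 200:05d}" for i in range(fs.size)],
        })
        reads_out[sp] = reads
        frags_out[sp] = frags
        dup_out[sp] = n_dup
        cat_out[sp] = counts
    return ReadSimResult(reads_out, frags_out, dup_out, cat_out)


# ---------------------------------------------------------------------------
# peak accessibility pseudo-bulks (for the conserved-peak PCA)
# ---------------------------------------------------------------------------

def simulate_peak_accessibility(truth: SimulationTruth, peak_ids: Sequence[str],
                                seed: int | None = None, tc_shift: float = 2.0,
                                sc_shift: float = 1.3, depth: float = 10.0
                                ) -> pd.DataFrame:
    """Accessibility pseudo-bulk counts (peaks x species|cell_type groups).

    Species identity is a one-dimensional gradient along a shared peak
    direction (so it dominates PC1), while theca cells carry a stronger
    accessibility shift than stromal cells along a second direction (so
    cell types separate on PC2, TC farthest from GC).
    """
    rng = np.random.default_rng(truth.rng_seed if seed is None else seed)
    n = len(peak_ids)
    base = np.exp(rng.normal(2.0, 0.4, n))
    species_dir = rng.normal(0.0, 0.35, n)
    ct_mask = np.zeros(n)
    ct_mask[rng.choice(n, size=max(1, n // 3), replace=False)] = 1.0
    cols = {}
    for i, sp in enumerate(truth.species):
        delta = 0.5 * i  # divergence gradient from the reference
        for ct in CELL_TYPES:
            mult = {"GC": 1.0, "SC": sc_shift, "TC": tc_shift}[ct]
            lam = base * np.exp(delta * species_dir) \
                * np.exp(np.log(mult) * ct_mask)
            cols[f"{sp}|{ct}"] = rng.poisson(lam * depth)
    return pd.DataFrame(cols, index=list(peak_ids))


# ---------------------------------------------------------------------------
# promoter-linked cCRE cohort
# ---------------------------------------------------------------------------

@dataclass
class LinkCohort:
    peaks: list[GenomicInterval]
    peak_names: list[str]
    genes: list[GeneModel]
    accessibility: CountMatrix          # peaks x cells
    expression: CountMatrix             # genes x cells
    metadata: CellMetadata
    planted_pairs: list[tuple[str, str]]   # (gene_id, peak_name)


def simulate_link_cohort(truth: SimulationTruth, n_genes: int = 60,
                         n_distal: int = 3, n_cells: int = 600,
                         n_planted: int = 8, seed: int | None = None,
                         species: str | None = None) -> LinkCohort:
    """Single-species theca-cell multiome stand-in: each gene has a promoter
    peak and n_distal distal peaks within 100 kb; for planted (gene, distal)
    pairs accessibility shares the gene's latent activity (metacell-level
    Pearson r ~ 0.9), all other distal peaks are co-accessible with the
    promoter but independent of expression."""
    rng = np.random.default_rng(truth.rng_seed if seed is None else seed)
    sp = species or truth.reference
    chrom = "chr1"
    spacing = 50_000
    peaks, peak_names, genes = [], [], []
    for g in range(n_genes):
        tss = 25_000 + g * spacing
        span = GenomicInterval(chrom, tss, tss + 2_000, "+")
        exons = (GenomicInterval(chrom, tss, tss + 2_000, "+"),)
        genes.append(GeneModel(f"{sp}_lg{g:04d}", f"{sp}_lg{g:04d}",
                               "protein_coding", "+", tss, exons, span))
        peaks.append(GenomicInterval(chrom, tss - 200, tss + 200))
        peak_names.append(f"{sp}_prom{g:04d}")
        for j in range(n_distal):
            s = tss + 8_000 + 4_000 * j
            peaks.append(GenomicInterval(chrom, s, s + 400))
            peak_names.append(f"{sp}_dist{g:04d}_{j}")

    planted = []
    chosen = rng.choice(n_genes, size=n_planted, replace=False)
    planted_distal = {int(g): int(rng.integers(0, n_distal)) for g in chosen}
    for g, j in sorted(planted_distal.items()):
        planted.append((f"{sp}_lg{g:04d}", f"{sp}_dist{g:04d}_{j}"))
    truth.planted_links = list(planted)

    expr = np.zeros((n_genes, n_cells), dtype=int)
    acc = np.zeros((len(peaks), n_cells), dtype=int)
    for g in range(n_genes):
        z = rng.gamma(2.0, 1.0, n_cells)       # expression-driving activity
        u = rng.gamma(2.0, 1.0, n_cells)       # accessibility-only activity
        expr[g] = rng.poisson(20.0 * z)
        prom_row = g * (n_distal + 1)
        acc[prom_row] = rng.poisson(8.0 * (z + u))
        for j in range(n_distal):
            row = prom_row + 1 + j
            if planted_distal.get(g) == j:
                acc[row] = rng.poisson(12.0 * z)
            else:
                v = rng.gamma(2.0, 1.0, n_cells)
                acc[row] = rng.poisson(8.0 * (u + v))

    cell_ids = [f"{sp}_link_c{i:05d}" for i in range(n_cells)]
    meta = CellMetadata(pd.DataFrame({
        "cell_id": cell_ids, "species": sp,
        "cell_type": "TC", "library_id": f"{sp}_multiome",
    }))
    return LinkCohort(
        peaks, peak_names, genes,
        CountMatrix(peak_names, cell_ids, acc),
        CountMatrix([g.gene_id for g in genes], cell_ids, expr),
        meta, planted,
    )


# ---------------------------------------------------------------------------
# patterned expression cohort (NMF ground truth)
# ---------------------------------------------------------------------------

@dataclass
class PatternCohort:
    counts: dict[str, CountMatrix]
    metadata: dict[str, CellMetadata]
    amplitude: np.ndarray               # genes x k, planted
    pattern_names: list[str]
    specific_pattern: str               # reference-species-specific pattern
    specific_cell_type: str


def simulate_patterned_expression(truth: SimulationTruth, n_genes: int = 400,
                                  cells_per_type: int = 100,
                                  seed: int | None = None) -> PatternCohort:
    """Expression generated from 5 planted non-negative patterns: one program
    per cell type, one housekeeping program, and one theca program active
    only in the reference species (the species-specific pattern of the
    projection analysis)."""
    rng = np.random.default_rng(truth.rng_seed if seed is None else seed)
    k = 5
    block = 60
    names = ["GC_program", "SC_program", "TC_program", "housekeeping",
             f"{truth.reference}_TC_specific"]
    A = np.zeros((n_genes, k))
    for p in range(k):
        A[p * block:(p + 1) * block, p] = rng.uniform(2.0, 4.0, block)
    # ambient expression restricted to non-program tail genes, so pattern
    # blocks stay exclusive to their programs
    baseline = np.zeros((n_genes, 1))
    baseline[k * block:] = 0.5
    truth.pattern_gene_blocks = {
        names[p]: [p * block, (p + 1) * block] for p in range(k)}

    counts, metadata = {}, {}
    for sp in truth.species:
        n_cells = cells_per_type * len(CELL_TYPES)
        W = np.zeros((k, n_cells))
        types = []
        for t, ct in enumerate(CELL_TYPES):
            cols = slice(t * cells_per_type, (t + 1) * cells_per_type)
            W[t, cols] = rng.gamma(4.0, 0.5, cells_per_type)
            W[3, cols] = rng.gamma(4.0, 0.25, cells_per_type)
            if sp == truth.reference and ct == "TC":
                W[4, cols] = rng.gamma(4.0, 0.5, cells_per_type)
            types.extend([ct] * cells_per_type)
        X = rng.poisson(A @ W + baseline)
        cell_ids = [f"{sp}_p{i:05d}" for i in range(n_cells)]
        counts[sp] = CountMatrix([f"pg{i:05d}" for i in range(n_genes)],
                                 cell_ids, X)
        metadata[sp] = CellMetadata(pd.DataFrame({
            "cell_id": cell_ids, "species": sp, "cell_type": types,
            "library_id": f"{sp}_lib1",
        }))
    return PatternCohort(counts, metadata, A, names, names[4], "TC")


# ---------------------------------------------------------------------------
# motif cohort
# ---------------------------------------------------------------------------

@dataclass
class MotifCohort:
    foreground: dict[str, str]
    background: dict[str, str]
    meme_text: str
    planted_motif: str
    fg_with_site: int
    bg_with_site: int


def _pwm_from_consensus(consensus: str, major: float = 0.85) -> np.ndarray:
    minor = (1.0 - major) / 3.0
    pwm = np.full((len(consensus), 4), minor)
    for i, b in enumerate(consensus):
        pwm[i, "ACGT".index(b)] = major
    return pwm


def _meme_block(name: str, pwm: np.ndarray) -> str:
    lines = [f"MOTIF {name} {name}",
             f"letter-probability matrix: alength= 4 w= {pwm.shape[0]} "
             f"nsites= 20 E= 0"]
    for row in pwm:
        lines.append(" ".join(f"{v:.6f}" for v in row))
    return "\n".join(lines) + "\n"


def write_meme(motifs: dict[str, np.ndarray]) -> str:
    head = ("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n"
            "Background letter frequencies\nA 0.25 C 0.25 G 0.25 T 0.25\n\n")
    return head + "\n".join(_meme_block(n, p) for n, p in motifs.items())


def simulate_motif_cohort(truth: SimulationTruth, n_fg: int = 150,
                          n_bg: int = 150, seq_len: int = 300,
                          seed: int | None = None) -> MotifCohort:
    """Foreground sequences carry a planted consensus at motif_fg_rate,
    background at motif_bg_rate (5x lower by default); decoy PWMs are
    never embedded."""
    rng = np.random.default_rng(truth.rng_seed if seed is None else seed)
    consensus = "TGACGTCA"
    decoys = ["CCAATGGA", "GATAAGCG", "TTGCCAAC", "AGGTCAAG"]
    motifs = {"PLANTED": _pwm_from_consensus(consensus)}
    for i, d in enumerate(decoys):
        motifs[f"DECOY{i + 1}"] = _pwm_from_consensus(d)

    def make(n: int, rate: float, prefix: str) -> tuple[dict[str, str], int]:
        seqs, n_site = {}, 0
        for i in range(n):
            arr = _random_seq_array(rng, seq_len)
            if rng.random() < rate:
                pos = int(rng.integers(0, seq_len - len(consensus)))
                arr[pos:pos + len(consensus)] = np.frombuffer(
                    consensus.encode(), dtype=np.uint8)
                n_site += 1
            seqs[f"{prefix}{i:04d}"] = _arr_to_str(arr)
        return seqs, n_site

    fg, fg_n = make(n_fg, truth.motif_fg_rate, "fg")
    bg, bg_n = make(n_bg, truth.motif_bg_rate, "bg")
    return MotifCohort(fg, bg, write_meme(motifs), "PLANTED", fg_n, bg_n)


# ---------------------------------------------------------------------------
# TF filter cohort
# ---------------------------------------------------------------------------

@dataclass
class TFFilterCohort:
    enriched: dict[str, set[str]]
    expression: dict[str, CountMatrix]
    metadata: dict[str, CellMetadata]
    tf_to_gene: dict[str, str]
    expected_shared: set[str]
    expected_expressed: set[str]
    expected_conserved: set[str]


def simulate_tf_filter_cohort(truth: SimulationTruth, n_shared: int = 22,
                              n_expressed: int = 12, n_conserved: int = 7,
                              cells_per_species: int = 100,
                              seed: int | None = None) -> TFFilterCohort:
    """Per-species enriched TF sets sharing a planted core, with nested
    planted expressed / conserved subsets in the reference cell type."""
    rng = np.random.default_rng(truth.rng_seed if seed is None else seed)
    shared = [f"TF{i:03d}" for i in range(n_shared)]
    expressed = shared[:n_expressed]
    conserved = shared[:n_conserved]
    enriched = {}
    for i, sp in enumerate(truth.species):
        extras = {f"TF{100 + 10 * i + j:03d}" for j in range(5)}
        enriched[sp] = set(shared) | extras

    filler = [f"filler{i:03d}" for i in range(50)]
    expr, meta = {}, {}
    for sp in truth.species:
        genes = shared + filler
        mat = np.zeros((len(genes), cells_per_species), dtype=int)
        for r, tf in enumerate(shared):
            on = tf in conserved or (sp == truth.reference and tf in expressed)
            lam = 5.0 if on else 0.01
            mat[r] = rng.poisson(lam, cells_per_species)
        mat[len(shared):] = rng.poisson(40.0, (len(filler), cells_per_species))
        cell_ids = [f"{sp}_tf_c{i:04d}" for i in range(cells_per_species)]
        expr[sp] = CountMatrix(genes, cell_ids, mat)
        meta[sp] = CellMetadata(pd.DataFrame({
            "cell_id": cell_ids, "species": sp, "cell_type": "TC",
            "library_id": f"{sp}_lib1",
        }))
    return TFFilterCohort(enriched, expr, meta, {tf: tf for tf in shared},
                          set(shared), set(expressed), set(conserved))
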