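"""Pseudo-bulk expression phylogenetics and the branch-length divergence test.

Pseudo-bulk profiles (per species, or per species x cell type) are built
over 1:1 orthologues, converted to Spearman correlation distances, and
summarized as neighbor-joining trees with gene-resampling bootstrap. The
divergence test compares total tree branch length distributions (over
bootstrap replicates) between cell types with a two-sided Wilcoxon
rank-sum test; a longer tree means more expression change along the
phylogeny. The same machinery serves conserved-peak sequence trees via
concatenated p-distances.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats
from skbio import DistanceMatrix as SkbioDM
from skbio.tree import nj

from .core_io import CellMetadata, CountMatrix


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape does not match labels")
        if np.isnan(v).any():
            raise ValueError("NaN in distance matrix")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix not symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("nonzero diagonal")
        if (v < -1e-12).any():
            raise ValueError("negative distances")
        self.values = v


@dataclass
class PhyloTree:
    """Unrooted NJ tree with optional per-split bootstrap supports."""

    tree: "object"              # skbio TreeNode
    labels: list[str]
    supports: dict[frozenset, float] = field(default_factory=dict)
    replicate_totals: np.ndarray | None = None

    @property
    def total_length(self) -> float:
        return float(sum(n.length or 0.0 for n in self.tree.traverse()
                         if not n.is_root()))

    def splits(self) -> set[frozenset]:
        return _splits(self.tree, self.labels)

    def tip_distance(self, a: str, b: str) -> float:
        return float(self.tree.find(a).distance(self.tree.find(b)))

    def to_newick(self) -> str:
        t = self.tree.copy()
        for node in t.non_tips():
            clade = frozenset(x.name for x in node.tips())
            key = _canonical_split(clade, self.labels)
            if key in self.supports:
                node.name = f"{self.supports[key]:.0f}"
        return str(t)


@dataclass
class BranchLengthReport:
    lengths: dict[str, np.ndarray]          # cell type -> totals per replicate
    p_values: dict[tuple[str, str], float]
    stars: dict[tuple[str, str], str]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"group_a": a, "group_b": b, "p_value": p,
             "significance": self.stars[(a, b)]}
            for (a, b), p in sorted(self.p_values.items())
        ]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# pseudo-bulk
# ---------------------------------------------------------------------------

def combine_cohort(counts: dict[str, CountMatrix],
                   metadata: dict[str, CellMetadata]
                   ) -> tuple[CountMatrix, CellMetadata]:
    """Stack per-species matrices into one block-diagonal multi-species matrix."""
    species = list(counts)
    mats = [sp.coo_matrix(counts[s].counts) for s in species]
    combined = sp.block_diag(mats, format="csr")
    features = [f for s in species for f in counts[s].feature_ids]
    cells = [c for s in species for c in counts[s].cell_ids]
    meta = CellMetadata(pd.concat([metadata[s].table for s in species],
                                  ignore_index=True))
    return CountMatrix(features, cells, combined), meta


def aggregate_pseudobulk(counts: CountMatrix, meta: CellMetadata,
                         orthologs: pd.DataFrame,
                         group_by: Sequence[str] = ("species",),
                         reference: str | None = None) -> pd.DataFrame:
    """Per-group gene sums -> CPM -> log1p over 1:1 orthologues.

    Rows are reference-species orthologue identifiers, columns are groups
    (``species`` or ``species|cell_type``), in sorted order. Genes absent
    from the orthologue table are dropped.
    """
    if len(orthologs) < 100:
        raise ValueError("orthologue table must cover >= 100 genes")
    for col in group_by:
        if col not in ("species", "cell_type"):
            raise ValueError(f"unsupported grouping column {col!r}")
    meta = meta.aligned_to(counts)
    ref = reference or orthologs.columns[0]
    dense = counts.dense().astype(float)
    feat_index = {f: i for i, f in enumerate(counts.feature_ids)}

    tab = meta.table
    keys = tab[list(group_by)].apply(tuple, axis=1)
    groups = sorted(set(keys))
    columns: dict[str, np.ndarray] = {}
    kept: list[pd.Index] = []
    per_group_rows: dict[str, tuple[np.ndarray, pd.Index]] = {}
    for key in groups:
        species_name = key[0]
        if species_name not in orthologs.columns:
            raise ValueError(f"species {species_name!r} absent from orthologue table")
        cells = np.nonzero((keys == key).to_numpy())[0]
        if cells.size == 0:
            raise ValueError(f"empty group {key}")
        present = orthologs[orthologs[species_name].isin(feat_index)]
        rows = np.array([feat_index[f] for f in present[species_name]])
        label = "|".join(key)
        per_group_rows[label] = (rows, pd.Index(present[ref]))
        sums = dense[np.ix_(rows, cells)].sum(axis=1)
        columns[label] = sums
        kept.append(pd.Index(present[ref]))

    common = kept[0]
    for idx in kept[1:]:
        common = common.intersection(idx)
    out = {}
    for label, sums in columns.items():
        _, ref_ids = per_group_rows[label]
        series = pd.Series(sums, index=ref_ids).loc[common]
        total = series.sum()
        if total <= 0:
            raise ValueError(f"empty group {label}: zero total counts")
        out[label] = np.log1p(series.to_numpy() / total * 1e6)
    return pd.DataFrame(out, index=common)


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def expression_distance(pb: pd.DataFrame) -> DistanceMatrix:
    """1 - Spearman correlation between pseudo-bulk columns."""
    if pb.shape[1] < 3:
        raise ValueError("need >= 3 pseudo-bulk columns")
    mat = pb.to_numpy()
    if (mat.std(axis=0) == 0).any():
        bad = [c for c, s in zip(pb.columns, mat.std(axis=0)) if s == 0]
        raise ValueError(f"constant pseudo-bulk column(s): {bad}")
    ranks = np.apply_along_axis(scipy.stats.rankdata, 0, mat)
    rho = np.corrcoef(ranks, rowvar=False)
    d = 1.0 - rho
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    return DistanceMatrix(list(pb.columns), d)


_GAP_CHARS = frozenset("-N")


def sequence_distance(seqs: dict[str, str], jukes_cantor: bool = False
                      ) -> DistanceMatrix:
    """Concatenated p-distance between aligned per-species sequences.

    Columns where either sequence is a gap/N are excluded pairwise; with
    ``jukes_cantor`` the p-distance is transformed to a JC69 distance.
    """
    labels = sorted(seqs)
    lengths = {len(seqs[s]) for s in labels}
    if len(lengths) != 1:
        raise ValueError("aligned sequences must have equal length")
    arrs = {s: np.frombuffer(seqs[s].encode(), dtype=np.uint8) for s in labels}
    gap = np.frombuffer("-N".encode(), dtype=np.uint8)
    is_gap = {s: np.isin(arrs[s], gap) for s in labels}
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~(is_gap[labels[i]] | is_gap[labels[j]])
            if not ok.any():
                raise ValueError(
                    f"no comparable columns between {labels[i]} and {labels[j]}")
            p = float(np.mean(arrs[labels[i]][ok] != arrs[labels[j]][ok]))
            if jukes_cantor:
                if p >= 0.75:
                    raise ValueError("p-distance saturates the JC69 transform")
                p = -0.75 * np.log1p(-4.0 * p / 3.0)
            d[i, j] = d[j, i] = p
    return DistanceMatrix(labels, d)


# ---------------------------------------------------------------------------
# neighbor joining + bootstrap
# ---------------------------------------------------------------------------

def _canonical_split(clade: frozenset, labels: Sequence[str]) -> frozenset:
    """Represent a bipartition by the side not containing the first label."""
    return clade if labels[0] not in clade else frozenset(labels) - clade


def _splits(tree, labels: Sequence[str]) -> set[frozenset]:
    n = len(labels)
    out = set()
    for node in tree.non_tips(include_self=False):
        clade = frozenset(t.name for t in node.tips())
        if 1 < len(clade) < n - 1:
            out.add(_canonical_split(clade, labels))
    return out


def nj_tree(dist: DistanceMatrix) -> PhyloTree:
    """Standard neighbor joining (negative branch estimates clamped to 0)."""
    tree = nj(SkbioDM(dist.values, ids=dist.labels), neg_as_zero=True)
    return PhyloTree(tree, list(dist.labels))


def build_nj_tree(dist: DistanceMatrix,
                  resampler: Callable[[np.random.Generator], DistanceMatrix]
                  | None = None,
                  n_boot: int = 0, seed: int = 0) -> PhyloTree:
    """NJ tree with optional bootstrap supports.

    ``resampler`` draws one replicate distance matrix (resampled genes or
    alignment columns); per-split support is the bipartition frequency over
    replicates x 100. Replicate total branch lengths are retained for the
    divergence test.
    """
    base = nj_tree(dist)
    if resampler is None or n_boot <= 0:
        return base
    rng = np.random.default_rng(seed)
    ref_splits = base.splits()
    hits = {s: 0 for s in ref_splits}
    totals = np.empty(n_boot)
    for b in range(n_boot):
        rep = nj_tree(resampler(rng))
        totals[b] = rep.total_length
        for s in rep.splits():
            if s in hits:
                hits[s] += 1
    base.supports = {s: 100.0 * h / n_boot for s, h in hits.items()}
    base.replicate_totals = totals
    return base


def expression_resampler(pb: pd.DataFrame) -> Callable:
    mat = pb.to_numpy()
    labels = list(pb.columns)
    n = mat.shape[0]

    def draw(rng: np.random.Generator) -> DistanceMatrix:
        idx = rng.integers(0, n, n)
        return expression_distance(pd.DataFrame(mat[idx], columns=labels))

    return draw


def sequence_resampler(seqs: dict[str, str]) -> Callable:
    labels = sorted(seqs)
    arrs = np.vstack([np.frombuffer(seqs[s].encode(), dtype=np.uint8)
                      for s in labels])
    L = arrs.shape[1]

    def draw(rng: np.random.Generator) -> DistanceMatrix:
        idx = rng.integers(0, L, L)
        sub = arrs[:, idx]
        return sequence_distance(
            {s: sub[i].tobytes().decode() for i, s in enumerate(labels)})

    return draw


# ---------------------------------------------------------------------------
# branch-length divergence test
# ---------------------------------------------------------------------------

def wilcoxon_rank_sum(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided rank-sum p; exact when both n <= 20 and tie-free, else
    normal approximation with tie correction."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    ties = len(np.unique(np.concatenate([x, y]))) < x.size + y.size
    method = "exact" if (x.size <= 20 and y.size <= 20 and not ties) else "asymptotic"
    return float(scipy.stats.mannwhitneyu(x, y, alternative="two-sided",
                                          method=method).pvalue)


def significance_stars(p: float) -> str:
    if p <= 1e-4:
        return "****"
    if p <= 1e-3:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "n.s."


def branch_length_test(lengths: dict[str, np.ndarray]) -> BranchLengthReport:
    sizes = {len(v) for v in lengths.values()}
    if len(sizes) != 1:
        raise ValueError("bootstrap replicate counts differ between cell types")
    (b,) = sizes
    if b < 50:
        raise ValueError("need >= 50 bootstrap replicates")
    groups = sorted(lengths)
    p_values, stars = {}, {}
    for i, a in enumerate(groups):
        for c in groups[i + 1:]:
            p = wilcoxon_rank_sum(lengths[a], lengths[c])
            p_values[(a, c)] = p
            stars[(a, c)] = significance_stars(p)
    return BranchLengthReport({g: np.asarray(lengths[g]) for g in groups},
                              p_values, stars)


def celltype_branch_lengths(counts: CountMatrix, meta: CellMetadata,
                            orthologs: pd.DataFrame, n_boot: int = 100,
                            seed: int = 0, reference: str | None = None
                            ) -> tuple[dict[str, np.ndarray], dict[str, PhyloTree]]:
    """Per-cell-type bootstrap distributions of total expression-tree length.

    Builds species x cell-type pseudo-bulks once, then per cell type runs
    the gene-resampling NJ bootstrap over the species columns of that type.
    """
    pb = aggregate_pseudobulk(counts, meta, orthologs,
                              group_by=("species", "cell_type"),
                              reference=reference)
    cell_types = sorted({c.split("|")[1] for c in pb.columns})
    totals: dict[str, np.ndarray] = {}
    trees: dict[str, PhyloTree] = {}
    for k, ct in enumerate(cell_types):
        cols = [c for c in pb.columns if c.endswith(f"|{ct}")]
        sub = pb[cols].rename(columns=lambda c: c.split("|")[0])
        tree = build_nj_tree(expression_distance(sub),
                             expression_resampler(sub), n_boot=n_boot,
                             seed=seed + k)
        totals[ct] = tree.replicate_totals
        trees[ct] = tree
    return totals, trees
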