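"""Motif enrichment, over-representation analysis, rank-sum DE and TF filters.

The motif stage is a calibrated log-odds PWM scan: per motif, the hit
threshold is set so a background-random window passes with a chosen
per-position probability (exact dynamic programming over the discrete
score distribution), and enrichment of foreground over background
sequence sets is a one-sided Fisher exact test. Gene-set
over-representation is a hypergeometric tail; differential expression is
a per-gene two-sided Wilcoxon rank-sum with Benjamini-Hochberg control;
TF conservation filtering applies the nested enriched -> expressed ->
conserved rule.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
from Bio import motifs as bio_motifs
from Bio.Seq import Seq
from statsmodels.stats.multitest import multipletests

from .core_io import CellMetadata, CountMatrix
from .patterns import lognormalize
from .phylo_divergence import wilcoxon_rank_sum

logger = logging.getLogger(__name__)

UNIFORM_BG = {"A": 0.25, "C": 0.25, "G": 0.25, "T": 0.25}


# ---------------------------------------------------------------------------
# PWM scanning
# ---------------------------------------------------------------------------

def read_meme_motifs(source: str) -> list:
    """Parse MEME minimal format from a path or literal text."""
    text = source
    if "\n" not in source:
        text = open(source).read()
    return bio_motifs.parse(io.StringIO(text), "minimal")


def scan_motifs(sequences: Mapping[str, str], motif_list: Sequence,
                background: Mapping[str, float] | None = None,
                per_position_p: float = 1e-4,
                return_counts: bool = False) -> pd.DataFrame:
    """Log-odds scan of both strands; a sequence 'hits' a motif when any
    window scores above the threshold calibrated to the given per-position
    false-positive probability under the background model (exact dynamic
    programming over the discretized score distribution).

    Returns a boolean DataFrame (sequences x motifs), or window hit counts
    with ``return_counts``. Sequences shorter than a motif are skipped for
    it (logged).
    """
    bg = dict(background or UNIFORM_BG)
    seq_ids = list(sequences)
    fill = 0 if return_counts else False
    hits = pd.DataFrame(fill, index=seq_ids,
                        columns=[m.name for m in motif_list])
    for motif in motif_list:
        pwm = motif.counts.normalize(pseudocounts=0.01)
        pssm = pwm.log_odds(bg)
        threshold = pssm.distribution(background=bg, precision=10 ** 3
                                      ).threshold_fpr(per_position_p)
        rpssm = pssm.reverse_complement()
        for sid in seq_ids:
            seq = sequences[sid]
            if len(seq) < motif.length:
                logger.info("sequence %s shorter than motif %s; skipped",
                            sid, motif.name)
                continue
            fwd = pssm.calculate(Seq(seq))
            rev = rpssm.calculate(Seq(seq))
            scores = np.concatenate([np.atleast_1d(fwd), np.atleast_1d(rev)])
            if return_counts:
                hits.loc[sid, motif.name] = int((scores > threshold).sum())
            else:
                hits.loc[sid, motif.name] = bool(np.nanmax(scores) > threshold)
    return hits


def motif_hit_offsets(sequence: str, motif, background=None,
                      per_position_p: float = 1e-4) -> list[int]:
    """Forward-strand window offsets scoring above the calibrated threshold."""
    bg = dict(background or UNIFORM_BG)
    pwm = motif.counts.normalize(pseudocounts=0.01)
    pssm = pwm.log_odds(bg)
    threshold = pssm.distribution(background=bg, precision=10 ** 3
                                  ).threshold_fpr(per_position_p)
    scores = np.atleast_1d(pssm.calculate(Seq(sequence)))
    return [int(i) for i in np.nonzero(scores > threshold)[0]]


@dataclass
class MotifEnrichmentResult:
    motif_id: str
    tf_name: str
    fg_hits: int
    fg_total: int
    bg_hits: int
    bg_total: int
    odds_ratio: float
    p_value: float
    enriched: bool

    def __post_init__(self) -> None:
        if self.fg_hits > self.fg_total or self.bg_hits > self.bg_total:
            raise ValueError("hit counts exceed totals")
        if not 0 < self.p_value <= 1:
            raise ValueError("p-value out of (0, 1]")


def motif_enrichment(fg_hits: pd.DataFrame, bg_hits: pd.DataFrame,
                     p_max: float = 0.05,
                     tf_names: Mapping[str, str] | None = None
                     ) -> list[MotifEnrichmentResult]:
    """One-sided Fisher exact test per motif on sequences-with-hit counts;
    a motif is enriched iff its raw p-value is below ``p_max``."""
    if fg_hits.empty:
        raise ValueError("empty foreground")
    shared = set(fg_hits.index) & set(bg_hits.index)
    if shared:
        raise ValueError("foreground and background sets must be disjoint")
    out = []
    for motif in fg_hits.columns:
        a = int(fg_hits[motif].sum())
        b = int(fg_hits.shape[0] - a)
        c = int(bg_hits[motif].sum())
        d = int(bg_hits.shape[0] - c)
        odds, p = scipy.stats.fisher_exact([[a, b], [c, d]],
                                           alternative="greater")
        out.append(MotifEnrichmentResult(
            motif, (tf_names or {}).get(motif, motif),
            a, fg_hits.shape[0], c, bg_hits.shape[0],
            float(odds), float(p), bool(p < p_max)))
    return sorted(out, key=lambda r: (r.p_value, r.motif_id))


# ---------------------------------------------------------------------------
# set intersections
# ---------------------------------------------------------------------------

def intersect_sets(sets: Mapping[str, Iterable]) -> pd.DataFrame:
    """UpSet-style exclusive intersection cells.

    Every element of the union is assigned to exactly one cell keyed by its
    exact membership pattern; cell counts therefore sum to |union|.
    """
    if len(sets) < 2:
        raise ValueError("need >= 2 sets")
    names = sorted(sets)
    members = {n: set(sets[n]) for n in names}
    cells: dict[tuple[str, ...], set] = {}
    for x in set().union(*members.values()):
        key = tuple(n for n in names if x in members[n])
        cells.setdefault(key, set()).add(x)
    rows = [{"sets": "&".join(key), "degree": len(key), "count": len(v),
             "members": ";".join(sorted(map(str, v)))}
            for key, v in sorted(cells.items(), key=lambda kv: (-len(kv[0]),
                                                                kv[0]))]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# TF expression / conservation filters
# ---------------------------------------------------------------------------

@dataclass
class TFFilterReport:
    shared: set[str]
    expressed: set[str]
    conserved: set[str]
    mean_expression: pd.DataFrame    # TF x species mean normalized expression

    def __post_init__(self) -> None:
        if not (self.conserved <= self.expressed <= self.shared):
            raise AssertionError("conserved <= expressed <= shared violated")


def mean_normalized_expression(cm: CountMatrix, meta: CellMetadata,
                               cell_type: str) -> pd.Series:
    """Mean log-normalized expression over cells of one type."""
    meta = meta.aligned_to(cm)
    mask = (meta.table["cell_type"] == cell_type).to_numpy()
    if not mask.any():
        raise ValueError(f"no {cell_type} cells")
    norm = lognormalize(cm)
    return pd.Series(norm[:, mask].mean(axis=1), index=cm.feature_ids)


def tf_filters(enriched: Mapping[str, Iterable[str]],
               expression: Mapping[str, CountMatrix],
               metadata: Mapping[str, CellMetadata],
               tf_to_gene: Mapping[str, str],
               reference: str, cell_type: str = "TC",
               expression_min: float = 0.2) -> TFFilterReport:
    """Shared = intersection of per-species enriched TF sets; expressed =
    shared TFs with mean normalized expression strictly above the threshold
    in the reference species' cell type; conserved = expressed in every
    species."""
    shared = set.intersection(*(set(v) for v in enriched.values()))
    mapped = {}
    for tf in sorted(shared):
        if tf not in tf_to_gene:
            logger.info("TF %s has no gene mapping; excluded", tf)
            continue
        mapped[tf] = tf_to_gene[tf]
    shared = set(mapped)
    means = {}
    for sp, cm in expression.items():
        mu = mean_normalized_expression(cm, metadata[sp], cell_type)
        means[sp] = pd.Series(
            {tf: float(mu.get(g, 0.0)) for tf, g in mapped.items()})
    mean_df = pd.DataFrame(means)
    if shared:
        expressed = {tf for tf in shared
                     if mean_df.loc[tf, reference] > expression_min}
        conserved = {tf for tf in expressed
                     if (mean_df.loc[tf] > expression_min).all()}
    else:
        expressed, conserved = set(), set()
    return TFFilterReport(shared, expressed, conserved, mean_df)


# ---------------------------------------------------------------------------
# differential expression
# ---------------------------------------------------------------------------

def wilcoxon_de(cm: CountMatrix, meta: CellMetadata, group_a: str,
                group_b: str, key: str = "cell_type") -> pd.DataFrame:
    """Two-sided rank-sum per gene on normalized expression, BH-adjusted;
    log2 fold change of group means with pseudocount 1."""
    meta = meta.aligned_to(cm)
    labels = meta.table[key].to_numpy()
    mask_a, mask_b = labels == group_a, labels == group_b
    if mask_a.sum() < 3 or mask_b.sum() < 3:
        missing = group_a if mask_a.sum() < 3 else group_b
        raise ValueError(f"group {missing!r} absent or too small")
    norm = lognormalize(cm)
    pvals = np.array([
        wilcoxon_rank_sum(norm[g, mask_a], norm[g, mask_b])
        for g in range(norm.shape[0])
    ])
    qvals = multipletests(pvals, method="fdr_bh")[1]
    lfc = np.log2((norm[:, mask_a].mean(axis=1) + 1.0)
                  / (norm[:, mask_b].mean(axis=1) + 1.0))
    return pd.DataFrame({
        "gene": cm.feature_ids, "log2fc": lfc, "p_value": pvals,
        "q_value": qvals,
    }).sort_values("p_value", kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# over-representation analysis
# ---------------------------------------------------------------------------

def ora(gene_list: Iterable[str], universe: Iterable[str],
        gene_sets: Mapping[str, Iterable[str]]) -> pd.DataFrame:
    """One-sided hypergeometric over-representation per gene set, BH across
    sets. The query list must be contained in the universe."""
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    query = set(gene_list)
    if not query <= universe:
        raise ValueError("gene list not contained in universe")
    N, n = len(universe), len(query)
    rows = []
    for name in sorted(gene_sets):
        members = set(gene_sets[name]) & universe
        K = len(members)
        k = len(members & query)
        p = float(scipy.stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append({"set": name, "overlap": k, "set_size": K,
                     "query_size": n, "universe_size": N,
                     "p_value": min(1.0, p)})
    df = pd.DataFrame(rows)
    df["q_value"] = multipletests(df["p_value"].to_numpy(), method="fdr_bh")[1]
    return df.sort_values("p_value", kind="stable").reset_index(drop=True)
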