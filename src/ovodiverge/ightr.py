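"""Intergenic highly-transcribed region (igHTR) calling and profiling.

Duplicate-filtered reads falling in intergenic, repeat-free space are
clustered left-to-right: a read joins the current cluster while the gap to
the cluster's rightmost covered base is below 150 bp, and a cluster becomes
an igHTR when it holds strictly more than 10 reads. The module also
accounts for transcriptome composition by genomic category, measures
igHTR-to-TSS distances, profiles Tn5 insertion coverage over igHTRs against
length-matched random intergenic controls, and classifies igHTR
conservation through chain lifting against reference igHTRs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .core_io import ChainMap, GeneModel, GenomicInterval, PipelineConfig
from .peak_conservation import lift_interval, _overlap_index

DUPLICATE_FLAG = 0x400

COMPOSITION_CATEGORIES = ("exon", "intron", "ncRNA", "repeat", "intergenic")

IGHTR_CONSERVATION = ("NOT_CONSERVED", "CONSERVED_NOT_IGHTR", "CONSERVED")


@dataclass(frozen=True)
class IgHTRRegion:
    interval: GenomicInterval
    read_count: int
    reads_per_kb: float
    distance_to_tss: int | None = None
    conservation: str | None = None


# ---------------------------------------------------------------------------
# duplicate filtering
# ---------------------------------------------------------------------------

def filter_duplicates(reads: pd.DataFrame) -> pd.DataFrame:
    """Drop reads whose SAM flag has the PCR/optical-duplicate bit (0x400)
    set; input order is preserved."""
    keep = (reads["flag"].to_numpy() & DUPLICATE_FLAG) == 0
    return reads.loc[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# genomic category assignment
# ---------------------------------------------------------------------------

class _IntervalIndex:
    """Point-membership queries against sorted non-overlapping intervals."""

    def __init__(self, intervals: Sequence[GenomicInterval]):
        self.by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom in sorted({iv.chrom for iv in intervals}):
            ivs = sorted((iv for iv in intervals if iv.chrom == chrom),
                         key=lambda x: x.start)
            starts = np.array([iv.start for iv in ivs])
            ends = np.array([iv.end for iv in ivs])
            if (starts[1:] < ends[:-1]).any():
                raise ValueError(f"overlapping intervals on {chrom}")
            self.by_chrom[chrom] = (starts, ends)

    def contains(self, chrom: np.ndarray, pos: np.ndarray) -> np.ndarray:
        out = np.zeros(pos.size, dtype=bool)
        for c, (starts, ends) in self.by_chrom.items():
            mask = chrom == c
            if not mask.any():
                continue
            idx = np.searchsorted(starts, pos[mask], side="right")
            hit = (idx > 0) & (pos[mask] < ends[np.maximum(idx - 1, 0)])
            out[mask] = hit
        return out

    def overlaps_interval(self, iv: GenomicInterval) -> bool:
        if iv.chrom not in self.by_chrom:
            return False
        starts, ends = self.by_chrom[iv.chrom]
        return _overlap_index(iv, starts, ends) is not None


def _category_indexes(genes: Sequence[GeneModel],
                      repeats: Sequence[GenomicInterval]
                      ) -> dict[str, _IntervalIndex]:
    coding = [g for g in genes if g.is_coding]
    nc = [g for g in genes if not g.is_coding]
    return {
        "exon": _IntervalIndex([e for g in coding for e in g.exons]),
        "gene_span": _IntervalIndex([g.span for g in coding]),
        "ncRNA": _IntervalIndex([e for g in nc for e in g.exons]),
        "nc_span": _IntervalIndex([g.span for g in nc]),
        "repeat": _IntervalIndex(list(repeats)),
    }


def assign_read_categories(reads: pd.DataFrame, genes: Sequence[GeneModel],
                           repeats: Sequence[GenomicInterval]) -> pd.Series:
    """Category of each read by midpoint, with precedence
    exon > intron > ncRNA > repeat > intergenic."""
    idx = _category_indexes(genes, repeats)
    chrom = reads["chrom"].to_numpy()
    mid = ((reads["start"].to_numpy() + reads["end"].to_numpy()) // 2)
    cat = np.full(len(reads), "intergenic", dtype=object)
    in_exon = idx["exon"].contains(chrom, mid)
    in_gene = idx["gene_span"].contains(chrom, mid)
    in_nc = idx["ncRNA"].contains(chrom, mid) | idx["nc_span"].contains(chrom, mid)
    in_rep = idx["repeat"].contains(chrom, mid)
    # assign lowest-precedence first so later writes override
    cat[in_rep] = "repeat"
    cat[in_nc] = "ncRNA"
    cat[in_gene & ~in_exon] = "intron"
    cat[in_exon] = "exon"
    return pd.Series(cat, index=reads.index, name="category")


def compose_transcriptome(reads: pd.DataFrame, genes: Sequence[GeneModel],
                          repeats: Sequence[GenomicInterval]) -> pd.Series:
    """Fraction of (duplicate-filtered) reads per genomic category.

    Fractions sum to 1; callers handle one species x cell type at a time.
    """
    cats = assign_read_categories(reads, genes, repeats)
    frac = cats.value_counts(normalize=True)
    out = pd.Series({c: float(frac.get(c, 0.0)) for c in COMPOSITION_CATEGORIES})
    assert abs(out.sum() - 1.0) < 1e-9 or len(reads) == 0
    return out


# ---------------------------------------------------------------------------
# igHTR calling
# ---------------------------------------------------------------------------

def call_ightrs(reads: pd.DataFrame, genes: Sequence[GeneModel],
                repeats: Sequence[GenomicInterval],
                config: PipelineConfig | None = None) -> list[IgHTRRegion]:
    """Two-parameter igHTR caller.

    Single left-to-right sweep per chromosome over position-sorted,
    duplicate-filtered reads restricted to intergenic repeat-free space: a
    new cluster starts when the gap between a read's start and the current
    cluster's rightmost covered base reaches ``ightr_max_gap`` (strict
    < 150 bp merges); clusters with read count strictly greater than
    ``ightr_min_reads`` are emitted. The region interval is the union of
    its member reads.
    """
    config = config or PipelineConfig()
    if (reads["flag"].to_numpy() & DUPLICATE_FLAG).any():
        raise ValueError("reads must be duplicate-filtered first")
    starts_all = reads["start"].to_numpy()
    chrom_all = reads["chrom"].to_numpy()
    for c in pd.unique(chrom_all):
        s = starts_all[chrom_all == c]
        if (np.diff(s) < 0).any():
            raise ValueError("reads must be position-sorted per chromosome")

    cats = assign_read_categories(reads, genes, repeats)
    inter = reads.loc[cats == "intergenic"]

    gene_idx = _IntervalIndex([g.span for g in genes])
    rep_idx = _IntervalIndex(list(repeats))

    regions: list[IgHTRRegion] = []
    min_reads = config.ightr_min_reads
    passes = ((lambda n: n >= min_reads) if config.ightr_count_inclusive
              else (lambda n: n > min_reads))

    end_to_start = config.ightr_gap_mode == "end_to_start"
    for chrom, grp in inter.groupby("chrom", sort=True):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()

        def emit(cluster: list[int]) -> None:
            if not passes(len(cluster)):
                return
            lo = int(min(starts[k] for k in cluster))
            hi = int(max(ends[k] for k in cluster))
            iv = GenomicInterval(str(chrom), lo, hi)
            # re-validate the type invariant: no gene/ncRNA/repeat overlap
            if gene_idx.overlaps_interval(iv) or rep_idx.overlaps_interval(iv):
                return
            regions.append(IgHTRRegion(iv, len(cluster),
                                       len(cluster) / (iv.length / 1000.0)))

        cluster: list[int] = []
        right = last_start = 0
        for k in range(len(grp)):
            s, e = int(starts[k]), int(ends[k])
            if cluster:
                gap = s - right if end_to_start else s - last_start
                if gap >= config.ightr_max_gap:
                    emit(cluster)
                    cluster = []
            right = e if not cluster else max(right, e)
            cluster.append(k)
            last_start = s
        if cluster:
            emit(cluster)
    return regions


def brute_force_ightrs(reads: pd.DataFrame, genes: Sequence[GeneModel],
                       repeats: Sequence[GenomicInterval],
                       config: PipelineConfig | None = None
                       ) -> list[IgHTRRegion]:
    """O(n^2) clustering oracle used to verify the sweep caller.

    For every read, membership is decided by a fresh scan over all reads
    already assigned to the open cluster (no incremental state): the read
    joins iff its start minus the cluster's maximum end (or, in
    start-to-start mode, the latest member start) is below the gap
    threshold. Count rule, interval union and the annotation-overlap
    invariant are applied independently of the sweep implementation.
    """
    config = config or PipelineConfig()
    cats = assign_read_categories(reads, genes, repeats)
    inter = reads.loc[cats == "intergenic"]
    gene_idx = _IntervalIndex([g.span for g in genes])
    rep_idx = _IntervalIndex(list(repeats))
    end_to_start = config.ightr_gap_mode == "end_to_start"
    out: list[IgHTRRegion] = []
    for chrom, grp in inter.groupby("chrom", sort=True):
        pairs = sorted(zip(grp["start"].astype(int), grp["end"].astype(int)))
        clusters: list[list[tuple[int, int]]] = []
        for s, e in pairs:
            joined = False
            if clusters:
                members = clusters[-1]
                if end_to_start:
                    anchor = max(m[1] for m in members)  # O(n) rescan
                else:
                    anchor = members[-1][0]
                if s - anchor < config.ightr_max_gap:
                    members.append((s, e))
                    joined = True
            if not joined:
                clusters.append([(s, e)])
        min_reads = config.ightr_min_reads
        for members in clusters:
            n = len(members)
            ok = n >= min_reads if config.ightr_count_inclusive else n > min_reads
            if not ok:
                continue
            iv = GenomicInterval(str(chrom), min(m[0] for m in members),
                                 max(m[1] for m in members))
            if gene_idx.overlaps_interval(iv) or rep_idx.overlaps_interval(iv):
                continue
            out.append(IgHTRRegion(iv, n, n / (iv.length / 1000.0)))
    return sorted(out, key=lambda r: (r.interval.chrom, r.interval.start))


# ---------------------------------------------------------------------------
# TSS distance
# ---------------------------------------------------------------------------

DEFAULT_TSS_BINS = (0.0, 1e3, 1e4, 1e5, 1e6, np.inf)


def tss_distance(regions: Sequence[IgHTRRegion], genes: Sequence[GeneModel],
                 bins: Sequence[float] = DEFAULT_TSS_BINS
                 ) -> tuple[list[IgHTRRegion], pd.Series]:
    """Absolute distance from each region midpoint to the nearest TSS,
    plus a histogram over log-scaled distance bins."""
    if not regions:
        raise ValueError("no igHTRs supplied")
    if not genes:
        raise ValueError("genome has no annotated genes")
    tss_by_chrom: dict[str, np.ndarray] = {}
    for g in genes:
        tss_by_chrom.setdefault(g.span.chrom, [])
    for g in genes:
        tss_by_chrom[g.span.chrom].append(g.tss)
    tss_by_chrom = {c: np.array(sorted(v)) for c, v in tss_by_chrom.items()}

    annotated = []
    dists = []
    for r in regions:
        mid = r.interval.midpoint
        best = None
        arr = tss_by_chrom.get(r.interval.chrom)
        if arr is not None and arr.size:
            i = int(np.searchsorted(arr, mid))
            for j in (i - 1, i):
                if 0 <= j < arr.size:
                    d = abs(int(arr[j]) - mid)
                    best = d if best is None else min(best, d)
        if best is None:
            best = -1
        annotated.append(replace(r, distance_to_tss=best))
        dists.append(best)

    edges = np.asarray(bins, dtype=float)
    labels = [f"({edges[i]:g}, {edges[i + 1]:g}]" for i in range(len(edges) - 1)]
    valid = np.array([d for d in dists if d >= 0], dtype=float)
    hist = pd.Series(0, index=labels, dtype=int)
    if valid.size:
        # zero distances fall in the first bin
        which = np.clip(np.digitize(valid, edges, right=True) - 1, 0,
                        len(labels) - 1)
        for w in which:
            hist.iloc[int(w)] += 1
    return annotated, hist


# ---------------------------------------------------------------------------
# accessibility profile
# ---------------------------------------------------------------------------

@dataclass
class ProfileMatrix:
    bin_labels: list[str]
    region_track: np.ndarray     # mean insertions per bp per bin
    control_track: np.ndarray


def _insertion_positions(fragments: pd.DataFrame) -> dict[str, np.ndarray]:
    """Tn5 insertion sites: both fragment ends, sorted per chromosome."""
    out: dict[str, np.ndarray] = {}
    for chrom, grp in fragments.groupby("chrom", sort=True):
        pos = np.concatenate([grp["start"].to_numpy(),
                              grp["end"].to_numpy() - 1])
        pos.sort(kind="stable")
        out[str(chrom)] = pos
    return out


def _bin_coverage(ins: dict[str, np.ndarray], iv: GenomicInterval,
                  edges: np.ndarray) -> np.ndarray:
    pos = ins.get(iv.chrom)
    if pos is None:
        return np.zeros(edges.size - 1)
    counts = np.diff(np.searchsorted(pos, edges))
    widths = np.diff(edges)
    return counts / np.maximum(widths, 1)


def accessibility_profile(regions: Sequence[GenomicInterval],
                          fragments: pd.DataFrame,
                          intergenic_space: Sequence[GenomicInterval],
                          flank: int = 2000, n_bins: int = 20,
                          flank_bin: int = 100,
                          control_seed: int = 0) -> ProfileMatrix:
    """Mean Tn5 insertion coverage over regions scaled to ``n_bins`` plus
    fixed-width flanks, with an equally sized, length-matched random
    intergenic control track (seeded)."""
    if flank < flank_bin:
        raise ValueError("flank smaller than a flank bin")
    ins = _insertion_positions(fragments)
    n_flank = flank // flank_bin
    labels = ([f"up{-(n_flank - i) * flank_bin}" for i in range(n_flank)]
              + [f"body{i}" for i in range(n_bins)]
              + [f"down{(i + 1) * flank_bin}" for i in range(n_flank)])

    rng = np.random.default_rng(control_seed)
    space = [iv for iv in intergenic_space]
    controls: list[GenomicInterval] = []
    for r in regions:
        for _ in range(1000):
            host = space[int(rng.integers(0, len(space)))]
            if host.length < r.length:
                continue
            s = int(rng.integers(host.start, host.end - r.length + 1))
            controls.append(GenomicInterval(host.chrom, s, s + r.length))
            break
        else:
            raise ValueError("could not place a length-matched control region")

    def track(ivs: Sequence[GenomicInterval]) -> np.ndarray:
        acc = np.zeros(len(labels))
        for iv in ivs:
            up = np.arange(max(0, iv.start - flank), iv.start + 1, flank_bin,
                           dtype=float)
            if up.size != n_flank + 1:
                up = np.linspace(max(0, iv.start - flank), iv.start, n_flank + 1)
            body = np.linspace(iv.start, iv.end, n_bins + 1)
            down = np.linspace(iv.end, iv.end + flank, n_flank + 1)
            edges = np.concatenate([up[:-1], body[:-1], down])
            acc += _bin_coverage(ins, iv, edges)
        return acc / max(1, len(ivs))

    return ProfileMatrix(labels, track(list(regions)), track(controls))


# ---------------------------------------------------------------------------
# igHTR conservation
# ---------------------------------------------------------------------------

def classify_ightr_conservation(regions: Sequence[IgHTRRegion],
                                chain_map: ChainMap,
                                reference_ightrs: Sequence[IgHTRRegion],
                                min_match: float = 0.95) -> list[IgHTRRegion]:
    """Lift each igHTR to the reference genome: lift failure is
    NOT_CONSERVED; a lifted region overlapping (>= 1 bp) a reference igHTR
    is CONSERVED, otherwise CONSERVED_NOT_IGHTR."""
    ref_ivs = sorted((r.interval for r in reference_ightrs),
                     key=lambda iv: (iv.chrom, iv.start))
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in {iv.chrom for iv in ref_ivs}:
        ivs = [iv for iv in ref_ivs if iv.chrom == chrom]
        by_chrom[chrom] = (np.array([iv.start for iv in ivs]),
                           np.array([iv.end for iv in ivs]))
    out = []
    for r in regions:
        lift = lift_interval(r.interval, chain_map, min_match)
        if not lift.ok:
            cls = "NOT_CONSERVED"
        else:
            lifted = lift.interval
            hit = None
            if lifted.chrom in by_chrom:
                starts, ends = by_chrom[lifted.chrom]
                hit = _overlap_index(lifted, starts, ends)
            cls = "CONSERVED" if hit is not None else "CONSERVED_NOT_IGHTR"
        out.append(replace(r, conservation=cls))
    return out
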