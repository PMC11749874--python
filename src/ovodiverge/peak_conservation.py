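"""Cross-genome interval lifting and the peak conservation taxonomy.

Peaks from a query species are mapped onto the reference genome through a
UCSC chain file and classified as NOT_ALIGNABLE (lift failure),
ALIGNABLE_NOT_ACCESSIBLE (lifted, but no overlap with a reference peak) or
CONSERVED_ACCESSIBLE (lifted onto an open reference peak, >= 1 bp overlap).
Classification is exhaustive and mutually exclusive per peak.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .core_io import ChainMap, GenomicInterval

CONSERVATION_CLASSES = (
    "NOT_ALIGNABLE",
    "ALIGNABLE_NOT_ACCESSIBLE",
    "CONSERVED_ACCESSIBLE",
)

LIFT_OK = "OK"
LIFT_NO_CHAIN = "NO_CHAIN"
LIFT_BELOW_MIN_MATCH = "PARTIAL_BELOW_MIN_MATCH"
LIFT_SPLIT = "SPLIT"


@dataclass(frozen=True)
class LiftResult:
    status: str
    interval: GenomicInterval | None = None
    mapped_fraction: float = 0.0

    @property
    def ok(self) -> bool:
        return self.status == LIFT_OK


def _map_through_chain(iv: GenomicInterval, chain) -> tuple[int, int | None, int | None]:
    """Walk the chain blocks; return (mapped bases of iv, min/max target
    position on the plus strand of the target genome)."""
    s_pos, t_pos = chain.s_start, chain.t_start
    mapped = 0
    tmin: int | None = None
    tmax: int | None = None
    for block in chain.blocks:
        lo = max(iv.start, s_pos)
        hi = min(iv.end, s_pos + block.size)
        if hi > lo:
            mapped += hi - lo
            a = t_pos + (lo - s_pos)
            b = t_pos + (hi - s_pos)  # exclusive
            if chain.t_strand == "-":
                a, b = chain.t_size - b, chain.t_size - a
            tmin = a if tmin is None else min(tmin, a)
            tmax = b if tmax is None else max(tmax, b)
        s_pos += block.size + block.dt
        t_pos += block.size + block.dq
    return mapped, tmin, tmax


def lift_interval(iv: GenomicInterval, chain_map: ChainMap,
                  min_match: float = 0.95) -> LiftResult:
    """Map an interval through the best-scoring overlapping chain.

    Succeeds iff the fraction of bases falling in aligned blocks of that
    chain is >= ``min_match``; the result is the plus-strand span of the
    mapped bases on the target genome. Failure is a typed status, never an
    exception.
    """
    candidates = chain_map.overlapping(iv)
    if not candidates:
        return LiftResult(LIFT_NO_CHAIN)
    best = candidates[0]
    mapped, tmin, tmax = _map_through_chain(iv, best)
    frac = mapped / iv.length
    if frac >= min_match and tmin is not None:
        return LiftResult(LIFT_OK,
                          GenomicInterval(best.t_chrom, tmin, tmax), frac)
    if len(candidates) > 1:
        return LiftResult(LIFT_SPLIT, mapped_fraction=frac)
    return LiftResult(LIFT_BELOW_MIN_MATCH, mapped_fraction=frac)


@dataclass
class ConservationReport:
    species: str
    table: pd.DataFrame          # name, chrom, start, end, class, lifted coords
    counts: dict[str, int]
    fractions: dict[str, float]

    def __post_init__(self) -> None:
        total = sum(self.counts.values())
        if total != len(self.table):
            raise AssertionError("class counts do not sum to the peak count")
        if total and abs(sum(self.fractions.values()) - 1.0) > 1e-9:
            raise AssertionError("class fractions do not sum to 1")


def _overlap_index(iv: GenomicInterval, starts: np.ndarray, ends: np.ndarray
                   ) -> int | None:
    """Index of a sorted, non-overlapping target interval overlapping iv."""
    idx = int(np.searchsorted(starts, iv.end))
    if idx > 0 and ends[idx - 1] > iv.start:
        return idx - 1
    return None


def classify_peaks(source_peaks: Sequence[GenomicInterval],
                   chain_map: ChainMap,
                   target_peaks: Sequence[GenomicInterval],
                   min_match: float = 0.95,
                   species: str = "query",
                   peak_names: Sequence[str] | None = None
                   ) -> ConservationReport:
    """Assign every source peak to exactly one conservation class.

    Target peaks must be sorted and non-overlapping (per chromosome).
    A lifted peak must share >= 1 bp with a target peak to count as
    conserved accessible; book-ended peaks do not overlap.
    """
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, list[int]]] = {}
    order = sorted(range(len(target_peaks)), key=lambda i: (target_peaks[i].chrom,
                                                            target_peaks[i].start))
    for chrom in {p.chrom for p in target_peaks}:
        idxs = [i for i in order if target_peaks[i].chrom == chrom]
        starts = np.array([target_peaks[i].start for i in idxs])
        ends = np.array([target_peaks[i].end for i in idxs])
        if (starts[1:] < ends[:-1]).any():
            raise ValueError("target peaks must be non-overlapping")
        by_chrom[chrom] = (starts, ends, idxs)

    rows = []
    names = peak_names or [f"peak{i:05d}" for i in range(len(source_peaks))]
    for name, peak in zip(names, source_peaks):
        lift = lift_interval(peak, chain_map, min_match)
        if not lift.ok:
            cls, lifted = "NOT_ALIGNABLE", None
        else:
            lifted = lift.interval
            hit = None
            if lifted.chrom in by_chrom:
                starts, ends, idxs = by_chrom[lifted.chrom]
                hit = _overlap_index(lifted, starts, ends)
            cls = ("CONSERVED_ACCESSIBLE" if hit is not None
                   else "ALIGNABLE_NOT_ACCESSIBLE")
        rows.append({
            "name": name, "chrom": peak.chrom, "start": peak.start,
            "end": peak.end, "class": cls,
            "lifted_chrom": lifted.chrom if lifted else "",
            "lifted_start": lifted.start if lifted else -1,
            "lifted_end": lifted.end if lifted else -1,
            "lift_status": lift.status,
        })
    table = pd.DataFrame(rows)
    counts = {c: int((table["class"] == c).sum()) for c in CONSERVATION_CLASSES}
    n = max(1, len(table))
    fractions = {c: counts[c] / n for c in CONSERVATION_CLASSES}
    return ConservationReport(species, table, counts, fractions)


def conserved_peak_sequences(ref_peaks: Sequence[GenomicInterval],
                             ref_genome: dict[str, str],
                             species_data: dict[str, tuple[ConservationReport,
                                                           Sequence[GenomicInterval],
                                                           dict[str, str]]],
                             ref_species: str = "human",
                             peak_cell_types: Sequence[str] | None = None,
                             ) -> dict[str, dict[str, str]]:
    """Aligned sequences of peaks conserved accessible in *all* species,
    keyed by the reference peak they lift onto, concatenated per species
    (optionally split by the peak's cell type of origin).

    Returns {cell_type (or "all"): {species: concatenated sequence}}.
    """
    order = sorted(range(len(ref_peaks)), key=lambda i: (ref_peaks[i].chrom,
                                                         ref_peaks[i].start))
    starts = np.array([ref_peaks[i].start for i in order])
    ends = np.array([ref_peaks[i].end for i in order])
    chroms = [ref_peaks[i].chrom for i in order]

    per_ref: dict[int, dict[str, GenomicInterval]] = {}
    for sp, (report, peaks, _genome) in species_data.items():
        for i, row in report.table.iterrows():
            if row["class"] != "CONSERVED_ACCESSIBLE":
                continue
            lifted = GenomicInterval(row["lifted_chrom"],
                                     int(row["lifted_start"]),
                                     int(row["lifted_end"]))
            idx = _overlap_index(lifted, starts, ends)
            if idx is None or chroms[idx] != lifted.chrom:
                continue
            ref_idx = order[idx]
            per_ref.setdefault(ref_idx, {})[sp] = peaks[i]

    all_species = set(species_data)
    out: dict[str, dict[str, str]] = {}
    for ref_idx in sorted(per_ref):
        src = per_ref[ref_idx]
        if set(src) != all_species:
            continue
        ref_iv = ref_peaks[ref_idx]
        ct = (peak_cell_types[ref_idx] if peak_cell_types is not None else "all")
        bucket = out.setdefault(ct, {s: "" for s in all_species | {ref_species}})
        bucket[ref_species] += ref_genome[ref_iv.chrom][ref_iv.start:ref_iv.end]
        for sp, iv in src.items():
            genome = species_data[sp][2]
            bucket[sp] += genome[iv.chrom][iv.start:iv.end]
    return out


def conserved_peak_pca(accessibility: pd.DataFrame, n_components: int = 5
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """PCA of group (species x cell type) accessibility pseudo-bulks.

    ``accessibility`` has peaks as rows and groups labelled "species|cell_type"
    as columns; values are counts. Columns are log1p CPM scaled, features
    standardized, and the per-species |PC2| separations between cell types
    are reported alongside the coordinates.
    """
    n_peaks, n_groups = accessibility.shape
    if n_groups < 3:
        raise ValueError("need >= 3 groups")
    if n_peaks < n_groups:
        raise ValueError("fewer peaks than groups")
    counts = accessibility.to_numpy(dtype=float)
    cpm = np.log1p(counts / counts.sum(axis=0, keepdims=True) * 1e6)
    X = cpm.T  # groups as samples
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    X = (X - mu) / sd
    k = min(n_components, n_groups - 1, n_peaks)
    pca = PCA(n_components=k, svd_solver="full")
    coords = pca.fit_transform(X)
    coord_df = pd.DataFrame(coords, index=accessibility.columns,
                            columns=[f"PC{i + 1}" for i in range(k)])

    rows = []
    groups = [c.split("|") for c in accessibility.columns]
    species = sorted({g[0] for g in groups if len(g) == 2})
    for sp in species:
        cts = sorted(g[1] for g in groups if g[0] == sp)
        for i, a in enumerate(cts):
            for b in cts[i + 1:]:
                d = abs(coord_df.loc[f"{sp}|{a}", "PC2"]
                        - coord_df.loc[f"{sp}|{b}", "PC2"])
                rows.append({"species": sp, "cell_type_a": a,
                             "cell_type_b": b, "pc2_distance": float(d)})
    return coord_df, pd.DataFrame(rows)
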