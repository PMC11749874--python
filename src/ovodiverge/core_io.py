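"""Shared domain types and readers/writers for the standard formats.

All genomic coordinates inside the package are 0-based half-open (BED
convention). GTF input (1-based, inclusive) is converted on read. Chain
files follow UCSC semantics: the alignment maps the *source* genome (the
``t`` fields of the header) onto the *target* genome (the ``q`` fields).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml

VALID_STRANDS = {"+", "-", "."}


# ---------------------------------------------------------------------------
# coordinate types
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) with optional strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end ({self.end}) must exceed start ({self.start})")
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        """Strict half-open overlap: book-ended intervals do not overlap."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains_point(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end


@dataclass(frozen=True)
class GeneModel:
    """A gene with its TSS, exon structure and biotype."""

    gene_id: str
    gene_name: str
    biotype: str
    strand: str
    tss: int
    exons: tuple[GenomicInterval, ...]
    span: GenomicInterval

    def __post_init__(self) -> None:
        for ex in self.exons:
            if ex.start < self.span.start or ex.end > self.span.end:
                raise ValueError(f"exon {ex} outside span {self.span} of {self.gene_id}")
        expected = self.span.start if self.strand == "+" else self.span.end - 1
        if self.tss != expected:
            raise ValueError(f"tss {self.tss} inconsistent with strand/span of {self.gene_id}")

    @property
    def is_coding(self) -> bool:
        return self.biotype == "protein_coding"


# ---------------------------------------------------------------------------
# count matrix + metadata
# ---------------------------------------------------------------------------

@dataclass
class CountMatrix:
    """Features x cells integer counts, sparse-capable."""

    feature_ids: list[str]
    cell_ids: list[str]
    counts: sp.spmatrix | np.ndarray

    def __post_init__(self) -> None:
        n_feat, n_cell = self.shape
        if n_feat != len(self.feature_ids) or n_cell != len(self.cell_ids):
            raise ValueError("counts shape does not match identifier lists")
        if len(set(self.feature_ids)) != n_feat:
            raise ValueError("duplicate feature identifiers")
        if len(set(self.cell_ids)) != n_cell:
            raise ValueError("duplicate cell identifiers")
        if self.dense().min() < 0:
            raise ValueError("negative counts")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def dense(self) -> np.ndarray:
        if sp.issparse(self.counts):
            return np.asarray(self.counts.todense())
        return np.asarray(self.counts)

    def subset_features(self, keep: Sequence[str]) -> "CountMatrix":
        index = {f: i for i, f in enumerate(self.feature_ids)}
        rows = [index[f] for f in keep]
        dense = self.dense()[rows, :]
        return CountMatrix(list(keep), list(self.cell_ids), dense)

    def subset_cells(self, keep: Sequence[str]) -> "CountMatrix":
        index = {c: i for i, c in enumerate(self.cell_ids)}
        cols = [index[c] for c in keep]
        dense = self.dense()[:, cols]
        return CountMatrix(list(self.feature_ids), list(keep), dense)


CELL_TYPES = ("GC", "SC", "TC")


@dataclass
class CellMetadata:
    """Per-cell annotations: species, cell type and library of origin."""

    table: pd.DataFrame

    REQUIRED = ("cell_id", "species", "cell_type", "library_id")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"metadata missing columns: {missing}")
        if self.table["cell_id"].duplicated().any():
            raise ValueError("duplicate cell_id in metadata")
        self.table = self.table.reset_index(drop=True)

    def aligned_to(self, cm: CountMatrix) -> "CellMetadata":
        """Reorder to the matrix's cells; reject cells absent from metadata."""
        tab = self.table.set_index("cell_id")
        unknown = [c for c in cm.cell_ids if c not in tab.index]
        if unknown:
            raise ValueError(f"cells absent from metadata: {unknown[:5]}...")
        out = tab.loc[list(cm.cell_ids)].reset_index()
        return CellMetadata(out)


# ---------------------------------------------------------------------------
# chain map
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChainBlock:
    size: int   # ungapped aligned length
    dt: int     # gap on source genome after the block (0 on last block)
    dq: int     # gap on target genome after the block


@dataclass(frozen=True)
class Chain:
    score: float
    s_chrom: str
    s_size: int
    s_strand: str
    s_start: int
    s_end: int
    t_chrom: str
    t_size: int
    t_strand: str
    t_start: int
    t_end: int
    chain_id: int
    blocks: tuple[ChainBlock, ...]

    def __post_init__(self) -> None:
        s_span = sum(b.size + b.dt for b in self.blocks)
        t_span = sum(b.size + b.dq for b in self.blocks)
        if s_span != self.s_end - self.s_start:
            raise ValueError(
                f"chain {self.chain_id}: source blocks span {s_span} != "
                f"{self.s_end - self.s_start}"
            )
        if t_span != self.t_end - self.t_start:
            raise ValueError(
                f"chain {self.chain_id}: target blocks span {t_span} != "
                f"{self.t_end - self.t_start}"
            )
        if any(b.size <= 0 for b in self.blocks):
            raise ValueError(f"chain {self.chain_id}: non-positive block size")


@dataclass
class ChainMap:
    """Ordered (by score, descending) collection of chains."""

    chains: list[Chain]

    def __post_init__(self) -> None:
        self.chains = sorted(self.chains, key=lambda c: -c.score)

    def overlapping(self, iv: GenomicInterval) -> list[Chain]:
        """Chains whose source span overlaps iv, best score first."""
        return [
            c
            for c in self.chains
            if c.s_chrom == iv.chrom and c.s_start < iv.end and iv.start < c.s_end
        ]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """All tunable thresholds of the pipeline, with their conventional defaults.

    ightr_max_gap / ightr_min_reads are the two-parameter intergenic
    highly-transcribed-region rule (neighbour spacing < 150 bp, strictly
    more than 10 reads). link_r_quantile is the empirical-quantile rule for
    gene-linked cCREs. tf_expression_min is the mean normalized-expression
    floor for calling a TF expressed.
    """

    ightr_max_gap: int = 150
    ightr_min_reads: int = 10          # strictly-greater threshold
    link_r_quantile: float = 0.95
    tf_expression_min: float = 0.2
    motif_p_max: float = 0.05
    n_pcs_integration: int = 30        # provenance only
    liftover_min_match: float = 0.95
    promoter_upstream: int = 2000
    promoter_downstream: int = 500
    coaccess_min_score: float = 0.25
    coaccess_max_span: int = 100_000
    profile_flank: int = 2000
    metacell_size: int = 20
    ightr_gap_mode: str = "end_to_start"   # or "start_to_start"
    ightr_count_inclusive: bool = False    # True reads "more 10" as >= 10
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.ightr_max_gap <= 0 or self.ightr_min_reads < 0:
            raise ValueError("igHTR thresholds out of domain")
        for name in ("link_r_quantile", "liftover_min_match", "motif_p_max"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.ightr_gap_mode not in ("end_to_start", "start_to_start"):
            raise ValueError(f"unknown ightr_gap_mode {self.ightr_gap_mode!r}")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

def _parse_gtf_attributes(attr: str, lineno: int) -> dict[str, str]:
    out: dict[str, str] = {}
    for part in attr.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        if " " not in part:
            raise ValueError(f"GTF line {lineno}: malformed attribute {part!r}")
        key, value = part.split(" ", 1)
        out[key] = value.strip().strip('"')
    return out


def read_gtf(path: str | Path) -> list[GeneModel]:
    """Parse an Ensembl-dialect GTF into GeneModels (0-based half-open).

    Uses ``gene`` records for span/biotype and ``exon`` records for exon
    structure; the TSS is derived from the span per strand.
    """
    genes: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 9:
                raise ValueError(f"GTF line {lineno}: expected 9 columns, got {len(cols)}")
            chrom, _src, feature, start, end, _score, strand, _frame, attr = cols
            try:
                start0, end0 = int(start) - 1, int(end)
            except ValueError as exc:
                raise ValueError(f"GTF line {lineno}: non-integer coordinates") from exc
            attrs = _parse_gtf_attributes(attr, lineno)
            if "gene_id" not in attrs:
                raise ValueError(f"GTF line {lineno}: missing gene_id attribute")
            gid = attrs["gene_id"]
            if gid not in genes:
                genes[gid] = {
                    "chrom": chrom,
                    "strand": strand,
                    "name": attrs.get("gene_name", gid),
                    "biotype": attrs.get("gene_biotype", "protein_coding"),
                    "span": None,
                    "exons": [],
                }
                order.append(gid)
            rec = genes[gid]
            if feature == "gene":
                rec["span"] = (start0, end0)
                rec["biotype"] = attrs.get("gene_biotype", rec["biotype"])
                rec["name"] = attrs.get("gene_name", rec["name"])
            elif feature == "exon":
                rec["exons"].append(GenomicInterval(chrom, start0, end0, strand))

    models = []
    for gid in order:
        rec = genes[gid]
        if rec["span"] is None:
            if not rec["exons"]:
                continue
            lo = min(e.start for e in rec["exons"])
            hi = max(e.end for e in rec["exons"])
            rec["span"] = (lo, hi)
        span = GenomicInterval(rec["chrom"], rec["span"][0], rec["span"][1], rec["strand"])
        tss = span.start if rec["strand"] == "+" else span.end - 1
        models.append(
            GeneModel(
                gene_id=gid,
                gene_name=rec["name"],
                biotype=rec["biotype"],
                strand=rec["strand"],
                tss=tss,
                exons=tuple(sorted(rec["exons"], key=lambda e: e.start)),
                span=span,
            )
        )
    return models


def write_gtf(genes: Iterable[GeneModel], path: str | Path, source: str = "ovodiverge") -> None:
    """Write GeneModels back to 1-based inclusive GTF."""
    with open(path, "w") as fh:
        for g in genes:
            attrs = (
                f'gene_id "{g.gene_id}"; gene_name "{g.gene_name}"; '
                f'gene_biotype "{g.biotype}";'
            )
            fh.write(
                "\t".join(
                    [
                        g.span.chrom, source, "gene", str(g.span.start + 1),
                        str(g.span.end), ".", g.strand, ".", attrs,
                    ]
                )
                + "\n"
            )
            for ex in g.exons:
                fh.write(
                    "\t".join(
                        [
                            ex.chrom, source, "exon", str(ex.start + 1),
                            str(ex.end), ".", g.strand, ".", attrs,
                        ]
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> list[GenomicInterval]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 3:
                raise ValueError(f"BED line {lineno}: fewer than 3 columns")
            strand = cols[5] if len(cols) >= 6 else "."
            out.append(GenomicInterval(cols[0], int(cols[1]), int(cols[2]), strand))
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path,
              names: Sequence[str] | None = None,
              extra: Sequence[Sequence] | None = None) -> None:
    ivs = list(intervals)
    with open(path, "w") as fh:
        for i, iv in enumerate(ivs):
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if names is not None or extra is not None or iv.strand != ".":
                cols.append(names[i] if names is not None else f"region_{i}")
                cols.append("0")
                cols.append(iv.strand)
            if extra is not None:
                cols.extend(str(x) for x in extra[i])
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# chain
# ---------------------------------------------------------------------------

def read_chain(path: str | Path) -> ChainMap:
    """Read a UCSC chain file; per-chain block arithmetic is verified."""
    chains: list[Chain] = []
    header: list[str] | None = None
    blocks: list[ChainBlock] = []

    def flush() -> None:
        nonlocal header, blocks
        if header is None:
            return
        (_kw, score, s_chrom, s_size, s_strand, s_start, s_end,
         t_chrom, t_size, t_strand, t_start, t_end, cid) = header
        chains.append(
            Chain(
                score=float(score),
                s_chrom=s_chrom, s_size=int(s_size), s_strand=s_strand,
                s_start=int(s_start), s_end=int(s_end),
                t_chrom=t_chrom, t_size=int(t_size), t_strand=t_strand,
                t_start=int(t_start), t_end=int(t_end),
                chain_id=int(cid), blocks=tuple(blocks),
            )
        )
        header, blocks = None, []

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("chain"):
                flush()
                header = line.split()
                if len(header) != 13:
                    raise ValueError(f"chain line {lineno}: expected 13 fields")
            else:
                parts = line.split()
                if header is None:
                    raise ValueError(f"chain line {lineno}: block outside chain")
                if len(parts) == 3:
                    blocks.append(ChainBlock(int(parts[0]), int(parts[1]), int(parts[2])))
                elif len(parts) == 1:
                    blocks.append(ChainBlock(int(parts[0]), 0, 0))
                else:
                    raise ValueError(f"chain line {lineno}: malformed block")
    flush()
    return ChainMap(chains)


def write_chain(cm: ChainMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        for c in cm.chains:
            fh.write(
                f"chain {c.score:g} {c.s_chrom} {c.s_size} {c.s_strand} "
                f"{c.s_start} {c.s_end} {c.t_chrom} {c.t_size} {c.t_strand} "
                f"{c.t_start} {c.t_end} {c.chain_id}\n"
            )
            for b in c.blocks[:-1]:
                fh.write(f"{b.size} {b.dt} {b.dq}\n")
            fh.write(f"{c.blocks[-1].size}\n\n")


# ---------------------------------------------------------------------------
# counts + metadata
# ---------------------------------------------------------------------------

def read_counts(path: str | Path, metadata: str | Path | None = None
                ) -> tuple[CountMatrix, CellMetadata | None]:
    """Read counts from an MTX triplet directory or a dense TSV.

    The triplet directory holds matrix.mtx, features.tsv, barcodes.tsv.
    A dense TSV has feature rows, cell columns, both labelled. When a
    metadata TSV (keyed by cell_id) is given, it is aligned to the matrix
    and cells absent from it are rejected.
    """
    path = Path(path)
    if path.is_dir():
        counts = scipy.io.mmread(path / "matrix.mtx").tocsr()
        features = (path / "features.tsv").read_text().split()
        barcodes = (path / "barcodes.tsv").read_text().split()
        cm = CountMatrix(features, barcodes, counts)
    else:
        df = pd.read_csv(path, sep="\t", index_col=0)
        cm = CountMatrix(list(df.index), list(df.columns), df.to_numpy())
    meta = None
    if metadata is not None:
        meta = read_cell_metadata(metadata).aligned_to(cm)
    return cm, meta


def write_counts(cm: CountMatrix, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mat = sp.coo_matrix(cm.counts)
    scipy.io.mmwrite(str(outdir / "matrix.mtx"), mat)
    (outdir / "features.tsv").write_text("\n".join(cm.feature_ids) + "\n")
    (outdir / "barcodes.tsv").write_text("\n".join(cm.cell_ids) + "\n")


def read_cell_metadata(path: str | Path) -> CellMetadata:
    return CellMetadata(pd.read_csv(path, sep="\t", dtype=str))


def write_cell_metadata(meta: CellMetadata, path: str | Path) -> None:
    meta.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# orthologue table, GMT, FASTA
# ---------------------------------------------------------------------------

def read_orthologs(path: str | Path) -> pd.DataFrame:
    """1:1 orthologue table: one column per species, rows are orthologue sets."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("orthologue table needs at least two species columns")
    return df


def write_orthologs(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = set(g for g in parts[2:] if g)
    return sets


def write_gmt(sets: dict[str, Iterable[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, name] + sorted(members)) + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# reads / fragments tables
# ---------------------------------------------------------------------------

READ_COLUMNS = ["chrom", "start", "end", "flag", "barcode"]
FRAGMENT_COLUMNS = ["chrom", "start", "end", "barcode"]


def read_reads_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=0)
    missing = [c for c in READ_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"reads table missing columns {missing}")
    return df


def write_reads_table(df: pd.DataFrame, path: str | Path) -> None:
    df[READ_COLUMNS].to_csv(path, sep="\t", index=False)


def read_fragments_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=0)
    missing = [c for c in FRAGMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"fragments table missing columns {missing}")
    return df


def write_fragments_table(df: pd.DataFrame, path: str | Path) -> None:
    df[FRAGMENT_COLUMNS].to_csv(path, sep="\t", index=False)


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
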