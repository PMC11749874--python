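"""NMF pattern discovery and cross-species non-negative projection.

A deterministic multiplicative-update NMF factorizes reference-species
log-normalized expression into non-negative gene amplitudes and cell
weights; other species' cells are projected onto the fixed amplitudes by
per-cell non-negative least squares, and each pattern is summarized by the
Pearson correlation of its weights with cell-type indicator vectors. This
reproduces the transfer-learning use of Bayesian sparse NMF pattern sets:
conserved programs correlate with their cell type in every species, a
species-specific program only in its own.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.optimize

from .core_io import CellMetadata, CountMatrix

_EPS = 1e-12


def lognormalize(cm: CountMatrix, scale: float = 1e4) -> np.ndarray:
    """Seurat-style normalization: log1p of per-cell depth-scaled counts."""
    dense = cm.dense().astype(float)
    depth = dense.sum(axis=0, keepdims=True)
    depth[depth == 0] = 1.0
    return np.log1p(dense / depth * scale)


@dataclass
class PatternModel:
    amplitude: np.ndarray        # genes x k, columns unit L2 norm
    weights: np.ndarray          # k x reference cells
    k: int
    gene_ids: list[str]
    n_iter: int
    objective: float
    seed: int

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(self.amplitude, index=self.gene_ids,
                     columns=[f"pattern{i + 1}" for i in range(self.k)]
                     ).to_csv(outdir / "amplitude.tsv", sep="\t")
        pd.DataFrame(self.weights).to_csv(outdir / "weights.tsv", sep="\t")
        (outdir / "model.json").write_text(json.dumps({
            "k": self.k, "n_iter": self.n_iter,
            "objective": self.objective, "seed": self.seed,
        }, indent=2) + "\n")


@dataclass
class ProjectionResult:
    weights: dict[str, np.ndarray]                 # species -> k x cells
    correlations: dict[str, pd.DataFrame]          # species -> pattern x cell type


def fit_patterns(X: np.ndarray, gene_ids: list[str], k: int, seed: int = 0,
                 n_iter: int = 2000, tol: float = 1e-9,
                 n_restarts: int = 5) -> PatternModel:
    """Multiplicative-update NMF minimizing squared Frobenius error.

    The input is any non-negative expression matrix (genes x cells); raw
    counts suit data whose structure is linear on the count scale, log1p
    normalized values suit heavy-tailed real data. Runs ``n_restarts``
    seeded random initializations and keeps the lowest-objective solution
    (multiplicative updates can strand a component at zero from a bad
    start). Deterministic given the seed; the objective is checked to be
    non-increasing every 10 iterations; amplitude columns are scaled to
    unit L2 norm at the end (scale folded into the weights).
    """
    best: PatternModel | None = None
    for r in range(max(1, n_restarts)):
        model = _fit_once(X, gene_ids, k, seed + 7919 * r, n_iter, tol)
        if best is None or model.objective < best.objective:
            best = model
    return best


def _fit_once(X: np.ndarray, gene_ids: list[str], k: int, seed: int,
              n_iter: int, tol: float) -> PatternModel:
    X = np.asarray(X, dtype=float)
    if (X < 0).any():
        raise ValueError("NMF input must be non-negative")
    n_genes, n_cells = X.shape
    if not 0 < k < min(n_genes, n_cells):
        raise ValueError("k must satisfy 0 < k < min(genes, cells)")
    rng = np.random.default_rng(seed)
    scale = np.sqrt(X.mean() / k)
    A = rng.uniform(0.0, 1.0, (n_genes, k)) * scale + _EPS
    W = rng.uniform(0.0, 1.0, (k, n_cells)) * scale + _EPS

    def objective() -> float:
        return float(np.linalg.norm(X - A @ W) ** 2)

    prev = objective()
    it = 0
    for it in range(1, n_iter + 1):
        W *= (A.T @ X) / (A.T @ A @ W + _EPS)
        A *= (X @ W.T) / (A @ (W @ W.T) + _EPS)
        if it % 10 == 0:
            cur = objective()
            if cur > prev * (1 + 1e-8) + 1e-10:
                raise AssertionError("NMF objective increased")
            if prev > 0 and (prev - cur) / prev < tol:
                prev = cur
                break
            prev = cur
    norms = np.linalg.norm(A, axis=0)
    norms[norms == 0] = 1.0
    A = A / norms
    W = W * norms[:, None]
    return PatternModel(A, W, k, list(gene_ids), it, objective(), seed)


def project_patterns(model: PatternModel, Y: np.ndarray,
                     gene_ids: list[str], meta: CellMetadata
                     ) -> tuple[np.ndarray, pd.DataFrame]:
    """Project target cells onto the model's amplitudes by per-cell NNLS,
    then correlate pattern weights with cell-type indicators.

    Genes missing from the target are dropped from both sides; fewer than
    50% shared genes is an error.
    """
    shared = [g for g in model.gene_ids if g in set(gene_ids)]
    if len(shared) < 0.5 * len(model.gene_ids):
        raise ValueError("fewer than 50% of model genes present in target")
    model_rows = {g: i for i, g in enumerate(model.gene_ids)}
    target_rows = {g: i for i, g in enumerate(gene_ids)}
    A = model.amplitude[[model_rows[g] for g in shared]]
    Ysub = np.asarray(Y, dtype=float)[[target_rows[g] for g in shared]]

    n_cells = Ysub.shape[1]
    W = np.zeros((model.k, n_cells))
    for c in range(n_cells):
        col = Ysub[:, c]
        if col.max() == 0:
            continue  # all-zero cell -> zero weights
        W[:, c], _ = scipy.optimize.nnls(A, col)

    types = meta.table["cell_type"].to_numpy()
    cts = sorted(set(types))
    corr = np.zeros((model.k, len(cts)))
    for j, ct in enumerate(cts):
        ind = (types == ct).astype(float)
        ind = ind - ind.mean()
        denom_i = np.linalg.norm(ind)
        for p in range(model.k):
            w = W[p] - W[p].mean()
            denom = np.linalg.norm(w) * denom_i
            corr[p, j] = float(w @ ind / denom) if denom > 0 else 0.0
    corr_df = pd.DataFrame(corr, columns=cts,
                           index=[f"pattern{i + 1}" for i in range(model.k)])
    return W, corr_df


def project_cohort(model: PatternModel,
                   counts: dict[str, CountMatrix],
                   metadata: dict[str, CellMetadata],
                   log_normalize: bool = False) -> ProjectionResult:
    """Project every species onto the model, on the same scale the model
    was fitted on."""
    weights, corrs = {}, {}
    for sp in sorted(counts):
        cm = counts[sp]
        Y = lognormalize(cm) if log_normalize else cm.dense().astype(float)
        W, corr = project_patterns(model, Y, list(cm.feature_ids),
                                   metadata[sp])
        weights[sp] = W
        corrs[sp] = corr
    return ProjectionResult(weights, corrs)


def match_patterns(fitted: np.ndarray, planted: np.ndarray
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Optimal one-to-one pattern matching by cosine similarity (Hungarian);
    returns (assignment of planted -> fitted column, cosine per planted)."""
    fa = fitted / np.maximum(np.linalg.norm(fitted, axis=0), _EPS)
    pa = planted / np.maximum(np.linalg.norm(planted, axis=0), _EPS)
    sim = pa.T @ fa
    rows, cols = scipy.optimize.linear_sum_assignment(-sim)
    return cols, sim[rows, cols]
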