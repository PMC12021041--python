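"""Cell/gene quality-control filters and library-size normalization.

QC removes cells with fewer than 200 detected genes or more than 30%
mitochondrial counts, then genes detected in fewer than 3 remaining cells.
Normalization divides by the cell's total count, multiplies by a scale
factor (default 1e4) and takes log1p — the standard log-normalization.
"""

from __future__ import annotations

import logging

import numpy as np

from .types import CountMatrix, NormalizedMatrix

log = logging.getLogger(__name__)


def qc_filter(
    counts: CountMatrix,
    mito_genes: list[str] | None = None,
    min_genes: int = 200,
    max_mito_frac: float = 0.30,
    min_cells_per_gene: int = 3,
) -> CountMatrix:
    """Filter low-quality cells, then sparsely detected genes.

    A cell is kept iff it has >= ``min_genes`` detected genes and a
    mitochondrial count fraction <= ``max_mito_frac`` (strictly more than
    the threshold is removed). Genes detected in fewer than
    ``min_cells_per_gene`` of the remaining cells are then dropped.
    Retained order is preserved.
    """
    mito_genes = mito_genes or []
    unknown = set(mito_genes) - set(counts.genes)
    if unknown:
        raise ValueError(f"mito genes not in gene universe: {sorted(unknown)[:5]}")

    X = counts.counts
    detected = (X > 0).sum(axis=1).A1
    totals = np.asarray(X.sum(axis=1)).ravel()
    mito_idx = [counts.genes.index(g) for g in mito_genes]
    mito_counts = (
        np.asarray(X[:, mito_idx].sum(axis=1)).ravel() if mito_idx else np.zeros(len(counts.cells))
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(totals > 0, mito_counts / np.maximum(totals, 1), 0.0)

    cell_mask = (detected >= min_genes) & (mito_frac <= max_mito_frac)
    if not cell_mask.any():
        raise ValueError("empty matrix after QC: all cells removed")
    kept = counts.subset(cell_mask, None)

    gene_cells = (kept.counts > 0).sum(axis=0).A1
    gene_mask = gene_cells >= min_cells_per_gene
    out = kept.subset(None, gene_mask)
    log.info(
        "QC kept %d/%d cells and %d/%d genes",
        len(out.cells), len(counts.cells), len(out.genes), len(counts.genes),
    )
    return out


def lognormalize(counts: CountMatrix, scale_factor: float = 1e4) -> NormalizedMatrix:
    """value(c,g) = ln(1 + count(c,g) * scale_factor / total(c))."""
    totals = np.asarray(counts.counts.sum(axis=1)).ravel().astype(float)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(f"all-zero cell: {counts.cells[zero[0]]!r}")
    dense = counts.counts.toarray().astype(float)
    values = np.log1p(dense * (scale_factor / totals[:, None]))
    return NormalizedMatrix(list(counts.cells), list(counts.genes), values, scale_factor)
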