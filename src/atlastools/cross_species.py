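"""Cross-study / cross-species cell-type comparison.

Highly variable genes are picked by variance-stabilizing-transform-style
standardized variance; cell-type replicability across studies is the
neighbor-voting AUROC (each test cell votes with its mean Spearman affinity
to a reference type's cells, and the AUROC asks whether cells of the target
type receive higher votes); cell-type profiles are compared across species
with Spearman correlation over the HVGs; trees are plain agglomerative
clusters; marker genes pass p < 0.05 and |log2FC| > 0.25.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.stats as ss

from .types import CountMatrix, NormalizedMatrix

log = logging.getLogger(__name__)


def select_hvgs(counts: CountMatrix, n: int = 2000, clip: float | None = None) -> list[str]:
    """Top-n genes by standardized variance.

    A degree-2 polynomial of log10(variance) on log10(mean) is fit over
    genes with positive mean; each gene's counts are standardized by the
    predicted sd, clipped at sqrt(n_cells), and genes are ranked by the
    variance of the clipped values.
    """
    X = counts.counts.toarray().astype(float)
    n_cells = X.shape[0]
    if n_cells < 2:
        raise ValueError("need >= 2 cells")
    mean = X.mean(axis=0)
    var = X.var(axis=0, ddof=1)
    positive = mean > 0
    usable = positive & (var > 0)
    if positive.sum() < n:
        log.warning("only %d genes with positive mean; returning all", int(positive.sum()))

    coef = np.polyfit(np.log10(mean[usable]), np.log10(var[usable]), deg=2)
    pred_sd = np.sqrt(10 ** np.polyval(coef, np.log10(mean[positive])))
    clip_at = np.sqrt(n_cells) if clip is None else clip

    Z = (X[:, positive] - mean[positive]) / pred_sd
    Z = np.clip(Z, -clip_at, clip_at)
    std_var = Z.var(axis=0, ddof=1)

    genes = np.asarray(counts.genes)[positive]
    order = np.argsort(-std_var, kind="stable")
    return genes[order][: min(n, len(genes))].tolist()


def _rank_rows(values: np.ndarray) -> np.ndarray:
    """Average ranks within each row (per-cell rank standardization)."""
    return np.apply_along_axis(ss.rankdata, 1, values)


def neighbor_voting_auroc(
    expr: NormalizedMatrix | pd.DataFrame,
    annotation: pd.DataFrame,
    hvgs: list[str],
) -> pd.DataFrame:
    """AUROC matrix over (study, cell_type) pairs.

    Rows index the reference (voting) type, columns the target (voted)
    type; votes only cross studies, so same-study blocks are NA. Requires
    >= 2 studies and >= 2 cell types per study (a single-type study yields
    NA with a warning).
    """
    df = expr.to_frame() if isinstance(expr, NormalizedMatrix) else expr
    ann = annotation.loc[df.index]
    if ann["study"].nunique() < 2:
        raise ValueError("need >= 2 studies for neighbor voting")
    usable = [g for g in hvgs if g in df.columns]
    ranks = _rank_rows(df[usable].to_numpy(float))
    affinity = np.corrcoef(ranks)  # Spearman across hvgs

    studies = ann["study"].to_numpy()
    types = ann["cell_type"].to_numpy()
    pairs = sorted(set(zip(studies, types)))
    index = pd.MultiIndex.from_tuples(pairs, names=["study", "cell_type"])
    out = pd.DataFrame(np.nan, index=index, columns=index)

    for s2 in np.unique(studies):
        mask2 = studies == s2
        target_types = np.unique(types[mask2])
        if len(target_types) < 2:
            log.warning("study %r has a single cell type; AUROC undefined", s2)
            continue
        for s1, r in pairs:
            if s1 == s2:
                continue
            ref_mask = (studies == s1) & (types == r)
            votes = affinity[np.ix_(mask2, ref_mask)].mean(axis=1)
            vote_ranks = ss.rankdata(votes)  # average ranks count ties 1/2
            for t in target_types:
                pos = types[mask2] == t
                n_pos, n_neg = int(pos.sum()), int((~pos).sum())
                auroc = (vote_ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
                out.loc[(s1, r), (s2, t)] = auroc
    return out


def symmetrize_auroc(auroc: pd.DataFrame) -> pd.DataFrame:
    """Mean of the matrix and its transpose, ignoring NA on one side."""
    a = auroc.to_numpy(float)
    stack = np.stack([a, a.T])
    mask = np.isnan(stack)
    both_nan = mask.all(axis=0)
    sym = np.where(both_nan, np.nan, np.nansum(np.where(mask, 0.0, stack), axis=0)
                   / np.maximum((~mask).sum(axis=0), 1))
    return pd.DataFrame(sym, index=auroc.index, columns=auroc.columns)


def celltype_spearman(
    expr: NormalizedMatrix | pd.DataFrame,
    annotation: pd.DataFrame,
    hvgs: list[str],
    species_pair: tuple[str, str],
) -> pd.DataFrame:
    """Spearman rho between the two species' per-type mean expression
    vectors over the HVGs; types absent in one species get NA."""
    df = expr.to_frame() if isinstance(expr, NormalizedMatrix) else expr
    ann = annotation.loc[df.index]
    usable = [g for g in hvgs if g in df.columns]
    s1, s2 = species_pair
    rows = []
    all_types = sorted(ann["cell_type"].unique())
    for t in all_types:
        m1 = (ann["species"] == s1) & (ann["cell_type"] == t)
        m2 = (ann["species"] == s2) & (ann["cell_type"] == t)
        if not (m1.any() and m2.any()):
            rows.append({"cell_type": t, "rho": np.nan, "n_genes": len(usable)})
            continue
        p1 = df.loc[m1.to_numpy(), usable].mean(axis=0)
        p2 = df.loc[m2.to_numpy(), usable].mean(axis=0)
        rho = ss.spearmanr(p1, p2).statistic
        rows.append({"cell_type": t, "rho": float(rho), "n_genes": len(usable)})
    return pd.DataFrame(rows)


def hierarchical_tree(
    dist: pd.DataFrame,
    linkage: str = "average",
    tol: float = 1e-8,
):
    """Agglomerative tree on a square symmetric distance matrix.

    Returns (scipy linkage matrix, Newick string with branch lengths).
    Deterministic for a fixed input order (ties merge the lowest-index
    pair, scipy's convention).
    """
    D = dist.to_numpy(float)
    if D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if np.abs(D - D.T).max() > tol:
        raise ValueError("distance matrix is asymmetric beyond tolerance")
    if (D < -tol).any():
        raise ValueError("distances must be non-negative")
    D = (D + D.T) / 2
    np.fill_diagonal(D, 0.0)
    condensed = D[np.triu_indices_from(D, k=1)]
    if linkage not in {"average", "ward", "complete"}:
        raise ValueError(f"unsupported linkage: {linkage!r}")
    Z = sch.linkage(condensed, method=linkage)
    labels = [str(x) for x in dist.index]
    return Z, to_newick(Z, labels)


def to_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Serialize a scipy linkage matrix to Newick with branch lengths."""
    tree = sch.to_tree(Z)

    def walk(node, parent_height: float) -> str:
        length = parent_height - (0.0 if node.is_leaf() else node.dist)
        if node.is_leaf():
            length = parent_height
            return f"{labels[node.id]}:{length:.10g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.10g}"

    inner = f"({walk(tree.left, tree.dist)},{walk(tree.right, tree.dist)});"
    return inner


def find_markers(
    expr: NormalizedMatrix | pd.DataFrame,
    annotation: pd.DataFrame,
    target_type: str,
    alpha: float = 0.05,
    log2fc_min: float = 0.25,
    eps: float = 1e-9,
) -> pd.DataFrame:
    """Wilcoxon rank-sum markers of ``target_type`` against all other cells.

    log2FC compares group means on the expm1 (de-logged) scale with
    pseudocount ``eps``; a gene passes iff p < alpha and |log2FC| >
    log2fc_min, both strict.
    """
    df = expr.to_frame() if isinstance(expr, NormalizedMatrix) else expr
    ann = annotation.loc[df.index]
    in_mask = (ann["cell_type"] == target_type).to_numpy()
    if in_mask.sum() < 3 or (~in_mask).sum() < 3:
        raise ValueError("target type and complement each need >= 3 cells")
    X = df.to_numpy(float)
    mean_in = np.expm1(X[in_mask]).mean(axis=0)
    mean_out = np.expm1(X[~in_mask]).mean(axis=0)
    log2fc = np.log2((mean_in + eps) / (mean_out + eps))
    pvals = np.ones(X.shape[1])
    for j in range(X.shape[1]):
        a, b = X[in_mask, j], X[~in_mask, j]
        if np.all(a == a[0]) and np.all(b == a[0]):
            pvals[j] = 1.0
            continue
        pvals[j] = ss.mannwhitneyu(a, b, alternative="two-sided").pvalue
    out = pd.DataFrame(
        {
            "gene": df.columns,
            "cell_type": target_type,
            "log2fc": log2fc,
            "p_value": pvals,
        }
    )
    out["passes"] = is_marker(out["p_value"], out["log2fc"], alpha, log2fc_min)
    return out


def map_orthologs(
    expr: NormalizedMatrix | pd.DataFrame, mapping: dict[str, str]
) -> pd.DataFrame:
    """Rename genes to their orthologs, dropping unmapped genes and any
    target symbol hit more than once (ambiguous orthology)."""
    df = expr.to_frame() if isinstance(expr, NormalizedMatrix) else expr
    keep = [g for g in df.columns if g in mapping]
    out = df[keep].rename(columns=mapping)
    dup = out.columns[out.columns.duplicated(keep=False)]
    if len(dup):
        log.warning("%d ambiguous ortholog targets dropped", dup.nunique())
        out = out.loc[:, ~out.columns.isin(set(dup))]
    return out


def is_marker(p_value, log2fc, alpha: float = 0.05, log2fc_min: float = 0.25):
    """Marker rule: p < alpha AND |log2FC| > log2fc_min, both strict."""
    return (np.asarray(p_value) < alpha) & (np.abs(np.asarray(log2fc)) > log2fc_min)
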