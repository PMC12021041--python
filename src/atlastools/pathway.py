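"""Metabolic pathway activity per cell type with a permutation null.

A gene's relative expression in a cell type is its mean expression there
divided by the average of its per-type means (1 = average across types);
means are taken on the linear expression scale (log-normalized input is
de-logged first).
Pathway activity is the weighted mean of member-gene relative expressions,
each gene down-weighted by the number of pathways it belongs to. Genes with
zero overall mean, or detected in fewer than 25% of cells in every type,
are excluded. Significance of elevated activity comes from recomputing the
score under random permutations of the cell-type labels.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .types import GeneSetCollection, NormalizedMatrix

log = logging.getLogger(__name__)


def _dense(expr) -> pd.DataFrame:
    """Expression on the linear scale.

    A NormalizedMatrix is log-scale by definition and is de-logged with
    expm1 (relative expression is a ratio of mean expression levels, not of
    log levels); a plain DataFrame is used as given.
    """
    if isinstance(expr, NormalizedMatrix):
        return pd.DataFrame(np.expm1(expr.values), index=expr.cells, columns=expr.genes)
    return expr


def _relative_expression_arrays(
    X: np.ndarray, detected: np.ndarray, type_codes: np.ndarray, n_types: int,
    detection_min_frac: float,
) -> np.ndarray:
    """Gene x type relative expression with excluded genes as NaN."""
    onehot = np.zeros((X.shape[0], n_types))
    onehot[np.arange(X.shape[0]), type_codes] = 1.0
    counts = onehot.sum(axis=0)
    means = (onehot.T @ X) / counts[:, None]          # type x gene
    det_frac = (onehot.T @ detected) / counts[:, None]

    overall = means.mean(axis=0)
    keep = (overall > 0) & (det_frac >= detection_min_frac).any(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = means / overall[None, :]
    rel[:, ~keep] = np.nan
    return rel.T  # gene x type


def relative_expression(
    expr: NormalizedMatrix | pd.DataFrame,
    annotation: pd.DataFrame,
    detection_min_frac: float = 0.25,
) -> pd.DataFrame:
    """Genes x cell types matrix of relative expression.

    A gene is excluded (NaN in all types) when its overall mean is zero or
    it is detected (expression > 0) in fewer than ``detection_min_frac`` of
    the cells of every cell type.
    """
    df = _dense(expr)
    ann = annotation.loc[df.index]
    types = pd.Categorical(ann["cell_type"])
    if len(types.categories) < 2:
        log.warning("single cell type: relative expression is identically 1")
    rel = _relative_expression_arrays(
        df.to_numpy(float), (df.to_numpy(float) > 0).astype(float),
        types.codes.astype(int), len(types.categories), detection_min_frac,
    )
    return pd.DataFrame(rel, index=df.columns, columns=list(types.categories))


def pathway_score(
    rel: pd.DataFrame,
    pathways: GeneSetCollection,
    weighting: str = "inverse_pathway_count",
) -> pd.DataFrame:
    """Pathways x cell types weighted mean relative expression.

    Weights are 1/(number of pathways containing the gene) by default, or
    uniform. Pathways with no usable (non-NaN) gene score NA with a warning.
    """
    if weighting not in {"inverse_pathway_count", "uniform"}:
        raise ValueError(f"unknown weighting: {weighting!r}")
    mult = pathways.gene_multiplicity()
    out = pd.DataFrame(index=pathways.names(), columns=rel.columns, dtype=float)
    for name, members in pathways.items():
        genes = [g for g in members if g in rel.index and not rel.loc[g].isna().all()]
        if not genes:
            log.warning("pathway %r has no usable genes; scored NA", name)
            out.loc[name] = np.nan
            continue
        w = np.array(
            [1.0 / mult[g] if weighting == "inverse_pathway_count" else 1.0 for g in genes]
        )
        vals = rel.loc[genes].to_numpy(float)
        out.loc[name] = (w[:, None] * vals).sum(axis=0) / w.sum()
    return out


def permutation_pvalue(
    expr: NormalizedMatrix | pd.DataFrame,
    annotation: pd.DataFrame,
    pathways: GeneSetCollection,
    n_perm: int = 1000,
    seed: int = 0,
    detection_min_frac: float = 0.25,
    weighting: str = "inverse_pathway_count",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One-sided permutation p-values for elevated pathway activity.

    Cell-type labels are shuffled globally over cells; the full score
    (including the detection filter) is recomputed per permutation and
    p(P,t) = (1 + #{permuted >= observed}) / (n_perm + 1). Returns
    (observed scores, p-values); both deterministic given ``seed``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    df = _dense(expr)
    ann = annotation.loc[df.index]
    types = pd.Categorical(ann["cell_type"])
    codes = types.codes.astype(int)
    n_types = len(types.categories)
    X = df.to_numpy(float)
    detected = (X > 0).astype(float)

    def score_for(codes_perm: np.ndarray) -> pd.DataFrame:
        rel = _relative_expression_arrays(X, detected, codes_perm, n_types, detection_min_frac)
        rel_df = pd.DataFrame(rel, index=df.columns, columns=list(types.categories))
        return pathway_score(rel_df, pathways, weighting=weighting)

    observed = score_for(codes)
    rng = np.random.default_rng(seed)
    exceed = np.zeros(observed.shape)
    obs = observed.to_numpy(float)
    for _ in range(n_perm):
        perm = rng.permutation(codes)
        s = score_for(perm).to_numpy(float)
        with np.errstate(invalid="ignore"):
            exceed += (s >= obs).astype(float)
    pvals = (1.0 + exceed) / (n_perm + 1.0)
    pvals = pd.DataFrame(pvals, index=observed.index, columns=observed.columns)
    pvals[observed.isna()] = np.nan
    return observed, pvals
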