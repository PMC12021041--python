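"""Rank-based AUC gene-set activity per cell and the cycling index.

The per-cell score is the area under the set-recovery curve over the
top-ranked fraction of that cell's genes, normalized by the maximal
achievable area — the AUCell statistic. Cells are classified cycling or
noncycling by comparing the two scores, and the per-type cycling index is
log2((n_cycling+1)/(n_noncycling+1)).
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from .types import GeneSetCollection, NormalizedMatrix

log = logging.getLogger(__name__)


def aucell_score(
    expr: NormalizedMatrix | pd.DataFrame,
    sets: GeneSetCollection,
    top_fraction: float = 0.05,
) -> pd.DataFrame:
    """Cells x sets activity in [0,1].

    Per cell, genes are ranked by decreasing expression (ties broken by
    gene-universe order, deterministic); with k = floor(top_fraction * G)
    the raw area is sum_{i=1..k} H(i), H(i) = number of set genes at rank
    <= i, normalized by the area when min(|S|, k) set genes occupy the top
    ranks. A set with no gene in the universe scores NA with a warning.
    """
    df = expr.to_frame() if isinstance(expr, NormalizedMatrix) else expr
    n_cells, G = df.shape
    if G == 0:
        raise ValueError("empty gene universe")
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must lie in (0, 1]")
    k = max(1, math.floor(top_fraction * G))

    values = df.to_numpy()
    # stable argsort on -expression keeps gene-universe order among ties
    order = np.argsort(-values, axis=1, kind="stable")
    rank = np.empty_like(order)
    rows = np.arange(n_cells)[:, None]
    rank[rows, order] = np.arange(1, G + 1)[None, :]

    gene_pos = {g: i for i, g in enumerate(df.columns)}
    out = pd.DataFrame(index=df.index, columns=sets.names(), dtype=float)
    for name, members in sets.items():
        idx = [gene_pos[g] for g in members if g in gene_pos]
        if not idx:
            log.warning("gene set %r has no gene in the universe; scored NA", name)
            out[name] = np.nan
            continue
        s = min(len(idx), k)
        max_raw = s * (s + 1) // 2 + (k - s) * s
        r = rank[:, idx]
        raw = np.where(r <= k, k - r + 1, 0).sum(axis=1)
        out[name] = raw / max_raw
    return out


def classify_cycling(
    activity: pd.DataFrame,
    cycling_set: str = "cycling",
    noncycling_set: str = "noncycling",
) -> pd.Series:
    """Label each cell cycling iff its cycling score strictly exceeds the
    noncycling score; exact ties go to noncycling (conservative)."""
    for name in (cycling_set, noncycling_set):
        if name not in activity.columns:
            raise ValueError(f"missing set in activity matrix: {name!r}")
    cyc = activity[cycling_set] > activity[noncycling_set]
    return pd.Series(np.where(cyc, "cycling", "noncycling"), index=activity.index, name="label")


def cycling_index(labels: pd.Series, annotation: pd.DataFrame) -> pd.DataFrame:
    """Per cell type: n_cycling, n_noncycling, and the log2 ratio with
    pseudocount 1."""
    missing = set(labels.index) - set(annotation.index)
    if missing:
        raise ValueError(f"{len(missing)} labeled cells missing from annotation")
    types = annotation.loc[labels.index, "cell_type"]
    rows = []
    for t, group in labels.groupby(types, sort=True):
        n_cyc = int((group == "cycling").sum())
        n_non = int((group == "noncycling").sum())
        if n_cyc + n_non == 0:
            raise ValueError(f"cell type {t!r} has zero cells")
        rows.append(
            {
                "cell_type": t,
                "n_cycling": n_cyc,
                "n_noncycling": n_non,
                "index": math.log2((n_cyc + 1) / (n_non + 1)),
            }
        )
    return pd.DataFrame(rows)
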