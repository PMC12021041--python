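"""TF co-activity modules: Pearson correlation of regulon activities, the
connectivity specificity index (CSI), and Ward-clustered modules.

CSI(A,B) is the fraction of all regulons C whose correlation with both A
and B is strictly below PCC(A,B) — high when A and B correlate with each
other more specifically than with the rest of the network. Modules come
from Ward clustering of the CSI matrix after sub-threshold entries
(default CSI < 0.9) are floored to zero.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from sklearn.metrics import silhouette_score

log = logging.getLogger(__name__)


def regulon_pcc(activity: pd.DataFrame) -> pd.DataFrame:
    """Regulons x regulons Pearson correlation of per-cell activities.

    Zero-variance regulons get NA rows/columns with a warning.
    """
    if activity.shape[0] < 3:
        raise ValueError("need >= 3 cells to correlate regulon activities")
    X = activity.to_numpy(float)
    sd = X.std(axis=0)
    flat = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        pcc = np.corrcoef(X, rowvar=False)
    pcc = np.atleast_2d(pcc)
    pcc[flat, :] = np.nan
    pcc[:, flat] = np.nan
    np.fill_diagonal(pcc, np.where(flat, np.nan, 1.0))
    if flat.any():
        log.warning("%d zero-variance regulons set to NA", int(flat.sum()))
    return pd.DataFrame(pcc, index=activity.columns, columns=activity.columns)


def compute_csi(pcc: pd.DataFrame, denominator: str = "n") -> pd.DataFrame:
    """CSI(A,B) = #{C : PCC(C,A) < PCC(A,B) and PCC(C,B) < PCC(A,B)} / N.

    Counts run over all N regulons including A and B themselves; with unit
    self-correlation neither is ever counted, so the choice of denominator
    only rescales (set denominator="n-2" for the excluded-pair scale).
    Strict inequalities; CSI(A,A) = 1 by convention.
    """
    P = pcc.to_numpy(float)
    n = P.shape[0]
    if P.shape[0] != P.shape[1]:
        raise ValueError("PCC matrix must be square")
    if denominator not in {"n", "n-2"}:
        raise ValueError("denominator must be 'n' or 'n-2'")
    denom = n if denominator == "n" else max(n - 2, 1)
    csi = np.empty((n, n))
    for a in range(n):
        # below[c, b] = PCC(c,a) < PCC(a,b);  count C with both below
        below_a = P[:, a][:, None] < P[a, :][None, :]
        below_b = P < P[a, :][None, :]
        csi[a, :] = np.logical_and(below_a, below_b).sum(axis=0) / denom
    np.fill_diagonal(csi, 1.0)
    return pd.DataFrame(csi, index=pcc.index, columns=pcc.columns)


def cluster_modules(
    csi: pd.DataFrame,
    csi_floor: float = 0.9,
    n_modules: int | str = "auto",
):
    """Ward-cluster regulons on the floored CSI matrix.

    Entries below ``csi_floor`` are set to 0, Ward agglomeration runs on
    Euclidean distances between the floored rows, and the tree is cut at
    ``n_modules`` clusters ("auto" maximizes mean silhouette over
    2..min(12, N-1)). Returns (assignment Series with module ids 1..M,
    linkage matrix).
    """
    n = csi.shape[0]
    if n < 3:
        raise ValueError("need >= 3 regulons to cluster")
    X = csi.to_numpy(float).copy()
    X[X < csi_floor] = 0.0
    Z = sch.linkage(X, method="ward")

    if n_modules == "auto":
        best_k, best_s = 2, -np.inf
        for k in range(2, min(12, n - 1) + 1):
            labels = sch.fcluster(Z, k, criterion="maxclust")
            if len(np.unique(labels)) < 2:
                continue
            try:
                s = silhouette_score(X, labels)
            except ValueError:
                continue
            if s > best_s + 1e-12:
                best_k, best_s = k, s
        if not np.isfinite(best_s) or best_s <= 1e-9:
            log.warning("degenerate CSI matrix: silhouette ~ 0, returning 2 clusters")
        k = best_k
    else:
        k = int(n_modules)
    labels = sch.fcluster(Z, k, criterion="maxclust")
    assignment = pd.Series(labels, index=csi.index, name="module")
    return assignment, Z
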