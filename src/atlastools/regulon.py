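"""Regulon specificity scores (RSS), their Z-normalization (RSSZ), and the
specific-TF selection rule.

RSS(regulon, group) = 1 - sqrt(JSD(p, q)) where p is the regulon's activity
normalized to a distribution over cells, q the uniform distribution over the
group's cells, and JSD the Jensen-Shannon divergence with base-2 entropies
(so JSD and RSS lie in [0,1]). RSSZ standardizes RSS across regulons within
each group; a TF is called group-specific when its mean activity in the
group exceeds 0.1 and its RSSZ exceeds 1.0 (both strict).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.spatial.distance import jensenshannon

log = logging.getLogger(__name__)


def compute_rss(activity: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Regulons x groups RSS matrix.

    ``activity`` is cells x regulons with non-negative entries; ``groups``
    labels every cell. Regulons with all-zero activity get NA.
    """
    groups = pd.Series(groups).reindex(activity.index)
    if groups.isna().any():
        raise ValueError("every cell must carry a group label")
    if (activity.to_numpy() < 0).any():
        raise ValueError("activity must be non-negative")

    group_names = sorted(groups.unique())
    out = pd.DataFrame(index=activity.columns, columns=group_names, dtype=float)
    totals = activity.sum(axis=0)
    for g in group_names:
        q = (groups == g).to_numpy(float)
        q /= q.sum()
        for r in activity.columns:
            if totals[r] == 0:
                out.loc[r, g] = np.nan
                continue
            p = activity[r].to_numpy(float) / totals[r]
            # jensenshannon returns sqrt(JSD); base 2 keeps it in [0,1]
            out.loc[r, g] = 1.0 - jensenshannon(p, q, base=2)
    if out.isna().any().any():
        log.warning("regulons with all-zero activity scored NA")
    return out


def rss_zscore(rss: pd.DataFrame) -> pd.DataFrame:
    """Z-score RSS across regulons within each group column (sample sd).

    A zero-sd column yields all zeros with a warning.
    """
    if rss.shape[0] < 2:
        raise ValueError("need >= 2 regulons to Z-score")
    out = pd.DataFrame(index=rss.index, columns=rss.columns, dtype=float)
    for g in rss.columns:
        col = rss[g].astype(float)
        sd = col.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            log.warning("group %r has constant RSS; RSSZ set to 0", g)
            out[g] = 0.0
        else:
            out[g] = (col - col.mean()) / sd
    return out


def mean_activity_by_group(activity: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Regulons x groups mean activity (the per-group AUCell score)."""
    groups = pd.Series(groups).reindex(activity.index)
    return activity.groupby(groups, sort=True).mean().T


def select_specific_tfs(
    rssz: pd.DataFrame,
    mean_activity: pd.DataFrame,
    rss: pd.DataFrame | None = None,
    activity_min: float = 0.1,
    rssz_min: float = 1.0,
) -> pd.DataFrame:
    """Long-format table flagging (regulon, group) pairs with
    mean_activity > activity_min AND rssz > rssz_min, both strict."""
    if not rssz.index.equals(mean_activity.index) or not rssz.columns.equals(
        mean_activity.columns
    ):
        raise ValueError("rssz and mean_activity must share regulon/group keys")
    rows = []
    for r in rssz.index:
        for g in rssz.columns:
            z = rssz.loc[r, g]
            a = mean_activity.loc[r, g]
            rows.append(
                {
                    "regulon": r,
                    "group": g,
                    "rss": np.nan if rss is None else rss.loc[r, g],
                    "rssz": z,
                    "mean_activity": a,
                    "selected": bool((a > activity_min) and (z > rssz_min)),
                }
            )
    return pd.DataFrame(rows)
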