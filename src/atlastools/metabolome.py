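"""Multispecies metabolome statistics.

Covers the four downstream stages applied to a samples x metabolites
abundance table with species labels: (1) per-species tertile abundance
classes on min-max-normalized mean levels; (2) differential metabolites by
Welch t-test plus PLS-DA variable importance in projection (VIP), selected
at p < 0.05 and VIP > 1; (3) correlation-network metabolite modules via a
soft-thresholded adjacency, topological overlap, and an average-linkage
tree cut; (4) key metabolites by module membership (MM) and metabolite
significance (MS), both > 0.9 for the focal species.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.stats as ss

from .types import MetaboliteTable

log = logging.getLogger(__name__)


# ---------------------------------------------------------------- tertiles

def tertile_classes(table: MetaboliteTable, normalize: str = "per_species") -> pd.DataFrame:
    """High / intermediate / low abundance class per metabolite and species.

    Per species, metabolite means over replicates are min-max normalized to
    u in [0,1] and binned at thirds: low if u < 1/3, intermediate if
    1/3 <= u < 2/3, high if u >= 2/3. ``normalize="per_metabolite"``
    instead min-max scales each metabolite across species before binning.
    """
    if normalize not in {"per_species", "per_metabolite"}:
        raise ValueError(f"unknown normalization: {normalize!r}")
    means = table.data.groupby(table.species).mean()  # species x metabolites
    if normalize == "per_species":
        lo = means.min(axis=1)
        span = means.max(axis=1) - lo
        u = means.sub(lo, axis=0).div(span.replace(0, np.nan), axis=0)
    else:
        lo = means.min(axis=0)
        span = means.max(axis=0) - lo
        u = means.sub(lo, axis=1).div(span.replace(0, np.nan), axis=1)
    if u.isna().any().any():
        log.warning("constant profile: affected classes set to intermediate")

    rows = []
    for sp_name in means.index:
        for m in means.columns:
            val = u.loc[sp_name, m]
            if pd.isna(val):
                cls = "intermediate"
            elif val < 1 / 3:
                cls = "low"
            elif val < 2 / 3:
                cls = "intermediate"
            else:
                cls = "high"
            rows.append(
                {"metabolite": m, "species": sp_name, "normalized": val, "class": cls}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------- PLS VIP

def _nipals_pls1(X: np.ndarray, y: np.ndarray, n_components: int):
    """NIPALS PLS with a single response; returns (W, ssy) where W holds the
    unit x-weights per component and ssy the response variance explained."""
    Xa = X.copy()
    ya = y.astype(float).copy()
    p = X.shape[1]
    W = np.zeros((p, n_components))
    ssy = np.zeros(n_components)
    for a in range(n_components):
        w = Xa.T @ ya
        norm = np.linalg.norm(w)
        if norm < 1e-12:
            W = W[:, :a]
            ssy = ssy[:a]
            break
        w /= norm
        t = Xa @ w
        tt = t @ t
        if tt < 1e-12:
            W = W[:, :a]
            ssy = ssy[:a]
            break
        p_load = (Xa.T @ t) / tt
        q = (ya @ t) / tt
        Xa = Xa - np.outer(t, p_load)
        ya = ya - q * t
        W[:, a] = w
        ssy[a] = q * q * tt
    return W, ssy


def _autoscale(X: np.ndarray):
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    return (X - mean) / sd


def pls_vip(
    table: MetaboliteTable,
    contrast: tuple[str, str],
    n_components: int | str = "cv",
    max_components: int = 3,
) -> pd.Series:
    """Per-metabolite VIP from a two-class PLS-DA fit.

    Metabolites are autoscaled (zero-variance ones dropped with a warning,
    VIP = NaN); the response is +/-1 class coding, centered. VIP_j =
    sqrt(p * sum_a SSY_a (w_ja)^2 / sum_a SSY_a) with unit weight vectors,
    so mean(VIP^2) = 1 for every fit. ``n_components="cv"`` picks the
    component count (1..max_components) maximizing leave-one-out Q^2.
    """
    s1, s2 = contrast
    mask = table.species.isin([s1, s2]).to_numpy()
    if (table.species[mask] == s1).sum() < 3 or (table.species[mask] == s2).sum() < 3:
        raise ValueError("both species need >= 3 replicates")
    X_all = table.data.loc[mask].to_numpy(float)
    y = np.where(table.species[mask] == s1, 1.0, -1.0)
    y = y - y.mean()

    sd = X_all.std(axis=0, ddof=1)
    keep = sd > 0
    if (~keep).any():
        log.warning("%d zero-variance metabolites dropped before autoscaling", int((~keep).sum()))
    X = _autoscale(X_all[:, keep])
    p = X.shape[1]

    if n_components == "cv":
        best_a, best_q2 = 1, -np.inf
        press_denom = float(y @ y)
        for a in range(1, min(max_components, X.shape[0] - 1, p) + 1):
            press = 0.0
            for i in range(X.shape[0]):
                tr = np.ones(X.shape[0], bool)
                tr[i] = False
                Xi = X[tr] - X[tr].mean(axis=0)
                yi = y[tr] - y[tr].mean()
                W, ssy = _nipals_pls1(Xi, yi, a)
                # rebuild regression coefficients from the NIPALS factors
                beta = _pls_coefficients(Xi, yi, a)
                x0 = X[i] - X[tr].mean(axis=0)
                pred = x0 @ beta + y[tr].mean()
                press += (y[i] - pred) ** 2
            q2 = 1.0 - press / press_denom
            if q2 > best_q2 + 1e-12:
                best_a, best_q2 = a, q2
        a_use = best_a
    else:
        a_use = int(n_components)

    W, ssy = _nipals_pls1(X, y, a_use)
    if W.shape[1] == 0 or ssy.sum() <= 0:
        vip_kept = np.full(p, np.nan)
    else:
        vip_kept = np.sqrt(p * ((W ** 2) @ ssy) / ssy.sum())
    vip = np.full(X_all.shape[1], np.nan)
    vip[keep] = vip_kept
    return pd.Series(vip, index=table.data.columns, name="vip")


def _pls_coefficients(X: np.ndarray, y: np.ndarray, n_components: int) -> np.ndarray:
    """Regression coefficients of a NIPALS PLS1 fit (for CV prediction)."""
    Xa = X.copy()
    ya = y.copy()
    Ws, Ps, qs = [], [], []
    for _ in range(n_components):
        w = Xa.T @ ya
        norm = np.linalg.norm(w)
        if norm < 1e-12:
            break
        w /= norm
        t = Xa @ w
        tt = t @ t
        if tt < 1e-12:
            break
        p_load = (Xa.T @ t) / tt
        q = (ya @ t) / tt
        Xa = Xa - np.outer(t, p_load)
        ya = ya - q * t
        Ws.append(w)
        Ps.append(p_load)
        qs.append(q)
    if not Ws:
        return np.zeros(X.shape[1])
    Wm, Pm, qv = np.column_stack(Ws), np.column_stack(Ps), np.array(qs)
    return Wm @ np.linalg.solve(Pm.T @ Wm, qv)


def differential_metabolites(
    table: MetaboliteTable,
    contrast: tuple[str, str],
    alpha: float = 0.05,
    vip_min: float = 1.0,
    n_components: int | str = "cv",
) -> pd.DataFrame:
    """Welch t-test (log abundances) + VIP selection: p < alpha AND VIP > vip_min."""
    s1, s2 = contrast
    logab = np.log(table.data)
    a = logab.loc[(table.species == s1).to_numpy()]
    b = logab.loc[(table.species == s2).to_numpy()]
    t = ss.ttest_ind(a, b, axis=0, equal_var=False)
    vip = pls_vip(table, contrast, n_components=n_components)
    out = pd.DataFrame(
        {
            "metabolite": table.data.columns,
            "p_value": t.pvalue,
            "vip": vip.to_numpy(),
            "log2fc": (a.mean(axis=0) - b.mean(axis=0)).to_numpy() / np.log(2),
        }
    )
    out["selected"] = is_differential(out["p_value"], out["vip"], alpha, vip_min)
    return out


def is_differential(p_value, vip, alpha: float = 0.05, vip_min: float = 1.0):
    """Differential-metabolite rule: p < alpha AND VIP > vip_min, both strict."""
    return (np.asarray(p_value) < alpha) & (np.asarray(vip) > vip_min)


# ---------------------------------------------------------------- modules

@dataclass
class MetaboliteModuleResult:
    assignment: pd.Series            # metabolite -> module id (0 = unassigned)
    eigen: pd.DataFrame              # samples x modules
    membership: pd.Series            # MM per metabolite
    significance: pd.DataFrame       # metabolites x species MS
    linkage: np.ndarray
    tom: pd.DataFrame


def _tom_similarity(adj: np.ndarray) -> np.ndarray:
    """Topological overlap from an adjacency with zeroed diagonal."""
    a = adj.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    shared = a @ a
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (shared + a) / denom
    np.fill_diagonal(tom, 1.0)
    return tom


def metabolite_modules(
    table: MetaboliteTable,
    beta: int = 6,
    min_module_size: int = 3,
    cut_height: float = 0.25,
    log_transform: bool = True,
) -> MetaboliteModuleResult:
    """Correlation-network modules with eigen-metabolites.

    Abundances are log-transformed first (log-normal scale; disable with
    ``log_transform=False``). Adjacency |cor|^beta over samples, topological overlap, average-linkage
    tree on 1 - TOM, static cut at ``cut_height``; branches smaller than
    ``min_module_size`` land in module 0 ("unassigned"). Eigen-metabolite =
    first PC of the autoscaled module submatrix, oriented to correlate
    positively with the module mean profile.

    ``cut_height`` is measured down from the top of the dendrogram as a
    fraction of its merge-height range: the cut runs at
    h_max - cut_height * (h_max - h_min), so 0.25 severs only the topmost
    quarter of merges. The 1 - TOM scale rarely drops below ~0.5 even for
    tight modules, so an absolute cut would be meaningless across inputs.
    """
    data = np.log(table.data) if log_transform else table.data
    sd = data.std(axis=0, ddof=1)
    if (sd == 0).any():
        log.warning("%d constant metabolites dropped", int((sd == 0).sum()))
        data = data.loc[:, sd > 0]
    if data.shape[1] < 2 * min_module_size:
        raise ValueError("too few metabolites for module detection")
    if data.shape[0] < 4:
        raise ValueError("need >= 4 samples")

    corr = np.corrcoef(data.to_numpy(float), rowvar=False)
    adj = np.abs(corr) ** beta
    tom = _tom_similarity(adj)
    diss = 1.0 - tom
    np.fill_diagonal(diss, 0.0)
    Z = sch.linkage(diss[np.triu_indices_from(diss, k=1)], method="average")
    heights = Z[:, 2]
    threshold = heights.max() - cut_height * (heights.max() - heights.min())
    raw = sch.fcluster(Z, t=threshold, criterion="distance")

    sizes = pd.Series(raw).value_counts()
    module_of = {}
    next_id = 1
    for branch in sizes.index:
        if sizes[branch] >= min_module_size:
            module_of[branch] = next_id
            next_id += 1
        else:
            module_of[branch] = 0
    assignment = pd.Series(
        [module_of[b] for b in raw], index=data.columns, name="module"
    )

    scaled = (data - data.mean(axis=0)) / data.std(axis=0, ddof=1)
    eigens = {}
    for mod in sorted(set(assignment) - {0}):
        sub = scaled.loc[:, assignment == mod].to_numpy(float)
        u, s, vt = np.linalg.svd(sub, full_matrices=False)
        pc = u[:, 0] * s[0]
        if np.corrcoef(pc, sub.mean(axis=1))[0, 1] < 0:
            pc = -pc
        eigens[mod] = pc / np.sqrt(len(pc) - 1)  # unit-variance convention
    eigen = pd.DataFrame(eigens, index=data.index)

    mm = pd.Series(np.nan, index=data.columns, name="membership")
    for m in data.columns:
        mod = assignment[m]
        if mod != 0:
            mm[m] = abs(np.corrcoef(data[m], eigen[mod])[0, 1])

    species_names = sorted(table.species.unique())
    ms = pd.DataFrame(index=data.columns, columns=species_names, dtype=float)
    for sp_name in species_names:
        ind = (table.species == sp_name).to_numpy(float)
        for m in data.columns:
            ms.loc[m, sp_name] = abs(np.corrcoef(data[m], ind)[0, 1])

    return MetaboliteModuleResult(
        assignment=assignment,
        eigen=eigen,
        membership=mm,
        significance=ms,
        linkage=Z,
        tom=pd.DataFrame(tom, index=data.columns, columns=data.columns),
    )


def key_metabolites(
    modules: MetaboliteModuleResult,
    focal_species: str,
    mm_min: float = 0.9,
    ms_min: float = 0.9,
) -> pd.DataFrame:
    """Metabolites with MM > mm_min and MS > ms_min for the focal species,
    excluding the unassigned module."""
    if focal_species not in modules.significance.columns:
        raise ValueError(f"unknown species: {focal_species!r}")
    out = pd.DataFrame(
        {
            "metabolite": modules.assignment.index,
            "module": modules.assignment.to_numpy(),
            "mm": modules.membership.to_numpy(),
            "ms": modules.significance[focal_species].to_numpy(),
        }
    )
    out["key"] = (out["module"] != 0) & (out["mm"] > mm_min) & (out["ms"] > ms_min)
    return out


def module_species_association(
    modules: MetaboliteModuleResult, table: MetaboliteTable
) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum p of each module eigen-metabolite,
    focal species vs the rest (exact distribution for n <= 20)."""
    rows = []
    n_total = len(table.data)
    for mod in modules.eigen.columns:
        e = modules.eigen[mod]
        for sp_name in sorted(table.species.unique()):
            mask = (table.species == sp_name).to_numpy()
            if mask.sum() < 2 or (~mask).sum() < 2:
                raise ValueError("need >= 2 samples per group")
            a, b = e[mask], e[~mask]
            if a.nunique() == 1 and b.nunique() == 1 and a.iloc[0] == b.iloc[0]:
                p = 1.0
            else:
                method = "exact" if n_total <= 20 else "auto"
                p = ss.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue
            rows.append({"module": mod, "species": sp_name, "p_value": float(p)})
    return pd.DataFrame(rows)
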