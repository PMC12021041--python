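"""Validation scenarios: brute-force oracles and planted-truth recovery.

Each function runs a self-contained scenario — comparing an implementation
against an independent brute-force computation, evaluating a closed form,
measuring type-I error under a null generator, or measuring recovery of
planted structure — and returns the measured quantity. The test suite
asserts on these numbers and the reproduction script reports them.

The oracles here are deliberately naive (explicit loops, enumeration) and
share no code with the implementations they check.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import scipy.stats as ss
from sklearn.metrics import adjusted_rand_score

from . import (
    AtlasSimSpec,
    MetabolomeSimSpec,
    RegulonSimSpec,
    aucell_score,
    compute_csi,
    compute_rss,
    celltype_spearman,
    differential_metabolites,
    lognormalize,
    mean_activity_by_group,
    metabolite_modules,
    module_species_association,
    neighbor_voting_auroc,
    permutation_pvalue,
    regulon_pcc,
    rss_zscore,
    select_specific_tfs,
    simulate_counts,
    simulate_metabolome,
    simulate_regulon_activity,
)
from .modules import cluster_modules
from .types import GeneSetCollection, MetaboliteTable


# ------------------------------------------------------------------ oracles

def _aucell_step_curve(expr_row, set_idx, top_fraction):
    """Naive recovery-curve enumeration."""
    G = len(expr_row)
    k = max(1, math.floor(top_fraction * G))
    order = sorted(range(G), key=lambda i: (-expr_row[i], i))
    raw, hits = 0, 0
    for i in range(k):
        if order[i] in set_idx:
            hits += 1
        raw += hits
    s = min(len(set_idx), k)
    max_raw = sum(min(i + 1, s) for i in range(k))
    return raw / max_raw


def aucell_oracle_agreement(seed: int, n_instances: int = 100) -> float:
    """Fraction of random 20-gene instances where the rank-AUC score equals
    the step-curve enumeration exactly (to 1e-12)."""
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_instances):
        G = 20
        expr = rng.integers(0, 6, G).astype(float)
        idx = rng.choice(G, size=int(rng.integers(1, 8)), replace=False)
        frac = float(rng.uniform(0.1, 1.0))
        df = pd.DataFrame([expr], index=["c"], columns=[f"g{i}" for i in range(G)])
        got = aucell_score(df, GeneSetCollection({"S": [f"g{i}" for i in idx]}),
                           top_fraction=frac).iloc[0, 0]
        want = _aucell_step_curve(expr, set(idx), frac)
        agree += abs(got - want) < 1e-12
    return agree / n_instances


def csi_oracle_agreement(seed: int, n_matrices: int = 200) -> float:
    """Fraction of random PCC matrices (size <= 10) where the CSI matrix
    equals an exhaustive triple loop exactly."""
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_matrices):
        n = int(rng.integers(3, 11))
        M = rng.uniform(-1, 1, (n, n))
        P = (M + M.T) / 2
        np.fill_diagonal(P, 1.0)
        names = [f"r{i}" for i in range(n)]
        got = compute_csi(pd.DataFrame(P, index=names, columns=names)).to_numpy()
        want = np.zeros((n, n))
        for a in range(n):
            for b in range(n):
                if a == b:
                    want[a, b] = 1.0
                    continue
                count = 0
                for c in range(n):
                    if P[c, a] < P[a, b] and P[c, b] < P[a, b]:
                        count += 1
                want[a, b] = count / n
        agree += np.abs(got - want).max() < 1e-12
    return agree / n_matrices


def auroc_oracle_agreement(seed: int, n_instances: int = 50) -> float:
    """Fraction of random two-study instances (<= 8 cells per study) where
    neighbor-voting AUROC equals the exhaustive pairwise comparison."""
    rng = np.random.default_rng(seed)
    genes = [f"g{i}" for i in range(12)]
    agree = total = 0
    trials = 0
    while total < n_instances and trials < 10 * n_instances:
        trials += 1
        n1, n2 = int(rng.integers(4, 9)), int(rng.integers(4, 9))
        e1, e2 = rng.random((n1, 12)), rng.random((n2, 12))
        t1 = rng.choice(["A", "B"], n1)
        t2 = rng.choice(["A", "B"], n2)
        if len(set(t1)) < 2 or len(set(t2)) < 2:
            continue
        total += 1
        df = pd.DataFrame(np.vstack([e1, e2]), columns=genes,
                          index=[f"a{i}" for i in range(n1)] + [f"b{i}" for i in range(n2)])
        ann = pd.DataFrame({"cell_type": np.r_[t1, t2],
                            "study": ["S1"] * n1 + ["S2"] * n2}, index=df.index)
        auroc = neighbor_voting_auroc(df, ann, genes)
        r1 = np.apply_along_axis(ss.rankdata, 1, e1)
        r2 = np.apply_along_axis(ss.rankdata, 1, e2)
        aff = np.corrcoef(np.vstack([r1, r2]))[n1:, :n1]
        ok = True
        for ref in ("A", "B"):
            votes = aff[:, t1 == ref].mean(axis=1)
            for tgt in ("A", "B"):
                pos = votes[t2 == tgt]
                neg = votes[t2 != tgt]
                wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
                want = wins / (len(pos) * len(neg))
                if abs(auroc.loc[("S1", ref), ("S2", tgt)] - want) > 1e-12:
                    ok = False
        agree += ok
    return agree / total


# -------------------------------------------------------------- closed forms

def rss_uniform_half_indicator() -> float:
    """RSS of a uniform activity over 4 cells against a 2-cell group."""
    act = pd.DataFrame({"R": [1.0, 1.0, 1.0, 1.0]}, index=list("abcd"))
    groups = pd.Series(["g1", "g1", "g2", "g2"], index=list("abcd"))
    return float(compute_rss(act, groups).loc["R", "g1"])


def spearman_rank_example() -> float:
    """Spearman rho between per-type profiles with ranks (1..5), (2,1,3,5,4)."""
    genes = [f"g{i}" for i in range(5)]
    df = pd.DataFrame([[1, 2, 3, 4, 5], [2, 1, 3, 5, 4]],
                      index=["c1", "c2"], columns=genes, dtype=float)
    ann = pd.DataFrame({"cell_type": ["T", "T"], "species": ["sp1", "sp2"]}, index=df.index)
    return float(celltype_spearman(df, ann, genes, ("sp1", "sp2"))["rho"].iloc[0])


def wilcoxon_exact_separation_p() -> float:
    """One-sided exact rank-sum p for 5 fully separated samples vs 15."""
    from .metabolome import MetaboliteModuleResult

    eigen = pd.DataFrame({1: np.r_[np.arange(15.0), 100 + np.arange(5.0)]},
                         index=[f"s{i}" for i in range(20)])
    assignment = pd.Series([1] * 6, index=[f"m{i}" for i in range(6)])
    res = MetaboliteModuleResult(
        assignment=assignment, eigen=eigen,
        membership=pd.Series(1.0, index=assignment.index),
        significance=pd.DataFrame(), linkage=np.zeros((0, 4)), tom=pd.DataFrame(),
    )
    tab = MetaboliteTable(
        data=pd.DataFrame(np.ones((20, 6)) + 1e-3 * np.arange(20)[:, None],
                          index=eigen.index, columns=assignment.index),
        species=pd.Series(["other"] * 15 + ["focal"] * 5, index=eigen.index),
    )
    out = module_species_association(res, tab)
    two_sided = float(out[out.species == "focal"]["p_value"].iloc[0])
    return two_sided / 2  # the fully separated case doubles the one-sided tail


# --------------------------------------------------------------- calibration

def permutation_null_type1(seed: int, n_pathways: int = 50, n_perm: int = 199,
                           alpha: float = 0.05):
    """Fraction of pathway x type p-values <= alpha under a null atlas.

    Returns (fraction, n_cells_of_matrix). 50 pathways x 4 types = 200 cells.
    """
    spec = AtlasSimSpec(n_cell_types=4, cells_per_type=100, n_genes=320,
                        markers_per_type=1, marker_fold_change=1.0,
                        cycling_fraction_per_type=[0.0] * 4,
                        cycling_genes_per_set=5, cycling_log_fold=0.0, seed=seed)
    counts, ann, _, _ = simulate_counts(spec)
    norm = lognormalize(counts)
    rng = np.random.default_rng(seed + 1)
    genes = np.array(counts.genes)
    sets = {f"P{j}": list(rng.choice(genes, size=8, replace=False)) for j in range(n_pathways)}
    _, pvals = permutation_pvalue(norm, ann, GeneSetCollection(sets),
                                  n_perm=n_perm, seed=seed + 2)
    flat = pvals.to_numpy().ravel()
    flat = flat[~np.isnan(flat)]
    return float((flat <= alpha).mean()), int(flat.size)


def diffmet_null_type1(seed: int, n_seeds: int = 100, n_metabolites: int = 20,
                       alpha: float = 0.05):
    """Type-I error of the differential-metabolite stage under the null.

    Returns (t-test rejection fraction, selected fraction, n_tests). The
    conjunctive p AND VIP rule is conservative, so the t-test fraction is
    the calibrated quantity and the selected fraction sits at or below it.
    """
    rejected = selected = total = 0
    for s in range(n_seeds):
        spec = MetabolomeSimSpec(n_metabolites=n_metabolites, replicates=5,
                                 seed=seed + s)
        tab = simulate_metabolome(spec)
        out = differential_metabolites(tab, ("speciesA", "speciesB"))
        rejected += int((out["p_value"] < alpha).sum())
        selected += int(out["selected"].sum())
        total += len(out)
    return rejected / total, selected / total, total


# ----------------------------------------------------------------- recovery

def regulon_selection_recovery(seed: int, n_seeds: int = 20):
    """Precision and recall of specific-TF selection on planted regulons
    (10 regulons, 5 planted with shift 0.3, 2000 cells)."""
    spec0 = AtlasSimSpec(n_cell_types=5, cells_per_type=400, n_genes=150,
                         markers_per_type=4, cycling_fraction_per_type=[0.0] * 5,
                         seed=seed)
    _, ann, _, _ = simulate_counts(spec0)
    types = sorted(ann["cell_type"].unique())
    specific = [types[i] if i < 5 else None for i in range(10)]
    planted = {(f"R{i:03d}", types[i]) for i in range(5)}
    tp = fp = fn = 0
    for s in range(n_seeds):
        rspec = RegulonSimSpec(n_regulons=10, specific_type_per_regulon=specific,
                               shift=0.3, seed=seed + s)
        act = simulate_regulon_activity(rspec, ann)
        groups = ann["cell_type"]
        rss = compute_rss(act, groups)
        table = select_specific_tfs(rss_zscore(rss),
                                    mean_activity_by_group(act, groups), rss=rss)
        got = set(map(tuple, table[table["selected"]][["regulon", "group"]].to_numpy()))
        tp += len(got & planted)
        fp += len(got - planted)
        fn += len(planted - got)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn)
    return precision, recall


def tf_module_recovery(seed: int, n_seeds: int = 20) -> float:
    """Mean adjusted Rand index for 12 regulons in 3 planted modules.

    Clusters the raw CSI (floor 0): at N=12 the CSI is bounded by
    (N-2)/N ~ 0.83, so the atlas-scale 0.9 floor is vacuous here.
    """
    aris = []
    for s in range(n_seeds):
        spec0 = AtlasSimSpec(n_cell_types=2, cells_per_type=500, n_genes=100,
                             markers_per_type=5, cycling_fraction_per_type=[0, 0],
                             seed=seed + s)
        _, ann, _, _ = simulate_counts(spec0)
        truth = [i % 3 for i in range(12)]
        rspec = RegulonSimSpec(n_regulons=12, n_modules=3, module_assignment=truth,
                               within_module_corr=0.9, seed=seed + s)
        act = simulate_regulon_activity(rspec, ann)
        csi = compute_csi(regulon_pcc(act))
        labels, _ = cluster_modules(csi, csi_floor=0.0, n_modules=3)
        aris.append(adjusted_rand_score(truth, labels.to_numpy()))
    return float(np.mean(aris))


def metabolite_block_recovery(seed: int, n_seeds: int = 20) -> float:
    """Mean ARI for two planted 6-metabolite blocks among 50 metabolites."""
    aris = []
    truth = [1 if 10 <= i < 16 else 2 if 20 <= i < 26 else 0 for i in range(50)]
    for s in range(n_seeds):
        spec = MetabolomeSimSpec(
            n_metabolites=50, replicates=5,
            block_structure=[[f"M{i:04d}" for i in range(10, 16)],
                             [f"M{i:04d}" for i in range(20, 26)]],
            block_corr=0.8, seed=seed + s,
        )
        tab = simulate_metabolome(spec)
        res = metabolite_modules(tab)
        aris.append(adjusted_rand_score(truth, res.assignment.to_numpy()))
    return float(np.mean(aris))


def pathway_planted_recovery(seed: int, n_perm: int = 999):
    """(score, p) of a pathway whose genes carry fold 4 in one cell type
    (200 cells per type)."""
    spec = AtlasSimSpec(n_cell_types=2, cells_per_type=200, n_genes=120,
                        markers_per_type=10, marker_fold_change=4.0,
                        cycling_fraction_per_type=[0, 0], cycling_genes_per_set=10,
                        cycling_log_fold=0.0, seed=seed)
    counts, ann, sets, _ = simulate_counts(spec)
    norm = lognormalize(counts)
    paths = GeneSetCollection({"planted": sets["markers_type0"]})
    scores, pvals = permutation_pvalue(norm, ann, paths, n_perm=n_perm, seed=seed + 1)
    return float(scores.loc["planted", "type0"]), float(pvals.loc["planted", "type0"])


def diffmet_planted_recovery(seed: int, n_seeds: int = 20):
    """Precision and recall of the p AND VIP rule on a 12-metabolite panel
    with 5 planted (3-sd shift, 5 vs 5 replicates)."""
    tp = fp = fn = 0
    planted = {f"M{i:04d}" for i in range(5)}
    for s in range(n_seeds):
        rng = np.random.default_rng(seed + s)
        X = rng.normal(0, 1, (10, 12))
        X[:5, :5] += 3.0
        names = [f"M{i:04d}" for i in range(12)]
        data = pd.DataFrame(np.exp(X * 0.3 + 3),
                            index=[f"s{i}" for i in range(10)], columns=names)
        tab = MetaboliteTable(data=data, species=pd.Series(["A"] * 5 + ["B"] * 5,
                                                           index=data.index))
        out = differential_metabolites(tab, ("A", "B"))
        got = set(out[out["selected"]].metabolite)
        tp += len(got & planted)
        fp += len(got - planted)
        fn += len(planted - got)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn)
    return precision, recall
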