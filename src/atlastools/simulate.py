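"""Synthetic data with the statistical structure the pipeline assumes.

Three generators emulate the study designs the downstream statistics were
built for: (a) UMI counts with planted cell-type markers and a
cycling/noncycling subpopulation per type, (b) cell x regulon activity
matrices with correlated modules and cell-type-specific regulons, and
(c) a multi-species metabolome (4 species x 5 replicates by default) with
planted species-specific high-abundance metabolites and correlated blocks.

Every generator is a pure function of its spec; the seed lives in the spec.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .types import CountMatrix, GeneSetCollection, MetaboliteTable


@dataclass
class AtlasSimSpec:
    """Negative-binomial atlas with planted markers and cycling cells.

    ``dispersion`` is the NB shape theta (var = mu + mu^2/theta); smaller
    theta means noisier counts. Per-gene baseline means are drawn
    log-normally around ``baseline_mean`` with log-sd ``baseline_sigma``
    (real transcriptomes span orders of magnitude in expression). Marker
    genes of a type have their mean multiplied by ``marker_fold_change`` in
    cells of that type; cycling cells get the cycling gene set up-shifted
    by ``cycling_log_fold`` (natural-log fold) and noncycling cells the
    noncycling set.
    """

    n_cell_types: int = 4
    cells_per_type: int = 200
    n_genes: int = 500
    markers_per_type: int = 10
    marker_fold_change: float = 8.0
    baseline_mean: float = 1.0
    baseline_sigma: float = 1.0
    dispersion: float = 2.0
    cycling_fraction_per_type: list[float] = field(default_factory=lambda: [0.5, 0.2, 0.05, 0.0])
    cycling_genes_per_set: int = 30
    cycling_log_fold: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        needed = self.n_cell_types * self.markers_per_type + 2 * self.cycling_genes_per_set
        if needed > self.n_genes:
            raise ValueError(f"need at least {needed} genes for markers and cycling sets")
        if len(self.cycling_fraction_per_type) != self.n_cell_types:
            raise ValueError("one cycling fraction per cell type required")
        if not all(0.0 <= f <= 1.0 for f in self.cycling_fraction_per_type):
            raise ValueError("cycling fractions must lie in [0,1]")
        if self.marker_fold_change < 1:
            raise ValueError("marker_fold_change must be >= 1")


def simulate_counts(spec: AtlasSimSpec):
    """Returns (CountMatrix, annotation DataFrame, truth gene sets, cycling labels).

    The truth GeneSetCollection holds one marker set per type plus the
    'cycling' and 'noncycling' sets the cycling classifier consumes.
    """
    rng = np.random.default_rng(spec.seed)
    n_cells = spec.n_cell_types * spec.cells_per_type
    genes = [f"G{i:05d}" for i in range(spec.n_genes)]
    cells = [f"C{i:05d}" for i in range(n_cells)]
    types = [f"type{t}" for t in range(spec.n_cell_types)]
    cell_type = np.repeat(types, spec.cells_per_type)

    sets: dict[str, list[str]] = {}
    pos = 0
    marker_idx: dict[str, np.ndarray] = {}
    for t in types:
        idx = np.arange(pos, pos + spec.markers_per_type)
        marker_idx[t] = idx
        sets[f"markers_{t}"] = [genes[i] for i in idx]
        pos += spec.markers_per_type
    # interleave the two sets so the deterministic gene-index tie-break in
    # rank scoring favors neither
    cyc_idx = np.arange(pos, pos + 2 * spec.cycling_genes_per_set, 2)
    noncyc_idx = cyc_idx + 1
    sets["cycling"] = [genes[i] for i in cyc_idx]
    sets["noncycling"] = [genes[i] for i in noncyc_idx]

    cycling = np.zeros(n_cells, dtype=bool)
    for t, frac in zip(types, spec.cycling_fraction_per_type):
        mask = cell_type == t
        cycling[mask] = rng.random(mask.sum()) < frac

    gene_means = rng.lognormal(np.log(spec.baseline_mean), spec.baseline_sigma, spec.n_genes)
    # matched panels: each noncycling gene shares its paired cycling gene's
    # baseline, so score comparison is unbiased when no signal is planted
    gene_means[noncyc_idx] = gene_means[cyc_idx]
    mu = np.tile(gene_means, (n_cells, 1))
    for t in types:
        mu[np.ix_(cell_type == t, marker_idx[t])] *= spec.marker_fold_change
    shift = np.exp(spec.cycling_log_fold)
    mu[np.ix_(cycling, cyc_idx)] *= shift
    mu[np.ix_(~cycling, noncyc_idx)] *= shift

    # gamma-Poisson mixture = negative binomial with shape theta
    lam = rng.gamma(spec.dispersion, mu / spec.dispersion)
    counts = rng.poisson(lam)

    annotation = pd.DataFrame(
        {
            "tissue": "synthetic",
            "cell_type": cell_type,
            "species": "synthetic",
            "study": "sim",
        },
        index=pd.Index(cells, name="cell_id"),
    )
    labels = pd.Series(np.where(cycling, "cycling", "noncycling"), index=cells, name="truth")
    return (
        CountMatrix(cells, genes, sp.csr_matrix(counts)),
        annotation,
        GeneSetCollection(sets),
        labels,
    )


@dataclass
class RegulonSimSpec:
    """Regulon activities organized in correlated modules.

    Regulons in a module share a latent factor with correlation
    ``within_module_corr``; a regulon with an assigned specific type gets
    ``shift`` added to its activity in that type's cells.
    """

    n_regulons: int = 10
    n_modules: int = 2
    module_assignment: list[int] | None = None
    specific_type_per_regulon: list[str | None] | None = None
    within_module_corr: float = 0.6
    noise_sd: float = 0.15
    shift: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.within_module_corr < 1.0:
            raise ValueError("within_module_corr must lie in [0,1)")
        if self.module_assignment is None:
            self.module_assignment = [i % self.n_modules for i in range(self.n_regulons)]
        if len(self.module_assignment) != self.n_regulons:
            raise ValueError("one module per regulon required")
        counts = pd.Series(self.module_assignment).value_counts()
        if (counts < 2).any():
            raise ValueError("module sizes must be >= 2")
        if self.specific_type_per_regulon is not None and len(
            self.specific_type_per_regulon
        ) != self.n_regulons:
            raise ValueError("one specific type (or None) per regulon required")


def simulate_regulon_activity(spec: RegulonSimSpec, annotation: pd.DataFrame) -> pd.DataFrame:
    """Cells x regulons activity in [0,1], deterministic given the spec seed."""
    rng = np.random.default_rng(spec.seed)
    n_cells = len(annotation)
    rho = spec.within_module_corr
    modules = sorted(set(spec.module_assignment))
    factors = {m: rng.standard_normal(n_cells) for m in modules}

    cols = {}
    for j in range(spec.n_regulons):
        z = np.sqrt(rho) * factors[spec.module_assignment[j]] + np.sqrt(
            1.0 - rho
        ) * rng.standard_normal(n_cells)
        act = 0.5 + spec.noise_sd * z
        if spec.specific_type_per_regulon is not None:
            target = spec.specific_type_per_regulon[j]
            if target is not None:
                act = act + spec.shift * (annotation["cell_type"].to_numpy() == target)
        cols[f"R{j:03d}"] = np.clip(act, 0.0, 1.0)
    return pd.DataFrame(cols, index=annotation.index)


@dataclass
class MetabolomeSimSpec:
    """Log-normal multispecies metabolome with planted structure.

    ``planted_high_sets`` maps a species to metabolites shifted up by
    ``log_fold`` (natural log) in that species; ``block_structure`` lists
    groups of metabolites sharing a latent factor with loading
    ``block_corr`` (pairwise correlation of log abundances ~= block_corr).
    """

    n_species: int = 4
    replicates: int = 5
    n_metabolites: int = 60
    planted_high_sets: dict[str, list[str]] = field(default_factory=dict)
    block_structure: list[list[str]] = field(default_factory=list)
    block_corr: float = 0.8
    log_fold: float = 2.0
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 3:
            raise ValueError("need >= 3 replicates per species")
        planted = [m for s in self.planted_high_sets.values() for m in s]
        if len(planted) != len(set(planted)):
            raise ValueError("planted high sets must be disjoint")

    @property
    def species_names(self) -> list[str]:
        return [f"species{chr(ord('A') + i)}" for i in range(self.n_species)]

    @property
    def metabolite_names(self) -> list[str]:
        return [f"M{i:04d}" for i in range(self.n_metabolites)]


def simulate_metabolome(spec: MetabolomeSimSpec) -> MetaboliteTable:
    rng = np.random.default_rng(spec.seed)
    species = spec.species_names
    mets = spec.metabolite_names
    samples = [f"{s}_rep{r+1}" for s in species for r in range(spec.replicates)]
    species_of = np.repeat(species, spec.replicates)
    n = len(samples)

    met_index = {m: j for j, m in enumerate(mets)}
    base = rng.normal(3.0, 1.0, size=spec.n_metabolites)  # per-metabolite log level
    logab = np.tile(base, (n, 1))

    r = spec.block_corr
    for block in spec.block_structure:
        factor = rng.standard_normal(n)
        for m in block:
            logab[:, met_index[m]] += np.sqrt(r) * spec.noise_sd * factor

    for sp_name, planted in spec.planted_high_sets.items():
        mask = species_of == sp_name
        for m in planted:
            logab[mask, met_index[m]] += spec.log_fold

    in_block = {m for b in spec.block_structure for m in b}
    resid = np.array([np.sqrt(1 - r) if m in in_block else 1.0 for m in mets])
    logab += spec.noise_sd * resid * rng.standard_normal((n, spec.n_metabolites))

    data = pd.DataFrame(np.exp(logab), index=pd.Index(samples, name="sample"), columns=mets)
    return MetaboliteTable(data=data, species=pd.Series(species_of, index=data.index, name="species"))
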