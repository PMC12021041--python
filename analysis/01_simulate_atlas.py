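#!/usr/bin/env python
"""Generate the synthetic study inputs used by every downstream step.

Writes a planted-structure single-cell atlas (counts, annotation, truth
gene sets, cycling truth), a cell x regulon activity matrix with planted
specific regulons and correlated modules, and a 4-species x 5-replicate
metabolome with planted species-high metabolites and correlated blocks.
"""

from pathlib import Path

import atlastools as at
from atlastools import io as aio

SEED = 1
OUT = Path(__file__).resolve().parents[1] / "results" / "data"
OUT.mkdir(parents=True, exist_ok=True)

# --- atlas: 4 cell types, planted markers, graded cycling fractions
atlas_spec = at.AtlasSimSpec(
    n_cell_types=4, cells_per_type=200, n_genes=1000, markers_per_type=10,
    marker_fold_change=8.0, cycling_genes_per_set=50,
    cycling_fraction_per_type=[0.5, 0.2, 0.05, 0.0], seed=SEED,
)
counts, annotation, truth_sets, cycling_truth = at.simulate_counts(atlas_spec)
aio.write_counts(counts, OUT / "counts")
aio.write_annotation(annotation, OUT / "annotation.tsv")
aio.write_gmt(truth_sets, OUT / "truth_sets.gmt")
cycling_truth.rename_axis("cell_id").to_csv(OUT / "cycling_truth.csv")
print(f"atlas: {counts.shape[0]} cells x {counts.shape[1]} genes, "
      f"{annotation['cell_type'].nunique()} cell types")

# --- regulons: 12 regulons, 3 correlated modules, 6 planted specific
types = sorted(annotation["cell_type"].unique())
specific = [types[i % len(types)] if i < 6 else None for i in range(12)]
regulon_spec = at.RegulonSimSpec(
    n_regulons=12, n_modules=3, module_assignment=[i % 3 for i in range(12)],
    specific_type_per_regulon=specific, within_module_corr=0.7, seed=SEED,
)
activity = at.simulate_regulon_activity(regulon_spec, annotation)
activity.rename_axis("cell_id").to_csv(OUT / "regulon_activity.csv")
print(f"regulons: {activity.shape[1]} regulons x {activity.shape[0]} cells, "
      f"6 planted cell-type-specific")

# --- metabolome: 4 species x 5 replicates, planted structure
metab_spec = at.MetabolomeSimSpec(
    n_metabolites=60,
    planted_high_sets={"speciesA": [f"M{i:04d}" for i in range(5)]},
    block_structure=[[f"M{i:04d}" for i in range(10, 16)],
                     [f"M{i:04d}" for i in range(20, 26)]],
    block_corr=0.8, log_fold=2.0, seed=SEED,
)
table = at.simulate_metabolome(metab_spec)
aio.write_metabolite_table(table, OUT / "metabolome.csv")
print(f"metabolome: {table.data.shape[0]} samples x {table.data.shape[1]} metabolites, "
      f"5 planted high in speciesA, 2 correlated blocks")
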