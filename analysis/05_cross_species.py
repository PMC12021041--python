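#!/usr/bin/env python
"""Cross-study cell-type similarity: HVG selection, neighbor-voting AUROC
between two replicate studies, the similarity tree, per-type Spearman
correlation between "species", and marker genes for one cell type."""

from pathlib import Path

import numpy as np
import pandas as pd

import atlastools as at
from atlastools import io as aio

BASE = Path(__file__).resolve().parents[1] / "results"
DATA = BASE / "data"

counts = aio.read_counts(DATA / "counts")
annotation = aio.read_annotation(DATA / "annotation.tsv")
counts = at.qc_filter(counts, min_genes=100)
norm = at.lognormalize(counts)
hvgs = at.select_hvgs(counts, n=300)
Path(BASE / "hvgs.txt").write_text("\n".join(hvgs) + "\n")

# two "studies": split each cell type's cells into two halves, so both
# studies share the same underlying expression structure (as two datasets
# profiling the same tissue would)
df = norm.to_frame()
ann = annotation.loc[df.index].copy()
half = (
    ann.groupby("cell_type").cumcount() < ann.groupby("cell_type")["tissue"].transform("size") // 2
)
bann = ann.assign(study=np.where(half, "sim", "sim_b"))
both = df

auroc = at.neighbor_voting_auroc(both, bann, hvgs)
sym = at.symmetrize_auroc(auroc)
sym.to_csv(BASE / "auroc_matrix.csv")
matched = np.array([
    sym.loc[("sim", t), ("sim_b", t)] for t in sorted(annotation["cell_type"].unique())
])
cross = sym.loc["sim", "sim_b"].to_numpy()
off = cross[~np.eye(cross.shape[0], dtype=bool)]
print(f"matched-type AUROC: mean {matched.mean():.3f} (min {matched.min():.3f}); "
      f"mismatched: mean {np.nanmean(off):.3f}")

# tree over (study, cell type) profiles from 1 - symmetrized AUROC
dist = 1.0 - sym.fillna(sym.T).fillna(0.5)
np.fill_diagonal(dist.to_numpy(), 0.0)
dist.index = dist.columns = ["|".join(p) for p in sym.index]
_, newick = at.hierarchical_tree((dist + dist.T) / 2)
(BASE / "celltype_tree.nwk").write_text(newick + "\n")

rho = at.celltype_spearman(both, bann.assign(species=bann["study"]), hvgs, ("sim", "sim_b"))
rho.to_csv(BASE / "celltype_spearman.csv", index=False)
print("per-type cross-study Spearman rho:")
print(rho.round(3).to_string(index=False))

markers = at.find_markers(norm, annotation, "type0")
markers.to_csv(BASE / "markers_type0.csv", index=False)
print(f"type0 markers passing p<0.05 and |log2FC|>0.25: "
      f"{int(markers['passes'].sum())} genes")
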