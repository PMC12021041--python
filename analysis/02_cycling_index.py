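#!/usr/bin/env python
"""Score cycling vs noncycling gene sets per cell and compute the per-type
cycling index, then compare the classification against the planted truth."""

from pathlib import Path

import pandas as pd

import atlastools as at
from atlastools import io as aio
from atlastools.types import GeneSetCollection

BASE = Path(__file__).resolve().parents[1] / "results"
DATA = BASE / "data"
BASE.mkdir(exist_ok=True)

counts = aio.read_counts(DATA / "counts")
annotation = aio.read_annotation(DATA / "annotation.tsv")
sets = aio.read_gmt(DATA / "truth_sets.gmt")
truth = pd.read_csv(DATA / "cycling_truth.csv", index_col=0)["truth"]

counts = at.qc_filter(counts, min_genes=100)
norm = at.lognormalize(counts)
activity = at.aucell_score(
    norm, GeneSetCollection({"cycling": sets["cycling"], "noncycling": sets["noncycling"]})
)
labels = at.classify_cycling(activity)
index = at.cycling_index(labels, annotation)

activity.rename_axis("cell_id").to_csv(BASE / "cycling_activity.csv")
index.to_csv(BASE / "cycling_index.csv", index=False)

accuracy = (labels == truth.loc[labels.index]).mean()
print("per-type cycling index (log2 (n_cyc+1)/(n_noncyc+1)):")
print(index.to_string(index=False))
print(f"classification accuracy vs planted truth: {accuracy:.3f}")
print("types simulated with cycling fractions 0.5/0.2/0.05/0 should rank "
      "in that order; see cycling_index.csv")
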