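#!/usr/bin/env python
"""Multispecies metabolome stage: tertile abundance classes, differential
metabolites (Welch t + PLS-DA VIP), correlation-network modules with
eigen-metabolites, module-species association, and key metabolites."""

from pathlib import Path

import atlastools as at
from atlastools import io as aio

BASE = Path(__file__).resolve().parents[1] / "results"
DATA = BASE / "data"

table = aio.read_metabolite_table(DATA / "metabolome.csv")

classes = at.tertile_classes(table)
classes.to_csv(BASE / "metabolite_classes.csv", index=False)
print("tertile class counts per species:")
print(classes.groupby(["species", "class"]).size().unstack(fill_value=0).to_string())

diff = at.differential_metabolites(table, ("speciesA", "speciesB"))
diff.to_csv(BASE / "differential_metabolites.csv", index=False)
hits = diff[diff["selected"]].sort_values("p_value")
print(f"\n{len(hits)} differential metabolites (p<0.05, VIP>1) between "
      f"speciesA and speciesB (planted: M0000-M0004):")
print(hits[["metabolite", "p_value", "vip", "log2fc"]].round(4).to_string(index=False))

modules = at.metabolite_modules(table)
modules.assignment.rename_axis("metabolite").to_csv(BASE / "metabolite_modules.csv")
modules.eigen.rename_axis("sample").to_csv(BASE / "eigen_metabolites.csv")
assoc = at.module_species_association(modules, table)
assoc.to_csv(BASE / "module_species_assoc.csv", index=False)
sizes = modules.assignment[modules.assignment > 0].value_counts().sort_index()
print(f"\nmetabolite modules (planted blocks M0010-15, M0020-25): sizes "
      f"{sizes.to_dict()}")
print("module-species Wilcoxon p:")
print(assoc.pivot(index="module", columns="species", values="p_value")
      .round(4).to_string())

keys = at.key_metabolites(modules, "speciesA")
keys.to_csv(BASE / "key_metabolites_speciesA.csv", index=False)
print(f"\nkey metabolites for speciesA (MM>0.9 and MS>0.9): "
      f"{keys[keys.key].metabolite.tolist()}")
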