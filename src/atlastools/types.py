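"""Core containers shared by every pipeline stage.

Counts are kept sparse (CSR, cells x genes); continuous matrices
(normalized expression, gene-set activity) are pandas DataFrames so that
cell and set identifiers travel with the values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

ANNOTATION_COLUMNS = ["cell_id", "tissue", "cell_type", "species", "study"]


def _check_unique(ids, what: str) -> None:
    seen = pd.Index(ids)
    if seen.has_duplicates:
        dups = seen[seen.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what}: {dups[:5]}")


@dataclass
class CountMatrix:
    """Raw UMI counts, cells x genes, with identifier lists.

    Invariants: unique cell ids, unique gene symbols, non-negative
    integer counts, dimensions matching the id lists.
    """

    cells: list[str]
    genes: list[str]
    counts: sp.csr_matrix

    def __post_init__(self) -> None:
        self.cells = [str(c) for c in self.cells]
        self.genes = [str(g) for g in self.genes]
        _check_unique(self.cells, "cell ids")
        _check_unique(self.genes, "gene symbols")
        if not sp.issparse(self.counts):
            self.counts = sp.csr_matrix(np.asarray(self.counts))
        self.counts = self.counts.tocsr()
        if self.counts.shape != (len(self.cells), len(self.genes)):
            raise ValueError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.cells)} cells x {len(self.genes)} genes"
            )
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("negative counts")
        if not np.allclose(self.counts.data, np.round(self.counts.data)):
            raise ValueError("non-integer counts")
        self.counts.data = np.round(self.counts.data).astype(np.int64)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts.toarray(), index=self.cells, columns=self.genes
        )

    def subset(self, cell_mask=None, gene_mask=None) -> "CountMatrix":
        """Subset by boolean masks, preserving order."""
        cm = np.ones(len(self.cells), bool) if cell_mask is None else np.asarray(cell_mask)
        gm = np.ones(len(self.genes), bool) if gene_mask is None else np.asarray(gene_mask)
        return CountMatrix(
            [c for c, k in zip(self.cells, cm) if k],
            [g for g, k in zip(self.genes, gm) if k],
            self.counts[cm][:, gm],
        )


@dataclass
class NormalizedMatrix:
    """Log-scale library-size-normalized expression (cells x genes)."""

    cells: list[str]
    genes: list[str]
    values: np.ndarray
    scale_factor: float = 1e4

    def __post_init__(self) -> None:
        if sp.issparse(self.values):
            self.values = self.values.toarray()
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.cells), len(self.genes)):
            raise ValueError("value matrix shape does not match id lists")
        if self.values.size and self.values.min() < 0:
            raise ValueError("normalized expression must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cells, columns=self.genes)


class GeneSetCollection:
    """Named gene sets (pathways, regulon targets, cycling markers).

    Set names are unique, sets are non-empty, member order is preserved.
    """

    def __init__(self, sets: dict[str, list[str]], descriptions: dict[str, str] | None = None):
        self._sets: dict[str, list[str]] = {}
        for name, members in sets.items():
            members = [str(m) for m in members]
            if not members:
                raise ValueError(f"empty gene set: {name!r}")
            if name in self._sets:
                raise ValueError(f"duplicate set name: {name!r}")
            self._sets[str(name)] = members
        self.descriptions = dict(descriptions or {})

    def __getitem__(self, name: str) -> list[str]:
        return list(self._sets[name])

    def __contains__(self, name: str) -> bool:
        return name in self._sets

    def __iter__(self):
        return iter(self._sets)

    def __len__(self) -> int:
        return len(self._sets)

    def items(self):
        return self._sets.items()

    def names(self) -> list[str]:
        return list(self._sets)

    def gene_multiplicity(self) -> dict[str, int]:
        """Number of sets each gene belongs to (pathway multiplicity)."""
        mult: dict[str, int] = {}
        for members in self._sets.values():
            for g in set(members):
                mult[g] = mult.get(g, 0) + 1
        return mult


def validate_annotation(annotation: pd.DataFrame, cells: list[str] | None = None) -> pd.DataFrame:
    """Check a per-cell annotation table and return it indexed by cell_id."""
    ann = annotation.copy()
    if "cell_id" in ann.columns:
        ann = ann.set_index("cell_id")
    ann.index = ann.index.astype(str)
    if ann.index.has_duplicates:
        raise ValueError("duplicate cell_id in annotation")
    if cells is not None:
        missing = set(cells) - set(ann.index)
        if missing:
            raise ValueError(f"{len(missing)} cells missing from annotation")
        ann = ann.loc[list(cells)]
    return ann


@dataclass
class MetaboliteTable:
    """Samples x metabolites positive abundances with species labels."""

    data: pd.DataFrame
    species: pd.Series
    classes: pd.Series | None = field(default=None)

    def __post_init__(self) -> None:
        self.species = pd.Series(self.species).reindex(self.data.index)
        if self.species.isna().any():
            raise ValueError("every sample needs a species label")
        if (self.data.to_numpy() <= 0).any():
            raise ValueError("abundances must be positive")

    @property
    def metabolites(self) -> list[str]:
        return list(self.data.columns)

    def species_groups(self) -> dict[str, pd.DataFrame]:
        return {s: self.data.loc[self.species == s] for s in self.species.unique()}
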