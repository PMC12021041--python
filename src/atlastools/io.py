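"""Readers and writers for the standard on-disk formats.

Counts travel either as a MatrixMarket triplet (matrix.mtx + barcodes.tsv +
features.tsv, genes x cells on disk as CellRanger writes them) or as a dense
CSV with cells in rows and a header of gene symbols. Gene sets use GMT.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml

from .types import CountMatrix, GeneSetCollection, MetaboliteTable, validate_annotation

log = logging.getLogger(__name__)


def read_counts(path: str | Path, format: str = "auto") -> CountMatrix:
    """Read raw counts from an mtx triplet directory or a dense CSV/TSV.

    The mtx triplet stores genes x cells; orientation is normalized to
    cells x genes on read.
    """
    path = Path(path)
    if format == "auto":
        format = "mtx-triplet" if path.is_dir() else "dense-csv"
    if format == "mtx-triplet":
        mtx = path / "matrix.mtx"
        barcodes = path / "barcodes.tsv"
        features = path / "features.tsv"
        for f in (mtx, barcodes, features):
            if not f.exists():
                raise FileNotFoundError(f"missing sidecar file: {f}")
        mat = sp.csr_matrix(scipy.io.mmread(mtx)).T  # genes x cells on disk
        cells = pd.read_csv(barcodes, header=None, sep="\t")[0].astype(str).tolist()
        genes = pd.read_csv(features, header=None, sep="\t")[0].astype(str).tolist()
        if mat.shape != (len(cells), len(genes)):
            raise ValueError(
                f"matrix shape {mat.shape[::-1]} does not match "
                f"{len(genes)} features x {len(cells)} barcodes"
            )
        return CountMatrix(cells, genes, mat)
    if format == "dense-csv":
        sep = "\t" if path.suffix in {".tsv", ".txt"} else ","
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split(sep)[1:]
        if pd.Index(header).has_duplicates:  # pandas would mangle these
            raise ValueError("duplicate gene symbols in header")
        df = pd.read_csv(path, index_col=0, sep=sep)
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError("non-numeric entries in count matrix")
        return CountMatrix(df.index.astype(str).tolist(), df.columns.tolist(), sp.csr_matrix(values))
    raise ValueError(f"unknown count format: {format!r}")


def write_counts(counts: CountMatrix, path: str | Path, format: str = "mtx-triplet") -> None:
    path = Path(path)
    if format == "mtx-triplet":
        path.mkdir(parents=True, exist_ok=True)
        scipy.io.mmwrite(path / "matrix.mtx", counts.counts.T.tocoo(), field="integer")
        (path / "barcodes.tsv").write_text("\n".join(counts.cells) + "\n")
        (path / "features.tsv").write_text("\n".join(counts.genes) + "\n")
    elif format == "dense-csv":
        counts.to_frame().to_csv(path)
    else:
        raise ValueError(f"unknown count format: {format!r}")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: name <tab> description <tab> member genes..."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"GMT line {ln} has fewer than 3 fields")
        name, desc, *members = fields
        if name in sets:
            raise ValueError(f"duplicate set name {name!r} at line {ln}")
        unique, seen = [], set()
        for m in members:
            if m in seen:
                log.warning("duplicate member %r in set %r deduplicated", m, name)
            elif m:
                unique.append(m)
                seen.add(m)
        sets[name] = unique
        descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(sets: GeneSetCollection, path: str | Path) -> None:
    lines = [
        "\t".join([name, sets.descriptions.get(name, ".")] + members)
        for name, members in sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_annotation(path: str | Path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", dtype=str)
    return validate_annotation(ann)


def write_annotation(annotation: pd.DataFrame, path: str | Path) -> None:
    annotation.rename_axis("cell_id").reset_index().to_csv(path, sep="\t", index=False)


def read_metabolite_table(path: str | Path) -> MetaboliteTable:
    """CSV with columns: sample id, species, then one column per metabolite."""
    df = pd.read_csv(path, index_col=0)
    species = df.iloc[:, 0].astype(str)
    data = df.iloc[:, 1:].astype(float)
    return MetaboliteTable(data=data, species=species)


def write_metabolite_table(table: MetaboliteTable, path: str | Path) -> None:
    out = table.data.copy()
    out.insert(0, "species", table.species)
    out.rename_axis("sample").to_csv(path)


def read_ortholog_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV mapping source gene symbols to target orthologs.

    Later duplicate source symbols are dropped with a warning (one-to-one
    mapping; many-to-many orthology should be resolved upstream).
    """
    mapping: dict[str, str] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise ValueError(f"ortholog map line {ln} needs 2 columns")
        src, dst = fields[0], fields[1]
        if src in mapping:
            log.warning("duplicate source gene %r at line %d dropped", src, ln)
            continue
        mapping[src] = dst
    return mapping


def load_config(path: str | Path | None) -> dict:
    """YAML key-value config shared by all CLI subcommands."""
    if path is None:
        return {}
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config must be a YAML mapping")
    return cfg
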