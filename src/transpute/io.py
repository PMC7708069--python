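"""Readers and writers for expression matrices, gene lists and labels.

On-disk conventions
-------------------
Delimited expression matrices are samples-as-rows tables whose header names
the gene columns.  The first column holds sample ids; two reserved columns,
``dataset`` and (optionally) ``date``, carry sample metadata; every other
column is a gene.  Comma and tab separators are auto-detected from the
header; writers emit tabs by default.  A binary HDF5 container is supported
for large matrices.  Missing (empty) cells are rejected outright: this
package addresses the unmeasured-gene problem, not within-dataset
missing-value recovery.
"""

from __future__ import annotations

import os
from typing import Iterable

import numpy as np
import pandas as pd

from .data import DataError, ExpressionMatrix, TissueLabels, SampleSplit

RESERVED_COLUMNS = ("dataset", "date")

_HDF5_SUFFIXES = (".h5", ".hdf5")


def _detect_sep(path: str) -> str:
    with open(path, "r") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def _infer_format(path: str, format: str | None) -> str:
    if format is not None:
        if format not in ("tsv", "csv", "hdf5", "delimited"):
            raise DataError(f"unknown format {format!r}")
        return format
    if os.path.splitext(path)[1].lower() in _HDF5_SUFFIXES:
        return "hdf5"
    return "delimited"


def read_expression(path: str, format: str | None = None) -> ExpressionMatrix:
    """Read an expression matrix from delimited text or an HDF5 container.

    Raises :class:`DataError` on duplicate ids, non-numeric or empty cells,
    or missing dataset metadata.
    """
    fmt = _infer_format(path, format)
    if fmt == "hdf5":
        return _read_hdf5(path)
    sep = _detect_sep(path) if fmt == "delimited" else ("\t" if fmt == "tsv" else ",")
    df = pd.read_csv(path, sep=sep, dtype=str, index_col=0, keep_default_na=False)
    if "dataset" not in df.columns:
        raise DataError(f"{path}: missing required 'dataset' column")
    sample_ids = [str(s) for s in df.index]
    from .data import _check_unique

    _check_unique(sample_ids, "sample ids")
    dataset_ids = list(df["dataset"])
    if any(d == "" for d in dataset_ids):
        bad = sample_ids[dataset_ids.index("")]
        raise DataError(f"{path}: sample {bad} has no dataset_id")
    dates: list[str | None] | None = None
    if "date" in df.columns:
        dates = [d if d != "" else None for d in df["date"]]
    gene_cols = [c for c in df.columns if c not in RESERVED_COLUMNS]
    if not gene_cols:
        raise DataError(f"{path}: no gene columns found")
    _check_unique(gene_cols, "gene ids")
    gene_df = df[gene_cols]
    values = np.empty(gene_df.shape, dtype=float)
    for j, col in enumerate(gene_cols):
        raw = gene_df[col].to_numpy()
        try:
            # numpy's str->float conversion is correctly rounded (unlike
            # pandas' fast parser), preserving bitwise round-trips
            values[:, j] = raw.astype(float)
        except ValueError:
            for i, cell in enumerate(raw):
                if cell == "":
                    raise DataError(
                        f"{path}: empty cell at sample {sample_ids[i]}, "
                        f"gene {col}"
                    ) from None
                try:
                    float(cell)
                except ValueError:
                    raise DataError(
                        f"{path}: non-numeric value {cell!r} at sample "
                        f"{sample_ids[i]}, gene {col}"
                    ) from None
            raise
    return ExpressionMatrix(
        values=values,
        sample_ids=sample_ids,
        gene_ids=gene_cols,
        dataset_ids=dataset_ids,
        dates=dates,
    )


def write_expression(
    matrix: ExpressionMatrix, path: str, format: str | None = None
) -> None:
    """Write a matrix so that :func:`read_expression` round-trips it exactly."""
    if matrix.n_genes == 0:
        raise DataError("refusing to write a matrix with no genes")
    fmt = _infer_format(path, format)
    if fmt == "hdf5":
        _write_hdf5(matrix, path)
        return
    sep = "," if fmt == "csv" else "\t"
    df = pd.DataFrame(
        matrix.values, index=matrix.sample_ids, columns=matrix.gene_ids
    )
    df.insert(0, "dataset", matrix.dataset_ids)
    if matrix.dates is not None:
        df.insert(1, "date", [d if d is not None else "" for d in matrix.dates])
    df.index.name = "sample"
    # repr() of a float round-trips under float(): bitwise-exact re-read
    df.to_csv(path, sep=sep, float_format=lambda v: repr(float(v)))


def _read_hdf5(path: str) -> ExpressionMatrix:
    import h5py

    with h5py.File(path, "r") as f:
        values = f["values"][...]
        sample_ids = [s.decode() for s in f["sample_ids"][...]]
        gene_ids = [g.decode() for g in f["gene_ids"][...]]
        dataset_ids = [d.decode() for d in f["dataset_ids"][...]]
        dates = None
        if "dates" in f:
            dates = [d.decode() or None for d in f["dates"][...]]
    return ExpressionMatrix(values, sample_ids, gene_ids, dataset_ids, dates)


def _write_hdf5(matrix: ExpressionMatrix, path: str) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=matrix.values)
        f.create_dataset(
            "sample_ids", data=np.array(matrix.sample_ids, dtype="S")
        )
        f.create_dataset("gene_ids", data=np.array(matrix.gene_ids, dtype="S"))
        f.create_dataset(
            "dataset_ids", data=np.array(matrix.dataset_ids, dtype="S")
        )
        if matrix.dates is not None:
            f.create_dataset(
                "dates",
                data=np.array(
                    [d if d is not None else "" for d in matrix.dates], dtype="S"
                ),
            )


def read_gene_list(path: str) -> list[str]:
    """Read a line-oriented gene list ('#' comment lines allowed)."""
    genes: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            genes.append(line)
    if not genes:
        raise DataError(f"{path}: empty gene list")
    seen: set[str] = set()
    for g in genes:
        if g in seen:
            raise DataError(f"{path}: duplicate gene id {g}")
        seen.add(g)
    return genes


def write_gene_list(genes: Iterable[str], path: str) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")


def read_tissue_labels(path: str) -> TissueLabels:
    """Read a two-column (sample_id, tissue) delimited file."""
    sep = _detect_sep(path)
    labels: dict[str, str] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split(sep)
            if len(parts) != 2:
                raise DataError(f"{path}:{ln}: expected two columns")
            sid, tissue = parts[0].strip(), parts[1].strip()
            if sid in labels and labels[sid] != tissue:
                raise DataError(
                    f"{path}: sample {sid} labeled both {labels[sid]} and {tissue}"
                )
            labels[sid] = tissue
    return TissueLabels(labels)


def write_tissue_labels(labels: TissueLabels, path: str) -> None:
    with open(path, "w") as fh:
        for sid, tissue in labels.labels.items():
            fh.write(f"{sid}\t{tissue}\n")


def read_sample_split(path: str) -> SampleSplit:
    """Read a two-column (sample_id, split) TSV into a SampleSplit."""
    parts: dict[str, list[str]] = {"train": [], "validation": [], "test": []}
    sep = _detect_sep(path)
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split(sep)
            if len(cols) != 2:
                raise DataError(f"{path}:{ln}: expected two columns")
            sid, part = cols[0].strip(), cols[1].strip()
            if part not in parts:
                raise DataError(f"{path}:{ln}: unknown split name {part!r}")
            parts[part].append(sid)
    return SampleSplit(**parts)


def write_sample_split(split: SampleSplit, path: str) -> None:
    with open(path, "w") as fh:
        for part in ("train", "validation", "test"):
            for sid in getattr(split, part):
                fh.write(f"{sid}\t{part}\n")


def write_metric_table(table: pd.DataFrame, path: str) -> None:
    """Write a long-format per-gene metric table as TSV."""
    table.to_csv(path, sep="\t", index=False)


def read_metric_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
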