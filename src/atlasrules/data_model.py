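"""Core dataset container and readers/writers for expression matrices.

The central object is :class:`ExpressionDataset`: a dense cells x genes
matrix of non-negative expression values together with per-cell tissue
labels.  Two on-disk layouts are supported:

* sparse MatrixMarket (``prefix.mtx``) with one-id-per-line sidecars
  ``prefix.genes.tsv`` / ``prefix.cells.tsv`` and a two-column
  ``prefix.labels.tsv`` (``cell_id<TAB>tissue``);
* dense CSV (``prefix.csv``; header = gene ids, first column = cell id)
  with the same sidecars.

Cells are always rows and genes columns in memory; MTX files stored in
either orientation are disambiguated by the sidecar lengths.  Expression
values are taken as-is — no normalisation is applied here.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.io import mmread, mmwrite

__all__ = [
    "DatasetError",
    "ExpressionDataset",
    "FeatureSubsetView",
    "load_dataset",
    "write_dataset",
    "subset_features",
]


class DatasetError(ValueError):
    """Raised when a dataset or its on-disk representation is invalid."""


def _class_names_from_labels(labels) -> list[str]:
    """Distinct labels ordered by first appearance."""
    seen: dict[str, None] = {}
    for lab in labels:
        seen.setdefault(str(lab), None)
    return list(seen)


@dataclass
class ExpressionDataset:
    """Cells x genes expression matrix with one tissue label per cell.

    Parameters
    ----------
    matrix
        Dense float array, shape ``(n_cells, n_genes)``, finite and >= 0.
    gene_ids, cell_ids
        Ordered unique identifiers for columns / rows.
    labels
        One tissue-category string per cell.
    class_names
        Ordered distinct tissue categories.  Defaults to first-appearance
        order of ``labels``; all confusion matrices downstream use this
        order.
    """

    matrix: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    labels: list[str]
    class_names: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2:
            raise DatasetError("matrix must be 2-dimensional (cells x genes)")
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.labels = [str(l) for l in self.labels]
        n_cells, n_genes = self.matrix.shape
        if len(self.cell_ids) != n_cells:
            raise DatasetError(
                f"cell axis mismatch: matrix has {n_cells} rows but "
                f"{len(self.cell_ids)} cell ids"
            )
        if len(self.gene_ids) != n_genes:
            raise DatasetError(
                f"gene axis mismatch: matrix has {n_genes} columns but "
                f"{len(self.gene_ids)} gene ids"
            )
        if len(self.labels) != n_cells:
            raise DatasetError(
                f"label mismatch: {len(self.labels)} labels for {n_cells} cells"
            )
        if len(set(self.gene_ids)) != n_genes:
            raise DatasetError("gene_ids are not unique")
        if len(set(self.cell_ids)) != n_cells:
            raise DatasetError("cell_ids are not unique")
        bad = ~np.isfinite(self.matrix)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise DatasetError(f"non-finite value at cell {i}, gene {j}")
        neg = self.matrix < 0
        if neg.any():
            i, j = np.argwhere(neg)[0]
            raise DatasetError(
                f"negative value {self.matrix[i, j]} at cell {i}, gene {j}"
            )
        if self.class_names is None:
            self.class_names = _class_names_from_labels(self.labels)
        else:
            self.class_names = [str(c) for c in self.class_names]
        known = set(self.class_names)
        for lab in self.labels:
            if lab not in known:
                raise DatasetError(f"label {lab!r} not in class_names")

    # ------------------------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[1]

    @property
    def y(self) -> np.ndarray:
        """Integer class codes, following ``class_names`` order."""
        code = {c: i for i, c in enumerate(self.class_names)}
        return np.fromiter((code[l] for l in self.labels), dtype=np.intp,
                           count=self.n_cells)

    def equals(self, other: "ExpressionDataset") -> bool:
        return (
            isinstance(other, ExpressionDataset)
            and self.gene_ids == other.gene_ids
            and self.cell_ids == other.cell_ids
            and self.labels == other.labels
            and self.class_names == other.class_names
            and self.matrix.shape == other.matrix.shape
            and np.array_equal(self.matrix, other.matrix)
        )


@dataclass
class FeatureSubsetView:
    """Ordered column subset of a parent dataset (the 'top k genes' object).

    Cell order and labels are those of the parent; only the gene axis is
    restricted/reordered.
    """

    parent: ExpressionDataset
    feature_indices: np.ndarray

    def __post_init__(self) -> None:
        idx = np.asarray(self.feature_indices, dtype=np.intp)
        if idx.ndim != 1:
            raise DatasetError("feature_indices must be one-dimensional")
        if idx.size and (idx.min() < 0 or idx.max() >= self.parent.n_genes):
            raise DatasetError(
                f"feature index out of range [0, {self.parent.n_genes})"
            )
        if len(np.unique(idx)) != idx.size:
            raise DatasetError("duplicate feature index in subset")
        self.feature_indices = idx

    @property
    def matrix(self) -> np.ndarray:
        return self.parent.matrix[:, self.feature_indices]

    @property
    def gene_ids(self) -> list[str]:
        return [self.parent.gene_ids[i] for i in self.feature_indices]

    @property
    def labels(self) -> list[str]:
        return self.parent.labels

    @property
    def class_names(self) -> list[str]:
        return self.parent.class_names

    @property
    def y(self) -> np.ndarray:
        return self.parent.y

    @property
    def n_cells(self) -> int:
        return self.parent.n_cells

    @property
    def n_genes(self) -> int:
        return int(self.feature_indices.size)


def subset_features(ds: ExpressionDataset, indices) -> FeatureSubsetView:
    """View of ``ds`` restricted to the given gene columns, in order."""
    return FeatureSubsetView(ds, np.asarray(indices))


# ----------------------------------------------------------------------
# I/O
# ----------------------------------------------------------------------

def _read_id_file(path) -> list[str]:
    with open(path) as fh:
        return [line.rstrip("\n") for line in fh if line.rstrip("\n") != ""]


def _read_labels(path) -> dict[str, str]:
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise DatasetError(
                    f"{path}: line {ln} is not 'cell_id<TAB>tissue'"
                )
            mapping[parts[0]] = parts[1]
    return mapping


def load_dataset(matrix_path, genes_path, cells_path, labels_path,
                 fmt: str = "mtx") -> ExpressionDataset:
    """Read a dataset from disk and validate it.

    ``fmt`` is ``"mtx"`` (MatrixMarket, either orientation) or ``"csv"``
    (dense, cells as rows).  The labels file must map every cell id —
    and only those — to a tissue category; class order follows first
    appearance in the labels file.
    """
    for p in (matrix_path, genes_path, cells_path, labels_path):
        if not os.path.exists(p):
            raise DatasetError(f"missing input file: {p}")
    genes = _read_id_file(genes_path)
    cells = _read_id_file(cells_path)

    if fmt == "mtx":
        mat = mmread(matrix_path)
        if sparse.issparse(mat):
            mat = mat.toarray()
        mat = np.asarray(mat, dtype=np.float64)
        if mat.shape == (len(cells), len(genes)):
            pass
        elif mat.shape == (len(genes), len(cells)):
            mat = mat.T
        else:
            raise DatasetError(
                f"matrix shape {mat.shape} matches neither "
                f"(cells={len(cells)}, genes={len(genes)}) nor its transpose"
            )
    elif fmt == "csv":
        df = pd.read_csv(matrix_path, index_col=0,
                         float_precision="round_trip")
        if list(df.columns) != genes:
            raise DatasetError("gene axis mismatch: CSV header != genes file")
        if [str(i) for i in df.index] != cells:
            raise DatasetError("cell axis mismatch: CSV index != cells file")
        mat = df.to_numpy(dtype=np.float64)
    else:
        raise DatasetError(f"unsupported format: {fmt!r} (use 'mtx' or 'csv')")

    label_map = _read_labels(labels_path)
    unknown = set(label_map) - set(cells)
    if unknown:
        raise DatasetError(
            f"labels file mentions unknown cell id(s): {sorted(unknown)[:5]}"
        )
    missing = [c for c in cells if c not in label_map]
    if missing:
        raise DatasetError(
            f"labels file is missing cell id(s): {missing[:5]}"
        )
    labels = [label_map[c] for c in cells]
    # class order = first appearance in the labels *file*
    class_names = _class_names_from_labels(label_map.values())
    return ExpressionDataset(mat, genes, cells, labels, class_names)


def write_dataset(ds: ExpressionDataset, out_prefix, fmt: str = "mtx") -> list[str]:
    """Write ``ds`` as matrix + gene/cell/label sidecars; returns paths.

    ``load_dataset`` inverts this exactly (values are written with enough
    digits to round-trip float64).
    """
    out_prefix = str(out_prefix)
    d = os.path.dirname(out_prefix)
    if d:
        os.makedirs(d, exist_ok=True)
    genes_path = out_prefix + ".genes.tsv"
    cells_path = out_prefix + ".cells.tsv"
    labels_path = out_prefix + ".labels.tsv"

    if fmt == "mtx":
        matrix_path = out_prefix + ".mtx"
        mmwrite(matrix_path, sparse.coo_matrix(ds.matrix), precision=17)
    elif fmt == "csv":
        matrix_path = out_prefix + ".csv"
        df = pd.DataFrame(ds.matrix, index=ds.cell_ids, columns=ds.gene_ids)
        df.index.name = "cell_id"
        df.to_csv(matrix_path, float_format="%.17g")   # exact float64 round-trip
    else:
        raise DatasetError(f"unsupported format: {fmt!r} (use 'mtx' or 'csv')")

    with open(genes_path, "w") as fh:
        fh.writelines(g + "\n" for g in ds.gene_ids)
    with open(cells_path, "w") as fh:
        fh.writelines(c + "\n" for c in ds.cell_ids)
    with open(labels_path, "w") as fh:
        fh.writelines(f"{c}\t{l}\n" for c, l in zip(ds.cell_ids, ds.labels))
    return [matrix_path, genes_path, cells_path, labels_path]
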