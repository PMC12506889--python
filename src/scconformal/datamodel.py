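"""Dataset container, reference splits, and single-cell format I/O.

The pipeline's in-memory unit is :class:`CellDataset`: a dense cells x genes
expression matrix with cell/gene identifiers, optional per-cell type labels
and batch tags, and a ``layer_state`` flag recording whether the matrix holds
raw counts or CPM/log2-normalized values.  Reference data is partitioned into
train / validation / calibration / internal-test index sets by
:func:`make_splits`, stratified by cell type so that every class is present
in both the training and the calibration pools.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CellDataset",
    "SplitPlan",
    "load_dataset",
    "save_dataset",
    "align_feature_spaces",
    "make_splits",
]

RAW_COUNTS = "raw_counts"
CPM_LOG2 = "cpm_log2"


@dataclass
class CellDataset:
    """Expression matrix (cells x genes) with identifiers and annotations.

    Parameters
    ----------
    matrix
        Dense non-negative float array, shape ``(n_cells, n_genes)``.
    cell_ids, gene_ids
        Unique string identifiers for rows and columns.
    labels
        Optional per-cell categorical cell-type labels.
    batch
        Optional per-cell batch tags.
    layer_state
        ``"raw_counts"`` (integral entries) or ``"cpm_log2"``.
    """

    matrix: np.ndarray
    cell_ids: np.ndarray
    gene_ids: np.ndarray
    labels: Optional[np.ndarray] = None
    batch: Optional[np.ndarray] = None
    layer_state: str = RAW_COUNTS

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=object)
        if self.batch is not None:
            self.batch = np.asarray(self.batch, dtype=object)
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        n, p = self.matrix.shape
        if n != len(self.cell_ids) or p != len(self.gene_ids):
            raise ValueError(
                f"matrix shape {self.matrix.shape} does not match "
                f"{len(self.cell_ids)} cells x {len(self.gene_ids)} genes"
            )
        if len(set(self.cell_ids)) != n:
            raise ValueError("cell_ids are not unique")
        if len(set(self.gene_ids)) != p:
            raise ValueError("gene_ids are not unique")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("matrix contains non-finite entries")
        if np.any(self.matrix < 0):
            raise ValueError("matrix contains negative entries")
        if self.layer_state == RAW_COUNTS and self.matrix.size:
            if not np.allclose(self.matrix, np.round(self.matrix)):
                raise ValueError("raw_counts layer must hold integral values")
        if self.labels is not None and len(self.labels) != n:
            raise ValueError("labels length does not match number of cells")
        if self.batch is not None and len(self.batch) != n:
            raise ValueError("batch length does not match number of cells")

    # -- conveniences ----------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[1]

    @property
    def label_space(self) -> list:
        """Sorted list of distinct cell-type labels (the class order used
        everywhere downstream)."""
        if self.labels is None:
            raise ValueError("dataset has no labels")
        return sorted(set(self.labels))

    def subset_cells(self, idx: Sequence[int]) -> "CellDataset":
        idx = np.asarray(idx, dtype=int)
        return CellDataset(
            matrix=self.matrix[idx],
            cell_ids=self.cell_ids[idx],
            gene_ids=self.gene_ids,
            labels=None if self.labels is None else self.labels[idx],
            batch=None if self.batch is None else self.batch[idx],
            layer_state=self.layer_state,
        )

    def subset_genes(self, gidx: Sequence[int]) -> "CellDataset":
        gidx = np.asarray(gidx, dtype=int)
        return CellDataset(
            matrix=self.matrix[:, gidx],
            cell_ids=self.cell_ids,
            gene_ids=self.gene_ids[gidx],
            labels=self.labels,
            batch=self.batch,
            layer_state=self.layer_state,
        )


@dataclass
class SplitPlan:
    """Disjoint index sets partitioning reference cells into
    train / validation / calibration / internal-test."""

    train_idx: np.ndarray
    val_idx: np.ndarray
    cal_idx: np.ndarray
    test_idx: np.ndarray
    seed: int
    stratified: bool = True

    def __post_init__(self) -> None:
        parts = [self.train_idx, self.val_idx, self.cal_idx, self.test_idx]
        parts = [np.asarray(p, dtype=int) for p in parts]
        self.train_idx, self.val_idx, self.cal_idx, self.test_idx = parts
        combined = np.concatenate(parts)
        if len(combined) != len(set(combined.tolist())):
            raise ValueError("split index sets are not pairwise disjoint")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def load_dataset(
    path: str,
    format: str,
    label_key: Optional[str] = None,
    batch_key: Optional[str] = None,
) -> CellDataset:
    """Read a count matrix into a :class:`CellDataset` (``layer_state="raw_counts"``).

    Supported formats:

    ``h5ad``
        AnnData HDF5; labels/batch looked up in ``.obs[label_key]``.
    ``mtx``
        MatrixMarket cells x genes matrix with ``genes.tsv`` and
        ``barcodes.tsv`` sidecars next to it; an optional ``labels.tsv``
        sidecar (columns named by key) supplies annotations.
    ``csv``
        Comma-separated, first column cell id, header row gene ids; a label
        or batch column is referenced by its header name.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if format == "h5ad":
        return _load_h5ad(path, label_key, batch_key)
    if format == "mtx":
        return _load_mtx(path, label_key, batch_key)
    if format == "csv":
        return _load_csv(path, label_key, batch_key)
    raise ValueError(f"unknown format {format!r}; expected h5ad, mtx or csv")


def _lookup(table: pd.DataFrame, key: Optional[str], what: str) -> Optional[np.ndarray]:
    if key is None:
        return None
    if key not in table.columns:
        raise KeyError(
            f"{what} key {key!r} not found; available keys: {sorted(table.columns)}"
        )
    return table[key].to_numpy(dtype=object)


def _load_h5ad(path, label_key, batch_key) -> CellDataset:
    import anndata as ad

    adata = ad.read_h5ad(path)
    matrix = adata.X
    if not isinstance(matrix, np.ndarray):
        matrix = matrix.toarray()
    return CellDataset(
        matrix=np.asarray(matrix, dtype=float),
        cell_ids=adata.obs_names.to_numpy(dtype=object),
        gene_ids=adata.var_names.to_numpy(dtype=object),
        labels=_lookup(adata.obs, label_key, "label"),
        batch=_lookup(adata.obs, batch_key, "batch"),
        layer_state=RAW_COUNTS,
    )


def _load_mtx(path, label_key, batch_key) -> CellDataset:
    from scipy.io import mmread

    base = os.path.dirname(path)
    mat = mmread(path)
    if hasattr(mat, "toarray"):
        mat = mat.toarray()
    matrix = np.asarray(mat, dtype=float)
    genes = pd.read_csv(os.path.join(base, "genes.tsv"), sep="\t", header=None)[0]
    cells = pd.read_csv(os.path.join(base, "barcodes.tsv"), sep="\t", header=None)[0]
    labels = batch = None
    side = os.path.join(base, "labels.tsv")
    if label_key is not None or batch_key is not None:
        if not os.path.exists(side):
            raise KeyError(
                "label/batch key requested but no labels.tsv sidecar found"
            )
        table = pd.read_csv(side, sep="\t")
        labels = _lookup(table, label_key, "label")
        batch = _lookup(table, batch_key, "batch")
    return CellDataset(
        matrix=matrix,
        cell_ids=cells.to_numpy(dtype=object),
        gene_ids=genes.to_numpy(dtype=object),
        labels=labels,
        batch=batch,
        layer_state=RAW_COUNTS,
    )


def _load_csv(path, label_key, batch_key) -> CellDataset:
    table = pd.read_csv(path, index_col=0)
    labels = _lookup(table, label_key, "label") if label_key else None
    batch = _lookup(table, batch_key, "batch") if batch_key else None
    drop = [k for k in (label_key, batch_key) if k is not None]
    expr = table.drop(columns=drop)
    return CellDataset(
        matrix=expr.to_numpy(dtype=float),
        cell_ids=table.index.to_numpy(dtype=object),
        gene_ids=expr.columns.to_numpy(dtype=object),
        labels=labels,
        batch=batch,
        layer_state=RAW_COUNTS,
    )


def save_dataset(ds: CellDataset, path: str, format: str,
                 label_key: str = "cell_type", batch_key: str = "batch") -> None:
    """Write a :class:`CellDataset` in one of the supported formats (inverse of
    :func:`load_dataset` up to float representation)."""
    if format == "h5ad":
        import anndata as ad

        obs = pd.DataFrame(index=pd.Index(ds.cell_ids.astype(str), name="cell_id"))
        if ds.labels is not None:
            obs[label_key] = ds.labels.astype(str)
        if ds.batch is not None:
            obs[batch_key] = ds.batch.astype(str)
        adata = ad.AnnData(
            X=ds.matrix.copy(),
            obs=obs,
            var=pd.DataFrame(index=pd.Index(ds.gene_ids.astype(str), name="gene_id")),
        )
        adata.write_h5ad(path)
    elif format == "mtx":
        from scipy.io import mmwrite
        from scipy.sparse import csr_matrix

        base = os.path.dirname(path) or "."
        mmwrite(path, csr_matrix(ds.matrix))
        pd.Series(ds.gene_ids).to_csv(
            os.path.join(base, "genes.tsv"), sep="\t", header=False, index=False)
        pd.Series(ds.cell_ids).to_csv(
            os.path.join(base, "barcodes.tsv"), sep="\t", header=False, index=False)
        if ds.labels is not None or ds.batch is not None:
            table = pd.DataFrame(index=range(ds.n_cells))
            if ds.labels is not None:
                table[label_key] = ds.labels
            if ds.batch is not None:
                table[batch_key] = ds.batch
            table.to_csv(os.path.join(base, "labels.tsv"), sep="\t", index=False)
    elif format == "csv":
        table = pd.DataFrame(ds.matrix, index=ds.cell_ids, columns=ds.gene_ids)
        if ds.labels is not None:
            table[label_key] = ds.labels
        if ds.batch is not None:
            table[batch_key] = ds.batch
        table.to_csv(path)
    else:
        raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# Feature-space alignment and reference splitting
# ---------------------------------------------------------------------------

def align_feature_spaces(ref: CellDataset, query: CellDataset):
    """Restrict both datasets to the shared genes, ordered by the reference.

    Returns ``(ref_aligned, query_aligned)``.  Raises if the gene sets are
    disjoint.  Gene matching is by exact string identity of ``gene_ids``.
    """
    query_pos = {g: j for j, g in enumerate(query.gene_ids)}
    ref_keep = [i for i, g in enumerate(ref.gene_ids) if g in query_pos]
    if not ref_keep:
        raise ValueError("reference and query share no genes")
    query_keep = [query_pos[ref.gene_ids[i]] for i in ref_keep]
    return ref.subset_genes(ref_keep), query.subset_genes(query_keep)


def make_splits(
    ref: CellDataset,
    test_frac: float = 0.10,
    val_frac: float = 0.15,
    cal_frac_of_train: float = 0.40,
    seed: int = 0,
) -> SplitPlan:
    """Stratified partition of reference cells into internal-test, validation,
    calibration and proper-training index sets.

    The fractions are applied sequentially: ``test_frac`` of all reference
    cells go to the internal test set; ``val_frac`` of the remainder to
    validation; of the cells then left ("available training samples"),
    ``cal_frac_of_train`` go to calibration and the rest to proper training.
    Splitting is stratified by cell-type label and deterministic given
    ``seed``.
    """
    for name, f in (("test_frac", test_frac), ("val_frac", val_frac),
                    ("cal_frac_of_train", cal_frac_of_train)):
        if not (0.0 < f < 1.0):
            raise ValueError(f"{name} must lie in (0,1), got {f}")
    if ref.labels is None:
        raise ValueError("make_splits requires labels for stratification")

    counts = pd.Series(ref.labels).value_counts()
    too_small = counts[counts < 4]
    if len(too_small):
        raise ValueError(
            "classes with fewer than 4 cells cannot be stratified: "
            f"{sorted(too_small.index)}; apply filter_rare_types first"
        )

    rng = np.random.default_rng(seed)
    train, val, cal, test = [], [], [], []
    for cls in sorted(counts.index):
        idx = np.flatnonzero(ref.labels == cls)
        idx = rng.permutation(idx)
        n = len(idx)
        n_test = int(round(test_frac * n))
        n_val = int(round(val_frac * (n - n_test)))
        n_avail = n - n_test - n_val
        n_cal = int(round(cal_frac_of_train * n_avail))
        # every class must reach train and cal (classwise calibration)
        n_cal = max(1, min(n_cal, n_avail - 1))
        test.append(idx[:n_test])
        val.append(idx[n_test:n_test + n_val])
        cal.append(idx[n_test + n_val:n_test + n_val + n_cal])
        train.append(idx[n_test + n_val + n_cal:])
    return SplitPlan(
        train_idx=np.sort(np.concatenate(train)),
        val_idx=np.sort(np.concatenate(val)),
        cal_idx=np.sort(np.concatenate(cal)),
        test_idx=np.sort(np.concatenate(test)),
        seed=seed,
        stratified=True,
    )
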