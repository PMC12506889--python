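"""Quality control, normalization and feature selection.

The canonical order is QC filter -> rare-type filter -> CPM/log2
normalization -> highly-variable-gene selection -> optional batch
integration.  QC removes cells whose mitochondrial / ribosomal / hemoglobin
count fractions strictly exceed configurable thresholds (gene families are
matched by name prefix); cell types with fewer than ``min_cells`` reference
observations are dropped before splitting.  HVG selection uses the
dispersion-based flavor: genes are binned by mean expression and ranked by
the within-bin z-score of dispersion (variance/mean).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Tuple

import numpy as np
import pandas as pd

from .datamodel import CPM_LOG2, RAW_COUNTS, CellDataset

__all__ = [
    "QCThresholds",
    "qc_filter",
    "filter_rare_types",
    "normalize_cpm_log2",
    "select_hvg",
    "batch_integration_hook",
]


@dataclass
class QCThresholds:
    """Per-cell QC cutoffs; a cell is removed when a family's count fraction
    strictly exceeds its threshold."""

    mito_max_ratio: float = 0.10
    ribo_max_ratio: float = 0.60
    hemo_max_ratio: float = 0.60
    min_cells_per_type: int = 60
    mito_prefixes: Tuple[str, ...] = ("MT-", "mt-")
    ribo_prefixes: Tuple[str, ...] = ("RPS", "RPL")
    hemo_prefixes: Tuple[str, ...] = ("HB",)
    hemo_exclude_prefixes: Tuple[str, ...] = ("HBP",)

    def __post_init__(self) -> None:
        for name in ("mito_max_ratio", "ribo_max_ratio", "hemo_max_ratio"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0,1], got {v}")
        if self.min_cells_per_type < 1:
            raise ValueError("min_cells_per_type must be >= 1")


def _family_mask(gene_ids: np.ndarray, prefixes, exclude=()) -> np.ndarray:
    gene_ids = np.asarray(gene_ids, dtype=str)
    mask = np.zeros(len(gene_ids), dtype=bool)
    for p in prefixes:
        mask |= np.char.startswith(gene_ids, p)
    for p in exclude:
        mask &= ~np.char.startswith(gene_ids, p)
    return mask


def qc_filter(ds: CellDataset, thr: QCThresholds = QCThresholds()):
    """Remove low-quality cells / flagged doublets by gene-family count ratios.

    Returns ``(filtered_dataset, report)`` where the report is a DataFrame
    with one row per cell: the three ratios, whether it was removed, and the
    triggering rule(s).
    """
    if ds.layer_state != RAW_COUNTS:
        raise ValueError("qc_filter expects raw counts")
    totals = ds.matrix.sum(axis=1)
    safe = np.where(totals > 0, totals, 1.0)
    ratios = {}
    for fam, prefixes, exclude, cutoff in (
        ("mito", thr.mito_prefixes, (), thr.mito_max_ratio),
        ("ribo", thr.ribo_prefixes, (), thr.ribo_max_ratio),
        ("hemo", thr.hemo_prefixes, thr.hemo_exclude_prefixes, thr.hemo_max_ratio),
    ):
        mask = _family_mask(ds.gene_ids, prefixes, exclude)
        ratios[fam] = ds.matrix[:, mask].sum(axis=1) / safe

    report = pd.DataFrame({
        "cell_id": ds.cell_ids,
        "mito_ratio": ratios["mito"],
        "ribo_ratio": ratios["ribo"],
        "hemo_ratio": ratios["hemo"],
    })
    rules = []
    removed = np.zeros(ds.n_cells, dtype=bool)
    for fam, cutoff in (("mito", thr.mito_max_ratio),
                        ("ribo", thr.ribo_max_ratio),
                        ("hemo", thr.hemo_max_ratio)):
        hit = ratios[fam] > cutoff  # strict, as specified
        removed |= hit
        rules.append(np.where(hit, f"{fam}>{cutoff:g}", ""))
    report["removed"] = removed
    report["rule"] = [";".join(r for r in row if r)
                      for row in zip(*rules)]
    if removed.all():
        warnings.warn("qc_filter removed every cell")
    return ds.subset_cells(np.flatnonzero(~removed)), report


def filter_rare_types(ds: CellDataset, min_cells: int = 60) -> CellDataset:
    """Drop every cell whose type has fewer than ``min_cells`` observations;
    the label space shrinks accordingly."""
    if ds.labels is None:
        raise ValueError("filter_rare_types requires labels")
    counts = pd.Series(ds.labels).value_counts()
    keep_types = set(counts[counts >= min_cells].index)
    if not keep_types:
        raise ValueError(
            f"no cell type has >= {min_cells} observations; nothing would remain"
        )
    keep = np.array([lab in keep_types for lab in ds.labels])
    return ds.subset_cells(np.flatnonzero(keep))


def normalize_cpm_log2(ds: CellDataset) -> CellDataset:
    """Counts-per-million per cell followed by log2(x+1)."""
    if ds.layer_state != RAW_COUNTS:
        raise ValueError("normalize_cpm_log2 expects raw counts (already normalized?)")
    totals = ds.matrix.sum(axis=1)
    zero = np.flatnonzero(totals == 0)
    if len(zero):
        raise ValueError(
            f"cells with zero total count cannot be CPM-normalized: "
            f"{list(ds.cell_ids[zero[:5]])}"
        )
    cpm = ds.matrix / totals[:, None] * 1e6
    return CellDataset(
        matrix=np.log2(cpm + 1.0),
        cell_ids=ds.cell_ids,
        gene_ids=ds.gene_ids,
        labels=ds.labels,
        batch=ds.batch,
        layer_state=CPM_LOG2,
    )


def select_hvg(ref: CellDataset, n_top: int = 2000, n_bins: int = 20) -> List[int]:
    """Top highly-variable genes by mean-binned normalized dispersion.

    Per gene: dispersion = variance / mean (0 where the mean is 0).  Genes are
    cut into ``n_bins`` equal-width bins of mean expression and the dispersion
    is z-scored within each bin; the ``n_top`` genes with the largest
    normalized dispersion are returned (ties broken by gene index).  Computed
    on the reference only; the resulting gene index list is applied verbatim
    to the query.
    """
    if ref.layer_state != CPM_LOG2:
        raise ValueError("select_hvg expects cpm_log2 data")
    p = ref.n_genes
    if n_top >= p:
        if n_top > p:
            warnings.warn(f"n_top={n_top} > {p} genes; returning all genes")
        return list(range(p))
    means = ref.matrix.mean(axis=0)
    variances = ref.matrix.var(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        dispersion = np.where(means > 0, variances / np.where(means > 0, means, 1.0), 0.0)
    bins = pd.cut(means, bins=n_bins, labels=False, duplicates="drop")
    bins = np.asarray(bins, dtype=float)
    bins[np.isnan(bins)] = -1
    norm_disp = np.zeros(p)
    for b in np.unique(bins):
        members = np.flatnonzero(bins == b)
        d = dispersion[members]
        sd = d.std()
        norm_disp[members] = (d - d.mean()) / sd if sd > 0 else 0.0
    # stable sort descending on normalized dispersion, ascending gene index on ties
    order = np.lexsort((np.arange(p), -norm_disp))
    return sorted(order[:n_top].tolist())


def batch_integration_hook(ref: CellDataset, query: CellDataset, method: str = "none"):
    """Optional batch-effect integration of reference and query.

    ``method="none"`` returns the inputs unchanged.  ``method="external_harmony"``
    delegates to an installed ``harmonypy``; the algorithm is never
    reimplemented here.
    """
    if ref.layer_state != CPM_LOG2 or query.layer_state != CPM_LOG2:
        raise ValueError("batch integration expects cpm_log2 data")
    if list(ref.gene_ids) != list(query.gene_ids):
        raise ValueError("datasets must be gene-aligned before integration")
    if method == "none":
        return ref, query
    if method == "external_harmony":
        try:
            import harmonypy
        except ImportError as exc:
            raise ImportError(
                "external_harmony requires the harmonypy package; "
                "install it with `pip install harmonypy`"
            ) from exc
        version = getattr(harmonypy, "__version__", "unknown")
        data = np.vstack([ref.matrix, query.matrix])
        meta = pd.DataFrame({
            "dataset": ["ref"] * ref.n_cells + ["query"] * query.n_cells})
        out = harmonypy.run_harmony(data, meta, ["dataset"])
        corrected = np.maximum(np.asarray(out.Z_corr).T, 0.0)
        warnings.warn(f"harmonypy {version} applied to the expression matrix")
        ref_c = CellDataset(corrected[:ref.n_cells], ref.cell_ids, ref.gene_ids,
                            ref.labels, ref.batch, CPM_LOG2)
        query_c = CellDataset(corrected[ref.n_cells:], query.cell_ids,
                              query.gene_ids, query.labels, query.batch, CPM_LOG2)
        return ref_c, query_c
    raise ValueError(f"unknown integration method {method!r}")
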