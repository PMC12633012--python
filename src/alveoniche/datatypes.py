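"""Core data containers shared across the package.

Count matrices are stored genes x cells in CSR form, mirroring the usual
Matrix Market layout of droplet pipelines (genes.tsv rows, barcodes.tsv
columns).  Per-cell metadata lives in a DataFrame indexed by cell ID.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

MITO_PATTERN = r"^MT-"
RIBO_PATTERN = r"^RP[SL]"


def gene_mask(genes: Sequence[str], patterns: Sequence[str]) -> np.ndarray:
    """Boolean mask over ``genes`` matching any regex in ``patterns``."""
    rx = [re.compile(p) for p in patterns]
    return np.array([any(r.search(g) for r in rx) for g in genes], dtype=bool)


@dataclass
class CountMatrix:
    """Genes x cells non-negative integer counts with per-cell metadata."""

    genes: np.ndarray
    cells: np.ndarray
    counts: sp.csr_matrix
    cell_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.genes = np.asarray(self.genes, dtype=object)
        self.cells = np.asarray(self.cells, dtype=object)
        if not sp.issparse(self.counts):
            self.counts = sp.csr_matrix(self.counts)
        self.counts = self.counts.tocsr()
        if self.counts.shape != (len(self.genes), len(self.cells)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.genes)} genes x {len(self.cells)} cells"
            )
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("negative entries in count matrix")
        if len(set(self.cells)) != len(self.cells):
            raise ValueError("cell IDs are not unique")
        if not self.cell_meta.index.equals(pd.Index(self.cells)):
            self.cell_meta = self.cell_meta.reindex(self.cells)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def compute_qc_metrics(
        self,
        mito_patterns: Sequence[str] = (MITO_PATTERN,),
        ribo_patterns: Sequence[str] = (RIBO_PATTERN,),
        overwrite: bool = False,
    ) -> "CountMatrix":
        """Fill n_features / n_molecules / frac_mito / frac_ribo columns.

        Existing columns are kept unless ``overwrite``.
        """
        meta = self.cell_meta.copy()
        csc = self.counts.tocsc()
        totals = np.asarray(csc.sum(axis=0)).ravel()
        nfeat = np.asarray((csc > 0).sum(axis=0)).ravel()
        mmask = gene_mask(self.genes, mito_patterns)
        rmask = gene_mask(self.genes, ribo_patterns)
        with np.errstate(invalid="ignore", divide="ignore"):
            fmito = np.where(
                totals > 0, np.asarray(csc[mmask].sum(axis=0)).ravel() / np.maximum(totals, 1), 0.0
            )
            fribo = np.where(
                totals > 0, np.asarray(csc[rmask].sum(axis=0)).ravel() / np.maximum(totals, 1), 0.0
            )
        for col, vals in [
            ("n_features", nfeat),
            ("n_molecules", totals.astype(np.int64)),
            ("frac_mito", fmito),
            ("frac_ribo", fribo),
        ]:
            if overwrite or col not in meta.columns:
                meta[col] = vals
        return replace(self, cell_meta=meta)

    def subset_cells(self, mask_or_idx) -> "CountMatrix":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return CountMatrix(
            genes=self.genes,
            cells=self.cells[idx],
            counts=self.counts[:, idx].tocsr(),
            cell_meta=self.cell_meta.iloc[idx],
        )

    def subset_genes(self, mask_or_idx) -> "CountMatrix":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return CountMatrix(
            genes=self.genes[idx],
            cells=self.cells,
            counts=self.counts[idx].tocsr(),
            cell_meta=self.cell_meta,
        )


@dataclass
class NormalizedMatrix:
    """Log-normalized expression on the same axes as the source counts."""

    genes: np.ndarray
    cells: np.ndarray
    values: sp.csr_matrix
    scale_factor: float
    cell_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.genes = np.asarray(self.genes, dtype=object)
        self.cells = np.asarray(self.cells, dtype=object)
        if not sp.issparse(self.values):
            self.values = sp.csr_matrix(self.values)
        self.values = self.values.tocsr()

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def gene_index(self) -> dict:
        return {g: i for i, g in enumerate(self.genes)}

    def dense(self) -> np.ndarray:
        return np.asarray(self.values.todense())

    def subset_cells(self, mask_or_idx) -> "NormalizedMatrix":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return NormalizedMatrix(
            genes=self.genes,
            cells=self.cells[idx],
            values=self.values[:, idx].tocsr(),
            scale_factor=self.scale_factor,
            cell_meta=self.cell_meta.iloc[idx],
        )


@dataclass
class GeneSignature:
    """Named, ordered gene list (rank order is meaningful)."""

    name: str
    genes: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.genes = list(self.genes)
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"signature {self.name!r} contains duplicate genes")

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)


@dataclass
class SpatialCellMap:
    """Per-section table of cell centroids (um), labels and panel counts."""

    section_id: str
    cells: pd.DataFrame  # columns: cell_id, x_um, y_um, label (label may be absent)
    panel_genes: Optional[np.ndarray] = None
    panel_counts: Optional[sp.csr_matrix] = None  # genes x cells

    def __post_init__(self) -> None:
        req = {"cell_id", "x_um", "y_um"}
        missing = req - set(self.cells.columns)
        if missing:
            raise ValueError(f"spatial table missing columns: {sorted(missing)}")
        xy = self.cells[["x_um", "y_um"]].to_numpy(dtype=float)
        if not np.all(np.isfinite(xy)):
            raise ValueError(f"non-finite coordinates in section {self.section_id}")
        if self.cells["cell_id"].duplicated().any():
            raise ValueError(f"duplicate cell_ids in section {self.section_id}")
        self.cells = self.cells.reset_index(drop=True)
        if self.panel_genes is not None:
            self.panel_genes = np.asarray(self.panel_genes, dtype=object)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def coords(self) -> np.ndarray:
        return self.cells[["x_um", "y_um"]].to_numpy(dtype=float)

    def labels(self) -> np.ndarray:
        return self.cells["label"].to_numpy(dtype=object)
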