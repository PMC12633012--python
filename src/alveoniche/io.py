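"""Standard-format readers and writers.

Count matrices round-trip as Matrix Market triplets (genes x cells) with
genes.tsv / barcodes.tsv sidecars and a per-cell metadata CSV; spatial maps
as cells.csv (cell_id, section_id, x_um, y_um, label) plus an optional
panel count matrix.  CSV outputs carry a comment header naming the
producing stage and config hash; readers skip ``#`` lines.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

from .datatypes import CountMatrix, GeneSignature, SpatialCellMap


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def _write_csv(df: pd.DataFrame, path: Path, stage: str, cfg_hash: str, index: bool) -> None:
    with open(path, "w") as fh:
        fh.write(f"# alveoniche stage={stage} config={cfg_hash}\n")
        df.to_csv(fh, index=index, lineterminator="\n")


def read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_counts(
    m: CountMatrix, outdir, stage: str = "counts", cfg_hash: str = "none"
) -> None:
    """Write matrix.mtx + genes.tsv + barcodes.tsv + cell_meta.csv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mmwrite(
        str(outdir / "matrix.mtx"),
        m.counts.tocoo(),
        comment=f"alveoniche stage={stage} config={cfg_hash}",
        field="integer",
    )
    (outdir / "genes.tsv").write_text("\n".join(map(str, m.genes)) + "\n")
    (outdir / "barcodes.tsv").write_text("\n".join(map(str, m.cells)) + "\n")
    meta = m.cell_meta.copy()
    meta.index.name = "cell_id"
    _write_csv(meta, outdir / "cell_meta.csv", stage, cfg_hash, index=True)


def load_counts(path) -> CountMatrix:
    """Load a Matrix Market triplet directory (or a dense CSV file)."""
    path = Path(path)
    if path.is_file() and path.suffix == ".csv":
        df = pd.read_csv(path, index_col=0, comment="#")
        counts = sp.csr_matrix(df.to_numpy())
        genes = np.array(df.index, dtype=object)
        cells = np.array(df.columns, dtype=object)
        meta = pd.DataFrame(index=cells)
        return CountMatrix(genes=genes, cells=cells, counts=counts, cell_meta=meta)
    mtx = path / "matrix.mtx"
    if not mtx.exists():
        raise FileNotFoundError(f"no matrix.mtx under {path}")
    counts = sp.csr_matrix(mmread(str(mtx)))
    if counts.nnz and counts.data.min() < 0:
        raise ValueError(f"negative entries in {mtx}")
    genes = np.array(
        [l for l in (path / "genes.tsv").read_text().splitlines() if l], dtype=object
    )
    cells = np.array(
        [l for l in (path / "barcodes.tsv").read_text().splitlines() if l], dtype=object
    )
    if counts.shape != (len(genes), len(cells)):
        raise ValueError(
            f"{mtx}: shape {counts.shape} does not match {len(genes)} genes "
            f"x {len(cells)} barcodes"
        )
    meta_path = path / "cell_meta.csv"
    if meta_path.exists():
        meta = read_csv(meta_path).set_index("cell_id")
        missing = [c for c in cells if c not in meta.index]
        if missing:
            raise ValueError(f"barcodes missing from cell_meta.csv: {missing[:5]}")
        meta = meta.loc[cells]
    else:
        meta = pd.DataFrame(index=pd.Index(cells, name="cell_id"))
    return CountMatrix(genes=genes, cells=cells, counts=counts, cell_meta=meta)


def write_spatial(
    sections: Sequence[SpatialCellMap], outdir, stage: str = "spatial", cfg_hash: str = "none"
) -> None:
    """Write cells.csv (all sections) and per-section panel matrices."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    frames = []
    for s in sections:
        df = s.cells.copy()
        df.insert(1, "section_id", s.section_id)
        frames.append(df)
    _write_csv(pd.concat(frames, ignore_index=True), outdir / "cells.csv", stage, cfg_hash, index=False)
    for s in sections:
        if s.panel_counts is None:
            continue
        d = outdir / f"panel_{s.section_id}"
        d.mkdir(exist_ok=True)
        mmwrite(
            str(d / "matrix.mtx"),
            s.panel_counts.tocoo(),
            comment=f"alveoniche stage={stage} config={cfg_hash}",
            field="integer",
        )
        (d / "genes.tsv").write_text("\n".join(map(str, s.panel_genes)) + "\n")
        (d / "barcodes.tsv").write_text("\n".join(s.cells["cell_id"]) + "\n")


def load_spatial(
    path,
    min_counts: int = 25,
    max_gene_prevalence: float = 0.95,
) -> List[SpatialCellMap]:
    """Load cells.csv (+ optional panel matrices) into per-section maps.

    When panel counts are present, cells with total counts below
    ``min_counts`` are excluded (strict "less than" rule) and panel genes
    detected in more than ``max_gene_prevalence`` of cells are dropped.
    """
    path = Path(path)
    csv = path / "cells.csv" if path.is_dir() else path
    df = read_csv(csv)
    req = {"cell_id", "section_id", "x_um", "y_um"}
    missing = req - set(df.columns)
    if missing:
        raise ValueError(f"cells.csv missing columns: {sorted(missing)}")
    base = csv.parent
    out: List[SpatialCellMap] = []
    for sec, sub in df.groupby("section_id", sort=True):
        sub = sub.drop(columns=["section_id"]).reset_index(drop=True)
        panel_dir = base / f"panel_{sec}"
        panel_genes = panel_counts = None
        if panel_dir.exists():
            counts = sp.csc_matrix(mmread(str(panel_dir / "matrix.mtx")))
            genes = np.array(
                [l for l in (panel_dir / "genes.tsv").read_text().splitlines() if l],
                dtype=object,
            )
            barcodes = [
                l for l in (panel_dir / "barcodes.tsv").read_text().splitlines() if l
            ]
            order = pd.Index(barcodes).get_indexer(sub["cell_id"])
            if (order < 0).any():
                bad = sub["cell_id"][order < 0].iloc[0]
                raise ValueError(f"cell {bad!r} missing from panel barcodes")
            counts = counts[:, order]
            totals = np.asarray(counts.sum(axis=0)).ravel()
            keep_cells = totals >= min_counts
            sub = sub[keep_cells].reset_index(drop=True)
            counts = counts[:, keep_cells]
            prevalence = np.asarray((counts > 0).mean(axis=1)).ravel()
            keep_genes = prevalence <= max_gene_prevalence + 1e-9
            panel_genes = genes[keep_genes]
            panel_counts = sp.csr_matrix(counts[keep_genes])
        out.append(
            SpatialCellMap(
                section_id=str(sec),
                cells=sub,
                panel_genes=panel_genes,
                panel_counts=panel_counts,
            )
        )
    return out


def write_signatures_csv(
    sigs: Sequence[GeneSignature], path, stage: str = "signatures", cfg_hash: str = "none"
) -> None:
    rows = [
        {"signature": s.name, "rank": i + 1, "gene": g}
        for s in sigs
        for i, g in enumerate(s.genes)
    ]
    _write_csv(pd.DataFrame(rows), Path(path), stage, cfg_hash, index=False)


def write_signatures_gmt(sigs: Sequence[GeneSignature], path) -> None:
    with open(path, "w") as fh:
        for s in sigs:
            fh.write("\t".join([s.name, "alveoniche"] + list(s.genes)) + "\n")


def read_signatures_csv(path) -> List[GeneSignature]:
    df = read_csv(path)
    out = []
    for name, sub in df.groupby("signature", sort=True):
        sub = sub.sort_values("rank") if "rank" in sub.columns else sub
        out.append(GeneSignature(name=str(name), genes=sub["gene"].tolist()))
    return out
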