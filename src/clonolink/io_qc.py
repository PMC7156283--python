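"""Reading/writing single-cell count data and cell-quality filtering.

The expression substrate is a sparse cells x genes UMI count matrix with
per-cell metadata (tissue, treatment, replicate).  Files follow the standard
triplet convention: MatrixMarket matrix + barcodes.tsv + features.tsv, plus a
metadata CSV keyed on barcode.

Quality control removes cells with fewer than ``min_genes`` detected genes
(low-quality transcriptomes) or more than ``max_genes`` (putative doublets);
the removal is strict on both sides, so cells at exactly 500 or exactly 8,000
detected genes are retained under the defaults.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "CellMatrix",
    "QCReport",
    "NormalizedMatrix",
    "read_count_matrix",
    "write_count_matrix",
    "qc_filter",
    "log_normalize",
    "per_cell_summary",
    "to_anndata",
]

META_COLUMNS = ("tissue", "treatment", "replicate")


@dataclass
class CellMatrix:
    """Sparse UMI counts (cells x genes) with aligned per-cell metadata.

    ``cell_meta`` is indexed by barcode and carries at least tissue,
    treatment and replicate columns.
    """

    counts: sp.csr_matrix
    barcodes: list[str]
    gene_ids: list[str]
    gene_names: list[str]
    cell_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        n, g = self.counts.shape
        if n != len(self.barcodes):
            raise ValueError(
                f"matrix has {n} rows but {len(self.barcodes)} barcodes"
            )
        if g != len(self.gene_ids):
            raise ValueError(
                f"matrix has {g} columns but {len(self.gene_ids)} gene ids"
            )
        if len(set(self.barcodes)) != len(self.barcodes):
            raise ValueError("barcodes are not unique")
        if (self.counts.data < 0).any():
            raise ValueError("counts must be nonnegative")
        self.cell_meta = self.cell_meta.reindex(self.barcodes)

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def genes_detected(self) -> np.ndarray:
        """Number of genes with count > 0 per cell."""
        return np.asarray((self.counts > 0).sum(axis=1)).ravel()

    def total_molecules(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=1)).ravel()

    def subset_cells(self, mask: np.ndarray) -> "CellMatrix":
        """New CellMatrix keeping cells where mask is True (order preserved)."""
        mask = np.asarray(mask, dtype=bool)
        keep = [b for b, m in zip(self.barcodes, mask) if m]
        return CellMatrix(
            counts=self.counts[mask],
            barcodes=keep,
            gene_ids=list(self.gene_ids),
            gene_names=list(self.gene_names),
            cell_meta=self.cell_meta.loc[keep],
        )


@dataclass
class QCReport:
    n_cells_in: int
    n_cells_out: int
    removed_low: int
    removed_high: int
    min_genes: int
    max_genes: int
    genes_detected: pd.Series = field(repr=False)
    total_molecules: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        assert self.n_cells_in == self.n_cells_out + self.removed_low + self.removed_high


@dataclass
class NormalizedMatrix:
    """Real-valued expression matrix aligned with its source CellMatrix."""

    matrix: sp.csr_matrix
    barcodes: list[str]
    gene_names: list[str]
    description: str

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape

    def dense(self) -> np.ndarray:
        return np.asarray(self.matrix.todense())


def read_count_matrix(
    matrix_path: str | Path,
    barcodes_path: str | Path,
    features_path: str | Path,
    metadata_path: str | Path | None = None,
) -> CellMatrix:
    """Read a MatrixMarket triplet plus metadata into a :class:`CellMatrix`.

    Orientation is auto-detected: a genes x cells matrix (the 10x layout) is
    transposed so the result is always cells x genes.  Metadata is joined on
    barcode; a metadata barcode absent from the matrix is an error naming the
    barcode.
    """
    mat = sp.csr_matrix(scipy.io.mmread(str(matrix_path)))
    barcodes = _read_single_column(barcodes_path)
    feats = pd.read_csv(features_path, sep="\t", header=None, dtype=str)
    gene_ids = feats[0].tolist()
    gene_names = feats[1].tolist() if feats.shape[1] > 1 else list(gene_ids)

    nb, ng = len(barcodes), len(gene_ids)
    if mat.shape == (nb, ng):
        pass
    elif mat.shape == (ng, nb):
        mat = sp.csr_matrix(mat.T)
    else:
        raise ValueError(
            f"matrix shape {mat.shape} matches neither {nb} barcodes x {ng} "
            f"features nor its transpose"
        )

    if metadata_path is not None:
        meta = pd.read_csv(metadata_path, dtype={"replicate": str})
        if "barcode" not in meta.columns:
            raise ValueError("metadata file must have a 'barcode' column")
        missing = set(meta["barcode"]) - set(barcodes)
        if missing:
            raise ValueError(
                f"metadata barcode not present in matrix: {sorted(missing)[0]!r}"
            )
        meta = meta.set_index("barcode")
    else:
        meta = pd.DataFrame(index=pd.Index(barcodes, name="barcode"))
    return CellMatrix(mat, barcodes, gene_ids, gene_names, meta)


def write_count_matrix(cm: CellMatrix, outdir: str | Path) -> dict[str, Path]:
    """Write the triplet + metadata files; returns the paths written.

    The matrix is stored genes x cells (10x convention);
    :func:`read_count_matrix` transposes it back.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": outdir / "matrix.mtx",
        "barcodes": outdir / "barcodes.tsv",
        "features": outdir / "features.tsv",
        "metadata": outdir / "metadata.csv",
    }
    scipy.io.mmwrite(str(paths["matrix"]), sp.coo_matrix(cm.counts.T), field="integer")
    paths["barcodes"].write_text("\n".join(cm.barcodes) + "\n")
    with open(paths["features"], "w") as fh:
        for gid, gname in zip(cm.gene_ids, cm.gene_names):
            fh.write(f"{gid}\t{gname}\n")
    cm.cell_meta.reset_index().rename(columns={"index": "barcode"}).to_csv(
        paths["metadata"], index=False
    )
    return paths


def qc_filter(
    cm: CellMatrix, min_genes: int = 500, max_genes: int = 8000
) -> tuple[CellMatrix, QCReport]:
    """Remove cells with < min_genes or > max_genes detected genes.

    Cells at exactly the boundaries are retained.  Ordering of the surviving
    cells is preserved.  An empty result is permitted (warning, not error).
    """
    if min_genes > max_genes:
        raise ValueError("min_genes must be <= max_genes")
    detected = cm.genes_detected()
    low = detected < min_genes
    high = detected > max_genes
    keep = ~(low | high)
    if not keep.any():
        warnings.warn("qc_filter removed every cell", stacklevel=2)
    report = QCReport(
        n_cells_in=cm.n_cells,
        n_cells_out=int(keep.sum()),
        removed_low=int(low.sum()),
        removed_high=int(high.sum()),
        min_genes=min_genes,
        max_genes=max_genes,
        genes_detected=pd.Series(detected, index=cm.barcodes),
        total_molecules=pd.Series(cm.total_molecules(), index=cm.barcodes),
    )
    return cm.subset_cells(keep), report


def log_normalize(cm: CellMatrix, scale: float = 1e4) -> NormalizedMatrix:
    """Library-size normalization to ``scale`` counts per cell, then log1p.

    value = log(1 + scale * count / cell_total).  An all-zero cell passes
    through as zeros with a warning.
    """
    totals = cm.total_molecules().astype(float)
    zero = totals == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} all-zero cell(s) left as zeros", stacklevel=2)
        totals[zero] = 1.0
    factors = scale / totals
    mat = sp.csr_matrix(cm.counts, dtype=float, copy=True)
    # row-scale then log1p on the stored entries only
    mat = sp.diags(factors) @ mat
    mat.data = np.log1p(mat.data)
    return NormalizedMatrix(
        matrix=sp.csr_matrix(mat),
        barcodes=list(cm.barcodes),
        gene_names=list(cm.gene_names),
        description=f"log1p(count/total*{scale:g})",
    )


def per_cell_summary(cm: CellMatrix) -> pd.DataFrame:
    """Per-cell genes_detected and total molecules, with metadata columns.

    Group means by treatment (molecule/gene recovery concordance between
    arms) are one ``groupby`` away:
    ``per_cell_summary(cm).groupby("treatment")[["total_molecules"]].mean()``.
    """
    if cm.n_cells == 0:
        return pd.DataFrame(
            columns=["barcode", "genes_detected", "total_molecules", *META_COLUMNS]
        )
    df = pd.DataFrame(
        {
            "barcode": cm.barcodes,
            "genes_detected": cm.genes_detected(),
            "total_molecules": cm.total_molecules(),
        }
    )
    for col in META_COLUMNS:
        if col in cm.cell_meta.columns:
            df[col] = cm.cell_meta[col].to_numpy()
    return df


def to_anndata(cm: CellMatrix, nm: NormalizedMatrix | None = None):
    """Convert to an :class:`anndata.AnnData` (counts in ``layers['counts']``)."""
    import anndata as ad

    adata = ad.AnnData(
        X=(nm.matrix if nm is not None else cm.counts.astype(float)).copy(),
        obs=cm.cell_meta.copy(),
        var=pd.DataFrame({"gene_name": cm.gene_names}, index=cm.gene_ids),
    )
    adata.obs_names = cm.barcodes
    adata.layers["counts"] = cm.counts.copy()
    return adata


def _read_single_column(path: str | Path) -> list[str]:
    return [ln.split("\t")[0] for ln in Path(path).read_text().splitlines() if ln]
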