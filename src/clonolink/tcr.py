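"""Single-cell TCR parsing, the single-productive-pair rule, and clonotypes.

A cell enters the clonotype analysis only if it has exactly one productive
TRA contig and exactly one productive TRB contig; extra non-productive
contigs do not disqualify it, but a second productive contig of either chain
does.  A clonotype is the exact key (alpha V, alpha J, alpha CDR3, beta V,
beta J, beta CDR3); CDR3 identity is at the nucleotide level by default and
allele suffixes on gene calls (``*01``) are stripped before comparison.
TCR cells are merged with the transcriptome by the shared cell barcode.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple
import warnings

import pandas as pd

from .io_qc import CellMatrix
from .cell_state import CellStateAssignment

__all__ = [
    "ContigRecord",
    "PairedTcr",
    "Clonotype",
    "LinkedDataset",
    "read_contigs",
    "filter_paired_cells",
    "assign_clonotypes",
    "merge_tcr_transcriptome",
]

REQUIRED_COLUMNS = ("barcode", "chain", "v_gene", "j_gene", "cdr3", "cdr3_nt", "productive")
_TRUTHY = {"true", "t", "1", "yes"}


class ContigRecord(NamedTuple):
    barcode: str
    chain: str
    v_gene: str
    j_gene: str
    cdr3: str
    cdr3_nt: str
    productive: bool


class ChainCall(NamedTuple):
    v_gene: str
    j_gene: str
    cdr3_nt: str
    cdr3_aa: str


class PairedTcr(NamedTuple):
    barcode: str
    alpha: ChainCall
    beta: ChainCall


@dataclass
class Clonotype:
    id: str
    key: tuple
    barcodes: list[str]

    @property
    def size(self) -> int:
        return len(self.barcodes)


@dataclass
class LinkedDataset:
    """Cells present in both the TCR and transcriptome tables.

    ``cells`` is indexed by barcode with columns clonotype_id, state,
    tissue, treatment, replicate.
    """

    cells: pd.DataFrame
    n_tcr_only: int = 0
    n_transcriptome_only: int = 0
    clonotypes: list[Clonotype] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.cells)


def read_contigs(path: str | Path) -> pd.DataFrame:
    """Read a 10x-style contig annotation CSV into a typed table.

    Unknown chains are preserved as "other".  A missing required column is
    an error naming the column.
    """
    df = pd.read_csv(path, dtype=str)
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"contig file is missing required column {col!r}")
    df = df.loc[:, list(REQUIRED_COLUMNS)].copy()
    df["chain"] = df["chain"].where(df["chain"].isin(["TRA", "TRB"]), "other")
    df["productive"] = (
        df["productive"].astype(str).str.strip().str.lower().isin(_TRUTHY)
    )
    df["cdr3_nt"] = df["cdr3_nt"].fillna("")
    bad = df[df["productive"] & (df["cdr3_nt"] == "")]
    if len(bad):
        raise ValueError(
            f"productive contig with empty cdr3_nt at barcode {bad.iloc[0]['barcode']!r}"
        )
    return df


def filter_paired_cells(contigs: pd.DataFrame) -> list[PairedTcr]:
    """Keep barcodes with exactly one productive TRA and one productive TRB.

    Non-productive contigs are ignored when counting; two or more productive
    contigs of the same chain exclude the cell.
    """
    prod = contigs[contigs["productive"].astype(bool)]
    pairs: list[PairedTcr] = []
    for bc, grp in prod.groupby("barcode", sort=True):
        tra = grp[grp["chain"] == "TRA"]
        trb = grp[grp["chain"] == "TRB"]
        if len(tra) != 1 or len(trb) != 1:
            continue
        a, b = tra.iloc[0], trb.iloc[0]
        pairs.append(
            PairedTcr(
                barcode=bc,
                alpha=ChainCall(a["v_gene"], a["j_gene"], a["cdr3_nt"], a["cdr3"]),
                beta=ChainCall(b["v_gene"], b["j_gene"], b["cdr3_nt"], b["cdr3"]),
            )
        )
    return pairs


def _strip_allele(gene: str) -> str:
    return gene.split("*", 1)[0]


def clonotype_key(
    pair: PairedTcr, cdr3_level: str = "nt", strip_alleles: bool = True
) -> tuple:
    """Exact-identity clonotype key of a paired TCR."""
    if cdr3_level not in ("nt", "aa"):
        raise ValueError("cdr3_level must be 'nt' or 'aa'")
    fix = _strip_allele if strip_alleles else (lambda g: g)
    a_cdr3 = pair.alpha.cdr3_nt if cdr3_level == "nt" else pair.alpha.cdr3_aa
    b_cdr3 = pair.beta.cdr3_nt if cdr3_level == "nt" else pair.beta.cdr3_aa
    return (
        fix(pair.alpha.v_gene), fix(pair.alpha.j_gene), a_cdr3,
        fix(pair.beta.v_gene), fix(pair.beta.j_gene), b_cdr3,
    )


def assign_clonotypes(
    pairs: list[PairedTcr], cdr3_level: str = "nt", strip_alleles: bool = True
) -> list[Clonotype]:
    """Partition paired cells by exact clonotype-key equality.

    Ids are assigned in sorted-key order, so the partition (and the ids) are
    invariant to input order.  A duplicate barcode is an error.
    """
    if not pairs:
        raise ValueError("no paired cells to assign")
    seen: set[str] = set()
    groups: dict[tuple, list[str]] = {}
    for p in pairs:
        if p.barcode in seen:
            raise ValueError(f"duplicate barcode {p.barcode!r}")
        seen.add(p.barcode)
        groups.setdefault(clonotype_key(p, cdr3_level, strip_alleles), []).append(p.barcode)
    width = max(4, len(str(len(groups))))
    return [
        Clonotype(id=f"CT{i:0{width}d}", key=key, barcodes=sorted(groups[key]))
        for i, key in enumerate(sorted(groups), start=1)
    ]


def merge_tcr_transcriptome(
    clonotypes: list[Clonotype],
    cm: CellMatrix,
    assign: CellStateAssignment | None = None,
) -> LinkedDataset:
    """Inner join of clonotyped cells with the transcriptome on barcode.

    Cells lacking either side are dropped and counted in the report fields.
    """
    clono_of = {bc: ct.id for ct in clonotypes for bc in ct.barcodes}
    matrix_bcs = set(cm.barcodes)
    shared = [bc for bc in sorted(clono_of) if bc in matrix_bcs]
    n_tcr_only = len(clono_of) - len(shared)
    n_tx_only = len(matrix_bcs) - len(shared)
    if not shared:
        warnings.warn("no barcodes shared between TCR and transcriptome", stacklevel=2)
    cells = pd.DataFrame(index=pd.Index(shared, name="barcode"))
    cells["clonotype_id"] = [clono_of[bc] for bc in shared]
    if assign is not None:
        cells["state"] = assign.labels.reindex(shared)
    for col in ("tissue", "treatment", "replicate"):
        if col in cm.cell_meta.columns:
            cells[col] = cm.cell_meta[col].reindex(shared)
    kept = [
        Clonotype(ct.id, ct.key, [bc for bc in ct.barcodes if bc in matrix_bcs])
        for ct in clonotypes
    ]
    kept = [ct for ct in kept if ct.size > 0]
    return LinkedDataset(
        cells=cells,
        n_tcr_only=n_tcr_only,
        n_transcriptome_only=n_tx_only,
        clonotypes=kept,
    )
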