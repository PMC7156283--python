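from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from clonolink import (
    CellMatrix,
    NormalizedMatrix,
    SyntheticConfig,
    generate_dataset,
    log_normalize,
    qc_filter,
    assign_clonotypes,
    filter_paired_cells,
    merge_tcr_transcriptome,
)
from clonolink.cell_state import CellStateAssignment
from clonolink.tcr import LinkedDataset


def make_cell_matrix(counts, tissue=None, treatment=None, replicate=None) -> CellMatrix:
    counts = np.asarray(counts)
    n, g = counts.shape
    barcodes = [f"BC{i:04d}" for i in range(n)]
    meta = pd.DataFrame(
        {
            "tissue": tissue if tissue is not None else ["spleen"] * n,
            "treatment": treatment if treatment is not None else ["Iso"] * n,
            "replicate": replicate if replicate is not None else ["1"] * n,
        },
        index=pd.Index(barcodes, name="barcode"),
    )
    return CellMatrix(
        counts=sp.csr_matrix(counts),
        barcodes=barcodes,
        gene_ids=[f"G{j:04d}" for j in range(g)],
        gene_names=[f"Gene{j:04d}" for j in range(g)],
        cell_meta=meta,
    )


def make_linked(records) -> LinkedDataset:
    """LinkedDataset from (barcode, clonotype_id, state, tissue, treatment[, replicate])."""
    cols = ["barcode", "clonotype_id", "state", "tissue", "treatment", "replicate"]
    rows = [list(r) + ["1"] * (6 - len(r)) for r in records]
    cells = pd.DataFrame(rows, columns=cols).set_index("barcode")
    return LinkedDataset(cells=cells)


def linked_from_truth(cm, contigs, truth) -> LinkedDataset:
    """Linked dataset using the planted state labels (bypasses clustering)."""
    pairs = filter_paired_cells(contigs)
    clonotypes = assign_clonotypes(pairs)
    assign = CellStateAssignment(labels=truth.state.copy(), resolution=0.0)
    return merge_tcr_transcriptome(clonotypes, cm, assign)


@pytest.fixture(scope="session")
def small_dataset():
    """800-cell default-structured dataset shared by fast tests."""
    cfg = SyntheticConfig(n_cells=800, seed=7)
    return generate_dataset(cfg), cfg


@pytest.fixture(scope="session")
def study_dataset():
    """Study-scale recovery dataset: 5,000 cells, 10 states, marker fold 4."""
    cfg = SyntheticConfig(n_cells=5000, seed=11)
    return generate_dataset(cfg), cfg


@pytest.fixture(scope="session")
def small_linked(small_dataset):
    # no QC here: exact-recovery checks need every planted cell present
    (cm, contigs, truth), _ = small_dataset
    nm = log_normalize(cm)
    return linked_from_truth(cm, contigs, truth), nm, truth
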