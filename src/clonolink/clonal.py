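"""Clonal-family statistics: cell-state axes, chord links, tissue sharing,
expansion summaries, and the associated Fisher exact tests.

A clonal family (CF) is a clonotype observed in at least two linked cells.
The cell-state-axis statistic counts, per treatment condition, every
unordered pair of same-family cells and attributes it to the unordered pair
of states of its two members (same-state pairs, e.g. C4-C4, count); the
axis frequency divides that pair count by the total number of clonotypes
(singletons included) in the analyzed subset.  Spleen and lung cells only by
default, mirroring the network analysis this statistic feeds.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .tcr import LinkedDataset

__all__ = [
    "ClonalFamily",
    "find_clonal_families",
    "family_counts",
    "axis_frequencies",
    "chord_links",
    "tissue_sharing",
    "cf_treatment_test",
    "expansion_summary",
    "percent_change",
]


@dataclass
class ClonalFamily:
    clonotype_id: str
    members: pd.DataFrame  # index barcode; columns state, tissue, treatment, replicate

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def tissues(self) -> set[str]:
        return set(self.members["tissue"])

    @property
    def states(self) -> set[str]:
        return set(self.members["state"]) if "state" in self.members else set()


def _families_from_cells(cells: pd.DataFrame) -> list[ClonalFamily]:
    sizes = cells["clonotype_id"].value_counts()
    fam_ids = sorted(sizes[sizes >= 2].index)
    return [
        ClonalFamily(fid, cells[cells["clonotype_id"] == fid].sort_index())
        for fid in fam_ids
    ]


def find_clonal_families(linked: LinkedDataset) -> list[ClonalFamily]:
    """Clonotypes shared by at least two linked cells."""
    return _families_from_cells(linked.cells)


def family_counts(linked: LinkedDataset) -> pd.DataFrame:
    """Per-condition clonotype / CF / CF-cell counts."""
    rows = []
    for trt, grp in linked.cells.groupby("treatment", sort=True):
        sizes = grp["clonotype_id"].value_counts()
        rows.append(
            {
                "treatment": trt,
                "n_cells": len(grp),
                "n_clonotypes": len(sizes),
                "n_CFs": int((sizes >= 2).sum()),
                "n_CF_cells": int(sizes[sizes >= 2].sum()),
            }
        )
    return pd.DataFrame(rows)


def axis_frequencies(
    linked: LinkedDataset,
    treatment: str | None = None,
    tissues: tuple[str, ...] | None = ("spleen", "lung"),
    denominator: str = "clonotypes",
) -> pd.DataFrame:
    """Shared-cell-pair counts and frequencies per unordered state pair.

    Cells are restricted to ``tissues`` (spleen + lung by default) and, if
    given, to one treatment; families and the clonotype denominator are
    recomputed inside that subset.  ``denominator`` is "clonotypes" (all
    clonotypes in the subset, singletons included) or "cf_pairs" (total
    same-family pairs).
    """
    cells = linked.cells
    if "state" not in cells.columns or cells["state"].isna().any():
        raise ValueError("every linked cell must carry a state label")
    if treatment is not None:
        cells = cells[cells["treatment"] == treatment]
    if tissues is not None:
        cells = cells[cells["tissue"].isin(tissues)]
    n_clonotypes = cells["clonotype_id"].nunique()
    pair_counts: dict[tuple[str, str], int] = {}
    for fam in _families_from_cells(cells):
        for a, b in itertools.combinations(fam.members["state"], 2):
            key = tuple(sorted((a, b)))
            pair_counts[key] = pair_counts.get(key, 0) + 1
    total_pairs = sum(pair_counts.values())
    denom = n_clonotypes if denominator == "clonotypes" else max(total_pairs, 1)
    if denominator not in ("clonotypes", "cf_pairs"):
        raise ValueError("denominator must be 'clonotypes' or 'cf_pairs'")
    rows = [
        {
            "state_a": a,
            "state_b": b,
            "pair_count": c,
            "frequency": c / denom if denom else np.nan,
            "condition": treatment if treatment is not None else "all",
        }
        for (a, b), c in sorted(pair_counts.items())
    ]
    df = pd.DataFrame(
        rows, columns=["state_a", "state_b", "pair_count", "frequency", "condition"]
    )
    df.attrs["n_clonotypes"] = n_clonotypes
    df.attrs["total_pairs"] = total_pairs
    return df


def chord_links(linked: LinkedDataset) -> pd.DataFrame:
    """All unordered same-clonotype cell pairs with tissue/state annotation.

    A family of size n contributes C(n, 2) links; the class is
    "intra-<tissue>" when both members share the tissue, else "inter-tissue".
    Ordering is deterministic (family id, then barcode pairs).
    """
    rows = []
    for fam in find_clonal_families(linked):
        m = fam.members
        for (bc_a, row_a), (bc_b, row_b) in itertools.combinations(m.iterrows(), 2):
            same = row_a["tissue"] == row_b["tissue"]
            rows.append(
                {
                    "cell_a": bc_a,
                    "cell_b": bc_b,
                    "clonotype_id": fam.clonotype_id,
                    "tissue_a": row_a["tissue"],
                    "tissue_b": row_b["tissue"],
                    "state_a": row_a.get("state"),
                    "state_b": row_b.get("state"),
                    "link_class": f"intra-{row_a['tissue']}" if same else "inter-tissue",
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "cell_a", "cell_b", "clonotype_id", "tissue_a", "tissue_b",
            "state_a", "state_b", "link_class",
        ],
    )


def tissue_sharing(linked: LinkedDataset) -> tuple[pd.DataFrame, dict[str, float]]:
    """Inter- vs intra-tissue CF percentages per treatment, with Fisher tests.

    A CF is inter-tissue if its members span >= 2 tissues.  Percentages are
    relative to the total number of clonotypes in that treatment.  For each
    class, a 2x2 Fisher exact test ([class CFs, other clonotypes] x
    treatment) tests the treatment effect on that class's frequency.
    """
    per_trt: dict[str, dict[str, int]] = {}
    for trt, grp in linked.cells.groupby("treatment", sort=True):
        fams = _families_from_cells(grp)
        inter = sum(1 for f in fams if len(f.tissues) >= 2)
        per_trt[trt] = {
            "n_clonotypes": grp["clonotype_id"].nunique(),
            "n_inter": inter,
            "n_intra": len(fams) - inter,
        }
    rows = []
    for trt, d in per_trt.items():
        denom = d["n_clonotypes"]
        rows.append(
            {
                "condition": trt,
                "n_clonotypes": denom,
                "n_inter_tissue_CF": d["n_inter"],
                "n_intra_tissue_CF": d["n_intra"],
                "pct_inter_tissue_CF": 100.0 * d["n_inter"] / denom if denom else 0.0,
                "pct_intra_tissue_CF": 100.0 * d["n_intra"] / denom if denom else 0.0,
            }
        )
    table = pd.DataFrame(rows)
    fisher: dict[str, float] = {}
    if {"Iso", "IL2M"} <= set(per_trt):
        for cls in ("inter", "intra"):
            t = [
                [per_trt[trt][f"n_{cls}"], per_trt[trt]["n_clonotypes"] - per_trt[trt][f"n_{cls}"]]
                for trt in ("Iso", "IL2M")
            ]
            fisher[cls] = float(stats.fisher_exact(t, alternative="two-sided")[1])
    return table, fisher


def cf_treatment_test(linked: LinkedDataset) -> float:
    """Fisher exact test of independence between CF membership and treatment.

    2x2 table: (cell in a CF vs not) x (Iso vs IL2M), two-sided.
    """
    counts = family_counts(linked).set_index("treatment")
    if not {"Iso", "IL2M"} <= set(counts.index):
        raise ValueError("both treatments must be present")
    table = [
        [int(counts.loc[trt, "n_CF_cells"]),
         int(counts.loc[trt, "n_cells"] - counts.loc[trt, "n_CF_cells"])]
        for trt in ("Iso", "IL2M")
    ]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def percent_change(before: float, after: float) -> float:
    """(after - before) / before * 100; NaN when before is zero."""
    if before == 0:
        return float("nan")
    return (after - before) / before * 100.0


def expansion_summary(linked: LinkedDataset) -> pd.DataFrame:
    """Per-treatment TCR-cell / clonotype / CF-cell counts with the
    IL2M-vs-Iso percent changes (rounded for display, unrounded retained)."""
    counts = family_counts(linked).set_index("treatment")
    if not {"Iso", "IL2M"} <= set(counts.index):
        raise ValueError("both treatments must be present")
    out = counts.reset_index()
    for col, name in [
        ("n_CF_cells", "pct_change_CF_cells"),
        ("n_cells", "pct_change_TCR_cells"),
        ("n_clonotypes", "pct_change_clonotypes"),
    ]:
        change = percent_change(counts.loc["Iso", col], counts.loc["IL2M", col])
        out[name] = change
        out[name + "_display"] = (
            int(round(change)) if np.isfinite(change) else pd.NA
        )
    return out
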