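"""Transcriptional correlation of same-clonotype cell pairs vs a resampled
null of unrelated pairs.

Same-clonotype correlations: one Pearson correlation per unordered pair of
cells that share a clonal family, computed on log-normalized expression of
the most variable genes.  The null: pairs of linked cells that do NOT share
a clonal family, sampled uniformly without replacement.  The two groups are
compared with a two-tailed t test, optionally after subsampling the larger
group to the smaller group's size ("equal numbers" mode).
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats

from .io_qc import NormalizedMatrix
from .tcr import LinkedDataset
from .clonal import find_clonal_families

__all__ = [
    "top_variable_genes",
    "same_clonotype_correlations",
    "sample_null_correlations",
    "compare_correlations",
]


def top_variable_genes(nm: NormalizedMatrix, n_top: int = 2000) -> np.ndarray:
    """Column indices of the ``n_top`` highest-variance genes."""
    X = nm.matrix
    mean = np.asarray(X.mean(axis=0)).ravel()
    meansq = np.asarray(X.multiply(X).mean(axis=0)).ravel()
    var = meansq - mean**2
    n_top = min(n_top, X.shape[1])
    idx = np.argsort(var)[::-1][:n_top]
    return np.sort(idx)


def _standardized_rows(
    nm: NormalizedMatrix, barcodes: list[str], gene_idx: np.ndarray
) -> tuple[np.ndarray, dict[str, int]]:
    order = {bc: i for i, bc in enumerate(barcodes)}
    lookup = {bc: i for i, bc in enumerate(nm.barcodes)}
    pos = [lookup[bc] for bc in barcodes]
    X = nm.dense()[np.ix_(pos, gene_idx)]
    X = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(X, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return X / norms, order


def _pair_corr(Z: np.ndarray, i: int, j: int) -> float:
    return float(np.clip(Z[i] @ Z[j], -1.0, 1.0))


def same_clonotype_correlations(
    linked: LinkedDataset,
    nm: NormalizedMatrix,
    n_top_genes: int = 2000,
    gene_idx: np.ndarray | None = None,
) -> pd.DataFrame:
    """Pearson correlation for every unordered same-family cell pair."""
    fams = find_clonal_families(linked)
    if not fams:
        raise ValueError("no clonal families in the linked dataset")
    if gene_idx is None:
        gene_idx = top_variable_genes(nm, n_top_genes)
    bcs = sorted({bc for f in fams for bc in f.members.index})
    Z, order = _standardized_rows(nm, bcs, gene_idx)
    rows = []
    for fam in fams:
        for a, b in itertools.combinations(sorted(fam.members.index), 2):
            rows.append(
                {
                    "label": "same_clonotype",
                    "cell_a": a,
                    "cell_b": b,
                    "correlation": _pair_corr(Z, order[a], order[b]),
                }
            )
    return pd.DataFrame(rows)


def sample_null_correlations(
    linked: LinkedDataset,
    nm: NormalizedMatrix,
    n_pairs: int = 10000,
    seed: int = 0,
    n_top_genes: int = 2000,
    gene_idx: np.ndarray | None = None,
) -> pd.DataFrame:
    """Correlations of randomly sampled pairs that never share a family.

    Pairs are drawn uniformly without replacement among eligible pairs; if
    fewer than ``n_pairs`` are eligible, all of them are returned (the
    DataFrame's ``attrs["exhaustive"]`` flags this).  Deterministic given
    ``seed``.
    """
    cells = linked.cells
    sizes = cells["clonotype_id"].value_counts()
    fam_ids = set(sizes[sizes >= 2].index)
    bcs = list(cells.index)
    fam_of = {
        bc: (cid if cid in fam_ids else None)
        for bc, cid in cells["clonotype_id"].items()
    }
    n = len(bcs)
    if n < 2:
        raise ValueError("need at least two linked cells")
    rng = np.random.default_rng(seed)
    total_pairs = n * (n - 1) // 2
    # eligible pair count: all pairs minus same-family pairs
    co_familial = sum(
        s * (s - 1) // 2 for s in sizes[sizes >= 2]
    )
    n_eligible = total_pairs - co_familial
    if n_eligible == 0:
        raise ValueError("no eligible (non-co-familial) pairs")
    exhaustive = n_eligible <= n_pairs
    if exhaustive or total_pairs <= 4 * n_pairs:
        all_pairs = [
            (i, j)
            for i in range(n)
            for j in range(i + 1, n)
            if fam_of[bcs[i]] is None or fam_of[bcs[i]] != fam_of[bcs[j]]
        ]
        if exhaustive:
            chosen = all_pairs
        else:
            pick = rng.choice(len(all_pairs), size=n_pairs, replace=False)
            chosen = [all_pairs[k] for k in np.sort(pick)]
    else:
        # rejection sampling: the co-familial fraction is tiny, so draws are
        # cheap; dedupe keeps the sample without-replacement
        seen: set[tuple[int, int]] = set()
        while len(seen) < n_pairs:
            need = n_pairs - len(seen)
            ii = rng.integers(n, size=2 * need + 16)
            jj = rng.integers(n, size=2 * need + 16)
            for i, j in zip(ii, jj):
                if i == j:
                    continue
                a, b = (int(i), int(j)) if i < j else (int(j), int(i))
                fa = fam_of[bcs[a]]
                if fa is not None and fa == fam_of[bcs[b]]:
                    continue
                seen.add((a, b))
                if len(seen) == n_pairs:
                    break
        chosen = sorted(seen)
    if gene_idx is None:
        gene_idx = top_variable_genes(nm, n_top_genes)
    used = sorted({bcs[i] for p in chosen for i in p})
    Z, order = _standardized_rows(nm, used, gene_idx)
    rows = [
        {
            "label": "unrelated",
            "cell_a": bcs[i],
            "cell_b": bcs[j],
            "correlation": _pair_corr(Z, order[bcs[i]], order[bcs[j]]),
        }
        for i, j in chosen
    ]
    df = pd.DataFrame(rows)
    df.attrs["exhaustive"] = exhaustive
    return df


def compare_correlations(
    same: pd.DataFrame,
    null: pd.DataFrame,
    mode: str = "equal_n",
    seed: int = 0,
    equal_var: bool = False,
) -> dict:
    """Two-tailed t test of same-clonotype vs unrelated correlations.

    mode="all" compares the full groups; mode="equal_n" subsamples the
    larger group (seeded) to the smaller group's size before testing.
    Welch's unequal-variance t by default.
    """
    if mode not in ("all", "equal_n"):
        raise ValueError("mode must be 'all' or 'equal_n'")
    x = same["correlation"].to_numpy(dtype=float)
    y = null["correlation"].to_numpy(dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("both groups need at least two correlations")
    if mode == "equal_n" and len(x) != len(y):
        rng = np.random.default_rng(seed)
        if len(x) > len(y):
            x = rng.choice(x, size=len(y), replace=False)
        else:
            y = rng.choice(y, size=len(x), replace=False)
    if np.var(x) == 0 and np.var(y) == 0:
        t, p = (0.0, 1.0) if x.mean() == y.mean() else (np.inf, 0.0)
    else:
        t, p = stats.ttest_ind(x, y, equal_var=equal_var)
    return {
        "t": float(t),
        "p_value": float(p),
        "mean_same": float(x.mean()),
        "mean_null": float(y.mean()),
        "n_same": int(len(x)),
        "n_null": int(len(y)),
        "mode": mode,
    }
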