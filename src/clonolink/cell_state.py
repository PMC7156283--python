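"""Cell-state classification and state-level statistics.

Cells are embedded by PCA, joined into a k-nearest-neighbor graph and
partitioned with the Leiden algorithm (RBConfiguration quality, resolution
parameter as in graph-based Louvain clustering); labels are "C1", "C2", ...
ordered by decreasing cluster size.  Marker genes per state come from a
two-sided Wilcoxon rank-sum test of in-state vs all other cells with
Benjamini-Hochberg correction within the state, and hallmark genes are the
top 10 markers passing adjusted p < 0.01, average log2 fold change > 0.3,
and significance in fewer than half of all states, with mitochondrial and
pseudogene names excluded.

Composition shifts between treatments are tested per (tissue, state) with
Welch's t across replicate frequencies; batch effects per state with
pairwise Fisher exact tests on in-state counts.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import igraph
import leidenalg
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors
from statsmodels.stats.multitest import multipletests

from .io_qc import NormalizedMatrix

__all__ = [
    "CellStateAssignment",
    "cluster_cells",
    "resolution_sweep",
    "rank_markers",
    "rank_all_markers",
    "select_hallmarks",
    "composition_shift",
    "batch_effect_test",
    "DEFAULT_EXCLUDE_PATTERNS",
]

# Mitochondrial gene names and common mouse pseudogene patterns; the list is
# configurable because annotation-complete pseudogene calls need a reference.
DEFAULT_EXCLUDE_PATTERNS = (r"(?i)^mt-", r"^Gm\d+$", r"-ps\d*$", r"Rik$")


@dataclass
class CellStateAssignment:
    """Per-cell state labels, a partition of the barcodes."""

    labels: pd.Series  # barcode -> "C1".."Ck"
    resolution: float
    subset_map: dict[str, str] = field(default_factory=dict)

    @property
    def states(self) -> list[str]:
        return sorted(self.labels.unique(), key=lambda s: int(s.lstrip("C")))

    @property
    def n_states(self) -> int:
        return self.labels.nunique()


def _pca_embed(nm: NormalizedMatrix, n_pcs: int, seed: int) -> np.ndarray:
    X = nm.dense()
    n_pcs = min(n_pcs, min(X.shape) - 1)
    if n_pcs < 1:
        return X
    return PCA(n_components=n_pcs, svd_solver="randomized", random_state=seed).fit_transform(X)


def _knn_graph(emb: np.ndarray, n_neighbors: int) -> igraph.Graph:
    nn = NearestNeighbors(n_neighbors=n_neighbors + 1).fit(emb)
    _, idx = nn.kneighbors(emb)
    edges = {
        (min(i, j), max(i, j))
        for i, row in enumerate(idx)
        for j in row[1:]  # drop self
    }
    return igraph.Graph(n=emb.shape[0], edges=sorted(edges))


def cluster_cells(
    nm: NormalizedMatrix,
    n_neighbors: int = 15,
    resolution: float = 0.6,
    seed: int = 0,
    n_pcs: int = 30,
) -> CellStateAssignment:
    """Graph-based community detection on the expression kNN graph.

    Default resolution 0.6.  Deterministic given ``seed``.  Labels are
    assigned by decreasing community size.  An expression matrix with no
    variance at all (every cell identical) collapses to a single state.
    """
    if resolution <= 0:
        raise ValueError("resolution must be > 0")
    n = nm.shape[0]
    if n <= n_neighbors:
        raise ValueError(f"need more than n_neighbors={n_neighbors} cells, got {n}")
    X = nm.dense()
    if np.allclose(X, X[0]):
        membership = np.zeros(n, dtype=int)
    else:
        emb = _pca_embed(nm, n_pcs, seed)
        g = _knn_graph(emb, n_neighbors)
        part = leidenalg.find_partition(
            g,
            leidenalg.RBConfigurationVertexPartition,
            resolution_parameter=resolution,
            seed=seed,
            n_iterations=2,
        )
        membership = np.asarray(part.membership)
    order = pd.Series(membership).value_counts().index  # size desc, stable
    rename = {comm: f"C{rank + 1}" for rank, comm in enumerate(order)}
    labels = pd.Series(
        [rename[m] for m in membership], index=nm.barcodes, name="state"
    )
    return CellStateAssignment(labels=labels, resolution=resolution)


def resolution_sweep(
    nm: NormalizedMatrix,
    resolutions: list[float] | None = None,
    seed: int = 0,
    n_neighbors: int = 15,
    n_pcs: int = 30,
    n_top_markers: int = 5,
) -> pd.DataFrame:
    """Cluster at each resolution; report state counts and the smallest
    state's size and top marker genes (the sweep used to pick a resolution).
    """
    if resolutions is None:
        resolutions = [round(0.1 * k, 1) for k in range(1, 11)]
    if not resolutions:
        raise ValueError("resolution list must be nonempty")
    rows = []
    for res in resolutions:
        assign = cluster_cells(
            nm, n_neighbors=n_neighbors, resolution=res, seed=seed, n_pcs=n_pcs
        )
        sizes = assign.labels.value_counts()
        smallest = sizes.index[-1]
        if sizes.loc[smallest] >= 3:
            mt = rank_markers(nm, assign, smallest)
            top = ",".join(mt.sort_values("adjusted_p")["gene"].head(n_top_markers))
        else:
            top = ""
        rows.append(
            {
                "resolution": res,
                "n_states": assign.n_states,
                "smallest_state": smallest,
                "smallest_size": int(sizes.loc[smallest]),
                "smallest_top_markers": top,
            }
        )
    return pd.DataFrame(rows)


def _rank_sum_pvalues(
    x: np.ndarray, y: np.ndarray, method: str
) -> np.ndarray:
    """Two-sided Mann-Whitney/Wilcoxon rank-sum p per column.

    "asymptotic" uses the normal approximation with tie correction;
    "exact" enumerates the rank-sum null (tie-free data, small groups).
    Degenerate columns (all values identical) get p = 1.
    """
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.mannwhitneyu(
            x, y, axis=0, alternative="two-sided", method=method
        )
    p = np.atleast_1d(np.asarray(res.pvalue, dtype=float))
    degenerate = np.array(
        [len(np.unique(np.concatenate([x[:, j], y[:, j]]))) == 1 for j in range(x.shape[1])]
    )
    p[degenerate | ~np.isfinite(p)] = 1.0
    return np.minimum(p, 1.0)


def rank_markers(
    nm: NormalizedMatrix,
    assign: CellStateAssignment,
    state: str,
    method: str = "asymptotic",
    eps: float = 1e-9,
) -> pd.DataFrame:
    """Differential expression of one state vs all other cells.

    Returns one row per gene: p_value, BH adjusted_p (within this state),
    avg_log2fc on expm1-backtransformed means, and expressing fractions.
    """
    if state not in set(assign.labels):
        raise ValueError(f"state {state!r} not present in assignment")
    mask = (assign.labels.reindex(nm.barcodes) == state).to_numpy()
    if mask.sum() < 3:
        raise ValueError(f"state {state!r} has fewer than 3 cells")
    X = nm.dense()
    xin, xout = X[mask], X[~mask]
    p = _rank_sum_pvalues(xin, xout, method)
    adj = multipletests(p, method="fdr_bh")[1]
    mean_in = np.expm1(xin).mean(axis=0)
    mean_out = np.expm1(xout).mean(axis=0)
    log2fc = np.log2((mean_in + eps) / (mean_out + eps))
    return pd.DataFrame(
        {
            "gene": nm.gene_names,
            "state": state,
            "p_value": p,
            "adjusted_p": np.maximum(adj, p),
            "avg_log2fc": log2fc,
            "frac_expressing_in": (xin > 0).mean(axis=0),
            "frac_expressing_out": (xout > 0).mean(axis=0),
        }
    )


def rank_all_markers(
    nm: NormalizedMatrix, assign: CellStateAssignment, method: str = "asymptotic"
) -> pd.DataFrame:
    """Marker table over every state with >= 3 cells."""
    parts = [
        rank_markers(nm, assign, s, method=method)
        for s in assign.states
        if (assign.labels == s).sum() >= 3
    ]
    return pd.concat(parts, ignore_index=True)


def select_hallmarks(
    marker_table: pd.DataFrame,
    n_states: int,
    max_genes: int = 10,
    adj_p_max: float = 0.01,
    log2fc_min: float = 0.3,
    exclude_patterns: tuple[str, ...] = DEFAULT_EXCLUDE_PATTERNS,
) -> dict[str, list[str]]:
    """Hallmark genes per state by the three-threshold rule.

    Per state, genes with adjusted p < ``adj_p_max`` and avg log2FC >
    ``log2fc_min`` are ranked by adjusted p (ties: fold change descending,
    then name) and truncated to ``max_genes``.  A gene significantly
    enriched (adjusted p < ``adj_p_max``) in at least half of all states is
    excluded everywhere, as are mitochondrial/pseudogene names.
    """
    mt = marker_table
    # "significant enrichment": adjusted p below threshold AND elevated in
    # that state (the rank-sum test is two-sided, so a marker of one state is
    # also significantly *depleted* elsewhere — depletion must not count)
    sig = mt[(mt["adjusted_p"] < adj_p_max) & (mt["avg_log2fc"] > 0)]
    n_sig_states = sig.groupby("gene")["state"].nunique()
    promiscuous = set(n_sig_states[n_sig_states >= n_states / 2].index)
    excluded_names = {
        g
        for g in mt["gene"].unique()
        if any(re.search(pat, g) for pat in exclude_patterns)
    }
    out: dict[str, list[str]] = {}
    for state, grp in mt.groupby("state"):
        ok = grp[
            (grp["adjusted_p"] < adj_p_max)
            & (grp["avg_log2fc"] > log2fc_min)
            & ~grp["gene"].isin(promiscuous)
            & ~grp["gene"].isin(excluded_names)
        ]
        ranked = ok.sort_values(
            ["adjusted_p", "avg_log2fc", "gene"], ascending=[True, False, True]
        )
        out[state] = ranked["gene"].head(max_genes).tolist()
    return out


def _welch(a: np.ndarray, b: np.ndarray) -> tuple[float, float, bool]:
    """Welch t with the zero-variance limit handled: equal means -> (0, 1),
    unequal means with no variance -> (+/-inf, 0) flagged degenerate."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if np.ptp(a) == 0 and np.ptp(b) == 0:  # all values identical in both arms
        if a.mean() == b.mean():
            return 0.0, 1.0, True
        return (np.inf if b.mean() > a.mean() else -np.inf), 0.0, True
    t, p = stats.ttest_ind(b, a, equal_var=False)
    return float(t), float(p), False


def composition_shift(
    assign: CellStateAssignment, cell_meta: pd.DataFrame
) -> pd.DataFrame:
    """Treatment shift in state frequencies per tissue.

    Frequency = state cells / (tissue, treatment, replicate) cells; Welch's
    unequal-variance t across replicates, Iso vs IL2M, per (tissue, state).
    Fold change is mean IL2M frequency over mean Iso frequency.  With fewer
    than two replicates in either arm only the frequencies are reported
    (t and p are NaN).
    """
    df = cell_meta.copy()
    df["state"] = assign.labels.reindex(df.index)
    states = assign.states
    rows = []
    for tissue, tgrp in df.groupby("tissue", sort=True):
        freq: dict[str, pd.DataFrame] = {}
        for trt, ggrp in tgrp.groupby("treatment"):
            tab = (
                ggrp.groupby("replicate")["state"]
                .value_counts(normalize=True)
                .unstack(fill_value=0.0)
                .reindex(columns=states, fill_value=0.0)
            )
            freq[trt] = tab
        for state in states:
            f_iso = freq.get("Iso", pd.DataFrame()).get(state)
            f_il2m = freq.get("IL2M", pd.DataFrame()).get(state)
            row = {
                "tissue": tissue,
                "state": state,
                "freq_iso": np.nan if f_iso is None else f_iso.mean(),
                "freq_il2m": np.nan if f_il2m is None else f_il2m.mean(),
                "t": np.nan,
                "p_value": np.nan,
                "fold_change": np.nan,
                "degenerate": False,
            }
            if f_iso is not None and f_il2m is not None:
                if f_iso.mean() > 0:
                    row["fold_change"] = f_il2m.mean() / f_iso.mean()
                if len(f_iso) >= 2 and len(f_il2m) >= 2:
                    t, p, degen = _welch(f_iso.to_numpy(), f_il2m.to_numpy())
                    row.update(t=t, p_value=p, degenerate=degen)
            rows.append(row)
    return pd.DataFrame(rows)


def batch_effect_test(
    assign: CellStateAssignment, replicate: pd.Series
) -> pd.DataFrame:
    """Pairwise-batch Fisher exact test of per-state cell counts.

    For each state and each pair of batches, the 2x2 table is
    [[in-state A, in-state B], [other A, other B]]; two-sided p.
    """
    rep = replicate.reindex(assign.labels.index)
    batches = sorted(rep.unique())
    if len(batches) < 2:
        raise ValueError("need at least two batches")
    totals = rep.value_counts()
    rows = []
    for state in assign.states:
        in_state = rep[assign.labels == state].value_counts()
        for i, a in enumerate(batches):
            for b in batches[i + 1 :]:
                na, nb = int(in_state.get(a, 0)), int(in_state.get(b, 0))
                table = [[na, nb], [int(totals[a]) - na, int(totals[b]) - nb]]
                _, p = stats.fisher_exact(table, alternative="two-sided")
                rows.append(
                    {"state": state, "batch_a": a, "batch_b": b, "p_value": float(p)}
                )
    return pd.DataFrame(rows)
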