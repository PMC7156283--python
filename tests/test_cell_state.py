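import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from clonolink import (
    SyntheticConfig,
    generate_dataset,
    log_normalize,
    cluster_cells,
    resolution_sweep,
    rank_markers,
    rank_all_markers,
    select_hallmarks,
    composition_shift,
    batch_effect_test,
)
from clonolink.cell_state import CellStateAssignment
from clonolink.io_qc import NormalizedMatrix

from conftest import make_cell_matrix
from _oracles import exact_ranksum_p, fisher_p_enumeration

import scipy.sparse as sp


def make_nm(values, barcodes=None) -> NormalizedMatrix:
    values = np.asarray(values, dtype=float)
    if barcodes is None:
        barcodes = [f"BC{i:04d}" for i in range(values.shape[0])]
    return NormalizedMatrix(
        matrix=sp.csr_matrix(values),
        barcodes=list(barcodes),
        gene_names=[f"Gene{j:04d}" for j in range(values.shape[1])],
        description="raw",
    )


def make_assignment(labels, barcodes=None) -> CellStateAssignment:
    if barcodes is None:
        barcodes = [f"BC{i:04d}" for i in range(len(labels))]
    return CellStateAssignment(
        labels=pd.Series(list(labels), index=barcodes, name="state"), resolution=0.6
    )


@pytest.fixture(scope="module")
def two_state_nm():
    cfg = SyntheticConfig(
        n_cells=400, n_genes=300, n_states=2, markers_per_state=20,
        marker_fold=8.0, clonal_family_rate=0.0, seed=21,
    )
    cm, _, truth = generate_dataset(cfg)
    return log_normalize(cm), truth


class TestClustering:
    def test_recovers_two_planted_states(self, two_state_nm):
        nm, truth = two_state_nm
        assign = cluster_cells(nm, resolution=0.3, seed=0)
        ari = adjusted_rand_score(truth.state.reindex(nm.barcodes), assign.labels)
        assert ari >= 0.9

    def test_deterministic_under_seed(self, two_state_nm):
        nm, _ = two_state_nm
        a1 = cluster_cells(nm, resolution=0.6, seed=42)
        a2 = cluster_cells(nm, resolution=0.6, seed=42)
        pd.testing.assert_series_equal(a1.labels, a2.labels)

    def test_identical_cells_single_community(self):
        nm = make_nm(np.ones((60, 20)))
        assign = cluster_cells(nm, n_neighbors=15, seed=0)
        assert assign.n_states == 1

    def test_too_few_cells_rejected(self):
        nm = make_nm(np.random.default_rng(0).random((10, 5)))
        with pytest.raises(ValueError, match="n_neighbors"):
            cluster_cells(nm, n_neighbors=15)

    def test_labels_partition_all_cells(self, two_state_nm):
        nm, _ = two_state_nm
        assign = cluster_cells(nm, seed=1)
        assert assign.labels.notna().all()
        assert list(assign.labels.index) == nm.barcodes


class TestResolutionSweep:
    def test_single_resolution_single_row_consistent(self, two_state_nm):
        nm, _ = two_state_nm
        table = resolution_sweep(nm, resolutions=[0.6], seed=0)
        assert len(table) == 1
        direct = cluster_cells(nm, resolution=0.6, seed=0)
        assert table.iloc[0]["n_states"] == direct.n_states

    def test_n_states_nondecreasing_in_resolution(self, two_state_nm):
        nm, _ = two_state_nm
        table = resolution_sweep(nm, resolutions=[0.2, 0.5, 0.8], seed=0)
        ns = table["n_states"].tolist()
        assert ns == sorted(ns)

    def test_empty_resolution_list_rejected(self, two_state_nm):
        nm, _ = two_state_nm
        with pytest.raises(ValueError, match="nonempty"):
            resolution_sweep(nm, resolutions=[])


class TestRankMarkers:
    def test_fully_separated_gene_attains_enumeration_minimum(self):
        # gene 0 higher in every in-state cell; tie-free values
        rng = np.random.default_rng(0)
        n1, n2 = 5, 5
        gene0 = np.concatenate([10 + rng.random(n1), rng.random(n2)])
        gene1 = rng.random(n1 + n2)
        X = np.column_stack([gene0, gene1])
        nm = make_nm(X)
        assign = make_assignment(["C1"] * n1 + ["C2"] * n2)
        mt = rank_markers(nm, assign, "C1", method="exact")
        oracle_p = exact_ranksum_p(gene0[:n1], gene0[n1:])
        assert mt.iloc[0]["p_value"] == pytest.approx(oracle_p, rel=1e-9)
        assert oracle_p == pytest.approx(2 / 252)  # 2 / C(10,5)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_exact_method_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = rng.integers(3, 9), rng.integers(3, 9)
        X = rng.random((n1 + n2, 4))
        nm = make_nm(X)
        assign = make_assignment(["C1"] * n1 + ["C2"] * n2)
        mt = rank_markers(nm, assign, "C1", method="exact")
        for j in range(4):
            oracle = exact_ranksum_p(X[:n1, j], X[n1:, j])
            assert mt.iloc[j]["p_value"] == pytest.approx(oracle, rel=1e-9)

    def test_null_genes_yield_no_hallmark_significance(self):
        rng = np.random.default_rng(5)
        X = rng.random((30, 50))
        nm = make_nm(X)
        assign = make_assignment(["C1"] * 15 + ["C2"] * 15)
        mt = rank_markers(nm, assign, "C1")
        assert (mt["adjusted_p"] >= 0.01).all()

    def test_degenerate_gene_gets_p_one(self):
        X = np.zeros((10, 2))
        X[:, 1] = np.arange(10)
        nm = make_nm(X)
        assign = make_assignment(["C1"] * 5 + ["C2"] * 5)
        mt = rank_markers(nm, assign, "C1")
        assert mt.iloc[0]["p_value"] == 1.0

    def test_absent_state_rejected(self):
        nm = make_nm(np.random.default_rng(0).random((6, 3)))
        assign = make_assignment(["C1"] * 6)
        with pytest.raises(ValueError, match="C9"):
            rank_markers(nm, assign, "C9")

    def test_adjusted_p_dominates_raw(self, small_linked):
        _, nm, truth = small_linked
        assign = CellStateAssignment(labels=truth.state.reindex(nm.barcodes), resolution=0.0)
        mt = rank_markers(nm, assign, "C1")
        assert (mt["adjusted_p"] >= mt["p_value"] - 1e-12).all()
        # BH monotone: adjusted p is nondecreasing along increasing raw p
        srt = mt.sort_values("p_value")["adjusted_p"].to_numpy()
        assert (np.diff(srt) >= -1e-12).all()

    def test_planted_marker_in_top10(self, small_linked):
        _, nm, truth = small_linked
        assign = CellStateAssignment(labels=truth.state.reindex(nm.barcodes), resolution=0.0)
        mt = rank_markers(nm, assign, "C1")
        top10 = set(mt.sort_values("adjusted_p")["gene"].head(10))
        assert top10 & set(truth.markers["C1"])


def _marker_row(gene, state, adj_p, fc):
    return {"gene": gene, "state": state, "p_value": adj_p / 2,
            "adjusted_p": adj_p, "avg_log2fc": fc,
            "frac_expressing_in": 0.5, "frac_expressing_out": 0.1}


class TestHallmarks:
    def test_promiscuous_gene_excluded_everywhere(self):
        rows = [_marker_row("Ubiq", f"C{k}", 0.001, 1.0) for k in range(1, 7)]
        rows += [_marker_row("Ubiq", f"C{k}", 0.5, 1.0) for k in range(7, 11)]
        rows += [_marker_row("Good", "C1", 0.005, 0.5)]
        hs = select_hallmarks(pd.DataFrame(rows), n_states=10)
        assert all("Ubiq" not in genes for genes in hs.values())
        assert "Good" in hs["C1"]

    def test_thresholds_inclusive_exclusive(self):
        rows = [
            _marker_row("Borderline", "C1", 0.009, 0.31),   # passes both
            _marker_row("Borderline", "C2", 0.005, 0.4),    # sig in 2/10 only
            _marker_row("WeakFold", "C1", 0.001, 0.25),     # fails fc > 0.3
            _marker_row("WeakP", "C1", 0.02, 1.0),          # fails p < 0.01
        ]
        hs = select_hallmarks(pd.DataFrame(rows), n_states=10)
        assert hs["C1"] == ["Borderline"]

    def test_mitochondrial_and_pseudogenes_excluded(self):
        rows = [
            _marker_row("mt-Co1", "C1", 1e-6, 2.0),
            _marker_row("Gm12345", "C1", 1e-6, 2.0),
            _marker_row("Actb", "C1", 1e-4, 1.0),
        ]
        hs = select_hallmarks(pd.DataFrame(rows), n_states=10)
        assert hs["C1"] == ["Actb"]

    def test_truncates_to_ten_ranked_by_adjusted_p(self):
        rows = [_marker_row(f"G{i:02d}", "C1", 0.0001 * (i + 1), 1.0) for i in range(15)]
        hs = select_hallmarks(pd.DataFrame(rows), n_states=10)
        assert len(hs["C1"]) == 10
        assert hs["C1"][0] == "G00"

    def test_output_satisfies_invariants_on_random_tables(self):
        rng = np.random.default_rng(33)
        genes = [f"G{i}" for i in range(40)] + ["mt-Nd1", "Gm999"]
        rows = [
            _marker_row(g, f"C{s}", float(rng.random() * 0.05), float(rng.normal(0.3, 0.4)))
            for g in genes for s in range(1, 6)
        ]
        mt = pd.DataFrame(rows)
        hs = select_hallmarks(mt, n_states=5)
        sig = mt[(mt["adjusted_p"] < 0.01) & (mt["avg_log2fc"] > 0)]
        n_sig = sig.groupby("gene")["state"].nunique()
        for state, hallmark_genes in hs.items():
            assert len(hallmark_genes) <= 10
            for g in hallmark_genes:
                row = mt[(mt["gene"] == g) & (mt["state"] == state)].iloc[0]
                assert row["adjusted_p"] < 0.01 and row["avg_log2fc"] > 0.3
                assert n_sig.get(g, 0) < 5 / 2
                assert not g.startswith(("mt-", "Gm"))


class TestCompositionShift:
    @staticmethod
    def _meta(freqs_by_trt, n_per_rep=100, n_reps=3):
        rows = []
        i = 0
        for trt, freq in freqs_by_trt.items():
            for rep in range(1, n_reps + 1):
                for state, f in freq.items():
                    for _ in range(int(round(f * n_per_rep))):
                        rows.append((f"BC{i:05d}", "spleen", trt, str(rep), state))
                        i += 1
        df = pd.DataFrame(rows, columns=["barcode", "tissue", "treatment", "replicate", "state"])
        meta = df.set_index("barcode")[["tissue", "treatment", "replicate"]]
        assign = CellStateAssignment(labels=df.set_index("barcode")["state"], resolution=0.6)
        return assign, meta

    def test_identical_replicates_give_t0_p1(self):
        freq = {"C1": 0.5, "C2": 0.5}
        assign, meta = self._meta({"Iso": freq, "IL2M": freq})
        out = composition_shift(assign, meta)
        row = out[(out["state"] == "C1")].iloc[0]
        assert row["t"] == 0.0 and row["p_value"] == 1.0 and row["degenerate"]

    def test_zero_variance_difference_reports_limit(self):
        assign, meta = self._meta(
            {"Iso": {"C1": 0.5, "C2": 0.5}, "IL2M": {"C1": 0.1, "C2": 0.9}}
        )
        out = composition_shift(assign, meta)
        row = out[out["state"] == "C1"].iloc[0]
        assert row["p_value"] == 0.0 and row["degenerate"]
        assert row["fold_change"] == pytest.approx(0.2)

    def test_planted_twofold_shift_recovered(self):
        comp = {
            "Iso": {t: np.array([0.1, 0.5, 0.4]) for t in ("spleen", "lung", "gut")},
            "IL2M": {t: np.array([0.2, 0.45, 0.35]) for t in ("spleen", "lung", "gut")},
        }
        cfg = SyntheticConfig(
            n_cells=4000, n_genes=300, n_states=3, markers_per_state=10,
            clonal_family_rate=0.0, tissue_composition=comp, seed=12,
        )
        cm, _, truth = generate_dataset(cfg)
        assign = CellStateAssignment(labels=truth.state, resolution=0.0)
        out = composition_shift(assign, cm.cell_meta)
        folds = out[out["state"] == "C1"]["fold_change"]
        assert folds.mean() == pytest.approx(2.0, rel=0.2)

    def test_single_replicate_reports_frequencies_only(self):
        assign, meta = self._meta(
            {"Iso": {"C1": 1.0}, "IL2M": {"C1": 1.0}}, n_reps=1
        )
        out = composition_shift(assign, meta)
        assert out["p_value"].isna().all()
        assert out["freq_iso"].notna().all()


class TestBatchEffects:
    def test_identical_margins_give_p_one(self):
        labels = ["C1"] * 10 + ["C2"] * 90 + ["C1"] * 10 + ["C2"] * 90
        reps = ["1"] * 100 + ["2"] * 100
        assign = make_assignment(labels)
        out = batch_effect_test(assign, pd.Series(reps, index=assign.labels.index))
        assert (out["p_value"] == 1.0).all()

    def test_matches_hypergeometric_oracle(self):
        # batch 1: 5 in-state of 5; batch 2: 0 of 5
        labels = ["C1"] * 5 + ["C2"] * 5
        reps = ["1"] * 5 + ["2"] * 5
        assign = make_assignment(labels)
        out = batch_effect_test(assign, pd.Series(reps, index=assign.labels.index))
        p = out[out["state"] == "C1"].iloc[0]["p_value"]
        assert p == pytest.approx(fisher_p_enumeration([[5, 0], [0, 5]]), rel=1e-9)
        assert p == pytest.approx(2 / 252, rel=1e-9)

    def test_single_batch_rejected(self):
        assign = make_assignment(["C1"] * 4)
        with pytest.raises(ValueError, match="two batches"):
            batch_effect_test(assign, pd.Series(["1"] * 4, index=assign.labels.index))

    def test_null_batches_are_calibrated(self):
        rng = np.random.default_rng(77)
        rejections, total = 0, 0
        for _ in range(40):
            n = 300
            labels = rng.choice(["C1", "C2", "C3"], size=n, p=[0.5, 0.3, 0.2])
            reps = rng.choice(["1", "2", "3"], size=n)
            assign = make_assignment(labels)
            out = batch_effect_test(assign, pd.Series(reps, index=assign.labels.index))
            rejections += int((out["p_value"] < 0.05).sum())
            total += len(out)
        assert rejections / total <= 0.08  # Fisher is conservative under the null
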