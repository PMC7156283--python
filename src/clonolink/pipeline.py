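"""End-to-end orchestration: simulate/load -> qc -> cluster -> tcr ->
clonal statistics -> correlation null, with a run manifest.

The manifest records parameters, per-stage outputs and SHA-256 hashes of
every file written, so a run can be re-executed bit-identically from the
same config and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .synthetic import SyntheticConfig, generate_dataset, write_dataset
from .io_qc import read_count_matrix, qc_filter, log_normalize, per_cell_summary
from .cell_state import (
    cluster_cells,
    rank_all_markers,
    select_hallmarks,
    composition_shift,
    batch_effect_test,
)
from .tcr import read_contigs, filter_paired_cells, assign_clonotypes, merge_tcr_transcriptome
from .clonal import (
    axis_frequencies,
    chord_links,
    tissue_sharing,
    cf_treatment_test,
    expansion_summary,
    family_counts,
)
from .correlation import (
    same_clonotype_correlations,
    sample_null_correlations,
    compare_correlations,
)

__all__ = ["RunConfig", "run_pipeline", "ConfigError", "DataError"]

log = logging.getLogger("clonolink")


class ConfigError(ValueError):
    """Invalid run configuration (CLI exit code 2)."""


class DataError(ValueError):
    """Malformed or inconsistent input data (CLI exit code 3)."""


@dataclass
class RunConfig:
    outdir: str | Path = "clonolink_run"
    seed: int = 0
    # exactly one input source: a synthetic config, or a directory of files
    synthetic: SyntheticConfig | None = None
    input_dir: str | Path | None = None
    # stage parameters
    min_genes: int = 500
    max_genes: int = 8000
    norm_scale: float = 1e4
    n_neighbors: int = 15
    resolution: float = 0.6
    n_pcs: int = 30
    cdr3_level: str = "nt"
    axis_tissues: tuple[str, ...] = ("spleen", "lung")
    n_null_pairs: int = 10000
    corr_mode: str = "equal_n"
    n_top_genes: int = 2000

    def validate(self) -> None:
        if (self.synthetic is None) == (self.input_dir is None):
            raise ConfigError("exactly one of synthetic config or input_dir required")
        if self.min_genes > self.max_genes:
            raise ConfigError("min_genes must be <= max_genes")
        if self.input_dir is not None:
            d = Path(self.input_dir)
            for name in ("matrix.mtx", "barcodes.tsv", "features.tsv", "metadata.csv", "contigs.csv"):
                if not (d / name).exists():
                    raise ConfigError(f"missing input file: {d / name}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(cfg: RunConfig) -> dict:
    """Run all stages; returns the manifest (also written as manifest.json).

    Stage failures propagate with the failing stage named; outputs of
    completed stages are left on disk.
    """
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "parameters": {
            k: (str(v) if isinstance(v, Path) else list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(cfg).items()
        },
        "stages": {},
    }
    stage = "simulate"
    try:
        t0 = time.time()
        if cfg.synthetic is not None:
            syn = dataclasses.replace(cfg.synthetic, seed=cfg.seed)
            cm, contigs, truth = generate_dataset(syn)
            data_dir = outdir / "data"
            write_dataset(cm, contigs, truth, data_dir)
            written = sorted(str(p) for p in data_dir.iterdir())
        else:
            d = Path(cfg.input_dir)
            cm = read_count_matrix(
                d / "matrix.mtx", d / "barcodes.tsv", d / "features.tsv", d / "metadata.csv"
            )
            contigs = read_contigs(d / "contigs.csv")
            written = []
        _record(manifest, stage, t0, written, n_cells=cm.n_cells, n_genes=cm.n_genes)

        stage = "qc"
        t0 = time.time()
        cm_f, report = qc_filter(cm, cfg.min_genes, cfg.max_genes)
        nm = log_normalize(cm_f, cfg.norm_scale)
        summary = per_cell_summary(cm_f)
        qc_path = outdir / "qc_report.json"
        qc_path.write_text(
            json.dumps(
                {
                    "n_cells_in": report.n_cells_in,
                    "n_cells_out": report.n_cells_out,
                    "removed_low": report.removed_low,
                    "removed_high": report.removed_high,
                    "min_genes": report.min_genes,
                    "max_genes": report.max_genes,
                },
                indent=2,
            )
        )
        summary.to_csv(outdir / "per_cell_summary.csv", index=False)
        _record(
            manifest, stage, t0,
            [str(qc_path), str(outdir / "per_cell_summary.csv")],
            n_cells_out=report.n_cells_out,
            removed_low=report.removed_low,
            removed_high=report.removed_high,
        )

        stage = "cluster"
        t0 = time.time()
        assign = cluster_cells(
            nm, n_neighbors=cfg.n_neighbors, resolution=cfg.resolution,
            seed=cfg.seed, n_pcs=cfg.n_pcs,
        )
        markers = rank_all_markers(nm, assign)
        hallmarks = select_hallmarks(markers, assign.n_states)
        comp = composition_shift(assign, cm_f.cell_meta)
        batch = batch_effect_test(assign, cm_f.cell_meta["replicate"])
        assign.labels.rename("state").to_csv(outdir / "labels.csv")
        markers.to_csv(outdir / "markers.csv", index=False)
        (outdir / "hallmarks.json").write_text(json.dumps(hallmarks, indent=2))
        comp.to_csv(outdir / "composition.csv", index=False)
        batch.to_csv(outdir / "batch_effects.csv", index=False)
        _record(
            manifest, stage, t0,
            [str(outdir / n) for n in
             ("labels.csv", "markers.csv", "hallmarks.json", "composition.csv", "batch_effects.csv")],
            n_states=assign.n_states,
        )

        stage = "tcr"
        t0 = time.time()
        pairs = filter_paired_cells(contigs)
        if not pairs:
            raise DataError("no cells pass the single-productive-pair filter")
        clonotypes = assign_clonotypes(pairs, cdr3_level=cfg.cdr3_level)
        linked = merge_tcr_transcriptome(clonotypes, cm_f, assign)
        clono_df = pd.DataFrame(
            [
                {"clonotype_id": ct.id, "size": ct.size,
                 "alpha_v": ct.key[0], "alpha_j": ct.key[1], "alpha_cdr3": ct.key[2],
                 "beta_v": ct.key[3], "beta_j": ct.key[4], "beta_cdr3": ct.key[5]}
                for ct in clonotypes
            ]
        )
        clono_df.to_csv(outdir / "clonotypes.csv", index=False)
        linked.cells.to_csv(outdir / "linked.csv")
        _record(
            manifest, stage, t0,
            [str(outdir / "clonotypes.csv"), str(outdir / "linked.csv")],
            n_paired=len(pairs), n_clonotypes=len(clonotypes), n_linked=len(linked),
        )

        stage = "clonal"
        t0 = time.time()
        axis_parts = [
            axis_frequencies(linked, treatment=trt, tissues=cfg.axis_tissues)
            for trt in sorted(linked.cells["treatment"].unique())
        ]
        axes = pd.concat(axis_parts, ignore_index=True)
        chords = chord_links(linked)
        sharing, sharing_fisher = tissue_sharing(linked)
        summary_obj = {
            "family_counts": family_counts(linked).to_dict(orient="records"),
            "expansion": expansion_summary(linked).to_dict(orient="records"),
            "cf_treatment_fisher_p": cf_treatment_test(linked),
            "tissue_sharing_fisher_p": sharing_fisher,
        }
        axes.to_csv(outdir / "axes.csv", index=False)
        chords.to_csv(outdir / "chords.csv", index=False)
        sharing.to_csv(outdir / "sharing.csv", index=False)
        (outdir / "summary.json").write_text(json.dumps(summary_obj, indent=2, default=str))
        _record(
            manifest, stage, t0,
            [str(outdir / n) for n in ("axes.csv", "chords.csv", "sharing.csv", "summary.json")],
            n_chord_links=len(chords),
        )

        stage = "corr_null"
        t0 = time.time()
        same = same_clonotype_correlations(linked, nm, n_top_genes=cfg.n_top_genes)
        null = sample_null_correlations(
            linked, nm, n_pairs=cfg.n_null_pairs, seed=cfg.seed,
            n_top_genes=cfg.n_top_genes,
        )
        test = compare_correlations(same, null, mode=cfg.corr_mode, seed=cfg.seed)
        pd.concat([same, null], ignore_index=True).to_csv(
            outdir / "correlations.csv", index=False
        )
        (outdir / "test.json").write_text(json.dumps(test, indent=2))
        _record(
            manifest, stage, t0,
            [str(outdir / "correlations.csv"), str(outdir / "test.json")],
            **{k: test[k] for k in ("t", "p_value", "mean_same", "mean_null")},
        )
    except (ConfigError, DataError):
        raise
    except Exception as exc:  # noqa: BLE001 - annotate with the failing stage
        raise DataError(f"stage {stage!r} failed: {exc}") from exc

    for st in manifest["stages"].values():
        st["hashes"] = {p: _sha256(Path(p)) for p in st["outputs"]}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _record(manifest: dict, stage: str, t0: float, outputs: list[str], **counts) -> None:
    elapsed = time.time() - t0
    manifest["stages"][stage] = {
        "outputs": outputs,
        "seconds": round(elapsed, 3),
        **{k: (v if isinstance(v, str) else _jsonable(v)) for k, v in counts.items()},
    }
    log.info("stage %s done in %.2fs %s", stage, elapsed, counts)


def _jsonable(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    return v
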