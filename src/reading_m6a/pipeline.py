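"""End-to-end orchestration: readout calling -> site filtering -> feature
encoding -> model training -> reports, on synthetic or user-supplied inputs.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from . import m6a_sites, model, readouts, rbp_features, synthetic
from .config import PipelineConfig

log = logging.getLogger("reading_m6a.pipeline")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(cfg: PipelineConfig, outdir: str) -> Path:
    """Run the synthetic end-to-end pipeline and write per-stage reports.

    Idempotent given identical config and seed: outputs are byte-stable.
    Returns the run directory.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.write_resolved(str(out / "resolved_config.yaml"))
    header = cfg.provenance_header()

    sim_kwargs = dict(cfg.simulation)
    sim_kwargs.setdefault("seed", cfg.seed)
    sim_cfg = synthetic.SimulationConfig(**sim_kwargs)

    stage = "simulate"
    try:
        data = synthetic.simulate_all(sim_cfg)
        log.info("simulate: %d genes, %d m6A sites, %d RBP tracks",
                 len(data["txome"].genes), len(data["truth"].m6a_sites),
                 len(data["rbp_tracks"]))

        stage = "halflife"
        norm = readouts.ercc_normalize(data["decay_counts"])
        est_c, _ = readouts.fit_decay(norm, "shControl")
        est_k, _ = readouts.fit_decay(norm, "shMETTL3")
        hl_calls = readouts.classify_halflife(est_c, est_k, fold=cfg.hl_fold)
        _write(out / "halflife.tsv", readouts.calls_to_frame(hl_calls), header)

        stage = "te"
        te = readouts.te_change(data["rpf"], data["rna"],
                                fold=cfg.te_fold, alpha=cfg.te_p)
        te_df = pd.DataFrame([(t.gene_id, t.log2fc, t.pvalue, t.direction)
                              for t in te],
                             columns=["gene_id", "log2fc", "pvalue", "direction"])
        _write(out / "te_change.tsv", te_df, header)

        stage = "splice"
        psi_calls = readouts.classify_splicing(
            data["exon_events"], synthetic.psi_samples_by_condition(sim_cfg),
            dpsi_min=cfg.dpsi_min, fdr_max=cfg.psi_fdr)
        _write(out / "psi_events.tsv", readouts.calls_to_frame(psi_calls), header)

        stage = "sites"
        filtered = m6a_sites.filter_glori(
            data["glori_control"], data["glori_kd"], rate_min=cfg.glori_rate_min)
        filtered = [s for s in filtered
                    if m6a_sites.drach_match(data["genome"], s)]
        m6a_sites.sites_to_bed(filtered, str(out / "m6a_sites.bed"))
        log.info("sites: %d retained after GLORI+DRACH filters", len(filtered))

        stage = "encode"
        by_gene: dict[str, list] = {}
        for s in filtered:
            for g in s.gene_ids:
                by_gene.setdefault(g, []).append(s)
        features = rbp_features.assemble_features(
            sorted(by_gene), by_gene, data["rbp_tracks"], data["txome"],
            data["tx_sequences"], expression=data["expression"],
            dependency=data["dependency"], level="gene")
        _write(out / "features.tsv", features.reset_index(), header)

        stage = "model"
        labels = data["truth"].model_labels
        pos = [g for g in features.index if labels.get(g) == 1]
        neg = [g for g in features.index if labels.get(g) == 0]
        task = model.ModelTask("HL_down", cfg.cell_type, pos, neg, seed=cfg.seed)
        cv = model.train_cv(task, features)
        scores = pd.DataFrame({"unit_id": cv.unit_ids, "label": cv.labels,
                               "score": cv.scores, "fold": cv.folds})
        _write(out / "cv_scores.tsv", scores, header)
        _write(out / "roc.tsv", cv.roc, header)
        imp = model.rbp_importance(cv).reset_index()
        _write(out / "importance.tsv", imp, header)
        summary = pd.DataFrame([{
            "cell_type": cfg.cell_type, "readout": task.readout,
            "n_pos": len(pos), "n_neg": len(neg),
            "auc": cv.auc, "sens_at_80spec": cv.sens_at_80spec,
        }])
        _write(out / "model_summary.tsv", summary, header)
        log.info("model: AUC %.3f on %d+%d units", cv.auc, len(pos), len(neg))
    except Exception as exc:  # surface the failing stage
        raise StageError(stage, exc) from exc
    return out


def _write(path: Path, df: pd.DataFrame, header: str) -> None:
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")
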