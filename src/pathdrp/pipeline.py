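"""End-to-end workflow: harmonize -> pathway features -> drug features ->
pre-train -> transfer (with and without transferred layers) -> evaluate ->
explain, on synthetic cohorts or user-supplied files.

Every invocation writes one run directory containing the intermediate
artifacts (all re-readable by io_formats), a JSON-lines log of every
parameter actually used, and a report.json with both arms' fold scores,
their comparison p-value, per-drug breakdowns, and the explanation tables.
All randomness flows from the single global seed, so a rerun with the same
config reproduces the report byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from pathdrp import datagen, harmonize, io_formats, model_core
from pathdrp.drug_features import morgan_fingerprint, netpea_scores
from pathdrp.evaluate import compare_models, per_group_performance, repeated_cv
from pathdrp.explain import (
    categorize_predictions,
    compare_groups,
    rank_importance,
    shapley_values,
)
from pathdrp.model_core import TrainConfig, assemble_features, predict, pretrain
from pathdrp.pathway_features import ssgsea_matrix
from pathdrp.transfer import TransferConfig, fine_tune, subsample_nonresponders, transfer_build

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "demo_config"]

TOY_WIDTHS = (64, 32, 16, 8)


@dataclasses.dataclass
class PipelineConfig:
    """All stage parameters; defaults run the synthetic demo workflow."""

    seed: int = 0
    out_dir: str = "pathdrp_run"
    datagen: dict = dataclasses.field(default_factory=dict)
    ssgsea: dict = dataclasses.field(
        default_factory=lambda: {"weight_exponent": 0.25, "min_overlap": 5, "normalize": True}
    )
    netpea: dict = dataclasses.field(
        default_factory=lambda: {"restart_prob": 0.5, "n_perm": 100}
    )
    widths: tuple[int, ...] = TOY_WIDTHS
    learning_rate: float = 0.003  # toy-width nets need a larger step than the full-scale 4e-4
    pretrain_epochs: int = 150
    finetune_epochs: int = 150
    patience: int = 30
    arms: tuple[str, ...] = ("transfer", "no_transfer")
    n_transfer_layers: int | None = None  # default: all hidden layers
    retrain_transferred: bool = True
    subsample_ratio: int | None = None  # None: no subsampling
    cv_k: int = 5
    cv_repeats: int = 5
    explain_top_k: int = 10
    explain_perms: int = 10
    explain_baselines: int = 10
    write_artifacts: bool = True

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(**d)
        cfg.widths = tuple(cfg.widths)
        cfg.arms = tuple(cfg.arms)
        return cfg


def demo_config(seed: int = 0, out_dir: str = "pathdrp_demo") -> PipelineConfig:
    """Small synthetic configuration that exercises every stage quickly."""
    return PipelineConfig(
        seed=seed,
        out_dir=out_dir,
        datagen={
            "n_genes": 120,
            "n_pathways": 12,
            "pathway_size_range": (8, 14),
            "n_cell_samples": 1000,
            "n_tumor_samples": 60,
            "n_drugs": 3,
        },
        pretrain_epochs=120,
        finetune_epochs=120,
        patience=20,
        cv_repeats=2,
        explain_perms=5,
        explain_baselines=5,
    )


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the full workflow; returns the report dict (also written to
    <out_dir>/report.json)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run_log.jsonl"
    log_fh = open(log_path, "w")

    def log_event(stage: str, **params) -> None:
        log_fh.write(json.dumps({"stage": stage, **params}, sort_keys=True, default=str) + "\n")
        log_fh.flush()

    config_echo = dataclasses.asdict(cfg)
    config_echo.pop("out_dir")  # report must not depend on where it is written
    report: dict = {"seed": cfg.seed, "config": config_echo}
    try:
        # --- stage 1: synthetic cohort -----------------------------------
        sim = datagen.SimulationConfig(**{"seed": cfg.seed, **cfg.datagen})
        log_event("datagen", **dataclasses.asdict(sim))
        cohort = datagen.generate_cohort(sim)
        if cfg.write_artifacts:
            io_formats.write_expression(cohort.cells, out / "cells.tsv", out / "cells_annot.tsv")
            io_formats.write_expression(cohort.tumors, out / "tumors.tsv", out / "tumors_annot.tsv")
            io_formats.write_gmt(cohort.pathways, out / "pathways.gmt")
            io_formats.write_drug_table(cohort.drugs, out / "drugs.tsv")
            io_formats.write_edge_list(cohort.ppi, out / "ppi.tsv")
            io_formats.write_response_table(cohort.cell_response_continuous, out / "cell_response.tsv")
            io_formats.write_response_table(cohort.tumor_response_dichotomous, out / "tumor_response.tsv")
            cohort.truth.to_json(out / "ground_truth.json")

        # --- stage 2: harmonization --------------------------------------
        log_event("harmonize", n_matrices=2)
        joint = harmonize.harmonize_run([cohort.cells, cohort.tumors])

        # --- stage 3: EXP features ---------------------------------------
        log_event("ssgsea", **cfg.ssgsea)
        exp_all = ssgsea_matrix(joint, cohort.pathways, **cfg.ssgsea)

        # --- stage 4: drug features --------------------------------------
        log_event("drug_features", **cfg.netpea)
        chem = {
            d.drug_id: morgan_fingerprint(d.smiles, drug_id=d.drug_id) for d in cohort.drugs
        }
        dgnet = {
            d.drug_id: netpea_scores(
                cohort.ppi, d, cohort.pathways, seed=cfg.seed + 17, **cfg.netpea
            )
            for d in cohort.drugs
        }

        # --- stage 5: pre-train on cell lines ----------------------------
        cell_table = assemble_features(exp_all, chem, dgnet, cohort.cell_response_continuous)
        pre_cfg = TrainConfig(
            loss="rmse", learning_rate=cfg.learning_rate,
            max_epochs=cfg.pretrain_epochs, patience=cfg.patience, seed=cfg.seed,
        )
        log_event("pretrain", widths=cfg.widths, **dataclasses.asdict(pre_cfg))
        pretrained = pretrain(cell_table, pre_cfg, widths=cfg.widths)
        best = pretrained.training_log[-1]
        report["pretrain"] = {
            "val_rmse": best["best_val_loss"],
            "best_epoch": best["best_epoch"],
            "n_rows": cell_table.n_rows,
            "n_features": cell_table.n_features,
        }
        if cfg.write_artifacts:
            model_core.save_model(pretrained, out / "pretrained.npz")

        # --- stage 6: transfer arms on the tumor task --------------------
        tumor_resp = cohort.tumor_response_dichotomous
        if cfg.subsample_ratio is not None:
            tumor_resp = subsample_nonresponders(tumor_resp, cfg.subsample_ratio, seed=cfg.seed)
        tumor_table = assemble_features(exp_all, chem, dgnet, tumor_resp)
        n_hidden = len(cfg.widths)
        n_transfer = cfg.n_transfer_layers if cfg.n_transfer_layers is not None else n_hidden

        arm_scores: dict[str, np.ndarray] = {}
        arm_results = {}
        for arm in cfg.arms:
            n_tl = n_transfer if arm == "transfer" else 0
            counter = {"i": 0}

            def fit_predict(train_t, test_t, _n_tl=n_tl):
                counter["i"] += 1
                tcfg = TransferConfig(
                    n_transfer_layers=_n_tl,
                    retrain_transferred=cfg.retrain_transferred,
                    new_hidden_layers=() if _n_tl else cfg.widths,
                    head="classification",
                    train=TrainConfig(
                        loss="bce",
                        learning_rate=cfg.learning_rate,
                        max_epochs=cfg.finetune_epochs,
                        patience=cfg.patience,
                        seed=cfg.seed * 100 + counter["i"],
                    ),
                    seed=cfg.seed * 100 + counter["i"],
                )
                model = transfer_build(pretrained, tcfg)
                tuned = fine_tune(model, train_t, tcfg)
                return predict(tuned, test_t.X)

            log_event("transfer_arm", arm=arm, n_transfer_layers=n_tl,
                      retrain=cfg.retrain_transferred, k=cfg.cv_k, repeats=cfg.cv_repeats)
            cv = repeated_cv(
                fit_predict, tumor_table, "classification",
                k=cfg.cv_k, repeats=cfg.cv_repeats, seed=cfg.seed,
            )
            arm_scores[arm] = cv.fold_scores
            per_drug = per_group_performance(cv.predictions, "drug_id", min_group_n=5)
            arm_results[arm] = {
                "fold_auroc": cv.fold_scores.ravel().tolist(),
                "mean_auroc": cv.mean,
                "sd_auroc": cv.sd,
                "summary": cv.summary(),
                "per_drug": per_drug.drop(columns=["in_source_panel"]).to_dict(orient="records"),
            }
        report["arms"] = arm_results
        if len(cfg.arms) == 2:
            report["transfer_vs_no_transfer_p"] = compare_models(
                arm_scores[cfg.arms[0]], arm_scores[cfg.arms[1]]
            )

        # --- stage 7: explanation ----------------------------------------
        tcfg = TransferConfig(
            n_transfer_layers=n_transfer,
            retrain_transferred=cfg.retrain_transferred,
            head="classification",
            train=TrainConfig(
                loss="bce", learning_rate=cfg.learning_rate,
                max_epochs=cfg.finetune_epochs, patience=cfg.patience, seed=cfg.seed,
            ),
            seed=cfg.seed,
        )
        log_event("explain", top_k=cfg.explain_top_k, perms=cfg.explain_perms,
                  baselines=cfg.explain_baselines)
        final_model = fine_tune(transfer_build(pretrained, tcfg), tumor_table, tcfg)
        probs = predict(final_model, tumor_table.X)

        exp_block = tumor_table.blocks["EXP"]
        exp_names = tumor_table.feature_names[exp_block]
        explain_out = {}
        truth_hits_shap = 0
        truth_hits_group = 0
        n_drugs_scored = 0
        tumor_scores = exp_all.scores.loc[cohort.tumors.sample_ids]
        for drug in cohort.drugs:
            rows = np.array([i for i, d in enumerate(tumor_table.drug_ids) if d == drug.drug_id])
            if len(rows) == 0:
                continue
            sub = tumor_table.subset(rows)
            rng = np.random.default_rng(cfg.seed + 29)
            base_idx = rng.choice(sub.n_rows, size=min(cfg.explain_baselines, sub.n_rows), replace=False)
            att = shapley_values(
                lambda Z: predict(final_model, Z),
                sub.X,
                tumor_table.feature_names,
                sub.X[base_idx],
                n_samples_per_feature=cfg.explain_perms,
                seed=cfg.seed + 31,
                sample_ids=sub.sample_ids,
            )
            exp_att = att.values.loc[:, exp_names]
            top = rank_importance(
                AttributionView(exp_att), cfg.explain_top_k
            )
            top_pathways = [f.split(":", 1)[1] for f in top.index]

            tp, tn = categorize_predictions(sub.y, probs[rows], sub.sample_ids)
            comparison = None
            sig_pathways: list[str] = []
            if len(tp) >= 3 and len(tn) >= 3:
                gc = compare_groups(tumor_scores, tp, tn)
                comparison = gc.table.to_dict(orient="records")
                sig_pathways = gc.table.loc[gc.table["significant"], "pathway"].tolist()

            signal = set(cohort.truth.signal_pathways[drug.drug_id])
            n_drugs_scored += 1
            if signal & set(top_pathways):
                truth_hits_shap += 1
            if signal & set(sig_pathways):
                truth_hits_group += 1
            explain_out[drug.drug_id] = {
                "top_pathways": top_pathways,
                "top_importance": top.tolist(),
                "n_tp": len(tp),
                "n_tn": len(tn),
                "significant_pathways": sig_pathways,
                "signal_pathways": sorted(signal),
                "comparison": comparison,
            }
        report["explain"] = explain_out
        report["signal_recovery"] = {
            "n_drugs": n_drugs_scored,
            "shapley_top_hit_fraction": truth_hits_shap / max(1, n_drugs_scored),
            "group_test_hit_fraction": truth_hits_group / max(1, n_drugs_scored),
        }

        # harmonization diagnostics for the report
        gap = _batch_mean_gap(joint)
        report["harmonization"] = {"mean_between_batch_gap": gap}
        log_event("done")
    except Exception as exc:
        log_event("error", error=str(exc))
        raise
    finally:
        log_fh.close()

    report_json = json.dumps(report, sort_keys=True, indent=2)
    (out / "report.json").write_text(report_json)
    return report


class AttributionView:
    """Adapter exposing a sub-block of an attribution frame to
    rank_importance."""

    def __init__(self, frame: pd.DataFrame):
        self.values = frame

    @property
    def importance(self) -> pd.Series:
        return self.values.abs().mean(axis=0)


def _batch_mean_gap(matrix) -> float:
    """Mean absolute between-batch difference of per-gene means."""
    batches = sorted(set(matrix.batch))
    means = []
    arr = np.array(matrix.batch)
    for b in batches:
        means.append(matrix.values[:, arr == b].mean(axis=1))
    gaps = [
        np.abs(means[i] - means[j]).mean()
        for i in range(len(means))
        for j in range(i + 1, len(means))
    ]
    return float(np.mean(gaps))
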