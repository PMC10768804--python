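"""End-to-end orchestration: pretrain → featurize → split → train → evaluate.

`run_pipeline` executes the full method on a directory of inputs
(compounds CSV, PDB structures, interaction table — e.g. as written by
the fixture generator), stamps every artifact with the config hash and
seed, and emits machine-readable JSON logs per stage. Per-fold
predictions are written as TSV and summarized in a metrics report.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .chem import generate_conformers, parse_molecule
from .config import RunConfig, config_hash
from .graphnet import PNAConfig
from .metrics import MetricsReport, constant_baseline_mse, evaluate_regression
from .model import (FusionConfig, FusionModel, InteractionRecord, featurize_protein,
                    predict_dataset, train)
from .pretrain import apply_freeze, build_freeze_mask, pretrain
from .protein import parse_structure
from .split import make_split

__all__ = ["run_pipeline", "PipelineResult"]


@dataclass
class PipelineResult:
    report: MetricsReport
    fold_mse: dict[int, float]
    fold_baseline_mse: dict[int, float]
    output_dir: Path


class _StageLogger:
    def __init__(self, path: Path):
        self.path = path
        self.path.parent.mkdir(parents=True, exist_ok=True)
        self._fh = open(path, "a")

    def log(self, stage: str, **fields) -> None:
        rec = {"ts": time.strftime("%Y-%m-%dT%H:%M:%S"), "stage": stage, **fields}
        self._fh.write(json.dumps(rec) + "\n")
        self._fh.flush()

    def close(self) -> None:
        self._fh.close()


def _fusion_config(cfg: RunConfig) -> FusionConfig:
    m = cfg.model
    return FusionConfig(
        pna=PNAConfig(hidden_dim=m.hidden_dim, n_layers=m.n_pna_layers,
                      out_dim=m.hidden_dim),
        fp_bits=m.fp_bits, fp_embed_dim=m.attn_dim, attn_dim=m.attn_dim,
        n_heads=m.n_heads, conv1d_channels=m.conv1d_channels,
        conv2d_channels=m.conv2d_channels, head_hidden=m.head_hidden,
        fourier_F=m.fourier_F, max_residues=m.max_residues,
        max_atoms=m.max_atoms, task=cfg.task)


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    data_dir = Path(cfg.paths.data)
    out_dir = Path(cfg.paths.output)
    out_dir.mkdir(parents=True, exist_ok=True)
    stamp = {"config_hash": config_hash(cfg), "seed": cfg.seed}
    logger = _StageLogger(out_dir / "pipeline.log.jsonl")
    try:
        # -- load & featurize ------------------------------------------------
        stage = "featurize"
        try:
            comp_df = pd.read_csv(data_dir / "compounds.csv")
            inter_df = pd.read_csv(data_dir / "interactions.csv")
            compounds = {}
            for _, row in comp_df.iterrows():
                rec = parse_molecule(row["smiles"], str(row["compound_id"]),
                                     fp_radius=cfg.model.fp_radius,
                                     fp_bits=cfg.model.fp_bits)
                compounds[rec.id] = rec
            structures = {}
            for pid, path in (inter_df[["protein_id", "structure_path"]]
                              .drop_duplicates().itertuples(index=False)):
                structures[str(pid)] = parse_structure(
                    (data_dir / path).read_text(), structure_id=str(pid))
            fusion_cfg = _fusion_config(cfg)
            proteins = {pid: featurize_protein(s, fusion_cfg)
                        for pid, s in structures.items()}
            interactions = [
                InteractionRecord(str(r.compound_id), str(r.protein_id),
                                  float(r.label), str(r.task))
                for r in inter_df.itertuples(index=False)]
            logger.log(stage, n_compounds=len(compounds),
                       n_proteins=len(proteins),
                       n_interactions=len(interactions), **stamp)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

        # -- pretrain ---------------------------------------------------------
        stage = "pretrain"
        try:
            pre = None
            if cfg.training.pretrain_epochs > 0:
                mols = [generate_conformers(rec, n_conf=2, seed=cfg.seed + i)
                        for i, rec in enumerate(compounds.values())]
                pre = pretrain(mols, cfg=fusion_cfg.pna,
                               epochs=cfg.training.pretrain_epochs,
                               seed=cfg.seed, tau=cfg.training.tau,
                               lr=cfg.training.pretrain_lr)
                logger.log(stage, initial_loss=pre.losses[0],
                           final_loss=pre.losses[-1], **stamp)
            else:
                logger.log(stage, skipped=True, **stamp)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

        # -- split --------------------------------------------------------------
        stage = "split"
        try:
            fps = {cid: rec.fingerprint for cid, rec in compounds.items()}
            seqs = {pid: s.sequence for pid, s in structures.items()}
            split = make_split(interactions, fps, seqs,
                               setting=cfg.split.setting,
                               n_folds=cfg.split.n_folds,
                               sim_threshold=cfg.split.sim_threshold,
                               butina_cutoff=cfg.split.butina_cutoff,
                               seed=cfg.seed)
            (out_dir / "split.json").write_text(json.dumps({
                **stamp, "setting": split.setting,
                "fold_of_interaction": {str(k): v for k, v in
                                        split.fold_of_interaction.items()},
                "audit": {
                    "max_compound_tanimoto": split.audit.max_compound_tanimoto_train_vs_test,
                    "max_protein_similarity": split.audit.max_protein_similarity_train_vs_test,
                    "n_removed": split.audit.n_removed}}, indent=1))
            for f in split.test_indices:
                rows = [{"compound_id": interactions[i].compound_id,
                         "protein_id": interactions[i].protein_id,
                         "label": interactions[i].label, "role": role}
                        for role, idxs in (("train", split.train_indices[f]),
                                           ("test", split.test_indices[f]))
                        for i in idxs]
                pd.DataFrame(rows).to_csv(out_dir / f"fold{f}.csv", index=False)
            logger.log(stage, n_folds=split.n_folds,
                       n_removed=split.audit.n_removed, **stamp)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

        # -- train & evaluate per fold ------------------------------------------
        stage = "train"
        y_all, yhat_all = [], []
        fold_mse, fold_base = {}, {}
        try:
            for f in sorted(split.test_indices):
                rng = np.random.default_rng(cfg.seed + 17 * (f + 1))
                model = FusionModel(fusion_cfg, rng,
                                    atom_matrix_width=next(iter(proteins.values())).A.shape[1])
                if pre is not None:
                    model.pna.load_state_dict(pre.encoder2d.state_dict())
                if cfg.model.freeze_fraction > 0:
                    mask = build_freeze_mask(model.pna, cfg.model.freeze_fraction)
                    apply_freeze(model.pna, mask)
                train_set = [interactions[i] for i in split.train_indices[f]]
                test_set = [interactions[i] for i in split.test_indices[f]]
                result = train(train_set, compounds, proteins, model,
                               epochs=cfg.training.epochs,
                               batch_size=cfg.training.batch_size,
                               lr=cfg.training.lr, seed=cfg.seed + f,
                               patience=cfg.training.patience)
                yhat = predict_dataset(test_set, compounds, proteins, model)
                y = np.array([r.label for r in test_set])
                train_y = np.array([r.label for r in train_set])
                fold_mse[f] = float(np.mean((y - yhat) ** 2))
                fold_base[f] = constant_baseline_mse(train_y, y)
                pd.DataFrame({
                    "compound_id": [r.compound_id for r in test_set],
                    "protein_id": [r.protein_id for r in test_set],
                    "y_true": y, "y_pred": yhat,
                }).to_csv(out_dir / f"predictions_fold{f}.tsv", sep="\t", index=False)
                with open(out_dir / f"train_log_fold{f}.jsonl", "w") as fh:
                    for rec in result.history:
                        fh.write(json.dumps({**stamp, **rec}) + "\n")
                y_all.append(y)
                yhat_all.append(yhat)
                logger.log(stage, fold=f, test_mse=fold_mse[f],
                           baseline_mse=fold_base[f], **stamp)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

        stage = "evaluate"
        try:
            y = np.concatenate(y_all)
            yhat = np.concatenate(yhat_all)
            report = evaluate_regression(y, yhat) if cfg.task == "regression" \
                else MetricsReport(mse=float(np.mean((y - yhat) ** 2)))
            (out_dir / "metrics.json").write_text(json.dumps(
                {**stamp, **report.to_dict(),
                 "fold_mse": fold_mse, "fold_baseline_mse": fold_base}, indent=1))
            logger.log(stage, mse=report.mse, **stamp)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        return PipelineResult(report=report, fold_mse=fold_mse,
                              fold_baseline_mse=fold_base, output_dir=out_dir)
    finally:
        logger.close()
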