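"""End-to-end pipeline orchestration: parenchyma segmentation → nodule
segmentation → spiculation-sign recognition, with evaluation against
supplied ground truth."""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np

from . import metrics, multiview, nodules, parenchyma, signs, volio

log = logging.getLogger("nodulekit")


@dataclass
class PipelineConfig:
    volume_path: str
    output_dir: str
    parenchyma_checkpoint: str
    nodule_checkpoints: dict[str, str]  # position -> path
    sign_model_path: str | None = None
    window_width: float = 1500.0
    window_level: float = -600.0
    fusion_rule: str = "majority"
    prob_threshold: float = 0.5
    min_circularity: float = 0.55
    diam_range_mm: tuple[float, float] = (4.0, 12.0)
    resample_mm: float | None = 1.0
    seed: int = 0
    parenchyma_truth: str | None = None
    nodule_truth: str | None = None

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "diam_range_mm" in raw:
            raw["diam_range_mm"] = tuple(raw["diam_range_mm"])
        return cls(**raw)

    def validate(self) -> None:
        missing = [p for p in
                   [self.volume_path, self.parenchyma_checkpoint,
                    *self.nodule_checkpoints.values()]
                   + ([self.sign_model_path] if self.sign_model_path else [])
                   if p and not os.path.exists(p)]
        if missing:
            raise FileNotFoundError(f"missing input file(s): {missing}")


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the full staged run and write masks, candidates and report.

    Any stage failure is re-raised with the stage name prefixed. With a
    fixed config (including seed) the run is deterministic.
    """
    cfg.validate()
    os.makedirs(cfg.output_dir, exist_ok=True)
    report: dict = {"config": {k: v for k, v in vars(cfg).items()
                               if not isinstance(v, dict)},
                    "stages": {}}
    window = volio.WindowSetting(cfg.window_width, cfg.window_level)

    def stage(name, fn):
        log.info("stage %s starting", name)
        try:
            return fn()
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc

    volume = stage("load", lambda: volio.read_volume(cfg.volume_path))
    if cfg.resample_mm is not None:
        volume = stage("resample",
                       lambda: volio.resample_isotropic(volume, cfg.resample_mm))

    def run_parenchyma():
        net = parenchyma.load_checkpoint(cfg.parenchyma_checkpoint)
        norm = volio.normalize_hu(volume, window)
        probs = parenchyma.predict_slices(net, norm)
        return probs >= cfg.prob_threshold

    lung_mask = stage("parenchyma", run_parenchyma)
    volio.write_mask(lung_mask, volume.spacing,
                     os.path.join(cfg.output_dir, "parenchyma.nii.gz"))
    report["stages"]["parenchyma"] = {"voxels": int(lung_mask.sum())}

    def run_nodules():
        nets = {pos: parenchyma.load_checkpoint(path, nodules.BiFPNUNet)
                for pos, path in cfg.nodule_checkpoints.items()}
        ncfg = nodules.NoduleNetConfig(
            prob_threshold=cfg.prob_threshold, fusion_rule=cfg.fusion_rule,
            min_circularity=cfg.min_circularity,
            diam_range_mm=cfg.diam_range_mm)
        return nodules.segment_nodules(volume, lung_mask, nets, ncfg)

    nodule_mask, candidates = stage("nodules", run_nodules)
    volio.write_mask(nodule_mask, volume.spacing,
                     os.path.join(cfg.output_dir, "nodules.nii.gz"))
    report["stages"]["nodules"] = {
        "candidates": [c.to_json() for c in candidates]}

    if cfg.sign_model_path:
        def run_signs():
            res = signs.load_sign_model(cfg.sign_model_path)
            out = []
            for cand in candidates:
                import pandas as pd

                per_pos = {}
                for pos in multiview.POSITIONS:
                    row = pd.DataFrame([signs.extract_position_features(
                        volume, cand, pos)])
                    per_pos[pos] = bool(res.predict(row)[0])
                out.append({
                    "component_id": cand.component_id,
                    "positions": per_pos,
                    "spiculated": signs.fuse_sign_decisions(
                        [per_pos[p] for p in multiview.POSITIONS]),
                })
            return out

        report["stages"]["signs"] = stage("signs", run_signs)

    if cfg.parenchyma_truth:
        truth = volio.read_mask(cfg.parenchyma_truth)
        report["stages"]["parenchyma"]["scores"] = metrics.seg_scores(
            truth, lung_mask).as_dict()
    if cfg.nodule_truth and nodule_mask.any():
        truth = volio.read_mask(cfg.nodule_truth)
        report["stages"]["nodules"]["scores"] = metrics.seg_scores(
            truth, nodule_mask).as_dict()

    with open(os.path.join(cfg.output_dir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    return report


def evaluate_run(pred_dir: str, truth_dir: str) -> dict:
    """Per-case and aggregate Md/Vd/Ud/CM over matching mask files."""
    preds = {f for f in os.listdir(pred_dir) if f.endswith((".nii", ".nii.gz"))}
    truths = {f for f in os.listdir(truth_dir) if f.endswith((".nii", ".nii.gz"))}
    if not preds:
        raise ValueError(f"no prediction masks in {pred_dir!r}")
    unmatched = sorted(preds ^ truths)
    common = sorted(preds & truths)
    if not common:
        raise ValueError(f"no matching case names; unmatched: {unmatched}")
    cases = {}
    for name in common:
        s = metrics.seg_scores(
            volio.read_mask(os.path.join(truth_dir, name)),
            volio.read_mask(os.path.join(pred_dir, name)))
        cases[name] = s.as_dict()
    agg = {k: float(np.mean([c[k] for c in cases.values()]))
           for k in ("Md", "Vd", "Ud", "CM")}
    return {"cases": cases, "aggregate": agg, "unmatched": unmatched}
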