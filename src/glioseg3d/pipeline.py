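"""End-to-end pipeline: generate -> preprocess -> train -> evaluate.

Driven by a versioned YAML config with fail-fast schema validation
(unknown keys rejected).  Every stage logs its resolved configuration and
seeds as JSON lines and drops a completion marker containing the stage
config hash, so re-runs skip completed stages unless forced.
"""

from __future__ import annotations

import csv
import hashlib
import json
import os
import time
import numpy as np
import yaml

from .io import load_manifest, read_case
from .loss import LossConfig
from .metrics import REGIONS
from .network.model import NetworkConfig
from .phantom import PhantomSpec, export_dataset, generate_phantom
from .preprocess import SRConfig, crop_resample, sr_enhance_volume, zscore_normalize
from .train import TrainConfig, evaluate, load_checkpoint, split_dataset, train
from .volumes import InvalidSpecError, MultimodalVolume

CONFIG_VERSION = 1

_SCHEMA: dict[str, set[str]] = {
    "": {"version", "workdir", "stages", "generate", "preprocess", "network", "loss", "train"},
    "generate": {
        "num_cases", "grid_shape", "seed", "noise_sigma", "bias_amplitude",
        "brain_radius_vox", "r_net", "r_et", "r_ed",
    },
    "preprocess": {"target_shape", "spacing", "sr", "sr_k", "sr_seed", "mask_threshold"},
    "network": {"base_channels", "depth", "aspp_rates", "dropout_rate", "negative_slope", "seed"},
    "loss": {"alpha", "beta", "lambda", "eps", "log_base"},
    "train": {
        "epochs", "max_steps", "learning_rate", "weight_decay", "split_fraction", "seed",
    },
}

_DEFAULT_STAGES = ("generate", "preprocess", "train", "evaluate")


def validate_config(cfg: dict) -> dict:
    if not isinstance(cfg, dict):
        raise InvalidSpecError("pipeline config must be a mapping")
    unknown = set(cfg) - _SCHEMA[""]
    if unknown:
        raise InvalidSpecError(f"unknown config keys: {sorted(unknown)}")
    version = cfg.get("version", CONFIG_VERSION)
    if version != CONFIG_VERSION:
        raise InvalidSpecError(f"unsupported config version {version}; expected {CONFIG_VERSION}")
    for section, allowed in _SCHEMA.items():
        if not section or section not in cfg:
            continue
        if not isinstance(cfg[section], dict):
            raise InvalidSpecError(f"section {section!r} must be a mapping")
        bad = set(cfg[section]) - allowed
        if bad:
            raise InvalidSpecError(f"unknown keys in section {section!r}: {sorted(bad)}")
    return cfg


def load_config(path: str) -> dict:
    with open(path) as fh:
        return validate_config(yaml.safe_load(fh))


def _hash_section(cfg: dict, *sections: str) -> str:
    payload = json.dumps({s: cfg.get(s, {}) for s in sections}, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


class PipelineRunner:
    def __init__(self, config: dict, force: bool = False):
        self.cfg = validate_config(config)
        self.force = force
        self.workdir = self.cfg.get("workdir", "glioseg_run")
        os.makedirs(self.workdir, exist_ok=True)
        self._log_path = os.path.join(self.workdir, "log.jsonl")

    # -- infrastructure ------------------------------------------------------

    def log(self, event: str, **payload) -> None:
        entry = {"time": time.time(), "event": event, **payload}
        with open(self._log_path, "a") as fh:
            fh.write(json.dumps(entry) + "\n")

    def _marker(self, stage: str) -> str:
        return os.path.join(self.workdir, f"{stage}.done.json")

    def _is_cached(self, stage: str, config_hash: str) -> bool:
        marker = self._marker(stage)
        if self.force or not os.path.exists(marker):
            return False
        with open(marker) as fh:
            return json.load(fh).get("config_hash") == config_hash

    def _mark_done(self, stage: str, config_hash: str, **extra) -> None:
        with open(self._marker(stage), "w") as fh:
            json.dump({"stage": stage, "config_hash": config_hash, **extra}, fh, indent=2)

    # -- stages --------------------------------------------------------------

    def stage_generate(self) -> str:
        section = self.cfg.get("generate", {})
        h = _hash_section(self.cfg, "generate")
        out_dir = os.path.join(self.workdir, "raw")
        manifest_path = os.path.join(out_dir, "manifest.json")
        if self._is_cached("generate", h):
            self.log("stage_cached", stage="generate")
            return manifest_path
        num_cases = int(section.get("num_cases", 8))
        base_seed = int(section.get("seed", 0))
        grid_shape = tuple(section.get("grid_shape", (32, 32, 32)))
        rng = np.random.default_rng(base_seed)
        cases, seeds = [], []
        for i in range(num_cases):
            seed = base_seed + i
            margin = min(grid_shape) * 0.1
            center = tuple(
                (n - 1) / 2.0 + rng.uniform(-margin, margin) for n in grid_shape
            )
            r_ed = float(section.get("r_ed", min(grid_shape) * 0.2)) * rng.uniform(0.8, 1.0)
            spec = PhantomSpec(
                grid_shape=grid_shape,
                brain_radius_vox=float(section.get("brain_radius_vox", min(grid_shape) * 0.42)),
                tumor_center_vox=center,
                r_net=min(float(section.get("r_net", r_ed * 0.35)), r_ed),
                r_et=min(float(section.get("r_et", r_ed * 0.6)), r_ed),
                r_ed=r_ed,
                noise_sigma=float(section.get("noise_sigma", 0.02)),
                bias_amplitude=float(section.get("bias_amplitude", 0.1)),
                seed=seed,
            )
            cases.append(generate_phantom(spec))
            seeds.append(seed)
            self.log("phantom_generated", case=i, seed=seed, grid_shape=list(grid_shape))
        export_dataset(cases, out_dir, seeds=seeds)
        self._mark_done("generate", h, manifest=manifest_path, num_cases=num_cases)
        return manifest_path

    def stage_preprocess(self, manifest_path: str) -> str:
        section = self.cfg.get("preprocess", {})
        h = _hash_section(self.cfg, "generate", "preprocess")
        out_dir = os.path.join(self.workdir, "preprocessed")
        out_manifest = os.path.join(out_dir, "manifest.json")
        if self._is_cached("preprocess", h):
            self.log("stage_cached", stage="preprocess")
            return out_manifest
        records = load_manifest(manifest_path)
        target_shape = tuple(section.get("target_shape", (32, 32, 32)))
        spacing = tuple(section.get("spacing", (1.0, 1.0, 1.0)))
        use_sr = bool(section.get("sr", False))
        threshold = float(section.get("mask_threshold", 0.1))
        processed = []
        for rec in records:
            vol, lab = read_case(rec)
            mask = np.any(vol.data > threshold, axis=0)
            channels = np.stack([zscore_normalize(vol.data[c], mask) for c in range(4)])
            if use_sr:
                sr_cfg = SRConfig(
                    k=float(section.get("sr_k", 1.0)), seed=int(section.get("sr_seed", 0))
                )
                channels = np.stack(
                    [sr_enhance_volume(channels[c], sr_cfg)[0] for c in range(4)]
                )
            norm_vol = MultimodalVolume(channels, spacing=vol.spacing, affine=vol.affine)
            out_vol, out_lab = crop_resample(norm_vol, lab, target_shape, spacing)
            processed.append((out_vol, out_lab))
            self.log("case_preprocessed", case=rec.case_id, target_shape=list(target_shape))
        export_dataset(
            processed, out_dir,
            case_ids=[r.case_id for r in records],
            seeds=[r.seed if r.seed is not None else -1 for r in records],
        )
        self._mark_done("preprocess", h, manifest=out_manifest)
        return out_manifest

    def stage_train(self, manifest_path: str) -> str:
        h = _hash_section(self.cfg, "generate", "preprocess", "network", "loss", "train")
        ckpt_dir = os.path.join(self.workdir, "checkpoints")
        ckpt_path = os.path.join(ckpt_dir, "best.npz")
        if self._is_cached("train", h):
            self.log("stage_cached", stage="train")
            return ckpt_path
        net_section = dict(self.cfg.get("network", {}))
        loss_section = dict(self.cfg.get("loss", {}))
        if "lambda" in loss_section:
            loss_section["lam"] = loss_section.pop("lambda")
        train_section = dict(self.cfg.get("train", {}))
        model_cfg = NetworkConfig(**net_section)
        loss_cfg = LossConfig(**loss_section)
        train_cfg = TrainConfig(**train_section, checkpoint_dir=ckpt_dir)
        records = load_manifest(manifest_path)
        train_list, val_list = split_dataset(
            records, train_cfg.split_fraction, train_cfg.seed
        )
        self.log(
            "split", train=[r.case_id for r in train_list], val=[r.case_id for r in val_list],
            seed=train_cfg.seed,
        )
        _, trace = train(
            model_cfg, loss_cfg, train_cfg, train_list, val_list,
            log_fn=lambda rec: self.log("epoch", **rec),
        )
        with open(os.path.join(self.workdir, "train_trace.json"), "w") as fh:
            json.dump(
                {
                    "train_loss": trace.train_loss,
                    "val_loss": trace.val_loss,
                    "val_dsc": trace.val_dsc,
                },
                fh, indent=2,
            )
        self._mark_done("train", h, checkpoint=ckpt_path)
        return ckpt_path

    def stage_evaluate(self, manifest_path: str, ckpt_path: str) -> str:
        h = _hash_section(self.cfg, "generate", "preprocess", "network", "loss", "train")
        csv_path = os.path.join(self.workdir, "metrics.csv")
        if self._is_cached("evaluate", h):
            self.log("stage_cached", stage="evaluate")
            return csv_path
        model = load_checkpoint(ckpt_path)
        records = load_manifest(manifest_path)
        reports, aggregate = evaluate(model, records)
        write_metrics_csv(csv_path, [r.case_id for r in records], reports, aggregate)
        self._mark_done("evaluate", h, metrics=csv_path)
        return csv_path

    # -- orchestration -------------------------------------------------------

    def run(self) -> dict:
        stages = self.cfg.get("stages", list(_DEFAULT_STAGES))
        self.log("run_start", config=self.cfg, force=self.force)
        artifacts: dict = {}
        try:
            manifest = None
            if "generate" in stages:
                manifest = self.stage_generate()
                artifacts["raw_manifest"] = manifest
            if "preprocess" in stages:
                manifest = self.stage_preprocess(manifest or artifacts["raw_manifest"])
                artifacts["preprocessed_manifest"] = manifest
            if "train" in stages:
                artifacts["checkpoint"] = self.stage_train(manifest)
            if "evaluate" in stages:
                artifacts["metrics_csv"] = self.stage_evaluate(manifest, artifacts["checkpoint"])
        except Exception as exc:
            self.log("run_failed", error=str(exc))
            raise
        self.log("run_complete", artifacts=artifacts)
        return artifacts


def write_metrics_csv(path: str, case_ids: list[str], reports, aggregate) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["case", "region", "dsc", "recall", "precision", "iou", "hd95"])
        for cid, report in zip(case_ids, reports):
            for region in REGIONS:
                m = report.per_region[region]
                writer.writerow([cid, region, m.dsc, m.recall, m.precision, m.iou, m.hd95])
        for region in REGIONS:
            agg = aggregate[region]
            writer.writerow(
                ["__aggregate__", region, agg["dsc"], agg["recall"],
                 agg["precision"], agg["iou"], agg["hd95"]]
            )


def run_pipeline(config: dict | str, force: bool = False) -> dict:
    """Run the configured stages; returns a dict of produced artifact paths."""
    cfg = load_config(config) if isinstance(config, str) else validate_config(config)
    return PipelineRunner(cfg, force=force).run()
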