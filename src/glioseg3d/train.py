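"""Optimization loop, dataset split, checkpointing and model evaluation.

Adam (lr 1e-3, weight decay 1e-4 by default; the weight-decay term realises
the L2 penalty) on the compound Dice+Focal objective; deterministic given a
seed.  Desk-scale protocol: seeded phantom sets stand in for full-size
training data.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, no_grad, tune_allocator
from .io import CaseRecord, read_case, remap_labels
from .loss import LossConfig, combined_loss_tensor, one_hot
from .metrics import REGIONS, MetricsReport, dsc, evaluate_case, region_masks
from .network.model import NetworkConfig, UNet3D
from .volumes import InvalidSpecError, LabelVolume, MultimodalVolume


@dataclass
class TrainConfig:
    learning_rate: float = 1e-3
    weight_decay: float = 1e-4
    epochs: int = 10
    max_steps: int | None = None
    batch_size: int = 1
    patch_shape: tuple[int, int, int] | None = None
    split_fraction: float = 0.8
    seed: int = 0
    checkpoint_dir: str | None = None
    early_stop_patience: int = 20

    def __post_init__(self) -> None:
        if not (0.0 < self.split_fraction < 1.0):
            raise InvalidSpecError("split_fraction must lie in (0, 1)")
        if self.epochs <= 0 or self.batch_size <= 0:
            raise InvalidSpecError("epochs and batch_size must be positive")


@dataclass
class TrainTrace:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_dsc: list[dict[str, float]] = field(default_factory=list)
    step_loss: list[float] = field(default_factory=list)


class Adam:
    """Adam with an L2 weight-decay term added to the gradient."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data, dtype=np.float64) for p in self.params]
        self.v = [np.zeros_like(p.data, dtype=np.float64) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad.astype(np.float64)
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            m_hat = self.m[i] / (1 - self.b1 ** self.t)
            v_hat = self.v[i] / (1 - self.b2 ** self.t)
            p.data = (p.data - self.lr * m_hat / (np.sqrt(v_hat) + self.eps)).astype(p.data.dtype)


def split_dataset(cases: list, fraction: float = 0.8, seed: int = 0) -> tuple[list, list]:
    """Seeded shuffle then split; partitions are disjoint and exhaustive."""
    if len(cases) < 2:
        raise InvalidSpecError("need at least 2 cases to split")
    n_train = int(round(len(cases) * fraction))
    if n_train == 0 or n_train == len(cases):
        raise InvalidSpecError(
            f"fraction {fraction} yields an empty partition for {len(cases)} cases"
        )
    order = np.random.default_rng(seed).permutation(len(cases))
    train_list = [cases[i] for i in order[:n_train]]
    val_list = [cases[i] for i in order[n_train:]]
    return train_list, val_list


def _resolve_case(case) -> tuple[MultimodalVolume, LabelVolume]:
    if isinstance(case, CaseRecord):
        vol, lab = read_case(case)
        if lab is None:
            raise InvalidSpecError(f"case {case.case_id!r} has no label volume")
        return vol, lab
    vol, lab = case
    return vol, lab


def _case_tensors(case, num_classes: int) -> tuple[np.ndarray, np.ndarray]:
    vol, lab = _resolve_case(case)
    x = vol.data.astype(np.float32)
    g = one_hot(remap_labels(lab.data, "to_internal"), num_classes)
    return x, g


def save_checkpoint(path: str, model: UNet3D) -> None:
    """Single-file checkpoint: weights + network config + label remap table."""
    meta = {
        "network_config": model.cfg.to_dict(),
        "label_remap": {"internal_to_brats": {"0": 0, "1": 1, "2": 2, "3": 4}},
    }
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **model.state_dict())


def load_checkpoint(path: str) -> UNet3D:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        cfg = NetworkConfig.from_dict(meta["network_config"])
        model = UNet3D(cfg)
        state = {k: data[k] for k in data.files if k != "__meta__"}
    model.load_state_dict(state)
    return model


def _validation_metrics(model: UNet3D, cases: list, loss_cfg: LossConfig) -> tuple[float, dict[str, float]]:
    model.eval()
    losses, region_scores = [], {r: [] for r in REGIONS}
    with no_grad():
        for case in cases:
            x, g = _case_tensors(case, model.cfg.num_classes)
            probs = model(Tensor(x))
            losses.append(combined_loss_tensor(probs, g, loss_cfg).item())
            pred_internal = probs.data.argmax(axis=0)
            pred_brats = remap_labels(pred_internal.astype(np.int16), "to_brats")
            truth_brats = remap_labels(np.argmax(g, axis=0).astype(np.int16), "to_brats")
            pm, tm = region_masks(pred_brats), region_masks(truth_brats)
            for r in REGIONS:
                region_scores[r].append(dsc(tm[r], pm[r]))
    model.train()
    return float(np.mean(losses)), {r: float(np.mean(v)) for r, v in region_scores.items()}


def train(
    model_cfg: NetworkConfig,
    loss_cfg: LossConfig,
    train_cfg: TrainConfig,
    data: list,
    val_data: list | None = None,
    log_fn=None,
) -> tuple[UNet3D, TrainTrace]:
    """Train a fresh model; returns the best-validation-DSC weights (falling
    back to the final weights when no validation set is given)."""
    tune_allocator()
    model = UNet3D(model_cfg)
    model.train()
    opt = Adam(model.parameters(), lr=train_cfg.learning_rate,
               weight_decay=train_cfg.weight_decay)
    trace = TrainTrace()
    order_rng = np.random.default_rng(train_cfg.seed)

    # pre-materialise arrays (desk-scale datasets are small)
    cases = [_case_tensors(c, model_cfg.num_classes) for c in data]
    steps_done = 0
    best_dsc, best_state = -1.0, None
    stagnant = 0

    for epoch in range(train_cfg.epochs):
        order = order_rng.permutation(len(cases))
        epoch_losses = []
        for idx in order:
            if train_cfg.max_steps is not None and steps_done >= train_cfg.max_steps:
                break
            x, g = cases[idx]
            probs = model(Tensor(x))
            loss = combined_loss_tensor(probs, g, loss_cfg)
            value = loss.item()
            if not math.isfinite(value):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}, step {steps_done}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            steps_done += 1
            epoch_losses.append(value)
            trace.step_loss.append(value)
        if not epoch_losses:
            break
        trace.train_loss.append(float(np.mean(epoch_losses)))
        if val_data:
            v_loss, v_dsc = _validation_metrics(model, val_data, loss_cfg)
            trace.val_loss.append(v_loss)
            trace.val_dsc.append(v_dsc)
            mean_dsc = float(np.mean(list(v_dsc.values())))
            if mean_dsc > best_dsc:
                best_dsc, best_state = mean_dsc, model.state_dict()
                stagnant = 0
            else:
                stagnant += 1
        if log_fn is not None:
            log_fn(
                {
                    "epoch": epoch,
                    "train_loss": trace.train_loss[-1],
                    "val_loss": trace.val_loss[-1] if val_data else None,
                    "steps": steps_done,
                }
            )
        if train_cfg.max_steps is not None and steps_done >= train_cfg.max_steps:
            break
        if val_data and stagnant >= train_cfg.early_stop_patience:
            break

    if best_state is not None:
        model.load_state_dict(best_state)
    if train_cfg.checkpoint_dir:
        os.makedirs(train_cfg.checkpoint_dir, exist_ok=True)
        save_checkpoint(os.path.join(train_cfg.checkpoint_dir, "best.npz"), model)
    return model, trace


def predict_labels(model: UNet3D, vol: MultimodalVolume) -> LabelVolume:
    """Forward pass, argmax, remap to BraTS coding."""
    model.eval()
    with no_grad():
        probs = model(Tensor(vol.data.astype(np.float32)))
    pred = remap_labels(probs.data.argmax(axis=0).astype(np.int16), "to_brats")
    return LabelVolume(pred, spacing=vol.spacing, affine=vol.affine)


def evaluate(model: UNet3D, cases: list) -> tuple[list[MetricsReport], dict[str, dict[str, float]]]:
    """Per-case metric reports plus per-region aggregate means."""
    reports = []
    for case in cases:
        vol, lab = _resolve_case(case)
        pred = predict_labels(model, vol)
        reports.append(evaluate_case(lab.data, pred.data, spacing=vol.spacing))
    aggregate: dict[str, dict[str, float]] = {}
    for region in REGIONS:
        aggregate[region] = {}
        for metric in ("dsc", "recall", "precision", "iou", "hd95"):
            values = [getattr(r.per_region[region], metric) for r in reports]
            finite = [v for v in values if math.isfinite(v)]
            aggregate[region][metric] = float(np.mean(finite)) if finite else float("nan")
    return reports, aggregate
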