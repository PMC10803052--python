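"""Training and evaluation engine: splits, batching, optimization,
checkpointing and metric reports.

The engine is CPU-only and fully deterministic for a fixed seed under
single-threaded execution (BLAS parallelism does not change results on a
given machine, but thread-count-dependent reductions are outside our
control across machines; reproducibility claims are per-machine).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .errors import ConfigError, ValidationError
from .losses_metrics import (DEFAULT_THRESHOLD, MetricsReport, combined_loss)
from .network import CrossGatedUNet, NetworkConfig
from .nn import Adam, Tensor, cosine_lr, no_grad
from .synthetic import (AugmentConfig, SegmentationSample, augment,
                        read_dataset)

__all__ = ["TrainConfig", "RunRecord", "split_dataset", "train",
           "train_on_samples", "evaluate", "evaluate_model",
           "save_checkpoint", "load_checkpoint", "predict_padded"]


@dataclass(frozen=True)
class TrainConfig:
    """Experimental-protocol knobs.

    The split ratio (7:2:1), batch size (8) and epoch budget (100) follow
    the benchmark protocol this package replicates; the optimizer choice
    (Adam, lr 1e-4, cosine decay, no weight decay) is this package's own
    default and is echoed in every run record.
    """

    ratios: tuple = (0.7, 0.2, 0.1)
    batch_size: int = 8
    epochs: int = 100
    seed: int = 0
    optimizer: str = "adam"
    lr: float = 1e-4
    schedule: str = "cosine"        # "cosine" or "constant"
    weight_decay: float = 0.0
    augment: bool = False
    aug: AugmentConfig = field(default_factory=AugmentConfig)
    threshold: float = DEFAULT_THRESHOLD
    checkpoint_dir: str | None = None
    device: str = "cpu"

    def __post_init__(self):
        if len(self.ratios) != 3 or any(r < 0 for r in self.ratios) \
                or self.ratios[0] <= 0 or abs(sum(self.ratios) - 1.0) > 1e-6:
            raise ConfigError(
                f"ratios must be three non-negative numbers summing to 1 "
                f"with a positive train share, got {self.ratios}")
        if self.batch_size < 1:
            raise ConfigError(f"batch_size must be >= 1, got {self.batch_size}")
        if self.epochs < 0:
            raise ConfigError(f"epochs must be >= 0, got {self.epochs}")
        if self.optimizer != "adam":
            raise ConfigError(f"unknown optimizer {self.optimizer!r}")
        if self.schedule not in ("cosine", "constant"):
            raise ConfigError(f"unknown schedule {self.schedule!r}")
        if self.device != "cpu":
            raise ConfigError("only device='cpu' is supported")


@dataclass
class RunRecord:
    """Per-epoch history and the best-checkpoint bookkeeping of one run."""

    history: list = field(default_factory=list)
    best_checkpoint: str | None = None
    best_val_iou: float = float("-inf")
    config: dict = field(default_factory=dict)
    seed: int = 0

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))


def split_dataset(samples: list, ratios=(0.7, 0.2, 0.1), seed: int = 0):
    """Seeded shuffle followed by a contiguous train/val/test partition.

    Validation and test sizes are the rounded ratio shares; the remainder
    goes to train.  The three parts are disjoint and cover the input.
    """
    n = len(samples)
    if n < 3:
        raise ValidationError(f"need at least 3 samples to split, got {n}")
    if len(ratios) != 3 or any(r < 0 for r in ratios) \
            or abs(sum(ratios) - 1.0) > 1e-6:
        raise ConfigError(f"invalid split ratios {ratios}")
    order = np.random.default_rng(seed).permutation(n)
    n_val = int(round(ratios[1] * n))
    n_test = int(round(ratios[2] * n))
    n_train = n - n_val - n_test
    if n_train < 1:
        raise ValidationError(f"split leaves no training samples (n={n}, "
                              f"ratios={ratios})")
    shuffled = [samples[i] for i in order]
    return (shuffled[:n_train], shuffled[n_train:n_train + n_val],
            shuffled[n_train + n_val:])


def _batch_arrays(samples: list[SegmentationSample]):
    x = np.stack([s.image for s in samples]).astype(np.float32) / 255.0
    y = np.stack([s.mask for s in samples]).astype(np.float32)
    return x, y


def _squeeze_prob(logits: Tensor) -> Tensor:
    return logits.reshape(*logits.shape[:-1]).sigmoid()


def train_on_samples(model: CrossGatedUNet, samples: list[SegmentationSample],
                     steps: int, lr: float = 1e-4, batch_size: int = 8,
                     seed: int = 0, schedule: str = "cosine",
                     weight_decay: float = 0.0,
                     aug_cfg: AugmentConfig | None = None) -> list[float]:
    """Optimize the combined loss for ``steps`` Adam steps; returns the
    per-step training losses.  Aborts on non-finite loss."""
    opt = Adam(model.parameters(), lr=lr, weight_decay=weight_decay)
    rng = np.random.default_rng(seed)
    model.train()
    losses = []
    order: list[int] = []
    for step in range(steps):
        if len(order) < batch_size:
            order = list(rng.permutation(len(samples))) + order
        take, order = order[:batch_size], order[batch_size:]
        batch = [samples[i] for i in take]
        if aug_cfg is not None:
            batch = [augment(s, aug_cfg, rng) for s in batch]
        xb, yb = _batch_arrays(batch)
        if schedule == "cosine":
            opt.lr = cosine_lr(lr, step, steps)
        prob = _squeeze_prob(model(Tensor(xb)))
        loss = combined_loss(yb, prob)
        val = loss.item()
        if not np.isfinite(val):
            raise RuntimeError(
                f"training diverged: non-finite loss {val} at step {step} "
                f"(lr={opt.lr:.2e}); lower the learning rate")
        losses.append(val)
        opt.zero_grad()
        loss.backward()
        opt.step()
    return losses


def evaluate_model(model: CrossGatedUNet, samples: list[SegmentationSample],
                   threshold: float = DEFAULT_THRESHOLD) -> MetricsReport:
    """Per-image IoU/F1 of the model on a sample list.

    Images whose size violates the network's divisibility requirement are
    reflect-padded to the nearest valid size and the prediction is cropped
    back (logged per image via the report id suffix '(padded)')."""
    report = MetricsReport(threshold=threshold)
    for s in samples:
        prob, padded = predict_padded(model, s.image)
        report.add(s.id + (" (padded)" if padded else ""), s.mask, prob)
    return report


def predict_padded(model: CrossGatedUNet, image: np.ndarray):
    """Sigmoid probability map for one 8-bit image, reflect-padding to the
    nearest valid size if needed.  Returns (prob, was_padded)."""
    h, w = image.shape[:2]
    d = model.cfg.size_divisor
    ph, pw = -h % d, -w % d
    x = image.astype(np.float32) / 255.0
    if ph or pw:
        x = np.pad(x, ((0, ph), (0, pw), (0, 0)), mode="reflect")
    prob = model.predict_proba(x)[..., 0]
    return prob[:h, :w], bool(ph or pw)


def save_checkpoint(model: CrossGatedUNet, path) -> None:
    """Weights, buffers and the architecture config in one ``.npz`` file."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    state = model.state_arrays()
    meta = json.dumps({"network": asdict(model.cfg)})
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
             **state)


def load_checkpoint(path) -> CrossGatedUNet:
    with np.load(Path(path)) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        cfg_d = meta["network"]
        for key in ("stage_widths", "gate_widths", "image_size"):
            if key in cfg_d and cfg_d[key] is not None:
                cfg_d[key] = tuple(cfg_d[key])
        model = CrossGatedUNet(NetworkConfig(**cfg_d), seed=0)
        model.load_state_arrays({k: data[k] for k in data.files
                                 if k != "__meta__"})
    return model


def train(model_cfg: NetworkConfig, train_cfg: TrainConfig, data_dir,
          out_dir=None) -> RunRecord:
    """Full protocol: read dataset, 7:2:1 split, optimize the combined loss,
    evaluate on the validation split each epoch, keep the best-IoU
    checkpoint."""
    samples = read_dataset(data_dir)
    train_s, val_s, _ = split_dataset(samples, train_cfg.ratios,
                                      train_cfg.seed)
    if not train_s or (train_cfg.epochs and not val_s):
        raise ValidationError(
            f"empty split (train {len(train_s)}, val {len(val_s)}); "
            f"need more samples or different ratios")
    model = CrossGatedUNet(model_cfg, seed=train_cfg.seed)
    record = RunRecord(config={"network": asdict(model_cfg),
                               "train": asdict(train_cfg)},
                       seed=train_cfg.seed)
    out_dir = Path(out_dir) if out_dir is not None else None
    ckpt_dir = Path(train_cfg.checkpoint_dir) if train_cfg.checkpoint_dir \
        else (out_dir / "checkpoints" if out_dir else None)

    opt = Adam(model.parameters(), lr=train_cfg.lr,
               weight_decay=train_cfg.weight_decay)
    rng = np.random.default_rng(train_cfg.seed)
    steps_per_epoch = max(1, (len(train_s) + train_cfg.batch_size - 1)
                          // train_cfg.batch_size)
    total_steps = train_cfg.epochs * steps_per_epoch
    step = 0
    for epoch in range(train_cfg.epochs):
        model.train()
        epoch_losses = []
        order = rng.permutation(len(train_s))
        for b0 in range(0, len(train_s), train_cfg.batch_size):
            batch = [train_s[i] for i in order[b0:b0 + train_cfg.batch_size]]
            if train_cfg.augment:
                batch = [augment(s, train_cfg.aug, rng) for s in batch]
            xb, yb = _batch_arrays(batch)
            if train_cfg.schedule == "cosine":
                opt.lr = cosine_lr(train_cfg.lr, step, total_steps)
            prob = _squeeze_prob(model(Tensor(xb)))
            loss = combined_loss(yb, prob)
            val = loss.item()
            if not np.isfinite(val):
                raise RuntimeError(
                    f"training diverged: non-finite loss at epoch {epoch}, "
                    f"step {step}")
            epoch_losses.append(val)
            opt.zero_grad()
            loss.backward()
            opt.step()
            step += 1

        val_report = evaluate_model(model, val_s, train_cfg.threshold)
        with no_grad():
            model.eval()
            val_losses = []
            for s in val_s:
                xb, yb = _batch_arrays([s])
                val_losses.append(float(combined_loss(
                    yb, _squeeze_prob(model(Tensor(xb))).data)))
        entry = {"epoch": epoch,
                 "train_loss": float(np.mean(epoch_losses)),
                 "val_loss": float(np.mean(val_losses)) if val_losses
                 else float("nan"),
                 "val_iou": val_report.mean_iou,
                 "val_f1": val_report.mean_f1}
        record.history.append(entry)
        if val_report.mean_iou > record.best_val_iou and ckpt_dir is not None:
            record.best_val_iou = val_report.mean_iou
            ckpt = ckpt_dir / "best.npz"
            save_checkpoint(model, ckpt)
            record.best_checkpoint = str(ckpt)
        elif val_report.mean_iou > record.best_val_iou:
            record.best_val_iou = val_report.mean_iou
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        record.write(out_dir / "run_record.json")
    return record


def evaluate(checkpoint, data_dir, threshold: float = DEFAULT_THRESHOLD,
             out_dir=None) -> MetricsReport:
    """Evaluate a checkpoint (path) or in-memory model on a dataset
    directory; optionally writes metrics.csv and metrics.json."""
    model = checkpoint if isinstance(checkpoint, CrossGatedUNet) \
        else load_checkpoint(checkpoint)
    samples = read_dataset(data_dir)
    report = evaluate_model(model, samples, threshold)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        report.write(out / "metrics.csv", out / "metrics.json")
    return report
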