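"""Training, evaluation and prediction orchestration.

Training follows the reference recipe: Adam at a constant learning rate of
0.001, batch size 2, the multi-output weighted BCE loss over all four decoder
heads, 120-150 epochs for a real run (default 130; far fewer for smoke tests).
Every run is a pure function of its ``TrainConfig``: the model init seed,
DropBlock mask streams and batch shuffling all derive from ``cfg.seed``, and
the fully resolved config is persisted next to the checkpoints.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .autograd import Tensor, no_grad
from .data_io import SegmentationSample, augment, load_dataset
from .losses import LossWeights, total_training_loss
from .metrics import confusion_counts, dice, metrics_report
from .network import NetworkConfig, SDRVesselNet, predict_mask
from .nn import Adam

__all__ = ["TrainConfig", "Trainer", "train", "evaluate", "predict_probability",
           "save_checkpoint", "load_checkpoint", "TrainingDiverged", "training_dice"]


class TrainingDiverged(RuntimeError):
    pass


@dataclass
class TrainConfig:
    dataset: str = ""
    layout: str = "flat"
    split: str = "all"
    augmentations: list = field(default_factory=list)
    epochs: int = 130
    batch_size: int = 2
    learning_rate: float = 1e-3
    threshold: float = 0.5
    seed: int = 0
    val_fraction: float = 0.0
    network: NetworkConfig = field(default_factory=NetworkConfig)
    loss: LossWeights = field(default_factory=LossWeights)
    out_dir: str = "runs/default"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["network"] = self.network.to_dict()
        d["loss"] = asdict(self.loss)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        d = dict(d)
        if "network" in d:
            d["network"] = NetworkConfig.from_dict(dict(d["network"]))
        loss = dict(d.get("loss", {}))
        profile = loss.pop("profile", None)
        if profile is not None:
            d["loss"] = LossWeights.for_profile(profile, **loss)
        elif "loss" in d:
            d["loss"] = LossWeights(**loss)
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "TrainConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _to_batch(samples: list[SegmentationSample]) -> tuple[np.ndarray, np.ndarray]:
    images = np.stack([s.image.transpose(2, 0, 1) for s in samples]).astype(np.float32)
    masks = np.stack([s.mask for s in samples])[:, None].astype(np.float32)
    return images, masks


class Trainer:
    """Step-level training driver over an in-memory sample list."""

    def __init__(self, model: SDRVesselNet, samples: list[SegmentationSample],
                 loss_weights: LossWeights, learning_rate: float = 1e-3,
                 batch_size: int = 2, seed: int = 0):
        if not samples:
            raise ValueError("empty training set")
        self.model = model
        self.samples = samples
        self.loss_weights = loss_weights
        self.batch_size = batch_size
        self.optimizer = Adam(model.parameters(), lr=learning_rate)
        self._shuffle_rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
        self._order: list[int] = []

    def _next_batch(self) -> list[SegmentationSample]:
        while len(self._order) < self.batch_size:
            self._order.extend(self._shuffle_rng.permutation(len(self.samples)).tolist())
        idx, self._order = self._order[: self.batch_size], self._order[self.batch_size :]
        return [self.samples[i] for i in idx]

    def step(self) -> float:
        """One optimizer step on the next shuffled batch; returns the loss."""
        self.model.train()
        images, masks = _to_batch(self._next_batch())
        outputs = self.model(Tensor(images))
        loss = total_training_loss(outputs, masks, self.loss_weights)
        value = loss.item()
        if not np.isfinite(value):
            raise TrainingDiverged(f"non-finite training loss: {value}")
        self.optimizer.zero_grad()
        loss.backward()
        self.optimizer.step()
        return value

    def steps_per_epoch(self) -> int:
        return max(int(np.ceil(len(self.samples) / self.batch_size)), 1)


def overfit_history(samples: list[SegmentationSample], network_cfg: NetworkConfig,
                    loss_weights: LossWeights, iterations: int = 200, eval_every: int = 10,
                    seed: int = 0, batch_size: int = 2, learning_rate: float = 1e-3,
                    threshold: float = 0.5, return_model: bool = False):
    """Learning-curve probe: train on ``samples`` for a fixed number of
    optimizer steps, recording loss and training-set dice every ``eval_every``
    steps.  Returns rows {iteration, loss, dice} (and the trained model when
    ``return_model`` is set)."""
    model = SDRVesselNet(network_cfg, seed=seed)
    trainer = Trainer(model, samples, loss_weights, learning_rate, batch_size, seed=seed)
    rows = []
    for it in range(1, iterations + 1):
        loss = trainer.step()
        if it % eval_every == 0:
            rows.append({"iteration": it, "loss": loss,
                         "dice": training_dice(model, samples, threshold)})
    return (rows, model) if return_model else rows


def iterations_to_dice(history: list[dict], target: float = 0.90) -> int | None:
    """First recorded iteration whose training dice exceeds ``target``."""
    for row in history:
        if row["dice"] > target:
            return row["iteration"]
    return None


def training_dice(model: SDRVesselNet, samples: list[SegmentationSample], threshold: float = 0.5) -> float:
    """Macro-average dice of the final head over a sample list (inference mode)."""
    scores = []
    for s in samples:
        pred = predict_mask(model, s.image.transpose(2, 0, 1), threshold)
        scores.append(dice(confusion_counts(pred, s.mask)))
    return float(np.mean(scores))


# ---------------------------------------------------------------------------
# checkpoints

def save_checkpoint(model: SDRVesselNet, path, cfg: TrainConfig | None = None, extra: dict | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = {"network": model.cfg.to_dict()}
    if cfg is not None:
        meta["train_config"] = cfg.to_dict()
    if extra:
        meta["extra"] = extra
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **model.state_dict())


def load_checkpoint(path) -> tuple[SDRVesselNet, dict]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"checkpoint not found: {path}")
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        state = {k: data[k] for k in data.files if k != "__meta__"}
    model = SDRVesselNet(NetworkConfig.from_dict(meta["network"]))
    model.load_state_dict(state)
    model.eval()
    return model, meta


# ---------------------------------------------------------------------------
# high-level entry points

def _load_training_samples(cfg: TrainConfig) -> list[SegmentationSample]:
    samples = load_dataset(cfg.dataset, layout=cfg.layout, split=cfg.split)
    if cfg.augmentations:
        ss = np.random.SeedSequence(cfg.seed).spawn(len(samples))
        expanded = []
        for s, child in zip(samples, ss):
            expanded.extend(augment(s, cfg.augmentations, seed=int(child.generate_state(1)[0] % 2**31),
                                    include_original=True))
        samples = expanded
    return samples


def train(cfg: TrainConfig, progress=None) -> dict:
    """Full training run: returns paths of the final/best checkpoints and log."""
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "config.yaml").write_text(yaml.safe_dump(cfg.to_dict()))

    samples = _load_training_samples(cfg)
    n_val = int(round(cfg.val_fraction * len(samples)))
    val_samples = samples[:n_val]
    train_samples = samples[n_val:]
    if not train_samples:
        raise ValueError("validation fraction leaves no training samples")

    model = SDRVesselNet(cfg.network, seed=cfg.seed)
    trainer = Trainer(model, train_samples, cfg.loss, cfg.learning_rate, cfg.batch_size, seed=cfg.seed)

    rows = []
    best_dice, best_path = -1.0, out_dir / "best.npz"
    for epoch in range(1, cfg.epochs + 1):
        losses = [trainer.step() for _ in range(trainer.steps_per_epoch())]
        row = {"epoch": epoch, "mean_loss": float(np.mean(losses)), "lr": cfg.learning_rate}
        if val_samples:
            row["val_dice"] = training_dice(model, val_samples, cfg.threshold)
            if row["val_dice"] > best_dice:
                best_dice = row["val_dice"]
                save_checkpoint(model, best_path, cfg, {"epoch": epoch, "val_dice": best_dice})
        rows.append(row)
        if progress is not None:
            progress(row)
    log = pd.DataFrame(rows)
    log.to_csv(out_dir / "train_log.csv", index=False)
    final_path = out_dir / "final.npz"
    save_checkpoint(model, final_path, cfg, {"epoch": cfg.epochs})
    if not val_samples:
        save_checkpoint(model, best_path, cfg, {"epoch": cfg.epochs})
    return {"final": final_path, "best": best_path, "log": out_dir / "train_log.csv",
            "epoch_losses": [r["mean_loss"] for r in rows]}


def evaluate(checkpoint, dataset, layout: str = "flat", split: str = "all",
             threshold: float = 0.5, out_csv=None, aggregation: str = "macro",
             use_fov: bool = False) -> pd.DataFrame:
    """Run inference over a dataset and report per-image + aggregate metrics."""
    model, _ = load_checkpoint(checkpoint)
    samples = load_dataset(dataset, layout=layout, split=split)
    preds, truths, ids = [], [], []
    regions = [] if use_fov else None
    for s in samples:
        preds.append(predict_mask(model, s.image.transpose(2, 0, 1), threshold))
        truths.append(s.mask)
        ids.append(s.id)
        if use_fov:
            regions.append(s.fov if s.fov is not None else np.ones_like(s.mask))
    df = metrics_report(preds, truths, ids, threshold, regions=regions, aggregation=aggregation)
    if out_csv is not None:
        Path(out_csv).parent.mkdir(parents=True, exist_ok=True)
        df.to_csv(out_csv, index=False)
    return df


def predict_probability(model: SDRVesselNet, image: np.ndarray, pad_to_16: bool = False) -> np.ndarray:
    """Final-head probability map for an (H, W, 3) image in [0, 1].

    With ``pad_to_16`` the image is reflect-padded to the next multiple of 16
    and the map cropped back; otherwise indivisible sizes raise.
    """
    h, w = image.shape[:2]
    x = image.transpose(2, 0, 1)[None].astype(np.float32)
    if pad_to_16 and (h % 16 or w % 16):
        ph, pw = (-h) % 16, (-w) % 16
        x = np.pad(x, ((0, 0), (0, 0), (0, ph), (0, pw)), mode="reflect")
    model.eval()
    with no_grad():
        prob = model(Tensor(x)).final.data[0, 0]
    return prob[:h, :w]
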