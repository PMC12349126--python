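"""Training recipe, checkpointing and batch prediction.

Defaults follow the published recipe: AdamW at initial learning rate 1e-3
with cosine annealing over the full schedule, batch size 16, BCE-Dice loss
with deep supervision, 100 epochs, random flip / right-angle rotation
augmentation.  Checkpoint selection keeps the weights with the best
validation DSC.  Every source of randomness (weight init, shuffling,
augmentation) derives from ``TrainConfig.seed``.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import nn
from .backbone import EncoderConfig
from .data import SegSample, augment, to_batch
from .metrics import binarize, evaluate
from .model import AblationFlags, SGNet, bce_dice_loss
from .nn import Tensor


@dataclass
class TrainConfig:
    # optimisation
    batch_size: int = 16
    learning_rate: float = 1e-3
    weight_decay: float = 1e-2
    epochs: int = 100
    eta_min: float = 1e-6
    seed: int = 0
    augment: bool = True
    # model
    input_size: int = 256
    encoder_variant: str = "vmamba_tiny"
    stage_depths: tuple = (2, 2, 9, 2)
    state_dim: int = 16
    patch_size: int = 4
    expansion_ratio: float = 2.0
    use_ddbe: bool = True
    use_stfu: bool = True
    use_gmsr_sagm: bool = True
    couple_kernels: tuple = (1, 3, 5)

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        for name in ("stage_depths", "couple_kernels"):
            setattr(self, name, tuple(getattr(self, name)))

    def encoder_config(self) -> EncoderConfig:
        return EncoderConfig(variant=self.encoder_variant,
                             stage_depths=self.stage_depths,
                             state_dim=self.state_dim,
                             patch_size=self.patch_size,
                             expansion_ratio=self.expansion_ratio)

    def ablation_flags(self) -> AblationFlags:
        return AblationFlags(self.use_ddbe, self.use_stfu, self.use_gmsr_sagm)

    def build_model(self) -> SGNet:
        nn.init.seed_all(self.seed)
        return SGNet(input_size=self.input_size,
                     encoder_config=self.encoder_config(),
                     flags=self.ablation_flags(),
                     couple_kernels=self.couple_kernels)

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "TrainConfig":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        return cls(**yaml.safe_load(text))


def train(model: SGNet, train_samples: list[SegSample],
          val_samples: list[SegSample], config: TrainConfig,
          checkpoint_path: str | Path | None = None,
          log_file: str | Path | None = None,
          verbose: bool = False) -> tuple[list[dict], dict]:
    """Train; returns (per-epoch history, best-validation-DSC state dict)."""
    if not train_samples or not val_samples:
        raise ValueError("train and val splits must be non-empty")
    rng = np.random.default_rng(config.seed + 1)
    opt = nn.AdamW(model.parameters(), lr=config.learning_rate,
                   weight_decay=config.weight_decay)
    sched = nn.CosineAnnealingLR(opt, t_max=config.epochs,
                                 eta_min=config.eta_min)
    history: list[dict] = []
    best = {"dsc": -1.0, "state": None, "epoch": -1}
    log_fh = open(log_file, "a") if log_file else None
    try:
        for epoch in range(1, config.epochs + 1):
            model.train()
            order = rng.permutation(len(train_samples))
            losses = []
            for start in range(0, len(order), config.batch_size):
                idx = order[start:start + config.batch_size]
                batch = [train_samples[i] for i in idx]
                if config.augment:
                    batch = [augment(s, np.random.default_rng(
                        rng.integers(2 ** 31))) for s in batch]
                images, masks = to_batch(batch)
                out = model(Tensor(images))
                loss = bce_dice_loss(out, Tensor(masks))
                if not np.isfinite(loss.item()):
                    raise RuntimeError(
                        f"training diverged: non-finite loss at epoch {epoch} "
                        f"(lr={opt.lr:.2e}); lower the learning rate")
                opt.zero_grad()
                loss.backward()
                opt.step()
                losses.append(loss.item())
            val = validate(model, val_samples, config.batch_size)
            record = {"epoch": epoch, "loss": float(np.mean(losses)),
                      "val_miou": val["miou"], "val_dsc": val["dsc"],
                      "lr": float(opt.lr)}
            history.append(record)
            if log_fh:
                log_fh.write(json.dumps(record) + "\n")
                log_fh.flush()
            if verbose:
                print(f"epoch {epoch:3d}  loss {record['loss']:.4f}  "
                      f"val mIoU {val['miou']:.4f}  val DSC {val['dsc']:.4f}")
            if val["dsc"] > best["dsc"]:
                best = {"dsc": val["dsc"], "epoch": epoch,
                        "state": {k: v.copy() for k, v
                                  in model.state_dict().items()}}
            sched.step()
    finally:
        if log_fh:
            log_fh.close()
    if checkpoint_path is not None and best["state"] is not None:
        save_checkpoint(best["state"], config, checkpoint_path,
                        epoch=best["epoch"], val_dsc=best["dsc"])
    return history, best["state"]


def validate(model: SGNet, samples: list[SegSample],
             batch_size: int = 16) -> dict:
    model.eval()
    pairs = []
    with nn.no_grad():
        for start in range(0, len(samples), batch_size):
            chunk = samples[start:start + batch_size]
            images, _ = to_batch(chunk)
            probs = predict_probs(model, images)
            for p, s in zip(probs, chunk):
                pairs.append((binarize(p[0]), s.mask[0]))
    report = evaluate(pairs)
    return {"miou": report.miou, "dsc": report.dsc}


def predict_probs(model: SGNet, images: np.ndarray) -> np.ndarray:
    """Sigmoid probabilities of the final map for a (B,3,H,W) float batch."""
    with nn.no_grad():
        out = model(Tensor(images.astype(np.float32)))
        from scipy.special import expit
        return expit(out.final.data)


def smoothed(values: list[float], window: int = 3) -> list[float]:
    """Moving-average smoothing used when judging loss trends."""
    v = np.asarray(values, dtype=float)
    if len(v) < window:
        return list(v)
    kernel = np.ones(window) / window
    return list(np.convolve(v, kernel, mode="valid"))


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(state: dict, config: TrainConfig, path: str | Path,
                    **extra):
    meta = {"config": asdict(config), **extra}
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **state)


def load_checkpoint(path: str | Path) -> tuple[SGNet, TrainConfig, dict]:
    """Rebuild the model a checkpoint was trained with and load its weights."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        state = {k: data[k] for k in data.files if k != "__meta__"}
    config = TrainConfig(**meta.pop("config"))
    model = config.build_model()
    model.load_state_dict(state)
    model.eval()
    return model, config, meta
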