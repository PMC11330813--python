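"""Training loop, checkpointing and prediction.

Protocol: Adam (lr 0.001 by default), Dice loss, batch size 4, fixed epoch
budget, no LR schedule and no early stopping.  Everything is seeded: weight
initialisation comes from the model config seed, the (once-per-run) sample
shuffle from the training seed.  The best-validation-IoU checkpoint and the
last checkpoint are both retained; training is resumable from the latter.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from PIL import Image

from .backbone import MaresNet, ModelConfig, build_model
from .data import ImageSample, SplitManifest, load_pairs
from .metrics import dice_loss, dice_loss_grad, evaluate_masks
from .nn import Adam, BatchNorm2d


@dataclass
class TrainConfig:
    model: ModelConfig = field(default_factory=ModelConfig)
    epochs: int = 200
    batch_size: int = 4
    learning_rate: float = 0.001
    optimizer: str = "adam"
    loss: str = "dice"
    seed: int = 0
    threshold: float = 0.5
    data_dir: str | None = None
    checkpoint_dir: str | None = None
    log_path: str | None = None

    def validate(self) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be non-negative")
        if self.optimizer != "adam":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")
        if self.loss != "dice":
            raise ValueError(f"unsupported loss {self.loss!r}")
        self.model.validate()

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        d = dict(d)
        if isinstance(d.get("model"), dict):
            d["model"] = ModelConfig.from_dict(d["model"])
        cfg = cls(**{k: v for k, v in d.items() if k in cls.__dataclass_fields__})
        cfg.validate()
        return cfg


def preprocess(image: np.ndarray) -> np.ndarray:
    """uint8 (H, W) -> float (H, W, 1) in [0, 1]."""
    return (np.asarray(image, dtype=np.float32) / 255.0)[..., None]


def _batch_arrays(samples: list[ImageSample], dtype) -> tuple[np.ndarray, np.ndarray]:
    x = np.stack([preprocess(s.image) for s in samples]).astype(dtype)
    t = np.stack([s.mask[..., None] for s in samples]).astype(dtype)
    return x, t


# -- checkpointing ------------------------------------------------------------

def _bn_layers(model: MaresNet) -> list[BatchNorm2d]:
    return [m for m in model.modules() if isinstance(m, BatchNorm2d)]


def save_checkpoint(path, model: MaresNet, optimizer: Adam | None = None,
                    epoch: int = 0, best_val_iou: float = -1.0,
                    train_config: TrainConfig | None = None) -> None:
    arrays = {f"param_{i}": p.value for i, p in enumerate(model.parameters())}
    for i, bn in enumerate(_bn_layers(model)):
        arrays[f"bn_mean_{i}"] = bn.running_mean
        arrays[f"bn_var_{i}"] = bn.running_var
    if optimizer is not None:
        state = optimizer.state_dict()
        arrays["adam_t"] = np.array(state["t"])
        for i, (m, v) in enumerate(zip(state["m"], state["v"])):
            arrays[f"adam_m_{i}"] = m
            arrays[f"adam_v_{i}"] = v
    meta = {"model_config": model.config.to_dict(), "epoch": epoch,
            "best_val_iou": best_val_iou}
    if train_config is not None:
        meta["train_config"] = train_config.to_dict()
    arrays["meta_json"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **arrays)


def load_checkpoint(path) -> tuple[MaresNet, dict]:
    """Rebuild the model embedded in a checkpoint; returns (model, meta) where
    meta carries epoch, best_val_iou, optimizer state and configs."""
    with np.load(path) as z:
        arrays = {k: z[k] for k in z.files}
    meta = json.loads(bytes(arrays.pop("meta_json")).decode())
    model = build_model(ModelConfig.from_dict(meta["model_config"]))
    params = model.parameters()
    for i, p in enumerate(params):
        p.value[...] = arrays[f"param_{i}"]
    for i, bn in enumerate(_bn_layers(model)):
        bn.running_mean[...] = arrays[f"bn_mean_{i}"]
        bn.running_var[...] = arrays[f"bn_var_{i}"]
    if "adam_t" in arrays:
        meta["adam_state"] = {
            "t": int(arrays["adam_t"]),
            "m": [arrays[f"adam_m_{i}"] for i in range(len(params))],
            "v": [arrays[f"adam_v_{i}"] for i in range(len(params))],
        }
    return model, meta


# -- training -----------------------------------------------------------------

def _load_split_samples(data_dir) -> tuple[list[ImageSample], list[ImageSample]]:
    data_dir = Path(data_dir)
    samples = load_pairs(data_dir / "images", data_dir / "masks")
    manifest_path = data_dir / "split.json"
    if manifest_path.exists():
        manifest = SplitManifest.load(manifest_path)
        train = [s for s in samples if manifest.split_of(s.source_id) == "train"]
        val = [s for s in samples if manifest.split_of(s.source_id) == "validation"]
        return train, val
    return samples, []


def train(config: TrainConfig, train_samples: list[ImageSample] | None = None,
          val_samples: list[ImageSample] | None = None,
          resume_from=None, verbose: bool = False):
    """Seeded, resumable Dice/Adam training.

    Returns ``(model, log)`` where ``log`` has one record per completed
    epoch.  With ``checkpoint_dir`` set, ``best.npz`` (highest validation
    IoU) and ``last.npz`` (resume point) are maintained; with ``log_path``
    set, records are appended as JSON lines after every epoch.
    """
    config.validate()
    if train_samples is None:
        if config.data_dir is None:
            raise ValueError("either train_samples or config.data_dir required")
        train_samples, loaded_val = _load_split_samples(config.data_dir)
        if val_samples is None:
            val_samples = loaded_val
    if len(train_samples) == 0:
        raise ValueError("empty training set")
    val_samples = val_samples or []

    start_epoch, best_val_iou = 0, -1.0
    log: list[dict] = []
    if resume_from is not None:
        model, meta = load_checkpoint(resume_from)
        start_epoch = int(meta["epoch"])
        best_val_iou = float(meta["best_val_iou"])
        optimizer = Adam(model.parameters(), lr=config.learning_rate)
        if "adam_state" in meta:
            optimizer.load_state_dict(meta["adam_state"])
    else:
        model = build_model(config.model)
        optimizer = Adam(model.parameters(), lr=config.learning_rate)

    dtype = config.model.np_dtype
    # one seeded shuffle per run: keeps every epoch's batch partition
    # identical, so the run is exactly reproducible and resumable
    order = np.random.default_rng(config.seed).permutation(len(train_samples))
    shuffled = [train_samples[i] for i in order]
    batches = [shuffled[i:i + config.batch_size]
               for i in range(0, len(shuffled), config.batch_size)]

    ckpt_dir = Path(config.checkpoint_dir) if config.checkpoint_dir else None
    for epoch in range(start_epoch, config.epochs):
        t0 = time.time()
        losses, accs = [], []
        for batch in batches:
            x, t = _batch_arrays(batch, dtype)
            prob = model.forward(x, train=True)
            batch_loss = float(np.mean(
                [dice_loss(prob[i], t[i]) for i in range(len(batch))]))
            if not np.isfinite(batch_loss):
                raise RuntimeError(
                    f"non-finite training loss {batch_loss} at epoch {epoch + 1}; "
                    f"reduce the learning rate or check the input data")
            dprob = np.stack([dice_loss_grad(prob[i], t[i])
                              for i in range(len(batch))]) / len(batch)
            optimizer.zero_grad()
            model.backward(dprob.astype(dtype))
            optimizer.step()
            losses.append(batch_loss)
            accs.append(float(((prob >= 0.5) == (t >= 0.5)).mean()))

        record = {"epoch": epoch + 1,
                  "train_loss": float(np.mean(losses)),
                  "train_pixel_acc": float(np.mean(accs))}
        if val_samples:
            vloss, vreport = _validate(model, val_samples, config, dtype)
            record.update({"val_loss": vloss,
                           "val_precision": vreport.precision,
                           "val_recall": vreport.recall,
                           "val_iou": vreport.iou,
                           "val_f1": vreport.f1})
            if vreport.iou > best_val_iou:
                best_val_iou = vreport.iou
                if ckpt_dir is not None:
                    save_checkpoint(ckpt_dir / "best.npz", model, optimizer,
                                    epoch + 1, best_val_iou, config)
        record["seconds"] = round(time.time() - t0, 3)
        log.append(record)
        if ckpt_dir is not None:
            save_checkpoint(ckpt_dir / "last.npz", model, optimizer,
                            epoch + 1, best_val_iou, config)
        if config.log_path:
            Path(config.log_path).parent.mkdir(parents=True, exist_ok=True)
            with open(config.log_path, "a") as fh:
                fh.write(json.dumps(record) + "\n")
        if verbose:
            print(json.dumps(record))
    if ckpt_dir is not None and not val_samples:
        save_checkpoint(ckpt_dir / "best.npz", model, optimizer,
                        config.epochs, best_val_iou, config)
    return model, log


def _validate(model, val_samples, config, dtype):
    probs, truths, vlosses = [], [], []
    for s in val_samples:
        x = _batch_arrays([s], dtype)[0]
        p = model.forward(x, train=False)[0, ..., 0]
        vlosses.append(dice_loss(p, s.mask))
        probs.append(p)
        truths.append(s.mask)
    report = evaluate_masks(probs, truths, threshold=config.threshold)
    return float(np.mean(vlosses)), report


# -- prediction ---------------------------------------------------------------

def predict_probability(model: MaresNet, image: np.ndarray) -> np.ndarray:
    """Probability map for one uint8 grayscale image.

    Sizes not divisible by 2**depth are reflect-padded up to the next
    multiple and the output cropped back, so any image size works.
    """
    h, w = image.shape[:2]
    factor = 2 ** model.config.depth
    ph = (factor - h % factor) % factor
    pw = (factor - w % factor) % factor
    x = preprocess(image)
    if ph or pw:
        x = np.pad(x, ((0, ph), (0, pw), (0, 0)), mode="reflect")
    prob = model.forward(x[None].astype(model.config.np_dtype), train=False)
    return prob[0, :h, :w, 0]


def predict(model_or_checkpoint, images: list[np.ndarray],
            out_dir=None, threshold: float = 0.5,
            names: list[str] | None = None):
    """Probability maps and binary masks for a list of images; optionally
    writes per-image probability (8-bit scaled) and mask PNGs."""
    if isinstance(model_or_checkpoint, (str, Path)):
        model, _ = load_checkpoint(model_or_checkpoint)
    else:
        model = model_or_checkpoint
    probs = [predict_probability(model, img) for img in images]
    masks = [(p >= threshold).astype(np.uint8) for p in probs]
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        names = names or [f"image_{i:04d}" for i in range(len(images))]
        for name, p, m in zip(names, probs, masks):
            Image.fromarray(np.round(p * 255).astype(np.uint8)).save(
                out_dir / f"{name}_prob.png")
            Image.fromarray((m * 255).astype(np.uint8)).save(
                out_dir / f"{name}_mask.png")
    return probs, masks


# -- ablation harness ---------------------------------------------------------

def run_ablation(configs: list[TrainConfig],
                 train_samples: list[ImageSample],
                 val_samples: list[ImageSample],
                 test_samples: list[ImageSample]) -> list[dict]:
    """Train each variant on the shared dataset and tabulate test metrics.

    Returns one row per config: model name plus precision/recall/IoU/F1 (in
    percent, two decimals, table convention).
    """
    from .backbone import model_name

    rows = []
    for cfg in configs:
        model, _ = train(cfg, train_samples, val_samples or None)
        probs = [predict_probability(model, s.image) for s in test_samples]
        report = evaluate_masks(probs, [s.mask for s in test_samples],
                                threshold=cfg.threshold)
        row = {"model": model_name(cfg.model)}
        row.update({k: v for k, v in report.as_percent_dict().items()
                    if k in ("precision", "recall", "iou", "f1")})
        rows.append(row)
    return rows


def ablation_table_csv(rows: list[dict]) -> str:
    cols = ["model", "precision", "recall", "iou", "f1"]
    lines = [",".join(cols)]
    for r in rows:
        lines.append(",".join(str(r[c]) for c in cols))
    return "\n".join(lines) + "\n"
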