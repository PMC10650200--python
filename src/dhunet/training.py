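"""End-to-end training, evaluation and prediction.

Both output heads are supervised with the chosen objective (binary
cross-entropy or ``1 - Dice``), summed with configurable weights and
minimised with Adam at the published defaults (learning rate 0.005,
batch size 32).  Shuffling and initialisation draw from seeded
generators, so a fixed seed reproduces a run bit-for-bit on one machine.

The module also exposes a small modelling front-end in the spirit of
statistical-modelling packages: ``DHuNeTModel`` wraps a dataset and an
architecture, ``fit()`` returns a ``TrainResults`` with the history,
metrics, ``summary()`` and prediction helpers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as dio
from .architecture import DHuNeT, build_dhunet
from .config import DHuNeTConfig, PreprocessConfig, TrainConfig
from .exceptions import ValidationError
from .nn import autograd as ag
from .nn.optim import Adam
from .objectives import (MetricsReport, bce_loss, confusion_counts, dice_index,
                         dice_loss, segmentation_metrics)
from .preprocess import preprocess_sample


# ---------------------------------------------------------------------
# data plumbing
# ---------------------------------------------------------------------

def load_arrays(manifest, input_size: int | None = None,
                split: str | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Materialise a dataset as (X, Y) arrays.

    ``manifest`` may be a manifest path, a list of ``ManifestRow``, or an
    ``(X, Y)`` tuple already in memory.  X is (N, 3, H, W) float32 in
    [0, 1]; Y is (N, H, W) uint8.
    """
    if isinstance(manifest, tuple) and len(manifest) == 2:
        x, y = manifest
        return np.asarray(x, dtype=np.float32), np.asarray(y, dtype=np.uint8)
    if isinstance(manifest, (str, Path)):
        rows = dio.load_manifest(manifest, split=split)
    else:
        rows = list(manifest)
    if not rows:
        raise ValidationError("empty manifest")
    xs, ys = [], []
    for row in rows:
        image, mask = dio.load_sample(row.image, row.mask)
        if input_size is not None and image.shape[0] != input_size:
            raise ValidationError(
                f"sample {row.image} is {image.shape[0]}px, model wants "
                f"{input_size}px; preprocess first")
        xs.append(image.astype(np.float32).transpose(2, 0, 1) / 255.0)
        ys.append(mask)
    return np.stack(xs), np.stack(ys)


@dataclass
class TrainHistory:
    """One record per completed epoch."""

    records: list[dict] = field(default_factory=list)

    def append(self, **kw):
        self.records.append(kw)

    def __len__(self):
        return len(self.records)

    def series(self, key: str) -> list[float]:
        return [r[key] for r in self.records]


def _loss_fn(strategy: str):
    if strategy == "bce":
        return ag.bce_loss_graph
    return ag.dice_loss_graph


def train(model: DHuNeT, train_manifest, val_manifest=None,
          cfg: TrainConfig | None = None) -> tuple[DHuNeT, TrainHistory]:
    """Optimise both heads of ``model``; returns the model and its history.

    The best-validation-Dice (head 2) state is checkpointed when
    ``cfg.checkpoint_dir`` is set.  Zero epochs is a no-op.
    """
    cfg = cfg or TrainConfig()
    x_train, y_train = load_arrays(train_manifest)
    if x_train.shape[0] == 0:
        raise ValidationError("empty training set")
    val = None if val_manifest is None else load_arrays(val_manifest)
    history = TrainHistory()
    if cfg.epochs == 0:
        return model, history

    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.parameters(), lr=cfg.learning_rate)
    loss_graph = _loss_fn(cfg.strategy)
    w1, w2 = cfg.head_loss_weights
    n = x_train.shape[0]
    best_dice = -1.0
    ckpt_dir = Path(cfg.checkpoint_dir) if cfg.checkpoint_dir else None

    model.train()
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        ep_loss, ep_l1, ep_l2, n_batches = 0.0, 0.0, 0.0, 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            xb = x_train[idx]
            yb = y_train[idx][:, None].astype(np.float32)
            m1, m2, _ = model.forward(xb)
            l1 = loss_graph(m1, yb)
            l2 = loss_graph(m2, yb)
            total = ag.add(ag.scale(l1, w1), ag.scale(l2, w2))
            if not np.isfinite(total.data):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}: "
                    f"head1={l1.item()}, head2={l2.item()}")
            opt.zero_grad()
            total.backward()
            opt.step()
            ep_loss += total.item()
            ep_l1 += l1.item()
            ep_l2 += l2.item()
            n_batches += 1
        record = {
            "epoch": epoch,
            "loss": ep_loss / n_batches,
            "loss_head1": ep_l1 / n_batches,
            "loss_head2": ep_l2 / n_batches,
        }
        if val is not None:
            r1, r2 = evaluate(model, val, threshold=cfg.threshold)
            record.update(val_dice_head1=r1.dice, val_dice_head2=r2.dice,
                          val_precision_head2=r2.precision,
                          val_recall_head2=r2.recall)
            if ckpt_dir is not None and r2.dice > best_dice:
                best_dice = r2.dice
                save_model(model, ckpt_dir / "best.npz")
        history.append(**record)
        model.train()
    return model, history


def evaluate(model: DHuNeT, manifest, threshold: float = 0.5,
             aggregation: str = "global", strategy: str = "",
             batch_size: int = 16) -> tuple[MetricsReport, MetricsReport]:
    """Metrics for both heads on a dataset.

    ``aggregation='global'`` pools confusion counts over every pixel of
    the set (micro); ``'per-image-mean'`` averages per-image metric
    values (macro).
    """
    if aggregation not in ("global", "per-image-mean"):
        raise ValidationError(f"unknown aggregation {aggregation!r}")
    x, y = load_arrays(manifest)
    if x.shape[0] == 0:
        raise ValidationError("empty evaluation set")
    preds1, preds2 = [], []
    for start in range(0, x.shape[0], batch_size):
        m1, m2 = model.predict_masks(x[start:start + batch_size])
        preds1.append(m1)
        preds2.append(m2)
    p1, p2 = np.concatenate(preds1), np.concatenate(preds2)

    out = []
    for head, pred in ((1, p1), (2, p2)):
        if aggregation == "global":
            counts = confusion_counts(y, pred, threshold)
            rep = segmentation_metrics(
                counts, pair=(y, (pred >= threshold).astype(float)),
                head=head, aggregation=aggregation, strategy=strategy)
        else:
            per = [segmentation_metrics(
                confusion_counts(y[i], pred[i], threshold),
                pair=(y[i], (pred[i] >= threshold).astype(float)), head=head)
                for i in range(y.shape[0])]
            rep = MetricsReport(
                precision=float(np.mean([m.precision for m in per])),
                recall=float(np.mean([m.recall for m in per])),
                f1=float(np.mean([m.f1 for m in per])),
                dice=float(np.mean([m.dice for m in per])),
                counts=None, head=head, aggregation=aggregation,
                strategy=strategy)
        out.append(rep)
    return out[0], out[1]


def predict(model: DHuNeT, image_path: str | Path, out_dir: str | Path,
            pre_cfg: PreprocessConfig | None = None,
            threshold: float = 0.5) -> dict[str, Path]:
    """Segment one photograph and write the three-row artifact set per
    head: soft mask, binarised mask, and the masked region (image x mask)."""
    pre_cfg = pre_cfg or PreprocessConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    image = dio.load_image(image_path)
    sample = preprocess_sample(image, np.zeros(image.shape[:2], np.uint8), pre_cfg)
    x = sample.image.astype(np.float32).transpose(2, 0, 1)[None]
    m1, m2 = model.predict_masks(x)
    written: dict[str, Path] = {}
    img8 = np.clip(np.rint(sample.image * 255), 0, 255).astype(np.uint8)
    for head, soft in ((1, m1[0]), (2, m2[0])):
        binary = (soft >= threshold).astype(np.uint8)
        overlay = img8 * binary[:, :, None]
        soft_p = out_dir / f"head{head}_soft.png"
        mask_p = out_dir / f"head{head}_mask.png"
        over_p = out_dir / f"head{head}_overlay.png"
        dio.save_mask(mask_p, binary)
        dio.save_image(over_p, overlay)
        from PIL import Image
        Image.fromarray(np.clip(np.rint(soft * 255), 0, 255).astype(np.uint8),
                        mode="L").save(soft_p)
        written.update({f"head{head}_soft": soft_p, f"head{head}_mask": mask_p,
                        f"head{head}_overlay": over_p})
    return written


# ---------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------

def save_model(model: DHuNeT, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    state = model.state_dict()
    state["__config__"] = np.frombuffer(
        json.dumps(model.config.__dict__).encode(), dtype=np.uint8)
    np.savez(path, **state)
    return path


def load_model(path: str | Path) -> DHuNeT:
    with np.load(path) as npz:
        cfg = DHuNeTConfig(**json.loads(bytes(npz["__config__"]).decode()))
        model = build_dhunet(cfg, seed=0)
        model.load_state_dict({k: npz[k] for k in npz.files if k != "__config__"})
    return model


# ---------------------------------------------------------------------
# modelling front-end
# ---------------------------------------------------------------------

class DHuNeTModel:
    """Segmentation model bound to a dataset, statsmodels-style.

    Parameters
    ----------
    train_data, val_data : manifest path, list of rows, or (X, Y) arrays
    config : DHuNeTConfig, architecture of the dual UNet
    seed : initialisation seed for the parameters
    """

    def __init__(self, train_data, val_data=None,
                 config: DHuNeTConfig | None = None, seed: int = 0):
        self.config = config or DHuNeTConfig()
        self.train_data = train_data
        self.val_data = val_data
        self.network = build_dhunet(self.config, seed=seed)

    @classmethod
    def from_manifest(cls, manifest_path: str | Path, **kw) -> "DHuNeTModel":
        rows = dio.load_manifest(manifest_path)
        train_rows = [r for r in rows if r.split == "train"]
        other = [r for r in rows if r.split in ("val", "test")]
        return cls(train_rows, other or None, **kw)

    def fit(self, cfg: TrainConfig | None = None) -> "TrainResults":
        cfg = cfg or TrainConfig()
        _, history = train(self.network, self.train_data, self.val_data, cfg)
        return TrainResults(self, cfg, history)


class TrainResults:
    """Fitted state: trained parameters, history and evaluation helpers."""

    def __init__(self, model: DHuNeTModel, train_cfg: TrainConfig,
                 history: TrainHistory):
        self.model = model
        self.network = model.network
        self.train_cfg = train_cfg
        self.history = history

    @property
    def parameter_count(self) -> int:
        return self.network.parameter_count

    def evaluate(self, data=None, threshold: float = 0.5,
                 aggregation: str = "global"):
        data = data if data is not None else (self.model.val_data
                                              or self.model.train_data)
        return evaluate(self.network, data, threshold=threshold,
                        aggregation=aggregation,
                        strategy=self.train_cfg.strategy)

    def predict(self, image_path, out_dir, **kw):
        return predict(self.network, image_path, out_dir, **kw)

    def save(self, path):
        return save_model(self.network, path)

    def summary(self) -> str:
        lines = [
            "Dual-phase stacked UNet — fit summary",
            "=" * 46,
            f"strategy:          {self.train_cfg.strategy}",
            f"epochs run:        {len(self.history)}",
            f"learning rate:     {self.train_cfg.learning_rate}",
            f"batch size:        {self.train_cfg.batch_size}",
            f"parameters:        {self.parameter_count:,}",
        ]
        if len(self.history):
            first, last = self.history.records[0], self.history.records[-1]
            lines.append(f"loss (first/last): {first['loss']:.4f} / {last['loss']:.4f}")
            if "val_dice_head2" in last:
                lines.append(f"val Dice head 1:   {last['val_dice_head1']:.4f}")
                lines.append(f"val Dice head 2:   {last['val_dice_head2']:.4f}")
        return "\n".join(lines)
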