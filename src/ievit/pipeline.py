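"""Training and evaluation pipeline over image-folder datasets.

Protocol defaults follow the reference training setup: Adam, learning rate
0.001, batch size 32, categorical cross-entropy on a softmax head, stratified
80/20 split.  Every run is fully seeded: the split, weight initialization and
batch shuffling all derive from ``RunConfig.seed``, so artifacts are
reproducible from the logged configuration alone.
"""

from __future__ import annotations

import json
import logging
import sys
import time
from dataclasses import asdict, dataclass, replace
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np

from . import autograd as ag
from .blocks import TensorSpec
from .metrics import MetricReport, classification_metrics, confusion
from .model import IEViT, IEViTConfig, build_ievit
from .optim import make_optimizer
from .synthetic import load_images, load_manifest, train_val_split

__all__ = ["RunConfig", "RunResult", "train", "evaluate", "sweep"]

log = logging.getLogger("ievit")
if not log.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("%(asctime)s %(name)s: %(message)s"))
    log.addHandler(_h)
    log.setLevel(logging.INFO)


@dataclass(frozen=True)
class RunConfig:
    """One training run; defaults reproduce the reference protocol."""
    data_root: str = "."
    optimizer: str = "adam"
    learning_rate: float = 0.001
    batch_size: int = 32
    epochs: int = 100
    patch_size: int = 8
    image_size: int = 32
    num_classes: int = 3
    train_fraction: float = 0.8
    label_smoothing: float = 0.0
    seed: int = 0

    def model_config(self) -> IEViTConfig:
        return IEViTConfig(
            input=TensorSpec(self.image_size, self.image_size, 3),
            num_classes=self.num_classes,
            patch_size=self.patch_size,
            seed=self.seed,
        )

    def to_yaml(self) -> str:
        import yaml
        return yaml.safe_dump(asdict(self), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        import yaml
        return cls(**(yaml.safe_load(text) or {}))


@dataclass
class RunResult:
    run_dir: Path
    curves: List[dict]
    best_val_accuracy: float
    final_train_accuracy: float
    weights_path: Path
    config: RunConfig


def _batches(n, batch_size, rng):
    idx = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield idx[start:start + batch_size]


def train(config: RunConfig, run_dir, model: Optional[IEViT] = None,
          quiet: bool = False) -> RunResult:
    """Train on the manifest under ``config.data_root``; write run artifacts.

    Artifacts: ``config.yaml``, ``curves.tsv`` (one row per epoch with train
    and validation accuracy/loss) and ``weights_best.npz`` (best validation
    accuracy).  The best-validation weights are restored into the returned
    model state at the end.
    """
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    run_id = f"run-{int(time.time())}-s{config.seed}"
    root = Path(config.data_root)
    rows = load_manifest(root / "manifest.tsv")
    if not rows:
        raise ValueError("empty dataset manifest")
    labels_present = {l for _, l in rows}
    if max(labels_present) >= config.num_classes:
        raise ValueError("manifest labels exceed configured class count")

    tr_rows, va_rows = train_val_split(rows, config.train_fraction, config.seed)
    x_tr, y_tr = load_images(tr_rows, root, config.image_size)
    x_va, y_va = load_images(va_rows, root, config.image_size)
    if not quiet:
        log.info("%s: %d train / %d val images, %d classes", run_id,
                 len(x_tr), len(x_va), config.num_classes)

    if model is None:
        model = build_ievit(config.model_config())
    opt = make_optimizer(config.optimizer, model.parameters(),
                         config.learning_rate)
    rng = np.random.default_rng(config.seed + 1)

    (run_dir / "config.yaml").write_text(config.to_yaml())
    curves = []
    best_val, best_state = -1.0, None
    weights_path = run_dir / "weights_best.npz"
    for epoch in range(config.epochs):
        losses = []
        correct = 0
        for idx in _batches(len(x_tr), config.batch_size, rng):
            opt.zero_grad()
            logits = model.logits(x_tr[idx], training=True)
            loss = _loss(logits, y_tr[idx], config)
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
            correct += int((logits.data.argmax(axis=1) == y_tr[idx]).sum())
        train_loss = float(np.mean(losses))
        train_acc = correct / len(x_tr)
        val_loss, val_acc = _eval_loss(model, x_va, y_va, config)
        curves.append(dict(epoch=epoch + 1, train_loss=train_loss,
                           train_acc=train_acc, val_loss=val_loss,
                           val_acc=val_acc))
        if not quiet:
            log.info("%s epoch %d/%d: loss %.4f acc %.4f | val loss %.4f "
                     "acc %.4f", run_id, epoch + 1, config.epochs, train_loss,
                     train_acc, val_loss, val_acc)
        if val_acc > best_val:
            best_val = val_acc
            best_state = {k: v.copy() for k, v in model.state().items()}

    if best_state is not None:
        model.load_state(best_state)
        model.save_weights(weights_path)
    _write_curves(run_dir / "curves.tsv", curves)
    return RunResult(run_dir=run_dir, curves=curves, best_val_accuracy=best_val,
                     final_train_accuracy=curves[-1]["train_acc"],
                     weights_path=weights_path, config=config)


def _loss(logits, labels, config: RunConfig):
    s = config.label_smoothing
    if s <= 0:
        return ag.softmax_cross_entropy(logits, labels)
    # soft-target cross-entropy: -mean_i sum_c q_ic log p_ic
    n, k = logits.shape
    q = np.full((n, k), s / k, dtype=np.float32)
    q[np.arange(n), labels] += 1.0 - s
    logp = _log_softmax(logits)
    return ag.mul(ag.sum_(ag.mul(logp, q)), -1.0 / n)


def _log_softmax(z):
    # numerically stable identity: log softmax(z) = z - logsumexp(z)
    return ag.add(z, ag.mul(_logsumexp(z), -1.0))


def _logsumexp(z):
    m = z.data.max(axis=-1, keepdims=True)     # constant shift
    e = ag.sum_(_exp(ag.add(z, -m)), axis=-1, keepdims=True)
    return ag.add(_log(e), m)


def _exp(t):
    out = np.exp(t.data)

    def vjp(g):
        return (g * out,)

    return ag._node(out, (t,), vjp)


def _log(t):
    out = np.log(t.data)

    def vjp(g):
        return (g / t.data,)

    return ag._node(out, (t,), vjp)


def _eval_loss(model, x, y, config: RunConfig, batch_size=64):
    losses, correct = [], 0
    for start in range(0, len(x), batch_size):
        xb, yb = x[start:start + batch_size], y[start:start + batch_size]
        logits = model.logits(xb, training=False)
        loss = _loss(logits, yb, config)
        losses.append(float(loss.data) * len(xb))
        correct += int((logits.data.argmax(axis=1) == yb).sum())
    return sum(losses) / len(x), correct / len(x)


def _write_curves(path, curves):
    cols = ["epoch", "train_loss", "train_acc", "val_loss", "val_acc"]
    lines = ["\t".join(cols)]
    for row in curves:
        lines.append("\t".join(f"{row[c]:.6f}" if c != "epoch"
                               else str(row[c]) for c in cols))
    Path(path).write_text("\n".join(lines) + "\n")


def evaluate(model: IEViT, manifest_rows: Sequence[Tuple[str, int]],
             data_root, image_size: int,
             num_classes: int) -> Tuple[MetricReport, np.ndarray]:
    """Metric report and confusion matrix over a manifest."""
    x, y = load_images(manifest_rows, data_root, image_size)
    preds = []
    for start in range(0, len(x), 64):
        probs = model.forward(x[start:start + 64]).data
        preds.extend(probs.argmax(axis=1).tolist())
    cm = confusion(y, preds, num_classes)
    return classification_metrics(cm), cm.counts


def evaluate_weights(weights_path, config: RunConfig,
                     manifest_rows, data_root):
    model = build_ievit(config.model_config())
    try:
        model.load_weights(weights_path)
    except (KeyError, ValueError) as exc:
        raise ValueError(
            f"weights at {weights_path} do not match the configured "
            f"architecture: {exc}") from exc
    return evaluate(model, manifest_rows, data_root, config.image_size,
                    config.num_classes)


def sweep(config: RunConfig, axis: str, values: Sequence, out_dir) -> List[dict]:
    """Train/evaluate once per value of ``axis`` (optimizer or patch_size).

    Returns a collated table with train/validation accuracy and loss per
    value, also written as ``sweep.tsv``.
    """
    if axis not in ("optimizer", "patch_size"):
        raise ValueError("axis must be 'optimizer' or 'patch_size'")
    if not values:
        raise ValueError("empty sweep value list")
    out_dir = Path(out_dir)
    table = []
    for v in values:
        cfg = replace(config, **{axis: v})
        result = train(cfg, out_dir / f"{axis}-{v}")
        last = result.curves[-1]
        table.append({axis: v, "train_acc": last["train_acc"],
                      "train_loss": last["train_loss"],
                      "val_acc": last["val_acc"],
                      "val_loss": last["val_loss"],
                      "seed": cfg.seed})
    cols = [axis, "train_loss", "train_acc", "val_loss", "val_acc", "seed"]
    lines = ["\t".join(cols)]
    for row in table:
        lines.append("\t".join(str(row[c]) if c in (axis, "seed")
                               else f"{row[c]:.6f}" for c in cols))
    (out_dir / "sweep.tsv").write_text("\n".join(lines) + "\n")
    (out_dir / "sweep.json").write_text(json.dumps(table, indent=2))
    return table
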