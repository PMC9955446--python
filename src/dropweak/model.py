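"""A compact two-block residual image classifier with DropWeak.

The architecture mirrors the two-block topology the masking scheme is
designed for: Block 1's convolutions (and the fully connected head's
weights) are DropWeak-wrapped — node dropout, per-weight DropConnect
masking and weak-weight zeroing, resampled every stochastic pass — while
Block 2 receives only plain DropOut. A SoftMax layer produces the class
probability distribution.

Scale notes. The reference training regime for this family of models on
clinical CT archives is 256x256 inputs, Adam at 1e-5 with plateau factor
0.2, batch size 16, 750 epochs and an 80/10/10 split. The desk-scale
defaults here are 64x64 inputs, Adam at 1e-3 and a few tens of epochs —
small enough to train from scratch on one CPU core in minutes — with the
full-scale values reachable through configuration.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .masking import DropWeakSpec, WeakRule
from .rng import substream

__all__ = [
    "ArchitectureConfig",
    "TrainConfig",
    "ArrayDataset",
    "ResidualClassifier",
    "build_model",
    "train",
    "split_dataset",
    "DivergenceError",
    "NaiveBayesHead",
    "naive_bayes_head_fit",
    "fused_predict",
    "save_checkpoint",
    "load_checkpoint",
]


class DivergenceError(RuntimeError):
    """Raised when the training loss becomes non-finite."""

    def __init__(self, msg: str, last_good: "ResidualClassifier | None" = None):
        super().__init__(msg)
        self.last_good = last_good


@dataclass(frozen=True)
class ArchitectureConfig:
    input_size: tuple[int, int] = (64, 64)
    channels: tuple[int, int] = (8, 16)
    n_res_blocks: int = 1
    n_classes: int = 2
    dropweak_spec: DropWeakSpec = field(default_factory=lambda: DropWeakSpec(0.1, 0.1))
    dropout_prob: float = 0.2
    optional_nb_head: bool = False

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if len(self.channels) != 2 or any(c < 1 for c in self.channels):
            raise ValueError("channels must be two positive stage widths")
        if not 0.0 <= self.dropout_prob < 1.0:
            raise ValueError("dropout_prob must lie in [0, 1)")
        if self.n_res_blocks < 1:
            raise ValueError("n_res_blocks must be >= 1")


@dataclass(frozen=True)
class TrainConfig:
    optimizer: str = "adam"
    learning_rate: float = 1e-3  # full-scale reference value: 1e-5
    lr_factor: float = 0.2  # reduce-on-plateau multiplier
    lr_patience: int = 10
    batch_size: int = 16
    epochs: int = 20  # full-scale reference value: 750
    seed: int = 0
    split: tuple[float, float, float] = (0.8, 0.1, 0.1)
    augmentation: bool = False

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if any(f <= 0 for f in self.split) or abs(sum(self.split) - 1.0) > 1e-9:
            raise ValueError("split fractions must be positive and sum to 1")
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is supported")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")


@dataclass
class ArrayDataset:
    """In-memory dataset: grayscale images in [0,1] plus integer labels."""

    images: np.ndarray  # (N, H, W)
    labels: np.ndarray  # (N,)
    splits: dict[str, np.ndarray] | None = None  # name -> index array

    def subset(self, name: str) -> tuple[np.ndarray, np.ndarray]:
        if not self.splits or name not in self.splits:
            raise ValueError(f"dataset has no split {name!r}")
        idx = self.splits[name]
        return self.images[idx], self.labels[idx]


def split_dataset(
    n: int, fractions: tuple[float, float, float], rng: np.random.Generator, labels: np.ndarray | None = None
) -> dict[str, np.ndarray]:
    """Random train/val/test index split; stratified when labels given."""
    order = rng.permutation(n)
    if labels is not None:  # round-robin by class keeps splits stratified
        interleaved = []
        per_class = [order[labels[order] == c] for c in np.unique(labels)]
        longest = max(len(p) for p in per_class)
        for i in range(longest):
            for p in per_class:
                if i < len(p):
                    interleaved.append(p[i])
        order = np.asarray(interleaved)
    n_train = int(round(fractions[0] * n))
    n_val = int(round(fractions[1] * n))
    return {
        "train": np.sort(order[:n_train]),
        "val": np.sort(order[n_train : n_train + n_val]),
        "test": np.sort(order[n_train + n_val :]),
    }


class ResidualClassifier:
    """Two-stage residual CNN; see the module docstring for the topology."""

    def __init__(self, cfg: ArchitectureConfig, rng: np.random.Generator):
        self.cfg = cfg
        c1, c2 = cfg.channels
        dw = cfg.dropweak_spec
        self.stages: list[nn.Layer] = []

        def add(layer: nn.Layer) -> nn.Layer:
            self.stages.append(layer)
            return layer

        add(nn.Conv2d(1, c1, 3, rng, stride=2, pad=1, name="stem"))
        add(nn.ReLU(name="stem_relu"))
        for i in range(cfg.n_res_blocks):
            add(nn.ResidualBlock(c1, rng, dropweak=dw, name=f"block1_{i}"))
        add(nn.Conv2d(c1, c2, 3, rng, stride=2, pad=1, name="trans"))
        add(nn.ReLU(name="trans_relu"))
        for i in range(cfg.n_res_blocks):
            add(nn.ResidualBlock(c2, rng, name=f"block2_{i}"))
        add(nn.Dropout(cfg.dropout_prob, name="dropout"))
        add(nn.GlobalAvgPool(name="gap"))
        add(nn.Dense(c2, cfg.n_classes, rng, dropweak=dw, name="fc"))

        self.norm_mean: float = 0.0
        self.norm_std: float = 1.0
        self.training_log: list[dict] = []
        self.rng_note: str = ""

    # -- naming ---------------------------------------------------------
    @property
    def stage_names(self) -> list[str]:
        return [s.name for s in self.stages]

    @property
    def default_cam_layer(self) -> str:
        # the stem feature map: at this depth (5 effective conv layers)
        # it has the highest spatial fidelity, and deeper maps encode
        # increasingly global size cues that blur attention; any conv
        # stage remains selectable
        return "stem_relu"

    def stage(self, name: str) -> nn.Layer:
        for s in self.stages:
            if s.name == name:
                return s
        raise KeyError(f"no stage named {name!r}")

    # -- forward / backward --------------------------------------------
    def _check_batch(self, batch: np.ndarray) -> np.ndarray:
        x = np.asarray(batch, dtype=nn.DTYPE)
        if x.ndim == 2:
            x = x[None]
        if x.ndim != 3 or x.shape[1:] != tuple(self.cfg.input_size):
            raise ValueError(
                f"expected batch of {self.cfg.input_size} grayscale images, got {x.shape}"
            )
        return (x[:, None] - self.norm_mean) / self.norm_std

    def forward_logits(
        self, batch: np.ndarray, stochastic: bool = False, rng: np.random.Generator | None = None
    ) -> np.ndarray:
        if stochastic and rng is None:
            raise ValueError("stochastic forward requires a random generator")
        h = self._check_batch(batch)
        self._stage_out: dict[str, np.ndarray] = {}
        for s in self.stages:
            h = s.forward(h, stochastic, rng)
            self._stage_out[s.name] = h
        return h

    def forward(
        self, batch: np.ndarray, stochastic: bool = False, rng: np.random.Generator | None = None
    ) -> np.ndarray:
        """Class-probability matrix (N x C); rows on the simplex."""
        return nn.softmax(self.forward_logits(batch, stochastic, rng))

    def backward_logits(self, dlogits: np.ndarray, stop_at: str | None = None) -> np.ndarray:
        """Backprop from the logits; returns the gradient w.r.t. the
        output of stage ``stop_at`` (or the input when ``None``)."""
        dout = dlogits
        for s in reversed(self.stages):
            if stop_at is not None and s.name == stop_at:
                return dout
            dout = s.backward(dout)
        return dout

    def head_from(self, name: str, activation: np.ndarray) -> np.ndarray:
        """Deterministically run the stages after ``name`` on a given
        activation (used by gradient-checking oracles)."""
        idx = self.stage_names.index(name)
        h = activation
        for s in self.stages[idx + 1 :]:
            h = s.forward(h, False, None)
        return h

    def stage_output(self, name: str) -> np.ndarray:
        return self._stage_out[name]

    # -- parameters -----------------------------------------------------
    def named_params(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for s in self.stages:
            for k, v in s.params().items():
                out[f"{s.name}/{k}"] = v
        return out

    def named_grads(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for s in self.stages:
            for k, v in s.grads().items():
                out[f"{s.name}/{k}"] = v
        return out

    def zero_grad(self) -> None:
        for s in self.stages:
            s.zero_grad()

    def param_count(self) -> int:
        return int(sum(p.size for p in self.named_params().values()))

    def get_weights(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.named_params().items()}

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        params = self.named_params()
        if set(weights) != set(params):
            raise ValueError("weight names do not match the architecture")
        for k, v in weights.items():
            params[k][...] = v


def build_model(cfg: ArchitectureConfig, rng: np.random.Generator) -> ResidualClassifier:
    return ResidualClassifier(cfg, rng)


def _augment(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    from scipy.ndimage import rotate

    out = x.copy()
    flip = rng.random(len(out)) < 0.5
    out[flip] = out[flip, :, ::-1]
    angles = rng.uniform(-10, 10, len(out))
    for i, a in enumerate(angles):
        out[i] = rotate(out[i], a, reshape=False, order=1, mode="nearest")
    return out


def train(model: ResidualClassifier, dataset: ArrayDataset, tcfg: TrainConfig) -> ResidualClassifier:
    """Cross-entropy training with fresh DropWeak masks per batch.

    Logs per-epoch train loss and validation accuracy, decays the
    learning rate by ``lr_factor`` on a validation plateau, and restores
    the best-validation-accuracy weights before returning.
    """
    if dataset.splits is None:
        idx_rng = substream(tcfg.seed, "split")
        dataset.splits = split_dataset(len(dataset.images), tcfg.split, idx_rng, dataset.labels)
    x_train, y_train = dataset.subset("train")
    x_val, y_val = dataset.subset("val")
    if len(x_train) == 0 or len(x_val) == 0:
        raise ValueError("empty train or validation split")
    if y_train.min() < 0 or y_train.max() >= model.cfg.n_classes:
        raise ValueError("labels must lie in {0..C-1}")

    # standardize with training-split statistics only (no leakage)
    model.norm_mean = float(x_train.mean())
    model.norm_std = float(x_train.std() + 1e-8)

    opt = nn.Adam(lr=tcfg.learning_rate)
    best_acc, best_weights, since_best = -1.0, model.get_weights(), 0
    last_good = model.get_weights()
    n = len(x_train)

    for epoch in range(tcfg.epochs):
        order = substream(tcfg.seed, "shuffle", epoch).permutation(n)
        mask_rng = substream(tcfg.seed, "masks", epoch)
        losses = []
        for start in range(0, n, tcfg.batch_size):
            idx = order[start : start + tcfg.batch_size]
            xb, yb = x_train[idx], y_train[idx]
            if tcfg.augmentation:
                xb = _augment(xb, substream(tcfg.seed, "augment", epoch, start))
            try:
                probs = model.forward(xb, stochastic=True, rng=mask_rng)
            except ValueError:
                finite = all(np.all(np.isfinite(p)) for p in model.named_params().values())
                if finite:
                    raise
                good = build_model(model.cfg, substream(tcfg.seed, "init"))
                good.set_weights(last_good)
                raise DivergenceError(f"non-finite weights at epoch {epoch}", last_good=good)
            loss = nn.cross_entropy(probs, yb)
            if not np.isfinite(loss):
                good = build_model(model.cfg, substream(tcfg.seed, "init"))
                good.set_weights(last_good)
                raise DivergenceError(f"non-finite loss at epoch {epoch}", last_good=good)
            losses.append(loss)
            onehot = np.zeros_like(probs)
            onehot[np.arange(len(yb)), yb] = 1.0
            model.backward_logits((probs - onehot) / len(yb))
            opt.step(model.named_params(), model.named_grads())
            model.zero_grad()
        last_good = model.get_weights()

        val_probs = model.forward(x_val, stochastic=False)
        val_acc = float((val_probs.argmax(axis=1) == y_val).mean())
        model.training_log.append(
            {"epoch": epoch, "train_loss": float(np.mean(losses)), "val_accuracy": val_acc, "lr": opt.lr}
        )
        if val_acc > best_acc:
            best_acc, best_weights, since_best = val_acc, model.get_weights(), 0
        else:
            since_best += 1
            if since_best >= tcfg.lr_patience:
                opt.lr *= tcfg.lr_factor
                since_best = 0

    model.set_weights(best_weights)
    return model


# -- checkpointing ------------------------------------------------------


def save_checkpoint(model: ResidualClassifier, path: str | Path) -> None:
    """Single-archive checkpoint: weight arrays + JSON metadata."""
    meta = {
        "architecture": _arch_to_dict(model.cfg),
        "norm_mean": model.norm_mean,
        "norm_std": model.norm_std,
        "training_log": model.training_log,
        "rng_note": model.rng_note,
    }
    buf = io.BytesIO()
    np.savez(buf, **model.get_weights())
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("weights.npz", buf.getvalue())
        zf.writestr("meta.json", json.dumps(meta, indent=1))


def load_checkpoint(path: str | Path) -> ResidualClassifier:
    with zipfile.ZipFile(path) as zf:
        meta = json.loads(zf.read("meta.json"))
        with np.load(io.BytesIO(zf.read("weights.npz"))) as npz:
            weights = {k: npz[k] for k in npz.files}
    cfg = _arch_from_dict(meta["architecture"])
    model = ResidualClassifier(cfg, np.random.default_rng(0))
    model.set_weights(weights)
    model.norm_mean = meta["norm_mean"]
    model.norm_std = meta["norm_std"]
    model.training_log = meta["training_log"]
    model.rng_note = meta.get("rng_note", "")
    return model


def _arch_to_dict(cfg: ArchitectureConfig) -> dict:
    d = asdict(cfg)
    d["dropweak_spec"]["weak_rule"] = (
        None if cfg.dropweak_spec.weak_rule is None else asdict(cfg.dropweak_spec.weak_rule)
    )
    return d


def _arch_from_dict(d: dict) -> ArchitectureConfig:
    dw = dict(d["dropweak_spec"])
    wr = dw.pop("weak_rule")
    spec = DropWeakSpec(
        node_drop_prob=dw["node_drop_prob"],
        weight_drop_prob=dw["weight_drop_prob"],
        weak_rule=None if wr is None else WeakRule(wr["kind"], wr["value"]),
        scale_mode=dw["scale_mode"],
    )
    return ArchitectureConfig(
        input_size=tuple(d["input_size"]),
        channels=tuple(d["channels"]),
        n_res_blocks=d["n_res_blocks"],
        n_classes=d["n_classes"],
        dropweak_spec=spec,
        dropout_prob=d["dropout_prob"],
        optional_nb_head=d["optional_nb_head"],
    )


# -- optional Naive-Bayes fusion head -----------------------------------


@dataclass
class NaiveBayesHead:
    """Gaussian Naive-Bayes head over pooled penultimate features."""

    gnb: object  # sklearn GaussianNB

    def posteriors(self, features: np.ndarray) -> np.ndarray:
        return self.gnb.predict_proba(features)


def _pooled_features(model: ResidualClassifier, images: np.ndarray) -> np.ndarray:
    model.forward_logits(images, stochastic=False)
    return model.stage_output("gap")


def naive_bayes_head_fit(
    model: ResidualClassifier, images: np.ndarray, labels: np.ndarray, var_floor: float = 1e-9
) -> NaiveBayesHead:
    from sklearn.naive_bayes import GaussianNB

    gnb = GaussianNB(var_smoothing=var_floor)
    gnb.fit(_pooled_features(model, images), labels)
    return NaiveBayesHead(gnb)


def fused_predict(model: ResidualClassifier, head: NaiveBayesHead, images: np.ndarray) -> np.ndarray:
    """Renormalized elementwise product of SoftMax and NB posteriors."""
    p_net = model.forward(images, stochastic=False)
    p_nb = head.posteriors(_pooled_features(model, images))
    fused = p_net * p_nb
    return fused / fused.sum(axis=1, keepdims=True)
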