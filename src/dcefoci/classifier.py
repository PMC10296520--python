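"""Dual-resolution patch CNN for cancer vs non-cancer focus classification.

The network has two independent convolutional feature extractors — one for
the 24x24 local patch, one for the 128x128 context patch — each a stack of
[3x3 conv -> ReLU -> 2x2 max-pool stride 2] blocks. Branch outputs are
flattened, concatenated, and fed to an MLP ending in a 2-way softmax
(index 0 = non-cancer, index 1 = cancer). Training minimizes binary
cross-entropy (2-class softmax form) with Adam at learning rate 1e-4.

The convolutional branches can optionally be pre-trained on a small labeled
image set (a bundled synthetic textured-image corpus by default) before the
classifier head is re-initialized and the whole model fine-tuned.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage.transform import resize

from .errors import ConfigurationError, DataError, FormatError, ParameterError
from .io import CONTEXT_PATCH_SIZE, LOCAL_PATCH_SIZE, PatchPair
from .nn import Adam, Conv3x3, Dense, Dropout, MaxPool2, ReLU, cross_entropy_grad, softmax

CLASS_NAMES = ("non-cancer", "cancer")  # output index order


@dataclass
class ModelConfig:
    local_branch_blocks: list[int] = field(default_factory=lambda: [16, 32])
    context_branch_blocks: list[int] = field(default_factory=lambda: [16, 32, 64, 64])
    mlp_hidden: int = 128
    dropout_rate: float = 0.25
    learning_rate: float = 1e-4
    epochs: int = 50
    batch_size: int = 16
    augment_flips: bool = True
    class_weights: bool = True
    pretrain: bool = False
    pretrain_epochs: int = 3
    seed: int = 0

    def validate(self) -> None:
        if not (0 <= self.dropout_rate < 1):
            raise ConfigurationError("dropout_rate must lie in [0, 1)")
        if self.learning_rate <= 0 or self.epochs < 1 or self.batch_size < 1:
            raise ConfigurationError("learning_rate, epochs, batch_size must be positive")
        _propagate(LOCAL_PATCH_SIZE, self.local_branch_blocks)
        _propagate(CONTEXT_PATCH_SIZE, self.context_branch_blocks)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ParameterError(f"unknown model parameters: {sorted(unknown)}")
        return cls(**d)


def _propagate(size: int, blocks: list[int]) -> int:
    """Spatial size after the block stack; each 2x2/stride-2 pool halves it."""
    s = size
    for _ in blocks:
        if s < 2:
            raise ConfigurationError(
                f"block stack {blocks} reduces a {size}-px input below 1 px"
            )
        s //= 2
    return s


@dataclass
class PatchDataset:
    """Labeled patch pairs ready for training/evaluation."""

    local: np.ndarray  # (n, 24, 24)
    context: np.ndarray  # (n, 128, 128)
    labels: np.ndarray  # (n,) int, 1 = cancer
    subject_ids: list[str]

    def __len__(self) -> int:
        return len(self.labels)

    def subset(self, idx) -> "PatchDataset":
        idx = np.asarray(idx, dtype=np.intp)
        return PatchDataset(
            self.local[idx],
            self.context[idx],
            self.labels[idx],
            [self.subject_ids[i] for i in idx],
        )

    def save(self, directory: str | Path) -> Path:
        """Cache the patch set: compressed arrays plus an index CSV."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savez_compressed(
            directory / "patches.npz", local=self.local, context=self.context
        )
        with open(directory / "index.csv", "w", newline="") as fh:
            fh.write("subject_id,label\r\n")
            for sid, lbl in zip(self.subject_ids, self.labels):
                fh.write(f"{sid},{int(lbl)}\r\n")
        return directory

    @classmethod
    def load(cls, directory: str | Path) -> "PatchDataset":
        directory = Path(directory)
        with np.load(directory / "patches.npz") as npz:
            local, context = npz["local"], npz["context"]
        ids, labels = [], []
        with open(directory / "index.csv") as fh:
            next(fh)
            for line in fh:
                sid, lbl = line.strip().split(",")
                ids.append(sid)
                labels.append(int(lbl))
        return cls(local, context, np.asarray(labels), ids)


class _Branch:
    def __init__(self, c_blocks: list[int], in_size: int, rng: np.random.Generator):
        self.layers = []
        c_prev = 1
        for c in c_blocks:
            self.layers += [Conv3x3(c_prev, c, rng), ReLU(), MaxPool2()]
            c_prev = c
        self.out_dim = c_prev * _propagate(in_size, c_blocks) ** 2

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x.reshape(x.shape[0], -1)

    def backward(self, dflat: np.ndarray, out_shape) -> None:
        dy = dflat.reshape(out_shape)
        for layer in reversed(self.layers):
            dy = layer.backward(dy)

    def params(self):
        return [p for layer in self.layers for p in layer.params()]


class DualPatchCNN:
    """The two-branch network; also carries its training log after fitting."""

    def __init__(self, config: ModelConfig):
        config.validate()
        self.config = config
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=config.seed, spawn_key=(0,))
        )
        self.local_branch = _Branch(config.local_branch_blocks, LOCAL_PATCH_SIZE, rng)
        self.context_branch = _Branch(
            config.context_branch_blocks, CONTEXT_PATCH_SIZE, rng
        )
        self.concat_dim = self.local_branch.out_dim + self.context_branch.out_dim
        self._build_head(rng)
        self.loss_log: list[float] = []

    def _build_head(self, rng: np.random.Generator) -> None:
        self.fc1 = Dense(self.concat_dim, self.config.mlp_hidden, rng)
        self.relu = ReLU()
        self.dropout = Dropout(self.config.dropout_rate)
        self.fc2 = Dense(self.config.mlp_hidden, 2, rng)

    def reinit_head(self) -> None:
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=self.config.seed, spawn_key=(1,))
        )
        self._build_head(rng)

    # -- forward/backward ---------------------------------------------------

    def _forward(self, xl, xc, train=False, rng=None):
        fl = self.local_branch.forward(xl, train)
        fc = self.context_branch.forward(xc, train)
        feats = np.concatenate([fl, fc], axis=1)
        h = self.relu.forward(self.fc1.forward(feats, train), train)
        h = self.dropout.forward(h, train, rng)
        logits = self.fc2.forward(h, train)
        if train:
            self._shapes = (fl.shape[1],)
        return logits

    def _backward(self, dlogits):
        dh = self.fc2.backward(dlogits)
        dh = self.dropout.backward(dh)
        dfeat = self.fc1.backward(self.relu.backward(dh))
        nl = self._shapes[0]
        b = dfeat.shape[0]
        lb, cb = self.local_branch, self.context_branch
        nlo = self.config.local_branch_blocks[-1]
        slo = int(np.sqrt(nl // nlo))
        nco = self.config.context_branch_blocks[-1]
        sco = int(np.sqrt(cb.out_dim // nco))
        lb.backward(dfeat[:, :nl], (b, slo, slo, nlo))
        cb.backward(dfeat[:, nl:], (b, sco, sco, nco))

    def params(self, head=True, branches=True):
        out = []
        if branches:
            out += self.local_branch.params() + self.context_branch.params()
        if head:
            out += self.fc1.params() + self.fc2.params()
        return out

    # -- inference ----------------------------------------------------------

    def predict_proba(self, local: np.ndarray, context: np.ndarray) -> np.ndarray:
        """Class probabilities for a batch; evaluation mode (no dropout)."""
        if local.shape[1:] != (LOCAL_PATCH_SIZE, LOCAL_PATCH_SIZE) or context.shape[
            1:
        ] != (CONTEXT_PATCH_SIZE, CONTEXT_PATCH_SIZE):
            raise FormatError(
                f"bad patch shapes {local.shape[1:]} / {context.shape[1:]}"
            )
        xl = local[..., None].astype(np.float32)
        xc = context[..., None].astype(np.float32)
        return softmax(self._forward(xl, xc, train=False).astype(np.float64))

    def weight_checksum(self) -> str:
        h = hashlib.sha256()
        for attr, layer in self.params():
            h.update(np.ascontiguousarray(getattr(layer, attr)).tobytes())
        return h.hexdigest()

    # -- persistence --------------------------------------------------------

    def save(self, path: str | Path) -> None:
        path = Path(path)
        arrays = {
            f"p{i}_{attr}": getattr(layer, attr)
            for i, (attr, layer) in enumerate(self.params())
        }
        np.savez(path.with_suffix(".npz"), **arrays)
        sidecar = {
            "config": dataclasses.asdict(self.config),
            "seed": self.config.seed,
            "weight_checksum": self.weight_checksum(),
            "loss_log": self.loss_log,
        }
        with open(path.with_suffix(".json"), "w") as fh:
            json.dump(sidecar, fh, indent=2)

    @classmethod
    def load(cls, path: str | Path) -> "DualPatchCNN":
        path = Path(path)
        with open(path.with_suffix(".json")) as fh:
            sidecar = json.load(fh)
        model = cls(ModelConfig.from_dict(sidecar["config"]))
        with np.load(path.with_suffix(".npz")) as npz:
            for i, (attr, layer) in enumerate(model.params()):
                setattr(layer, attr, npz[f"p{i}_{attr}"])
        model.loss_log = list(sidecar.get("loss_log", []))
        if model.weight_checksum() != sidecar["weight_checksum"]:
            raise FormatError(f"weight checksum mismatch loading {path}")
        return model


# ---------------------------------------------------------------------------
# Spec-level operations
# ---------------------------------------------------------------------------


def build_model(config: ModelConfig) -> DualPatchCNN:
    return DualPatchCNN(config)


def _augment(xl, xc, rng):
    codes = rng.integers(0, 4, size=xl.shape[0])
    xl, xc = xl.copy(), xc.copy()
    for i, code in enumerate(codes):
        if code & 1:
            xl[i] = xl[i, :, ::-1]
            xc[i] = xc[i, :, ::-1]
        if code & 2:
            xl[i] = xl[i, ::-1]
            xc[i] = xc[i, ::-1]
    return xl, xc


def train(
    model: DualPatchCNN,
    dataset: PatchDataset,
    config: ModelConfig | None = None,
    seed: int | None = None,
    allow_single_class: bool = False,
) -> DualPatchCNN:
    """Fit the model in place; returns it with a per-epoch loss log.

    Fully reproducible given ``seed`` (defaults to the model config's seed).
    ``allow_single_class`` lets leave-one-out folds of very small datasets
    train on a degenerate one-class remainder instead of failing.
    """
    config = config or model.config
    if len(dataset) == 0:
        raise DataError("empty training dataset")
    classes = np.unique(dataset.labels)
    if len(classes) < 2 and not allow_single_class:
        raise DataError(f"training set contains a single class: {classes.tolist()}")
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(2,)))

    n = len(dataset)
    labels = dataset.labels.astype(np.int64)
    if config.class_weights and len(classes) == 2:
        counts = np.bincount(labels, minlength=2).astype(np.float64)
        class_w = n / (2.0 * np.maximum(counts, 1))
    else:
        class_w = np.ones(2)
    xl_all = dataset.local[..., None].astype(np.float32)
    xc_all = dataset.context[..., None].astype(np.float32)

    opt = Adam(model.params(), lr=config.learning_rate)
    model.loss_log = []
    for _ in range(config.epochs):
        perm = rng.permutation(n)
        losses, weights = [], []
        for start in range(0, n, config.batch_size):
            idx = perm[start : start + config.batch_size]
            xl, xc, y = xl_all[idx], xc_all[idx], labels[idx]
            if config.augment_flips:
                xl, xc = _augment(xl[..., 0], xc[..., 0], rng)
                xl, xc = xl[..., None], xc[..., None]
            logits = model._forward(xl, xc, train=True, rng=rng)
            loss, dlog = cross_entropy_grad(logits, y, class_w[y])
            model._backward(dlog)
            opt.step()
            losses.append(loss * len(idx))
            weights.append(len(idx))
        model.loss_log.append(float(np.sum(losses) / np.sum(weights)))
    return model


def predict(model: DualPatchCNN, pair: PatchPair) -> np.ndarray:
    """Probability vector over (non-cancer, cancer) for a single patch pair.

    Hard labels are the argmax; an exact tie resolves to non-cancer (index 0).
    """
    proba = model.predict_proba(pair.local_patch[None], pair.context_patch[None])
    return proba[0]


def hard_label(proba: np.ndarray) -> str:
    return CLASS_NAMES[int(np.argmax(proba))]


# ---------------------------------------------------------------------------
# Pre-training on a small labeled image corpus
# ---------------------------------------------------------------------------


def generate_texture_images(
    n: int, seed: int = 0, size: int = 32
) -> tuple[np.ndarray, np.ndarray]:
    """Bundled synthetic textured-image corpus for extractor pre-training.

    Four classes of small grayscale textures: Gaussian blobs, oriented
    stripes, checkerboards, and smooth random fields.
    """
    rng = np.random.default_rng(seed)
    from scipy.ndimage import gaussian_filter

    images = np.empty((n, size, size), dtype=np.float32)
    labels = rng.integers(0, 4, size=n)
    yy, xx = np.mgrid[0:size, 0:size]
    for i, lbl in enumerate(labels):
        if lbl == 0:  # blobs
            img = np.zeros((size, size))
            for _ in range(rng.integers(2, 6)):
                cy, cx = rng.uniform(4, size - 4, 2)
                s = rng.uniform(1.5, 4.0)
                img += np.exp(-(((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * s**2)))
        elif lbl == 1:  # stripes
            theta = rng.uniform(0, np.pi)
            freq = rng.uniform(0.2, 0.8)
            img = np.sin(freq * (yy * np.sin(theta) + xx * np.cos(theta)))
        elif lbl == 2:  # checkerboard
            p = rng.integers(3, 7)
            img = ((yy // p + xx // p) % 2).astype(float)
        else:  # smooth field
            img = gaussian_filter(rng.standard_normal((size, size)), 3.0)
        img = img + 0.1 * rng.standard_normal((size, size))
        images[i] = (img - img.mean()) / (img.std() + 1e-8)
    return images, labels.astype(np.int64)


def pretrain_extractors(
    model: DualPatchCNN,
    images: np.ndarray | None = None,
    labels: np.ndarray | None = None,
) -> DualPatchCNN:
    """Supervised pre-training of both branches on a small labeled image set.

    Each image is resized to both input sizes and classified through a
    temporary head; afterwards the classifier head is re-initialized. A no-op
    when the config's ``pretrain`` flag is off.
    """
    if not model.config.pretrain:
        return model
    if images is None:
        images, labels = generate_texture_images(200, seed=model.config.seed)
    if len(images) == 0:
        raise DataError("empty pre-training image set")
    n_classes = int(labels.max()) + 1
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=model.config.seed, spawn_key=(3,))
    )

    def _resize_batch(imgs, size):
        out = np.empty((len(imgs), size, size), dtype=np.float32)
        for i, im in enumerate(imgs):
            out[i] = resize(
                im.astype(np.float64), (size, size), order=1, mode="edge",
                anti_aliasing=False, preserve_range=True,
            )
        return out

    xl_all = _resize_batch(images, LOCAL_PATCH_SIZE)[..., None]
    xc_all = _resize_batch(images, CONTEXT_PATCH_SIZE)[..., None]
    head = Dense(model.concat_dim, n_classes, rng)
    opt = Adam(
        model.params(head=False) + head.params(), lr=model.config.learning_rate * 10
    )
    n = len(images)
    for _ in range(model.config.pretrain_epochs):
        perm = rng.permutation(n)
        for start in range(0, n, model.config.batch_size):
            idx = perm[start : start + model.config.batch_size]
            fl = model.local_branch.forward(xl_all[idx], True)
            fc = model.context_branch.forward(xc_all[idx], True)
            feats = np.concatenate([fl, fc], axis=1)
            logits = head.forward(feats, True)
            _, dlog = cross_entropy_grad(logits, labels[idx])
            dfeat = head.backward(dlog)
            nl = fl.shape[1]
            nlo = model.config.local_branch_blocks[-1]
            slo = int(np.sqrt(nl // nlo))
            nco = model.config.context_branch_blocks[-1]
            sco = int(np.sqrt(fc.shape[1] // nco))
            model.local_branch.backward(dfeat[:, :nl], (len(idx), slo, slo, nlo))
            model.context_branch.backward(dfeat[:, nl:], (len(idx), sco, sco, nco))
            opt.step()
    model.reinit_head()
    return model
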