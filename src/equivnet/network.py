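"""Composing RC-equivariant layers into trainable binary sequence classifiers.

A network is a composition ``F = F_n ∘ ... ∘ F_1`` acting on a one-hot
``[4, N]`` input.  When every layer is equivariant and an RC orbit pooling
layer occurs before the first dense layer, the whole network is exactly
invariant: ``F(X) == F(RC(X))`` for every input, to floating-point precision.

Two prediction modes are supported for dropout-trained networks:

* *Monte Carlo (Bayesian) dropout*: average ``K`` stochastic forward passes,
  each with its own dropout mask set sampled once and shared across all test
  examples, approximating the posterior predictive.  With RC-symmetric masks
  every sampled network is itself RC-invariant, so the MC average is exactly
  RC-symmetric as well.
* *Weight averaging (conventional dropout)*: a single deterministic forward
  pass with no masks.

Training is plain backpropagation on the softmax cross-entropy with an
optional L2 penalty on (free) convolution and dense weights; equivariant
weight ties are enforced by reparameterization so they hold exactly after
every optimizer step.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
from sklearn.metrics import roc_auc_score

from . import layers as L
from .sequences import encode_batch, rc_seq, read_fasta, write_fasta

LAYER_KINDS = ("conv", "dropout", "rc_orbit_pool", "spatial_pool", "global_pool", "dense", "softmax")


class TrainingDivergence(RuntimeError):
    """Raised when the training loss becomes non-finite."""


# ---------------------------------------------------------------------------
# Configuration

@dataclass
class LayerSpec:
    kind: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in LAYER_KINDS:
            raise ValueError(f"unknown layer kind {self.kind!r}; choose from {LAYER_KINDS}")


def conv(n_f: int, f_l: int, activation: str = "elu") -> LayerSpec:
    return LayerSpec("conv", {"n_f": n_f, "f_l": f_l, "activation": activation})


def dropout(keep_p: float) -> LayerSpec:
    return LayerSpec("dropout", {"keep_p": keep_p})


def rc_orbit_pool(mode: str = "max") -> LayerSpec:
    return LayerSpec("rc_orbit_pool", {"mode": mode})


def spatial_pool(p_l: int) -> LayerSpec:
    return LayerSpec("spatial_pool", {"p_l": p_l})


def global_pool() -> LayerSpec:
    return LayerSpec("global_pool", {})


def dense(units: int = 2) -> LayerSpec:
    return LayerSpec("dense", {"units": units})


def softmax() -> LayerSpec:
    return LayerSpec("softmax", {})


@dataclass
class NetworkConfig:
    """Declarative layer stack plus training hyperparameters.

    ``equivariant`` ties convolution weights and makes dropout masks
    RC-symmetric; it requires an ``rc_orbit_pool`` layer before the first
    dense layer so dense layers act on an RC-invariant representation.
    ``bayesian`` selects MC-dropout prediction as the default mode.
    """

    layers: list[LayerSpec]
    equivariant: bool = True
    bayesian: bool = True
    l2_coeff: float = 0.0
    mc_samples: int = 16
    learning_rate: float = 3e-3
    batch_size: int = 64
    epochs: int = 10
    optimizer: str = "adam"
    seed: int | None = None

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "NetworkConfig":
        d = json.loads(s)
        d["layers"] = [LayerSpec(**ls) for ls in d["layers"]]
        return cls(**d)


def default_config(
    n_filters: int = 16,
    filter_len: int = 12,
    activation: str = "elu",
    keep_p: float = 0.7,
    orbit_mode: str = "max",
    pool_width: int = 8,
    equivariant: bool = True,
    bayesian: bool = True,
    **hyper,
) -> NetworkConfig:
    """The reference architecture: the smallest stack exercising every construct.

    conv → dropout → [rc_orbit_pool if equivariant] → spatial max-pool →
    global spatial max → dense(2, custom init) → softmax.
    """
    stack = [conv(n_filters, filter_len, activation), dropout(keep_p)]
    if equivariant:
        stack.append(rc_orbit_pool(orbit_mode))
    stack += [spatial_pool(pool_width), global_pool(), dense(2), softmax()]
    return NetworkConfig(stack, equivariant=equivariant, bayesian=bayesian, **hyper)


def validate_config(config: NetworkConfig) -> None:
    kinds = [ls.kind for ls in config.layers]
    if kinds.count("softmax") != 1 or kinds[-1] != "softmax":
        raise ValueError("config must end in exactly one softmax layer")
    if "dense" not in kinds:
        raise ValueError("config needs at least one dense layer before softmax")
    if kinds[-2] != "dense":
        raise ValueError("the softmax must directly follow the final dense layer")
    if kinds.count("conv") > 1 or (kinds.count("conv") == 1 and kinds[0] != "conv"):
        raise ValueError("only a single, first-layer convolution is supported")
    first_dense = kinds.index("dense")
    if "global_pool" not in kinds[:first_dense]:
        raise ValueError("dense layers require a preceding global spatial pooling")
    if config.equivariant:
        if "rc_orbit_pool" not in kinds[:first_dense]:
            raise ValueError("equivariant configs need an rc_orbit_pool layer before the first dense layer")
        for ls in config.layers:
            if ls.kind == "conv" and ls.params["n_f"] % 2:
                raise ValueError("equivariant convolutions need an even filter count n_f")
    final_dense = config.layers[len(kinds) - 2]
    if final_dense.params["units"] != 2:
        raise ValueError("the terminal softmax is over exactly 2 classes")


def layer_shapes(config: NetworkConfig, n_in: int) -> list[tuple[int, ...]]:
    """Output shape (without batch axis) after each layer for input length ``n_in``.

    The network-level spatial pool crops the trailing remainder when the pool
    width does not divide the length; cropping occurs after orbit pooling in
    equivariant stacks, where RC already acts as the identity, so exact RC
    invariance is preserved.
    """
    shape: tuple[int, ...] = (4, n_in)
    out = []
    for ls in config.layers:
        if ls.kind == "conv":
            if shape[1] < ls.params["f_l"]:
                raise ValueError("sequence shorter than the convolution filter")
            shape = (ls.params["n_f"], shape[1] - ls.params["f_l"] + 1)
        elif ls.kind == "dropout":
            pass
        elif ls.kind == "rc_orbit_pool":
            if shape[0] % 2:
                raise ValueError("orbit pooling requires an even channel count")
            shape = (shape[0] // 2, shape[1])
        elif ls.kind == "spatial_pool":
            p = ls.params["p_l"]
            if shape[1] < p:
                raise ValueError("spatial pool wider than remaining length")
            shape = (shape[0], shape[1] // p)
        elif ls.kind == "global_pool":
            shape = (shape[0],)
        elif ls.kind == "dense":
            shape = (ls.params["units"],)
        elif ls.kind == "softmax":
            pass
        out.append(shape)
    return out


# ---------------------------------------------------------------------------
# Model

@dataclass
class Model:
    """Parameter blocks per layer plus the config that shaped them.

    Equivariant convolutions store only the free half (``w_free``/``b_free``);
    the realized bank, reconstructed on every forward pass, satisfies the RC
    weight tie exactly at all times.
    """

    config: NetworkConfig
    params: dict[int, dict[str, np.ndarray]]
    seed: int | None = None

    def conv_bank(self, idx: int) -> L.ConvFilterBank:
        blk = self.params[idx]
        if "w_free" in blk:
            return L.symmetrize(L.FreeConvParams(blk["w_free"], blk["b_free"]))
        return L.ConvFilterBank(blk["w"], blk["b"])


def build_model(config: NetworkConfig, rng: np.random.Generator | None = None) -> Model:
    """Initialize parameters.

    Hidden conv/dense weights use scaled (He) normal initialization; the final
    dense layer is initialized with all weights exactly 1 and biases (1, -1),
    which empirically sits close to the optimum for two-class score heads and
    speeds convergence.
    """
    validate_config(config)
    if rng is None:
        rng = np.random.default_rng(config.seed)
    params: dict[int, dict[str, np.ndarray]] = {}
    channels = 4
    last_dense = max(i for i, ls in enumerate(config.layers) if ls.kind == "dense")
    for i, ls in enumerate(config.layers):
        if ls.kind == "conv":
            n_f, f_l = ls.params["n_f"], ls.params["f_l"]
            std = np.sqrt(2.0 / (channels * f_l))
            if config.equivariant:
                if n_f % 2:
                    raise ValueError("equivariant convolutions need an even filter count n_f")
                params[i] = {
                    "w_free": rng.normal(0.0, std, (channels, f_l, n_f // 2)),
                    "b_free": np.zeros(n_f // 2),
                }
            else:
                params[i] = {
                    "w": rng.normal(0.0, std, (channels, f_l, n_f)),
                    "b": np.zeros(n_f),
                }
            channels = n_f
        elif ls.kind == "rc_orbit_pool":
            channels //= 2
        elif ls.kind == "dense":
            units = ls.params["units"]
            if i == last_dense:
                params[i] = {"w": np.ones((channels, units)), "b": np.array([1.0, -1.0])}
            else:
                params[i] = {
                    "w": rng.normal(0.0, np.sqrt(2.0 / channels), (channels, units)),
                    "b": np.zeros(units),
                }
            channels = units
    return Model(config=config, params=params, seed=config.seed)


# ---------------------------------------------------------------------------
# Forward / backward

def _forward_cached(model: Model, X: np.ndarray, masks: Mapping[int, L.DropoutMask] | None):
    """Forward pass on a [B, 4, N] batch, keeping per-layer caches for backprop."""
    cfg = model.config
    T = X
    caches: list[tuple] = []
    for i, ls in enumerate(cfg.layers):
        if ls.kind == "conv":
            bank = model.conv_bank(i)
            P = L.conv_patches(T, bank.filter_len)            # [B, L1, 4*f_l]
            z = P @ bank.w.reshape(-1, bank.n_filters) + bank.b
            z = np.moveaxis(z, -1, -2)                        # [B, n_f, L1]
            T = L.activate(z, ls.params["activation"])
            caches.append(("conv", P, z))
        elif ls.kind == "dropout":
            mask = None if masks is None else masks.get(i)
            if mask is None:
                caches.append(("dropout", None))
            else:
                factor = mask.eps / mask.keep_p
                T = T * factor
                caches.append(("dropout", factor))
        elif ls.kind == "rc_orbit_pool":
            mode = ls.params["mode"]
            h = T.shape[-2] // 2
            if T.shape[-2] % 2:
                raise ValueError("orbit pooling requires an even channel count")
            a = T[..., :h, :]
            b = T[..., h:, :][..., ::-1, ::-1]
            if mode == "max":
                sel = a >= b
                T = np.where(sel, a, b)
                caches.append(("rc_orbit_pool", mode, sel))
            else:
                T = a + b if mode == "sum" else (a + b) / 2.0
                caches.append(("rc_orbit_pool", mode, None))
        elif ls.kind == "spatial_pool":
            p = ls.params["p_l"]
            Lsp = T.shape[-1]
            Lc = Lsp - Lsp % p
            Tc = T[..., :Lc].reshape(*T.shape[:-1], Lc // p, p)
            idx = Tc.argmax(axis=-1)
            T = np.take_along_axis(Tc, idx[..., None], axis=-1)[..., 0]
            caches.append(("spatial_pool", p, Lsp, idx))
        elif ls.kind == "global_pool":
            idx = T.argmax(axis=-1)
            Lsp = T.shape[-1]
            T = np.take_along_axis(T, idx[..., None], axis=-1)[..., 0]
            caches.append(("global_pool", Lsp, idx))
        elif ls.kind == "dense":
            blk = model.params[i]
            caches.append(("dense", T))
            T = T @ blk["w"] + blk["b"]
        elif ls.kind == "softmax":
            zmax = T.max(axis=-1, keepdims=True)
            e = np.exp(T - zmax)
            T = e / e.sum(axis=-1, keepdims=True)
            caches.append(("softmax",))
    return T, caches


def forward(
    model: Model,
    X: np.ndarray,
    masks: Mapping[int, L.DropoutMask] | None = None,
) -> np.ndarray:
    """Class-probability output for a ``[4, N]`` input or ``[B, 4, N]`` batch.

    With ``masks=None`` dropout layers act as the identity (weight-averaged
    prediction); otherwise the given masks are applied with inverted scaling.
    """
    X = np.asarray(X, dtype=np.float64)
    single = X.ndim == 2
    if single:
        X = X[None]
    probs, _ = _forward_cached(model, X, masks)
    return probs[0] if single else probs


def _loss_and_grads(model: Model, X: np.ndarray, y: np.ndarray, masks):
    cfg = model.config
    B = X.shape[0]
    probs, caches = _forward_cached(model, X, masks)
    p_true = np.clip(probs[np.arange(B), y], 1e-12, None)
    loss = -np.mean(np.log(p_true))
    grads: dict[int, dict[str, np.ndarray]] = {}

    onehot = np.zeros_like(probs)
    onehot[np.arange(B), y] = 1.0
    dT = None
    for i in range(len(cfg.layers) - 1, -1, -1):
        ls, cache = cfg.layers[i], caches[i]
        if ls.kind == "softmax":
            dT = (probs - onehot) / B          # grad wrt pre-softmax logits
        elif ls.kind == "dense":
            a_in = cache[1]
            blk = model.params[i]
            grads[i] = {"w": a_in.T @ dT, "b": dT.sum(axis=0)}
            dT = dT @ blk["w"].T
        elif ls.kind == "global_pool":
            _, Lsp, idx = cache
            dfull = np.zeros((*dT.shape, Lsp))
            np.put_along_axis(dfull, idx[..., None], dT[..., None], axis=-1)
            dT = dfull
        elif ls.kind == "spatial_pool":
            _, p, Lsp, idx = cache
            Lc = Lsp - Lsp % p
            dTc = np.zeros((*idx.shape, p))
            np.put_along_axis(dTc, idx[..., None], dT[..., None], axis=-1)
            dfull = np.zeros((*dT.shape[:-1], Lsp))
            dfull[..., :Lc] = dTc.reshape(*dT.shape[:-1], Lc)
            dT = dfull
        elif ls.kind == "rc_orbit_pool":
            _, mode, sel = cache
            if mode == "max":
                da = dT * sel
                db = dT * (~sel)
            elif mode == "sum":
                da = dT
                db = dT
            else:
                da = dT / 2.0
                db = dT / 2.0
            dT = np.concatenate([da, db[..., ::-1, ::-1]], axis=-2)
        elif ls.kind == "dropout":
            factor = cache[1]
            if factor is not None:
                dT = dT * factor
        elif ls.kind == "conv":
            _, P, z = cache
            dZ = dT * L.activation_grad(z, ls.params["activation"])
            dZm = np.moveaxis(dZ, -2, -1)                 # [B, L1, n_f]
            n_f = dZm.shape[-1]
            dWmat = np.tensordot(P, dZm, axes=([0, 1], [0, 1]))   # [4*f_l, n_f]
            dW = dWmat.reshape(4, -1, n_f)
            db = dZ.sum(axis=(0, 2))
            if "w_free" in model.params[i]:
                h = n_f // 2
                grads[i] = {
                    "w_free": dW[:, :, :h] + dW[:, :, h:][::-1, ::-1, ::-1],
                    "b_free": db[:h] + db[h:][::-1],
                }
            else:
                grads[i] = {"w": dW, "b": db}
            dT = None  # first layer: input gradient not needed

    if cfg.l2_coeff > 0:
        for i, blk in model.params.items():
            for name, w in blk.items():
                if name.startswith("b"):
                    continue
                loss += cfg.l2_coeff * float(np.sum(w * w))
                grads[i][name] = grads[i][name] + 2.0 * cfg.l2_coeff * w
    return loss, grads


# ---------------------------------------------------------------------------
# Training

class _Adam:
    def __init__(self, lr: float, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m: dict = {}
        self.v: dict = {}
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        for i, blk in grads.items():
            for name, g in blk.items():
                key = (i, name)
                m = self.m.get(key, 0.0)
                v = self.v.get(key, 0.0)
                m = self.b1 * m + (1 - self.b1) * g
                v = self.b2 * v + (1 - self.b2) * g * g
                self.m[key], self.v[key] = m, v
                mhat = m / (1 - self.b1**self.t)
                vhat = v / (1 - self.b2**self.t)
                params[i][name] = params[i][name] - self.lr * mhat / (np.sqrt(vhat) + self.eps)


class _SGD:
    def __init__(self, lr: float):
        self.lr = lr

    def step(self, params, grads):
        for i, blk in grads.items():
            for name, g in blk.items():
                params[i][name] = params[i][name] - self.lr * g


def _dropout_shapes(config: NetworkConfig, n_in: int) -> dict[int, tuple[int, int]]:
    shapes = layer_shapes(config, n_in)
    out = {}
    for i, ls in enumerate(config.layers):
        if ls.kind == "dropout" and ls.params["keep_p"] < 1.0:
            prev = (4, n_in) if i == 0 else shapes[i - 1]
            out[i] = prev  # (C, L)
    return out


def sample_mask_set(
    config: NetworkConfig, n_in: int, rng: np.random.Generator
) -> dict[int, L.DropoutMask]:
    """One dropout mask per active dropout layer (RC-symmetric if equivariant)."""
    return {
        i: L.sample_mask(shape, config.layers[i].params["keep_p"], config.equivariant, rng)
        for i, shape in _dropout_shapes(config, n_in).items()
    }


def train(
    model: Model,
    data: "LabeledDataset | tuple[np.ndarray, np.ndarray]",
    rng: np.random.Generator | None = None,
) -> Model:
    """Mini-batch training; returns the same (mutated) model.

    A fresh mask set is sampled per batch and shared across the batch's
    examples.  Hyperparameters (learning rate, batch size, epochs, optimizer,
    L2) come from ``model.config``.  Raises :class:`TrainingDivergence` with
    the offending epoch if the loss becomes non-finite.
    """
    cfg = model.config
    if isinstance(data, LabeledDataset):
        if len(data) == 0:
            raise ValueError("empty training set")
        seqs, y = data.sequences, np.asarray(data.labels, dtype=np.int64)
        X_all = None
        n_in = len(seqs[0])
        n = len(seqs)
    else:
        X_all, y = data
        X_all = np.asarray(X_all, dtype=np.float64)
        y = np.asarray(y, dtype=np.int64)
        n_in = X_all.shape[-1]
        n = X_all.shape[0]
    if n == 0:
        raise ValueError("empty training set")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    opt = _Adam(cfg.learning_rate) if cfg.optimizer == "adam" else _SGD(cfg.learning_rate)
    has_dropout = bool(_dropout_shapes(cfg, n_in))
    history = []
    for epoch in range(cfg.epochs):
        perm = rng.permutation(n)
        epoch_loss = 0.0
        nb = 0
        for start in range(0, n, cfg.batch_size):
            idx = perm[start : start + cfg.batch_size]
            Xb = X_all[idx] if X_all is not None else encode_batch([seqs[j] for j in idx])
            masks = sample_mask_set(cfg, n_in, rng) if has_dropout else None
            loss, grads = _loss_and_grads(model, Xb, y[idx], masks)
            if not np.isfinite(loss):
                raise TrainingDivergence(f"non-finite loss at epoch {epoch}")
            opt.step(model.params, grads)
            epoch_loss += loss
            nb += 1
        history.append(epoch_loss / max(nb, 1))
    model.loss_curve_ = history  # type: ignore[attr-defined]
    return model


# ---------------------------------------------------------------------------
# Prediction

def _as_batch(data) -> np.ndarray:
    if isinstance(data, LabeledDataset):
        return encode_batch(data.sequences)
    arr = np.asarray(data)
    if arr.dtype.kind in "UO":
        return encode_batch(list(data))
    if arr.ndim == 2:
        arr = arr[None]
    return arr.astype(np.float64)


def predict_mc(
    model: Model, data, K: int | None = None, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Monte Carlo dropout prediction: mean class-1 probability over K mask sets.

    Each of the K sampled networks is applied to *all* examples (masks fixed
    beforehand), so the predictive function is a fixed symmetric function of
    the input; with equivariant masks it is exactly RC-symmetric.
    """
    cfg = model.config
    if not cfg.bayesian:
        warnings.warn("predict_mc on a model not configured as bayesian", stacklevel=2)
    if K is None:
        K = cfg.mc_samples
    if K < 1:
        raise ValueError("K must be >= 1")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    X = _as_batch(data)
    n_in = X.shape[-1]
    acc = np.zeros(X.shape[0])
    for _ in range(K):
        masks = sample_mask_set(cfg, n_in, rng)
        probs, _ = _forward_cached(model, X, masks or None)
        acc += probs[:, 1]
    return acc / K


def predict_weight_avg(model: Model, data) -> np.ndarray:
    """Deterministic prediction: one forward pass, no masks, no scaling."""
    X = _as_batch(data)
    probs, _ = _forward_cached(model, X, None)
    return probs[:, 1]


# ---------------------------------------------------------------------------
# Datasets

@dataclass
class LabeledDataset:
    """Equal-length DNA sequences with binary labels and optional split tags."""

    sequences: list[str]
    labels: np.ndarray
    ids: list[str] | None = None
    split: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if len(self.sequences) != len(self.labels):
            raise ValueError("sequences and labels differ in length")
        if len({len(s) for s in self.sequences} or {0}) > 1:
            raise ValueError("sequences must all have the same length")
        if not np.isin(self.labels, [0, 1]).all():
            raise ValueError("labels must be binary")
        if self.ids is None:
            self.ids = [f"seq{i:06d}" for i in range(len(self.sequences))]
        if self.split is not None:
            self.split = np.asarray(self.split)

    def __len__(self) -> int:
        return len(self.sequences)

    def subset(self, mask_or_tag) -> "LabeledDataset":
        if isinstance(mask_or_tag, str):
            if self.split is None:
                raise ValueError("dataset has no split tags")
            mask = self.split == mask_or_tag
        else:
            mask = np.asarray(mask_or_tag)
        idx = np.flatnonzero(mask)
        return LabeledDataset(
            [self.sequences[i] for i in idx],
            self.labels[idx],
            [self.ids[i] for i in idx],
            None if self.split is None else self.split[idx],
        )


def assign_split(
    data: LabeledDataset, test_frac: float, rng: np.random.Generator
) -> LabeledDataset:
    """Randomly tag a fraction of records as 'test', the rest 'train'."""
    n = len(data)
    tags = np.array(["train"] * n, dtype=object)
    tags[rng.permutation(n)[: int(round(test_frac * n))]] = "test"
    data.split = tags
    return data


def augment_dataset(data: LabeledDataset) -> LabeledDataset:
    """Classical RC data augmentation: append the RC of every sequence, same label."""
    seqs = list(data.sequences) + [rc_seq(s) for s in data.sequences]
    labels = np.concatenate([data.labels, data.labels])
    ids = list(data.ids) + [f"{i}_rc" for i in data.ids]
    split = None if data.split is None else np.concatenate([data.split, data.split])
    return LabeledDataset(seqs, labels, ids, split)


def save_dataset(prefix: str, data: LabeledDataset) -> None:
    """Write ``<prefix>.fasta`` plus a two-column ``<prefix>.labels.tsv``."""
    write_fasta(f"{prefix}.fasta", zip(data.ids, data.sequences))
    with open(f"{prefix}.labels.tsv", "w") as fh:
        for name, lab in zip(data.ids, data.labels):
            fh.write(f"{name}\t{int(lab)}\n")


def load_dataset(fasta_path: str, labels_path: str) -> LabeledDataset:
    records = read_fasta(fasta_path)
    lab = {}
    with open(labels_path) as fh:
        for line in fh:
            if line.strip():
                name, value = line.split("\t")
                lab[name] = int(value)
    ids = [name for name, _ in records]
    return LabeledDataset([s for _, s in records], np.array([lab[i] for i in ids]), ids)


# ---------------------------------------------------------------------------
# Metrics

def auroc(scores, labels) -> float:
    """Area under the ROC curve (midrank tie convention)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUROC needs both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=np.float64)))


def prediction_consistency(runs: Sequence[np.ndarray]) -> np.ndarray:
    """Pearson correlation for every unordered pair of prediction vectors.

    For R runs this returns R(R-1)/2 values; a pair involving a constant
    vector (undefined correlation) is reported as NaN with a warning.
    """
    if len(runs) < 2:
        raise ValueError("need at least two prediction runs")
    vecs = [np.asarray(r, dtype=np.float64) for r in runs]
    if len({v.shape for v in vecs}) != 1:
        raise ValueError("prediction vectors must have equal length")
    out = []
    for a, b in itertools.combinations(range(len(vecs)), 2):
        va, vb = vecs[a], vecs[b]
        if va.std() == 0 or vb.std() == 0:
            warnings.warn(f"constant prediction vector in pair ({a}, {b}); correlation undefined", stacklevel=2)
            out.append(np.nan)
        else:
            out.append(float(np.corrcoef(va, vb)[0, 1]))
    return np.asarray(out)


# ---------------------------------------------------------------------------
# Serialization

def save_model(path: str, model: Model) -> None:
    """Single-archive model format: config JSON + raw parameter arrays (bit-exact)."""
    payload = {"__config__": np.frombuffer(model.config.to_json().encode(), dtype=np.uint8)}
    payload["__seed__"] = np.array([-1 if model.seed is None else model.seed], dtype=np.int64)
    for i, blk in model.params.items():
        for name, arr in blk.items():
            payload[f"p{i}__{name}"] = arr
    with open(path, "wb") as fh:
        np.savez(fh, **payload)


def load_model(path: str) -> Model:
    with np.load(path) as z:
        config = NetworkConfig.from_json(bytes(z["__config__"]).decode())
        seed = int(z["__seed__"][0])
        params: dict[int, dict[str, np.ndarray]] = {}
        for key in z.files:
            if key.startswith("p"):
                idx_s, name = key[1:].split("__", 1)
                params.setdefault(int(idx_s), {})[name] = z[key]
    return Model(config=config, params=params, seed=None if seed < 0 else seed)
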