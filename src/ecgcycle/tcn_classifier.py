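"""Parallel-branch temporal-convolutional multi-label arrhythmia classifier.

Architecture: a causal 2-D-style convolution front end spanning all eight
leads (temporal kernel 50) inside a residual block; three parallel TCN
branches with kernel lengths 3, 5 and 7, each stacking three blocks with
dilation factors 1, 2, 4 and two weight-normalised dilated causal
convolutions per block; and an output head of three parallel average-pooling
layers whose pooled features are concatenated and fed to a single linear
layer of width 34.

The receptive field of a branch is (k - 1) * sum(d) * n + 1, giving 29, 57
and 85 samples for the three default branches; every convolution is causal,
so position t never sees samples after t.

Class imbalance is handled by a class-weighted binary cross entropy,
    loss_n = -w_n [y_n log x_n + (1 - y_n) log(1 - x_n)],
with inverse-frequency weights by default.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from ._autograd import Tensor, concat
from ._nn import Adam, Conv1d, Dropout, Linear, Module, WNConv1d
from .ecgsynth import N_CLASSES, EcgRecord, LabelSet, ParameterError
from .metrics import multilabel_report
from .signal_io import normalize_array


@dataclass
class TcnBranchConfig:
    kernel_size: int
    dilations: tuple[int, ...] = (1, 2, 4)
    layers_per_block: int = 2
    channels: int = 64

    def __post_init__(self):
        if self.kernel_size <= 0 or self.kernel_size % 2 == 0:
            raise ParameterError("branch kernel size must be an odd positive integer")
        if len(self.dilations) == 0 or any(d <= 0 for d in self.dilations):
            raise ParameterError("dilations must be nonempty and positive")
        if self.layers_per_block < 1:
            raise ParameterError("layers_per_block must be >= 1")


@dataclass
class TcnClassifierConfig:
    frontend_kernel: int = 50
    frontend_channels: int = 32
    branches: tuple[TcnBranchConfig, ...] = field(
        default_factory=lambda: tuple(TcnBranchConfig(k) for k in (3, 5, 7))
    )
    n_classes: int = N_CLASSES
    input_leads: int = 8
    dropout: float = 0.1

    def __post_init__(self):
        if len(self.branches) == 0:
            raise ParameterError("at least one TCN branch is required")

    @property
    def max_receptive_field(self) -> int:
        return max(receptive_field(b) for b in self.branches)


def receptive_field(cfg: TcnBranchConfig) -> int:
    """Receptive field of one dilated-causal branch: (k-1) * sum(d) * n + 1."""
    return (cfg.kernel_size - 1) * sum(cfg.dilations) * cfg.layers_per_block + 1


@dataclass
class ClassWeights:
    """Per-class loss weights w_n, non-negative and mean-normalised."""

    w: np.ndarray

    def __post_init__(self):
        self.w = np.asarray(self.w, dtype=float)
        if not np.isfinite(self.w).all() or (self.w < 0).any():
            raise ParameterError("class weights must be finite and non-negative")


def class_weights_from_counts(
    counts: np.ndarray, policy: str = "inverse", cap: float = 100.0
) -> ClassWeights:
    """Weights from per-class label counts.

    ``inverse`` (default): w_c proportional to total/count_c, capped at
    ``cap`` times the smallest weight; zero-count classes receive the cap.
    ``proportional``: w_c proportional to count_c (the literal reading of
    "weight proportional to that category's data").
    Both are normalised to mean 1.
    """
    counts = np.asarray(counts, dtype=float)
    if (counts < 0).any():
        raise ParameterError("counts must be non-negative")
    if policy == "inverse":
        pos = counts > 0
        if not pos.any():
            raise ParameterError("at least one class must have observations")
        raw = np.empty_like(counts)
        raw[pos] = counts.sum() / counts[pos]
        w_min = raw[pos].min()
        raw[pos] = np.minimum(raw[pos], cap * w_min)
        raw[~pos] = cap * w_min
    elif policy == "proportional":
        raw = counts.copy()
        if raw.sum() == 0:
            raise ParameterError("at least one class must have observations")
    else:
        raise ParameterError(f"unknown weight policy {policy!r}")
    return ClassWeights(raw / raw.mean())


def weighted_bce(pred, truth, weights: ClassWeights | None = None,
                 eps: float = 1e-7) -> float:
    """Mean over classes of -w_n [y_n log x_n + (1-y_n) log(1-x_n)].

    `pred` holds probabilities in (0, 1); values are clamped at `eps` so the
    exact 0/1 limits stay finite (and contribute 0 when prediction matches
    truth).
    """
    x = np.clip(np.asarray(pred, dtype=float), eps, 1.0 - eps)
    y = np.asarray(truth.vector if isinstance(truth, LabelSet) else truth, dtype=float)
    w = np.ones_like(x) if weights is None else weights.w
    per_class = -w * (y * np.log(x) + (1.0 - y) * np.log(1.0 - x))
    return float(per_class.mean())


# -- network -----------------------------------------------------------------------


class TcnBlock(Module):
    """n causal dilated convolutions (weight-normalised) with a residual skip."""

    def __init__(self, in_channels: int, cfg: TcnBranchConfig, dilation: int,
                 rng, dropout: float):
        k, c = cfg.kernel_size, cfg.channels
        self.convs = [
            WNConv1d(
                in_channels if j == 0 else c, c, k,
                padding=(dilation * (k - 1), 0), dilation=dilation, rng=rng,
            )
            for j in range(cfg.layers_per_block)
        ]
        self.dropouts = [Dropout(dropout, rng=np.random.default_rng(rng.integers(2**31)))
                         for _ in range(cfg.layers_per_block)]
        self.residual = (
            Conv1d(in_channels, c, 1, rng=rng) if in_channels != c else None
        )

    def forward(self, x: Tensor) -> Tensor:
        h = x
        for conv, drop in zip(self.convs, self.dropouts):
            h = drop(conv(h).relu())
        res = x if self.residual is None else self.residual(x)
        return (h + res).relu()


class TcnBranch(Module):
    """One parallel branch: a TCN block per dilation factor."""

    def __init__(self, in_channels: int, cfg: TcnBranchConfig, rng, dropout: float):
        self.cfg = cfg
        self.blocks = []
        c_in = in_channels
        for d in cfg.dilations:
            self.blocks.append(TcnBlock(c_in, cfg, d, rng, dropout))
            c_in = cfg.channels

    def forward(self, x: Tensor) -> Tensor:
        for blk in self.blocks:
            x = blk(x)
        return x


class TcnClassifierNet(Module):
    """(N, leads, T) -> (N, n_classes) logits."""

    def __init__(self, cfg: TcnClassifierConfig, rng=None):
        rng = rng or np.random.default_rng()
        self.cfg = cfg
        kf, cf = cfg.frontend_kernel, cfg.frontend_channels
        # causal front-end convolution spanning all leads, with 1x1 residual
        self.frontend_conv = Conv1d(cfg.input_leads, cf, kf, padding=(kf - 1, 0),
                                    rng=rng)
        self.frontend_proj = Conv1d(cfg.input_leads, cf, 1, rng=rng)
        self.branches = [
            TcnBranch(cf, bc, rng, cfg.dropout) for bc in cfg.branches
        ]
        total = sum(bc.channels for bc in cfg.branches)
        self.head = Linear(total, cfg.n_classes, rng=rng)

    def _check_length(self, t: int) -> None:
        fld = self.cfg.max_receptive_field
        if t < fld:
            raise ValueError(
                f"input length {t} is shorter than the maximum branch "
                f"receptive field {fld}"
            )

    def _frontend(self, x: Tensor) -> Tensor:
        return (self.frontend_conv(x) + self.frontend_proj(x)).relu()

    def _branch_tensors(self, x: Tensor) -> list[Tensor]:
        h = self._frontend(x)
        return [branch(h) for branch in self.branches]

    def forward(self, x: Tensor) -> Tensor:
        self._check_length(x.shape[-1])
        feats = self._branch_tensors(x)
        pooled = concat([f.mean(axis=2) for f in feats], axis=1)
        return self.head(pooled)

    def branch_features(self, x: np.ndarray) -> list[np.ndarray]:
        """Pre-pooling feature maps of every branch, dropout off."""
        x = np.asarray(x, dtype=float)
        if x.ndim == 2:
            x = x[None]
        self._check_length(x.shape[-1])
        was_training = self.training
        self.eval()
        feats = [f.data.copy() for f in self._branch_tensors(Tensor(x))]
        self.train(was_training)
        return feats

    def predict_logits(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.ndim == 2:
            x = x[None]
        was_training = self.training
        self.eval()
        outs = [self.forward(Tensor(x[i : i + batch_size])).data
                for i in range(0, len(x), batch_size)]
        self.train(was_training)
        return np.concatenate(outs, axis=0).astype(float)


def build_classifier(cfg: TcnClassifierConfig | None = None,
                     seed: int = 0) -> TcnClassifierNet:
    return TcnClassifierNet(cfg or TcnClassifierConfig(), np.random.default_rng(seed))


def parameter_count(module: Module) -> int:
    return int(sum(p.data.size for p in module.parameters()))


# -- causality and receptive-field probes ----------------------------------------------


def causality_check(model, x: np.ndarray, t: int, tol: float = 1e-6,
                    seed: int = 0) -> bool:
    """True iff perturbing samples strictly after `t` leaves every branch's
    pre-pooling feature at position `t` unchanged (within `tol`)."""
    x = np.asarray(x, dtype=float)
    if x.ndim == 2:
        x = x[None]
    n_t = x.shape[-1]
    if not 0 <= t < n_t:
        raise ParameterError(f"position {t} outside input of length {n_t}")
    rng = np.random.default_rng(seed)
    x2 = x.copy()
    if t + 1 < n_t:
        x2[..., t + 1 :] += 1.0 + rng.standard_normal(x2[..., t + 1 :].shape)
    base = model.branch_features(x)
    pert = model.branch_features(x2)
    return all(
        np.abs(b[..., t] - p[..., t]).max() <= tol for b, p in zip(base, pert)
    )


def probe_receptive_field(branch: TcnBranch, in_channels: int, t_len: int = 200,
                          seed: int = 0, delta: float = 10.0) -> int:
    """Brute-force receptive field: earliest input index whose perturbation
    moves the branch feature at the last position, as a span in samples."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((1, in_channels, t_len))
    was_training = branch.training
    branch.eval()
    base = branch(Tensor(x)).data[0, :, -1]
    # one batched forward: sample i of the batch perturbs input position i
    batch = np.repeat(x, t_len, axis=0)
    batch[np.arange(t_len), :, np.arange(t_len)] += delta
    feats = branch(Tensor(batch)).data[:, :, -1]
    branch.train(was_training)
    changed = np.abs(feats - base[None, :]).max(axis=1) > 1e-9
    if not changed.any():
        raise RuntimeError("perturbation probe detected no influence at all")
    first = int(np.flatnonzero(changed).min())
    return t_len - first


# -- losses on logits (numerically stable forms used in training) ------------------------


def _bce_logits(z: Tensor, y: Tensor, w: np.ndarray | None) -> Tensor:
    # max(z,0) - z*y + log(1 + exp(-|z|))
    loss = z.relu() - z * y + (1.0 + (-(z.abs())).exp()).log()
    if w is not None:
        loss = loss * Tensor(w)
    return loss.mean()

def _focal_logits(z: Tensor, y: Tensor, gamma: float = 2.0,
                  alpha: float = 0.25) -> Tensor:
    p = z.sigmoid().clamp(1e-7, 1.0 - 1e-7)
    pos = (1.0 - p) ** gamma * p.log() * y * alpha
    neg = p**gamma * (1.0 - p).log() * (1.0 - y) * (1.0 - alpha)
    return -(pos + neg).mean()

def _mse_logits(z: Tensor, y: Tensor) -> Tensor:
    return ((z.sigmoid() - y) ** 2).mean()


LOSSES = ("weighted_bce", "bce", "focal", "mse")

#: TCN-layer architecture sweep: single-branch k=3/5/7, the default parallel
#: model, and the parallel model with dilations 1, 4, 8
MODEL_PRESETS: dict[str, dict] = {
    "model_1": {"branch_kernels": (3,), "dilations": (1, 2, 4)},
    "model_2": {"branch_kernels": (5,), "dilations": (1, 2, 4)},
    "model_3": {"branch_kernels": (7,), "dilations": (1, 2, 4)},
    "model_4": {"branch_kernels": (3, 5, 7), "dilations": (1, 2, 4)},
    "model_5": {"branch_kernels": (3, 5, 7), "dilations": (1, 4, 8)},
}


def train_classifier(
    net: TcnClassifierNet,
    X: np.ndarray,
    Y: np.ndarray,
    loss: str = "weighted_bce",
    epochs: int = 30,
    lr: float = 1e-3,
    batch_size: int = 32,
    seed: int = 0,
    class_weights: ClassWeights | None = None,
) -> tuple[TcnClassifierNet, pd.DataFrame]:
    """Seeded mini-batch training; returns the net and a per-epoch metric trace
    (training loss, subset accuracy, macro precision/recall/F1)."""
    if loss not in LOSSES:
        raise ParameterError(f"loss must be one of {LOSSES}")
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.ndim != 3 or Y.ndim != 2 or X.shape[0] != Y.shape[0]:
        raise ParameterError("X must be (n, leads, T) and Y (n, n_classes)")
    if loss == "weighted_bce" and class_weights is None:
        class_weights = class_weights_from_counts(Y.sum(axis=0))
    w = class_weights.w if loss == "weighted_bce" else None
    rng = np.random.default_rng(seed)
    opt = Adam(net.parameters(), lr=lr)
    rows = []
    n = len(X)
    bs = min(batch_size, n)
    net.train()
    for epoch in range(epochs):
        perm = rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n - bs + 1, bs):
            idx = perm[start : start + bs]
            z = net(Tensor(X[idx]))
            y = Tensor(Y[idx])
            if loss in ("weighted_bce", "bce"):
                obj = _bce_logits(z, y, w)
            elif loss == "focal":
                obj = _focal_logits(z, y)
            else:
                obj = _mse_logits(z, y)
            opt.zero_grad()
            obj.backward()
            opt.step()
            epoch_loss += obj.item()
            n_batches += 1
        probs = 1.0 / (1.0 + np.exp(-net.predict_logits(X)))
        report = multilabel_report((probs >= 0.5).astype(int), Y.astype(int))
        rows.append(
            {
                "epoch": epoch,
                "loss": epoch_loss / max(n_batches, 1),
                "subset_accuracy": report["subset_accuracy"],
                "precision_macro": report["precision_macro"],
                "recall_macro": report["recall_macro"],
                "f1_macro": report["f1_macro"],
            }
        )
    net.eval()
    return net, pd.DataFrame(rows)


def classify(net: TcnClassifierNet, record: EcgRecord,
             threshold: float = 0.5) -> tuple[LabelSet, np.ndarray]:
    """Sigmoid probabilities of each arrhythmia class, thresholded to a
    multi-hot label set; the raw probability vector is always returned."""
    x = normalize_array(record.signal, "zscore")
    logits = net.predict_logits(x)[0]
    probs = 1.0 / (1.0 + np.exp(-logits))
    return LabelSet((probs >= threshold).astype(np.int8)), probs


# -- persistence ---------------------------------------------------------------------


def save_classifier(net: TcnClassifierNet, path) -> None:
    arrays = {f"p__{i:03d}": a for i, a in enumerate(net.state_arrays())}
    cfg = asdict(net.cfg)
    arrays["config_json"] = np.frombuffer(json.dumps(cfg).encode(), dtype=np.uint8)
    np.savez(Path(path), **arrays)


def load_classifier(path) -> TcnClassifierNet:
    with np.load(Path(path)) as data:
        cfg = json.loads(bytes(data["config_json"].tobytes()).decode())
        cfg["branches"] = tuple(
            TcnBranchConfig(**{**b, "dilations": tuple(b["dilations"])})
            for b in cfg["branches"]
        )
        net = build_classifier(TcnClassifierConfig(**cfg), seed=0)
        keys = sorted(k for k in data.files if k.startswith("p__"))
        net.load_state_arrays([data[k] for k in keys])
    return net


# -- sklearn-style estimator -----------------------------------------------------------


class TcnClassifier(ClassifierMixin, BaseEstimator):
    """Multi-label arrhythmia classifier with a fit/predict interface.

    ``fit(X, Y)`` takes ``X`` of shape (n_records, leads, T) and a multi-hot
    ``Y`` of shape (n_records, n_classes).  ``predict_proba`` returns
    per-class sigmoid probabilities; ``predict`` thresholds them.

    The three default parallel branches use kernels 3, 5 and 7 with dilation
    factors 1, 2, 4 and two convolutions per block (receptive fields 29, 57
    and 85 samples).  ``loss`` selects the training objective; class weights
    for ``weighted_bce`` follow ``weight_policy``.
    """

    def __init__(
        self,
        frontend_kernel: int = 50,
        frontend_channels: int = 32,
        branch_kernels: tuple[int, ...] = (3, 5, 7),
        dilations: tuple[int, ...] = (1, 2, 4),
        layers_per_block: int = 2,
        channels: int = 64,
        n_classes: int = N_CLASSES,
        dropout: float = 0.1,
        loss: str = "weighted_bce",
        weight_policy: str = "inverse",
        epochs: int = 30,
        lr: float = 1e-3,
        batch_size: int = 32,
        threshold: float = 0.5,
        random_state: int | None = None,
    ):
        self.frontend_kernel = frontend_kernel
        self.frontend_channels = frontend_channels
        self.branch_kernels = branch_kernels
        self.dilations = dilations
        self.layers_per_block = layers_per_block
        self.channels = channels
        self.n_classes = n_classes
        self.dropout = dropout
        self.loss = loss
        self.weight_policy = weight_policy
        self.epochs = epochs
        self.lr = lr
        self.batch_size = batch_size
        self.threshold = threshold
        self.random_state = random_state

    @classmethod
    def from_preset(cls, name: str, **overrides) -> "TcnClassifier":
        if name not in MODEL_PRESETS:
            raise ParameterError(f"unknown preset {name!r}")
        return cls(**{**MODEL_PRESETS[name], **overrides})

    def _config(self, input_leads: int) -> TcnClassifierConfig:
        branches = tuple(
            TcnBranchConfig(k, tuple(self.dilations), self.layers_per_block,
                            self.channels)
            for k in self.branch_kernels
        )
        return TcnClassifierConfig(
            frontend_kernel=self.frontend_kernel,
            frontend_channels=self.frontend_channels,
            branches=branches,
            n_classes=self.n_classes,
            input_leads=input_leads,
            dropout=self.dropout,
        )

    def fit(self, X, Y):
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        if X.ndim != 3:
            raise ValueError("X must have shape (n_records, leads, T)")
        if Y.ndim != 2 or Y.shape != (X.shape[0], self.n_classes):
            raise ValueError(f"Y must have shape (n_records, {self.n_classes})")
        seed = 0 if self.random_state is None else int(self.random_state)
        cfg = self._config(input_leads=X.shape[1])
        self.net_ = build_classifier(cfg, seed=seed)
        self.class_weights_ = class_weights_from_counts(
            Y.sum(axis=0), policy=self.weight_policy
        )
        self.net_, self.trace_ = train_classifier(
            self.net_, X, Y, loss=self.loss, epochs=self.epochs, lr=self.lr,
            batch_size=self.batch_size, seed=seed,
            class_weights=self.class_weights_ if self.loss == "weighted_bce" else None,
        )
        self.n_features_in_ = X.shape[1] * X.shape[2]
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "net_")
        logits = self.net_.predict_logits(np.asarray(X, dtype=float))
        return 1.0 / (1.0 + np.exp(-logits))

    def predict(self, X):
        return (self.predict_proba(X) >= self.threshold).astype(np.int8)

    def score(self, X, Y):
        """Subset accuracy (exact label-set match)."""
        return float((self.predict(X) == np.asarray(Y)).all(axis=1).mean())
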