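"""The 2D-like sequential feature extractor (2D-SFE) and its training engine.

The network treats each 4-channel x 1000-sample window like a small image: a
stack of 8 weight-bearing convolution blocks (conv -> activation repeats
closed by a pooling layer, 62 processing layers in total) reduces the window
to a compact feature vector, and a 2-layer fully connected head with softmax
classifies it.  Training optimizes a mixed objective

    L = lambda * triplet(features) + (1 - lambda) * cross_entropy(probs),

so the extractor learns a metric space (same-class windows close, other
classes at least a margin away) while the head learns the decision rule.

The learning-rate schedule and the Adam-style update with the attenuation-rate
(AR) diagnostic follow the published recurrences; see :func:`lr_schedule` and
:func:`optimizer_step`.  Subject adaptation retrains only the
fully connected head on a small labeled set from the new subject, with the
convolutional extractor frozen.

Public surface follows the Model/Results convention: build an
:class:`SFEClassifier` from a :class:`~larynet.preprocess.Dataset`, call
``fit()`` and work with the returned :class:`SFEResults`.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, asdict

import numpy as np

from ._nn import (
    Conv1D,
    Dense,
    GlobalAvgPool,
    Layer,
    L2Norm,
    MaxPool1D,
    ReLU,
    Residual,
    Sequential,
    iter_atomic_layers,
    softmax,
)
from .preprocess import Dataset, one_hot

# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------


@dataclass
class ModelConfig:
    """Architecture and training hyperparameters of the 2D-SFE.

    The processing-layer census must come out exactly: each weight block b
    contributes ``2 * block_convs[b] + 1`` processing layers (conv and
    activation pairs plus one pooling layer), and the census over all blocks
    must equal ``n_processing_layers``.  The default partition
    (1,1,1,2,3,5,6,8) gives 8 blocks and 62 layers, concentrating convolution
    repeats in the deeper blocks where the pooled feature maps are short.
    """

    n_classes: int = 13
    n_weight_blocks: int = 8
    n_processing_layers: int = 62
    n_classifying_layers: int = 2
    block_convs: tuple[int, ...] = (1, 1, 1, 2, 3, 5, 6, 8)
    channels_per_block: tuple[int, ...] = (8, 8, 8, 12, 12, 16, 16, 16)
    kernel_len: int = 5
    n_channels: int = 4
    window_len: int = 1000
    embedding_dim: int = 16
    hidden_dim: int = 32
    triplet_margin: float = 1.0
    loss_mix: float = 0.5  # lambda: weight of the triplet term
    batch_size: int = 64
    epochs: int = 100

    def __post_init__(self) -> None:
        if len(self.block_convs) != self.n_weight_blocks:
            raise ValueError(
                f"block_convs has {len(self.block_convs)} entries but "
                f"n_weight_blocks = {self.n_weight_blocks}"
            )
        if len(self.channels_per_block) != self.n_weight_blocks:
            raise ValueError("channels_per_block must list one width per block")
        census = sum(2 * r + 1 for r in self.block_convs)
        if census != self.n_processing_layers:
            raise ValueError(
                f"layer accounting mismatch: blocks {self.block_convs} give "
                f"sum(2r+1) = {census} processing layers, expected "
                f"{self.n_processing_layers}"
            )
        if self.n_classifying_layers != 2:
            raise ValueError("the classifying head is fixed at 2 fully connected layers")
        if self.embedding_dim != self.channels_per_block[-1]:
            raise ValueError(
                "embedding_dim must equal the last block's channel width "
                f"({self.channels_per_block[-1]}) because the feature vector is "
                "the globally pooled final feature map"
            )
        if self.batch_size < 2:
            raise ValueError("batch_size must be >= 2")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not 0.0 <= self.loss_mix <= 1.0:
            raise ValueError("loss_mix must lie in [0, 1]")


@dataclass
class LRScheduleConfig:
    """Learning-rate schedule.

    ``as_printed`` evaluates the published recurrence literally,
    LR(x) = (1 + 0.5 cos(x + pi/epochs)) * (1 - iLR), which oscillates near
    1.5 and is kept as a fidelity mode.  ``cosine_annealing`` is the
    conventional reading used for actual training:
    LR(x) = iLR * 0.5 * (1 + cos(pi * x / epochs)), decaying from the initial
    rate iLR to zero over ``epochs``.
    """

    iLR: float = 1e-4
    epochs: int = 100
    mode: str = "cosine_annealing"

    def __post_init__(self) -> None:
        if self.iLR <= 0:
            raise ValueError("initial learning rate must be > 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.mode not in ("as_printed", "cosine_annealing"):
            raise ValueError(f"unknown schedule mode {self.mode!r}")


def lr_schedule(x: float, cfg: LRScheduleConfig) -> float:
    """Learning rate at training-epoch index ``x`` (see LRScheduleConfig)."""
    if x < 0:
        raise ValueError("schedule index must be >= 0")
    if cfg.mode == "as_printed":
        return float((1.0 + 0.5 * np.cos(x + np.pi / cfg.epochs)) * (1.0 - cfg.iLR))
    return float(cfg.iLR * 0.5 * (1.0 + np.cos(np.pi * x / cfg.epochs)))


# --------------------------------------------------------------------------
# optimizer
# --------------------------------------------------------------------------


@dataclass
class OptimizerState:
    """Adam moment accumulators plus the scalar attenuation-rate diagnostic."""

    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    t: int = 0
    ar: float = 0.9  # attenuation rate, published initial value
    m: list[np.ndarray] = field(default_factory=list)
    v: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (0 < self.beta1 < 1 and 0 < self.beta2 < 1):
            raise ValueError("beta1 and beta2 must lie in (0, 1)")
        if self.eps <= 0:
            raise ValueError("eps must be > 0")


def optimizer_step(
    state: OptimizerState,
    params: list[np.ndarray],
    grads: list[np.ndarray],
    lr: float,
) -> OptimizerState:
    """One Adam-style update, in place on ``params``.

    Moments follow m_t = b1 m_{t-1} + (1-b1) g and v_t = b2 v_{t-1} + (1-b2) g^2;
    each parameter moves by -lr * m_hat / (eps + sqrt(v_hat)) with the usual
    bias corrections.  The scalar attenuation rate AR follows the same
    recurrence applied to the mean update term, AR_t = AR_{t-1} - lr * <u>,
    starting from 0.9; with zero gradients both parameters and AR are
    untouched.
    """
    if len(params) != len(grads):
        raise ValueError("params and grads must align")
    for g in grads:
        if not np.all(np.isfinite(g)):
            raise ValueError("non-finite gradient; step rejected")
    if not state.m:
        state.m = [np.zeros_like(p) for p in params]
        state.v = [np.zeros_like(p) for p in params]
    state.t += 1
    b1, b2, eps, t = state.beta1, state.beta2, state.eps, state.t
    c1 = 1.0 - b1**t
    c2 = 1.0 - b2**t
    total, count = 0.0, 0
    for p, g, m, v in zip(params, grads, state.m, state.v):
        m *= b1
        m += (1.0 - b1) * g
        v *= b2
        v += (1.0 - b2) * np.square(g)
        update = (m / c1) / (eps + np.sqrt(v / c2))
        p -= (lr * update).astype(p.dtype)
        total += float(update.sum())
        count += update.size
    state.ar -= lr * (total / max(count, 1))
    return state


# --------------------------------------------------------------------------
# losses
# --------------------------------------------------------------------------


def triplet_loss(
    anchor: np.ndarray,
    positive: np.ndarray,
    negative: np.ndarray,
    margin: float = 1.0,
) -> float:
    """Batch-mean hinge triplet loss with Euclidean distances."""
    a, p, n = (np.atleast_2d(np.asarray(v, dtype=float)) for v in
               (anchor, positive, negative))
    if not a.shape == p.shape == n.shape:
        raise ValueError("anchor/positive/negative must share a shape")
    d_ap = np.linalg.norm(a - p, axis=1)
    d_an = np.linalg.norm(a - n, axis=1)
    return float(np.mean(np.maximum(0.0, d_ap - d_an + margin)))


def cross_entropy_loss(probabilities: np.ndarray, one_hot_targets: np.ndarray) -> float:
    """Mean -log p(true class), with a 1e-12 numerical floor on probabilities."""
    p = np.atleast_2d(np.asarray(probabilities, dtype=float))
    t = np.atleast_2d(np.asarray(one_hot_targets, dtype=float))
    if p.shape != t.shape:
        raise ValueError(
            f"probabilities {p.shape} and targets {t.shape} shapes differ"
        )
    p_true = np.clip((p * t).sum(axis=1), 1e-12, None)
    return float(-np.mean(np.log(p_true)))


def _mine_triplets(
    emb: np.ndarray, labels: np.ndarray, margin: float
) -> tuple[float, np.ndarray]:
    """Within-batch semi-hard mining; returns (loss, d loss / d embeddings).

    For each anchor: positive = hardest (farthest) same-class sample;
    negative = the closest other-class sample farther than the positive
    (semi-hard), falling back to the overall closest negative.  Anchors
    without a positive or negative contribute nothing.
    """
    n = emb.shape[0]
    diff = emb[:, None, :] - emb[None, :, :]
    dist = np.sqrt(np.maximum((diff**2).sum(axis=2), 1e-12))
    same = labels[:, None] == labels[None, :]
    eye = np.eye(n, dtype=bool)
    grad = np.zeros_like(emb)
    total, used = 0.0, 0
    for i in range(n):
        pos_mask = same[i] & ~eye[i]
        neg_mask = ~same[i]
        if not pos_mask.any() or not neg_mask.any():
            continue
        p_idx = np.flatnonzero(pos_mask)
        j = int(p_idx[np.argmax(dist[i, p_idx])])
        d_ap = dist[i, j]
        n_idx = np.flatnonzero(neg_mask)
        semi = n_idx[dist[i, n_idx] > d_ap]
        cand = semi if semi.size else n_idx
        k = int(cand[np.argmin(dist[i, cand])])
        d_an = dist[i, k]
        hinge = d_ap - d_an + margin
        used += 1
        if hinge <= 0:
            continue
        total += hinge
        g_ap = (emb[i] - emb[j]) / d_ap
        g_an = (emb[i] - emb[k]) / d_an
        grad[i] += g_ap - g_an
        grad[j] -= g_ap
        grad[k] += g_an
    if used == 0:
        return 0.0, grad
    return total / used, grad / used


# --------------------------------------------------------------------------
# the network
# --------------------------------------------------------------------------


class SFENetwork:
    """Extractor (8 conv blocks) + 2-layer classifying head, numpy arrays."""

    def __init__(self, config: ModelConfig, seed: int):
        self.config = config
        self.seed = seed
        rng = np.random.default_rng(seed)
        layers: list[Layer] = []
        c_in = config.n_channels
        for width, reps in zip(config.channels_per_block, config.block_convs):
            for r in range(reps):
                conv = Conv1D(c_in, width, config.kernel_len, rng)
                act = ReLU()
                if c_in == width:
                    # identity skip keeps deep blocks trainable
                    layers.append(Residual([conv, act]))
                else:
                    layers.extend([conv, act])
                c_in = width
            layers.append(MaxPool1D())
        self.extractor = Sequential(layers)
        self._pool = GlobalAvgPool()
        self._l2 = L2Norm()
        self.head = Sequential(
            [
                Dense(config.embedding_dim, config.hidden_dim, rng),
                ReLU(),
                Dense(config.hidden_dim, config.n_classes, rng),
            ]
        )

    # -- census ------------------------------------------------------------
    def layer_census(self) -> dict[str, int]:
        counts = {"conv": 0, "pool": 0, "activation": 0}
        for lay in iter_atomic_layers(self.extractor.layers):
            counts[lay.kind] += 1
        counts["processing"] = sum(counts.values())
        counts["classifying"] = sum(
            1 for lay in self.head.layers if lay.kind == "dense"
        )
        counts["weight_blocks"] = self.config.n_weight_blocks
        return counts

    # -- forward -----------------------------------------------------------
    def embed(self, x: np.ndarray) -> np.ndarray:
        """(N, C, L) windows -> (N, embedding_dim) feature vectors."""
        x = np.asarray(x, dtype=np.float32)
        if x.ndim != 3 or x.shape[1:] != (self.config.n_channels, self.config.window_len):
            raise ValueError(
                f"expected windows of shape (n, {self.config.n_channels}, "
                f"{self.config.window_len}), got {x.shape}"
            )
        # engine runs channel-last; feature vectors are unit-norm
        return self._l2.forward(
            self._pool.forward(self.extractor.forward(x.transpose(0, 2, 1)))
        )

    def head_probs(self, emb: np.ndarray) -> np.ndarray:
        return softmax(self.head.forward(emb))

    def forward(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        emb = self.embed(x)
        return emb, self.head_probs(emb)

    # -- parameter plumbing --------------------------------------------------
    @property
    def all_params(self) -> list[np.ndarray]:
        return self.extractor.params + self.head.params

    @property
    def all_grads(self) -> list[np.ndarray]:
        return self.extractor.grads + self.head.grads

    @property
    def all_buffers(self) -> list[np.ndarray]:
        return self.extractor.buffers + self.head.buffers

    def set_training(self, flag: bool) -> None:
        self.extractor.set_training(flag)
        self.head.set_training(flag)

    def copy(self) -> "SFENetwork":
        return copy.deepcopy(self)

    def state_arrays(self) -> list[np.ndarray]:
        return [p.copy() for p in self.all_params + self.all_buffers]

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        targets = self.all_params + self.all_buffers
        if len(arrays) != len(targets):
            raise ValueError("checkpoint parameter count mismatch")
        for p, a in zip(targets, arrays):
            if p.shape != a.shape:
                raise ValueError("checkpoint parameter shape mismatch")
            p[...] = a


def build_model(config: ModelConfig, seed: int = 0) -> SFENetwork:
    """Seeded construction of the 2D-SFE network (validates the layer census)."""
    return SFENetwork(config, seed)


def predict(
    model: SFENetwork, windows: np.ndarray, batch_size: int = 256
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Features, class probabilities and argmax class per window."""
    windows = np.asarray(windows, dtype=np.float32)
    model.set_training(False)
    embs, probs = [], []
    for i in range(0, len(windows), batch_size):
        e, p = model.forward(windows[i: i + batch_size])
        embs.append(e)
        probs.append(p)
    emb = np.concatenate(embs) if embs else np.empty((0, model.config.embedding_dim))
    prob = np.concatenate(probs) if probs else np.empty((0, model.config.n_classes))
    return emb, prob, prob.argmax(axis=1) if prob.size else np.empty(0, dtype=int)


# --------------------------------------------------------------------------
# training
# --------------------------------------------------------------------------


@dataclass
class TrainState:
    """Per-epoch training history plus the optimizer/schedule state."""

    seed: int
    schedule: LRScheduleConfig
    optimizer: OptimizerState
    lr_history: list[float] = field(default_factory=list)
    triplet_history: list[float] = field(default_factory=list)
    ce_history: list[float] = field(default_factory=list)
    train_acc_history: list[float] = field(default_factory=list)
    test_acc_history: list[float] = field(default_factory=list)
    ar_history: list[float] = field(default_factory=list)
    best_epoch: int = -1
    best_test_acc: float = 0.0


def _accuracy(model: SFENetwork, X: np.ndarray, y: np.ndarray) -> float:
    if len(X) == 0:
        return float("nan")
    _, _, pred = predict(model, X)
    return float(np.mean(pred == y))


def train(
    model: SFENetwork,
    dataset: Dataset,
    schedule_cfg: LRScheduleConfig | None = None,
    optimizer_cfg: OptimizerState | None = None,
    epochs: int | None = None,
    seed: int = 0,
    eval_role: str | None = None,
) -> tuple[SFENetwork, TrainState]:
    """Fit the 2D-SFE on the dataset's training windows.

    Every epoch: seeded shuffle, mini-batches of ``config.batch_size``, mixed
    objective ``loss_mix * triplet + (1 - loss_mix) * cross-entropy``, one
    Adam-style step per batch at the scheduled epoch learning rate.  Both
    losses and both split accuracies are recorded per epoch; the returned
    model is the snapshot with the best evaluation accuracy.

    ``eval_role`` names the window role used for the per-epoch evaluation
    accuracy ("heldout" when present, else "test").
    """
    cfg = model.config
    epochs = epochs if epochs is not None else cfg.epochs
    schedule_cfg = schedule_cfg or LRScheduleConfig(epochs=epochs)
    opt = optimizer_cfg or OptimizerState()
    X_tr, y_tr, _ = dataset.tensors("train")
    if len(X_tr) == 0:
        raise ValueError("dataset has no training windows")
    if np.unique(y_tr).size < 2:
        raise ValueError("training data holds a single class; triplets are impossible")
    if eval_role is None:
        eval_role = "heldout" if dataset._select("heldout").size else "test"
    X_ev, y_ev, _ = dataset.tensors(eval_role)

    state = TrainState(seed=seed, schedule=schedule_cfg, optimizer=opt)
    rng = np.random.default_rng(seed)
    best_params = model.state_arrays()
    n = len(X_tr)
    onehot_all = one_hot(y_tr, cfg.n_classes)
    lam = cfg.loss_mix
    for epoch in range(epochs):
        lr = lr_schedule(epoch, schedule_cfg)
        order = rng.permutation(n)
        ep_trip, ep_ce, n_batches = 0.0, 0.0, 0
        model.set_training(True)
        for start in range(0, n, cfg.batch_size):
            idx = order[start: start + cfg.batch_size]
            if idx.size < 2:
                continue
            xb = X_tr[idx]
            yb = y_tr[idx]
            tb = onehot_all[idx]
            feat_map = model.extractor.forward(xb.transpose(0, 2, 1))
            emb = model._l2.forward(model._pool.forward(feat_map))
            logits = model.head.forward(emb)
            probs = softmax(logits)
            ce = cross_entropy_loss(probs, tb)
            trip, d_emb_trip = _mine_triplets(
                emb.astype(np.float64), yb, cfg.triplet_margin
            )
            # backward: head CE path then merge the triplet path at the embedding
            d_logits = ((probs - tb) / idx.size).astype(np.float32)
            d_emb = model.head.backward((1.0 - lam) * d_logits)
            d_emb = d_emb + lam * d_emb_trip.astype(np.float32)
            model.extractor.backward(
                model._pool.backward(model._l2.backward(d_emb))
            )
            optimizer_step(opt, model.all_params, model.all_grads, lr)
            ep_trip += trip
            ep_ce += ce
            n_batches += 1
        state.lr_history.append(lr)
        state.triplet_history.append(ep_trip / max(n_batches, 1))
        state.ce_history.append(ep_ce / max(n_batches, 1))
        state.ar_history.append(opt.ar)
        tr_acc = _accuracy(model, X_tr, y_tr)
        ev_acc = _accuracy(model, X_ev, y_ev)
        state.train_acc_history.append(tr_acc)
        state.test_acc_history.append(ev_acc)
        score = ev_acc if np.isfinite(ev_acc) else tr_acc
        if score >= state.best_test_acc:
            state.best_test_acc = score
            state.best_epoch = epoch
            best_params = model.state_arrays()
    model.load_state_arrays(best_params)
    return model, state


def adapt(
    model: SFENetwork,
    windows: np.ndarray,
    labels: np.ndarray,
    epochs_adapt: int = 20,
    seed: int = 0,
    lr: float = 3e-3,
    batch_size: int | None = None,
) -> SFENetwork:
    """Subject adaptation: retrain only the fully connected head.

    The convolutional extractor is frozen (bitwise unchanged); embeddings of
    the adaptation windows are computed once and the 2 classifying layers are
    refit with cross-entropy.  ``epochs_adapt = 0`` returns an identical copy
    (zero-shot path).
    """
    labels = np.asarray(labels, dtype=int)
    if labels.size and labels.max() >= model.config.n_classes:
        raise ValueError(
            f"adaptation labels reference class {labels.max()} but the model "
            f"has {model.config.n_classes} classes"
        )
    new = model.copy()
    if epochs_adapt == 0:
        return new
    if labels.size != len(windows):
        raise ValueError("windows and labels must align")
    emb_all = []
    for i in range(0, len(windows), 256):
        emb_all.append(new.embed(np.asarray(windows[i: i + 256], dtype=np.float32)))
    emb = np.concatenate(emb_all)
    targets = one_hot(labels, new.config.n_classes)
    opt = OptimizerState()
    rng = np.random.default_rng(seed)
    bs = batch_size or min(64, len(windows))
    sched = LRScheduleConfig(iLR=lr, epochs=epochs_adapt)
    for epoch in range(epochs_adapt):
        order = rng.permutation(len(windows))
        step_lr = lr_schedule(epoch, sched)
        for start in range(0, len(windows), bs):
            idx = order[start: start + bs]
            logits = new.head.forward(emb[idx])
            probs = softmax(logits)
            d_logits = ((probs - targets[idx]) / idx.size).astype(np.float32)
            new.head.backward(d_logits)
            optimizer_step(opt, new.head.params, new.head.grads, step_lr)
    return new


# --------------------------------------------------------------------------
# Model / Results surface
# --------------------------------------------------------------------------


class SFEClassifier:
    """2D-SFE classification model bound to a window dataset.

    Parameters
    ----------
    dataset : Dataset
        Windowed, subject-split data from :func:`larynet.preprocess.assemble_dataset`.
    config : ModelConfig, optional
        Architecture/training settings; ``n_classes`` is taken from the
        dataset when omitted.
    schedule : LRScheduleConfig, optional
    optimizer : OptimizerState, optional

    Examples
    --------
    >>> model = SFEClassifier.from_dataset(dataset)          # doctest: +SKIP
    >>> res = model.fit(epochs=30, seed=0)                   # doctest: +SKIP
    >>> print(res.summary())                                 # doctest: +SKIP
    """

    def __init__(
        self,
        dataset: Dataset,
        config: ModelConfig | None = None,
        schedule: LRScheduleConfig | None = None,
        optimizer: OptimizerState | None = None,
    ):
        if config is None:
            config = ModelConfig(n_classes=dataset.n_classes)
        if config.n_classes != dataset.n_classes:
            raise ValueError(
                f"config.n_classes = {config.n_classes} but the dataset has "
                f"{dataset.n_classes} classes"
            )
        self.dataset = dataset
        self.config = config
        self.schedule = schedule
        self.optimizer = optimizer

    @classmethod
    def from_dataset(cls, dataset: Dataset, **kwargs) -> "SFEClassifier":
        return cls(dataset, **kwargs)

    def fit(self, epochs: int | None = None, seed: int = 0) -> "SFEResults":
        epochs = epochs if epochs is not None else self.config.epochs
        network = build_model(self.config, seed=seed)
        schedule = self.schedule or LRScheduleConfig(iLR=1e-2, epochs=epochs)
        network, state = train(
            network,
            self.dataset,
            schedule_cfg=schedule,
            optimizer_cfg=self.optimizer,
            epochs=epochs,
            seed=seed,
        )
        return SFEResults(self, network, state)


class SFEResults:
    """Fitted 2D-SFE: trained parameters, history and evaluation helpers."""

    def __init__(self, model: SFEClassifier, network: SFENetwork, state: TrainState):
        self.model = model
        self.network = network
        self.state = state

    # -- headline quantities -------------------------------------------------
    @property
    def train_accuracy(self) -> float:
        return self.state.train_acc_history[self.state.best_epoch]

    @property
    def test_accuracy(self) -> float:
        return self.state.best_test_acc

    @property
    def history(self) -> dict[str, np.ndarray]:
        s = self.state
        return {
            "lr": np.array(s.lr_history),
            "triplet_loss": np.array(s.triplet_history),
            "cross_entropy_loss": np.array(s.ce_history),
            "train_accuracy": np.array(s.train_acc_history),
            "test_accuracy": np.array(s.test_acc_history),
            "attenuation_rate": np.array(s.ar_history),
        }

    # -- inference -----------------------------------------------------------
    def predict(self, windows: np.ndarray):
        return predict(self.network, windows)

    def embed(self, windows: np.ndarray) -> np.ndarray:
        emb, _, _ = predict(self.network, windows)
        return emb

    def adapt(
        self,
        windows: np.ndarray,
        labels: np.ndarray,
        epochs_adapt: int = 20,
        seed: int = 0,
    ) -> "SFEResults":
        """Head-only adaptation to a new subject; returns new results."""
        network = adapt(self.network, windows, labels, epochs_adapt, seed)
        return SFEResults(self.model, network, self.state)

    # -- reporting -----------------------------------------------------------
    def summary(self) -> str:
        census = self.network.layer_census()
        cfg = self.model.config
        s = self.state
        lines = [
            "2D-like Sequential Feature Extractor — fit results",
            "=" * 52,
            f"classes:             {cfg.n_classes}",
            f"weight blocks:       {census['weight_blocks']}",
            (
                f"processing layers:   {census['processing']} "
                f"(conv {census['conv']}, pool {census['pool']}, "
                f"activation {census['activation']})"
            ),
            f"classifying layers:  {census['classifying']}",
            f"batch size:          {cfg.batch_size}",
            f"loss mix (triplet):  {cfg.loss_mix}",
            f"epochs run:          {len(s.lr_history)}",
            f"best epoch:          {s.best_epoch}",
            f"train accuracy:      {self.train_accuracy:.4f}",
            f"eval accuracy:       {self.test_accuracy:.4f}",
            f"final triplet loss:  {s.triplet_history[-1]:.4f}",
            f"final CE loss:       {s.ce_history[-1]:.4f}",
            f"attenuation rate:    {s.ar_history[-1]:.6f}",
        ]
        return "\n".join(lines)

    def plot_history(self, ax=None):
        """Loss/accuracy curves over epochs (matplotlib axes)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        h = self.history
        epochs = np.arange(len(h["lr"]))
        ax.plot(epochs, h["train_accuracy"], label="train accuracy")
        ax.plot(epochs, h["test_accuracy"], label="eval accuracy")
        ax.plot(epochs, h["triplet_loss"] / max(h["triplet_loss"].max(), 1e-9),
                label="triplet loss (norm.)", ls="--")
        ax.plot(epochs, h["cross_entropy_loss"] / max(h["cross_entropy_loss"].max(),
                                                      1e-9),
                label="cross-entropy (norm.)", ls="--")
        ax.set_xlabel("epoch")
        ax.legend()
        return ax

    def config_dict(self) -> dict:
        return asdict(self.model.config)
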