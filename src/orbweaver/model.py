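"""The four-layer PWM-anchored network and its training loop.

Architecture (fixed skeleton, configurable sizes):

    one-hot 500 x 4
      -> frozen conv: log2-odds PWM filters, valid, strand-maxed  -> ReLU
      -> max-pool (non-overlapping, width ``pool1_width``)
      -> learnable conv (``conv2_filters`` x ``conv2_width``)     -> ReLU
      -> global max-pool
      -> dense (``dense_units``)                                  -> ReLU
      -> 7 output units, sigmoid

The first layer is *never* trained: its weights are the log-transformed PWMs
and a checksum of them is carried in the model manifest.  The seven sigmoid
units model the probability of each accessibility category; training
minimizes per-unit cross-entropy against the one-hot category with ADADELTA.
A softmax head is available behind ``output_head="softmax"``.

Per-cell-type open probability is obtained by marginalizing the category
scores: p_t = sum of scores of categories open in t, renormalized by the sum
of all seven scores.

Everything is plain numpy: forward, backward and the optimizer are
implemented here, which keeps runs deterministic for a given seed.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import asdict, dataclass, field

import numpy as np

from .genome import OneHotWindow
from .labeling import CELL_TYPES, LabeledLocus, categories_containing
from .pwm import FilterBank, scan_batch

log = logging.getLogger("orbweaver")


class ModelError(ValueError):
    pass


@dataclass
class ModelConfig:
    conv2_filters: int = 64
    conv2_width: int = 8
    pool1_width: int = 8
    dense_units: int = 128
    output_units: int = 7
    output_head: str = "sigmoid"  # or "softmax"
    adadelta_rho: float = 0.95
    adadelta_epsilon: float = 1e-6
    adadelta_lr: float = 1.0
    epochs: int = 12
    batch_size: int = 128
    window_width: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.output_units != 7:
            raise ModelError("the accessibility head has exactly 7 categories")
        if self.output_head not in ("sigmoid", "softmax"):
            raise ModelError(f"unknown output head {self.output_head!r}")


@dataclass
class Prediction:
    """Seven category scores and the marginal per-cell-type open probability."""

    scores: np.ndarray  # (7,), each in (0, 1)
    p_celltype: dict = field(default_factory=dict)

    @property
    def category(self) -> int:
        return int(np.argmax(self.scores)) + 1


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=-1, keepdims=True)


class OrbWeaverNet:
    """Trainable network over a frozen PWM filter bank."""

    def __init__(self, filter_bank: FilterBank, config: ModelConfig | None = None):
        self.bank = filter_bank
        self.config = config or ModelConfig()
        self.history: list[float] = []
        self.category_prior: np.ndarray | None = None
        self.frozen_checksum = filter_bank.checksum()
        self._init_params()

    # ---- geometry -------------------------------------------------------
    @property
    def p1(self) -> int:  # frozen-conv output length
        return self.config.window_width - self.bank.max_width + 1

    @property
    def p2(self) -> int:  # pooled length (tail positions beyond p2*pool unused)
        return self.p1 // self.config.pool1_width

    @property
    def p3(self) -> int:  # learnable-conv output length
        return self.p2 - self.config.conv2_width + 1

    def _init_params(self) -> None:
        cfg = self.config
        T, K, w2, D = (
            self.bank.n_filters,
            cfg.conv2_filters,
            cfg.conv2_width,
            cfg.dense_units,
        )
        if self.p3 < 1:
            raise ModelError(
                "pooled frozen-layer output shorter than the learnable "
                "convolution width; reduce pool1_width or conv2_width"
            )
        rng = np.random.default_rng(cfg.seed)
        he = lambda fan_in, shape: rng.normal(0.0, np.sqrt(2.0 / fan_in), shape)
        self.params = {
            "W2": he(w2 * T, (w2 * T, K)),
            "b2": np.zeros(K),
            "Wd": he(K, (K, D)),
            "bd": np.zeros(D),
            "Wo": rng.normal(0.0, np.sqrt(1.0 / D), (D, cfg.output_units)),
            "bo": np.zeros(cfg.output_units),
        }

    # ---- forward --------------------------------------------------------
    def frozen_features(self, X: np.ndarray, chunk: int = 512) -> np.ndarray:
        """Pooled post-ReLU frozen-layer activations for (B, 500, 4) inputs."""
        cfg = self.config
        outs = []
        for i in range(0, len(X), chunk):
            a1 = np.maximum(scan_batch(self.bank, X[i : i + chunk]), 0.0)
            a1 = a1[:, : self.p2 * cfg.pool1_width]
            pooled = a1.reshape(
                a1.shape[0], self.p2, cfg.pool1_width, self.bank.n_filters
            ).max(axis=2)
            outs.append(pooled)
        return np.concatenate(outs, axis=0)

    def _head_forward(self, pooled: np.ndarray) -> dict:
        """Layers 2..4 on pooled frozen features; returns all intermediates."""
        cfg = self.config
        B = pooled.shape[0]
        win = np.lib.stride_tricks.sliding_window_view(
            pooled, cfg.conv2_width, axis=1
        )  # (B, P3, T, w2)
        win = np.ascontiguousarray(np.swapaxes(win, 2, 3)).reshape(
            B, self.p3, cfg.conv2_width * self.bank.n_filters
        )
        z2 = win @ self.params["W2"] + self.params["b2"]
        a2 = np.maximum(z2, 0.0)
        g = a2.max(axis=1)  # global max-pool (B, K)
        hpre = g @ self.params["Wd"] + self.params["bd"]
        h = np.maximum(hpre, 0.0)
        z = h @ self.params["Wo"] + self.params["bo"]
        s = _sigmoid(z) if cfg.output_head == "sigmoid" else _softmax(z)
        return {
            "win": win, "z2": z2, "a2": a2, "g": g,
            "hpre": hpre, "h": h, "z": z, "s": s,
        }

    def forward_batch(self, X: np.ndarray, return_cache: bool = False):
        """Category scores (B, 7) for one-hot windows (B, 500, 4)."""
        X = np.asarray(X, dtype=np.float32)
        if X.ndim != 3 or X.shape[1] != self.config.window_width or X.shape[2] != 4:
            raise ModelError(
                f"expected input of shape (B, {self.config.window_width}, 4), "
                f"got {X.shape}"
            )
        cfg = self.config
        a1_full = np.maximum(scan_batch(self.bank, X), 0.0)  # (B, P1, T)
        a1 = a1_full[:, : self.p2 * cfg.pool1_width]
        shaped = a1.reshape(len(X), self.p2, cfg.pool1_width, self.bank.n_filters)
        pooled = shaped.max(axis=2)
        cache = self._head_forward(pooled)
        if return_cache:
            cache.update({"a1_full": a1_full, "pooled": pooled})
            return cache["s"], cache
        return cache["s"]

    def forward(self, window: OneHotWindow | np.ndarray) -> Prediction:
        matrix = window.matrix if isinstance(window, OneHotWindow) else window
        scores = self.forward_batch(matrix[None])[0]
        return Prediction(scores=scores, p_celltype=marginal_open(scores[None]))

    def predict_open(self, X: np.ndarray) -> np.ndarray:
        """Per-cell-type open probabilities (B, 3), columns ordered like CELL_TYPES."""
        s = self.forward_batch(X)
        m = marginal_open(s)
        return np.stack([m[t] for t in CELL_TYPES], axis=1)

    # ---- persistence ----------------------------------------------------
    def save(self, path: str) -> None:
        os.makedirs(path, exist_ok=True)
        with open(os.path.join(path, "config.json"), "w") as fh:
            json.dump(
                {
                    "config": asdict(self.config),
                    "tf_ids": self.bank.tf_ids,
                    "strand_policy": self.bank.strand_policy,
                    "pseudocount": self.bank.pseudocount,
                    "frozen_checksum": self.frozen_checksum,
                    "history": self.history,
                    "category_prior": (
                        None if self.category_prior is None
                        else self.category_prior.tolist()
                    ),
                },
                fh,
                indent=2,
            )
        arrays = dict(self.params)
        arrays["bank_fwd"] = self.bank.filters_fwd
        if self.bank.filters_rc is not None:
            arrays["bank_rc"] = self.bank.filters_rc
        arrays["bank_widths"] = self.bank.widths
        arrays["bank_background"] = self.bank.background
        np.savez(os.path.join(path, "weights.npz"), **arrays)

    @classmethod
    def load(cls, path: str) -> "OrbWeaverNet":
        with open(os.path.join(path, "config.json")) as fh:
            meta = json.load(fh)
        data = np.load(os.path.join(path, "weights.npz"))
        bank = FilterBank(
            filters_fwd=data["bank_fwd"],
            filters_rc=data["bank_rc"] if "bank_rc" in data else None,
            tf_ids=meta["tf_ids"],
            widths=data["bank_widths"],
            strand_policy=meta["strand_policy"],
            background=data["bank_background"],
            pseudocount=meta["pseudocount"],
        )
        net = cls(bank, ModelConfig(**meta["config"]))
        for k in net.params:
            net.params[k] = data[k]
        net.history = meta["history"]
        if meta["category_prior"] is not None:
            net.category_prior = np.array(meta["category_prior"])
        if net.frozen_checksum != meta["frozen_checksum"]:
            raise ModelError("filter-bank checksum mismatch on load")
        return net


def marginal_open(scores: np.ndarray) -> dict:
    """p_t = sum of category scores containing t / sum of all scores."""
    scores = np.atleast_2d(scores)
    total = scores.sum(axis=1)
    out = {}
    for t in CELL_TYPES:
        cats = np.array(categories_containing(t)) - 1
        out[t] = scores[:, cats].sum(axis=1) / total
    return out


class _Adadelta:
    """ADADELTA (adaptive per-parameter learning rates, no tuning)."""

    def __init__(self, params: dict, rho: float, eps: float, lr: float):
        self.rho, self.eps, self.lr = rho, eps, lr
        self.Eg = {k: np.zeros_like(v) for k, v in params.items()}
        self.Ex = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict, grads: dict) -> None:
        r, e = self.rho, self.eps
        for k, g in grads.items():
            self.Eg[k] = r * self.Eg[k] + (1 - r) * g * g
            dx = -np.sqrt(self.Ex[k] + e) / np.sqrt(self.Eg[k] + e) * g
            self.Ex[k] = r * self.Ex[k] + (1 - r) * dx * dx
            params[k] += self.lr * dx


def _loss_and_grad(net: OrbWeaverNet, cache: dict, y_onehot: np.ndarray):
    """Cross-entropy loss and gradients w.r.t. the learnable parameters."""
    cfg = net.config
    B = y_onehot.shape[0]
    s, z = cache["s"], cache["z"]
    eps = 1e-12
    if cfg.output_head == "sigmoid":
        loss = -np.mean(
            np.sum(
                y_onehot * np.log(s + eps) + (1 - y_onehot) * np.log(1 - s + eps),
                axis=1,
            )
        )
    else:
        loss = -np.mean(np.log(np.sum(s * y_onehot, axis=1) + eps))
    dz = (s - y_onehot) / B  # identical form for both heads

    h, g, a2, z2, win = cache["h"], cache["g"], cache["a2"], cache["z2"], cache["win"]
    grads = {}
    grads["Wo"] = h.T @ dz
    grads["bo"] = dz.sum(axis=0)
    dh = dz @ net.params["Wo"].T
    dh[cache["hpre"] <= 0] = 0.0
    grads["Wd"] = g.T @ dh
    grads["bd"] = dh.sum(axis=0)
    dg = dh @ net.params["Wd"].T  # (B, K)
    # global max-pool backward: route to argmax position
    idx = a2.argmax(axis=1)  # (B, K)
    da2 = np.zeros_like(a2)
    np.put_along_axis(da2, idx[:, None, :], dg[:, None, :], axis=1)
    da2[z2 <= 0] = 0.0
    flat_win = win.reshape(-1, win.shape[-1])
    flat_da2 = da2.reshape(-1, da2.shape[-1])
    grads["W2"] = flat_win.T @ flat_da2
    grads["b2"] = flat_da2.sum(axis=0)
    return loss, grads


def train(
    net: OrbWeaverNet,
    train_set: list[LabeledLocus] | tuple[np.ndarray, np.ndarray],
    config: ModelConfig | None = None,
) -> OrbWeaverNet:
    """Fit the learnable layers; the frozen PWM layer is never touched.

    ``train_set`` is either a list of labeled loci or a pair ``(X, categories)``
    with X (B, 500, 4) and categories in 1..7.  Frozen-layer features are
    precomputed once (the layer does not change), so epochs only touch the
    learnable head.  Returns ``net`` with a populated loss history.
    """
    if config is not None:
        net.config = config
    cfg = net.config
    if isinstance(train_set, tuple):
        X, cats = train_set
    else:
        X = np.stack([l.window.matrix for l in train_set])
        cats = np.array([l.label.category for l in train_set])
    cats = np.asarray(cats, dtype=int)
    if len(X) == 0:
        raise ModelError("empty training set")
    if len(np.unique(cats)) < 2:
        raise ModelError("training set must contain at least 2 categories")

    before = net.bank.checksum()
    y = np.zeros((len(X), 7))
    y[np.arange(len(X)), cats - 1] = 1.0
    net.category_prior = y.mean(axis=0)

    pooled = net.frozen_features(np.asarray(X, dtype=np.float32))
    rng = np.random.default_rng(cfg.seed)
    opt = _Adadelta(net.params, cfg.adadelta_rho, cfg.adadelta_epsilon, cfg.adadelta_lr)
    n = len(X)
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        total, seen = 0.0, 0
        for start in range(0, n, cfg.batch_size):
            sel = order[start : start + cfg.batch_size]
            cache = net._head_forward(pooled[sel])
            loss, grads = _loss_and_grad(net, cache, y[sel])
            if not np.isfinite(loss):
                raise ModelError(
                    f"NaN/inf loss at epoch {epoch}; ADADELTA lr="
                    f"{cfg.adadelta_lr}, rho={cfg.adadelta_rho} — reduce the "
                    "learning rate or inspect the input encoding"
                )
            opt.step(net.params, grads)
            total += loss * len(sel)
            seen += len(sel)
        net.history.append(total / seen)
        log.info("epoch %d/%d: loss %.5f", epoch + 1, cfg.epochs, net.history[-1])
    if net.bank.checksum() != before:
        raise ModelError("frozen filter bank changed during training")
    return net


def _auc_rank(scores: np.ndarray, labels: np.ndarray) -> float | None:
    """Mann-Whitney AUC of scores against binary labels (None if one class)."""
    from sklearn.metrics import roc_auc_score

    labels = np.asarray(labels, dtype=bool)
    if labels.all() or (~labels).all():
        return None
    return float(roc_auc_score(labels, scores))


def evaluate_auc(
    net: OrbWeaverNet,
    test_set: list[LabeledLocus] | tuple[np.ndarray, np.ndarray],
) -> dict:
    """Per-cell-type AUC of the marginal open probability vs the open flag.

    ``test_set`` is a list of labeled loci or ``(X, flags)`` with flags
    (B, 3) booleans ordered like CELL_TYPES.  A cell type with a single
    class in the test set yields None.
    """
    if isinstance(test_set, tuple):
        X, flags = test_set
    else:
        X = np.stack([l.window.matrix for l in test_set])
        flags = np.array([l.label.open_flags for l in test_set])
    p = net.predict_open(np.asarray(X, dtype=np.float32))
    return {
        t: _auc_rank(p[:, i], flags[:, i]) for i, t in enumerate(CELL_TYPES)
    }


def cross_auc_matrix(
    net: OrbWeaverNet,
    test_set: list[LabeledLocus] | tuple[np.ndarray, np.ndarray],
) -> dict:
    """AUC of cell type s's score applied to cell type t's labels.

    The diagonal reproduces :func:`evaluate_auc`; off-diagonal entries show
    how poorly one cell type's accessibility score transfers to another.
    """
    if isinstance(test_set, tuple):
        X, flags = test_set
    else:
        X = np.stack([l.window.matrix for l in test_set])
        flags = np.array([l.label.open_flags for l in test_set])
    p = net.predict_open(np.asarray(X, dtype=np.float32))
    return {
        (s, t): _auc_rank(p[:, i], flags[:, j])
        for i, s in enumerate(CELL_TYPES)
        for j, t in enumerate(CELL_TYPES)
    }
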