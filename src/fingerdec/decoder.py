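"""LF-CNN: a compact interpretable convolutional decoder for MEG epochs.

The network has exactly four layers.  For an epoch ``X`` of shape
(channels n x samples t):

1. spatial demixing — k spatial filters, ``S = W^T X + b`` (Eq. ``S_hat =
   W^T X``); each of the k rows of S is a latent source time course;
2. temporal filtering — one length-p FIR kernel per component, applied
   component-wise (depthwise) with zero-padded same-length output;
3. temporal max-pooling by ``pool_factor`` (non-overlapping windows),
   reducing t to ceil(t / pool_factor);
4. affine readout of the flattened pooled features + softmax.

Training is mini-batch Adam on the softmax cross-entropy with L2 penalty
on the spatial and readout weights.  Model selection follows a nested
6-fold / 5-fold scheme: each outer iteration holds out one fold for
testing; a 5-fold cross-validation inside the outer-training portion
drives early stopping (patience on validation loss); the final model for
that outer iteration is retrained on the full outer-training set for the
selected number of epochs.

The forward/backward passes are written directly in numpy — the model is
small enough (tens of thousands of parameters) that no deep-learning
framework is needed, and the explicit code doubles as the reference for
the layer-by-layer composition tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import h5py
import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .data import EpochSet
from .simulate import ConfigurationError

logger = logging.getLogger("fingerdec")

TASKS = ("LR", "withinL", "withinR", "four")

# class enumeration per task: label -> integer class
TASK_CLASSES: dict[str, dict[str, int]] = {
    "LR": {"LI": 0, "LM": 0, "RI": 1, "RM": 1},
    "withinL": {"LI": 0, "LM": 1},
    "withinR": {"RI": 0, "RM": 1},
    "four": {"LI": 0, "LM": 1, "RI": 2, "RM": 3},
}
TASK_CLASS_NAMES: dict[str, tuple[str, ...]] = {
    "LR": ("left", "right"),
    "withinL": ("LI", "LM"),
    "withinR": ("RI", "RM"),
    "four": ("LI", "LM", "RI", "RM"),
}


@dataclass(frozen=True)
class LFCNNHyperparams:
    n_channels: int = 204
    n_times: int = 200
    k: int = 32
    p: int = 7
    pool_factor: int = 10
    n_classes: int = 4
    l2_weight: float = 3e-2
    learn_rate: float = 3e-3
    batch_size: int = 100
    max_epochs: int = 1000
    patience: int = 3
    seed: int = 0

    def validate(self) -> None:
        if self.p > self.n_times:
            raise ConfigurationError("FIR length p must not exceed epoch length t")
        if self.pool_factor < 1 or self.k < 1:
            raise ConfigurationError("pool_factor and k must be >= 1")
        if self.n_classes < 2:
            raise ConfigurationError("n_classes must be >= 2")

    @property
    def pooled_len(self) -> int:
        return -(-self.n_times // self.pool_factor)  # ceil(t / pool_factor)


@dataclass
class LFCNN:
    """Weights of one LF-CNN instance (see module docstring for layers)."""

    W: np.ndarray          # (n, k) spatial filters
    b_spat: np.ndarray     # (k,)
    fir: np.ndarray        # (k, p) depthwise FIR kernels
    b_fir: np.ndarray      # (k,)
    V: np.ndarray          # (k * pooled_len, n_classes) readout weights
    b_out: np.ndarray      # (n_classes,)
    hp: LFCNNHyperparams
    history: dict = field(default_factory=dict)

    def copy(self) -> "LFCNN":
        return LFCNN(
            self.W.copy(), self.b_spat.copy(), self.fir.copy(), self.b_fir.copy(),
            self.V.copy(), self.b_out.copy(), self.hp, dict(self.history),
        )

    # -- layer-wise forward ------------------------------------------------
    def spatial(self, X: np.ndarray) -> np.ndarray:
        if X.shape[1] != self.hp.n_channels:
            raise ValueError(
                f"channel mismatch: data has {X.shape[1]}, model expects "
                f"{self.hp.n_channels}"
            )
        S = np.tensordot(self.W, X, axes=([0], [1]))       # (k, B, t), BLAS
        return np.swapaxes(S, 0, 1) + self.b_spat[None, :, None]

    def temporal(self, S: np.ndarray, include_bias: bool = True) -> np.ndarray:
        Y = _depthwise_fir(S, self.fir)
        if include_bias:
            Y = Y + self.b_fir[None, :, None]
        return Y

    def pool(self, Y: np.ndarray) -> np.ndarray:
        P, _ = _maxpool(Y, self.hp.pool_factor)
        return P

    def readout(self, P: np.ndarray) -> np.ndarray:
        # flatten time-major (tp, k) to match the training path's layout
        flat = np.swapaxes(P, 1, 2).reshape(P.shape[0], -1)
        return flat @ self.V + self.b_out

    def forward(self, X: np.ndarray) -> np.ndarray:
        return _softmax(self.readout(self.pool(self.temporal(self.spatial(X)))))

    def predict_proba(self, X) -> np.ndarray:
        return self.forward(_as_array(X))

    def predict(self, X) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)

    @property
    def n_parameters(self) -> int:
        return (self.W.size + self.b_spat.size + self.fir.size + self.b_fir.size
                + self.V.size + self.b_out.size)


def _as_array(X) -> np.ndarray:
    return X.data if isinstance(X, EpochSet) else np.asarray(X)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _depthwise_fir(S: np.ndarray, fir: np.ndarray) -> np.ndarray:
    """Component-wise same-length correlation with zero padding.

    ``Y[b, c, i] = sum_j fir[c, j] * S[b, c, i + j - p//2]``.
    """
    p = fir.shape[1]
    pad_l = p // 2
    pad_r = p - 1 - pad_l
    S_pad = np.pad(S, ((0, 0), (0, 0), (pad_l, pad_r)))
    t = S.shape[2]
    Y = np.zeros_like(S)
    for j in range(p):
        Y += fir[None, :, j, None] * S_pad[:, :, j:j + t]
    return Y


def _maxpool(Y: np.ndarray, factor: int) -> tuple[np.ndarray, np.ndarray]:
    """Non-overlapping max-pool along time; pads with -inf to a multiple."""
    b, k, t = Y.shape
    tp = -(-t // factor)
    pad = tp * factor - t
    if pad:
        Y = np.pad(Y, ((0, 0), (0, 0), (0, pad)), constant_values=-np.inf)
    Yr = Y.reshape(b, k, tp, factor)
    idx = Yr.argmax(axis=3)
    P = np.take_along_axis(Yr, idx[..., None], axis=3)[..., 0]
    return P, idx


def build_model(hp: LFCNNHyperparams) -> LFCNN:
    """Seeded Glorot-style initialization of all four layers."""
    hp.validate()
    rng = np.random.default_rng(hp.seed)
    n, k, p, tp, c = hp.n_channels, hp.k, hp.p, hp.pooled_len, hp.n_classes

    def glorot(shape):
        lim = np.sqrt(6.0 / (shape[0] + shape[-1]))
        return rng.uniform(-lim, lim, size=shape)

    return LFCNN(
        W=glorot((n, k)),
        b_spat=np.zeros(k),
        fir=glorot((k, p)),
        b_fir=np.zeros(k),
        V=glorot((k * tp, c)),
        b_out=np.zeros(c),
        hp=hp,
    )


def spatial_project(model_or_W, x) -> np.ndarray:
    """Latent sources ``S_hat = W^T X`` per trial (spatial layer, no bias).

    Accepts an :class:`LFCNN` or a raw (n x k) demixing matrix, and an
    :class:`EpochSet` or array.  Linear in the input by construction.
    """
    X = _as_array(x)
    W = model_or_W.W if isinstance(model_or_W, LFCNN) else np.asarray(model_or_W)
    if X.shape[1] != W.shape[0]:
        raise ValueError(
            f"channel mismatch: data has {X.shape[1]} channels, W expects {W.shape[0]}"
        )
    return np.swapaxes(np.tensordot(W, X, axes=([0], [1])), 0, 1)


def latent_sources(model: LFCNN, x) -> np.ndarray:
    """Temporal-layer output per trial: FIR applied to the spatial layer."""
    return model.temporal(model.spatial(_as_array(x)))


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def remap_task(labels: np.ndarray, task: str) -> tuple[np.ndarray, np.ndarray]:
    """Map finger labels to integer classes for one of the four tasks.

    Returns (y, mask): ``mask`` selects the trials that participate
    (within-hand tasks use only one hand's trials).
    """
    if task not in TASKS:
        raise ConfigurationError(f"unknown task {task!r}; expected one of {TASKS}")
    mapping = TASK_CLASSES[task]
    labels = np.asarray(labels, dtype=str)
    mask = np.isin(labels, list(mapping))
    y = np.array([mapping[l] for l in labels[mask]], dtype=int)
    n_classes = len(set(mapping.values()))
    present = np.unique(y)
    if present.size < n_classes:
        missing = sorted(set(range(n_classes)) - set(present.tolist()))
        raise ValueError(f"task {task}: class(es) {missing} empty after remapping")
    return y, mask


@dataclass
class FoldAssignment:
    """Nested fold bookkeeping: ``outer[i]`` in 1..n_outer per trial;
    ``inner[f]`` assigns 1..n_inner to the trials *outside* outer fold f
    (indexed in original trial order via ``inner_index[f]``)."""

    outer: np.ndarray
    inner: dict[int, np.ndarray]
    inner_index: dict[int, np.ndarray]
    n_outer: int
    n_inner: int


def make_folds(
    labels: np.ndarray,
    n_outer: int = 6,
    n_inner: int = 5,
    seed: int = 0,
    stratified: bool = True,
) -> FoldAssignment:
    """Stratified shuffled nested partition (5/6 train, 1/6 test by default).

    ``stratified=False`` assigns block-contiguous chunks instead (for the
    phase analyses where trial order must be preserved).
    """
    y = np.asarray(labels)
    n = y.size
    if n < n_outer:
        raise ConfigurationError(f"need at least {n_outer} trials, got {n}")
    classes, counts = np.unique(y, return_counts=True)
    too_few = classes[counts < n_outer]
    if stratified and too_few.size:
        raise ConfigurationError(
            f"class(es) {too_few.tolist()} have fewer trials than n_outer={n_outer}"
        )
    outer = np.empty(n, dtype=int)
    if stratified:
        skf = StratifiedKFold(n_splits=n_outer, shuffle=True, random_state=seed)
        for f, (_, test_idx) in enumerate(skf.split(np.zeros(n), y), start=1):
            outer[test_idx] = f
    else:
        outer[:] = 1 + (np.arange(n) * n_outer) // n

    inner: dict[int, np.ndarray] = {}
    inner_index: dict[int, np.ndarray] = {}
    for f in range(1, n_outer + 1):
        tr = np.flatnonzero(outer != f)
        assign = np.empty(tr.size, dtype=int)
        if stratified:
            skf_i = StratifiedKFold(n_splits=n_inner, shuffle=True,
                                    random_state=seed + f)
            for g, (_, val_idx) in enumerate(skf_i.split(np.zeros(tr.size), y[tr]),
                                             start=1):
                assign[val_idx] = g
        else:
            assign[:] = 1 + (np.arange(tr.size) * n_inner) // tr.size
        inner[f] = assign
        inner_index[f] = tr
    return FoldAssignment(outer, inner, inner_index, n_outer, n_inner)


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float,
                 beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _loss_and_grads(model: LFCNN, Xbtn: np.ndarray, y: np.ndarray):
    """Forward + backward on a batch in time-major layout (B, t, n)."""
    hp = model.hp
    B, t = Xbtn.shape[0], hp.n_times
    p, factor, tp, k = hp.p, hp.pool_factor, hp.pooled_len, hp.k
    pad_l, pad_r = p // 2, p - 1 - p // 2

    # (1) spatial: one GEMM over the flattened batch, (B*t, n) @ (n, k)
    S = (Xbtn.reshape(B * t, -1) @ model.W).reshape(B, t, k) + model.b_spat
    # (2) depthwise FIR along time
    S_pad = np.pad(S, ((0, 0), (pad_l, pad_r), (0, 0)))
    Y = np.zeros_like(S)
    for j in range(p):
        Y += model.fir[:, j] * S_pad[:, j:j + t, :]
    Y += model.b_fir
    # (3) max-pool along time
    pool_pad = tp * factor - t
    Yp = np.pad(Y, ((0, 0), (0, pool_pad), (0, 0)), constant_values=-np.inf) \
        if pool_pad else Y
    Yr = Yp.reshape(B, tp, factor, k)
    pool_idx = Yr.argmax(axis=2)
    P = np.take_along_axis(Yr, pool_idx[:, :, None, :], axis=2)[:, :, 0, :]
    # (4) affine readout + softmax
    flat = P.reshape(B, tp * k)
    z = flat @ model.V + model.b_out
    probs = _softmax(z)
    ce = -np.log(probs[np.arange(B), y] + 1e-12).mean()
    loss = ce + 0.5 * hp.l2_weight * (
        np.sum(model.W**2) + np.sum(model.V**2)
    )

    dz = probs.copy()
    dz[np.arange(B), y] -= 1.0
    dz /= B
    dV = flat.T @ dz + hp.l2_weight * model.V
    db_out = dz.sum(axis=0)
    dP = (dz @ model.V.T).reshape(B, tp, k)

    # un-pool: gradient flows to the argmax sample of each window
    dY_pad = np.zeros((B, tp, factor, k))
    np.put_along_axis(dY_pad, pool_idx[:, :, None, :], dP[:, :, None, :], axis=2)
    dY = dY_pad.reshape(B, tp * factor, k)[:, :t, :]

    db_fir = dY.sum(axis=(0, 1))
    dfir = np.empty_like(model.fir)
    dS_pad = np.zeros_like(S_pad)
    for j in range(p):
        dfir[:, j] = np.einsum("btc,btc->c", dY, S_pad[:, j:j + t, :])
        dS_pad[:, j:j + t, :] += model.fir[:, j] * dY
    dS = dS_pad[:, pad_l:pad_l + t, :]

    db_spat = dS.sum(axis=(0, 1))
    dW = Xbtn.reshape(B * t, -1).T @ dS.reshape(B * t, k) + hp.l2_weight * model.W

    acc = float((probs.argmax(axis=1) == y).mean())
    grads = [dW, db_spat, dfir, db_fir, dV, db_out]
    return loss, acc, grads


def _eval_loss(model: LFCNN, X: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    probs = model.forward(X)
    ce = -np.log(probs[np.arange(X.shape[0]), y] + 1e-12).mean()
    ce += 0.5 * model.hp.l2_weight * (np.sum(model.W**2) + np.sum(model.V**2))
    acc = float((probs.argmax(axis=1) == y).mean())
    return float(ce), acc


def fit(
    model: LFCNN,
    X: np.ndarray,
    y: np.ndarray,
    X_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
    n_epochs: int | None = None,
    rng: np.random.Generator | None = None,
) -> LFCNN:
    """Train in place with Adam; early stopping on validation loss.

    If a validation set is given, training stops once validation loss has
    not improved for ``hp.patience`` consecutive epochs and the best-epoch
    weights are restored.  With ``n_epochs`` set, trains exactly that many
    epochs with no early stopping (used for the post-selection retrain).
    """
    hp = model.hp
    rng = rng or np.random.default_rng(hp.seed)
    # time-major contiguous layout: every training matmul is a plain GEMM
    Xbtn = np.ascontiguousarray(np.swapaxes(np.asarray(X, dtype=float), 1, 2))
    opt = _Adam([model.W, model.b_spat, model.fir, model.b_fir, model.V, model.b_out],
                hp.learn_rate)
    max_epochs = n_epochs if n_epochs is not None else hp.max_epochs
    hist: dict[str, list] = {"train_loss": [], "train_acc": [],
                             "val_loss": [], "val_acc": []}
    best_val = np.inf
    best_epoch = 0
    best_weights = None
    bad = 0
    n = Xbtn.shape[0]
    for ep in range(1, max_epochs + 1):
        order = rng.permutation(n)
        ep_loss, ep_acc, nb = 0.0, 0.0, 0
        for start in range(0, n, hp.batch_size):
            idx = order[start:start + hp.batch_size]
            loss, acc, grads = _loss_and_grads(model, Xbtn[idx], y[idx])
            params = [model.W, model.b_spat, model.fir, model.b_fir,
                      model.V, model.b_out]
            opt.step(params, grads)
            ep_loss += loss
            ep_acc += acc
            nb += 1
        hist["train_loss"].append(ep_loss / nb)
        hist["train_acc"].append(ep_acc / nb)
        if X_val is not None and n_epochs is None:
            vl, va = _eval_loss(model, X_val, y_val)
            hist["val_loss"].append(vl)
            hist["val_acc"].append(va)
            if vl < best_val - 1e-6:
                best_val, best_epoch, bad = vl, ep, 0
                best_weights = [model.W.copy(), model.b_spat.copy(),
                                model.fir.copy(), model.b_fir.copy(),
                                model.V.copy(), model.b_out.copy()]
            else:
                bad += 1
                if bad >= hp.patience:
                    break
    if best_weights is not None:
        model.W, model.b_spat, model.fir, model.b_fir, model.V, model.b_out = \
            best_weights
    hist["best_epoch"] = best_epoch if best_weights is not None else max_epochs
    model.history = hist
    return model


@dataclass
class TrainResult:
    """Outcome of nested cross-validated training for one task."""

    models: list[LFCNN]
    predictions: pd.DataFrame      # trial, fold, y_true, y_pred, proba_*
    fold_accuracy: np.ndarray
    class_names: tuple[str, ...]
    folds: FoldAssignment
    task: str
    trial_mask: np.ndarray         # which trials of the input participated

    @property
    def mean_accuracy(self) -> float:
        return float(self.fold_accuracy.mean())

    @property
    def pooled_accuracy(self) -> float:
        p = self.predictions
        return float((p["y_pred"] == p["y_true"]).mean())


def train(
    x: EpochSet,
    task: str = "four",
    hp: LFCNNHyperparams | None = None,
    folds: FoldAssignment | None = None,
    seed: int = 0,
    n_outer: int = 6,
    n_inner: int = 5,
    shuffle_training_labels: int | None = None,
) -> TrainResult:
    """Nested cross-validated training of the LF-CNN on one task.

    For each outer fold: inner 5-fold CV (early stopping per split) picks
    the stopping epoch; the fold's model is retrained on the whole
    outer-training portion for that many epochs; held-out predictions are
    collected from the outer test fold.  Deterministic given ``seed``.

    ``shuffle_training_labels`` (a seed) activates the null-calibration
    mode: within each outer iteration the *training* labels are shuffled
    independently, destroying any label information while leaving the
    signal intact; held-out predictions are still scored against the true
    labels.  Shuffling per outer iteration (rather than once globally)
    keeps the null unbiased and averages out the accidental class-to-label
    association any single shuffle retains.
    """
    y, mask = remap_task(x.labels, task)
    X = np.ascontiguousarray(x.data[mask])
    n_classes = len(TASK_CLASS_NAMES[task])
    if hp is None:
        hp = LFCNNHyperparams()
    hp = replace(hp, n_channels=X.shape[1], n_times=X.shape[2],
                 n_classes=n_classes, seed=seed)
    hp.validate()
    if folds is None:
        folds = make_folds(y, n_outer=n_outer, n_inner=n_inner, seed=seed)

    models: list[LFCNN] = []
    rows = []
    fold_acc = np.empty(folds.n_outer)
    trial_ids = np.flatnonzero(mask)
    for f in range(1, folds.n_outer + 1):
        tr = folds.inner_index[f]
        te = np.flatnonzero(folds.outer == f)
        inner_assign = folds.inner[f]
        y_train = y.copy()
        if shuffle_training_labels is not None:
            sh_rng = np.random.default_rng(shuffle_training_labels + f)
            y_train[tr] = sh_rng.permutation(y_train[tr])
        best_epochs = []
        for g in range(1, folds.n_inner + 1):
            fit_idx = tr[inner_assign != g]
            val_idx = tr[inner_assign == g]
            m = build_model(replace(hp, seed=seed + 1000 * f + g))
            fit(m, X[fit_idx], y_train[fit_idx], X[val_idx], y_train[val_idx],
                rng=np.random.default_rng(seed + 1000 * f + g))
            best_epochs.append(max(m.history["best_epoch"], 1))
        n_ep = int(round(np.mean(best_epochs)))
        final = build_model(replace(hp, seed=seed + 1000 * f))
        fit(final, X[tr], y_train[tr], n_epochs=n_ep,
            rng=np.random.default_rng(seed + 1000 * f))
        final.history["selected_epochs"] = n_ep
        models.append(final)
        probs = final.predict_proba(X[te])
        pred = probs.argmax(axis=1)
        fold_acc[f - 1] = float((pred == y[te]).mean())
        logger.info("task %s outer fold %d: %d epochs, test acc %.3f",
                    task, f, n_ep, fold_acc[f - 1])
        for i, trial in enumerate(te):
            rows.append(
                {"trial": int(trial_ids[trial]), "fold": f,
                 "y_true": int(y[trial]), "y_pred": int(pred[i]),
                 **{f"proba_{c}": float(probs[i, j])
                    for j, c in enumerate(TASK_CLASS_NAMES[task])}}
            )
    predictions = pd.DataFrame(rows).sort_values("trial").reset_index(drop=True)
    return TrainResult(models, predictions, fold_acc,
                       TASK_CLASS_NAMES[task], folds, task, mask)


# ---------------------------------------------------------------------------
# ablation & checkpoints
# ---------------------------------------------------------------------------

class CentroidReadout:
    """Readout ablation: nearest class centroid on the pooled features."""

    def __init__(self, base: LFCNN, X_train: np.ndarray, y_train: np.ndarray):
        self.base = base
        feats = self._features(X_train)
        classes = np.unique(y_train)
        self.classes = classes
        self.centroids = np.stack([feats[y_train == c].mean(axis=0)
                                   for c in classes])

    def _features(self, X) -> np.ndarray:
        b = self.base
        P = b.pool(b.temporal(b.spatial(_as_array(X))))
        return P.reshape(P.shape[0], -1)

    def predict(self, X) -> np.ndarray:
        feats = self._features(X)
        d2 = ((feats[:, None, :] - self.centroids[None]) ** 2).sum(axis=2)
        return self.classes[d2.argmin(axis=1)]

    def predict_proba(self, X) -> np.ndarray:
        feats = self._features(X)
        d2 = ((feats[:, None, :] - self.centroids[None]) ** 2).sum(axis=2)
        return _softmax(-d2)


def ablate(model: LFCNN, part: str, X_train=None, y_train=None):
    """Replace one layer with a fixed non-learned surrogate.

    spatial -> every component becomes the channel mean; temporal -> the
    FIR kernels become identity (unit centre tap); readout -> nearest
    class centroid on the pooled features (requires training data).  The
    remaining layers are NOT retrained.
    """
    if part == "spatial":
        out = model.copy()
        out.W = np.full_like(model.W, 1.0 / model.hp.n_channels)
        out.b_spat = np.zeros_like(model.b_spat)
        return out
    if part == "temporal":
        out = model.copy()
        out.fir = np.zeros_like(model.fir)
        out.fir[:, model.hp.p // 2] = 1.0
        out.b_fir = np.zeros_like(model.b_fir)
        return out
    if part == "readout":
        if X_train is None or y_train is None:
            raise ValueError("readout ablation requires training data")
        return CentroidReadout(model, _as_array(X_train), np.asarray(y_train))
    raise ValueError(f"unknown part {part!r}; expected spatial|temporal|readout")


def save_model_h5(path, model: LFCNN) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("W", data=model.W)
        f.create_dataset("b_spat", data=model.b_spat)
        f.create_dataset("fir", data=model.fir)
        f.create_dataset("b_fir", data=model.b_fir)
        f.create_dataset("readout/V", data=model.V)
        f.create_dataset("readout/b", data=model.b_out)
        for key, val in vars(model.hp).items():
            f.attrs[f"hp_{key}"] = val


def load_model_h5(path) -> LFCNN:
    with h5py.File(path, "r") as f:
        hp_kw = {k[3:]: v for k, v in f.attrs.items() if k.startswith("hp_")}
        hp = LFCNNHyperparams(
            **{k: (int(v) if k != "l2_weight" and k != "learn_rate" else float(v))
               for k, v in hp_kw.items()}
        )
        return LFCNN(
            W=f["W"][()], b_spat=f["b_spat"][()], fir=f["fir"][()],
            b_fir=f["b_fir"][()], V=f["readout/V"][()], b_out=f["readout/b"][()],
            hp=hp,
        )
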