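"""Model training and the trained BindingPredictor wrapper."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from ..seqs import one_hot, validate_acgt
from .dataset import Dataset, WindowSet
from .net import Adam, NetConfig, ProfileNet, profile_loss_and_grads

log = logging.getLogger(__name__)


@dataclass
class Hyperparams:
    filters: int = 32
    first_width: int = 25
    n_dilated: int = 6
    head_width: int = 25
    learning_rate: float = 0.004
    batch_size: int = 32
    max_epochs: int = 60
    patience: int = 5
    counts_weight: Optional[float] = None  # None: mean counts per window / 2
    balance_tasks: bool = True             # inverse-mean-count profile NLL weights
    lr_decay: float = 0.5                  # reduce-on-plateau factor (1 = off)
    weight_decay: float = 1e-4             # decoupled L2 on weights
    rc_augment: bool = True                # reverse-complement training windows


class TrainingDiverged(RuntimeError):
    pass


class TrainedPredictor:
    """BindingPredictor backed by a trained ProfileNet.

    predict(sequence) -> per task (expected plus counts, expected minus
    counts, total counts); profile probabilities (softmax over 2 strands x L)
    scaled by the counts head's expm1 output.
    """

    def __init__(self, net: ProfileNet):
        self.net = net
        self.task_names = list(net.config.tasks)
        self.window = net.config.input_length

    def _forward(self, X: np.ndarray):
        logits, logc = self.net.forward(X)
        B, twoT, L = logits.shape
        T = twoT // 2
        lg = logits.reshape(B, T, 2 * L)
        lg = lg - lg.max(axis=2, keepdims=True)
        p = np.exp(lg)
        p /= p.sum(axis=2, keepdims=True)
        totals = np.expm1(np.clip(logc, 0.0, 30.0))
        expected = p * totals[:, :, None]
        return expected.reshape(B, T, 2, L), totals

    def predict(self, sequence: str):
        out = self.predict_batch([sequence])
        return {t: (out[t][0][0], out[t][1][0], float(out[t][2][0]))
                for t in self.task_names}

    def predict_batch(self, sequences: Sequence[str], chunk: int = 64,
                      rc_average: bool = True):
        """Expected counts per task; predictions averaged over both
        orientations by default (the model is only approximately
        strand-equivariant)."""
        for s in sequences:
            if len(s) != self.window:
                raise ValueError(f"sequence length {len(s)} != model window {self.window}")
        plus = {t: [] for t in self.task_names}
        minus = {t: [] for t in self.task_names}
        totals = {t: [] for t in self.task_names}
        for i in range(0, len(sequences), chunk):
            X = np.stack([one_hot(validate_acgt(s)) for s in sequences[i:i + chunk]])
            expected, tot = self._forward(X)
            if rc_average:
                expected_rc, tot_rc = self._forward(X[:, ::-1, ::-1])
                # map back: strands swap, coordinates mirror
                expected = 0.5 * (expected + expected_rc[:, :, ::-1, ::-1])
                tot = 0.5 * (tot + tot_rc)
            for j, t in enumerate(self.task_names):
                plus[t].append(expected[:, j, 0])
                minus[t].append(expected[:, j, 1])
                totals[t].append(tot[:, j])
        return {t: (np.concatenate(plus[t]), np.concatenate(minus[t]),
                    np.concatenate(totals[t])) for t in self.task_names}

    def profile_probabilities(self, sequence: str):
        """Per task (2, L) probabilities summing to 1; the raw profile head."""
        X = one_hot(validate_acgt(sequence))[None]
        expected, totals = self._forward(X)
        out = {}
        for j, t in enumerate(self.task_names):
            tot = totals[0, j]
            prof = expected[0, j]
            s = prof.sum()
            out[t] = prof / s if s > 0 else np.full_like(prof, 1.0 / prof.size)
        return out

    def input_gradient(self, X: np.ndarray, task: str) -> np.ndarray:
        """Gradient of the task's (log-scale) count output wrt one-hot input."""
        idx = self.task_names.index(task)
        return self.net.input_gradient(np.asarray(X, dtype=np.float32)[None], idx)[0]

    def save(self, path: str) -> None:
        self.net.save(path)

    @classmethod
    def load(cls, path: str) -> "TrainedPredictor":
        return cls(ProfileNet.load(path))


def _epoch_loss(net: ProfileNet, ws: WindowSet, tasks: List[str],
                lambdas: np.ndarray, weights: Optional[np.ndarray] = None,
                batch: int = 64) -> float:
    total, n = 0.0, len(ws)
    if n == 0:
        return float("nan")
    Y = ws.stacked_counts(tasks)
    for i in range(0, n, batch):
        logits, logc = net.forward(ws.X[i:i + batch])
        nll, mse, _, _ = profile_loss_and_grads(logits, logc, Y[i:i + batch],
                                                lambdas, weights)
        total += (nll + mse) * min(batch, n - i)
    return total / n


def train_model(dataset: Dataset, hyperparams: Optional[Hyperparams] = None,
                seed: int = 0) -> Tuple[TrainedPredictor, Dict[str, list]]:
    """Train with multinomial profile NLL + weighted log-counts MSE.

    Early stopping on validation loss (patience from hyperparams); the best
    validation weights are restored. Returns (predictor, history).
    """
    hp = hyperparams or Hyperparams()
    train, val = dataset["train"], dataset["val"]
    if len(train) == 0 or len(val) == 0:
        raise ValueError("train and val splits must be non-empty")
    tasks = dataset.tasks
    cfg = NetConfig(tasks=tasks, input_length=dataset.window, filters=hp.filters,
                    first_width=hp.first_width, n_dilated=hp.n_dilated,
                    head_width=hp.head_width)
    net = ProfileNet(cfg, seed=seed)
    opt = Adam(net.params, lr=hp.learning_rate, weight_decay=hp.weight_decay)
    Y_train = train.stacked_counts(tasks)
    mean_counts = Y_train.sum(axis=(2, 3)).mean(axis=0)  # per task
    if hp.counts_weight is None:
        lambdas = (mean_counts / 2.0).astype(np.float64)
    else:
        lambdas = np.full(len(tasks), float(hp.counts_weight))
    weights = None
    if hp.balance_tasks:
        weights = mean_counts.mean() / np.maximum(mean_counts, 1e-9)
    rng = np.random.default_rng(seed + 1)
    history: Dict[str, list] = {"train_loss": [], "val_loss": []}
    best = (np.inf, None)
    bad_epochs = 0
    n = len(train)
    for epoch in range(hp.max_epochs):
        order = rng.permutation(n)
        running = 0.0
        for i in range(0, n, hp.batch_size):
            idx = order[i:i + hp.batch_size]
            Xb = train.X[idx]
            Yb = Y_train[idx]
            if hp.rc_augment:
                flip = rng.random(len(idx)) < 0.5
                if flip.any():
                    Xb = Xb.copy()
                    Yb = Yb.copy()
                    Xb[flip] = Xb[flip][:, ::-1, ::-1]
                    Yb[flip] = Yb[flip][:, :, ::-1, ::-1]
            logits, logc, cache = net.forward(np.ascontiguousarray(Xb),
                                              want_cache=True)
            nll, mse, dlg, dlc = profile_loss_and_grads(logits, logc, Yb,
                                                        lambdas, weights)
            loss = nll + mse
            if not np.isfinite(loss):
                raise TrainingDiverged(f"non-finite loss at epoch {epoch}")
            running += loss * len(idx)
            grads = net.backward(cache, dlg, dlc)
            opt.step(net.params, grads)
        train_loss = running / n
        val_loss = _epoch_loss(net, val, tasks, lambdas, weights)
        history["train_loss"].append(train_loss)
        history["val_loss"].append(val_loss)
        log.info("epoch %d train %.3f val %.3f", epoch, train_loss, val_loss)
        if val_loss < best[0] - 1e-6:
            best = (val_loss, {k: v.copy() for k, v in net.params.items()})
            bad_epochs = 0
        else:
            bad_epochs += 1
            if hp.lr_decay < 1.0 and bad_epochs == max(2, hp.patience // 2):
                opt.lr *= hp.lr_decay
                log.info("reducing learning rate to %.5f", opt.lr)
            if bad_epochs >= hp.patience:
                break
    if best[1] is not None:
        net.load_state(best[1])
    return TrainedPredictor(net), history
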