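"""Evaluation metrics: counts correlation, profile JSD, binned auPRC."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence

import numpy as np
from scipy.spatial.distance import jensenshannon
from scipy.stats import spearmanr
from sklearn.metrics import average_precision_score

from .dataset import WindowSet
from .train import TrainedPredictor


@dataclass
class TaskEval:
    counts_spearman: float
    auprc: Dict[int, float]
    jsd_median: float
    jsd_values: np.ndarray
    n_zero_regions: int


@dataclass
class ModelEvalReport:
    tasks: Dict[str, TaskEval]

    def __getitem__(self, task: str) -> TaskEval:
        return self.tasks[task]


def _binned(arr: np.ndarray, res: int) -> np.ndarray:
    L = arr.shape[-1]
    n = L // res
    return arr[..., :n * res].reshape(*arr.shape[:-1], n, res).sum(axis=-1)


def _predicted_profiles(predictor, ws: WindowSet, tasks: Sequence[str]):
    """(N, T, 2, L) expected counts from any BindingPredictor."""
    from ..seqs import decode

    N, _, L = ws.X.shape
    out = np.zeros((N, len(tasks), 2, L))
    if isinstance(predictor, TrainedPredictor) or hasattr(predictor, "predict_batch"):
        seqs = [decode(ws.X[i].argmax(axis=0)) for i in range(N)]
        res = predictor.predict_batch(seqs)
        for j, t in enumerate(tasks):
            out[:, j, 0] = res[t][0]
            out[:, j, 1] = res[t][1]
    else:
        for i in range(N):
            seq = decode(ws.X[i].argmax(axis=0))
            pred = predictor.predict(seq)
            for j, t in enumerate(tasks):
                out[i, j, 0] = pred[t][0]
                out[i, j, 1] = pred[t][1]
    return out


def jsd_profile(observed: np.ndarray, predicted: np.ndarray) -> float:
    """Base-2 Jensen-Shannon distance (in [0,1]) between L1-normalized
    concatenated-strand profiles."""
    a = observed.ravel().astype(float)
    b = predicted.ravel().astype(float)
    if a.sum() <= 0 or b.sum() <= 0:
        return float("nan")
    d = float(jensenshannon(a / a.sum(), b / b.sum(), base=2))
    # scipy returns NaN from sqrt of a tiny negative rounding error when the
    # distributions coincide
    return 0.0 if np.isnan(d) else d


def evaluate_model(predictor, heldout: WindowSet,
                   tasks: Sequence[str] = None,
                   resolutions: Sequence[int] = (1, 2, 5, 10)) -> ModelEvalReport:
    """Counts Spearman on log1p totals, per-region JSD, binned auPRC.

    auPRC binarization: a bin is positive when observed binned counts >=
    max(1, 1.5 x window mean); bins between 0.5x and 1.5x the window mean are
    ambiguous and excluded. Regions with zero observed counts are excluded
    from JSD and counted.
    """
    tasks = list(tasks or sorted(heldout.Y))
    obs = heldout.stacked_counts(tasks)              # (N, T, 2, L)
    pred = _predicted_profiles(predictor, heldout, tasks)
    report: Dict[str, TaskEval] = {}
    for j, t in enumerate(tasks):
        o_tot = obs[:, j].sum(axis=(1, 2))
        p_tot = pred[:, j].sum(axis=(1, 2))
        rho = spearmanr(np.log1p(o_tot), np.log1p(p_tot)).statistic
        jsds, n_zero = [], 0
        for i in range(obs.shape[0]):
            if obs[i, j].sum() <= 0:
                n_zero += 1
                continue
            jsds.append(jsd_profile(obs[i, j], pred[i, j]))
        jsds = np.asarray(jsds)
        auprc: Dict[int, float] = {}
        for res in resolutions:
            ob = _binned(obs[:, j].reshape(obs.shape[0], -1), res)
            pb = _binned(pred[:, j].reshape(pred.shape[0], -1), res)
            means = ob.mean(axis=1, keepdims=True)
            pos = ob >= np.maximum(1.0, 1.5 * means)
            ambiguous = (~pos) & (ob >= 0.5 * means) & (means > 0)
            keep = ~ambiguous
            labels = pos[keep].ravel()
            scores = pb[keep].ravel()
            if labels.any() and not labels.all():
                auprc[res] = float(average_precision_score(labels, scores))
            else:
                auprc[res] = float("nan")
        report[t] = TaskEval(counts_spearman=float(rho), auprc=auprc,
                             jsd_median=float(np.median(jsds)) if len(jsds) else float("nan"),
                             jsd_values=jsds, n_zero_regions=n_zero)
    return ModelEvalReport(report)
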