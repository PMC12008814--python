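"""Per-base contribution scores for any BindingPredictor.

Two routes behind one signature:

* predictors exposing ``input_gradient(onehot, task)`` (e.g. the trained
  network) get a gradient x input attribution against an ensemble of
  dinucleotide-shuffled reference sequences: the gradient of the task's count
  output is taken at the observed input and multiplied by (input - mean
  reference), so the map's sum first-order-approximates the prediction
  difference against the references;
* predictors exposing an exact analytic ``contribution_map(sequence, task)``
  (the grammar oracle) are used directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np

from ..seqs import dinucleotide_shuffle, one_hot, validate_acgt


@dataclass
class ContributionMap:
    contig: str
    start: int
    end: int
    task: str
    scores: np.ndarray          # signed, one per base
    sequence: str = ""
    reference_spec: str = ""

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.scores) != self.end - self.start:
            raise ValueError("scores length does not match region width")
        if not np.isfinite(self.scores).all():
            raise ValueError("non-finite contribution scores")

    @property
    def width(self) -> int:
        return self.end - self.start


def contribution_scores(predictor, sequence: str, task: str,
                        n_refs: int = 20, seed: int = 0,
                        contig: str = "seq", start: int = 0) -> ContributionMap:
    """Signed per-base contributions of `sequence` to `task`'s predicted counts."""
    sequence = validate_acgt(sequence)
    if n_refs < 1:
        raise ValueError("n_refs must be >= 1")
    if hasattr(predictor, "contribution_map"):
        scores = predictor.contribution_map(sequence, task)
        spec = "analytic marginal (oracle)"
    else:
        x = one_hot(sequence, dtype=np.float64)
        grad = np.asarray(predictor.input_gradient(x, task), dtype=np.float64)
        if grad.shape != x.shape:
            raise ValueError("input_gradient must return a (4, L) array")
        rng = np.random.default_rng(seed)
        ref_mean = np.zeros_like(x)
        for _ in range(n_refs):
            ref_mean += one_hot(dinucleotide_shuffle(sequence, rng), dtype=np.float64)
        ref_mean /= n_refs
        scores = (grad * (x - ref_mean)).sum(axis=0)
        spec = f"{n_refs} dinucleotide-shuffled references, seed={seed}"
    return ContributionMap(contig, start, start + len(sequence), task,
                           scores, sequence=sequence, reference_spec=spec)
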