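"""High-contribution seqlet extraction from contribution maps."""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence

import numpy as np

from ..seqs import one_hot
from .contrib import ContributionMap


@dataclass
class Seqlet:
    contig: str
    start: int
    end: int
    sequence: str
    scores: np.ndarray   # signed per-base contributions over the span
    task: str = ""

    @property
    def total(self) -> float:
        return float(np.abs(self.scores).sum())

    @property
    def width(self) -> int:
        return self.end - self.start

    def matrix(self) -> np.ndarray:
        """(4, W) signed matrix: one-hot of the sequence scaled by the scores."""
        return one_hot(self.sequence, dtype=np.float64) * self.scores


def _smooth(x: np.ndarray, w: int) -> np.ndarray:
    if w <= 1:
        return x
    kernel = np.ones(w) / w
    return np.convolve(x, kernel, mode="same")


def extract_seqlets(maps: Sequence[ContributionMap], flank: int = 3,
                    threshold_quantile: float = 0.99,
                    smooth_window: int = 7) -> List[Seqlet]:
    """Maximal runs of smoothed |score| above the per-map quantile, flank-extended.

    Overlapping runs (after extension) are merged. Maps must carry sequences.
    """
    if not 0 < threshold_quantile < 1:
        raise ValueError("threshold_quantile must be in (0, 1)")
    out: List[Seqlet] = []
    for cmap in maps:
        mag = _smooth(np.abs(cmap.scores), smooth_window)
        thr = float(np.quantile(mag, threshold_quantile))
        if thr <= 0:
            continue
        above = mag >= thr
        if not above.any():
            continue
        # run starts/ends
        padded = np.concatenate([[False], above, [False]])
        starts = np.nonzero(padded[1:].astype(int) - padded[:-1].astype(int) == 1)[0]
        ends = np.nonzero(padded[1:].astype(int) - padded[:-1].astype(int) == -1)[0]
        spans = []
        for s, e in zip(starts, ends):
            s = max(0, s - flank)
            e = min(cmap.width, e + flank)
            if spans and s <= spans[-1][1]:
                spans[-1] = (spans[-1][0], max(spans[-1][1], e))
            else:
                spans.append((s, e))
        for s, e in spans:
            out.append(Seqlet(cmap.contig, cmap.start + s, cmap.start + e,
                              cmap.sequence[s:e], cmap.scores[s:e].copy(),
                              task=cmap.task))
    return out
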