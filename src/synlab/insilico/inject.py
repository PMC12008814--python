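"""In-silico motif injection and the binding-enhancement statistic.

Motifs (as sequences) are injected into seeded randomized backgrounds; four
cases (neither, A only, B only, both) are evaluated on otherwise identical
sequences and predicted counts are summed in a fixed window centered on motif
A's intended position. Enhancement = log2((hAB - (hB - h0)) / hA).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from ..seqs import random_sequence, revcomp, validate_acgt


@dataclass
class InjectionResult:
    motifA: str
    motifB: Optional[str]
    distance: int
    h0: float
    hA: float
    hB: float
    hAB: float
    n_backgrounds: int
    task: str = ""
    enhancement: float = float("nan")  # NaN flags an undefined value

    def __post_init__(self):
        for name in ("h0", "hA", "hB", "hAB"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def enhancement(h0: float, hA: float, hB: float, hAB: float) -> float:
    """log2((hAB - (hB - h0)) / hA); NaN when the numerator is non-positive."""
    if hA <= 0:
        raise ValueError("hA must be > 0")
    numerator = hAB - (hB - h0)
    if numerator <= 0:
        return float("nan")
    return float(np.log2(numerator / hA))


def _predict_many(predictor, sequences: List[str], task: str) -> Tuple[np.ndarray, np.ndarray]:
    """(plus, minus) expected count arrays, stacked (N, L)."""
    if hasattr(predictor, "predict_batch"):
        out = predictor.predict_batch(sequences)[task]
        return np.asarray(out[0]), np.asarray(out[1])
    plus, minus = [], []
    for seq in sequences:
        p, m, _ = predictor.predict(seq)[task]
        plus.append(p)
        minus.append(m)
    return np.asarray(plus), np.asarray(minus)


def _background_length(predictor, requested: Optional[int]) -> int:
    win = getattr(predictor, "window", None)
    if win:
        return int(win)
    return int(requested or 1000)


def inject_predict(predictor, motifA: str, motifB: Optional[str], distance: int,
                   task: str, n_backgrounds: int = 256, window: int = 50,
                   seed: int = 0, gc: float = 0.42,
                   background_motif: Optional[str] = None,
                   background_length: Optional[int] = None,
                   orientB: str = "+") -> InjectionResult:
    """Evaluate the four injection cases and fill the h-values.

    Backgrounds are shared across the four cases (variance reduction). h is
    the mean over backgrounds of summed predicted counts in `window` bp
    centered on motif A's intended position (used for h0/hB as well).
    `background_motif`, when given, is written into every background at a
    seeded position within 150 bp of the center.
    """
    motifA = validate_acgt(motifA, name="motifA")
    if n_backgrounds < 1:
        raise ValueError("n_backgrounds must be >= 1")
    if motifB is not None:
        motifB = validate_acgt(motifB, name="motifB")
        if orientB == "-":
            motifB = revcomp(motifB)
        if distance < 0:
            raise ValueError("distance < 0 would overlap the motifs")
    L = _background_length(predictor, background_length)
    a_start = L // 2 - len(motifA) // 2
    a_end = a_start + len(motifA)
    if motifB is not None:
        b_start = a_end + distance
        b_end = b_start + len(motifB)
        if b_end > L:
            raise ValueError("motif B does not fit at the requested distance")
    center = a_start + len(motifA) // 2
    lo, hi = center - window // 2, center - window // 2 + window
    rng = np.random.default_rng(seed)
    cases: Dict[str, List[str]] = {"0": [], "A": [], "B": [], "AB": []}
    for _ in range(n_backgrounds):
        bg = random_sequence(L, rng, gc=gc)
        if background_motif is not None:
            bm = validate_acgt(background_motif, name="background_motif")
            gap = int(rng.integers(10, 151))
            s = a_start - gap - len(bm)
            if s < 0:
                raise ValueError("background_motif does not fit within 150 bp of center")
            bg = bg[:s] + bm + bg[s + len(bm):]
        sA = bg[:a_start] + motifA + bg[a_end:]
        cases["0"].append(bg)
        cases["A"].append(sA)
        if motifB is not None:
            cases["B"].append(bg[:b_start] + motifB + bg[b_end:])
            cases["AB"].append(sA[:b_start] + motifB + sA[b_end:])
    h: Dict[str, float] = {}
    for key in ("0", "A", "B", "AB"):
        if not cases[key]:
            continue
        plus, minus = _predict_many(predictor, cases[key], task)
        h[key] = float((plus[:, lo:hi].sum(axis=1) + minus[:, lo:hi].sum(axis=1)).mean())
    if motifB is None:
        h["B"], h["AB"] = h["0"], h["A"]
    enh = enhancement(h["0"], h["A"], h["B"], h["AB"]) if h["A"] > 0 else float("nan")
    return InjectionResult(motifA, motifB, distance, h["0"], h["A"], h["B"], h["AB"],
                           n_backgrounds, task=task, enhancement=enh)


def distance_sweep(predictor, motifA: str, motifB: str, distances: Sequence[int],
                   task: str, n_backgrounds: int = 256, seed: int = 0,
                   window: int = 50, orientations: str = "both",
                   **kwargs) -> List[InjectionResult]:
    """One InjectionResult per distance; B's two orientations averaged by default."""
    orients = ("+", "-") if orientations == "both" else (orientations,)
    out: List[InjectionResult] = []
    for d in distances:
        hs = np.zeros(4)
        for o in orients:
            r = inject_predict(predictor, motifA, motifB, d, task,
                               n_backgrounds=n_backgrounds, seed=seed,
                               window=window, orientB=o, **kwargs)
            hs += np.array([r.h0, r.hA, r.hB, r.hAB])
        hs /= len(orients)
        enh = enhancement(*hs) if hs[1] > 0 else float("nan")
        out.append(InjectionResult(motifA, motifB, d, *hs, n_backgrounds,
                                   task=task, enhancement=enh))
    return out


def fit_exponential_decay(distances: Sequence[float],
                          enhancements: Sequence[float]) -> Tuple[float, float]:
    """Fit 2^enhancement - 1 = c * exp(-d / tau); returns (c, tau).

    Log-linear least squares on the positive excess values.
    """
    d = np.asarray(distances, dtype=float)
    y = np.power(2.0, np.asarray(enhancements, dtype=float)) - 1.0
    good = np.isfinite(y) & (y > 0)
    if good.sum() < 3:
        raise ValueError("too few positive points to fit a decay")
    b, a = np.polyfit(d[good], np.log(y[good]), 1)
    if b >= 0:
        raise ValueError("no decay: fitted rate is non-negative")
    return float(np.exp(a)), float(-1.0 / b)
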