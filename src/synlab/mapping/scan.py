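"""Motif instance mapping: CWM scanning on contribution maps, PWM log-odds
scanning on sequence, and reciprocal-overlap deduplication."""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence

import numpy as np

from ..attribution.contrib import ContributionMap
from ..attribution.discover import continuous_jaccard
from ..core import Motif, MotifInstance
from ..seqs import encode, one_hot


def _unit(mat: np.ndarray) -> np.ndarray:
    s = np.abs(mat).sum()
    return mat / s if s > 0 else mat


def _jaccard_profile(enc: np.ndarray, scores: np.ndarray, cwm: np.ndarray) -> np.ndarray:
    """Continuous-Jaccard of every width-W window vs the CWM, with both sides
    masked to the observed base per position (hypothetical entries zeroed)."""
    W = cwm.shape[1]
    n = len(enc) - W + 1
    if n <= 0:
        return np.zeros(0)
    win = np.lib.stride_tricks.sliding_window_view(enc, W)          # (n, W)
    cols = np.arange(W)
    a = cwm[win, cols]                                              # (n, W)
    b = np.lib.stride_tricks.sliding_window_view(scores, W).astype(float)
    an = np.abs(a).sum(axis=1, keepdims=True)
    bn = np.abs(b).sum(axis=1, keepdims=True)
    a = a / np.where(an == 0, 1.0, an)
    b = b / np.where(bn == 0, 1.0, bn)
    sa, sb = np.abs(a), np.abs(b)
    agree = (np.sign(a) * np.sign(b)) > 0
    num = np.where(agree, np.minimum(sa, sb), 0.0).sum(axis=1)
    den = np.maximum(sa, sb).sum(axis=1)
    den[den == 0] = 1.0
    return num / den


def cwm_scan(cmap: ContributionMap, motif: Motif, sim_threshold: float = 0.4,
             contrib_threshold: Optional[float] = None) -> List[MotifInstance]:
    """Slide the CWM (both orientations) over the one-hot-masked contribution
    matrix; emit windows passing similarity AND total |contribution| filters.

    contrib_threshold=None uses the adaptive default: 10% of the largest
    window |score| sum on this map (weak near-consensus background matches
    carry real but small contribution and are excluded by this floor).
    """
    W = motif.width
    if cmap.width < W:
        raise ValueError("map shorter than motif width")
    enc = encode(cmap.sequence)
    sims_f = _jaccard_profile(enc, cmap.scores, motif.cwm)
    sims_r = _jaccard_profile(enc, cmap.scores, motif.cwm[::-1, ::-1])
    mag = np.abs(cmap.scores)
    csum = np.concatenate([[0.0], np.cumsum(mag)])
    window_abs = csum[W:] - csum[:-W]
    ssum = np.concatenate([[0.0], np.cumsum(cmap.scores)])
    window_sig = ssum[W:] - ssum[:-W]
    if contrib_threshold is None:
        contrib_threshold = 0.1 * float(window_abs.max()) if len(window_abs) else 0.0
    strand_is_fwd = sims_f >= sims_r
    sims = np.where(strand_is_fwd, sims_f, sims_r)
    hits = np.nonzero((sims >= sim_threshold) & (window_abs >= contrib_threshold))[0]
    out = []
    for i in hits:
        out.append(MotifInstance(cmap.contig, cmap.start + int(i), cmap.start + int(i) + W,
                                 "+" if strand_is_fwd[i] else "-", motif.name,
                                 match_score=float(sims[i]),
                                 total_contribution=float(window_sig[i]),
                                 source="cwm"))
    return out


def pwm_scan(sequence: str, motif: Motif,
             background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
             score_threshold: Optional[float] = None,
             pseudocount: float = 0.01,
             contig: str = "seq", offset: int = 0) -> List[MotifInstance]:
    """Log2-odds scan vs background at every position, both strands.

    Max-strand semantics: one candidate per position, keeping the better
    strand (ties to +). Default threshold: 0.8 x the consensus (maximum)
    score in bits.
    """
    bg = np.asarray(background, dtype=float)
    if bg.shape != (4,) or not np.isclose(bg.sum(), 1.0, atol=1e-6) or (bg <= 0).any():
        raise ValueError("background must be 4 positive frequencies summing to 1")
    p = motif.pwm + pseudocount
    p = p / p.sum(axis=0)
    M = np.log2(p / bg[:, None])
    W = motif.width
    enc = encode(sequence)
    if len(enc) < W:
        return []
    win = np.lib.stride_tricks.sliding_window_view(enc, W)  # (n, W)
    cols = np.arange(W)
    scores_f = M[win, cols].sum(axis=1)
    Mr = M[::-1, ::-1]
    scores_r = Mr[win, cols].sum(axis=1)
    if score_threshold is None:
        score_threshold = 0.8 * float(M.max(axis=0).sum())
    fwd = scores_f >= scores_r
    scores = np.where(fwd, scores_f, scores_r)
    hits = np.nonzero(scores >= score_threshold)[0]
    return [MotifInstance(contig, offset + int(i), offset + int(i) + W,
                          "+" if fwd[i] else "-", motif.name,
                          match_score=float(scores[i]), source="pwm")
            for i in hits]


def _score_of(inst: MotifInstance) -> float:
    if inst.source == "cwm" and inst.total_contribution is not None:
        return inst.total_contribution
    return inst.match_score


def _reciprocal_overlap(a: MotifInstance, b: MotifInstance) -> float:
    ov = min(a.end, b.end) - max(a.start, b.start)
    if ov <= 0:
        return 0.0
    return min(ov / (a.end - a.start), ov / (b.end - b.start))


def dedup_instances(instances: Sequence[MotifInstance],
                    min_reciprocal_overlap: float = 0.5) -> List[MotifInstance]:
    """Best-first filtering of same-motif instances overlapping >= 50% reciprocally.

    Highest total_contribution (cwm) or match_score (pwm) wins; ties broken
    by leftmost start then + strand. Idempotent.
    """
    order = sorted(instances,
                   key=lambda i: (-_score_of(i), i.contig, i.start, i.strand != "+"))
    kept: List[MotifInstance] = []
    for cand in order:
        clash = any(k.motif_name == cand.motif_name and k.contig == cand.contig
                    and _reciprocal_overlap(k, cand) >= min_reciprocal_overlap
                    for k in kept)
        if not clash:
            kept.append(cand)
    kept.sort(key=lambda i: (i.contig, i.start, i.end, i.strand))
    return kept
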