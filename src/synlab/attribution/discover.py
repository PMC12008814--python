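"""Greedy alignment clustering of seqlets into CWM/PWM motifs.

A deliberately small surrogate for full seqlet-clustering pipelines: clusters
are seeded from the highest-contribution seqlet; seqlets join the cluster
whose CWM they match best (continuous-Jaccard over ungapped offsets, both
orientations) above a similarity threshold; a second pass reassigns all
seqlets against the frozen cluster averages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from ..core import Motif
from ..seqs import one_hot
from .seqlets import Seqlet


def continuous_jaccard(a: np.ndarray, b: np.ndarray) -> float:
    """Sum of sign-agreeing min(|a|,|b|) over sum of max(|a|,|b|)."""
    sa, sb = np.abs(a), np.abs(b)
    agree = (np.sign(a) * np.sign(b)) > 0
    den = np.maximum(sa, sb).sum()
    if den <= 0:
        return 0.0
    num = np.where(agree, np.minimum(sa, sb), 0.0).sum()
    return float(num / den)


def _norm(mat: np.ndarray) -> np.ndarray:
    s = np.abs(mat).sum()
    return mat / s if s > 0 else mat


def best_alignment(ref: np.ndarray, mat: np.ndarray,
                   min_overlap: int = 4) -> Tuple[float, int, bool]:
    """Best (similarity, offset, flipped) of `mat` against `ref`, zero-padded."""
    ref = _norm(ref)
    Wr, Wm = ref.shape[1], mat.shape[1]
    best = (-1.0, 0, False)
    for flip in (False, True):
        m = _norm(mat[::-1, ::-1] if flip else mat)
        for off in range(-Wm + min_overlap, Wr - min_overlap + 1):
            lo, hi = min(0, off), max(Wr, off + Wm)
            a = np.zeros((4, hi - lo))
            b = np.zeros((4, hi - lo))
            a[:, -lo:-lo + Wr] = ref
            b[:, off - lo:off - lo + Wm] = m
            s = continuous_jaccard(a, b)
            if s > best[0]:
                best = (s, off, flip)
    return best


@dataclass
class _Cluster:
    width: int
    cwm_sum: np.ndarray
    pwm_sum: np.ndarray
    counts: np.ndarray
    members: List[Tuple[Seqlet, int, bool]] = field(default_factory=list)

    @classmethod
    def seeded(cls, width: int) -> "_Cluster":
        return cls(width, np.zeros((4, width)), np.zeros((4, width)), np.zeros(width))

    def add(self, seqlet: Seqlet, offset: int, flip: bool) -> None:
        mat = seqlet.matrix()
        oh = one_hot(seqlet.sequence, dtype=np.float64)
        if flip:
            mat = mat[::-1, ::-1]
            oh = oh[::-1, ::-1]
        lo = max(0, offset)
        hi = min(self.width, offset + mat.shape[1])
        if hi <= lo:
            return
        self.cwm_sum[:, lo:hi] += mat[:, lo - offset:hi - offset]
        self.pwm_sum[:, lo:hi] += oh[:, lo - offset:hi - offset]
        self.counts[lo:hi] += 1
        self.members.append((seqlet, offset, flip))

    def cwm(self) -> np.ndarray:
        c = np.maximum(self.counts, 1.0)
        return self.cwm_sum / c

    def pwm(self) -> np.ndarray:
        out = np.full((4, self.width), 0.25)
        nz = self.counts > 0
        out[:, nz] = self.pwm_sum[:, nz] / self.counts[nz]
        cols = out.sum(axis=0)
        return out / cols

    def total_contribution(self) -> float:
        return float(sum(s.total for s, _, _ in self.members))


def _trim_seqlet(seqlet: Seqlet, max_width: int) -> Seqlet:
    if seqlet.width <= max_width:
        return seqlet
    center = int(np.argmax(np.abs(seqlet.scores)))
    lo = int(np.clip(center - max_width // 2, 0, seqlet.width - max_width))
    hi = lo + max_width
    return Seqlet(seqlet.contig, seqlet.start + lo, seqlet.start + hi,
                  seqlet.sequence[lo:hi], seqlet.scores[lo:hi], task=seqlet.task)


def _trim_motif(cwm: np.ndarray, pwm: np.ndarray, frac: float = 0.05
                ) -> Tuple[np.ndarray, np.ndarray]:
    mag = np.abs(cwm).max(axis=0)
    peak = mag.max()
    if peak <= 0:
        return cwm, pwm
    keep = np.nonzero(mag >= frac * peak)[0]
    lo, hi = int(keep[0]), int(keep[-1]) + 1
    if hi - lo < 5:  # keep a minimal width
        lo = max(0, min(lo, cwm.shape[1] - 5))
        hi = min(cwm.shape[1], lo + 5)
    return cwm[:, lo:hi], pwm[:, lo:hi]


def discover_motifs(seqlets: Sequence[Seqlet], min_support: int = 10,
                    max_motifs: int = 10, sim_threshold: float = 0.3,
                    max_width: int = 25) -> List[Motif]:
    """Cluster seqlets into motifs; returns <= max_motifs sorted by contribution."""
    if not seqlets:
        return []
    trimmed = [_trim_seqlet(s, max_width) for s in seqlets]
    order = sorted(range(len(trimmed)), key=lambda i: -trimmed[i].total)
    clusters: List[_Cluster] = []
    for i in order:
        s = trimmed[i]
        best_c, best = None, (sim_threshold, 0, False)
        for c in clusters:
            sim, off, flip = best_alignment(c.cwm(), s.matrix())
            if sim > best[0]:  # ties broken toward the earlier-seeded cluster
                best_c, best = c, (sim, off, flip)
        if best_c is None:
            c = _Cluster.seeded(s.width)
            c.add(s, 0, False)
            clusters.append(c)
        else:
            best_c.add(s, best[1], best[2])
    # second pass against frozen averages
    frozen = [c.cwm() for c in clusters]
    final = [_Cluster.seeded(c.width) for c in clusters]
    for i in order:
        s = trimmed[i]
        best_j, best = None, (sim_threshold, 0, False)
        for j, ref in enumerate(frozen):
            sim, off, flip = best_alignment(ref, s.matrix())
            if sim > best[0]:
                best_j, best = j, (sim, off, flip)
        if best_j is not None:
            final[best_j].add(s, best[1], best[2])
    final = [c for c in final if len(c.members) >= min_support]
    final.sort(key=lambda c: -c.total_contribution())
    motifs: List[Motif] = []
    for k, c in enumerate(final[:max_motifs]):
        cwm, pwm = _trim_motif(c.cwm(), c.pwm())
        motifs.append(Motif(f"motif_{k + 1}", pwm, cwm, support=len(c.members)))
    return motifs
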