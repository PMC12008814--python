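"""Core record types shared across modules."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np


@dataclass
class MotifInstance:
    """A located motif occurrence (0-based, half-open coordinates)."""

    contig: str
    start: int
    end: int
    strand: str
    motif_name: str
    match_score: float = 0.0
    total_contribution: Optional[float] = None
    source: str = "planted"  # {cwm, pwm, planted}
    occupancy: Optional[float] = None  # expected reads; planted instances only

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"empty span {self.start}..{self.end} on {self.contig}")
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> float:
        return (self.start + self.end) / 2

    def copy(self, **changes) -> "MotifInstance":
        return replace(self, **changes)


@dataclass
class StrandedProfile:
    """Per-base counts on both strands over one region for one task.

    Counts are integer when simulated and real when predicted; always >= 0.
    """

    contig: str
    start: int
    end: int
    task: str
    plus: np.ndarray
    minus: np.ndarray

    def __post_init__(self):
        self.plus = np.asarray(self.plus, dtype=float)
        self.minus = np.asarray(self.minus, dtype=float)
        w = self.end - self.start
        if len(self.plus) != w or len(self.minus) != w:
            raise ValueError("profile length does not match region width")
        if (self.plus < 0).any() or (self.minus < 0).any():
            raise ValueError("negative counts")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def total(self) -> float:
        return float(self.plus.sum() + self.minus.sum())

    def slice(self, start: int, end: int) -> "StrandedProfile":
        s, e = start - self.start, end - self.start
        if s < 0 or e > self.width:
            raise ValueError("slice outside region")
        return StrandedProfile(self.contig, start, end, self.task,
                               self.plus[s:e].copy(), self.minus[s:e].copy())


@dataclass
class Motif:
    """A named pattern: frequency PWM, signed CWM, and consensus."""

    name: str
    pwm: np.ndarray  # (4, W) column-stochastic
    cwm: np.ndarray  # (4, W) signed contributions
    consensus: str = ""
    support: int = 0

    def __post_init__(self):
        self.pwm = np.asarray(self.pwm, dtype=float)
        self.cwm = np.asarray(self.cwm, dtype=float)
        if self.pwm.shape != self.cwm.shape or self.pwm.shape[0] != 4:
            raise ValueError("pwm/cwm must both be (4, W)")
        colsums = self.pwm.sum(axis=0)
        if not np.allclose(colsums, 1.0, atol=1e-6):
            raise ValueError("pwm columns must sum to 1")
        if not self.consensus:
            from .seqs import ALPHABET
            self.consensus = "".join(ALPHABET[i] for i in self.pwm.argmax(axis=0))

    @property
    def width(self) -> int:
        return self.pwm.shape[1]

    def reverse_complement(self) -> "Motif":
        return Motif(self.name, self.pwm[::-1, ::-1].copy(), self.cwm[::-1, ::-1].copy(),
                     support=self.support)


def motif_from_consensus(name: str, consensus: str, match_prob: float = 0.85) -> Motif:
    """Build a sharply peaked PWM (and matching CWM) from a consensus string."""
    from .seqs import encode
    idx = encode(consensus)
    w = len(consensus)
    pwm = np.full((4, w), (1 - match_prob) / 3)
    pwm[idx, np.arange(w)] = match_prob
    lo = np.log2(pwm / 0.25)
    return Motif(name, pwm, lo, consensus=consensus)
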