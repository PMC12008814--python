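"""IUPAC double-motif scanning and spacing frequency tables."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np

from ..core import MotifInstance
from ..seqs import SequenceError, encode, iupac_onehot_mask, revcomp_iupac

DEFAULT_PATTERN = "RMATTCCWD"
CORE_LENGTH = 7  # spacing is defined on the core (pattern minus degenerate tail)


@dataclass
class SpacingTable:
    counts: Dict[int, int]
    pattern: str
    core: str
    max_gap: int
    strand_policy: str = "both"

    def total(self) -> int:
        return sum(self.counts.values())


def _iupac_match_positions(enc: np.ndarray, pattern: str) -> np.ndarray:
    mask = iupac_onehot_mask(pattern)
    W = mask.shape[1]
    if len(enc) < W:
        return np.zeros(0, dtype=int)
    win = np.lib.stride_tricks.sliding_window_view(enc, W)
    ok = mask[win, np.arange(W)].all(axis=1)
    return np.nonzero(ok)[0]


def scan_double_pattern(contigs: Dict[str, str], core_pattern: str = DEFAULT_PATTERN,
                        max_gap: int = 23, core_length: int = CORE_LENGTH
                        ) -> Tuple[SpacingTable, List[MotifInstance], List[MotifInstance]]:
    """Exact IUPAC matching on both strands; pairs of motif cores within
    max_gap recorded by spacing (bp between first core end and next core start).

    The full pattern (e.g. the 9-mer) is required for isolated single-motif
    calls; pairing operates on the core (first core_length bp), so a spacing-2
    double corresponds to core + NN + core. Returns (SpacingTable, double
    instances, single instances).
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    core = core_pattern[:core_length]
    counts: Dict[int, int] = {}
    doubles: List[MotifInstance] = []
    singles: List[MotifInstance] = []
    for contig in sorted(contigs):
        try:
            enc = encode(contigs[contig])
        except SequenceError as err:
            raise SequenceError(f"{contig}: {err}") from None
        # full-pattern single matches, both strands
        hits: List[Tuple[int, int, str]] = []
        for strand, pat in (("+", core_pattern), ("-", revcomp_iupac(core_pattern))):
            for pos in _iupac_match_positions(enc, pat):
                singles.append(MotifInstance(contig, int(pos), int(pos) + len(pat),
                                             strand, "single", source="pwm"))
        # core matches for pairing
        for strand, pat in (("+", core), ("-", revcomp_iupac(core))):
            for pos in _iupac_match_positions(enc, pat):
                hits.append((int(pos), int(pos) + len(core), strand))
        hits.sort()
        for i, (s1, e1, st1) in enumerate(hits):
            for s2, e2, st2 in hits[i + 1:]:
                gap = s2 - e1
                if gap > max_gap:
                    break
                if gap < 0:
                    continue
                counts[gap] = counts.get(gap, 0) + 1
                doubles.append(MotifInstance(contig, s1, e2, "+",
                                             f"double_s{gap}", source="pwm"))
    return (SpacingTable(counts, core_pattern, core, max_gap), doubles, singles)
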