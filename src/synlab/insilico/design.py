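"""Minimal-mutation enhancer design and motif moving."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from ..attribution.contrib import ContributionMap
from ..core import Motif, MotifInstance
from ..seqs import ALPHABET, BASE_INDEX, revcomp


@dataclass
class MutationReport:
    positions: List[int]            # sequence coordinates, ascending
    old_bases: List[str]
    new_bases: List[str]
    contributions: List[float]
    tie_break_used: bool = False


def design_minimal_mutation(cmap: ContributionMap, instance: MotifInstance,
                            motif: Motif, k: int = 2
                            ) -> Tuple[str, MutationReport]:
    """Mutate the k most-contributing bases of the instance to the motif's
    least-contributing base at each position (per its CWM).

    Coordinates of `instance` are in the map's coordinate space. Returns the
    edited window sequence and a per-position report. Equal contributions are
    resolved toward the leftmost position and flagged.
    """
    if k > instance.width:
        raise ValueError("k exceeds motif width")
    lo = instance.start - cmap.start
    hi = instance.end - cmap.start
    if lo < 0 or hi > cmap.width:
        raise ValueError("instance outside the contribution map")
    if instance.width != motif.width:
        raise ValueError("instance width does not match motif width")
    seq = list(cmap.sequence)
    report = MutationReport([], [], [], [])
    if k == 0:
        return cmap.sequence, report
    span = cmap.scores[lo:hi]
    # stable argsort descending => leftmost wins ties
    order = np.argsort(-span, kind="stable")[:k]
    report.tie_break_used = len(np.unique(np.round(span, 12))) < len(span)
    cwm = motif.cwm if instance.strand == "+" else motif.cwm[::-1, ::-1]
    for off in sorted(int(o) for o in order):
        pos = lo + off
        old = seq[pos]
        new = ALPHABET[int(np.argmin(cwm[:, off]))]
        seq[pos] = new
        report.positions.append(cmap.start + pos)
        report.old_bases.append(old)
        report.new_bases.append(new)
        report.contributions.append(float(span[off]))
    return "".join(seq), report


def move_motif(sequence: str, instance: MotifInstance, anchor: MotifInstance,
               new_gap: int, cmap: ContributionMap, motif: Motif,
               k_mutations: int = 2) -> str:
    """Rewrite the instance's motif consensus at `new_gap` bp from the anchor
    and knock out the original instance by minimal mutation.

    All coordinates are in `sequence`/`cmap` space (cmap must cover the same
    window). Substitution only: output length equals input length.
    """
    if len(sequence) != cmap.width or sequence != cmap.sequence:
        raise ValueError("sequence and contribution map disagree")
    w = motif.width
    on_right = instance.start >= anchor.end
    if on_right:
        new_start = anchor.end - cmap.start + new_gap
    else:
        new_start = anchor.start - cmap.start - new_gap - w
    new_end = new_start + w
    if new_start < 0 or new_end > len(sequence):
        raise ValueError("requested position out of bounds")
    a_lo, a_hi = anchor.start - cmap.start, anchor.end - cmap.start
    i_lo, i_hi = instance.start - cmap.start, instance.end - cmap.start
    if new_start < a_hi and a_lo < new_end:
        raise ValueError("target span overlaps the anchor")
    same_site = (new_start, new_end) == (i_lo, i_hi)
    if not same_site and new_start < i_hi and i_lo < new_end:
        raise ValueError("target span partially overlaps the original instance")
    consensus = motif.consensus if instance.strand == "+" else revcomp(motif.consensus)
    mutated, _ = design_minimal_mutation(cmap, instance, motif, k=k_mutations)
    return mutated[:new_start] + consensus + mutated[new_end:]
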