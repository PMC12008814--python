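"""Motif islands: merged 500 bp enhancer windows centered on mapped motifs."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

from ..core import MotifInstance


@dataclass
class Island:
    contig: str
    start: int
    end: int
    members: List[MotifInstance] = field(default_factory=list)

    @property
    def motif_counts(self) -> Dict[str, int]:
        out: Dict[str, int] = {}
        for m in self.members:
            out[m.motif_name] = out.get(m.motif_name, 0) + 1
        return out

    @property
    def width(self) -> int:
        return self.end - self.start


def build_islands(instances: Sequence[MotifInstance], window: int = 500,
                  contig_lengths: Optional[Dict[str, int]] = None) -> List[Island]:
    """window-bp regions centered on each instance midpoint, transitively
    merged while overlapping, clipped to contig bounds.

    Islands are pairwise disjoint; every instance belongs to exactly one
    island; output is independent of input order.
    """
    half = window // 2
    by_contig: Dict[str, List[MotifInstance]] = {}
    for inst in instances:
        by_contig.setdefault(inst.contig, []).append(inst)
    islands: List[Island] = []
    for contig in sorted(by_contig):
        insts = sorted(by_contig[contig], key=lambda i: (i.start, i.end, i.strand))
        current: Optional[Island] = None
        for inst in insts:
            mid = (inst.start + inst.end) // 2
            lo, hi = mid - half, mid - half + window
            if contig_lengths and contig in contig_lengths:
                lo = max(0, lo)
                hi = min(contig_lengths[contig], hi)
            else:
                lo = max(0, lo)
            if current is not None and lo < current.end:
                current.end = max(current.end, hi)
                current.members.append(inst)
            else:
                current = Island(contig, lo, hi, [inst])
                islands.append(current)
    return islands
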