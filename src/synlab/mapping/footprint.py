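"""Footprint validation: stranded average matrices around mapped instances."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence

import numpy as np

from ..core import MotifInstance, StrandedProfile


@dataclass
class FootprintReport:
    plus: np.ndarray            # (n, 2*flank + width), orientation-normalized
    minus: np.ndarray
    scores: np.ndarray          # per-instance edge-enrichment score
    instances: List[MotifInstance]
    n_skipped: int = 0

    def median_score(self) -> float:
        return float(np.median(self.scores))


def footprint_matrix(instances: Sequence[MotifInstance],
                     profiles: Dict[str, StrandedProfile],
                     flank: int = 200,
                     edge_pad: int = 20) -> FootprintReport:
    """Per-instance +/- profiles in +/- flank, oriented by instance strand.

    Footprint score = mean signal within edge_pad of the motif edges over the
    mean signal in the outer flanks (>= 1 means enrichment). Rows are sorted
    by total signal, descending. Instances too close to a region edge are
    skipped and counted.
    """
    insts = list(instances)
    if not insts:
        raise ValueError("empty instance list")
    widths = {i.width for i in insts}
    if len(widths) > 1:
        raise ValueError("instances must share one motif width")
    w = widths.pop()
    if flank <= edge_pad:
        raise ValueError("flank must exceed edge_pad")
    span = 2 * flank + w
    rows_p, rows_m, scores, kept = [], [], [], []
    skipped = 0
    for inst in insts:
        prof = profiles.get(inst.contig)
        if prof is None:
            skipped += 1
            continue
        lo, hi = inst.start - flank, inst.end + flank
        if lo < prof.start or hi > prof.end:
            skipped += 1
            continue
        s, e = lo - prof.start, hi - prof.start
        plus = prof.plus[s:e].copy()
        minus = prof.minus[s:e].copy()
        if inst.strand == "-":
            plus, minus = minus[::-1].copy(), plus[::-1].copy()
        inner = slice(flank - edge_pad, flank + w + edge_pad)
        sig = plus + minus
        inner_mean = sig[inner].mean()
        outer = np.concatenate([sig[:flank - edge_pad], sig[flank + w + edge_pad:]])
        outer_mean = outer.mean()
        score = inner_mean / outer_mean if outer_mean > 0 else np.inf
        rows_p.append(plus)
        rows_m.append(minus)
        scores.append(score)
        kept.append(inst)
    if not kept:
        raise ValueError("no instance fully inside the profiled regions")
    plus = np.asarray(rows_p)
    minus = np.asarray(rows_m)
    scores = np.asarray(scores)
    order = np.argsort(-(plus.sum(axis=1) + minus.sum(axis=1)))
    return FootprintReport(plus[order], minus[order], scores[order],
                           [kept[i] for i in order], n_skipped=skipped)
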