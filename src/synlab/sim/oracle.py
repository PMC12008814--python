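"""Analytic oracle: a noise-free BindingPredictor implementing the grammar.

The oracle scans a sequence for exact and near-consensus motif matches,
applies the grammar's occupancy model (affinity scaling, strict-spacing
cooperativity, directional soft boosts), and lays footprint kernels. It also
provides exact per-base contribution maps (marginal occupancy of each matched
instance, distributed over its bases), so attribution and mapping machinery
can be validated independently of model training.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from ..core import MotifInstance
from ..seqs import encode, revcomp
from .genome import SyntheticGenome, base_occupancy, soft_boost
from .grammar import GroundTruthGrammar


class OracleError(ValueError):
    pass


@dataclass
class _Unit:
    """A bound entity: a single motif match or a merged strict-spacing pair."""

    motif: str
    start: int
    end: int
    strand: str
    task: str
    occ: float                      # before soft boosts
    boost: float = 1.0
    spans: List[Tuple[int, int]] = field(default_factory=list)  # base-carrying spans

    @property
    def occupancy(self) -> float:
        return self.occ * self.boost


def oracle_occupancy(grammar: GroundTruthGrammar, genome: SyntheticGenome,
                     instance: MotifInstance) -> float:
    """Expected reads for a truth instance under the grammar."""
    if instance.motif_name not in grammar.motifs:
        raise OracleError(f"instance motif {instance.motif_name!r} not in grammar")
    occ = base_occupancy(grammar, instance.motif_name, genome.instance_sequence(instance))
    neighbours = [i for i in genome.truth if i.contig == instance.contig]
    return occ * soft_boost(grammar, instance, neighbours, genome)


class OraclePredictor:
    """Noise-free predictor satisfying the BindingPredictor contract.

    predict(sequence) returns, per task, expected stranded base-resolution
    read profiles and total counts. Accepts any sequence length >= the widest
    motif (window is unconstrained).
    """

    window: Optional[int] = None

    def __init__(self, grammar: GroundTruthGrammar, depth: Optional[float] = None):
        self.grammar = grammar
        self.depth = grammar.depth if depth is None else float(depth)
        self.task_names = list(grammar.task_names)
        self._per_mismatch_bits = float(np.log2(0.85 / 0.05))
        # precompute encoded consensi for scanning (singles only; doubles
        # emerge as strict-spacing half pairs)
        self._scan_motifs = []
        for m in grammar.single_motifs():
            fwd = encode(m.consensus)
            rev = encode(revcomp(m.consensus))
            self._scan_motifs.append((m, fwd, rev))

    # ------------------------------------------------------------------
    def _find_matches(self, enc: np.ndarray) -> List[_Unit]:
        L = len(enc)
        units: List[_Unit] = []
        for motif, fwd, rev in self._scan_motifs:
            w = len(fwd)
            if L < w:
                continue
            win = np.lib.stride_tricks.sliding_window_view(enc, w)
            for strand, pat in (("+", fwd), ("-", rev)):
                mm = (win != pat).sum(axis=1)
                hits = np.nonzero(mm <= self.grammar.max_mismatches)[0]
                beta = self.grammar.beta_for(motif.name)
                for pos in hits:
                    deficit = self._per_mismatch_bits * int(mm[pos])
                    occ = motif.amplitude * float(np.exp(-beta * deficit))
                    units.append(_Unit(motif.name, int(pos), int(pos) + w, strand,
                                       motif.task, occ, spans=[(int(pos), int(pos) + w)]))
        units.sort(key=lambda u: (u.start, u.end, u.strand, u.motif))
        return units

    def _merge_strict(self, units: List[_Unit]) -> List[_Unit]:
        for rule in self.grammar.strict_rules:
            used = set()
            merged: List[_Unit] = []
            halves = [u for u in units if u.motif == rule.half_site]
            for i, a in enumerate(halves):
                if id(a) in used:
                    continue
                for b in halves[i + 1:]:
                    if id(b) in used:
                        continue
                    if b.strand == a.strand and b.start - a.end == rule.spacing:
                        occ = rule.kappa * (a.occ + b.occ)
                        merged.append(_Unit(rule.name, a.start, b.end, a.strand,
                                            a.task, occ,
                                            spans=[(a.start, a.end), (b.start, b.end)]))
                        used.add(id(a))
                        used.add(id(b))
                        break
            units = [u for u in units if id(u) not in used] + merged
        units.sort(key=lambda u: (u.start, u.end))
        return units

    def _apply_soft(self, units: List[_Unit]) -> None:
        for u in units:
            u.boost = 1.0
        for rule in self.grammar.soft_rules:
            amp = self.grammar.motifs[rule.partner].amplitude
            partners = [p for p in units if p.motif == rule.partner]
            for u in units:
                if u.task != rule.task or u.motif == rule.partner:
                    continue
                for p in partners:
                    if p is u:
                        continue
                    d = max(u.start, p.start) - min(u.end, p.end)
                    if 0 <= d <= rule.max_range:
                        # boost weighted by the partner's relative affinity
                        w = p.occ / amp if amp > 0 else 0.0
                        u.boost *= 1.0 + rule.c * w * np.exp(-d / rule.tau)

    def units(self, sequence: str) -> List[_Unit]:
        enc = encode(sequence)
        units = self._merge_strict(self._find_matches(enc))
        self._apply_soft(units)
        return units

    # ------------------------------------------------------------------
    def predict(self, sequence: str) -> Dict[str, Tuple[np.ndarray, np.ndarray, float]]:
        """Per task: (expected plus counts, expected minus counts, total)."""
        from .profiles import add_instance_footprint

        units = self.units(sequence)
        L = len(sequence)
        out: Dict[str, Tuple[np.ndarray, np.ndarray, float]] = {}
        for task in self.grammar.direct_tasks:
            plus = np.full(L, self.depth)
            minus = np.full(L, self.depth)
            kernel = self.grammar.kernel_for(task)
            for u in units:
                if u.task != task:
                    continue
                add_instance_footprint(plus, minus, kernel, u.start, u.end,
                                       u.strand, u.occupancy)
            out[task] = (plus, minus, float(plus.sum() + minus.sum()))
        for task, driver in self.grammar.indirect_map.items():
            plus, minus, total = out[driver]
            out[task] = (plus.copy(), minus.copy(), total)
        return out

    def predicted_counts(self, sequence: str, task: str) -> float:
        return self.predict(sequence)[task][2]

    # ------------------------------------------------------------------
    def _task_total(self, units: List[_Unit], task: str) -> float:
        direct = self.grammar.indirect_map.get(task, task)
        return sum(u.occupancy for u in units if u.task == direct)

    def contribution_map(self, sequence: str, task: str) -> np.ndarray:
        """Exact per-base contributions: each matched unit's marginal occupancy
        (full model minus model-without-the-unit), distributed across its
        base-carrying spans proportional to per-base match weight."""
        if task not in self.task_names:
            raise OracleError(f"unknown task {task!r}")
        all_units = self.units(sequence)
        scores = np.zeros(len(sequence))
        full = self._task_total(all_units, task)
        for u in all_units:
            rest = [v for v in all_units if v is not u]
            self._apply_soft(rest)
            delta = full - self._task_total(rest, task)
            if delta == 0.0:
                continue
            width = sum(e - s for s, e in u.spans)
            for s, e in u.spans:
                scores[s:e] += delta / width
        self._apply_soft(all_units)  # restore boosts
        return scores


def oracle_predictor(grammar: GroundTruthGrammar,
                     depth: Optional[float] = None) -> OraclePredictor:
    return OraclePredictor(grammar, depth=depth)
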