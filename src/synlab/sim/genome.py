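"""Synthetic genome simulation: iid background plus planted motif instances."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Union

import numpy as np

from ..core import MotifInstance
from ..seqs import decode, encode, revcomp
from .grammar import GroundTruthGrammar

_ATTEMPTS_PER_INSTANCE = 200


class SimulationError(RuntimeError):
    pass


@dataclass
class SyntheticGenome:
    contigs: Dict[str, str]
    truth: List[MotifInstance] = field(default_factory=list)

    def fetch(self, contig: str, start: int, end: int) -> str:
        seq = self.contigs[contig]
        if start < 0 or end > len(seq):
            raise ValueError(f"window {start}..{end} outside contig {contig}")
        return seq[start:end]

    def instance_sequence(self, inst: MotifInstance) -> str:
        s = self.fetch(inst.contig, inst.start, inst.end)
        return revcomp(s) if inst.strand == "-" else s

    def contig_lengths(self) -> Dict[str, int]:
        return {name: len(seq) for name, seq in self.contigs.items()}


def _mutate(consensus: str, k: int, rng: np.random.Generator) -> str:
    idx = encode(consensus).copy()
    pos = rng.choice(len(idx), size=k, replace=False)
    for p in pos:
        idx[p] = (idx[p] + 1 + rng.integers(3)) % 4
    return decode(idx)


def _edge_gap(a: MotifInstance, b: MotifInstance) -> float:
    """Gap in bp between nearest motif edges; 0 for adjacent, <0 overlapping."""
    if a.contig != b.contig:
        return float("inf")
    return float(max(a.start, b.start) - min(a.end, b.end))


def log_odds_deficit(grammar: GroundTruthGrammar, motif_name: str, observed: str) -> float:
    """Bits lost by `observed` (motif-strand) relative to the motif consensus."""
    sm = grammar.scoring_motif(motif_name)
    lo = np.log2(sm.pwm / 0.25)
    idx = encode(observed)
    s = float(lo[idx, np.arange(len(idx))].sum())
    s_max = float(lo.max(axis=0).sum())
    return s_max - s


def base_occupancy(grammar: GroundTruthGrammar, motif_name: str, observed: str) -> float:
    """A_t * exp(-beta * (s_max - s)); doubles score kappa * (left + right)."""
    rule = grammar.strict_rule_for(motif_name)
    if rule is not None:
        half = grammar.motifs[rule.half_site]
        w = half.width
        left, right = observed[:w], observed[-w:]
        return rule.kappa * (base_occupancy(grammar, rule.half_site, left)
                             + base_occupancy(grammar, rule.half_site, right))
    m = grammar.motifs[motif_name]
    beta = grammar.beta_for(motif_name)
    return m.amplitude * float(np.exp(-beta * log_odds_deficit(grammar, motif_name, observed)))


def soft_boost(grammar: GroundTruthGrammar, inst: MotifInstance,
               others: List[MotifInstance],
               genome: Optional["SyntheticGenome"] = None) -> float:
    """Product of directional soft-syntax boosts acting on `inst`'s task.

    Each partner's boost is weighted by its relative affinity
    w = exp(-beta * deficit) in (0, 1], so degenerate near-matches confer
    proportionally weaker cooperativity.
    """
    task = grammar.motifs[inst.motif_name].task
    factor = 1.0
    for rule in grammar.soft_rules:
        if rule.task != task:
            continue
        for other in others:
            if other is inst or other.motif_name != rule.partner:
                continue
            d = _edge_gap(inst, other)
            if 0 <= d <= rule.max_range:
                w = 1.0
                if genome is not None:
                    w = np.exp(-grammar.beta_for(other.motif_name) * log_odds_deficit(
                        grammar, other.motif_name, genome.instance_sequence(other)))
                factor *= 1.0 + rule.c * w * np.exp(-d / rule.tau)
    return factor


def annotate_occupancies(grammar: GroundTruthGrammar, genome: SyntheticGenome) -> None:
    """Fill in effective expected reads for every truth instance in place."""
    by_contig: Dict[str, List[MotifInstance]] = {}
    for inst in genome.truth:
        by_contig.setdefault(inst.contig, []).append(inst)
    for insts in by_contig.values():
        for inst in insts:
            occ = base_occupancy(grammar, inst.motif_name, genome.instance_sequence(inst))
            occ *= soft_boost(grammar, inst, insts, genome)
            inst.occupancy = occ


def simulate_genome(grammar: GroundTruthGrammar,
                    n_contigs: int,
                    contig_len: int,
                    density: Union[float, Dict[str, float]],
                    gc: Optional[float] = None,
                    seed: int = 0,
                    *,
                    pair_fraction: float = 0.0,
                    mismatch_prob: float = 0.0,
                    max_planted_mismatches: int = 2) -> SyntheticGenome:
    """Simulate contigs of iid background with planted motif instances.

    density is instances/kb, per motif (scalar applies to every grammar motif,
    including materialized double motifs). With pair_fraction > 0, that
    fraction of instances of soft-boosted motifs additionally receives a
    partner motif planted at a random edge gap in [0, 2 * max_range], so
    distance-dependence is observable. Planted instances never overlap.
    """
    if contig_len < 1000:
        raise ValueError("contig_len must be >= 1000")
    gc = grammar.gc if gc is None else gc
    rng = np.random.default_rng(seed)
    if not isinstance(density, dict):
        density = {name: float(density) for name in grammar.motifs}
    partner_of = {}
    for rule in grammar.soft_rules:
        for m in grammar.motifs.values():
            if m.task == rule.task and grammar.strict_rule_for(m.name) is None:
                partner_of[m.name] = rule
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    contigs: Dict[str, str] = {}
    truth: List[MotifInstance] = []
    for ci in range(n_contigs):
        name = f"syn{ci + 1}"
        arr = rng.choice(4, size=contig_len, p=p).astype(np.int64)
        occupied = np.zeros(contig_len, dtype=bool)

        def plant(consensus: str, motif_name: str, lo: int, hi: int) -> Optional[MotifInstance]:
            w = len(consensus)
            hi = min(hi, contig_len - w)
            if hi < lo:
                return None
            for _ in range(_ATTEMPTS_PER_INSTANCE):
                pos = int(rng.integers(lo, hi + 1))
                if occupied[pos:pos + w].any():
                    continue
                strand = "+" if rng.random() < 0.5 else "-"
                planted = consensus
                if mismatch_prob > 0 and rng.random() < mismatch_prob:
                    planted = _mutate(consensus, 1 + int(rng.integers(max_planted_mismatches)), rng)
                written = revcomp(planted) if strand == "-" else planted
                arr[pos:pos + w] = encode(written)
                occupied[pos:pos + w] = True
                inst = MotifInstance(name, pos, pos + w, strand, motif_name,
                                     source="planted")
                truth.append(inst)
                return inst
            return None

        for motif_name, dens in density.items():
            if dens < 0:
                raise ValueError("density must be >= 0")
            n = int(rng.poisson(contig_len * dens / 1000.0))
            motif = grammar.motifs[motif_name]
            planted_count = 0
            for _ in range(n):
                inst = plant(motif.consensus, motif_name, 0, contig_len - motif.width)
                if inst is None:
                    raise SimulationError(
                        f"could not plant {motif_name} on {name}: density infeasible")
                planted_count += 1
                rule = partner_of.get(motif_name)
                if rule is not None and rng.random() < pair_fraction:
                    partner = grammar.motifs[rule.partner]
                    gap = int(rng.integers(0, int(2 * rule.max_range) + 1))
                    side = 1 if rng.random() < 0.5 else -1
                    if side > 0:
                        lo = hi = inst.end + gap
                    else:
                        lo = hi = inst.start - gap - partner.width
                    if 0 <= lo <= contig_len - partner.width:
                        plant(partner.consensus, rule.partner, lo, hi)
        contigs[name] = decode(arr)
    genome = SyntheticGenome(contigs=contigs, truth=truth)
    annotate_occupancies(grammar, genome)
    genome.truth.sort(key=lambda i: (i.contig, i.start))
    return genome
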