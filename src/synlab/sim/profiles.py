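"""ChIP-nexus-like stranded footprint simulation with count noise."""

from __future__ import annotations

from typing import Dict, List, Optional

import numpy as np

from ..core import MotifInstance, StrandedProfile
from .grammar import FootprintKernel, GroundTruthGrammar
from .genome import SyntheticGenome, annotate_occupancies


def _add_kernel(target: np.ndarray, kernel: np.ndarray, center: int, weight: float) -> None:
    """Add weight * kernel centered at `center`, truncating at array bounds."""
    half = len(kernel) // 2
    lo, hi = center - half, center - half + len(kernel)
    klo, khi = max(0, -lo), len(kernel) - max(0, hi - len(target))
    lo, hi = max(lo, 0), min(hi, len(target))
    if lo < hi:
        target[lo:hi] += weight * kernel[klo:khi]


def add_instance_footprint(plus: np.ndarray, minus: np.ndarray,
                           kernel: FootprintKernel, inst_start: int, inst_end: int,
                           strand: str, occupancy: float) -> None:
    """Lay one instance's expected footprint onto per-base strand arrays.

    + instance: plus kernel at start + offset_plus, minus kernel at
    end - 1 + 1 + offset_minus; - instance is the coordinate mirror with
    strands swapped (reverse-complement symmetry).
    """
    c_plus = inst_start + kernel.offset_plus
    c_minus = inst_end - 1 + kernel.offset_minus + 1
    if strand == "+":
        _add_kernel(plus, kernel.plus, c_plus, occupancy)
        _add_kernel(minus, kernel.minus, c_minus, occupancy)
    else:
        _add_kernel(plus, kernel.minus[::-1], c_plus, occupancy)
        _add_kernel(minus, kernel.plus[::-1], c_minus, occupancy)


def expected_profiles(genome: SyntheticGenome, grammar: GroundTruthGrammar,
                      depth: float,
                      expectation: str = "truth") -> Dict[str, Dict[str, StrandedProfile]]:
    """Noise-free expected stranded coverage per task per contig.

    expectation="truth" lays footprints at planted truth instances only (the
    annotated ground-truth reads); expectation="oracle" uses the analytic
    oracle's prediction over each contig, so every near-consensus match in
    the background is bound at its affinity-scaled occupancy and the
    simulated world is exactly consistent with the oracle predictor.
    """
    if expectation not in ("truth", "oracle"):
        raise ValueError("expectation must be 'truth' or 'oracle'")
    if expectation == "oracle":
        from .oracle import OraclePredictor

        pred = OraclePredictor(grammar, depth=depth)
        out: Dict[str, Dict[str, StrandedProfile]] = {t: {} for t in grammar.task_names}
        for contig, seq in genome.contigs.items():
            res = pred.predict(seq)
            for task in grammar.task_names:
                plus, minus, _ = res[task]
                out[task][contig] = StrandedProfile(contig, 0, len(seq), task,
                                                    plus, minus)
        return out
    if any(inst.occupancy is None for inst in genome.truth):
        annotate_occupancies(grammar, genome)
    out: Dict[str, Dict[str, StrandedProfile]] = {t: {} for t in grammar.task_names}
    direct: Dict[str, Dict[str, StrandedProfile]] = {}
    for task in grammar.direct_tasks:
        kernel = grammar.kernel_for(task)
        direct[task] = {}
        for contig, seq in genome.contigs.items():
            plus = np.full(len(seq), float(depth))
            minus = np.full(len(seq), float(depth))
            for inst in genome.truth:
                if inst.contig != contig:
                    continue
                if grammar.motifs[inst.motif_name].task != task:
                    continue
                add_instance_footprint(plus, minus, kernel, inst.start, inst.end,
                                       inst.strand, inst.occupancy)
            direct[task][contig] = StrandedProfile(contig, 0, len(seq), task, plus, minus)
        out[task] = direct[task]
    for task, driver in grammar.indirect_map.items():
        out[task] = {
            contig: StrandedProfile(contig, 0, prof.width, task,
                                    prof.plus.copy(), prof.minus.copy())
            for contig, prof in direct[driver].items()
        }
    return out


def simulate_profiles(genome: SyntheticGenome, grammar: GroundTruthGrammar,
                      depth: float = 0.01, seed: int = 0,
                      noise: str = "poisson",
                      nb_dispersion: float = 0.2,
                      expectation: str = "truth") -> Dict[str, Dict[str, StrandedProfile]]:
    """Sample stranded count profiles: counts ~ Poisson(expected) per base.

    noise="nb" draws gamma-Poisson (negative binomial) counts with the given
    dispersion (variance = mu + dispersion * mu^2). See expected_profiles for
    the expectation modes.
    """
    if noise not in ("poisson", "nb"):
        raise ValueError("noise must be 'poisson' or 'nb'")
    rng = np.random.default_rng(seed)
    expected = expected_profiles(genome, grammar, depth, expectation=expectation)
    out: Dict[str, Dict[str, StrandedProfile]] = {}
    for task in sorted(expected):
        out[task] = {}
        for contig in sorted(expected[task]):
            prof = expected[task][contig]
            arrays = []
            for mu in (prof.plus, prof.minus):
                if noise == "poisson":
                    arrays.append(rng.poisson(mu).astype(float))
                else:
                    r = 1.0 / nb_dispersion
                    lam = rng.gamma(shape=r, scale=np.maximum(mu, 1e-12) / r)
                    arrays.append(rng.poisson(lam).astype(float))
            out[task][contig] = StrandedProfile(contig, 0, prof.width, task,
                                                arrays[0], arrays[1])
    return out
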