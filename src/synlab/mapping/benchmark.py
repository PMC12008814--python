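"""Benchmark PWM-frequency vs CWM-frequency vs CWM-contribution motif mapping."""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence

import numpy as np

from ..attribution import contribution_scores
from ..core import Motif, MotifInstance, StrandedProfile
from .footprint import footprint_matrix
from .scan import cwm_scan, dedup_instances, pwm_scan


def cwm_derived_pwm(motif: Motif, name_suffix: str = "_cwmfreq") -> Motif:
    """Frequency-style PWM reconstituted from the CWM's positive part."""
    pos = np.clip(motif.cwm, 0.0, None)
    cols = pos.sum(axis=0)
    pwm = np.where(cols > 0, pos / np.maximum(cols, 1e-12), 0.25)
    pwm = pwm / pwm.sum(axis=0)
    return Motif(motif.name + name_suffix, pwm, motif.cwm.copy(), support=motif.support)


def _injected_predictions(predictor, task: str, sequences: Sequence[str],
                          n_backgrounds: int, seed: int, window: int = 50) -> np.ndarray:
    from ..insilico.inject import inject_predict  # local import; no cycle at module load

    vals = []
    for i, seq in enumerate(sequences):
        res = inject_predict(predictor, seq, None, distance=0, task=task,
                             n_backgrounds=n_backgrounds, seed=seed + i, window=window)
        vals.append(res.hA)
    return np.asarray(vals)


def benchmark_scanners(genome, profiles: Dict[str, Dict[str, StrandedProfile]],
                       predictor, motif: Motif, task: str,
                       *, window: int = 400, sim_threshold: float = 0.3,
                       n_backgrounds: int = 32, max_unique: int = 25,
                       seed: int = 0) -> Dict[str, dict]:
    """Map instances three ways and report footprint + injected-prediction stats.

    Groups: pwm_freq (frequency PWM log-odds scan), cwm_freq (PWM
    reconstituted from the CWM, log-odds scan), cwm_contrib (CWM scanning on
    contribution maps over windows centered on truth instances).
    """
    report: Dict[str, dict] = {}
    contigs = getattr(genome, "contigs", {})
    if not contigs:
        return report
    groups: Dict[str, List[MotifInstance]] = {}
    pwm_hits: List[MotifInstance] = []
    for contig, seq in contigs.items():
        pwm_hits += pwm_scan(seq, motif, contig=contig)
    groups["pwm_freq"] = dedup_instances(pwm_hits)
    alt = cwm_derived_pwm(motif)
    alt_hits: List[MotifInstance] = []
    for contig, seq in contigs.items():
        alt_hits += pwm_scan(seq, alt, contig=contig)
    groups["cwm_freq"] = dedup_instances(
        [h.copy(motif_name=motif.name) for h in alt_hits])
    cwm_hits: List[MotifInstance] = []
    for inst in getattr(genome, "truth", []):
        mid = (inst.start + inst.end) // 2
        lo = mid - window // 2
        if lo < 0 or lo + window > len(contigs[inst.contig]):
            continue
        cmap = contribution_scores(predictor, genome.fetch(inst.contig, lo, lo + window),
                                   task, seed=seed, contig=inst.contig, start=lo)
        cwm_hits += cwm_scan(cmap, motif, sim_threshold=sim_threshold)
    groups["cwm_contrib"] = dedup_instances(cwm_hits)

    task_profiles = profiles.get(task, {})
    rng = np.random.default_rng(seed)
    for name, insts in groups.items():
        entry: Dict[str, object] = {"n": len(insts)}
        if insts and task_profiles:
            try:
                fp = footprint_matrix(insts, task_profiles)
                entry["footprint_scores"] = fp.scores
                entry["median_footprint"] = fp.median_score()
            except ValueError:
                entry["footprint_scores"] = np.asarray([])
        seqs = []
        seen = set()
        for inst in insts:
            s = genome.instance_sequence(inst)
            if s not in seen:
                seen.add(s)
                seqs.append(s)
        if len(seqs) > max_unique:
            idx = rng.choice(len(seqs), size=max_unique, replace=False)
            seqs = [seqs[i] for i in sorted(idx)]
        if seqs:
            inj = _injected_predictions(predictor, task, seqs, n_backgrounds, seed)
            entry["injected"] = inj
            entry["median_injected"] = float(np.median(inj))
        report[name] = entry
    return report
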