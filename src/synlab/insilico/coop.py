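"""Double-motif cooperativity: whole vs summed half-sites, spacing edits."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from ..seqs import random_sequence, validate_acgt
from .inject import _background_length, _predict_many


@dataclass
class CooperativityResult:
    double_sequence: str
    half_left: str
    half_right: str
    pred_whole: float
    pred_additive: float
    h0: float
    fold: float
    n_backgrounds: int
    task: str = ""


def double_cooperativity(predictor, double_sequence: str, split: int, task: str,
                         n_backgrounds: int = 256, window: int = 50, seed: int = 0,
                         gc: float = 0.42,
                         background_correction: bool = True) -> CooperativityResult:
    """Inject the whole double motif and each half separately into the same
    seeded backgrounds; compare whole vs background-corrected summed halves.

    pred_additive = pred(left) + pred(right) - h0 by default, so that pure
    additivity yields fold exactly 1; set background_correction=False for the
    uncorrected sum.
    """
    double_sequence = validate_acgt(double_sequence, name="double_sequence")
    if not 0 < split < len(double_sequence):
        raise ValueError("split must fall inside the sequence")
    left, right = double_sequence[:split], double_sequence[split:]
    L = _background_length(predictor, None)
    w_start = L // 2 - len(double_sequence) // 2
    center = w_start + len(double_sequence) // 2
    lo, hi = center - window // 2, center - window // 2 + window
    rng = np.random.default_rng(seed)
    cases: Dict[str, List[str]] = {"0": [], "whole": [], "left": [], "right": []}
    for _ in range(n_backgrounds):
        bg = random_sequence(L, rng, gc=gc)
        cases["0"].append(bg)
        cases["whole"].append(bg[:w_start] + double_sequence + bg[w_start + len(double_sequence):])
        cases["left"].append(bg[:w_start] + left + bg[w_start + len(left):])
        rs = w_start + split
        cases["right"].append(bg[:rs] + right + bg[rs + len(right):])
    h: Dict[str, float] = {}
    for key, seqs in cases.items():
        plus, minus = _predict_many(predictor, seqs, task)
        h[key] = float((plus[:, lo:hi].sum(axis=1) + minus[:, lo:hi].sum(axis=1)).mean())
    additive = h["left"] + h["right"] - (h["0"] if background_correction else 0.0)
    fold = h["whole"] / additive if additive > 0 else float("nan")
    return CooperativityResult(double_sequence, left, right, h["whole"], additive,
                               h["0"], fold, n_backgrounds, task=task)


def apply_gap_edit(sequence: str, linker_span: Tuple[int, int], op: str, k: int,
                   fill: str = "A") -> Tuple[str, Tuple[int, int]]:
    """Insert or delete k bp at the start of the linker; cores stay intact.

    Returns (edited sequence, new linker span). Deleting more than the linker
    holds would destroy a half-site core and is rejected.
    """
    s, e = linker_span
    if not 0 <= s <= e <= len(sequence):
        raise ValueError("linker span outside sequence")
    if k < 0:
        raise ValueError("edit size must be >= 0")
    if op == "delete":
        if k > e - s:
            raise ValueError("edit would destroy a half-site core")
        return sequence[:s] + sequence[s + k:], (s, e - k)
    if op == "insert":
        ins = (fill * k)[:k]
        return sequence[:s] + ins + sequence[s:], (s, e + k)
    raise ValueError(f"unknown edit op {op!r}")


def spacing_perturbation(predictor, double_sequence: str, linker_span: Tuple[int, int],
                         edits: Sequence[Tuple[str, int]], task: str,
                         n_backgrounds: int = 256, window: int = 50, seed: int = 0,
                         gc: float = 0.42) -> Dict[str, dict]:
    """Apply each (op, k) gap edit and re-run double_cooperativity.

    Returns per-edit {'sequence', 'fold', 'result'} keyed by "op<k>";
    includes the unedited sequence under 'wildtype'.
    """
    out: Dict[str, dict] = {}
    variants: List[Tuple[str, str]] = [("wildtype", double_sequence)]
    for op, k in edits:
        edited, _ = apply_gap_edit(double_sequence, linker_span, op, k)
        variants.append((f"{op}{k}", edited))
    split = linker_span[0]
    for name, seq in variants:
        res = double_cooperativity(predictor, seq, split, task,
                                   n_backgrounds=n_backgrounds, window=window,
                                   seed=seed, gc=gc)
        out[name] = {"sequence": seq, "fold": res.fold, "result": res}
    return out
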