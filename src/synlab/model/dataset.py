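"""Training-set assembly: windows centered on truth instances plus background."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from ..core import StrandedProfile
from ..seqs import one_hot
from ..sim.genome import SyntheticGenome

log = logging.getLogger(__name__)


@dataclass
class WindowSet:
    X: np.ndarray                      # (N, 4, window) one-hot float32
    Y: Dict[str, np.ndarray]           # task -> (N, 2, window) counts
    coords: List[Tuple[str, int]]      # (contig, start)

    def __len__(self) -> int:
        return self.X.shape[0]

    def stacked_counts(self, tasks: Sequence[str]) -> np.ndarray:
        """(N, T, 2, window) in the given task order."""
        return np.stack([self.Y[t] for t in tasks], axis=1)


@dataclass
class Dataset:
    window: int
    tasks: List[str]
    splits: Dict[str, WindowSet]
    n_dropped: int = 0

    def __getitem__(self, split: str) -> WindowSet:
        return self.splits[split]


def make_training_set(genome: SyntheticGenome,
                      profiles: Dict[str, Dict[str, StrandedProfile]],
                      window: int = 1000,
                      split: Optional[Dict[str, str]] = None,
                      background_fraction: float = 0.1,
                      seed: int = 0) -> Dataset:
    """Disjoint train/val/test windows (by contig) with per-task count targets.

    Windows are centered on truth instances (the synthetic stand-in for
    peaks); background_fraction adds uniformly placed motif-free-ish windows.
    Windows extending past a contig are dropped with a logged count.
    """
    tasks = sorted(profiles)
    contigs = sorted(genome.contigs)
    if split is None:
        # default contig rotation: every third contig to val/test
        split = {}
        for i, c in enumerate(contigs):
            split[c] = ("test" if i % 4 == 3 else "val" if i % 4 == 2 else "train")
    missing = [c for c in contigs if c not in split]
    if missing:
        raise ValueError(f"split does not cover contigs: {missing}")
    rng = np.random.default_rng(seed)
    half = window // 2
    windows: Dict[str, List[Tuple[str, int]]] = {"train": [], "val": [], "test": []}
    n_dropped = 0
    for inst in genome.truth:
        mid = (inst.start + inst.end) // 2
        start = mid - half
        if start < 0 or start + window > len(genome.contigs[inst.contig]):
            n_dropped += 1
            continue
        windows[split[inst.contig]].append((inst.contig, start))
    n_background = int(round(background_fraction * len(genome.truth)))
    lengths = genome.contig_lengths()
    eligible = [c for c in contigs if lengths[c] >= window]
    for _ in range(n_background):
        if not eligible:
            break
        contig = eligible[int(rng.integers(len(eligible)))]
        start = int(rng.integers(0, lengths[contig] - window + 1))
        windows[split[contig]].append((contig, start))
    if n_dropped:
        log.warning("dropped %d windows extending past contig bounds", n_dropped)
    if all(len(v) == 0 for v in windows.values()):
        log.warning("no usable windows (window=%d too large for contigs?)", window)
    splits: Dict[str, WindowSet] = {}
    for name, coords in windows.items():
        coords = sorted(coords)
        X = np.zeros((len(coords), 4, window), dtype=np.float32)
        Y = {t: np.zeros((len(coords), 2, window), dtype=np.float32) for t in tasks}
        for i, (contig, start) in enumerate(coords):
            X[i] = one_hot(genome.fetch(contig, start, start + window))
            for t in tasks:
                prof = profiles[t][contig]
                Y[t][i, 0] = prof.plus[start:start + window]
                Y[t][i, 1] = prof.minus[start:start + window]
        splits[name] = WindowSet(X, Y, coords)
    return Dataset(window=window, tasks=tasks, splits=splits, n_dropped=n_dropped)
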