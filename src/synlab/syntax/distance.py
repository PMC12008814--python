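"""Distance-dependence of motif contributions: binned statistics and slope."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from ..attribution.contrib import ContributionMap
from ..core import MotifInstance

_EPS = 1e-9


def _edge_gap(a: MotifInstance, b: MotifInstance) -> float:
    if a.contig != b.contig:
        return float("inf")
    return float(max(a.start, b.start) - min(a.end, b.end))


def _contribution_of(inst: MotifInstance,
                     maps: Sequence[ContributionMap]) -> Optional[float]:
    if inst.total_contribution is not None:
        return float(inst.total_contribution)
    for cmap in maps:
        if cmap.contig == inst.contig and cmap.start <= inst.start and inst.end <= cmap.end:
            lo, hi = inst.start - cmap.start, inst.end - cmap.start
            return float(cmap.scores[lo:hi].sum())
    return None


def pair_table(instancesA: Sequence[MotifInstance], instancesB: Sequence[MotifInstance],
               maps: Sequence[ContributionMap]) -> pd.DataFrame:
    """Nearest-B-per-A pairs: edge gap and B's total contribution.

    Nearest partner = minimum edge gap, ties to the left.
    """
    rows = []
    for a in instancesA:
        best: Tuple[float, int, Optional[MotifInstance]] = (float("inf"), 0, None)
        for b in instancesB:
            d = _edge_gap(a, b)
            if d < best[0] or (d == best[0] and best[2] is not None
                               and b.start < best[2].start):
                best = (d, b.start, b)
        if best[2] is None or not np.isfinite(best[0]):
            continue
        contrib = _contribution_of(best[2], maps)
        if contrib is None:
            continue
        rows.append({"gap": best[0], "contribution": contrib,
                     "contig": a.contig, "a_start": a.start, "b_start": best[2].start})
    return pd.DataFrame(rows, columns=["gap", "contribution", "contig", "a_start", "b_start"])


def distance_contributions(instancesA: Sequence[MotifInstance],
                           instancesB: Sequence[MotifInstance],
                           maps: Sequence[ContributionMap],
                           bins: Sequence[float] = (0, 30, 60, 150),
                           baseline_min_gap: float = 150.0) -> pd.DataFrame:
    """Median log2 ratio of B's contribution vs baseline per distance bin.

    Baseline = contributions of B instances whose nearest A is farther than
    baseline_min_gap. Each bin row carries n, median_log2_ratio (NaN when the
    bin is empty) and a two-sided rank-sum p-value vs the baseline.
    """
    pairs = pair_table(instancesA, instancesB, maps)
    baseline_vals = []
    for b in instancesB:
        gaps = [_edge_gap(b, a) for a in instancesA]
        nearest = min(gaps) if gaps else float("inf")
        if nearest > baseline_min_gap:
            contrib = _contribution_of(b, maps)
            if contrib is not None:
                baseline_vals.append(contrib)
    if not baseline_vals:
        raise ValueError("empty baseline: enlarge the simulation or relax "
                         "baseline_min_gap")
    baseline = np.asarray(baseline_vals, dtype=float)
    base_med = float(np.median(baseline))
    edges = list(bins)
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = pairs[(pairs.gap >= lo) & (pairs.gap < hi)]
        if len(sel) == 0:
            rows.append({"bin_lo": lo, "bin_hi": hi, "n": 0,
                         "median_log2_ratio": np.nan, "p_value": np.nan})
            continue
        vals = sel.contribution.to_numpy(dtype=float)
        ratio = np.log2(np.maximum(vals, _EPS) / max(base_med, _EPS))
        if np.all(vals == base_med) and np.all(baseline == base_med):
            p = 1.0
        else:
            p = float(stats.mannwhitneyu(vals, baseline,
                                         alternative="two-sided").pvalue)
        rows.append({"bin_lo": lo, "bin_hi": hi, "n": len(sel),
                     "median_log2_ratio": float(np.median(ratio)), "p_value": p})
    return pd.DataFrame(rows)


@dataclass
class SlopeResult:
    slope_pct_per_10bp: float     # NaN when the percent form is unavailable
    slope: float                  # raw contribution units per bp
    intercept: float
    p_value: float
    n: int
    percent_form_valid: bool


def distance_slope(pairs: pd.DataFrame, max_gap: float = 150.0) -> SlopeResult:
    """OLS of contribution on edge gap; slope as percent of the zero-distance
    (intercept) level per 10 bp."""
    sel = pairs[pairs.gap <= max_gap]
    if len(sel) < 10:
        raise ValueError("need >= 10 pairs within max_gap")
    x = sel.gap.to_numpy(dtype=float)
    y = sel.contribution.to_numpy(dtype=float)
    if np.allclose(y, y[0]):
        return SlopeResult(0.0, 0.0, float(y[0]), 1.0, len(sel), True)
    fit = stats.linregress(x, y)
    valid = fit.intercept > 0
    pct = 100.0 * 10.0 * fit.slope / fit.intercept if valid else float("nan")
    return SlopeResult(pct, float(fit.slope), float(fit.intercept),
                       float(fit.pvalue), len(sel), bool(valid))
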