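"""Motif-variant frequency vs predicted-binding analysis."""

from __future__ import annotations

import warnings
from collections import Counter
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from ..insilico.inject import inject_predict


def variant_frequency_analysis(sequences: Sequence[str], predictor, task: str,
                               n_backgrounds: int = 256, seed: int = 0,
                               min_count: int = 10, percentile: float = 90.0,
                               percentile_mode: str = "top",
                               window: int = 50) -> pd.DataFrame:
    """Group identical instance sequences, filter by frequency, and predict
    binding of each surviving pattern injected into randomized backgrounds.

    Filters: count >= min_count AND (percentile_mode="top") count >= the
    `percentile`-th percentile of pattern counts; percentile_mode="above_low"
    instead requires count >= the (100 - percentile)-th percentile (the looser
    reading of "top 90th percentile").
    """
    counts = Counter(s.upper() for s in sequences)
    if not counts:
        warnings.warn("no input sequences: empty variant table")
        return pd.DataFrame(columns=["pattern", "frequency", "mean_prediction"])
    values = np.array(list(counts.values()), dtype=float)
    if percentile_mode == "top":
        cutoff = float(np.percentile(values, percentile))
    elif percentile_mode == "above_low":
        cutoff = float(np.percentile(values, 100.0 - percentile))
    else:
        raise ValueError("percentile_mode must be 'top' or 'above_low'")
    surviving = {p: c for p, c in counts.items() if c >= min_count and c >= cutoff}
    if not surviving:
        warnings.warn("no pattern survives the frequency filters")
        return pd.DataFrame(columns=["pattern", "frequency", "mean_prediction"])
    rows = []
    for i, (pattern, freq) in enumerate(sorted(surviving.items(),
                                               key=lambda kv: (-kv[1], kv[0]))):
        res = inject_predict(predictor, pattern, None, 0, task,
                             n_backgrounds=n_backgrounds, seed=seed + i,
                             window=window)
        rows.append({"pattern": pattern, "frequency": freq,
                     "mean_prediction": res.hA})
    return pd.DataFrame(rows)
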