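"""Scoring predicted bins against a known truth table.

Kept separate from the binning code on purpose: binning never sees origin
labels; accuracy is computed afterwards by the caller (tests, benchmarks)
from the simulator's truth table.
"""

from __future__ import annotations

from typing import Hashable, Mapping

import numpy as np
from scipy.optimize import linear_sum_assignment


def best_match_accuracy(
    predicted: Mapping[str, Hashable], truth: Mapping[str, Hashable]
) -> float:
    """Fraction of sequences correctly grouped, under the best bin<->origin match.

    Bin labels are arbitrary, so predicted bins are matched to true origins by
    maximum-agreement assignment (Hungarian algorithm on the contingency
    table); the accuracy is the matched count divided by the number of
    sequences. Both mappings must cover the same ids.
    """
    if set(predicted) != set(truth):
        raise ValueError("predicted and truth cover different sequence ids")
    ids = sorted(predicted)
    pred_levels = {p: i for i, p in enumerate(sorted({predicted[s] for s in ids}, key=str))}
    true_levels = {t: i for i, t in enumerate(sorted({truth[s] for s in ids}, key=str))}
    table = np.zeros((len(pred_levels), len(true_levels)), dtype=int)
    for s in ids:
        table[pred_levels[predicted[s]], true_levels[truth[s]]] += 1
    rows, cols = linear_sum_assignment(table, maximize=True)
    return float(table[rows, cols].sum() / len(ids))
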