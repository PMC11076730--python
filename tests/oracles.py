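"""Independent brute-force oracles used across the test suite."""

from fractions import Fraction
from math import comb

import numpy as np


def fisher_enumeration_oracle(a: int, b: int, c: int, d: int) -> float:
    """Exact two-sided Fisher p by full enumeration with rational arithmetic.

    Enumerates every 2x2 table with the observed margins, weights each by
    its (integer) hypergeometric weight and sums the weights not exceeding
    the observed table's weight.
    """
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    lo, hi = max(0, c1 - r2), min(r1, c1)
    weights = {k: comb(r1, k) * comb(r2, c1 - k) for k in range(lo, hi + 1)}
    total = comb(n, c1)
    p = sum(w for w in weights.values() if w <= weights[a])
    return float(Fraction(p, total))


def auc_pair_counting_oracle(case_scores, control_scores) -> float:
    """AUC by explicit loop over all (case, control) pairs, higher = case."""
    wins = ties = 0
    for x in case_scores:
        for y in control_scores:
            if x > y:
                wins += 1
            elif x == y:
                ties += 1
    return (wins + 0.5 * ties) / (len(case_scores) * len(control_scores))


def youden_scan_oracle(case_scores, control_scores):
    """Exhaustive Youden scan over a fine threshold grid, higher = case."""
    case = np.asarray(case_scores, dtype=float)
    control = np.asarray(control_scores, dtype=float)
    pooled = np.unique(np.concatenate([case, control]))
    grid = np.concatenate([[pooled[0] - 1], (pooled[:-1] + pooled[1:]) / 2,
                           [pooled[-1] + 1]]) if len(pooled) > 1 else \
        np.array([pooled[0] - 1, pooled[0] + 1])
    best = None
    for cut in grid:
        sens = float((case > cut).mean())
        spec = float((control <= cut).mean())
        j = sens + spec - 1
        if best is None or j > best[0] + 1e-12:
            best = (j, sens, spec)
    return best
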