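"""Independent brute-force oracles shared by the test modules."""

import math

import numpy as np


def enumerate_threshold(pwm, alpha, granularity):
    """Exhaustive 4^n threshold oracle.

    Enumerates every length-n sequence, discretizes its score by rounding the
    per-column log-odds to the granularity grid (the same convention the DP
    uses), finds the smallest grid score whose background tail is <= alpha,
    and returns the smallest real score among sequences reaching it.
    """
    n = pwm.length
    lo = pwm.log_odds
    r = np.rint(lo / granularity).astype(np.int64)
    grid_sums = np.zeros(1, dtype=np.int64)
    real_sums = np.zeros(1)
    probs = np.ones(1)
    for i in range(n):
        grid_sums = (grid_sums[:, None] + r[i][None, :]).ravel()
        real_sums = (real_sums[:, None] + lo[i][None, :]).ravel()
        probs = (probs[:, None] * pwm.background[None, :]).ravel()
    order = np.argsort(grid_sums)[::-1]
    tail = np.cumsum(probs[order])
    ok = tail <= alpha + 1e-15
    if not ok.any():
        return math.inf
    g = grid_sums[order][np.nonzero(ok)[0].max()]
    return float(real_sums[grid_sums >= g].min())
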