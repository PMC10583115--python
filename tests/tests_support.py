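"""Brute-force oracles shared by acceptance checks.

These deliberately use naive all-pairs / exhaustive-search formulations so
they stay independent of the implementations they verify.
"""

import numpy as np


def brute_force_auroc_oracle(scores, labels):
    scores, labels = np.asarray(scores, float), np.asarray(labels)
    pos, neg = scores[labels == 1], scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def brute_force_otsu_oracle(gray):
    g = np.asarray(gray).ravel().astype(float)
    n = g.size
    best_t, best_v = None, -1.0
    for t in range(1, 256):
        lo, hi = g[g < t], g[g >= t]
        if lo.size == 0 or hi.size == 0:
            continue
        v = (lo.size / n) * (hi.size / n) * (lo.mean() - hi.mean()) ** 2
        if v > best_v + 1e-12:
            best_v, best_t = v, t
    return best_t
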