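"""Independent brute-force oracles shared by the test modules."""

from itertools import combinations

import numpy as np


def oracle_mic(x, y, alpha=0.6, max_bins=4):
    """Exhaustive MIC over every grid up to max_bins x max_bins within B(n)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = len(x)
    budget = max(4.0, n ** alpha)
    xs, ys = np.unique(x), np.unique(y)
    xcuts = (xs[:-1] + xs[1:]) / 2
    ycuts = (ys[:-1] + ys[1:]) / 2
    best = 0.0
    for a in range(2, max_bins + 1):
        for b in range(2, max_bins + 1):
            if a * b > budget or a - 1 > len(xcuts) or b - 1 > len(ycuts):
                continue
            for xc in combinations(xcuts, a - 1):
                for yc in combinations(ycuts, b - 1):
                    xb = np.digitize(x, xc)
                    yb = np.digitize(y, yc)
                    counts = np.zeros((a, b))
                    np.add.at(counts, (xb, yb), 1)
                    p = counts / n
                    px = p.sum(1, keepdims=True)
                    py = p.sum(0, keepdims=True)
                    with np.errstate(divide="ignore", invalid="ignore"):
                        mi = np.nansum(p * np.log(p / (px * py)))
                    best = max(best, mi / np.log(min(a, b)))
    return best
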