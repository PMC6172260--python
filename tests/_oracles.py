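"""Independent brute-force oracles used by several test modules."""

import numpy as np


def exhaustive_maxima_oracle(smoothed, sep, margin, threshold):
    """O(N * sep^2) pixel scan for qualifying neighbourhood maxima with
    greedy brighter-first suppression; independent of the package's
    filter-based implementation."""
    h, w = smoothed.shape
    peaks = []
    for y in range(margin, h - margin):
        for x in range(margin, w - margin):
            v = smoothed[y, x]
            neigh = smoothed[max(0, y - sep):y + sep + 1,
                             max(0, x - sep):x + sep + 1]
            if v >= neigh.max() and v > neigh.min():
                peaks.append((y, x, v))
    peaks.sort(key=lambda p: (-p[2], p[0], p[1]))
    kept = []
    for y, x, v in peaks:
        if any(abs(y - ky) <= sep and abs(x - kx) <= sep for ky, kx, _ in kept):
            continue
        kept.append((y, x, v))
    return sorted((y, x) for y, x, v in kept if v >= threshold)
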