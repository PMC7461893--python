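"""Independent brute-force reference implementations used only by tests."""

import numpy as np


def naive_upgma(d):
    """O(n^3) UPGMA: recompute every pairwise cluster average at every step.

    Keeps explicit member lists and recomputes the mean inter-cluster
    distance from the original matrix for all active pairs each iteration.
    Tie-break: smallest (min label, max label). Returns (merges, heights
    implicit in merges) in the same label convention as the package.
    """
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    clusters = {i + 1: np.array([i]) for i in range(n)}
    merges = []
    for k in range(1, n):
        best = None
        for la in sorted(clusters):
            for lb in sorted(clusters):
                if la >= lb:
                    continue
                avg = float(d[np.ix_(clusters[la], clusters[lb])].mean())
                key = (avg, la, lb)
                if best is None or key < best:
                    best = key
        avg, la, lb = best
        merged = np.sort(np.concatenate([clusters[la], clusters[lb]]))
        del clusters[la], clusters[lb]
        clusters[n + k] = merged
        merges.append((la, lb, avg))
    return merges
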