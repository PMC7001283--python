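"""Independent brute-force oracles used by the test suite.

These are written with plain Python loops, directly from the defining
formulas, and deliberately share no code with the package implementation.
"""

from __future__ import annotations

import math

import numpy as np


def nsc_bruteforce(X, y, delta, x_new, priors=None, threshold=0.90):
    """Nearest-shrunken-centroid posteriors for one sample, by direct loops.

    Returns (posteriors dict, call, shrunken centroids dict).
    """
    X = [list(map(float, row)) for row in np.asarray(X)]
    y = list(y)
    classes = sorted(set(y))
    n = len(X)
    p = len(X[0])
    n_k = {c: sum(1 for lab in y if lab == c) for c in classes}

    overall = [sum(row[j] for row in X) / n for j in range(p)]
    cent = {c: [sum(row[j] for row, lab in zip(X, y) if lab == c) / n_k[c]
                for j in range(p)] for c in classes}

    pooled = []
    for j in range(p):
        ss = 0.0
        for row, lab in zip(X, y):
            ss += (row[j] - cent[lab][j]) ** 2
        pooled.append(math.sqrt(ss / (n - len(classes))))
    s0 = float(np.median(pooled))

    m = {c: math.sqrt(1.0 / n_k[c] - 1.0 / n) for c in classes}
    shrunken = {}
    for c in classes:
        vals = []
        for j in range(p):
            d = (cent[c][j] - overall[j]) / (m[c] * (pooled[j] + s0))
            d_p = math.copysign(max(abs(d) - delta, 0.0), d)
            vals.append(overall[j] + m[c] * (pooled[j] + s0) * d_p)
        shrunken[c] = vals

    if priors is None:
        priors = {c: n_k[c] / n for c in classes}
    disc = {}
    for c in classes:
        total = 0.0
        for j in range(p):
            total += (x_new[j] - shrunken[c][j]) ** 2 / (pooled[j] + s0) ** 2
        disc[c] = total - 2.0 * math.log(priors[c])

    dmin = min(disc.values())
    raw = {c: math.exp(-(disc[c] - dmin) / 2.0) for c in classes}
    z = sum(raw.values())
    post = {c: raw[c] / z for c in classes}

    best = max(classes, key=lambda c: post[c])
    call = best if post[best] >= threshold else "indeterminate"
    return post, call, shrunken


def upgma_merge_heights(points):
    """All merge heights of average-linkage clustering, by direct recursion.

    Clusters are frozensets of point indices; the distance between two
    clusters is the unweighted average of all pairwise Euclidean distances.
    """
    points = [np.asarray(p, float) for p in points]

    def dist(a, b):
        return float(np.sqrt(((a - b) ** 2).sum()))

    clusters = [frozenset([i]) for i in range(len(points))]
    heights = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                total = sum(dist(points[a], points[b])
                            for a in clusters[i] for b in clusters[j])
                d = total / (len(clusters[i]) * len(clusters[j]))
                if best is None or d < best[0]:
                    best = (d, i, j)
        d, i, j = best
        heights.append(d)
        merged = clusters[i] | clusters[j]
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
    return heights


def loocv_accuracy_bruteforce(X, y, delta):
    """Leave-one-out NSC accuracy by an independent double loop."""
    X = np.asarray(X, float)
    y = list(y)
    correct = 0
    for held in range(len(y)):
        keep = [i for i in range(len(y)) if i != held]
        X_fit = X[keep]
        y_fit = [y[i] for i in keep]
        post, _, _ = nsc_bruteforce(X_fit, y_fit, delta, X[held])
        pred = max(post, key=post.get)
        correct += int(pred == y[held])
    return correct / len(y)


def pair_spacing_search(log_doses, log_high):
    """Exhaustive search for the low/mid pair closest to even log thirds."""
    log_lo = min(log_doses)
    span = log_high - log_lo
    t1, t2 = log_lo + span / 3.0, log_lo + 2.0 * span / 3.0
    best = None
    for a in range(len(log_doses)):
        for b in range(len(log_doses)):
            if log_doses[a] >= log_doses[b]:
                continue
            cost = abs(log_doses[a] - t1) + abs(log_doses[b] - t2)
            key = (cost, log_doses[a], log_doses[b])
            if best is None or key < best[0]:
                best = (key, a, b)
    return best[1], best[2]
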