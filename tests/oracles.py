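"""Independent brute-force reference implementations used as test oracles.

Everything here is deliberately naive (set enumeration, explicit loops,
exhaustive search) and shares no code with the package internals.
"""

from __future__ import annotations

import itertools

import numpy as np


def jaccard_oracle(x, y) -> float:
    """1 - |X∩Y| / |X∪Y| by explicit set enumeration."""
    X = {i for i, v in enumerate(x) if v}
    Y = {i for i, v in enumerate(y) if v}
    return 1.0 - len(X & Y) / len(X | Y)


def sorensen_oracle(x, y) -> float:
    X = {i for i, v in enumerate(x) if v}
    Y = {i for i, v in enumerate(y) if v}
    return 1.0 - 2 * len(X & Y) / (len(X) + len(Y))


def upgma_cophenetic_oracle(D: np.ndarray) -> np.ndarray:
    """Exhaustive UPGMA: recompute all cross-pair means every step."""
    n = D.shape[0]
    clusters = [[i] for i in range(n)]
    coph = np.zeros((n, n))
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = float(np.mean([D[i, j] for i in clusters[a] for j in clusters[b]]))
                if best is None or d < best[0] - 1e-12:
                    best = (d, a, b)
        d, a, b = best
        for i in clusters[a]:
            for j in clusters[b]:
                coph[i, j] = coph[j, i] = d
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    return coph


def pearson_phi_oracle(p, g) -> float:
    """phi via the direct Pearson correlation formula over the pairs."""
    p = np.asarray(p, dtype=float)
    g = np.asarray(g, dtype=float)
    pm, gm = p - p.mean(), g - g.mean()
    return float((pm * gm).sum() / np.sqrt((pm**2).sum() * (gm**2).sum()))


def partitions_into_k(n: int, k: int):
    """All partitions of range(n) into exactly k non-empty blocks."""
    def rec(i, blocks):
        if i == n:
            if len(blocks) == k:
                yield [list(b) for b in blocks]
            return
        # prune: remaining items cannot fill the missing blocks
        if len(blocks) + (n - i) < k:
            return
        for b in blocks:
            b.append(i)
            yield from rec(i + 1, blocks)
            b.pop()
        if len(blocks) < k:
            blocks.append([i])
            yield from rec(i + 1, blocks)
            blocks.pop()

    yield from rec(0, [])


def best_kmeans_partition_oracle(X: np.ndarray, k: int):
    """Exhaustive search for the minimum within-cluster sum of squares."""
    X = np.asarray(X, dtype=float)
    best_inertia, best_blocks = np.inf, None
    for blocks in partitions_into_k(X.shape[0], k):
        inertia = 0.0
        for b in blocks:
            sub = X[b]
            inertia += float(((sub - sub.mean(axis=0)) ** 2).sum())
        if inertia < best_inertia - 1e-12:
            best_inertia, best_blocks = inertia, [sorted(b) for b in blocks]
    return best_inertia, best_blocks


def we_oracle(matrix_values, taxon_ids, ranges: dict) -> list:
    """Weighted endemism by explicit double loop."""
    n_taxa, n_units = matrix_values.shape
    out = []
    for j in range(n_units):
        total = 0.0
        for i in range(n_taxa):
            if matrix_values[i, j]:
                total += 1.0 / ranges[taxon_ids[i]]
        out.append(total)
    return out


def rand_index(labels_a, labels_b) -> float:
    a = list(labels_a)
    b = list(labels_b)
    n = len(a)
    agree = 0
    pairs = 0
    for i, j in itertools.combinations(range(n), 2):
        pairs += 1
        if (a[i] == a[j]) == (b[i] == b[j]):
            agree += 1
    return agree / pairs


def exact_max_phi_pvalue(presence, labels, combos_masks) -> float:
    """Exact permutation probability P(max-phi >= observed) over all
    arrangements of the presence vector."""
    p = np.asarray(presence, dtype=float)

    def stat(v):
        return max(pearson_phi_oracle(v, m) for m in combos_masks)

    obs = stat(p)
    count = 0
    total = 0
    for perm in itertools.permutations(p):
        total += 1
        if stat(np.asarray(perm)) >= obs - 1e-12:
            count += 1
    return count / total
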