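"""Independent brute-force oracles used across the test suite.

Each oracle computes its quantity from first principles (pair enumeration,
exhaustive partition search, exhaustive simple-path enumeration) and shares
no code path with the implementation it checks.
"""

from itertools import combinations, permutations

import numpy as np


def ari_pair_enumeration(a, b) -> float:
    """Hubert–Arabie ARI by enumerating all C(L,2) item pairs.

    Counts, over every unordered pair of positions, whether the two positions
    are co-labeled in a and in b, then applies the pair-count identity
    ARI = 2(AD - BC) / ((A+B)(B+D) + (A+C)(C+D)).
    """
    a = list(a)
    b = list(b)
    A = B = C = D = 0
    for i, j in combinations(range(len(a)), 2):
        same_a = a[i] == a[j]
        same_b = b[i] == b[j]
        if same_a and same_b:
            A += 1
        elif same_a and not same_b:
            B += 1
        elif not same_a and same_b:
            C += 1
        else:
            D += 1
    denom = (A + B) * (B + D) + (A + C) * (C + D)
    if denom == 0:
        # both labelings constant, or perfectly aligned trivial cases
        return 1.0 if a == b else 0.0
    return 2.0 * (A * D - B * C) / denom


def set_partitions(items):
    """Yield every partition of a list of items (Bell-number many)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for smaller in set_partitions(rest):
        for i in range(len(smaller)):
            yield smaller[:i] + [[first] + smaller[i]] + smaller[i + 1:]
        yield [[first]] + smaller


def modularity_direct(weights, labels) -> float:
    """Literal double-sum evaluation of Newman's Q."""
    weights = np.asarray(weights, dtype=float)
    labels = np.asarray(labels)
    two_m = weights.sum()
    if two_m == 0:
        return 0.0
    s = weights.sum(axis=1)
    q = 0.0
    n = len(labels)
    for i in range(n):
        for j in range(n):
            if labels[i] == labels[j]:
                q += weights[i, j] - s[i] * s[j] / two_m
    return q / two_m


def max_modularity_exhaustive(weights):
    """Maximum Q over every partition of the nodes, by exhaustive search."""
    n = len(weights)
    best_q, best_labels = -np.inf, None
    for partition in set_partitions(list(range(n))):
        labels = np.empty(n, dtype=int)
        for c, block in enumerate(partition):
            labels[list(block)] = c
        q = modularity_direct(weights, labels)
        if q > best_q:
            best_q, best_labels = q, labels
    return best_q, best_labels


def geodesics_exhaustive(weights):
    """All-pairs shortest paths by enumerating every simple path.

    Edge length is 1/weight. Returns (dist, paths) where dist[i][j] is the
    geodesic distance (inf if unreachable) and paths[i][j] the list of all
    geodesics (as node tuples) achieving it, within a 1e-12 tie tolerance.
    """
    weights = np.asarray(weights, dtype=float)
    n = len(weights)
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    paths = {(i, j): [] for i in range(n) for j in range(n)}

    def path_length(path):
        total = 0.0
        for u, v in zip(path, path[1:]):
            if weights[u, v] <= 0:
                return None
            total += 1.0 / weights[u, v]
        return total

    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            candidates = []
            others = [v for v in range(n) if v not in (i, j)]
            for r in range(len(others) + 1):
                for mid in permutations(others, r):
                    path = (i, *mid, j)
                    length = path_length(path)
                    if length is not None:
                        candidates.append((length, path))
            if candidates:
                best = min(length for length, _ in candidates)
                dist[i, j] = best
                paths[(i, j)] = [
                    p for length, p in candidates if length <= best + 1e-12
                ]
    return dist, paths


def betweenness_exhaustive(weights):
    """Freeman betweenness from the exhaustive geodesic enumeration."""
    n = len(weights)
    _, paths = geodesics_exhaustive(weights)
    bc = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            geos = paths[(s, t)]
            if not geos:
                continue
            for v in range(n):
                if v in (s, t):
                    continue
                through = sum(1 for p in geos if v in p)
                bc[v] += through / len(geos)
    return bc


def closeness_exhaustive(weights):
    """Wasserman–Faust closeness from the exhaustive distance matrix."""
    weights = np.asarray(weights, dtype=float)
    n = len(weights)
    dist, _ = geodesics_exhaustive(weights)
    cc = np.zeros(n)
    for i in range(n):
        reachable = [j for j in range(n) if j != i and np.isfinite(dist[i, j])]
        if not reachable:
            continue
        total = sum(dist[i, j] for j in reachable)
        r = len(reachable)
        cc[i] = (r / total) * (r / (n - 1))
    return cc
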