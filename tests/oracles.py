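"""Independent brute-force oracles the tests check the package against.

These deliberately share no code with the implementation: the UPGMA
oracle recomputes every cluster distance as a direct mean over leaf
pairs of the original matrix, and the alignment oracle is a plain
three-state dynamic program over dictionaries.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

NEG = float("-inf")


def brute_force_upgma(dist: pd.DataFrame):
    """Agglomerate by direct leaf-pair means.

    Returns (topology, heights) where topology is a nested frozenset
    structure and heights maps each merged cluster's leaf frozenset to
    its merge height.
    """
    labels = list(dist.index)
    clusters: list[frozenset[str]] = [frozenset([l]) for l in labels]
    shape: dict[frozenset[str], object] = {c: min(c) for c in clusters}
    heights: dict[frozenset[str], float] = {}

    def cdist(c1: frozenset[str], c2: frozenset[str]) -> float:
        vals = [dist.loc[a, b] for a in c1 for b in c2]
        return float(np.mean(vals))

    while len(clusters) > 1:
        best = None
        for c1, c2 in itertools.combinations(sorted(clusters, key=min), 2):
            key = (cdist(c1, c2), min(min(c1), min(c2)), max(min(c1), min(c2)))
            if best is None or key < best[0]:
                best = (key, c1, c2)
        (dij, _, _), c1, c2 = best
        merged = c1 | c2
        heights[merged] = dij / 2.0
        shape[merged] = frozenset({shape[c1], shape[c2]})
        clusters = [c for c in clusters if c not in (c1, c2)] + [merged]
    return shape[clusters[0]], heights


def tree_shape(tree) -> object:
    """The nested frozenset topology of a ClusterTree."""
    if tree.is_leaf:
        return tree.label
    return frozenset(tree_shape(c) for c in tree.children)


def tree_heights(tree) -> dict[frozenset, float]:
    out: dict[frozenset, float] = {}

    def walk(node):
        if node.is_leaf:
            return frozenset([node.label])
        leaves = frozenset()
        for c in node.children:
            leaves |= walk(c)
        out[leaves] = node.height
        return leaves

    walk(tree)
    return out


def sw_oracle(query: str, target: str, match=1, mismatch=-1, gap_open=2, gap_extend=1):
    """Plain-dictionary affine-gap Smith-Waterman; returns (score, identity).

    Gap of length k costs gap_open + k * gap_extend. Identity is
    matches / alignment columns over the traced optimal path (ties broken
    diagonal-first, matching a substitution-only interpretation).
    """
    n, m = len(query), len(target)
    H = {}
    E = {}
    F = {}
    for i in range(n + 1):
        for j in range(m + 1):
            if i == 0 or j == 0:
                H[i, j], E[i, j], F[i, j] = 0, NEG, NEG
                continue
            E[i, j] = max(H[i, j - 1] - gap_open - gap_extend, E[i, j - 1] - gap_extend)
            F[i, j] = max(H[i - 1, j] - gap_open - gap_extend, F[i - 1, j] - gap_extend)
            s = match if query[i - 1] == target[j - 1] else mismatch
            H[i, j] = max(0, H[i - 1, j - 1] + s, E[i, j], F[i, j])
    best = max(H.values())
    if best <= 0:
        return 0, None
    (bi, bj) = max((k for k, v in H.items() if v == best))
    i, j = bi, bj
    matches = cols = 0
    state = "H"
    while i > 0 and j > 0:
        if state == "H":
            if H[i, j] == 0:
                break
            s = match if query[i - 1] == target[j - 1] else mismatch
            if H[i, j] == H[i - 1, j - 1] + s:
                cols += 1
                matches += query[i - 1] == target[j - 1]
                i, j = i - 1, j - 1
            elif H[i, j] == E[i, j]:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            cols += 1
            if E[i, j] == H[i, j - 1] - gap_open - gap_extend:
                state = "H"
            j -= 1
        else:
            cols += 1
            if F[i, j] == H[i - 1, j] - gap_open - gap_extend:
                state = "H"
            i -= 1
    return best, 100.0 * matches / cols
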