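"""Cross-metagenome proportion-profile clustering.

Per-metagenome feature counts (CAZy families or COGs) are converted to
proportion profiles (rows sum to 1), pairwise row correlation (Spearman
with mid-rank tie correction, or Pearson) gives a similarity matrix,
distance is 1 - r, and UPGMA agglomeration yields an ultrametric rooted
tree emitted as newick. The nearest neighbor of a metagenome is its
sister leaf or cluster at its first merge.

UPGMA ties are broken by merging the pair whose representative leaf
labels are lexicographically smallest, so trees are deterministic.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger("hortus")

__all__ = [
    "ClusterTree",
    "build_profile_matrix",
    "correlation_similarity",
    "similarity_to_distance",
    "upgma",
    "cluster_metagenomes",
    "parse_newick",
]


def _fmt(x: float) -> str:
    s = f"{x:.10g}"
    if "." not in s and "e" not in s and "inf" not in s:
        s += ".0"
    return s


@dataclass
class ClusterTree:
    """A rooted (sub)tree with merge heights; leaves have height 0.

    Branch length to a child is ``height - child.height``, so every
    leaf-to-root path has the same length: the tree is ultrametric.
    """

    label: str | None = None
    height: float = 0.0
    children: list["ClusterTree"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            if not self.label:
                raise ValueError("unlabeled leaf")
            return [self.label]
        return [l for c in self.children for l in c.leaves()]

    def n_internal(self) -> int:
        return 0 if self.is_leaf else 1 + sum(c.n_internal() for c in self.children)

    def _newick(self) -> str:
        if self.is_leaf:
            if not self.label:
                raise ValueError("unlabeled leaf")
            return self.label
        parts = [
            f"{c._newick()}:{_fmt(self.height - c.height)}" for c in self.children
        ]
        return "(" + ",".join(parts) + ")"

    def to_newick(self) -> str:
        if len(self.leaves()) < 2:
            raise ValueError("newick output needs >= 2 leaves")
        return self._newick() + ";"

    def cophenetic(self) -> pd.DataFrame:
        """Leaf x leaf matrix of 2 x merge-height distances."""
        labels = sorted(self.leaves())
        d = pd.DataFrame(0.0, index=labels, columns=labels)

        def walk(node: ClusterTree) -> list[str]:
            if node.is_leaf:
                return [node.label]  # type: ignore[list-item]
            groups = [walk(c) for c in node.children]
            for ga, gb in itertools.combinations(groups, 2):
                for a in ga:
                    for b in gb:
                        d.loc[a, b] = d.loc[b, a] = 2.0 * node.height
            return [l for g in groups for l in g]

        walk(self)
        return d

    def find_parent_of_leaf(self, label: str) -> "ClusterTree | None":
        for c in self.children:
            if c.is_leaf and c.label == label:
                return self
            if not c.is_leaf and label in c.leaves():
                return c.find_parent_of_leaf(label)
        return None

    def sister_of(self, label: str) -> list[str]:
        """Leaves of the sibling cluster joined at ``label``'s first merge."""
        parent = self.find_parent_of_leaf(label)
        if parent is None:
            raise KeyError(label)
        out = []
        for c in parent.children:
            if c.is_leaf and c.label == label:
                continue
            out.extend(c.leaves())
        return sorted(out)


def parse_newick(text: str) -> ClusterTree:
    """Parse a newick string with branch lengths into a ClusterTree."""
    text = text.strip()
    if not text.endswith(";"):
        raise ValueError("newick string must end with ';'")
    pos = 0

    def parse_node() -> tuple[ClusterTree, float]:
        nonlocal pos
        if text[pos] == "(":
            pos += 1
            children: list[tuple[ClusterTree, float]] = [parse_node()]
            while text[pos] == ",":
                pos += 1
                children.append(parse_node())
            if text[pos] != ")":
                raise ValueError(f"expected ')' at position {pos}")
            pos += 1
        else:
            children = []
        start = pos
        while pos < len(text) and text[pos] not in ":,();":
            pos += 1
        label = text[start:pos] or None
        bl = 0.0
        if pos < len(text) and text[pos] == ":":
            pos += 1
            start = pos
            while pos < len(text) and text[pos] not in ",();":
                pos += 1
            bl = float(text[start:pos])
        if children:
            child_nodes = []
            height = 0.0
            for node, cbl in children:
                height = node.height + cbl  # equal for ultrametric input
                child_nodes.append(node)
            return ClusterTree(label=label, height=height, children=child_nodes), bl
        return ClusterTree(label=label, height=0.0), bl

    node, _ = parse_node()
    if text[pos] != ";":
        raise ValueError("trailing characters after newick tree")
    return node


# ---------------------------------------------------------------------------
# matrices


def build_profile_matrix(
    counts: Mapping[str, Mapping[str, float]],
) -> pd.DataFrame:
    """Metagenome x feature proportion matrix.

    Columns are the union of features over all metagenomes (absent
    features are 0); each row is divided by its total so rows sum to 1.
    A metagenome with zero annotated features is an error.
    """
    if not counts:
        raise ValueError("no metagenomes given")
    df = pd.DataFrame(counts).T.fillna(0.0)
    df = df.reindex(sorted(df.index), axis=0).reindex(sorted(df.columns), axis=1)
    totals = df.sum(axis=1)
    empty = totals[totals <= 0]
    if len(empty):
        raise ValueError(f"metagenome(s) with zero annotations: {list(empty.index)}")
    if (df.values < 0).any():
        raise ValueError("negative feature counts")
    return df.div(totals, axis=0)


def correlation_similarity(matrix: pd.DataFrame, method: str = "spearman") -> pd.DataFrame:
    """Pairwise row correlation (Spearman mid-ranks or Pearson)."""
    if method not in ("spearman", "pearson"):
        raise ValueError(f"unknown correlation method {method!r}")
    if matrix.shape[0] < 2 or matrix.shape[1] < 3:
        raise ValueError("need >= 2 metagenomes and >= 3 features")
    flat = matrix.std(axis=1)
    zero_var = flat[flat == 0]
    if len(zero_var):
        raise ValueError(
            f"zero-variance profile row(s): {list(zero_var.index)} — correlation undefined"
        )
    sim = matrix.T.corr(method=method)
    sim = (sim + sim.T) / 2.0
    np.fill_diagonal(sim.values, 1.0)
    return sim


def similarity_to_distance(sim: pd.DataFrame) -> pd.DataFrame:
    """d = 1 - r with an exactly zero diagonal.

    1 - r is not a metric in general; triangle-inequality violations are
    logged at debug level, not rejected.
    """
    d = 1.0 - sim
    np.fill_diagonal(d.values, 0.0)
    labels = list(d.index)
    for a, b, c in itertools.combinations(labels, 3):
        ab, bc, ac = d.loc[a, b], d.loc[b, c], d.loc[a, c]
        if ab > bc + ac + 1e-12 or bc > ab + ac + 1e-12 or ac > ab + bc + 1e-12:
            log.debug("triangle inequality violated for (%s, %s, %s)", a, b, c)
    return d


def upgma(dist: pd.DataFrame) -> ClusterTree:
    """Unweighted pair-group agglomeration with arithmetic mean.

    Repeatedly merges the closest pair of clusters at height d/2; the
    distance from a merged cluster to any other is the size-weighted
    average of its parts' distances (equivalently the mean over all
    leaf pairs). Ties are broken by the lexicographically smallest pair
    of representative labels.
    """
    if dist.shape[0] < 2:
        raise ValueError("UPGMA needs >= 2 items")
    if not np.allclose(dist.values, dist.values.T, atol=1e-12):
        raise ValueError("distance matrix is not symmetric")
    labels = list(dist.index)
    clusters: dict[str, tuple[ClusterTree, int]] = {
        l: (ClusterTree(label=l), 1) for l in labels
    }
    d: dict[frozenset[str], float] = {
        frozenset((a, b)): float(dist.loc[a, b])
        for a, b in itertools.combinations(labels, 2)
    }
    while len(clusters) > 1:
        reps = sorted(clusters)
        best = None
        for a, b in itertools.combinations(reps, 2):
            key = (d[frozenset((a, b))], a, b)
            if best is None or key < best:
                best = key
        dij, a, b = best  # type: ignore[misc]
        na, nb = clusters[a][1], clusters[b][1]
        node = ClusterTree(
            height=dij / 2.0, children=[clusters[a][0], clusters[b][0]]
        )
        for other in reps:
            if other in (a, b):
                continue
            da = d.pop(frozenset((a, other)))
            db_ = d.pop(frozenset((b, other)))
            # mean of equal values is that value: keeps ultrametric inputs
            # bit-exact through the agglomeration
            d[frozenset((a, other))] = da if da == db_ else (na * da + nb * db_) / (na + nb)
        d.pop(frozenset((a, b)))
        del clusters[b]
        clusters[a] = (node, na + nb)
    (root, _), = clusters.values()
    return root


def cluster_metagenomes(
    counts: Mapping[str, Mapping[str, float]],
    method: str = "spearman",
) -> tuple[ClusterTree, pd.DataFrame]:
    """Profile -> correlation -> 1-r distance -> UPGMA, plus a neighbor report.

    Returns the tree and a table of each metagenome's nearest neighbor
    (its sister leaf or cluster at its first merge).
    """
    if len(counts) < 3:
        raise ValueError("need >= 3 metagenomes to cluster")
    matrix = build_profile_matrix(counts)
    sim = correlation_similarity(matrix, method)
    tree = upgma(similarity_to_distance(sim))
    rows = [
        {"metagenome": m, "nearest_neighbor": ",".join(tree.sister_of(m))}
        for m in sorted(counts)
    ]
    return tree, pd.DataFrame(rows)
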