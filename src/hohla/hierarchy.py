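"""Sequence-similarity hierarchy over HLA alleles (HOH step 1).

Alleles are compared by normalized Hamming distance over aligned
mature-chain residues (missing residues excluded pairwise), organized into
an ultrametric tree by UPGMA (average linkage) agglomeration, and clusters
are read off the tree as smallest covering subtrees.  Ties between candidate
merges are broken lexicographically on the smallest leaf name so the tree is
deterministic for a given catalog.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .catalog import MISSING, AlleleCatalog, AlleleName, ResiduePosition, parse_allele_name

__all__ = [
    "DistanceMatrix",
    "TreeNode",
    "SimilarityTree",
    "Cluster",
    "pairwise_distances",
    "build_tree",
    "extract_cluster",
    "write_newick",
    "parse_newick",
]


@dataclass
class DistanceMatrix:
    """Symmetric allele-allele distances in [0, 1] with zero diagonal."""

    labels: list[AlleleName]
    d: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("distance matrix diagonal not zero")
        if np.any(self.d < 0) or np.any(self.d > 1):
            raise ValueError("distances must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        names = [a.canonical for a in self.labels]
        return pd.DataFrame(self.d, index=names, columns=names)

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="allele")


def pairwise_distances(
    catalog: AlleleCatalog,
    positions: Optional[Sequence[ResiduePosition]] = None,
    include_signal_peptide: bool = False,
) -> DistanceMatrix:
    """Normalized Hamming distance between every pair of catalog alleles.

    ``d(a, b)`` is the proportion of positions, among those non-missing in
    both alleles, at which the residues differ.  By default only mature-chain
    positions (β1..β237) enter; the signal peptide is excluded because the
    functional comparison concerns the expressed chain.

    Raises
    ------
    ValueError
        If fewer than two alleles, or a pair shares no non-missing position.
    """
    labels = sorted(catalog.names)
    if len(labels) < 2:
        raise ValueError("need at least two alleles")
    if positions is None:
        positions = (
            catalog.positions if include_signal_peptide else catalog.mature_positions()
        )
    idx = [catalog.position_index(p) for p in positions]
    mat = np.array(
        [[catalog.alleles[a][i] for i in idx] for a in labels], dtype="U1"
    )
    present = mat != MISSING
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = present[i] & present[j]
            m = int(both.sum())
            if m == 0:
                raise ValueError(
                    f"{labels[i].canonical} and {labels[j].canonical} share "
                    "no non-missing positions"
                )
            d[i, j] = d[j, i] = float((mat[i, both] != mat[j, both]).sum()) / m
    return DistanceMatrix(labels=labels, d=d)


@dataclass
class TreeNode:
    """Node of the merge tree; leaves carry an allele name, internals a height."""

    height: float = 0.0
    name: Optional[AlleleName] = None
    children: list["TreeNode"] = field(default_factory=list)
    #: branch length to the parent, fixed at construction/parse so Newick
    #: serialization round-trips byte-identically
    length: Optional[float] = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out: list[TreeNode] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_names(self) -> list[AlleleName]:
        return [lf.name for lf in self.leaves()]


@dataclass
class SimilarityTree:
    """Ultrametric UPGMA hierarchy over alleles."""

    root: TreeNode

    def leaf_names(self) -> list[AlleleName]:
        return self.root.leaf_names()

    def internal_heights(self) -> list[float]:
        out = []

        def rec(node: TreeNode) -> None:
            if not node.is_leaf:
                out.append(node.height)
                for c in node.children:
                    rec(c)

        rec(self.root)
        return out


@dataclass
class Cluster:
    """A labelled set of alleles occupying one subtree."""

    label: str
    members: frozenset[AlleleName]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("cluster must be nonempty")

    def __contains__(self, allele: AlleleName) -> bool:
        return allele in self.members

    def sorted_members(self) -> list[AlleleName]:
        return sorted(self.members)


def build_tree(dm: DistanceMatrix) -> SimilarityTree:
    """UPGMA (average-linkage) agglomeration of a distance matrix.

    Merge heights are half the average inter-cluster distance, so two leaves
    at distance *d* join at height *d*/2 and the result is ultrametric.
    When several candidate merges tie at the minimum distance, the pair whose
    smallest member name sorts first lexicographically (then its partner's)
    is merged, making the tree deterministic.
    """
    if not np.all(np.isfinite(dm.d)):
        raise ValueError("non-finite distances")
    nodes = [TreeNode(height=0.0, name=a) for a in dm.labels]
    sizes = [1] * len(nodes)
    # min canonical name per active cluster, for tie-breaking
    keys = [a.canonical for a in dm.labels]
    d = dm.d.astype(float).copy()
    active = list(range(len(nodes)))
    while len(active) > 1:
        best = None
        for ii, i in enumerate(active):
            for j in active[ii + 1:]:
                a, b = (i, j) if keys[i] <= keys[j] else (j, i)
                cand = (d[i, j], keys[a], keys[b], a, b)
                if best is None or cand[:3] < best[:3]:
                    best = cand
        dist, _, _, i, j = best
        parent = TreeNode(height=dist / 2.0, children=[nodes[i], nodes[j]])
        for child in parent.children:
            child.length = parent.height - child.height
        # average-linkage update of distances to the merged cluster (into i)
        for k in active:
            if k in (i, j):
                continue
            d[i, k] = d[k, i] = (
                sizes[i] * d[i, k] + sizes[j] * d[j, k]
            ) / (sizes[i] + sizes[j])
        nodes[i] = parent
        sizes[i] += sizes[j]
        keys[i] = min(keys[i], keys[j])
        active.remove(j)
    return SimilarityTree(root=nodes[active[0]])


def extract_cluster(
    tree: SimilarityTree,
    seed_alleles: Sequence[AlleleName],
    label: str = "cluster",
) -> Cluster:
    """Members of the smallest subtree containing every seed allele."""
    seeds = set(seed_alleles)
    if not seeds:
        raise ValueError("need at least one seed allele")
    leaves = set(tree.leaf_names())
    missing = seeds - leaves
    if missing:
        raise KeyError(
            "seed(s) not leaves of the tree: "
            + ", ".join(sorted(a.canonical for a in missing))
        )

    def smallest(node: TreeNode) -> Optional[TreeNode]:
        # returns the smallest subtree of `node` covering all seeds, if any
        here = set(node.leaf_names())
        if not seeds <= here:
            return None
        for c in node.children:
            sub = smallest(c)
            if sub is not None:
                return sub
        return node

    covering = smallest(tree.root)
    assert covering is not None
    return Cluster(label=label, members=frozenset(covering.leaf_names()))


def _quote_label(label: str) -> str:
    # allele names contain ':' and '*', both special in Newick
    if any(c in label for c in ":,();' \t"):
        return "'" + label.replace("'", "''") + "'"
    return label


def _newick_node(node: TreeNode, parent_height: float) -> str:
    length = node.length if node.length is not None else parent_height - node.height
    length = float(length)  # repr of a Python float is shortest-exact
    if node.is_leaf:
        return f"{_quote_label(node.name.canonical)}:{length!r}"
    inner = ",".join(_newick_node(c, node.height) for c in node.children)
    return f"({inner}):{length!r}"


def to_newick(tree: SimilarityTree) -> str:
    """Newick string with branch lengths equal to height differences.

    Leaf labels are single-quoted because allele names contain ``:``.
    """
    root = tree.root
    if root.is_leaf:
        return f"{_quote_label(root.name.canonical)};"
    inner = ",".join(_newick_node(c, root.height) for c in root.children)
    return f"({inner});"


def write_newick(tree: SimilarityTree, path: str | Path) -> None:
    Path(path).write_text(to_newick(tree) + "\n")


def parse_newick(text: str) -> SimilarityTree:
    """Parse the Newick dialect produced by :func:`to_newick`.

    Heights are recovered from branch lengths assuming an ultrametric tree
    (leaves at height 0), so a write→parse→write round trip is the identity.
    """
    text = text.strip().rstrip(";").strip()
    pos = 0

    def parse_node() -> tuple[TreeNode, float]:
        # returns (node, branch length to parent)
        nonlocal pos
        if text[pos] == "(":
            pos += 1
            children: list[tuple[TreeNode, float]] = [parse_node()]
            while text[pos] == ",":
                pos += 1
                children.append(parse_node())
            if text[pos] != ")":
                raise ValueError(f"expected ')' at offset {pos}")
            pos += 1
            node = TreeNode(children=[c for c, _ in children])
            # child heights + branch lengths must agree; take the max for safety
            node.height = max(c.height + bl for c, bl in children)
        elif text[pos] == "'":
            pos += 1
            chars: list[str] = []
            while True:
                if text[pos] == "'":
                    if pos + 1 < len(text) and text[pos + 1] == "'":
                        chars.append("'")
                        pos += 2
                    else:
                        pos += 1
                        break
                else:
                    chars.append(text[pos])
                    pos += 1
            node = TreeNode(height=0.0, name=parse_allele_name("".join(chars)))
        else:
            start = pos
            while pos < len(text) and text[pos] not in ":,()":
                pos += 1
            node = TreeNode(height=0.0, name=parse_allele_name(text[start:pos]))
        length = 0.0
        if pos < len(text) and text[pos] == ":":
            pos += 1
            start = pos
            while pos < len(text) and text[pos] not in ",()":
                pos += 1
            length = float(text[start:pos])
            node.length = length
        return node, length

    node, _ = parse_node()
    if pos != len(text):
        raise ValueError("trailing characters in Newick input")
    return SimilarityTree(root=node)


def is_ultrametric(tree: SimilarityTree, tol: float = 1e-9) -> bool:
    """Check heights are nonincreasing from root to leaves."""

    def rec(node: TreeNode, parent_height: float) -> bool:
        if node.height > parent_height + tol:
            return False
        return all(rec(c, node.height) for c in node.children)

    return rec(tree.root, math.inf)
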