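"""Mutation-annotated reconstructed phylogenetic trees.

A :class:`ReconTree` is the observable of the inference problem: a rooted
binary tree whose branches carry non-negative *integer* mutation counts.
Branch durations in calendar time and the hidden divisions along branches are
latent; the simulator can attach them as ground-truth annotations.

The root is the most recent common ancestor of the sampled cells and carries
no stem branch: only its two child branches (and everything below) enter the
likelihood.
"""

from __future__ import annotations

import logging
from typing import Iterator, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["ReconTree"]


class ReconTree:
    """Rooted tree with an integer mutation count on every non-root branch.

    Node 0 is the root.  ``parent[v]`` is the parent index (-1 for the root)
    and ``mutations[v]`` the number of mutations on the branch from
    ``parent[v]`` to ``v`` (unused for the root).

    Optional per-branch truth annotations from the simulator:
    ``durations[v]`` (calendar length ``tau_s - tau_e``) and
    ``hidden_births[v]`` (number of divisions strictly inside the branch
    whose other daughter left no sampled descendant).
    """

    def __init__(
        self,
        parent: Sequence[int],
        mutations: Sequence[int],
        labels: Sequence[str] | None = None,
        durations: Sequence[float] | None = None,
        hidden_births: Sequence[int] | None = None,
    ):
        self.parent = np.asarray(parent, dtype=np.int64)
        self.mutations = np.asarray(mutations, dtype=np.int64)
        n = len(self.parent)
        if len(self.mutations) != n:
            raise ValueError("parent and mutations must have equal length")
        if n < 3:
            raise ValueError("a tree needs a root and at least two leaves")
        if self.parent[0] != -1 or np.any(self.parent[1:] < 0):
            raise ValueError("node 0 must be the unique root (parent == -1)")
        if np.any(self.mutations[1:] < 0):
            raise ValueError("mutation counts must be non-negative integers")
        self.children: list[list[int]] = [[] for _ in range(n)]
        for v in range(1, n):
            p = int(self.parent[v])
            if p >= v:
                raise ValueError("parents must precede children (topological order)")
            self.children[p].append(v)
        self.labels = list(labels) if labels is not None else [""] * n
        self.durations = None if durations is None else np.asarray(durations, float)
        self.hidden_births = (
            None if hidden_births is None else np.asarray(hidden_births, np.int64)
        )

    # -- basic structure ---------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    def is_leaf(self, v: int) -> bool:
        return not self.children[v]

    @property
    def leaves(self) -> list[int]:
        return [v for v in range(self.n_nodes) if not self.children[v]]

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    def is_binary(self) -> bool:
        return all(len(c) in (0, 2) for c in self.children)

    def postorder(self) -> Iterator[int]:
        """Children before parents (reverse topological index order)."""
        return iter(range(self.n_nodes - 1, -1, -1))

    def root_distances(self) -> np.ndarray:
        """Mutation distance from the root to every node."""
        d = np.zeros(self.n_nodes, dtype=np.int64)
        for v in range(1, self.n_nodes):
            d[v] = d[self.parent[v]] + self.mutations[v]
        return d

    def leaf_counts(self) -> np.ndarray:
        """Number of leaves below (and including) every node."""
        c = np.zeros(self.n_nodes, dtype=np.int64)
        for v in self.postorder():
            if not self.children[v]:
                c[v] = 1
            else:
                c[v] = sum(c[w] for w in self.children[v])
        return c

    # -- editing -----------------------------------------------------------

    def resolve_polytomies(self) -> "ReconTree":
        """Return a binary tree, resolving k>2-furcations caterpillar-style.

        Simultaneous divisions have probability zero in continuous time, so a
        polytomy stands for consecutive divisions not separated by mutations:
        zero-mutation internal branches are inserted, keeping input order.
        """
        if self.is_binary():
            return self
        parent = [-1]
        mutations = [0]
        labels = [self.labels[0]]
        mapping = {0: 0}

        def add(p_new: int, m: int, label: str) -> int:
            parent.append(p_new)
            mutations.append(m)
            labels.append(label)
            return len(parent) - 1

        # BFS so parents are created before children
        queue = [0]
        while queue:
            v = queue.pop(0)
            kids = self.children[v]
            attach = mapping[v]
            if len(kids) > 2:
                logger.info(
                    "resolving %d-furcation at node %d caterpillar-style", len(kids), v
                )
            while len(kids) > 2:
                first, rest = kids[0], kids[1:]
                mapping[first] = add(attach, int(self.mutations[first]), self.labels[first])
                queue.append(first)
                attach = add(attach, 0, "")  # zero-mutation resolution branch
                kids = rest
            for w in kids:
                mapping[w] = add(attach, int(self.mutations[w]), self.labels[w])
                queue.append(w)
        return ReconTree(parent, mutations, labels)

    def subtree(self, v: int) -> "ReconTree":
        """Clade rooted at node ``v`` as an independent tree (stem dropped)."""
        if self.is_leaf(v):
            raise ValueError("cannot take the clade of a leaf")
        order = [v]
        i = 0
        while i < len(order):
            order.extend(self.children[order[i]])
            i += 1
        mapping = {w: k for k, w in enumerate(order)}
        parent = [-1] + [mapping[int(self.parent[w])] for w in order[1:]]
        mutations = [0] + [int(self.mutations[w]) for w in order[1:]]
        labels = [self.labels[w] for w in order]
        return ReconTree(parent, mutations, labels)

    # -- serialization -----------------------------------------------------

    def to_newick(self) -> str:
        """Newick string; branch length field = integer mutation count."""

        def fmt(v: int) -> str:
            if not self.children[v]:
                body = self.labels[v] or f"n{v}"
            else:
                body = "(" + ",".join(fmt(w) for w in self.children[v]) + ")"
                if self.labels[v]:
                    body += self.labels[v]
            if v == 0:
                return body
            return f"{body}:{int(self.mutations[v])}"

        return fmt(0) + ";"

    @classmethod
    def from_newick(cls, newick: str, rounding_warning: bool = True) -> "ReconTree":
        """Parse a Newick string with mutation counts in the length field."""
        import dendropy

        dtree = dendropy.Tree.get(
            data=newick, schema="newick", suppress_internal_node_taxa=False
        )
        return cls.from_dendropy(dtree, rounding_warning=rounding_warning)

    @classmethod
    def from_dendropy(cls, dtree, rounding_warning: bool = True) -> "ReconTree":
        parent: list[int] = []
        mutations: list[int] = []
        labels: list[str] = []
        index = {}
        for node in dtree.preorder_node_iter():
            idx = len(parent)
            index[node] = idx
            parent.append(-1 if node.parent_node is None else index[node.parent_node])
            length = node.edge.length
            if node.parent_node is None or length is None:
                m = 0
            else:
                if length < 0:
                    raise ValueError(f"negative branch length {length!r}")
                m = int(round(length))
                if rounding_warning and abs(length - m) > 1e-9:
                    logger.warning(
                        "non-integer branch length %r rounded to %d", length, m
                    )
            mutations.append(m)
            label = ""
            if node.taxon is not None and node.taxon.label:
                label = node.taxon.label
            elif getattr(node, "label", None):
                label = node.label
            labels.append(label)
        tree = cls(parent, mutations, labels)
        if not tree.is_binary():
            tree = tree.resolve_polytomies()
        return tree

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"ReconTree(n_leaves={self.n_leaves}, n_nodes={self.n_nodes}, "
            f"total_mutations={int(self.mutations[1:].sum())})"
        )
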