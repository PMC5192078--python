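"""Rooted bifurcating phylogenies with stable branch identities.

Trees are parsed from Newick (via dendropy) into a lightweight node
structure in which every non-root node owns the branch leading to it from
its parent; branch ids therefore equal child-node ids.  Internal nodes get
deterministic ids assigned in post-order, so repeated runs on the same
input name the same branches — a requirement for reproducible posterior
tables and for the branch mapping produced by pruning.

Pruning a tree to a taxon subset collapses chains of unary nodes; the
:class:`BranchMapping` records, for every surviving branch, the ordered
root-ward chain of original branches it absorbs.  Gain/loss posteriors
computed on the full tree can then be transferred to the pruned tree by
combining probabilities along each chain (see :mod:`traitpred.events`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import dendropy

__all__ = ["Node", "Phylogeny", "BranchMapping", "prune_to_labeled"]


@dataclass
class Node:
    id: str
    length: float = 0.0  # branch length from parent; 0 for the root
    children: list["Node"] = field(default_factory=list)
    parent: "Node | None" = None

    @property
    def is_leaf(self) -> bool:
        return not self.children


class Phylogeny:
    """A rooted bifurcating tree with branch lengths and unique leaf labels."""

    def __init__(self, root: Node):
        self.root = root
        labels = [n.id for n in self.leaves()]
        if len(set(labels)) != len(labels):
            raise ValueError("leaf labels must be unique")
        for node in self.postorder():
            if node.children and len(node.children) != 2:
                raise ValueError(
                    f"tree must be bifurcating; node {node.id!r} has {len(node.children)} children"
                )

    # -- construction -------------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        """Parse a rooted Newick string; internal nodes without labels get
        deterministic post-order ids ``N1, N2, ...``."""
        try:
            dtree = dendropy.Tree.get(data=newick, schema="newick", rooting="force-rooted")
        except Exception as exc:  # dendropy raises its own hierarchy
            if "Duplicate taxon" in str(exc) or "Multiple occurrences" in str(exc):
                raise ValueError("leaf labels must be unique") from exc
            raise
        counter = 0

        def convert(dnode) -> Node:
            nonlocal counter
            children = [convert(c) for c in dnode.child_nodes()]
            if dnode.is_leaf():
                label = dnode.taxon.label if dnode.taxon else dnode.label
                if label is None:
                    raise ValueError("leaf without label")
                node = Node(id=str(label).replace(" ", "_"))
            else:
                counter += 1
                node = Node(id=dnode.label or f"N{counter}")
            node.length = float(dnode.edge.length) if dnode.edge.length is not None else 0.0
            node.children = children
            for c in children:
                c.parent = node
            return node

        return cls(convert(dtree.seed_node))

    def to_newick(self) -> str:
        def fmt(node: Node) -> str:
            if node.is_leaf:
                core = node.id
            else:
                core = "(" + ",".join(fmt(c) for c in node.children) + ")" + node.id
            if node.parent is None:
                return core
            return f"{core}:{node.length:.10g}"

        return fmt(self.root) + ";"

    # -- traversal ----------------------------------------------------------

    def postorder(self) -> Iterator[Node]:
        def walk(node: Node) -> Iterator[Node]:
            for c in node.children:
                yield from walk(c)
            yield node

        return walk(self.root)

    def preorder(self) -> Iterator[Node]:
        def walk(node: Node) -> Iterator[Node]:
            yield node
            for c in node.children:
                yield from walk(c)

        return walk(self.root)

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_labels(self) -> list[str]:
        return [n.id for n in self.leaves()]

    def nodes_by_id(self) -> dict[str, Node]:
        return {n.id: n for n in self.postorder()}

    def branch_ids(self) -> list[str]:
        """Ids of all branches (every node except the root), post-order."""
        return [n.id for n in self.postorder() if n.parent is not None]

    def n_leaves(self) -> int:
        return len(self.leaves())

    def copy(self) -> "Phylogeny":
        def dup(node: Node) -> Node:
            new = Node(id=node.id, length=node.length)
            new.children = [dup(c) for c in node.children]
            for c in new.children:
                c.parent = new
            return new

        return Phylogeny(dup(self.root))


@dataclass
class BranchMapping:
    """Maps pruned-tree branches back to the original branches they absorb.

    ``chains[b']`` is the ordered (root-ward first) list of original branch
    ids collapsed into pruned branch ``b'``.  Original branches that vanish
    with a pruned subtree appear in no chain.
    """

    chains: dict[str, list[str]]

    def source_branches(self) -> set[str]:
        return {b for chain in self.chains.values() for b in chain}


def prune_to_labeled(tree: Phylogeny, labeled_taxa: Sequence[str] | set[str]):
    """Restrict a tree to the given leaves, collapsing unary nodes.

    Returns ``(pruned_tree, mapping)``.  The pruned tree is the induced
    subtree on ``labeled_taxa``; each surviving branch's length is the sum
    over its absorbed chain, and the mapping records which original
    branches were merged (the basis for combining per-branch gain/loss
    posteriors).  At least 3 retained leaves are required for a
    non-degenerate bifurcating tree.
    """
    labeled = set(labeled_taxa)
    leaf_set = set(tree.leaf_labels())
    unknown = sorted(labeled - leaf_set)
    if unknown:
        raise ValueError(f"labeled taxa absent from tree: {unknown}")
    if len(labeled) < 3:
        raise ValueError(f"need >= 3 labeled taxa, got {len(labeled)}")

    chains: dict[str, list[str]] = {}

    def build(node: Node) -> tuple[Node, list[str], float] | None:
        """Return (pruned subtree root, rootward branch chain, summed length)."""
        if node.is_leaf:
            if node.id not in labeled:
                return None
            return Node(id=node.id), [node.id], node.length
        kept = [r for r in (build(c) for c in node.children) if r is not None]
        if not kept:
            return None
        if len(kept) == 1:
            sub, chain, length = kept[0]
            if node.parent is None:
                # old root became unary: the surviving child is the new root
                # and its accumulated chain has no counterpart branch
                return sub, [], 0.0
            return sub, [node.id] + chain, node.length + length
        new = Node(id=node.id)
        for sub, chain, length in kept:
            sub.parent = new
            sub.length = length
            chains[sub.id] = chain
            new.children.append(sub)
        return new, [node.id], node.length

    result = build(tree.root)
    assert result is not None  # |labeled| >= 3 guarantees survivors
    root, _, _ = result
    root.parent = None
    root.length = 0.0
    return Phylogeny(root), BranchMapping(chains=chains)
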