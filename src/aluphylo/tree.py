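"""Minimal rooted binary trees used by the simulator and the parsimony engine.

A deliberately small, dependency-free node type: parsimony scoring visits
every node of thousands of candidate topologies, so the container has to be
cheap to build, copy and hash.  Newick parsing of user input goes through
dendropy; this module only needs to hold the result.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

import dendropy


@dataclass
class Clade:
    """A rooted (sub)tree node.  Leaves have a name and no children."""

    name: Optional[str] = None
    length: float = 0.0
    children: list["Clade"] = field(default_factory=list)

    # -- topology queries ---------------------------------------------------
    @property
    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self) -> Iterator["Clade"]:
        stack, out = [self], []
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def leaves(self) -> list["Clade"]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def edges(self) -> Iterator[tuple["Clade", "Clade"]]:
        """Yield (parent, child) pairs."""
        for node in self.postorder():
            for child in node.children:
                yield node, child

    def total_branch_length(self) -> float:
        return sum(child.length for _, child in self.edges())

    def copy(self) -> "Clade":
        return Clade(
            self.name, self.length, [c.copy() for c in self.children]
        )

    # -- canonical forms ----------------------------------------------------
    def canonical(self):
        """Hashable topology key, invariant under child ordering."""
        if self.is_leaf:
            return self.name
        return tuple(sorted((c.canonical() for c in self.children), key=repr))

    def clades(self) -> list[frozenset]:
        """Leaf sets of every internal (non-root, non-leaf) node."""
        out = []
        root = self
        for node in self.postorder():
            if node.is_leaf or node is root:
                continue
            out.append(frozenset(node.leaf_names()))
        return out

    # -- serialisation ------------------------------------------------------
    def newick(self, lengths: bool = True, labels: dict | None = None) -> str:
        def fmt(node: Clade) -> str:
            if node.is_leaf:
                body = node.name
            else:
                inner = ",".join(fmt(c) for c in sorted_children(node))
                lab = ""
                if labels is not None:
                    key = frozenset(node.leaf_names())
                    if key in labels:
                        lab = str(labels[key])
                body = f"({inner}){lab}"
            if lengths:
                body += f":{node.length:g}"
            return body

        def sorted_children(node: Clade) -> list[Clade]:
            return sorted(node.children, key=lambda c: min(c.leaf_names()))

        return fmt(self) + ";"

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Clade({self.newick(lengths=False)})"


def from_dendropy(tree: dendropy.Tree) -> Clade:
    def convert(node) -> Clade:
        name = node.taxon.label if node.taxon is not None else None
        length = node.edge.length if node.edge.length is not None else 0.0
        return Clade(name, float(length), [convert(c) for c in node.child_nodes()])

    return convert(tree.seed_node)


def parse_newick(text: str) -> Clade:
    tree = dendropy.Tree.get(data=text, schema="newick", preserve_underscores=True)
    return from_dendropy(tree)


def to_dendropy(clade: Clade, taxon_namespace=None) -> dendropy.Tree:
    return dendropy.Tree.get(
        data=clade.newick(),
        schema="newick",
        preserve_underscores=True,
        taxon_namespace=taxon_namespace,
    )


def mrca_map(root: Clade) -> dict[frozenset, Clade]:
    """Map each internal node's leaf set to the node (for clade lookups)."""
    return {frozenset(n.leaf_names()): n for n in root.postorder() if not n.is_leaf}
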