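"""Species-tree wrapper used for Dollo placement and clade simulation.

Branches are identified by the clade below them: a branch's label is the
internal node's own newick label when present, otherwise the sorted leaf
names of its clade joined with ``+`` (a terminal branch is labelled by its
leaf). This makes branch assignments comparable between the simulator's
truth table and the comparative module without relying on node object
identity.
"""

from __future__ import annotations

import dendropy


class TreeError(ValueError):
    pass


class SpeciesTree:
    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        tree.is_rooted = True
        labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
        if len(labels) != len(set(labels)):
            raise TreeError("duplicate leaf labels in tree")
        self._leaves = labels

    # ---- construction ------------------------------------------------------

    @classmethod
    def from_string(cls, newick: str) -> "SpeciesTree":
        try:
            tree = dendropy.Tree.get(data=newick, schema="newick",
                                     suppress_internal_node_taxa=True)
        except Exception as exc:  # dendropy raises several parse error types
            raise TreeError(f"invalid newick: {exc}") from exc
        return cls(tree)

    @classmethod
    def from_file(cls, path) -> "SpeciesTree":
        with open(path) as fh:
            return cls.from_string(fh.read())

    def as_newick(self) -> str:
        return self._tree.as_string(schema="newick").strip()

    # ---- queries -----------------------------------------------------------

    @property
    def leaves(self) -> list:
        return list(self._leaves)

    @property
    def root(self):
        return self._tree.seed_node

    def clade_leaves(self, node) -> list:
        return sorted(lf.taxon.label for lf in node.leaf_iter())

    def branch_label(self, node) -> str:
        if node.is_leaf():
            return node.taxon.label
        if node.label:
            return node.label
        return "+".join(self.clade_leaves(node))

    def node_for_branch(self, label: str):
        """Node whose subtending branch carries ``label``."""
        want = set(label.split("+"))
        for node in self._tree.preorder_node_iter():
            if self.branch_label(node) == label:
                return node
            if not node.is_leaf() and set(self.clade_leaves(node)) == want:
                return node
        raise TreeError(f"no branch labelled {label!r} in tree")

    def mrca(self, labels):
        labels = list(labels)
        missing = set(labels) - set(self._leaves)
        if missing:
            raise TreeError(f"species not in tree: {sorted(missing)}")
        if not labels:
            raise TreeError("MRCA of an empty species set")
        if len(labels) == 1:
            for lf in self._tree.leaf_node_iter():
                if lf.taxon.label == labels[0]:
                    return lf
        return self._tree.mrca(taxon_labels=labels)

    def preorder_edges(self):
        """Yield (parent_node, child_node, edge_length) from the root down."""
        for node in self._tree.preorder_node_iter():
            if node.parent_node is not None:
                length = node.edge.length if node.edge.length is not None else 1.0
                yield node.parent_node, node, float(length)

    def path_length(self, a: str, b: str) -> float:
        """Patristic distance between two leaves (unit lengths where absent)."""
        anc = self.mrca([a, b])
        total = 0.0
        for leaf in (a, b):
            node = self.mrca([leaf])
            while node is not anc:
                total += node.edge.length if node.edge.length is not None else 1.0
                node = node.parent_node
        return total
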