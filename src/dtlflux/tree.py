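"""Rooted species tree container used throughout the pipeline.

The tree is the coordinate system of every ancestral quantity: branch
event tallies, ancestral gene-content states and pathway-completeness
trajectories are all indexed by its node ids.  Nodes are stored in
preorder; the edge "above" a node is identified with the node itself,
so a branch id is simply a node id (the root has no branch).
"""

from __future__ import annotations

import io as _io
import warnings
from dataclasses import dataclass, field
from typing import Iterator, Optional

import dendropy

__all__ = ["TreeNode", "SpeciesTree", "UnsupportedTopologyError"]


class UnsupportedTopologyError(ValueError):
    """Raised for unrooted or multifurcating input topologies."""


@dataclass
class TreeNode:
    """One node of a rooted species tree.

    ``length`` is the length of the edge connecting the node to its
    parent, in arbitrary time units; the root's length is 0 by
    convention.  ``clade`` is an optional lineage label shared by all
    nodes of a labelled clade (stem branch included).
    """

    id: str
    parent: Optional[str]
    length: float
    is_tip: bool
    clade: Optional[str] = None
    children: list[str] = field(default_factory=list)


class SpeciesTree:
    """A rooted, binary, branch-length-bearing species tree.

    Invariants enforced at construction: exactly one root, unique node
    ids, unique tip labels, binary internal nodes, branch lengths >= 0.
    """

    def __init__(self, nodes: list[TreeNode]):
        if not nodes:
            raise ValueError("tree must have at least one node")
        self._nodes: dict[str, TreeNode] = {}
        roots = []
        for node in nodes:
            if node.id in self._nodes:
                raise ValueError(f"duplicate node id {node.id!r}")
            if node.length < 0:
                raise ValueError(f"negative branch length at {node.id!r}")
            self._nodes[node.id] = node
            if node.parent is None:
                roots.append(node.id)
        if len(roots) != 1:
            raise ValueError(f"expected exactly one root, found {len(roots)}")
        self._root = roots[0]
        for node in nodes:
            node.children = []
        for node in nodes:
            if node.parent is not None:
                if node.parent not in self._nodes:
                    raise ValueError(f"unknown parent {node.parent!r} of {node.id!r}")
                self._nodes[node.parent].children.append(node.id)
        for node in nodes:
            n_children = len(node.children)
            if node.is_tip and n_children:
                raise ValueError(f"tip {node.id!r} has children")
            if not node.is_tip and n_children != 2:
                raise UnsupportedTopologyError(
                    f"internal node {node.id!r} has {n_children} children; "
                    "only rooted binary trees are supported"
                )
        self._preorder: list[str] = []
        stack = [self._root]
        while stack:
            nid = stack.pop()
            self._preorder.append(nid)
            stack.extend(reversed(self._nodes[nid].children))
        # depth of each node measured from the root (root time 0)
        self._time: dict[str, float] = {}
        for nid in self._preorder:
            node = self._nodes[nid]
            base = 0.0 if node.parent is None else self._time[node.parent]
            self._time[nid] = base + (0.0 if node.parent is None else node.length)

    # -- basic accessors -------------------------------------------------
    @property
    def root(self) -> str:
        return self._root

    @property
    def tips(self) -> list[str]:
        return [n for n in self._preorder if self._nodes[n].is_tip]

    @property
    def n_tips(self) -> int:
        return len(self.tips)

    def __contains__(self, node_id: str) -> bool:
        return node_id in self._nodes

    def __len__(self) -> int:
        return len(self._nodes)

    def node(self, node_id: str) -> TreeNode:
        return self._nodes[node_id]

    def parent(self, node_id: str) -> Optional[str]:
        return self._nodes[node_id].parent

    def children(self, node_id: str) -> list[str]:
        return list(self._nodes[node_id].children)

    def is_tip(self, node_id: str) -> bool:
        return self._nodes[node_id].is_tip

    def length(self, node_id: str) -> float:
        return self._nodes[node_id].length

    def time(self, node_id: str) -> float:
        """Depth of the node below the root, in branch-length units."""
        return self._time[node_id]

    @property
    def depth(self) -> float:
        return max(self._time.values())

    @property
    def total_length(self) -> float:
        return sum(n.length for n in self._nodes.values())

    def preorder(self) -> Iterator[str]:
        return iter(self._preorder)

    def postorder(self) -> Iterator[str]:
        return reversed(self._preorder)

    def node_ids(self) -> list[str]:
        return list(self._preorder)

    def subtree(self, node_id: str) -> list[str]:
        """Node ids of the subtree rooted at ``node_id`` (preorder)."""
        out, stack = [], [node_id]
        while stack:
            nid = stack.pop()
            out.append(nid)
            stack.extend(reversed(self._nodes[nid].children))
        return out

    def mrca(self, tip_ids: list[str]) -> str:
        """Most recent common ancestor of a set of node ids."""
        if not tip_ids:
            raise ValueError("mrca of an empty set")
        paths = []
        for tid in tip_ids:
            if tid not in self._nodes:
                raise KeyError(tid)
            path, cur = [], tid
            while cur is not None:
                path.append(cur)
                cur = self._nodes[cur].parent
            paths.append(list(reversed(path)))
        mrca = self._root
        for level in zip(*paths):
            if len(set(level)) == 1:
                mrca = level[0]
            else:
                break
        return mrca

    # -- clades ----------------------------------------------------------
    def label_clade(self, label: str, root_id: str) -> None:
        """Label every node of the subtree at ``root_id`` (stem included)."""
        if root_id not in self._nodes:
            raise KeyError(root_id)
        for nid in self.subtree(root_id):
            self._nodes[nid].clade = label

    def clade_nodes(self, label: str) -> list[str]:
        out = [n for n in self._preorder if self._nodes[n].clade == label]
        if not out:
            raise KeyError(f"no clade labelled {label!r}")
        return out

    def clade_labels(self) -> list[str]:
        seen: list[str] = []
        for nid in self._preorder:
            lab = self._nodes[nid].clade
            if lab is not None and lab not in seen:
                seen.append(lab)
        return seen

    # -- conversion ------------------------------------------------------
    @classmethod
    def from_dendropy(cls, dtree: "dendropy.Tree",
                      default_length: float = 1.0,
                      resolve_multifurcations: bool = False) -> "SpeciesTree":
        """Build a SpeciesTree from a dendropy tree.

        Unlabelled internal nodes receive deterministic ids ``"n" +
        preorder index``; missing branch lengths default to
        ``default_length`` with a warning.  Multifurcations raise
        :class:`UnsupportedTopologyError` unless ``resolve_multifurcations``
        is set, in which case they are resolved arbitrarily but
        deterministically (zero-length edges) by dendropy.
        """
        dtree = dtree.clone(depth=1)
        if any(len(nd.child_nodes()) > 2 for nd in dtree.preorder_node_iter()):
            if not resolve_multifurcations:
                raise UnsupportedTopologyError(
                    "multifurcating input; pass resolve_multifurcations=True "
                    "to resolve arbitrarily (deterministic, zero-length edges)"
                )
            dtree.resolve_polytomies(limit=2, update_bipartitions=False)
        missing = False
        nodes: list[TreeNode] = []
        ids: dict[int, str] = {}
        for i, nd in enumerate(dtree.preorder_node_iter()):
            if nd.is_leaf():
                nid = nd.taxon.label if nd.taxon is not None else (nd.label or f"n{i}")
            else:
                nid = nd.label or f"n{i}"
            ids[id(nd)] = nid
            length = nd.edge.length
            if nd.parent_node is None:
                length = 0.0
            elif length is None:
                length = default_length
                missing = True
            parent = ids[id(nd.parent_node)] if nd.parent_node is not None else None
            nodes.append(TreeNode(id=nid, parent=parent, length=float(length),
                                  is_tip=nd.is_leaf()))
        if missing:
            warnings.warn(
                f"missing branch lengths set to {default_length}", UserWarning
            )
        return cls(nodes)

    def to_dendropy(self) -> "dendropy.Tree":
        taxa = dendropy.TaxonNamespace()
        dtree = dendropy.Tree(taxon_namespace=taxa)
        dnodes: dict[str, dendropy.Node] = {}
        for nid in self._preorder:
            node = self._nodes[nid]
            dn = dendropy.Node()
            if node.is_tip:
                dn.taxon = taxa.new_taxon(label=nid)
            else:
                dn.label = nid
            dn.edge.length = node.length if node.parent is not None else None
            dnodes[nid] = dn
            if node.parent is None:
                dtree.seed_node = dn
            else:
                dnodes[node.parent].add_child(dn)
        dtree.is_rooted = True
        return dtree

    @classmethod
    def from_newick(cls, newick: str, **kwargs) -> "SpeciesTree":
        dtree = dendropy.Tree.get(
            data=newick, schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
        return cls.from_dendropy(dtree, **kwargs)

    def to_newick(self) -> str:
        buf = _io.StringIO()
        self.to_dendropy().write(
            file=buf, schema="newick",
            suppress_rooting=True, unquoted_underscores=True,
        )
        return buf.getvalue().strip() + "\n"

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (f"SpeciesTree(n_tips={self.n_tips}, n_nodes={len(self)}, "
                f"depth={self.depth:.3g})")
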