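"""Emergence-node assignment of multi-species blocks on a species tree.

For an internal node, the ingroup is the set of leaf species descending
from it and the outgroup is every other leaf.  A block is *novel* at the
node when at least two ingroup species carry it, at least two of the node's
children clades are represented, and no outgroup species carries it; it is
*inherited* when at least two ingroup and two outgroup species carry it;
otherwise it is *absent* at that node.  The emergence node of a block is
the novel node closest to the root (single-gain parsimony).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import stats as sps

from .blocks import MultiSpeciesBlock

__all__ = [
    "SpeciesTree",
    "NodeAssignment",
    "classify_block_at_node",
    "assign_emergence",
    "node_block_counts",
    "retention_and_loss",
    "recency_correlation",
    "NOVEL",
    "INHERITED",
    "ABSENT",
]

NOVEL = "novel"
INHERITED = "inherited"
ABSENT = "absent"


class SpeciesTree:
    """A rooted species tree with named internal nodes (multifurcations OK).

    Thin wrapper over a dendropy tree: leaves are species ids, internal
    node labels name ancestors, and an optional recency map gives each
    internal node a relative age rank (higher = younger ancestor).
    """

    def __init__(
        self, tree: dendropy.Tree, recency: Mapping[str, float] | None = None
    ) -> None:
        self._tree = tree
        self.recency: dict[str, float] = dict(recency or {})
        self.leaves: frozenset[str] = frozenset(
            lf.taxon.label for lf in tree.leaf_node_iter()
        )
        if len(self.leaves) != sum(1 for _ in tree.leaf_node_iter()):
            raise ValueError("duplicate leaf names in species tree")
        self._nodes: dict[str, dendropy.Node] = {}
        self._depth: dict[str, int] = {}
        for node in tree.preorder_node_iter():
            if node.is_leaf():
                continue
            label = node.label
            if label is None:
                raise ValueError("species tree has an unnamed internal node")
            if label in self._nodes:
                raise ValueError(f"duplicate internal node label {label!r}")
            self._nodes[label] = node
            depth = 0
            p = node.parent_node
            while p is not None:
                depth += 1
                p = p.parent_node
            self._depth[label] = depth
        self._leafset: dict[str, frozenset[str]] = {
            label: frozenset(
                lf.taxon.label for lf in node.leaf_iter()
            )
            for label, node in self._nodes.items()
        }

    @classmethod
    def from_newick(
        cls, source: str | Path, recency: Mapping[str, float] | None = None
    ) -> "SpeciesTree":
        text = (
            Path(source).read_text()
            if isinstance(source, Path) or str(source).endswith((".nwk", ".newick", ".tre"))
            else str(source)
        )
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
        return cls(tree, recency)

    @property
    def internal_nodes(self) -> list[str]:
        """Internal node labels in preorder (root first)."""
        return sorted(self._nodes, key=lambda n: (self._depth[n], n))

    @property
    def root(self) -> str:
        return min(self._nodes, key=lambda n: (self._depth[n], n))

    def is_internal(self, node: str) -> bool:
        return node in self._nodes

    def depth(self, node: str) -> int:
        return self._depth[node]

    def leaves_under(self, node: str) -> frozenset[str]:
        if node in self._leafset:
            return self._leafset[node]
        if node in self.leaves:
            return frozenset({node})
        raise KeyError(f"unknown node {node!r}")

    def children_leafsets(self, node: str) -> list[frozenset[str]]:
        try:
            n = self._nodes[node]
        except KeyError:
            raise ValueError(f"{node!r} is not an internal node") from None
        out = []
        for child in n.child_nodes():
            if child.is_leaf():
                out.append(frozenset({child.taxon.label}))
            else:
                out.append(self._leafset[child.label])
        return out


@dataclass
class NodeAssignment:
    """Per-block emergence node and per-node status."""

    emergence_node: dict[int, str | None]
    status: dict[int, dict[str, str]]  # block_id -> node -> status
    blocks: dict[int, MultiSpeciesBlock] = field(default_factory=dict)

    def novel_blocks_of(self, node: str) -> list[int]:
        return sorted(
            bid for bid, node_of in self.emergence_node.items() if node_of == node
        )


def classify_block_at_node(
    block: MultiSpeciesBlock,
    tree: SpeciesTree,
    node: str,
    strict_novelty: bool = False,
) -> str:
    """Classify one block as novel / inherited / absent at an internal node.

    With ``strict_novelty`` the novelty condition requires at least two
    present species in each of at least two children clades, instead of the
    default two present ingroup species spread over at least two children.
    """
    if not tree.is_internal(node):
        raise ValueError(f"{node!r} is a leaf; classification needs an internal node")
    present = block.species_set & tree.leaves
    ingroup = tree.leaves_under(node)
    in_present = present & ingroup
    out_present = present - ingroup
    children = tree.children_leafsets(node)
    if strict_novelty:
        represented = sum(1 for c in children if len(present & c) >= 2)
    else:
        represented = sum(1 for c in children if present & c)
    if len(in_present) >= 2 and represented >= 2 and not out_present:
        return NOVEL
    if len(in_present) >= 2 and len(out_present) >= 2:
        return INHERITED
    return ABSENT


def assign_emergence(
    blocks: Sequence[MultiSpeciesBlock],
    tree: SpeciesTree,
    strict_novelty: bool = False,
) -> NodeAssignment:
    """Assign each block its emergence node (deepest node where novel)."""
    emergence: dict[int, str | None] = {}
    status: dict[int, dict[str, str]] = {}
    for block in blocks:
        per_node = {
            node: classify_block_at_node(block, tree, node, strict_novelty)
            for node in tree.internal_nodes
        }
        status[block.block_id] = per_node
        novel_nodes = [n for n, s in per_node.items() if s == NOVEL]
        if novel_nodes:
            emergence[block.block_id] = min(
                novel_nodes, key=lambda n: (tree.depth(n), n)
            )
        else:
            emergence[block.block_id] = None
    return NodeAssignment(
        emergence_node=emergence,
        status=status,
        blocks={b.block_id: b for b in blocks},
    )


def node_block_counts(
    assignment: NodeAssignment, tree: SpeciesTree
) -> dict[str, dict[str, int]]:
    """Per-node novel and inherited block counts."""
    counts = {
        node: {"novel": 0, "inherited": 0} for node in tree.internal_nodes
    }
    for bid, per_node in assignment.status.items():
        emerged_at = assignment.emergence_node.get(bid)
        for node, s in per_node.items():
            if s == INHERITED:
                counts[node]["inherited"] += 1
            elif s == NOVEL and node == emerged_at:
                counts[node]["novel"] += 1
    return counts


def retention_and_loss(
    assignment: NodeAssignment,
    blocks: Sequence[MultiSpeciesBlock],
    tree: SpeciesTree,
    taxa: Sequence[str],
) -> pd.DataFrame:
    """Retention matrix: % of each node's novel blocks kept in each clade.

    A node's novel block is retained in a clade when at least one species of
    the clade carries the block; lost% = 100 - retained%.  Nodes with no
    novel blocks get NaN.
    """
    by_id = {b.block_id: b for b in blocks}
    nodes = tree.internal_nodes
    data = {}
    for taxon in taxa:
        clade = tree.leaves_under(taxon)
        col = []
        for node in nodes:
            novel = assignment.novel_blocks_of(node)
            if not novel:
                col.append(np.nan)
                continue
            kept = sum(1 for bid in novel if by_id[bid].species_set & clade)
            col.append(100.0 * kept / len(novel))
        data[taxon] = col
    return pd.DataFrame(data, index=nodes)


def recency_correlation(
    counts: Mapping[str, float], recency: Mapping[str, float]
) -> tuple[float, float]:
    """Pearson correlation between per-node block counts and node recency.

    Uses the product-moment r with a two-sided t-test on n-2 degrees of
    freedom over nodes present in both maps.
    """
    nodes = sorted(set(counts) & set(recency))
    if len(nodes) < 3:
        raise ValueError("need at least 3 nodes with both a count and a recency")
    x = np.array([recency[n] for n in nodes], dtype=float)
    y = np.array([counts[n] for n in nodes], dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("undefined correlation: zero variance")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)
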