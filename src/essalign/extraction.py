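"""Extraction of enzymatic step sequences (ESS) from reaction graphs.

From each metabolic-map graph a set of *initialization nodes* is
chosen: (1) reactions none of whose substrates are produced by any
other reaction in the map (sources of metabolic flow), and (2)
reactions adjacent to a cross-map link with two or fewer neighbours.
Each initialization node roots a breadth-first tree — restricted to
forward edges when the graph is directed — and each leaf of the tree
yields one ESS: the path from that leaf back to the root, reported in
root-to-leaf order so the sequence reads in the direction of flow.  A
tree therefore produces as many sequences as it has leaves.

Each step is labelled by the EC number of its reaction at four and
three classification levels; a reaction with several EC numbers
(complexes, isoenzymes) is collapsed to its numerically smallest EC,
with the full gene association kept in the provenance.  Identical
sequences arising from different maps or organisms are collapsed into a
non-redundant set (nrESS) that remembers where each representative came
from.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

from .labels import UNASSIGNED, ec3_of, ec_sort_key, format_ess
from .kgml import PathwayGraph

#: paths shorter than this many steps carry no step-order information
MIN_ESS_LENGTH = 2


@dataclass(frozen=True)
class ESS:
    """One enzymatic step sequence with its provenance."""

    labels3: tuple[str, ...]
    labels4: tuple[str, ...]
    organism: str
    map_id: str
    gene_steps: tuple[frozenset[str], ...]
    node_ids: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.labels3)

    def __str__(self) -> str:
        return format_ess(self.labels3)

    @property
    def provenance(self) -> tuple[str, str, tuple[frozenset[str], ...]]:
        return (self.organism, self.map_id, self.gene_steps)


@dataclass
class BFSTree:
    root: str
    parent: dict[str, str] = field(default_factory=dict)
    children: dict[str, list[str]] = field(default_factory=dict)

    @property
    def nodes(self) -> set[str]:
        return {self.root} | set(self.parent)

    @property
    def leaves(self) -> set[str]:
        """Tree nodes with no children; the root is never a leaf."""
        return {
            n for n in self.nodes if not self.children.get(n) and n != self.root
        }

    def path_to_root(self, leaf: str) -> list[str]:
        path = [leaf]
        while path[-1] != self.root:
            path.append(self.parent[path[-1]])
        return path


def select_initialization_nodes(graph: PathwayGraph) -> list[str]:
    """BFS roots for a map, deterministically ordered.

    Criterion (1): no substrate of the reaction appears among the
    declared products of any other reaction in the map.  Criterion (2):
    the reaction sits next to a cross-map link and has fewer than three
    neighbours.  A graph where neither criterion fires (e.g. a pure
    cycle) yields an empty list and hence no ESS.
    """
    selected = set()
    for node_id, node in graph.nodes.items():
        produced_elsewhere = set()
        for other_id, other in graph.nodes.items():
            if other_id != node_id:
                produced_elsewhere |= other.products
        if not (node.substrates & produced_elsewhere):
            selected.add(node_id)
    for node_id in graph.map_links:
        if node_id in graph.nodes and graph.degree(node_id) < 3:
            selected.add(node_id)
    return sorted(selected)


def build_bfs_tree(graph: PathwayGraph, root: str) -> BFSTree:
    """Breadth-first tree from ``root``; forward edges only when directed.

    Neighbour visiting order is sorted by node id so the tree — and
    every ESS downstream of it — is reproducible.
    """
    if root not in graph.nodes:
        raise KeyError(f"unknown reaction node: {root!r}")
    tree = BFSTree(root=root)
    visited = {root}
    queue = deque([root])
    while queue:
        current = queue.popleft()
        tree.children.setdefault(current, [])
        for nbr in sorted(graph.forward_neighbors(current)):
            if nbr not in visited:
                visited.add(nbr)
                tree.parent[nbr] = current
                tree.children[current].append(nbr)
                queue.append(nbr)
    return tree


def _step_labels(node) -> tuple[str, str]:
    """(labels3, labels4) for one reaction, smallest EC when ambiguous."""
    if not node.ec4:
        return UNASSIGNED, UNASSIGNED
    ec3 = min(node.ec3, key=ec_sort_key)
    ec4 = min((e for e in node.ec4 if ec3_of(e) == ec3), key=ec_sort_key)
    return ec3, ec4


def extract_ess(
    tree: BFSTree, graph: PathwayGraph, min_length: int = MIN_ESS_LENGTH
) -> list[ESS]:
    """One ESS per leaf, in root-to-leaf order, one per tree leaf.

    Single-node trees (and any path below ``min_length``) produce
    nothing.
    """
    out = []
    for leaf in sorted(tree.leaves):
        path = tree.path_to_root(leaf)
        path.reverse()  # traced leaf -> root, reported root -> leaf
        if len(path) < min_length:
            continue
        labels3 = []
        labels4 = []
        genes = []
        for node_id in path:
            node = graph.nodes[node_id]
            l3, l4 = _step_labels(node)
            labels3.append(l3)
            labels4.append(l4)
            genes.append(frozenset(node.gene_ids))
        out.append(
            ESS(
                labels3=tuple(labels3),
                labels4=tuple(labels4),
                organism=graph.organism,
                map_id=graph.map_id,
                gene_steps=tuple(genes),
                node_ids=tuple(path),
            )
        )
    return out


def extract_all(graph: PathwayGraph, min_length: int = MIN_ESS_LENGTH) -> list[ESS]:
    """All ESS of one map: every initialization node, every tree leaf."""
    out = []
    for root in select_initialization_nodes(graph):
        out.extend(extract_ess(build_bfs_tree(graph, root), graph, min_length))
    return out


def make_nonredundant(
    ess_list: list[ESS],
) -> tuple[list[ESS], dict[tuple[str, ...], list[ESS]]]:
    """Collapse identical three-level sequences to one representative.

    Returns the nrESS list (first occurrence wins, input order kept)
    and a map from each representative's labels3 to every original ESS
    it stands for.  Applying this to its own output changes nothing.
    """
    representatives: list[ESS] = []
    redundancy: dict[tuple[str, ...], list[ESS]] = {}
    for ess in ess_list:
        key = ess.labels3
        if key not in redundancy:
            redundancy[key] = []
            representatives.append(ess)
        redundancy[key].append(ess)
    return representatives, redundancy
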