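"""KGML parsing and reaction-graph construction.

A KGML document (the KEGG pathway XML dialect) lists *entries* (genes,
enzymes, compounds, cross-map links), *reactions* (with substrate and
product compounds) and *relations*.  Here a metabolic map becomes a
graph whose nodes are enzymatic reactions and whose edges are
product/substrate relationships: reaction A is joined to reaction B,
labelled with compound C, when C is a product of one and a substrate of
the other.  Compounds themselves are never nodes — they live only on
edge labels.

Entries that catalyse the same reaction (isoenzymes, complex subunits)
are merged into a single reaction node carrying the union of their gene
identifiers.  Reversibility comes from the reaction ``type`` attribute;
in a directed graph a reversible reaction contributes traversable
connectivity in both directions across itself.  ``relation`` elements
never contribute edges; they are consulted only to record which
reaction nodes sit next to a ``map``-type entry (a link into another
metabolic map), which the ESS extractor needs for picking tree roots.
"""

from __future__ import annotations

import re
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

from .labels import UNASSIGNED, ec3_of, is_ec4


class KGMLParseError(ValueError):
    """Malformed KGML input."""


class InvalidMapIdError(ValueError):
    """A map identifier with no 5-digit numeric code."""


_MAP_CODE_RE = re.compile(r"(\d{5})")

# entry-name namespaces that are not gene identifiers
_NON_GENE_PREFIXES = ("ec:", "rn:", "cpd:", "path:", "gl:", "dr:")


def is_strict_map(map_id: str) -> bool:
    """True for strict (non-global) metabolic maps: numeric code < 01000.

    Accepts bare codes ("00010") as well as prefixed forms such as
    "eco00010" or "path:map00010".
    """
    match = _MAP_CODE_RE.search(map_id)
    if match is None:
        raise InvalidMapIdError(f"no 5-digit map code in {map_id!r}")
    return int(match.group(1)) < 1000


@dataclass
class ReactionNode:
    """One enzymatic reaction: a single enzyme or an enzymatic complex."""

    reaction_id: str
    gene_ids: set[str] = field(default_factory=set)
    ec4: set[str] = field(default_factory=set)
    reversible: bool = False
    substrates: set[str] = field(default_factory=set)
    products: set[str] = field(default_factory=set)

    @property
    def ec3(self) -> set[str]:
        """Three-level prefixes of ec4, or {"9.9.9"} when none assigned."""
        if not self.ec4:
            return {UNASSIGNED}
        return {ec3_of(ec) for ec in self.ec4}


@dataclass
class PathwayGraph:
    """Reaction graph of one metabolic map.

    ``graph`` is a :class:`networkx.MultiDiGraph` when ``directed`` is
    true, otherwise a :class:`networkx.MultiGraph`; edge keys are the
    shared compound identifiers.
    """

    map_id: str
    organism: str
    nodes: dict[str, ReactionNode]
    graph: nx.MultiGraph | nx.MultiDiGraph
    directed: bool
    map_links: set[str] = field(default_factory=set)

    @property
    def is_empty(self) -> bool:
        """True when the map declared no reactions at all."""
        return not self.nodes

    def degree(self, node_id: str) -> int:
        """Number of distinct neighbouring reactions, ignoring direction."""
        if node_id not in self.nodes:
            raise KeyError(f"unknown reaction node: {node_id!r}")
        g = self.graph
        if self.directed:
            nbrs = set(g.successors(node_id)) | set(g.predecessors(node_id))
        else:
            nbrs = set(g.neighbors(node_id))
        nbrs.discard(node_id)
        return len(nbrs)

    def forward_neighbors(self, node_id: str) -> set[str]:
        """Nodes reachable in one traversal step (direction-aware)."""
        if node_id not in self.nodes:
            raise KeyError(f"unknown reaction node: {node_id!r}")
        if self.directed:
            nbrs = set(self.graph.successors(node_id))
        else:
            nbrs = set(self.graph.neighbors(node_id))
        nbrs.discard(node_id)
        return nbrs

    def has_edge(self, a: str, b: str) -> bool:
        return self.graph.has_edge(a, b)


def _entry_genes_and_ecs(entry: ET.Element) -> tuple[set[str], set[str]]:
    genes: set[str] = set()
    ecs: set[str] = set()
    for token in entry.get("name", "").split():
        if token.startswith("ec:"):
            ec = token[3:]
            if is_ec4(ec):
                ecs.add(ec)
        elif not token.startswith(_NON_GENE_PREFIXES):
            genes.add(token)
    if not genes:
        entry_id = entry.get("id")
        if entry_id:
            genes.add(f"entry:{entry_id}")
    return genes, ecs


def parse_kgml(source, directed: bool = False) -> PathwayGraph:
    """Parse a KGML document into a :class:`PathwayGraph`.

    ``source`` may be a path, an open file object, or an XML string.
    A well-formed map with no reaction elements yields an empty graph
    (``is_empty`` is true); malformed XML raises
    :class:`KGMLParseError`.
    """
    text = None
    if isinstance(source, (str, Path)):
        p = Path(source)
        # a long XML string is not a path; Path() on it may even blow up
        try:
            is_file = p.is_file()
        except (OSError, ValueError):
            is_file = False
        text = p.read_text() if is_file else str(source)
    else:
        text = source.read()
    try:
        root = ET.fromstring(text)
    except ET.ParseError as exc:
        raise KGMLParseError(f"malformed KGML document: {exc}") from exc
    if root.tag != "pathway":
        raise KGMLParseError(f"expected <pathway> root, found <{root.tag}>")

    map_id = root.get("number") or root.get("name", "")
    organism = root.get("org", "")

    entries = root.findall("entry")
    entry_by_id = {e.get("id"): e for e in entries}

    # reaction name -> node, merging duplicate reaction elements and
    # isoenzyme entries into one node each
    nodes: dict[str, ReactionNode] = {}
    reaction_elem_ids: dict[str, str] = {}  # reaction element id -> reaction name
    for rxn in root.findall("reaction"):
        name = rxn.get("name")
        if not name:
            raise KGMLParseError("reaction element without a name attribute")
        node = nodes.setdefault(name, ReactionNode(reaction_id=name))
        if rxn.get("type", "irreversible") == "reversible":
            node.reversible = True
        for sub in rxn.findall("substrate"):
            node.substrates.add(sub.get("name") or sub.get("id", ""))
        for prod in rxn.findall("product"):
            node.products.add(prod.get("name") or prod.get("id", ""))
        rid = rxn.get("id")
        if rid:
            reaction_elem_ids[rid] = name

    entry_reactions: dict[str, list[str]] = {}  # entry id -> reaction names
    for entry in entries:
        linked = []
        for rname in entry.get("reaction", "").split():
            if rname in nodes:
                linked.append(rname)
        if not entry.get("reaction"):
            # KGML variants where reaction@id mirrors the entry id
            rid_link = reaction_elem_ids.get(entry.get("id", ""))
            if rid_link:
                linked.append(rid_link)
        if not linked:
            continue
        entry_reactions[entry.get("id", "")] = linked
        genes, ecs = _entry_genes_and_ecs(entry)
        for rname in linked:
            nodes[rname].gene_ids |= genes
            nodes[rname].ec4 |= ecs

    # map links: reaction nodes related to a map-type entry
    map_links: set[str] = set()
    for rel in root.findall("relation"):
        e1 = entry_by_id.get(rel.get("entry1", ""))
        e2 = entry_by_id.get(rel.get("entry2", ""))
        if e1 is None or e2 is None:
            continue
        for map_entry, other in ((e1, e2), (e2, e1)):
            if map_entry.get("type") == "map":
                for rname in entry_reactions.get(other.get("id", ""), []):
                    map_links.add(rname)

    graph: nx.MultiGraph | nx.MultiDiGraph
    graph = nx.MultiDiGraph() if directed else nx.MultiGraph()
    graph.add_nodes_from(nodes)
    ordered = sorted(nodes)
    for a in ordered:
        na = nodes[a]
        for b in ordered:
            if a == b:
                continue
            nb = nodes[b]
            for compound in sorted(na.products & nb.substrates):
                if directed:
                    if not graph.has_edge(a, b, key=compound):
                        graph.add_edge(a, b, key=compound, compound=compound)
                    if (na.reversible or nb.reversible) and not graph.has_edge(
                        b, a, key=compound
                    ):
                        graph.add_edge(b, a, key=compound, compound=compound)
                else:
                    if not graph.has_edge(a, b, key=compound):
                        graph.add_edge(a, b, key=compound, compound=compound)

    return PathwayGraph(
        map_id=map_id,
        organism=organism,
        nodes=nodes,
        graph=graph,
        directed=directed,
        map_links=map_links,
    )
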