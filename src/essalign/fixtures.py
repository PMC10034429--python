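"""Synthetic KGML maps and ESS databases with known ground truth.

Real inputs are KEGG pathway files, which cannot be redistributed, so
everything downstream is exercised on generated data instead.  The
KGML generator emits minimal but valid pathway documents for a few
canonical topologies — a linear chain, a two-armed branch, a cycle and
a chain ending in a cross-map link — together with the exact ESS the
extraction pipeline must produce from them, which makes the generator
the pipeline's primary oracle.  The database generator builds families
of near-identical sequences (point EC substitutions at a chosen rate)
over per-family EC alphabets drawn from distinct first-level classes,
giving a known similarity structure for testing batch alignment and
the shuffled-null significance machinery.

These synthetic maps mimic product/substrate topology only; they do not
emulate real map statistics (size, branching, EC reuse across maps).
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass, field

import numpy as np

TOPOLOGIES = ("chain", "branch", "cycle", "cross_map")

DEFAULT_EC_ALPHABET = (
    "2.7.1",
    "5.3.1",
    "4.1.2",
    "1.2.1",
    "2.3.1",
    "4.2.1",
    "6.3.4",
    "3.5.4",
)


@dataclass(frozen=True)
class FixtureSpec:
    topology: str = "chain"
    n_reactions: int = 4
    ec_alphabet: tuple[str, ...] = DEFAULT_EC_ALPHABET
    reversible_fraction: float = 0.0
    seed: int = 0


@dataclass
class KGMLFixture:
    """A synthetic map plus the ground truth its extraction must yield."""

    kgml: str
    init_nodes: list[str]
    ess_directed: list[list[str]] = field(default_factory=list)
    ess_undirected: list[list[str]] = field(default_factory=list)

    def expected_ess(self, directed: bool) -> list[list[str]]:
        return self.ess_directed if directed else self.ess_undirected


def _reaction_name(i: int) -> str:
    return f"rn:R{i}"


def _emit_kgml(
    reactions: list[tuple[str, str, list[str], list[str], bool]],
    map_link_entry: str | None = None,
) -> str:
    """Serialise (name, ec4, substrates, products, reversible) tuples.

    ``map_link_entry`` names a reaction to relate to a map-type entry.
    """
    root = ET.Element(
        "pathway",
        name="path:syn00042",
        org="syn",
        number="00042",
        title="synthetic pathway",
    )
    entry_id_of = {}
    for idx, (name, ec4, _subs, _prods, _rev) in enumerate(reactions, start=1):
        entry_id_of[name] = str(idx)
        ET.SubElement(
            root,
            "entry",
            id=str(idx),
            name=f"syn:g{idx} ec:{ec4}",
            type="enzyme",
            reaction=name,
        )
    if map_link_entry is not None:
        map_id = str(len(reactions) + 1)
        ET.SubElement(root, "entry", id=map_id, name="path:syn00099", type="map")
        ET.SubElement(
            root,
            "relation",
            entry1=entry_id_of[map_link_entry],
            entry2=map_id,
            type="maplink",
        )
    for idx, (name, _ec4, subs, prods, rev) in enumerate(reactions, start=1):
        rxn = ET.SubElement(
            root,
            "reaction",
            id=str(idx),
            name=name,
            type="reversible" if rev else "irreversible",
        )
        for sub in subs:
            ET.SubElement(rxn, "substrate", id=f"s{sub}", name=f"cpd:{sub}")
        for prod in prods:
            ET.SubElement(rxn, "product", id=f"p{prod}", name=f"cpd:{prod}")
    return ET.tostring(root, encoding="unicode", xml_declaration=True)


def make_kgml(spec: FixtureSpec) -> KGMLFixture:
    """Build one synthetic KGML map and its expected extraction output.

    Expected ESS are given for both the directed and the undirected
    construction; they are closed-form consequences of the topology.
    """
    if spec.topology not in TOPOLOGIES:
        raise ValueError(f"unsupported topology: {spec.topology!r}")
    n = spec.n_reactions
    if n < 1:
        raise ValueError("n_reactions must be >= 1")
    rng = np.random.default_rng(spec.seed)

    def ec3(i: int) -> str:
        return spec.ec_alphabet[i % len(spec.ec_alphabet)]

    def ec4(i: int) -> str:
        return ec3(i) + ".1"

    def rev(i: int) -> bool:
        return bool(rng.random() < spec.reversible_fraction)

    if spec.topology in ("chain", "cross_map"):
        if spec.topology == "cross_map" and spec.reversible_fraction > 0:
            # reverse edges would open extra routes from the link node,
            # breaking the closed-form expectation below
            raise ValueError("cross_map fixtures must be irreversible")
        reactions = [
            (_reaction_name(i + 1), ec4(i), [f"C{i}"], [f"C{i + 1}"], rev(i))
            for i in range(n)
        ]
        chain_labels = [ec3(i) for i in range(n)]
        link = _reaction_name(n) if spec.topology == "cross_map" else None
        init = [_reaction_name(1)]
        ess_directed = [chain_labels] if n >= 2 else []
        ess_undirected = [chain_labels] if n >= 2 else []
        if spec.topology == "cross_map":
            init = sorted(init + [_reaction_name(n)])
            if n >= 2:
                ess_undirected = ess_undirected + [chain_labels[::-1]]
            # directed: the link node has no forward edges, so no extra ESS
        return KGMLFixture(
            kgml=_emit_kgml(reactions, map_link_entry=link),
            init_nodes=init,
            ess_directed=ess_directed,
            ess_undirected=sorted(ess_undirected),
        )

    if spec.topology == "branch":
        if n < 3 or n % 2 == 0:
            raise ValueError("branch topology needs an odd n_reactions >= 3")
        k = (n - 1) // 2
        reactions = [(_reaction_name(1), ec4(0), ["C0"], ["C1"], rev(0))]
        expected = []
        idx = 1
        for arm in ("A", "B"):
            labels = [ec3(0)]
            prev = "C1"
            for step in range(k):
                name = _reaction_name(idx + 1)
                prod = f"C{arm}{step + 1}"
                reactions.append((name, ec4(idx), [prev], [prod], rev(idx)))
                labels.append(ec3(idx))
                prev = prod
                idx += 1
            expected.append(labels)
        return KGMLFixture(
            kgml=_emit_kgml(reactions),
            init_nodes=[_reaction_name(1)],
            ess_directed=sorted(expected),
            ess_undirected=sorted(expected),
        )

    # cycle: every substrate is produced in-map, so no initialization
    # nodes and no ESS
    reactions = [
        (
            _reaction_name(i + 1),
            ec4(i),
            [f"C{i}"],
            [f"C{(i + 1) % n}"],
            rev(i),
        )
        for i in range(n)
    ]
    return KGMLFixture(kgml=_emit_kgml(reactions), init_nodes=[])


def make_ess_db(
    n_families: int,
    family_size: int,
    mutation_rate: float,
    seed: int,
    min_length: int = 6,
    max_length: int = 10,
    alphabet_size: int = 8,
) -> tuple[list[list[str]], list[int]]:
    """Families of near-identical ESS with point EC substitutions.

    Each family draws its labels from a private alphabet confined to one
    first-level EC class (classes cycle through 1..7), so up to seven
    families are fully disjoint at the first level and every
    cross-family substitution scores the maximum dissimilarity.  Every
    member is the family's base sequence with each position replaced,
    with probability ``mutation_rate``, by another label of the family
    alphabet.  Returns the sequences and their family index, in family
    order; a fixed seed reproduces the database exactly.
    """
    if n_families < 1 or family_size < 1:
        raise ValueError("n_families and family_size must be >= 1")
    if not 0.0 <= mutation_rate <= 1.0:
        raise ValueError("mutation_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    sequences: list[list[str]] = []
    families: list[int] = []
    for fam in range(n_families):
        klass = (fam % 7) + 1
        alphabet = []
        while len(alphabet) < alphabet_size:
            label = f"{klass}.{rng.integers(1, 21)}.{rng.integers(1, 31)}"
            if label not in alphabet:
                alphabet.append(label)
        length = int(rng.integers(min_length, max_length + 1))
        base = [alphabet[int(rng.integers(len(alphabet)))] for _ in range(length)]
        for _ in range(family_size):
            member = list(base)
            for pos in range(length):
                if rng.random() < mutation_rate:
                    choices = [a for a in alphabet if a != member[pos]]
                    member[pos] = choices[int(rng.integers(len(choices)))]
            sequences.append(member)
            families.append(fam)
    return sequences, families
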