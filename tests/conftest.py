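"""Shared fixtures: small hierarchies and on-disk ontology-format fixtures.

All fixture files are generated at test time; the worked example is the
hormone-secretion chain from GO (A is-a B is-a ... is-a F) with the direct
shortcut A is-a F that makes the direct edge redundant.
"""

import textwrap

import networkx as nx
import pytest

from fedrr import ConceptGraph

# GO hormone-secretion chain: each pair is (child, parent).
HORMONE_CHAIN = [
    ("GO:0046879", "GO:0009914"),  # hormone secretion is-a hormone transport
    ("GO:0009914", "GO:0010817"),
    ("GO:0010817", "GO:0065008"),
    ("GO:0065008", "GO:0065007"),
    ("GO:0065007", "GO:0008150"),  # ... is-a biological process
]
HORMONE_SHORTCUT = ("GO:0046879", "GO:0008150")


@pytest.fixture
def hormone_chain_graph() -> ConceptGraph:
    """The 6-term chain plus the redundant direct shortcut."""
    return ConceptGraph(HORMONE_CHAIN + [HORMONE_SHORTCUT])


@pytest.fixture
def diamond_graph() -> ConceptGraph:
    """A->{B,C}->D diamond plus the redundant direct edge (A, D)."""
    return ConceptGraph([("A", "B"), ("A", "C"), ("B", "D"), ("C", "D"), ("A", "D")])


def to_networkx(graph: ConceptGraph) -> nx.DiGraph:
    g = nx.DiGraph()
    g.add_nodes_from(graph.nodes)
    g.add_edges_from(graph.edges)
    return g


@pytest.fixture
def obo_fixture(tmp_path):
    """OBO file encoding the chain + shortcut, plus edge cases.

    Includes an obsolete term (must vanish), a term whose is_a target has no
    stanza (edge dropped, term kept), a part_of relationship (ignored) and a
    trailing ``!`` comment.
    """
    text = textwrap.dedent("""\
        format-version: 1.2
        ontology: go

        [Term]
        id: GO:0046879
        name: hormone secretion
        is_a: GO:0009914 ! hormone transport
        is_a: GO:0008150

        [Term]
        id: GO:0009914
        name: hormone transport
        is_a: GO:0010817

        [Term]
        id: GO:0010817
        name: regulation of hormone levels
        is_a: GO:0065008

        [Term]
        id: GO:0065008
        name: regulation of biological quality
        is_a: GO:0065007

        [Term]
        id: GO:0065007
        name: biological regulation
        is_a: GO:0008150

        [Term]
        id: GO:0008150
        name: biological process

        [Term]
        id: GO:9000001
        name: withdrawn term
        is_obsolete: true
        is_a: GO:0008150

        [Term]
        id: GO:8000001
        name: dangling child
        is_a: GO:7777777
        relationship: part_of GO:0008150
        """)
    path = tmp_path / "fixture.obo"
    path.write_text(text)
    return path


_RF2_CONCEPT_HEADER = "id\teffectiveTime\tactive\tmoduleId\tdefinitionStatusId"
_RF2_REL_HEADER = ("id\teffectiveTime\tactive\tmoduleId\tsourceId\tdestinationId"
                   "\trelationshipGroup\ttypeId\tcharacteristicTypeId\tmodifierId")


@pytest.fixture
def rf2_fixture(tmp_path):
    """RF2 snapshot pair encoding a diamond + shortcut with noise rows.

    Concepts 100..103 are active, 104 inactive.  Noise: an inactive is-a
    row, a non-is-a (attribute) row, and an is-a row touching the inactive
    concept.  Expected graph: diamond 100->{101,102}->103 plus the
    redundant (100, 103).
    """
    def rel(rid, active, src, dst, type_id="116680003"):
        return f"{rid}\t20150901\t{active}\t900000000000207008\t{src}\t{dst}\t0\t{type_id}\t900000000000011006\t900000000000451002"

    concepts = [_RF2_CONCEPT_HEADER] + [
        f"{cid}\t20150901\t{act}\t900000000000207008\t900000000000074008"
        for cid, act in [(100, 1), (101, 1), (102, 1), (103, 1), (104, 0)]
    ]
    rels = [_RF2_REL_HEADER,
            rel(1, 1, 100, 101),
            rel(2, 1, 100, 102),
            rel(3, 1, 101, 103),
            rel(4, 1, 102, 103),
            rel(5, 1, 100, 103),            # the redundant shortcut
            rel(6, 0, 101, 100),            # inactive row: ignored
            rel(7, 1, 100, 103, "363698007"),  # attribute row: ignored
            rel(8, 1, 104, 103)]            # touches inactive concept: dropped
    cpath = tmp_path / "sct2_Concept_Snapshot.txt"
    rpath = tmp_path / "sct2_Relationship_Snapshot.txt"
    cpath.write_text("\n".join(concepts) + "\n")
    rpath.write_text("\n".join(rels) + "\n")
    return cpath, rpath


@pytest.fixture
def mrrel_fixture(tmp_path):
    """MRREL.RRF rows encoding the chain + shortcut under SAB=GO at AUI level.

    REL=CHD asserts AUI2 is a child of AUI1.  Noise: a SUPPRESS='O' row, a
    non-hierarchical REL=RB row, and rows from another vocabulary.
    """
    def row(aui1, rel, aui2, rela, sab, suppress=""):
        cols = ["C000000", aui1, "AUI", rel, "C000001", aui2, "AUI", rela,
                "R00000000", "", sab, sab, "", "", suppress, ""]
        return "|".join(cols) + "|"

    parent_child = [(p, c) for c, p in HORMONE_CHAIN + [HORMONE_SHORTCUT]]
    lines = [row(f"A{p[3:]}", "CHD", f"A{c[3:]}", "isa", "GO")
             for p, c in parent_child]
    lines.append(row("A0008150", "CHD", "A9000001", "isa", "GO", suppress="O"))
    lines.append(row("A0008150", "RB", "A0046879", "", "GO"))
    lines.append(row("A7770001", "CHD", "A7770002", "isa", "MSH"))
    path = tmp_path / "MRREL.RRF"
    path.write_text("\n".join(lines) + "\n")
    return path
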