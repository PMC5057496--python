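"""Readers and writers for ontology hierarchy formats.

Every reader normalises its source into a :class:`~fedrr.graph.ConceptGraph`
with edges stored child->parent ("A is-a B" becomes the pair ``(A, B)``),
regardless of how the source file orients its rows.  Supported sources:

* OBO 1.2/1.4 flat files (Gene Ontology releases) — via :mod:`obonet`;
* SNOMED CT RF2 Snapshot concept + relationship TSV files;
* UMLS ``MRREL.RRF`` pipe-separated relation files at the AUI level;
* a generic two-column child<TAB>parent edge list.

Dropped rows (inactive, filtered, malformed targets) are counted and logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

import obonet
import pandas as pd

from .errors import EmptyGraphError, ParseError
from .graph import ConceptGraph, GraphStats, RedundantRelation

logger = logging.getLogger(__name__)

__all__ = [
    "SourceSpec",
    "load_source",
    "read_obo",
    "read_rf2",
    "read_mrrel",
    "read_edge_tsv",
    "write_edge_tsv",
    "write_report",
    "IS_A_TYPE_ID",
]

#: SNOMED CT relationship typeId of the is-a relation.
IS_A_TYPE_ID = "116680003"

# MRREL.RRF column positions (pipe-separated, no header).
_MRREL_AUI1 = 1
_MRREL_REL = 3
_MRREL_AUI2 = 5
_MRREL_RELA = 7
_MRREL_SAB = 10
_MRREL_SUPPRESS = 14
_MRREL_MIN_COLS = 15


@dataclass
class SourceSpec:
    """Which file(s) to read and how.

    ``format`` is one of ``obo``, ``rf2``, ``mrrel``, ``tsv``.  RF2 needs two
    paths (concept file then relationship file); the others need one.
    ``options`` carries format-specific filters, e.g. ``sab`` (source
    vocabulary) and ``suppress_obsolete`` for MRREL.
    """

    format: str
    paths: list[str]
    options: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.format not in ("obo", "rf2", "mrrel", "tsv"):
            raise ValueError(f"unknown format {self.format!r}")
        need = 2 if self.format == "rf2" else 1
        if len(self.paths) != need:
            raise ValueError(
                f"format {self.format!r} requires {need} path(s), got {len(self.paths)}")


def load_source(spec: SourceSpec) -> ConceptGraph:
    """Dispatch a :class:`SourceSpec` to the matching reader."""
    if spec.format == "obo":
        return read_obo(spec.paths[0])
    if spec.format == "rf2":
        return read_rf2(spec.paths[0], spec.paths[1])
    if spec.format == "mrrel":
        return read_mrrel(
            spec.paths[0],
            source_vocab=spec.options["sab"],
            suppress_obsolete=spec.options.get("suppress_obsolete", True),
        )
    return read_edge_tsv(spec.paths[0])


def read_obo(path) -> ConceptGraph:
    """Read the is-a hierarchy of an OBO flat file.

    Nodes are all non-obsolete ``[Term]`` stanzas; edges are the ``is_a:``
    tags of those terms whose target is itself a non-obsolete term.  Other
    relationship tags (``part_of`` etc.) are ignored, as are trailing ``!``
    comments (handled by the OBO parser).  Edges pointing at a term that has
    no stanza (e.g. an obsolete target) are dropped with a logged count.
    """
    try:
        g = obonet.read_obo(path)
    except ValueError as exc:
        raise ParseError(path, f"malformed OBO file: {exc}") from exc
    # obonet creates attribute-less placeholder nodes for referenced ids
    # that have no [Term] stanza of their own; those are not concepts.
    terms = {n for n, data in g.nodes(data=True) if data}
    edges = []
    dropped = 0
    for child, parent, key in g.edges(keys=True):
        if key != "is_a":
            continue
        if child not in terms or parent not in terms:
            dropped += 1
            continue
        edges.append((child, parent))
    if dropped:
        logger.warning("%s: dropped %d is_a edge(s) with missing target", path, dropped)
    return ConceptGraph(edges, nodes=terms)


def _require_columns(df: pd.DataFrame, cols: Iterable[str], path) -> None:
    for col in cols:
        if col not in df.columns:
            raise ParseError(path, f"missing required column {col!r}")


def read_rf2(concept_path, relationship_path) -> ConceptGraph:
    """Read a SNOMED CT RF2 Snapshot is-a hierarchy.

    Nodes are concept ids with ``active = 1``.  Edges are relationship rows
    with ``active = 1`` and ``typeId = 116680003`` (is-a), oriented
    ``(sourceId, destinationId)`` which is already child->parent in RF2.
    Rows touching inactive concepts are dropped with a logged count.
    """
    concepts = pd.read_csv(concept_path, sep="\t", dtype=str)
    _require_columns(concepts, ("id", "active"), concept_path)
    rels = pd.read_csv(relationship_path, sep="\t", dtype=str)
    _require_columns(
        rels, ("sourceId", "destinationId", "typeId", "active"), relationship_path)

    active = set(concepts.loc[concepts["active"] == "1", "id"])
    isa = rels[(rels["active"] == "1") & (rels["typeId"] == IS_A_TYPE_ID)]
    alive = isa["sourceId"].isin(active) & isa["destinationId"].isin(active)
    dropped = int((~alive).sum())
    if dropped:
        logger.warning(
            "%s: dropped %d is-a row(s) touching inactive concepts",
            relationship_path, dropped)
    edges = list(zip(isa.loc[alive, "sourceId"], isa.loc[alive, "destinationId"]))
    return ConceptGraph(edges, nodes=active)


def read_mrrel(path, source_vocab: str, suppress_obsolete: bool = True) -> ConceptGraph:
    """Read AUI-level is-a relations of one source vocabulary from MRREL.RRF.

    Keeps rows with ``SAB == source_vocab``, ``REL == 'CHD'`` and ``RELA`` of
    ``isa`` or empty; when ``suppress_obsolete`` is set, rows with
    ``SUPPRESS == 'O'`` are excluded.  In MRREL, ``REL`` is the relation the
    second atom has to the first, so a ``CHD`` row asserts that AUI2 is a
    child of AUI1 and is normalised to the edge ``(AUI2, AUI1)``.  Nodes are
    all AUIs appearing in kept rows.

    Raises :class:`~fedrr.errors.EmptyGraphError` when the source vocabulary
    is absent or the filters leave no hierarchical rows, and
    :class:`~fedrr.errors.ParseError` on rows with too few columns.
    """
    try:
        df = pd.read_csv(path, sep="|", header=None, dtype=str,
                         keep_default_na=False, engine="c", quoting=3)
    except pd.errors.ParserError as exc:
        raise ParseError(path, f"malformed RRF file: {exc}") from exc
    if df.shape[1] < _MRREL_MIN_COLS:
        raise ParseError(path, f"expected >= {_MRREL_MIN_COLS} pipe-separated "
                               f"columns, found {df.shape[1]}", line=1)

    in_sab = df[df[_MRREL_SAB] == source_vocab]
    if in_sab.empty:
        raise EmptyGraphError(
            f"{path}: no rows with SAB={source_vocab!r}; unknown source vocabulary?")

    kept = in_sab[(in_sab[_MRREL_REL] == "CHD")
                  & (in_sab[_MRREL_RELA].isin(("isa", "")))]
    if suppress_obsolete:
        n_before = len(kept)
        kept = kept[kept[_MRREL_SUPPRESS] != "O"]
        n_obsolete = n_before - len(kept)
        if n_obsolete:
            logger.info("%s: suppressed %d obsolete relation row(s)", path, n_obsolete)
    if kept.empty:
        raise EmptyGraphError(
            f"{path}: SAB={source_vocab!r} has no hierarchical is-a rows after filtering")
    logger.info("%s: kept %d of %d SAB=%s row(s)",
                path, len(kept), len(in_sab), source_vocab)
    edges = list(zip(kept[_MRREL_AUI2], kept[_MRREL_AUI1]))
    return ConceptGraph(edges)


def read_edge_tsv(path) -> ConceptGraph:
    """Read a generic two-column child<TAB>parent edge list.

    Blank lines and lines starting with ``#`` are ignored.  Any other line
    must have exactly two tab-separated fields.
    """
    edges = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(path, f"expected 2 tab-separated columns, "
                                       f"found {len(parts)}", line=lineno)
            edges.append((parts[0], parts[1]))
    return ConceptGraph(edges)


def write_edge_tsv(graph: ConceptGraph, path) -> None:
    """Write a graph's edges as a sorted child<TAB>parent list."""
    with open(path, "w", encoding="utf-8") as fh:
        for child, parent in sorted(graph.edges):
            fh.write(f"{child}\t{parent}\n")


def write_report(relations: list[RedundantRelation], stats: GraphStats, path) -> None:
    """Write a redundancy report: ``#`` stats preamble, then one TSV row per
    redundant relation, sorted by child then parent.

    Columns: child, parent, indirect_path_length, witness_path (nodes joined
    by ``|``).
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# n_concepts\t{stats.n_concepts}\n")
        fh.write(f"# n_relations\t{stats.n_relations}\n")
        fh.write(f"# tc_pairs\t{stats.tc_pairs}\n")
        fh.write(f"# rr_count\t{stats.rr_count}\n")
        fh.write(f"# rr_percent\t{stats.rr_percent:.5f}\n")
        fh.write(f"# c\t{stats.c:.2f}\n")
        fh.write("child\tparent\tindirect_path_length\twitness_path\n")
        for rel in sorted(relations, key=lambda r: (r.child, r.parent)):
            fh.write(f"{rel.child}\t{rel.parent}\t{rel.indirect_path_length}\t"
                     f"{'|'.join(rel.witness_path)}\n")
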