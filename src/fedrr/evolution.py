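"""Longitudinal analyses across ontology versions.

Two questions about an evolving hierarchy are answered here: how much the
relation set churns between releases (the *change rate*), and which edges
flip back and forth across releases (*revision reversals*).  The change
rate between an old edge set O and a new edge set N is

    (|N - O| + |O - N|) / (|O| + |N|)

using true set differences — note that in general ``N - O != O - N`` and
``|N - O| != |N| - |O|``.  The rate is symmetric, lies in [0, 1], is 0 iff
the sets are equal, and is 1 for disjoint non-empty sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

from .errors import UndefinedRateError
from .graph import ConceptGraph, fedrr_detect

__all__ = ["VersionDiff", "Reversal", "change_rate",
           "redundant_change_rate", "detect_reversals"]

Edge = tuple[str, str]


@dataclass(frozen=True)
class VersionDiff:
    """Edge-set difference between an old and a new version."""

    added: frozenset[Edge]      # N - O
    removed: frozenset[Edge]    # O - N
    change_rate: float
    n_old: int
    n_new: int


@dataclass(frozen=True)
class Reversal:
    """An edge whose revision was later undone.

    ``pattern`` is ``added-then-removed`` (absent, present, absent again) or
    ``removed-then-added``; ``versions`` are the labels of the two releases
    where the presence flips occurred, in order.
    """

    edge: Edge
    pattern: str
    versions: tuple[str, ...]


def change_rate(old_edges: Iterable[Edge], new_edges: Iterable[Edge]) -> VersionDiff:
    """Diff two versions' edge sets and compute the change rate.

    Raises :class:`~fedrr.errors.UndefinedRateError` when both sets are
    empty (the rate's denominator vanishes).
    """
    old, new = frozenset(old_edges), frozenset(new_edges)
    if not old and not new:
        raise UndefinedRateError("change rate undefined for two empty edge sets")
    added = new - old
    removed = old - new
    rate = (len(added) + len(removed)) / (len(old) + len(new))
    return VersionDiff(added, removed, rate, len(old), len(new))


def redundant_change_rate(old_graph: ConceptGraph, new_graph: ConceptGraph
                          ) -> tuple[Optional[VersionDiff], VersionDiff]:
    """Change rate of the redundant edges versus the full edge sets.

    Returns ``(rr_diff, all_diff)``.  When neither version contains any
    redundant edge the redundant-set rate is undefined and ``rr_diff`` is
    ``None`` rather than zero.
    """
    old_rr, _ = fedrr_detect(old_graph)
    new_rr, _ = fedrr_detect(new_graph)
    all_diff = change_rate(old_graph.edges, new_graph.edges)
    if not old_rr and not new_rr:
        return None, all_diff
    return change_rate(old_rr, new_rr), all_diff


def _runs(bits: list[bool]) -> list[tuple[bool, int]]:
    """Compress a presence sequence to (value, start-index) runs."""
    runs = []
    for i, b in enumerate(bits):
        if not runs or runs[-1][0] != b:
            runs.append((b, i))
    return runs


def detect_reversals(edge_sets: list[tuple[str, set[Edge]]]) -> list[Reversal]:
    """Find every revision reversal across >= 3 chronological versions.

    For each edge ever present, its presence sequence across versions is
    scanned; every absent->present->absent alternation (with arbitrary gaps)
    yields an ``added-then-removed`` reversal and every
    present->absent->present alternation a ``removed-then-added`` one.
    Overlapping occurrences each count: a sequence 0,1,0,1 holds one of
    each pattern.
    """
    if len(edge_sets) < 3:
        raise ValueError("reversal detection needs at least 3 versions")
    labels = [label for label, _ in edge_sets]
    sets = [frozenset(es) for _, es in edge_sets]
    universe: set[Edge] = set().union(*sets)

    out: list[Reversal] = []
    for edge in sorted(universe):
        bits = [edge in s for s in sets]
        runs = _runs(bits)
        for j in range(len(runs) - 2):
            (b0, _), (_, i1), (_, i2) = runs[j], runs[j + 1], runs[j + 2]
            pattern = "removed-then-added" if b0 else "added-then-removed"
            out.append(Reversal(edge, pattern, (labels[i1], labels[i2])))
    return out
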