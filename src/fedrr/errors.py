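"""Exception hierarchy shared across the package."""

from __future__ import annotations


class FedrrError(Exception):
    """Base class for all package errors."""


class GraphError(FedrrError):
    """Structural problem with a concept graph."""


class SelfLoopError(GraphError):
    """An edge relates a concept to itself."""

    def __init__(self, concept: str):
        self.concept = concept
        super().__init__(f"self-loop on concept {concept!r}")


class CycleError(GraphError):
    """The hierarchy contains a directed cycle.

    ``nodes`` holds at least one node that lies on (or feeds into) a cycle;
    a topological order cannot place these nodes.
    """

    def __init__(self, nodes):
        self.nodes = list(nodes)
        shown = ", ".join(map(str, self.nodes[:5]))
        more = "" if len(self.nodes) <= 5 else f" (+{len(self.nodes) - 5} more)"
        super().__init__(f"hierarchy is not acyclic; nodes on a cycle: {shown}{more}")


class InconsistentPairError(GraphError):
    """A pair claimed redundant has no indirect path in the graph."""


class ParseError(FedrrError):
    """A source file could not be parsed."""

    def __init__(self, path, message: str, line: int | None = None):
        self.path = path
        self.line = line
        where = f"{path}:{line}" if line is not None else str(path)
        super().__init__(f"{where}: {message}")


class EmptyGraphError(FedrrError):
    """Filtering a relation source produced no edges at all."""


class InfeasibleSpecError(FedrrError):
    """A random-DAG specification cannot be satisfied."""


class UndefinedRateError(FedrrError):
    """A change rate is requested for two empty relation sets."""
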