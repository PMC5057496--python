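"""Seeded generation of random layered ontology-like DAGs.

Real is-a hierarchies are broad at the bottom and narrow toward a handful of
roots, with each parent holding a bounded number of children.  The generator
emulates this shape: nodes are assigned to layers whose sizes decay
geometrically from the bottom up, every non-bottom node draws its children
uniformly at random from the strictly lower layers, and per-node child
counts are balanced so the requested edge total is hit exactly.  Because
edges only run from lower layers to higher ones, acyclicity holds by
construction.

A ``DAG(N, E, C_min, C_max)`` instance has exactly ``N`` nodes, exactly
``E`` edges, and every node has either no children (bottom layer) or a
children count within ``[C_min, C_max]``.  Identical seeds reproduce the
graph edge-for-edge.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil, floor

import numpy as np
import pandas as pd

from .errors import InfeasibleSpecError
from .graph import ConceptGraph, compute_stats

__all__ = ["RandomDagSpec", "generate", "density_sweep"]


@dataclass(frozen=True)
class RandomDagSpec:
    """Parameters of a random ``DAG(N, E, C_min, C_max)`` draw."""

    n_nodes: int
    n_edges: int
    c_min: int
    c_max: int
    seed: int

    def __post_init__(self):
        if self.n_nodes < 1:
            raise InfeasibleSpecError("need at least one node")
        if self.n_edges < 0:
            raise InfeasibleSpecError("edge count must be non-negative")
        if not (0 <= self.c_min <= self.c_max):
            raise InfeasibleSpecError("need 0 <= c_min <= c_max")
        if self.n_edges > self.n_nodes * self.c_max:
            raise InfeasibleSpecError(
                f"{self.n_edges} edges unreachable with {self.n_nodes} nodes "
                f"and at most {self.c_max} children per node")


def _n_internal(spec: RandomDagSpec) -> int:
    """Number of non-bottom (parent) nodes so child counts can sum to E.

    Child counts are balanced at ``E // m`` or ``E // m + 1`` over the ``m``
    internal nodes, so ``m`` must satisfy ``m*c_min <= E <= m*c_max``, leave
    at least one bottom node, and keep the largest count within the bottom
    pool ``N - m`` (the lowest internal layer draws only from the bottom).
    Among valid values, the one closest to ``E / mean(c_min, c_max)`` is
    used so densities track the requested child-count range.
    """
    n, e = spec.n_nodes, spec.n_edges
    if e == 0:
        return 0
    if spec.c_max == 0:
        raise InfeasibleSpecError("edges requested but c_max is 0")
    low = ceil(e / spec.c_max)
    high = floor(e / spec.c_min) if spec.c_min > 0 else n - 1
    high = min(high, n - 1)  # keep at least one bottom node
    target = round(2 * e / (spec.c_min + spec.c_max))
    target = min(max(target, low), high) if low <= high else low

    def fits(m: int) -> bool:
        base, extra = divmod(e, m)
        return (base + (1 if extra else 0)) <= n - m

    best = None
    for m in range(low, high + 1):
        if fits(m) and (best is None or abs(m - target) < abs(best - target)):
            best = m
    if best is None:
        raise InfeasibleSpecError(
            f"no layered DAG with {n} nodes, {e} edges and child counts "
            f"in [{spec.c_min}, {spec.c_max}]")
    return best


def _layer_sizes(m: int, c_min: int, c_max: int) -> list[int]:
    """Sizes of the internal layers, bottom-up, decaying geometrically.

    The decay ratio tracks the mean child count: in a forest each layer
    would be about that factor smaller than the one below it, which is what
    puts a 500k-node hierarchy at around 6-12 layers.
    """
    ratio = max(2.0, (c_min + c_max) / 2.0)
    sizes = []
    remaining = m
    while remaining > 0:
        s = max(1, round(remaining * (1 - 1 / ratio)))
        s = min(s, remaining)
        sizes.append(s)
        remaining -= s
    return sizes


def generate(spec: RandomDagSpec) -> tuple[ConceptGraph, int]:
    """Draw one random layered DAG; returns ``(graph, n_layers)``.

    Node identifiers are ``n0 .. n{N-1}``.  Layer 1 is the bottom (childless)
    layer; every node in a higher layer draws its children without
    replacement from the pool of all strictly lower nodes.  Per-node child
    counts are ``E // m`` or ``E // m + 1`` over the ``m`` internal nodes,
    guaranteed to lie in ``[c_min, c_max]`` by the choice of ``m``.

    Raises :class:`~fedrr.errors.InfeasibleSpecError` when no layered graph
    can satisfy the spec (including a lower-layer pool too small to supply a
    node's children).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_nodes
    m = _n_internal(spec)
    names = [f"n{i}" for i in range(n)]
    if m == 0:
        return ConceptGraph((), nodes=names), 1

    internal_sizes = _layer_sizes(m, spec.c_min, spec.c_max)
    n_layers = 1 + len(internal_sizes)

    # per-parent child counts: as even as possible, summing exactly to E
    base, extra = divmod(spec.n_edges, m)
    counts = [base + 1] * extra + [base] * (m - extra)
    rng.shuffle(counts)

    # nodes 0..(n-m-1) form the bottom layer; internal layers stack above
    edges: list[tuple[str, str]] = []
    pool_end = n - m  # nodes with index < pool_end are in strictly lower layers
    next_node = n - m
    ci = 0
    for size in internal_sizes:
        pool = np.arange(pool_end)
        for _ in range(size):
            cnt = counts[ci]
            ci += 1
            if cnt > len(pool):
                raise InfeasibleSpecError(
                    f"a node needs {cnt} children but only {len(pool)} "
                    f"lower-layer nodes exist")
            parent = names[next_node]
            for child_idx in rng.choice(pool, size=cnt, replace=False):
                edges.append((names[int(child_idx)], parent))
            next_node += 1
        pool_end = next_node
    return ConceptGraph(edges, nodes=names), n_layers


def density_sweep(base_spec: RandomDagSpec, edge_counts: list[int],
                  n_reps: int = 5) -> pd.DataFrame:
    """Redundancy metrics across an edge-density sweep.

    For each edge count, ``n_reps`` graphs are drawn with seeds derived
    deterministically from the base seed, and the run with the median
    redundant-relation count is reported.  Columns: ``n_edges``,
    ``n_layers``, ``tc_pairs``, ``rr_count``, ``rr_percent``.
    """
    rows = []
    for i, n_edges in enumerate(edge_counts):
        reps = []
        for rep in range(n_reps):
            seed = (base_spec.seed + 100_003 * i + rep) % (2**31)
            spec = RandomDagSpec(base_spec.n_nodes, n_edges,
                                 base_spec.c_min, base_spec.c_max, seed)
            graph, n_layers = generate(spec)
            stats = compute_stats(graph)
            reps.append((stats.rr_count, n_layers, stats))
        reps.sort(key=lambda r: r[0])
        rr, n_layers, stats = reps[len(reps) // 2]
        rows.append({"n_edges": n_edges, "n_layers": n_layers,
                     "tc_pairs": stats.tc_pairs, "rr_count": rr,
                     "rr_percent": stats.rr_percent})
    return pd.DataFrame(rows)
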