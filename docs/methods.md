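# Methods

## Model

An ontology hierarchy is a directed acyclic graph *G* = (*V*, *E*): nodes
are concept identifiers (opaque strings — GO accessions, SNOMED CT integer
ids, UMLS AUIs), and an edge is stored as the ordered pair
`(child, parent)` meaning "child is-a parent". All file readers normalise
to this orientation. Because is-a is transitive, an edge (*s*, *t*) that
coexists with an indirect path of length ≥ 2 from *s* to *t* asserts
nothing new; it is a *redundant relation* and the object of detection.

Acyclicity is assumed, not repaired: a cycle makes subsumption meaningless,
so topological sorting fails loudly with a witness list of nodes that could
not be placed. Cycle-breaking is a separate curation task upstream of this
tool. Self-loops are rejected at construction; duplicate edges are
silently deduplicated with a logged count (set semantics).

## Detection algorithm

Nodes are processed in a Kahn topological order (children before parents,
FIFO queue). When node *u* is dequeued, all of its children have final
sets, and

* D-set: `D[u] = {v | (v, u) in E}` — the direct children;
* I-set: `I[u] = union over v in D[u] of (D[v] | I[v])` — every node with a
  path of length ≥ 2 to *u*.

Every `v in D[u] & I[u]` marks the redundant edge `(v, u)`. Correctness
follows by induction on dequeue order — when *u* is dequeued each child's
sets already equal the true direct/indirect descendant sets — and the
detected set is invariant to queue tie-breaking (the sets themselves are
order-free unions). The FIFO tie-break is kept only so that witness paths
are reproducible run-to-run.

Cost is `O(c*|V| + |E|)` with `c = sum_v(|D_v| + |I_v|) / |V|`, the mean
transitive-closure pairs per concept. The sum counts a redundant pair
twice — once in the D-set, once in the I-set of the same parent — because
the formula is taken literally over both sets; consequently the closure
total of a graph equals that of its transitive reduction plus the redundant
count, a property the test suite checks. Identifiers are interned to dense
integers `0..|V|-1` so the I-sets (millions of members at SNOMED scale) are
sets of small ints; nothing is freed early — at ≈ 5.5 M closure pairs the
working set is well within a workstation's memory, and simplicity wins.

The brute-force cross-check (`oracle_detect`) answers the same question per
edge: remove `(s, t)`, search for any remaining path `s -> t`. In a DAG
such a path necessarily has length ≥ 2, so the two detectors must agree
exactly; the suite verifies this on a thousand random DAGs, and separately
checks the detected set against networkx's transitive reduction — two
independent routes to the same answer.

## Indirect-path lengths

Released hierarchies are summarised by how long the indirect evidence path
is (ℓ = 2, 3, …). Whether "the" indirect path means the longest or the
shortest one is genuinely open; the default here is the **longest** path
(dynamic programming over the topological order, direct edge excluded),
because the motivating GO example is naturally read as the full five-step
chain, and the longest path bounds how much structure the shortcut
collapses. `classify_lengths(..., metric="shortest")` (and the CLI's
`--length-metric`) switches the convention. Lengths are always ≥ 2; asking
for the length of a pair with no indirect path is an error, not a zero.

## File formats

* **OBO** (GO releases): parsed with `obonet`. Non-obsolete `[Term]`
  stanzas become nodes; each `is_a:` tag one edge; `part_of` and other
  relationship tags are ignored. Targets with no stanza of their own
  (e.g. obsolete targets) surface as attribute-less placeholder nodes and
  their edges are dropped with a logged count.
* **SNOMED CT RF2 Snapshot**: concepts with `active = 1` are nodes; edges
  are relationship rows with `active = 1` and `typeId = 116680003` (is-a),
  oriented `(sourceId, destinationId)`. Rows touching inactive concepts
  are dropped and counted. The whole active is-a graph is treated as one
  DAG; sub-hierarchies are not split out. Full/Delta history files are out
  of scope.
* **UMLS MRREL.RRF** (AUI level): pipe-separated, no quoting, UTF-8.
  The kept-row predicate is `SAB == <source>`, `REL == 'CHD'`,
  `RELA in {'isa', ''}`, and (by default) `SUPPRESS != 'O'`. Since `REL`
  describes the second atom's relation to the first, a `CHD` row is the
  edge `(AUI2, AUI1)`. The exact predicate for "is-a" is not standardised
  across consumers, so it is a documented, test-pinned choice here; an
  empty result after filtering is an explicit error rather than a silent
  zero-redundancy report.
* **Edge TSV**: two tab-separated columns child, parent; `#` comments.
  The report writer emits `#`-prefixed summary lines (|V|, |E|, TC, RR,
  RR%, c) followed by one row per redundant relation, sorted by child then
  parent for deterministic diffs.

## Random layered hierarchies

`DAG(N, E, C_min, C_max)` draws emulate the shape of curated ontologies:
broad bottom, narrow top, bounded fan-in of children per parent. The
construction: choose the number *m* of internal (parent) nodes so that
per-node child counts of `E//m` or `E//m + 1` lie in `[C_min, C_max]`
(picking *m* nearest `E / mean(C_min, C_max)`); stack internal layers whose
sizes decay geometrically with ratio `max(2, mean(C_min, C_max))` above a
bottom layer of `N - m` childless nodes; each internal node samples its
children uniformly without replacement from all strictly lower nodes.
Edges only run upward, so acyclicity holds by construction; N and E are hit
exactly; a single `numpy` generator seeded from the spec makes draws
reproducible edge-for-edge. Specs too close to the layered capacity (or
otherwise unsatisfiable) raise an infeasibility error up front.

The decay ratio reproduces realistic layer counts (about 6–12 layers for
half-million-node draws, fewer when the child-count cap is generous), and
redundancy arises only from genuinely random shortcuts, which keeps random
hierarchies far less redundant than curated ones at comparable density —
the qualitative contrast the generator exists to exhibit. What these draws
do *not* emulate: semantic clustering into sub-hierarchies, heavy-tailed
degree distributions, or the editorial correlation between shortcuts and
hub concepts in real ontologies; a detector result on random draws
therefore validates correctness and scaling, not curation behaviour.

`density_sweep` follows the published experimental procedure: per edge
count it runs five seeded draws and reports the run with the median
redundant count. At the desk scale used in the tests (N = 5,000, E from
5,500 to 13,000 — a 1:100 scale-down of the published half-million-node
sweep) the median redundant counts are small (units), so the stepwise
trend is checked at a fixed seed while the robust signal is the
end-to-end increase from the sparsest to the densest sweep point.

## Version analyses

The change rate between an old edge set O and a new edge set N is
`(|N-O| + |O-N|) / (|O| + |N|)` using true set differences (in general
`N-O != O-N` and `|N-O| != |N| - |O|`). It is symmetric, lies in [0, 1],
is 0 iff the sets are equal, and is undefined (an error) when both sets
are empty. `redundant_change_rate` applies it to the detected redundant
subsets and the full edge sets of two versions; when neither version has
redundant edges the redundant-set rate is reported as absent (`None`),
never as zero.

A *revision reversal* is an edge whose presence across ≥ 3 chronological
versions alternates: absent → present → absent (added-then-removed) or
present → absent → present (removed-then-added), gaps allowed. The scan
run-length-compresses each edge's presence sequence and emits one reversal
per alternation triple, so overlapping patterns each count (0,1,0,1 holds
one of each). Versions are opaque labels; no date parsing. Attribution of
flips to editorial causes, and the "segment induced" by a redundant
relation, are out of scope.

## Numerical and degenerate-input choices

* Empty graph: closure total 0; `c` and RR% reported as 0, not NaN.
* `GraphStats.from_counts` reproduces summary constants from published
  counts exactly as ratios (`c = TC / |V|`, `RR% = 100 * RR / TC`).
* All randomness flows through explicit integer seeds; sweep sub-seeds are
  derived arithmetically from the base seed and kept below 2^31.
* Report rows and generated edge lists are emitted sorted, so identical
  inputs yield byte-identical outputs.

## Known limitations

Only a single relation type is analysed per run; cross-relation redundancy
(e.g. is-a composed with part-of) is out of scope, as are OWL/RDF parsing,
description-logic reasoning, and any cycle-repair heuristics. The
all-pairs longest-path baseline exists only as the small-instance oracle —
running it at release scale is exactly what the detector is designed to
avoid. Release-scale count reproductions require the archived GO/SNOMED CT
release files, which are large and (for SNOMED CT) licensed; the
corresponding tests run only when those files are provided locally.
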