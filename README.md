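# fedrr

Fast, exhaustive detection of redundant is-a relations in biomedical
ontology hierarchies.

## The problem

Hierarchical relations such as *is-a* are transitive: if A is-a B and B is-a
C, then A is-a C follows and — by the principle of parsimony — should not be
asserted explicitly. A **redundant relation** in a hierarchy
*G* = (*V*, *E*) is a direct edge (*s*, *t*) ∈ *E* for which an indirect
path (length ≥ 2) from *s* to *t* also exists. Such edges are curation
defects: they inflate maintenance burden and short-circuit every method
built on ontological distance or neighborhood (semantic similarity,
alignment, mapping). Large terminologies — SNOMED CT with >300 k active
concepts, the Gene Ontology, the UMLS source vocabularies — accumulate
hundreds to thousands of them as they evolve.

Finding them naively means an all-pairs longest-path computation,
*O*(|*V*|·|*E*|), which is intractable at SNOMED scale. This package finds
**all** of them in *O*(*c*·|*V*| + |*E*|) time by dynamic programming over a
topological order: for each node *u* it maintains the **D-set**
*D<sub>u</sub>* = {*v* | (*v*, *u*) ∈ *E*} of direct children and the
**I-set** *I<sub>u</sub>* of all indirect descendants, computed as
*I<sub>u</sub>* = ⋃<sub>*v* ∈ *D<sub>u</sub>*</sub> (*D<sub>v</sub>* ∪ *I<sub>v</sub>*).
An edge (*v*, *u*) is redundant exactly when *v* ∈ *D<sub>u</sub>* ∩
*I<sub>u</sub>*. The constant *c* = Σ<sub>*v*</sub>(|*D<sub>v</sub>*| +
|*I<sub>v</sub>*|) / |*V*| — the transitive-closure pair total per concept —
is small in practice (≈ 17 for SNOMED CT, ≈ 13 for GO).

Besides the detector, the package ships:

* readers for OBO flat files, SNOMED CT RF2 Snapshot files, UMLS
  `MRREL.RRF` (AUI level), and generic child↹parent TSV edge lists;
* a seeded random layered DAG generator `DAG(N, E, C_min, C_max)` for
  scalability and density experiments;
* longitudinal analyses: edge-set change rates
  (|N−O| + |O−N|) / (|O| + |N|) between versions, and revision-reversal
  detection (edges added then removed again, or vice versa);
* a `fedrr` command-line tool (`detect | stats | gen | diff | reversals`).

## Worked example

The classic defect pattern from GO: *hormone secretion* (GO:0046879) is-a
*hormone transport* is-a … is-a *biological process* (GO:0008150) in five
steps, while `GO:0046879 is-a GO:0008150` is *also* asserted directly.

```python
from fedrr import ConceptGraph, fedrr_detect, classify_lengths, compute_stats

edges = [
    ("GO:0046879", "GO:0009914"),
    ("GO:0009914", "GO:0010817"),
    ("GO:0010817", "GO:0065008"),
    ("GO:0065008", "GO:0065007"),
    ("GO:0065007", "GO:0008150"),
    ("GO:0046879", "GO:0008150"),   # the redundant shortcut
]
g = ConceptGraph(edges)
pairs, sets = fedrr_detect(g)
print(pairs)
print(classify_lengths(g, pairs)[0])
print(compute_stats(g))
```

prints

```
{('GO:0046879', 'GO:0008150')}
RedundantRelation(child='GO:0046879', parent='GO:0008150', indirect_path_length=5, witness_path=('GO:0046879', 'GO:0009914', 'GO:0010817', 'GO:0065008', 'GO:0065007', 'GO:0008150'))
GraphStats(n_concepts=6, n_relations=6, tc_pairs=16, rr_count=1, rr_percent=6.25, c=2.6666666666666665)
```

i.e. exactly one redundant edge, whose longest indirect path has 5 steps;
the graph has 16 transitive-closure pairs (the redundant pair counts once in
the D-set and once in the I-set of GO:0008150), so 6.25 % of closure pairs
are redundant assertions.

The same from the shell:

```sh
fedrr detect --format tsv --in chain.tsv --out report.tsv
fedrr stats --format obo --in go.obo
fedrr gen -N 1000 -E 1300 --cmin 2 --cmax 20 --seed 7 --out random.tsv
fedrr diff old.tsv new.tsv
```

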