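# ppimod

Prior-knowledge-based functional module mining from protein–protein
interaction (PPI) networks.

Curated PPI databases under-record the interactions inside many protein
complexes, so purely topological module detectors miss complexes whose
recorded shape is sparse — most visibly "star/spoke" complexes, where the
leaves share a function but no recorded edges.  `ppimod` mines the Gene
Ontology for an independent functional signal: it computes
information-content (relevance) semantic similarity between gene products,

    sim(c₁, c₂) = max_{c ∈ S(c₁,c₂)} [ 2 ln p(c) / (ln p(c₁) + ln p(c₂)) ] · (1 − p(c)),

extracts gene pairs with near-perfect similarity (≥ 0.999 by default) as
*functional pairs*, and uses them in two ways:

1. **edge augmentation** — add the pairs to the network as ordinary edges;
2. **must-link supervision** — treat the pairs as constraints: seed
   hierarchical clustering with their transitive closures (ssHC), or
   over-split with NG / MCL / MCODE and merge sub-modules connected by
   constraints (ssNG, ssMCL, ssMCODE).

The library also provides the four base detectors (agglomerative
hierarchical clustering on edge-clustering-coefficient or
Czekanowski–Dice neighborhood similarity, Girvan–Newman divisive
clustering, Markov clustering, MCODE), the topological metrics behind
them, modularity/enrichment/coverage evaluation against a complex
catalog, and a planted-module benchmark generator (clique and star
topologies) so the whole pipeline runs offline.

## Worked example

```python
from ppimod import (
    generate_benchmark, generate_constraints, augment_network,
    build_transitive_closures, mcl, ss_two_stage, partition_agreement,
)

bench = generate_benchmark(seed=1)          # 3 cliques + 3 stars of size 10
cons = generate_constraints(bench, within_rate=0.6, seed=11)
print(len(cons), "constraints")
closures = build_transitive_closures(cons)
print(len(closures), "closures, sizes", sorted(len(c) for c in closures))

plain = mcl(bench.network, r=5.0)
ss = ss_two_stage(augment_network(bench.network, cons), "mcl", cons)
print("plain MCL r=5:", len(plain), "modules, ARI",
      round(partition_agreement(plain, bench.truth), 3))
print("ssMCL:       ", len(ss), "modules, ARI",
      round(partition_agreement(ss, bench.truth), 3))
```

prints

```
167 constraints
6 closures, sizes [10, 10, 10, 10, 10, 10]
plain MCL r=5: 24 modules, ARI 0.56
ssMCL:        6 modules, ARI 1.0
```

Plain MCL at the over-splitting inflation r = 5 shatters the 60-protein
benchmark into 24 modules (adjusted Rand index 0.56 against the planted
truth — the star modules fragment into singletons).  The same constraints
that augment the network then merge the sub-modules back: ssMCL returns
exactly the six planted modules (ARI 1.0).

The same workflow is available from the shell:

```sh
ppimod simulate --seed 1 --outdir bench/
ppimod semsim --obo bench/toy.obo --gaf bench/toy.gaf --out pairs.tsv
ppimod pairs --pairs pairs.tsv --min-sim 0.999 --out constraints.tsv
ppimod augment --network bench/network.tsv --pairs bench/constraints.tsv --out aug.tsv
ppimod sscluster --method mcl --network aug.tsv --pairs bench/constraints.tsv --out modules.tsv
ppimod evaluate --modules modules.tsv --network bench/network.tsv --catalog catalog.tsv --out report.tsv
```

See `docs/methods.md` for the model, parameter meanings and the design
choices.

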