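# rankedcoal

Probabilities of **ranked gene tree topologies** under the multispecies
coalescent, in polynomial time, with the tools that grow out of them:
unranked gene tree probabilities, the MAC/MDC parsimony criteria, and
maximum-likelihood species-tree inference from collections of ranked gene
trees.

## The problem

Gene trees disagree with the species tree that contains them because of
incomplete lineage sorting. Statistical species-tree inference therefore
needs `P[G | T]`: the probability of an observed gene tree `G` given a
candidate species tree `T`. For *unranked* gene tree topologies no
polynomial-time algorithm is known — existing approaches enumerate
coalescent histories or ancestral configurations, both of which can grow
exponentially. A **ranked** gene tree topology (the tree shape plus the
temporal order of its internal nodes, without branch lengths) removes that
obstruction: the ranking fixes the sequence of coalescences, so the
ancestral configuration in each inter-divergence interval is determined by
a single integer, the number of surviving lineages.

## The algorithm

Let the species tree on `n` taxa have divergence times
`s_1 > … > s_{n−1}` (coalescent units, one sampled gene per species) and
intervals `τ_i = [s_i, s_{i−1})`. Writing `G_{i,ℓ}` for the part of the
gene tree more recent than `s_i` with `ℓ` surviving lineages, the package
computes

* `g_i` — the minimum number of gene lineages at `s_i` compatible with
  the ranking, from the species-side least common ancestors of the gene
  nodes;
* `k_{i,j,z}` — lineage counts per population `z` of the "beaded"
  species tree in interval `τ_i`, just after the `j`-th coalescence of the
  interval (forward in time), with total rates
  `λ_{i,j} = Σ_z C(k_{i,j,z}, 2)`;
* the per-interval transition probability (hypoexponential CDF/density)

  `P[G_{i−1,ℓ'} | G_{i,ℓ}, T] = Σ_j exp(−λ_{i,j}(s_{i−1}−s_i)) / Π_{k≠j}(λ_{i,k}−λ_{i,j})`;

* the dynamic program
  `P[G_{i,ℓ}|T] = Σ_{ℓ'} P[G_{i,ℓ}|G_{i+1,ℓ'},T] · P[G_{i+1,ℓ'}|T]`
  with `P[G_{n−1,n}|T] = 1`, and finally

  `P[G|T] = Σ_{ℓ} P[G_{1,ℓ}|T] / H_ℓ`, `H_ℓ = ℓ!(ℓ−1)!/2^{ℓ−1}`,

  the labeled-history correction for coalescences above the root.

Total cost is `O(n^5)`. Built on top: unranked probabilities by summing
over all rankings (linear extensions) of a shape; the **MAC** criterion
`Σ_i (g_i − (i+1))` counting coalescences forced into over-ancient
intervals; classical **MDC** as a baseline; a multinomial likelihood
`Π_i P[G^{(i)}|T]^{n_i}` maximized over divergence times (and, for small
`n`, over all ranked species topologies); and an exact MSC simulator used
as a Monte-Carlo cross-check.

## Worked example

The five-taxon species tree `(((A,B)4,C)2,(D,E)3)1` with node ages
4 > 2 > 1.7 > 1:

```python
from rankedcoal import (build_species_tree, parse_ranked_newick,
                        ranked_probability, mac_cost, mdc_cost)

model = build_species_tree("(((A:1,B:1):1,C:2):2,(D:1.7,E:1.7):2.3);")
for nwk in ["(((A,B)4,C)2,(D,E)3)1;",   # matches the species ranking
            "(((A,B)3,C)2,(D,E)4)1;",   # same shape, AB/DE ranks swapped
            "((A,(B,C)3)2,(D,E)4)1;"]:  # B,C coalesce before A joins
    G = parse_ranked_newick(nwk)
    print(nwk, ranked_probability(G, model),
          mac_cost(G, model.topology), mdc_cost(G, model.topology))
```

prints

```
(((A,B)4,C)2,(D,E)3)1; 0.3541014467979013 0 0
(((A,B)3,C)2,(D,E)4)1; 0.06131666081742271 1 0
((A,(B,C)3)2,(D,E)4)1; 0.04614250887688016 2 1
```

The matching ranked topology is the most probable (no anomaly at these
branch lengths). The second tree has the *same unranked shape* as the
species tree but swaps the order of the AB and DE coalescences — MDC is
blind to this (cost 0) while MAC charges one ancient coalescence. The
third tree is a genuine deep-coalescence case: MDC cost 1, MAC cost 2
(the uncoalesced A,B pair occupies an extra lineage across two beaded
edges). Summing ranked probabilities over the three rankings of the shape
`(((A,B),C),(D,E))` gives its unranked probability, 0.6356408285177936.

The same computations are available from the shell:

```sh
rankedcoal prob-ranked species.nwk genes.txt      # TSV: newick, P, log P
rankedcoal prob-unranked species.nwk gene.txt     # sum over rankings
rankedcoal mac species.nwk genes.txt              # parsimony cost tables
rankedcoal simulate species.nwk -n 1000 --seed 7  # MSC replicates
rankedcoal mle genes.txt --seed 1                 # ML species tree (JSON)
```

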