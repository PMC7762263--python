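# iacd — community detection by internode attraction

`iacd` finds non-overlapping communities in undirected, unweighted networks
with a parameter-free, deterministic method built on a gravity analogy.
It is aimed at anyone partitioning interaction networks — protein–protein
interaction maps, social graphs, co-purchase networks — who wants a stable
result without tuning a resolution parameter or supplying the number of
communities.

## The method

For a simple graph *G = (V, E)*:

1. **Node influence.** Every node gets
   `IF(v) = Deg(v) · KScore(v)`, the product of its degree and its k-core
   (k-shell) index, so a node is influential when it is both well connected
   and close to the network's core. Influence is normalised to
   `GIF(v) = IF(v) / MAX_IF ∈ [0, 1]`.

2. **Internode attraction.** For each node *v* and each candidate *m* in its
   closed second-order neighborhood (all nodes within distance 2 reachable
   through *v*'s neighbors):

   `Attr(v, m) = P(v, m) · GIF(v) · GIF(m) / SL(v, m)²`

   where `P(v, m) = (Triangle(v, m) + 1) / Deg(v)` counts the common
   neighbors of the pair and `SL` is their shortest path length (1 or 2).
   Like gravity: proportional to the masses (influences), inversely
   proportional to the squared distance.

3. **Pairing and merging.** Each node is paired with its strongest attractor
   (maximal `Attr`, ties to the smaller `SL`, remaining ties to the smallest
   label by default). The pairs are merged with union-find; the connected
   components of the pair graph are the communities.

The pipeline costs O(n·⟨k⟩² + e) time and needs no parameters.

The package also provides the three partition-agreement metrics used to
score detections against ground truth — NMI (arithmetic normalisation),
the Hubert–Arabie adjusted Rand index, and Purity — plus LFR and
planted-partition benchmark generators with seeded, reproducible output.

## Worked example

The package ships a 16-node, 30-edge example network with three planted
communities (`iacd.synthetic.figure1_fixture`). From Python:

```python
from iacd import detect, influence_table
from iacd.synthetic import figure1_fixture

inst = figure1_fixture()          # self-validates on construction
inf = influence_table(inst.network)
print(inf.influence["1"], round(inf.gif["8"], 2))   # -> 15 0.27
print(detect(inst.network).community_sets())
```

prints influence 15 for node 1 (degree 5 in the 3-core), normalised
influence 0.27 for the peripheral node 8 (4/15), and the three communities
`{1,2,3,4,5}`, `{6,…,12}`, `{13,…,16}`.

The same run from the shell:

```console
$ iacd detect --input example.edgelist --output pred.tsv
INFO iacd: n=16 e=30 communities=3 sizes=[7, 5, 4] elapsed=0.001s
$ iacd evaluate --pred pred.tsv --truth example.communities
nmi	1.0000
ari	1.0000
purity	1.0000
```

All three agreement scores are 1.0000 because the detected partition equals
the planted one exactly. `iacd benchmark` sweeps LFR parameter grids
(mixing parameter, density, size) over seed lists and writes a long-format
CSV of NMI/ARI/Purity per instance.

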