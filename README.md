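# fossilplace

Parsimony placement of fossil taxa on molecular scaffold topologies.

## The problem

Fossils usually preserve too few characters to estimate a whole phylogeny,
but their *position* on a well-supported molecular tree of living relatives
is often recoverable from morphology alone.  The molecular-scaffold approach
does exactly that: the extant backbone topology is held fixed, the fossil is
the only taxon free to move, and its attachment edge is chosen by unordered
(Fitch) maximum parsimony on a discrete morphological matrix.  The backbone
is enforced by appending one binary character per backbone bipartition,
weighted 99 versus 1 for the morphology, so that breaking a molecular clade
is never parsimonious.

`fossilplace` implements this workflow end to end for the classic use case —
a single fossil flower placed among the 24 sampled extant genera of
Rhamnaceae under two alternative molecular backbones — but every component
(NEXUS morphological matrices, Newick scaffolds, constraint encoding, Fitch
scoring, exhaustive and ratchet search, strict consensus, recovery
simulation) is generic.

Formally, for a scaffold tree *S* with edges *E(S)* and a fossil *x* scored
in matrix *M*, the method reports

&nbsp;&nbsp;&nbsp;&nbsp;argmin<sub>e ∈ E(S)</sub> L(S + x@e, M)

where *L* is the weighted Fitch length and *S + x@e* is the tree obtained by
attaching *x* on edge *e*.  All equally most-parsimonious edges and trees are
reported, along with how many extra steps any restricted placement (e.g. "the
fossil is a rhamnoid") would cost.

## Worked example

The package ships a synthetic 25 x 30 stand-in matrix with the shape of the
real dataset (24 extant genera + the fossil taxon, 25 floral + 5 foliar
characters) and two 24-genus scaffold fixtures.  Place the fossil using only
the floral characters against the Hauenschild-style backbone:

```sh
fossilplace place \
  --matrix src/fossilplace/data/standin_matrix_synthetic.nex \
  --scaffold hauenschild2016 --fossil Notiantha \
  --chars floral --out demo/
```

which prints

```
2 MP tree(s), morphological length 185
```

meaning two attachment edges tie at the minimum morphological length of 185
steps.  `demo/positions.json` classifies them relative to the named clades of
the scaffold:

```json
{
  "Helinus": "within Gouanieae",
  "Ampelozizyphus|Bathiorhamnus": "sister to ampelozizyphoid"
}
```

(each key is the scaffold edge, named by the leaves on its smaller side).
`demo/edge_scores.tsv` holds the full per-edge table — morphological length,
constraint length and total for every one of the 2 x 24 - 3 = 45 candidate
edges:

```
edge            morph_length  constraint_length  total  is_mp
Bathiorhamnus   187           2079               2266   0
Berchemia       189           2079               2268   0
...
```

The constraint component (21 columns x weight 99 = 2079) is constant across
placements — the scaffold is never broken — and is excluded from all
"steps longer" comparisons.  `demo/mp_trees.nwk` and `demo/consensus.nwk`
hold the MP trees and their strict consensus; `demo/run.json` records seed,
configuration and input hashes.  Because the stand-in matrix is synthetic,
these particular placements are properties of the simulation, not botany.

Other subcommands: `fossilplace simulate` (Mk matrices on random trees),
`fossilplace recover` (prune-and-replace recovery experiment),
`fossilplace consensus` (strict consensus of a Newick tree list).  The same
operations are available as a library:

```python
from fossilplace import bundled_scaffold, read_nexus, subset_characters, enumerate_placements

matrix = read_nexus("src/fossilplace/data/standin_matrix_synthetic.nex")
result = enumerate_placements(bundled_scaffold("onstein2015"), "Notiantha",
                              subset_characters(matrix, "floral"))
print(result.min_morph_length, len(result.mp_trees))
```

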