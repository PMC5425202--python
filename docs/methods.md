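# Methods

## The problem

A fossil taxon scored for discrete morphology is to be placed in a clade of
extant taxa whose relationships are already well resolved by molecular data.
Re-estimating the whole tree from a few dozen morphological characters would
discard that molecular signal, so the classic *molecular scaffold* approach is
used instead: the extant backbone is held fixed, only the fossil's attachment
point varies, and the optimality criterion is unordered (Fitch) parsimony on
the morphological matrix.

The concrete system this package was built around is the placement of an early
Danian fossil flower in Rhamnaceae: 24 extant genera spanning the ziziphoid,
rhamnoid and ampelozizyphoid clades, a 25 x 30 matrix (25 floral + 5 foliar
characters), and two alternative molecular backbones (a two-marker and a
seven-marker genus-level phylogeny).  Everything is parameterized, so nothing
is specific to that dataset.

## Scaffold constraints as weighted binary characters

A scaffold over n backbone taxa is encoded, TNT-style, as one binary character
per non-trivial bipartition of the backbone (n - 3 characters for a binary
scaffold): taxa on one side of the split are scored 1, the other side 0, and
floating taxa are scored missing.  Each column is weighted 99 against weight 1
for the morphological characters.

On any tree that displays the split, the column costs exactly 1 Fitch step; on
a tree that breaks it, at least 2.  A violated constraint therefore costs at
least +99, while the largest possible morphological saving is bounded by the
total morphological weight (30 at unit weights here), so the weighted "soft"
constraint behaves exactly like a hard topological filter at these problem
sizes.  Both modes are implemented (`mode="soft"` / `"hard"`); the test suite
checks exhaustively (7 backbone taxa + 1 floating taxon, all binary trees)
that *compliance <=> every constraint column costs exactly 1*, and on 100
random instances that the two modes select identical MP placements.

## Fitch scoring

Cells are state sets: a single observed state, a polymorphic set such as
`{01}`, or missing.  Missing and inapplicable (`-`) are conflated — the
scoring makes no gap/missing distinction, as is usual in morphological
parsimony.  Polymorphic cells use uncertainty semantics (the tip may take any
member state); the "requires both states" costing is deliberately not
implemented.  States are bitmasks (up to 16 states) and the Fitch pass is
vectorized over characters with numpy, so scoring a candidate tree is tens of
microseconds.  Lengths are exact integers throughout; weights must be
integers.

Trees must be binary when viewed unrooted; Fitch length is root-invariant, and
the implementation folds a degree-3 internal root pairwise, which equals
rooting along an incident edge.  An independent brute-force oracle enumerates
all internal-node state assignments (bounded at 12 leaves / 4 observed
states); the suite sweeps every unrooted binary topology on 4-6 leaves with
random characters (including missing and polymorphic cells) and requires
exact agreement.

## Placement search

With one floating taxon the search space is the 2n - 3 edges of the binary
scaffold, so `enumerate_placements` is exact: it attaches the fossil to every
edge, scores each candidate, and reports per-edge morphological and constraint
lengths separately.  "Steps longer" comparisons (`extra_steps_under_restriction`)
use the morphological component only — constraint steps are scaffolding, not
evidence.  Polytomous scaffolds are expanded into all binary resolutions
first (capped at 1000); MP trees then pool over resolutions, which is why the
number of MP trees can exceed the number of tied MP edges.  Tied-edge counts
and deduplicated-tree counts are both reported, since published tree counts
can follow either convention.

The parsimony ratchet is implemented for protocol fidelity: independent sets
(default 10), each starting from a random attachment and alternating two
phases per iteration (default 200) — re-optimize the fossil's placement under
perturbed weights (a random 10% of morphological characters upweighted x2),
then re-optimize under the original weights — pooling every optimum seen.
Because a single taxon's placement re-optimization is an exactly solvable
subproblem (a scan over candidate edges), the ratchet provably attains the
exhaustive optimum whenever it runs at least one iteration; the suite checks
agreement of minimum length and MP tree sets on 20 simulated instances at the
study's size (24 backbone taxa, 30 characters).  The per-set RNG is seeded
`seed + set_index`, so runs are reproducible and sets are independent.
Multi-taxon search is out of scope and raises `NotImplementedError`.

`ratchet_search` takes the combined matrix (morphology + constraints) and
reconstructs the backbone from the constraint columns themselves — each
column *is* a bipartition — which keeps the function's contract independent
of the Scaffold object.

## Synthetic data

`simulate_characters` evolves unordered characters independently under the
symmetric k-state Mk model: uniform root state, and along a branch of length
t (expected substitutions) the probability of ending in a different state is
(k-1)/k * (1 - exp(-k/(k-1) t)).  No rate heterogeneity is modelled; the
simulator's job is plausible homoplasy for a parsimony pipeline, not model
realism.  `degrade_matrix` emulates fossil incompleteness with *exact*
per-row counts: `round(f_missing * n)` cells set to missing and
`round(f_poly * n)` widened to polymorphic supersets that always contain the
true state.

Default shapes mirror the study: 24-leaf backbone + 1 fossil, 30 characters
(25 "floral" + 5 "foliar"), 3 states, ~30% missing on the fossil row, branch
lengths 0.25 — enough homoplasy that placements are non-trivial.

The recovery experiment (`placement_recovery_experiment`) simulates, prunes a
random leaf as the "fossil", degrades its row, re-places it exhaustively, and
records whether the true edge is among the MP edges.  Its *noise-free*
regime uses branch length 0.02 with 100 characters on 10 leaves: about two
expected changes per branch across the matrix, enough to mark every branch
while parallel changes are rare, so the true edge is recovered in every
replicate.  At longer branches (0.1-0.3) parsimony still almost always
recovers the edge, but occasional homoplastic excesses (1-2 steps) can favour
a neighbouring edge — that regime is deliberately exercised elsewhere in the
suite, just not called noise-free.  What passing recovery tests show is that
the pipeline is internally consistent under its own generative model; they do
not certify performance on real morphology, which is non-independent,
selected for preservability, and not Mk-distributed.

## Bundled fixtures

* `hauenschild2016.nwk/.json`, `onstein2015.nwk/.json` — 24-genus backbone
  topologies *consistent with* the two published molecular phylogenies.
  They are approximate transcriptions: tribe composition follows the
  published classification and the figure captions; within-tribe and
  backbone resolution is reconstructed, not copied from the original figure
  files.  The sidecar JSON names backbone/floating taxa, a source tag, and
  the named clades used by position reports.
* `standin_matrix_synthetic.nex` — a synthetic 25 x 30 stand-in with the
  same shape and partition structure as the study's MorphoBank matrix
  (project P2506, matrix 24392), generated by `scripts/build_fixtures.py`
  (Mk(3) on the Hauenschild-style backbone with the fossil on the Paliureae
  stem, 7% missing on extant rows, 30% missing + 7% polymorphic on the
  fossil row).  It exercises the full pipeline at the real problem size; its
  MP-tree counts are its own, not the published ones.  Reproducing the
  published counts (2, 5, 8, 4) and the 2-step rhamnoid suboptimality
  requires downloading the real matrix to
  `data/real/morphobank_p24392.nex`; the corresponding tests fail with an
  explanatory message until it is present.

## Numerical and design notes

* Character indices are 1-based in NEXUS files and the CLI, 0-based in the
  API's internals; partitions default to floral = 1-25, foliar = 26-30 for
  30-character matrices without explicit CHARSETs.
* Unrooted topology identity is equality of non-trivial bipartition sets;
  the canonical Newick writer roots at the smallest leaf's neighbour and
  sorts children by minimum descendant label, so equal topologies serialize
  to identical strings (property-tested exhaustively at 6 leaves).
* Character weights are carried in a NEXUS `ASSUMPTIONS`/`WTSET` block.
* Ties everywhere are broken deterministically (lexicographic edge order),
  and every stochastic component takes an explicit seed, so runs are
  bit-reproducible.

## Known limitations

* Single floating taxon only; no branch swapping of the backbone (by
  design — the backbone is the constraint).
* No ordered/Wagner characters, step matrices, or implied weighting.
* The bundled scaffolds are reconstructions at the resolution the figure
  captions support; analyses of the real matrix should be read with that
  transcription caveat in mind.
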