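"""Synthetic morphological matrices with known ground truth.

Characters evolve independently under the symmetric k-state Mk model
(Lewis 2001) on a known tree: the root state is uniform and along a branch
of length t (expected substitutions) the probability that the end state
differs from the start state is (k-1)/k * (1 - exp(-k/(k-1) * t)).  The
simulator then optionally degrades chosen rows — setting an exact number
of cells to MISSING and widening others into polymorphic supersets — to
emulate an incompletely preserved fossil.

The default scenario mirrors the target study's shape: a 24-leaf backbone
plus one floating "fossil", 30 characters split 25 floral / 5 foliar, and
roughly 30% missing data on the fossil row.  No rate heterogeneity is
modelled (an extension hook, not needed for parsimony-level realism).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

import numpy as np

from .matrix_io import CharacterMatrix
from .parsimony import MISSING, Cell
from .placement import enumerate_placements
from .scaffold import Scaffold
from .trees import Node, PhyloTree, parse_newick, same_topology

__all__ = [
    "SimulationConfig",
    "RecoveryReport",
    "simulate_characters",
    "degrade_matrix",
    "placement_recovery_experiment",
    "random_binary_tree",
    "default_scenario",
]


@dataclass
class SimulationConfig:
    """Mk simulation settings.

    ``tree`` must carry branch lengths in expected substitutions per
    character; ``n_states`` is the size of the symmetric state alphabet.
    """

    tree: PhyloTree
    n_characters: int = 30
    n_states: int = 3
    missing_fraction: float = 0.0
    polymorphic_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_characters <= 0:
            raise ValueError("n_characters must be positive")
        if self.n_states < 2:
            raise ValueError("n_states must be >= 2")
        if not (0 <= self.missing_fraction < 1):
            raise ValueError("missing_fraction must be in [0, 1)")
        if not (0 <= self.polymorphic_fraction < 1):
            raise ValueError("polymorphic_fraction must be in [0, 1)")
        for node in self.tree.postorder():
            if node.parent is not None and (node.length or 0.0) < 0:
                raise ValueError("negative branch length")


@dataclass
class RecoveryReport:
    """Per-replicate truth-vs-recovered placements and summary rates."""

    records: List[dict] = field(default_factory=list)

    @property
    def n_replicates(self) -> int:
        return len(self.records)

    @property
    def hit_rate(self) -> float:
        if not self.records:
            return float("nan")
        return sum(r["hit"] for r in self.records) / len(self.records)

    @property
    def mean_mp_edges(self) -> float:
        if not self.records:
            return float("nan")
        return sum(r["n_mp_edges"] for r in self.records) / len(self.records)

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_replicates": self.n_replicates,
                "hit_rate": self.hit_rate,
                "mean_mp_edges": self.mean_mp_edges,
                "records": self.records,
            },
            indent=2,
        )

    def to_tsv(self) -> str:
        lines = ["replicate\tfossil\thit\tn_mp_edges"]
        for r in self.records:
            lines.append(f"{r['replicate']}\t{r['fossil']}\t{int(r['hit'])}\t{r['n_mp_edges']}")
        return "\n".join(lines) + "\n"


def mk_change_probability(k: int, t: float) -> float:
    """P(end state != start state) along a branch of length t under Mk(k)."""
    return (k - 1) / k * (1.0 - np.exp(-k / (k - 1) * t))


def simulate_characters(config: SimulationConfig) -> Tuple[CharacterMatrix, PhyloTree]:
    """Evolve ``n_characters`` independent Mk characters down ``config.tree``.

    Returns the leaf matrix (with degradation applied uniformly to all taxa
    at the configured fractions) and the true tree.  Deterministic under a
    fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    k, n = config.n_states, config.n_characters
    states: Dict[int, np.ndarray] = {}
    root = config.tree.root
    states[id(root)] = rng.integers(0, k, size=n)
    order = [node for node in config.tree.postorder()]
    for node in reversed(order):  # preorder
        if node.parent is None:
            continue
        t = node.length or 0.0
        p_change = mk_change_probability(k, t)
        parent_states = states[id(node.parent)]
        change = rng.random(n) < p_change
        # a changed site moves to one of the k-1 other states uniformly
        offset = rng.integers(1, k, size=n)
        states[id(node)] = np.where(change, (parent_states + offset) % k, parent_states)

    taxa = sorted(config.tree.leaf_labels())
    leaf_states = {
        node.label: states[id(node)] for node in config.tree.leaves()
    }
    rows: Dict[str, List[Cell]] = {
        t: [frozenset([int(s)]) for s in leaf_states[t]] for t in taxa
    }
    partitions = (
        {"floral": list(range(25)), "foliar": list(range(25, 30))} if n == 30 else {}
    )
    matrix = CharacterMatrix(taxa, rows, partitions=partitions)
    if config.missing_fraction > 0 or config.polymorphic_fraction > 0:
        matrix = degrade_matrix(
            matrix,
            frozenset(taxa),
            config.missing_fraction,
            config.polymorphic_fraction,
            seed=int(rng.integers(2**31)),
            n_states=k,
        )
    return matrix, config.tree


def degrade_matrix(
    matrix: CharacterMatrix,
    target_taxa: FrozenSet[str],
    missing_fraction: float,
    polymorphic_fraction: float,
    seed: int,
    n_states: Optional[int] = None,
) -> CharacterMatrix:
    """Set an exact number of cells per target row to MISSING and widen
    another exact number into polymorphic supersets of the true state.

    Counts are ``round(fraction * n_characters)`` per row; cells are chosen
    uniformly without replacement under the seed.  Fractions summing above
    one (after rounding) are rejected.
    """
    unknown = set(target_taxa) - set(matrix.taxa)
    if unknown:
        raise ValueError(f"unknown target taxa: {sorted(unknown)}")
    n = matrix.n_characters
    n_missing = round(missing_fraction * n)
    n_poly = round(polymorphic_fraction * n)
    if n_missing + n_poly > n:
        raise ValueError("missing and polymorphic fractions exceed the row length")
    k = n_states if n_states is not None else matrix.max_state() + 1
    rng = np.random.default_rng(seed)
    rows = {t: list(matrix.rows[t]) for t in matrix.taxa}
    for taxon in sorted(target_taxa):
        chosen = rng.choice(n, size=n_missing + n_poly, replace=False)
        for i in chosen[:n_missing]:
            rows[taxon][i] = MISSING
        for i in chosen[n_missing:]:
            cell = rows[taxon][i]
            if cell is MISSING or cell == MISSING:
                continue
            others = [s for s in range(k) if s not in cell]
            if not others:
                continue
            extra = rng.choice(others)
            rows[taxon][i] = frozenset(cell) | {int(extra)}
    return CharacterMatrix(
        matrix.taxa,
        rows,
        weights=matrix.weights,
        partitions=matrix.partitions,
        char_labels=matrix.char_labels,
    )


def random_binary_tree(
    labels: Sequence[str], seed: int, branch_length: float = 0.3
) -> PhyloTree:
    """Uniform random unrooted binary topology with constant branch lengths."""
    labels = list(labels)
    if len(labels) < 3:
        raise ValueError("need at least 3 leaves")
    rng = np.random.default_rng(seed)
    order = list(labels)
    rng.shuffle(order)
    root = Node()
    for lab in order[:3]:
        root.add_child(Node(lab, branch_length))
    tree = PhyloTree(root)
    for lab in order[3:]:
        edges = sorted(tree.edges(), key=lambda s: (len(s), sorted(s)))
        edge = edges[int(rng.integers(len(edges)))]
        tree = tree.attach_leaf(edge, lab)
    for node in tree.postorder():
        if node.parent is not None:
            node.length = branch_length
    return tree


def _true_attachment_edge(true_tree: PhyloTree, backbone: PhyloTree, fossil: str):
    """The backbone edge whose fossil attachment reproduces the true topology."""
    for edge in backbone.edges():
        if same_topology(backbone.attach_leaf(edge, fossil), true_tree):
            return edge
    raise RuntimeError("no attachment edge reproduces the true tree")


def placement_recovery_experiment(
    config: SimulationConfig,
    n_replicates: int,
    seed: Optional[int] = None,
    constraint_weight: int = 99,
) -> RecoveryReport:
    """Simulate, prune a random leaf as the "fossil", degrade its row, place
    it back by exhaustive enumeration, and record whether the true edge is
    recovered.  Bit-reproducible under fixed seeds.
    """
    if config.tree.n_leaves < 6:
        raise ValueError("recovery experiment needs a tree with >= 6 leaves")
    base_seed = config.seed if seed is None else seed
    report = RecoveryReport()
    labels = sorted(config.tree.leaf_labels())
    for rep in range(n_replicates):
        rep_rng = np.random.default_rng((base_seed + 7919 * rep) % (2**31))
        sim_config = SimulationConfig(
            tree=config.tree,
            n_characters=config.n_characters,
            n_states=config.n_states,
            seed=int(rep_rng.integers(2**31)),
        )
        matrix, true_tree = simulate_characters(sim_config)
        fossil = labels[int(rep_rng.integers(len(labels)))]
        backbone = true_tree.prune_leaf(fossil)
        matrix = degrade_matrix(
            matrix,
            frozenset([fossil]),
            config.missing_fraction,
            config.polymorphic_fraction,
            seed=int(rep_rng.integers(2**31)),
            n_states=config.n_states,
        )
        scaffold = Scaffold(
            topology=backbone,
            backbone_taxa=backbone.leaf_labels(),
            floating_taxa=frozenset([fossil]),
            source="simulation",
        )
        result = enumerate_placements(
            scaffold, fossil, matrix, constraint_weight=constraint_weight
        )
        true_edge = _true_attachment_edge(true_tree, backbone, fossil)
        report.records.append(
            {
                "replicate": rep,
                "fossil": fossil,
                "hit": true_edge in result.mp_edges,
                "n_mp_edges": len(result.mp_edges),
            }
        )
    return report


def default_scenario(seed: int = 42) -> SimulationConfig:
    """The shipped scenario mimicking the study's shape: 24-leaf backbone
    plus one fossil, 30 characters, 3 states, ~30% missing on degradation."""
    labels = [f"genus{chr(ord('A') + i)}" for i in range(24)] + ["fossil_taxon"]
    tree = random_binary_tree(labels, seed=seed, branch_length=0.25)
    return SimulationConfig(
        tree=tree,
        n_characters=30,
        n_states=3,
        missing_fraction=0.3,
        polymorphic_fraction=0.0,
        seed=seed,
    )
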