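"""Fossil placement: exhaustive edge evaluation, parsimony ratchet, reports.

With a single floating taxon and a fixed backbone, the search space is the
set of scaffold edges, so exhaustive evaluation of every attachment point
is exact and is the default analysis mode (and the oracle the ratchet is
tested against).  The ratchet mirrors the classic protocol: independent
sets, each alternating placement re-optimization under perturbed
(upweighted) and original character weights, pooling every optimum seen.

Lengths are carried in two ledgers: the morphological component (the
evidence) and the constraint component (the scaffolding); "steps longer"
statements use the morphological component only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

import numpy as np

from .matrix_io import CharacterMatrix, append_characters
from .parsimony import MISSING, WeightedLength, fitch_lengths
from .scaffold import Scaffold, encode_scaffold
from .trees import (
    EdgeId,
    Node,
    PhyloTree,
    parse_newick,
    same_topology,
    tree_from_splits,
    write_newick,
)

__all__ = [
    "RatchetConfig",
    "PlacementResult",
    "enumerate_placements",
    "ratchet_search",
    "extra_steps_under_restriction",
    "summarize_mp_positions",
    "edge_scores_tsv",
]

_MAX_RESOLUTIONS = 1000


@dataclass(frozen=True)
class RatchetConfig:
    """Parsimony-ratchet settings; defaults follow the published protocol
    (10 sets of 200 iterations, 10% of characters perturbed per cycle)."""

    n_sets: int = 10
    iterations_per_set: int = 200
    perturbation_fraction: float = 0.10
    upweight_factor: int = 2
    seed: int = 0
    constraint_weight: int = 99

    def __post_init__(self):
        if self.n_sets <= 0:
            raise ValueError("n_sets must be positive")
        if self.iterations_per_set < 0:
            raise ValueError("iterations_per_set must be non-negative")
        if not (0 < self.perturbation_fraction < 1):
            raise ValueError("perturbation_fraction must be in (0, 1)")
        if self.upweight_factor < 2:
            raise ValueError("upweight_factor must be >= 2")
        if self.constraint_weight <= 0:
            raise ValueError("constraint_weight must be positive")


@dataclass
class PlacementResult:
    """Scores per candidate attachment edge and the most-parsimonious set.

    ``edge_scores`` totals include the weighted constraint component;
    ``morph_scores``/``constraint_scores`` split the two ledgers.  Edge ids
    are bipartition sides of the *scaffold* (fossil excluded), so they are
    comparable across result objects.  ``mp_trees`` are deduplicated
    unrooted topologies; with a fully resolved scaffold there is exactly
    one per MP edge, while polytomy resolutions can add more.
    """

    edge_scores: Dict[EdgeId, WeightedLength]
    morph_scores: Dict[EdgeId, int]
    constraint_scores: Dict[EdgeId, int]
    min_length: int
    min_morph_length: int
    mp_edges: FrozenSet[EdgeId]
    mp_trees: List[PhyloTree]
    config: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.mp_edges:
            raise ValueError("empty MP edge set")


# -- polytomy resolution ------------------------------------------------------------


def _copy_subtree(n: Node) -> Node:
    c = Node(n.label, n.length)
    for ch in n.children:
        c.add_child(_copy_subtree(ch))
    return c


def _rooted_shapes(subtrees: Sequence[Node]) -> List[Node]:
    """Every rooted binary tree joining the given subtrees (fresh copies)."""
    first = Node()
    first.add_child(_copy_subtree(subtrees[0]))
    first.add_child(_copy_subtree(subtrees[1]))
    shapes = [first]
    for sub in subtrees[2:]:
        grown: List[Node] = []
        for shape in shapes:
            # insertion positions: above every non-root node, plus above the root
            n_positions = sum(1 for _ in _descendants(shape)) + 1
            for pos in range(n_positions):
                clone = _copy_subtree(shape)
                extra = _copy_subtree(sub)
                if pos == n_positions - 1:
                    top = Node()
                    top.add_child(clone)
                    top.add_child(extra)
                    grown.append(top)
                else:
                    target = _descendants(clone)[pos]
                    parent = target.parent
                    joint = Node()
                    parent.children[parent.children.index(target)] = joint
                    joint.parent = parent
                    joint.add_child(target)
                    joint.add_child(extra)
                    grown.append(clone)
        shapes = grown
        if len(shapes) > _MAX_RESOLUTIONS:
            raise ValueError("too many polytomy resolutions")
    return shapes


def _descendants(node: Node) -> List[Node]:
    out: List[Node] = []
    stack = list(reversed(node.children))
    while stack:
        n = stack.pop()
        out.append(n)
        stack.extend(reversed(n.children))
    return out


def _binary_resolutions(tree: PhyloTree) -> List[PhyloTree]:
    """All binary resolutions of an unrooted tree (identity for binary input)."""
    if tree.is_binary_unrooted():
        return [tree]
    work = tree.copy()
    root = work.root
    if len(root.children) > 2:
        # re-hang along the edge to the first child; the old root keeps its
        # unrooted degree, so no implicit resolution happens here
        new_root = Node()
        first = root.children[0]
        root.children = root.children[1:]
        first.parent = None
        new_root.add_child(first)
        new_root.add_child(root)
        work = PhyloTree(new_root)

    def expand(node: Node) -> List[Node]:
        if node.is_leaf:
            return [_copy_subtree(node)]
        variant_lists = [expand(c) for c in node.children]
        out: List[Node] = []
        for combo in product(*variant_lists):
            if len(combo) <= 2:
                clone = Node(node.label, node.length)
                for c in combo:
                    clone.add_child(_copy_subtree(c))
                out.append(clone)
            else:
                out.extend(_rooted_shapes(combo))
            if len(out) > _MAX_RESOLUTIONS:
                raise ValueError("too many polytomy resolutions")
        return out

    resolved: List[PhyloTree] = []
    for combo in product(*(expand(c) for c in work.root.children)):
        top = Node()
        for c in combo:
            top.add_child(_copy_subtree(c))
        resolved.append(PhyloTree(top))
        if len(resolved) > _MAX_RESOLUTIONS:
            raise ValueError("too many polytomy resolutions")
    return resolved


# -- scoring ------------------------------------------------------------------------


def _restrict_taxa(matrix: CharacterMatrix, taxa: Sequence[str]) -> CharacterMatrix:
    keep = [t for t in matrix.taxa if t in set(taxa)]
    return CharacterMatrix(
        keep,
        {t: matrix.rows[t] for t in keep},
        weights=matrix.weights,
        partitions=matrix.partitions,
        char_labels=matrix.char_labels,
    )


class _Scorer:
    """Caches per-edge per-character Fitch step vectors for one backbone tree."""

    def __init__(self, backbone: PhyloTree, fossil: str, matrix: CharacterMatrix):
        self.backbone = backbone
        self.fossil = fossil
        self.matrix = matrix
        self.masks = {t: matrix.row_masks(t) for t in matrix.taxa}
        self.weights = np.asarray(matrix.weights, dtype=np.int64)
        self._steps: Dict[EdgeId, np.ndarray] = {}
        self._trees: Dict[EdgeId, PhyloTree] = {}

    def edges(self) -> List[EdgeId]:
        return sorted(self.backbone.edges(), key=lambda s: (len(s), sorted(s)))

    def tree(self, edge: EdgeId) -> PhyloTree:
        if edge not in self._trees:
            self._trees[edge] = self.backbone.attach_leaf(edge, self.fossil)
        return self._trees[edge]

    def steps(self, edge: EdgeId) -> np.ndarray:
        if edge not in self._steps:
            self._steps[edge] = fitch_lengths(self.tree(edge), self.masks)
        return self._steps[edge]


def _split_indices(matrix: CharacterMatrix) -> Tuple[np.ndarray, np.ndarray]:
    """(morphological, constraint) 0-based index arrays."""
    constraint = np.asarray(
        matrix.partitions.get("constraints", ()), dtype=np.int64
    )
    mask = np.ones(matrix.n_characters, dtype=bool)
    if constraint.size:
        mask[constraint] = False
    return np.flatnonzero(mask), constraint


def _build_result(
    matrix: CharacterMatrix,
    entries: List[Tuple[EdgeId, np.ndarray, PhyloTree]],
    mode: str,
    config: dict,
) -> PlacementResult:
    """Assemble a PlacementResult from (edge, step-vector, candidate tree) entries.

    Several entries may share an edge id (polytomy resolutions); per-edge
    scores keep the best entry, while MP trees pool over all entries.
    """
    morph_idx, con_idx = _split_indices(matrix)
    w = np.asarray(matrix.weights, dtype=np.int64)

    def totals(steps: np.ndarray) -> Tuple[int, int, int]:
        morph = int((w[morph_idx] * steps[morph_idx]).sum())
        con = int((w[con_idx] * steps[con_idx]).sum())
        return morph + con, morph, con

    edge_scores: Dict[EdgeId, WeightedLength] = {}
    morph_scores: Dict[EdgeId, int] = {}
    con_scores: Dict[EdgeId, int] = {}
    scored = []
    for edge, steps, tree in entries:
        total, morph, con = totals(steps)
        scored.append((edge, steps, tree, total, morph, con))
        if edge not in edge_scores or total < edge_scores[edge].total:
            edge_scores[edge] = WeightedLength(
                total=total, per_character=tuple(int(s) for s in steps)
            )
            morph_scores[edge] = morph
            con_scores[edge] = con

    if mode == "hard":
        min_con = min(item[5] for item in scored)
        eligible = [item for item in scored if item[5] == min_con]
        rank = lambda item: item[4]  # morphological length
    else:
        eligible = scored
        rank = lambda item: item[3]  # total weighted length
    best = min(rank(item) for item in eligible)
    mp_edges = frozenset(item[0] for item in eligible if rank(item) == best)
    mp_trees: List[PhyloTree] = []
    for item in sorted(
        (it for it in eligible if rank(it) == best),
        key=lambda it: (len(it[0]), sorted(it[0])),
    ):
        if not any(same_topology(item[2], t) for t in mp_trees):
            mp_trees.append(item[2])
    min_morph = min(item[4] for item in eligible if rank(item) == best)
    return PlacementResult(
        edge_scores=edge_scores,
        morph_scores=morph_scores,
        constraint_scores=con_scores,
        min_length=min(item[3] for item in scored),
        min_morph_length=min_morph,
        mp_edges=mp_edges,
        mp_trees=mp_trees,
        config=config,
    )


# -- exhaustive placement -----------------------------------------------------------


def enumerate_placements(
    scaffold: Scaffold,
    fossil: str,
    matrix: CharacterMatrix,
    constraint_weight: int = 99,
    mode: str = "soft",
) -> PlacementResult:
    """Attach the fossil to every scaffold edge and score each candidate.

    Deterministic and exact: with one floating taxon the 2n-3 edges of a
    binary n-leaf scaffold are the whole search space.  A polytomous
    scaffold is expanded into its binary resolutions first (each resolution
    contributes its own edges; MP trees pool over all of them).

    ``mode="soft"`` ranks by total weighted length including the constraint
    columns; ``mode="hard"`` ranks by morphological length among trees with
    the minimal constraint cost.  On a compliant backbone both agree.
    """
    if mode not in ("soft", "hard"):
        raise ValueError("mode must be 'soft' or 'hard'")
    if fossil not in matrix.taxa:
        raise ValueError(
            f"fossil {fossil!r} not in matrix; available taxa: {sorted(matrix.taxa)}"
        )
    if fossil not in scaffold.floating_taxa:
        raise ValueError(f"fossil {fossil!r} is not a floating taxon of the scaffold")
    missing = scaffold.backbone_taxa - set(matrix.taxa)
    if missing:
        raise ValueError(f"matrix lacks backbone taxa: {sorted(missing)}")
    work = _restrict_taxa(matrix, sorted(scaffold.backbone_taxa | {fossil}))
    block = encode_scaffold(scaffold, weight=constraint_weight)
    combined = append_characters(work, block.columns)

    entries: List[Tuple[EdgeId, np.ndarray, PhyloTree]] = []
    for resolution in _binary_resolutions(scaffold.topology):
        scorer = _Scorer(resolution, fossil, combined)
        for edge in scorer.edges():
            entries.append((edge, scorer.steps(edge), scorer.tree(edge)))
    return _build_result(
        combined,
        entries,
        mode,
        config={
            "method": "exhaustive",
            "mode": mode,
            "constraint_weight": constraint_weight,
            "fossil": fossil,
            "scaffold": scaffold.source,
        },
    )


# -- ratchet ------------------------------------------------------------------------


def _backbone_from_constraints(
    matrix: CharacterMatrix, free_taxa: FrozenSet[str]
) -> PhyloTree:
    """Rebuild the backbone tree from the 'constraints' partition's columns."""
    if "constraints" not in matrix.partitions:
        raise ValueError("matrix has no 'constraints' partition")
    backbone = sorted(set(matrix.taxa) - free_taxa)
    splits = []
    for i in matrix.partitions["constraints"]:
        side = frozenset(
            t
            for t in backbone
            if matrix.rows[t][i] != MISSING and 1 in matrix.rows[t][i]
        )
        splits.append(side)
    tree = tree_from_splits(backbone, splits)
    # canonical re-rooting gives a root of degree >= 3, which keeps the
    # edge-adjacency bookkeeping below simple
    return parse_newick(write_newick(tree))


def ratchet_search(
    matrix_plus_constraints: CharacterMatrix,
    config: RatchetConfig,
    free_taxa: FrozenSet[str],
) -> PlacementResult:
    """Parsimony-ratchet search over attachment positions of a floating taxon.

    The backbone is reconstructed from the weighted binary constraint
    columns (exactly the information the scaffold encoding carries).  Each
    of ``n_sets`` independent runs starts from a random attachment and then
    alternates the two ratchet phases: re-optimize the free taxon's
    placement under perturbed (upweighted) character weights, then again
    under the original weights.  With a single free taxon each
    re-optimization is solved exactly over the candidate edges, so the
    ratchet's role here is protocol fidelity (and a harness for multi-taxon
    extension) rather than extra search power.  Every optimum seen under
    the original weights is pooled; ``min_length`` is <= every visited
    length by construction.
    """
    free_taxa = frozenset(free_taxa)
    if not free_taxa:
        raise ValueError("free_taxa must be non-empty")
    if len(free_taxa) > 1:
        raise NotImplementedError("multi-fossil ratchet search is not supported")
    unknown = free_taxa - set(matrix_plus_constraints.taxa)
    if unknown:
        raise ValueError(f"free taxa absent from matrix: {sorted(unknown)}")
    fossil = next(iter(free_taxa))
    backbone = _backbone_from_constraints(matrix_plus_constraints, free_taxa)
    if not backbone.is_binary_unrooted():
        raise ValueError(
            "constraint columns do not resolve the backbone to a binary tree"
        )
    scorer = _Scorer(backbone, fossil, matrix_plus_constraints)
    edges = scorer.edges()
    morph_idx, _ = _split_indices(matrix_plus_constraints)
    base_w = scorer.weights
    n_perturb = max(1, math.ceil(config.perturbation_fraction * len(morph_idx)))

    best: List[Optional[int]] = [None]
    pool: Set[EdgeId] = set()
    visited: Dict[EdgeId, np.ndarray] = {}

    def consider(edge: EdgeId) -> None:
        steps = scorer.steps(edge)
        visited[edge] = steps
        score = int((base_w * steps).sum())
        if best[0] is None or score < best[0]:
            best[0] = score
            pool.clear()
        if score == best[0]:
            pool.add(edge)

    def reoptimize(weights: np.ndarray) -> EdgeId:
        chosen, chosen_score = None, None
        for edge in edges:
            consider(edge)
            score = int((weights * scorer.steps(edge)).sum())
            if chosen_score is None or score < chosen_score:
                chosen, chosen_score = edge, score
        return chosen

    for s in range(config.n_sets):
        rng = np.random.default_rng((config.seed + s) % (2**31))
        current = edges[int(rng.integers(len(edges)))]
        consider(current)
        for _ in range(config.iterations_per_set):
            perturbed = base_w.copy()
            chosen = rng.choice(morph_idx, size=n_perturb, replace=False)
            perturbed[chosen] *= config.upweight_factor
            current = reoptimize(perturbed)
            current = reoptimize(base_w)

    entries = [(e, steps, scorer.tree(e)) for e, steps in visited.items()]
    return _build_result(
        matrix_plus_constraints,
        entries,
        "soft",
        config={
            "method": "ratchet",
            "n_sets": config.n_sets,
            "iterations_per_set": config.iterations_per_set,
            "perturbation_fraction": config.perturbation_fraction,
            "upweight_factor": config.upweight_factor,
            "seed": config.seed,
            "constraint_weight": config.constraint_weight,
            "fossil": fossil,
        },
    )


# -- reporting ----------------------------------------------------------------------


def extra_steps_under_restriction(
    result: PlacementResult, allowed_edges
) -> int:
    """Extra morphological steps the best placement within ``allowed_edges``
    costs relative to the global optimum (>= 0)."""
    allowed = [frozenset(e) for e in allowed_edges]
    if not allowed:
        raise ValueError("allowed_edges must be non-empty")
    unknown = [e for e in allowed if e not in result.morph_scores]
    if unknown:
        raise KeyError(f"unknown edge ids: {[sorted(e) for e in unknown]}")
    global_min = min(result.morph_scores.values())
    return min(result.morph_scores[e] for e in allowed) - global_min


def summarize_mp_positions(
    result: PlacementResult,
    scaffold: Scaffold,
    named_clades: Optional[Dict[str, FrozenSet[str]]] = None,
) -> Dict[str, str]:
    """Classify each MP attachment edge relative to named scaffold clades.

    Returns {rendered edge id: description}: "sister to K" for K's stem
    edge, "within K" for an edge strictly inside K (smallest such K), or a
    backbone description otherwise.  Every named clade must be a clade of
    the scaffold.
    """
    clades = {k: frozenset(v) for k, v in (named_clades or scaffold.clades).items()}
    backbone = scaffold.backbone_taxa
    sides = set(scaffold.topology.edges())
    full_sides = sides | {backbone - s for s in sides}
    for name, members in clades.items():
        if not (len(members) == 1 or members == backbone or members in full_sides):
            raise ValueError(f"named clade {name!r} is not a clade of the scaffold")
    out: Dict[str, str] = {}
    for edge in sorted(result.mp_edges, key=lambda s: (len(s), sorted(s))):
        orientations = [frozenset(edge), backbone - frozenset(edge)]
        label = None
        best_size = None
        for name, members in clades.items():
            for side in orientations:
                hit = None
                if side == members:
                    hit = f"sister to {name}"
                elif side < members:
                    hit = f"within {name}"
                if hit and (best_size is None or len(members) < best_size):
                    label, best_size = hit, len(members)
        if label is None:
            small = min(orientations, key=len)
            label = "on backbone between " + "+".join(sorted(small)) + " and the rest"
        out["|".join(sorted(min(orientations, key=len)))] = label
    return out


def edge_scores_tsv(result: PlacementResult) -> str:
    """Edge-score table: edge id, morphological, constraint, total length."""
    lines = ["edge\tmorph_length\tconstraint_length\ttotal\tis_mp"]
    for edge in sorted(result.edge_scores, key=lambda s: (len(s), sorted(s))):
        lines.append(
            "\t".join(
                [
                    "|".join(sorted(edge)),
                    str(result.morph_scores[edge]),
                    str(result.constraint_scores[edge]),
                    str(result.edge_scores[edge].total),
                    "1" if edge in result.mp_edges else "0",
                ]
            )
        )
    return "\n".join(lines) + "\n"
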