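"""Molecular scaffold constraints encoded as weighted binary characters.

A scaffold is a fixed backbone topology over the extant taxa, taken from a
published molecular phylogeny.  To force a parsimony search to respect it,
each non-trivial bipartition of the backbone is translated into one binary
character (taxa on one side scored 0, the other side 1, floating taxa
scored missing) and the column is weighted heavily — 99 versus 1 for the
morphological characters.  Because one violated constraint then costs at
least 99 extra steps while the entire morphological matrix can save far
fewer, the weighted soft constraint behaves exactly like a hard topological
constraint at the problem sizes this package targets; both modes are
provided and tested for agreement.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, FrozenSet, List, Optional, Tuple, Union

from .matrix_io import CharacterColumn
from .parsimony import MISSING, Cell, fitch_steps
from .trees import EdgeId, PhyloTree, parse_newick

__all__ = [
    "Scaffold",
    "ConstraintBlock",
    "encode_scaffold",
    "satisfies_scaffold",
    "restricted_bipartitions",
    "load_scaffold",
    "bundled_scaffold",
    "BUNDLED_SCAFFOLDS",
]

BUNDLED_SCAFFOLDS = ("hauenschild2016", "onstein2015")


@dataclass
class Scaffold:
    """A backbone topology plus the taxa that remain free to move."""

    topology: PhyloTree
    backbone_taxa: FrozenSet[str]
    floating_taxa: FrozenSet[str]
    source: str = ""
    clades: Dict[str, FrozenSet[str]] = field(default_factory=dict)

    def __post_init__(self):
        self.backbone_taxa = frozenset(self.backbone_taxa)
        self.floating_taxa = frozenset(self.floating_taxa)
        if self.backbone_taxa & self.floating_taxa:
            raise ValueError("backbone and floating taxa overlap")
        if self.topology.leaf_labels() != self.backbone_taxa:
            raise ValueError("scaffold topology leaves differ from backbone_taxa")
        self.clades = {k: frozenset(v) for k, v in self.clades.items()}


@dataclass
class ConstraintBlock:
    """One weighted binary character per scaffold bipartition."""

    columns: List[CharacterColumn]
    weight: int
    provenance: List[FrozenSet[str]]  # the bipartition side scored 1, per column

    def __len__(self) -> int:
        return len(self.columns)


def encode_scaffold(scaffold: Scaffold, weight: int = 99) -> ConstraintBlock:
    """Translate every non-trivial backbone bipartition into a binary column.

    Backbone taxa are scored 1 on the canonical side of the split and 0 on
    the other; floating taxa are scored MISSING so only the backbone is
    constrained.  A scaffold with fewer than four backbone taxa has no
    non-trivial splits and yields an empty block (with a warning).
    """
    if weight <= 0:
        raise ValueError("constraint weight must be positive")
    splits = sorted(scaffold.topology.bipartitions(), key=lambda s: (len(s), sorted(s)))
    if len(scaffold.backbone_taxa) < 4 or not splits:
        if len(scaffold.backbone_taxa) < 4:
            warnings.warn("scaffold has < 4 backbone taxa; no constraints encoded")
        return ConstraintBlock(columns=[], weight=weight, provenance=[])
    columns = []
    for i, side in enumerate(splits):
        cells: Dict[str, Cell] = {}
        for taxon in scaffold.backbone_taxa:
            cells[taxon] = frozenset([1]) if taxon in side else frozenset([0])
        for taxon in scaffold.floating_taxa:
            cells[taxon] = MISSING
        columns.append(CharacterColumn(cells=cells, weight=weight, label=f"scaffold{i+1}"))
    return ConstraintBlock(columns=columns, weight=weight, provenance=list(splits))


def restricted_bipartitions(tree: PhyloTree, taxa: FrozenSet[str]) -> FrozenSet[EdgeId]:
    """Non-trivial bipartitions of ``tree`` restricted to the taxon subset."""
    missing = taxa - tree.leaf_labels()
    if missing:
        raise ValueError(f"tree lacks backbone taxa: {sorted(missing)}")
    ref = min(taxa)
    n = len(taxa)
    out = set()
    for side in tree.edges():
        restricted = side & taxa
        if ref in restricted:
            restricted = taxa - restricted
        if 2 <= len(restricted) <= n - 2:
            out.add(frozenset(restricted))
    return frozenset(out)


def satisfies_scaffold(tree: PhyloTree, scaffold: Scaffold) -> bool:
    """True iff the tree, restricted to the backbone, displays every scaffold split."""
    scaffold_splits = set()
    ref = min(scaffold.backbone_taxa)
    for side in scaffold.topology.bipartitions():
        if ref in side:
            side = scaffold.backbone_taxa - side
        scaffold_splits.add(frozenset(side))
    return restricted_bipartitions(tree, scaffold.backbone_taxa) >= scaffold_splits


def constraint_steps(tree: PhyloTree, block: ConstraintBlock) -> List[int]:
    """Unweighted Fitch length of each constraint column on ``tree``."""
    return [fitch_steps(tree, col.cells) for col in block.columns]


# -- fixture loading ----------------------------------------------------------------


def load_scaffold(newick_path: Union[str, Path], sidecar_path: Optional[Union[str, Path]] = None) -> Scaffold:
    """Load a scaffold from a Newick file plus a JSON sidecar.

    The sidecar (defaulting to the Newick path with a .json suffix) names
    the backbone taxa, floating taxa, source tag, and optionally named
    clades used by position reports.
    """
    newick_path = Path(newick_path)
    if sidecar_path is None:
        sidecar_path = newick_path.with_suffix(".json")
    text = newick_path.read_text()
    tree_line = next(
        line for line in text.splitlines() if line.strip() and not line.startswith("[")
    )
    topology = parse_newick(tree_line)
    meta = json.loads(Path(sidecar_path).read_text())
    return Scaffold(
        topology=topology,
        backbone_taxa=frozenset(meta["backbone_taxa"]),
        floating_taxa=frozenset(meta.get("floating_taxa", [])),
        source=meta.get("source", ""),
        clades={k: frozenset(v) for k, v in meta.get("clades", {}).items()},
    )


def bundled_scaffold(tag: str) -> Scaffold:
    """Load one of the scaffolds shipped with the package by tag."""
    if tag not in BUNDLED_SCAFFOLDS:
        raise KeyError(f"unknown scaffold tag {tag!r}; have {BUNDLED_SCAFFOLDS}")
    data = resources.files("fossilplace") / "data"
    return load_scaffold(data / f"{tag}.nwk", data / f"{tag}.json")


def fixture_hash(path: Union[str, Path]) -> str:
    """Short content hash for run-bundle provenance records."""
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:12]
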