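"""Discrete morphological character matrices: NEXUS I/O, subsetting, validation.

The NEXUS dialect accepted is the one MorphoBank (and TNT exports) emit:
a DATA or CHARACTERS block with DIMENSIONS/FORMAT/MATRIX, optional
interleaving, polymorphic cells as ``{01}`` or ``(01)``, ``?`` for missing
and ``-`` for inapplicable.  Inapplicable is conflated with missing — the
downstream parsimony scoring makes no gap/missing distinction, matching how
TNT treats morphological gaps.

Character indices are 1-based in files and in the public selection API, and
0-based internally.  Parsing is delegated to dendropy; the one command
dendropy does not expose, ASSUMPTIONS/WTSET (character weights), is read by
a small supplementary scan.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple, Union

import dendropy
import numpy as np

from .parsimony import MISSING, Cell, encode_cells

__all__ = [
    "CharacterMatrix",
    "CharacterColumn",
    "ValidationReport",
    "NexusParseError",
    "read_nexus",
    "write_nexus",
    "subset_characters",
    "append_characters",
    "validate_matrix",
    "to_tsv",
]


class NexusParseError(ValueError):
    pass


@dataclass
class CharacterColumn:
    """One character column to append: cells for every taxon, a weight, a label."""

    cells: Dict[str, Cell]
    weight: int = 1
    label: Optional[str] = None


@dataclass
class ValidationReport:
    errors: List[Tuple[str, str]] = field(default_factory=list)
    warnings: List[Tuple[str, str]] = field(default_factory=list)

    @property
    def is_valid(self) -> bool:
        return not self.errors


class CharacterMatrix:
    """A rectangular taxa x characters table of state-sets.

    Treated as immutable: all editing operations return a new matrix.

    Parameters
    ----------
    taxa:
        Ordered unique taxon labels.
    rows:
        Per taxon, a sequence of cells: a frozenset of integer states or
        the MISSING token.
    weights:
        Per-character non-negative integer weights (default all 1).
    partitions:
        Named, disjoint sets of 0-based character indices.
    char_labels:
        Optional per-character labels.
    """

    def __init__(
        self,
        taxa: Sequence[str],
        rows: Dict[str, Sequence[Cell]],
        weights: Optional[Sequence[int]] = None,
        partitions: Optional[Dict[str, Sequence[int]]] = None,
        char_labels: Optional[Sequence[str]] = None,
    ):
        self.taxa: Tuple[str, ...] = tuple(taxa)
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxon labels")
        if not self.taxa:
            raise ValueError("no taxa")
        lengths = {len(rows[t]) for t in self.taxa}
        if len(lengths) != 1:
            raise ValueError("matrix is not rectangular")
        self.n_characters: int = lengths.pop()
        self.rows: Dict[str, Tuple[Cell, ...]] = {}
        for t in self.taxa:
            cleaned = []
            for cell in rows[t]:
                if cell is MISSING or cell == MISSING:
                    cleaned.append(MISSING)
                else:
                    s = frozenset(int(x) for x in cell)
                    if not s:
                        raise ValueError(f"empty state set for {t!r}")
                    cleaned.append(s)
            self.rows[t] = tuple(cleaned)
        self.weights: Tuple[int, ...] = tuple(
            int(w) for w in (weights if weights is not None else [1] * self.n_characters)
        )
        if len(self.weights) != self.n_characters:
            raise ValueError("weights length mismatch")
        if any(w < 0 for w in self.weights):
            raise ValueError("negative weight")
        parts: Dict[str, Tuple[int, ...]] = {}
        seen: set = set()
        for name, idxs in (partitions or {}).items():
            idxs = tuple(sorted(int(i) for i in idxs))
            for i in idxs:
                if not (0 <= i < self.n_characters):
                    raise ValueError(f"partition {name!r} index {i} out of range")
                if i in seen:
                    raise ValueError(f"partition indices overlap at {i}")
                seen.add(i)
            parts[name] = idxs
        self.partitions: Dict[str, Tuple[int, ...]] = parts
        self.char_labels: Optional[Tuple[str, ...]] = (
            tuple(char_labels) if char_labels is not None else None
        )
        if self.char_labels is not None and len(self.char_labels) != self.n_characters:
            raise ValueError("char_labels length mismatch")
        self._mask_cache: Dict[str, np.ndarray] = {}

    # -- access ---------------------------------------------------------------

    def cell(self, taxon: str, index: int) -> Cell:
        """Cell for (taxon, 0-based character index)."""
        return self.rows[taxon][index]

    def column(self, index: int) -> Dict[str, Cell]:
        """Character column (0-based) as a {taxon: cell} map."""
        return {t: self.rows[t][index] for t in self.taxa}

    def row_masks(self, taxon: str) -> np.ndarray:
        """Bitmask encoding of a taxon's row (cached)."""
        if taxon not in self._mask_cache:
            self._mask_cache[taxon] = encode_cells(self.rows[taxon])
        return self._mask_cache[taxon]

    def __eq__(self, other) -> bool:
        if not isinstance(other, CharacterMatrix):
            return NotImplemented
        return (
            self.taxa == other.taxa
            and self.rows == other.rows
            and self.weights == other.weights
            and self.partitions == other.partitions
        )

    def __repr__(self) -> str:
        return f"<CharacterMatrix {len(self.taxa)} taxa x {self.n_characters} characters>"

    def max_state(self) -> int:
        m = 0
        for t in self.taxa:
            for cell in self.rows[t]:
                if cell is not MISSING and cell != MISSING:
                    m = max(m, max(cell))
        return m


# -- reading ------------------------------------------------------------------------

_WTSET_RE = re.compile(
    r"\bWTSET\b\s+\*?\s*[\w.]+\s*(?:\([^)]*\))?\s*=\s*([^;]+);", re.IGNORECASE
)


def _parse_index_spec(spec: str, n: int) -> List[int]:
    """Parse NEXUS 1-based index lists like '1-25 28 30' to 0-based indices."""
    out: List[int] = []
    for tok in spec.split():
        if "-" in tok and tok != "-":
            lo, hi = tok.split("-")
            hi = n if hi.strip() == "." else int(hi)
            out.extend(range(int(lo) - 1, hi))
        else:
            out.append(int(tok) - 1)
    return out


def read_nexus(path: Union[str, Path]) -> CharacterMatrix:
    """Read a NEXUS DATA/CHARACTERS block into a CharacterMatrix.

    ``?`` and ``-`` both parse to MISSING; ``{..}`` and ``(..)`` to state
    sets; CHARSET commands populate partitions.  A 30-character matrix with
    no partitions in the file gets the default floral (1-25) / foliar
    (26-30) split.
    """
    path = Path(path)
    text = path.read_text()
    try:
        ds = dendropy.DataSet.get(data=text, schema="nexus", preserve_underscores=True)
    except Exception as exc:
        raise NexusParseError(f"{path}: {exc}") from exc
    if not ds.char_matrices:
        raise NexusParseError(f"{path}: no DATA or CHARACTERS block found")
    m = ds.char_matrices[0]

    taxa = [t.label for t in m.taxon_namespace]
    if len(set(taxa)) != len(taxa):
        raise NexusParseError(f"{path}: duplicate taxon label")
    # dendropy tolerates a DIMENSIONS/body disagreement; reject it here
    dim = re.search(r"\bNTAX\s*=\s*(\d+)", text, re.IGNORECASE)
    if dim and int(dim.group(1)) != len(taxa):
        raise NexusParseError(
            f"{path}: NTAX={dim.group(1)} but matrix has {len(taxa)} taxa"
        )
    dim = re.search(r"\bNCHAR\s*=\s*(\d+)", text, re.IGNORECASE)
    if dim:
        declared_nchar = int(dim.group(1))
        for tax in m.taxon_namespace:
            if len(m[tax]) != declared_nchar:
                raise NexusParseError(
                    f"{path}: NCHAR={declared_nchar} but {tax.label!r} has "
                    f"{len(m[tax])} cells"
                )
    rows: Dict[str, List[Cell]] = {}
    n_chars = None
    for tax in m.taxon_namespace:
        cells: List[Cell] = []
        for c in m[tax]:
            if c.symbol in ("?", "-"):
                cells.append(MISSING)
            elif c.state_denomination == 0:  # single fundamental state
                cells.append(frozenset([int(c.symbol)]))
            else:
                symbols = {s.symbol for s in c.member_states}
                states = frozenset(int(s) for s in symbols if s.isdigit())
                cells.append(states if states else MISSING)
        if n_chars is None:
            n_chars = len(cells)
        elif len(cells) != n_chars:
            raise NexusParseError(
                f"{path}: row length mismatch for taxon {tax.label!r}"
            )
        rows[tax.label] = cells

    partitions = {
        name: sorted(sub.character_indices)
        for name, sub in m.character_subsets.items()
    }
    if not partitions and n_chars == 30:
        partitions = {"floral": list(range(25)), "foliar": list(range(25, 30))}

    weights = [1] * n_chars
    wt = _WTSET_RE.search(text)
    if wt:
        for part in wt.group(1).split(","):
            w_str, _, idx_spec = part.partition(":")
            for i in _parse_index_spec(idx_spec, n_chars):
                weights[i] = int(float(w_str))

    return CharacterMatrix(taxa, rows, weights=weights, partitions=partitions)


# -- writing ------------------------------------------------------------------------


def _format_cell(cell: Cell) -> str:
    if cell is MISSING or cell == MISSING:
        return "?"
    states = sorted(cell)
    if len(states) == 1:
        return str(states[0])
    return "{" + "".join(str(s) for s in states) + "}"


def _nexus_label(label: str) -> str:
    if re.fullmatch(r"[\w.\-]+", label):
        return label
    return "'" + label.replace("'", "''") + "'"


def _ranges(indices: Sequence[int]) -> str:
    """Render sorted 0-based indices as a 1-based NEXUS range list."""
    spans: List[str] = []
    idxs = sorted(i + 1 for i in indices)
    start = prev = idxs[0]
    for i in idxs[1:] + [None]:
        if i is not None and i == prev + 1:
            prev = i
            continue
        spans.append(str(start) if start == prev else f"{start}-{prev}")
        if i is not None:
            start = prev = i
    return " ".join(spans)


def write_nexus(matrix: CharacterMatrix, path: Union[str, Path]) -> None:
    """Serialize a matrix to NEXUS, readable back by :func:`read_nexus`.

    Deterministic layout: the same matrix always produces the same bytes.
    """
    path = Path(path)
    symbols = "".join(str(s) for s in range(matrix.max_state() + 1))
    lines = ["#NEXUS", "", "BEGIN DATA;"]
    lines.append(
        f"    DIMENSIONS NTAX={len(matrix.taxa)} NCHAR={matrix.n_characters};"
    )
    lines.append(
        f'    FORMAT DATATYPE=STANDARD SYMBOLS="{symbols}" MISSING=? GAP=-;'
    )
    lines.append("    MATRIX")
    width = max(len(_nexus_label(t)) for t in matrix.taxa) + 2
    for t in matrix.taxa:
        row = "".join(_format_cell(c) for c in matrix.rows[t])
        lines.append(f"    {_nexus_label(t):<{width}}{row}")
    lines.append("    ;")
    lines.append("END;")
    if matrix.partitions:
        lines.append("")
        lines.append("BEGIN SETS;")
        for name in sorted(matrix.partitions):
            lines.append(
                f"    CHARSET {name} = {_ranges(matrix.partitions[name])};"
            )
        lines.append("END;")
    if any(w != 1 for w in matrix.weights):
        groups: Dict[int, List[int]] = {}
        for i, w in enumerate(matrix.weights):
            groups.setdefault(w, []).append(i)
        parts = [f"{w}: {_ranges(groups[w])}" for w in sorted(groups)]
        lines.append("")
        lines.append("BEGIN ASSUMPTIONS;")
        lines.append(f"    WTSET * untitled = {', '.join(parts)};")
        lines.append("END;")
    path.write_text("\n".join(lines) + "\n")


# -- editing ------------------------------------------------------------------------


def subset_characters(
    matrix: CharacterMatrix, selection: Union[str, Sequence[int]]
) -> CharacterMatrix:
    """Restrict to a partition by name, or to an explicit list of 1-based indices.

    Weights, labels and (restricted, re-indexed) partitions carry over;
    taxa are unchanged.  Duplicate indices are rejected.
    """
    if isinstance(selection, str):
        if selection not in matrix.partitions:
            raise KeyError(
                f"unknown partition {selection!r}; have {sorted(matrix.partitions)}"
            )
        idxs = list(matrix.partitions[selection])
    else:
        idxs = [int(i) - 1 for i in selection]
        if len(set(idxs)) != len(idxs):
            raise ValueError("duplicate character indices in selection")
        for i in idxs:
            if not (0 <= i < matrix.n_characters):
                raise IndexError(f"character index {i + 1} out of range")
    remap = {old: new for new, old in enumerate(idxs)}
    rows = {t: [matrix.rows[t][i] for i in idxs] for t in matrix.taxa}
    partitions = {}
    for name, pidx in matrix.partitions.items():
        kept = [remap[i] for i in pidx if i in remap]
        if kept:
            partitions[name] = kept
    return CharacterMatrix(
        matrix.taxa,
        rows,
        weights=[matrix.weights[i] for i in idxs],
        partitions=partitions,
        char_labels=(
            [matrix.char_labels[i] for i in idxs] if matrix.char_labels else None
        ),
    )


def append_characters(
    matrix: CharacterMatrix, extra: Sequence[CharacterColumn]
) -> CharacterMatrix:
    """Append character columns; they land in a partition named 'constraints'."""
    if not extra:
        return matrix
    for col in extra:
        unknown = set(col.cells) - set(matrix.taxa)
        if unknown:
            raise ValueError(f"column references unknown taxa: {sorted(unknown)}")
        missing = set(matrix.taxa) - set(col.cells)
        if missing:
            raise ValueError(f"column lacks cells for taxa: {sorted(missing)}")
    rows = {
        t: list(matrix.rows[t]) + [col.cells[t] for col in extra] for t in matrix.taxa
    }
    n_new = len(extra)
    new_idx = list(range(matrix.n_characters, matrix.n_characters + n_new))
    partitions = {k: list(v) for k, v in matrix.partitions.items()}
    partitions.setdefault("constraints", [])
    partitions["constraints"] = list(partitions["constraints"]) + new_idx
    labels = None
    if matrix.char_labels is not None or any(c.label for c in extra):
        base = list(matrix.char_labels or [f"char{i+1}" for i in range(matrix.n_characters)])
        labels = base + [c.label or f"constraint{i+1}" for i, c in enumerate(extra)]
    return CharacterMatrix(
        matrix.taxa,
        rows,
        weights=list(matrix.weights) + [c.weight for c in extra],
        partitions=partitions,
        char_labels=labels,
    )


# -- validation and export ----------------------------------------------------------


def validate_matrix(matrix: CharacterMatrix) -> ValidationReport:
    """Report structural problems (errors) and suspicious content (warnings)."""
    report = ValidationReport()
    for ci in range(matrix.n_characters):
        col = [matrix.rows[t][ci] for t in matrix.taxa]
        observed = [c for c in col if c is not MISSING and c != MISSING]
        loc = f"character {ci + 1}"
        if not observed:
            report.warnings.append((loc, "all cells missing"))
        elif len({frozenset(c) for c in observed}) == 1 and all(
            len(c) == 1 for c in observed
        ):
            report.warnings.append((loc, "constant character"))
    for t in matrix.taxa:
        n_missing = sum(
            1 for c in matrix.rows[t] if c is MISSING or c == MISSING
        )
        if n_missing == matrix.n_characters:
            report.warnings.append((f"taxon {t}", "all cells missing"))
        elif n_missing / matrix.n_characters > 0.5:
            report.warnings.append(
                (
                    f"taxon {t}",
                    f"missing {n_missing}/{matrix.n_characters} cells "
                    f"({n_missing / matrix.n_characters:.0%})",
                )
            )
    return report


def to_tsv(matrix: CharacterMatrix) -> str:
    """Tab-separated rendering for inspection (taxa as rows)."""
    header = "taxon\t" + "\t".join(
        matrix.char_labels
        if matrix.char_labels
        else [f"char{i+1}" for i in range(matrix.n_characters)]
    )
    lines = [header]
    for t in matrix.taxa:
        lines.append(t + "\t" + "\t".join(_format_cell(c) for c in matrix.rows[t]))
    return "\n".join(lines) + "\n"
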