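"""NEXUS reading/writing, subsetting, appending, validation."""

import textwrap

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fossilplace.matrix_io import (
    CharacterColumn,
    CharacterMatrix,
    NexusParseError,
    append_characters,
    read_nexus,
    subset_characters,
    to_tsv,
    validate_matrix,
    write_nexus,
)
from fossilplace.parsimony import MISSING


def make_nexus(tmp_path, body, name="m.nex"):
    path = tmp_path / name
    path.write_text(textwrap.dedent(body))
    return path


SMALL = """\
    #NEXUS
    BEGIN DATA;
    DIMENSIONS NTAX=4 NCHAR=5;
    FORMAT DATATYPE=STANDARD SYMBOLS="012" MISSING=? GAP=-;
    MATRIX
    Alpha  01{01}?0
    Beta   0-1(12)2
    Gamma  00000
    Delta  11111
    ;
    END;
    BEGIN SETS;
    CHARSET floral = 1-3;
    CHARSET foliar = 4-5;
    END;
    """


class TestReading:
    def test_tokens(self, tmp_path):
        m = read_nexus(make_nexus(tmp_path, SMALL))
        assert m.taxa == ("Alpha", "Beta", "Gamma", "Delta")
        assert m.n_characters == 5
        assert m.cell("Alpha", 2) == frozenset({0, 1})  # "{01}"
        assert m.cell("Alpha", 3) is MISSING  # "?"
        assert m.cell("Beta", 1) is MISSING  # "-" conflated with missing
        assert m.cell("Beta", 3) == frozenset({1, 2})  # "(12)"
        assert m.partitions == {"floral": (0, 1, 2), "foliar": (3, 4)}

    def test_interleaved(self, tmp_path):
        body = """\
            #NEXUS
            BEGIN DATA;
            DIMENSIONS NTAX=2 NCHAR=4;
            FORMAT DATATYPE=STANDARD SYMBOLS="01" MISSING=? INTERLEAVE;
            MATRIX
            A 01
            B 10
            A 11
            B 00
            ;
            END;
            """
        m = read_nexus(make_nexus(tmp_path, body))
        assert m.rows["A"] == tuple(frozenset([s]) for s in (0, 1, 1, 1))
        assert m.rows["B"] == tuple(frozenset([s]) for s in (1, 0, 0, 0))

    def test_ntax_mismatch_raises(self, tmp_path):
        body = SMALL.replace("NTAX=4", "NTAX=5")
        with pytest.raises(NexusParseError):
            read_nexus(make_nexus(tmp_path, body))

    def test_malformed_block_raises(self, tmp_path):
        with pytest.raises(NexusParseError):
            read_nexus(make_nexus(tmp_path, "#NEXUS\nBEGIN DATA;\nMATRIX\nA 01\n"))

    def test_default_partitions_for_30_characters(self, tmp_path):
        row = "0" * 30
        body = (
            "#NEXUS\nBEGIN DATA;\nDIMENSIONS NTAX=2 NCHAR=30;\n"
            'FORMAT DATATYPE=STANDARD SYMBOLS="01" MISSING=?;\n'
            f"MATRIX\nA {row}\nB {'1'*30}\n;\nEND;\n"
        )
        m = read_nexus(make_nexus(tmp_path, body))
        assert m.partitions["floral"] == tuple(range(25))
        assert m.partitions["foliar"] == tuple(range(25, 30))

    def test_weights_roundtrip(self, tmp_path):
        m = read_nexus(make_nexus(tmp_path, SMALL))
        weighted = CharacterMatrix(
            m.taxa, m.rows, weights=[1, 1, 1, 99, 99], partitions=m.partitions
        )
        out = tmp_path / "w.nex"
        write_nexus(weighted, out)
        again = read_nexus(out)
        assert again.weights == (1, 1, 1, 99, 99)


class TestWriting:
    def test_roundtrip_identity(self, tmp_path):
        m = read_nexus(make_nexus(tmp_path, SMALL))
        out = tmp_path / "out.nex"
        write_nexus(m, out)
        assert read_nexus(out) == m

    def test_double_serialization_byte_identical(self, tmp_path):
        m = read_nexus(make_nexus(tmp_path, SMALL))
        p1, p2 = tmp_path / "a.nex", tmp_path / "b.nex"
        write_nexus(m, p1)
        write_nexus(read_nexus(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_no_sets_block_without_partitions(self, tmp_path):
        m = CharacterMatrix(["A", "B"], {"A": [frozenset([0])], "B": [frozenset([1])]})
        out = tmp_path / "p.nex"
        write_nexus(m, out)
        text = out.read_text()
        assert "BEGIN DATA;" in text and "SETS" not in text

    def test_polymorphism_multiset_preserved(self, tmp_path):
        """No polymorphic state is silently dropped on a write/read cycle."""
        m = CharacterMatrix(
            ["A", "B", "C"],
            {
                "A": [frozenset([0, 2]), MISSING],
                "B": [frozenset([1]), frozenset([0, 1, 2])],
                "C": [MISSING, frozenset([2])],
            },
        )
        out = tmp_path / "poly.nex"
        write_nexus(m, out)
        assert read_nexus(out).rows == m.rows


cells = st.one_of(
    st.just(MISSING),
    st.frozensets(st.integers(0, 3), min_size=1, max_size=3),
)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    n_taxa=st.integers(2, 8),
    n_chars=st.integers(1, 12),
    data=st.data(),
)
def test_roundtrip_property(tmp_path_factory, n_taxa, n_chars, data):
    """read(write(M)) == M for arbitrary matrices (cells, weights, partitions)."""
    taxa = [f"tax{i}" for i in range(n_taxa)]
    rows = {
        t: [data.draw(cells) for _ in range(n_chars)] for t in taxa
    }
    # ensure at least one observed state overall so SYMBOLS is non-empty
    rows[taxa[0]][0] = frozenset([0])
    weights = data.draw(
        st.lists(st.integers(0, 99), min_size=n_chars, max_size=n_chars)
    )
    cut = data.draw(st.integers(0, n_chars))
    partitions = {}
    if cut > 0:
        partitions["front"] = list(range(cut))
    if cut < n_chars and n_chars != 30:
        partitions["back"] = list(range(cut, n_chars))
    m = CharacterMatrix(taxa, rows, weights=weights, partitions=partitions)
    path = tmp_path_factory.mktemp("rt") / "m.nex"
    write_nexus(m, path)
    assert read_nexus(path) == m


class TestSubset:
    @pytest.fixture
    def matrix(self, tmp_path):
        return read_nexus(make_nexus(tmp_path, SMALL))

    def test_by_partition_name(self, matrix):
        sub = subset_characters(matrix, "floral")
        assert sub.n_characters == 3
        assert sub.taxa == matrix.taxa
        assert sub.rows["Alpha"] == matrix.rows["Alpha"][:3]

    def test_all_indices_is_identity(self, matrix):
        assert subset_characters(matrix, [1, 2, 3, 4, 5]) == matrix

    def test_duplicate_indices_rejected(self, matrix):
        with pytest.raises(ValueError):
            subset_characters(matrix, [1, 1])

    def test_unknown_partition(self, matrix):
        with pytest.raises(KeyError):
            subset_characters(matrix, "nope")

    def test_subset_plus_complement_reconstitutes(self, matrix):
        """Selecting a block and appending its complement permutes columns only."""
        sub = subset_characters(matrix, [1, 2, 3])
        complement = [
            CharacterColumn(
                cells={t: matrix.rows[t][i] for t in matrix.taxa},
                weight=matrix.weights[i],
            )
            for i in (3, 4)
        ]
        rebuilt = append_characters(sub, complement)
        assert rebuilt.n_characters == matrix.n_characters
        for t in matrix.taxa:
            assert sorted(map(repr, rebuilt.rows[t])) == sorted(
                map(repr, matrix.rows[t])
            )


class TestAppend:
    @pytest.fixture
    def matrix(self, tmp_path):
        return read_nexus(make_nexus(tmp_path, SMALL))

    def test_append_nothing_is_identity(self, matrix):
        assert append_characters(matrix, []) is matrix

    def test_append_weighted_binary_column(self, matrix):
        col = CharacterColumn(
            cells={t: frozenset([0]) for t in matrix.taxa}, weight=99
        )
        out = append_characters(matrix, [col])
        assert out.n_characters == 6
        assert out.weights == (1, 1, 1, 1, 1, 99)
        assert out.partitions["constraints"] == (5,)
        assert out.partitions["floral"] == (0, 1, 2)

    def test_incomplete_column_rejected(self, matrix):
        with pytest.raises(ValueError):
            append_characters(
                matrix, [CharacterColumn(cells={"Alpha": frozenset([0])})]
            )
        with pytest.raises(ValueError):
            append_characters(
                matrix,
                [
                    CharacterColumn(
                        cells={
                            **{t: frozenset([0]) for t in matrix.taxa},
                            "Ghost": frozenset([1]),
                        }
                    )
                ],
            )


class TestValidation:
    def test_clean_matrix(self):
        m = CharacterMatrix(
            ["A", "B"], {"A": [frozenset([0])], "B": [frozenset([1])]}
        )
        assert validate_matrix(m).is_valid

    def test_constant_character_warning(self):
        m = CharacterMatrix(
            ["A", "B"], {"A": [frozenset([1])], "B": [frozenset([1])]}
        )
        rep = validate_matrix(m)
        assert rep.is_valid
        assert any("constant" in msg for _, msg in rep.warnings)

    def test_sparse_fossil_row_reports_coverage(self):
        rows = {
            "Fossil": [MISSING] * 20 + [frozenset([0])] * 10,
            "Extant": [frozenset([0])] * 15 + [frozenset([1])] * 15,
        }
        rep = validate_matrix(CharacterMatrix(["Fossil", "Extant"], rows))
        hits = [msg for loc, msg in rep.warnings if "Fossil" in loc]
        assert hits and "20/30" in hits[0]

    def test_tsv_export_shape(self, tmp_path):
        m = read_nexus(make_nexus(tmp_path, SMALL))
        lines = to_tsv(m).strip().splitlines()
        assert len(lines) == 5  # header + 4 taxa
        assert lines[1].startswith("Alpha\t")
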