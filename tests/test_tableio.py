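"""STAR and delimited-text serialization: involution, dialect details and
agreement with the independent minimal reference parser."""

import pytest
from hypothesis import given, settings, strategies as st

from emkit import Column, FormatError, StarDocument, Table
from emkit import tableio
from emkit.table import MISSING
from emkit import fixtures


# --- randomized document generation for the involution property ----------

_names = st.from_regex(r"[A-Za-z][A-Za-z0-9_]{0,8}", fullmatch=True)
_strings = st.text(
    alphabet=st.characters(codec="ascii", exclude_characters="'\"\n\r\t;"),
    min_size=0, max_size=12,
)


@st.composite
def star_documents(draw):
    n_blocks = draw(st.integers(1, 3))
    blocks = {}
    block_names = draw(st.lists(_names, min_size=n_blocks,
                                max_size=n_blocks, unique=True))
    for bname in block_names:
        n_cols = draw(st.integers(1, 8))
        col_names = draw(st.lists(_names, min_size=n_cols, max_size=n_cols,
                                  unique=True))
        ctypes = draw(st.lists(st.sampled_from(["int", "float", "string"]),
                               min_size=n_cols, max_size=n_cols))
        n_rows = draw(st.integers(0, 50))
        cols = [Column(n, c) for n, c in zip(col_names, ctypes)]
        rows = []
        for _ in range(n_rows):
            row = []
            for c in cols:
                if c.ctype == "int":
                    row.append(draw(st.integers(-10**6, 10**6)))
                elif c.ctype == "float":
                    row.append(draw(st.floats(allow_nan=False,
                                              allow_infinity=False,
                                              width=32)))
                else:
                    row.append(draw(_strings))
            rows.append(row)
        tab = Table(cols, rows)
        # sprinkle one all-missing row while keeping >=1 real value per
        # typed column so read-side type inference can recover the ctype
        if n_rows >= 2 and draw(st.booleans()):
            out_rows = list(tab.rows)
            miss_row = draw(st.integers(1, n_rows - 1))
            out_rows[miss_row] = tuple(MISSING for _ in cols)
            tab = Table(cols, out_rows)
        blocks[bname] = tab
    return StarDocument(blocks)


class TestStarRoundTrip:
    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(star_documents())
    def test_involution_on_random_documents(self, tmp_path_factory, doc):
        """read(write(doc)) reproduces block names, columns and values.

        Zero-row blocks are compared on structure only: an empty loop
        carries no tokens to infer element types from.
        """
        path = tmp_path_factory.mktemp("star") / "doc.star"
        tableio.write_star(doc, path)
        back = tableio.read_star(path)
        assert back.block_names == doc.block_names
        for name in doc.block_names:
            a, b = doc[name], back[name]
            assert b.column_names == a.column_names
            assert b.n_rows == a.n_rows
            if a.n_rows:
                assert b == a

    def test_quoted_string_with_space(self, tmp_path):
        t = Table([Column("name", "string")], [("mic 001",)])
        p = tmp_path / "q.star"
        tableio.write_star(StarDocument({"b": t}), p)
        assert "'mic 001'" in p.read_text()
        assert tableio.read_star(p)["b"] == t

    def test_missing_written_as_dot(self, tmp_path):
        t = Table([Column("v", "float")], [(1.5,), (MISSING,)])
        p = tmp_path / "m.star"
        tableio.write_star(StarDocument({"b": t}), p)
        assert "\n." in "\n" + "\n".join(
            line for line in p.read_text().splitlines())
        assert tableio.read_star(p)["b"].rows[1][0] is MISSING

    def test_numeric_looking_string_stays_string(self, tmp_path):
        t = Table([Column("v", "string")], [("123",), ("4.5e6",)])
        p = tmp_path / "s.star"
        tableio.write_star(StarDocument({"b": t}), p)
        assert tableio.read_star(p)["b"] == t


class TestStarParsing:
    def test_loop_with_ordinals_and_comments(self, tmp_path):
        p = tmp_path / "a.star"
        p.write_text(
            "# a comment\n"
            "data_images\n\nloop_\n"
            "_defocus #2\n_id #1\n"
            "1 1.2\n"
            "2 2.5  # trailing comment\n"
        )
        t = tableio.read_star(p)["images"]
        # the #N ordinals order the columns, not the file order
        assert t.column_names == ("id", "defocus")
        assert t.rows == ((1, 1.2), (2, 2.5))

    def test_empty_loop_keeps_columns(self, tmp_path):
        p = tmp_path / "a.star"
        p.write_text("data_b\nloop_\n_x #1\n_y #2\ndata_c\n_k 1\n")
        t = tableio.read_star(p)["b"]
        assert t.column_names == ("x", "y") and t.n_rows == 0

    def test_key_value_block_is_single_row(self, tmp_path):
        p = tmp_path / "a.star"
        p.write_text("data_general\n_voltage 300\n_cs 2.7\n_mode 'counting'\n")
        t = tableio.read_star(p)["general"]
        assert t.n_rows == 1
        assert t.rows[0] == (300, 2.7, "counting")

    def test_value_count_mismatch_errors(self, tmp_path):
        p = tmp_path / "a.star"
        p.write_text("data_b\nloop_\n_x #1\n_y #2\n_z #3\n1 2\n")
        with pytest.raises(FormatError):
            tableio.read_star(p)

    def test_duplicate_labels_error(self, tmp_path):
        p = tmp_path / "a.star"
        p.write_text("data_b\nloop_\n_x #1\n_x #2\n1 2\n")
        with pytest.raises(FormatError):
            tableio.read_star(p)

    def test_unterminated_quote_errors(self, tmp_path):
        p = tmp_path / "a.star"
        p.write_text("data_b\nloop_\n_x #1\n'oops\n")
        with pytest.raises(FormatError):
            tableio.read_star(p)

    def test_semicolon_text_field_read(self, tmp_path):
        p = tmp_path / "a.star"
        p.write_text("data_b\nloop_\n_x #1\n;\nline one\nline two\n;\n")
        t = tableio.read_star(p)["b"]
        assert t.rows[0][0] == "line one\nline two"

    def test_question_mark_reads_as_missing(self, tmp_path):
        p = tmp_path / "a.star"
        p.write_text("data_b\nloop_\n_x #1\n? \n3\n")
        assert tableio.read_star(p)["b"].rows[0][0] is MISSING


class TestReferenceParserAgreement:
    def test_written_star_matches_minimal_parser(self, tmp_path, rng):
        from conftest import random_table
        t = random_table(rng, 20, with_missing=True)
        p = tmp_path / "x.star"
        tableio.write_star(StarDocument({"particles": t}), p)
        ref = fixtures.parse_star_minimal(p)
        labels, rows = ref["particles"]
        assert labels == list(t.column_names)
        assert len(rows) == t.n_rows
        # spot-check raw token round trip of the float column
        for raw, row in zip(rows, t.rows):
            if row[1] is MISSING:
                assert raw[1] == "."
            else:
                assert float(raw[1]) == row[1]

    def test_toy_star_cross_implementation(self, tmp_path):
        p = tmp_path / "toy.star"
        fixtures.make_toy_star(p)
        t = tableio.read_star(p)["micrographs"]
        assert [c.ctype for c in t.columns] == ["int", "float", "string",
                                                "float"]
        assert t.rows[2][2] == "mic c"  # quoting preserved the space
        assert t.rows[3][3] is MISSING
        assert [r[0] for r in t.filter("defocus < 2.0").rows] == [1, 3]


class TestDelimited:
    def test_star_tsv_cross_format_identity(self, tmp_path):
        fixtures.make_toy_star(tmp_path / "toy.star")
        t = tableio.read_star(tmp_path / "toy.star")["micrographs"]
        tableio.write_tsv(t, tmp_path / "t.tsv")
        assert tableio.read_tsv(tmp_path / "t.tsv") == t

    def test_zero_row_round_trip(self, tmp_path):
        t = Table([Column("a", "string"), Column("b", "string")])
        tableio.write_tsv(t, tmp_path / "e.tsv")
        back = tableio.read_tsv(tmp_path / "e.tsv")
        assert back.column_names == ("a", "b") and back.n_rows == 0

    def test_ragged_row_errors(self, tmp_path):
        (tmp_path / "r.tsv").write_text("a\tb\n1\t2\n3\n")
        with pytest.raises(FormatError):
            tableio.read_tsv(tmp_path / "r.tsv")

    def test_csv_delimiter(self, tmp_path):
        t = Table([Column("a", "int"), Column("b", "float")],
                  [(1, 0.5), (2, 1.5)])
        tableio.write_tsv(t, tmp_path / "x.csv", delimiter=",")
        assert tableio.read_tsv(tmp_path / "x.csv", delimiter=",") == t
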