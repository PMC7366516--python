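import numpy as np
import pytest

from conftest import data_path, generic_matrix, random_matrix
from karyophylo import (
    CharacterMatrix,
    HomologyMap,
    RearrangementCharacter,
    SegmentAssignment,
    build_matrix,
    classification_counts,
    classify_characters,
    enumerate_characters,
    parse_homology_tsv,
    read_matrix,
    score_taxon,
    write_matrix,
)
from karyophylo.labels import parse_label


def _map(taxon, pairs, two_n=78):
    """pairs: iterable of (ancestral text, descendant text)."""
    return HomologyMap(taxon, two_n, tuple(
        SegmentAssignment(taxon=taxon, ancestral=parse_label(a),
                          descendant=parse_label(d))
        for a, d in pairs))


def identity_pairs(taxon, n=6):
    return [(f"PAK{i}", f"{taxon}{i}") for i in range(1, n + 1)]


@pytest.fixture(scope="module")
def table5_maps():
    maps = {m.taxon: m for m in
            parse_homology_tsv(data_path("table5_all_species.tsv"))}
    return [maps[t] for t in
            ("AHY", "ACH", "PFR", "AMA", "MMO", "AAE", "GGA", "TRU")]


class TestEnumeration:
    def test_identical_maps_yield_no_characters(self):
        maps = [_map("A", identity_pairs("A")), _map("B", identity_pairs("B"))]
        assert enumerate_characters(maps) == []

    def test_single_fusion_yields_single_character(self):
        a = _map("A", identity_pairs("A"))
        pairs = identity_pairs("B")
        # fuse PAK2 and PAK3 onto one chromosome of B
        pairs = [(anc, d) for anc, d in pairs if anc not in ("PAK2", "PAK3")]
        pairs += [("PAK2", "B2"), ("PAK3", "B2")]
        b = _map("B", pairs)
        chars = enumerate_characters([a, b])
        assert len(chars) == 1
        (c,) = chars
        assert c.kind == "fusion-association"
        assert {p.number for p in c.definition} == {2, 3}

    def test_table5_contains_pak1_pak4_association(self, table5_maps):
        chars = enumerate_characters(table5_maps)
        ids = [c.id for c in chars]
        assert "fus_PAK1+PAK4" in ids
        # ordering: all fusion characters precede all fission characters
        kinds = [c.kind for c in chars]
        assert kinds == sorted(kinds, key=["fusion-association",
                                           "fission-pattern"].index)

    def test_micro_unknown_never_codes(self):
        a = _map("A", identity_pairs("A"))
        b = _map("B", identity_pairs("B") + [("micro", "B1")])
        # B1 carries PAK1 + an unidentified micro: not a codable association
        assert enumerate_characters([a, b]) == []


class TestScoring:
    def test_association_present(self, table5_maps):
        mmo = next(m for m in table5_maps if m.taxon == "MMO")
        char = RearrangementCharacter(
            id="fus_PAK8+PAK9", kind="fusion-association",
            definition=frozenset([parse_label("PAK8"), parse_label("PAK9")]))
        assert score_taxon(mmo, char) == "1"

    def test_association_absent(self, table5_maps):
        aae = next(m for m in table5_maps if m.taxon == "AAE")
        char = RearrangementCharacter(
            id="fus_PAK8+PAK9", kind="fusion-association",
            definition=frozenset([parse_label("PAK8"), parse_label("PAK9")]))
        assert score_taxon(aae, char) == "0"

    def test_unassayed_chromosome_scores_missing(self):
        m = _map("A", identity_pairs("A", n=5))  # PAK12 never assayed
        char = RearrangementCharacter(
            id="fus_PAK1+PAK12", kind="fusion-association",
            definition=frozenset([parse_label("PAK1"), parse_label("PAK12")]))
        assert score_taxon(m, char) == "?"

    def test_superset_counts_as_presence(self, table5_maps):
        # MMO9 carries PAK6+PAK7+PAK11; the plain PAK6/PAK7 association is
        # therefore present in MMO
        mmo = next(m for m in table5_maps if m.taxon == "MMO")
        char = RearrangementCharacter(
            id="fus_PAK6+PAK7", kind="fusion-association",
            definition=frozenset([parse_label("PAK6"), parse_label("PAK7")]))
        assert score_taxon(mmo, char) == "1"

    def test_fission_pattern_exact_count(self, table5_maps):
        mmo = next(m for m in table5_maps if m.taxon == "MMO")
        gga = next(m for m in table5_maps if m.taxon == "GGA")
        four = RearrangementCharacter(
            id="fis_PAK1_x4", kind="fission-pattern",
            definition=frozenset([parse_label("PAK1")]), descendant_count=4)
        assert score_taxon(mmo, four) == "1"
        assert score_taxon(gga, four) == "0"


class TestMatrix:
    def test_pak1_pak4_column(self, table5_maps):
        matrix = build_matrix(table5_maps)
        for taxon in ("AHY", "ACH", "PFR", "AMA"):
            assert matrix.state(taxon, "fus_PAK1+PAK4") == "1"
        assert matrix.state("GGA", "fus_PAK1+PAK4") == "0"
        assert matrix.state("MMO", "fus_PAK1+PAK4") == "0"

    def test_identical_maps_give_zero_variable_columns(self):
        maps = [_map(t, identity_pairs(t)) for t in "ABC"]
        matrix = build_matrix(maps)
        assert matrix.ncharacters == 0

    def test_order_invariance(self, table5_maps):
        a = build_matrix(table5_maps)
        b = build_matrix(list(reversed(table5_maps)))
        assert [c.id for c in a.characters] == [c.id for c in b.characters]
        for t in a.taxa:
            assert a.row_string(t) == b.row_string(t)

    def test_classification(self):
        m = generic_matrix([[1, 1, 1], [1, 0, 1], [0, 0, -1], [0, 0, -1],
                            [0, 0, 1], [0, 0, 1], [0, 0, 1], [0, 0, 1]])
        assert classify_characters(m) == ["informative", "uninformative",
                                          "constant"]
        counts = classification_counts(m)
        assert sum(counts.values()) == m.ncharacters

    def test_drop_character(self, table5_maps):
        matrix = build_matrix(table5_maps)
        nchar = matrix.ncharacters
        dropped = matrix.drop_character("fus_PAK1+PAK4")
        assert dropped.ncharacters == nchar - 1
        assert matrix.ncharacters == nchar  # original unchanged
        assert "fus_PAK1+PAK4" not in [c.id for c in dropped.characters]
        with pytest.raises(KeyError):
            matrix.drop_character("no_such_character")

    def test_drop_each_column(self):
        m = generic_matrix(np.eye(4, dtype=np.int8))
        for c in m.characters:
            assert m.drop_character(c.id).ncharacters == 3

    def test_all_missing_column_rejected(self):
        with pytest.raises(ValueError):
            generic_matrix([[0, -1], [1, -1]])


class TestMatrixIO:
    @pytest.mark.parametrize("fmt", ["nexus", "phylip"])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_round_trip(self, tmp_path, fmt, seed):
        rng = np.random.default_rng(seed)
        m = random_matrix(rng, 8, 34, missing_frac=0.1)
        path = tmp_path / f"m.{fmt}"
        write_matrix(m, path, format=fmt)
        again = read_matrix(path, format=fmt)
        assert again.taxa == m.taxa
        assert np.array_equal(again.states, m.states)
        if fmt == "nexus":  # character ids ride along in CHARLABELS
            assert [c.id for c in again.characters] == [c.id for c in m.characters]

    def test_long_taxon_names_phylip(self, tmp_path):
        m = generic_matrix([[0, 1], [1, 0]], taxa=["Gallus_gallus_dom",
                                                   "Turdus_rufiventris"])
        write_matrix(m, tmp_path / "m.phy", format="phylip")
        again = read_matrix(tmp_path / "m.phy", format="phylip")
        assert again.taxa == m.taxa

    def test_interleaved_nexus_matches_hand_parser(self, tmp_path):
        nex = (
            "#NEXUS\nBEGIN DATA;\nDIMENSIONS NTAX=3 NCHAR=6;\n"
            'FORMAT DATATYPE=STANDARD SYMBOLS="01" MISSING=? GAP=- '
            "INTERLEAVE=YES;\nMATRIX\nA 010\nB 1?0\nC 001\n\n"
            "A 110\nB 011\nC ?01\n;\nEND;\n")
        p = tmp_path / "i.nex"
        p.write_text(nex)
        parsed = read_matrix(p)
        # independent minimal parser: concatenate per-taxon row chunks
        rows: dict[str, str] = {}
        in_matrix = False
        for line in nex.splitlines():
            line = line.strip()
            if line == "MATRIX":
                in_matrix = True
                continue
            if line.startswith(";"):
                in_matrix = False
            if in_matrix and line:
                name, chunk = line.split()
                rows[name] = rows.get(name, "") + chunk
        for t in parsed.taxa:
            assert parsed.row_string(t) == rows[t]

    def test_declared_dimension_mismatch(self, tmp_path):
        bad = ("#NEXUS\nBEGIN DATA;\nDIMENSIONS NTAX=4 NCHAR=2;\n"
               'FORMAT DATATYPE=STANDARD SYMBOLS="01" MISSING=?;\n'
               "MATRIX\nA 01\nB 10\nC 11\n;\nEND;\n")
        p = tmp_path / "bad.nex"
        p.write_text(bad)
        with pytest.raises(Exception):
            read_matrix(p)
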