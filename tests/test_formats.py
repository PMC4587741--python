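"""BNX / CMAP / XMAP / AGP readers and writers: fixtures and round trips."""

from __future__ import annotations

import pytest
from hypothesis import given, settings, strategies as st

from stitchkit.formats import (
    AgpRecord,
    CmapSite,
    ConsensusMap,
    InvariantError,
    MapAlignment,
    MoleculeMap,
    ParseError,
    read_agp,
    read_bnx,
    read_cmap,
    read_xmap,
    reconstruct_fasta,
    reverse_complement,
    validate_agp,
    write_agp,
    write_bnx,
    write_cmap,
    write_xmap,
)
from stitchkit.simulate import simulate_consensus_maps, tile_intervals


# ---------------------------------------------------------------------------
# BNX
# ---------------------------------------------------------------------------


class TestBnx:
    def test_two_molecule_fixture_round_trip(self, two_molecules, tmp_path):
        path = tmp_path / "mols.bnx"
        write_bnx(two_molecules, path)
        back = read_bnx(path)
        assert back == two_molecules
        assert [m.length for m in back] == [180000.0, 210000.0]
        assert [len(m.label_positions) for m in back] == [5, 7]

    def test_one_line_ends_with_molecule_length(self, two_molecules, tmp_path):
        path = tmp_path / "mols.bnx"
        write_bnx(two_molecules, path)
        one_lines = [ln for ln in path.read_text().splitlines()
                     if ln.startswith("1\t")]
        assert one_lines[0].split("\t")[-1] == "180000.0"
        assert one_lines[1].split("\t")[-1] == "210000.0"

    def test_headers_only_file_is_empty_collection(self, tmp_path):
        path = tmp_path / "empty.bnx"
        write_bnx([], path)
        assert path.read_text().startswith("# BNX File Version")
        assert read_bnx(path) == []

    def test_invariant_breach_refused_naming_molecule(self, tmp_path):
        bad = MoleculeMap(7, 1000.0, [500.0, 1500.0])
        with pytest.raises(InvariantError, match="molecule 7"):
            write_bnx([bad], tmp_path / "bad.bnx")

    def test_block_row_before_zero_line_names_line_number(self, tmp_path):
        path = tmp_path / "broken.bnx"
        path.write_text("# BNX File Version:\t1.2\n1\t100.0\t200.0\n")
        with pytest.raises(ParseError, match=":2"):
            read_bnx(path)

    def test_non_numeric_position_is_parse_error(self, tmp_path):
        path = tmp_path / "broken.bnx"
        path.write_text("# BNX File Version:\t1.2\n"
                        "0\t1\t1000.0\t0\t0\t1\t1\t1\t-1\tFC\tFC\t1\t1\n"
                        "1\t10.0\tnope\t1000.0\n")
        with pytest.raises(ParseError, match="non-numeric"):
            read_bnx(path)

    @settings(max_examples=25, derandomize=True)
    @given(st.lists(
        st.lists(st.integers(1, 10**5), min_size=0, max_size=8,
                 unique=True).map(sorted),
        min_size=0, max_size=5))
    def test_round_trip_identity_property(self, tmp_path_factory, label_sets):
        molecules = [
            MoleculeMap(i + 1, 2e5, [float(p) for p in positions])
            for i, positions in enumerate(label_sets)
        ]
        path = tmp_path_factory.mktemp("bnx") / "prop.bnx"
        write_bnx(molecules, path)
        assert read_bnx(path) == molecules


# ---------------------------------------------------------------------------
# CMAP
# ---------------------------------------------------------------------------


class TestCmap:
    def test_three_site_fixture(self, tmp_path):
        cm = ConsensusMap(1, 50000.0, [
            CmapSite(1, 1, 1000.0), CmapSite(2, 1, 20000.0),
            CmapSite(3, 1, 45000.0)])
        path = tmp_path / "maps.cmap"
        write_cmap([cm], path)
        back = read_cmap(path)
        assert back == [cm]
        assert back[0].num_sites == 3
        # end marker row: channel 0 at the contig length
        last_row = path.read_text().splitlines()[-1].split("\t")
        assert last_row[4] == "0" and last_row[5] == "50000.0"

    def test_empty_file_with_header(self, tmp_path):
        path = tmp_path / "empty.cmap"
        write_cmap([], path)
        assert read_cmap(path) == []

    def test_round_trip_216_simulated_maps(self, ds_clean, tmp_path):
        intervals = tile_intervals(len(ds_clean.truth.genome),
                                   map_length=46_000, overlap=23_000)[:216]
        maps, _ = simulate_consensus_maps(ds_clean.truth.genome,
                                          intervals=intervals, seed=5)
        assert len(maps) == 216
        path = tmp_path / "big.cmap"
        write_cmap(maps, path)
        assert read_cmap(path) == maps

    def test_numsites_disagreement_is_error(self, tmp_path):
        path = tmp_path / "bad.cmap"
        path.write_text("1\t1000.0\t2\t1\t1\t100.0\t0.0\t1.0\t1.0\n"
                        "1\t1000.0\t2\t2\t0\t1000.0\t0.0\t1.0\t1.0\n")
        with pytest.raises(ParseError, match="NumSites"):
            read_cmap(path)

    def test_missing_end_marker_tolerated_with_warning(self, tmp_path):
        path = tmp_path / "nomarker.cmap"
        path.write_text("1\t1000.0\t1\t1\t1\t100.0\t0.0\t1.0\t1.0\n")
        with pytest.warns(UserWarning, match="end marker"):
            maps = read_cmap(path)
        assert maps[0].num_sites == 1


# ---------------------------------------------------------------------------
# XMAP
# ---------------------------------------------------------------------------


def _plus_minus_fixture() -> list[MapAlignment]:
    return [
        MapAlignment.create(1, 10, 20, (100.0, 900.0), (50.0, 850.0), "+",
                            15.5, qry_len=1000.0, ref_len=2000.0),
        MapAlignment.create(2, 11, 20, (200.0, 700.0), (900.0, 1400.0), "-",
                            9.25, qry_len=800.0, ref_len=2000.0,
                            label_pairs=[(1, 5), (2, 4)]),
    ]


class TestXmap:
    def test_plus_minus_fixture_round_trip(self, tmp_path):
        alignments = _plus_minus_fixture()
        path = tmp_path / "aln.xmap"
        write_xmap(alignments, path)
        back = read_xmap(path)
        assert back == alignments
        # negative-strand record stores qry_start > qry_end as on disk
        assert back[1].orientation == "-"
        assert back[1].qry_start > back[1].qry_end

    def test_empty(self, tmp_path):
        path = tmp_path / "empty.xmap"
        write_xmap([], path)
        assert read_xmap(path) == []

    def test_missing_confidence_column_names_it(self, tmp_path):
        path = tmp_path / "short.xmap"
        path.write_text("1\t1\t2\t0.0\t100.0\t0.0\t100.0\t+\n")
        with pytest.raises(ParseError, match="Confidence"):
            read_xmap(path)

    def test_unknown_orientation_token(self, tmp_path):
        path = tmp_path / "orient.xmap"
        path.write_text("1\t1\t2\t0.0\t100.0\t0.0\t100.0\t?\t10.0\n")
        with pytest.raises(ParseError, match="orientation"):
            read_xmap(path)


# ---------------------------------------------------------------------------
# AGP
# ---------------------------------------------------------------------------


def _three_part_object() -> list[AgpRecord]:
    # A(+) 10 kb, estimated gap +500, B(-) 8 kb -> object of 18 500 bp
    return [
        AgpRecord("obj", 1, 10000, 1, "W", component_id="A",
                  component_start=1, component_end=10000, orientation="+"),
        AgpRecord("obj", 10001, 10500, 2, "N", gap_length=500),
        AgpRecord("obj", 10501, 18500, 3, "W", component_id="B",
                  component_start=1, component_end=8000, orientation="-"),
    ]


class TestAgp:
    def test_positive_gap_object_tiles_to_18500(self, tmp_path):
        records = _three_part_object()
        path = tmp_path / "out.agp"
        write_agp(records, path)
        back = read_agp(path)
        assert len(back) == 3
        assert back[-1].object_end == 18500
        validate_agp(back)

    def test_u_gap_line_format(self, tmp_path):
        records = [
            AgpRecord("obj", 1, 100, 1, "W", component_id="A",
                      component_start=1, component_end=100, orientation="+"),
            AgpRecord("obj", 101, 200, 2, "U", gap_length=100),
            AgpRecord("obj", 201, 300, 3, "W", component_id="B",
                      component_start=1, component_end=100, orientation="+"),
        ]
        path = tmp_path / "u.agp"
        write_agp(records, path)
        middle = path.read_text().splitlines()[2].split("\t")
        assert middle[4:] == ["U", "100", "scaffold", "yes", "map"]

    def test_single_unjoined_scaffold_single_w_line(self):
        rec = AgpRecord("sc1", 1, 5000, 1, "W", component_id="sc1",
                        component_start=1, component_end=5000, orientation="+")
        validate_agp([rec])

    def test_tiling_violation_is_error(self):
        records = _three_part_object()
        records[1].object_start = 10002  # hole after part 1
        with pytest.raises(InvariantError, match="part 2"):
            validate_agp(records)

    def test_u_gap_must_be_100(self):
        rec = AgpRecord("obj", 1, 50, 1, "U", gap_length=50)
        with pytest.raises(InvariantError, match="100"):
            validate_agp([rec])

    def test_reconstruction_applies_reverse_complement(self):
        components = {"A": "ACGT" * 2500, "B": "GGATCC" + "A" * 7994}
        seqs = reconstruct_fasta(_three_part_object(), components)
        expected = components["A"] + "N" * 500 + reverse_complement(
            components["B"])
        assert seqs["obj"] == expected
        assert len(seqs["obj"]) == 18500
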