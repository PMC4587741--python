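"""The Stitch pass: inversion, PAT, filtering, selection, gaps, building."""

from __future__ import annotations

from collections import Counter

import pytest

from stitchkit.formats import KeyRow, MapAlignment, reconstruct_fasta
from stitchkit.simulate import truth_xmap
from stitchkit.stitch import (
    AlignmentFilterSet,
    StitchConfig,
    filter_alignments,
    flag_issues,
    infer_gaps,
    invert_xmap,
    make_scaffolding_alignment,
    percent_aligned,
    select_scaffolding_alignments,
    stitch_once,
)


def aln(entry=1, qry=1, ref=1, qry_iv=(0.0, 100.0), ref_iv=(0.0, 100.0),
        orientation="+", conf=20.0, qry_len=100.0, ref_len=100.0):
    return MapAlignment.create(entry, qry, ref, qry_iv, ref_iv, orientation,
                               conf, qry_len=qry_len, ref_len=ref_len)


class TestInvert:
    def test_role_swap(self):
        a = aln(qry=5, ref=2, qry_iv=(10.0, 90.0), ref_iv=(100.0, 180.0),
                qry_len=100.0, ref_len=200.0)
        inv = invert_xmap([a])[0]
        assert (inv.qry_id, inv.ref_id) == (2, 5)
        assert (inv.ref_start, inv.ref_end) == (10.0, 90.0)
        assert (inv.qry_start, inv.qry_end) == (100.0, 180.0)
        assert (inv.qry_len, inv.ref_len) == (200.0, 100.0)
        assert inv.orientation == "+"

    def test_double_inversion_is_identity(self):
        fixture = [
            aln(1, qry=5, ref=2, qry_iv=(10.0, 90.0), ref_iv=(0.0, 80.0),
                qry_len=100.0, ref_len=200.0),
            aln(2, qry=6, ref=2, qry_iv=(5.0, 60.0), ref_iv=(100.0, 155.0),
                orientation="-", qry_len=80.0, ref_len=200.0),
        ]
        assert invert_xmap(invert_xmap(fixture)) == sorted(
            fixture, key=lambda a: (a.ref_id, a.ref_start))

    def test_negative_strand_convention_reestablished(self):
        a = aln(qry=7, ref=3, qry_iv=(20.0, 70.0), ref_iv=(100.0, 150.0),
                orientation="-", qry_len=90.0, ref_len=300.0)
        assert a.qry_start > a.qry_end  # stored descending pre-inversion
        inv = invert_xmap([a])[0]
        assert inv.qry_start > inv.qry_end  # new query side now descending
        assert inv.ref_start < inv.ref_end

    def test_missing_lengths_is_error(self):
        a = aln()
        a.qry_len = None
        with pytest.raises(ValueError):
            invert_xmap([a])

    def test_sorted_by_new_reference_then_start(self):
        records = [
            aln(1, qry=9, ref=1, qry_iv=(50.0, 90.0), ref_iv=(0.0, 40.0)),
            aln(2, qry=2, ref=1, qry_iv=(0.0, 40.0), ref_iv=(50.0, 90.0)),
        ]
        inv = invert_xmap(records)
        assert [a.ref_id for a in inv] == [2, 9]


class TestPercentAligned:
    def test_end_overlap_geometry_scores_100(self):
        a = aln(qry_iv=(0.0, 200.0), ref_iv=(800.0, 1000.0),
                qry_len=500.0, ref_len=1000.0)
        assert percent_aligned(a) == pytest.approx(100.0)

    def test_containment_scores_100(self):
        a = aln(qry_iv=(0.0, 300.0), ref_iv=(400.0, 700.0),
                qry_len=300.0, ref_len=1000.0)
        assert percent_aligned(a) == pytest.approx(100.0)

    def test_interior_local_hit_scores_20(self):
        a = aln(qry_iv=(400.0, 600.0), ref_iv=(400.0, 600.0),
                qry_len=1000.0, ref_len=1000.0)
        assert percent_aligned(a) == pytest.approx(20.0)

    def test_orientation_swaps_query_overhangs(self):
        # '-' dovetail at the reference start: the query START overhangs
        # past the reference start side, so both limiting overhangs are 0
        a = aln(qry_iv=(0.0, 200.0), ref_iv=(0.0, 200.0),
                orientation="-", qry_len=1000.0, ref_len=900.0)
        assert percent_aligned(a) == pytest.approx(100.0)

    def test_zero_span_is_error(self):
        a = aln()
        a.ref_end = a.ref_start
        with pytest.raises(ValueError):
            percent_aligned(a)

    def test_pat_in_range_on_simulated_alignments(self, ds_noisy):
        alignments = invert_xmap(truth_xmap(
            ds_noisy.provenance, ds_noisy.consensus_maps, ds_noisy.truth,
            ds_noisy.key_rows))
        for a in alignments:
            assert 0 < percent_aligned(a) <= 100


class TestFilterAlignments:
    defaults = (AlignmentFilterSet(13, 30), AlignmentFilterSet(8, 90))

    def _with_pat(self, conf, pat_target, entry=1, qry=1):
        # interior alignment tuned to the requested PAT on a 1000 bp ref
        aligned = 100.0
        overhang = (100.0 / pat_target - 1) * aligned / 2
        return aln(entry, qry=qry, qry_iv=(overhang, overhang + aligned),
                   ref_iv=(overhang, overhang + aligned), conf=conf,
                   qry_len=2 * overhang + aligned,
                   ref_len=2 * overhang + aligned)

    def test_passes_second_set_only(self):
        kept = filter_alignments([self._with_pat(10, 95)], self.defaults)
        assert len(kept) == 1

    def test_fails_both_sets(self):
        assert filter_alignments([self._with_pat(14, 25)], self.defaults) == []

    def test_boundary_values_inclusive(self):
        kept = filter_alignments([self._with_pat(13, 30)], self.defaults)
        assert len(kept) == 1
        assert kept[0].pat == pytest.approx(30.0)

    def test_union_keeps_superset_of_single_set(self, ds_noisy,
                                                sim_stitch_config):
        alignments = invert_xmap(truth_xmap(
            ds_noisy.provenance, ds_noisy.consensus_maps, ds_noisy.truth,
            ds_noisy.key_rows))
        s1, s2 = sim_stitch_config.filter_sets
        only_s1 = {a.alignment.entry_id
                   for a in filter_alignments(alignments, [s1])}
        union = {a.alignment.entry_id
                 for a in filter_alignments(alignments, [s1, s2])}
        assert only_s1 <= union


class TestSelection:
    def test_longest_alignment_wins(self):
        short = aln(1, qry=2, ref=1, qry_iv=(0.0, 120.0), ref_iv=(0.0, 120.0),
                    qry_len=120.0, ref_len=500.0)
        long = aln(2, qry=2, ref=2, qry_iv=(0.0, 180.0), ref_iv=(0.0, 180.0),
                   qry_len=180.0, ref_len=500.0)
        other = aln(3, qry=3, ref=1, qry_iv=(0.0, 50.0), ref_iv=(200.0, 250.0),
                    qry_len=50.0, ref_len=500.0)
        other2 = aln(4, qry=4, ref=2, qry_iv=(0.0, 50.0), ref_iv=(300.0, 350.0),
                     qry_len=50.0, ref_len=500.0)
        chosen = select_scaffolding_alignments(
            [make_scaffolding_alignment(a)
             for a in (short, long, other, other2)])
        per_map = {sa.insilico_id: sa for sa in chosen}
        assert per_map[2].alignment.entry_id == 2

    def test_confidence_breaks_span_ties(self):
        a = aln(1, qry=2, ref=1, conf=12.0, ref_iv=(0.0, 100.0))
        b = aln(2, qry=2, ref=2, conf=15.0, ref_iv=(0.0, 100.0))
        filler1 = aln(3, qry=3, ref=1, ref_iv=(200.0, 250.0),
                      qry_iv=(0.0, 50.0), qry_len=50.0, ref_len=500.0)
        filler2 = aln(4, qry=4, ref=2, ref_iv=(200.0, 250.0),
                      qry_iv=(0.0, 50.0), qry_len=50.0, ref_len=500.0)
        for x in (a, b):
            x.qry_len, x.ref_len = 100.0, 500.0
        chosen = select_scaffolding_alignments(
            [make_scaffolding_alignment(x) for x in (a, b, filler1, filler2)])
        assert {sa.insilico_id: sa.alignment.entry_id
                for sa in chosen}[2] == 2

    def test_full_tie_resolves_to_smallest_consensus_id(self):
        a = aln(5, qry=2, ref=4, conf=12.0)
        b = aln(6, qry=2, ref=3, conf=12.0)
        fill3 = aln(7, qry=8, ref=3, ref_iv=(200.0, 250.0), qry_iv=(0.0, 50.0),
                    qry_len=50.0, ref_len=500.0)
        fill4 = aln(8, qry=9, ref=4, ref_iv=(200.0, 250.0), qry_iv=(0.0, 50.0),
                    qry_len=50.0, ref_len=500.0)
        for x in (a, b):
            x.qry_len, x.ref_len = 100.0, 500.0
        chosen = select_scaffolding_alignments(
            [make_scaffolding_alignment(x) for x in (a, b, fill3, fill4)])
        assert {sa.insilico_id: sa.consensus_id for sa in chosen}[2] == 3

    def test_consensus_maps_with_single_alignment_are_not_candidates(self):
        lone = aln(1, qry=2, ref=1)
        assert select_scaffolding_alignments(
            [make_scaffolding_alignment(lone)]) == []


class TestInferGaps:
    def test_projected_gap_arithmetic(self):
        a = aln(1, qry=1, ref=1, qry_iv=(0.0, 140.0), ref_iv=(100.0, 240.0),
                qry_len=150.0, ref_len=1000.0)  # trailing overhang 10
        b = aln(2, qry=2, ref=1, qry_iv=(10.0, 200.0), ref_iv=(300.0, 490.0),
                qry_len=200.0, ref_len=1000.0)  # leading overhang 10
        plan = infer_gaps([make_scaffolding_alignment(x) for x in (a, b)])
        assert plan.gaps == [pytest.approx(40.0)]

    def test_touching_and_overlapping_projections(self):
        a = aln(1, qry=1, ref=1, qry_iv=(0.0, 100.0), ref_iv=(0.0, 100.0),
                qry_len=100.0, ref_len=1000.0)
        touch = aln(2, qry=2, ref=1, qry_iv=(0.0, 100.0),
                    ref_iv=(100.0, 200.0), qry_len=100.0, ref_len=1000.0)
        overlap = aln(3, qry=3, ref=1, qry_iv=(0.0, 100.0),
                      ref_iv=(80.0, 180.0), qry_len=100.0, ref_len=1000.0)
        t = infer_gaps([make_scaffolding_alignment(x) for x in (a, touch)])
        assert t.gaps == [pytest.approx(0.0)]
        o = infer_gaps([make_scaffolding_alignment(x) for x in (a, overlap)])
        assert o.gaps[0] == pytest.approx(-20.0)

    def test_requires_two_on_one_map(self):
        with pytest.raises(ValueError):
            infer_gaps([make_scaffolding_alignment(aln())])


class TestFlags:
    config = StitchConfig()

    def _plan(self, gap):
        a = aln(1, qry=1, ref=1, qry_iv=(0.0, 100_000.0),
                ref_iv=(0.0, 100_000.0), qry_len=100_000.0,
                ref_len=300_000.0)
        b = aln(2, qry=2, ref=1, qry_iv=(0.0, 100_000.0),
                ref_iv=(100_000.0 + gap, 200_000.0 + gap),
                qry_len=100_000.0, ref_len=300_000.0)
        return infer_gaps([make_scaffolding_alignment(x) for x in (a, b)])

    def test_partial_alignment_flag_below_60(self):
        # PAT 45: passed set 1 (conf high, PAT >= 30) but below the partial
        # threshold
        aligned, pat = 90.0, 45.0
        overhang = (100.0 / pat - 1) * aligned / 2
        partial = aln(1, qry_iv=(overhang, overhang + aligned),
                      ref_iv=(overhang, overhang + aligned), conf=20.0,
                      qry_len=2 * overhang + aligned,
                      ref_len=2 * overhang + aligned)
        sa = make_scaffolding_alignment(partial)
        flags, _ = flag_issues([], [sa], self.config)
        assert [f.kind for f in flags] == ["partial_alignment"]

    @pytest.mark.parametrize("gap,expected", [
        (-25_000.0, ["extreme_negative_gap"]),
        (-5_000.0, []),
        (500.0, []),
    ])
    def test_extreme_negative_gap_boundary(self, gap, expected):
        flags, excluded = flag_issues([self._plan(gap)], [], self.config)
        assert [f.kind for f in flags] == expected
        assert excluded == set()

    def test_v145_exclusion_removes_both_flanks(self):
        config = StitchConfig(min_negative_gap_exclusion=-10_000.0)
        flags, excluded = flag_issues([self._plan(-15_000.0)], [], config)
        assert excluded == {1, 2}
        assert "excluded_join" in [f.kind for f in flags]


class TestBuild:
    def _fixture(self, gap):
        scaffolds = {"A": "ACGT" * 2500, "B": "TTGGCCAA" * 1000}
        key = [KeyRow(1, "A", 10_000), KeyRow(2, "B", 8_000)]
        a = aln(1, qry=1, ref=1, qry_iv=(0.0, 10_000.0),
                ref_iv=(1000.0, 11_000.0), qry_len=10_000.0, ref_len=40_000.0)
        b = aln(2, qry=2, ref=1, qry_iv=(0.0, 8_000.0),
                ref_iv=(11_000.0 + gap, 19_000.0 + gap), orientation="-",
                qry_len=8_000.0, ref_len=40_000.0)
        return scaffolds, key, [a, b]

    def test_positive_gap_join(self):
        scaffolds, key, alignments = self._fixture(500.0)
        result = stitch_once(scaffolds, alignments, key)
        assert result.n_new_joins == 1
        seq = result.fasta["Super_scaffold_1"]
        assert len(seq) == 18_500
        assert seq[10_000:10_500] == "N" * 500
        from stitchkit.formats import reverse_complement
        assert seq[10_500:] == reverse_complement(scaffolds["B"])

    def test_negative_gap_uses_100bp_spacer_and_u_line(self):
        scaffolds, key, alignments = self._fixture(-2_000.0)
        result = stitch_once(scaffolds, alignments, key)
        seq = result.fasta["Super_scaffold_1"]
        assert len(seq) == 10_000 + 100 + 8_000
        gap_lines = [r for r in result.agp if r.is_gap]
        assert [(r.component_type, r.gap_length) for r in gap_lines] == [
            ("U", 100)]

    def test_agp_fasta_consistency_byte_exact(self):
        scaffolds, key, alignments = self._fixture(321.0)
        result = stitch_once(scaffolds, alignments, key)
        rebuilt = reconstruct_fasta(result.agp, scaffolds)
        assert rebuilt == result.fasta

    def test_non_n_base_conservation(self):
        scaffolds, key, alignments = self._fixture(777.0)
        result = stitch_once(scaffolds, alignments, key)
        before = Counter("".join(scaffolds.values()).replace("N", ""))
        after_seq = "".join(result.fasta.values()).replace("N", "")
        # reverse complement permutes the base multiset (A<->T, C<->G must
        # balance against the input's joined-strand counts); compare via a
        # strand-insensitive canonical count
        def canonical(counter):
            return {
                "AT": counter["A"] + counter["T"],
                "CG": counter["C"] + counter["G"],
            }
        assert canonical(Counter(after_seq)) == canonical(before)
        assert len(after_seq) == sum(len(s) for s in scaffolds.values())

    def test_no_joins_identity(self):
        scaffolds = {"A": "ACGT" * 100, "B": "GGCC" * 100}
        key = [KeyRow(1, "A", 400), KeyRow(2, "B", 400)]
        result = stitch_once(scaffolds, [], key)
        assert result.fasta == scaffolds
        assert result.n_new_joins == 0

    def test_missing_sequence_is_error(self):
        scaffolds, key, alignments = self._fixture(500.0)
        del scaffolds["B"]
        with pytest.raises(KeyError, match="B"):
            stitch_once(scaffolds, alignments, key)

    def test_unresolved_key_ids_are_listed(self):
        scaffolds, key, alignments = self._fixture(500.0)
        with pytest.raises(KeyError, match="2"):
            stitch_once(scaffolds, alignments, key[:1])


class TestStitchOnceOnSimulation:
    def test_truth_alignments_recover_all_adjacencies_one_pass(
            self, ds_clean, sim_stitch_config):
        """Noise-free truth alignments joined in a single pass recover the
        scaffold order and orientation along every consensus map."""
        alignments = invert_xmap(truth_xmap(
            ds_clean.provenance, ds_clean.consensus_maps, ds_clean.truth,
            ds_clean.key_rows))
        result = stitch_once(ds_clean.scaffolds, alignments,
                             ds_clean.key_rows, sim_stitch_config)
        eligible = {k.header for k in ds_clean.key_rows}
        id_to_header = {k.cmap_id: k.header for k in ds_clean.key_rows}
        components = {
            p.name: [(id_to_header[i], o) for i, o in p.components]
            for p in result.plans
        }
        from stitchkit.simulate import adjacency_recovery
        recovered, total = adjacency_recovery(ds_clean.truth, components,
                                              eligible)
        assert total > 0
        assert recovered == total

    def test_one_alignment_per_insilico_map_per_iteration(
            self, ds_noisy, sim_stitch_config):
        alignments = invert_xmap(truth_xmap(
            ds_noisy.provenance, ds_noisy.consensus_maps, ds_noisy.truth,
            ds_noisy.key_rows))
        result = stitch_once(ds_noisy.scaffolds, alignments,
                             ds_noisy.key_rows, sim_stitch_config)
        placed = [i for p in result.plans for i, _ in p.components]
        assert len(placed) == len(set(placed))
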