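"""Unit definition, target assignment, and composition classification."""

import random

import pandas as pd
import pytest

from lsutools import (
    LsuTable,
    assign_markers,
    classify_composition,
    composition_matrix,
    coverage_summary,
    define_lsus,
    filter_usable,
)

from conftest import make_record


class TestFilterUsable:
    def test_missing_and_every_duplicated_line_removed(self, v5_table_text):
        from lsutools import parse_full_table

        kept = filter_usable(parse_full_table(v5_table_text))
        assert [(r.marker_id, r.status) for r in kept] == [
            ("1at7088", "Complete"),
            ("4at7088", "Fragmented"),
        ]

    def test_drop_fragmented_flag(self, v5_table_text):
        from lsutools import parse_full_table

        kept = filter_usable(parse_full_table(v5_table_text), drop_fragmented=True)
        assert [r.status for r in kept] == ["Complete"]

    def test_all_missing_errors(self):
        from lsutools import MarkerRecord

        with pytest.raises(ValueError, match="no usable"):
            filter_usable([MarkerRecord(marker_id="1at0", status="Missing")])


class TestDefineLsus:
    def test_ranks_follow_coordinates_not_input_order(self):
        records = [
            make_record("b", sequence_id="Chr2", start=300, end=310),
            make_record("a", sequence_id="Chr1", start=500, end=510),
            make_record("c", sequence_id="Chr1", start=100, end=110),
            make_record("d", sequence_id="Chr2", start=50, end=60),
            make_record("e", sequence_id="Chr1", start=900, end=910),
            make_record("f", sequence_id="Chr2", start=700, end=710),
        ]
        table = define_lsus(records)
        ranks = {(e.lsu_id, e.anchor_rank): e.marker_id for e in table.entries}
        assert ranks[("LSU_1", 1)] == "c" and ranks[("LSU_1", 3)] == "e"
        assert ranks[("LSU_2", 1)] == "d" and ranks[("LSU_2", 3)] == "f"

    def test_z_chromosome_named_last(self):
        records = [
            make_record("a", sequence_id="ChrZ", start=1, end=2),
            make_record("b", sequence_id="Chr2", start=1, end=2),
            make_record("c", sequence_id="Chr10", start=1, end=2),
            make_record("d", sequence_id="Chr1", start=1, end=2),
        ]
        table = define_lsus(records, naming_policy="by_sequence_suffix")
        by_seq = {e.anchor_sequence_id: e.lsu_id for e in table.entries}
        assert by_seq == {"Chr1": "LSU_1", "Chr2": "LSU_2", "Chr10": "LSU_3",
                          "ChrZ": "LSU_4"}

    def test_by_length_desc_policy(self):
        from lsutools import SequenceLengths

        records = [
            make_record("a", sequence_id="scafX", start=1, end=2),
            make_record("b", sequence_id="scafY", start=1, end=2),
        ]
        lengths = SequenceLengths(lengths={"scafX": 100, "scafY": 900})
        table = define_lsus(records, naming_policy="by_length_desc", lengths=lengths)
        by_seq = {e.anchor_sequence_id: e.lsu_id for e in table.entries}
        assert by_seq == {"scafY": "LSU_1", "scafX": "LSU_2"}
        with pytest.raises(ValueError, match="requires sequence lengths"):
            define_lsus(records, naming_policy="by_length_desc")

    def test_random_markers_ranks_match_independent_sort(self):
        rng = random.Random(7)
        records = []
        for i in range(100):
            start = rng.randrange(1, 10**6)
            records.append(
                make_record(f"m{i}at0", sequence_id=f"Chr{rng.randrange(1, 6)}",
                            start=start, end=start + 10)
            )
        table = define_lsus(records)
        # independent oracle: plain sorted() per chromosome
        by_chrom = {}
        for r in records:
            by_chrom.setdefault(r.sequence_id, []).append(r)
        for seq, rs in by_chrom.items():
            expected = [r.marker_id for r in
                        sorted(rs, key=lambda r: (r.start, r.end, r.marker_id))]
            got = [e.marker_id for e in
                   sorted((e for e in table.entries if e.anchor_sequence_id == seq),
                          key=lambda e: e.anchor_rank)]
            assert got == expected
            ranks = [e.anchor_rank for e in table.entries
                     if e.anchor_sequence_id == seq]
            assert sorted(ranks) == list(range(1, len(rs) + 1))

    def test_unit_table_tsv_roundtrip(self, small_units):
        again = LsuTable.from_tsv(small_units.to_tsv())
        assert again.entries == small_units.entries
        assert again.anchor_name == small_units.anchor_name
        assert again.to_tsv() == small_units.to_tsv()


class TestCoverageSummary:
    def test_single_marker_span(self):
        summary = coverage_summary([make_record("a", start=100, end=200)])
        (row,) = summary.rows
        assert (row.from_pos, row.to_pos, row.n_markers) == (100, 200, 1)

    def test_matches_brute_force_group_stats(self, small_anchor):
        summary = coverage_summary(small_anchor)
        frame = pd.DataFrame(
            [(r.sequence_id, r.start, r.end) for r in small_anchor],
            columns=["seq", "start", "end"],
        )
        grouped = frame.groupby("seq").agg(
            from_pos=("start", "min"), to_pos=("end", "max"), n=("start", "size"))
        for row in summary.rows:
            g = grouped.loc[row.sequence_id]
            assert (row.from_pos, row.to_pos, row.n_markers) == (
                g.from_pos, g.to_pos, g.n)


class TestAssignMarkers:
    def test_anchor_against_itself_is_identity(self, small_anchor, small_units):
        assignment = assign_markers(filter_usable(small_anchor), small_units)
        assert all(r.lsu_id is not None for r in assignment.rows)
        for seq in assignment.sequences():
            rows = sorted((r for r in assignment.rows if r.target_sequence_id == seq),
                          key=lambda r: r.target_rank)
            anchor_ranks = [r.anchor_rank for r in rows]
            assert anchor_ranks == sorted(anchor_ranks)

    def test_unknown_marker_is_unassigned(self, small_units):
        records = [
            make_record(small_units.entries[0].marker_id, start=10, end=20),
            make_record("NOVEL1at0", start=30, end=40),
        ]
        assignment = assign_markers(records, small_units)
        by_id = {r.marker_id: r.lsu_id for r in assignment.rows}
        assert by_id["NOVEL1at0"] is None

    def test_zero_overlap_errors(self, small_units):
        with pytest.raises(ValueError, match="no overlap"):
            assign_markers([make_record("NOVel9at9")], small_units)

    def test_shuffled_target_join_equals_dict_lookup(self, small_anchor, small_units):
        records = list(small_anchor)
        random.Random(3).shuffle(records)
        assignment = assign_markers(records, small_units)
        lookup = {e.marker_id: (e.lsu_id, e.anchor_rank) for e in small_units.entries}
        for row in assignment.rows:
            assert (row.lsu_id, row.anchor_rank) == lookup[row.marker_id]


class TestComposition:
    def test_identity_matrix_is_diagonal(self, small_anchor, small_units):
        assignment = assign_markers(filter_usable(small_anchor), small_units)
        report = composition_matrix(assignment)
        matrix = report.matrix
        assert int(matrix.values.sum()) == len(assignment.assigned())
        for seq in matrix.index:
            assert (matrix.loc[seq] > 0).sum() == 1

    def test_matrix_equals_brute_force_tally(self, small_anchor, small_units):
        records = list(small_anchor)
        random.Random(5).shuffle(records)
        assignment = assign_markers(records, small_units)
        matrix = composition_matrix(assignment).matrix
        tally = {}
        for row in assignment.assigned():
            tally[(row.target_sequence_id, row.lsu_id)] = (
                tally.get((row.target_sequence_id, row.lsu_id), 0) + 1)
        for (seq, lsu), n in tally.items():
            assert matrix.at[seq, lsu] == n
        assert int(matrix.values.sum()) == sum(tally.values())

    def test_identity_all_single_and_intact(self, small_anchor, small_units):
        assignment = assign_markers(filter_usable(small_anchor), small_units)
        report = classify_composition(composition_matrix(assignment))
        assert all(c.call == "single" for c in report.chromosome_calls.values())
        assert all(c.call == "intact" for c in report.lsu_calls.values())

    def test_fused_row_called_fusion_of_2(self):
        matrix = pd.DataFrame(
            {"LSU_1": [100, 0], "LSU_2": [100, 0], "LSU_3": [0, 100]},
            index=["t1", "t2"],
        )
        from lsutools.lsu_core import CompositionReport

        report = classify_composition(CompositionReport(matrix=matrix))
        assert report.chromosome_calls["t1"].call == "fusion_of_2"
        assert report.chromosome_calls["t2"].call == "single"
        assert report.lsu_calls["LSU_1"].call == "intact"

    def test_pulverized_unit_called_dispersed(self):
        # one unit: 44 of 129 markers on one chromosome, 1-4 on many others,
        # none of the minor recipients reaching component thresholds
        recipients = {"Z": 44}
        remaining = 129 - 44
        i = 0
        while remaining > 0:
            n = min(4, remaining)
            recipients[f"t{i}"] = n
            remaining -= n
            i += 1
        index = list(recipients)
        matrix = pd.DataFrame(0, index=index, columns=["LSU_18", "HOME"])
        for seq, n in recipients.items():
            matrix.at[seq, "LSU_18"] = n
            matrix.at[seq, "HOME"] = 150  # each chromosome dominated by its own unit
        from lsutools.lsu_core import CompositionReport

        report = classify_composition(CompositionReport(matrix=matrix))
        assert report.lsu_calls["LSU_18"].call == "dispersed"
        top_seq, top_n, top_frac = report.lsu_calls["LSU_18"].contributions[0]
        assert (top_seq, top_n) == ("Z", 44)

    def test_split_unit(self):
        matrix = pd.DataFrame({"LSU_1": [60, 69]}, index=["t1", "t2"])
        from lsutools.lsu_core import CompositionReport

        report = classify_composition(CompositionReport(matrix=matrix))
        assert report.lsu_calls["LSU_1"].call == "split"

    def test_chromosome_fractions_sum_to_one(self, small_anchor, small_units):
        assignment = assign_markers(filter_usable(small_anchor), small_units)
        report = classify_composition(composition_matrix(assignment))
        for call in report.chromosome_calls.values():
            assert sum(f for _, _, f in call.components) == pytest.approx(1.0)

    def test_component_count_monotone_in_fraction_threshold(self):
        matrix = pd.DataFrame(
            {"LSU_1": [50, 5], "LSU_2": [30, 60], "LSU_3": [20, 8]},
            index=["t1", "t2"],
        )
        from lsutools.lsu_core import CompositionReport

        previous = None
        for frac in (0.01, 0.05, 0.1, 0.2, 0.3, 0.5, 0.9):
            report = classify_composition(
                CompositionReport(matrix=matrix),
                min_component_markers=1,
                min_component_fraction=frac,
            )
            counts = {s: len(c.components) for s, c in report.chromosome_calls.items()}
            if previous is not None:
                assert all(counts[s] <= previous[s] for s in counts)
            previous = counts

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"min_component_markers": 0},
            {"min_component_fraction": 0.0},
            {"min_component_fraction": 1.5},
            {"intact_fraction": 0.0},
        ],
    )
    def test_threshold_validation(self, kwargs):
        matrix = pd.DataFrame({"LSU_1": [10]}, index=["t1"])
        from lsutools.lsu_core import CompositionReport

        with pytest.raises(ValueError):
            classify_composition(CompositionReport(matrix=matrix), **kwargs)
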