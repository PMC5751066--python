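"""Group building: homology lookup, reconciliation, ordering, concatenation,
lift-over and transcript assignment."""

import random

import pytest

from synanchor.formats_io import AlignmentHit, SequenceRecord, ValidationError
from synanchor.groups import (
    HomologyTable,
    InSilicoGroup,
    Placement,
    concatenate_group,
    lift_coordinate,
    lift_coordinate_inverse,
    map_transcripts_to_groups,
    order_scaffolds,
    reconcile_placement,
)
from synanchor.homology import ReferenceAssignment, ScaffoldEvidence


@pytest.fixture(scope="module")
def table():
    return HomologyTable.default()


class TestHomologyLookup:
    def test_packaged_pairs(self, table):
        assert table.lookup("SQ12") == "OL8"
        assert table.lookup("OL5") == "SQ1"
        assert table.lookup("SQ24") == "OL7"
        assert len(table) == 24

    def test_unknown_label_rejected(self, table):
        with pytest.raises(ValidationError):
            table.lookup("SQ25")

    def test_output_naming(self, table):
        assert table.output_name("SQ12") == "SD12"
        assert table.rh_group_for_output("SD12") == "SQ12"

    def test_non_bijective_table_rejected(self):
        with pytest.raises(ValidationError):
            HomologyTable([("SQ1", "OL1"), ("SQ2", "OL1")])


def _ev(sid="scafA", votes=None, ref=None, ranks=None):
    return ScaffoldEvidence(
        scaffold_id=sid,
        rh_votes=votes or {},
        reference=ref,
        supporting_marker_ranks=ranks or {},
    )


class TestReconcilePlacement:
    def test_consistent_dual_evidence(self, table):
        ref = ReferenceAssignment("OL8", 5000, "+", 300.0)
        p = reconcile_placement(_ev(votes={"SQ12": 200.0}, ref=ref), table)
        assert p.status == "placed_dual"
        assert p.group == "SD12"
        assert p.order_key == 5000.0

    def test_reference_only_uses_inverse_lookup(self, table):
        ref = ReferenceAssignment("OL8", 5000, "-", 300.0)
        p = reconcile_placement(_ev(ref=ref), table)
        assert p.status == "placed_ref_only"
        assert p.group == "SD12"
        assert p.orientation == "-"

    def test_rh_only_uses_min_marker_rank(self, table):
        p = reconcile_placement(
            _ev(votes={"SQ12": 200.0}, ranks={"SQ12": [7, 3, 9]}), table
        )
        assert p.status == "placed_rh_only"
        assert p.group == "SD12"
        assert p.order_key == 3.0
        assert p.orientation == "+"

    def test_inconsistent_channels_conflict(self, table):
        ref = ReferenceAssignment("OL5", 5000, "+", 300.0)
        p = reconcile_placement(_ev(votes={"SQ12": 200.0}, ref=ref), table)
        assert p.status == "conflict"
        assert p.group is None

    def test_tied_rh_vote_is_conflict(self, table):
        ref = ReferenceAssignment("OL8", 5000, "+", 300.0)
        p = reconcile_placement(
            _ev(votes={"SQ12": 200.0, "SQ3": 200.0}, ref=ref), table
        )
        assert p.status == "conflict"

    def test_no_evidence_unplaced(self, table):
        assert reconcile_placement(_ev(), table).status == "unplaced"


def _pl(sid, key, status="placed_dual", length=100, group="SD1"):
    return Placement(
        scaffold_id=sid, status=status, group=group, order_key=float(key),
        scaffold_length=length,
    )


class TestOrderScaffolds:
    def test_ascending_by_reference_position(self):
        got = order_scaffolds([_pl("a", 5000), _pl("b", 1200), _pl("c", 300)])
        assert [p.scaffold_id for p in got] == ["c", "b", "a"]

    def test_equal_positions_longer_first(self):
        got = order_scaffolds([_pl("a", 100, length=80), _pl("b", 100, length=200)])
        assert [p.scaffold_id for p in got] == ["b", "a"]

    def test_rh_only_after_positioned(self):
        got = order_scaffolds(
            [_pl("r", 0, status="placed_rh_only"), _pl("a", 9000), _pl("b", 100)]
        )
        assert [p.scaffold_id for p in got] == ["b", "a", "r"]

    def test_mixed_groups_rejected(self):
        with pytest.raises(ValidationError):
            order_scaffolds([_pl("a", 1, group="SD1"), _pl("b", 2, group="SD2")])


class TestConcatenateGroup:
    SEQS = {
        "a": SequenceRecord(id="a", residues="A" * 100),
        "b": SequenceRecord(id="b", residues="C" * 50),
    }

    def test_offsets_and_agp_structure(self):
        rec, agp, grp = concatenate_group(
            [_pl("a", 1, length=100), _pl("b", 2, length=50)], self.SEQS, gap_length=100
        )
        assert grp.total_length == 250
        assert [p[1] for p in grp.placements] == [0, 200]
        assert len(agp) == 3
        assert agp[-1].object_end == 250
        assert len(rec.residues) == 250
        assert rec.residues[100:200] == "N" * 100

    def test_single_scaffold_identity(self):
        rec, agp, grp = concatenate_group([_pl("a", 1, length=100)], self.SEQS)
        assert rec.residues == self.SEQS["a"].residues
        assert len(agp) == 1
        assert grp.total_length == 100

    def test_minus_orientation_reverse_complements(self):
        seqs = {"x": SequenceRecord(id="x", residues="AACG")}
        minus = Placement(
            scaffold_id="x", status="placed_dual", group="SD1", order_key=1.0,
            orientation="-", scaffold_length=4,
        )
        rec, _, _ = concatenate_group([minus], seqs)
        assert rec.residues == "CGTT"

    def test_missing_sequence_rejected(self):
        with pytest.raises(ValidationError, match="zzz"):
            concatenate_group([_pl("zzz", 1)], self.SEQS)


class TestLiftover:
    GRP = InSilicoGroup(
        group_id="SD1",
        placements=[("a", 0, 100, "+"), ("b", 200, 50, "-")],
        gap_length=100,
        total_length=250,
    )

    def test_forward_strand_arithmetic(self):
        grp = InSilicoGroup("SD1", [("a", 0, 100, "+"), ("b", 200, 50, "+")], 100, 250)
        assert lift_coordinate(grp, "b", 10) == ("SD1", 210)

    def test_reverse_strand_formula(self):
        assert lift_coordinate(self.GRP, "b", 0) == ("SD1", 249)

    def test_gap_position_on_inverse_is_error(self):
        with pytest.raises(ValidationError, match="gap"):
            lift_coordinate_inverse(self.GRP, 150)

    def test_unknown_scaffold_is_error(self):
        with pytest.raises(ValidationError):
            lift_coordinate(self.GRP, "nope", 0)

    def test_bijection_on_random_groups(self):
        rng = random.Random(13)
        for _ in range(50):
            n = rng.randint(1, 6)
            gap = rng.choice([0, 10, 100])
            placements, offset = [], 0
            for i in range(n):
                length = rng.randint(1, 400)
                placements.append(
                    (f"s{i}", offset, length, rng.choice("+-"))
                )
                offset += length + gap
            total = offset - gap if n else 0
            grp = InSilicoGroup("G", placements, gap, total)
            for sid, off, length, _ in placements:
                for pos in {0, length - 1, rng.randrange(length)}:
                    gid, gpos = lift_coordinate(grp, sid, pos)
                    assert lift_coordinate_inverse(grp, gpos) == (sid, pos)


class TestTranscriptMapping:
    @staticmethod
    def _hit(query, subject, bit=400.0, s_start=1, s_end=200):
        return AlignmentHit(
            query_id=query, subject_id=subject, percent_identity=100.0,
            alignment_length=abs(s_end - s_start) + 1, mismatches=0, gap_opens=0,
            q_start=1, q_end=abs(s_end - s_start) + 1,
            s_start=s_start, s_end=s_end, e_value=0.0, bit_score=bit,
        )

    def test_per_group_counts(self):
        hits = [self._hit(f"t{i}", "SD12") for i in range(3)]
        assignment, counts = map_transcripts_to_groups(hits)
        assert counts == {"SD12": 3}
        assert assignment["t0"][0] == "SD12"

    def test_transcript_without_hit_absent(self):
        assignment, counts = map_transcripts_to_groups([])
        assert assignment == {} and counts == {}

    def test_equal_score_tie_break_is_lexicographic(self):
        # "SD12" < "SD3" in string order; brute-force over both input orders
        h1, h2 = self._hit("t1", "SD3"), self._hit("t1", "SD12")
        for hits in ([h1, h2], [h2, h1]):
            assignment, _ = map_transcripts_to_groups(hits)
            assert assignment["t1"][0] == "SD12"

    def test_span_is_zero_based_half_open(self):
        assignment, _ = map_transcripts_to_groups([self._hit("t1", "SD1", s_start=101, s_end=300)])
        assert assignment["t1"][1] == (100, 300)


class TestBuildPartition:
    def test_every_scaffold_in_exactly_one_bucket(self, clean_scenario, clean_result):
        counts = clean_result.status_counts()
        assert sum(counts.values()) == len(clean_scenario.scaffolds)
        assert len(clean_result.placements) == len(clean_scenario.scaffolds)
        assert len({p.scaffold_id for p in clean_result.placements}) == len(
            clean_result.placements
        )

    def test_group_sequence_length_matches_agp(self, clean_result):
        agp_end = {}
        for rec in clean_result.agp:
            agp_end[rec.object_id] = rec.object_end
        for rec in clean_result.records:
            assert len(rec.residues) == agp_end[rec.id]
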