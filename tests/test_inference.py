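"""Constraint semantics, propagation-vs-enumeration equivalence, grading."""

import numpy as np
import pytest

from conftest import random_case
from xlinkmap.datamodel import Call, FragmentCall, Intensity, Observation, ProteinConstruct
from xlinkmap.inference import (
    SegmentPartition,
    brute_force_consistent_sets,
    infer_contacts,
    observation_constraint,
    oracle_infer,
    partition_for,
    propagate,
    untested_regions,
)


def lane(construct, n=None, c=None, index=3, promoter="U6"):
    """Observation shorthand: n/c are None (occluded), False, or an Intensity."""

    def fc(v):
        if v is None:
            return FragmentCall(call=Call.occluded)
        if v is False:
            return FragmentCall(call=Call.not_crosslinked)
        return FragmentCall(call=Call.crosslinked, intensity=v)

    return Observation(
        construct=construct,
        phosphate_index=index,
        strand="non_template" if index % 2 else "template",
        promoter=promoter,
        calls={"N": fc(n), "C": fc(c)},
    )


S, W = Intensity.strong, Intensity.weak


class TestObservationConstraint:
    def test_c_only_lane_excludes_the_n_side(self, constructs, full_partition):
        # cut after 409: C cross-linked, N not => contacts within [410, 721]
        obs = lane("D", n=False, c=S)
        cons = observation_constraint(obs, constructs["D"], full_partition)
        assert cons.excluded_mask == full_partition.mask_within((1, 409))
        assert len(cons.clauses) == 1
        assert cons.clauses[0].fragment_mask == full_partition.mask_within((410, 721))

    def test_fully_occluded_lane_is_empty(self, constructs, full_partition):
        cons = observation_constraint(lane("C"), constructs["C"], full_partition)
        assert cons.excluded_mask == 0 and cons.clauses == [] and cons.covered_mask == 0

    def test_unknown_fragment_label_rejected(self, constructs, full_partition):
        obs = lane("D", n=S, c=False)
        obs.calls["I9"] = FragmentCall(call=Call.occluded)
        with pytest.raises(ValueError, match="I9"):
            observation_constraint(obs, constructs["D"], full_partition)


class TestPossibleWorlds:
    def test_single_both_sides_lane_gives_two_regions_no_required(
        self, constructs, full_partition
    ):
        # on the full panel grid one double-sided lane pins nothing down:
        # one contact somewhere on each side, no individually required segment
        obs = [lane("C", n=S, c=S)]
        result = propagate(obs, constructs, full_partition)
        assert result.required_mask == 0
        assert result.intervals == ((1, 358, "region"), (359, 721, "region"))
        assert set(result.statuses) == {"ambiguous"}
        assert (
            oracle_infer(obs, constructs, full_partition).comparable()
            == result.comparable()
        )

    def test_contradictory_lanes_conflict(self, constructs):
        obs = [lane("D", n=S, c=False), lane("D", n=False, c=S)]
        result = propagate(obs, constructs)
        assert result.conflicts
        assert len(brute_force_consistent_sets(obs, constructs)) == 0
        assert oracle_infer(obs, constructs).comparable() == result.comparable()

    def test_no_observation_means_everything_untested(self, constructs):
        part = SegmentPartition.from_cut_sites([358], 721)
        assert untested_regions([], constructs, part) == [(1, 721)]

    def test_brute_force_refuses_large_grids(self):
        c = {"x": ProteinConstruct(name="x", length=30, cleavage_sites=tuple(range(1, 25)))}
        obs = [
            Observation(
                construct="x",
                phosphate_index=3,
                strand="non_template",
                calls={},
            )
        ]
        part = SegmentPartition.from_cut_sites(tuple(range(1, 25)), 30)
        with pytest.raises(ValueError, match="refusing"):
            brute_force_consistent_sets(obs, c, part)

    def test_propagation_equals_enumeration_on_random_tables(self):
        rng = np.random.default_rng(2024)
        for _ in range(300):
            obs, cons, part = random_case(rng)
            assert propagate(obs, cons, part).comparable() == oracle_infer(
                obs, cons, part
            ).comparable()

    def test_adding_a_consistent_lane_is_monotone(self):
        """Certainty only grows as consistent lanes accumulate."""
        rng = np.random.default_rng(7)
        checked = 0
        while checked < 100:
            obs, cons, part = random_case(rng)
            if propagate(obs, cons, part).conflicts:
                continue
            prev = None
            for k in range(1, len(obs) + 1):
                res = propagate(obs[:k], cons, part)
                if prev is not None:
                    assert res.required_mask & prev.required_mask == prev.required_mask
                    assert res.excluded_mask & prev.excluded_mask == prev.excluded_mask
                    assert prev.untested_mask & res.untested_mask == res.untested_mask
                    open_prev = prev.ambiguous_mask | prev.untested_mask
                    open_now = res.ambiguous_mask | res.untested_mask
                    assert open_prev & open_now == open_now
                prev = res
            checked += 1


class TestGrading:
    def test_all_strong_lanes_grade_everything_strong(self, constructs):
        obs = [lane("H", n=False, c=S), lane("D", n=S, c=False), lane("A", n=False, c=S)]
        asg = infer_contacts(obs, constructs)
        assert all(iv.grade == "strong" for iv in asg.intervals)

    def test_disagreeing_isolating_lanes_warn_and_take_majority(self, constructs):
        """Replicate lanes isolating the same weak domain at different grades."""
        obs = [
            lane("H", n=False, c=S),
            lane("A", n=False, c=S),
            lane("B", n=S, c=W),
            lane("B", n=S, c=Intensity.very_weak),
            lane("NT", n=S, c=False),
            lane("D", n=S, c=False),
            lane("E", n=S, c=False),
        ]
        asg = infer_contacts(obs, constructs)
        assert [iv.interval for iv in asg.intervals] == [(248, 305), (306, 358)]
        assert asg.intervals[0].grade == "strong"
        # tie between weak and very_weak resolves to the stronger grade
        assert asg.intervals[1].grade == "weak"
        assert any("disagree" in w for w in asg.warnings)

    def test_tag_variant_lanes_pin_the_ambiguous_boundary(self, constructs, observations):
        """Without the cut-358 lanes the position-7 contact could extend to 409."""
        full = observations.for_probe(7, "U6")
        reduced = [o for o in full if o.construct not in {"UT", "NT", "CT", "C"}]
        asg_red = infer_contacts(reduced, constructs)
        # at the reduced grid (no 358 cut) the weaker domain spans 306-409
        assert [iv.interval for iv in asg_red.intervals] == [(248, 305), (306, 409)]
        asg_full = infer_contacts(full, constructs)
        assert [iv.interval for iv in asg_full.intervals] == [(248, 305), (306, 358)]
        assert (359, 721) in asg_full.excluded


class TestAssignmentShape:
    def test_pieces_tile_protein_for_all_packaged_probes(self, u6_architecture):
        for asg in u6_architecture.assignments.values():
            covered = sorted(
                [iv.interval for iv in asg.intervals]
                + asg.ambiguous
                + asg.excluded
                + asg.untested
            )
            cursor = 0
            for a, b in covered:
                assert a == cursor + 1
                cursor = b
            assert cursor == 721

    def test_boundaries_sit_on_cut_sites(self, u6_architecture, constructs):
        sites = {s for c in constructs.values() for s in c.cleavage_sites}
        edges = sites | {0, 721}
        for asg in u6_architecture.assignments.values():
            for iv in asg.intervals:
                assert iv.lo - 1 in edges and iv.hi in edges

    def test_oracle_flag_agrees_on_every_packaged_probe(self, constructs, observations):
        from xlinkmap import packaged

        for k in packaged.U6_PHOSPHATES:
            obs = observations.for_probe(k, "U6")
            a = infer_contacts(obs, constructs)
            b = infer_contacts(obs, constructs, oracle=True)
            assert a.intervals == b.intervals
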