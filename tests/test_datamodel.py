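"""Validation and round-trip behavior of the domain types and file formats."""

import pytest
from pydantic import ValidationError

from xlinkmap import packaged
from xlinkmap.datamodel import (
    ContactAssignment,
    ContactInterval,
    CrossLinkProbe,
    ProteinConstruct,
    load_constructs,
    read_architecture,
    read_assignment,
    write_architecture,
    write_assignment,
)
from xlinkmap.fragments import digest


class TestConstructs:
    def test_packaged_panel(self, constructs):
        assert len(constructs) == 12
        sites = {name: c.cleavage_sites for name, c in constructs.items()}
        assert sites["H"] == (168,)
        assert sites["Ha"] == (189,)
        assert sites["De"] == (445,)
        assert sites["dE"] == (463,)
        assert sites["E"] == (483,)
        assert {sites[n][0] for n in ("C", "UT", "NT", "CT")} == {358}
        assert constructs["UT"].tag == "none"
        assert constructs["CT"].tag == "C"
        assert all(c.length == 721 for c in constructs.values())

    def test_cleavage_after_last_residue_rejected(self):
        with pytest.raises(ValidationError, match="721"):
            ProteinConstruct(name="bad", length=721, cleavage_sites=(721,))

    def test_sites_must_increase(self):
        with pytest.raises(ValidationError):
            ProteinConstruct(name="bad", length=721, cleavage_sites=(300, 200))

    def test_no_cut_construct_digests_to_one_fragment(self):
        c = ProteinConstruct(name="uncut", length=721)
        frags = digest(c)
        assert len(frags) == 1
        assert frags[0].interval == (1, 721)

    def test_duplicate_names_rejected(self, tmp_path):
        p = tmp_path / "c.tsv"
        p.write_text(
            "name\tlength\tcleavage_sites\ttag\ttag_mass_shift\n"
            "X\t721\t100\tN\t2.3\nX\t721\t200\tN\t2.3\n"
        )
        with pytest.raises(ValueError, match="duplicate"):
            load_constructs(p)

    def test_bad_row_error_names_the_row(self, tmp_path):
        p = tmp_path / "c.tsv"
        p.write_text(
            "name\tlength\tcleavage_sites\ttag\ttag_mass_shift\n"
            "X\t721\t900\tN\t2.3\n"
        )
        with pytest.raises(ValueError, match="row 0"):
            load_constructs(p)


class TestProbes:
    def test_packaged_probes(self):
        probes = packaged.load_packaged_probes()
        assert len(probes) == 16
        assert {p.phosphate_index for p in probes} == set(packaged.U6_PHOSPHATES)
        psea = {p.psea for p in probes}
        assert psea == {"TAATTCTCAACTGCTCTTTCC"}
        assert all(len(p.duplex) == 78 for p in probes)

    def test_parity_rule(self):
        duplex = "A" * 78
        ok = CrossLinkProbe(
            duplex=duplex, psea_offset=31, phosphate_index=3, strand="non_template"
        )
        assert ok.strand == "non_template"
        with pytest.raises(ValidationError, match="parity"):
            CrossLinkProbe(
                duplex=duplex, psea_offset=31, phosphate_index=8, strand="non_template"
            )

    def test_phosphate_outside_duplex_rejected(self):
        with pytest.raises(ValidationError, match="outside"):
            CrossLinkProbe(
                duplex="A" * 40, psea_offset=31, phosphate_index=11, strand="non_template"
            )


class TestObservations:
    def test_every_lane_covers_the_digestion(self, observations, constructs):
        for obs in observations.observations:
            labels = {f.label for f in digest(constructs[obs.construct])}
            assert set(obs.calls) == labels

    def test_intensity_present_iff_crosslinked(self, observations):
        for obs in observations.observations:
            for fc in obs.calls.values():
                assert (fc.call.value == "crosslinked") == (fc.intensity is not None)


class TestAssignmentIO:
    def test_round_trip(self, tmp_path, u6_architecture):
        asg = u6_architecture.assignments[3]
        path = tmp_path / "pos3.json"
        write_assignment(asg, path)
        assert read_assignment(path) == asg
        assert asg.intervals[0].interval == (410, 483)

    def test_empty_assignment_round_trip(self, tmp_path):
        asg = ContactAssignment(
            phosphate_index=9,
            strand="non_template",
            promoter="U6",
            protein_length=721,
            untested=[(1, 721)],
        )
        path = tmp_path / "empty.json"
        write_assignment(asg, path)
        assert read_assignment(path) == asg

    def test_assignment_pieces_must_tile(self):
        with pytest.raises(ValidationError, match="tile"):
            ContactAssignment(
                phosphate_index=3,
                strand="non_template",
                promoter="U6",
                protein_length=721,
                intervals=[ContactInterval(lo=410, hi=483, grade="strong")],
                excluded=[(1, 409)],  # [484, 721] unaccounted for
            )

    def test_architecture_round_trip(self, tmp_path, u1_architecture):
        path = tmp_path / "u1.json"
        write_architecture(u1_architecture, path)
        assert read_architecture(path) == u1_architecture

    def test_u1_fixture_states_only_text_backed_intervals(self, u1_architecture):
        localized = {
            k
            for k, a in u1_architecture.assignments.items()
            if any(iv.grade != "unresolved" for iv in a.intervals)
        }
        assert localized == {3, 5, 7, 8, 10, 12, 20}
        assert set(u1_architecture.contacted()) == {3, 5, 7, 8, 10, 12, 14, 17, 20, 22, 24, 25}
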