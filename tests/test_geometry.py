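"""Helix construction, symmetry properties and groove classification."""

import math

import numpy as np
import pytest

from xlinkmap.datamodel import ContactArchitecture
from xlinkmap.geometry import (
    GrooveThresholds,
    HelixParams,
    build_helix,
    distance,
    groove_relationship,
    project_architecture,
    write_pdb,
)


class TestHelixBuild:
    def test_one_turn_returns_to_the_same_face(self, helix):
        a = helix.coordinate("non_template", 3)
        b = helix.coordinate("non_template", 13)
        assert a.face_angle_deg == pytest.approx(b.face_angle_deg)
        assert b.xyz[2] - a.xyz[2] == pytest.approx(10 * 3.34)

    def test_adjacent_phosphate_distance_closed_form(self, helix):
        # chord of 36 deg on a 9.4 A circle plus one rise
        expected = math.sqrt((2 * 9.4 * math.sin(math.radians(18))) ** 2 + 3.34**2)
        got = distance(
            helix.coordinate("non_template", 5), helix.coordinate("non_template", 6)
        )
        assert got == pytest.approx(expected)

    def test_single_bp_rejected(self):
        with pytest.raises(ValueError):
            build_helix(1)

    def test_regeneration_is_bit_identical(self):
        a = build_helix(25).coordinates()
        b = build_helix(25).coordinates()
        assert a == b

    def test_helical_symmetry(self, helix):
        """Rotating by k*twist and translating k*rise maps bp i to bp i+k."""
        k = 4
        theta = math.radians(k * helix.params.twist_deg)
        rot = np.array(
            [
                [math.cos(theta), -math.sin(theta), 0],
                [math.sin(theta), math.cos(theta), 0],
                [0, 0, 1],
            ]
        )
        for strand in ("non_template", "template"):
            for bp in range(1, helix.n_bp - k + 1):
                src = np.array(helix.coordinate(strand, bp).xyz)
                dst = np.array(helix.coordinate(strand, bp + k).xyz)
                moved = rot @ src + np.array([0, 0, k * helix.params.rise_A])
                assert np.allclose(moved, dst, atol=1e-9)


class TestGrooveClassification:
    def test_classification_depends_only_on_index_offset(self, helix):
        """Re-indexing the duplex origin leaves every classification fixed."""
        for shift in (0, 3, 7):
            rel = groove_relationship(
                ("template", 8 + shift), ("non_template", 11 + shift), helix
            )
            assert rel.kind == "minor_groove_span"

    def test_distance_invariant_under_rigid_motion(self, helix):
        # distances come from coordinates; a rigid motion of both points is a no-op
        c1 = np.array(helix.coordinate("template", 8).xyz)
        c2 = np.array(helix.coordinate("non_template", 13).xyz)
        theta = 1.234
        rot = np.array(
            [
                [math.cos(theta), 0, math.sin(theta)],
                [0, 1, 0],
                [-math.sin(theta), 0, math.cos(theta)],
            ]
        )
        t = np.array([5.0, -2.0, 11.0])
        moved = np.linalg.norm((rot @ c1 + t) - (rot @ c2 + t))
        assert moved == pytest.approx(np.linalg.norm(c1 - c2))

    def test_mirror_swapping_strands_swaps_grooves(self, helix):
        minor = groove_relationship(("template", 8), ("non_template", 11), helix)
        swapped = groove_relationship(("non_template", 8), ("template", 11), helix)
        assert minor.kind == "minor_groove_span"
        assert swapped.kind == "major_groove_span"

    def test_same_phosphate_is_same_strand_track(self, helix):
        rel = groove_relationship(("template", 8), ("template", 8), helix)
        assert rel.kind == "same_strand_track" and rel.distance_A == 0.0

    def test_thresholds_are_configurable(self, helix):
        strict = GrooveThresholds(span_max_distance_A=5.0)
        rel = groove_relationship(("template", 8), ("non_template", 11), helix, strict)
        assert rel.kind == "minor_groove_span" and not rel.within_span_distance


class TestProjection:
    def test_packaged_architecture_projects_all_contacts(self, u6_architecture, helix):
        proj = project_architecture(u6_architecture, helix)
        assert len(proj) == 16
        domains = {p.phosphate_index: p.domain for p in proj}
        assert domains[8] == "Rc" and domains[11] == "Rc" and domains[13] == "Rc"
        assert domains[2] == "Ra" and domains[4] == "Ra" and domains[7] == "Ra"
        assert domains[14] == "Rh"
        assert domains[19] == "N-term"

    def test_empty_architecture_is_valid(self, helix):
        arch = ContactArchitecture(
            promoter="X", subunit="S", protein_length=721, assignments={}
        )
        assert project_architecture(arch, helix) == []

    def test_phosphate_outside_model_reported(self, u6_architecture):
        small = build_helix(10)
        with pytest.raises(ValueError) as err:
            project_architecture(u6_architecture, small)
        assert "25" in str(err.value)

    def test_pdb_export_is_deterministic(self, u6_architecture, helix, tmp_path):
        proj = project_architecture(u6_architecture, helix)
        p1, p2 = tmp_path / "a.pdb", tmp_path / "b.pdb"
        write_pdb(proj, p1)
        write_pdb(proj, p2)
        assert p1.read_bytes() == p2.read_bytes()
        text = p1.read_text()
        assert text.count("ATOM") == 16


def test_nonstandard_params_validate():
    with pytest.raises(ValueError):
        HelixParams(twist_deg=0)
    with pytest.raises(ValueError):
        HelixParams(rise_A=-1)
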