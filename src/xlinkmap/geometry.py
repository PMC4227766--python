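"""Ideal B-form DNA geometry for backbone phosphates.

The model is an unbent, sequence-independent double helix: one phosphate
per strand per base pair, on a cylinder of fixed radius, advancing by a
fixed twist and rise.  The two strands' phosphates at the same base pair
are separated by the interstrand angular offset measured across the minor
groove (~154 degrees for canonical B-DNA), which is what makes the minor
and major grooves distinguishable.

Cross-strand phosphate pairs are classified by the *helical phase*

    phase = twist * (bp_nt - bp_t) - interstrand_offset

(non-template bp index minus template bp index, in degrees, unwrapped).
Phase near 0 means the non-template phosphate has rotated into the gap
across the minor groove from the template phosphate (a minor-groove span);
phase near -360 means the pair flanks the major groove; a wrapped phase
near 180 puts the two phosphates on opposite faces of the duplex.  The
windows and the span distance cutoff are configurable thresholds
calibrated to reproduce qualitative groove calls, not measured constants.
"""

from __future__ import annotations

import math
from typing import Iterable, Literal, NamedTuple

import gemmi
import numpy as np
from pydantic import BaseModel, Field, model_validator

from .datamodel import (
    ContactArchitecture,
    ProbeNumbering,
    Strand,
    grade_rank,
    strand_of_index,
)


class HelixParams(BaseModel):
    """Canonical B-DNA defaults; all values overridable."""

    twist_deg: float = Field(default=36.0, gt=0, le=45)
    rise_A: float = Field(default=3.34, gt=0)
    phosphate_radius_A: float = Field(default=9.4, gt=0)
    interstrand_offset_deg: float = Field(default=154.0, gt=0, lt=360)
    handedness: Literal["right"] = "right"


class GrooveThresholds(BaseModel):
    """Windows for qualitative groove classification (degrees / Angstroms)."""

    opposite_face_min_deg: float = 150.0
    minor_window_deg: float = 180.0
    span_max_distance_A: float = 18.0


class PhosphateCoordinate(NamedTuple):
    phosphate_index: int | None
    strand: Strand
    bp_index: int
    xyz: tuple[float, float, float]
    face_angle_deg: float


GrooveClass = Literal[
    "same_strand_track", "minor_groove_span", "major_groove_span", "opposite_face"
]


class GrooveRelationship(NamedTuple):
    kind: GrooveClass
    distance_A: float
    phase_deg: float
    within_span_distance: bool


def wrap180(angle: float) -> float:
    """Wrap an angle into (-180, 180]."""
    a = math.fmod(angle, 360.0)
    if a <= -180.0:
        a += 360.0
    elif a > 180.0:
        a -= 360.0
    return a


class HelixModel(BaseModel):
    n_bp: int
    params: HelixParams

    def face_angle(self, strand: Strand, bp_index: int) -> float:
        theta = self.params.twist_deg * (bp_index - 1)
        if strand == "template":
            theta += self.params.interstrand_offset_deg
        return theta % 360.0

    def coordinate(self, strand: Strand, bp_index: int, phosphate_index: int | None = None) -> PhosphateCoordinate:
        if not (1 <= bp_index <= self.n_bp):
            raise ValueError(f"bp index {bp_index} outside the {self.n_bp}-bp model")
        theta_deg = self.params.twist_deg * (bp_index - 1)
        if strand == "template":
            theta_deg += self.params.interstrand_offset_deg
        theta = math.radians(theta_deg)
        r = self.params.phosphate_radius_A
        xyz = (r * math.cos(theta), r * math.sin(theta), (bp_index - 1) * self.params.rise_A)
        return PhosphateCoordinate(phosphate_index, strand, bp_index, xyz, theta_deg % 360.0)

    def coordinates(self) -> list[PhosphateCoordinate]:
        return [
            self.coordinate(strand, bp)
            for strand in ("non_template", "template")
            for bp in range(1, self.n_bp + 1)
        ]


def build_helix(n_bp: int, params: HelixParams | None = None) -> HelixModel:
    if n_bp < 2:
        raise ValueError("a helix needs at least 2 base pairs")
    return HelixModel(n_bp=n_bp, params=params or HelixParams())


def distance(p1: PhosphateCoordinate, p2: PhosphateCoordinate) -> float:
    return float(np.linalg.norm(np.subtract(p1.xyz, p2.xyz)))


def groove_relationship(
    p1: tuple[Strand, int],
    p2: tuple[Strand, int],
    helix: HelixModel,
    thresholds: GrooveThresholds | None = None,
) -> GrooveRelationship:
    """Classify the backbone relationship of two phosphates.

    ``p1``/``p2`` are (strand, bp_index) pairs.  Same-strand pairs are
    ``same_strand_track``.  For cross-strand pairs the unwrapped helical
    phase decides which groove the shorter inter-backbone path crosses,
    except that a wrapped phase beyond the opposite-face window means the
    pair sits on nearly opposite faces of the duplex.
    """
    thresholds = thresholds or GrooveThresholds()
    c1 = helix.coordinate(*p1)
    c2 = helix.coordinate(*p2)
    dist = distance(c1, c2)
    within = dist <= thresholds.span_max_distance_A
    if p1[0] == p2[0]:
        return GrooveRelationship("same_strand_track", dist, 0.0, within)

    nt = p1 if p1[0] == "non_template" else p2
    t = p2 if p1[0] == "non_template" else p1
    phase = helix.params.twist_deg * (nt[1] - t[1]) - helix.params.interstrand_offset_deg
    wrapped = wrap180(phase)
    if abs(wrapped) >= thresholds.opposite_face_min_deg:
        return GrooveRelationship("opposite_face", dist, phase, within)
    # Fold the phase to (-360, 360]: |m| below the minor window means the
    # pair flanks the minor groove, beyond it the major groove.
    m = math.fmod(phase, 720.0)
    if m <= -360.0:
        m += 720.0
    elif m > 360.0:
        m -= 720.0
    kind: GrooveClass = (
        "minor_groove_span" if abs(m) <= thresholds.minor_window_deg else "major_groove_span"
    )
    return GrooveRelationship(kind, dist, phase, within)


class ProjectedPhosphate(NamedTuple):
    phosphate_index: int
    strand: Strand
    bp_index: int
    xyz: tuple[float, float, float]
    face_angle_deg: float
    domain: str | None
    grade: str


_GRADE_OCCUPANCY = {"unresolved": 0.25, "very_weak": 0.5, "weak": 0.75, "strong": 1.0}


def project_architecture(
    architecture: ContactArchitecture,
    helix: HelixModel,
    numbering: ProbeNumbering | None = None,
) -> list[ProjectedPhosphate]:
    """Map every contacted phosphate onto the helix with its domain label."""
    numbering = numbering or ProbeNumbering(psea_offset=1)
    out: list[ProjectedPhosphate] = []
    outside: list[int] = []
    for index in architecture.contacted():
        bp = numbering.bp_index(index)
        strand = strand_of_index(index)
        if not (1 <= bp <= helix.n_bp):
            outside.append(index)
            continue
        assignment = architecture.assignments[index]
        best = max(
            assignment.intervals,
            key=lambda iv: (grade_rank(iv.grade), -iv.lo),
        )
        domain = None
        overlap_best = 0
        for name, a, b in architecture.domains:
            overlap = min(b, best.hi) - max(a, best.lo) + 1
            if overlap > overlap_best:
                overlap_best, domain = overlap, name
        coord = helix.coordinate(strand, bp, index)
        out.append(
            ProjectedPhosphate(
                index, strand, bp, coord.xyz, coord.face_angle_deg, domain, best.grade
            )
        )
    if outside:
        raise ValueError(f"phosphates outside the helix model: {outside}")
    return out


def write_pdb(projection: Iterable[ProjectedPhosphate], path: str) -> None:
    """Export pseudo-atoms (one P per contacted phosphate) as PDB.

    Occupancy encodes the grade; the segment id carries the domain label,
    so any structure viewer can color by domain.  Output is deterministic.
    """
    structure = gemmi.Structure()
    structure.name = "xlinkmap"
    model = gemmi.Model("1")
    chains = {"non_template": gemmi.Chain("N"), "template": gemmi.Chain("T")}
    for p in sorted(projection, key=lambda p: (p.strand, p.bp_index)):
        residue = gemmi.Residue()
        residue.name = "DP"
        residue.het_flag = "A"
        residue.seqid = gemmi.SeqId(p.bp_index, " ")
        atom = gemmi.Atom()
        atom.name = "P"
        atom.element = gemmi.Element("P")
        atom.pos = gemmi.Position(*p.xyz)
        atom.occ = _GRADE_OCCUPANCY.get(p.grade, 0.25)
        atom.b_iso = 0.0
        residue.add_atom(atom)
        residue.segment = (p.domain or "")[:4]
        chains[p.strand].add_residue(residue)
    for chain in chains.values():
        model.add_chain(chain)
    structure.add_model(model)
    structure.setup_entities()
    doc = structure.make_pdb_string()
    with open(path, "w") as fh:
        fh.write(doc)
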