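"""Quantitative comparison of two promoter contact architectures.

Signs follow the promoter orientation: base-pair indices increase toward
the transcription start site, so a positive axial shift is a *downstream*
movement.  Rotation is the circular-mean difference of phosphate face
angles, positive in the direction of advancing helix twist (clockwise when
viewed from upstream looking toward the start site).
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel

from .datamodel import ContactArchitecture, ProbeNumbering, grade_rank, strand_of_index
from .geometry import HelixModel, wrap180


def circular_mean_deg(angles_deg: Sequence[float]) -> float:
    """Mean direction of angles in degrees, in (-180, 180]."""
    if len(angles_deg) == 0:
        raise ValueError("circular mean of no angles")
    radians = np.radians(np.asarray(angles_deg, dtype=float))
    s, c = np.sin(radians).sum(), np.cos(radians).sum()
    if s == 0 and c == 0:
        raise ValueError("circular mean undefined: antipodal angle set")
    return wrap180(math.degrees(math.atan2(s, c)))


class DomainShift(BaseModel):
    domain: str
    contacts_a: list[int]
    contacts_b: list[int]
    axial_shift_bp: Optional[float] = None
    rotation_deg: Optional[float] = None
    low_confidence: bool = False


class ArchitectureDiff(BaseModel):
    promoter_a: str
    promoter_b: str
    shared: list[int]
    unique_to_a: list[int]
    unique_to_b: list[int]
    per_domain: dict[str, DomainShift]


def _domain_contacts(arch: ContactArchitecture) -> dict[str, list[int]]:
    """Phosphates grouped by the domain of their strongest interval."""
    out: dict[str, list[int]] = {name: [] for name, _, _ in arch.domains}
    for index in arch.contacted():
        assignment = arch.assignments[index]
        graded = [iv for iv in assignment.intervals if iv.grade != "unresolved"]
        if not graded:
            continue  # contacted but interval unstated; annotation only
        best = max(graded, key=lambda iv: (grade_rank(iv.grade), -iv.lo))
        domain, overlap_best = None, 0
        for name, a, b in arch.domains:
            overlap = min(b, best.hi) - max(a, best.lo) + 1
            if overlap > overlap_best:
                overlap_best, domain = overlap, name
        if domain is not None:
            out[domain].append(index)
    return out


def domain_shift(
    domain: str,
    a: ContactArchitecture,
    b: ContactArchitecture,
    helix: HelixModel,
    numbering: ProbeNumbering | None = None,
) -> DomainShift:
    """Axial (bp) and rotational (deg) displacement of one domain, B vs A."""
    numbering = numbering or ProbeNumbering(psea_offset=1)
    ca = _domain_contacts(a).get(domain, [])
    cb = _domain_contacts(b).get(domain, [])
    shift = DomainShift(domain=domain, contacts_a=sorted(ca), contacts_b=sorted(cb))
    if not ca or not cb:
        return shift  # undefined, not zero
    bps_a = [numbering.bp_index(k) for k in ca]
    bps_b = [numbering.bp_index(k) for k in cb]
    shift.axial_shift_bp = float(np.mean(bps_b) - np.mean(bps_a))
    ang_a = [helix.face_angle(strand_of_index(k), numbering.bp_index(k)) for k in ca]
    ang_b = [helix.face_angle(strand_of_index(k), numbering.bp_index(k)) for k in cb]
    shift.rotation_deg = wrap180(circular_mean_deg(ang_b) - circular_mean_deg(ang_a))
    shift.low_confidence = len(ca) == 1 or len(cb) == 1
    return shift


def diff_architectures(
    a: ContactArchitecture,
    b: ContactArchitecture,
    helix: HelixModel,
    numbering: ProbeNumbering | None = None,
) -> ArchitectureDiff:
    """Shared/unique contacts plus per-domain displacement summaries."""
    if a.protein_length != b.protein_length:
        raise ValueError(
            f"architectures describe different proteins "
            f"({a.protein_length} vs {b.protein_length} residues)"
        )
    set_a, set_b = set(a.contacted()), set(b.contacted())
    domains = [name for name, _, _ in (a.domains or b.domains)]
    return ArchitectureDiff(
        promoter_a=a.promoter,
        promoter_b=b.promoter,
        shared=sorted(set_a & set_b),
        unique_to_a=sorted(set_a - set_b),
        unique_to_b=sorted(set_b - set_a),
        per_domain={d: domain_shift(d, a, b, helix, numbering) for d in domains},
    )


def diff_report(diff: ArchitectureDiff) -> str:
    """Human-readable comparison mirroring the projection narrative."""
    lines = [
        f"Contact architecture comparison: {diff.promoter_a} vs {diff.promoter_b}",
        f"  shared contacts:            {diff.shared}",
        f"  unique to {diff.promoter_a}: {diff.unique_to_a}",
        f"  unique to {diff.promoter_b}: {diff.unique_to_b}",
    ]
    for name, s in diff.per_domain.items():
        if s.axial_shift_bp is None:
            lines.append(f"  {name}: displacement undefined (no contacts in one architecture)")
            continue
        direction = "downstream" if s.axial_shift_bp > 0 else "upstream" if s.axial_shift_bp < 0 else "no axial"
        rot = "clockwise" if (s.rotation_deg or 0) > 0 else "counterclockwise"
        flag = "  [low confidence: single contact]" if s.low_confidence else ""
        lines.append(
            f"  {name}: {s.axial_shift_bp:+.2f} bp ({direction}), "
            f"{s.rotation_deg:+.1f} deg ({rot}){flag}"
        )
    return "\n".join(lines)
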