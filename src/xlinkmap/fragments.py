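"""Digestion products, gel mass prediction and co-migration analysis.

Gel migration is modelled as a pure function of fragment mass: two bands
are indistinguishable when their relative mass difference is below the gel
model's tolerance.  That is sufficient to reproduce the interpretive logic
of the cross-linking gels (which fragments can be confused, and how epitope
tags separate them); anomalous migration is a documented non-goal.
"""

from __future__ import annotations

from typing import NamedTuple, Optional, Sequence

from pydantic import BaseModel, Field, model_validator

from .datamodel import Fragment, ProteinConstruct

# Average amino-acid residue mass, kDa.  Used when no sequence is available;
# only relative migration matters for the band logic.
DEFAULT_RESIDUE_MASS_KDA = 0.110

# Monoisotopic-free average residue masses (kDa) for sequence-based prediction.
_AVG_RESIDUE_KDA = {
    "A": 0.0710788, "R": 0.1561875, "N": 0.1141038, "D": 0.1150886,
    "C": 0.1031388, "E": 0.1291155, "Q": 0.1281307, "G": 0.0570519,
    "H": 0.1371411, "I": 0.1131594, "L": 0.1131594, "K": 0.1281741,
    "M": 0.1311926, "F": 0.1471766, "P": 0.0971167, "S": 0.0870782,
    "T": 0.1011051, "W": 0.1862132, "Y": 0.1631760, "V": 0.0991326,
}


class GelModel(BaseModel):
    """Parameters of the denaturing-gel band model."""

    avg_residue_mass: float = Field(default=DEFAULT_RESIDUE_MASS_KDA, gt=0)
    rel_tolerance: float = Field(default=0.05, gt=0, lt=1)
    extra_bands: list[tuple[str, float]] = []


class Band(NamedTuple):
    label: str
    mass_kda: float
    fragment: Optional[Fragment]


class ComigrationPair(NamedTuple):
    a: Band
    b: Band
    rel_difference: float


def digest(construct: ProteinConstruct) -> list[Fragment]:
    """Complete hydroxylamine digestion: fragments tiling [1, length].

    The tagged flag lands on the fragment carrying the tagged terminus.
    """
    sites = construct.cleavage_sites
    bounds = [0, *sites, construct.length]
    fragments: list[Fragment] = []
    n = len(bounds) - 1
    for i in range(n):
        a, b = bounds[i] + 1, bounds[i + 1]
        if n == 1:
            label, terminus = "NC", "NC"
        elif i == 0:
            label, terminus = "N", "N"
        elif i == n - 1:
            label, terminus = "C", "C"
        else:
            label, terminus = f"I{i}", "internal"
        tagged = (construct.tag == "N" and i == 0) or (construct.tag == "C" and i == n - 1)
        if n == 1:
            tagged = construct.tag != "none"
        fragments.append(
            Fragment(
                parent=construct.name,
                interval=(a, b),
                label=label,
                terminus=terminus,
                tagged=tagged,
                tag_mass_shift=construct.tag_mass_shift if tagged else 0.0,
                sequence=None if construct.sequence is None else construct.sequence[a - 1 : b],
            )
        )
    return fragments


def predict_mass(fragment: Fragment, gel: GelModel | None = None) -> float:
    """Predicted band mass in kDa (residue mass sum plus any tag shift)."""
    gel = gel or GelModel()
    if fragment.residue_count <= 0:
        raise ValueError("zero-length fragment has no mass")
    if fragment.sequence is not None:
        mass = sum(_AVG_RESIDUE_KDA[aa] for aa in fragment.sequence) + 0.0180153
    else:
        mass = fragment.residue_count * gel.avg_residue_mass
    return mass + fragment.tag_mass_shift


def _bands(fragments: Sequence[Fragment], gel: GelModel) -> list[Band]:
    bands = [Band(f"{f.parent}:{f.label}", predict_mass(f, gel), f) for f in fragments]
    bands.extend(Band(label, mass, None) for label, mass in gel.extra_bands)
    return bands


def rel_difference(m1: float, m2: float) -> float:
    return abs(m1 - m2) / max(m1, m2)


def comigration_pairs(
    fragments: Sequence[Fragment], gel: GelModel | None = None
) -> list[ComigrationPair]:
    """All band pairs indistinguishable at the gel tolerance, closest first."""
    gel = gel or GelModel()
    bands = _bands(fragments, gel)
    pairs = [
        ComigrationPair(bands[i], bands[j], rel_difference(bands[i].mass_kda, bands[j].mass_kda))
        for i in range(len(bands))
        for j in range(i + 1, len(bands))
        if rel_difference(bands[i].mass_kda, bands[j].mass_kda) <= gel.rel_tolerance
    ]
    return sorted(pairs, key=lambda p: p.rel_difference)


class TagVariantPlan(BaseModel):
    """Recommended side-by-side tag-variant experiment for one construct.

    ``band_masses`` maps variant name -> {fragment label -> predicted kDa}.
    The design is resolvable when, for every ambiguous fragment pair, at
    least one variant separates the two bands beyond the gel tolerance.
    """

    construct: str
    resolvable: bool
    variants: list[str] = []
    band_masses: dict[str, dict[str, float]] = {}
    ambiguous_pairs: list[tuple[str, str]] = []
    explanation: str = ""


DEFAULT_TAG_SHIFTS = {"N": 2.3, "C": 5.7}  # kDa, FLAG-tag mobility shifts


def design_tag_resolution(
    construct: ProteinConstruct,
    gel: GelModel | None = None,
    tag_shifts: dict[str, float] | None = None,
) -> TagVariantPlan:
    """Plan untagged/N-tagged/C-tagged variants to resolve co-migration.

    An N-terminal tag retards only the N-side fragment and a C-terminal tag
    only the C-side fragment, so running the three variants side by side
    identifies which fragment carries the cross-link even when the untagged
    fragments co-migrate.
    """
    gel = gel or GelModel()
    shifts = dict(DEFAULT_TAG_SHIFTS if tag_shifts is None else tag_shifts)

    untagged = construct.model_copy(update={"tag": "none", "tag_mass_shift": 0.0})
    base_pairs = comigration_pairs(digest(untagged), gel)
    # Ambiguity from a tagged parent counts too: check the construct as given.
    own_pairs = comigration_pairs(digest(construct), gel)
    frag_pairs = [
        (p.a.label, p.b.label)
        for p in base_pairs + own_pairs
        if p.a.fragment is not None and p.b.fragment is not None
    ]
    frag_pairs = sorted(set(frag_pairs))
    if not frag_pairs:
        return TagVariantPlan(
            construct=construct.name,
            resolvable=True,
            explanation="no co-migrating fragment pair; no tag variants needed",
        )

    def variant(tag: str) -> ProteinConstruct:
        return construct.model_copy(
            update={"tag": tag if tag != "UT" else "none",
                    "tag_mass_shift": shifts.get(tag, 0.0)}
        )

    names = {"UT": variant("UT"), "NT": variant("N"), "CT": variant("C")}
    masses = {
        vname: {f"{construct.name}:{f.label}": predict_mass(f, gel) for f in digest(v)}
        for vname, v in names.items()
    }
    resolvable = True
    for a_label, b_label in frag_pairs:
        separated = any(
            rel_difference(m[a_label], m[b_label]) > gel.rel_tolerance
            for m in masses.values()
        )
        resolvable = resolvable and separated
    explanation = (
        "run UT, NT and CT side by side: the N tag shifts only the N-side band "
        f"(+{shifts.get('N', 0.0)} kDa) and the C tag only the C-side band "
        f"(+{shifts.get('C', 0.0)} kDa)"
        if resolvable
        else "unresolvable: the available tag shifts cannot separate the pair "
        "at the gel tolerance"
    )
    return TagVariantPlan(
        construct=construct.name,
        resolvable=resolvable,
        variants=["UT", "NT", "CT"] if resolvable else [],
        band_masses=masses,
        ambiguous_pairs=frag_pairs,
        explanation=explanation,
    )
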