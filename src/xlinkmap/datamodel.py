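"""Domain types and file I/O for cross-link domain mapping.

The experiment this package interprets: a DNA-binding protein is
photo-cross-linked to a duplex probe carrying an azidophenacyl group on one
specific backbone phosphate, then cleaved at a single engineered Asn-Gly
(NG) site with hydroxylamine.  Which cleavage fragment carries the
radiolabel after digestion brackets the cross-linked residue interval
between cut sites.  A panel of single-site constructs therefore maps each
phosphate onto a residue-interval "segment grid".

Numbering conventions
---------------------
* Residues are 1-based; intervals are closed ``[a, b]``.  Cleavage "at
  residue s" (an NG bond between s and s+1) yields fragments ``[1, s]`` and
  ``[s+1, L]``.
* Phosphates are numbered along the promoter element (the PSEA): odd
  indices sit on the non-template strand, even indices on the template
  strand (the parity rule).  The phosphate-to-base-pair convention is an
  explicit adapter (:class:`ProbeNumbering`), not a hidden constant.
"""

from __future__ import annotations

import json
from enum import Enum
from pathlib import Path
from typing import Iterable, Literal, Optional

import pandas as pd
from Bio import SeqIO
from pydantic import BaseModel, Field, field_validator, model_validator


class Call(str, Enum):
    """Outcome recorded for one gel band (one digestion fragment)."""

    crosslinked = "crosslinked"
    not_crosslinked = "not_crosslinked"
    occluded = "occluded"


class Intensity(str, Enum):
    """Ordinal band intensity; no densitometry, only the gel's language."""

    very_weak = "very_weak"
    weak = "weak"
    strong = "strong"

    @property
    def rank(self) -> int:
        return {"very_weak": 1, "weak": 2, "strong": 3}[self.value]

    def __lt__(self, other: "Intensity") -> bool:  # type: ignore[override]
        return self.rank < other.rank


GRADE_ORDER = ["unresolved", "very_weak", "weak", "strong"]


def grade_rank(grade: str) -> int:
    return GRADE_ORDER.index(grade)


Strand = Literal["non_template", "template"]
Tag = Literal["none", "N", "C"]


def strand_of_index(phosphate_index: int) -> Strand:
    """Parity rule: odd phosphate indices lie on the non-template strand."""
    return "non_template" if phosphate_index % 2 == 1 else "template"


class ProteinConstruct(BaseModel):
    """A protein variant with zero or more engineered NG cleavage sites."""

    name: str
    length: int = Field(gt=0)
    cleavage_sites: tuple[int, ...] = ()
    tag: Tag = "none"
    tag_mass_shift: float = Field(default=0.0, ge=0.0)
    sequence: Optional[str] = None

    @model_validator(mode="after")
    def _check(self) -> "ProteinConstruct":
        prev = 0
        for s in self.cleavage_sites:
            if not (1 <= s < self.length):
                raise ValueError(
                    f"construct {self.name!r}: cleavage site {s} outside "
                    f"[1, {self.length - 1}] (cleavage after the last residue "
                    "would leave an empty C-terminal fragment)"
                )
            if s <= prev:
                raise ValueError(
                    f"construct {self.name!r}: cleavage sites must be strictly increasing"
                )
            prev = s
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError(
                f"construct {self.name!r}: sequence length {len(self.sequence)} "
                f"!= declared length {self.length}"
            )
        return self


class Fragment(BaseModel):
    """One product of a complete hydroxylamine digestion.

    ``label`` identifies the fragment within its construct ("N", "C",
    internal "I1", "I2", ... or "NC" for an uncut protein).  ``tag_mass_shift``
    is carried from the parent so that mass prediction is self-contained.
    """

    parent: str
    interval: tuple[int, int]
    label: str
    terminus: Literal["N", "internal", "C", "NC"]
    tagged: bool = False
    tag_mass_shift: float = 0.0
    sequence: Optional[str] = None

    @model_validator(mode="after")
    def _check(self) -> "Fragment":
        a, b = self.interval
        if not (1 <= a <= b):
            raise ValueError(f"fragment interval {self.interval} invalid")
        return self

    @property
    def residue_count(self) -> int:
        a, b = self.interval
        return b - a + 1


class ProbeNumbering(BaseModel):
    """Adapter from PSEA phosphate indices to duplex / helix coordinates.

    ``phosphate k`` denotes the phosphate immediately 5' of base k of the
    PSEA-aligned numbering of its own strand; template-strand indices use
    the base-pair index of the complementary position.  ``bp_origin``
    shifts the helical base-pair index assigned to phosphate k
    (``bp = k + bp_origin``); only the parity rule is fixed by the data.
    """

    psea_offset: int = Field(gt=0, description="1-based duplex position of PSEA base 1")
    psea_length: int = 21
    bp_origin: int = 0

    def duplex_position(self, phosphate_index: int) -> int:
        """1-based duplex base position (non-template coordinates) of base k."""
        return self.psea_offset + phosphate_index - 1

    def bp_index(self, phosphate_index: int) -> int:
        return phosphate_index + self.bp_origin


class CrossLinkProbe(BaseModel):
    """A duplex probe with the cross-linker on one numbered phosphate."""

    duplex: str
    psea_offset: int = Field(gt=0)
    phosphate_index: int = Field(ge=2)
    strand: Strand
    radiolabel_offset: int = 2
    promoter: str = "U6"

    @model_validator(mode="after")
    def _check(self) -> "CrossLinkProbe":
        expected = strand_of_index(self.phosphate_index)
        if self.strand != expected:
            raise ValueError(
                f"parity rule violated: phosphate {self.phosphate_index} must be "
                f"on the {expected} strand, not {self.strand}"
            )
        pos = self.numbering.duplex_position(self.phosphate_index)
        if not (2 <= pos <= len(self.duplex)):
            raise ValueError(
                f"phosphate {self.phosphate_index} maps to duplex position {pos}, "
                f"outside the {len(self.duplex)}-nt duplex"
            )
        return self

    @property
    def numbering(self) -> ProbeNumbering:
        return ProbeNumbering(psea_offset=self.psea_offset)

    @property
    def psea(self) -> str:
        return self.duplex[self.psea_offset - 1 : self.psea_offset - 1 + 21]


class FragmentCall(BaseModel):
    call: Call
    intensity: Optional[Intensity] = None

    @model_validator(mode="after")
    def _check(self) -> "FragmentCall":
        if (self.call is Call.crosslinked) != (self.intensity is not None):
            raise ValueError("intensity must be present iff the call is crosslinked")
        return self


class Observation(BaseModel):
    """Fragment-level cross-link calls for one (construct, probe) gel lane."""

    construct: str
    phosphate_index: int
    strand: Strand
    promoter: str = "U6"
    calls: dict[str, FragmentCall]
    full_length_seen: bool = True

    def is_informative(self) -> bool:
        return any(c.call is not Call.occluded for c in self.calls.values())


class ObservationTable(BaseModel):
    observations: list[Observation]

    def by_probe(self) -> dict[tuple[int, str], list[Observation]]:
        out: dict[tuple[int, str], list[Observation]] = {}
        for obs in self.observations:
            out.setdefault((obs.phosphate_index, obs.promoter), []).append(obs)
        return out

    def for_probe(self, phosphate_index: int, promoter: str = "U6") -> list[Observation]:
        return [
            o
            for o in self.observations
            if o.phosphate_index == phosphate_index and o.promoter == promoter
        ]


class ContactInterval(BaseModel):
    lo: int
    hi: int
    grade: str = "unresolved"
    certainty: Literal["exact", "region"] = "exact"

    @model_validator(mode="after")
    def _check(self) -> "ContactInterval":
        if self.lo > self.hi:
            raise ValueError("interval lo > hi")
        if self.grade not in GRADE_ORDER:
            raise ValueError(f"unknown grade {self.grade!r}")
        return self

    @property
    def interval(self) -> tuple[int, int]:
        return (self.lo, self.hi)


class ContactAssignment(BaseModel):
    """Per-phosphate conclusion: residue intervals with grades and caveats.

    ``intervals``, ``ambiguous``, ``excluded`` and ``untested`` jointly tile
    ``[1, protein_length]``; interval boundaries -/+1 coincide with cleavage
    sites or the protein termini.
    """

    phosphate_index: int
    strand: Strand
    promoter: str = "U6"
    protein_length: int
    intervals: list[ContactInterval] = []
    ambiguous: list[tuple[int, int]] = []
    excluded: list[tuple[int, int]] = []
    untested: list[tuple[int, int]] = []
    conflicts: list[str] = []
    warnings: list[str] = []
    notes: dict[str, str] = {}

    @model_validator(mode="after")
    def _check(self) -> "ContactAssignment":
        pieces = sorted(
            [iv.interval for iv in self.intervals]
            + list(self.ambiguous)
            + list(self.excluded)
            + list(self.untested)
        )
        if not self.conflicts:
            cur = 0
            for a, b in pieces:
                if a != cur + 1:
                    raise ValueError(
                        f"assignment pieces do not tile [1,{self.protein_length}]: "
                        f"gap/overlap before {a}"
                    )
                cur = b
            if pieces and cur != self.protein_length:
                raise ValueError(
                    f"assignment pieces do not tile [1,{self.protein_length}]: "
                    f"coverage stops at {cur}"
                )
        return self


class ContactArchitecture(BaseModel):
    """Full phosphate -> assignment map for one protein on one promoter."""

    promoter: str
    subunit: str
    protein_length: int
    assignments: dict[int, ContactAssignment]
    domains: list[tuple[str, int, int]] = []

    @model_validator(mode="after")
    def _check(self) -> "ContactArchitecture":
        for k, asg in self.assignments.items():
            if asg.phosphate_index != k:
                raise ValueError(f"assignment keyed {k} holds phosphate {asg.phosphate_index}")
        if self.domains:
            cur = 0
            for name, a, b in sorted(self.domains, key=lambda d: d[1]):
                if a != cur + 1:
                    raise ValueError(f"domain annotation does not tile: gap before {name}")
                cur = b
            if cur != self.protein_length:
                raise ValueError("domain annotation stops short of the protein length")
        return self

    def contacted(self) -> list[int]:
        return sorted(k for k, a in self.assignments.items() if a.intervals)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _parse_multivalue(cell) -> tuple[int, ...]:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)) or str(cell).strip() == "":
        return ()
    return tuple(int(x) for x in str(cell).split(";"))


def load_constructs(path: str | Path) -> list[ProteinConstruct]:
    """Read a construct panel from TSV (``;``-separated multi-value cells)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"name", "length", "cleavage_sites", "tag", "tag_mass_shift"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    out: list[ProteinConstruct] = []
    seen: set[str] = set()
    for i, row in df.iterrows():
        name = str(row["name"])
        if name in seen:
            raise ValueError(f"{path} row {i}: duplicate construct name {name!r}")
        seen.add(name)
        try:
            out.append(
                ProteinConstruct(
                    name=name,
                    length=int(row["length"]),
                    cleavage_sites=_parse_multivalue(row["cleavage_sites"]),
                    tag=str(row["tag"]),
                    tag_mass_shift=float(row["tag_mass_shift"]),
                    sequence=None
                    if "sequence" not in df.columns or pd.isna(row.get("sequence"))
                    else str(row["sequence"]),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path} row {i} ({name!r}): {exc}") from exc
    return out


def load_probe_set(fasta_path: str | Path, table_path: str | Path) -> list[CrossLinkProbe]:
    """Build probes from a duplex FASTA plus a phosphate table.

    The FASTA record's description may carry ``psea_offset=<n>``; otherwise
    the table must provide a ``psea_offset`` column.
    """
    record = next(SeqIO.parse(str(fasta_path), "fasta"))
    duplex = str(record.seq).upper()
    offset = None
    for token in record.description.split():
        if token.startswith("psea_offset="):
            offset = int(token.split("=", 1)[1])
    df = pd.read_csv(table_path, sep="\t", dtype=str)
    probes: list[CrossLinkProbe] = []
    for i, row in df.iterrows():
        off = int(row["psea_offset"]) if "psea_offset" in df.columns else offset
        if off is None:
            raise ValueError(f"{table_path} row {i}: no PSEA offset available")
        try:
            probes.append(
                CrossLinkProbe(
                    duplex=duplex,
                    psea_offset=off,
                    phosphate_index=int(row["phosphate_index"]),
                    strand=str(row["strand"]),
                    promoter=str(row.get("promoter", "U6")),
                )
            )
        except ValueError as exc:
            raise ValueError(f"{table_path} row {i}: {exc}") from exc
    return probes


def load_observations(path: str | Path) -> ObservationTable:
    """Read fragment-level gel calls from TSV.

    Columns: phosphate_index, strand, promoter, construct, fragment, call,
    intensity (empty unless call == crosslinked).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    grouped: dict[tuple[int, str, str], dict[str, FragmentCall]] = {}
    for _, row in df.iterrows():
        key = (int(row["phosphate_index"]), str(row["promoter"]), str(row["construct"]))
        intensity = row.get("intensity")
        grouped.setdefault(key, {})[str(row["fragment"])] = FragmentCall(
            call=Call(str(row["call"])),
            intensity=None if pd.isna(intensity) or intensity == "" else Intensity(str(intensity)),
        )
    observations = [
        Observation(
            construct=construct,
            phosphate_index=idx,
            strand=strand_of_index(idx),
            promoter=promoter,
            calls=calls,
        )
        for (idx, promoter, construct), calls in grouped.items()
    ]
    return ObservationTable(observations=observations)


def write_assignment(assignment: ContactAssignment, path: str | Path) -> None:
    Path(path).write_text(assignment.model_dump_json(indent=2) + "\n")


def read_assignment(path: str | Path) -> ContactAssignment:
    return ContactAssignment.model_validate_json(Path(path).read_text())


def write_architecture(arch: ContactArchitecture, path: str | Path) -> None:
    Path(path).write_text(arch.model_dump_json(indent=2) + "\n")


def read_architecture(path: str | Path) -> ContactArchitecture:
    raw = json.loads(Path(path).read_text())
    # JSON object keys are strings; restore integer phosphate keys.
    raw["assignments"] = {int(k): v for k, v in raw["assignments"].items()}
    return ContactArchitecture.model_validate(raw)


def merge_runs(values: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping or adjacent closed intervals."""
    out: list[tuple[int, int]] = []
    for a, b in sorted(values):
        if out and a <= out[-1][1] + 1:
            out[-1] = (out[-1][0], max(out[-1][1], b))
        else:
            out.append((a, b))
    return out
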