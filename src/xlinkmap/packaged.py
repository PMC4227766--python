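"""Access to the packaged promoter cross-linking dataset.

The package ships the transcribed gel results for the SNAP190 subunit of
the fly snRNA-activating protein complex on a U6-promoter probe: the
single-cut construct panel, the 78-nt probe duplex with its 21-bp PSEA,
per-phosphate fragment call tables for the 16 cross-linked phosphate
positions, and the previously mapped U1 architecture restated at the same
resolution.  Everything here is plain text (TSV/FASTA/JSON) and loads into
the validated domain types.
"""

from __future__ import annotations

from importlib.resources import as_file, files

from .datamodel import (
    ContactArchitecture,
    CrossLinkProbe,
    ObservationTable,
    ProteinConstruct,
    load_constructs,
    load_observations,
    load_probe_set,
    read_architecture,
)
from .inference import infer_contacts

PROTEIN_LENGTH = 721
PSEA_OFFSET = 31  # 1-based duplex position of PSEA base 1

#: Display domains bounded by the panel's cleavage sites (half-repeat to
#: half-repeat through the Myb region).
DOMAINS: list[tuple[str, int, int]] = [
    ("N-term", 1, 189),
    ("Rh", 190, 247),
    ("Ra", 248, 305),
    ("Rb", 306, 358),
    ("Rc", 359, 409),
    ("Rd", 410, 483),
    ("C-term", 484, 721),
]

U6_PHOSPHATES = [2, 3, 4, 5, 7, 8, 10, 11, 12, 13, 14, 17, 19, 22, 24, 25]

_DATA = files("xlinkmap") / "data"


def _path(name: str):
    return as_file(_DATA / name)


def load_packaged_constructs() -> list[ProteinConstruct]:
    with _path("constructs_u6.tsv") as p:
        return load_constructs(p)


def load_packaged_probes() -> list[CrossLinkProbe]:
    with _path("u6_duplex.fasta") as fasta, _path("probes_u6.tsv") as table:
        return load_probe_set(fasta, table)


def load_packaged_observations() -> ObservationTable:
    with _path("observations_u6.tsv") as p:
        return load_observations(p)


def load_packaged_u1_architecture() -> ContactArchitecture:
    with _path("u1_architecture.json") as p:
        return read_architecture(p)


def infer_u6_architecture(oracle: bool = False) -> ContactArchitecture:
    """Run the full per-phosphate inference over the packaged U6 lanes."""
    constructs = {c.name: c for c in load_packaged_constructs()}
    table = load_packaged_observations()
    assignments = {
        k: infer_contacts(table.for_probe(k, "U6"), constructs, oracle=oracle)
        for k in U6_PHOSPHATES
    }
    return ContactArchitecture(
        promoter="U6",
        subunit="SNAP190",
        protein_length=PROTEIN_LENGTH,
        assignments=assignments,
        domains=DOMAINS,
    )
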