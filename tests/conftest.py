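import numpy as np
import pytest

from xlinkmap import packaged
from xlinkmap.datamodel import (
    Call,
    FragmentCall,
    Intensity,
    Observation,
    ProteinConstruct,
)
from xlinkmap.fragments import digest
from xlinkmap.geometry import build_helix
from xlinkmap.inference import SegmentPartition


@pytest.fixture(scope="session")
def constructs() -> dict[str, ProteinConstruct]:
    return {c.name: c for c in packaged.load_packaged_constructs()}


@pytest.fixture(scope="session")
def panel(constructs):
    """The nine single-cut constructs, N-terminally tagged."""
    return [constructs[n] for n in ["H", "Ha", "A", "B", "C", "D", "De", "dE", "E"]]


@pytest.fixture(scope="session")
def observations():
    return packaged.load_packaged_observations()


@pytest.fixture(scope="session")
def full_partition() -> SegmentPartition:
    return SegmentPartition.from_cut_sites(
        [168, 189, 247, 305, 358, 409, 445, 463, 483], 721
    )


@pytest.fixture(scope="session")
def helix():
    return build_helix(30)


@pytest.fixture(scope="session")
def u6_architecture():
    return packaged.infer_u6_architecture()


@pytest.fixture(scope="session")
def u1_architecture():
    return packaged.load_packaged_u1_architecture()


def random_case(rng: np.random.Generator, max_segments: int = 12):
    """A random observation table over a random segment grid.

    Mixes cross-linked (graded), negative and occluded calls, single- and
    two-cut constructs; used by the propagation-vs-oracle equivalence
    suites.
    """
    length = 120
    n_seg = int(rng.integers(2, max_segments + 1))
    sites = sorted(rng.choice(np.arange(1, length), size=n_seg - 1, replace=False).tolist())
    constructs: dict[str, ProteinConstruct] = {}
    observations: list[Observation] = []
    for i in range(int(rng.integers(1, 7))):
        k = min(int(rng.integers(1, 3)), len(sites))
        csites = tuple(sorted(rng.choice(sites, size=k, replace=False).tolist())) if k else ()
        name = f"c{i}"
        constructs[name] = ProteinConstruct(name=name, length=length, cleavage_sites=csites)
        calls = {}
        for frag in digest(constructs[name]):
            r = rng.random()
            if r < 0.35:
                grade = [Intensity.very_weak, Intensity.weak, Intensity.strong][
                    int(rng.integers(0, 3))
                ]
                calls[frag.label] = FragmentCall(call=Call.crosslinked, intensity=grade)
            elif r < 0.7:
                calls[frag.label] = FragmentCall(call=Call.not_crosslinked)
            else:
                calls[frag.label] = FragmentCall(call=Call.occluded)
        observations.append(
            Observation(
                construct=name,
                phosphate_index=3,
                strand="non_template",
                promoter="X",
                calls=calls,
            )
        )
    partition = SegmentPartition.from_cut_sites(sites, length)
    return observations, constructs, partition
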