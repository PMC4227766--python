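"""Residue-interval contact inference from fragment cross-link calls.

Semantics
---------
The construct panel's cleavage sites induce a *segment grid* on the
protein.  A ground truth is a subset of contacted segments.  Each gel lane
(one construct, one probe) constrains the truth:

* an N-side fragment [1, s] that cross-linked means some contacted segment
  lies within [1, s]; likewise for the C side;
* a fragment that did **not** cross-link means no contacted segment lies
  within it;
* an occluded band contributes nothing (never treated as a negative).

The specification of the method is possible-world semantics: enumerate all
segment subsets, keep the ones consistent with every lane.  A segment is
``required`` when contacted in every consistent world, ``excluded`` when in
none, ``ambiguous`` otherwise, and ``untested`` when no informative lane
covers it.  :func:`propagate` computes the same result in closed form
(negative calls exclude; each cross-linked fragment becomes a positive
clause over its non-excluded segments; singleton clauses force contacts);
:func:`brute_force_consistent_sets` is the independent enumeration oracle.

Reported contact intervals are of two kinds:

* ``exact`` — maximal runs of individually required segments;
* ``region`` — the span of an inclusion-minimal clause none of whose
  segments is required: every consistent world places a contact somewhere
  in the run, but the data cannot localize it further (the "between
  residues a and b" conclusions of the gels).

Intensity is ordinal and handled after the binary step.  The strongest
contact must lie under the most intense band of every fully resolved lane,
so intersecting those footprints localizes the top-graded domain; the
remaining intervals are graded by the lanes that isolate them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np

from .datamodel import (
    Call,
    ContactAssignment,
    ContactInterval,
    Intensity,
    Observation,
    ProteinConstruct,
)
from .fragments import digest

MAX_ORACLE_SEGMENTS = 20


def _merge_overlapping(spans) -> list[tuple[int, int]]:
    """Merge strictly overlapping spans; adjacent regions stay distinct
    conclusions (one guaranteed contact each)."""
    out: list[tuple[int, int]] = []
    for a, b in sorted(spans):
        if out and a <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], b))
        else:
            out.append((a, b))
    return out


@dataclass(frozen=True)
class SegmentPartition:
    """Closed residue intervals tiling [1, length], bounded by cut sites."""

    length: int
    cut_sites: tuple[int, ...]
    segments: tuple[tuple[int, int], ...]

    @classmethod
    def from_cut_sites(cls, cut_sites: Sequence[int], length: int) -> "SegmentPartition":
        sites = tuple(sorted(set(cut_sites)))
        if any(not (1 <= s < length) for s in sites):
            raise ValueError(f"cut sites {sites} outside [1, {length - 1}]")
        bounds = [0, *sites, length]
        segments = tuple((bounds[i] + 1, bounds[i + 1]) for i in range(len(bounds) - 1))
        return cls(length=length, cut_sites=sites, segments=segments)

    @property
    def n(self) -> int:
        return len(self.segments)

    def mask_within(self, interval: tuple[int, int]) -> int:
        """Bitmask of segments wholly inside the closed residue interval."""
        a, b = interval
        mask = 0
        for i, (lo, hi) in enumerate(self.segments):
            if lo >= a and hi <= b:
                mask |= 1 << i
        return mask

    def span(self, mask: int) -> tuple[int, int]:
        idx = [i for i in range(self.n) if mask >> i & 1]
        return (self.segments[idx[0]][0], self.segments[idx[-1]][1])

    def run_intervals(self, mask: int) -> list[tuple[int, int]]:
        """Maximal runs of set segments, as residue intervals."""
        runs: list[tuple[int, int]] = []
        i = 0
        while i < self.n:
            if mask >> i & 1:
                j = i
                while j + 1 < self.n and mask >> (j + 1) & 1:
                    j += 1
                runs.append((self.segments[i][0], self.segments[j][1]))
                i = j + 1
            else:
                i += 1
        return runs


def partition_for(
    observations: Sequence[Observation], constructs: dict[str, ProteinConstruct]
) -> SegmentPartition:
    """Segment grid from the union of cut sites of informative lanes."""
    lengths = {constructs[o.construct].length for o in observations}
    if len(lengths) != 1:
        raise ValueError(f"observations mix protein lengths {sorted(lengths)}")
    sites: set[int] = set()
    for obs in observations:
        if obs.is_informative():
            sites.update(constructs[obs.construct].cleavage_sites)
    return SegmentPartition.from_cut_sites(sorted(sites), lengths.pop())


@dataclass(frozen=True)
class Clause:
    """A cross-linked fragment's positive constraint (pre-exclusion)."""

    construct: str
    fragment_label: str
    fragment_mask: int
    intensity: Intensity


@dataclass
class ProbeConstraints:
    partition: SegmentPartition
    excluded_mask: int = 0
    covered_mask: int = 0  # segments under at least one informative call
    clauses: list[Clause] = field(default_factory=list)


def observation_constraint(
    observation: Observation,
    construct: ProteinConstruct,
    partition: SegmentPartition,
) -> ProbeConstraints:
    """Translate one lane into exclusions and positive clauses."""
    fragments = {f.label: f for f in digest(construct)}
    unknown = set(observation.calls) - set(fragments)
    if unknown:
        raise ValueError(
            f"lane {observation.construct}/{observation.phosphate_index}: calls "
            f"reference fragments {sorted(unknown)} not produced by the digestion"
        )
    out = ProbeConstraints(partition=partition)
    for label, fc in observation.calls.items():
        mask = partition.mask_within(fragments[label].interval)
        if fc.call is Call.occluded:
            continue
        out.covered_mask |= mask
        if fc.call is Call.not_crosslinked:
            out.excluded_mask |= mask
        else:
            out.clauses.append(
                Clause(
                    construct=construct.name,
                    fragment_label=label,
                    fragment_mask=mask,
                    intensity=fc.intensity,
                )
            )
    return out


def _collect(
    observations: Sequence[Observation],
    constructs: dict[str, ProteinConstruct],
    partition: SegmentPartition,
) -> ProbeConstraints:
    merged = ProbeConstraints(partition=partition)
    for obs in observations:
        c = observation_constraint(obs, constructs[obs.construct], partition)
        merged.excluded_mask |= c.excluded_mask
        merged.covered_mask |= c.covered_mask
        merged.clauses.extend(c.clauses)
    return merged


@dataclass
class InferenceResult:
    """Binary (grade-free) inference outcome on the segment grid."""

    partition: SegmentPartition
    required_mask: int
    excluded_mask: int
    untested_mask: int
    ambiguous_mask: int
    intervals: tuple[tuple[int, int, str], ...]  # (lo, hi, certainty)
    conflicts: tuple[str, ...]

    @property
    def statuses(self) -> Optional[tuple[str, ...]]:
        if self.conflicts:
            return None
        out = []
        for i in range(self.partition.n):
            bit = 1 << i
            if self.required_mask & bit:
                out.append("required")
            elif self.excluded_mask & bit:
                out.append("excluded")
            elif self.untested_mask & bit:
                out.append("untested")
            else:
                out.append("ambiguous")
        return tuple(out)

    def comparable(self) -> tuple:
        """Canonical form for propagation-vs-oracle equivalence checks."""
        return (self.statuses, self.intervals, bool(self.conflicts))


def _regions_from_minimal_clauses(
    clause_masks: list[int],
    required_mask: int,
    excluded_mask: int,
    partition: SegmentPartition,
) -> list[tuple[int, int]]:
    """Containment-minimal clause spans free of required/excluded segments.

    A span whose interior touches a required segment is already satisfied
    (no extra region to report); one bridging an excluded gap cannot be
    stated as a clean closed interval and its segments stay ambiguous.
    """
    spans: set[tuple[int, int]] = set()
    for m in clause_masks:
        if not m:
            continue
        lo, hi = partition.span(m)
        if partition.mask_within((lo, hi)) & (required_mask | excluded_mask):
            continue
        spans.add((lo, hi))
    minimal = [
        s
        for s in spans
        if not any(t != s and t[0] >= s[0] and t[1] <= s[1] for t in spans)
    ]
    return _merge_overlapping(minimal)


def propagate(
    observations: Sequence[Observation],
    constructs: dict[str, ProteinConstruct],
    partition: SegmentPartition | None = None,
) -> InferenceResult:
    """Closed-form constraint propagation (matches the enumeration oracle)."""
    partition = partition or partition_for(observations, constructs)
    cons = _collect(observations, constructs, partition)
    full = (1 << partition.n) - 1

    conflicts: list[str] = []
    reduced: list[int] = []
    for cl in cons.clauses:
        m = cl.fragment_mask & ~cons.excluded_mask
        if m == 0:
            conflicts.append(
                f"lane {cl.construct}:{cl.fragment_label} cross-linked but every "
                "segment of the fragment is excluded by other lanes"
            )
        reduced.append(m)

    required = 0
    for m in reduced:
        if m and m & (m - 1) == 0:  # singleton clause
            required |= m

    untested = full & ~cons.covered_mask
    excluded = cons.excluded_mask
    ambiguous = full & ~(required | excluded | untested)

    if conflicts:
        return InferenceResult(
            partition, 0, excluded, untested, 0, (), tuple(conflicts)
        )

    intervals: list[tuple[int, int, str]] = [
        (lo, hi, "exact") for lo, hi in partition.run_intervals(required)
    ]
    intervals += [
        (lo, hi, "region")
        for lo, hi in _regions_from_minimal_clauses(reduced, required, excluded, partition)
    ]
    return InferenceResult(
        partition,
        required,
        excluded,
        untested,
        ambiguous,
        tuple(sorted(intervals)),
        (),
    )


def brute_force_consistent_sets(
    observations: Sequence[Observation],
    constructs: dict[str, ProteinConstruct],
    partition: SegmentPartition | None = None,
) -> np.ndarray:
    """All segment subsets (as bitmasks) consistent with every lane."""
    partition = partition or partition_for(observations, constructs)
    if partition.n > MAX_ORACLE_SEGMENTS:
        raise ValueError(f"refusing enumeration over {partition.n} > {MAX_ORACLE_SEGMENTS} segments")
    cons = _collect(observations, constructs, partition)
    worlds = np.arange(1 << partition.n, dtype=np.int64)
    ok = (worlds & cons.excluded_mask) == 0
    for cl in cons.clauses:
        ok &= (worlds & cl.fragment_mask) != 0
    return worlds[ok]


def oracle_infer(
    observations: Sequence[Observation],
    constructs: dict[str, ProteinConstruct],
    partition: SegmentPartition | None = None,
) -> InferenceResult:
    """Inference by exhaustive enumeration; the independent reference path."""
    partition = partition or partition_for(observations, constructs)
    cons = _collect(observations, constructs, partition)
    full = (1 << partition.n) - 1
    worlds = brute_force_consistent_sets(observations, constructs, partition)
    untested = full & ~cons.covered_mask
    excluded_syntactic = cons.excluded_mask

    if len(worlds) == 0:
        return InferenceResult(
            partition, 0, excluded_syntactic, untested, 0,
            (), ("observations are mutually unsatisfiable",),
        )

    required = int(np.bitwise_and.reduce(worlds))
    possible = int(np.bitwise_or.reduce(worlds))
    excluded = full & ~possible & cons.covered_mask
    ambiguous = full & ~(required | excluded | untested)

    intervals = [(lo, hi, "exact") for lo, hi in partition.run_intervals(required)]

    # Certain-contact regions: contiguous runs of segments hit by every
    # consistent world, containing no required segment, minimal under
    # containment.
    runs: list[tuple[int, int, int]] = []  # (start, end, mask) in segment indices
    for i, j in combinations(range(partition.n + 1), 2):
        mask = ((1 << (j - i)) - 1) << i
        if mask & required or mask & excluded:
            continue
        if np.all((worlds & mask) != 0):
            runs.append((i, j - 1, mask))
    minimal = [
        (i, j, m)
        for (i, j, m) in runs
        if not any((i2 >= i and j2 <= j and (i2, j2) != (i, j)) for i2, j2, _ in runs)
    ]
    spans = _merge_overlapping(
        (partition.segments[i][0], partition.segments[j][1]) for i, j, _ in minimal
    )
    intervals += [(lo, hi, "region") for lo, hi in spans]

    return InferenceResult(
        partition, required, excluded, untested, ambiguous,
        tuple(sorted(intervals)), (),
    )


# ---------------------------------------------------------------------------
# Intensity grading
# ---------------------------------------------------------------------------

def _lane_segments(
    obs: Observation, construct: ProteinConstruct, partition: SegmentPartition
) -> dict[str, tuple[int, Call, Optional[Intensity]]]:
    frags = {f.label: f for f in digest(construct)}
    return {
        label: (partition.mask_within(frags[label].interval), fc.call, fc.intensity)
        for label, fc in obs.calls.items()
    }


def grade_intensity(
    result: InferenceResult,
    observations: Sequence[Observation],
    constructs: dict[str, ProteinConstruct],
) -> tuple[list[ContactInterval], list[str]]:
    """Attach ordinal grades to the inferred intervals.

    Returns graded intervals (possibly with one new top-grade interval when
    the intensity pattern pinpoints segments the binary logic left
    ambiguous) plus any grading warnings.
    """
    partition = result.partition
    warnings: list[str] = []
    crosslinked = [
        (obs, label, mask, intensity)
        for obs in observations
        for label, (mask, call, intensity) in _lane_segments(
            obs, constructs[obs.construct], partition
        ).items()
        if call is Call.crosslinked
    ]
    if not crosslinked or result.conflicts:
        return [
            ContactInterval(lo=lo, hi=hi, grade="unresolved", certainty=c)
            for lo, hi, c in result.intervals
        ], warnings

    top = max((i for _, _, _, i in crosslinked), key=lambda i: i.rank)

    # Footprint of the strongest contact: under the most intense band of
    # every fully resolved lane whose own maximum reaches the global top.
    strongest: Optional[int] = None
    for obs in observations:
        lane = _lane_segments(obs, constructs[obs.construct], partition)
        if any(call is Call.occluded for _, call, _ in lane.values()):
            continue
        lane_x = [(m, i) for m, call, i in lane.values() if call is Call.crosslinked]
        if not lane_x:
            continue
        lane_max = max((i for _, i in lane_x), key=lambda i: i.rank)
        if lane_max.rank < top.rank:
            warnings.append(
                f"lane {obs.construct}: maximum intensity {lane_max.value} is below "
                f"the global maximum {top.value}; lane skipped for top-grade localization"
            )
            continue
        union = 0
        for m, i in lane_x:
            if i == lane_max:
                union |= m & ~result.excluded_mask
        strongest = union if strongest is None else strongest & union
    if strongest == 0:
        warnings.append("intensity pattern inconsistent: strongest-contact footprint is empty")
        strongest = None

    def unit_grade(mask: int, lo: int, hi: int) -> str:
        if strongest is not None and mask and mask & ~strongest == 0:
            return top.value
        return _grade_by_isolating_lanes(lo, hi, mask, result, crosslinked, warnings)

    graded: list[ContactInterval] = []
    for lo, hi, certainty in result.intervals:
        if certainty == "region":
            mask = partition.mask_within((lo, hi))
            graded.append(
                ContactInterval(lo=lo, hi=hi, grade=unit_grade(mask, lo, hi), certainty=certainty)
            )
            continue
        # Exact runs are graded per segment; adjacent segments sharing a
        # grade merge back into one interval, so a strong/weak split inside
        # a required run is reported as two intervals.
        pieces: list[ContactInterval] = []
        for i, (slo, shi) in enumerate(partition.segments):
            if slo < lo or shi > hi:
                continue
            g = unit_grade(1 << i, slo, shi)
            if pieces and pieces[-1].grade == g and pieces[-1].hi + 1 == slo:
                pieces[-1] = ContactInterval(
                    lo=pieces[-1].lo, hi=shi, grade=g, certainty="exact"
                )
            else:
                pieces.append(ContactInterval(lo=slo, hi=shi, grade=g, certainty="exact"))
        graded.extend(pieces)

    # The strongest contact necessarily lies inside the footprint.  Only
    # when the footprint is disjoint from every known interval does that
    # force a contact the binary logic missed (otherwise an existing
    # interval may host it and nothing new is implied).
    interval_union = 0
    for lo, hi, _ in result.intervals:
        interval_union |= partition.mask_within((lo, hi))
    if strongest is not None and not strongest & (interval_union | result.required_mask):
        for lo, hi in partition.run_intervals(strongest):
            mask = partition.mask_within((lo, hi))
            graded.append(
                ContactInterval(
                    lo=lo,
                    hi=hi,
                    grade=top.value,
                    certainty="exact" if mask & (mask - 1) == 0 else "region",
                )
            )
    return sorted(graded, key=lambda iv: iv.lo), warnings


def _grade_by_isolating_lanes(
    lo: int,
    hi: int,
    interval_mask: int,
    result: InferenceResult,
    crosslinked: list,
    warnings: list[str],
) -> str:
    """Grade from lanes whose cross-linked band isolates these segments."""
    votes: list[Intensity] = []
    for obs, label, mask, intensity in crosslinked:
        informative = mask & ~result.excluded_mask
        if informative and informative & ~interval_mask == 0:
            votes.append(intensity)
    if not votes:
        return "unresolved"
    if len(set(votes)) > 1:
        warnings.append(
            f"interval [{lo},{hi}]: isolating lanes disagree on intensity "
            f"({sorted(v.value for v in set(votes))}); majority grade used"
        )
        counts: dict[Intensity, int] = {}
        for v in votes:
            counts[v] = counts.get(v, 0) + 1
        return max(counts.items(), key=lambda kv: (kv[1], kv[0].rank))[0].value
    return votes[0].value


# ---------------------------------------------------------------------------
# Top-level per-probe inference
# ---------------------------------------------------------------------------

def infer_contacts(
    observations: Sequence[Observation],
    constructs: Sequence[ProteinConstruct] | dict[str, ProteinConstruct],
    oracle: bool = False,
) -> ContactAssignment:
    """Infer the contact assignment for one probe from its gel lanes."""
    if not observations:
        raise ValueError("no observations for this probe")
    keys = {(o.phosphate_index, o.strand, o.promoter) for o in observations}
    if len(keys) != 1:
        raise ValueError(f"observations mix probes: {sorted(keys)}")
    index, strand, promoter = keys.pop()
    cmap = constructs if isinstance(constructs, dict) else {c.name: c for c in constructs}

    partition = partition_for(observations, cmap)
    engine = oracle_infer if oracle else propagate
    result = engine(observations, cmap, partition)
    if oracle:
        check = propagate(observations, cmap, partition)
        if check.comparable() != result.comparable():
            raise AssertionError(
                "constraint propagation disagrees with the enumeration oracle: "
                f"{check.comparable()} != {result.comparable()}"
            )
    intervals, warnings = grade_intensity(result, observations, cmap)

    interval_masks = 0
    for iv in intervals:
        interval_masks |= partition.mask_within(iv.interval)
    ambiguous_left = result.ambiguous_mask & ~interval_masks
    required_uncovered = result.required_mask & ~interval_masks  # conflicts only

    return ContactAssignment(
        phosphate_index=index,
        strand=strand,
        promoter=promoter,
        protein_length=partition.length,
        intervals=intervals,
        ambiguous=partition.run_intervals(ambiguous_left | required_uncovered),
        excluded=partition.run_intervals(result.excluded_mask),
        untested=partition.run_intervals(result.untested_mask),
        conflicts=list(result.conflicts),
        warnings=warnings,
    )


def untested_regions(
    observations: Sequence[Observation],
    constructs: Sequence[ProteinConstruct] | dict[str, ProteinConstruct],
    partition: SegmentPartition | None = None,
) -> list[tuple[int, int]]:
    """Residue intervals not constrained by any informative lane."""
    cmap = constructs if isinstance(constructs, dict) else {c.name: c for c in constructs}
    if not observations:
        if partition is None:
            raise ValueError("need a partition or at least one observation")
        return [(1, partition.length)]
    partition = partition or partition_for(observations, cmap)
    cons = _collect(observations, cmap, partition)
    full = (1 << partition.n) - 1
    return partition.run_intervals(full & ~cons.covered_mask)
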