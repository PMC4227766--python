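"""Synthetic ground truths and forward-simulated observation tables.

The forward model mirrors the real experiment: a ground-truth contact map
assigns residue intervals (with ordinal intensities) to each phosphate; a
fragment cross-links exactly when it overlaps a contacted interval, and
its band intensity is the maximum over the intervals it covers.  Noise
enters as per-band false negatives, intensity misgrades, and occlusion by
co-migrating bands from other proteins (occluded calls are dropped from
inference, never flipped to negatives, so occlusion cannot create false
positives).
"""

from __future__ import annotations

from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from .datamodel import (
    Call,
    FragmentCall,
    Intensity,
    Observation,
    ObservationTable,
    ProteinConstruct,
    strand_of_index,
)
from .fragments import GelModel, digest, predict_mass, rel_difference
from .inference import SegmentPartition, infer_contacts

_INTENSITIES = [Intensity.very_weak, Intensity.weak, Intensity.strong]


class GroundTruth(BaseModel):
    protein_length: int
    promoter: str = "synthetic"
    contacts: dict[int, list[tuple[int, int, Intensity]]]

    def intervals(self, phosphate: int) -> list[tuple[int, int, Intensity]]:
        return self.contacts.get(phosphate, [])


class NoiseModel(BaseModel):
    p_false_negative: float = Field(default=0.0, ge=0.0, le=1.0)
    p_intensity_misgrade: float = Field(default=0.0, ge=0.0, le=1.0)
    occluders: list[tuple[str, float]] = []


def sample_truth(
    rng: np.random.Generator,
    partition: SegmentPartition,
    phosphates: Sequence[int],
    max_domains: int = 3,
) -> GroundTruth:
    """Draw 1-3 contacted domains per phosphate on the segment grid.

    Each domain is a single inter-cut-site segment and domains are kept
    non-adjacent, emulating the observed pattern of distinct repeats
    touching each phosphate.  Intensities are uniform over the ordinal
    scale except that with three domains the middle one is drawn strictly
    dominant: a single-cut panel reads band intensities as running maxima
    from either terminus, so an interior domain is visible to the assay
    only when it out-shines its flanks (the observed three-domain contact
    is exactly of this kind).
    """
    contacts: dict[int, list[tuple[int, int, Intensity]]] = {}
    n = partition.n
    for k in phosphates:
        n_domains = int(rng.integers(1, max_domains + 1))
        chosen: list[int] = []
        candidates = list(range(n))
        rng.shuffle(candidates)
        for idx in candidates:
            if len(chosen) == n_domains:
                break
            if all(abs(idx - c) > 1 for c in chosen):
                chosen.append(idx)
        chosen.sort()
        if len(chosen) >= 3:
            grades = [_INTENSITIES[int(rng.integers(0, 2))] for _ in chosen]
            grades[len(chosen) // 2] = Intensity.strong
        else:
            grades = [_INTENSITIES[int(rng.integers(0, 3))] for _ in chosen]
        contacts[k] = [
            (partition.segments[i][0], partition.segments[i][1], g)
            for i, g in zip(chosen, grades)
        ]
    return GroundTruth(protein_length=partition.length, contacts=contacts)


def _misgrade(intensity: Intensity, rng: np.random.Generator) -> Intensity:
    i = _INTENSITIES.index(intensity)
    if i == 0:
        j = 1
    elif i == 2:
        j = 1
    else:
        j = int(rng.choice([0, 2]))
    return _INTENSITIES[j]


def simulate_observations(
    truth: GroundTruth,
    constructs: Sequence[ProteinConstruct],
    gel: GelModel | None = None,
    noise: NoiseModel | None = None,
    rng: np.random.Generator | None = None,
) -> ObservationTable:
    """Forward-simulate one gel lane per (construct, contacted phosphate)."""
    gel = gel or GelModel()
    noise = noise or NoiseModel()
    rng = rng or np.random.default_rng(0)
    observations: list[Observation] = []
    for phosphate in sorted(truth.contacts):
        intervals = truth.intervals(phosphate)
        for construct in constructs:
            calls: dict[str, FragmentCall] = {}
            for frag in digest(construct):
                a, b = frag.interval
                hits = [i for lo, hi, i in intervals if lo <= b and hi >= a]
                if hits:
                    grade = max(hits, key=lambda i: i.rank)
                    if rng.random() < noise.p_false_negative:
                        fc = FragmentCall(call=Call.not_crosslinked)
                    else:
                        if rng.random() < noise.p_intensity_misgrade:
                            grade = _misgrade(grade, rng)
                        fc = FragmentCall(call=Call.crosslinked, intensity=grade)
                else:
                    fc = FragmentCall(call=Call.not_crosslinked)
                mass = predict_mass(frag, gel)
                if any(
                    rel_difference(mass, occ_mass) <= gel.rel_tolerance
                    for _, occ_mass in noise.occluders
                ):
                    fc = FragmentCall(call=Call.occluded)
                calls[frag.label] = fc
            observations.append(
                Observation(
                    construct=construct.name,
                    phosphate_index=phosphate,
                    strand=strand_of_index(phosphate),
                    promoter=truth.promoter,
                    calls=calls,
                )
            )
    return ObservationTable(observations=observations)


def _truth_runs(truth: GroundTruth, phosphate: int) -> list[tuple[int, int]]:
    runs: list[tuple[int, int]] = []
    for lo, hi, _ in sorted(truth.intervals(phosphate)):
        if runs and lo == runs[-1][1] + 1:
            runs[-1] = (runs[-1][0], hi)
        else:
            runs.append((lo, hi))
    return runs


def recovery_experiment(
    n_replicates: int,
    constructs: Sequence[ProteinConstruct],
    noise_grid: Sequence[float],
    seed: int,
    gel: GelModel | None = None,
    occluders: Sequence[tuple[str, float]] = (),
    truth_sampler: Optional[Callable[[np.random.Generator, SegmentPartition], GroundTruth]] = None,
) -> pd.DataFrame:
    """Monte-Carlo recovery of random truths across false-negative rates.

    Returns one row per noise level: fraction of replicates recovered
    exactly at segment resolution, mean boundary error (in segments, over
    conflict-free replicates), and the conflict rate.
    """
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    sites = sorted({s for c in constructs for s in c.cleavage_sites})
    length = constructs[0].length
    partition = SegmentPartition.from_cut_sites(sites, length)
    seg_starts = {lo: i for i, (lo, hi) in enumerate(partition.segments)}
    seg_ends = {hi: i for i, (lo, hi) in enumerate(partition.segments)}
    rows = []
    for p_fn in noise_grid:
        rng = np.random.default_rng([seed, int(round(p_fn * 1_000_000))])
        noise = NoiseModel(p_false_negative=p_fn, occluders=list(occluders))
        n_exact = n_conflict = n_cases = 0
        boundary_errors: list[float] = []
        for _ in range(n_replicates):
            if truth_sampler is None:
                truth = sample_truth(rng, partition, [1])
            else:
                truth = truth_sampler(rng, partition)
            table = simulate_observations(truth, constructs, gel, noise, rng)
            for phosphate in sorted(truth.contacts):
                n_cases += 1
                assignment = infer_contacts(table.for_probe(phosphate, truth.promoter), constructs)
                true_runs = _truth_runs(truth, phosphate)
                inferred = [iv.interval for iv in assignment.intervals]
                if assignment.conflicts:
                    n_conflict += 1
                    continue
                if inferred == true_runs:
                    n_exact += 1
                errs = []
                for lo, hi in true_runs:
                    if not inferred:
                        errs.append(partition.n)
                        continue
                    errs.append(
                        min(
                            abs(seg_starts[lo] - seg_starts.get(ilo, 0))
                            + abs(seg_ends[hi] - seg_ends.get(ihi, partition.n - 1))
                            for ilo, ihi in inferred
                        )
                        / 2.0
                    )
                boundary_errors.append(float(np.mean(errs)))
        rows.append(
            {
                "p_false_negative": p_fn,
                "n_cases": n_cases,
                "recovery_fraction": n_exact / n_cases,
                "mean_boundary_error_segments": float(np.mean(boundary_errors))
                if boundary_errors
                else float("nan"),
                "conflict_rate": n_conflict / n_cases,
                "seed": seed,
            }
        )
    return pd.DataFrame(rows)
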