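# Methods

## Experimental logic being modelled

A DNA-binding protein is bound to a duplex probe carrying an
azidophenacyl photo-cross-linker on one numbered backbone phosphate
(parity rule: odd indices on the non-template strand, even on the
template strand; the phosphate-to-base-pair mapping is an explicit
`ProbeNumbering` adapter, default `bp = index`).  After UV cross-linking
the protein is cleaved with hydroxylamine at the single engineered
Asn-Gly site of the construct in use; cleavage "at residue s" produces
fragments [1, s] and [s+1, L] (residues 1-based, intervals closed).  The
radiolabeled band on a denaturing gel reports which fragment carries the
cross-link.  A panel of constructs with different single sites turns this
into an interval-bracketing assay whose resolution is the *segment grid*:
the partition of [1, L] induced by the union of cut sites of the
informative lanes.

## Inference semantics

A ground truth is a set of contacted segments.  Lane constraints:

* cross-linked fragment → at least one contacted segment inside it
  (a positive clause over its non-excluded segments);
* fragment cleanly not cross-linked → no contacted segment inside it;
* occluded band (co-migrating species, or an unresolvable co-migrating
  N/C pair) → no constraint.  Occlusion is never read as a negative.
* the full-length band only reflects incomplete digestion and is ignored.

The *specification* of the method is possible-world semantics: enumerate
all 2^n segment subsets and keep those satisfying every lane
(`brute_force_consistent_sets`, refused above 20 segments).  A segment is
`required` iff contacted in every consistent world, `excluded` iff in
none, `untested` iff no informative lane covers it, `ambiguous`
otherwise.  `propagate` computes the identical result in closed form —
negatives exclude; a cross-linked fragment whose non-excluded content is
a single segment forces it; an emptied clause is a conflict (reported
per probe, never resolved silently) — and the equivalence is enforced two
ways: a randomized property suite (propagation vs enumeration on 1000
random tables) and an `oracle=True` flag on `infer_contacts` that runs
both paths and raises on any disagreement.

Reported intervals come in two kinds.  `exact` intervals are maximal runs
of individually required segments.  `region` intervals are
containment-minimal clause spans containing no required segment: every
consistent world places a contact somewhere in the run, but the panel
cannot tighten the boundary (the "between residues 1 and 189"
conclusions, where the 168-cut lane is occluded).  Adjacent regions are
deliberately not merged — each carries its own guaranteed contact.  The
independent oracle derives regions its own way, as minimal contiguous
runs hit by every consistent world.

## Intensity grading

Band intensity is ordinal (very_weak < weak < strong); there is no
densitometry.  Because a fragment's band reflects the *maximum* grade of
the contacts it contains, the dominant contact must lie under the most
intense band of every fully resolved lane (no occlusions, lane maximum
equal to the global maximum).  Intersecting those footprints localizes
the top-graded domain; if the footprint is disjoint from every
binary-derived interval it forces a new top-grade interval — this is
exactly how a dominant middle domain (position 14) is pinned even though
binary logic alone leaves it ambiguous.  All other intervals are graded
by the lanes whose cross-linked fragment isolates them (non-excluded
content inside the interval); disagreeing replicate lanes downgrade to
the majority (ties to the stronger grade) with a recorded warning, and
intervals no lane isolates are `unresolved`.

A consequence worth stating: with single-cut constructs the N- and
C-band intensities are running maxima from either terminus, so an
interior domain that does not out-shine its flanks is *physically
invisible* to the assay, not merely unresolved.

## Gel band model

Migration is a pure function of mass: `mass = residues x 0.110 kDa`
(average residue mass; a per-residue table is used when a sequence is
supplied) plus the tag shift (+2.3 kDa N-terminal FLAG, +5.7 kDa
C-terminal, the stated approximate shifts).  Two bands are
indistinguishable below a relative tolerance of 0.05, a calibration under
which the 358-cut construct's N/C fragments co-migrate (39.4 vs 39.9 kDa
untagged; 41.7 vs 39.9 tagged, 4.2%) while the 483-cut construct's do not
(55.4 vs 26.2 kDa).  `design_tag_resolution` recommends the side-by-side
untagged/N-tagged/C-tagged experiment whenever a pair co-migrates and
reports `unresolvable` when no available shift separates it.  Anomalous
migration is out of scope.

## Helix geometry

Ideal, unbent, sequence-independent B-DNA: twist 36°/bp, rise 3.34 Å,
phosphate radius 9.4 Å, both strands' phosphates at the same bp separated
by a 154° interstrand offset across the minor groove.  For a cross-strand
pair the unwrapped helical phase `36·(bp_nt − bp_t) − 154` classifies the
pair: |phase| within the 180° window → the short path crosses the minor
groove; the window around −360° → major groove; wrapped phase beyond 150°
→ opposite faces of the duplex.  Groove spans additionally carry an
18 Å distance gate.  The windows and gate are configuration
(`GrooveThresholds`), calibrated to reproduce the qualitative
classifications (8t–11n/13n and 2t/4t–7n minor-groove spans; 19n vs 20t
opposite faces); no numeric groove measurements are claimed.  PDB export
writes one P pseudo-atom per contacted phosphate, occupancy encoding the
grade and the segment id the domain, deterministically.

## Architecture comparison

Phosphates are attributed to the display domain (N-term, Rh, Ra, Rb, Rc,
Rd, C-term — boundaries on the panel's cut sites) that maximally overlaps
their strongest interval; contacted positions whose interval is
unresolved are annotation-only.  Axial shift is the difference of mean bp
indices (positive = downstream, toward the transcription start);
rotation is the wrapped difference of circular-mean face angles, positive
in the direction of advancing twist (clockwise viewed from upstream).
The hand-rolled circular mean is validated against `scipy.stats.circmean`
in the test suite.  Domains with no contacts in one architecture get an
explicitly undefined (not zero) displacement; single-contact domains are
flagged low-confidence.

## Synthetic data

`sample_truth` draws 1–3 contacted domains per phosphate on the segment
grid, each one segment wide and mutually non-adjacent (matching the
observed pattern of distinct repeats contacting a phosphate), with
uniform ordinal intensities — except that three-domain truths make the
middle domain strictly dominant, since (see above) only a dominant
interior domain is detectable by the assay; the observed three-domain
contact is of exactly this kind.  The forward model cross-links a
fragment iff it overlaps a contacted interval, grades it by the maximum
overlapped intensity, then applies per-band false negatives, ±1-step
intensity misgrades, and occlusion whenever a configured extraneous band
co-migrates within the gel tolerance (the call becomes `occluded`,
never a false positive).  A single `numpy` generator seeded from one
integer governs all randomness.

With zero noise this forward/inverse loop is exact at segment resolution
(tested over 500 random truths), and `recovery_experiment` tabulates
exact-recovery fraction, mean boundary error (segments) and conflict rate
across a false-negative grid; recovery is non-increasing in the noise
rate.  What the simulations do *not* emulate: continuous band
intensities, partial digestion, lane-to-lane loading variation, and
anomalous migration — so passing recovery tests demonstrate the
correctness of the deductive machinery, not robustness to every gel
artifact.

## Problem sizes and numerical choices

The packaged dataset is desk-scale (16 probes × ≤11 lanes) and the
default validation sizes — 1000 random tables for oracle equivalence,
500 noiseless replicates, 200 replicates per noise level — run in seconds
while exercising every code path; enumeration is capped at 20 segments
(2^20 worlds).  Ties in majority grading resolve to the stronger grade;
strongest-interval ties resolve to the most N-terminal interval;
assignment pieces (intervals, ambiguous, excluded, untested) are checked
to tile [1, L] exactly.

## Known limitations

* Interval resolution can never exceed the segment grid; conclusions are
  only as sharp as the panel of cleavage sites.
* Weaker interior domains are undetectable in principle (running-maximum
  band physics), and cross-lane intensity comparisons assume consistent
  relative band grading between lanes.
* The helix is ideal and unbent; bent or non-B DNA would shift the
  phase-based groove calls.
* The U1 architecture fixture restates only interval conclusions that are
  textually fixed at this resolution; five of its contacted positions are
  packaged as contacted-with-unstated-interval and participate in contact
  set arithmetic but not in domain displacement estimates.
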