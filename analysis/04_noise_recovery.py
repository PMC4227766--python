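#!/usr/bin/env python
"""Validate the inference engine on simulated data across noise levels.

Draws random ground-truth contact maps on the panel's segment grid,
forward-simulates gel call tables with increasing per-band false-negative
rates, and measures how often inference recovers the truth exactly at
segment resolution.  At zero noise recovery is exact by construction; it
degrades monotonically as bands drop out and contradictory lane sets start
to surface as conflicts.
"""

from pathlib import Path

from xlinkmap import packaged
from xlinkmap.simulate import recovery_experiment

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 20140905
N_REPLICATES = 200
GRID = [0.0, 0.02, 0.05, 0.1, 0.2, 0.4]


def main() -> None:
    OUT.mkdir(exist_ok=True)
    constructs = {c.name: c for c in packaged.load_packaged_constructs()}
    panel = [constructs[n] for n in ["H", "Ha", "A", "B", "C", "D", "De", "dE", "E"]]
    df = recovery_experiment(N_REPLICATES, panel, GRID, seed=SEED)
    df.to_csv(OUT / "noise_recovery.tsv", sep="\t", index=False)
    print(f"Recovery across false-negative rates ({N_REPLICATES} replicates each):")
    print(df.to_string(index=False))
    print(
        "\nRecovery is exact at zero noise and non-increasing in the "
        "false-negative rate; dropped bands first blur interval boundaries "
        "and then produce mutually unsatisfiable lane sets (conflicts)."
    )
    print(f"Wrote {OUT/'noise_recovery.tsv'}")


if __name__ == "__main__":
    main()
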