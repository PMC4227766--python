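#!/usr/bin/env python
"""Infer the U6-promoter contact map of SNAP190 from the packaged gel calls.

For each of the 16 cross-linked phosphate positions, combines the fragment
cross-link calls of the single-cut construct panel into residue-interval
contact assignments (cross-checked against brute-force possible-world
enumeration) and writes the architecture plus a flat summary table.
"""

from pathlib import Path

import pandas as pd

from xlinkmap import packaged
from xlinkmap.datamodel import write_architecture

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    arch = packaged.infer_u6_architecture(oracle=True)
    write_architecture(arch, OUT / "u6_architecture.json")

    rows = []
    for k in packaged.U6_PHOSPHATES:
        a = arch.assignments[k]
        for iv in a.intervals:
            rows.append(
                {
                    "phosphate": k,
                    "strand": a.strand,
                    "interval": f"{iv.lo}-{iv.hi}",
                    "grade": iv.grade,
                    "certainty": iv.certainty,
                }
            )
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "u6_contact_intervals.tsv", sep="\t", index=False)

    print("U6 contact map (SNAP190), one row per inferred interval:")
    print(df.to_string(index=False))
    n_multi = df.groupby("phosphate").size().gt(1).sum()
    print(
        f"\n{df['phosphate'].nunique()} phosphate positions mapped; "
        f"{n_multi} carry more than one contacting domain "
        "(including the two-domain assignment at position 2 and the "
        "three-domain assignment at position 14)."
    )
    print(f"Wrote {OUT/'u6_architecture.json'} and {OUT/'u6_contact_intervals.tsv'}")


if __name__ == "__main__":
    main()
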