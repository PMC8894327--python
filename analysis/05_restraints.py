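#!/usr/bin/env python
"""Export docking distance restraints for accepted cross-links.

One line per accepted (prey protein, residue) pairing the bait's ncAA
position with the cross-linked nucleophile, with a configurable distance
bound (default 15 A). Output: results/restraints.tsv.
"""

import pathlib

import pandas as pd

from gecxms.io_formats import write_restraints

ROOT = pathlib.Path(__file__).resolve().parent.parent / "results"


def main():
    res = pd.read_csv(ROOT / "results.tsv", sep="\t", comment="#")
    acc = res[(res["qvalue"] <= 0.05) & (~res["is_decoy"])].copy()
    if "bait_ncaa_site_protein" not in acc.columns:
        acc["bait_ncaa_site_protein"] = acc["bait_ncaa_position"]
        acc["bait_protein"] = "BAIT"
    out = ROOT / "restraints.tsv"
    write_restraints(acc, out, distance_angstrom=15.0)
    n = len(out.read_text().splitlines()) - 2
    print(f"wrote {n} restraints for {acc['prey_protein'].nunique()} "
          f"prey proteins to {out}")


if __name__ == "__main__":
    main()
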