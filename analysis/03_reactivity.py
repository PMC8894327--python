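#!/usr/bin/env python
"""Tally accepted unique cross-linked peptides by targeted residue.

Recovers the reactivity profile of the alkyl-bromide ncAA across the eight
nucleophiles (Cys, Asp, Glu, His, Lys, Ser, Thr, Tyr) from the accepted
search results; with the generator's Cys-dominant prior the Cys bucket should
dominate. Writes results/reactivity.tsv.
"""

import pathlib

import pandas as pd

ROOT = pathlib.Path(__file__).resolve().parent.parent / "results"


def main():
    res = pd.read_csv(ROOT / "results.tsv", sep="\t", comment="#")
    acc = res[(res["qvalue"] <= 0.05) & (~res["is_decoy"])]
    uniq = acc.sort_values("score", ascending=False).drop_duplicates(
        ["bait_sequence", "prey_sequence", "prey_protein", "prey_start",
         "site_position_peptide", "bait_mods", "prey_mods"])
    unambiguous = uniq[uniq["site_ambiguous"].isna()
                       | (uniq["site_ambiguous"] == "")]
    counts = unambiguous["site_residue"].value_counts()
    table = pd.DataFrame({
        "residue": list("CDEHKSTY"),
        "unique_peptides": [int(counts.get(aa, 0)) for aa in "CDEHKSTY"],
    })
    table.to_csv(ROOT / "reactivity.tsv", sep="\t", index=False)
    cys = int(counts.get("C", 0))
    non_cys = int(sum(counts.get(aa, 0) for aa in "DEHKSTY"))
    print(table.to_string(index=False))
    print(f"\n{len(uniq)} unique cross-linked peptides "
          f"({cys} Cys, {non_cys} non-Cys, "
          f"{len(uniq) - len(unambiguous)} ambiguous site)")
    print(f"binder proteins: {uniq['prey_protein'].nunique()}")
    print(f"wrote {ROOT/'reactivity.tsv'}")


if __name__ == "__main__":
    main()
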