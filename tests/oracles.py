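"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive and self-contained: residue elemental
formulas are typed out, digestion is an exhaustive substring filter, and
candidate enumeration is an all-pairs scan. None of it shares code with the
implementation it checks.
"""

from __future__ import annotations

from typing import Dict, List, Tuple

# IUPAC monoisotopic atomic masses
ATOM = {"H": 1.00782503207, "C": 12.0, "N": 14.0030740048,
        "O": 15.99491461956, "S": 31.97207100}

# residue (i.e. dehydrated) elemental formulas of the 20 amino acids
RESIDUE_FORMULA: Dict[str, Dict[str, int]] = {
    "G": dict(C=2, H=3, N=1, O=1),
    "A": dict(C=3, H=5, N=1, O=1),
    "S": dict(C=3, H=5, N=1, O=2),
    "P": dict(C=5, H=7, N=1, O=1),
    "V": dict(C=5, H=9, N=1, O=1),
    "T": dict(C=4, H=7, N=1, O=2),
    "C": dict(C=3, H=5, N=1, O=1, S=1),
    "L": dict(C=6, H=11, N=1, O=1),
    "I": dict(C=6, H=11, N=1, O=1),
    "N": dict(C=4, H=6, N=2, O=2),
    "D": dict(C=4, H=5, N=1, O=3),
    "Q": dict(C=5, H=8, N=2, O=2),
    "K": dict(C=6, H=12, N=2, O=1),
    "E": dict(C=5, H=7, N=1, O=3),
    "M": dict(C=5, H=9, N=1, O=1, S=1),
    "H": dict(C=6, H=7, N=3, O=1),
    "F": dict(C=9, H=9, N=1, O=1),
    "R": dict(C=6, H=12, N=4, O=1),
    "Y": dict(C=9, H=9, N=1, O=2),
    "W": dict(C=11, H=10, N=2, O=1),
}


def peptide_mass_bruteforce(sequence: str) -> float:
    """Atom-by-atom elemental sum: residues plus one water."""
    total = 2 * ATOM["H"] + ATOM["O"]
    for aa in sequence:
        for el, n in RESIDUE_FORMULA[aa].items():
            total += n * ATOM[el]
    return total


def digest_bruteforce(protein: str, cleave_after: str, suppressed_before: str,
                      max_missed: int) -> set:
    """All substrings that are valid digestion products.

    A substring [i, j) qualifies iff i and j are cleavage boundaries (or the
    protein ends) and it spans at most max_missed internal uncut sites.
    """
    def is_boundary(k: int) -> bool:
        if k == 0 or k == len(protein):
            return True
        return (protein[k - 1] in cleave_after
                and protein[k] not in suppressed_before)

    out = set()
    n = len(protein)
    for i in range(n):
        for j in range(i + 1, n + 1):
            if not (is_boundary(i) and is_boundary(j)):
                continue
            internal = sum(1 for k in range(i + 1, j) if is_boundary(k))
            if internal <= max_missed:
                out.add((i + 1, j, protein[i:j], internal))
    return out


def enumerate_candidates_bruteforce(
    observed_neutral: float,
    bait_masses: List[Tuple[str, float]],
    prey_entries: List[Tuple[str, float, str, frozenset]],
    leaving_group: float,
    tol_ppm: float,
) -> set:
    """All-pairs scan: every (bait, prey, reactive site) whose conjugate mass
    matches the observed neutral within tol_ppm of the theoretical."""
    out = set()
    for bait_id, mb in bait_masses:
        for prey_id, mp, seq, reactive in prey_entries:
            total = mb + mp - leaving_group
            if abs(observed_neutral - total) <= tol_ppm * 1e-6 * total:
                for pos, aa in enumerate(seq, start=1):
                    if aa in reactive:
                        out.add((bait_id, prey_id, pos))
    return out
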