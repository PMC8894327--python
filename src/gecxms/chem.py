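"""Mass arithmetic for cross-linking MS.

Monoisotopic masses throughout (Orbitrap-style acquisition). The module owns
the mass model for cross-linked species: a bait peptide carrying an
electrophilic alkyl-halide non-canonical amino acid (ncAA) conjugated to a
prey peptide through a nucleophilic side chain, expelling the halide as HX
(HBr for an alkyl bromide), so

    M(conjugate) = m(bait, ncAA included) + m(prey) - m(leaving group).

Elemental and residue masses come from pyteomics' NIST/Unimod-derived tables;
nothing here is re-typed by hand.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Tuple

from pyteomics import mass as _pmass

__all__ = [
    "MassTable",
    "Modification",
    "CrossLinker",
    "DEFAULT_MASS_TABLE",
    "HBR_MASS",
    "NCAA_MARKER",
    "REACTIVE_RESIDUES",
    "mod_mass_from_formula",
    "parse_formula",
    "peptide_mass",
    "crosslinked_mass",
    "mz_to_neutral",
    "neutral_to_mz",
    "ppm_error",
    "carbamidomethyl",
]

#: Placeholder letter marking the ncAA position inside a peptide/protein
#: sequence. Not a member of the 20-letter alphabet, never cleaved by any
#: protease rule, and its mass is always supplied by a CrossLinker.
NCAA_MARKER = "U"

#: Nucleophilic side chains the alkyl-bromide ncAA can attack: Cys, Asp, Glu,
#: His, Lys, Ser, Thr, Tyr.
REACTIVE_RESIDUES = frozenset("CDEHKSTY")

STANDARD_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class MassTable:
    """Monoisotopic residue and atomic masses (Da)."""

    residue_masses: Mapping[str, float]
    atom_masses: Mapping[str, float]
    water_mass: float
    proton_mass: float

    def residue(self, letter: str) -> float:
        try:
            return self.residue_masses[letter]
        except KeyError:
            raise KeyError(f"unknown residue {letter!r}") from None


def _default_table() -> MassTable:
    atoms = {el: data[0][0] for el, data in _pmass.nist_mass.items()}
    residues = {aa: _pmass.std_aa_mass[aa] for aa in STANDARD_RESIDUES}
    water = 2 * atoms["H"] + atoms["O"]
    return MassTable(
        residue_masses=residues,
        atom_masses=atoms,
        water_mass=water,
        proton_mass=1.00727646677,
    )


DEFAULT_MASS_TABLE = _default_table()

#: Mass of the HBr leaving group lost on alkyl-bromide substitution.
HBR_MASS = DEFAULT_MASS_TABLE.atom_masses["H"] + DEFAULT_MASS_TABLE.atom_masses["Br"]


def parse_formula(formula: str) -> dict:
    """Parse ``"C2H3NO"`` into ``{"C": 2, "H": 3, "N": 1, "O": 1}``."""
    counts: dict = {}
    pos = 0
    for match in _FORMULA_RE.finditer(formula):
        if match.start() != pos:
            raise ValueError(f"malformed formula {formula!r} at {formula[pos:]!r}")
        pos = match.end()
        el, n = match.group(1), match.group(2)
        counts[el] = counts.get(el, 0) + (int(n) if n else 1)
    if pos != len(formula):
        raise ValueError(f"malformed formula {formula!r} at {formula[pos:]!r}")
    return counts


def mod_mass_from_formula(formula: str, table: MassTable = DEFAULT_MASS_TABLE) -> float:
    """Monoisotopic mass of an elemental composition, e.g. C2H3NO -> 57.02146."""
    total = 0.0
    for el, n in parse_formula(formula).items():
        if el not in table.atom_masses:
            raise ValueError(f"unknown element {el!r} in formula {formula!r}")
        total += n * table.atom_masses[el]
    return total


@dataclass(frozen=True)
class Modification:
    """A fixed or variable residue modification with a known mass delta."""

    name: str
    delta_mass: float
    target_residues: frozenset
    variable: bool = True

    def __post_init__(self):
        if not self.target_residues:
            raise ValueError("modification needs at least one target residue")


def carbamidomethyl(table: MassTable = DEFAULT_MASS_TABLE) -> Modification:
    """Cys +57.02146 from iodoacetamide alkylation (variable here)."""
    return Modification(
        name="carbamidomethyl",
        delta_mass=mod_mass_from_formula("C2H3NO", table),
        target_residues=frozenset("C"),
        variable=True,
    )


@dataclass(frozen=True)
class CrossLinker:
    """Alkyl-halide ncAA cross-linker chemistry.

    ncaa_residue_mass is the mass of the intact ncAA *residue* as incorporated
    into the bait chain; it is a user-supplied configuration value (no
    published constant exists for BprY) and is therefore required.
    """

    name: str
    ncaa_residue_mass: float
    leaving_group_mass: float = HBR_MASS
    reactive_residues: frozenset = REACTIVE_RESIDUES

    def __post_init__(self):
        if self.ncaa_residue_mass <= 0:
            raise ValueError("ncaa_residue_mass must be positive")
        if self.leaving_group_mass < 0:
            raise ValueError("leaving_group_mass must be non-negative")


def peptide_mass(
    sequence: str,
    mods: Sequence[Tuple[int, Modification]] = (),
    ncaa_position: Optional[int] = None,
    linker: Optional[CrossLinker] = None,
    table: MassTable = DEFAULT_MASS_TABLE,
) -> float:
    """Neutral monoisotopic mass of a (possibly modified) peptide.

    ``mods`` holds ``(position, Modification)`` pairs with 1-based positions.
    If ``ncaa_position`` (1-based) is given, that residue contributes
    ``linker.ncaa_residue_mass`` instead of its canonical residue mass.
    """
    if not sequence:
        raise ValueError("empty peptide sequence")
    if ncaa_position is not None:
        if linker is None:
            raise ValueError("ncaa_position given without a CrossLinker")
        if not 1 <= ncaa_position <= len(sequence):
            raise ValueError(f"ncaa_position {ncaa_position} outside peptide")
    total = table.water_mass
    for i, letter in enumerate(sequence, start=1):
        if ncaa_position is not None and i == ncaa_position:
            total += linker.ncaa_residue_mass
        else:
            total += table.residue(letter)
    for pos, mod in mods:
        if not 1 <= pos <= len(sequence):
            raise ValueError(f"modification position {pos} outside peptide")
        if ncaa_position is not None and pos == ncaa_position:
            raise ValueError("the ncAA position cannot carry a modification")
        if sequence[pos - 1] not in mod.target_residues:
            raise ValueError(
                f"{mod.name} does not target residue {sequence[pos - 1]!r} at {pos}"
            )
        total += mod.delta_mass
    return total


def crosslinked_mass(bait, prey, linker: CrossLinker, *,
                     bait_mods: Sequence[Tuple[int, Modification]] = (),
                     prey_mods: Sequence[Tuple[int, Modification]] = (),
                     table: MassTable = DEFAULT_MASS_TABLE) -> float:
    """Neutral mass of the covalent bait-prey conjugate.

    ``bait`` and ``prey`` are peptide records (anything with ``sequence`` and
    ``ncaa_position`` attributes). The bait must carry the ncAA; the reaction
    expels the linker's leaving group (HBr for alkyl bromide chemistry).
    """
    if getattr(bait, "ncaa_position", None) is None:
        raise ValueError("bait peptide does not contain the ncAA")
    m_bait = peptide_mass(bait.sequence, bait_mods,
                          ncaa_position=bait.ncaa_position, linker=linker,
                          table=table)
    m_prey = peptide_mass(prey.sequence, prey_mods,
                          ncaa_position=getattr(prey, "ncaa_position", None),
                          linker=linker if getattr(prey, "ncaa_position", None) else None,
                          table=table)
    return m_bait + m_prey - linker.leaving_group_mass


def mz_to_neutral(mz: float, z: int, table: MassTable = DEFAULT_MASS_TABLE) -> float:
    """Neutral mass from observed m/z at charge z (protonation model)."""
    if z < 1:
        raise ValueError(f"charge must be >= 1, got {z}")
    return z * mz - z * table.proton_mass


def neutral_to_mz(neutral: float, z: int, table: MassTable = DEFAULT_MASS_TABLE) -> float:
    if z < 1:
        raise ValueError(f"charge must be >= 1, got {z}")
    return (neutral + z * table.proton_mass) / z


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed relative mass error in parts per million."""
    if theoretical <= 0:
        raise ValueError("theoretical mass must be positive")
    return 1e6 * (observed - theoretical) / theoretical
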