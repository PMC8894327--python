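"""Post-identification summaries.

Reactivity profiling over the eight-residue nucleophile set (C, D, E, H, K,
S, T, Y), site-centred +/-15-residue motif windows with a position frequency
matrix and log-odds (inputs for external motif discovery such as MEME), and
window export. Motif discovery itself (EM over the windows) is an external
tool's job and is not reimplemented here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np

from .chem import REACTIVE_RESIDUES, STANDARD_RESIDUES
from .io_formats import ProteinRecord
from .xl_search import CrossLinkPSM

__all__ = [
    "ReactivityTable",
    "MotifWindowSet",
    "count_by_residue",
    "extract_windows",
    "export_meme_fasta",
    "WINDOW_FLANK",
    "PAD",
]

WINDOW_FLANK = 15          # residues either side of the cross-linked site
PAD = "-"                  # terminal padding character
AA_INDEX = {aa: i for i, aa in enumerate(STANDARD_RESIDUES)}


@dataclass
class ReactivityTable:
    """Unique cross-linked peptide counts per targeted residue."""

    counts: Dict[str, int]
    ambiguous: int = 0

    @property
    def total(self) -> int:
        return sum(self.counts.values()) + self.ambiguous

    @property
    def cys(self) -> int:
        return self.counts.get("C", 0)

    @property
    def non_cys(self) -> int:
        return sum(n for aa, n in self.counts.items() if aa != "C")


def count_by_residue(uniques: Sequence[CrossLinkPSM]) -> ReactivityTable:
    """Tally unique cross-linked peptides by their localized site residue.

    Peptides whose site is ambiguous (tied localization score) go into a
    separate bucket rather than being split fractionally.
    """
    counts = {aa: 0 for aa in sorted(REACTIVE_RESIDUES)}
    ambiguous = 0
    for psm in uniques:
        if psm.ambiguous_sites:
            ambiguous += 1
            continue
        residue = psm.candidate.prey.peptide.sequence[psm.candidate.prey_site - 1]
        counts[residue] = counts.get(residue, 0) + 1
    return ReactivityTable(counts=counts, ambiguous=ambiguous)


@dataclass
class MotifWindowSet:
    """Site-centred windows and their position frequency statistics.

    Windows are (2*flank+1)-mers with the cross-linked residue at the centre
    (index flank, position 16 in 1-based counting for flank=15) and '-'
    padding where the window runs off the protein terminus.
    """

    windows: List[str]
    names: List[str]
    background: np.ndarray          # length-20 residue frequencies
    pfm: np.ndarray                 # (2*flank+1, 20) observation counts
    log_odds: np.ndarray            # (2*flank+1, 20) log2 odds vs background
    flank: int = WINDOW_FLANK


def _background_frequencies(proteome: Sequence[ProteinRecord]) -> np.ndarray:
    counts = np.zeros(20)
    for rec in proteome:
        if rec.is_decoy:
            continue
        for aa in rec.sequence:
            i = AA_INDEX.get(aa)
            if i is not None:
                counts[i] += 1
    total = counts.sum()
    if total == 0:
        return np.full(20, 1 / 20)
    return counts / total


def extract_windows(
    sites: Sequence[Tuple[str, int]],
    proteome: Sequence[ProteinRecord],
    flank: int = WINDOW_FLANK,
    pseudocount: float = 1.0,
) -> MotifWindowSet:
    """Windows of +/-flank residues around each (protein id, 1-based position).

    The position frequency matrix counts non-pad residues per column; log-odds
    are log2((count + pseudocount) / (n_col + 20*pseudocount) / background).
    """
    by_id = {rec.id: rec for rec in proteome}
    width = 2 * flank + 1
    windows: List[str] = []
    names: List[str] = []
    for protein_id, pos in sites:
        rec = by_id.get(protein_id)
        if rec is None:
            raise ValueError(f"unknown protein {protein_id!r} for site {pos}")
        if not 1 <= pos <= len(rec.sequence):
            raise ValueError(
                f"site {protein_id}:{pos} outside protein of length {len(rec.sequence)}"
            )
        left = pos - 1 - flank
        right = pos + flank
        core = rec.sequence[max(left, 0):min(right, len(rec.sequence))]
        window = (PAD * max(-left, 0)) + core + (PAD * max(right - len(rec.sequence), 0))
        assert len(window) == width
        windows.append(window)
        names.append(f"{protein_id}_{pos}")

    background = _background_frequencies(proteome)
    pfm = np.zeros((width, 20))
    for window in windows:
        for col, aa in enumerate(window):
            i = AA_INDEX.get(aa)
            if i is not None:
                pfm[col, i] += 1
    n_col = pfm.sum(axis=1, keepdims=True)
    freqs = (pfm + pseudocount) / (n_col + 20 * pseudocount)
    # residues absent from the whole background have no defined odds ratio
    with np.errstate(divide="ignore", invalid="ignore"):
        log_odds = np.log2(freqs / background[None, :])
    log_odds[:, background == 0] = np.nan
    return MotifWindowSet(windows=windows, names=names, background=background,
                          pfm=pfm, log_odds=log_odds, flank=flank)


def export_meme_fasta(windowset: MotifWindowSet, path) -> None:
    """FASTA of windows with terminal pads stripped (MEME convention)."""
    with open(path, "w") as out:
        for name, window in zip(windowset.names, windowset.windows):
            out.write(f">{name}\n{window.strip(PAD)}\n")
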