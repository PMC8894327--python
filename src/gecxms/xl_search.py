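"""Cross-link search engine core.

Identifies covalent bait-prey peptide conjugates from centroided MS/MS
spectra: a mass-sorted prey index supports precursor-driven candidate
enumeration at ppm tolerance; each candidate is scored with a two-chain
binomial-tail score over HCD b/y fragments; the cross-linked prey residue is
localized by exhaustive site-variant rescoring.

Fragment model: b/y ions of both chains at charge 1-2. Any fragment whose
residue span covers its chain's cross-link position (the ncAA on the bait,
the nucleophilic site on the prey) carries the *entire* partner chain minus
the leaving group, because the conjugate bond survives HCD while the backbone
fragments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats
from scipy.special import logsumexp

from .chem import (
    CrossLinker,
    DEFAULT_MASS_TABLE,
    MassTable,
    Modification,
    mz_to_neutral,
    peptide_mass,
    ppm_error,
)
from .digestion import DigestLimits, PeptideRecord, ProteaseRule, digest
from .io_formats import ProteinRecord, SpectrumRecord

__all__ = [
    "IndexedPeptide",
    "PreyIndex",
    "CrossLinkCandidate",
    "FragmentIon",
    "CrossLinkPSM",
    "expand_variable_mods",
    "build_prey_index",
    "enumerate_candidates",
    "theoretical_fragments",
    "score_psm",
    "localize_site",
    "search_spectrum",
    "search_spectra",
]

ModList = Tuple[Tuple[int, Modification], ...]


@dataclass(frozen=True)
class IndexedPeptide:
    """A peptide plus one concrete variable-modification assignment."""

    peptide: PeptideRecord
    mods: ModList
    mass: float

    def mod_positions(self) -> frozenset:
        return frozenset(pos for pos, _ in self.mods)


@dataclass
class PreyIndex:
    """Prey peptides (targets + decoys) sorted by neutral mass."""

    entries: List[IndexedPeptide]
    masses: np.ndarray

    def __len__(self) -> int:
        return len(self.entries)

    def lookup(self, lo: float, hi: float) -> List[IndexedPeptide]:
        """All entries with mass in [lo, hi]."""
        i = int(np.searchsorted(self.masses, lo, side="left"))
        j = int(np.searchsorted(self.masses, hi, side="right"))
        return self.entries[i:j]


@dataclass(frozen=True)
class CrossLinkCandidate:
    bait: IndexedPeptide
    prey: IndexedPeptide
    prey_site: int  # 1-based within the prey peptide
    theoretical_mass: float


@dataclass(frozen=True)
class FragmentIon:
    chain: str        # "bait" | "prey"
    series: str       # "b" | "y"
    ordinal: int
    charge: int
    carries_partner: bool
    mz: float


@dataclass
class CrossLinkPSM:
    scan_id: str
    candidate: CrossLinkCandidate
    score: float
    matched_bait: int
    matched_prey: int
    theoretical_bait: int
    theoretical_prey: int
    intensity_fraction_bait: float
    intensity_fraction_prey: float
    precursor_ppm: float
    precursor_charge: int
    site_delta_score: float = math.inf
    ambiguous_sites: Tuple[int, ...] = ()
    qvalue: Optional[float] = None

    @property
    def is_decoy(self) -> bool:
        return self.candidate.prey.peptide.is_decoy


def expand_variable_mods(
    peptide: PeptideRecord,
    variable_mods: Sequence[Modification],
    max_mods: int = 3,
) -> List[ModList]:
    """All variable-mod assignments (including none), capped at max_mods.

    The ncAA position never carries a modification.
    """
    from itertools import combinations

    slots: List[Tuple[int, Modification]] = []
    for mod in variable_mods:
        for i, letter in enumerate(peptide.sequence, start=1):
            if peptide.ncaa_position is not None and i == peptide.ncaa_position:
                continue
            if letter in mod.target_residues:
                slots.append((i, mod))
    assignments: List[ModList] = [()]
    for k in range(1, min(max_mods, len(slots)) + 1):
        for combo in combinations(slots, k):
            positions = [pos for pos, _ in combo]
            if len(set(positions)) != len(positions):
                continue
            assignments.append(tuple(sorted(combo, key=lambda pm: pm[0])))
    return assignments


def build_prey_index(
    db: Sequence[ProteinRecord],
    rule: ProteaseRule,
    linker: CrossLinker,
    variable_mods: Sequence[Modification] = (),
    limits: Optional[DigestLimits] = DigestLimits(),
    max_mods: int = 3,
    min_mass: Optional[float] = 500.0,
    max_mass: Optional[float] = 6000.0,
    table: MassTable = DEFAULT_MASS_TABLE,
) -> PreyIndex:
    """Digest the database and index peptides carrying >=1 reactive residue."""
    if not db:
        raise ValueError("empty protein database")
    entries: List[IndexedPeptide] = []
    for protein in db:
        for pep in digest(protein.sequence, rule, protein_id=protein.id,
                          limits=limits, is_decoy=protein.is_decoy):
            if not any(r in linker.reactive_residues for r in pep.sequence):
                continue
            for mods in expand_variable_mods(pep, variable_mods, max_mods):
                m = peptide_mass(pep.sequence, mods, table=table)
                if min_mass is not None and m < min_mass:
                    continue
                if max_mass is not None and m > max_mass:
                    continue
                entries.append(IndexedPeptide(peptide=pep, mods=mods, mass=m))
    entries.sort(key=lambda e: (e.mass, e.peptide.protein_id, e.peptide.start,
                                e.peptide.sequence, len(e.mods)))
    return PreyIndex(entries=entries,
                     masses=np.array([e.mass for e in entries], dtype=float))


def candidate_sites(prey: IndexedPeptide, linker: CrossLinker) -> List[int]:
    """Reactive positions in the prey; a carbamidomethylated Cys is blocked."""
    blocked = prey.mod_positions()
    return [i for i, letter in enumerate(prey.peptide.sequence, start=1)
            if letter in linker.reactive_residues and i not in blocked]


def enumerate_candidates(
    spectrum: SpectrumRecord,
    bait_variants: Sequence[IndexedPeptide],
    index: PreyIndex,
    linker: CrossLinker,
    tol_ppm: float = 10.0,
    table: MassTable = DEFAULT_MASS_TABLE,
) -> List[CrossLinkCandidate]:
    """Candidates whose conjugate mass matches the precursor within tol_ppm."""
    observed = mz_to_neutral(spectrum.precursor_mz, spectrum.precursor_charge,
                             table)
    out: List[CrossLinkCandidate] = []
    f = tol_ppm * 1e-6
    for bait in bait_variants:
        # |obs - M| <= f*M  =>  M in [obs/(1+f), obs/(1-f)]
        lo = observed / (1 + f) - bait.mass + linker.leaving_group_mass
        hi = observed / (1 - f) - bait.mass + linker.leaving_group_mass
        for prey in index.lookup(lo, hi):
            total = bait.mass + prey.mass - linker.leaving_group_mass
            if abs(observed - total) > f * total:
                continue
            for site in candidate_sites(prey, linker):
                out.append(CrossLinkCandidate(
                    bait=bait, prey=prey, prey_site=site,
                    theoretical_mass=total,
                ))
    return out


def _chain_residue_masses(entry: IndexedPeptide, linker: CrossLinker,
                          table: MassTable) -> np.ndarray:
    seq = entry.peptide.sequence
    masses = np.empty(len(seq))
    for i, letter in enumerate(seq):
        if entry.peptide.ncaa_position is not None and i + 1 == entry.peptide.ncaa_position:
            masses[i] = linker.ncaa_residue_mass
        else:
            masses[i] = table.residue(letter)
    for pos, mod in entry.mods:
        masses[pos - 1] += mod.delta_mass
    return masses


def _chain_fragments(
    chain: str,
    entry: IndexedPeptide,
    link_site: int,
    partner_mass: float,
    linker: CrossLinker,
    table: MassTable,
    fragment_charges: Sequence[int],
) -> List[FragmentIon]:
    residues = _chain_residue_masses(entry, linker, table)
    n = len(residues)
    prefix = np.concatenate([[0.0], np.cumsum(residues)])
    partner_add = partner_mass - linker.leaving_group_mass
    ions: List[FragmentIon] = []
    for k in range(1, n):
        b_neutral = prefix[k]
        y_neutral = (prefix[n] - prefix[n - k]) + table.water_mass
        b_covers = link_site <= k
        y_covers = link_site > n - k
        for series, neutral, covers in (("b", b_neutral, b_covers),
                                        ("y", y_neutral, y_covers)):
            if covers:
                neutral = neutral + partner_add
            for z in fragment_charges:
                ions.append(FragmentIon(
                    chain=chain, series=series, ordinal=k, charge=z,
                    carries_partner=covers,
                    mz=(neutral + z * table.proton_mass) / z,
                ))
    return ions


def theoretical_fragments(
    candidate: CrossLinkCandidate,
    linker: CrossLinker,
    table: MassTable = DEFAULT_MASS_TABLE,
    fragment_charges: Sequence[int] = (1, 2),
) -> List[FragmentIon]:
    """b/y ions of both chains; site-covering fragments carry the partner."""
    bait_site = candidate.bait.peptide.ncaa_position
    if bait_site is None:
        raise ValueError("bait peptide lacks an ncAA position")
    ions = _chain_fragments("bait", candidate.bait, bait_site,
                            candidate.prey.mass, linker, table, fragment_charges)
    ions += _chain_fragments("prey", candidate.prey, candidate.prey_site,
                             candidate.bait.mass, linker, table, fragment_charges)
    return ions


def _match_ions(ions: List[FragmentIon], spectrum: SpectrumRecord,
                tol_ppm: float) -> Dict[int, int]:
    """Greedy unique ion->peak matching; returns {ion index: peak index}.

    Both sides sorted ascending; each ion takes the lowest unused peak in its
    window — the optimal greedy for interval bipartite matching, so matched
    counts are monotone in peak count and tolerance.
    """
    order = sorted(range(len(ions)), key=lambda i: ions[i].mz)
    used = set()
    assignment: Dict[int, int] = {}
    mzs = spectrum.mz
    for idx in order:
        mz = ions[idx].mz
        half = tol_ppm * 1e-6 * mz
        j = int(np.searchsorted(mzs, mz - half, side="left"))
        while j < len(mzs) and mzs[j] <= mz + half:
            if j not in used:
                used.add(j)
                assignment[idx] = j
                break
            j += 1
    return assignment


def _match_probability(spectrum: SpectrumRecord, ions: List[FragmentIon],
                       tol_ppm: float) -> float:
    if spectrum.n_peaks == 0 or not ions:
        return 0.0
    span = max(float(spectrum.mz[-1] - spectrum.mz[0]), 100.0)
    mean_mz = float(np.mean([ion.mz for ion in ions]))
    p = spectrum.n_peaks * 2.0 * tol_ppm * 1e-6 * mean_mz / span
    return float(min(max(p, 1e-6), 0.5))


def _chain_score(k: int, n: int, p: float) -> float:
    # -log10 P[Binom(n, p) >= k], evaluated in log space so that scores do
    # not saturate for near-complete fragment matches
    if k == 0 or n == 0 or p <= 0:
        return 0.0
    support = np.arange(k, n + 1)
    log_tail = logsumexp(stats.binom.logpmf(support, n, p))
    return float(-log_tail / math.log(10))


def score_psm(
    spectrum: SpectrumRecord,
    candidate: CrossLinkCandidate,
    linker: CrossLinker,
    frag_tol_ppm: float = 20.0,
    table: MassTable = DEFAULT_MASS_TABLE,
    fragment_charges: Sequence[int] = (1, 2),
) -> CrossLinkPSM:
    """Two-chain binomial-tail score of a candidate against a spectrum.

    Per chain: with N theoretical ions, k matched within tolerance, and
    per-ion chance match probability p estimated from spectrum peak density,
    the chain score is -log10 P[Binom(N, p) >= k]; the PSM score is the sum
    over the two chains.
    """
    ions = theoretical_fragments(candidate, linker, table, fragment_charges)
    assignment = _match_ions(ions, spectrum, frag_tol_ppm)
    p = _match_probability(spectrum, ions, frag_tol_ppm)

    totals = {"bait": 0, "prey": 0}
    matched = {"bait": 0, "prey": 0}
    matched_intensity = {"bait": 0.0, "prey": 0.0}
    for i, ion in enumerate(ions):
        totals[ion.chain] += 1
        if i in assignment:
            matched[ion.chain] += 1
            matched_intensity[ion.chain] += float(spectrum.intensity[assignment[i]])
    total_intensity = float(spectrum.intensity.sum()) or 1.0

    score = (_chain_score(matched["bait"], totals["bait"], p)
             + _chain_score(matched["prey"], totals["prey"], p))
    return CrossLinkPSM(
        scan_id=spectrum.scan_id,
        candidate=candidate,
        score=score,
        matched_bait=matched["bait"],
        matched_prey=matched["prey"],
        theoretical_bait=totals["bait"],
        theoretical_prey=totals["prey"],
        intensity_fraction_bait=matched_intensity["bait"] / total_intensity,
        intensity_fraction_prey=matched_intensity["prey"] / total_intensity,
        precursor_ppm=ppm_error(
            mz_to_neutral(spectrum.precursor_mz, spectrum.precursor_charge, table),
            candidate.theoretical_mass,
        ),
        precursor_charge=spectrum.precursor_charge,
    )


def localize_site(psms: Sequence[CrossLinkPSM]) -> CrossLinkPSM:
    """Pick the best site among variants of one (bait, prey, mods) pair.

    Returns the winning PSM with site_delta_score = best - second best; a tie
    (delta == 0) reports all tied sites as ambiguous. A single variant has
    delta = +inf (nothing to confuse it with).
    """
    if not psms:
        raise ValueError("localize_site needs at least one scored variant")
    ranked = sorted(psms, key=lambda m: (-m.score, m.candidate.prey_site))
    best = ranked[0]
    if len(ranked) == 1:
        best.site_delta_score = math.inf
        best.ambiguous_sites = ()
        return best
    delta = best.score - ranked[1].score
    best.site_delta_score = delta
    if delta == 0:
        best.ambiguous_sites = tuple(m.candidate.prey_site for m in ranked
                                     if m.score == best.score)
    else:
        best.ambiguous_sites = ()
    return best


def _group_key(candidate: CrossLinkCandidate) -> tuple:
    prey = candidate.prey
    return (
        candidate.bait.peptide.sequence,
        tuple((pos, mod.name) for pos, mod in candidate.bait.mods),
        prey.peptide.protein_id, prey.peptide.start, prey.peptide.sequence,
        tuple((pos, mod.name) for pos, mod in prey.mods),
    )


def search_spectrum(
    spectrum: SpectrumRecord,
    bait_variants: Sequence[IndexedPeptide],
    index: PreyIndex,
    linker: CrossLinker,
    precursor_ppm: float = 10.0,
    frag_tol_ppm: float = 20.0,
    table: MassTable = DEFAULT_MASS_TABLE,
    require_both_chains: bool = True,
    fragment_charges: Sequence[int] = (1, 2),
) -> Optional[CrossLinkPSM]:
    """Best (rank-1) cross-link PSM for one spectrum, or None."""
    candidates = enumerate_candidates(spectrum, bait_variants, index, linker,
                                      precursor_ppm, table)
    if not candidates:
        return None
    groups: Dict[tuple, List[CrossLinkPSM]] = {}
    for cand in candidates:
        psm = score_psm(spectrum, cand, linker, frag_tol_ppm, table,
                        fragment_charges)
        groups.setdefault(_group_key(cand), []).append(psm)
    finalists = [localize_site(group) for group in groups.values()]
    if require_both_chains:
        finalists = [m for m in finalists
                     if m.matched_bait >= 1 and m.matched_prey >= 1]
    if not finalists:
        return None
    finalists.sort(key=lambda m: (
        -m.score,
        abs(m.precursor_ppm),
        m.candidate.bait.peptide.sequence,
        m.candidate.prey.peptide.sequence,
        m.candidate.prey.peptide.protein_id,
        m.candidate.prey_site,
    ))
    return finalists[0]


def search_spectra(
    spectra: Sequence[SpectrumRecord],
    bait_variants: Sequence[IndexedPeptide],
    index: PreyIndex,
    linker: CrossLinker,
    precursor_ppm: float = 10.0,
    frag_tol_ppm: float = 20.0,
    table: MassTable = DEFAULT_MASS_TABLE,
    require_both_chains: bool = True,
    fragment_charges: Sequence[int] = (1, 2),
) -> List[CrossLinkPSM]:
    """Rank-1 PSM per spectrum (spectra without a credible candidate drop out)."""
    out = []
    for spectrum in spectra:
        psm = search_spectrum(spectrum, bait_variants, index, linker,
                              precursor_ppm, frag_tol_ppm, table,
                              require_both_chains, fragment_charges)
        if psm is not None:
            out.append(psm)
    return out


def make_bait_variants(
    bait_peptides: Sequence[PeptideRecord],
    linker: CrossLinker,
    variable_mods: Sequence[Modification] = (),
    max_mods: int = 3,
    table: MassTable = DEFAULT_MASS_TABLE,
) -> List[IndexedPeptide]:
    """Bait peptides expanded over variable mods, with conjugation-ready masses."""
    out: List[IndexedPeptide] = []
    for pep in bait_peptides:
        if pep.ncaa_position is None:
            raise ValueError(f"bait peptide {pep.sequence!r} lacks the ncAA")
        for mods in expand_variable_mods(pep, variable_mods, max_mods):
            m = peptide_mass(pep.sequence, mods, ncaa_position=pep.ncaa_position,
                            linker=linker, table=table)
            out.append(IndexedPeptide(peptide=pep, mods=mods, mass=m))
    return out
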