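"""Synthetic GECX-MS runs with ground truth.

Generates random proteomes, a bait construct carrying the alkyl-bromide ncAA,
implanted bait-prey cross-links drawn from a Cys-dominant reactivity prior
over the eight nucleophiles, and noisy centroided HCD spectra (b/y ions of
both chains, partner-carrying fragments, exponential rank-decay intensities,
fragment dropout, ppm-scale mass error, uniform noise peaks, and background
spectra from linear peptides), together with a manifest linking every scan to
its implanted link or to background.

Everything is driven by one integer seed through a single numpy Generator;
outputs are byte-identical across runs with the same config.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .chem import (
    CrossLinker,
    DEFAULT_MASS_TABLE,
    MassTable,
    mod_mass_from_formula,
    neutral_to_mz,
    peptide_mass,
)
from .digestion import PeptideRecord, digest, generate_bait_peptides, trypsin
from .io_formats import ProteinRecord, SpectrumRecord, write_fasta, write_mgf
from .xl_search import CrossLinkCandidate, IndexedPeptide, theoretical_fragments

__all__ = [
    "SimConfig",
    "TrueLink",
    "GroundTruth",
    "SimBundle",
    "default_ncaa_residue_mass",
    "simulate_proteome",
    "implant_crosslinks",
    "render_spectra",
    "simulate_run",
    "write_run",
]

# Average proteome residue frequencies (UniProt-style composition); used for
# both random protein generation and as the generator's stated composition
# model.
RESIDUE_FREQUENCIES: Dict[str, float] = {
    "A": 0.0826, "R": 0.0553, "N": 0.0406, "D": 0.0546, "C": 0.0137,
    "Q": 0.0393, "E": 0.0674, "G": 0.0708, "H": 0.0227, "I": 0.0593,
    "L": 0.0965, "K": 0.0582, "M": 0.0241, "F": 0.0386, "P": 0.0472,
    "S": 0.0660, "T": 0.0535, "W": 0.0110, "Y": 0.0292, "V": 0.0687,
}

#: Cys-dominant reactivity prior over the nucleophile set: Cys carries most
#: of the cross-linking probability, the remaining seven nucleophiles share
#: the rest evenly (qualitative shape of observed GECX-MS reactivity).
DEFAULT_REACTIVITY_WEIGHTS: Dict[str, float] = {
    "C": 0.70, **{aa: 0.30 / 7 for aa in "DEHKSTY"},
}


def default_ncaa_residue_mass(table: MassTable = DEFAULT_MASS_TABLE) -> float:
    """Residue mass of a plausible O-(3-bromopropyl)-tyrosine ncAA.

    Synthetic stand-in for an alkyl-bromide ncAA: tyrosine residue plus a
    3-bromopropyl ether (+C3H5Br). Real analyses must supply the measured
    residue mass of their ncAA.
    """
    return table.residue_masses["Y"] + mod_mass_from_formula("C3H5Br", table)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic run."""

    seed: int = 7
    n_proteins: int = 200
    protein_length_mean: float = 300.0
    protein_length_sd: float = 80.0
    protein_length_min: int = 60
    n_true_links: int = 150
    reactivity_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_REACTIVITY_WEIGHTS))
    fragment_dropout_prob: float = 0.15
    mz_noise_ppm_sd: float = 3.0
    mean_noise_peaks: float = 30.0
    background_spectra_fraction: float = 0.5
    charge_min: int = 3
    charge_max: int = 7
    entrapment_fraction: float = 0.0
    plant_cxxc: bool = False
    plant_fraction: float = 0.7
    bait_length: int = 120
    ncaa_residue_mass: Optional[float] = None  # None -> default_ncaa_residue_mass()
    fragment_mz_min: float = 150.0
    fragment_mz_max: float = 2000.0

    def __post_init__(self):
        total = sum(self.reactivity_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"reactivity weights sum to {total}, expected 1")
        for name in ("fragment_dropout_prob", "background_spectra_fraction",
                     "entrapment_fraction", "plant_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 1 <= self.charge_min <= self.charge_max:
            raise ValueError("invalid precursor charge range")

    def linker(self, table: MassTable = DEFAULT_MASS_TABLE) -> CrossLinker:
        mass = self.ncaa_residue_mass
        if mass is None:
            mass = default_ncaa_residue_mass(table)
        return CrossLinker(name="alkyl-bromide-ncAA", ncaa_residue_mass=mass)


def noiseless_config(seed: int = 7, **overrides) -> "SimConfig":
    """The ideal-spectrum limit: no dropout, no mass error, no noise peaks,
    no background scans, and no detector m/z truncation. In this limit every
    implanted link is mathematically recoverable at rank 1 with its true
    site; it is the reference condition for round-trip tests.
    """
    params = dict(
        seed=seed,
        fragment_dropout_prob=0.0,
        mz_noise_ppm_sd=0.0,
        mean_noise_peaks=0.0,
        background_spectra_fraction=0.0,
        fragment_mz_min=0.0,
        fragment_mz_max=float("inf"),
    )
    params.update(overrides)
    return SimConfig(**params)


@dataclass(frozen=True)
class TrueLink:
    prey: PeptideRecord
    site: int  # 1-based within prey peptide

    @property
    def site_residue(self) -> str:
        return self.prey.sequence[self.site - 1]

    @property
    def site_protein_position(self) -> int:
        return self.prey.start + self.site - 1


@dataclass
class GroundTruth:
    bait_peptide: PeptideRecord
    links: List[TrueLink]
    # scan_id -> index into links, or -1 for background
    scans: Dict[str, int] = field(default_factory=dict)


@dataclass
class SimBundle:
    """Everything one synthetic run produced, in memory."""

    config: SimConfig
    proteins: List[ProteinRecord]        # prey database incl. entrapment
    bait: ProteinRecord
    ncaa_site: int
    truth: GroundTruth
    spectra: List[SpectrumRecord]
    truth_table: pd.DataFrame


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    letters = np.array(list(RESIDUE_FREQUENCIES))
    probs = np.array(list(RESIDUE_FREQUENCIES.values()))
    probs = probs / probs.sum()
    return "".join(rng.choice(letters, size=length, p=probs))


def _plant_cxxc(sequence: str, rng: np.random.Generator, fraction: float) -> str:
    """Force a Cys three residues downstream of existing Cys sites.

    Skips replacements that would touch K/R/P (to leave the tryptic cleavage
    pattern untouched) or an existing Cys.
    """
    seq = list(sequence)
    for i, aa in enumerate(sequence):
        if aa != "C" or i + 3 >= len(seq):
            continue
        if seq[i + 3] in "KRPC":
            continue
        if rng.random() < fraction:
            seq[i + 3] = "C"
    return "".join(seq)


def simulate_proteome(config: SimConfig, rng: Optional[np.random.Generator] = None
                      ) -> Tuple[List[ProteinRecord], ProteinRecord, int]:
    """Random prey proteome plus a bait construct with a usable ncAA site."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    proteins: List[ProteinRecord] = []
    for i in range(config.n_proteins):
        length = max(config.protein_length_min,
                     int(round(rng.normal(config.protein_length_mean,
                                          config.protein_length_sd))))
        seq = _random_sequence(rng, length)
        if config.plant_cxxc:
            seq = _plant_cxxc(seq, rng, config.plant_fraction)
        proteins.append(ProteinRecord(id=f"SYN{i + 1:04d}",
                                      description="synthetic prey protein",
                                      sequence=seq))
    # bait: regenerate until a mid-length tryptic peptide can host the ncAA
    for _ in range(100):
        bait_seq = _random_sequence(rng, config.bait_length)
        hosts = [pep for pep in digest(bait_seq, trypsin(0), limits=None)
                 if 8 <= len(pep.sequence) <= 25]
        candidates = []
        for pep in hosts:
            for j, aa in enumerate(pep.sequence[1:-1], start=2):
                if aa not in "KR":
                    candidates.append(pep.start + j - 1)
        if candidates:
            ncaa_site = int(candidates[rng.integers(len(candidates))])
            bait = ProteinRecord(id="BAIT", description="synthetic bait construct",
                                 sequence=bait_seq)
            return proteins, bait, ncaa_site
    raise RuntimeError("could not place an ncAA site in the bait construct")


def _prey_site_pool(proteins: Sequence[ProteinRecord], linker: CrossLinker,
                    table: MassTable) -> Dict[str, List[Tuple[PeptideRecord, int]]]:
    """Digest-compatible (peptide, site) pairs grouped by site residue.

    Zero-missed tryptic peptides of 6-40 residues whose mass falls safely
    inside standard index mass bounds, so every implanted link is findable.
    """
    pool: Dict[str, List[Tuple[PeptideRecord, int]]] = {
        aa: [] for aa in sorted(linker.reactive_residues)}
    for protein in proteins:
        for pep in digest(protein.sequence, trypsin(0), protein_id=protein.id,
                          limits=None):
            if not 6 <= len(pep.sequence) <= 40:
                continue
            mass = peptide_mass(pep.sequence, table=table)
            if not 520.0 <= mass <= 5800.0:
                continue
            for j, aa in enumerate(pep.sequence, start=1):
                if aa in linker.reactive_residues:
                    pool[aa].append((pep, j))
    return pool


def implant_crosslinks(
    proteins: Sequence[ProteinRecord],
    bait: ProteinRecord,
    ncaa_site: int,
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
    table: MassTable = DEFAULT_MASS_TABLE,
) -> GroundTruth:
    """Sample distinct (prey peptide, site) links under the reactivity prior."""
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    linker = config.linker(table)
    baits = [pep for pep in generate_bait_peptides(bait.sequence, ncaa_site,
                                                   trypsin(0), protein_id=bait.id,
                                                   limits=None)
             if pep.missed_cleavages == 0]
    if len(baits) != 1:
        raise RuntimeError("expected exactly one zero-missed bait peptide")
    pool = _prey_site_pool(proteins, linker, table)
    available = sum(len(v) for v in pool.values())
    if config.n_true_links > available:
        raise ValueError(
            f"requested {config.n_true_links} links but only {available} "
            "digest-compatible (peptide, site) pairs exist")
    links: List[TrueLink] = []
    for _ in range(config.n_true_links):
        residues = [aa for aa in pool if pool[aa]]
        weights = np.array([config.reactivity_weights.get(aa, 0.0)
                            for aa in residues])
        if weights.sum() == 0:
            weights = np.ones(len(residues))
        weights = weights / weights.sum()
        aa = residues[int(rng.choice(len(residues), p=weights))]
        k = int(rng.integers(len(pool[aa])))
        pep, site = pool[aa].pop(k)
        links.append(TrueLink(prey=pep, site=site))
    return GroundTruth(bait_peptide=baits[0], links=links)


def _linear_fragment_mzs(sequence: str, table: MassTable,
                         charges=(1, 2)) -> np.ndarray:
    residues = np.array([table.residue(aa) for aa in sequence])
    prefix = np.cumsum(residues)
    total = prefix[-1] + table.water_mass
    mzs = []
    for k in range(1, len(sequence)):
        b = prefix[k - 1]
        y = total - prefix[k - 1]
        for z in charges:
            mzs.append((b + z * table.proton_mass) / z)
            mzs.append((y + z * table.proton_mass) / z)
    return np.array(mzs)


def _render_one(mzs: np.ndarray, config: SimConfig,
                rng: np.random.Generator) -> Tuple[np.ndarray, np.ndarray]:
    """Apply the intensity/dropout/noise model to theoretical fragment m/z."""
    keep = (mzs >= config.fragment_mz_min) & (mzs <= config.fragment_mz_max)
    mzs = mzs[keep]
    n = mzs.size
    # exponential rank decay: a random permutation assigns ranks
    ranks = rng.permutation(n)
    intensity = 1000.0 * np.exp(-ranks / max(n / 3.0, 1.0))
    if config.fragment_dropout_prob > 0:
        survive = rng.random(n) >= config.fragment_dropout_prob
        mzs, intensity = mzs[survive], intensity[survive]
    if config.mz_noise_ppm_sd > 0:
        mzs = mzs * (1.0 + rng.normal(0.0, config.mz_noise_ppm_sd, mzs.size) * 1e-6)
    n_noise = int(rng.poisson(config.mean_noise_peaks)) if config.mean_noise_peaks > 0 else 0
    if n_noise:
        noise_mz = rng.uniform(config.fragment_mz_min, config.fragment_mz_max, n_noise)
        noise_int = rng.exponential(50.0, n_noise)
        mzs = np.concatenate([mzs, noise_mz])
        intensity = np.concatenate([intensity, noise_int])
    return mzs, intensity


def render_spectra(
    truth: GroundTruth,
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
    table: MassTable = DEFAULT_MASS_TABLE,
    background_pool: Optional[Sequence[PeptideRecord]] = None,
) -> Tuple[List[SpectrumRecord], pd.DataFrame]:
    """Noisy MS/MS spectra for every implanted link plus background scans."""
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    linker = config.linker(table)
    bait_mass = peptide_mass(truth.bait_peptide.sequence,
                             ncaa_position=truth.bait_peptide.ncaa_position,
                             linker=linker, table=table)
    bait_entry = IndexedPeptide(peptide=truth.bait_peptide, mods=(),
                                mass=bait_mass)

    f = config.background_spectra_fraction
    n_background = int(round(len(truth.links) * f / (1.0 - f))) if f < 1 else \
        max(len(truth.links), 1)
    jobs: List[int] = list(range(len(truth.links))) + [-1] * n_background
    if f >= 1:
        jobs = [-1] * n_background
    order = rng.permutation(len(jobs))

    spectra: List[SpectrumRecord] = []
    rows = []
    for scan_no, job_idx in enumerate(order, start=1):
        job = jobs[int(job_idx)]
        scan_id = f"scan={scan_no:06d}"
        z = int(rng.integers(config.charge_min, config.charge_max + 1))
        if job >= 0:
            link = truth.links[job]
            prey_entry = IndexedPeptide(
                peptide=link.prey, mods=(),
                mass=peptide_mass(link.prey.sequence, table=table))
            total = bait_entry.mass + prey_entry.mass - linker.leaving_group_mass
            cand = CrossLinkCandidate(bait=bait_entry, prey=prey_entry,
                                      prey_site=link.site, theoretical_mass=total)
            mzs = np.array([ion.mz for ion in
                            theoretical_fragments(cand, linker, table)])
            kind = "link"
        else:
            if background_pool:
                pep = background_pool[int(rng.integers(len(background_pool)))]
                mzs = _linear_fragment_mzs(pep.sequence, table)
                total = peptide_mass(pep.sequence, table=table)
            else:
                total = float(rng.uniform(1500.0, 5000.0))
                mzs = np.array([])
            link = None
            kind = "background"
        peak_mz, peak_int = _render_one(mzs, config, rng)
        precursor_ppm = (rng.normal(0.0, config.mz_noise_ppm_sd)
                         if config.mz_noise_ppm_sd > 0 else 0.0)
        precursor_mz = neutral_to_mz(total * (1.0 + precursor_ppm * 1e-6), z, table)
        spectra.append(SpectrumRecord(
            scan_id=scan_id, precursor_mz=precursor_mz, precursor_charge=z,
            mz=peak_mz, intensity=peak_int))
        truth.scans[scan_id] = job
        rows.append({
            "scan_id": scan_id,
            "kind": kind,
            "link_id": job if job >= 0 else -1,
            "bait_sequence": truth.bait_peptide.sequence if link else "",
            "prey_sequence": link.prey.sequence if link else "",
            "prey_protein": link.prey.protein_id if link else "",
            "prey_start": link.prey.start if link else -1,
            "site_position_peptide": link.site if link else -1,
            "site_position_protein": link.site_protein_position if link else -1,
            "site_residue": link.site_residue if link else "",
            "charge": z,
            "neutral_mass": total,
        })
    return spectra, pd.DataFrame(rows)


def add_entrapment(proteins: Sequence[ProteinRecord], fraction: float,
                   rng: np.random.Generator) -> List[ProteinRecord]:
    """Append residue-shuffled copies (absent from truth) as entrapment."""
    out = list(proteins)
    n = int(round(fraction * len(proteins)))
    picks = rng.choice(len(proteins), size=n, replace=False) if n else []
    for j, i in enumerate(sorted(int(x) for x in np.atleast_1d(picks))):
        shuffled = "".join(np.array(list(proteins[i].sequence))[
            rng.permutation(len(proteins[i].sequence))])
        out.append(ProteinRecord(id=f"ENTRAP{j + 1:04d}",
                                 description="shuffled entrapment sequence",
                                 sequence=shuffled))
    return out


def simulate_run(config: SimConfig,
                 table: MassTable = DEFAULT_MASS_TABLE) -> SimBundle:
    """Full synthetic run: proteome, implanted links, spectra, manifest."""
    rng = np.random.default_rng(config.seed)
    proteins, bait, ncaa_site = simulate_proteome(config, rng)
    truth = implant_crosslinks(proteins, bait, ncaa_site, config, rng, table)
    # background scans re-use linear target peptides (what an unassigned
    # spectrum in a real run mostly is); missed cleavages included because
    # the larger peptides are what charge-3+ precursor selection picks up
    background_pool = [pep for protein in proteins
                       for pep in digest(protein.sequence, trypsin(3),
                                         protein_id=protein.id, limits=None)
                       if 12 <= len(pep.sequence) <= 60]
    spectra, truth_table = render_spectra(truth, config, rng, table,
                                          background_pool=background_pool)
    db = add_entrapment(proteins, config.entrapment_fraction, rng) \
        if config.entrapment_fraction > 0 else list(proteins)
    return SimBundle(config=config, proteins=db, bait=bait,
                     ncaa_site=ncaa_site, truth=truth, spectra=spectra,
                     truth_table=truth_table)


def write_run(bundle: SimBundle, outdir) -> Dict[str, str]:
    """Write db.fasta, bait.fasta, run.mgf, truth.tsv, config.used.json."""
    import json
    import os

    os.makedirs(outdir, exist_ok=True)
    paths = {
        "db": os.path.join(outdir, "db.fasta"),
        "bait": os.path.join(outdir, "bait.fasta"),
        "mgf": os.path.join(outdir, "run.mgf"),
        "truth": os.path.join(outdir, "truth.tsv"),
        "config": os.path.join(outdir, "config.used.json"),
    }
    write_fasta(bundle.proteins, paths["db"])
    write_fasta([bundle.bait], paths["bait"])
    write_mgf(bundle.spectra, paths["mgf"])
    bundle.truth_table.to_csv(paths["truth"], sep="\t", index=False,
                              float_format="%.6f")
    cfg = {k: (dict(v) if isinstance(v, Mapping) else v)
           for k, v in vars(bundle.config).items()}
    cfg["ncaa_site"] = bundle.ncaa_site
    cfg["resolved_ncaa_residue_mass"] = bundle.config.linker().ncaa_residue_mass
    with open(paths["config"], "w") as out:
        json.dump(cfg, out, indent=2, sort_keys=True)
        out.write("\n")
    return paths
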