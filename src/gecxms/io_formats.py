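"""Readers/writers for the formats the pipeline touches.

FASTA, MGF and mzML parsing are delegated to pyteomics; this module enforces
the pipeline's type invariants on load (sorted peaks, unique protein ids,
uppercase sequences) and owns the tab-separated results/restraints formats.
MGF is the interchange format for spectra (text, diffable); mzML is supported
read-only.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from pyteomics import fasta as _pfasta
from pyteomics import mgf as _pmgf

__all__ = [
    "ProteinRecord",
    "SpectrumRecord",
    "DECOY_PREFIX",
    "RESULTS_VERSION",
    "RESULTS_COLUMNS",
    "read_fasta",
    "write_fasta",
    "make_decoys",
    "read_mgf",
    "write_mgf",
    "read_mzml",
    "write_results",
    "read_results",
    "write_restraints",
]

DECOY_PREFIX = "DECOY_"


@dataclass(frozen=True)
class ProteinRecord:
    id: str
    description: str
    sequence: str
    is_decoy: bool = False

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"protein {self.id!r} has an empty sequence")


@dataclass
class SpectrumRecord:
    """One centroided MS/MS spectrum. Peaks are kept sorted by m/z."""

    scan_id: str
    precursor_mz: float
    precursor_charge: int
    mz: np.ndarray
    intensity: np.ndarray
    retention_time: Optional[float] = None

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity arrays differ in length")
        if np.any(self.intensity < 0):
            raise ValueError(f"negative intensity in scan {self.scan_id}")
        if self.precursor_charge < 1:
            raise ValueError(f"scan {self.scan_id}: precursor charge must be >= 1")
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]

    @property
    def n_peaks(self) -> int:
        return int(self.mz.size)


def read_fasta(path) -> List[ProteinRecord]:
    """Load a FASTA database; sequences uppercased, trailing '*' stripped."""
    records: List[ProteinRecord] = []
    seen = set()
    with open(path) as handle:
        for header, sequence in _pfasta.read(handle):
            if not header:
                raise ValueError(f"{path}: empty FASTA header")
            ident = header.split()[0]
            desc = header[len(ident):].strip()
            if ident in seen:
                raise ValueError(f"{path}: duplicate protein id {ident!r}")
            seen.add(ident)
            seq = sequence.upper().replace("*", "")
            records.append(ProteinRecord(
                id=ident, description=desc, sequence=seq,
                is_decoy=ident.startswith(DECOY_PREFIX),
            ))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[ProteinRecord], path, width: int = 60) -> None:
    with open(path, "w") as out:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            out.write(f">{header}\n")
            for i in range(0, len(rec.sequence), width):
                out.write(rec.sequence[i:i + width] + "\n")


def make_decoys(db: Sequence[ProteinRecord]) -> List[ProteinRecord]:
    """Targets plus one whole-protein-reversed decoy per target."""
    out = list(db)
    for rec in db:
        out.append(ProteinRecord(
            id=DECOY_PREFIX + rec.id,
            description=rec.description,
            sequence=rec.sequence[::-1],
            is_decoy=True,
        ))
    return out


def _spectrum_from_pyteomics(entry, index: int, enumerate_charges=(3, 4, 5, 6, 7)) -> List[SpectrumRecord]:
    params = entry["params"]
    title = str(params.get("title", f"index={index}"))
    pepmass = params.get("pepmass", (None,))
    mz0 = pepmass[0] if isinstance(pepmass, (tuple, list)) else float(pepmass)
    if mz0 is None:
        raise ValueError(f"scan {title!r}: missing precursor m/z")
    rt = params.get("rtinseconds")
    charge = params.get("charge")
    charges: List[int]
    if charge:
        charges = [int(charge[0])]
    else:
        charges = list(enumerate_charges)
    out = []
    for z in charges:
        out.append(SpectrumRecord(
            scan_id=title if len(charges) == 1 else f"{title}/z{z}",
            precursor_mz=float(mz0),
            precursor_charge=abs(int(z)),
            mz=entry["m/z array"],
            intensity=entry["intensity array"],
            retention_time=float(rt) if rt is not None else None,
        ))
    return out


def read_mgf(path, enumerate_charges=(3, 4, 5, 6, 7)) -> List[SpectrumRecord]:
    """Load an MGF peak list; spectra without a CHARGE line are enumerated."""
    spectra: List[SpectrumRecord] = []
    with _pmgf.read(os.fspath(path), use_index=False) as reader:
        for i, entry in enumerate(reader):
            spectra.extend(_spectrum_from_pyteomics(entry, i, enumerate_charges))
    return spectra


def write_mgf(spectra: Iterable[SpectrumRecord], path) -> None:
    """Write spectra as MGF with fixed numeric formatting (diff-stable)."""
    with open(path, "w") as out:
        for s in spectra:
            out.write("BEGIN IONS\n")
            out.write(f"TITLE={s.scan_id}\n")
            out.write(f"PEPMASS={s.precursor_mz:.6f}\n")
            out.write(f"CHARGE={s.precursor_charge}+\n")
            if s.retention_time is not None:
                out.write(f"RTINSECONDS={s.retention_time:.2f}\n")
            for mz, inten in zip(s.mz, s.intensity):
                out.write(f"{mz:.6f} {inten:.2f}\n")
            out.write("END IONS\n")


def read_mzml(path, enumerate_charges=(3, 4, 5, 6, 7)) -> List[SpectrumRecord]:
    """Load MS2 spectra from an mzML file (read-only support)."""
    from pyteomics import mzml as _pmzml

    spectra: List[SpectrumRecord] = []
    with _pmzml.read(os.fspath(path)) as reader:
        for entry in reader:
            if entry.get("ms level") != 2:
                continue
            precursor = entry["precursorList"]["precursor"][0]
            ion = precursor["selectedIonList"]["selectedIon"][0]
            mz0 = float(ion["selected ion m/z"])
            z = ion.get("charge state")
            scan_id = str(entry.get("id", entry.get("index")))
            charges = [int(z)] if z is not None else list(enumerate_charges)
            for zz in charges:
                spectra.append(SpectrumRecord(
                    scan_id=scan_id if len(charges) == 1 else f"{scan_id}/z{zz}",
                    precursor_mz=mz0,
                    precursor_charge=zz,
                    mz=entry["m/z array"],
                    intensity=entry["intensity array"],
                ))
    return spectra


RESULTS_VERSION = "gecx-results v1"

RESULTS_COLUMNS = [
    "scan_id",
    "bait_sequence",
    "bait_ncaa_position",
    "bait_mods",
    "prey_sequence",
    "prey_protein",
    "prey_start",
    "prey_end",
    "prey_mods",
    "site_position_peptide",
    "site_position_protein",
    "site_residue",
    "site_ambiguous",
    "score",
    "site_delta_score",
    "qvalue",
    "precursor_ppm",
    "matched_bait",
    "matched_prey",
    "theoretical_bait",
    "theoretical_prey",
    "precursor_charge",
    "is_decoy",
]


def write_results(rows: pd.DataFrame, path) -> None:
    """Results TSV with a versioned header comment and frozen column order."""
    df = rows.reindex(columns=RESULTS_COLUMNS)
    bad_q = df["qvalue"].dropna()
    if len(bad_q) and ((bad_q < 0) | (bad_q > 1)).any():
        raise ValueError("q-values outside [0, 1]")
    with open(path, "w") as out:
        out.write(f"# {RESULTS_VERSION}\n")
        df.to_csv(out, sep="\t", index=False, float_format="%.6g")


def read_results(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    return df.reindex(columns=RESULTS_COLUMNS)


def write_restraints(rows: pd.DataFrame, path, distance_angstrom: float = 15.0) -> None:
    """One distance restraint per accepted cross-link for docking.

    Pairs the bait ncAA residue (protein coordinates) with the prey residue;
    the distance bound is configurable (the side-chain span of an alkyl
    bromide ncAA plus the nucleophile reach, ~15 A by default).
    """
    cols = ["bait_protein", "bait_residue", "prey_protein", "prey_residue",
            "prey_site_residue", "max_distance_A"]
    with open(path, "w") as out:
        out.write("# gecx-restraints v1\n")
        out.write("\t".join(cols) + "\n")
        if len(rows) == 0:
            return
        seen = set()
        for _, r in rows.iterrows():
            key = (r["prey_protein"], int(r["site_position_protein"]))
            if key in seen or bool(r.get("is_decoy", False)):
                continue
            seen.add(key)
            bait_res = int(r["bait_ncaa_site_protein"]) if "bait_ncaa_site_protein" in r \
                else int(r["bait_ncaa_position"])
            out.write("\t".join([
                str(r.get("bait_protein", "bait")),
                str(bait_res),
                str(r["prey_protein"]),
                str(int(r["site_position_protein"])),
                str(r["site_residue"]),
                f"{distance_angstrom:g}",
            ]) + "\n")
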