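"""Stage wiring: digest -> index -> search -> FDR -> downstream summaries.

Also the evaluation harness that scores a search result against a synthetic
run's ground-truth manifest (recall, false-discovery proportion, site
localization accuracy).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .chem import (
    CrossLinker,
    DEFAULT_MASS_TABLE,
    MassTable,
    carbamidomethyl,
    mod_mass_from_formula,
)
from .digestion import DigestLimits, PeptideRecord, PROTEASES, generate_bait_peptides
from .fdr import collapse_to_unique, compute_qvalues, filter_at_fdr
from .io_formats import ProteinRecord, SpectrumRecord, make_decoys
from .xl_search import (
    CrossLinkPSM,
    build_prey_index,
    make_bait_variants,
    search_spectra,
)

__all__ = [
    "RunConfig",
    "SearchResult",
    "run_search",
    "run_evaluate",
    "psms_to_dataframe",
]


@dataclass(frozen=True)
class RunConfig:
    """All search parameters; defaults follow standard GECX-MS practice:
    10 ppm precursor / 20 ppm fragment tolerance, 5% PSM-level FDR, up to
    three missed cleavages, variable Cys carbamidomethylation (+57.02146),
    precursor charges 3-7, fragment charges 1-2.
    """

    ncaa_site: int = 0
    ncaa_mass: float = 0.0
    precursor_ppm: float = 10.0
    fragment_ppm: float = 20.0
    fdr_alpha: float = 0.05
    max_missed: int = 3
    reactive_residues: str = "CDEHKSTY"
    protease: str = "trypsin"
    pro_rule: bool = True
    variable_cam: bool = True
    max_mods: int = 3
    min_peptide_length: int = 5
    max_peptide_length: int = 60
    min_peptide_mass: float = 500.0
    max_peptide_mass: float = 6000.0
    fragment_charges: Tuple[int, ...] = (1, 2)
    leaving_group_formula: str = "HBr"
    require_both_chains: bool = True
    plus_one: bool = True

    def build_linker(self, table: MassTable = DEFAULT_MASS_TABLE) -> CrossLinker:
        if self.ncaa_mass <= 0:
            raise ValueError("ncaa_mass must be configured (no published "
                             "constant exists for the ncAA residue mass)")
        return CrossLinker(
            name="alkyl-halide-ncAA",
            ncaa_residue_mass=self.ncaa_mass,
            leaving_group_mass=mod_mass_from_formula(self.leaving_group_formula,
                                                     table),
            reactive_residues=frozenset(self.reactive_residues),
        )

    def build_rule(self):
        factory = PROTEASES.get(self.protease)
        if factory is None:
            raise ValueError(f"unknown protease {self.protease!r}")
        if self.protease == "trypsin":
            return factory(self.max_missed, self.pro_rule)
        return factory(self.max_missed)

    def limits(self) -> DigestLimits:
        return DigestLimits(self.min_peptide_length, self.max_peptide_length)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True, default=list)


@dataclass
class SearchResult:
    config: RunConfig
    psms: List[CrossLinkPSM]          # all rank-1 PSMs with q-values
    accepted: List[CrossLinkPSM]      # targets at q <= alpha
    uniques: List[CrossLinkPSM]
    binders: List[str]
    sites: List[Tuple[str, int, str]]
    results: pd.DataFrame             # one row per rank-1 PSM
    stage_counts: Dict[str, int]


def psms_to_dataframe(psms: Sequence[CrossLinkPSM], bait_protein_id: str,
                      ncaa_site: int) -> pd.DataFrame:
    rows = []
    for m in psms:
        cand = m.candidate
        prey = cand.prey.peptide
        rows.append({
            "scan_id": m.scan_id,
            "bait_sequence": cand.bait.peptide.sequence,
            "bait_ncaa_position": cand.bait.peptide.ncaa_position,
            "bait_mods": ";".join(f"{pos}:{mod.name}" for pos, mod in cand.bait.mods),
            "prey_sequence": prey.sequence,
            "prey_protein": prey.protein_id,
            "prey_start": prey.start,
            "prey_end": prey.end,
            "prey_mods": ";".join(f"{pos}:{mod.name}" for pos, mod in cand.prey.mods),
            "site_position_peptide": cand.prey_site,
            "site_position_protein": prey.start + cand.prey_site - 1,
            "site_residue": prey.sequence[cand.prey_site - 1],
            "site_ambiguous": ";".join(map(str, m.ambiguous_sites)),
            "score": m.score,
            "site_delta_score": m.site_delta_score,
            "qvalue": m.qvalue,
            "precursor_ppm": m.precursor_ppm,
            "matched_bait": m.matched_bait,
            "matched_prey": m.matched_prey,
            "theoretical_bait": m.theoretical_bait,
            "theoretical_prey": m.theoretical_prey,
            "precursor_charge": m.precursor_charge,
            "is_decoy": m.is_decoy,
            "bait_protein": bait_protein_id,
            "bait_ncaa_site_protein": ncaa_site,
        })
    return pd.DataFrame(rows)


def run_search(
    db: Sequence[ProteinRecord],
    bait: ProteinRecord,
    spectra: Sequence[SpectrumRecord],
    config: RunConfig,
    table: MassTable = DEFAULT_MASS_TABLE,
) -> SearchResult:
    """Full search: decoys, index, per-spectrum search, FDR, collapse."""
    linker = config.build_linker(table)
    rule = config.build_rule()
    mods = [carbamidomethyl(table)] if config.variable_cam else []

    targets_plus_decoys = make_decoys([p for p in db if not p.is_decoy])
    index = build_prey_index(
        targets_plus_decoys, rule, linker, mods,
        limits=config.limits(), max_mods=config.max_mods,
        min_mass=config.min_peptide_mass, max_mass=config.max_peptide_mass,
        table=table,
    )
    bait_peptides = generate_bait_peptides(bait.sequence, config.ncaa_site,
                                           rule, protein_id=bait.id, limits=None)
    bait_variants = make_bait_variants(bait_peptides, linker, mods,
                                       config.max_mods, table)
    psms = search_spectra(
        spectra, bait_variants, index, linker,
        precursor_ppm=config.precursor_ppm, frag_tol_ppm=config.fragment_ppm,
        table=table, require_both_chains=config.require_both_chains,
        fragment_charges=config.fragment_charges,
    )
    matchset = compute_qvalues(psms, plus_one=config.plus_one)
    accepted = filter_at_fdr(matchset, config.fdr_alpha)
    uniques, binders, sites = collapse_to_unique(accepted)
    results = psms_to_dataframe(matchset.psms, bait.id, config.ncaa_site)
    counts = {
        "proteins": len(db),
        "indexed_peptides": len(index),
        "bait_variants": len(bait_variants),
        "spectra": len(spectra),
        "rank1_psms": len(psms),
        "decoy_psms": sum(m.is_decoy for m in psms),
        "accepted_psms": len(accepted),
        "accepted_decoys": sum(m.is_decoy and m.qvalue <= config.fdr_alpha
                               for m in matchset.psms),
        "unique_peptides": len(uniques),
        "binders": len(binders),
    }
    return SearchResult(config=config, psms=matchset.psms, accepted=accepted,
                        uniques=uniques, binders=binders, sites=sites,
                        results=results, stage_counts=counts)


def _accepted_rows(results: pd.DataFrame, alpha: float) -> pd.DataFrame:
    if results.empty:
        return results
    return results[(results["qvalue"] <= alpha) & (~results["is_decoy"])]


def run_evaluate(results: pd.DataFrame, truth: pd.DataFrame,
                 alpha: float = 0.05) -> Dict[str, float]:
    """Recovery metrics of a search against the ground-truth manifest.

    recall: fraction of implanted links with >=1 correctly matched accepted
    PSM (pair identity: bait sequence, prey sequence, protein, start).
    fdp: fraction of accepted PSMs whose pair does not match the scan's truth
    (background scans count as false).
    site_accuracy: among correctly paired accepted PSMs, fraction whose
    localized site equals the true site position.
    """
    accepted = _accepted_rows(results, alpha)
    truth_links = truth[truth["kind"] == "link"]
    n_links = truth_links["link_id"].nunique()
    if accepted.empty:
        return {"recall": 0.0, "fdp": 0.0, "site_accuracy": float("nan"),
                "n_accepted": 0, "n_links": int(n_links),
                "accepted_decoys": 0}
    merged = accepted.merge(truth, on="scan_id", how="left",
                            suffixes=("", "_true"))
    correct_pair = (
        (merged["kind"] == "link")
        & (merged["prey_sequence"] == merged["prey_sequence_true"])
        & (merged["prey_protein"] == merged["prey_protein_true"])
        & (merged["prey_start"] == merged["prey_start_true"])
        & (merged["bait_sequence"] == merged["bait_sequence_true"])
    )
    correct_site = correct_pair & (
        merged["site_position_protein"] == merged["site_position_protein_true"])
    n_accepted = len(merged)
    n_correct = int(correct_pair.sum())
    recovered_links = merged.loc[correct_pair, "link_id"].nunique()
    return {
        "recall": float(recovered_links / n_links) if n_links else 0.0,
        "fdp": float((n_accepted - n_correct) / n_accepted),
        "site_accuracy": float(correct_site.sum() / n_correct) if n_correct else float("nan"),
        "n_accepted": int(n_accepted),
        "n_links": int(n_links),
        "accepted_decoys": 0,
    }
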