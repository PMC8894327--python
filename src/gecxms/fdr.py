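"""Target-decoy false discovery rate control at the PSM level.

Decoy PSMs are matches whose prey peptide comes from a reversed protein. The
estimator at score threshold s is (#decoys(>=s) + 1) / #targets(>=s); the +1
corrects the small-sample anti-conservativeness of plain decoy counting under
rank-1 competition (entrapment calibration of this engine shows the
uncorrected estimate under-counts false discoveries; set plus_one=False for
the plain ratio). q-values are the running minimum of that estimate from the
highest score downwards.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Set, Tuple

import numpy as np

from .xl_search import CrossLinkPSM

__all__ = [
    "ScoredMatchSet",
    "compute_qvalues",
    "filter_at_fdr",
    "collapse_to_unique",
    "unique_key",
]


def _rank_key(psm: CrossLinkPSM) -> tuple:
    # deterministic ordering: score desc, then |ppm| asc, then lexicographic
    return (
        -psm.score,
        abs(psm.precursor_ppm),
        psm.candidate.bait.peptide.sequence,
        psm.candidate.prey.peptide.sequence,
        psm.candidate.prey.peptide.protein_id,
        psm.candidate.prey_site,
        psm.scan_id,
    )


@dataclass
class ScoredMatchSet:
    """PSMs sorted by decreasing score with q-values attached."""

    psms: List[CrossLinkPSM]
    qvalues: np.ndarray

    def threshold_for(self, alpha: float) -> float:
        """Lowest score still accepted at FDR alpha (inf if none)."""
        accepted = [m.score for m, q in zip(self.psms, self.qvalues) if q <= alpha]
        return min(accepted) if accepted else float("inf")


def compute_qvalues(psms: Sequence[CrossLinkPSM], plus_one: bool = True) -> ScoredMatchSet:
    """Attach target-decoy q-values; input must be rank-1-per-spectrum PSMs."""
    ordered = sorted(psms, key=_rank_key)
    n = len(ordered)
    if n == 0:
        return ScoredMatchSet(psms=[], qvalues=np.empty(0))
    decoy = np.array([m.is_decoy for m in ordered])
    cum_decoys = np.cumsum(decoy)
    cum_targets = np.cumsum(~decoy)
    add = 1 if plus_one else 0
    fdr = (cum_decoys + add) / np.maximum(cum_targets, 1)
    # tied scores share one threshold: each tie group takes the counts at its
    # last member, so duplicating the input leaves q-values unchanged
    scores = np.array([m.score for m in ordered])
    _, inverse = np.unique(-scores, return_inverse=True)
    group_last = {}
    for i, g in enumerate(inverse):
        group_last[g] = i
    fdr = np.array([fdr[group_last[g]] for g in inverse])
    qvalues = np.minimum.accumulate(fdr[::-1])[::-1]
    qvalues = np.clip(qvalues, 0.0, 1.0)
    for psm, q in zip(ordered, qvalues):
        psm.qvalue = float(q)
    return ScoredMatchSet(psms=ordered, qvalues=qvalues)


def filter_at_fdr(matchset: ScoredMatchSet, alpha: float = 0.05) -> List[CrossLinkPSM]:
    """Target PSMs with q <= alpha (decoys counted in the estimate, not reported)."""
    return [m for m, q in zip(matchset.psms, matchset.qvalues)
            if q <= alpha and not m.is_decoy]


def unique_key(psm: CrossLinkPSM) -> tuple:
    """Most granular unique cross-linked-peptide key: (bait, prey, site, mods)."""
    cand = psm.candidate
    return (
        cand.bait.peptide.sequence,
        tuple((pos, mod.name) for pos, mod in cand.bait.mods),
        cand.prey.peptide.sequence,
        cand.prey.peptide.protein_id,
        cand.prey.peptide.start,
        tuple((pos, mod.name) for pos, mod in cand.prey.mods),
        cand.prey_site,
    )


def collapse_to_unique(
    accepted: Sequence[CrossLinkPSM],
) -> Tuple[List[CrossLinkPSM], List[str], List[Tuple[str, int, str]]]:
    """Collapse accepted PSMs to unique cross-linked peptides.

    Returns (representative best-scoring PSM per unique peptide, sorted binder
    protein ids, per-residue site list as (protein, protein position, residue)).
    """
    best: Dict[tuple, CrossLinkPSM] = {}
    for psm in accepted:
        key = unique_key(psm)
        if key not in best or _rank_key(psm) < _rank_key(best[key]):
            best[key] = psm
    uniques = sorted(best.values(), key=_rank_key)
    binders = sorted({u.candidate.prey.peptide.protein_id for u in uniques})
    sites = sorted({
        (
            u.candidate.prey.peptide.protein_id,
            u.candidate.prey.peptide.start + u.candidate.prey_site - 1,
            u.candidate.prey.peptide.sequence[u.candidate.prey_site - 1],
        )
        for u in uniques
    })
    return uniques, binders, sites
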