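"""In-silico proteolysis.

Supports single-protease digestion with missed cleavages, the sequential
Lys-C -> trypsin double digestion used to enrich cross-linked peptides via a
retained-peptide predicate (modelling the His-tag re-purification between the
two digests), and bait-peptide generation around the ncAA site.

Coordinates are 1-based inclusive everywhere, matching the residue naming
conventions of the field (e.g. SUMO2 E49, RNF111 D384).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, List, Optional, Sequence

from .chem import NCAA_MARKER

__all__ = [
    "ProteaseRule",
    "PeptideRecord",
    "DigestLimits",
    "PROTEASES",
    "digest",
    "double_digest",
    "generate_bait_peptides",
]


@dataclass(frozen=True)
class ProteaseRule:
    """Cleave after ``cleave_after`` unless followed by ``suppressed_before``."""

    name: str
    cleave_after: frozenset
    suppressed_before: frozenset = frozenset()
    max_missed: int = 0

    def __post_init__(self):
        if self.max_missed < 0:
            raise ValueError("max_missed must be >= 0")

    def with_missed(self, max_missed: int) -> "ProteaseRule":
        return replace(self, max_missed=max_missed)


def trypsin(max_missed: int = 0, pro_rule: bool = True) -> ProteaseRule:
    """Trypsin: after K/R, by default suppressed before P (configurable)."""
    return ProteaseRule(
        name="trypsin",
        cleave_after=frozenset("KR"),
        suppressed_before=frozenset("P") if pro_rule else frozenset(),
        max_missed=max_missed,
    )


def lysc(max_missed: int = 0) -> ProteaseRule:
    return ProteaseRule(name="lysc", cleave_after=frozenset("K"),
                        max_missed=max_missed)


def no_protease() -> ProteaseRule:
    """A no-op 'protease' that leaves the chain intact."""
    return ProteaseRule(name="none", cleave_after=frozenset("$"), max_missed=0)


PROTEASES: dict = {
    "trypsin": trypsin,
    "lysc": lysc,
    "none": lambda max_missed=0: no_protease(),
}


@dataclass(frozen=True)
class PeptideRecord:
    """A digested peptide with provenance in its parent protein."""

    sequence: str
    protein_id: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive
    missed_cleavages: int = 0
    ncaa_position: Optional[int] = None  # 1-based within the peptide
    is_decoy: bool = False

    def __post_init__(self):
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError("coordinates inconsistent with sequence length")
        if self.ncaa_position is not None and not (
            1 <= self.ncaa_position <= len(self.sequence)
        ):
            raise ValueError("ncaa_position outside peptide")


@dataclass(frozen=True)
class DigestLimits:
    """Peptide length bounds applied at digestion time.

    Mass bounds belong to the search index (where neutral masses are computed
    anyway); see gecxms.xl_search.build_prey_index.
    """

    min_length: int = 5
    max_length: int = 60

    def admits(self, sequence: str) -> bool:
        return self.min_length <= len(sequence) <= self.max_length


def _cut_points(sequence: str, rule: ProteaseRule) -> List[int]:
    """0-based boundary indices: a cut between i-1 and i; includes 0 and len."""
    cuts = [0]
    for i in range(len(sequence) - 1):
        if sequence[i] in rule.cleave_after and sequence[i + 1] not in rule.suppressed_before:
            cuts.append(i + 1)
    cuts.append(len(sequence))
    return cuts


def digest(
    protein: str,
    rule: ProteaseRule,
    protein_id: str = "protein",
    limits: Optional[DigestLimits] = None,
    is_decoy: bool = False,
    offset: int = 0,
) -> List[PeptideRecord]:
    """All peptides with 0..max_missed missed cleavages.

    ``offset`` shifts reported coordinates (used when digesting a fragment of
    a larger protein). ``limits=None`` disables length bounds.
    """
    if not protein:
        return []
    cuts = _cut_points(protein, rule)
    peptides: List[PeptideRecord] = []
    for i in range(len(cuts) - 1):
        for k in range(rule.max_missed + 1):
            j = i + k + 1
            if j >= len(cuts):
                break
            seq = protein[cuts[i]:cuts[j]]
            if limits is not None and not limits.admits(seq):
                continue
            peptides.append(PeptideRecord(
                sequence=seq,
                protein_id=protein_id,
                start=offset + cuts[i] + 1,
                end=offset + cuts[j],
                missed_cleavages=k,
                is_decoy=is_decoy,
            ))
    return peptides


def double_digest(
    protein: str,
    first: ProteaseRule,
    second: ProteaseRule,
    retained_predicate: Callable[[PeptideRecord], bool],
    protein_id: str = "protein",
    limits: Optional[DigestLimits] = None,
    is_decoy: bool = False,
) -> List[PeptideRecord]:
    """Sequential digestion with an enrichment step between the proteases.

    The first protease is applied at zero missed cleavages (complete primary
    digestion), ``retained_predicate`` models the physical re-enrichment (e.g.
    "carries the C-terminal His tag" or "contains the ncAA"), and the second
    protease then digests only the retained peptides. Length limits apply to
    the final products.
    """
    stage1 = digest(protein, first.with_missed(0), protein_id=protein_id,
                    is_decoy=is_decoy)
    out: List[PeptideRecord] = []
    for pep in stage1:
        if not retained_predicate(pep):
            continue
        out.extend(digest(pep.sequence, second, protein_id=protein_id,
                          limits=limits, is_decoy=is_decoy,
                          offset=pep.start - 1))
    return out


def generate_bait_peptides(
    bait_protein: str,
    ncaa_site: int,
    rule: ProteaseRule,
    protein_id: str = "bait",
    limits: Optional[DigestLimits] = None,
) -> List[PeptideRecord]:
    """Digested peptides covering the ncAA site, with ncaa_position set.

    The residue at ``ncaa_site`` (1-based) is replaced by the ncAA marker
    before digestion, so an ncAA substituting a K or R is (correctly) no
    longer a cleavage site.
    """
    if not 1 <= ncaa_site <= len(bait_protein):
        raise ValueError(
            f"ncAA site {ncaa_site} outside protein of length {len(bait_protein)}"
        )
    marked = bait_protein[:ncaa_site - 1] + NCAA_MARKER + bait_protein[ncaa_site:]
    out = []
    for pep in digest(marked, rule, protein_id=protein_id, limits=limits):
        if pep.start <= ncaa_site <= pep.end:
            out.append(replace(pep, ncaa_position=ncaa_site - pep.start + 1))
    return out
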