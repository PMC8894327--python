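"""Search engine core: index lookup, candidate enumeration, the two-chain
fragment model, scoring, and site localization."""

import math

import numpy as np
import pytest

from gecxms.chem import (
    CrossLinker,
    DEFAULT_MASS_TABLE,
    carbamidomethyl,
    mz_to_neutral,
    neutral_to_mz,
    peptide_mass,
)
from gecxms.digestion import PeptideRecord, trypsin
from gecxms.io_formats import ProteinRecord, SpectrumRecord
from gecxms.xl_search import (
    CrossLinkCandidate,
    IndexedPeptide,
    build_prey_index,
    enumerate_candidates,
    localize_site,
    make_bait_variants,
    score_psm,
    theoretical_fragments,
)

from .oracles import enumerate_candidates_bruteforce

TABLE = DEFAULT_MASS_TABLE
LINKER = CrossLinker("test-ncaa", ncaa_residue_mass=283.0208)


def bait_entry(seq="GGAUGLK", pos=4):
    pep = PeptideRecord(sequence=seq, protein_id="BAIT", start=1, end=len(seq),
                        ncaa_position=pos)
    return IndexedPeptide(pep, (), peptide_mass(seq, ncaa_position=pos,
                                                linker=LINKER))


def prey_entry(seq="ACDK", protein="P1", start=1, decoy=False):
    pep = PeptideRecord(sequence=seq, protein_id=protein, start=start,
                        end=start + len(seq) - 1, is_decoy=decoy)
    return IndexedPeptide(pep, (), peptide_mass(seq))


def spectrum_for(candidate, scan_id="s1", charge=3):
    ions = theoretical_fragments(candidate, LINKER)
    mz = np.array(sorted(i.mz for i in ions))
    return SpectrumRecord(scan_id, neutral_to_mz(candidate.theoretical_mass, charge),
                          charge, mz, np.ones_like(mz))


def make_candidate(bait, prey, site):
    total = bait.mass + prey.mass - LINKER.leaving_group_mass
    return CrossLinkCandidate(bait, prey, site, total)


class TestPreyIndex:
    def test_reactive_lysine_peptide_indexed(self):
        db = [ProteinRecord("P1", "", "GGGGK")]
        idx = build_prey_index(db, trypsin(0), LINKER, limits=None,
                               min_mass=None, max_mass=None)
        assert {e.peptide.sequence for e in idx.entries} == {"GGGGK"}

    def test_peptides_without_reactive_residues_excluded(self):
        db = [ProteinRecord("P1", "", "GGGGGGRAAAAAAR")]
        idx = build_prey_index(db, trypsin(0), LINKER, limits=None,
                               min_mass=None, max_mass=None)
        assert len(idx) == 0

    def test_lookup_window_equals_linear_scan(self):
        rng = np.random.default_rng(5)
        letters = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        db = [ProteinRecord(f"P{i}", "", "".join(rng.choice(letters, size=50)))
              for i in range(20)]
        idx = build_prey_index(db, trypsin(1), LINKER, limits=None,
                               min_mass=None, max_mass=None)
        for _ in range(50):
            lo = float(rng.uniform(400, 3000))
            hi = lo + float(rng.uniform(0, 50))
            got = idx.lookup(lo, hi)
            want = [e for e in idx.entries if lo <= e.mass <= hi]
            assert got == want

    def test_variable_cam_expands_cys_peptides(self):
        db = [ProteinRecord("P1", "", "AACCDK")]
        idx = build_prey_index(db, trypsin(0), LINKER, [carbamidomethyl()],
                               limits=None, min_mass=None, max_mass=None)
        n_mods = sorted(len(e.mods) for e in idx.entries)
        assert n_mods == [0, 1, 1, 2]


class TestEnumeration:
    def test_exact_precursor_enumerated(self):
        bait, prey = bait_entry(), prey_entry("ACDK")
        idx = build_prey_index([ProteinRecord("P1", "", "ACDK")], trypsin(0),
                               LINKER, limits=None, min_mass=None, max_mass=None)
        total = bait.mass + prey.mass - LINKER.leaving_group_mass
        spec = SpectrumRecord("s", neutral_to_mz(total, 3), 3,
                              np.array([200.0]), np.array([1.0]))
        cands = enumerate_candidates(spec, [bait], idx, LINKER, tol_ppm=10)
        assert {c.prey_site for c in cands} == {2, 3, 4}  # C, D, K variants

    def test_25_ppm_displacement_not_enumerated(self):
        bait, prey = bait_entry(), prey_entry("ACDK")
        idx = build_prey_index([ProteinRecord("P1", "", "ACDK")], trypsin(0),
                               LINKER, limits=None, min_mass=None, max_mass=None)
        total = (bait.mass + prey.mass - LINKER.leaving_group_mass) * (1 + 25e-6)
        spec = SpectrumRecord("s", neutral_to_mz(total, 3), 3,
                              np.array([200.0]), np.array([1.0]))
        assert enumerate_candidates(spec, [bait], idx, LINKER, tol_ppm=10) == []

    def test_cam_blocked_cys_site_excluded(self):
        db = [ProteinRecord("P1", "", "ACDK")]
        idx = build_prey_index(db, trypsin(0), LINKER, [carbamidomethyl()],
                               limits=None, min_mass=None, max_mass=None)
        bait = bait_entry()
        cam_entry = [e for e in idx.entries if e.mods][0]
        total = bait.mass + cam_entry.mass - LINKER.leaving_group_mass
        spec = SpectrumRecord("s", neutral_to_mz(total, 3), 3,
                              np.array([200.0]), np.array([1.0]))
        cands = enumerate_candidates(spec, [bait], idx, LINKER, tol_ppm=10)
        cam_sites = {c.prey_site for c in cands if c.prey.mods}
        assert 2 not in cam_sites and cam_sites == {3, 4}

    def test_index_equals_allpairs_bruteforce(self):
        rng = np.random.default_rng(13)
        letters = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        db = [ProteinRecord(f"P{i}", "", "".join(rng.choice(letters, size=60)))
              for i in range(15)]
        idx = build_prey_index(db, trypsin(1), LINKER, limits=None,
                               min_mass=None, max_mass=None)
        assert len(idx) <= 200
        baits = [bait_entry(), bait_entry("AUK", 2)]
        prey_table = [
            (f"{e.peptide.protein_id}:{e.peptide.start}", e.mass,
             e.peptide.sequence, LINKER.reactive_residues)
            for e in idx.entries
        ]
        bait_table = [(b.peptide.sequence, b.mass) for b in baits]
        for _ in range(30):
            neutral = float(rng.uniform(1200, 6000))
            spec = SpectrumRecord("s", neutral_to_mz(neutral, 3), 3,
                                  np.array([200.0]), np.array([1.0]))
            got = {
                (c.bait.peptide.sequence,
                 f"{c.prey.peptide.protein_id}:{c.prey.peptide.start}",
                 c.prey_site)
                for c in enumerate_candidates(spec, baits, idx, LINKER, 10.0)
            }
            want = enumerate_candidates_bruteforce(
                neutral, bait_table, prey_table, LINKER.leaving_group_mass, 10.0)
            assert got == want


class TestFragments:
    def test_ion_counts(self):
        cand = make_candidate(bait_entry("GGAUGLK", 4), prey_entry("ACDK"), 2)
        ions = theoretical_fragments(cand, LINKER)
        bait_ions = [i for i in ions if i.chain == "bait"]
        prey_ions = [i for i in ions if i.chain == "prey"]
        # (n-1) b + (n-1) y ordinals per charge state
        assert len(bait_ions) == 2 * 2 * (7 - 1)
        assert len(prey_ions) == 2 * 2 * (4 - 1)

    def test_y1_not_covering_site_is_plain(self):
        cand = make_candidate(bait_entry(), prey_entry("ACDK"), 2)
        y1 = [i for i in theoretical_fragments(cand, LINKER)
              if i.chain == "prey" and i.series == "y" and i.ordinal == 1
              and i.charge == 1][0]
        assert not y1.carries_partner
        expected = TABLE.residue_masses["K"] + TABLE.water_mass + TABLE.proton_mass
        assert y1.mz == pytest.approx(expected, abs=1e-6)

    def test_b_ion_covering_site_carries_bait_minus_hbr(self):
        bait = bait_entry()
        cand = make_candidate(bait, prey_entry("ACDK"), 2)
        b2 = [i for i in theoretical_fragments(cand, LINKER)
              if i.chain == "prey" and i.series == "b" and i.ordinal == 2
              and i.charge == 1][0]
        assert b2.carries_partner
        plain = TABLE.residue_masses["A"] + TABLE.residue_masses["C"]
        expected = plain + bait.mass - LINKER.leaving_group_mass + TABLE.proton_mass
        assert b2.mz == pytest.approx(expected, abs=1e-6)

    def test_bookkeeping_b_plus_y_equals_chain_conjugate_mass(self):
        cand = make_candidate(bait_entry("GGAUGLK", 4), prey_entry("ACDEHK"), 3)
        ions = {(i.chain, i.series, i.ordinal): i
                for i in theoretical_fragments(cand, LINKER) if i.charge == 1}
        for chain, entry, partner in (("bait", cand.bait, cand.prey),
                                      ("prey", cand.prey, cand.bait)):
            n = len(entry.peptide.sequence)
            conjugate = entry.mass + partner.mass - LINKER.leaving_group_mass
            for k in range(1, n):
                b = ions[(chain, "b", k)]
                y = ions[(chain, "y", n - k)]
                assert b.carries_partner != y.carries_partner  # exactly one
                total = (b.mz - TABLE.proton_mass) + (y.mz - TABLE.proton_mass)
                assert total == pytest.approx(conjugate, abs=1e-6)


class TestScoring:
    def test_self_match_dominates_other_candidates(self):
        rng = np.random.default_rng(3)
        letters = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        bait = bait_entry()
        true_prey = prey_entry("ACDEHK")
        cand = make_candidate(bait, true_prey, 2)
        spec = spectrum_for(cand)
        self_psm = score_psm(spec, cand, LINKER)
        assert self_psm.matched_bait == self_psm.theoretical_bait
        assert self_psm.matched_prey == self_psm.theoretical_prey
        scores = []
        for _ in range(100):
            seq = "".join(rng.choice(letters, size=6)) + "K"
            other = make_candidate(bait, prey_entry(seq), 1)
            scores.append(score_psm(spec, other, LINKER).score)
        assert self_psm.score > max(scores)
        assert self_psm.score > np.mean(scores)

    def test_empty_spectrum_scores_zero(self):
        cand = make_candidate(bait_entry(), prey_entry("ACDK"), 2)
        spec = SpectrumRecord("s", 500.0, 3, np.array([]), np.array([]))
        psm = score_psm(spec, cand, LINKER)
        assert psm.score == 0.0 and psm.matched_bait == 0 and psm.matched_prey == 0

    def test_matched_count_monotone_in_tolerance_and_noise(self):
        rng = np.random.default_rng(9)
        cand = make_candidate(bait_entry(), prey_entry("ACDEHK"), 2)
        ions_mz = np.sort(np.array([i.mz for i in
                                    theoretical_fragments(cand, LINKER)]))
        jitter = ions_mz * (1 + rng.normal(0, 10e-6, ions_mz.size))
        spec = SpectrumRecord("s", 500.0, 3, jitter, np.ones_like(jitter))
        matched = []
        for tol in (5.0, 10.0, 20.0, 40.0):
            psm = score_psm(spec, cand, LINKER, frag_tol_ppm=tol)
            matched.append(psm.matched_bait + psm.matched_prey)
        assert matched == sorted(matched)
        # add noise peaks: matched count can only stay or grow
        base = score_psm(spec, cand, LINKER).matched_bait + \
            score_psm(spec, cand, LINKER).matched_prey
        noise = rng.uniform(150, 2000, 200)
        noisy = SpectrumRecord("s", 500.0, 3,
                               np.concatenate([spec.mz, noise]),
                               np.ones(spec.mz.size + 200))
        psm2 = score_psm(noisy, cand, LINKER)
        assert psm2.matched_bait + psm2.matched_prey >= base


class TestLocalization:
    def test_noiseless_full_coverage_identifies_site(self):
        bait = bait_entry()
        prey = prey_entry("GCDE")
        true_cand = make_candidate(bait, prey, 2)  # implanted at C
        spec = spectrum_for(true_cand)
        variants = [score_psm(spec, make_candidate(bait, prey, s), LINKER)
                    for s in (2, 3, 4)]
        best = localize_site(variants)
        assert best.candidate.prey_site == 2
        assert best.site_delta_score > 0
        assert best.ambiguous_sites == ()

    def test_no_site_determining_ions_reports_tie(self):
        bait = bait_entry()
        prey = prey_entry("GDEK")
        cand_d = make_candidate(bait, prey, 2)
        cand_e = make_candidate(bait, prey, 3)
        # spectrum containing only ions shared by the D and E site variants
        mz_d = {round(i.mz, 6) for i in theoretical_fragments(cand_d, LINKER)}
        mz_e = {round(i.mz, 6) for i in theoretical_fragments(cand_e, LINKER)}
        shared = np.array(sorted(mz_d & mz_e))
        spec = SpectrumRecord("s", 500.0, 3, shared, np.ones_like(shared))
        variants = [score_psm(spec, c, LINKER) for c in (cand_d, cand_e)]
        best = localize_site(variants)
        assert best.site_delta_score == 0.0
        assert set(best.ambiguous_sites) == {2, 3}
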