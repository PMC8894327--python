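"""Target-decoy q-values, FDR filtering, and collapsing to unique peptides."""

import numpy as np
import pytest

from gecxms.chem import peptide_mass
from gecxms.digestion import PeptideRecord
from gecxms.fdr import collapse_to_unique, compute_qvalues, filter_at_fdr
from gecxms.xl_search import CrossLinkCandidate, CrossLinkPSM, IndexedPeptide


def make_psm(score, decoy=False, scan="s", bait_seq="GUK", prey_seq="ACDK",
             prey_protein="P1", prey_start=1, site=2, ppm=0.0):
    bait = IndexedPeptide(
        PeptideRecord(bait_seq, "BAIT", 1, len(bait_seq), ncaa_position=2),
        (), 500.0)
    prey = IndexedPeptide(
        PeptideRecord(prey_seq, prey_protein, prey_start,
                      prey_start + len(prey_seq) - 1, is_decoy=decoy),
        (), peptide_mass(prey_seq))
    cand = CrossLinkCandidate(bait, prey, site, 1000.0)
    return CrossLinkPSM(scan_id=scan, candidate=cand, score=score,
                        matched_bait=3, matched_prey=3, theoretical_bait=10,
                        theoretical_prey=10, intensity_fraction_bait=0.5,
                        intensity_fraction_prey=0.5, precursor_ppm=ppm,
                        precursor_charge=3)


def qvalue_sweep_oracle(scored):
    """Brute-force oracle: for each PSM, min over thresholds t <= its rank of
    decoys/targets above t."""
    out = []
    for score, _ in scored:
        best = np.inf
        for t, _ in scored:
            if t > score:
                continue
            d = sum(1 for s, dec in scored if s >= t and dec)
            targets = sum(1 for s, dec in scored if s >= t and not dec)
            best = min(best, d / max(targets, 1))
        out.append(min(best, 1.0))
    return out


class TestQvalues:
    def test_no_decoy_above_targets_gives_zero(self):
        psms = [make_psm(10, scan="a"), make_psm(9, scan="b"),
                make_psm(8, scan="c"), make_psm(7, decoy=True, scan="d")]
        ms = compute_qvalues(psms, plus_one=False)
        target_qs = [m.qvalue for m in ms.psms if not m.is_decoy]
        assert target_qs == [0.0, 0.0, 0.0]

    def test_alternating_targets_and_decoys_reach_one(self):
        psms = []
        for i in range(20):
            psms.append(make_psm(100 - 2 * i, scan=f"t{i}"))
            psms.append(make_psm(99 - 2 * i, decoy=True, scan=f"d{i}"))
        ms = compute_qvalues(psms, plus_one=False)
        assert ms.qvalues[-1] == pytest.approx(1.0)

    def test_qvalues_match_threshold_sweep_oracle(self):
        rng = np.random.default_rng(17)
        psms = [make_psm(float(rng.uniform(0, 50)), decoy=bool(rng.random() < 0.5),
                         scan=f"s{i}") for i in range(300)]
        ms = compute_qvalues(psms, plus_one=False)
        scored = [(m.score, m.is_decoy) for m in ms.psms]
        want = qvalue_sweep_oracle(scored)
        np.testing.assert_allclose(ms.qvalues, want, atol=1e-12)

    def test_duplicated_list_gives_identical_qvalues(self):
        rng = np.random.default_rng(23)
        base = [(float(rng.uniform(0, 50)), bool(rng.random() < 0.4))
                for _ in range(50)]
        single = compute_qvalues([make_psm(s, d, scan=f"a{i}")
                                  for i, (s, d) in enumerate(base)],
                                 plus_one=False)
        double = compute_qvalues(
            [make_psm(s, d, scan=f"b{i}") for i, (s, d) in enumerate(base)]
            + [make_psm(s, d, scan=f"c{i}") for i, (s, d) in enumerate(base)],
            plus_one=False)
        by_score_1 = {m.score: m.qvalue for m in single.psms}
        for m in double.psms:
            assert m.qvalue == pytest.approx(by_score_1[m.score], abs=1e-12)

    def test_monotone_nonincreasing_in_score(self):
        rng = np.random.default_rng(31)
        psms = [make_psm(float(rng.uniform(0, 50)), decoy=bool(rng.random() < 0.5),
                         scan=f"s{i}") for i in range(200)]
        ms = compute_qvalues(psms, plus_one=False)
        assert np.all(np.diff(ms.qvalues) >= -1e-15)  # sorted by decreasing score

    def test_empty_input(self):
        ms = compute_qvalues([])
        assert ms.psms == [] and filter_at_fdr(ms, 0.05) == []


class TestFilter:
    def _mixed(self):
        psms = [make_psm(s, scan=f"t{s}") for s in (50, 40, 30, 20, 10)]
        psms += [make_psm(s, decoy=True, scan=f"d{s}") for s in (25, 5)]
        return compute_qvalues(psms, plus_one=False)

    def test_alpha_zero_keeps_only_above_all_decoys(self):
        ms = self._mixed()
        accepted = filter_at_fdr(ms, alpha=0.0)
        assert {m.score for m in accepted} == {50, 40, 30}

    def test_alpha_one_keeps_all_targets(self):
        ms = self._mixed()
        assert len(filter_at_fdr(ms, alpha=1.0)) == 5

    def test_nested_acceptance_in_alpha(self):
        rng = np.random.default_rng(41)
        psms = [make_psm(float(rng.uniform(0, 50)), decoy=bool(rng.random() < 0.5),
                         scan=f"s{i}") for i in range(200)]
        ms = compute_qvalues(psms, plus_one=False)
        previous = set()
        for alpha in (0.0, 0.01, 0.05, 0.2, 1.0):
            current = {id(m) for m in filter_at_fdr(ms, alpha)}
            assert previous <= current
            previous = current

    def test_decoys_never_reported(self):
        ms = self._mixed()
        assert not any(m.is_decoy for m in filter_at_fdr(ms, 1.0))


class TestCollapse:
    def test_same_pair_in_five_spectra_is_one_unique(self):
        psms = [make_psm(10 + i, scan=f"s{i}") for i in range(5)]
        uniques, binders, sites = collapse_to_unique(psms)
        assert len(uniques) == 1
        assert uniques[0].score == 14  # best-scoring representative
        assert binders == ["P1"]
        assert sites == [("P1", 2, "C")]

    def test_two_peptides_same_protein_one_binder(self):
        psms = [make_psm(10, scan="a", prey_seq="ACDK", prey_start=1),
                make_psm(9, scan="b", prey_seq="GGCEK", prey_start=40, site=3)]
        uniques, binders, sites = collapse_to_unique(psms)
        assert len(uniques) == 2 and binders == ["P1"]
        assert ("P1", 42, "C") in sites

    def test_different_sites_are_distinct_uniques(self):
        psms = [make_psm(10, scan="a", site=2), make_psm(9, scan="b", site=3)]
        uniques, _, _ = collapse_to_unique(psms)
        assert len(uniques) == 2


class TestPlusOneDefault:
    def test_corrected_estimator_is_more_conservative(self):
        psms = [make_psm(10, scan="a"), make_psm(9, scan="b"),
                make_psm(8, scan="c"), make_psm(7, decoy=True, scan="d")]
        plain = compute_qvalues([make_psm(m.score, m.is_decoy, scan=f"x{i}")
                                 for i, m in enumerate(psms)], plus_one=False)
        corrected = compute_qvalues(psms)  # +1 by default
        # every target's corrected q is at least the plain q; here 1/3 vs 0
        target_qs = [m.qvalue for m in corrected.psms if not m.is_decoy]
        assert target_qs == pytest.approx([1 / 3, 1 / 3, 1 / 3])
        assert all(q >= p for q, p in
                   zip(sorted(target_qs), sorted(m.qvalue for m in plain.psms
                                                 if not m.is_decoy)))
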