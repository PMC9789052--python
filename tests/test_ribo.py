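"""Periodicity statistics, start-step scores, calling and ranking."""

import math

import numpy as np
import pytest
from scipy.stats import binom

from ntescan.extension import CandidateStart, TheoreticalExtension
from ntescan.ribo import (
    RiboConfig,
    RiboProfile,
    call_and_rank,
    combine_pvalues,
    frame_counts,
    load_profiles,
    null_win_probability,
    periodicity_pvalues,
    score_candidate,
    start_step_score,
)


def _profile(counts, tid="tx", init=None):
    return RiboProfile(tid, dict(counts), dict(init or {}))


class TestLoadProfiles:
    def test_aggregation_across_files(self, tmp_path):
        for i in (1, 2):
            (tmp_path / f"p{i}.tsv").write_text("tx1\t5\t3\telong\n")
        profs = load_profiles([tmp_path / "p1.tsv", tmp_path / "p2.tsv"])
        assert profs["tx1"].elong[5] == 6

    def test_unknown_channel_skipped(self, tmp_path):
        p = tmp_path / "p.tsv"
        p.write_text("tx1\t5\t3\tweird\ntx1\t6\t2\telong\n")
        profs = load_profiles(p)
        assert profs["tx1"].elong == {6: 2} and not profs["tx1"].init

    def test_negative_count_fatal(self, tmp_path):
        p = tmp_path / "p.tsv"
        p.write_text("tx1\t5\t-3\telong\n")
        with pytest.raises(ValueError, match="corrupt_profile"):
            load_profiles(p)


class TestFrameCounts:
    def test_pure_frame0(self):
        prof = _profile({3 * i: 9 for i in range(10)})
        fc = frame_counts(prof, 0, 30)
        assert (fc.F0, fc.F1, fc.F2, fc.occupied, fc.wins) == (90, 0, 0, 10, 10)

    def test_ties_never_win(self):
        counts = {}
        for i in range(10):
            counts[3 * i] = counts[3 * i + 1] = counts[3 * i + 2] = 3
        fc = frame_counts(_profile(counts), 0, 30)
        assert (fc.F0, fc.F1, fc.F2, fc.wins, fc.occupied) == (30, 30, 30, 0, 10)

    def test_against_brute_force_tally(self, rng):
        for _ in range(100):
            L = int(rng.integers(1, 40))
            counts = {int(p): int(rng.integers(0, 6))
                      for p in rng.integers(0, 3 * L, size=2 * L)}
            fc = frame_counts(_profile(counts), 0, 3 * L)
            # independent per-position tally
            F = [0, 0, 0]
            occ = wins = 0
            for c in range(L):
                trio = [counts.get(3 * c + k, 0) for k in range(3)]
                for k in range(3):
                    F[k] += trio[k]
                if sum(trio) > 0:
                    occ += 1
                    if trio[0] > trio[1] and trio[0] > trio[2]:
                        wins += 1
            assert (fc.F0, fc.F1, fc.F2, fc.occupied, fc.wins) == (*F, occ, wins)


class TestPeriodicityPvalues:
    def test_all_frame0_closed_form(self):
        """90 reads all in frame: p_read is exactly (1/3)^90."""
        fc = frame_counts(_profile({3 * i: 9 for i in range(10)}), 0, 30)
        p_read, _ = periodicity_pvalues(fc)
        assert p_read == pytest.approx((1 / 3) ** 90, rel=1e-9)

    def test_zero_reads_give_unit_pvalues(self):
        fc = frame_counts(_profile({}), 0, 30)
        assert periodicity_pvalues(fc) == (1.0, 1.0)

    def test_uniform_case_matches_exact_enumeration(self):
        """(30,30,30) over 10 codons with 9 reads each, no wins."""
        counts = {}
        for i in range(10):
            counts[3 * i] = counts[3 * i + 1] = counts[3 * i + 2] = 3
        fc = frame_counts(_profile(counts), 0, 30)
        p_read, p_codon = periodicity_pvalues(fc)
        # independent oracle: exact binomial tails computed from first principles
        F, F0 = 90, 30
        tail = sum(math.comb(F, k) * (1 / 3) ** k * (2 / 3) ** (F - k)
                   for k in range(F0, F + 1))
        assert p_read == pytest.approx(tail, rel=1e-9)
        assert p_codon == 1.0   # wins = 0 -> whole distribution

    def test_null_win_probability_exact_small_counts(self):
        """Direct enumeration over all (a,b,c) outcomes for tiny read counts."""
        for c in (1, 2, 3, 5):
            total = 0.0
            for a in range(c + 1):
                for b in range(c - a + 1):
                    d = c - a - b
                    if a > b and a > d:
                        total += (math.factorial(c)
                                  / (math.factorial(a) * math.factorial(b)
                                     * math.factorial(d)) * (1 / 3) ** c)
            assert null_win_probability(c) == pytest.approx(total, rel=1e-12)
        assert null_win_probability(31) == pytest.approx(1 / 3)

    def test_combiner_is_valid_under_dependence(self):
        assert combine_pvalues(0.01, 0.5) == pytest.approx(0.02)
        assert combine_pvalues(1.0, 1.0) == 1.0
        # fisher option remains available
        assert 0 < combine_pvalues(0.01, 0.5, "fisher") < 0.05


class TestStartStep:
    def _setup(self, down_per_codon, up_per_codon, ext_codons=30, cand_idx=15):
        ext = TheoreticalExtension("tx", 0, ext_codons, "stop_bounded")
        cds_start = 3 * ext_codons
        cand = CandidateStart("tx", 3 * cand_idx, "CTG")
        counts = {}
        for i in range(cand_idx):
            if up_per_codon:
                counts[3 * i] = up_per_codon
        for i in range(cand_idx, ext_codons):
            if down_per_codon:
                counts[3 * i] = down_per_codon
        return _profile(counts), cand, ext, cds_start

    def test_step_from_silence(self):
        prof, cand, ext, cds = self._setup(5, 0)
        sigma, _ = start_step_score(prof, cand, ext, cds)
        assert sigma == pytest.approx(5.1 / 0.1)

    def test_uniform_profile_no_step(self):
        prof, cand, ext, cds = self._setup(2, 2)
        sigma, _ = start_step_score(prof, cand, ext, cds)
        assert sigma == pytest.approx(1.0)

    def test_sigma_monotone_in_planted_step(self, rng):
        """sigma grows with the planted downstream/upstream density ratio."""
        sigmas = []
        for mult in (1, 2, 5, 10):
            prof, cand, ext, cds = self._setup(2 * mult, 2)
            sigmas.append(start_step_score(prof, cand, ext, cds)[0])
        assert sigmas == sorted(sigmas) and sigmas[0] < sigmas[-1]

    def test_iota_initiation_peak(self):
        ext = TheoreticalExtension("tx", 0, 30, "stop_bounded")
        cand = CandidateStart("tx", 45, "CTG")
        prof = RiboProfile("tx", {0: 1}, {45: 20}, length=300)
        _, iota = start_step_score(prof, cand, ext, 90)
        assert iota == pytest.approx(20 / (20 / 100 + 0.1))


class TestCallAndRank:
    def _cohort(self):
        ext = TheoreticalExtension("tx1", 0, 30, "stop_bounded")
        cds = 90
        # periodic candidate at 0; noise candidate at 45
        counts = {3 * i: 8 for i in range(30)}
        for i in range(15, 30):
            counts[3 * i + 1] = 7
            counts[3 * i + 2] = 8
        prof = RiboProfile("tx1", counts, {}, length=120)
        cands = [CandidateStart("tx1", 0, "CTG"), CandidateStart("tx1", 45, "GTG")]
        return {"tx1": prof}, {"tx1": ext}, {"tx1": cands}, {"tx1": cds}

    def test_periodic_candidate_dominates(self):
        profiles, exts, cands, cds = self._cohort()
        calls = call_and_rank(profiles, exts, cands, cds)
        assert len(calls) == 1 and calls[0].start.position == 0

    def test_rank_tie_broken_by_density(self):
        ext = TheoreticalExtension("t", 0, 20, "stop_bounded")
        profs, exts, cands, cds = {}, {}, {}, {}
        for tid, depth in (("txA", 10), ("txB", 2)):
            counts = {3 * i: depth for i in range(20)}
            profs[tid] = RiboProfile(tid, counts, {}, length=100)
            e = TheoreticalExtension(tid, 0, 20, "stop_bounded")
            exts[tid] = e
            cands[tid] = [CandidateStart(tid, 0, "CTG")]
            cds[tid] = 60
        calls = call_and_rank(profs, exts, cands, cds)
        by_tid = {c.transcript_id: c for c in calls}
        if by_tid["txA"].p_comb == by_tid["txB"].p_comb:
            assert by_tid["txA"].rank < by_tid["txB"].rank
        else:
            assert by_tid["txA"].rank < by_tid["txB"].rank  # denser is also stronger

    def test_rank_is_a_permutation(self, detection_cohort):
        c = detection_cohort
        calls = call_and_rank(c["profiles"], c["extensions"], c["candidates"],
                              c["cds_starts"])
        ranks = [p.rank for p in calls]
        assert sorted(ranks) == list(range(1, len(calls) + 1))

    def test_zero_read_transcripts_never_called(self, detection_cohort):
        c = detection_cohort
        calls = call_and_rank(c["profiles"], c["extensions"], c["candidates"],
                              c["cds_starts"])
        called = {p.transcript_id for p in calls}
        for tid in called:
            assert c["profiles"][tid].elong

    def test_gate_blocks_thin_regions(self):
        prof = RiboProfile("tx", {0: 5}, {}, length=100)
        ext = TheoreticalExtension("tx", 0, 20, "stop_bounded")
        cand = CandidateStart("tx", 0, "CTG")
        assert score_candidate(prof, cand, ext, 60, RiboConfig()) is None


class TestCalibrationAndPower:
    def test_median_pcomb_monotone_in_frame_bias(self, rng):
        """Stronger planted frame-0 bias never raises the median p_comb
        (depth held fixed over the generator's bias grid)."""
        medians = []
        for bias in (1 / 3, 0.5, 0.65, 0.8):
            ps = []
            for _ in range(200):
                L = int(rng.integers(20, 121))
                counts = {}
                for i in range(L):
                    n = int(rng.poisson(6.0))
                    trio = rng.multinomial(n, [bias, (1 - bias) / 2, (1 - bias) / 2])
                    for k in range(3):
                        if trio[k]:
                            counts[3 * i + k] = int(trio[k])
                fc = frame_counts(RiboProfile("t", counts, {}), 0, 3 * L)
                pr, pc = periodicity_pvalues(fc)
                ps.append(combine_pvalues(pr, pc))
            medians.append(float(np.median(ps)))
        assert all(b <= a + 1e-12 for a, b in zip(medians, medians[1:]))
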