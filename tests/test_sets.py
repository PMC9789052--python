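"""Gene-set construction and comparison statistics."""

import math

import numpy as np
import pytest

from ntescan.extension import CandidateStart, TheoreticalExtension
from ntescan.ribo import NtePrediction, RiboProfile
from ntescan.sets import (
    GeneSet,
    UntranslConfig,
    build_riboset,
    build_untranslset,
    compare_score_distributions,
    hypergeom_overlap,
    intersect_variants,
    rank_sweep,
    rank_vs_coverage,
)
from ntescan.transcript_io import GenomicInterval, TranscriptRecord


def _pred(tid, rank, codon="CTG"):
    return NtePrediction(tid, CandidateStart(tid, 0, codon), 0.8, 1e-6, 1e-3,
                         2e-6, 0.9, 5.0, 3.0, 1.0, rank=rank)


class TestRiboset:
    def test_top_n_and_aug_exclusion(self):
        ranked = [_pred(f"tx{i}", i + 1, "ATG" if i % 5 == 0 else "CTG")
                  for i in range(20)]
        gene_of = {f"tx{i}": f"g{i}" for i in range(20)}
        gs = build_riboset(ranked, gene_of, top_n=10)
        assert gs.members == {f"g{i}" for i in range(10) if i % 5 != 0}
        assert gs.params["top_n"] == 10

    def test_top_n_beyond_available_warns_and_uses_all(self, caplog):
        ranked = [_pred("tx0", 1)]
        import logging
        with caplog.at_level(logging.WARNING):
            gs = build_riboset(ranked, {"tx0": "g0"}, top_n=500)
        assert gs.members == {"g0"}
        assert any("exceeds" in r.message for r in caplog.records)

    def test_empty_ranking_allowed(self, caplog):
        gs = build_riboset([], {}, top_n=500)
        assert gs.members == set()


class TestHypergeom:
    def test_exact_small_universe(self):
        """|U|=10, |a|=4, |b|=5, overlap 3: p = 66/252 by direct enumeration."""
        universe = {f"g{i}" for i in range(10)}
        a = GeneSet("a", {"g0", "g1", "g2", "g3"})
        b = GeneSet("b", {"g0", "g1", "g2", "g5", "g6"})
        (res,) = hypergeom_overlap([(a, b)], universe)
        assert res.overlap == 3
        assert res.p_raw == pytest.approx(66 / 252, rel=1e-9)

    def test_empty_set_gives_unit_p(self):
        universe = {"g0", "g1"}
        (res,) = hypergeom_overlap([(GeneSet("a", set()), GeneSet("b", {"g0"}))],
                                   universe)
        assert res.p_raw == 1.0

    def test_universe_violation_fatal(self):
        with pytest.raises(ValueError, match="universe_violation"):
            hypergeom_overlap([(GeneSet("a", {"gX"}), GeneSet("b", set()))], {"g0"})

    def test_matches_monte_carlo_within_3se(self, rng):
        """Upper-tail p agrees with sampled overlap frequency at 1e5 draws."""
        M, n, N = 40, 12, 15
        universe = {f"g{i}" for i in range(M)}
        a = GeneSet("a", {f"g{i}" for i in range(n)})
        b = GeneSet("b", {f"g{i}" for i in range(20, 20 + N)})
        k = len(a.members & b.members)
        (res,) = hypergeom_overlap([(a, b)], universe)
        draws = rng.hypergeometric(n, M - n, N, size=100_000)
        mc = float(np.mean(draws >= k))
        se = math.sqrt(mc * (1 - mc) / 100_000)
        assert abs(res.p_raw - mc) <= 3 * se + 1e-12

    def test_bh_is_monotone(self, rng):
        universe = {f"g{i}" for i in range(100)}
        pairs = []
        for j in range(6):
            a = GeneSet(f"a{j}", set(rng.choice(sorted(universe), 20, replace=False)))
            b = GeneSet(f"b{j}", set(rng.choice(sorted(universe), 25, replace=False)))
            pairs.append((a, b))
        res = hypergeom_overlap(pairs, universe)
        res.sort(key=lambda r: r.p_raw)
        adj = [r.p_adj for r in res]
        assert adj == sorted(adj)
        assert all(r.p_adj >= r.p_raw for r in res)


class TestRankSweep:
    def test_all_reference_in_first_bin(self):
        ranked = [f"g{i}" for i in range(1500)]
        ref = GeneSet("ref", {f"g{i}" for i in range(100)})
        sweep = rank_sweep(ranked, ref, step=500)
        assert sweep.observed_increments == [100, 0, 0]

    def test_reference_absent_from_ranking(self):
        ranked = [f"g{i}" for i in range(1000)]
        ref = GeneSet("ref", {"other1", "other2"})
        sweep = rank_sweep(ranked, ref, step=500)
        assert sweep.observed_increments == [0, 0]
        assert sum(sweep.expected_increments) == pytest.approx(0.0)

    def test_increments_sum_to_total_overlap(self, rng):
        ranked = [f"g{i}" for i in rng.permutation(3000)]
        ref = GeneSet("ref", {f"g{i}" for i in range(0, 3000, 7)})
        sweep = rank_sweep(ranked, ref, step=500)
        assert sum(sweep.observed_increments) == len(ref.members & set(ranked))

    def test_planted_enrichment_detected(self, rng):
        """Reference genes sampled with rank-decaying probability produce a
        significant observed-vs-expected difference."""
        n = 6000
        ranked = [f"g{i}" for i in range(n)]
        weights = 1.0 / (np.arange(n) + 10)
        weights /= weights.sum()
        ref_idx = rng.choice(n, size=120, replace=False, p=weights)
        ref = GeneSet("ref", {f"g{i}" for i in ref_idx})
        sweep = rank_sweep(ranked, ref, step=500)
        assert sweep.test_p < 0.05


class TestRankVsCoverage:
    def test_perfect_anti_monotone(self):
        rho, _ = rank_vs_coverage([1, 2, 3, 4, 5], [100.0, 50.0, 20.0, 10.0, 1.0])
        assert rho == pytest.approx(-1.0)

    def test_constant_coverage_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            rank_vs_coverage([1, 2, 3, 4, 5], [2.0] * 5)

    def test_too_few_pairs(self):
        with pytest.raises(ValueError, match="insufficient_n"):
            rank_vs_coverage([1, 2], [1.0, 2.0])

    def test_coverage_driven_ranking_strongly_negative(self, rng):
        """When ranks track density (denser -> better rank), rho << 0."""
        dens = rng.lognormal(2.0, 1.0, size=200)
        noisy = dens * rng.lognormal(0, 0.2, size=200)
        ranks = (len(dens) - np.argsort(np.argsort(noisy))).tolist()
        rho, p = rank_vs_coverage(ranks, dens.tolist())
        assert rho < -0.5 and p < 1e-6


class TestKSandPermutationOracles:
    def test_identical_samples(self):
        stat, p, method = compare_score_distributions([1, 2, 3], [1, 2, 3])
        assert stat == 0.0 and method == "exact"

    def test_disjoint_supports(self):
        stat, _, _ = compare_score_distributions([1, 2, 3], [10, 11, 12])
        assert stat == 1.0

    def test_ks_p_within_3se_of_permutation_oracle(self, rng):
        from scipy.stats import ks_2samp
        x = list(rng.normal(0, 1, 9))
        y = list(rng.normal(0.4, 1, 8))
        stat, p, _ = compare_score_distributions(x, y)
        pooled = np.array(x + y)
        n_perm = 10_000
        hits = 0
        for _ in range(n_perm):
            rng.shuffle(pooled)
            s = ks_2samp(pooled[:9], pooled[9:]).statistic
            hits += s >= stat - 1e-12
        est = hits / n_perm
        se = math.sqrt(est * (1 - est) / n_perm)
        assert abs(p - est) <= 3 * se + 0.01

    def test_mannwhitney_p_within_3se_of_permutation_oracle(self, rng):
        from scipy.stats import mannwhitneyu
        x = list(rng.normal(0, 1, 8))
        y = list(rng.normal(0.8, 1, 7))
        res = mannwhitneyu(x, y, alternative="two-sided", method="exact")
        stat_obs = abs(res.statistic - len(x) * len(y) / 2)
        pooled = np.array(x + y)
        n_perm = 10_000
        hits = 0
        for _ in range(n_perm):
            rng.shuffle(pooled)
            s = mannwhitneyu(pooled[:8], pooled[8:], alternative="two-sided",
                             method="asymptotic").statistic
            hits += abs(s - len(x) * len(y) / 2) >= stat_obs - 1e-12
        est = hits / n_perm
        se = math.sqrt(est * (1 - est) / n_perm)
        assert abs(res.pvalue - est) <= 3 * se + 0.01


def _untransl_fixture():
    """Hand-built cohort exercising every rule, including exact boundaries."""
    records, exts, profiles = {}, {}, {}

    def add(tid, ext_codons, cds_codons, elong, flags=frozenset()):
        seq = "TAA" + "GCA" * ext_codons + "ATG" + "GCA" * (cds_codons - 2) + "TAA"
        rec = TranscriptRecord(tid, f"gene_{tid}", seq, 3 + 3 * ext_codons,
                               3 + 3 * ext_codons + 3 * cds_codons,
                               flags=set(flags))
        records[tid] = rec
        exts[tid] = TheoreticalExtension(tid, 3, ext_codons, "stop_bounded")
        profiles[tid] = RiboProfile(tid, elong, {})
        return rec

    def cds_reads(rec, per_codon=2, covered_fraction=1.0):
        cs, ce = rec.cds_start, rec.cds_end
        n = (ce - cs) // 3
        reads = {}
        for i in range(int(n * covered_fraction)):
            reads[cs + 3 * i] = per_codon
        return reads

    r = add("t_trunc", 30, 100, {}, flags={"cds_start_NF"})
    profiles["t_trunc"].elong.update(cds_reads(r))
    r = add("t_short", 10, 100, {})
    profiles["t_short"].elong.update(cds_reads(r))
    r = add("t_pred", 30, 100, {})
    profiles["t_pred"].elong.update(cds_reads(r))
    # rule 5 boundary: 2000-nt extension, exactly 1 covered position = 0.0005
    r = add("t_ext_boundary", 667, 102, {})                       # 2001 nt ext
    r = add("t_ext_2000", 30, 100, {})
    profiles["t_ext_2000"].elong.update(cds_reads(records["t_ext_2000"]))
    profiles["t_ext_2000"].elong[10] = 1   # fraction 1/90 = 0.0111 > 0.0005
    # rule 6 boundary: exactly 1.0 in-frame read per codon passes
    r = add("t_cds_exact1", 30, 100, {})
    profiles["t_cds_exact1"].elong.update(cds_reads(r, per_codon=1))
    r = add("t_cds_low", 30, 100, {})
    profiles["t_cds_low"].elong.update(cds_reads(r, per_codon=1, covered_fraction=0.5))
    # rule 7 boundary: breadth exactly 0.3 passes, just below fails
    r = add("t_breadth_exact", 30, 100, {})
    reads = {}
    for i in range(90):
        reads[r.cds_start + 3 * i] = 2 if i < 10 else 1     # 100 reads, 90 covered
    profiles["t_breadth_exact"].elong = reads
    r = add("t_breadth_low", 30, 100, {})
    reads = {}
    for i in range(89):
        reads[r.cds_start + 3 * i] = 2 if i < 11 else 1     # 100 reads, 89 covered
    profiles["t_breadth_low"].elong = reads
    r = add("t_clean", 30, 100, {})
    profiles["t_clean"].elong.update(cds_reads(r))
    overlap_ok = {tid: tid != "t_overlap" for tid in records}
    r = add("t_overlap", 30, 100, {})
    profiles["t_overlap"].elong.update(cds_reads(r))
    overlap_ok["t_overlap"] = False
    return records, exts, overlap_ok, profiles


class TestUntranslset:
    def test_rules_fire_in_order_with_exact_boundaries(self):
        records, exts, overlap_ok, profiles = _untransl_fixture()
        # give the 2000-nt-extension gene a CDS and exactly one extension read
        rec = records["t_ext_boundary"]
        prof = profiles["t_ext_boundary"]
        for i in range((rec.cds_end - rec.cds_start) // 3):
            prof.elong[rec.cds_start + 3 * i] = 2
        prof.elong[rec.cds_start - 2001 + 5] = 1   # 1/2001 < 0.0005 -> passes
        gs, attrition, chosen = build_untranslset(
            records, exts, overlap_ok, profiles,
            predicted_transcripts={"t_pred"}, predicted_genes={"gene_t_pred"})
        assert attrition == {
            "truncated_cds": 1, "coding_overlap": 1, "short_extension": 1,
            "in_predicted_set": 1, "extension_covered": 1,
            "low_cds_coverage": 1, "low_cds_breadth": 1,
        }
        assert gs.members == {"gene_t_clean", "gene_t_cds_exact1",
                              "gene_t_breadth_exact", "gene_t_ext_boundary"}

    def test_exact_half_thousandth_extension_boundary(self):
        """Covered fraction exactly 0.0005 (1 of 2000 nt) is kept; 2 of 2000 dropped."""
        records, exts, profiles = {}, {}, {}
        seq = "TAA" + "GCA" * 667 + "ATG" + "GCA" * 100 + "TAA"
        # extension must be exactly 2000 nt: use 667 codons = 2001 -> build 666+2
        ext_codons = 667
        rec = TranscriptRecord("t", "g", seq, 3 + 3 * ext_codons,
                               3 + 3 * ext_codons + 306)
        ext = TheoreticalExtension("t", 3, ext_codons, "stop_bounded")
        elong = {rec.cds_start + 3 * i: 2 for i in range(102)}
        prof = RiboProfile("t", dict(elong), {})
        prof.elong[3] = 1   # 1/2001 = 0.0004997 <= 0.0005 -> keep
        gs, att, _ = build_untranslset({"t": rec}, {"t": ext}, {"t": True},
                                       {"t": prof}, set(), set())
        assert gs.members == {"g"}
        prof.elong[6] = 1   # 2/2001 > 0.0005 -> rule 5
        gs, att, _ = build_untranslset({"t": rec}, {"t": ext}, {"t": True},
                                       {"t": prof}, set(), set())
        assert att["extension_covered"] == 1 and not gs.members

    def test_one_transcript_per_gene_highest_cds_coverage(self):
        records, exts, profiles = {}, {}, {}
        for tid, per_codon in (("txA", 2), ("txB", 5)):
            seq = "TAA" + "GCA" * 30 + "ATG" + "GCA" * 98 + "TAA"
            rec = TranscriptRecord(tid, "g1", seq, 93, 393)
            records[tid] = rec
            exts[tid] = TheoreticalExtension(tid, 3, 30, "stop_bounded")
            profiles[tid] = RiboProfile(
                tid, {rec.cds_start + 3 * i: per_codon for i in range(100)}, {})
        gs, _, chosen = build_untranslset(records, exts, {t: True for t in records},
                                          profiles, set(), set())
        assert chosen == {"g1": "txB"}


class TestVariants:
    def _vcf(self, path, rows):
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n"
                     "##contig=<ID=chr1,length=100000>\n"
                     '##INFO=<ID=CLNSIG,Number=.,Type=String,Description="x">\n'
                     "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
            for pos1, vid, cls in rows:
                fh.write(f"chr1\t{pos1}\t{vid}\tA\tG\t.\t.\tCLNSIG={cls}\n")

    def _win(self, blocks):
        from ntescan.extension import ExtensionWindow
        n = sum(len(b) for b in blocks) // 3
        return ExtensionWindow("tx", 0, n, "GCA" * n, list(blocks))

    def test_coordinate_conversion_and_filter(self, tmp_path):
        """VCF pos 5001 (1-based) hits block (5000, 5060)."""
        p = tmp_path / "v.vcf"
        self._vcf(p, [(5001, "v_in", "Pathogenic"),
                      (5060, "v_in2", "Benign"),
                      (9000, "v_out", "Pathogenic")])
        win = self._win([GenomicInterval("chr1", 5000, 5060, "+")])
        hits = intersect_variants([win], p, classifications={"Pathogenic"})
        assert [(h[1], h[2]) for h in hits] == [("v_in", "Pathogenic")]
        hits_all = intersect_variants([win], p)
        assert {h[1] for h in hits_all} == {"v_in", "v_in2"}

    def test_generator_hits_match_interval_oracle(self, demo_bundle, demo_records):
        import json
        d, paths = demo_bundle
        from ntescan.extension import clip_window, extract_theoretical_extension
        truth = json.loads((d / "truth.json").read_text())
        windows = []
        for rec in demo_records:
            gt = truth[rec.gene_id]
            if gt["klass"] in ("overlap_victim", "overlap_source"):
                continue
            ext, _ = extract_theoretical_extension(rec)
            if ext is None or ext.length_codons < 20:
                continue
            windows.append(clip_window(ext, rec))
        gene_of = {r.transcript_id: r.gene_id for r in demo_records}
        hits = intersect_variants(windows, paths["vcf"], gene_of=gene_of)
        expected = set()
        for gid, gt in truth.items():
            for vid, cls in gt["expected_variant_hits"]:
                expected.add((gid, vid))
        assert {(g, v) for g, v, _ in hits} == expected
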