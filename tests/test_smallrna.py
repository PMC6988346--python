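"""Small-RNA quantification tests: classification, 1U fractions,
ping-pong Z-scores against an exhaustive pair-enumeration oracle, RPKM,
target prediction against a brute-force substring scan, and the de novo
signature thresholds."""

import numpy as np
import pytest

from tepirna.smallrna import (NormalizationTotals, SmallRNARecord,
                              build_profiles, classify_reads,
                              denovo_signature, first_nt_fractions,
                              pingpong_zscore, pirna_rpkm, predict_targets,
                              profile_rpkm, revcomp)
from tepirna.synth import ReadPlan, SynthConfig, make_smallrna_reads


def read(rid, seq, *hits):
    return SmallRNARecord(rid, seq, list(hits))


def brute_force_overlap_counts(records, ref_lengths, max_overlap=23):
    """O(n^2) oracle: enumerate all sense/antisense hit pairs and bin
    their 5'-5' overlap lengths with split weights."""
    counts = np.zeros(max_overlap)
    flat = []
    for rec in records:
        for ref, start, strand in rec.hits:
            five = start if strand == "+" else start + rec.length - 1
            flat.append((ref, strand, five, rec.weight_per_hit))
    for ref1, strand1, f1, w1 in flat:
        if strand1 != "+":
            continue
        for ref2, strand2, f2, w2 in flat:
            if strand2 != "-" or ref2 != ref1:
                continue
            o = f2 - f1 + 1
            if 1 <= o <= max_overlap:
                counts[o - 1] += w1 * w2
    return counts


def brute_force_targets(reads, refs):
    """Independent all-substring scan for seed (2-11) target prediction."""
    weights = {name: 0.0 for name in refs}
    for rec in reads:
        seq = rec.sequence.upper()
        if len(seq) < 11:
            continue
        probe = revcomp(seq[1:11])
        sites = []
        for name, ref in refs.items():
            for i in range(len(ref) - len(probe) + 1):
                if ref[i:i + len(probe)] == probe:
                    sites.append(name)
        if sites:
            for name in sites:
                weights[name] += 1.0 / len(sites)
    return weights


class TestClassify:
    def test_length_binning(self):
        recs = [read("a", "A" * 25, ("TE_1", 0, "+")),
                read("b", "A" * 21, ("TE_1", 0, "+")),
                read("c", "A" * 19, ("TE_1", 0, "+")),
                read("d", "A" * 31, ("TE_1", 0, "+"))]
        out = classify_reads(recs)
        assert [r.read_id for r in out["piRNA"]] == ["a"]
        assert [r.read_id for r in out["siRNA"]] == ["b"]
        assert {r.read_id for r in out["other"]} == {"c", "d"}

    def test_annotation_overlap_excludes(self):
        rec = read("a", "A" * 25, ("chr1", 100, "+"))
        out = classify_reads([rec], {"chr1": [(110, 200)]})
        assert out["excluded"] == [rec]
        out = classify_reads([rec], {"chr1": [(200, 300)]})
        assert out["piRNA"] == [rec]


class TestFirstNt:
    def test_all_u(self):
        recs = [read(f"r{i}", "T" + "A" * 24, ("TE_1", 0, "+"))
                for i in range(5)]
        assert first_nt_fractions(recs)["U"] == 1.0

    def test_uniform(self):
        recs = [read(f"r{i}", nt + "A" * 24, ("TE_1", 0, "+"))
                for i, nt in enumerate("ACGT")]
        fr = first_nt_fractions(recs)
        assert all(fr[k] == 0.25 for k in "ACGU")

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            first_nt_fractions([])

    def test_synthetic_bias_recovered(self):
        cfg = SynthConfig(seed=3, n_families=1, u1_bias=0.721,
                          te_length_range=(20000, 20000))
        from tepirna.synth import make_te_references
        refs = make_te_references(cfg)
        recs, _ = make_smallrna_reads(
            cfg, refs, {"TE_1": ReadPlan(sense=4000, antisense=4000)})
        fr = first_nt_fractions(recs)
        # binomial sampling: s.e. ~ sqrt(0.721*0.279/8000) ~ 0.005
        assert fr["U"] == pytest.approx(0.721, abs=0.02)


class TestPingPong:
    def test_counts_match_exhaustive_enumeration(self, cfg, te_refs):
        recs, _ = make_smallrna_reads(
            cfg, te_refs,
            {"TE_1": ReadPlan(sense=30, antisense=30, pingpong_pairs=15),
             "TE_2": ReadPlan(sense=20, antisense=20, pingpong_pairs=5)})
        lens = {k: len(v) for k, v in te_refs.items()}
        res = pingpong_zscore(recs, lens)
        oracle = brute_force_overlap_counts(recs, lens)
        assert np.allclose(res.counts, oracle, atol=1e-9)
        assert res.counts[9] >= 20  # at least the planted pairs

    def test_planted_overlap_dominates(self, cfg, te_refs):
        recs, _ = make_smallrna_reads(
            cfg, te_refs, {"TE_1": ReadPlan(pingpong_pairs=100)})
        res = pingpong_zscore(recs, {k: len(v) for k, v in te_refs.items()})
        assert res.defined
        assert res.z10 == res.zscores.max()
        assert res.z10 > 3

    def test_no_antisense_flagged_undefined(self):
        recs = [read(f"r{i}", "A" * 25, ("TE_1", i * 30, "+"))
                for i in range(10)]
        res = pingpong_zscore(recs, {"TE_1": 1000})
        assert not res.defined
        assert np.all(res.counts == 0)

    def test_null_overlaps_give_small_z10(self):
        hits = 0
        for seed in range(40):
            r = np.random.default_rng(seed)
            recs = []
            for i in range(120):
                strand = "+" if i % 2 == 0 else "-"
                recs.append(read(f"r{i}", "A" * 25,
                                 ("TE_1", int(r.integers(0, 500)), strand)))
            res = pingpong_zscore(recs, {"TE_1": 1000})
            if res.defined and abs(res.z10) < 2:
                hits += 1
        assert hits >= 36  # |Z(10)| < 2 in >= 90% of null draws


class TestRpkm:
    def test_direct_evaluation(self):
        totals = NormalizationTotals(1e6)
        assert pirna_rpkm(10.0, 1000, totals) == pytest.approx(10.0)

    def test_zero_count(self):
        assert pirna_rpkm(0.0, 1000, NormalizationTotals(1e6)) == 0.0

    def test_doubling_totals_halves_rpkm(self):
        a = pirna_rpkm(7.0, 500, NormalizationTotals(1e6))
        b = pirna_rpkm(7.0, 500, NormalizationTotals(2e6))
        assert a == pytest.approx(2 * b)

    def test_zero_totals_rejected(self):
        with pytest.raises(ValueError):
            pirna_rpkm(1.0, 100, NormalizationTotals(0.0))

    def test_weight_conservation_across_profiles(self, cfg, te_refs):
        plans = {f: ReadPlan(sense=40, antisense=40) for f in te_refs}
        recs, _ = make_smallrna_reads(cfg, te_refs, plans)
        profiles = build_profiles(recs,
                                  {k: len(v) for k, v in te_refs.items()})
        total = sum(p.total for p in profiles.values())
        assert total == pytest.approx(len(recs), abs=1e-9)


class TestPredictTargets:
    def test_unique_target_gets_full_weight(self):
        te1 = "A" * 50 + "GGATCCGGTT" + "A" * 50
        te2 = "C" * 100
        pirna = "G" + revcomp("GGATCCGGTT") + "G" * 14  # pos 2-11 seed
        out = predict_targets([read("r0", pirna, ("x", 0, "+"))],
                              {"TE1": te1, "TE2": te2})
        assert out["TE1"] == 1.0 and out["TE2"] == 0.0

    def test_shared_target_split_equally(self):
        motif = "GGATCCGGTT"
        te1 = "A" * 30 + motif + "A" * 30
        te2 = "T" * 30 + motif + "T" * 30
        pirna = "G" + revcomp(motif) + "G" * 14
        out = predict_targets([read("r0", pirna, ("x", 0, "+"))],
                              {"TE1": te1, "TE2": te2})
        assert out["TE1"] == pytest.approx(0.5)
        assert out["TE2"] == pytest.approx(0.5)

    def test_mismatch_in_seed_is_no_target(self):
        motif = "GGATCCGGTT"
        te1 = "A" * 30 + motif + "A" * 30
        seed = revcomp(motif)
        mutated = ("C" if seed[4] != "C" else "G")
        pirna = "G" + seed[:4] + mutated + seed[5:] + "G" * 14
        out = predict_targets([read("r0", pirna, ("x", 0, "+"))], {"TE1": te1})
        assert out["TE1"] == 0.0

    def test_agrees_with_brute_force_scan(self, cfg, te_refs):
        recs, _ = make_smallrna_reads(
            cfg, te_refs,
            {f: ReadPlan(sense=8, antisense=8) for f in te_refs})
        out = predict_targets(recs, te_refs)
        oracle = brute_force_targets(recs, te_refs)
        for name in te_refs:
            assert out[name] == pytest.approx(oracle[name], abs=1e-9)

    def test_short_read_skipped_with_warning(self):
        warnings = []
        out = predict_targets([read("r0", "ACGTACGT", ("x", 0, "+"))],
                              {"TE1": "A" * 50}, warn=warnings.append)
        assert out["TE1"] == 0.0
        assert len(warnings) == 1


class TestDeNovoSignature:
    totals = NormalizationTotals(1e6)

    def flank_reads(self, n_up_anti, n_up_sense, n_dn_sense, n_dn_anti,
                    pos=10000, contig="2L"):
        recs = []
        k = 0
        for n, strand, upstream in [(n_up_anti, "-", True),
                                    (n_up_sense, "+", True),
                                    (n_dn_sense, "+", False),
                                    (n_dn_anti, "-", False)]:
            for _ in range(n):
                start = pos - 1000 if upstream else pos + 500
                recs.append(read(f"f{k}", "A" * 25,
                                 (contig, start, strand)))
                k += 1
        return recs

    def call(self, recs, pos=10000):
        return denovo_signature(pos, recs, "2L", 1_000_000, self.totals)

    def test_clean_signature_positive(self):
        # 4 weighted reads over 4 kb at totals 1e6 -> 1.0 RPKM
        recs = self.flank_reads(2, 0, 2, 0)
        call = self.call(recs)
        assert call.positive and call.rpkm == pytest.approx(1.0)
        assert call.asymmetry == 1.0

    def test_rpkm_below_threshold_negative(self):
        # 1 read -> 0.25 RPKM < 0.5, despite perfect asymmetry
        call = self.call(self.flank_reads(1, 0, 0, 0))
        assert not call.positive
        assert call.rpkm == pytest.approx(0.25)

    def test_asymmetry_below_threshold_negative(self):
        # 6/10 on signature strands = 60% < 70%
        call = self.call(self.flank_reads(3, 2, 3, 2))
        assert not call.positive
        assert call.asymmetry == pytest.approx(0.6)

    def test_zero_flank_reads_negative_not_error(self):
        call = self.call([])
        assert not call.positive and call.n_reads == 0

    def test_multimappers_ignored_by_default(self):
        rec = read("m", "A" * 25, ("2L", 9000, "-"), ("2L", 500000, "-"))
        call = self.call([rec])
        assert call.n_reads == 0

    def test_threshold_sweep_flips_exactly_at_cutoffs(self):
        # depth sweep at perfect asymmetry: positive iff RPKM >= 0.5,
        # i.e. >= 2 weighted reads at these totals
        for n in range(0, 5):
            call = self.call(self.flank_reads(n, 0, 0, 0))
            assert call.positive == (n >= 2)
        # asymmetry sweep at ample depth (20 reads -> 5 RPKM)
        for sig in range(10, 21):
            call = self.call(self.flank_reads(sig // 2 + sig % 2, 0,
                                              sig // 2, 20 - sig))
            assert call.positive == (sig / 20.0 >= 0.70)
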