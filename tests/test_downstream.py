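import itertools

import numpy as np
import pytest

from chromoshatter import (KataegisCall, RegionStatistics, RunConfig,
                           SNVRecord, TIMING_SHATTER_FIRST,
                           TIMING_UNDETERMINED, TIMING_WGD_FIRST,
                           classify_apobec, detect_chromothripsis,
                           infer_wgd_timing, kataegis_in_region, make_sv,
                           repair_signature_summary, simulate_apobec_cluster,
                           simulate_chromothripsis)
from chromoshatter.caller import ChromothripsisCall

COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


def timing_call(lo, hi, run=8, canonical=True):
    stats = RegionStatistics(max_osc_2=run, frac_osc_2=0.9,
                             osc_levels=(lo, hi))
    return ChromothripsisCall(event_id="e", sample_id="s",
                              region_per_chrom={"chr1": (1, 100)},
                              stats_per_chrom={"chr1": stats},
                              confidence="high", defining_chrom="chr1",
                              canonical=canonical)


class TestWgdTiming:
    def test_two_four_oscillation_means_shattering_first(self, cfg):
        t = infer_wgd_timing(timing_call(2, 4), ploidy=3.9, cfg=cfg)
        assert t.relation == TIMING_SHATTER_FIRST

    def test_three_four_oscillation_means_doubling_first(self, cfg):
        t = infer_wgd_timing(timing_call(3, 4), ploidy=3.9, cfg=cfg)
        assert t.relation == TIMING_WGD_FIRST

    def test_diploid_sample_undetermined(self, cfg):
        t = infer_wgd_timing(timing_call(1, 2), ploidy=2.0, cfg=cfg)
        assert t.relation == TIMING_UNDETERMINED

    def test_one_two_pattern_is_ambiguous_even_in_polyploid(self, cfg):
        # (1,2) satisfies both the halved and the single-loss patterns
        t = infer_wgd_timing(timing_call(1, 2), ploidy=3.9, cfg=cfg)
        assert t.relation == TIMING_UNDETERMINED

    def test_short_run_undetermined(self, cfg):
        t = infer_wgd_timing(timing_call(2, 4, run=5), ploidy=3.9, cfg=cfg)
        assert t.relation == TIMING_UNDETERMINED

    @pytest.mark.parametrize("wgd,expected", [
        ("after", TIMING_SHATTER_FIRST), ("before", TIMING_WGD_FIRST)])
    def test_recovers_generating_order_and_never_opposite(self, wgd, expected, cfg):
        opposite = (TIMING_WGD_FIRST if expected == TIMING_SHATTER_FIRST
                    else TIMING_SHATTER_FIRST)
        correct = 0
        for seed in range(25):
            profile, _ = simulate_chromothripsis(wgd=wgd, seed=seed)
            calls = [c for c in detect_chromothripsis(profile, cfg)
                     if c.confidence != "none"]
            assert calls
            t = infer_wgd_timing(calls[0], profile.ploidy, cfg)
            assert t.relation != opposite
            correct += t.relation == expected
        assert correct >= 23  # canonical run survives in nearly all seeds


def apobec_oracle(ctx, ref, alt):
    """Independent restatement of the two-clause motif rule."""
    w = {"A", "T"}
    clause1 = (ref == "C" and ctx[0] == "T" and ctx[2] in w and alt in {"G", "T"})
    clause2 = (ref == "G" and ctx[2] == "A" and ctx[0] in w and alt in {"C", "A"})
    return clause1 or clause2


class TestApobecClassifier:
    def test_motif_examples(self):
        assert classify_apobec(SNVRecord("chr1", 1, "C", "T", "TCA")) is True
        assert classify_apobec(SNVRecord("chr1", 1, "C", "A", "TCA")) is False

    def test_exhaustive_context_alt_enumeration(self):
        bases = "ACGT"
        for l, ref, r in itertools.product(bases, repeat=3):
            for alt in bases:
                if alt == ref:
                    continue
                snv = SNVRecord("chr1", 10, ref, alt, f"{l}{ref}{r}")
                assert classify_apobec(snv) == apobec_oracle(f"{l}{ref}{r}",
                                                             ref, alt)

    def test_strand_symmetry(self):
        bases = "ACGT"
        for l, ref, r in itertools.product(bases, repeat=3):
            for alt in bases:
                if alt == ref:
                    continue
                fwd = SNVRecord("chr1", 10, ref, alt, f"{l}{ref}{r}")
                rev = SNVRecord("chr1", 10, COMP[ref], COMP[alt],
                                f"{COMP[r]}{COMP[ref]}{COMP[l]}")
                assert classify_apobec(fwd) == classify_apobec(rev)

    def test_context_ref_mismatch_is_contract_violation(self):
        with pytest.raises(ValueError):
            SNVRecord("chr1", 1, "C", "T", "TGA")


def apobec_snvs(n, spacing, start=1_000_000):
    return [SNVRecord("chr1", start + i * spacing, "C", "T", "TCA")
            for i in range(n)]


class TestKataegis:
    REGION = (1, 10_000_000)

    def test_six_close_mutations_cooccur_without_kataegis(self, cfg):
        kc = kataegis_in_region(apobec_snvs(6, 200), self.REGION, cfg)
        assert (kc.cooccurrence, kc.kataegis) == (True, False)

    def test_twentyfive_close_mutations_are_kataegis(self, cfg):
        kc = kataegis_in_region(apobec_snvs(25, 500), self.REGION, cfg)
        assert kc.kataegis is True

    def test_widely_spaced_mutations_never_chain(self, cfg):
        kc = kataegis_in_region(apobec_snvs(5, 50_000), self.REGION, cfg)
        assert (kc.cooccurrence, kc.max_cluster) == (False, 1)

    def test_non_apobec_mutations_ignored(self, cfg):
        snvs = [SNVRecord("chr1", 1000 + i * 100, "A", "G", "CAC")
                for i in range(30)]
        kc = kataegis_in_region(snvs, self.REGION, cfg)
        assert kc.n_apobec_in_region == 0

    def test_flags_monotone_in_chain_distance(self, cfg):
        rng = np.random.default_rng(8)
        pos = np.sort(rng.integers(1, 200_000, size=40))
        snvs = [SNVRecord("chr1", int(p), "C", "G", "TCT") for p in pos]
        prev = 0
        for imd in (100, 500, 1_000, 5_000, 50_000):
            kc = kataegis_in_region(snvs, self.REGION,
                                    cfg.replace(kataegis_imd=imd))
            assert kc.max_cluster >= prev
            prev = kc.max_cluster

    def test_simulated_shower_hits_thresholds(self, cfg):
        snvs = simulate_apobec_cluster(n=25, imd=500, seed=1)
        assert all(classify_apobec(s) for s in snvs)
        region = (min(s.pos for s in snvs) - 1, max(s.pos for s in snvs) + 1)
        assert kataegis_in_region(snvs, region, cfg).kataegis is True
        few = simulate_apobec_cluster(n=4, imd=500, seed=2)
        region = (min(s.pos for s in few) - 1, max(s.pos for s in few) + 1)
        assert kataegis_in_region(few, region, cfg).cooccurrence is False


def junctions(homs, inss):
    return [make_sv(f"j{k}", "chr1", 1000 * (k + 1), "+",
                    "chr1", 1_000_000 + 1000 * k, "-",
                    homology_len=h, insertion_len=i)
            for k, (h, i) in enumerate(zip(homs, inss))]


class TestRepairSignature:
    def test_short_homology_no_insertions_is_end_joining(self):
        svs = junctions([0, 1, 2, 3, 1], [0] * 5)
        assert repair_signature_summary(svs) == "EJ_like"

    def test_templated_insertions_with_microhomology_is_mmbir(self):
        svs = junctions([2, 3, 2, 4, 3], [120, 40, 379, 15, 11])
        assert repair_signature_summary(svs) == "MMBIR_like"

    def test_insufficient_annotation_missing(self):
        svs = junctions([None, None, 2], [None, None, 0])
        assert repair_signature_summary(svs) is None

    def test_long_homology_without_insertions_is_mixed(self):
        svs = junctions([40, 50, 60, 45, 55], [0] * 5)
        assert repair_signature_summary(svs) == "mixed"
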