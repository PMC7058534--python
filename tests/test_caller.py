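import numpy as np
import pytest

from chromoshatter import (CNSegment, GeneRecord, RegionStatistics, RunConfig,
                           build_clusters, canonical_flag, classify_confidence,
                           detect_chromothripsis, detect_double_minute,
                           evaluate_event, focal_amplifications,
                           fragment_join_test, lost_genes_in_event,
                           simulate_chromothripsis)
from chromoshatter.caller import CONF_HIGH, CONF_LOW, CONF_NONE, REASON_NO_CN

from conftest import staggered_cluster


def passing_stats(**overrides):
    """Region statistics that clear every gate at the high tier."""
    base = dict(max_osc_2=7, max_osc_3=8, frac_osc_2=0.9,
                p_fragment_joins=0.8, p_exponential=0.5, p_enrichment=1e-8,
                loh_interspersed=True, foldback_fraction=0.0,
                median_homology=2.0, frac_long_homology=0.0,
                n_segments=9, cn_coverage=1.0, evaluable=True)
    base.update(overrides)
    return RegionStatistics(**base)


@pytest.fixture
def six_sv_cluster():
    return build_clusters(staggered_cluster(6))[0]


class TestClassifyConfidence:
    def test_boundary_high_call(self, six_sv_cluster, cfg):
        conf, chrom, reason = classify_confidence(
            {"chr1": passing_stats()}, six_sv_cluster, cfg)
        assert (conf, chrom, reason) == (CONF_HIGH, "chr1", "")

    def test_oscillation_run_five_is_low(self, six_sv_cluster, cfg):
        conf, chrom, _ = classify_confidence(
            {"chr1": passing_stats(max_osc_2=5)}, six_sv_cluster, cfg)
        assert conf == CONF_LOW

    def test_oscillation_run_three_is_none(self, six_sv_cluster, cfg):
        conf, _, reason = classify_confidence(
            {"chr1": passing_stats(max_osc_2=3)}, six_sv_cluster, cfg)
        assert (conf, reason) == (CONF_NONE, "oscillation")

    def test_pure_tandem_dup_spectrum_rejected_on_joins(self, six_sv_cluster, cfg):
        # 20 duplication-like joins: imbalance far beyond the strict floor
        p = fragment_join_test((0, 20, 0, 0))
        assert p < cfg.alpha_joins_strict
        conf, _, reason = classify_confidence(
            {"chr1": passing_stats(p_fragment_joins=p)}, six_sv_cluster, cfg)
        assert (conf, reason) == (CONF_NONE, "fragment_joins")

    def test_marginal_join_imbalance_demotes_to_low(self, six_sv_cluster, cfg):
        conf, chrom, reason = classify_confidence(
            {"chr1": passing_stats(p_fragment_joins=0.02)}, six_sv_cluster, cfg)
        assert (conf, reason) == (CONF_LOW, "")

    def test_foldback_dominated_cluster_rejected(self, six_sv_cluster, cfg):
        conf, _, reason = classify_confidence(
            {"chr1": passing_stats(foldback_fraction=0.6)}, six_sv_cluster, cfg)
        assert (conf, reason) == (CONF_NONE, "foldback")

    def test_unevaluable_region_reports_cn_coverage(self, six_sv_cluster, cfg):
        conf, _, reason = classify_confidence(
            {"chr1": passing_stats(evaluable=False)}, six_sv_cluster, cfg)
        assert (conf, reason) == (CONF_NONE, REASON_NO_CN)

    def test_tier_monotone_under_gate_relaxation(self, cfg):
        rank = {CONF_NONE: 0, CONF_LOW: 1, CONF_HIGH: 2}
        relaxed = cfg.replace(alpha_joins=0.01, foldback_max=0.9,
                              homology_max=0.9, low_min_osc=3)
        for seed in range(20):
            profile, _ = simulate_chromothripsis(seed=seed)
            base = detect_chromothripsis(profile, cfg)
            loose = detect_chromothripsis(profile, relaxed)
            best = lambda calls: max((rank[c.confidence] for c in calls),
                                     default=0)
            assert best(loose) >= best(base), seed


class TestCanonicalFlag:
    def test_strict_threshold(self, cfg):
        assert canonical_flag(passing_stats(frac_osc_2=0.61), cfg) is True
        assert canonical_flag(passing_stats(frac_osc_2=0.60), cfg) is False


class TestEvaluateEvent:
    def test_simulated_canonical_event_statistics(self, cfg):
        profile, truth = simulate_chromothripsis(seed=1)
        from chromoshatter import cluster_sample
        cluster = cluster_sample(profile.svs)[0]
        stats = evaluate_event(profile, cluster, cfg)["chr1"]
        assert stats.max_osc_2 >= 7
        assert stats.loh_interspersed is True
        assert stats.frac_osc_2 > 0.6

    def test_region_without_cn_is_unevaluable(self, cfg, six_sv_cluster):
        from chromoshatter import SampleProfile
        profile = SampleProfile(sample_id="s", svs=staggered_cluster(6),
                                cn=[], chrom_lengths={"chr1": 1_000_000})
        stats = evaluate_event(profile, six_sv_cluster, cfg)
        assert stats["chr1"].evaluable is False
        conf, _, reason = classify_confidence(stats, six_sv_cluster, cfg)
        assert (conf, reason) == (CONF_NONE, REASON_NO_CN)

    def test_deterministic_under_input_permutation(self, cfg):
        profile, _ = simulate_chromothripsis(seed=9)
        rng = np.random.default_rng(0)
        calls_a = detect_chromothripsis(profile, cfg)
        profile.svs = [profile.svs[i] for i in rng.permutation(len(profile.svs))]
        profile.cn = sorted(profile.cn, key=lambda s: (s.chrom, s.start))
        calls_b = detect_chromothripsis(profile, cfg)
        assert [c.to_dict() for c in calls_a] == [c.to_dict() for c in calls_b]


class TestDoubleMinute:
    @pytest.mark.parametrize("states,expected", [
        ([2, 12, 2, 12, 2], True),
        ([2, 8, 2, 8], False),        # high state below the floor
        ([4, 10, 4, 10], True),       # boundary values inclusive
        ([2, 12, 2], False),          # run too short
    ])
    def test_examples(self, states, expected, cfg):
        assert detect_double_minute(states, cfg) is expected


class TestFocalAmplifications:
    GENES = [GeneRecord("MYCN", "chr1", 1_500_000, 1_600_000, "oncogene")]

    def test_small_high_cn_run_with_oncogene(self, cfg):
        segs = [CNSegment("chr1", 1, 1_000_000, 2, 1),
                CNSegment("chr1", 1_000_001, 3_000_000, 6, 1)]
        hits = focal_amplifications(segs, self.GENES, None, cfg)
        assert len(hits) == 1
        assert hits[0]["genes"] == ["MYCN"] and hits[0]["max_cn"] == 6

    def test_wide_run_fails_size_gate(self, cfg):
        segs = [CNSegment("chr1", 1, 7_000_000, 5, 1)]
        assert focal_amplifications(segs, [], None, cfg) == []

    def test_interrupted_runs_count_separately(self, cfg):
        segs = [CNSegment("chr1", 1, 1_000_000, 4, 1),
                CNSegment("chr1", 1_000_001, 2_000_000, 2, 1),
                CNSegment("chr1", 2_000_001, 3_000_000, 4, 1)]
        assert len(focal_amplifications(segs, [], None, cfg)) == 2


class TestLostGenes:
    REGION = {"chr1": (1, 10_000_000)}

    def test_gene_inside_deleted_fragment_listed(self):
        segs = [CNSegment("chr1", 1, 5_000_000, 1, 0),
                CNSegment("chr1", 5_000_001, 10_000_000, 2, 1)]
        genes = [GeneRecord("PTEN", "chr1", 100_000, 200_000, "tumor_suppressor")]
        assert lost_genes_in_event(self.REGION, segs, genes) == genes

    def test_gene_straddling_boundary_not_listed(self):
        segs = [CNSegment("chr1", 1, 5_000_000, 1, 0),
                CNSegment("chr1", 5_000_001, 10_000_000, 2, 1)]
        genes = [GeneRecord("X", "chr1", 4_900_000, 5_100_000)]
        assert lost_genes_in_event(self.REGION, segs, genes) == []

    def test_simulated_losses_recovered(self, cfg):
        profile, truth = simulate_chromothripsis(seed=4)
        genes = []
        for i in sorted(truth.lost):
            fs, fe = truth.fragments[i]
            if fe - fs > 2:
                genes.append(GeneRecord(f"g{i}", "chr1", fs + 1, fe - 1,
                                        "tumor_suppressor"))
        # genes inside retained fragments must not be reported
        retained = [i for i in range(len(truth.fragments)) if i not in truth.lost]
        for i in retained[:3]:
            fs, fe = truth.fragments[i]
            if fe - fs > 2:
                genes.append(GeneRecord(f"kept{i}", "chr1", fs + 1, fe - 1))
        calls = [c for c in detect_chromothripsis(profile, cfg, genes=genes)
                 if c.confidence != CONF_NONE]
        assert calls
        found = {g.name for g in calls[0].lost_genes}
        assert found == {g.name for g in genes if g.name.startswith("g")}


class TestHighCallInvariant:
    def test_every_high_call_has_seven_oscillations_or_inter_route(self, cfg):
        for seed in range(30):
            profile, _ = simulate_chromothripsis(seed=seed)
            for call in detect_chromothripsis(profile, cfg):
                if call.confidence == CONF_HIGH:
                    s = call.stats_per_chrom[call.defining_chrom]
                    assert (s.max_osc_2 >= cfg.high_min_osc
                            or (call.n_inter >= cfg.min_inter_link
                                and s.max_osc_2 >= cfg.low_min_osc))
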