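import numpy as np
import pytest
from hypothesis import given, settings, strategies as st_
from scipy import stats as sps

from chromoshatter import (CNSegment, breakpoint_exponential_test,
                           chromosome_enrichment_test, detect_interspersed_loh,
                           dominant_two_state_levels, foldback_fraction,
                           fraction_two_state, fragment_join_test,
                           homology_summary, make_sv, max_alternating_run)
from chromoshatter.statistics import (enumerate_compositions,
                                      equal_multinomial_logpmf)


def brute_max_alternating(seq, k):
    """Exhaustive O(n^2) window scan oracle."""
    best = 0
    for i in range(len(seq)):
        for j in range(i, len(seq)):
            w = seq[i:j + 1]
            if len(set(w)) <= k and all(a != b for a, b in zip(w, w[1:])):
                best = max(best, len(w))
    return best


class TestOscillation:
    @pytest.mark.parametrize("seq,k,expected", [
        ([2, 1, 2, 1, 2, 1, 2], 2, 7),
        ([2, 1, 2, 3, 2, 1], 2, 3),
        ([2, 1, 2, 3, 2, 1], 3, 6),
        ([4, 4, 4], 2, 1),
        ([], 2, 0),
    ])
    def test_examples(self, seq, k, expected):
        assert max_alternating_run(seq, k) == expected

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(0)
        for trial in range(500):
            n = int(rng.integers(0, 31))
            seq = [int(v) for v in rng.integers(0, 7, size=n)]
            for k in (2, 3):
                assert max_alternating_run(seq, k) == brute_max_alternating(seq, k), \
                    (trial, seq, k)

    @settings(derandomize=True, max_examples=200)
    @given(st_.lists(st_.integers(min_value=0, max_value=6), max_size=25))
    def test_matches_oracle_on_arbitrary_sequences(self, seq):
        for k in (2, 3):
            assert max_alternating_run(seq, k) == brute_max_alternating(seq, k)

    def test_three_state_run_at_least_two_state(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            seq = [int(v) for v in rng.integers(0, 5, size=20)]
            assert max_alternating_run(seq, 3) >= max_alternating_run(seq, 2)


class TestFractionTwoState:
    @pytest.mark.parametrize("seq,expected", [
        ([2, 1, 2, 1, 2], 1.0),
        ([2, 1, 2, 9, 2, 1], 5 / 6),
        ([2], 0.0),
        ([], 0.0),
    ])
    def test_examples(self, seq, expected):
        assert fraction_two_state(seq) == pytest.approx(expected)

    def test_dominant_levels_of_longest_run(self):
        assert dominant_two_state_levels([2, 4, 2, 4, 2, 4, 2]) == (2, 4, 7)
        assert dominant_two_state_levels([5, 3, 4, 3, 4, 3]) == (3, 4, 5)
        assert dominant_two_state_levels([2, 2, 2]) is None


class TestFragmentJoinTest:
    def test_single_cell_concentration_exact_value(self):
        # only the four single-cell vectors are as improbable as (12,0,0,0)
        assert fragment_join_test((12, 0, 0, 0)) == pytest.approx(
            4 * 0.25 ** 12, rel=1e-9)

    def test_balanced_vectors_give_p_one(self):
        assert fragment_join_test((5, 5, 5, 5), exact_cutoff=20) == pytest.approx(1.0)
        assert fragment_join_test((40, 40, 40, 40)) == pytest.approx(1.0)

    @pytest.mark.parametrize("n", [1, 5, 12])
    def test_exact_enumeration_total_mass_is_one(self, n):
        mass = np.exp(equal_multinomial_logpmf(enumerate_compositions(n))).sum()
        assert mass == pytest.approx(1.0, abs=1e-12)

    def test_exact_and_chisquare_branches_agree_on_average(self):
        # at n=40 the asymptotic branch tracks the exact one closely in the
        # mean; individual vectors may differ by the exact test's discreteness
        rng = np.random.default_rng(3)
        diffs = []
        for _ in range(100):
            c = rng.multinomial(40, [0.25] * 4)
            exact = fragment_join_test(c, exact_cutoff=40)
            chi = fragment_join_test(c, exact_cutoff=15)
            diffs.append(abs(exact - chi))
        assert np.mean(diffs) < 0.03
        assert max(diffs) < 0.10

    def test_type_one_error_near_nominal(self):
        rng = np.random.default_rng(4)
        rej = sum(fragment_join_test(rng.multinomial(24, [0.25] * 4)) < 0.05
                  for _ in range(2000))
        assert rej / 2000 <= 0.07

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fragment_join_test((1, -1, 0, 0))


class TestBreakpointRandomness:
    REGION = (0, 10_000_000)

    def test_calibrated_under_uniform_placement(self):
        rng = np.random.default_rng(5)
        rej = 0
        for _ in range(2000):
            pos = np.sort(rng.integers(*self.REGION, size=500))
            rej += breakpoint_exponential_test(pos, self.REGION) < 0.05
        assert 0.03 <= rej / 2000 <= 0.07

    def test_power_against_two_cluster_alternative(self):
        rng = np.random.default_rng(6)
        power = 0
        for _ in range(400):
            pos = np.concatenate([
                rng.integers(0, 1_000_000, size=32),        # 80% in 10%
                rng.integers(1_000_000, 10_000_000, size=8)])
            power += breakpoint_exponential_test(np.sort(pos), self.REGION) < 0.05
        assert power / 400 >= 0.9

    def test_periodic_grid_strongly_rejected(self):
        grid = np.arange(0, 10_000_000, 200_000)[:50]
        assert breakpoint_exponential_test(grid, self.REGION) < 1e-6

    def test_too_few_breakpoints_missing(self):
        assert breakpoint_exponential_test([10, 20, 30], self.REGION) is None


class TestEnrichment:
    def test_whole_chromosome_region_uninformative(self):
        assert chromosome_enrichment_test(20, 1e6, 20, 1e6) == pytest.approx(1.0)

    def test_total_concentration_closed_form(self):
        assert chromosome_enrichment_test(20, 1e4, 20, 1e6) == pytest.approx(
            0.01 ** 20, rel=1e-6)

    def test_binomial_tail_value(self):
        expected = float(sps.binom.sf(9, 100, 0.1))
        assert chromosome_enrichment_test(10, 1e5, 100, 1e6) == pytest.approx(
            expected)
        assert expected == pytest.approx(0.549, abs=0.005)

    def test_monotone_decreasing_in_region_count(self):
        ps = [chromosome_enrichment_test(k, 1e5, 100, 1e6) for k in range(1, 101)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_zero_length_is_contract_violation(self):
        with pytest.raises(ValueError):
            chromosome_enrichment_test(1, 0, 10, 1e6)


def _seg(start, end, total, minor):
    return CNSegment("chr1", start, end, total, minor)


class TestLoh:
    def test_alternating_minor_pattern(self):
        segs = [_seg(i * 100 + 1, (i + 1) * 100, 2, m)
                for i, m in enumerate([1, 0, 1, 0, 1, 0])]
        assert detect_interspersed_loh(segs) is True

    def test_single_switch_not_interspersed(self):
        segs = [_seg(i * 100 + 1, (i + 1) * 100, 2, m)
                for i, m in enumerate([1, 1, 0, 0, 0, 0])]
        assert detect_interspersed_loh(segs) is False

    def test_missing_minor_cn_gives_missing(self):
        segs = [_seg(1, 100, 2, None), _seg(101, 200, 1, None)]
        assert detect_interspersed_loh(segs) is None


class TestFoldbackAndHomology:
    def test_foldback_fraction_counts_short_inversions(self):
        svs = [make_sv(f"i{k}", "chr1", 1000 + 50_000 * k, "+",
                       "chr1", 1000 + 50_000 * k + 20_000, "+") for k in range(4)]
        svs += [make_sv(f"d{k}", "chr1", 500_000 + 1000 * k, "+",
                        "chr1", 900_000 + 1000 * k, "-") for k in range(6)]
        assert foldback_fraction(svs) == pytest.approx(0.4)

    def test_all_deletion_like_no_foldbacks(self):
        svs = [make_sv(f"d{k}", "chr1", 10 + k, "+", "chr1", 10_000 + k, "-")
               for k in range(5)]
        assert foldback_fraction(svs) == 0.0

    def test_simulated_bfb_series_is_foldback_dominated(self):
        from chromoshatter import simulate_bfb_series
        hits = 0
        for seed in range(100):
            profile = simulate_bfb_series(seed=seed)
            hits += foldback_fraction(profile.svs) > 0.5
        assert hits >= 95

    @pytest.mark.parametrize("homs,med,frac", [
        ([0, 1, 2, 3, 4], 2, 0.0),
        ([50, 60, 70], 60, 1.0),
    ])
    def test_homology_summary(self, homs, med, frac):
        svs = [make_sv(f"h{k}", "chr1", 10 + k, "+", "chr1", 1000 + k, "-",
                       homology_len=h) for k, h in enumerate(homs)]
        assert homology_summary(svs) == (pytest.approx(med), pytest.approx(frac))

    def test_homology_all_missing(self):
        svs = [make_sv("x", "chr1", 10, "+", "chr1", 1000, "-")]
        assert homology_summary(svs) == (None, None)
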