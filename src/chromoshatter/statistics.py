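"""Per-region statistical criteria for chromothripsis.

The shattering-and-religation model predicts, inside an affected region:

* copy number oscillating between two (or, with aneuploidy, three) states,
  because fragments are either retained on the derivative chromosome or lost;
* interspersed loss of heterozygosity wherever fragments of a single
  chromatid were lost;
* roughly equal proportions of the four fragment-join types (deletion-like,
  duplication-like, head-to-head and tail-to-tail inversions), since joins
  form by random religation;
* breakpoints scattered uniformly across the region, yet strongly
  concentrated relative to the whole chromosome.

Each prediction is measured here as a statistic or hypothesis test; the
caller module combines them into confidence tiers. Mimicking processes leave
different fingerprints — tandem-duplication showers are all duplication-like,
breakage–fusion–bridge cycles produce short fold-back inversions, stepwise
aneuploidy lacks interleaved SVs — and the same statistics discriminate them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .io_model import CNSegment, H2H_INV, SV, T2T_INV


@dataclass
class RegionStatistics:
    """All statistics evaluated on one chromosome of one event region."""

    max_osc_2: int = 0
    max_osc_3: int = 0
    frac_osc_2: float = 0.0
    p_fragment_joins: Optional[float] = None
    p_exponential: Optional[float] = None
    p_enrichment: Optional[float] = None
    loh_interspersed: Optional[bool] = None
    foldback_fraction: float = 0.0
    median_homology: Optional[float] = None
    frac_long_homology: Optional[float] = None
    osc_levels: Optional[tuple[int, int]] = None
    n_segments: int = 0
    cn_coverage: float = 0.0
    evaluable: bool = True


# ---------------------------------------------------------------------------
# Copy-number oscillation
# ---------------------------------------------------------------------------

def max_alternating_run(cn_states: Sequence[int], n_states: int = 2) -> int:
    """Longest contiguous run of CN states alternating among <= ``n_states``
    distinct levels, with every adjacent pair different.

    With ``n_states=2`` this is strict A/B alternation, the classic
    oscillating profile; ``n_states=3`` admits multi-level oscillations seen
    in aneuploid genomes. Empty input yields 0; a constant stretch counts 1.
    """
    if n_states not in (2, 3):
        raise ValueError("n_states must be 2 or 3")
    seq = list(cn_states)
    if not seq:
        return 0
    best = 1
    # two-pointer over windows where adjacent values differ and the window
    # holds at most n_states distinct levels
    start = 0
    counts: dict[int, int] = {seq[0]: 1}
    for i in range(1, len(seq)):
        if seq[i] == seq[i - 1]:
            start = i
            counts = {seq[i]: 1}
            continue
        counts[seq[i]] = counts.get(seq[i], 0) + 1
        while len(counts) > n_states:
            counts[seq[start]] -= 1
            if counts[seq[start]] == 0:
                del counts[seq[start]]
            start += 1
        best = max(best, i - start + 1)
    return best


def dominant_two_state_levels(
        cn_states: Sequence[int]) -> Optional[tuple[int, int, int]]:
    """(low, high, run_length) of the longest strict two-state alternating
    run; ties between equally long runs go to the level pair covering more
    segments overall. None when no adjacent pair differs."""
    seq = list(cn_states)
    if len(seq) < 2:
        return None
    total = {}
    for v in seq:
        total[v] = total.get(v, 0) + 1
    best: Optional[tuple[int, int, int]] = None
    best_key = (-1, -1)
    i = 0
    while i < len(seq) - 1:
        if seq[i] == seq[i + 1]:
            i += 1
            continue
        a, b = seq[i], seq[i + 1]
        j = i + 1
        while j + 1 < len(seq) and seq[j + 1] == seq[j - 1]:
            j += 1
        run_len = j - i + 1
        key = (run_len, total[a] + total[b])
        if key > best_key:
            best_key = key
            best = (min(a, b), max(a, b), run_len)
        i = j
    return best


def fraction_two_state(cn_states: Sequence[int]) -> float:
    """Fraction of region segments participating in the dominant two-state
    oscillation: segments at one of the two most frequent levels that are
    flanked on at least one side by the other level."""
    seq = list(cn_states)
    if len(seq) < 2:
        return 0.0
    counts: dict[int, int] = {}
    for v in seq:
        counts[v] = counts.get(v, 0) + 1
    # two most frequent levels; ties broken toward the lower level
    top2 = sorted(counts, key=lambda v: (-counts[v], v))[:2]
    if len(top2) < 2:
        return 0.0
    a, b = top2
    other = {a: b, b: a}
    n_osc = 0
    for i, v in enumerate(seq):
        if v not in other:
            continue
        left = seq[i - 1] if i > 0 else None
        right = seq[i + 1] if i < len(seq) - 1 else None
        if left == other[v] or right == other[v]:
            n_osc += 1
    return n_osc / len(seq)


# ---------------------------------------------------------------------------
# Fragment-join equal-proportions test
# ---------------------------------------------------------------------------

def enumerate_compositions(n: int) -> np.ndarray:
    """All 4-part compositions of ``n`` (the full multinomial outcome space)."""
    comps = [(i, j, k, n - i - j - k)
             for i in range(n + 1)
             for j in range(n - i + 1)
             for k in range(n - i - j + 1)]
    return np.array(comps, dtype=np.int64)


def equal_multinomial_logpmf(comps: np.ndarray) -> np.ndarray:
    """Log pmf of Multinomial(n, 1/4 each) over rows of count vectors."""
    from scipy.special import gammaln
    n = int(comps[0].sum())
    return (gammaln(n + 1) - gammaln(comps + 1).sum(axis=1)
            + n * math.log(0.25))


def _exact_multinomial_p(counts: Sequence[int]) -> float:
    """Exact equal-proportions multinomial test.

    p = P(count vector at least as extreme as observed), where extremeness
    is ordered by the Multinomial(n, 1/4 each) probability of the vector
    itself: sum the probability of every outcome whose probability does not
    exceed that of the observed vector (log-space tie tolerance 1e-9).
    """
    counts = np.asarray(list(counts), dtype=np.int64)
    n = int(counts.sum())
    comps = enumerate_compositions(n)
    logp = equal_multinomial_logpmf(comps)
    obs_logp = float(equal_multinomial_logpmf(counts[None, :])[0])
    mask = logp <= obs_logp + 1e-9
    return float(min(np.exp(logp[mask]).sum(), 1.0))


def fragment_join_test(type_counts: Sequence[int],
                       exact_cutoff: int = 15) -> float:
    """P-value for equal proportions of the four fragment-join types.

    Under random religation of shattered fragments the four join types are
    equally likely; a high p-value is consistent with that. Exact multinomial
    enumeration for total counts up to ``exact_cutoff``, chi-square
    goodness-of-fit (3 df) beyond.
    """
    counts = list(type_counts)
    if len(counts) != 4:
        raise ValueError("type_counts must have 4 entries")
    if any(c < 0 for c in counts):
        raise ValueError("negative counts")
    n = sum(counts)
    if n == 0:
        raise ValueError("at least one join required")
    if n <= exact_cutoff:
        return _exact_multinomial_p(counts)
    stat, p = stats.chisquare(counts, f_exp=[n / 4] * 4)
    return float(p)


# ---------------------------------------------------------------------------
# Breakpoint randomness
# ---------------------------------------------------------------------------

def breakpoint_exponential_test(positions: Sequence[int],
                                region: tuple[int, int]) -> Optional[float]:
    """Goodness-of-fit of inter-breakpoint spacings to the exponential law.

    Uniformly scattered breakpoints have exchangeable-exponential adjacent
    spacings with rate n / region length; clumped or periodic placement
    departs from that law in opposite directions, and both are caught by a
    Kolmogorov–Smirnov statistic on the spacings. Because the spacings are
    sum-constrained (not independent), a naive KS test is conservative;
    the ordered spacings are first passed through the Sukhatme
    transformation, whose normalised cumulative sums are exact uniform
    order statistics under the null, restoring calibration without losing
    sensitivity to either tight clumps or zero-variance (periodic) spacing.
    Requires at least 4 breakpoints inside the region, otherwise the
    statistic is missing (None).
    """
    lo, hi = region
    if hi <= lo:
        raise ValueError("degenerate region")
    pos = np.sort(np.asarray([p for p in positions if lo <= p <= hi]))
    n = len(pos)
    if n < 4:
        return None
    spacings = np.diff(pos).astype(float)
    m = len(spacings)
    g = np.sort(spacings)
    # Sukhatme: (m - i + 1) * (g_(i) - g_(i-1)) are again exchangeable
    # exponentials; their normalised cumulative sums are uniform order stats
    h = (m - np.arange(m)) * np.diff(np.concatenate([[0.0], g]))
    total = h.sum()
    if total == 0:
        return 0.0  # all breakpoints coincide
    u = np.cumsum(h)[:-1] / total
    res = stats.kstest(u, "uniform")
    return float(res.pvalue)


def chromosome_enrichment_test(n_region: int, region_len: float,
                               n_chrom: int, chrom_len: float) -> float:
    """One-sided binomial tail for breakpoint concentration in the region.

    P(X >= n_region) for X ~ Binomial(n_chrom, region_len / chrom_len):
    small values mean the chromosome's breakpoints pile up inside the
    region far beyond its share of the chromosome.
    """
    if region_len <= 0 or chrom_len <= 0:
        raise ValueError("lengths must be positive")
    if n_region > n_chrom:
        raise ValueError("n_region cannot exceed n_chrom")
    frac = min(region_len / chrom_len, 1.0)
    return float(stats.binom.sf(n_region - 1, n_chrom, frac))


# ---------------------------------------------------------------------------
# LOH, fold-backs, homology
# ---------------------------------------------------------------------------

def detect_interspersed_loh(segments: Sequence[CNSegment],
                            min_loh_switches: int = 4) -> Optional[bool]:
    """True when minor-allele CN switches between 0 and >= 1 at least
    ``min_loh_switches`` times across the region.

    Requires minor CN on at least half the region length; otherwise the
    verdict is missing (None). Isolated one-arm LOH produces a single switch
    and is not interspersed.
    """
    segs = [s for s in segments]
    if not segs:
        return None
    total_len = sum(s.length for s in segs)
    with_minor = [s for s in segs if s.minor_cn is not None]
    covered = sum(s.length for s in with_minor)
    if total_len == 0 or covered / total_len < 0.5:
        return None
    states = [1 if s.minor_cn >= 1 else 0 for s in with_minor]
    switches = sum(1 for a, b in zip(states, states[1:]) if a != b)
    return switches >= min_loh_switches


def foldback_fraction(svs: Sequence[SV], foldback_span: int = 30_000) -> float:
    """Fraction of members that are short inversions (span <= foldback_span).

    Fold-back inversions are the hallmark of breakage–fusion–bridge cycles;
    a high fraction argues against single-event shattering.
    """
    members = [sv for sv in svs if sv.is_intra]
    if not members:
        return 0.0
    n_fb = sum(1 for sv in members
               if sv.join_class in (H2H_INV, T2T_INV)
               and sv.span is not None and sv.span <= foldback_span)
    return n_fb / len(members)


def homology_summary(svs: Sequence[SV], long_homology_bp: int = 10
                     ) -> tuple[Optional[float], Optional[float]]:
    """(median homology length, fraction of junctions with homology longer
    than ``long_homology_bp``), or (None, None) when no junction carries a
    homology annotation."""
    lens = [sv.homology_len for sv in svs if sv.homology_len is not None]
    if not lens:
        return None, None
    median = float(np.median(lens))
    frac_long = sum(1 for h in lens if h > long_homology_bp) / len(lens)
    return median, frac_long
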