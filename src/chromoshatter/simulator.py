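"""Ground-truth rearrangement simulator.

Implements the single-chromatid shattering model: a region of one chromatid
is cut at uniformly placed points, each fragment is independently lost or
retained, and the retained fragments are religated in uniformly random order
and orientation. Junction SVs follow mechanically from the orientation with
which adjacent fragments meet in the derivative chromosome, and copy number
follows from the losses (background 2/1; lost fragments 1/0, producing
interspersed LOH). Whole-genome doubling can be applied after shattering
(2<->4 oscillations with LOH) or before it (3<->4 oscillations without LOH).

Confounder generators produce the classes of rearrangement that mimic
chromothripsis and that the caller must reject: tandem-duplication showers,
nested deletion cascades, breakage–fusion–bridge fold-back series, and
stepwise aneuploidy without SVs. A background generator adds sparse
unrelated SVs on a quiet genome.

Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .io_model import (CNSegment, SampleProfile, SNVRecord, SV,
                       merge_equal_neighbors, make_sv)

WGD_NONE = "none"
WGD_BEFORE = "before"
WGD_AFTER = "after"


@dataclass
class SimTruth:
    """Generative record of one simulated shattering event."""

    event_id: str
    chrom: str
    region: tuple[int, int]
    fragments: list[tuple[int, int]]
    lost: set[int]
    derivative_order: list[tuple[int, str]]  # (fragment index, orientation)
    junctions: list[SV]
    wgd: str
    seed: int


def _junction(pair_id: str, a_chrom: str, a_frag: tuple[int, int], a_or: str,
              b_chrom: str, b_frag: tuple[int, int], b_or: str,
              homology_len: Optional[int] = None,
              insertion_len: Optional[int] = None) -> SV:
    """SV joining the derivative-right end of oriented fragment A to the
    derivative-left end of oriented fragment B.

    A breakpoint's strand marks which side of it survives on the derivative:
    '+' keeps the reference-left side, '-' the reference-right side. A
    forward fragment exits at its reference end (left side kept, '+') and is
    entered at its reference start (right side kept, '-'); an inverted
    fragment swaps both.
    """
    pos_a = a_frag[1] if a_or == "+" else a_frag[0]
    strand_a = "+" if a_or == "+" else "-"
    pos_b = b_frag[0] if b_or == "+" else b_frag[1]
    strand_b = "-" if b_or == "+" else "+"
    return make_sv(pair_id, a_chrom, pos_a, strand_a, b_chrom, pos_b, strand_b,
                   homology_len=homology_len, insertion_len=insertion_len)


def _sample_junction_annotations(rng: np.random.Generator,
                                 hom_geom_p: float = 1 / 3,
                                 ins_prob: float = 0.1,
                                 ins_range: tuple[int, int] = (10, 500)
                                 ) -> tuple[int, int]:
    """Junction homology (geometric, mean 2 bp) and insertion length
    (10–500 bp templated insertion with probability ``ins_prob``, else 0)."""
    hom = int(rng.geometric(hom_geom_p)) - 1
    ins = 0
    if rng.random() < ins_prob:
        ins = int(rng.integers(ins_range[0], ins_range[1] + 1))
    return hom, ins


def _cut_fragments(rng: np.random.Generator, region: tuple[int, int],
                   n_fragments: int) -> list[tuple[int, int]]:
    lo, hi = region
    if n_fragments < 3:
        raise ValueError("n_fragments must be >= 3")
    if hi - lo < 10 * n_fragments:
        raise ValueError("region too small for requested fragment count")
    cuts = set()
    while len(cuts) < n_fragments - 1:
        cuts.add(int(rng.integers(lo + 1, hi - 1)))
    bounds = [lo - 1] + sorted(cuts) + [hi]
    return [(bounds[i] + 1, bounds[i + 1]) for i in range(n_fragments)]


def _apply_wgd_levels(wgd: str) -> tuple[tuple[int, int], tuple[int, int]]:
    """(total, minor) CN for retained and lost fragments under each WGD mode."""
    if wgd == WGD_NONE:
        return (2, 1), (1, 0)
    if wgd == WGD_AFTER:       # losses on one chromatid, then everything doubles
        return (4, 2), (2, 0)
    if wgd == WGD_BEFORE:      # doubling first, then one of four chromatids shatters
        return (4, 2), (3, 1)
    raise ValueError(f"unknown wgd mode {wgd!r}")


def _background_cn(wgd: str) -> tuple[int, int]:
    return (4, 2) if wgd in (WGD_BEFORE, WGD_AFTER) else (2, 1)


def _event_cn(chrom: str, chrom_len: int, region: tuple[int, int],
              fragments: Sequence[tuple[int, int]], lost: set[int],
              wgd: str) -> list[CNSegment]:
    retained_cn, lost_cn = _apply_wgd_levels(wgd)
    bg_total, bg_minor = _background_cn(wgd)
    lo, hi = region
    segs = []
    if lo > 1:
        segs.append(CNSegment(chrom, 1, lo - 1, bg_total, bg_minor))
    for i, (fs, fe) in enumerate(fragments):
        total, minor = lost_cn if i in lost else retained_cn
        segs.append(CNSegment(chrom, fs, fe, total, minor))
    if hi < chrom_len:
        segs.append(CNSegment(chrom, hi + 1, chrom_len, bg_total, bg_minor))
    return merge_equal_neighbors(segs)


def simulate_chromothripsis(chrom: str = "chr1",
                            chrom_len: int = 100_000_000,
                            region: tuple[int, int] = (30_000_000, 60_000_000),
                            n_fragments: int = 30,
                            p_loss: float = 0.3,
                            wgd: str = WGD_NONE,
                            seed: int = 0,
                            sample_id: Optional[str] = None
                            ) -> tuple[SampleProfile, SimTruth]:
    """Simulate one chromothripsis event on an otherwise quiet genome.

    Cut points are uniform in the region; each fragment is lost with
    probability ``p_loss`` (resampled until at least one fragment is lost
    and at least two are retained); retained fragments are religated in
    uniformly random order and orientation, anchored to the flanking
    chromosome arms on both sides.
    """
    if not 0 <= p_loss < 1:
        raise ValueError("p_loss must be in [0, 1)")
    rng = np.random.default_rng(seed)
    fragments = _cut_fragments(rng, region, n_fragments)
    while True:
        lost_mask = rng.random(n_fragments) < p_loss
        n_lost = int(lost_mask.sum())
        if 1 <= n_lost <= n_fragments - 2:
            break
    lost = {i for i in range(n_fragments) if lost_mask[i]}
    retained = [i for i in range(n_fragments) if i not in lost]
    order = [int(i) for i in rng.permutation(retained)]
    orients = ["+" if rng.random() < 0.5 else "-" for _ in order]
    derivative = list(zip(order, orients))

    lo, hi = region
    flank_left = (1, lo - 1)
    flank_right = (hi + 1, chrom_len)
    chain: list[tuple[tuple[int, int], str]] = (
        [(flank_left, "+")]
        + [(fragments[i], o) for i, o in derivative]
        + [(flank_right, "+")]
    )
    junctions = []
    for k, ((fa, oa), (fb, ob)) in enumerate(zip(chain, chain[1:]), 1):
        hom, ins = _sample_junction_annotations(rng)
        junctions.append(_junction(f"ct_s{seed}_j{k}", chrom, fa, oa,
                                   chrom, fb, ob,
                                   homology_len=hom, insertion_len=ins))

    cn = _event_cn(chrom, chrom_len, region, fragments, lost, wgd)
    ploidy = 3.9 if wgd in (WGD_BEFORE, WGD_AFTER) else 2.0
    profile = SampleProfile(sample_id=sample_id or f"sim_ct_{seed}",
                            svs=junctions, cn=cn, ploidy=ploidy,
                            chrom_lengths={chrom: chrom_len})
    truth = SimTruth(event_id=f"truth_ct_{seed}", chrom=chrom, region=region,
                     fragments=fragments, lost=lost,
                     derivative_order=derivative, junctions=junctions,
                     wgd=wgd, seed=seed)
    return profile, truth


def simulate_multi_chromothripsis(
        chroms: Sequence[str] = ("chr1", "chr2"),
        chrom_len: int = 100_000_000,
        regions: Optional[Sequence[tuple[int, int]]] = None,
        n_fragments: int = 20,
        p_loss: float = 0.3,
        seed: int = 0) -> tuple[SampleProfile, list[SimTruth]]:
    """Simultaneous shattering of several chromosomes (micronucleus-style):
    fragments from all chromosomes are pooled into one derivative, so
    junctions between fragments of different chromosomes become
    translocations."""
    rng = np.random.default_rng(seed)
    if regions is None:
        regions = [(30_000_000, 60_000_000)] * len(chroms)
    all_frags: list[tuple[str, tuple[int, int]]] = []
    frag_meta: dict[str, list[tuple[int, int]]] = {}
    lost_meta: dict[str, set[int]] = {}
    for chrom, region in zip(chroms, regions):
        fragments = _cut_fragments(rng, region, n_fragments)
        while True:
            lost_mask = rng.random(n_fragments) < p_loss
            n_lost = int(lost_mask.sum())
            if 1 <= n_lost <= n_fragments - 2:
                break
        frag_meta[chrom] = fragments
        lost_meta[chrom] = {i for i in range(n_fragments) if lost_mask[i]}
        all_frags.extend((chrom, fragments[i]) for i in range(n_fragments)
                         if i not in lost_meta[chrom])
    order = [int(i) for i in rng.permutation(len(all_frags))]
    chain: list[tuple[str, tuple[int, int], str]] = []
    first_chrom, first_region = chroms[0], regions[0]
    chain.append((first_chrom, (1, first_region[0] - 1), "+"))
    for i in order:
        c, frag = all_frags[i]
        chain.append((c, frag, "+" if rng.random() < 0.5 else "-"))
    chain.append((first_chrom, (first_region[1] + 1, chrom_len), "+"))
    junctions = []
    for k, ((ca, fa, oa), (cb, fb, ob)) in enumerate(zip(chain, chain[1:]), 1):
        hom, ins = _sample_junction_annotations(rng)
        junctions.append(_junction(f"mct_s{seed}_j{k}", ca, fa, oa, cb, fb, ob,
                                   homology_len=hom, insertion_len=ins))
    cn: list[CNSegment] = []
    truths = []
    for chrom, region in zip(chroms, regions):
        cn.extend(_event_cn(chrom, chrom_len, region, frag_meta[chrom],
                            lost_meta[chrom], WGD_NONE))
        truths.append(SimTruth(
            event_id=f"truth_mct_{chrom}_{seed}", chrom=chrom, region=region,
            fragments=frag_meta[chrom], lost=lost_meta[chrom],
            derivative_order=[], junctions=[], wgd=WGD_NONE, seed=seed))
    profile = SampleProfile(sample_id=f"sim_mct_{seed}", svs=junctions, cn=cn,
                            ploidy=2.0,
                            chrom_lengths={c: chrom_len for c in chroms})
    return profile, truths


# ---------------------------------------------------------------------------
# Confounders
# ---------------------------------------------------------------------------

def simulate_tandem_dup_cluster(chrom: str = "chr1",
                                chrom_len: int = 100_000_000,
                                region: tuple[int, int] = (30_000_000, 60_000_000),
                                n: int = 20,
                                seed: int = 0) -> SampleProfile:
    """Shower of overlapping tandem duplications: all duplication-like
    joins, stepwise CN gains, no LOH. The spans interleave (starts and ends
    both increase), so the cluster forms, but its join spectrum and CN
    profile are nothing like shattering."""
    if n < 6:
        raise ValueError("n must be >= 6")
    rng = np.random.default_rng(seed)
    lo, hi = region
    span = hi - lo
    starts = np.sort(rng.integers(lo, lo + int(0.4 * span), size=n))
    ends = np.sort(rng.integers(lo + int(0.5 * span), hi, size=n))
    svs = []
    for k, (s, e) in enumerate(zip(starts, ends), 1):
        svs.append(make_sv(f"td_s{seed}_{k}", chrom, int(s), "-",
                           chrom, int(e), "+",
                           homology_len=int(rng.geometric(1 / 3)) - 1,
                           insertion_len=0))
    # CN = 2 + number of covering duplications, piecewise between boundaries
    bounds = sorted({1, chrom_len + 1}
                    | {int(s) for s in starts} | {int(e) + 1 for e in ends})
    segs = []
    for a, b in zip(bounds, bounds[1:]):
        depth = int(np.sum((starts <= a) & (ends >= b - 1)))
        segs.append(CNSegment(chrom, a, b - 1, 2 + depth, 1))
    return SampleProfile(sample_id=f"sim_td_{seed}", svs=svs,
                         cn=merge_equal_neighbors(segs), ploidy=2.0,
                         chrom_lengths={chrom: chrom_len})


def simulate_nested_deletions(chrom: str = "chr1",
                              chrom_len: int = 100_000_000,
                              region: tuple[int, int] = (30_000_000, 60_000_000),
                              n: int = 10,
                              seed: int = 0) -> SampleProfile:
    """Cascade of strictly nested deletions: no pair is interleaved, so no
    cluster can form."""
    rng = np.random.default_rng(seed)
    lo, hi = region
    step = (hi - lo) // (2 * n + 2)
    svs = []
    for k in range(n):
        jitter = int(rng.integers(0, max(step // 4, 2)))
        s = lo + k * step + jitter
        e = hi - k * step - jitter
        svs.append(make_sv(f"nd_s{seed}_{k + 1}", chrom, s, "+", chrom, e, "-",
                           homology_len=int(rng.geometric(1 / 3)) - 1,
                           insertion_len=0))
    # concentric CN losses, floored at zero
    bounds = sorted({1, chrom_len + 1}
                    | {sv.pos1 for sv in svs} | {sv.pos2 + 1 for sv in svs})
    segs = []
    for a, b in zip(bounds, bounds[1:]):
        depth = sum(1 for sv in svs if sv.pos1 <= a and sv.pos2 >= b - 1)
        total = max(2 - depth, 0)
        minor = 1 if depth == 0 else 0
        segs.append(CNSegment(chrom, a, b - 1, total, minor))
    return SampleProfile(sample_id=f"sim_nd_{seed}", svs=svs,
                         cn=merge_equal_neighbors(segs), ploidy=2.0,
                         chrom_lengths={chrom: chrom_len})


def simulate_bfb_series(chrom: str = "chr1",
                        chrom_len: int = 100_000_000,
                        region: tuple[int, int] = (30_000_000, 60_000_000),
                        n_cycles: int = 5,
                        seed: int = 0,
                        foldback_span: int = 30_000) -> SampleProfile:
    """Breakage–fusion–bridge series: one fold-back inversion per cycle and
    a CN staircase climbing monotonically toward the fused (telomere-loss)
    end of the region."""
    if n_cycles < 3:
        raise ValueError("n_cycles must be >= 3")
    rng = np.random.default_rng(seed)
    lo, hi = region
    # fold-back positions spread across the region, ascending toward the
    # fused end at ``hi``
    breaks = np.sort(rng.integers(lo + (hi - lo) // 4, hi - foldback_span,
                                  size=n_cycles))
    svs = []
    for k, b in enumerate(breaks, 1):
        span = int(rng.integers(100, foldback_span))
        cls = "+" if k % 2 else "-"  # alternate h2h / t2t fold-backs
        svs.append(make_sv(f"bfb_s{seed}_{k}", chrom, int(b), cls,
                           chrom, int(b) + span, cls,
                           homology_len=int(rng.geometric(1 / 3)) - 1,
                           insertion_len=0))
    bounds = [1] + [int(b) for b in breaks] + [chrom_len + 1]
    segs = []
    for level, (a, b) in enumerate(zip(bounds, bounds[1:])):
        total = 2 + 2 * level
        segs.append(CNSegment(chrom, a, b - 1, total, 1))
    return SampleProfile(sample_id=f"sim_bfb_{seed}", svs=svs,
                         cn=merge_equal_neighbors(segs), ploidy=2.0,
                         chrom_lengths={chrom: chrom_len})


def simulate_stepwise_cn(chrom: str = "chr1",
                         chrom_len: int = 100_000_000,
                         region: tuple[int, int] = (30_000_000, 60_000_000),
                         n_steps: int = 8,
                         seed: int = 0) -> SampleProfile:
    """Stepwise aneuploid CN changes with no SVs at all: no cluster can
    form, whatever the CN profile looks like."""
    rng = np.random.default_rng(seed)
    lo, hi = region
    bounds = sorted({lo, hi + 1}
                    | {int(x) for x in rng.integers(lo + 1, hi, size=n_steps - 1)})
    segs = [CNSegment(chrom, 1, lo - 1, 2, 1)]
    level = 2
    for a, b in zip(bounds, bounds[1:]):
        level += int(rng.integers(1, 3))
        segs.append(CNSegment(chrom, a, b - 1, level, 1))
    segs.append(CNSegment(chrom, hi + 1, chrom_len, 2, 1))
    return SampleProfile(sample_id=f"sim_step_{seed}", svs=[],
                         cn=merge_equal_neighbors(segs), ploidy=2.0,
                         chrom_lengths={chrom: chrom_len})


def simulate_background(chroms: Sequence[str] = ("chr1", "chr2"),
                        chrom_len: int = 100_000_000,
                        sv_rate: float = 3.0,
                        seed: int = 0) -> SampleProfile:
    """Quiet genome with sparse independent SVs (Poisson per chromosome)
    and flat diploid CN."""
    if sv_rate < 0:
        raise ValueError("sv_rate must be >= 0")
    rng = np.random.default_rng(seed)
    svs = []
    cn = []
    strands = [("+", "-"), ("-", "+"), ("+", "+"), ("-", "-")]
    for chrom in chroms:
        cn.append(CNSegment(chrom, 1, chrom_len, 2, 1))
        for k in range(int(rng.poisson(sv_rate))):
            p1 = int(rng.integers(1, chrom_len - 1_000_000))
            p2 = p1 + int(rng.integers(10_000, 1_000_000))
            s1, s2 = strands[int(rng.integers(0, 4))]
            svs.append(make_sv(f"bg_{chrom}_s{seed}_{k + 1}", chrom, p1, s1,
                               chrom, p2, s2))
    return SampleProfile(sample_id=f"sim_bg_{seed}", svs=svs, cn=cn,
                         ploidy=2.0,
                         chrom_lengths={c: chrom_len for c in chroms})


# ---------------------------------------------------------------------------
# APOBEC clusters
# ---------------------------------------------------------------------------

def simulate_apobec_cluster(chrom: str = "chr1",
                            region: tuple[int, int] = (30_000_000, 60_000_000),
                            n: int = 25,
                            imd: int = 500,
                            seed: int = 0) -> list[SNVRecord]:
    """A kataegis-style shower of ``n`` APOBEC-motif mutations whose
    successive inter-mutation distances are at most ``imd``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    lo, hi = region
    start = int(rng.integers(lo, max(hi - n * imd, lo + 1)))
    pos = start
    out = []
    for k in range(n):
        if k:
            pos += int(rng.integers(1, imd + 1))
        w = "A" if rng.random() < 0.5 else "T"
        if rng.random() < 0.5:  # pyrimidine representation: tCw -> G/T
            ref, ctx = "C", f"T C {w}".replace(" ", "")
            alt = "G" if rng.random() < 0.5 else "T"
        else:                   # purine representation: wGa -> C/A
            ref, ctx = "G", f"{w} G A".replace(" ", "")
            alt = "C" if rng.random() < 0.5 else "A"
        out.append(SNVRecord(chrom=chrom, pos=pos, ref=ref, alt=alt,
                             context=ctx))
    return out
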