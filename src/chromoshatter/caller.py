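"""Chromothripsis calling: gates, confidence tiers, and CN annotations.

A candidate cluster becomes a call by passing, on at least one chromosome, a
fixed sequence of gates:

cluster size -> CN oscillation -> fragment-join balance -> breakpoint
randomness -> fold-back fraction -> junction homology.

High confidence requires a two-state oscillation run of at least 7 adjacent
segments (or, for multi-chromosome events bridged by enough translocations,
at least 4); low confidence requires a run of 4–6 segments. Rejections
record the first failing gate, in the fixed order above, for reproducible
diagnostics. A call is *canonical* when more than 60% of the region's
segments oscillate between two CN states.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

from .clustering import SVCluster, cluster_sample
from .config import RunConfig
from .io_model import CNSegment, GeneRecord, SampleProfile, SV, make_sv
from . import statistics as st

CONF_HIGH = "high"
CONF_LOW = "low"
CONF_NONE = "none"

GATE_ORDER = ("cluster_size", "oscillation", "fragment_joins",
              "randomness", "foldback", "homology")

REASON_NO_CN = "insufficient CN coverage"


@dataclass
class ChromothripsisCall:
    """One detected (or audited and rejected) event."""

    event_id: str
    sample_id: str
    region_per_chrom: dict[str, tuple[int, int]] = field(default_factory=dict)
    stats_per_chrom: dict[str, st.RegionStatistics] = field(default_factory=dict)
    member_ids: list[str] = field(default_factory=list)
    n_intra: int = 0
    n_inter: int = 0
    n_intra_per_chrom: dict[str, int] = field(default_factory=dict)
    type_counts_per_chrom: dict[str, tuple[int, int, int, int]] = field(default_factory=dict)
    confidence: str = CONF_NONE
    defining_chrom: Optional[str] = None
    canonical: bool = False
    double_minute_candidate: bool = False
    focal_amplifications: list[dict] = field(default_factory=list)
    lost_genes: list[GeneRecord] = field(default_factory=list)
    rejected_reason: str = ""

    @property
    def chroms(self) -> set[str]:
        return set(self.region_per_chrom)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        def stats_d(s: st.RegionStatistics) -> dict:
            return {
                "max_osc_2": s.max_osc_2, "max_osc_3": s.max_osc_3,
                "frac_osc_2": s.frac_osc_2,
                "p_fragment_joins": s.p_fragment_joins,
                "p_exponential": s.p_exponential,
                "p_enrichment": s.p_enrichment,
                "loh_interspersed": s.loh_interspersed,
                "foldback_fraction": s.foldback_fraction,
                "median_homology": s.median_homology,
                "frac_long_homology": s.frac_long_homology,
                "osc_levels": list(s.osc_levels) if s.osc_levels else None,
                "n_segments": s.n_segments, "cn_coverage": s.cn_coverage,
                "evaluable": s.evaluable,
            }
        return {
            "event_id": self.event_id,
            "sample_id": self.sample_id,
            "region_per_chrom": {c: list(r) for c, r in self.region_per_chrom.items()},
            "stats_per_chrom": {c: stats_d(s) for c, s in self.stats_per_chrom.items()},
            "member_ids": list(self.member_ids),
            "n_intra": self.n_intra,
            "n_inter": self.n_inter,
            "n_intra_per_chrom": dict(self.n_intra_per_chrom),
            "type_counts_per_chrom": {c: list(t) for c, t
                                      in self.type_counts_per_chrom.items()},
            "confidence": self.confidence,
            "defining_chrom": self.defining_chrom,
            "canonical": self.canonical,
            "double_minute_candidate": self.double_minute_candidate,
            "focal_amplifications": self.focal_amplifications,
            "lost_genes": [{"name": g.name, "chrom": g.chrom, "start": g.start,
                            "end": g.end, "role": g.role}
                           for g in self.lost_genes],
            "rejected_reason": self.rejected_reason,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ChromothripsisCall":
        def stats_o(sd: dict) -> st.RegionStatistics:
            kwargs = dict(sd)
            if kwargs.get("osc_levels") is not None:
                kwargs["osc_levels"] = tuple(kwargs["osc_levels"])
            return st.RegionStatistics(**kwargs)
        return cls(
            event_id=d["event_id"],
            sample_id=d["sample_id"],
            region_per_chrom={c: tuple(r) for c, r in d["region_per_chrom"].items()},
            stats_per_chrom={c: stats_o(s) for c, s in d["stats_per_chrom"].items()},
            member_ids=list(d["member_ids"]),
            n_intra=d["n_intra"],
            n_inter=d["n_inter"],
            n_intra_per_chrom=dict(d["n_intra_per_chrom"]),
            type_counts_per_chrom={c: tuple(t) for c, t
                                   in d["type_counts_per_chrom"].items()},
            confidence=d["confidence"],
            defining_chrom=d["defining_chrom"],
            canonical=d["canonical"],
            double_minute_candidate=d["double_minute_candidate"],
            focal_amplifications=list(d["focal_amplifications"]),
            lost_genes=[GeneRecord(**g) for g in d["lost_genes"]],
            rejected_reason=d["rejected_reason"],
        )

    def tsv_rows(self) -> list[dict]:
        rows = []
        for chrom in sorted(self.region_per_chrom):
            s = self.stats_per_chrom.get(chrom, st.RegionStatistics())
            tc = self.type_counts_per_chrom.get(chrom, (0, 0, 0, 0))
            lo, hi = self.region_per_chrom[chrom]
            rows.append({
                "sample_id": self.sample_id, "event_id": self.event_id,
                "chrom": chrom, "region_start": lo, "region_end": hi,
                "n_intra": self.n_intra_per_chrom.get(chrom, 0),
                "n_inter": self.n_inter,
                "n_del": tc[0], "n_dup": tc[1], "n_h2h": tc[2], "n_t2t": tc[3],
                "max_osc_2": s.max_osc_2, "max_osc_3": s.max_osc_3,
                "frac_osc_2": s.frac_osc_2,
                "p_fragment_joins": s.p_fragment_joins,
                "p_exponential": s.p_exponential,
                "p_enrichment": s.p_enrichment,
                "loh_interspersed": s.loh_interspersed,
                "foldback_fraction": s.foldback_fraction,
                "median_homology": s.median_homology,
                "frac_long_homology": s.frac_long_homology,
                "confidence": self.confidence, "canonical": self.canonical,
                "double_minute_candidate": self.double_minute_candidate,
                "rejected_reason": self.rejected_reason,
            })
        return rows


# ---------------------------------------------------------------------------
# Region evaluation
# ---------------------------------------------------------------------------

def clip_segments(segments: Sequence[CNSegment],
                  region: tuple[int, int]) -> list[CNSegment]:
    """Segments fully or partially inside the region, clipped at its bounds."""
    lo, hi = region
    out = []
    for s in segments:
        if s.end < lo or s.start > hi:
            continue
        out.append(replace(s, start=max(s.start, lo), end=min(s.end, hi)))
    return out


def evaluate_event(profile: SampleProfile, cluster: SVCluster,
                   cfg: RunConfig = RunConfig()
                   ) -> dict[str, st.RegionStatistics]:
    """Compute every region statistic on each chromosome of the cluster."""
    cn_by_chrom = profile.cn_by_chrom()
    out: dict[str, st.RegionStatistics] = {}
    for chrom in sorted(cluster.chroms):
        region = cluster.region(chrom)
        intra = cluster.intra_on(chrom)
        segs = clip_segments(cn_by_chrom.get(chrom, []), region)
        if cfg.min_segment_bp > 0:
            segs = [s for s in segs if s.length >= cfg.min_segment_bp]
        region_len = region[1] - region[0]
        coverage = sum(s.length for s in segs) / (region_len + 1)
        s = st.RegionStatistics(n_segments=len(segs),
                                cn_coverage=min(coverage, 1.0))
        s.foldback_fraction = st.foldback_fraction(intra, cfg.foldback_span)
        s.median_homology, s.frac_long_homology = st.homology_summary(
            cluster.members, cfg.long_homology_bp)
        if intra:
            s.p_fragment_joins = st.fragment_join_test(
                cluster.type_counts(chrom), cfg.exact_cutoff)
        bps = cluster.breakpoints_on(chrom)
        if region_len > 0:
            s.p_exponential = st.breakpoint_exponential_test(bps, region)
            n_chrom_bp = sum((sv.chrom1 == chrom) + (sv.chrom2 == chrom)
                             for sv in profile.svs)
            try:
                s.p_enrichment = st.chromosome_enrichment_test(
                    len(bps), region_len, max(n_chrom_bp, len(bps)),
                    profile.chrom_length(chrom))
            except Exception:
                s.p_enrichment = None
        if s.cn_coverage < cfg.min_cn_coverage:
            s.evaluable = False
            out[chrom] = s
            continue
        states = [seg.total_cn for seg in segs]
        s.max_osc_2 = st.max_alternating_run(states, 2)
        s.max_osc_3 = st.max_alternating_run(states, 3)
        s.frac_osc_2 = st.fraction_two_state(states)
        dom = st.dominant_two_state_levels(states)
        if dom is not None:
            s.osc_levels = (dom[0], dom[1])
        s.loh_interspersed = st.detect_interspersed_loh(
            segs, cfg.min_loh_switches)
        out[chrom] = s
    return out


# ---------------------------------------------------------------------------
# Gates and tiers
# ---------------------------------------------------------------------------

def _randomness_passes(s: st.RegionStatistics, cfg: RunConfig) -> bool:
    # breakpoints must look chromosomally concentrated (enrichment rejects
    # uniformity over the chromosome) OR uniform within the region
    # (exponential-spacing fit not rejected); either signature suffices
    enrich = s.p_enrichment is not None and s.p_enrichment < cfg.alpha_random
    uniform = s.p_exponential is not None and s.p_exponential >= cfg.alpha_random
    return enrich or uniform


def _gate_failures(s: st.RegionStatistics, n_intra: int, n_inter: int,
                   cfg: RunConfig, route: str) -> list[str]:
    """Names of failed gates, in the fixed diagnostic order.

    Route ``intra`` demands a per-chromosome cluster of min_cluster_svs
    intrachromosomal SVs and an oscillation run >= low_min_osc; route
    ``inter`` demands min_inter_link translocations instead, with the same
    oscillation floor.
    """
    fails = []
    if route == "intra":
        if n_intra < cfg.min_cluster_svs:
            fails.append("cluster_size")
    else:
        if n_inter < cfg.min_inter_link:
            fails.append("cluster_size")
    if s.max_osc_2 < cfg.low_min_osc:
        fails.append("oscillation")
    if s.p_fragment_joins is None or s.p_fragment_joins < cfg.alpha_joins:
        fails.append("fragment_joins")
    if not _randomness_passes(s, cfg):
        fails.append("randomness")
    if s.foldback_fraction >= cfg.foldback_max:
        fails.append("foldback")
    if (s.frac_long_homology is not None
            and s.frac_long_homology >= cfg.homology_max):
        fails.append("homology")
    return fails


def classify_confidence(stats_per_chrom: dict[str, st.RegionStatistics],
                        cluster: SVCluster,
                        cfg: RunConfig = RunConfig()
                        ) -> tuple[str, Optional[str], str]:
    """(confidence, defining chromosome, rejected_reason).

    High confidence: all gates pass on some chromosome with a two-state run
    of >= high_min_osc adjacent segments (intrachromosomal route), or a
    multi-chromosome event bridged by >= min_inter_link translocations with
    a run of >= low_min_osc. Low confidence: gates pass with a run in
    [low_min_osc, high_min_osc), or everything passes except a *marginal*
    join imbalance (alpha_joins_strict <= p < alpha_joins) — the join test
    is calibrated, so such p-values arise on a fraction alpha_joins of
    genuine events and demote rather than reject. Otherwise none, with the
    first failed gate (fixed order) on the chromosome that got furthest.
    """
    best_reason: str = "cluster_size"
    best_rank = -1
    low_chrom: Optional[str] = None
    for chrom in sorted(stats_per_chrom):
        s = stats_per_chrom[chrom]
        if not s.evaluable:
            continue
        n_intra = len(cluster.intra_on(chrom))
        routes = ["intra"]
        if cluster.n_inter >= cfg.min_inter_link:
            routes.append("inter")
        for route in routes:
            fails = _gate_failures(s, n_intra, cluster.n_inter, cfg, route)
            if not fails:
                if route == "inter" or s.max_osc_2 >= cfg.high_min_osc:
                    return CONF_HIGH, chrom, ""
                if low_chrom is None:
                    low_chrom = chrom
            elif (fails == ["fragment_joins"]
                    and s.p_fragment_joins is not None
                    and s.p_fragment_joins >= cfg.alpha_joins_strict):
                if low_chrom is None:
                    low_chrom = chrom
            else:
                rank = GATE_ORDER.index(fails[0])
                if rank > best_rank:
                    best_rank = rank
                    best_reason = fails[0]
    if low_chrom is not None:
        return CONF_LOW, low_chrom, ""
    if all(not s.evaluable for s in stats_per_chrom.values()):
        return CONF_NONE, None, REASON_NO_CN
    return CONF_NONE, None, best_reason


def canonical_flag(stats: st.RegionStatistics,
                   cfg: RunConfig = RunConfig()) -> bool:
    """True when strictly more than 60% of the defining chromosome's region
    segments oscillate between two CN states."""
    return stats.frac_osc_2 > cfg.canonical_min_frac


# ---------------------------------------------------------------------------
# Copy-number annotations
# ---------------------------------------------------------------------------

def detect_double_minute(cn_states: Sequence[int],
                         cfg: RunConfig = RunConfig()) -> bool:
    """Oscillation between one low (<= dm_low_cn) and one very high
    (>= dm_high_cn) CN state, in a run of >= dm_min_osc segments —
    consistent with a double minute."""
    def side(v: int) -> Optional[str]:
        if v <= cfg.dm_low_cn:
            return "lo"
        if v >= cfg.dm_high_cn:
            return "hi"
        return None

    run = 0
    prev_side: Optional[str] = None
    for v in cn_states:
        cur = side(v)
        if cur is not None and prev_side is not None and cur != prev_side:
            run = run + 1 if run else 2
        else:
            run = 1 if cur is not None else 0
        if run >= cfg.dm_min_osc:
            return True
        prev_side = cur
    return False


def focal_amplifications(segments: Sequence[CNSegment],
                         genes: Sequence[GeneRecord] = (),
                         event_regions: dict[str, tuple[int, int]] | None = None,
                         cfg: RunConfig = RunConfig()) -> list[dict]:
    """Maximal runs of contiguous high-CN segments smaller than the focal
    span gate, annotated with overlapping genes and whether they intersect a
    chromothripsis region."""
    by_chrom: dict[str, list[CNSegment]] = {}
    for s in segments:
        by_chrom.setdefault(s.chrom, []).append(s)
    hits: list[dict] = []
    for chrom in sorted(by_chrom):
        segs = sorted(by_chrom[chrom], key=lambda s: s.start)
        run: list[CNSegment] = []
        runs: list[list[CNSegment]] = []
        for s in segs:
            if s.total_cn >= cfg.focal_amp_min_cn:
                if run and s.start <= run[-1].end + 1:
                    run.append(s)
                else:
                    if run:
                        runs.append(run)
                    run = [s]
            else:
                if run:
                    runs.append(run)
                run = []
        if run:
            runs.append(run)
        for run in runs:
            start, end = run[0].start, run[-1].end
            if end - start + 1 >= cfg.focal_amp_max_span:
                continue
            overlap_genes = [g.name for g in genes if g.chrom == chrom
                             and g.start <= end and g.end >= start]
            in_event = False
            if event_regions and chrom in event_regions:
                lo, hi = event_regions[chrom]
                in_event = start <= hi and end >= lo
            hits.append({"chrom": chrom, "start": start, "end": end,
                         "max_cn": max(s.total_cn for s in run),
                         "genes": overlap_genes,
                         "in_chromothripsis_region": in_event})
    return hits


def lost_genes_in_event(region_per_chrom: dict[str, tuple[int, int]],
                        segments: Sequence[CNSegment],
                        genes: Sequence[GeneRecord]) -> list[GeneRecord]:
    """Genes fully inside an event region and fully covered by lost
    segments (total CN <= 1 or minor CN 0)."""
    by_chrom: dict[str, list[CNSegment]] = {}
    for s in segments:
        by_chrom.setdefault(s.chrom, []).append(s)
    out: list[GeneRecord] = []
    for g in genes:
        if g.chrom not in region_per_chrom:
            continue
        lo, hi = region_per_chrom[g.chrom]
        if not (lo <= g.start and g.end <= hi):
            continue
        lost_segs = sorted(
            (s for s in by_chrom.get(g.chrom, [])
             if (s.total_cn <= 1 or s.minor_cn == 0)
             and s.start <= g.end and s.end >= g.start),
            key=lambda s: s.start)
        # require gap-free coverage of the whole gene body
        cursor = g.start
        for s in lost_segs:
            if s.start > cursor:
                break
            cursor = max(cursor, s.end + 1)
        if cursor > g.end:
            out.append(g)
    return out


# ---------------------------------------------------------------------------
# Sample-level pipeline
# ---------------------------------------------------------------------------

def detect_chromothripsis(profile: SampleProfile,
                          cfg: RunConfig = RunConfig(),
                          genes: Sequence[GeneRecord] = (),
                          include_audit: bool = True
                          ) -> list[ChromothripsisCall]:
    """Run the full detection pipeline on one sample.

    Returns one call per linked cluster; with ``include_audit`` sub-floor
    components are also reported as non-calls so every gate outcome is
    auditable.
    """
    clusters = cluster_sample(profile.svs,
                              min_cluster_svs=cfg.min_cluster_svs,
                              min_inter_link=cfg.min_inter_link,
                              keep_small=include_audit)
    cn_by_chrom = profile.cn_by_chrom()
    calls: list[ChromothripsisCall] = []
    for cluster in clusters:
        stats = evaluate_event(profile, cluster, cfg)
        conf, def_chrom, reason = classify_confidence(stats, cluster, cfg)
        call = ChromothripsisCall(
            event_id=cluster.event_id,
            sample_id=profile.sample_id,
            region_per_chrom=dict(cluster.region_per_chrom),
            stats_per_chrom=stats,
            member_ids=sorted(cluster.member_ids),
            n_intra=cluster.n_intra,
            n_inter=cluster.n_inter,
            n_intra_per_chrom={c: len(cluster.intra_on(c))
                               for c in cluster.chroms},
            type_counts_per_chrom={c: cluster.type_counts(c)
                                   for c in cluster.chroms},
            confidence=conf,
            defining_chrom=def_chrom,
            rejected_reason=reason,
        )
        if def_chrom is not None:
            call.canonical = canonical_flag(stats[def_chrom], cfg)
        if conf != CONF_NONE:
            for chrom in sorted(cluster.chroms):
                segs = clip_segments(cn_by_chrom.get(chrom, []),
                                     cluster.region(chrom))
                if detect_double_minute([s.total_cn for s in segs], cfg):
                    call.double_minute_candidate = True
            call.focal_amplifications = focal_amplifications(
                profile.cn, genes, call.region_per_chrom, cfg)
            call.lost_genes = lost_genes_in_event(
                call.region_per_chrom, profile.cn, genes)
        calls.append(call)
    return calls
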