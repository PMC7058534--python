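"""Interleaved-SV graph construction and multi-chromosome event linking.

Two intrachromosomal SVs are *interleaved* when the genomic intervals bridged
by their breakpoints overlap without one being nested inside the other — the
footprint left by random religation of shattered fragments. Clusters are the
connected components of the graph with an edge for every interleaved pair;
components below the configured SV floor are not chromothripsis candidates.
Interchromosomal SVs then link clusters on different chromosomes into single
multi-chromosome events.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .io_model import INTRA_CLASSES, SV


def interleaved(a: SV, b: SV) -> bool:
    """True iff the intervals bridged by ``a`` and ``b`` overlap, neither
    containing the other. Both must be intrachromosomal on one chromosome."""
    if not (a.is_intra and b.is_intra):
        raise ValueError("interleaved() requires intrachromosomal SVs")
    if a.chrom1 != b.chrom1:
        raise ValueError("interleaved() requires SVs on the same chromosome")
    if a.pos1 > b.pos2 or b.pos1 > a.pos2:          # disjoint
        return False
    if a.pos1 <= b.pos1 and b.pos2 <= a.pos2:       # b nested in a
        return False
    if b.pos1 <= a.pos1 and a.pos2 <= b.pos2:       # a nested in b
        return False
    return True


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


@dataclass
class SVCluster:
    """A connected component of the interleaved-SV graph, possibly spanning
    several chromosomes after interchromosomal linking."""

    event_id: str
    members: list[SV] = field(default_factory=list)
    region_per_chrom: dict[str, tuple[int, int]] = field(default_factory=dict)

    @property
    def member_ids(self) -> set[str]:
        return {sv.id for sv in self.members}

    @property
    def chroms(self) -> set[str]:
        return set(self.region_per_chrom)

    @property
    def n_intra(self) -> int:
        return sum(1 for sv in self.members if sv.is_intra)

    @property
    def n_inter(self) -> int:
        return sum(1 for sv in self.members if not sv.is_intra)

    def intra_on(self, chrom: str) -> list[SV]:
        return [sv for sv in self.members if sv.is_intra and sv.chrom1 == chrom]

    def type_counts(self, chrom: Optional[str] = None) -> tuple[int, int, int, int]:
        """Counts of (DEL_like, DUP_like, h2h_inv, t2t_inv) members,
        optionally restricted to one chromosome."""
        svs = self.members if chrom is None else self.intra_on(chrom)
        counts = {c: 0 for c in INTRA_CLASSES}
        for sv in svs:
            if sv.join_class in counts:
                counts[sv.join_class] += 1
        return tuple(counts[c] for c in INTRA_CLASSES)

    def breakpoints_on(self, chrom: str) -> list[int]:
        pts: list[int] = []
        for sv in self.members:
            if sv.chrom1 == chrom:
                pts.append(sv.pos1)
            if sv.chrom2 == chrom:
                pts.append(sv.pos2)
        pts.sort()
        return pts

    def region(self, chrom: str) -> tuple[int, int]:
        if chrom not in self.region_per_chrom:
            raise ValueError(f"event {self.event_id} has no region on {chrom}")
        return self.region_per_chrom[chrom]

    def _recompute_regions(self) -> None:
        regions: dict[str, tuple[int, int]] = {}

        def extend(chrom: str, pos: int) -> None:
            lo, hi = regions.get(chrom, (pos, pos))
            regions[chrom] = (min(lo, pos), max(hi, pos))

        for sv in self.members:
            extend(sv.chrom1, sv.pos1)
            extend(sv.chrom2, sv.pos2)
        self.region_per_chrom = regions


def cluster_region(cluster: SVCluster, chrom: str) -> tuple[int, int]:
    """(min, max) over member breakpoint positions on ``chrom``."""
    return cluster.region(chrom)


def _interleaved_components(svs: Sequence[SV]) -> list[list[int]]:
    """Connected components of the interleaved relation, by index.

    Sweep over breakpoint-sorted intervals: for each SV, scan the later SVs
    whose interval starts before this one ends, and union the interleaved
    pairs. Equivalent to the quadratic all-pairs check kept as the test
    oracle, but skips provably disjoint pairs.
    """
    order = sorted(range(len(svs)), key=lambda i: (svs[i].pos1, svs[i].pos2))
    uf = _UnionFind(len(svs))
    for a_rank, i in enumerate(order):
        a = svs[i]
        for j in order[a_rank + 1:]:
            b = svs[j]
            if b.pos1 > a.pos2:
                break  # later starts are larger still: all disjoint from a
            # overlap guaranteed; exclude nesting (b starts inside a)
            if not (a.pos1 <= b.pos1 and b.pos2 <= a.pos2) and \
               not (b.pos1 <= a.pos1 and a.pos2 <= b.pos2):
                uf.union(i, j)
    comps: dict[int, list[int]] = {}
    for i in range(len(svs)):
        comps.setdefault(uf.find(i), []).append(i)
    return list(comps.values())


def build_clusters(svs: Sequence[SV], min_cluster_svs: int = 6,
                   event_prefix: str = "evt") -> list[SVCluster]:
    """Cluster intrachromosomal SVs of one chromosome by interleaving.

    Components with fewer than ``min_cluster_svs`` members are discarded.
    Clusters are ordered (and numbered) by leftmost breakpoint, so the
    result is independent of input order.
    """
    svs = list(svs)
    if not svs:
        return []
    chroms = {sv.chrom1 for sv in svs}
    if len(chroms) > 1 or any(not sv.is_intra for sv in svs):
        raise ValueError("build_clusters expects intrachromosomal SVs "
                         "of a single chromosome")
    comps = [c for c in _interleaved_components(svs)
             if len(c) >= min_cluster_svs]
    comps.sort(key=lambda c: min(svs[i].pos1 for i in c))
    chrom = next(iter(chroms))
    clusters = []
    for k, comp in enumerate(comps, 1):
        members = sorted((svs[i] for i in comp),
                         key=lambda sv: (sv.pos1, sv.pos2, sv.id))
        cl = SVCluster(event_id=f"{event_prefix}_{chrom}_{k}", members=members)
        cl._recompute_regions()
        clusters.append(cl)
    return clusters


def _in_region(pos: int, region: tuple[int, int]) -> bool:
    return region[0] <= pos <= region[1]


def link_interchromosomal(clusters: Sequence[SVCluster],
                          inter_svs: Sequence[SV],
                          min_inter_link: int = 3) -> list[SVCluster]:
    """Merge clusters bridged by interchromosomal SVs into multi-chromosome
    events.

    Two clusters merge when at least ``min_inter_link`` interchromosomal SVs
    have one breakpoint inside each cluster's region. An interchromosomal SV
    whose breakpoints fall inside the regions of a single cluster only is
    attached to that cluster and extends its region on the partner
    chromosome. SVs touching no cluster are left out.
    """
    clusters = list(clusters)
    n = len(clusters)

    def owners(sv: SV) -> tuple[set[int], set[int]]:
        """Cluster indices whose region contains breakpoint 1 resp. 2."""
        o1 = {k for k, cl in enumerate(clusters)
              if sv.chrom1 in cl.region_per_chrom
              and _in_region(sv.pos1, cl.region_per_chrom[sv.chrom1])}
        o2 = {k for k, cl in enumerate(clusters)
              if sv.chrom2 in cl.region_per_chrom
              and _in_region(sv.pos2, cl.region_per_chrom[sv.chrom2])}
        return o1, o2

    pair_links: dict[tuple[int, int], list[SV]] = {}
    attached: dict[int, list[SV]] = {}
    for sv in inter_svs:
        if sv.is_intra:
            raise ValueError("link_interchromosomal expects interchromosomal SVs")
        o1, o2 = owners(sv)
        touched = o1 | o2
        linked_pairs = {(min(i, j), max(i, j)) for i in o1 for j in o2 if i != j}
        if linked_pairs:
            for pair in linked_pairs:
                pair_links.setdefault(pair, []).append(sv)
        elif len(touched) >= 1:
            # anchored in one cluster only: attach to the leftmost-indexed one
            attached.setdefault(min(touched), []).append(sv)

    uf = _UnionFind(n)
    bridge_members: dict[int, list[SV]] = {}
    for (i, j), svs_ij in pair_links.items():
        if len(svs_ij) >= min_inter_link:
            uf.union(i, j)
        bridge_members.setdefault(i, []).extend(svs_ij)

    groups: dict[int, list[int]] = {}
    for k in range(n):
        groups.setdefault(uf.find(k), []).append(k)

    merged: list[SVCluster] = []
    for root, idxs in sorted(groups.items()):
        members: list[SV] = []
        seen: set[str] = set()
        for k in idxs:
            for sv in clusters[k].members:
                if sv.id not in seen:
                    members.append(sv)
                    seen.add(sv.id)
            for sv in attached.get(k, []):
                if sv.id not in seen:
                    members.append(sv)
                    seen.add(sv.id)
        # bridging SVs between pairs inside this group, and sub-threshold
        # bridges anchored here, travel with the event
        for k in idxs:
            for sv in bridge_members.get(k, []):
                if sv.id not in seen:
                    members.append(sv)
                    seen.add(sv.id)
        event_id = clusters[idxs[0]].event_id
        cl = SVCluster(event_id=event_id, members=members)
        cl._recompute_regions()
        merged.append(cl)
    merged.sort(key=lambda cl: min(cl.region_per_chrom[c][0]
                                   for c in cl.region_per_chrom))
    return merged


def cluster_sample(svs: Sequence[SV], min_cluster_svs: int = 6,
                   min_inter_link: int = 3,
                   keep_small: bool = False) -> list[SVCluster]:
    """Full clustering of one sample's SV set.

    Intrachromosomal SVs are clustered per chromosome, then linked across
    chromosomes through the interchromosomal SVs. Every component — including
    those below the SV floor — is a candidate link anchor, because a
    breakpoint-dense region without a qualifying cluster of its own can
    still be part of a multi-chromosome event. After linking, an event is
    retained when some chromosome carries at least ``min_cluster_svs``
    intrachromosomal members or at least ``min_inter_link`` translocations
    bridge it; with ``keep_small`` the rest are returned too (audit rows).
    """
    by_chrom: dict[str, list[SV]] = {}
    inter: list[SV] = []
    for sv in svs:
        if sv.is_intra:
            by_chrom.setdefault(sv.chrom1, []).append(sv)
        else:
            inter.append(sv)
    components: list[SVCluster] = []
    for chrom in sorted(by_chrom):
        components.extend(build_clusters(by_chrom[chrom], min_cluster_svs=1))
    linked = link_interchromosomal(components, inter,
                                   min_inter_link=min_inter_link)
    events: list[SVCluster] = []
    small: list[SVCluster] = []
    for cl in linked:
        qualifies = (cl.n_inter >= min_inter_link
                     or any(len(cl.intra_on(c)) >= min_cluster_svs
                            for c in cl.chroms))
        (events if qualifies else small).append(cl)
    return events + (small if keep_small else [])
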