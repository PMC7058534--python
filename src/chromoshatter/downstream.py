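"""Downstream interpretation of chromothripsis calls.

Three annotations, each reading the call plus auxiliary inputs:

* **WGD timing** — in a polyploid genome the levels of the dominant CN
  oscillation date the shattering relative to whole-genome doubling. A 2<->4
  oscillation means a single pre-doubling chromatid lost fragments and was
  then duplicated (shattering first); a 3<->4 oscillation means single-copy
  losses on an already doubled background (doubling first).
* **APOBEC kataegis** — clustered C>T/G mutations at tCw motifs (or the
  reverse-strand wGa representation) inside the event region, chained by
  inter-mutation distance; 5 clustered mutations flag co-occurrence, more
  than 20 flag kataegis.
* **Repair signature** — junction microhomology (mostly 0–6 bp) with few
  templated insertions points at end-joining (NHEJ/alt-EJ); recurrent 10–500
  bp insertions alongside microhomology point at a replicative, MMBIR-like
  mechanism.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .caller import ChromothripsisCall
from .config import RunConfig
from .io_model import SNVRecord, SV

TIMING_SHATTER_FIRST = "chromothripsis_before_WGD"
TIMING_WGD_FIRST = "WGD_before_chromothripsis"
TIMING_UNDETERMINED = "undetermined"

LABEL_EJ = "EJ_like"
LABEL_MMBIR = "MMBIR_like"
LABEL_MIXED = "mixed"


@dataclass(frozen=True)
class TimingCall:
    event_id: str
    relation: str
    osc_levels: Optional[tuple[int, int]] = None
    note: str = ""


@dataclass(frozen=True)
class KataegisCall:
    event_id: str
    n_apobec_in_region: int
    max_cluster: int
    cooccurrence: bool
    kataegis: bool


# ---------------------------------------------------------------------------
# WGD timing
# ---------------------------------------------------------------------------

def infer_wgd_timing(call: ChromothripsisCall, ploidy: float,
                     cfg: RunConfig = RunConfig()) -> TimingCall:
    """Date chromothripsis relative to whole-genome doubling from the two
    levels of the dominant oscillation.

    Only polyploid samples (ploidy >= 2.5) with a canonical two-state run of
    at least 7 adjacent segments are informative; everything else is
    undetermined. With oscillation levels (lo, hi):

    * lo == hi/2 (hi even): the lost state is half the retained one, so
      losses predate the doubling — chromothripsis before WGD (e.g. 2<->4);
    * lo == hi - 1: single-copy losses on a doubled background — WGD before
      chromothripsis (e.g. 3<->4).

    The (1, 2) pair satisfies both patterns and stays undetermined.
    """
    if ploidy < cfg.polyploid_min_ploidy:
        return TimingCall(call.event_id, TIMING_UNDETERMINED,
                          note="sample not polyploid")
    chrom = call.defining_chrom
    if chrom is None or not call.canonical:
        return TimingCall(call.event_id, TIMING_UNDETERMINED,
                          note="no canonical oscillation")
    s = call.stats_per_chrom[chrom]
    if s.max_osc_2 < cfg.high_min_osc or s.osc_levels is None:
        return TimingCall(call.event_id, TIMING_UNDETERMINED,
                          note="dominant run below high-confidence floor")
    lo, hi = s.osc_levels
    if hi <= lo:
        return TimingCall(call.event_id, TIMING_UNDETERMINED, (lo, hi),
                          note="degenerate levels")
    halved = hi % 2 == 0 and lo == hi // 2
    single_loss = lo == hi - 1
    if halved and not single_loss:
        return TimingCall(call.event_id, TIMING_SHATTER_FIRST, (lo, hi))
    if single_loss and not halved:
        return TimingCall(call.event_id, TIMING_WGD_FIRST, (lo, hi))
    return TimingCall(call.event_id, TIMING_UNDETERMINED, (lo, hi),
                      note="ambiguous level pattern")


# ---------------------------------------------------------------------------
# APOBEC / kataegis
# ---------------------------------------------------------------------------

_W = {"A", "T"}


def classify_apobec(snv: SNVRecord) -> bool:
    """True when the mutation matches the APOBEC motif on either strand:
    C in tCw mutated to G or T, or (reverse-strand representation) G in wGa
    mutated to C or A, with w one of A/T."""
    ctx = snv.context.upper()
    ref, alt = snv.ref.upper(), snv.alt.upper()
    if ctx[1] != ref:
        raise ValueError(f"context middle base {ctx[1]} != ref {ref}")
    if ref == "C":
        return ctx[0] == "T" and ctx[2] in _W and alt in {"G", "T"}
    if ref == "G":
        return ctx[2] == "A" and ctx[0] in _W and alt in {"C", "A"}
    return False


def kataegis_in_region(snvs: Sequence[SNVRecord],
                       region: tuple[int, int],
                       cfg: RunConfig = RunConfig(),
                       chrom: Optional[str] = None,
                       event_id: str = "") -> KataegisCall:
    """Chain APOBEC mutations inside the region by inter-mutation distance
    and apply the cluster-size thresholds."""
    lo, hi = region
    hits = sorted(s.pos for s in snvs
                  if (chrom is None or s.chrom == chrom)
                  and lo <= s.pos <= hi and classify_apobec(s))
    max_cluster = 0
    run = 0
    prev = None
    for pos in hits:
        if prev is not None and pos - prev <= cfg.kataegis_imd:
            run += 1
        else:
            run = 1
        max_cluster = max(max_cluster, run)
        prev = pos
    return KataegisCall(event_id=event_id,
                        n_apobec_in_region=len(hits),
                        max_cluster=max_cluster,
                        cooccurrence=max_cluster >= cfg.kataegis_cooccurrence,
                        kataegis=max_cluster > cfg.kataegis_min)


def annotate_kataegis(call: ChromothripsisCall,
                      snvs: Sequence[SNVRecord],
                      cfg: RunConfig = RunConfig()) -> KataegisCall:
    """Kataegis over every chromosome of the event; the largest chain wins."""
    best: Optional[KataegisCall] = None
    total = 0
    for chrom in sorted(call.region_per_chrom):
        kc = kataegis_in_region(snvs, call.region_per_chrom[chrom], cfg,
                                chrom=chrom, event_id=call.event_id)
        total += kc.n_apobec_in_region
        if best is None or kc.max_cluster > best.max_cluster:
            best = kc
    if best is None:
        return KataegisCall(call.event_id, 0, 0, False, False)
    return KataegisCall(call.event_id, total, best.max_cluster,
                        best.cooccurrence, best.kataegis)


# ---------------------------------------------------------------------------
# Repair signature
# ---------------------------------------------------------------------------

def repair_signature_summary(svs: Sequence[SV],
                             microhomology_max: int = 6,
                             insertion_range: tuple[int, int] = (10, 500)
                             ) -> Optional[str]:
    """Classify the repair fingerprint of an event's junction set.

    EJ_like: median homology <= 6 bp and fewer than 2 templated insertions
    (10–500 bp) — consistent with NHEJ/alt-EJ. MMBIR_like: at least 2
    junctions with microhomology and at least 2 with templated insertions.
    Mixed otherwise. Requires homology and insertion annotation on at least
    half the junctions; returns None below that.
    """
    junctions = list(svs)
    if not junctions:
        return None
    annotated = [sv for sv in junctions
                 if sv.homology_len is not None and sv.insertion_len is not None]
    if len(annotated) / len(junctions) < 0.5:
        return None
    homs = [sv.homology_len for sv in annotated]
    median_hom = float(np.median(homs))
    lo, hi = insertion_range
    n_templated = sum(1 for sv in annotated
                      if lo <= sv.insertion_len <= hi)
    n_microhom = sum(1 for h in homs if 1 <= h <= microhomology_max)
    if median_hom <= microhomology_max and n_templated < 2:
        return LABEL_EJ
    if n_microhom >= 2 and n_templated >= 2:
        return LABEL_MMBIR
    return LABEL_MIXED
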