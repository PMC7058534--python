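"""Run configuration: every tunable threshold of the detection pipeline.

All thresholds are exposed in one flat dataclass so that a YAML config file,
the CLI and the library share a single source of defaults. Unknown keys are
rejected on load to catch typos in user configs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml


@dataclass(frozen=True)
class RunConfig:
    """Thresholds and switches for chromothripsis detection.

    Attributes
    ----------
    min_cluster_svs:
        Minimum number of intrachromosomal SVs in an interleaved cluster for
        it to be considered a chromothripsis candidate. Clusters below this
        floor are reported as non-calls.
    min_inter_link:
        Minimum number of interchromosomal SVs bridging two regions for the
        regions to be merged into one multi-chromosome event, and the minimum
        translocation count for the interchromosomal high-confidence route.
    exact_cutoff:
        Largest total count for which the fragment-join equal-proportions
        test uses exact multinomial enumeration; above it a chi-square
        goodness-of-fit with 3 degrees of freedom is used.
    foldback_span:
        Maximum reference span (bp) of an inversion-type SV for it to count
        as a fold-back (breakage-fusion-bridge evidence).
    long_homology_bp:
        Junction homology longer than this is counted as "long" (evidence
        against end-joining repair of shattered fragments).
    min_loh_switches:
        Minimum number of transitions between minor-allele copy number 0 and
        >= 1 across a region for LOH to be called "interspersed".
    min_segment_bp:
        Copy-number segments shorter than this are dropped before oscillation
        counting (0 disables size filtering).
    alpha_joins:
        Significance level for the fragment-join test; a cluster passes when
        its p-value is >= alpha_joins (consistent with random joining).
    alpha_joins_strict:
        Hard floor for the fragment-join test. Below it the imbalance is
        positive evidence of a non-shattering mechanism and the cluster is
        rejected; between the floor and alpha_joins the call is demoted to
        low confidence instead of being discarded, because a calibrated test
        produces such marginal p-values on a fraction alpha_joins of genuine
        events.
    alpha_random:
        Significance level for the breakpoint-randomness criterion.
    foldback_max:
        Maximum tolerated fold-back fraction before a cluster is rejected
        as BFB-like.
    homology_max:
        Maximum tolerated fraction of long-homology junctions.
    min_cn_coverage:
        Minimum fraction of a region that must be covered by copy-number
        segments for the region statistics to be evaluable.
    dm_min_osc, dm_low_cn, dm_high_cn:
        Double-minute signature: an alternating run of at least ``dm_min_osc``
        segments between a level <= dm_low_cn and a level >= dm_high_cn.
    focal_amp_min_cn, focal_amp_max_span:
        Focal amplification: contiguous run with total CN >= focal_amp_min_cn
        spanning < focal_amp_max_span bp.
    kataegis_imd:
        Maximum inter-mutation distance (bp) for chaining APOBEC mutations
        into one cluster.
    kataegis_cooccurrence, kataegis_min:
        Cluster-size thresholds: co-occurrence when the largest chain has at
        least ``kataegis_cooccurrence`` mutations, kataegis when it exceeds
        ``kataegis_min``.
    diploid_max_ploidy, polyploid_min_ploidy:
        Ploidy class boundaries (diploid <= 2.1, polyploid >= 2.5).
    """

    min_cluster_svs: int = 6
    min_inter_link: int = 3
    exact_cutoff: int = 15
    foldback_span: int = 30_000
    long_homology_bp: int = 10
    min_loh_switches: int = 4
    min_segment_bp: int = 0
    alpha_joins: float = 0.05
    alpha_joins_strict: float = 0.001
    alpha_random: float = 0.05
    foldback_max: float = 0.5
    homology_max: float = 0.5
    min_cn_coverage: float = 0.5
    high_min_osc: int = 7
    low_min_osc: int = 4
    canonical_min_frac: float = 0.6
    dm_min_osc: int = 4
    dm_low_cn: int = 4
    dm_high_cn: int = 10
    focal_amp_min_cn: int = 4
    focal_amp_max_span: int = 6_000_000
    kataegis_imd: int = 1_000
    kataegis_cooccurrence: int = 5
    kataegis_min: int = 20
    diploid_max_ploidy: float = 2.1
    polyploid_min_ploidy: float = 2.5
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.min_cluster_svs < 1:
            raise ValueError("min_cluster_svs must be >= 1")
        if self.min_inter_link < 1:
            raise ValueError("min_inter_link must be >= 1")
        for name in ("alpha_joins", "alpha_random", "foldback_max",
                     "homology_max", "min_cn_coverage", "canonical_min_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.high_min_osc < self.low_min_osc:
            raise ValueError("high_min_osc must be >= low_min_osc")
        if self.dm_high_cn <= self.dm_low_cn:
            raise ValueError("dm_high_cn must exceed dm_low_cn")

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        """Build a config from a mapping, rejecting unknown keys."""
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError("config file must contain a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def replace(self, **kwargs: Any) -> "RunConfig":
        return dataclasses.replace(self, **kwargs)


DEFAULT_CONFIG = RunConfig()
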