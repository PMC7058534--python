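"""chromoshatter: chromothripsis detection from somatic SV and CN calls.

Detects clusters of interleaved rearrangements with oscillating copy number,
tiers them by confidence, links multi-chromosome events through
translocations, and annotates WGD timing, APOBEC kataegis, double-minute and
focal-amplification signals. A ground-truth simulator generates every input
class the caller consumes, including the mimicking processes it must reject.
"""

from .config import RunConfig, DEFAULT_CONFIG
from .io_model import (SV, CNSegment, SNVRecord, GeneRecord, SampleProfile,
                       DEL_LIKE, DUP_LIKE, H2H_INV, T2T_INV, INTERCHROMOSOMAL,
                       INTRA_CLASSES,
                       ParseError, ValidationError,
                       make_sv, join_class_from_strands,
                       read_sv_bedpe, write_sv_bedpe,
                       read_cn_segments, write_cn_segments,
                       merge_equal_neighbors,
                       read_snv_table, write_snv_table,
                       read_genes_bed, read_metadata,
                       write_calls, read_calls)
from .clustering import (SVCluster, interleaved, build_clusters,
                         link_interchromosomal, cluster_region, cluster_sample)
from .statistics import (RegionStatistics, max_alternating_run,
                         fraction_two_state, dominant_two_state_levels,
                         fragment_join_test, breakpoint_exponential_test,
                         chromosome_enrichment_test, detect_interspersed_loh,
                         foldback_fraction, homology_summary)
from .caller import (ChromothripsisCall, evaluate_event, classify_confidence,
                     canonical_flag, detect_double_minute,
                     focal_amplifications, lost_genes_in_event,
                     detect_chromothripsis,
                     CONF_HIGH, CONF_LOW, CONF_NONE)
from .downstream import (TimingCall, KataegisCall, infer_wgd_timing,
                         classify_apobec, kataegis_in_region,
                         annotate_kataegis, repair_signature_summary,
                         TIMING_SHATTER_FIRST, TIMING_WGD_FIRST,
                         TIMING_UNDETERMINED)
from .simulator import (SimTruth, simulate_chromothripsis,
                        simulate_multi_chromothripsis,
                        simulate_tandem_dup_cluster, simulate_nested_deletions,
                        simulate_bfb_series, simulate_stepwise_cn,
                        simulate_background, simulate_apobec_cluster,
                        WGD_NONE, WGD_BEFORE, WGD_AFTER)

__version__ = "0.1.0"
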