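"""End-to-end detection driver: split-read + copy-number -> variant calls."""

from __future__ import annotations

import logging

from svharvest import copynumber, integrate, splitread
from svharvest.config import PipelineConfig
from svharvest.io import GenomeRef

log = logging.getLogger(__name__)


def detect_variants(genome: GenomeRef, sample_alignments, control_alignments,
                    config: PipelineConfig | None = None,
                    kmer_index: splitread.KmerIndex | None = None,
                    id_prefix: str = "SV"):
    """Run the full detection workflow for one sample/control pair.

    Returns (calls, evidence, tracks). ``sample_alignments`` and
    ``control_alignments`` may be any iterable of AlignmentRecord (they are
    materialized once and traversed in a single pass each).
    """
    cfg = config or PipelineConfig()
    cfg.validate()
    sample = list(sample_alignments)
    control = list(control_alignments)
    log.info("detect: %d sample / %d control alignments", len(sample),
             len(control))

    # split-read side
    segments = splitread.extract_clipped(sample, cfg.min_clip_len)
    log.info("detect: %d clipped segments >= %d bp", len(segments),
             cfg.min_clip_len)
    if kmer_index is None:
        kmer_index = splitread.KmerIndex(genome, cfg.seed_len)
    breakpoints = splitread.classify_segments(segments, kmer_index,
                                              cfg.min_identity)
    log.info("detect: %d classified per-read breakpoints", len(breakpoints))
    evidence = splitread.cluster_evidence(breakpoints, cfg.cluster_tolerance,
                                          cfg.min_support)
    log.info("detect: %d junction clusters with support >= %d", len(evidence),
             cfg.min_support)

    # copy-number side
    raw_sample = copynumber.binned_depth(sample, genome, cfg.bin_size)
    raw_control = copynumber.binned_depth(control, genome, cfg.bin_size)
    norm_sample = copynumber.normalize(raw_sample)
    norm_control = copynumber.normalize(raw_control)
    tracks = {
        contig: copynumber.build_track(
            contig, cfg.bin_size, norm_sample[contig], norm_control[contig],
            cfg.cn_pseudo, cfg.control_min)
        for contig in genome.names
    }
    cn_segments = []
    for track in tracks.values():
        cn_segments.extend(copynumber.call_cn_segments(
            track, cfg.del_max, cfg.dup_min, cfg.mult_min, cfg.min_bins))
    log.info("detect: %d copy-number segments", len(cn_segments))

    # integration
    calls = integrate.combine_evidence(
        evidence, cn_segments, tracks, cfg.reciprocal_overlap,
        cfg.cn_only_min_len, cfg.mult_min, id_prefix=id_prefix)
    reads = integrate.ReadProfile.from_alignments(sample)
    integrate.assign_zygosity(calls, reads, cfg.min_clip_len, cfg.hom_min,
                              cfg.het_min)
    log.info("detect: %d calls", len(calls))
    return calls, evidence, tracks
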