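"""Scoring detected calls against a simulated truth table."""

from __future__ import annotations

from dataclasses import dataclass, field

from svharvest.integrate import StructuralVariantCall
from svharvest.simulate import TruthRecord


def match_call(truth: TruthRecord, call: StructuralVariantCall,
               tolerance: int = 0) -> bool:
    """True when a call recovers an engineered variant.

    Requires the same variant class and breakpoints within ``tolerance``.
    A translocation is recovered by either of its two junction calls: the
    insertion-site breakend plus one partner-segment boundary.
    """
    if call.svtype != truth.svtype:
        return False
    if truth.svtype == "TRA":
        if call.contig2 is None:
            return False
        ends = {(call.contig, call.start), (call.contig2, call.pos2)}
        site_hit = any(c == truth.contig and abs(p - truth.start) <= tolerance
                       for c, p in ends)
        partner_hit = any(
            c == truth.contig2 and (abs(p - truth.pos2_a) <= tolerance
                                    or abs(p - truth.pos2_b) <= tolerance)
            for c, p in ends)
        return site_hit and partner_hit
    return (call.contig == truth.contig
            and abs(call.start - truth.start) <= tolerance
            and abs(call.end - truth.end) <= tolerance)


@dataclass
class DetectionScore:
    n_truth: int
    n_recalled: int
    n_zygosity_correct: int
    misses: list[TruthRecord] = field(default_factory=list)

    @property
    def recall(self) -> float:
        return self.n_recalled / self.n_truth if self.n_truth else float("nan")

    @property
    def zygosity_accuracy(self) -> float:
        return (self.n_zygosity_correct / self.n_recalled
                if self.n_recalled else float("nan"))


def evaluate_detection(truth: list[TruthRecord],
                       calls: list[StructuralVariantCall],
                       tolerance: int = 0) -> DetectionScore:
    """Recall and zygosity accuracy of a call set against engineered truth."""
    recalled = zyg = 0
    misses = []
    for t in truth:
        hits = [c for c in calls if match_call(t, c, tolerance)]
        if hits:
            recalled += 1
            zyg += hits[0].zygosity == t.zygosity
        else:
            misses.append(t)
    return DetectionScore(len(truth), recalled, zyg, misses)
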