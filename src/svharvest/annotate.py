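"""Variant annotation against gene models and regulatory regions, and the
per-strain summary statistics (variants per strain, genes affected,
chromosomes carrying variants, size distribution, AT-content correlation).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
from intervaltree import IntervalTree
from scipy import stats

from svharvest.io import FeatureDB, GenomeRef
from svharvest.integrate import StructuralVariantCall

#: category precedence when a variant touches several feature kinds
CATEGORY_ORDER = ("CDS", "UTR", "exon", "intron", "pseudogene")
#: regulatory subcategory precedence for intergenic variants
SUBCATEGORY_ORDER = ("enhancer", "promoter", "TSS", "TF_binding_site",
                     "splice_leader")

_KIND_TO_CATEGORY = {
    "CDS": "CDS",
    "five_prime_UTR": "UTR",
    "three_prime_UTR": "UTR",
    "exon": "exon",
    "intron": "intron",
    "pseudogene": "pseudogene",
}


@dataclass
class VariantAnnotation:
    call_id: str
    category: str  # CDS/exon/intron/UTR/intergenic/pseudogene
    intergenic_subcategory: str | None  # present iff category == intergenic
    affected_gene_ids: list[str]


class Annotator:
    """Interval-tree index over a FeatureDB for fast overlap queries."""

    def __init__(self, db: FeatureDB):
        self.db = db
        self.gene_trees: dict[str, IntervalTree] = {}
        self.reg_trees: dict[str, IntervalTree] = {}
        self.span_trees: dict[str, IntervalTree] = {}
        for f in db.gene_features:
            self.gene_trees.setdefault(f.contig, IntervalTree()).addi(
                f.start, f.end, f)
        for f in db.regulatory_features:
            self.reg_trees.setdefault(f.contig, IntervalTree()).addi(
                f.start, f.end, f)
        for f in db.gene_spans.values():
            self.span_trees.setdefault(f.contig, IntervalTree()).addi(
                f.start, f.end, f)
        self.known_contigs = (set(self.gene_trees) | set(self.reg_trees)
                              | set(self.span_trees))

    def annotate_variant(self, call: StructuralVariantCall) -> VariantAnnotation:
        """Assign the feature category of one precise variant.

        The category follows the precedence CDS > UTR > exon > intron >
        pseudogene over every feature overlapping [start, end); a variant
        overlapping none is intergenic and receives a regulatory subcategory
        by the precedence enhancer > promoter > TSS > TF-binding site >
        splice leader > other.
        """
        if self.known_contigs and call.contig not in self.known_contigs:
            raise KeyError(f"contig {call.contig!r} absent from annotation")
        hits = (self.gene_trees.get(call.contig, IntervalTree())
                .overlap(call.start, call.end))
        categories = {_KIND_TO_CATEGORY[iv.data.kind] for iv in hits}
        genes = sorted({iv.data.gene_id for iv in hits if iv.data.gene_id})
        for cat in CATEGORY_ORDER:
            if cat in categories:
                return VariantAnnotation(call.id, cat, None, genes)
        reg_hits = (self.reg_trees.get(call.contig, IntervalTree())
                    .overlap(call.start, call.end))
        reg_kinds = {iv.data.kind for iv in reg_hits}
        sub = next((s for s in SUBCATEGORY_ORDER if s in reg_kinds), "other")
        return VariantAnnotation(call.id, "intergenic", sub, [])

    def genes_overlapping(self, contig: str, start: int, end: int) -> set[str]:
        tree = self.span_trees.get(contig)
        if tree is None:
            return set()
        return {iv.data.gene_id for iv in tree.overlap(start, end)}


def annotate_calls(calls: list[StructuralVariantCall], annotator: Annotator,
                   ) -> list[VariantAnnotation]:
    """Annotate every precise call in place (fills category/subcategory/genes)
    and return the annotation records."""
    out = []
    for call in calls:
        if call.imprecise:
            continue
        ann = annotator.annotate_variant(call)
        call.category = ann.category
        call.subcategory = ann.intergenic_subcategory
        call.genes = ann.affected_gene_ids
        out.append(ann)
    return out


def genes_affected(calls: list[StructuralVariantCall],
                   annotator: Annotator) -> int:
    """Distinct genes partially or completely deleted by one strain's
    DEL/DELINS calls (gene span intersects any deletion interval)."""
    hit: set[str] = set()
    for call in calls:
        if call.svtype in ("DEL", "DELINS") and not call.imprecise:
            hit |= annotator.genes_overlapping(call.contig, call.start, call.end)
    return len(hit)


def chromosome_stats(calls: list[StructuralVariantCall],
                     ) -> tuple[int, dict[str, int]]:
    """(number of chromosomes carrying a large variant, per-chromosome
    large-variant counts); only size_class == 'large' calls count."""
    counts = Counter(c.contig for c in calls if c.size_class == "large")
    return len(counts), dict(counts)


def size_distribution(calls: list[StructuralVariantCall],
                      ) -> tuple[float | None, float | None, list[int]]:
    """Median, IQR and raw lengths of deletion-type calls."""
    sizes = [c.length for c in calls if c.svtype in ("DEL", "DELINS")]
    if not sizes:
        return None, None, []
    arr = np.asarray(sizes, dtype=float)
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    return float(med), float(q3 - q1), sizes


def at_content_correlation(calls: list[StructuralVariantCall],
                           genome: GenomeRef, window: int = 100_000) -> float:
    """R^2 between per-window A/T fraction and per-window variant count.

    Windows of ``window`` bases tile each contig; a variant is counted in
    the window containing its start. A degenerate (constant) AT regressor
    yields R^2 = 0 by convention.
    """
    if window < 1000:
        raise ValueError("window must be >= 1000")
    at, counts = [], []
    win_index: dict[tuple[str, int], int] = {}
    for name, seq in genome.sequences.items():
        for wi, off in enumerate(range(0, len(seq), window)):
            chunk = seq[off:off + window]
            win_index[(name, wi)] = len(at)
            at.append((chunk.count("A") + chunk.count("T")) / len(chunk))
            counts.append(0)
    if len(at) < 3:
        raise ValueError("need at least 3 windows")
    for call in calls:
        key = (call.contig, call.start // window)
        if key in win_index:
            counts[win_index[key]] += 1
    x = np.asarray(at)
    y = np.asarray(counts, dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return 0.0
    res = stats.linregress(x, y)
    return float(res.rvalue ** 2)


def strain_summary(calls: list[StructuralVariantCall],
                   annotator: Annotator | None = None) -> dict:
    """Per-strain summary: variant counts by type/category, genes affected,
    chromosome spread, and the deletion size distribution."""
    med, iqr, sizes = size_distribution(calls)
    n_chrom, per_chrom = chromosome_stats(calls)
    summary = {
        "n_variants": len(calls),
        "n_large": sum(1 for c in calls if c.size_class == "large"),
        "by_svtype": dict(Counter(c.svtype for c in calls)),
        "by_category": dict(Counter(c.category for c in calls if c.category)),
        "by_subcategory": dict(
            Counter(c.subcategory for c in calls if c.subcategory)),
        "n_chromosomes_with_variant": n_chrom,
        "variants_per_chromosome": per_chrom,
        "deletion_size_median": med,
        "deletion_size_iqr": iqr,
        "deletion_sizes": sizes,
    }
    if annotator is not None:
        summary["genes_affected"] = genes_affected(calls, annotator)
    return summary
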