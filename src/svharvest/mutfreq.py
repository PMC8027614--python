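"""Genome-wide mutation-number extrapolation and deletion-size-class tests.

A forward-mutation reporter assay observes mutations only within its target
sequence; scaling the observed rate by genome size over target size
extrapolates the expected number of mutations per haploid genome:

    N = rate * genome_size / target_size

The two assays are the nicotine twitching assay (unc-22 coding region,
21,477 bp target) and stringent PCR over 48 amplicons (89,840 bp total),
both against the 100,272,607 bp C. elegans reference genome. Deletion size
spectra are compared as <50 bp vs >=50 bp counts with Fisher's exact test.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats


@dataclass(frozen=True)
class AssayConstants:
    genome_size: int = 100_272_607
    unc22_coding: int = 21_477
    amplified_total: int = 89_840

    def __post_init__(self) -> None:
        if not (0 < self.unc22_coding < self.genome_size
                and 0 < self.amplified_total < self.genome_size):
            raise ValueError("assay target sizes must be positive and "
                             "smaller than the genome")


CONSTANTS = AssayConstants()

ASSAY_TARGETS = {
    "twitching": CONSTANTS.unc22_coding,
    "pcr": CONSTANTS.amplified_total,
}


def estimate_mutation_count(rate: float, target_size: int,
                            genome_size: int = CONSTANTS.genome_size,
                            rate_is_percent: bool = True) -> float:
    """Expected mutations per haploid genome from a reporter-assay rate.

    ``rate`` is a percentage by default (as mutation frequencies are
    reported); pass rate_is_percent=False for a fraction. Linear in rate.
    """
    if target_size <= 0:
        raise ValueError("target_size must be positive")
    frac = rate / 100.0 if rate_is_percent else rate
    if not 0 <= frac <= 1:
        raise ValueError("rate outside [0, 100%]")
    return frac * genome_size / target_size


def estimate_for_assay(rate_percent: float, assay: str,
                       target_size: int | None = None) -> float:
    """Convenience wrapper: assay is 'twitching', 'pcr', or 'custom' (then
    target_size is required)."""
    if assay == "custom":
        if target_size is None:
            raise ValueError("custom assay needs target_size")
    else:
        target_size = ASSAY_TARGETS[assay]
    return estimate_mutation_count(rate_percent, target_size)


def size_class_fraction(deletion_sizes, threshold: int = 50) -> float:
    """Fraction of deletions smaller than ``threshold`` bases."""
    sizes = list(deletion_sizes)
    if not sizes:
        raise ValueError("empty deletion size list")
    return sum(1 for s in sizes if s < threshold) / len(sizes)


def size_class_table(group_a, group_b, threshold: int = 50):
    """2x2 contingency table: rows = groups, columns = (<threshold,
    >=threshold)."""
    a, b = list(group_a), list(group_b)
    if not a or not b:
        raise ValueError("both groups must be nonempty")
    return [
        [sum(1 for s in a if s < threshold), sum(1 for s in a if s >= threshold)],
        [sum(1 for s in b if s < threshold), sum(1 for s in b if s >= threshold)],
    ]


def size_class_test(group_a, group_b, threshold: int = 50):
    """Two-sided Fisher's exact test of the <50 / >=50 bp split between two
    groups of deletion sizes. Returns (table, p)."""
    table = size_class_table(group_a, group_b, threshold)
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return table, float(p)


def read_size_table(path, column: str = "size"):
    """Read deletion sizes from a TSV with a ``size`` column (one row per
    isolated allele); 'Not identified' or blank entries are skipped."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    sizes = pd.to_numeric(df[column], errors="coerce").dropna()
    return [int(s) for s in sizes]
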