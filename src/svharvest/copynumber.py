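"""Binned read-depth and copy-number-ratio analysis.

Read depth is binned per contig, normalized to a genome-wide mean of one,
and divided by the same quantity from an untreated control strain. The
ratio is the deletion/duplication indicator: ~0 over homozygous deletions,
~0.5 over heterozygous ones, ~2 over tandem duplications, >=3 over
multiplications. Candidate segments are maximal threshold runs; no
segmentation model is used beyond that.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

CN_CLASSES = ("DEL_CN", "DUP_CN", "MULT_CN")


@dataclass
class CNSegment:
    contig: str
    start: int  # 0-based reference coordinate (bin-resolution)
    end: int
    cn_class: str
    mean_ratio: float
    n_bins: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class CopyNumberTrack:
    """Normalized sample/control depth and their ratio along one contig."""

    contig: str
    bin_size: int
    sample_norm: np.ndarray
    control_norm: np.ndarray
    ratio: np.ndarray  # NaN where the control is unreliably low

    def ratio_at(self, start: int, end: int) -> float:
        """Mean ratio over the bins fully inside [start, end); partial edge
        bins dilute the signal and are used only when no bin fits entirely.
        NaN if every usable bin is masked."""
        i0 = -(-start // self.bin_size)  # first bin fully inside
        i1 = end // self.bin_size
        if i1 > i0:
            window = self.ratio[i0:i1]
        else:
            b0 = start // self.bin_size
            b1 = max(b0 + 1, -(-end // self.bin_size))
            window = self.ratio[b0:b1]
        if window.size == 0 or np.all(np.isnan(window)):
            return float("nan")
        return float(np.nanmean(window))


def binned_depth(alignments, genome, bin_size: int = 500) -> dict[str, np.ndarray]:
    """Count alignment starts per bin: each retained read adds one to the
    bin containing its leftmost aligned base, so totals conserve read count."""
    if bin_size < 50:
        raise ValueError("bin_size must be >= 50")
    counts = {
        name: np.zeros(-(-length // bin_size), dtype=np.int64)
        for name, length in genome.contigs
    }
    starts: dict[str, list[int]] = {name: [] for name in counts}
    for rec in alignments:
        starts[rec.contig].append(rec.pos)
    for name, pos_list in starts.items():
        if pos_list:
            binned = np.asarray(pos_list, dtype=np.int64) // bin_size
            counts[name] += np.bincount(binned, minlength=len(counts[name]))
    return counts


def normalize(raw: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Divide every bin by the genome-wide mean bin count (output mean 1)."""
    total = sum(int(v.sum()) for v in raw.values())
    nbins = sum(v.size for v in raw.values())
    if total == 0:
        raise ValueError("cannot normalize an all-zero depth track")
    mean = total / nbins
    return {name: v / mean for name, v in raw.items()}


def cn_ratio(sample_norm: np.ndarray, control_norm: np.ndarray,
             pseudo: float = 0.05, control_min: float = 0.25) -> np.ndarray:
    """Per-bin sample/control ratio with a pseudocount denominator floor.

    Bins where the control depth is below ``control_min`` are masked (NaN):
    the denominator is too unreliable to interpret.
    """
    if sample_norm.shape != control_norm.shape:
        raise ValueError("sample and control tracks differ in length")
    ratio = sample_norm / np.maximum(control_norm, pseudo)
    ratio = np.where(control_norm < control_min, np.nan, ratio)
    return ratio


def build_track(contig: str, bin_size: int, sample_norm: np.ndarray,
                control_norm: np.ndarray, pseudo: float = 0.05,
                control_min: float = 0.25) -> CopyNumberTrack:
    return CopyNumberTrack(
        contig=contig, bin_size=bin_size, sample_norm=sample_norm,
        control_norm=control_norm,
        ratio=cn_ratio(sample_norm, control_norm, pseudo, control_min))


def call_cn_segments(track: CopyNumberTrack, del_max: float = 0.25,
                     dup_min: float = 1.5, mult_min: float = 2.5,
                     min_bins: int = 2) -> list[CNSegment]:
    """Maximal runs of >= min_bins consecutive bins in one copy-state band.

    ratio <= del_max -> DEL_CN; dup_min <= ratio < mult_min -> DUP_CN;
    ratio >= mult_min -> MULT_CN. Masked (NaN) bins break runs.
    """
    if not del_max < dup_min < mult_min:
        raise ValueError("need del_max < dup_min < mult_min")
    ratio = track.ratio
    labels = np.full(ratio.size, "", dtype=object)
    with np.errstate(invalid="ignore"):
        labels[ratio <= del_max] = "DEL_CN"
        labels[(ratio >= dup_min) & (ratio < mult_min)] = "DUP_CN"
        labels[ratio >= mult_min] = "MULT_CN"
    segments = []
    i = 0
    n = ratio.size
    while i < n:
        if not labels[i]:
            i += 1
            continue
        j = i
        while j < n and labels[j] == labels[i]:
            j += 1
        if j - i >= min_bins:
            segments.append(CNSegment(
                contig=track.contig,
                start=i * track.bin_size,
                end=min(j * track.bin_size,
                        track.bin_size * n),  # bin grid end
                cn_class=str(labels[i]),
                mean_ratio=float(np.nanmean(ratio[i:j])),
                n_bins=j - i))
        i = j
    return segments


def write_bedgraph(tracks: dict[str, CopyNumberTrack], path) -> None:
    """Export the ratio tracks as bedGraph (masked bins omitted)."""
    with open(path, "w") as fh:
        fh.write('track type=bedGraph name="cn_ratio"\n')
        for contig, tr in tracks.items():
            for i, r in enumerate(tr.ratio):
                if np.isnan(r):
                    continue
                fh.write(f"{contig}\t{i * tr.bin_size}"
                         f"\t{(i + 1) * tr.bin_size}\t{r:.4f}\n")
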