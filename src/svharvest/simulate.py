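"""Synthetic genomes, engineered variants, and single-end read simulation.

Stands in for real resequencing data of mutagenized strains: random
genomes with a configurable AT fraction, engineered variant sets across all
structural-variant classes, and uniform single-end reads (default 120 bp at
15-20x, emulating short single-end fragment sequencing). Reads crossing an
engineered junction are emitted directly as reference alignments with the
correct soft clips at the junction — alignment emulation instead of an
external aligner — so the engineered truth is exact by construction. An
untreated control strain is simulated as reads from the unmodified
reference.

All randomness flows from a single seed; equal configurations produce
identical output.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field, replace

import numpy as np

from svharvest.io import AlignmentRecord, GenomeRef, reverse_complement
from svharvest.mlfilter import CandidateFeatureVector

_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    genome_length: int = 1_000_000
    n_contigs: int = 2
    at_fraction: float = 0.66  # roughly the C. elegans genome average
    read_length: int = 120
    depth: float = 20.0
    substitution_error: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.at_fraction <= 1:
            raise ValueError("at_fraction must lie in [0,1]")
        if min(self.genome_length, self.n_contigs, self.read_length) <= 0 \
                or self.depth <= 0:
            raise ValueError("all sizes must be positive")


@dataclass
class VariantSpec:
    """One engineered variant on the reference."""

    svtype: str
    contig: str
    start: int
    length: int = 0  # reference span (DEL/DUP/MULT/INV/DELINS); 0 for INS
    novel_seq: str = ""
    zygosity: str = "hom"
    is_background: bool = False
    copies: int = 2  # tandem copy number for DUP (2) / MULT (>=3)
    src_contig: str | None = None  # TRA: origin of the inserted segment
    src_start: int | None = None

    @property
    def end(self) -> int:
        return self.start + self.length


@dataclass
class TruthRecord:
    """Post-hoc reference coordinates of an engineered variant's junctions."""

    svtype: str
    contig: str
    start: int
    end: int
    length: int
    novel_seq: str
    zygosity: str
    is_background: bool
    contig2: str | None = None
    pos2_a: int | None = None  # TRA partner breakpoints (segment start/end)
    pos2_b: int | None = None


# haplotype block kinds
_FWD, _INV, _NOVEL = 0, 1, 2


@dataclass
class Haplotype:
    """A sample chromosome set as piecewise mappings onto the reference."""

    sequences: dict[str, str]
    # per contig: sorted (hap_start, hap_end, kind, ref_contig, ref_start, ref_end)
    blocks: dict[str, list[tuple]]
    starts: dict[str, list[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.starts = {c: [b[0] for b in bl] for c, bl in self.blocks.items()}


def simulate_genome(config: SimConfig, rng: np.random.Generator | None = None,
                    ) -> GenomeRef:
    """Random i.i.d. genome with P(A)=P(T)=at_fraction/2 over n_contigs of
    equal length, named chr1..chrN."""
    if config.genome_length < 10_000:
        raise ValueError("genome_length must be >= 10 kb")
    rng = rng or np.random.default_rng(config.seed)
    p_at = config.at_fraction / 2
    p_gc = (1 - config.at_fraction) / 2
    probs = [p_at, p_gc, p_gc, p_at]
    per = config.genome_length // config.n_contigs
    seqs = {}
    for i in range(config.n_contigs):
        n = per if i < config.n_contigs - 1 else (
            config.genome_length - per * (config.n_contigs - 1))
        seqs[f"chr{i + 1}"] = "".join(rng.choice(_BASES, size=n, p=probs))
    return GenomeRef(seqs)


def _check_specs(genome: GenomeRef, specs: list[VariantSpec]) -> None:
    by_contig: dict[str, list[tuple[int, int]]] = {}
    for sp in specs:
        if sp.contig not in genome.sequences:
            raise ValueError(f"unknown contig {sp.contig!r}")
        if sp.svtype == "TRA":
            if sp.src_contig is None or sp.src_start is None:
                raise ValueError("TRA spec needs src_contig and src_start")
            if sp.src_start + sp.length > genome.length(sp.src_contig):
                raise ValueError("TRA source segment runs off contig")
            span = (sp.start, sp.start + 1)
        elif sp.svtype == "INS":
            span = (sp.start, sp.start + 1)
        else:
            if sp.end > genome.length(sp.contig):
                raise ValueError(
                    f"variant at {sp.contig}:{sp.start} runs off contig")
            span = (sp.start, sp.end)
        if span[1] > genome.length(sp.contig):
            raise ValueError(f"variant at {sp.contig}:{sp.start} runs off contig")
        by_contig.setdefault(sp.contig, []).append(span)
    for contig, spans in by_contig.items():
        spans.sort()
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 < e1:
                raise ValueError(f"overlapping variant specs on {contig}")


def apply_variants(genome: GenomeRef, specs: list[VariantSpec],
                   ) -> tuple[tuple[Haplotype, Haplotype], list[TruthRecord]]:
    """Apply hom specs to both haplotypes and het specs to one; return the
    haplotype pair and a truth table of junction coordinates."""
    _check_specs(genome, specs)
    hap1 = _build_haplotype(genome, specs)
    hom_only = [sp for sp in specs if sp.zygosity == "hom"]
    hap2 = _build_haplotype(genome, hom_only)
    truth = []
    for sp in specs:
        length = len(sp.novel_seq) if sp.svtype == "INS" else sp.length
        truth.append(TruthRecord(
            svtype=sp.svtype, contig=sp.contig, start=sp.start,
            end=sp.start + 1 if sp.svtype in ("INS", "TRA") else sp.end,
            length=length, novel_seq=sp.novel_seq, zygosity=sp.zygosity,
            is_background=sp.is_background,
            contig2=sp.src_contig if sp.svtype == "TRA" else None,
            pos2_a=sp.src_start if sp.svtype == "TRA" else None,
            pos2_b=(sp.src_start + sp.length) if sp.svtype == "TRA" else None,
        ))
    return (hap1, hap2), truth


def _build_haplotype(genome: GenomeRef, specs: list[VariantSpec]) -> Haplotype:
    per_contig: dict[str, list[VariantSpec]] = {c: [] for c in genome.names}
    for sp in specs:
        per_contig[sp.contig].append(sp)
    seqs, blocks = {}, {}
    for contig, seq in genome.sequences.items():
        parts: list[str] = []
        blist: list[tuple] = []
        cursor = 0
        pos = 0  # haplotype coordinate

        def emit_ref(c, s, e, kind=_FWD):
            nonlocal pos
            if e <= s:
                return
            frag = genome.sequences[c][s:e]
            if kind == _INV:
                frag = reverse_complement(frag)
            parts.append(frag)
            blist.append((pos, pos + len(frag), kind, c, s, e))
            pos += len(frag)

        def emit_novel(novel):
            nonlocal pos
            if not novel:
                return
            parts.append(novel)
            blist.append((pos, pos + len(novel), _NOVEL, None, 0, 0))
            pos += len(novel)

        for sp in sorted(per_contig[contig], key=lambda s: s.start):
            emit_ref(contig, cursor, sp.start)
            if sp.svtype in ("DEL", "DELINS"):
                emit_novel(sp.novel_seq)
                cursor = sp.end
            elif sp.svtype == "INS":
                emit_novel(sp.novel_seq)
                cursor = sp.start
            elif sp.svtype in ("DUP", "MULT"):
                for _ in range(sp.copies):
                    emit_ref(contig, sp.start, sp.end)
                cursor = sp.end
            elif sp.svtype == "INV":
                emit_ref(contig, sp.start, sp.end, kind=_INV)
                cursor = sp.end
            elif sp.svtype == "TRA":
                emit_ref(sp.src_contig, sp.src_start, sp.src_start + sp.length)
                cursor = sp.start
            else:
                raise ValueError(f"unknown svtype {sp.svtype!r}")
        emit_ref(contig, cursor, len(seq))
        seqs[contig] = "".join(parts)
        blocks[contig] = blist
    return Haplotype(seqs, blocks)


def _read_pieces(hap: Haplotype, contig: str, start: int, length: int):
    """Split a haplotype interval into mapped/novel pieces.

    Yields (read_offset, piece_len, kind, ref_contig, ref_start) where
    ref_start is the leftmost reference coordinate of the piece.
    """
    blocks = hap.blocks[contig]
    i = bisect.bisect_right(hap.starts[contig], start) - 1
    end = start + length
    out = []
    while i < len(blocks) and blocks[i][0] < end:
        b_start, b_end, kind, r_contig, r_start, r_end = blocks[i]
        lo, hi = max(start, b_start), min(end, b_end)
        if hi > lo:
            if kind == _FWD:
                piece_ref = r_start + (lo - b_start)
            elif kind == _INV:
                piece_ref = r_end - (hi - b_start)
            else:
                piece_ref = 0
            out.append((lo - start, hi - lo, kind, r_contig, piece_ref))
        i += 1
    return out


def simulate_reads(haplotypes, genome: GenomeRef, config: SimConfig,
                   rng: np.random.Generator | None = None,
                   id_prefix: str = "read") -> list[AlignmentRecord]:
    """Uniform single-end reads from the haplotype pair, emitted as emulated
    reference alignments.

    Reads inside one colinear block become plain full-length matches; reads
    crossing a junction anchor on their largest reference-mapped piece and
    carry the rest as soft clips, which is what a clip-and-realign caller
    sees after real alignment. Reads entirely inside novel inserted sequence
    are unmappable and are not emitted. Substitution errors are applied
    before alignment emulation at the configured rate.
    """
    rng = rng or np.random.default_rng(config.seed + 1)
    if isinstance(haplotypes, Haplotype):
        haplotypes = (haplotypes,)
    records: list[AlignmentRecord] = []
    n_hap = len(haplotypes)
    L = config.read_length
    counter = 0
    for hap in haplotypes:
        contigs = [c for c in hap.sequences if len(hap.sequences[c]) >= L]
        lengths = np.array([len(hap.sequences[c]) for c in contigs], dtype=float)
        total = lengths.sum()
        n_reads = int(round(config.depth / n_hap * total / L))
        choice = rng.choice(len(contigs), size=n_reads, p=lengths / total)
        for ci in range(len(contigs)):
            contig = contigs[ci]
            n_c = int((choice == ci).sum())
            if n_c == 0:
                continue
            starts = rng.integers(0, len(hap.sequences[contig]) - L + 1,
                                  size=n_c)
            orient = rng.random(n_c) < 0.5
            for s, rev in zip(starts, orient):
                counter += 1
                rec = _emulate_alignment(
                    hap, contig, int(s), L, config, rng,
                    f"{id_prefix}{counter}", "-" if rev else "+")
                if rec is not None:
                    records.append(rec)
    return records


def _emulate_alignment(hap: Haplotype, contig: str, start: int, L: int,
                       config: SimConfig, rng: np.random.Generator,
                       read_id: str, orient: str) -> AlignmentRecord | None:
    seq = hap.sequences[contig][start:start + L]
    if config.substitution_error > 0:
        seq = _mutate(seq, config.substitution_error, rng)
    pieces = _read_pieces(hap, contig, start, L)
    mapped = [p for p in pieces if p[2] != _NOVEL]
    if not mapped:
        return None  # entirely novel sequence: unmappable
    off, plen, kind, r_contig, r_start = max(mapped, key=lambda p: p[1])
    if kind == _FWD:
        left, right = off, L - off - plen
        out_seq = seq
        strand = orient
    else:
        # primary maps on the minus strand: present the record in
        # reference-forward orientation of that piece
        out_seq = reverse_complement(seq)
        left, right = L - off - plen, off
        strand = "-" if orient == "+" else "+"
    cigar = []
    if left:
        cigar.append(("S", left))
    cigar.append(("M", plen))
    if right:
        cigar.append(("S", right))
    return AlignmentRecord(
        read_id=read_id, contig=r_contig, pos=r_start, strand=strand,
        cigar=cigar, mapq=60, seq=out_seq)


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    if hits.size == 0:
        return seq
    subs = rng.integers(1, 4, size=hits.size)
    base_idx = {b: i for i, b in enumerate(b"ACGT")}
    for pos, shift in zip(hits, subs):
        cur = base_idx.get(arr[pos][0], 0)
        arr[pos] = b"ACGT"[(cur + shift) % 4:][:1]
    return arr.tobytes().decode()


def random_variants(genome: GenomeRef, rng: np.random.Generator,
                    n_del: int = 30, n_del_het: int = 10, n_dup: int = 4,
                    n_mult: int = 2, n_ins: int = 4, n_delins: int = 4,
                    n_inv: int = 4, n_tra: int = 2, margin: int = 3000,
                    background_fraction: float = 0.0) -> list[VariantSpec]:
    """A non-overlapping engineered variant mix spanning every class.

    Deletion sizes are log-uniform over 60-5000 bp (the spectrum the
    mutagenesis produces); duplications/multiplications span >= 2 kb so the
    copy-number track resolves them; insertions add 50-60 bp of novel
    sequence; inversions span 300-2000 bp; translocated segments of
    500-1500 bp originate on a different contig.
    """
    specs: list[VariantSpec] = []
    contigs = genome.names
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in contigs}

    def place(contig: str, span: int) -> int | None:
        limit = genome.length(contig) - span - margin
        for _ in range(200):
            s = int(rng.integers(margin, limit))
            if all(s + span + margin <= a or s >= b + margin
                   for a, b in occupied[contig]):
                occupied[contig].append((s, s + span))
                return s
        return None

    def novel(n: int, contig: str, p: int, q: int) -> str:
        """Random inserted sequence replacing reference [p, q) whose
        terminal bases differ from the adjoining reference bases, so the
        junction carries no microhomology and the engineered breakpoint
        representation is unique."""
        seq = list(rng.choice(_BASES, size=n))
        ref = genome.sequences[contig]
        for idx, ref_pos in ((0, p), (-1, q - 1)):
            if 0 <= ref_pos < len(ref) and seq[idx] == ref[ref_pos]:
                choices = [b for b in "ACGT" if b != ref[ref_pos]]
                seq[idx] = choices[int(rng.integers(0, len(choices)))]
        return "".join(seq)

    def log_uniform(lo, hi):
        return int(np.exp(rng.uniform(np.log(lo), np.log(hi))))

    plan = (
        [("DEL", "hom")] * (n_del - n_del_het) + [("DEL", "het")] * n_del_het
        + [("DUP", "hom")] * n_dup + [("MULT", "hom")] * n_mult
        + [("INS", "hom")] * n_ins + [("DELINS", "hom")] * n_delins
        + [("INV", "hom")] * n_inv + [("TRA", "hom")] * n_tra
    )
    for svtype, zyg in plan:
        contig = contigs[int(rng.integers(0, len(contigs)))]
        if svtype == "DEL":
            size = log_uniform(60, 5000)
            s = place(contig, size)
            if s is None:
                continue
            specs.append(VariantSpec("DEL", contig, s, size, zygosity=zyg))
        elif svtype == "DUP":
            size = int(rng.integers(2000, 4000))
            s = place(contig, size)
            if s is not None:
                specs.append(VariantSpec("DUP", contig, s, size, zygosity=zyg,
                                         copies=2))
        elif svtype == "MULT":
            size = int(rng.integers(2000, 3000))
            s = place(contig, size)
            if s is not None:
                specs.append(VariantSpec("MULT", contig, s, size, zygosity=zyg,
                                         copies=3))
        elif svtype == "INS":
            s = place(contig, 1)
            if s is not None:
                specs.append(VariantSpec(
                    "INS", contig, s, 0,
                    novel_seq=novel(int(rng.integers(50, 61)), contig, s, s),
                    zygosity=zyg))
        elif svtype == "DELINS":
            size = int(rng.integers(100, 1000))
            s = place(contig, size)
            if s is not None:
                specs.append(VariantSpec(
                    "DELINS", contig, s, size,
                    novel_seq=novel(int(rng.integers(10, 31)), contig, s,
                                    s + size),
                    zygosity=zyg))
        elif svtype == "INV":
            size = int(rng.integers(300, 2000))
            s = place(contig, size)
            if s is not None:
                specs.append(VariantSpec("INV", contig, s, size, zygosity=zyg))
        elif svtype == "TRA":
            if len(contigs) < 2:
                continue
            size = int(rng.integers(500, 1500))
            others = [c for c in contigs if c != contig]
            src = others[int(rng.integers(0, len(others)))]
            src_s = place(src, size)
            s = place(contig, 1)
            if s is not None and src_s is not None:
                specs.append(VariantSpec(
                    "TRA", contig, s, size, zygosity=zyg,
                    src_contig=src, src_start=src_s))
    if background_fraction > 0:
        n_bg = int(round(len(specs) * background_fraction))
        for i in rng.choice(len(specs), size=n_bg, replace=False):
            specs[i] = replace(specs[i], is_background=True)
    return specs


class Simulation:
    """A full synthetic experiment: genome, engineered truth, and the
    sample/control read sets."""

    def __init__(self, config: SimConfig, specs: list[VariantSpec] | None = None):
        self.config = config
        self.rng = np.random.default_rng(config.seed)
        self.genome = simulate_genome(config, self.rng)
        if specs is None:
            specs = random_variants(self.genome, self.rng)
        self.specs = specs
        self.haplotypes, self.truth = apply_variants(self.genome, specs)

    def sample_reads(self) -> list[AlignmentRecord]:
        return simulate_reads(self.haplotypes, self.genome, self.config,
                              self.rng, id_prefix="smp")

    def control_reads(self) -> list[AlignmentRecord]:
        ref_hap = _build_haplotype(self.genome, [])
        return simulate_reads((ref_hap, ref_hap), self.genome, self.config,
                              self.rng, id_prefix="ctl")


def make_ml_dataset(n_true: int, n_false: int, seed: int,
                    genome_size: int = 100_272_607,
                    ) -> list[CandidateFeatureVector]:
    """Labeled synthetic candidate features for the classifier benchmark.

    The generating distributions are explicitly fictional; they model the
    qualitative separation seen in real candidate sets (true homozygous
    deletions: near-zero copy-number ratio, high variant frequency, many
    split reads, balanced strands; false positives the opposite) with
    partial overlap between the classes. depth_diff is generated as
    (1 - cn_ratio) plus noise, mirroring its redundancy with the ratio in
    real depth tracks.
    """
    if min(n_true, n_false) < 10:
        raise ValueError("need at least 10 candidates per class")
    rng = np.random.default_rng(seed)
    out = []
    for label, n in ((1, n_true), (0, n_false)):
        if label == 1:
            freq = rng.beta(8, 2, n)
            cn = np.clip(rng.normal(0.05, 0.05, n), 0, None)
            split = rng.poisson(8, n) + 3
            bias = rng.beta(2, 2, n)
        else:
            freq = rng.beta(2, 8, n)
            cn = np.clip(rng.normal(0.9, 0.15, n), 0, None)
            split = rng.poisson(2, n) + 1
            bias = 1 - rng.beta(1, 5, n)
        pos = rng.uniform(0, genome_size, n)
        del_len = rng.lognormal(np.log(300), 1.0, n)
        ins_len = rng.lognormal(np.log(5), 1.0, n)
        depth_diff = (1 - cn) + rng.normal(0, 0.1, n)
        for i in range(n):
            out.append(CandidateFeatureVector(
                abs_pos=float(pos[i]),
                log_del_len=float(np.log10(del_len[i] + 1)),
                log_ins_len=float(np.log10(ins_len[i] + 1)),
                cn_ratio=float(cn[i]),
                depth_diff=float(depth_diff[i]),
                frequency=float(np.clip(freq[i], 0, 1)),
                split_total=int(split[i]),
                strand_bias=float(np.clip(bias[i], 0, 1)),
                label=label,
            ))
    return out


def write_truth_tsv(truth: list[TruthRecord], path) -> None:
    cols = ("svtype", "contig", "start", "end", "length", "zygosity",
            "is_background", "novel_seq", "contig2", "pos2_a", "pos2_b")
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for t in truth:
            fh.write("\t".join("" if v is None else str(v) for v in (
                t.svtype, t.contig, t.start, t.end, t.length, t.zygosity,
                t.is_background, t.novel_seq, t.contig2, t.pos2_a, t.pos2_b))
                + "\n")


def write_ml_tsv(features: list[CandidateFeatureVector], path) -> None:
    from svharvest.mlfilter import features_to_frame

    features_to_frame(features).to_csv(path, sep="\t", index=False)
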