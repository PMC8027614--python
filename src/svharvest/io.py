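"""Readers and writers for the standard formats the pipeline touches.

All internal coordinates are 0-based half-open. SAM POS (1-based) is
converted on input; VCF output is 1-based. Hard clips carry no sequence and
are therefore unusable for split-read extraction; only soft clips are.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import pysam
from Bio import SeqIO

log = logging.getLogger(__name__)

# CIGAR operation classes
_QUERY_OPS = set("MIS=X")
_REF_OPS = set("MD=X")
_VALID_OPS = set("MIDSH=X")

_NON_ACGTN = re.compile(r"[^ACGTN]")


class FormatError(ValueError):
    """Malformed input file."""


@dataclass
class GenomeRef:
    """A reference genome: ordered contigs with uppercase ACGTN sequence."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        if not self.sequences:
            raise FormatError("genome has no contigs")
        for name, seq in self.sequences.items():
            if not seq:
                raise FormatError(f"empty contig {name!r}")

    @property
    def contigs(self) -> list[tuple[str, int]]:
        return [(name, len(seq)) for name, seq in self.sequences.items()]

    @property
    def names(self) -> list[str]:
        return list(self.sequences)

    def length(self, contig: str) -> int:
        return len(self.sequences[contig])

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    def offsets(self) -> dict[str, int]:
        """Cumulative start offset of each contig in declared order
        (basis of genome-wide absolute coordinates)."""
        out, acc = {}, 0
        for name, seq in self.sequences.items():
            out[name] = acc
            acc += len(seq)
        return out


@dataclass
class AlignmentRecord:
    """One aligned read; the source of clipped segments and binned depth."""

    read_id: str
    contig: str
    pos: int  # 0-based leftmost reference coordinate
    strand: str  # '+' or '-'
    cigar: list[tuple[str, int]]
    mapq: int
    seq: str  # reference-forward orientation, as stored in SAM
    is_supplementary: bool = False

    @property
    def query_length(self) -> int:
        return sum(n for op, n in self.cigar if op in _QUERY_OPS)

    @property
    def reference_span(self) -> int:
        return sum(n for op, n in self.cigar if op in _REF_OPS)

    @property
    def end(self) -> int:
        """0-based exclusive end of the aligned reference interval."""
        return self.pos + self.reference_span

    def validate(self, genome: GenomeRef | None = None) -> None:
        if self.seq and self.query_length != len(self.seq):
            raise FormatError(
                f"{self.read_id}: CIGAR consumes {self.query_length} query "
                f"bases but SEQ has {len(self.seq)}"
            )
        if genome is not None and self.end > genome.length(self.contig):
            raise FormatError(f"{self.read_id}: alignment runs off contig end")


@dataclass
class Interval:
    """A 0-based half-open genomic feature interval."""

    contig: str
    start: int
    end: int
    kind: str
    gene_id: str | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise FormatError(
                f"feature interval start {self.start} >= end {self.end}"
            )


GENE_FEATURE_KINDS = ("CDS", "exon", "intron", "five_prime_UTR",
                      "three_prime_UTR", "pseudogene")
REGULATORY_KINDS = ("enhancer", "promoter", "splice_leader", "TSS",
                    "TF_binding_site")


@dataclass
class FeatureDB:
    """Gene-model and regulatory intervals used for variant annotation."""

    gene_features: list[Interval] = field(default_factory=list)
    regulatory_features: list[Interval] = field(default_factory=list)
    gene_spans: dict[str, Interval] = field(default_factory=dict)


def read_genome(path) -> GenomeRef:
    """Load a FASTA reference.

    Lowercase bases are uppercased and any base outside ACGTN becomes N.
    Duplicate contig names are a format error.
    """
    sequences: dict[str, str] = {}
    n = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        n += 1
        if rec.id in sequences:
            raise FormatError(f"duplicate contig name {rec.id!r}")
        seq = _NON_ACGTN.sub("N", str(rec.seq).upper())
        if not seq:
            raise FormatError(f"empty contig {rec.id!r}")
        sequences[rec.id] = seq
    if n == 0:
        raise FormatError(f"no FASTA records in {path}")
    return GenomeRef(sequences)


def write_genome(genome: GenomeRef, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_alignments(path, genome: GenomeRef | None = None):
    """Stream AlignmentRecords from a SAM/BAM file.

    Unmapped and secondary records are skipped; supplementary records are
    retained and flagged. Records whose CIGAR and SEQ lengths disagree are
    logged and skipped (count reported at the end of the stream).
    """
    skipped = 0
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary:
                continue
            out = AlignmentRecord(
                read_id=rec.query_name,
                contig=rec.reference_name,
                pos=rec.reference_start,
                strand="-" if rec.is_reverse else "+",
                cigar=[(_CIGAR_OPS[op], n) for op, n in rec.cigartuples or []],
                mapq=rec.mapping_quality,
                seq=rec.query_sequence or "",
                is_supplementary=rec.is_supplementary,
            )
            try:
                out.validate(genome)
            except FormatError as exc:
                skipped += 1
                log.warning("skipping record: %s", exc)
                continue
            yield out
    if skipped:
        log.warning("skipped %d malformed alignment records", skipped)


_CIGAR_OPS = "MIDNSHP=X"


def write_alignments(records, genome: GenomeRef, path) -> None:
    """Write AlignmentRecords as a SAM file with @SQ lines from the genome."""
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": n, "LN": ln} for n, ln in genome.contigs],
    }
    tid = {name: i for i, (name, _) in enumerate(genome.contigs)}
    opcode = {op: i for i, op in enumerate(_CIGAR_OPS)}
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for rec in records:
            a = pysam.AlignedSegment(fh.header)
            a.query_name = rec.read_id
            a.reference_id = tid[rec.contig]
            a.reference_start = rec.pos
            a.mapping_quality = rec.mapq
            a.cigartuples = [(opcode[op], n) for op, n in rec.cigar]
            a.query_sequence = rec.seq
            a.flag = (16 if rec.strand == "-" else 0) | (
                2048 if rec.is_supplementary else 0)
            fh.write(a)


# ---------------------------------------------------------------------------
# Gene models (GFF3) and regulatory regions (BED + kind column)

_UTR_KINDS = {"five_prime_UTR", "three_prime_UTR", "5'UTR", "3'UTR"}


def read_gene_models(path, genome: GenomeRef | None = None) -> FeatureDB:
    """Build a FeatureDB from a GFF3 file.

    CDS/exon/UTR/pseudogene features are taken as given. Introns are derived
    per gene as the gene span minus its exons when the GFF3 lacks explicit
    intron features (the common dialect gap).
    """
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", force=True,
        keep_order=True,
    )
    out = FeatureDB()
    for f in db.all_features():
        kind = f.featuretype
        gid = _gene_id_of(db, f)
        contig = f.seqid
        if genome is not None and contig not in genome.sequences:
            raise FormatError(f"GFF3 contig {contig!r} not in genome")
        start, end = f.start - 1, f.end  # GFF3 is 1-based inclusive
        if kind in ("CDS", "exon", "pseudogene"):
            out.gene_features.append(Interval(contig, start, end, kind, gid))
        elif kind in _UTR_KINDS:
            canon = ("five_prime_UTR" if "five" in kind or kind.startswith("5")
                     else "three_prime_UTR")
            out.gene_features.append(Interval(contig, start, end, canon, gid))
        elif kind == "intron":
            out.gene_features.append(Interval(contig, start, end, "intron", gid))
        elif kind == "gene":
            out.gene_spans[gid] = Interval(contig, start, end, "gene", gid)
    _derive_introns(out)
    return out


def _gene_id_of(db, feature) -> str:
    if feature.featuretype in ("gene", "pseudogene") and "ID" in feature.attributes:
        return feature.attributes["ID"][0]
    cur = feature
    for _ in range(5):
        parents = list(db.parents(cur, featuretype="gene"))
        if parents:
            return parents[0].attributes.get("ID", [parents[0].id])[0]
        parents = list(db.parents(cur))
        if not parents:
            break
        cur = parents[0]
    return feature.attributes.get("ID", [feature.id])[0]


def _derive_introns(db: FeatureDB) -> None:
    have_introns = {f.gene_id for f in db.gene_features if f.kind == "intron"}
    by_gene: dict[str, list[Interval]] = {}
    for f in db.gene_features:
        if f.kind == "exon":
            by_gene.setdefault(f.gene_id, []).append(f)
    for gid, exons in by_gene.items():
        if gid in have_introns or gid not in db.gene_spans:
            continue
        span = db.gene_spans[gid]
        exons = sorted(exons, key=lambda f: f.start)
        cursor = span.start
        for ex in exons:
            if ex.start > cursor >= span.start:
                db.gene_features.append(
                    Interval(span.contig, cursor, ex.start, "intron", gid))
            cursor = max(cursor, ex.end)


def read_regulatory_bed(path, genome: GenomeRef | None = None) -> list[Interval]:
    """Read regulatory regions from a 5-column BED dialect:
    contig, start, end, name, kind (kind in REGULATORY_KINDS)."""
    out = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 5:
                raise FormatError(f"{path}:{line_no}: need 5 BED columns")
            contig, start, end, name, kind = cols[:5]
            if kind not in REGULATORY_KINDS:
                raise FormatError(f"{path}:{line_no}: unknown kind {kind!r}")
            if genome is not None and contig not in genome.sequences:
                raise FormatError(f"{path}:{line_no}: unknown contig {contig!r}")
            out.append(Interval(contig, int(start), int(end), kind, name))
    return out


# ---------------------------------------------------------------------------
# VCF 4.2 output for structural variants

_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of structural variant">
##INFO=<ID=END,Number=1,Type=Integer,Description="End position of the variant">
##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Length of the variant">
##INFO=<ID=INSSEQ,Number=1,Type=String,Description="Inserted sequence for complex deletion+insertion">
##INFO=<ID=CHR2,Number=1,Type=String,Description="Partner contig for translocations">
##INFO=<ID=POS2,Number=1,Type=Integer,Description="Partner position (1-based) for translocations">
##INFO=<ID=VF,Number=1,Type=Float,Description="Variant frequency at the breakpoint">
##INFO=<ID=ZYG,Number=1,Type=String,Description="Zygosity call (hom/het/unknown)">
##INFO=<ID=SUPPORT,Number=1,Type=Integer,Description="Split reads supporting the junction">
##INFO=<ID=FWD,Number=1,Type=Integer,Description="Forward-strand supporting reads">
##INFO=<ID=REV,Number=1,Type=Integer,Description="Reverse-strand supporting reads">
##INFO=<ID=CNR,Number=1,Type=Float,Description="Mean copy-number ratio over the variant">
##INFO=<ID=IMPRECISE,Number=0,Type=Flag,Description="Copy-number-only call with bin-resolution coordinates">
##INFO=<ID=SPLITONLY,Number=0,Type=Flag,Description="Split-read call with no copy-number support">
##INFO=<ID=CATEGORY,Number=1,Type=String,Description="Feature category of the variant">
##INFO=<ID=SUBCATEGORY,Number=1,Type=String,Description="Regulatory subcategory for intergenic variants">
##INFO=<ID=GENES,Number=.,Type=String,Description="Affected gene ids">
"""

_SYMBOLIC_ALT = {"DEL": "<DEL>", "DUP": "<DUP>", "MULT": "<DUP>",
                 "INS": "<INS>", "DELINS": "<DEL>", "INV": "<INV>",
                 "TRA": "<TRA>"}


def write_variant_calls(calls, path, genome: GenomeRef | None = None) -> None:
    """Write StructuralVariantCalls as VCF 4.2 with symbolic ALT alleles.

    POS is the 1-based base before the breakpoint; complex DELINS calls are
    emitted as <DEL> records with the inserted sequence in INSSEQ. Input must
    be sorted by contig then start.
    """
    prev = None
    for c in calls:
        key = (c.contig, c.start)
        if prev is not None and key < prev:
            raise ValueError("calls must be sorted by contig then start")
        prev = key
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        if genome is not None:
            for name, ln in genome.contigs:
                fh.write(f"##contig=<ID={name},length={ln}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in calls:
            svtype_out = "DEL" if c.svtype == "DELINS" else c.svtype
            info = [f"SVTYPE={svtype_out}", f"END={c.end}"]
            svlen = -c.length if c.svtype in ("DEL", "DELINS") else c.length
            info.append(f"SVLEN={svlen}")
            if c.novel_seq:
                info.append(f"INSSEQ={c.novel_seq}")
            if c.svtype == "TRA":
                info += [f"CHR2={c.contig2}", f"POS2={c.pos2 + 1}"]
            if c.frequency is not None:
                info.append(f"VF={c.frequency:.4f}")
            info.append(f"ZYG={c.zygosity}")
            info += [f"SUPPORT={c.support}", f"FWD={c.fwd_support}",
                     f"REV={c.rev_support}"]
            if c.cn_ratio_mean is not None:
                info.append(f"CNR={c.cn_ratio_mean:.4f}")
            if c.imprecise:
                info.append("IMPRECISE")
            if c.split_only:
                info.append("SPLITONLY")
            if c.category:
                info.append(f"CATEGORY={c.category}")
            if c.subcategory:
                info.append(f"SUBCATEGORY={c.subcategory}")
            if c.genes:
                info.append("GENES=" + ",".join(c.genes))
            filt = c.filter or "PASS"
            fh.write(
                f"{c.contig}\t{c.start}\t{c.id}\tN\t{_SYMBOLIC_ALT[c.svtype]}"
                f"\t.\t{filt}\t{';'.join(info)}\n"
            )


def read_variant_calls(path):
    """Read back a VCF produced by write_variant_calls (round-trip reader)."""
    from svharvest.integrate import StructuralVariantCall

    calls = []
    with pysam.VariantFile(str(path)) as fh:
        for rec in fh:
            info = rec.info
            svtype = info["SVTYPE"]
            start = rec.pos  # POS is 1-based base BEFORE breakpoint == 0-based start
            end = rec.stop  # pysam materializes the END INFO key here
            svlen = abs(info["SVLEN"])
            calls.append(StructuralVariantCall(
                id=rec.id,
                svtype="DELINS" if svtype == "DEL" and "INSSEQ" in info else svtype,
                contig=rec.chrom,
                start=start,
                end=end,
                length=svlen,
                novel_seq=info.get("INSSEQ", ""),
                frequency=round(info["VF"], 4) if "VF" in info else None,
                zygosity=info.get("ZYG", "unknown"),
                support=info.get("SUPPORT", 0),
                fwd_support=info.get("FWD", 0),
                rev_support=info.get("REV", 0),
                cn_ratio_mean=round(info["CNR"], 4) if "CNR" in info else None,
                imprecise="IMPRECISE" in info,
                split_only="SPLITONLY" in info,
                contig2=info.get("CHR2"),
                pos2=info["POS2"] - 1 if "POS2" in info else None,
                category=info.get("CATEGORY"),
                subcategory=info.get("SUBCATEGORY"),
                genes=list(info["GENES"]) if "GENES" in info else [],
                filter=rec.filter.keys()[0] if rec.filter.keys() else "PASS",
            ))
    return calls


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC)[::-1]


_RC = str.maketrans("ACGTN", "TGCAN")
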