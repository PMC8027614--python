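"""Feature-category assignment, per-strain statistics, AT-content R^2."""

import textwrap

import numpy as np
import pytest

from svharvest.annotate import (
    Annotator,
    at_content_correlation,
    chromosome_stats,
    genes_affected,
    size_distribution,
)
from svharvest.integrate import StructuralVariantCall
from svharvest.io import FeatureDB, GenomeRef, Interval, read_gene_models


def call(start, end, svtype="DEL", contig="chrI", cid="c"):
    length = end - start if svtype not in ("INS", "TRA") else 0
    return StructuralVariantCall(id=cid, svtype=svtype, contig=contig,
                                 start=start, end=end, length=length)


@pytest.fixture(scope="module")
def db():
    d = FeatureDB()
    # gene A: span 1000-2000, CDS 1200-1500, exons 1000-1600, UTRs around CDS
    d.gene_spans["geneA"] = Interval("chrI", 1000, 2000, "gene", "geneA")
    d.gene_features += [
        Interval("chrI", 1200, 1500, "CDS", "geneA"),
        Interval("chrI", 1000, 1600, "exon", "geneA"),
        Interval("chrI", 1000, 1200, "five_prime_UTR", "geneA"),
        Interval("chrI", 1600, 2000, "intron", "geneA"),
    ]
    # gene B: intron-only annotation next door
    d.gene_spans["geneB"] = Interval("chrI", 3000, 4000, "gene", "geneB")
    d.gene_features += [Interval("chrI", 3100, 3900, "intron", "geneB")]
    # pseudogene
    d.gene_features += [Interval("chrI", 6000, 6500, "pseudogene", "pseudoC")]
    d.gene_spans["pseudoC"] = Interval("chrI", 6000, 6500, "gene", "pseudoC")
    # regulatory intergenic features
    d.regulatory_features += [
        Interval("chrI", 8000, 8200, "enhancer", "enh1"),
        Interval("chrI", 8100, 8300, "promoter", "prom1"),
        Interval("chrI", 9000, 9100, "TF_binding_site", "tf1"),
    ]
    return d


@pytest.fixture(scope="module")
def annot(db):
    return Annotator(db)


class TestAnnotateVariant:
    def test_cds_wins_over_everything(self, annot):
        a = annot.annotate_variant(call(1100, 1700))
        assert a.category == "CDS"
        assert a.affected_gene_ids == ["geneA"]
        assert a.intergenic_subcategory is None

    def test_utr_beats_exon(self, annot):
        a = annot.annotate_variant(call(1050, 1150))
        assert a.category == "UTR"

    def test_intron_only(self, annot):
        assert annot.annotate_variant(call(3200, 3300)).category == "intron"

    def test_pseudogene(self, annot):
        assert annot.annotate_variant(call(6100, 6200)).category == "pseudogene"

    def test_cds_of_one_gene_and_intron_of_other_lists_both(self, annot):
        a = annot.annotate_variant(call(1300, 3500))
        assert a.category == "CDS"
        assert a.affected_gene_ids == ["geneA", "geneB"]

    def test_intergenic_with_enhancer_precedence(self, annot):
        a = annot.annotate_variant(call(8150, 8160))
        assert (a.category, a.intergenic_subcategory) == ("intergenic",
                                                          "enhancer")

    def test_intergenic_other(self, annot):
        a = annot.annotate_variant(call(20_000, 20_100))
        assert (a.category, a.intergenic_subcategory) == ("intergenic", "other")

    def test_unknown_contig_rejected(self, annot):
        with pytest.raises(KeyError):
            annot.annotate_variant(call(0, 10, contig="chrMissing"))

    def test_every_variant_gets_exactly_one_category(self, annot, rng):
        for _ in range(50):
            s = int(rng.integers(0, 20_000))
            a = annot.annotate_variant(call(s, s + int(rng.integers(1, 3000))))
            assert a.category in ("CDS", "UTR", "exon", "intron",
                                  "pseudogene", "intergenic")
            assert (a.intergenic_subcategory is not None) == \
                (a.category == "intergenic")


class TestGenesAffected:
    def test_two_deletions_same_gene_count_once(self, annot):
        calls = [call(1100, 1150, cid="a"), call(1800, 1900, cid="b")]
        assert genes_affected(calls, annot) == 1

    def test_no_deletions(self, annot):
        assert genes_affected([call(1000, 1200, svtype="INV")], annot) == 0

    def test_matches_direct_interval_oracle(self, db, annot, rng):
        """genes_affected equals a direct all-pairs interval check against
        the gene spans."""
        calls = [call(int(s), int(s) + 500, cid=f"c{i}")
                 for i, s in enumerate(rng.integers(0, 9500, size=20))]
        expected = {
            gid for gid, span in db.gene_spans.items()
            if any(c.start < span.end and span.start < c.end for c in calls)
        }
        assert genes_affected(calls, annot) == len(expected)


class TestChromosomeStats:
    def test_counts_large_calls_per_contig(self):
        calls = [call(1000, 2000, contig="chrI", cid=str(i)) for i in range(3)]
        calls += [call(1000, 2000, contig="chrII", cid="x")]
        calls += [call(1000, 1030, contig="chrIII", cid="small")]  # < 50 bp
        n, per = chromosome_stats(calls)
        assert n == 2 and per == {"chrI": 3, "chrII": 1}

    def test_empty(self):
        assert chromosome_stats([]) == (0, {})


class TestSizeDistribution:
    def test_median_of_three(self):
        med, iqr, vals = size_distribution(
            [call(0, n) for n in (100, 150, 200)])
        assert med == 150 and vals == [100, 150, 200]

    def test_single_value(self):
        med, iqr, _ = size_distribution([call(0, 120)])
        assert med == 120 and iqr == 0

    def test_empty_gives_missing(self):
        assert size_distribution([]) == (None, None, [])

    def test_matches_numpy_quantile_oracle(self, rng):
        sizes = rng.integers(60, 5000, size=37)
        med, iqr, _ = size_distribution([call(0, int(n)) for n in sizes])
        q1, q2, q3 = np.percentile(sizes, [25, 50, 75])
        assert med == q2 and iqr == pytest.approx(q3 - q1)


class TestAtContentCorrelation:
    def test_uniform_placement_uncorrelated(self):
        from svharvest.simulate import SimConfig, simulate_genome

        genome = simulate_genome(
            SimConfig(genome_length=200_000, n_contigs=1, seed=9))
        rng = np.random.default_rng(10)
        calls = [call(int(p), int(p) + 100, cid=str(i))
                 for i, p in enumerate(rng.integers(0, 199_000, size=300))]
        assert at_content_correlation(calls, genome, window=1000) < 0.05

    def test_at_biased_placement_correlated(self):
        """Variant density rising linearly with window AT content gives a
        strong positive R^2 (constructed positive control)."""
        rng = np.random.default_rng(11)
        window = 1000
        chunks, calls = [], []
        cid = 0
        for i in range(100):
            at = 0.2 + 0.6 * (i / 99)
            p = [at / 2, (1 - at) / 2, (1 - at) / 2, at / 2]
            chunks.append("".join(rng.choice(list("ACGT"), size=window, p=p)))
            for _ in range(i // 10):  # 0 calls in low-AT, 9 in high-AT windows
                cid += 1
                calls.append(call(i * window + 10, i * window + 60,
                                  cid=str(cid)))
        genome = GenomeRef({"chrI": "".join(chunks)})
        assert at_content_correlation(calls, genome, window=window) > 0.5

    def test_constant_at_defined_as_zero(self):
        genome = GenomeRef({"chrI": "AT" * 2000})
        calls = [call(10, 80)]
        assert at_content_correlation(calls, genome, window=1000) == 0.0

    def test_too_few_windows_rejected(self):
        genome = GenomeRef({"chrI": "ACGT" * 300})
        with pytest.raises(ValueError):
            at_content_correlation([], genome, window=1000)


class TestGff3Loading:
    GFF = textwrap.dedent("""\
        ##gff-version 3
        chrI\tx\tgene\t1001\t3000\t.\t+\t.\tID=geneZ
        chrI\tx\tmRNA\t1001\t3000\t.\t+\t.\tID=tZ;Parent=geneZ
        chrI\tx\texon\t1001\t1400\t.\t+\t.\tParent=tZ
        chrI\tx\texon\t2001\t3000\t.\t+\t.\tParent=tZ
        chrI\tx\tCDS\t1101\t1400\t.\t+\t0\tParent=tZ
        """)

    def test_intron_derived_from_gene_minus_exons(self, tmp_path):
        p = tmp_path / "toy.gff3"
        p.write_text(self.GFF)
        db = read_gene_models(p)
        introns = [f for f in db.gene_features if f.kind == "intron"]
        assert [(f.start, f.end, f.gene_id) for f in introns] == \
            [(1400, 2000, "geneZ")]

    def test_features_are_zero_based_half_open(self, tmp_path):
        p = tmp_path / "toy.gff3"
        p.write_text(self.GFF)
        db = read_gene_models(p)
        cds = [f for f in db.gene_features if f.kind == "CDS"]
        assert (cds[0].start, cds[0].end) == (1100, 1400)
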