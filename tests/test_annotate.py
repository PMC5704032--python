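"""Gene-region assignment, translational impact, population flags and
the phenotype-tag filter."""

import pytest
from Bio.Seq import Seq

from twinquad import CnvCall, SmallVariantCall
from twinquad.annotate import (
    GeneIndex,
    GeneModel,
    annotate_all,
    assign_region,
    flag_population,
    phenotype_tag_filter,
    read_gene_models,
    translational_impact,
)
from twinquad.sharing import ClassifiedVariant
from twinquad.simulate import write_gff3

# --- toy chromosome with one plus-strand two-exon gene -------------------
# exon1 [5000,5250) holds a 100 bp 5'UTR and the first 150 CDS bases,
# exon2 [5350,5600) holds 150 CDS bases and a 100 bp 3'UTR.
_CDS1 = "ATG" + "ATT" + "CTG" + "TGG" + "GCT" * 46
_CDS2 = "GCT" * 50


def _toy_sequence():
    seq = ["C"] * 12000
    seq[5100:5250] = list(_CDS1)
    seq[5350:5500] = list(_CDS2)
    return "".join(seq)


@pytest.fixture(scope="module")
def toy():
    gene = GeneModel(
        gene_id="toy1",
        chrom="chrT",
        strand="+",
        tx_start=5000,
        tx_end=5600,
        exons=((5000, 5250), (5350, 5600)),
        cds=((5100, 5250), (5350, 5500)),
    )
    reference = {"chrT": _toy_sequence()}
    return gene, reference, GeneIndex([gene])


def _snv(pos, ref, alt):
    return SmallVariantCall("s", "chrT", pos, ref, alt, 60, 150.0)


class TestRegions:
    @pytest.mark.parametrize(
        "pos0,region",
        [
            (5150, "exonic"),       # inside CDS
            (5250, "splice_site"),  # first intronic base after exon 1
            (5348, "splice_site"),  # second intronic base before exon 2
            (5300, "intronic"),     # mid-intron
            (5050, "utr5"),         # exon, before the CDS span
            (5550, "utr3"),         # exon, after the CDS span
            (4500, "promoter"),     # within 2 kb upstream
        ],
    )
    def test_precedence_and_windows(self, toy, pos0, region):
        gene, reference, index = toy
        base = reference["chrT"][pos0]
        alt = "A" if base != "A" else "G"
        hits = assign_region(_snv(pos0 + 1, base, alt), index)
        assert hits == [("toy1", region)]

    def test_intergenic_variant_hits_nothing(self, toy):
        _, reference, index = toy
        assert assign_region(_snv(100, "C", "A"), index) == []

    def test_cnv_spanning_three_genes(self):
        genes = [
            GeneModel(f"g{i}", "chr1", "+", s, s + 1000,
                      exons=((s, s + 1000),), cds=((s, s + 999),))
            for i, s in enumerate((10_000, 20_000, 30_000))
        ]
        index = GeneIndex(genes)
        cnv = CnvCall("s", "chr1", 9_000, 31_500, 3)
        hits = assign_region(cnv, index)
        assert sorted(g for g, _ in hits) == ["g0", "g1", "g2"]


class TestImpact:
    def test_missense_ile_to_ser(self, toy):
        """T>G at the second base of an ATT (Ile) codon gives AGT (Ser)."""
        gene, reference, _ = toy
        assert translational_impact(_snv(5105, "T", "G"), gene, reference) == "missense"

    def test_synonymous_leucine(self, toy):
        gene, reference, _ = toy
        # CTG -> CTA, both Leu
        assert translational_impact(_snv(5109, "G", "A"), gene, reference) == "synonymous"

    def test_stop_gain(self, toy):
        gene, reference, _ = toy
        # TGG (Trp) -> TAG (stop)
        assert translational_impact(_snv(5111, "G", "A"), gene, reference) == "stop_gain"

    @pytest.mark.parametrize("length", range(1, 10))
    def test_frameshift_iff_length_not_multiple_of_three(self, toy, length):
        gene, reference, _ = toy
        seq = reference["chrT"]
        ref = seq[5150 - 1]
        variant = _snv(5150, ref, ref + "A" * length)
        expected = "frameshift" if length % 3 else "in_frame"
        assert translational_impact(variant, gene, reference) == expected

    def test_in_frame_deletion(self, toy):
        gene, reference, _ = toy
        seq = reference["chrT"]
        variant = _snv(5150, seq[5149:5153], seq[5149])
        assert translational_impact(variant, gene, reference) == "in_frame"

    def test_variant_spanning_cds_boundary_is_complex(self, toy):
        gene, reference, _ = toy
        seq = reference["chrT"]
        variant = _snv(5246, seq[5245:5255], seq[5245])
        assert translational_impact(variant, gene, reference) == "complex"

    def test_minus_strand_impacts_equal_mirrored_plus_strand(self, toy):
        """Metamorphic check: mirroring the chromosome (reverse
        complement) and flipping the gene to the minus strand leaves
        every SNV's impact unchanged."""
        gene, reference, _ = toy
        seq = reference["chrT"]
        L = len(seq)
        mirrored_seq = str(Seq(seq).reverse_complement())
        mirror = GeneModel(
            gene_id="toy1m",
            chrom="chrT",
            strand="-",
            tx_start=L - gene.tx_end,
            tx_end=L - gene.tx_start,
            exons=tuple(sorted((L - e, L - s) for s, e in gene.exons)),
            cds=tuple(sorted((L - e, L - s) for s, e in gene.cds)),
        )
        mirrored_ref = {"chrT": mirrored_seq}
        comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
        for pos0 in list(range(5100, 5130)) + list(range(5350, 5380)):
            ref = seq[pos0]
            for alt in "ACGT":
                if alt == ref:
                    continue
                direct = translational_impact(
                    _snv(pos0 + 1, ref, alt), gene, reference
                )
                mirrored = translational_impact(
                    SmallVariantCall("s", "chrT", L - pos0, comp[ref],
                                     comp[alt], 60, 150.0),
                    mirror, mirrored_ref,
                )
                assert direct == mirrored, f"strand mismatch at {pos0}->{alt}"


class TestPopulationAndTags:
    def test_population_flag(self):
        key = ("chr1", 10, "A", "G")
        tables = [{key: 0.07}, {}]
        assert flag_population(key, tables) == ("polymorphic", (0.07,))
        assert flag_population(("chr1", 11, "A", "G"), tables)[0] == "novel"
        assert flag_population(key, [])[0] == "novel"

    def test_tag_filter_keeps_only_tagged_genes(self, toy):
        gene, reference, _ = toy
        genes = [gene] + [
            GeneModel(f"g{i}", "chrT", "+", 8000 + i * 1000, 8800 + i * 1000,
                      exons=((8000 + i * 1000, 8800 + i * 1000),),
                      cds=((8000 + i * 1000, 8300 + i * 1000 - 1),))
            for i in range(3)
        ]
        classified = [
            ClassifiedVariant(_snv(5150, reference["chrT"][5149], "A"),
                              "unshared", "de_novo"),
            ClassifiedVariant(_snv(8101, "C", "A"), "unshared", "de_novo"),
            ClassifiedVariant(_snv(100, "C", "A"), "unshared", "de_novo"),
        ]
        annotated = annotate_all(classified, genes, reference=reference)
        tags = {"toy1": {"neurological"}, "g0": {"metabolic"}}
        kept = phenotype_tag_filter(annotated, tags, ["neurological"])
        assert [a.genes for a in kept] == [{"toy1"}]
        # empty tag list is the identity (with a warning), not a wipe-out
        assert phenotype_tag_filter(annotated, tags, []) == list(annotated)

    def test_annotation_preserves_classification_labels(self, toy):
        gene, reference, _ = toy
        classified = [
            ClassifiedVariant(_snv(5105, "T", "G"), "unshared", "de_novo")
        ]
        annotated = annotate_all(classified, [gene], reference=reference)
        assert annotated[0].classified is classified[0]
        assert annotated[0].impact == "missense"
        assert annotated[0].classified.origin == "de_novo"


def test_cytoband_passthrough(tmp_path):
    from twinquad.annotate import cytoband_of, read_cytobands

    path = tmp_path / "bands.tsv"
    path.write_text(
        "chrom\tstart\tend\tband\n"
        "chr15\t20000000\t25000000\t15q11.2\n"
        "chr15\t25000000\t28000000\t15q12\n"
    )
    bands = read_cytobands(path)
    cnv = CnvCall("s", "chr15", 22422114, 22492114, 3)
    assert cytoband_of(cnv, bands) == "15q11.2"
    assert cytoband_of(CnvCall("s", "chr1", 0, 10, 3), bands) == ""


def test_gff3_round_trip(tmp_path, reference):
    path = tmp_path / "genes.gff3"
    write_gff3(reference.genes, path)
    back = read_gene_models(path)
    assert len(back) == len(reference.genes)
    by_id = {g.gene_id: g for g in back}
    for g in reference.genes:
        r = by_id[g.gene_id]
        assert (r.chrom, r.strand, r.tx_start, r.tx_end) == (
            g.chrom, g.strand, g.tx_start, g.tx_end
        )
        assert r.exons == g.exons and r.cds == g.cds
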