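"""Gene-level annotation of classified variants.

Each variant is annotated with the genes it overlaps, a gene region
(splice site, exonic, 5'/3' UTR, promoter, intronic), a translational
impact for coding hits (synonymous / missense / stop gain / frameshift /
in-frame), and a population flag (novel vs polymorphic) from
user-supplied frequency tables.  A flat gene->tag table supports a
biological-context filter (keep variants whose genes carry a phenotype
tag of interest).

Windows are configurable: the promoter defaults to 2000 bp upstream of
the transcript start and the splice-site window to the first 2 intronic
bases flanking each exon.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import gffutils
import pandas as pd
from Bio.Seq import Seq
from intervaltree import IntervalTree

from .callsets import CnvCall, SmallVariantCall, SvEvent
from .sharing import ClassifiedVariant

logger = logging.getLogger(__name__)

REGIONS = ("splice_site", "exonic", "utr5", "utr3", "promoter", "intronic")
IMPACTS = ("synonymous", "missense", "stop_gain", "frameshift", "in_frame",
           "complex", "none")

PROMOTER_WINDOW = 2000
SPLICE_WINDOW = 2


@dataclass(frozen=True)
class GeneModel:
    """One gene with a single representative transcript.

    All coordinates are 0-based half-open.  ``cds`` intervals are sorted
    in genomic order; for minus-strand genes transcription order is the
    reverse.  The synthetic generator always emits CDS totals divisible
    by 3; real annotations that do not are annotated best-effort.
    """

    gene_id: str
    chrom: str
    strand: str  # '+' | '-'
    tx_start: int
    tx_end: int
    exons: tuple[tuple[int, int], ...]
    cds: tuple[tuple[int, int], ...]

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        for s, e in self.exons:
            if not (self.tx_start <= s < e <= self.tx_end):
                raise ValueError(f"exon outside transcript span in {self.gene_id}")

    def promoter(self, window: int = PROMOTER_WINDOW) -> tuple[int, int]:
        """Strand-aware promoter interval upstream of the transcript start."""
        if self.strand == "+":
            return (max(0, self.tx_start - window), self.tx_start)
        return (self.tx_end, self.tx_end + window)

    @property
    def cds_span(self) -> tuple[int, int] | None:
        if not self.cds:
            return None
        return (min(s for s, _ in self.cds), max(e for _, e in self.cds))


def _overlaps(a_start, a_end, b_start, b_end) -> bool:
    return max(a_start, b_start) < min(a_end, b_end)


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Load gene models from GFF3 (gene -> mRNA -> exon/CDS).

    When a gene has several transcripts the first is used and the choice
    is logged, so isoform disagreements are visible rather than silent.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes = []
    for gene in db.features_of_type("gene"):
        transcripts = list(db.children(gene, featuretype="mRNA"))
        if not transcripts:
            continue
        if len(transcripts) > 1:
            logger.info(
                "gene %s has %d transcripts; using %s",
                gene.id, len(transcripts), transcripts[0].id,
            )
        tx = transcripts[0]
        exons = tuple(
            sorted(
                (f.start - 1, f.end)
                for f in db.children(tx, featuretype="exon")
            )
        )
        cds = tuple(
            sorted(
                (f.start - 1, f.end)
                for f in db.children(tx, featuretype="CDS")
            )
        )
        genes.append(
            GeneModel(
                gene_id=gene.id,
                chrom=gene.seqid,
                strand=gene.strand,
                tx_start=tx.start - 1,
                tx_end=tx.end,
                exons=exons,
                cds=cds,
            )
        )
    return genes


class GeneIndex:
    """Interval index over gene footprints (transcript plus promoter)."""

    def __init__(self, genes: Sequence[GeneModel],
                 promoter_window: int = PROMOTER_WINDOW):
        self.promoter_window = promoter_window
        self._trees: dict[str, IntervalTree] = {}
        for g in genes:
            ps, pe = g.promoter(promoter_window)
            lo = min(g.tx_start, ps)
            hi = max(g.tx_end, pe)
            self._trees.setdefault(g.chrom, IntervalTree()).addi(lo, hi, g)

    def hits(self, chrom: str, start: int, end: int) -> list[GeneModel]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        found = [iv.data for iv in tree.overlap(start, end)]
        return sorted(found, key=lambda g: (g.tx_start, g.gene_id))


def variant_interval(variant) -> tuple[str, int, int]:
    """Genomic footprint of a small call, CNV or interval SV as a
    0-based half-open interval."""
    if isinstance(variant, SmallVariantCall):
        return (variant.chrom, variant.pos - 1, variant.pos - 1 + len(variant.ref))
    if isinstance(variant, CnvCall):
        return variant.interval
    if isinstance(variant, SvEvent):
        if variant.category == "interchromosomal":
            # junction A footprint; junction B is looked up separately
            return (variant.chrom, variant.start, variant.start + 1)
        return variant.interval
    raise TypeError(f"cannot annotate {type(variant).__name__}")


def _region_for_gene(gene: GeneModel, start: int, end: int,
                     promoter_window: int, splice_window: int) -> str | None:
    """Region label of interval [start, end) within one gene, by the
    precedence splice_site > exonic(CDS) > UTR > promoter > intronic."""
    ps, pe = gene.promoter(promoter_window)
    in_tx = _overlaps(start, end, gene.tx_start, gene.tx_end)
    in_promoter = _overlaps(start, end, ps, pe)
    if not in_tx and not in_promoter:
        return None
    # splice sites: first `splice_window` intronic bases at internal
    # exon boundaries
    exons = gene.exons
    for i, (es, ee) in enumerate(exons):
        if i > 0 and _overlaps(start, end, es - splice_window, es):
            return "splice_site"
        if i < len(exons) - 1 and _overlaps(start, end, ee, ee + splice_window):
            return "splice_site"
    for cs, ce in gene.cds:
        if _overlaps(start, end, cs, ce):
            return "exonic"
    span = gene.cds_span
    for es, ee in exons:
        if _overlaps(start, end, es, ee):
            if span is None:
                return "utr5"
            lo, hi = span
            before = start < lo
            if gene.strand == "+":
                return "utr5" if before else "utr3"
            return "utr3" if before else "utr5"
    if in_tx:
        return "intronic"
    return "promoter"


def assign_region(
    variant,
    index: GeneIndex,
    splice_window: int = SPLICE_WINDOW,
) -> list[tuple[str, str]]:
    """All (gene_id, region) hits of a variant; empty for intergenic."""
    chrom, start, end = variant_interval(variant)
    hits = []
    for gene in index.hits(chrom, start, end):
        region = _region_for_gene(
            gene, start, end, index.promoter_window, splice_window
        )
        if region is not None:
            hits.append((gene.gene_id, region))
    if isinstance(variant, SvEvent) and variant.category == "interchromosomal":
        for gene in index.hits(variant.chrom2, variant.pos2, variant.pos2 + 1):
            region = _region_for_gene(
                gene, variant.pos2, variant.pos2 + 1,
                index.promoter_window, splice_window,
            )
            if region is not None and (gene.gene_id, region) not in hits:
                hits.append((gene.gene_id, region))
    return hits


def _coding_sequence(gene: GeneModel, reference: Mapping[str, str]) -> str:
    """Spliced CDS in transcription order (reverse-complemented for minus
    strand)."""
    seq = str(reference[gene.chrom])
    parts = [seq[s:e] for s, e in gene.cds]
    cds = "".join(parts).upper()
    if gene.strand == "-":
        cds = str(Seq(cds).reverse_complement())
    return cds


def _coding_offset(gene: GeneModel, genomic_pos0: int) -> int | None:
    """0-based offset of a genomic position within the spliced CDS, in
    transcription order; None when the position is non-coding."""
    total = sum(e - s for s, e in gene.cds)
    running = 0
    for s, e in gene.cds:
        if s <= genomic_pos0 < e:
            plus_offset = running + (genomic_pos0 - s)
            if gene.strand == "+":
                return plus_offset
            return total - 1 - plus_offset
        running += e - s
    return None


def translational_impact(
    variant: SmallVariantCall,
    gene: GeneModel,
    reference: Mapping[str, str],
) -> str:
    """Coding impact of a small variant on one gene.

    SNVs are translated codon-wise (strand aware): same amino acid ->
    synonymous, new stop -> stop_gain, else missense.  Length-changing
    variants are frameshift when the net length change is not a multiple
    of 3 and in_frame otherwise.  A variant that straddles a CDS
    boundary is reported as ``complex``.
    """
    chrom, start, end = variant_interval(variant)
    inside = any(cs <= start and end <= ce for cs, ce in gene.cds)
    touches = any(_overlaps(start, end, cs, ce) for cs, ce in gene.cds)
    if not touches:
        return "none"
    if not inside:
        logger.warning(
            "variant %s:%d spans a CDS boundary of %s; impact is complex",
            variant.chrom, variant.pos, gene.gene_id,
        )
        return "complex"
    net = len(variant.alt) - len(variant.ref)
    if variant.vclass == "SNV":
        offset = _coding_offset(gene, start)
        if offset is None:
            return "none"
        cds = _coding_sequence(gene, reference)
        codon_i = offset // 3
        codon = cds[codon_i * 3 : codon_i * 3 + 3]
        if len(codon) < 3:
            return "complex"
        base = variant.alt.upper()
        if gene.strand == "-":
            base = str(Seq(base).reverse_complement())
        within = offset % 3
        mutated = codon[:within] + base + codon[within + 1 :]
        aa_before = str(Seq(codon).translate())
        aa_after = str(Seq(mutated).translate())
        if aa_after == aa_before:
            return "synonymous"
        if aa_after == "*":
            return "stop_gain"
        return "missense"
    if net % 3 != 0:
        return "frameshift"
    return "in_frame"


@dataclass(frozen=True)
class AnnotatedVariant:
    """A classified variant plus its gene, impact and population
    annotations.  Classification labels pass through unchanged."""

    classified: object  # ClassifiedVariant or ClassifiedEvent
    gene_hits: tuple[tuple[str, str], ...] = ()
    impact: str = "none"
    population_flag: str = "novel"
    population_freqs: tuple[float, ...] = ()

    @property
    def genes(self) -> set[str]:
        return {g for g, _ in self.gene_hits}


def read_cytobands(path: str | Path) -> dict[str, IntervalTree]:
    """Read a cytoband table (TSV: chrom, start, end, band; 0-based
    half-open) into per-chromosome interval trees.  Band tables are
    build-specific and therefore always user-supplied."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "band": str})
    trees: dict[str, IntervalTree] = {}
    for r in df.itertuples(index=False):
        trees.setdefault(r.chrom, IntervalTree()).addi(
            int(r.start), int(r.end), str(r.band)
        )
    return trees


def cytoband_of(variant, bands: Mapping[str, IntervalTree]) -> str:
    """Band containing the variant's start (empty string if unknown)."""
    chrom, start, _ = variant_interval(variant)
    tree = bands.get(chrom)
    if tree is None:
        return ""
    hits = sorted(tree.overlap(start, start + 1))
    return hits[0].data if hits else ""


def read_frequency_table(path: str | Path) -> dict[tuple, float]:
    """Read a population-frequency table (TSV: chrom, pos, ref, alt,
    freq) keyed by canonical variant key."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return {
        (r.chrom, int(r.pos), r.ref, r.alt): float(r.freq)
        for r in df.itertuples(index=False)
    }


def flag_population(
    key: tuple, tables: Sequence[Mapping[tuple, float]]
) -> tuple[str, tuple[float, ...]]:
    """novel vs polymorphic: polymorphic iff the key is present with
    frequency > 0 in at least one table."""
    freqs = tuple(t[key] for t in tables if key in t)
    flag = "polymorphic" if any(f > 0 for f in freqs) else "novel"
    return flag, freqs


def annotate_variant(
    classified,
    index: GeneIndex,
    reference: Mapping[str, str] | None = None,
    frequency_tables: Sequence[Mapping[tuple, float]] = (),
    splice_window: int = SPLICE_WINDOW,
) -> AnnotatedVariant:
    """Annotate one classified small variant or CNV/SV event."""
    variant = getattr(classified, "call", None) or classified.event
    hits = assign_region(variant, index, splice_window)
    impact = "none"
    if isinstance(variant, SmallVariantCall):
        if reference is not None:
            genes_by_id = {iv.data.gene_id: iv.data
                           for tree in index._trees.values()
                           for iv in tree}
            for gene_id, region in hits:
                if region == "exonic":
                    impact = translational_impact(
                        variant, genes_by_id[gene_id], reference
                    )
                    break
        flag, freqs = flag_population(variant.key, frequency_tables)
    else:
        flag, freqs = "novel", ()
    return AnnotatedVariant(
        classified=classified,
        gene_hits=tuple(hits),
        impact=impact,
        population_flag=flag,
        population_freqs=freqs,
    )


def annotate_all(
    classified_list: Sequence,
    genes: Sequence[GeneModel],
    reference: Mapping[str, str] | None = None,
    frequency_tables: Sequence[Mapping[tuple, float]] = (),
    promoter_window: int = PROMOTER_WINDOW,
    splice_window: int = SPLICE_WINDOW,
) -> list[AnnotatedVariant]:
    index = GeneIndex(genes, promoter_window)
    return [
        annotate_variant(c, index, reference, frequency_tables, splice_window)
        for c in classified_list
    ]


def read_gene_tags(path: str | Path) -> dict[str, set[str]]:
    """Read a flat gene->tag table (TSV: gene, tag; one row per pair)."""
    df = pd.read_csv(path, sep="\t")
    tags: dict[str, set[str]] = {}
    for r in df.itertuples(index=False):
        tags.setdefault(str(r.gene), set()).add(str(r.tag))
    return tags


def phenotype_tag_filter(
    annotated: Sequence[AnnotatedVariant],
    gene_tags: Mapping[str, set[str]],
    tags: Sequence[str],
) -> list[AnnotatedVariant]:
    """Biological-context filter: keep variants whose genes carry any of
    the requested phenotype tags (a one-step gene->tag lookup).

    An empty tag list keeps everything, with a warning — an accidental
    empty filter should not silently empty the analysis.
    """
    if not tags:
        logger.warning("empty phenotype tag list: filter is the identity")
        return list(annotated)
    wanted = set(tags)
    return [
        a
        for a in annotated
        if any(gene_tags.get(g, set()) & wanted for g in a.genes)
    ]


def annotated_to_frame(annotated: Sequence[AnnotatedVariant]) -> pd.DataFrame:
    """Annotation report table (one row per variant) mirroring the
    exonic-variant report layout."""
    rows = []
    for a in annotated:
        variant = getattr(a.classified, "call", None) or a.classified.event
        if isinstance(variant, SmallVariantCall):
            chrom, pos, ref, alt = variant.key
            vtype = variant.vclass
        else:
            chrom, pos, ref, alt = variant.chrom, variant.start, "", ""
            vtype = (
                variant.cnv_type if isinstance(variant, CnvCall) else variant.category
            )
        rows.append(
            {
                "sample": variant.sample_id,
                "chrom": chrom,
                "pos": pos,
                "ref": ref,
                "alt": alt,
                "type": vtype,
                "genes": ";".join(sorted(a.genes)),
                "regions": ";".join(f"{g}:{r}" for g, r in a.gene_hits),
                "impact": a.impact,
                "population_flag": a.population_flag,
                "sharing": a.classified.sharing,
                "origin": a.classified.origin,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "sample", "chrom", "pos", "ref", "alt", "type", "genes",
            "regions", "impact", "population_flag", "sharing", "origin",
        ],
    )
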