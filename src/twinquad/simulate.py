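"""Synthetic family-quad generator.

Generates a small diploid-like reference (random sequence plus multi-exon
gene models and a gene-set collection) and a family quad of call sets —
father, mother and a pair of monozygotic twins — with known ground truth
for every planted variant:

* *transmitted* small variants are present in one parent and in both
  twins (monozygotic twins share their germline);
* *germline de novo* variants are present in both twins and neither
  parent;
* *post-zygotic* variants are present in exactly one twin, each with a
  cell fraction modelling somatic mosaicism;
* *discordant transmitted* decoys are present in one parent and only
  one twin, emulating the co-twin call dropout that makes some unshared
  variants classify as inherited;
* CNVs and SVs follow the same sharing structure, with small
  coordinate jitter on the co-twin/parent copies so that equivalence
  must be established by the 50% reciprocal-overlap matcher rather than
  by exact coordinates.

Default counts are a 1/1000 desk-scale rendition of a human genome's
per-genome totals (≈3600 SNVs, ≈400 indels, ≈75 block substitutions per
genome, transition/transversion ratio 2.1), with CNVs near full count
(≈150, already small) and SVs at 1/10 (≈90); class proportions, not
absolute totals, are what downstream stages depend on.

Determinism: one seed drives three independent generator streams
(reference, quad, dropout) derived through ``numpy.random.SeedSequence``
spawning, so reruns with the same configuration are byte-identical.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml
from intervaltree import IntervalTree
from scipy.stats import binom

from .annotate import GeneModel
from .callsets import (
    CnvCall,
    QuadCallsets,
    ROLES,
    SampleCallset,
    SmallVariantCall,
    SvEvent,
    normalize_variant,
    write_cnv_table,
    write_small_variants,
    write_sv_table,
)
from .enrichment import GeneSetCollection, write_gmt
from .errors import ConfigError

_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}
_BASES = "ACGT"

#: fraction of somatic small variants that are indels / block
#: substitutions (the remainder are SNVs), matching the genome-wide
#: class proportions 3600:400:75
SOMATIC_INDEL_FRAC = 0.10
SOMATIC_BLOCKSUB_FRAC = 0.02


@dataclass
class SimulationConfig:
    """Study conditions for one simulated family.

    Counts are desk-scaled; ``n_inherited_*`` are per-parent pools, all
    of which are transmitted to both twins, so each twin carries twice
    the pool in shared variants.
    """

    seed: int = 0
    family_id: str = "family1"

    # reference geometry
    n_chromosomes: int = 2
    chromosome_length_bp: int = 1_500_000
    n_genes: int = 160
    n_gene_sets: int = 24
    genes_per_set: int = 6
    gene_set_overlap: int = 0  # genes shared between consecutive sets

    # small sequence changes (per parent pool)
    n_inherited_snv: int = 1800
    n_inherited_indel: int = 200
    n_inherited_blocksub: int = 38
    n_germline_denovo: int = 3
    n_somatic_per_twin: int = 4
    n_inherited_discordant: int = 7  # per twin: parent + that twin only
    n_lowq_decoys: int = 0  # per twin: quality below the filter cutoff
    titv_ratio: float = 2.1

    # larger events
    n_cnv_shared: int = 140
    n_cnv_unique: int = 5  # per twin, post-zygotic
    n_cnv_unique_inherited: int = 2  # per twin, parent + that twin only
    n_sv_shared_by_category: dict = field(
        default_factory=lambda: {
            "deletion": 60,
            "tandem_duplication": 8,
            "distal_duplication": 6,
            "interchromosomal": 2,
            "inversion": 2,
        }
    )
    n_sv_unique_by_category: dict = field(
        default_factory=lambda: {"deletion": 3, "tandem_duplication": 1}
    )
    n_sv_unique_inherited_by_category: dict = field(
        default_factory=lambda: {
            "deletion": 7,
            "tandem_duplication": 1,
            "distal_duplication": 1,
            "interchromosomal": 1,
        }
    )

    # noise models
    mosaic_model: tuple = ("beta", 2.0, 5.0)  # or ("fixed", f)
    depth_mean: float = 100.0
    quality_high: float = 200.0
    quality_low: float = 30.0
    detection_floor: int = 3

    # pathway spiking: place this fraction of the affected twin's
    # somatic SNVs inside genes of the named sets (round-robin)
    spike_sets: tuple = ()
    spike_fraction: float = 0.8

    def validate(self) -> None:
        counts = [
            self.n_chromosomes,
            self.chromosome_length_bp,
            self.n_genes,
            self.n_gene_sets,
            self.genes_per_set,
            self.n_inherited_snv,
            self.n_inherited_indel,
            self.n_inherited_blocksub,
            self.n_germline_denovo,
            self.n_somatic_per_twin,
            self.n_inherited_discordant,
            self.n_lowq_decoys,
            self.n_cnv_shared,
            self.n_cnv_unique,
            self.n_cnv_unique_inherited,
        ]
        if any(c < 0 for c in counts[2:]) or self.n_chromosomes < 1:
            raise ConfigError("all simulation counts must be non-negative")
        if self.titv_ratio <= 0:
            raise ConfigError("titv_ratio must be positive")
        if self.depth_mean <= 0:
            raise ConfigError("depth_mean must be positive")
        if self.mosaic_model[0] == "fixed":
            f = self.mosaic_model[1]
            if not 0 < f <= 1:
                raise ConfigError("fixed mosaic fraction must be in (0, 1]")
        elif self.mosaic_model[0] == "beta":
            if self.mosaic_model[1] <= 0 or self.mosaic_model[2] <= 0:
                raise ConfigError("beta mosaic parameters must be positive")
        else:
            raise ConfigError(f"unknown mosaic model {self.mosaic_model[0]!r}")
        if not 0 <= self.spike_fraction <= 1:
            raise ConfigError("spike_fraction must be in [0, 1]")
        needed = (
            self.n_gene_sets * (self.genes_per_set - self.gene_set_overlap)
            + self.gene_set_overlap
        )
        if needed > self.n_genes:
            raise ConfigError(
                f"{self.n_gene_sets} sets of {self.genes_per_set} need "
                f"{needed} genes but only {self.n_genes} are generated"
            )


@dataclass(frozen=True)
class GroundTruthRecord:
    """Ground truth for one planted variant.

    ``key`` is the canonical small-variant key tuple for SSCs, or a
    descriptive event key for CNVs/SVs (the coordinates emitted,
    un-jittered, in the carrier twin's call set).
    """

    kind: str  # ssc | cnv | sv
    key: tuple
    origin: str
    cell_fraction: float
    expected_samples: frozenset
    decoy: bool = False
    retained: bool = True


@dataclass
class Reference:
    """Synthetic reference bundle: sequences, gene models, gene sets."""

    chromosomes: dict
    genes: list
    gene_sets: GeneSetCollection

    def __getitem__(self, chrom: str) -> str:
        return self.chromosomes[chrom]

    @property
    def contig_lengths(self) -> dict:
        return {c: len(s) for c, s in self.chromosomes.items()}


@dataclass
class SimulatedQuad:
    """A simulated family: call sets by role plus the truth table."""

    quad: QuadCallsets
    truth: list

    def truth_keys(self, origin: str, kind: str | None = None,
                   decoys: bool = False) -> set:
        return {
            t.key
            for t in self.truth
            if t.origin == origin and t.decoy == decoys and t.retained
            and (kind is None or t.kind == kind)
        }


def rng_streams(seed: int, n: int = 3) -> list:
    """Independent deterministic generator streams derived from one seed
    (order: reference, quad, dropout)."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


# ---------------------------------------------------------------------------
# reference generation
# ---------------------------------------------------------------------------


def _make_gene(
    gene_id: str, chrom: str, start: int, strand: str, rng
) -> GeneModel:
    """Build one multi-exon gene at ``start``: UTR + 2-4 CDS exons with
    every CDS piece a multiple of 3 bp."""
    n_exons = int(rng.integers(2, 5))
    utr5 = int(rng.integers(50, 200))
    utr3 = int(rng.integers(50, 200))
    cds_lens = [3 * int(rng.integers(30, 100)) for _ in range(n_exons)]
    introns = [int(rng.integers(200, 800)) for _ in range(n_exons - 1)]
    exons = []
    cds = []
    pos = start
    tx_start = pos
    for i, clen in enumerate(cds_lens):
        exon_start = pos
        if i == 0:
            pos += utr5
        cds.append((pos, pos + clen))
        pos += clen
        if i == n_exons - 1:
            pos += utr3
        exons.append((exon_start, pos))
        if i < n_exons - 1:
            pos += introns[i]
    return GeneModel(
        gene_id=gene_id,
        chrom=chrom,
        strand=strand,
        tx_start=tx_start,
        tx_end=pos,
        exons=tuple(exons),
        cds=tuple(cds),
    )


MAX_GENE_SPAN = 200 * 2 + 4 * 300 + 3 * 800  # utr + cds + introns, upper bound
GENE_GAP_MIN = 2500  # leaves room for a 2 kb promoter between genes


def generate_reference(config: SimulationConfig, rng=None) -> Reference:
    """Deterministically generate reference sequence, gene models and
    gene sets for one configuration."""
    config.validate()
    if rng is None:
        rng = rng_streams(config.seed)[0]
    chromosomes = {}
    for i in range(config.n_chromosomes):
        seq = rng.choice(list(_BASES), size=config.chromosome_length_bp)
        chromosomes[f"chr{i + 1}"] = "".join(seq)

    # genes, laid out left to right with randomized gaps
    per_chrom = [
        config.n_genes // config.n_chromosomes
        + (1 if i < config.n_genes % config.n_chromosomes else 0)
        for i in range(config.n_chromosomes)
    ]
    genes = []
    gene_no = 0
    for i, n_chrom_genes in enumerate(per_chrom):
        chrom = f"chr{i + 1}"
        length = config.chromosome_length_bp
        need = n_chrom_genes * (MAX_GENE_SPAN + GENE_GAP_MIN) + GENE_GAP_MIN
        if need > length:
            raise ConfigError(
                f"{chrom} ({length} bp) too short for {n_chrom_genes} genes "
                f"(needs >= {need} bp)"
            )
        slack = (length - need) // max(1, n_chrom_genes)
        pos = GENE_GAP_MIN
        for _ in range(n_chrom_genes):
            gene_no += 1
            pos += int(rng.integers(0, slack + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            gene = _make_gene(f"gene{gene_no:04d}", chrom, pos, strand, rng)
            genes.append(gene)
            pos = gene.tx_end + GENE_GAP_MIN

    # gene sets: consecutive blocks over a shuffled subset, with
    # configurable overlap between neighbouring sets
    order = list(rng.permutation(len(genes)))
    step = config.genes_per_set - config.gene_set_overlap
    sets = {}
    for s in range(config.n_gene_sets):
        lo = s * step
        members = [genes[j].gene_id for j in order[lo : lo + config.genes_per_set]]
        sets[f"pathway_{s + 1:02d}"] = frozenset(members)
    return Reference(
        chromosomes=chromosomes,
        genes=genes,
        gene_sets=GeneSetCollection(sets=sets),
    )


# ---------------------------------------------------------------------------
# variant planting
# ---------------------------------------------------------------------------


class _SscPlacer:
    """Collision-free positions for small variants (64 bp exclusion
    buckets with a pad wide enough to absorb left-alignment shifts)."""

    BUCKET = 64
    PAD = 40
    MAX_TRIES = 1000

    def __init__(self, contig_lengths: Mapping[str, int], rng,
                 exclude: Sequence[tuple] = ()):
        self.lengths = dict(contig_lengths)
        self.chroms = list(self.lengths)
        self.rng = rng
        self.used: dict[str, set[int]] = {c: set() for c in self.chroms}
        self.exclude = list(exclude)  # (chrom, lo, hi) no-go zones

    def _buckets(self, start: int, end: int) -> range:
        return range((start - self.PAD) // self.BUCKET, (end + self.PAD) // self.BUCKET + 1)

    def _excluded(self, chrom: str, start: int, end: int) -> bool:
        return any(
            c == chrom and start < hi and end > lo
            for c, lo, hi in self.exclude
        )

    def place(self, span: int = 1, region: tuple | None = None,
              avoid_excluded: bool = True) -> tuple[str, int]:
        """Reserve and return (chrom, pos0) for a variant of ``span``
        reference bases; ``region=(chrom, lo, hi)`` restricts placement."""
        for _ in range(self.MAX_TRIES):
            if region is not None:
                chrom, lo, hi = region
            else:
                chrom = self.chroms[int(self.rng.integers(len(self.chroms)))]
                lo, hi = 100, self.lengths[chrom] - 100 - span
            pos0 = int(self.rng.integers(lo, hi))
            if avoid_excluded and region is None and self._excluded(
                chrom, pos0, pos0 + span
            ):
                continue
            buckets = self._buckets(pos0, pos0 + span)
            if any(b in self.used[chrom] for b in buckets):
                continue
            self.used[chrom].update(buckets)
            return chrom, pos0
        raise ConfigError("could not place variant without collision; genome too dense")


class _EventPlacer:
    """Non-overlapping intervals for CNV/SV events so that distinct
    planted events can never spuriously satisfy reciprocal overlap."""

    MARGIN = 1500  # keeps distinct events' junctions > 500 bp apart even after jitter
    MAX_TRIES = 500

    def __init__(self, contig_lengths: Mapping[str, int], rng):
        self.lengths = dict(contig_lengths)
        self.chroms = list(self.lengths)
        self.rng = rng
        self.trees = {c: IntervalTree() for c in self.chroms}

    def place(self, length: int, chrom: str | None = None) -> tuple[str, int, int]:
        for _ in range(self.MAX_TRIES):
            c = chrom or self.chroms[int(self.rng.integers(len(self.chroms)))]
            start = int(self.rng.integers(1000, self.lengths[c] - length - 1000))
            if self.trees[c].overlap(start - self.MARGIN, start + length + self.MARGIN):
                continue
            self.trees[c].addi(start, start + length)
            return c, start, start + length
        raise ConfigError("could not place event without overlap; genome too dense")


def _draw_snv(seq: str, pos0: int, titv_ratio: float, rng) -> tuple[str, str]:
    ref = seq[pos0].upper()
    if rng.random() < titv_ratio / (titv_ratio + 1.0):
        alt = _TRANSITION[ref]
    else:
        alt = _TRANSVERSIONS[ref][int(rng.integers(2))]
    return ref, alt


def _draw_indel(seq: str, pos0: int, rng) -> tuple[str, str]:
    length = int(rng.integers(1, 9))
    if rng.random() < 0.5:  # insertion
        ref = seq[pos0].upper()
        ins = "".join(_BASES[int(b)] for b in rng.integers(0, 4, size=length))
        return ref, ref + ins
    ref = seq[pos0 : pos0 + 1 + length].upper()
    return ref, ref[0]


def _draw_blocksub(seq: str, pos0: int, rng) -> tuple[str, str]:
    ref_len = int(rng.integers(2, 6))
    alt_len = int(rng.integers(2, 6))
    ref = seq[pos0 : pos0 + ref_len].upper()
    for _ in range(100):
        alt = "".join(_BASES[int(b)] for b in rng.integers(0, 4, size=alt_len))
        if alt != ref and alt[0] != ref[0] and alt[-1] != ref[-1]:
            return ref, alt
    raise ConfigError("failed to draw a block substitution")


@dataclass
class _PlantedSsc:
    key: tuple  # (chrom, pos, ref, alt) normalized
    origin: str
    samples: frozenset
    cell_fraction: float = 1.0
    decoy: bool = False


def _plant_sscs(config: SimulationConfig, reference: Reference, rng) -> list[_PlantedSsc]:
    # genes of the spiked ("disease") pathways, interleaved across sets
    # so every spiked set accumulates hits even at low somatic counts;
    # all non-spiked placements avoid these genes' footprints so the
    # planted condition "spiked pathways are hit in the affected twin
    # only" holds exactly
    spike_genes: list[GeneModel] = []
    if config.spike_sets:
        by_id = {g.gene_id: g for g in reference.genes}
        per_set = [
            [by_id[m] for m in sorted(reference.gene_sets.sets[name])]
            for name in config.spike_sets
        ]
        for i in range(max(len(s) for s in per_set)):
            for members in per_set:
                if i < len(members):
                    spike_genes.append(members[i])
    exclude = [
        (g.chrom, g.tx_start - 2100, g.tx_end + 2100) for g in spike_genes
    ]
    placer = _SscPlacer(reference.contig_lengths, rng, exclude=exclude)
    planted: list[_PlantedSsc] = []
    both_twins = frozenset({"twin_affected", "twin_unaffected"})

    def plant(vtype: str, samples: frozenset, origin: str,
              cell_fraction: float = 1.0, decoy: bool = False,
              region: tuple | None = None) -> None:
        span = {"snv": 1, "indel": 10, "blocksub": 6}[vtype]
        chrom, pos0 = placer.place(span=span, region=region)
        seq = reference.chromosomes[chrom]
        if vtype == "snv":
            ref, alt = _draw_snv(seq, pos0, config.titv_ratio, rng)
        elif vtype == "indel":
            ref, alt = _draw_indel(seq, pos0, rng)
        else:
            ref, alt = _draw_blocksub(seq, pos0, rng)
        pos, ref, alt = normalize_variant(seq, pos0 + 1, ref, alt)
        planted.append(
            _PlantedSsc(
                key=(chrom, pos, ref, alt),
                origin=origin,
                samples=samples,
                cell_fraction=cell_fraction,
                decoy=decoy,
            )
        )

    # transmitted pools: parent + both twins
    for parent, origin in (("father", "transmitted_father"),
                           ("mother", "transmitted_mother")):
        samples = frozenset({parent}) | both_twins
        for _ in range(config.n_inherited_snv):
            plant("snv", samples, origin)
        for _ in range(config.n_inherited_indel):
            plant("indel", samples, origin)
        for _ in range(config.n_inherited_blocksub):
            plant("blocksub", samples, origin)

    # germline de novo: both twins, no parent
    for _ in range(config.n_germline_denovo):
        plant("snv", both_twins, "germline_denovo")

    # post-zygotic somatic variants, one twin each, with mosaic fractions
    n_indel = round(SOMATIC_INDEL_FRAC * config.n_somatic_per_twin)
    n_bs = round(SOMATIC_BLOCKSUB_FRAC * config.n_somatic_per_twin)
    n_snv = config.n_somatic_per_twin - n_indel - n_bs
    for role, origin in (("twin_affected", "postzygotic_twinA"),
                         ("twin_unaffected", "postzygotic_twinB")):
        samples = frozenset({role})
        n_spiked = 0
        if role == "twin_affected" and spike_genes:
            n_spiked = round(config.spike_fraction * n_snv)
        for i in range(n_snv):
            if config.mosaic_model[0] == "fixed":
                cf = float(config.mosaic_model[1])
            else:
                cf = float(rng.beta(config.mosaic_model[1], config.mosaic_model[2]))
                cf = min(max(cf, 1e-3), 1.0)
            region = None
            if i < n_spiked:
                gene = spike_genes[i % len(spike_genes)]
                region = (gene.chrom, gene.tx_start + 1, gene.tx_end - 12)
            plant("snv", samples, origin, cell_fraction=cf, region=region)
        for _ in range(n_indel):
            plant("indel", samples, origin)
        for _ in range(n_bs):
            plant("blocksub", samples, origin)

    # discordant transmitted decoys: parent + one twin only
    for role in ("twin_affected", "twin_unaffected"):
        for j in range(config.n_inherited_discordant):
            parent = "father" if j % 2 == 0 else "mother"
            plant(
                "snv",
                frozenset({parent, role}),
                f"transmitted_{parent}",
            )

    # low-quality decoys: one twin only, quality below the cutoff
    for role, origin in (("twin_affected", "postzygotic_twinA"),
                         ("twin_unaffected", "postzygotic_twinB")):
        for _ in range(config.n_lowq_decoys):
            plant("snv", frozenset({role}), origin, decoy=True)
    return planted


# ---------------------------------------------------------------------------
# CNV / SV planting
# ---------------------------------------------------------------------------


@dataclass
class _PlantedEvent:
    kind: str  # cnv | sv
    base: object  # CnvCall or SvEvent with sample_id="" (carrier coords)
    origin: str
    samples: frozenset


_CNV_STATES = (0, 1, 3, 4)

_SV_LENGTHS = {
    "deletion": (500, 3000),
    "tandem_duplication": (1000, 8000),
    "distal_duplication": (1000, 5000),
    "inversion": (2000, 15000),
}


def _plant_events(config: SimulationConfig, reference: Reference, rng) -> list[_PlantedEvent]:
    placer = _EventPlacer(reference.contig_lengths, rng)
    if config.spike_sets:
        # keep CNV/SV events off the spiked pathways' genes: the planted
        # condition is that those pathways are hit by the affected
        # twin's somatic small variants only
        spiked = set().union(
            *(reference.gene_sets.sets[n] for n in config.spike_sets)
        )
        for g in reference.genes:
            if g.gene_id in spiked:
                placer.trees[g.chrom].addi(g.tx_start - 2100, g.tx_end + 2100)
    planted: list[_PlantedEvent] = []
    both_twins = frozenset({"twin_affected", "twin_unaffected"})

    def plant_cnv(samples: frozenset, origin: str) -> None:
        length = int(rng.integers(1000, 4000))
        chrom, start, end = placer.place(length)
        state = int(_CNV_STATES[int(rng.integers(len(_CNV_STATES)))])
        base = CnvCall(sample_id="", chrom=chrom, start=start, end=end,
                       copy_state=state)
        planted.append(_PlantedEvent("cnv", base, origin, samples))

    def plant_sv(category: str, samples: frozenset, origin: str) -> None:
        if category == "interchromosomal":
            c1, p1, _ = placer.place(1)
            for _ in range(_EventPlacer.MAX_TRIES):
                c2, p2, _ = placer.place(1)
                if c2 != c1:
                    break
            else:
                raise ConfigError("need >= 2 chromosomes for interchromosomal events")
            base = SvEvent(sample_id="", category=category, chrom=c1, start=p1,
                           chrom2=c2, pos2=p2,
                           orientation="forward" if rng.random() < 0.5 else "reverse")
        else:
            lo, hi = _SV_LENGTHS[category]
            length = int(rng.integers(lo, hi))
            chrom, start, end = placer.place(length)
            base = SvEvent(sample_id="", category=category, chrom=chrom,
                           start=start, end=end,
                           orientation="forward" if rng.random() < 0.5 else "reverse")
        planted.append(_PlantedEvent("sv", base, origin, samples))

    # shared events: both twins + the transmitting parent
    for j in range(config.n_cnv_shared):
        parent = "father" if j % 2 == 0 else "mother"
        plant_cnv(both_twins | {parent}, f"transmitted_{parent}")
    for category, n in config.n_sv_shared_by_category.items():
        for j in range(n):
            parent = "father" if j % 2 == 0 else "mother"
            plant_sv(category, both_twins | {parent}, f"transmitted_{parent}")

    # unique events per twin
    for role, origin_dn in (("twin_affected", "postzygotic_twinA"),
                            ("twin_unaffected", "postzygotic_twinB")):
        for _ in range(config.n_cnv_unique):
            plant_cnv(frozenset({role}), origin_dn)
        for j in range(config.n_cnv_unique_inherited):
            parent = "father" if j % 2 == 0 else "mother"
            plant_cnv(frozenset({role, parent}), f"transmitted_{parent}")
        for category, n in config.n_sv_unique_by_category.items():
            for _ in range(n):
                plant_sv(category, frozenset({role}), origin_dn)
        for category, n in config.n_sv_unique_inherited_by_category.items():
            for j in range(n):
                parent = "father" if j % 2 == 0 else "mother"
                plant_sv(category, frozenset({role, parent}),
                         f"transmitted_{parent}")
    return planted


def _jitter_event(base, rng, frac: float = 0.08):
    """Shift a non-carrier sample's copy of an event by a small fraction
    of its length (junctions: < 200 bp), preserving equivalence under
    the matching rules."""
    if isinstance(base, CnvCall):
        shift = int(rng.integers(-int(frac * base.length), int(frac * base.length) + 1))
        return dataclasses.replace(base, start=base.start + shift, end=base.end + shift)
    if base.category == "interchromosomal":
        d1 = int(rng.integers(-200, 201))
        d2 = int(rng.integers(-200, 201))
        return dataclasses.replace(base, start=base.start + d1, pos2=base.pos2 + d2)
    length = base.end - base.start
    shift = int(rng.integers(-int(frac * length), int(frac * length) + 1))
    return dataclasses.replace(base, start=base.start + shift, end=base.end + shift)


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------


def simulate_quad(config: SimulationConfig, reference: Reference, rng=None) -> SimulatedQuad:
    """Plant all variant classes and assemble the four per-sample call
    sets plus the ground-truth table (noiseless: every planted variant
    is emitted in exactly its expected samples)."""
    config.validate()
    if rng is None:
        rng = rng_streams(config.seed)[1]
    sscs = _plant_sscs(config, reference, rng)
    events = _plant_events(config, reference, rng)

    samples = {
        role: SampleCallset(sample_id=f"{config.family_id}-{role}")
        for role in ROLES
    }
    # emit SSC calls per sample in fixed role order (deterministic
    # depth/quality draw order)
    for role in ROLES:
        callset = samples[role]
        for planted in sscs:
            if role not in planted.samples:
                continue
            chrom, pos, ref, alt = planted.key
            depth = int(rng.poisson(config.depth_mean))
            quality = (
                float(config.quality_low) if planted.decoy
                else float(config.quality_high)
            )
            callset.small.append(
                SmallVariantCall(
                    sample_id=callset.sample_id,
                    chrom=chrom, pos=pos, ref=ref, alt=alt,
                    depth=depth, quality=quality,
                )
            )
        callset.small.sort(key=lambda c: c.key)
    # emit events; the first expected twin carries the un-jittered base
    # coordinates (so truth keys are directly comparable), other samples
    # carry a jittered copy
    for planted in events:
        carrier_order = [r for r in ROLES if r in planted.samples]
        twins = [r for r in carrier_order if r.startswith("twin")]
        carrier = twins[0] if twins else carrier_order[0]
        for role in carrier_order:
            base = planted.base
            emitted = base if role == carrier else _jitter_event(base, rng)
            emitted = dataclasses.replace(
                emitted, sample_id=samples[role].sample_id
            )
            if planted.kind == "cnv":
                samples[role].cnv.append(emitted)
            else:
                samples[role].sv.append(emitted)
    for role in ROLES:
        samples[role].cnv.sort(key=lambda c: (c.chrom, c.start))
        samples[role].sv.sort(key=lambda e: (e.category, e.chrom, e.start))

    truth = [
        GroundTruthRecord(
            kind="ssc", key=p.key, origin=p.origin,
            cell_fraction=p.cell_fraction, expected_samples=p.samples,
            decoy=p.decoy,
        )
        for p in sscs
    ]
    for p in events:
        if p.kind == "cnv":
            key = ("cnv", p.base.chrom, p.base.start, p.base.end, p.base.copy_state)
        elif p.base.category == "interchromosomal":
            key = ("sv", p.base.category, p.base.chrom, p.base.start,
                   p.base.chrom2, p.base.pos2)
        else:
            key = ("sv", p.base.category, p.base.chrom, p.base.start, p.base.end)
        truth.append(
            GroundTruthRecord(
                kind=p.kind, key=key, origin=p.origin,
                cell_fraction=1.0, expected_samples=p.samples,
            )
        )
    return SimulatedQuad(quad=QuadCallsets(samples=samples), truth=truth)


# ---------------------------------------------------------------------------
# mosaic dropout
# ---------------------------------------------------------------------------


def retention_probability(depth: float, cell_fraction: float, floor: int = 3) -> float:
    """Probability that a post-zygotic variant at the given cell fraction
    is detected: P(Binomial(depth, cell_fraction / 2) >= floor).

    The allele fraction of a heterozygous somatic variant present in a
    fraction f of cells is f/2."""
    if not 0 <= cell_fraction <= 1:
        raise ConfigError("cell fraction must be in [0, 1]")
    return float(binom.sf(floor - 1, int(depth), cell_fraction / 2.0))


def apply_mosaic_dropout(
    sim: SimulatedQuad, config: SimulationConfig, rng=None
) -> SimulatedQuad:
    """Degrade a noiseless simulation: each post-zygotic small variant is
    kept only if binomially sampled supporting reads (at its call depth
    and allele fraction cell_fraction/2) reach the detection floor.

    Returns a new :class:`SimulatedQuad`; retention is recorded in the
    truth table."""
    if rng is None:
        rng = rng_streams(config.seed)[2]
    postzygotic = {
        t.key: t for t in sim.truth
        if t.kind == "ssc" and t.origin.startswith("postzygotic") and not t.decoy
    }
    retained: dict[tuple, bool] = {}
    new_samples = {}
    for role in ROLES:
        if role not in sim.quad.samples:
            continue
        old = sim.quad.samples[role]
        kept = []
        for call in old.small:
            t = postzygotic.get(call.key)
            if t is None or role not in t.expected_samples:
                kept.append(call)
                continue
            support = int(rng.binomial(call.depth, t.cell_fraction / 2.0))
            ok = support >= config.detection_floor
            retained[call.key] = ok
            if ok:
                kept.append(call)
        new_samples[role] = SampleCallset(
            sample_id=old.sample_id, small=kept, cnv=list(old.cnv), sv=list(old.sv)
        )
    new_truth = [
        dataclasses.replace(t, retained=retained.get(t.key, t.retained))
        if t.key in retained else t
        for t in sim.truth
    ]
    return SimulatedQuad(quad=QuadCallsets(samples=new_samples), truth=new_truth)


# ---------------------------------------------------------------------------
# on-disk round trip
# ---------------------------------------------------------------------------


def write_fasta(chromosomes: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in chromosomes.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_gff3(genes: Sequence[GeneModel], path: str | Path) -> None:
    """Write gene models as GFF3 (gene -> mRNA -> exon/CDS)."""
    lines = ["##gff-version 3"]
    for g in genes:
        tx_id = f"{g.gene_id}.t1"
        lines.append(
            f"{g.chrom}\ttwinquad\tgene\t{g.tx_start + 1}\t{g.tx_end}\t.\t"
            f"{g.strand}\t.\tID={g.gene_id}"
        )
        lines.append(
            f"{g.chrom}\ttwinquad\tmRNA\t{g.tx_start + 1}\t{g.tx_end}\t.\t"
            f"{g.strand}\t.\tID={tx_id};Parent={g.gene_id}"
        )
        for i, (s, e) in enumerate(g.exons, 1):
            lines.append(
                f"{g.chrom}\ttwinquad\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                f"ID={tx_id}.exon{i};Parent={tx_id}"
            )
        cds_order = g.cds if g.strand == "+" else tuple(reversed(g.cds))
        cum = 0
        phased = []
        for s, e in cds_order:
            phase = (3 - cum % 3) % 3
            phased.append((s, e, phase))
            cum += e - s
        for i, (s, e, phase) in enumerate(sorted(phased), 1):
            lines.append(
                f"{g.chrom}\ttwinquad\tCDS\t{s + 1}\t{e}\t.\t{g.strand}\t{phase}\t"
                f"ID={tx_id}.cds{i};Parent={tx_id}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


def write_truth_table(truth: Sequence[GroundTruthRecord], path: str | Path) -> None:
    lines = ["kind\tkey\torigin\tcell_fraction\texpected_samples\tdecoy\tretained"]
    for t in truth:
        key = ":".join(str(x) for x in t.key)
        samples = ",".join(sorted(t.expected_samples))
        lines.append(
            f"{t.kind}\t{key}\t{t.origin}\t{t.cell_fraction:.6g}\t{samples}\t"
            f"{int(t.decoy)}\t{int(t.retained)}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_simulation(
    reference: Reference,
    sim: SimulatedQuad,
    config: SimulationConfig,
    outdir: str | Path,
) -> Path:
    """Write the full simulated family to a directory: reference FASTA,
    gene models GFF3, gene sets GMT, per-sample VCF + CNV/SV tables,
    the truth table and a YAML echo of the configuration plus role map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(reference.chromosomes, outdir / "reference.fa")
    write_gff3(reference.genes, outdir / "genes.gff3")
    write_gmt(reference.gene_sets, outdir / "gene_sets.gmt")
    write_truth_table(sim.truth, outdir / "truth.tsv")
    roles = {}
    for role, callset in sim.quad.samples.items():
        write_small_variants(
            callset.small, outdir / f"{role}.vcf", callset.sample_id,
            contigs=reference.contig_lengths,
        )
        write_cnv_table(callset.cnv, outdir / f"{role}.cnv.tsv")
        write_sv_table(callset.sv, outdir / f"{role}.sv.tsv")
        roles[role] = {
            "sample_id": callset.sample_id,
            "vcf": f"{role}.vcf",
            "cnv": f"{role}.cnv.tsv",
            "sv": f"{role}.sv.tsv",
        }
    manifest = {
        "family_id": config.family_id,
        "reference": "reference.fa",
        "genes": "genes.gff3",
        "gene_sets": "gene_sets.gmt",
        "truth": "truth.tsv",
        "samples": roles,
        "config": dataclasses.asdict(config),
    }
    manifest["config"]["mosaic_model"] = list(config.mosaic_model)
    manifest["config"]["spike_sets"] = list(config.spike_sets)
    (outdir / "quad.yaml").write_text(yaml.safe_dump(manifest, sort_keys=True))
    return outdir / "quad.yaml"
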