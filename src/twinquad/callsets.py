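"""Reading, writing and canonicalization of per-sample call sets.

Three call classes are handled:

* small sequence changes (SSCs): SNVs, insertions, deletions and block
  substitutions, exchanged as VCF 4.2;
* copy-number variants (CNVs): genomic intervals with an integer copy
  state, exchanged as a tab-separated table;
* structural variants (SVs): interval- or junction-based events in five
  categories, exchanged as a tab-separated table.

Coordinate conventions: VCF positions are 1-based (the VCF standard);
CNV/SV intervals are 0-based half-open, so the length of an event is
always ``end - start``.

Variant identity across samples is defined by the canonical key
``(chrom, pos, ref, alt)`` of the *normalized* representation
(left-aligned, shared flanking bases trimmed).  Two calls in different
samples denote the same variant iff their keys are equal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pysam

from .errors import ConfigError, ContractViolation, ParseError

logger = logging.getLogger(__name__)

SSC_CLASSES = ("SNV", "insertion", "deletion", "substitution")
SV_CATEGORIES = (
    "deletion",
    "tandem_duplication",
    "distal_duplication",
    "interchromosomal",
    "inversion",
)
ROLES = ("father", "mother", "twin_affected", "twin_unaffected")

#: columns of the CNV interchange table
CNV_COLUMNS = ["sample", "chrom", "start", "end", "copy_state", "type"]
#: columns of the SV interchange table; interchromosomal events use
#: (chromA, startA) and (chromB, posB) as their two junctions
SV_COLUMNS = [
    "sample",
    "category",
    "chromA",
    "startA",
    "endA",
    "chromB",
    "posB",
    "orientation",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


def variant_class(ref: str, alt: str) -> str:
    """Classify a normalized ref/alt pair as SNV / insertion / deletion /
    (block) substitution."""
    if ref == alt:
        raise ValueError(f"ref == alt ({ref!r}); not a variant")
    if len(ref) == 1 and len(alt) == 1:
        return "SNV"
    if len(ref) < len(alt) and alt.startswith(ref):
        return "insertion"
    if len(alt) < len(ref) and ref.startswith(alt):
        return "deletion"
    return "substitution"


@dataclass(frozen=True)
class SmallVariantCall:
    """One called small sequence change in one sample.

    ``pos`` is 1-based (VCF convention); ``depth`` is ``None`` when the
    caller reported no read depth, in which case the call can never pass
    the high-confidence filter.
    """

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    depth: int | None = None
    quality: float | None = None

    def __post_init__(self):
        if self.ref == self.alt:
            raise ValueError(f"ref == alt at {self.chrom}:{self.pos}")

    @property
    def vclass(self) -> str:
        return variant_class(self.ref, self.alt)

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


def variant_key(call: SmallVariantCall) -> tuple[str, int, str, str]:
    """Canonical identity of a (normalized) call: ``(chrom, pos, ref, alt)``.

    Key equality across samples defines "same variant" throughout the
    pipeline.
    """
    return call.key


@dataclass(frozen=True)
class CnvCall:
    """A copy-number variant: a 0-based half-open interval with an integer
    copy state (0-10) relative to the diploid state 2."""

    sample_id: str
    chrom: str
    start: int
    end: int
    copy_state: int

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(
                f"CNV end must exceed start ({self.chrom}:{self.start}-{self.end})"
            )
        if not 0 <= self.copy_state <= 10:
            raise ValueError(f"copy state {self.copy_state} outside 0-10")
        if self.copy_state == 2:
            raise ValueError("copy state 2 is the diploid reference, not a CNV")

    @property
    def cnv_type(self) -> str:
        return "amp" if self.copy_state > 2 else "del"

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def interval(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


@dataclass(frozen=True)
class SvEvent:
    """A structural variant event.

    Interval categories (deletion, tandem/distal duplication, inversion)
    carry ``(chrom, start, end)``; interchromosomal events carry two
    junctions ``(chrom, start)`` and ``(chrom2, pos2)`` on different
    chromosomes, with ``end`` unused.
    """

    sample_id: str
    category: str
    chrom: str
    start: int
    end: int | None = None
    chrom2: str | None = None
    pos2: int | None = None
    orientation: str = "forward"

    def __post_init__(self):
        if self.category not in SV_CATEGORIES:
            raise ValueError(f"unknown SV category {self.category!r}")
        if self.orientation not in ("forward", "reverse"):
            raise ValueError(f"unknown orientation {self.orientation!r}")
        if self.category == "interchromosomal":
            if self.chrom2 is None or self.pos2 is None:
                raise ValueError("interchromosomal event needs two junctions")
            if self.chrom2 == self.chrom:
                raise ValueError(
                    "interchromosomal junctions must lie on different chromosomes"
                )
        else:
            if self.end is None or self.end <= self.start:
                raise ValueError(
                    f"interval SV needs end > start ({self.chrom}:{self.start}-{self.end})"
                )

    @property
    def interval(self) -> tuple[str, int, int]:
        if self.category == "interchromosomal":
            raise ContractViolation("interchromosomal events have no interval")
        return (self.chrom, self.start, self.end)

    @property
    def junctions(self) -> tuple[tuple[str, int], tuple[str, int]]:
        if self.category != "interchromosomal":
            raise ContractViolation("only interchromosomal events have junctions")
        return ((self.chrom, self.start), (self.chrom2, self.pos2))


@dataclass
class SampleCallset:
    """All calls of one sample."""

    sample_id: str
    small: list[SmallVariantCall] = field(default_factory=list)
    cnv: list[CnvCall] = field(default_factory=list)
    sv: list[SvEvent] = field(default_factory=list)


@dataclass
class QuadCallsets:
    """Role-resolved call sets of a twin family.

    Twin roles are always present; parents are either both present (quad
    mode) or both absent (twin-only mode, as when no parental genomes
    were sequenced).
    """

    samples: dict[str, SampleCallset]

    def __post_init__(self):
        for role in ("twin_affected", "twin_unaffected"):
            if role not in self.samples:
                raise ConfigError(f"missing required twin role {role!r}")
        has_f = "father" in self.samples
        has_m = "mother" in self.samples
        if has_f != has_m:
            raise ConfigError("parents must be both present or both absent")

    @property
    def parents_present(self) -> bool:
        return "father" in self.samples

    def __getitem__(self, role: str) -> SampleCallset:
        return self.samples[role]


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------


def normalize_variant(
    seq: str, pos: int, ref: str, alt: str
) -> tuple[int, str, str]:
    """Return the canonical (left-aligned, trimmed) representation of a
    variant on chromosome sequence ``seq``.

    ``pos`` is 1-based.  The algorithm repeatedly trims a shared terminal
    base (extending leftwards from the reference when an allele would
    become empty) and finally trims shared leading bases; this is the
    standard left-alignment procedure used by VCF normalizers.
    """
    ref = ref.upper()
    alt = alt.upper()
    if ref == alt:
        raise ValueError("ref == alt; not a variant")
    if seq[pos - 1 : pos - 1 + len(ref)].upper() != ref:
        raise ValueError(
            f"ref allele {ref!r} does not match reference at position {pos}"
        )
    while True:
        if ref and alt and ref[-1] == alt[-1] and (len(ref) > 1 or len(alt) > 1):
            ref, alt = ref[:-1], alt[:-1]
            continue
        if not ref or not alt:
            if pos == 1:
                raise ValueError("allele empty at contig start; cannot left-extend")
            base = seq[pos - 2].upper()
            ref, alt, pos = base + ref, base + alt, pos - 1
            continue
        break
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt, pos = ref[1:], alt[1:], pos + 1
    return pos, ref, alt


# ---------------------------------------------------------------------------
# VCF I/O
# ---------------------------------------------------------------------------


def read_small_variants(
    path: str | Path,
    sample_id: str,
    reference: Mapping[str, str] | None = None,
) -> list[SmallVariantCall]:
    """Read one sample's small-variant calls from a VCF 4.2 file.

    Multi-allelic records are split into one call per alternate allele.
    When ``reference`` (a mapping chrom -> sequence, e.g. a
    :class:`pyfaidx.Fasta`) is given, every call is normalized so that
    canonical keys are comparable across files.  Depth is taken from the
    first sample's ``DP`` FORMAT field, falling back to ``INFO/DP``;
    calls without depth are kept but flagged unknown (``depth=None``),
    which fails the high-confidence filter.
    """
    path = Path(path)
    calls: list[SmallVariantCall] = []
    n_record = 0
    seq_cache: dict[str, str] = {}

    def chrom_seq(chrom: str) -> str:
        if chrom not in seq_cache:
            seq_cache[chrom] = str(reference[chrom])
        return seq_cache[chrom]

    try:
        with pysam.VariantFile(str(path)) as vcf:
            vcf_samples = list(vcf.header.samples)
            for rec in vcf:
                n_record += 1
                depth = None
                if vcf_samples:
                    fmt = rec.samples[vcf_samples[0]]
                    if "DP" in fmt and fmt["DP"] is not None:
                        depth = int(fmt["DP"])
                if depth is None and "DP" in rec.info:
                    depth = int(rec.info["DP"])
                quality = float(rec.qual) if rec.qual is not None else None
                for alt in rec.alts or ():
                    if alt in (".", "<NON_REF>") or alt.startswith("<"):
                        continue
                    pos, ref_a, alt_a = rec.pos, rec.ref.upper(), alt.upper()
                    if reference is not None:
                        pos, ref_a, alt_a = normalize_variant(
                            chrom_seq(rec.chrom), pos, ref_a, alt_a
                        )
                    calls.append(
                        SmallVariantCall(
                            sample_id=sample_id,
                            chrom=rec.chrom,
                            pos=pos,
                            ref=ref_a,
                            alt=alt_a,
                            depth=depth,
                            quality=quality,
                        )
                    )
    except (ValueError, OSError) as exc:
        raise ParseError(
            f"{path}: malformed VCF near record {n_record + 1}: {exc}"
        ) from exc
    return calls


def write_small_variants(
    calls: Sequence[SmallVariantCall],
    path: str | Path,
    sample_id: str,
    contigs: Mapping[str, int] | None = None,
) -> None:
    """Write calls as a minimal single-sample VCF 4.2 (QUAL = call quality,
    FORMAT fields GT and DP).  Records are sorted by (chrom, pos, alt)."""
    path = Path(path)
    lines = ["##fileformat=VCFv4.2"]
    if contigs:
        for name, length in contigs.items():
            lines.append(f"##contig=<ID={name},length={length}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample_id
    )
    for c in sorted(calls, key=lambda c: (c.chrom, c.pos, c.ref, c.alt)):
        qual = "." if c.quality is None else f"{c.quality:g}"
        dp = "." if c.depth is None else str(c.depth)
        lines.append(
            f"{c.chrom}\t{c.pos}\t.\t{c.ref}\t{c.alt}\t{qual}\tPASS\t.\tGT:DP\t0/1:{dp}"
        )
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# CNV / SV tables
# ---------------------------------------------------------------------------


def read_cnv_table(path: str | Path) -> list[CnvCall]:
    """Read CNV calls from a tab-separated table (columns: sample, chrom,
    start, end, copy_state, type)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample": str})
    missing = set(CNV_COLUMNS[:5]) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: CNV table missing columns {sorted(missing)}")
    calls = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            calls.append(
                CnvCall(
                    sample_id=row.sample,
                    chrom=row.chrom,
                    start=int(row.start),
                    end=int(row.end),
                    copy_state=int(row.copy_state),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ParseError(f"{path}: line {i}: {exc}") from exc
    return calls


def write_cnv_table(calls: Sequence[CnvCall], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            (c.sample_id, c.chrom, c.start, c.end, c.copy_state, c.cnv_type)
            for c in calls
        ],
        columns=CNV_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_sv_table(path: str | Path) -> list[SvEvent]:
    """Read SV events from a tab-separated table (columns: sample, category,
    chromA, startA, endA, chromB, posB, orientation)."""
    df = pd.read_csv(
        path, sep="\t", dtype={"chromA": str, "chromB": str, "sample": str}
    )
    missing = set(SV_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: SV table missing columns {sorted(missing)}")
    events = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            end = None if pd.isna(row.endA) else int(row.endA)
            chrom2 = None if pd.isna(row.chromB) else str(row.chromB)
            pos2 = None if pd.isna(row.posB) else int(row.posB)
            events.append(
                SvEvent(
                    sample_id=row.sample,
                    category=row.category,
                    chrom=row.chromA,
                    start=int(row.startA),
                    end=end,
                    chrom2=chrom2,
                    pos2=pos2,
                    orientation=row.orientation,
                )
            )
        except (ValueError, TypeError) as exc:
            raise ParseError(f"{path}: line {i}: {exc}") from exc
    return events


def write_sv_table(events: Sequence[SvEvent], path: str | Path) -> None:
    rows = []
    for e in events:
        rows.append(
            (
                e.sample_id,
                e.category,
                e.chrom,
                e.start,
                e.end if e.end is not None else "",
                e.chrom2 if e.chrom2 is not None else "",
                e.pos2 if e.pos2 is not None else "",
                e.orientation,
            )
        )
    pd.DataFrame(rows, columns=SV_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------


def filter_high_confidence(
    calls: Iterable[SmallVariantCall],
    min_depth: int = 50,
    min_quality: float = 100.0,
) -> list[SmallVariantCall]:
    """Apply the stringent high-confidence filter: keep calls with read
    depth >= ``min_depth`` and call quality >= ``min_quality``.

    Thresholds are inclusive (a call at exactly depth 50 / quality 100
    passes).  Calls with unknown depth or quality are removed.  Input
    order is preserved; the number removed is logged.
    """
    if min_depth < 0 or min_quality < 0:
        raise ConfigError("filter thresholds must be non-negative")
    kept = [
        c
        for c in calls
        if c.depth is not None
        and c.quality is not None
        and c.depth >= min_depth
        and c.quality >= min_quality
    ]
    n_in = len(calls) if hasattr(calls, "__len__") else None
    if n_in is not None:
        logger.info(
            "high-confidence filter: kept %d of %d calls (removed %d)",
            len(kept),
            n_in,
            n_in - len(kept),
        )
    return kept


def dedupe_by_key(
    calls: Sequence[SmallVariantCall],
) -> list[SmallVariantCall]:
    """Drop duplicate canonical keys within one sample, keeping the first
    occurrence and warning about the rest."""
    seen: set[tuple] = set()
    out = []
    dropped = 0
    for c in calls:
        if c.key in seen:
            dropped += 1
            continue
        seen.add(c.key)
        out.append(c)
    if dropped:
        logger.warning("dropped %d duplicate call(s) within one sample", dropped)
    return out
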