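"""Liability-threshold comparison of per-individual pathway profiles.

Under a threshold model, pathways enriched in *both* members of a
discordant twin pair represent shared genetic predisposition (GP) that
is by itself insufficient for disease, while pathways unique to the
affected twin represent the additional load that pushed that twin over
the liability threshold (GPD, "genetic predisposition that led to
disease").  Intersecting the affected twins' GPD candidates across
unrelated families, then removing anything enriched in any unaffected
co-twin, isolates pathways recurrently and exclusively hit in patients.

All comparisons are by pathway-name membership of top-k lists;
names are canonicalized (lowercase, collapsed whitespace) before any
set operation, and near-duplicate names that differ after
canonicalization are reported rather than silently merged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .enrichment import GeneSetCollection, canonical_pathway_name
from .errors import ConfigError, ContractViolation

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PathwayProfile:
    """One individual's ordered top-k enriched pathway names."""

    individual_id: str
    family: str
    role: str  # affected | unaffected
    pathways: tuple[str, ...]

    def __post_init__(self):
        if self.role not in ("affected", "unaffected"):
            raise ConfigError(f"bad role {self.role!r}")

    @property
    def name_set(self) -> frozenset[str]:
        return frozenset(canonical_pathway_name(p) for p in self.pathways)


@dataclass
class ThresholdComparison:
    """Within-family GP/GPD labels plus the cross-family intersection."""

    gp: dict[str, frozenset[str]] = field(default_factory=dict)
    gpd: dict[str, frozenset[str]] = field(default_factory=dict)
    shared_affected: frozenset[str] = frozenset()
    final_gpd: frozenset[str] = frozenset()


def label_gp_gpd(
    affected: PathwayProfile, unaffected: PathwayProfile
) -> tuple[frozenset[str], frozenset[str]]:
    """Within one family: GP = affected ∩ unaffected, GPD = affected \\
    unaffected (canonical name sets)."""
    if affected.family != unaffected.family:
        raise ContractViolation("GP/GPD labelling needs co-twins of one family")
    a, u = affected.name_set, unaffected.name_set
    return a & u, a - u


def cross_family(profiles: Sequence[PathwayProfile]) -> ThresholdComparison:
    """Compare pathway profiles across families.

    ``shared_affected`` is the intersection of all affected twins'
    top-k name sets and ``final_gpd`` removes anything present in any
    unaffected twin's list.  With more than two families the
    intersection/union generalization is applied.  Unaffected profiles
    are optional (their absence removes nothing).
    """
    affected = [p for p in profiles if p.role == "affected"]
    unaffected = [p for p in profiles if p.role == "unaffected"]
    if len(affected) < 2:
        raise ContractViolation(
            "cross-family comparison needs affected profiles from >= 2 families"
        )
    comparison = ThresholdComparison()
    by_family: dict[str, dict[str, PathwayProfile]] = {}
    for p in profiles:
        by_family.setdefault(p.family, {})[p.role] = p
    for family, members in sorted(by_family.items()):
        if "affected" in members and "unaffected" in members:
            gp, gpd = label_gp_gpd(members["affected"], members["unaffected"])
            comparison.gp[family] = gp
            comparison.gpd[family] = gpd
    shared = affected[0].name_set
    for p in affected[1:]:
        shared &= p.name_set
    removed = frozenset()
    for p in unaffected:
        removed |= p.name_set
    comparison.shared_affected = frozenset(shared)
    comparison.final_gpd = frozenset(shared - removed)
    return comparison


def gene_overlap_report(
    final_gpd: frozenset[str],
    affected_genes: Mapping[str, Sequence[str]],
    collection: GeneSetCollection | None = None,
) -> dict[str, dict]:
    """Per-pathway gene table for the final GPD pathways.

    ``affected_genes`` maps each patient id to either a flat affected-
    gene list (intersected with the pathway's members, which requires
    ``collection``) or a mapping pathway -> member gene list.  The
    report gives each patient's affected member genes and their
    cross-patient intersection.
    """
    report: dict[str, dict] = {}
    canon_sets = (
        {canonical_pathway_name(n): m for n, m in collection.sets.items()}
        if collection is not None
        else None
    )
    for pathway in sorted(final_gpd):
        per_patient: dict[str, frozenset[str]] = {}
        for patient, genes in affected_genes.items():
            if isinstance(genes, Mapping):
                lookup = {canonical_pathway_name(n): v for n, v in genes.items()}
                members = frozenset(lookup.get(pathway, ()))
            else:
                if canon_sets is None:
                    raise ConfigError(
                        "flat gene lists need the gene-set collection"
                    )
                if pathway not in canon_sets:
                    raise ConfigError(
                        f"pathway {pathway!r} absent from the collection"
                    )
                members = frozenset(genes) & canon_sets[pathway]
            per_patient[patient] = members
        common = None
        for members in per_patient.values():
            common = members if common is None else (common & members)
        report[pathway] = {
            "per_patient": per_patient,
            "common": common if common is not None else frozenset(),
        }
    return report


def report_near_duplicates(profiles: Sequence[PathwayProfile]) -> list[tuple[str, str]]:
    """Pairs of raw pathway names that collide after canonicalization —
    surfaced so naming variants are reviewed, never silently merged."""
    seen: dict[str, str] = {}
    dupes = []
    for p in profiles:
        for raw in p.pathways:
            canon = canonical_pathway_name(raw)
            if canon in seen and seen[canon] != raw:
                dupes.append((seen[canon], raw))
            else:
                seen.setdefault(canon, raw)
    if dupes:
        logger.warning("pathway name variants detected: %s", dupes)
    return dupes
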