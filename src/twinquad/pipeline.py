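"""End-to-end orchestration of the discordance analysis.

For each family: read the quad's call sets, apply the high-confidence
filter, partition each twin's small variants into shared/unshared and
inherited/de-novo (or provisional de novo without parents), run the
reciprocal-overlap classification for CNVs and SVs, annotate the
de novo variants with overlapping genes, build each twin's affected-gene
list and rank pathway over-representation.  Across families, intersect
the affected twins' top-k pathway lists and subtract anything enriched
in an unaffected co-twin to obtain the final GPD pathways.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml
from pyfaidx import Fasta

from . import annotate as ann
from . import enrichment as enr
from . import sharing, svmatch, threshold
from .callsets import (
    QuadCallsets,
    SampleCallset,
    read_cnv_table,
    read_small_variants,
    read_sv_table,
)
from .errors import ConfigError

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All thresholds of the analysis in one place.

    Defaults are the standard operating point: read depth >= 50 and
    call quality >= 100 for high-confidence small variants, 50%
    reciprocal overlap and a 500 bp junction bound for CNV/SV identity,
    top-20 pathway lists, a 2 kb promoter and a 2 bp splice window.
    """

    min_depth: int = 50
    min_quality: float = 100.0
    overlap_threshold: float = 0.5
    junction_max_dist: int = 500
    top_k: int = 20
    promoter_window: int = 2000
    splice_window: int = 2
    filter_parents: bool = False

    def validate(self) -> None:
        if self.min_depth < 0 or self.min_quality < 0:
            raise ConfigError("filter thresholds must be non-negative")
        if not 0 < self.overlap_threshold <= 1:
            raise ConfigError("overlap threshold must be in (0, 1]")
        if self.junction_max_dist <= 0 or self.top_k <= 0:
            raise ConfigError("junction distance and top_k must be positive")


@dataclass
class FamilyResult:
    """Everything the pipeline derives for one family."""

    family_id: str
    mode: str  # quad | twin_only
    ssc: dict  # role -> classify_twin() result
    cnv: dict  # role -> list[ClassifiedEvent]
    sv: dict  # role -> list[ClassifiedEvent]
    annotated: dict  # role -> list[AnnotatedVariant] (de novo variants)
    gene_lists: dict  # role -> sorted list of affected genes
    enrichment: dict  # role -> list[EnrichmentRow]
    profiles: dict = field(default_factory=dict)  # role -> PathwayProfile

    def summary(self) -> dict:
        out = {
            "family_id": self.family_id,
            "mode": self.mode,
            "ssc": {r: v["summary"] for r, v in self.ssc.items()},
            "cnv": {r: svmatch.event_summary(v) for r, v in self.cnv.items()},
            "sv": {r: svmatch.event_summary(v) for r, v in self.sv.items()},
            "gene_list_sizes": {r: len(v) for r, v in self.gene_lists.items()},
            "top_pathways": {
                r: list(p.pathways) for r, p in self.profiles.items()
            },
        }
        return out


def load_quad(manifest_path: str | Path) -> tuple[QuadCallsets, dict]:
    """Load a family's call sets from a quad manifest (YAML written by
    the simulator or assembled by hand for real data)."""
    manifest_path = Path(manifest_path)
    manifest = yaml.safe_load(manifest_path.read_text())
    base = manifest_path.parent
    reference = Fasta(str(base / manifest["reference"]))
    samples = {}
    for role, entry in manifest["samples"].items():
        callset = SampleCallset(sample_id=entry["sample_id"])
        callset.small = read_small_variants(
            base / entry["vcf"], entry["sample_id"], reference=reference
        )
        if entry.get("cnv"):
            callset.cnv = read_cnv_table(base / entry["cnv"])
        if entry.get("sv"):
            callset.sv = read_sv_table(base / entry["sv"])
        samples[role] = callset
    return QuadCallsets(samples=samples), manifest


def _denovo_origins(mode: str) -> tuple[str, ...]:
    return ("de_novo",) if mode == "quad" else ("provisional_de_novo",)


def run_family(
    quad: QuadCallsets,
    reference: Mapping[str, str],
    genes: Sequence[ann.GeneModel],
    collection: enr.GeneSetCollection,
    config: PipelineConfig | None = None,
    family_id: str = "family",
    frequency_tables: Sequence[Mapping] = (),
) -> FamilyResult:
    """Run classification, annotation and enrichment for one family."""
    config = config or PipelineConfig()
    config.validate()
    mode = "quad" if quad.parents_present else "twin_only"
    denovo = _denovo_origins(mode)

    ssc = sharing.classify_quad(
        quad,
        min_depth=config.min_depth,
        min_quality=config.min_quality,
        filter_parents=config.filter_parents,
    )

    cnv: dict = {}
    sv: dict = {}
    for role, cotwin_role in (
        ("twin_affected", "twin_unaffected"),
        ("twin_unaffected", "twin_affected"),
    ):
        father = quad["father"].cnv if quad.parents_present else None
        mother = quad["mother"].cnv if quad.parents_present else None
        cnv[role] = svmatch.classify_event_inheritance(
            quad[role].cnv, quad[cotwin_role].cnv, father, mother,
            threshold=config.overlap_threshold,
            junction_max_dist=config.junction_max_dist,
        )
        father = quad["father"].sv if quad.parents_present else None
        mother = quad["mother"].sv if quad.parents_present else None
        sv[role] = svmatch.classify_event_inheritance(
            quad[role].sv, quad[cotwin_role].sv, father, mother,
            threshold=config.overlap_threshold,
            junction_max_dist=config.junction_max_dist,
        )

    annotated: dict = {}
    gene_lists: dict = {}
    enrichment: dict = {}
    profiles: dict = {}
    for role in ("twin_affected", "twin_unaffected"):
        to_annotate = [
            v for v in ssc[role]["classified"] if v.origin in denovo
        ]
        to_annotate += [e for e in cnv[role] if e.origin in denovo]
        to_annotate += [e for e in sv[role] if e.origin in denovo]
        annotated[role] = ann.annotate_all(
            to_annotate,
            genes,
            reference=reference,
            frequency_tables=frequency_tables,
            promoter_window=config.promoter_window,
            splice_window=config.splice_window,
        )
        genes_hit = sorted(set().union(*(a.genes for a in annotated[role]))
                           if annotated[role] else set())
        gene_lists[role] = genes_hit
        enrichment[role] = enr.enrich(genes_hit, collection)
        profiles[role] = threshold.PathwayProfile(
            individual_id=quad[role].sample_id,
            family=family_id,
            role="affected" if role == "twin_affected" else "unaffected",
            pathways=tuple(enr.top_k(enrichment[role], config.top_k)),
        )
    return FamilyResult(
        family_id=family_id,
        mode=mode,
        ssc=ssc,
        cnv=cnv,
        sv=sv,
        annotated=annotated,
        gene_lists=gene_lists,
        enrichment=enrichment,
        profiles=profiles,
    )


def run_family_from_manifest(
    manifest_path: str | Path,
    config: PipelineConfig | None = None,
) -> FamilyResult:
    """Convenience wrapper: load a quad manifest directory and run the
    single-family pipeline on it."""
    quad, manifest = load_quad(manifest_path)
    base = Path(manifest_path).parent
    reference = Fasta(str(base / manifest["reference"]))
    genes = ann.read_gene_models(base / manifest["genes"])
    collection = enr.read_gmt(base / manifest["gene_sets"])
    return run_family(
        quad, reference, genes, collection,
        config=config, family_id=manifest["family_id"],
    )


def compare_families(
    results: Sequence[FamilyResult],
    collection: enr.GeneSetCollection | None = None,
) -> dict:
    """Cross-family threshold-model comparison of the per-family
    results: GP/GPD labels, shared affected pathways, final GPD set and
    (when the collection is given) the per-pathway affected-gene
    overlap report."""
    profiles = [p for r in results for p in r.profiles.values()]
    comparison = threshold.cross_family(profiles)
    out = {
        "gp": {f: sorted(v) for f, v in comparison.gp.items()},
        "gpd": {f: sorted(v) for f, v in comparison.gpd.items()},
        "shared_affected": sorted(comparison.shared_affected),
        "final_gpd": sorted(comparison.final_gpd),
    }
    if collection is not None and comparison.final_gpd:
        affected_genes = {
            r.profiles["twin_affected"].individual_id: r.gene_lists["twin_affected"]
            for r in results
        }
        report = threshold.gene_overlap_report(
            comparison.final_gpd, affected_genes, collection
        )
        out["gene_overlap"] = {
            pathway: {
                "per_patient": {
                    p: sorted(g) for p, g in entry["per_patient"].items()
                },
                "common": sorted(entry["common"]),
            }
            for pathway, entry in report.items()
        }
    return out


def write_family_outputs(result: FamilyResult, outdir: str | Path) -> None:
    """Emit the per-stage report files for one family."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for role in ("twin_affected", "twin_unaffected"):
        sharing.classified_to_frame(result.ssc[role]["classified"]).to_csv(
            outdir / f"{role}.ssc_classified.tsv", sep="\t", index=False
        )
        rows = []
        for kind, events in (("cnv", result.cnv[role]), ("sv", result.sv[role])):
            for c in events:
                e = c.event
                rows.append(
                    {
                        "kind": kind,
                        "category": svmatch.event_category(e),
                        "chrom": e.chrom,
                        "start": e.start,
                        "end": getattr(e, "end", None),
                        "sharing": c.sharing,
                        "origin": c.origin,
                    }
                )
        pd.DataFrame(
            rows,
            columns=["kind", "category", "chrom", "start", "end", "sharing", "origin"],
        ).to_csv(outdir / f"{role}.events_classified.tsv", sep="\t", index=False)
        ann.annotated_to_frame(result.annotated[role]).to_csv(
            outdir / f"{role}.annotated.tsv", sep="\t", index=False
        )
        # interchromosomal events as a links table for external plotting
        links = [
            {
                "sample": c.event.sample_id,
                "chromA": c.event.chrom, "posA": c.event.start,
                "chromB": c.event.chrom2, "posB": c.event.pos2,
                "sharing": c.sharing, "origin": c.origin,
            }
            for c in result.sv[role]
            if c.event.category == "interchromosomal"
        ]
        pd.DataFrame(
            links,
            columns=["sample", "chromA", "posA", "chromB", "posB",
                     "sharing", "origin"],
        ).to_csv(outdir / f"{role}.links.tsv", sep="\t", index=False)
        enr.enrichment_to_frame(result.enrichment[role]).to_csv(
            outdir / f"{role}.enrichment.tsv", sep="\t", index=False
        )
    (outdir / "summary.json").write_text(
        json.dumps(result.summary(), indent=2, sort_keys=True) + "\n"
    )


def run_all(
    manifests: Sequence[str | Path],
    outdir: str | Path,
    config: PipelineConfig | None = None,
) -> dict:
    """Full pipeline over one or more family manifests.

    Writes per-family stage outputs plus, with at least two families, a
    cross-family GP/GPD comparison; returns the combined report dict.
    """
    config = config or PipelineConfig()
    outdir = Path(outdir)
    results = []
    collection = None
    for manifest_path in manifests:
        result = run_family_from_manifest(manifest_path, config=config)
        base = Path(manifest_path).parent
        manifest = yaml.safe_load(Path(manifest_path).read_text())
        collection = enr.read_gmt(base / manifest["gene_sets"])
        write_family_outputs(result, outdir / result.family_id)
        results.append(result)
    report = {"families": {r.family_id: r.summary() for r in results}}
    if len(results) >= 2:
        report["threshold_model"] = compare_families(results, collection)
    (outdir / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n"
    )
    return report
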