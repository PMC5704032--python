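"""Bundled worked-example tables for a two-family discordant-twin
analysis.

Three small data sets ship with the package so that every downstream
stage has a concrete, hand-checkable example:

* ``example_top20_pathways.tsv`` — the affected twin's top-20 enriched
  canonical pathway list for each of two unrelated families, with flags
  recording which other study members' top-20 lists also contained each
  pathway (``1A``/``1U``/``2A``/``2U`` = family 1/2, affected/
  unaffected);
* ``example_pathway_genes.tsv`` — the affected member genes of the two
  final GPD pathways in each patient;
* ``example_unique_cnvs.tsv`` — the CNVs unique to each family's
  affected twin, with coordinates, size and (family 1 only) their
  inherited/de-novo identity established from the parental genomes;
* ``example_variant_summaries.tsv`` — per-individual genome-wide count
  matrices (total / shared / unshared x inherited / de novo) for SSCs,
  CNVs and SVs.

The flags in the top-20 table only record membership for pathways that
appear in an affected list, so the unaffected "profiles" reconstructed
from them are partial — sufficient for the GP/GPD subtraction, which
never needs more.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .callsets import CnvCall
from .threshold import PathwayProfile

_FLAG_ROLES = {
    "1A": ("family1", "affected"),
    "1U": ("family1", "unaffected"),
    "2A": ("family2", "affected"),
    "2U": ("family2", "unaffected"),
}


def _data_path(name: str):
    return resources.files("twinquad").joinpath("data", name)


def load_table(name: str) -> pd.DataFrame:
    with resources.as_file(_data_path(name)) as path:
        return pd.read_csv(path, sep="\t", dtype={"chrom": str})


def load_top20_table() -> pd.DataFrame:
    """Raw top-20 pathway table (family, rank, pathway, shared_with,
    p_value)."""
    return load_table("example_top20_pathways.tsv")


def load_top20_profiles() -> list[PathwayProfile]:
    """The four individuals' pathway profiles.

    Affected profiles are the full printed top-20 lists; unaffected
    profiles are reconstructed from the sharing flags (every pathway
    flagged ``1U``/``2U`` anywhere in the table).
    """
    df = load_top20_table()
    profiles = []
    for family in ("family1", "family2"):
        sub = df[df.family == family].sort_values("rank")
        profiles.append(
            PathwayProfile(
                individual_id=f"{family}-affected",
                family=family,
                role="affected",
                pathways=tuple(sub.pathway),
            )
        )
    for flag in ("1U", "2U"):
        family, role = _FLAG_ROLES[flag]
        names = [
            row.pathway
            for row in df.itertuples(index=False)
            if flag in str(row.shared_with).split(",")
        ]
        # stable de-duplicated order
        seen: dict[str, None] = {}
        for n in names:
            seen.setdefault(n, None)
        profiles.append(
            PathwayProfile(
                individual_id=f"{family}-unaffected",
                family=family,
                role=role,
                pathways=tuple(seen),
            )
        )
    return profiles


def load_pathway_genes() -> dict[str, dict[str, list[str]]]:
    """Affected member genes of the final GPD pathways:
    {pathway: {family: [genes...]}}, in table order."""
    df = load_table("example_pathway_genes.tsv")
    out: dict[str, dict[str, list[str]]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.pathway, {}).setdefault(row.family, []).append(row.gene)
    return out


def load_unique_cnvs(family: str = "family1") -> pd.DataFrame:
    """CNVs unique to one family's affected twin."""
    df = load_table("example_unique_cnvs.tsv")
    return df[df.family == family].reset_index(drop=True)


_STATE = {"amp": 3, "del": 1}


def unique_cnv_calls(family: str = "family1") -> list[CnvCall]:
    """The unique-CNV table as CnvCall objects for the affected twin."""
    return [
        CnvCall(
            sample_id=f"{family}-twin_affected",
            chrom=row.chrom,
            start=int(row.start),
            end=int(row.end),
            copy_state=_STATE[row.cnv_type],
        )
        for row in load_unique_cnvs(family).itertuples(index=False)
    ]


def family1_cnv_inheritance_fixture() -> dict[str, list[CnvCall]]:
    """Family-1 fixture for the event-inheritance classifier: the seven
    unique CNVs of the affected twin, an empty co-twin set (they are
    unique), and parental sets holding only the two inherited rows."""
    twin = unique_cnv_calls("family1")
    df = load_unique_cnvs("family1")
    parents = [
        CnvCall(
            sample_id="family1-father",
            chrom=row.chrom,
            start=int(row.start),
            end=int(row.end),
            copy_state=_STATE[row.cnv_type],
        )
        for row in df.itertuples(index=False)
        if row.identity == "inherited"
    ]
    return {
        "twin": twin,
        "cotwin": [],
        "father": parents,
        "mother": [],
    }


def load_variant_summaries() -> pd.DataFrame:
    """Genome-wide per-individual count matrices for SSCs, CNVs and SVs
    (``-`` entries mark counts not derivable in twin-only mode)."""
    return load_table("example_variant_summaries.tsv")
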