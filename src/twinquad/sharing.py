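"""Shared/unshared partition of twin variants and inherited vs de novo
origin labelling.

A variant of one twin is *shared* when the same canonical key is called
in the co-twin and *unshared* otherwise.  In quad mode an unshared
variant found in at least one parent is *inherited* (it pre-dates the
zygote; the co-twin call is a dropout or a germline transmission
artefact), while a variant absent from both parents is a post-zygotic
*de novo* candidate.  Without parental genomes every unshared variant
can only be labelled *provisional de novo*.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .callsets import QuadCallsets, SmallVariantCall, dedupe_by_key
from .errors import ContractViolation

ORIGINS = ("inherited", "de_novo", "provisional_de_novo", "not_applicable")


@dataclass(frozen=True)
class ClassifiedVariant:
    """A small-variant call with its sharing and origin labels."""

    call: SmallVariantCall
    sharing: str  # shared | unshared
    origin: str = "not_applicable"

    def __post_init__(self):
        if self.sharing not in ("shared", "unshared"):
            raise ValueError(f"bad sharing label {self.sharing!r}")
        if self.origin not in ORIGINS:
            raise ValueError(f"bad origin label {self.origin!r}")


def partition_by_cotwin(
    subject_calls: Sequence[SmallVariantCall],
    cotwin_calls: Sequence[SmallVariantCall],
) -> tuple[list[SmallVariantCall], list[SmallVariantCall]]:
    """Split the subject twin's calls into (shared, unshared) by canonical
    key presence in the co-twin.  Duplicate keys within one sample are
    deduplicated with a warning.  ``shared + unshared`` is always the
    full deduplicated input, in input order."""
    subject_calls = dedupe_by_key(subject_calls)
    cotwin_keys = {c.key for c in cotwin_calls}
    shared = [c for c in subject_calls if c.key in cotwin_keys]
    unshared = [c for c in subject_calls if c.key not in cotwin_keys]
    return shared, unshared


def classify_inheritance(
    unshared_calls: Sequence[SmallVariantCall],
    father_calls: Iterable[SmallVariantCall],
    mother_calls: Iterable[SmallVariantCall],
) -> list[ClassifiedVariant]:
    """Label each unshared call *inherited* (key present in at least one
    parent) or *de_novo* (absent from both).  Quad mode only."""
    parent_keys = {c.key for c in father_calls} | {c.key for c in mother_calls}
    return [
        ClassifiedVariant(
            call=c,
            sharing="unshared",
            origin="inherited" if c.key in parent_keys else "de_novo",
        )
        for c in unshared_calls
    ]


def classify_provisional(
    unshared_calls: Sequence[SmallVariantCall],
) -> list[ClassifiedVariant]:
    """Twin-only mode: every unshared call becomes *provisional_de_novo*."""
    return [
        ClassifiedVariant(call=c, sharing="unshared", origin="provisional_de_novo")
        for c in unshared_calls
    ]


def classify_twin(
    quad: QuadCallsets,
    subject_role: str,
    min_depth: int = 50,
    min_quality: float = 100.0,
    filter_parents: bool = False,
) -> dict:
    """Run the full sharing/origin classification for one twin.

    The subject's calls are high-confidence filtered before comparison.
    By default the parental presence check uses *unfiltered* parental
    calls, so that a true parental variant that merely failed the depth
    filter cannot manufacture a false de novo; set ``filter_parents``
    to compare against filtered parents instead.

    Returns a dict with keys ``shared`` (list of calls), ``classified``
    (list of :class:`ClassifiedVariant` for the unshared calls) and
    ``summary`` (count dict mirroring the per-sample report row).
    """
    from .callsets import filter_high_confidence

    if subject_role not in ("twin_affected", "twin_unaffected"):
        raise ContractViolation(f"subject must be a twin role, got {subject_role!r}")
    cotwin_role = (
        "twin_unaffected" if subject_role == "twin_affected" else "twin_affected"
    )
    subject_all = quad[subject_role].small
    subject = filter_high_confidence(subject_all, min_depth, min_quality)
    cotwin = quad[cotwin_role].small

    shared, unshared = partition_by_cotwin(subject, cotwin)
    # unfiltered co-twin comparison for reporting both ways
    _, unshared_unfiltered = partition_by_cotwin(subject_all, cotwin)

    if quad.parents_present:
        father = quad["father"].small
        mother = quad["mother"].small
        if filter_parents:
            father = filter_high_confidence(father, min_depth, min_quality)
            mother = filter_high_confidence(mother, min_depth, min_quality)
        classified = classify_inheritance(unshared, father, mother)
    else:
        classified = classify_provisional(unshared)

    n_inh = sum(1 for v in classified if v.origin == "inherited")
    n_dn = sum(1 for v in classified if v.origin == "de_novo")
    summary = {
        "sample": quad[subject_role].sample_id,
        "role": subject_role,
        "total_calls": len(subject_all),
        "high_confidence": len(subject),
        "shared": len(shared),
        "unshared": len(unshared),
        "unshared_unfiltered": len(unshared_unfiltered),
        "inherited": n_inh if quad.parents_present else None,
        "de_novo": n_dn if quad.parents_present else None,
        "provisional_de_novo": None if quad.parents_present else len(classified),
    }
    return {"shared": shared, "classified": classified, "summary": summary}


def classify_quad(quad: QuadCallsets, **kwargs) -> dict:
    """Classify both twins; returns {'twin_affected': ..., 'twin_unaffected': ...}."""
    return {
        role: classify_twin(quad, role, **kwargs)
        for role in ("twin_affected", "twin_unaffected")
    }


def partition_identity_holds(summary: dict) -> bool:
    """Check the report-arithmetic invariant inherited + de novo =
    unshared (quad mode) or provisional = unshared (twin-only mode)."""
    if summary.get("inherited") is not None:
        return summary["inherited"] + summary["de_novo"] == summary["unshared"]
    return summary["provisional_de_novo"] == summary["unshared"]


def classified_to_frame(classified: Sequence[ClassifiedVariant]) -> pd.DataFrame:
    """Tabulate classified variants (canonical key columns + labels +
    depth/quality) for the per-stage TSV output."""
    rows = [
        {
            "sample": v.call.sample_id,
            "chrom": v.call.chrom,
            "pos": v.call.pos,
            "ref": v.call.ref,
            "alt": v.call.alt,
            "vclass": v.call.vclass,
            "depth": v.call.depth,
            "quality": v.call.quality,
            "sharing": v.sharing,
            "origin": v.origin,
        }
        for v in classified
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "sample",
            "chrom",
            "pos",
            "ref",
            "alt",
            "vclass",
            "depth",
            "quality",
            "sharing",
            "origin",
        ],
    )
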