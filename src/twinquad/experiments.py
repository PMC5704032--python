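"""Reproducible validation experiments.

Each function runs a self-contained computational experiment on
synthetic data and returns plain numbers, so the same protocols back
both the test suite and the reproduction script:

* two-family parameter recovery: plant post-zygotic variants and two
  spiked disease pathways, run the full pipeline, and measure precision
  and recall of the de novo calls plus the recovered GPD pathway set;
* mosaic degradation: recall of post-zygotic small variants as the
  somatic cell fraction shrinks;
* null calibration of the over-representation test against its exact
  attainable size;
* agreement of the reciprocal-overlap matcher with a base-counting
  oracle, and of the hypergeometric tail with exact rational
  enumeration.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np

from . import pipeline, sharing
from .callsets import CnvCall
from .enrichment import GeneSetCollection, enrich, hypergeometric_right_tail
from .simulate import (
    SimulationConfig,
    apply_mosaic_dropout,
    generate_reference,
    rng_streams,
    simulate_quad,
)
from .svmatch import reciprocal_overlap


def _precision_recall(predicted: set, truth: set) -> tuple[float, float]:
    if not predicted:
        return (1.0 if not truth else 0.0, 0.0 if truth else 1.0)
    tp = len(predicted & truth)
    return tp / len(predicted), (tp / len(truth)) if truth else 1.0


def _event_key(event) -> tuple:
    if isinstance(event, CnvCall):
        return ("cnv", event.chrom, event.start, event.end, event.copy_state)
    if event.category == "interchromosomal":
        return ("sv", event.category, event.chrom, event.start,
                event.chrom2, event.pos2)
    return ("sv", event.category, event.chrom, event.start, event.end)


def two_family_recovery(seed: int = 1, n_somatic: int = 20) -> dict:
    """Noiseless two-family experiment.

    Each family's affected twin carries somatic variants spiked into two
    pathways: one family-specific and one ("the disease pathway")
    planted in both families' affected twins.  The pipeline is run per
    family with top-k equal to the number of truly enriched pathways
    (two), then compared across families; the final GPD set should be
    exactly the doubly planted pathway, and de novo calls should match
    the planted truth with precision = recall = 1.
    """
    shared_set = "pathway_09"
    family_sets = {"family1": "pathway_03", "family2": "pathway_14"}
    base = SimulationConfig(seed=seed)
    reference = generate_reference(base, rng_streams(base.seed)[0])
    out: dict = {"families": {}}
    results = []
    collection = reference.gene_sets
    for i, (family, own_set) in enumerate(sorted(family_sets.items()), start=1):
        config = SimulationConfig(
            seed=seed + i,
            family_id=family,
            n_somatic_per_twin=n_somatic,
            spike_sets=(shared_set, own_set),
        )
        sim = simulate_quad(config, reference, rng_streams(config.seed)[1])
        result = pipeline.run_family(
            sim.quad, reference, reference.genes, collection,
            config=pipeline.PipelineConfig(top_k=2), family_id=family,
        )
        results.append(result)
        fam: dict = {}
        for role, origin in (("twin_affected", "postzygotic_twinA"),
                             ("twin_unaffected", "postzygotic_twinB")):
            predicted = {
                v.call.key for v in result.ssc[role]["classified"]
                if v.origin == "de_novo"
            }
            p, r = _precision_recall(predicted, sim.truth_keys(origin, kind="ssc"))
            fam[f"{role}_ssc_precision"] = p
            fam[f"{role}_ssc_recall"] = r
            predicted_ev = {
                _event_key(e.event)
                for e in result.cnv[role] + result.sv[role]
                if e.origin == "de_novo"
            }
            truth_ev = (sim.truth_keys(origin, kind="cnv")
                        | sim.truth_keys(origin, kind="sv"))
            p, r = _precision_recall(predicted_ev, truth_ev)
            fam[f"{role}_event_precision"] = p
            fam[f"{role}_event_recall"] = r
        fam["affected_top_pathways"] = list(
            result.profiles["twin_affected"].pathways
        )
        out["families"][family] = fam
    comparison = pipeline.compare_families(results)
    out["final_gpd"] = comparison["final_gpd"]
    out["shared_disease_pathway"] = shared_set
    out["n_planted_per_twin"] = n_somatic
    return out


def mosaic_recall_curve(
    seed: int = 1,
    cell_fractions: tuple = (0.9, 0.5, 0.2, 0.1, 0.05),
    n_somatic: int = 200,
    depth_mean: float = 100.0,
) -> dict:
    """Recall of post-zygotic small variants after mosaic read-support
    dropout, at a ladder of fixed cell fractions.

    Depth is kept high enough (Poisson mean 100) that essentially every
    call passes the depth-50 confidence filter, so the curve isolates
    the mosaic effect: with a detection floor of 3 supporting reads the
    expected retention is ~1 down to a cell fraction of ~0.2 and
    collapses below it, so recall falls monotonically along the ladder.
    """
    recalls = {}
    for i, f in enumerate(cell_fractions):
        config = SimulationConfig(
            seed=seed + 100 + i,
            n_somatic_per_twin=n_somatic,
            n_inherited_snv=100, n_inherited_indel=10, n_inherited_blocksub=5,
            n_inherited_discordant=0, n_germline_denovo=0,
            n_cnv_shared=5, n_cnv_unique=0, n_cnv_unique_inherited=0,
            n_sv_shared_by_category={"deletion": 3},
            n_sv_unique_by_category={}, n_sv_unique_inherited_by_category={},
            mosaic_model=("fixed", float(f)),
            depth_mean=depth_mean,
        )
        streams = rng_streams(config.seed)
        reference = generate_reference(config, streams[0])
        sim = simulate_quad(config, reference, streams[1])
        degraded = apply_mosaic_dropout(sim, config, streams[2])
        classified = sharing.classify_quad(degraded.quad)
        predicted = {
            v.call.key
            for v in classified["twin_affected"]["classified"]
            if v.origin == "de_novo"
        }
        planted = {
            t.key for t in sim.truth
            if t.kind == "ssc" and t.origin == "postzygotic_twinA"
        }
        precision, recall = _precision_recall(predicted, planted)
        recalls[float(f)] = {"recall": recall, "precision": precision}
    return recalls


def null_calibration(
    seed: int = 1,
    n_replicates: int = 1000,
    n_sets: int = 20,
    set_size: int = 10,
    query_size: int = 30,
    alpha: float = 0.05,
) -> dict:
    """Type-I behaviour of the over-representation test under random
    queries.

    With disjoint equal-size sets every set's null overlap is
    Hypergeom(N, K, n); p-values are discrete, so the exact attainable
    size at level ``alpha`` is P(X >= k*) for the smallest k* whose tail
    falls below alpha — the empirical rejection fraction is compared to
    that analytic value, not to alpha itself.
    """
    rng = np.random.default_rng(seed)
    universe = [f"g{i:03d}" for i in range(n_sets * set_size)]
    sets = {
        f"set{j:02d}": frozenset(universe[j * set_size : (j + 1) * set_size])
        for j in range(n_sets)
    }
    collection = GeneSetCollection(sets=sets)
    N = len(universe)
    k_star = next(
        k for k in range(set_size + 1)
        if hypergeometric_right_tail(N, set_size, query_size, k) < alpha
    )
    exact_size = hypergeometric_right_tail(N, set_size, query_size, k_star)
    rejected = 0
    for _ in range(n_replicates):
        query = list(rng.choice(universe, size=query_size, replace=False))
        rows = enrich(query, collection)
        rejected += sum(1 for r in rows if r.p_value < alpha)
    empirical = rejected / (n_replicates * n_sets)
    return {
        "empirical_rate": empirical,
        "exact_attainable_size": float(exact_size),
        "nominal_alpha": alpha,
        "n_tests": n_replicates * n_sets,
    }


def overlap_oracle_agreement(seed: int = 1, n_pairs: int = 1000) -> dict:
    """Fraction of random interval pairs (10 kb toy chromosome) on which
    the reciprocal-overlap matcher agrees with base-by-base counting."""
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_pairs):
        sa, sb = rng.integers(0, 9000, size=2)
        a = ("chr1", int(sa), int(sa + rng.integers(1, 1000)))
        b = ("chr1", int(sb), int(sb + rng.integers(1, 1000)))
        shared = max(0, min(a[2], b[2]) - max(a[1], b[1]))
        la, lb = a[2] - a[1], b[2] - b[1]
        oracle = (shared / la >= 0.5) and (shared / lb >= 0.5)
        result = reciprocal_overlap(a, b)
        ok = (
            result.matched == oracle
            and abs(result.fraction_a - shared / la) < 1e-12
            and abs(result.fraction_b - shared / lb) < 1e-12
        )
        agree += ok
    return {"agreement": agree / n_pairs, "n_pairs": n_pairs}


def hypergeometric_oracle_error(max_n: int = 25) -> dict:
    """Maximum absolute difference between the implementation and exact
    rational enumeration over every configuration with N <= max_n."""
    worst = 0.0
    n_checked = 0
    for N in range(1, max_n + 1):
        for K in range(0, N + 1):
            for n in range(0, N + 1):
                for k in range(0, min(K, n) + 1):
                    exact = Fraction(0)
                    for j in range(k, min(K, n) + 1):
                        exact += Fraction(
                            comb(K, j) * comb(N - K, n - j), comb(N, n)
                        )
                    got = hypergeometric_right_tail(N, K, n, k)
                    worst = max(worst, abs(got - float(exact)))
                    n_checked += 1
    return {"max_abs_error": worst, "n_configurations": n_checked}
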