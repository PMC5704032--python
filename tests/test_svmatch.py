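"""Reciprocal-overlap, junction and inversion matching; merged groups."""

import numpy as np
import pytest

from twinquad import (
    CnvCall,
    SvEvent,
    build_match_groups,
    classify_event_inheritance,
    events_match,
    match_interchromosomal,
    match_inversion,
    reciprocal_overlap,
)
from twinquad import examples
from twinquad.errors import ContractViolation


def _overlap_oracle(a, b):
    """Base-by-base counting: number of integer positions both intervals
    cover (independent of the arithmetic implementation)."""
    (_, sa, ea), (_, sb, eb) = a, b
    return len(set(range(sa, ea)) & set(range(sb, eb)))


class TestReciprocalOverlap:
    def test_identity(self):
        r = reciprocal_overlap(("chr1", 0, 100), ("chr1", 0, 100))
        assert (r.fraction_a, r.fraction_b, r.matched) == (1.0, 1.0, True)

    def test_half_overlap_matches_at_threshold(self):
        r = reciprocal_overlap(("chr1", 0, 100), ("chr1", 50, 150))
        assert r.fraction_a == 0.5 and r.fraction_b == 0.5 and r.matched

    def test_reciprocity_rejects_nested_small_interval(self):
        r = reciprocal_overlap(("chr1", 0, 100), ("chr1", 0, 1000))
        assert r.fraction_a == 1.0 and r.fraction_b == pytest.approx(0.1)
        assert not r.matched

    def test_different_chromosomes_never_match(self):
        r = reciprocal_overlap(("chr1", 0, 100), ("chr2", 0, 100))
        assert r == reciprocal_overlap(("chr1", 0, 100), ("chr2", 0, 100))
        assert not r.matched and r.fraction_a == 0.0

    def test_zero_length_interval_rejected(self):
        with pytest.raises(ValueError):
            reciprocal_overlap(("chr1", 5, 5), ("chr1", 0, 10))

    def test_agrees_with_counting_oracle_on_random_pairs(self):
        """1000 random interval pairs on a 10 kb toy chromosome."""
        rng = np.random.default_rng(2024)
        for _ in range(1000):
            sa, sb = rng.integers(0, 9000, size=2)
            a = ("chr1", int(sa), int(sa + rng.integers(1, 1000)))
            b = ("chr1", int(sb), int(sb + rng.integers(1, 1000)))
            shared = _overlap_oracle(a, b)
            r = reciprocal_overlap(a, b)
            la, lb = a[2] - a[1], b[2] - b[1]
            assert r.fraction_a == pytest.approx(shared / la)
            assert r.fraction_b == pytest.approx(shared / lb)
            assert r.matched == (shared / la >= 0.5 and shared / lb >= 0.5)
            # symmetry and reflexivity
            flipped = reciprocal_overlap(b, a)
            assert flipped.matched == r.matched
            assert reciprocal_overlap(a, a).matched

    def test_raising_threshold_never_adds_matches(self):
        rng = np.random.default_rng(7)
        thresholds = (0.3, 0.5, 0.7, 0.9)
        for _ in range(200):
            sa, sb = rng.integers(0, 9000, size=2)
            a = ("chr1", int(sa), int(sa + rng.integers(1, 1000)))
            b = ("chr1", int(sb), int(sb + rng.integers(1, 1000)))
            matched = [reciprocal_overlap(a, b, t).matched for t in thresholds]
            assert matched == sorted(matched, reverse=True)


def _inter(sample, p1, p2, c1="chr2", c2="chr17"):
    return SvEvent(sample, "interchromosomal", c1, p1, None, c2, p2)


class TestInterchromosomal:
    def test_identical_junctions_match(self):
        assert match_interchromosomal(_inter("a", 100, 5000), _inter("b", 100, 5000))

    def test_strict_500_bound(self):
        assert match_interchromosomal(_inter("a", 0, 0, c2="chr17"),
                                      _inter("b", 499, 499, c2="chr17"))
        assert not match_interchromosomal(_inter("a", 0, 0),
                                          _inter("b", 500, 0))

    def test_chromosome_mismatch(self):
        assert not match_interchromosomal(
            _inter("a", 100, 100, "chr2", "chr17"),
            _inter("b", 100, 100, "chr2", "chr16"),
        )

    def test_requires_interchromosomal_events(self):
        deletion = SvEvent("a", "deletion", "chr1", 0, 100)
        with pytest.raises(ContractViolation):
            match_interchromosomal(deletion, deletion)


def _inv(sample, start, end, orientation="forward"):
    return SvEvent(sample, "inversion", "chr1", start, end,
                   orientation=orientation)


class TestInversion:
    def test_same_interval_same_direction(self):
        assert match_inversion(_inv("a", 0, 100), _inv("b", 0, 100))

    def test_opposite_direction_never_matches(self):
        assert not match_inversion(_inv("a", 0, 100),
                                   _inv("b", 0, 100, "reverse"))

    def test_fifty_percent_is_inclusive(self):
        assert match_inversion(_inv("a", 0, 100), _inv("b", 50, 150))


class TestMatchGroups:
    def test_chain_merges_into_one_group(self):
        """A~B and B~C merge even though A and C do not match directly
        (verified against an explicit pairwise check)."""
        a = CnvCall("s1", "chr1", 0, 100, 3)
        b = CnvCall("s2", "chr1", 40, 140, 3)
        c = CnvCall("s3", "chr1", 80, 180, 3)
        assert events_match(a, b) and events_match(b, c)
        assert not events_match(a, c)
        groups = build_match_groups([a, b, c])
        assert len(groups) == 1
        assert groups[0].sample_ids == {"s1", "s2", "s3"}

    def test_no_matches_gives_singletons(self):
        events = [CnvCall(f"s{i}", "chr1", i * 10_000, i * 10_000 + 100, 3)
                  for i in range(5)]
        groups = build_match_groups(events)
        assert len(groups) == 5
        assert all(len(g.members) == 1 for g in groups)

    def test_amp_and_del_never_mix(self):
        amp = CnvCall("s1", "chr1", 0, 100, 3)
        dele = CnvCall("s2", "chr1", 0, 100, 1)
        assert not events_match(amp, dele)
        with pytest.raises(ContractViolation):
            build_match_groups([amp, dele])

    def test_shared_cnvs_group_both_twins(self, sim, default_config):
        twin_a = sim.quad["twin_affected"].cnv
        twin_b = sim.quad["twin_unaffected"].cnv
        for cnv_type in ("amp", "del"):
            events = [e for e in twin_a + twin_b if e.cnv_type == cnv_type]
            groups = build_match_groups(events)
            both = [g for g in groups if len(g.sample_ids) == 2]
            singles = [g for g in groups if len(g.sample_ids) == 1]
            assert all(len(g.members) == 2 for g in both)
            # every shared planted CNV of this type forms one two-twin group
            n_shared_type = sum(
                1 for t in sim.truth
                if t.kind == "cnv"
                and t.expected_samples >= {"twin_affected", "twin_unaffected"}
                and (("amp" if t.key[4] > 2 else "del") == cnv_type)
            )
            assert len(both) == n_shared_type
            assert all(len(g.members) == 1 for g in singles)


class TestEventInheritance:
    def test_printed_cnv_fixture_yields_five_de_novo(self):
        """Seven unique CNVs with parents carrying only the two inherited
        rows: the 50% reciprocal-overlap classifier calls 5 de novo."""
        fx = examples.family1_cnv_inheritance_fixture()
        labels = classify_event_inheritance(
            fx["twin"], fx["cotwin"], fx["father"], fx["mother"]
        )
        assert all(l.sharing == "unshared" for l in labels)
        assert sum(1 for l in labels if l.origin == "de_novo") == 5
        assert sum(1 for l in labels if l.origin == "inherited") == 2

    def test_sixty_percent_cotwin_overlap_is_shared(self):
        twin = [CnvCall("a", "chr1", 0, 1000, 3)]
        cotwin = [CnvCall("b", "chr1", 400, 1400, 3)]  # 60% reciprocal
        labels = classify_event_inheritance(twin, cotwin, [], [])
        assert labels[0].sharing == "shared"

    def test_twin_only_mode_gives_provisional(self):
        twin = [CnvCall("a", "chr1", 0, 1000, 3)]
        labels = classify_event_inheritance(twin, [], None, None)
        assert labels[0].origin == "provisional_de_novo"
        with pytest.raises(ContractViolation):
            classify_event_inheritance(twin, [], [], None)

    def test_simulated_quad_label_matrix_equals_truth(self, sim):
        """Noiseless SV quad: the classifier reproduces the planted
        sharing/origin matrix event for event."""
        q = sim.quad
        for kind in ("cnv", "sv"):
            events = {r: getattr(q[r], kind) for r in q.samples}
            truth = {
                t.key: t for t in sim.truth if t.kind == kind
            }
            for role, cotwin, origin_dn in (
                ("twin_affected", "twin_unaffected", "postzygotic_twinA"),
                ("twin_unaffected", "twin_affected", "postzygotic_twinB"),
            ):
                labels = classify_event_inheritance(
                    events[role], events[cotwin],
                    events["father"], events["mother"],
                )
                dn = {l for l in labels if l.origin == "de_novo"}
                assert {_event_key(l.event, kind) for l in dn} == {
                    k for k, t in truth.items() if t.origin == origin_dn
                }
                # partition arithmetic: unshared = inherited + de novo
                n_unshared = sum(1 for l in labels if l.sharing == "unshared")
                n_inh = sum(1 for l in labels if l.origin == "inherited")
                assert n_inh + len(dn) == n_unshared


def _event_key(event, kind):
    if kind == "cnv":
        return ("cnv", event.chrom, event.start, event.end, event.copy_state)
    if event.category == "interchromosomal":
        return ("sv", event.category, event.chrom, event.start,
                event.chrom2, event.pos2)
    return ("sv", event.category, event.chrom, event.start, event.end)
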