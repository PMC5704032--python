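"""Synthetic quad generator: construction guarantees, determinism,
class proportions and the mosaic-dropout model."""

import filecmp
import math

import pytest

import twinquad as tq
from twinquad.errors import ConfigError
from twinquad.simulate import retention_probability


def _quad(config):
    ref = tq.generate_reference(config, tq.rng_streams(config.seed)[0])
    sim = tq.simulate_quad(config, ref, tq.rng_streams(config.seed)[1])
    return ref, sim


def _ssc_keys(callset):
    return {c.key for c in callset.small}


class TestReference:
    def test_gene_models_have_translatable_cds(self, reference):
        assert len(reference.genes) == 160
        strands = {g.strand for g in reference.genes}
        assert strands == {"+", "-"}
        for g in reference.genes:
            total = sum(e - s for s, e in g.cds)
            assert total % 3 == 0
            assert total > 0
            for s, e in g.exons:
                assert g.tx_start <= s < e <= g.tx_end

    def test_disjoint_gene_sets_partition(self):
        config = tq.SimulationConfig(
            seed=3, n_genes=20, n_gene_sets=4, genes_per_set=5
        )
        ref = tq.generate_reference(config, tq.rng_streams(3)[0])
        sets = ref.gene_sets.sets
        assert len(sets) == 4
        assert all(len(m) == 5 for m in sets.values())
        union = set().union(*sets.values())
        assert len(union) == 20  # disjoint partition of the subset

    def test_same_seed_reproduces_files_byte_for_byte(self, tmp_path):
        config = tq.SimulationConfig(seed=5, n_inherited_snv=50,
                                     n_inherited_indel=5, n_inherited_blocksub=2,
                                     n_cnv_shared=10)
        dirs = []
        for name in ("a", "b"):
            ref, sim = _quad(config)
            out = tmp_path / name
            tq.write_simulation(ref, sim, config, out)
            dirs.append(out)
        files = sorted(p.name for p in dirs[0].iterdir())
        match, mismatch, errors = filecmp.cmpfiles(
            dirs[0], dirs[1], files, shallow=False
        )
        assert mismatch == [] and errors == []
        assert set(match) == set(files)

    def test_chromosome_too_short_is_sizing_error(self):
        config = tq.SimulationConfig(seed=1, chromosome_length_bp=50_000)
        with pytest.raises(ConfigError):
            tq.generate_reference(config, tq.rng_streams(1)[0])


class TestQuadConstruction:
    def test_somatic_counts_are_exact(self):
        config = tq.SimulationConfig(
            seed=9, n_somatic_per_twin=5, n_inherited_discordant=0,
            n_germline_denovo=0,
        )
        _, sim = _quad(config)
        q = sim.quad
        a_only = (_ssc_keys(q["twin_affected"]) - _ssc_keys(q["twin_unaffected"])
                  - _ssc_keys(q["father"]) - _ssc_keys(q["mother"]))
        b_only = (_ssc_keys(q["twin_unaffected"]) - _ssc_keys(q["twin_affected"])
                  - _ssc_keys(q["father"]) - _ssc_keys(q["mother"]))
        assert len(a_only) == 5 and len(b_only) == 5
        assert a_only == sim.truth_keys("postzygotic_twinA", kind="ssc")
        assert b_only == sim.truth_keys("postzygotic_twinB", kind="ssc")

    def test_germline_denovo_in_both_twins_neither_parent(self, sim):
        gdn = sim.truth_keys("germline_denovo", kind="ssc")
        assert len(gdn) == 3
        q = sim.quad
        for key in gdn:
            assert key in _ssc_keys(q["twin_affected"])
            assert key in _ssc_keys(q["twin_unaffected"])
            assert key not in _ssc_keys(q["father"])
            assert key not in _ssc_keys(q["mother"])

    def test_role_consistency_no_orphan_transmitted_variant(self, sim):
        """Every transmitted variant is present in the parent named by
        its origin (noiseless mode)."""
        q = sim.quad
        parent_keys = {"father": _ssc_keys(q["father"]),
                       "mother": _ssc_keys(q["mother"])}
        for t in sim.truth:
            if t.kind == "ssc" and t.origin.startswith("transmitted_"):
                parent = t.origin.removeprefix("transmitted_")
                assert t.key in parent_keys[parent]

    def test_every_planted_variant_in_exactly_expected_samples(self, sim):
        keys_by_role = {r: _ssc_keys(sim.quad[r]) for r in sim.quad.samples}
        for t in sim.truth:
            if t.kind != "ssc":
                continue
            present = {r for r, keys in keys_by_role.items() if t.key in keys}
            assert present == set(t.expected_samples)

    def test_doubling_inherited_pool_doubles_shared_snvs_exactly(self):
        counts = {}
        for n in (100, 200):
            config = tq.SimulationConfig(
                seed=13, n_inherited_snv=n, n_inherited_indel=0,
                n_inherited_blocksub=0, n_germline_denovo=0,
                n_somatic_per_twin=0, n_inherited_discordant=0,
            )
            _, sim = _quad(config)
            shared = (_ssc_keys(sim.quad["twin_affected"])
                      & _ssc_keys(sim.quad["twin_unaffected"]))
            counts[n] = len(shared)
        assert counts[200] == 2 * counts[100] == 400

    def test_transition_fraction_matches_titv(self):
        """SNV transition fraction ~ titv/(titv+1) within 3 binomial SD."""
        config = tq.SimulationConfig(
            seed=17, n_inherited_snv=5000, n_inherited_indel=0,
            n_inherited_blocksub=0, n_germline_denovo=0,
            n_somatic_per_twin=0, n_inherited_discordant=0,
            n_cnv_shared=0, n_cnv_unique=0, n_cnv_unique_inherited=0,
            n_sv_shared_by_category={}, n_sv_unique_by_category={},
            n_sv_unique_inherited_by_category={},
        )
        _, sim = _quad(config)
        transitions = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
        snvs = [t for t in sim.truth
                if t.kind == "ssc" and len(t.key[2]) == 1 and len(t.key[3]) == 1]
        n = len(snvs)
        assert n == 10000
        ti = sum(1 for t in snvs if (t.key[2], t.key[3]) in transitions)
        p = 2.1 / 3.1
        sd = math.sqrt(n * p * (1 - p))
        assert abs(ti - n * p) < 3 * sd

    def test_low_quality_decoys_fail_the_filter(self):
        config = tq.SimulationConfig(
            seed=19, n_somatic_per_twin=10, n_lowq_decoys=10,
            n_inherited_discordant=0, n_germline_denovo=0,
        )
        _, sim = _quad(config)
        twin = sim.quad["twin_affected"]
        cotwin_keys = _ssc_keys(sim.quad["twin_unaffected"])
        own = [c for c in twin.small if c.key not in cotwin_keys]
        assert len(own) == 20  # 10 somatic + 10 decoys planted
        kept = tq.filter_high_confidence(own)
        assert len(kept) == 10
        assert {c.key for c in kept} == sim.truth_keys(
            "postzygotic_twinA", kind="ssc"
        )


class TestMosaicDropout:
    def test_retention_probability_matches_exact_binomial_sum(self):
        """Cross-check against a from-scratch binomial tail."""
        for depth, cf, floor in [(50, 1.0, 3), (50, 0.2, 3), (30, 0.5, 5),
                                 (100, 0.05, 3)]:
            p = cf / 2.0
            exact = sum(
                math.comb(depth, j) * p**j * (1 - p) ** (depth - j)
                for j in range(floor, depth + 1)
            )
            assert retention_probability(depth, cf, floor) == pytest.approx(
                exact, rel=1e-9
            )

    def test_limits(self):
        assert retention_probability(50, 1.0, 3) > 0.999
        assert retention_probability(50, 1e-6, 3) < 1e-6
        with pytest.raises(ConfigError):
            retention_probability(50, 1.5)

    def test_dropout_is_deterministic_and_marks_truth(self):
        config = tq.SimulationConfig(
            seed=23, n_somatic_per_twin=50, mosaic_model=("fixed", 0.08),
            depth_mean=50.0, n_inherited_discordant=0,
        )
        ref, sim = _quad(config)
        drops = []
        for _ in range(2):
            degraded = tq.apply_mosaic_dropout(
                sim, config, tq.rng_streams(config.seed)[2]
            )
            lost = {
                t.key for t in degraded.truth
                if t.origin.startswith("postzygotic") and not t.retained
            }
            drops.append(lost)
            # emitted call sets agree with the recorded retention flags
            for role, origin in (("twin_affected", "postzygotic_twinA"),
                                 ("twin_unaffected", "postzygotic_twinB")):
                emitted = _ssc_keys(degraded.quad[role])
                for t in degraded.truth:
                    if t.origin == origin and t.kind == "ssc":
                        assert (t.key in emitted) == t.retained
        assert drops[0] == drops[1]
        assert drops[0], "a 0.08 cell fraction at depth 50 must lose calls"

    def test_full_cell_fraction_retains_everything(self):
        config = tq.SimulationConfig(
            seed=29, n_somatic_per_twin=30, mosaic_model=("fixed", 1.0),
            depth_mean=100.0, n_inherited_discordant=0,
        )
        _, sim = _quad(config)
        degraded = tq.apply_mosaic_dropout(sim, config,
                                           tq.rng_streams(config.seed)[2])
        assert all(t.retained for t in degraded.truth)


def test_invalid_configs_rejected():
    with pytest.raises(ConfigError):
        tq.SimulationConfig(seed=1, titv_ratio=0).validate()
    with pytest.raises(ConfigError):
        tq.SimulationConfig(seed=1, mosaic_model=("fixed", 0.0)).validate()
    with pytest.raises(ConfigError):
        tq.SimulationConfig(seed=1, n_genes=10).validate()  # sets need 144
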