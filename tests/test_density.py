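"""Density profiling, matched random sampling, CNGD and regimes."""

import numpy as np
import pytest

from syndense import (
    GeneRecord,
    OrthologyMap,
    block_cngd,
    build_genome_index,
    classify_paralogous,
    cngd,
    compare_to_random,
    cross_taxon_cngd,
    min_orthogroup_pair_distance,
    profile_instance,
    regime_classify,
    sample_random_blocks,
)
from syndense.blocks import BlockInstance, MultiSpeciesBlock
from syndense.density import CngdRecord

from conftest import make_genome, uniform_genome


def instance_of(genome, gene_ids, idx=0):
    genes = tuple(genome.gene(g) for g in gene_ids)
    return BlockInstance(genome.species_id, genes[0].chromosome_id, genes, idx)


class TestProfileInstance:
    def test_direct_arithmetic(self):
        # 10 genes fully inside a 100 kb span; genome 200 genes / 10 Mb
        layout = {
            "chr1": [(f"g{i}", 10_000 * i + 1, 10_000 * i + 4_000) for i in range(10)]
        }
        layout["chr2"] = [
            (f"h{i}", 50_000 * i + 1, 50_000 * i + 4_000) for i in range(190)
        ]
        g = make_genome("s", layout, assembly_size=10_000_000)
        inst = instance_of(g, ["g0", "g4", "g9"])
        prof = profile_instance(inst, g)
        assert prof.span == 94_000
        assert prof.genes_in_span == 10
        assert prof.raw_density == pytest.approx(10 / 94_000)
        whole = 200 / 10_000_000
        assert prof.normalized_density == pytest.approx((10 / 94_000) / whole)

    def test_intergenic_median_and_span(self):
        g = make_genome(
            "s",
            {"chr1": [("a", 100, 200), ("b", 301, 400), ("c", 901, 1000)]},
        )
        prof = profile_instance(instance_of(g, ["a", "b", "c"]), g)
        assert prof.span == 901
        assert prof.median_intergenic_distance == 300.0

    def test_overlapping_members_clamp_to_zero(self):
        g = make_genome(
            "s",
            {"chr1": [("a", 100, 300), ("b", 250, 400), ("c", 500, 600)]},
        )
        prof = profile_instance(instance_of(g, ["a", "b", "c"]), g)
        assert prof.median_intergenic_distance == np.median([0, 99])

    def test_partially_overlapping_genes_not_counted(self):
        g = make_genome(
            "s",
            {"chr1": [("a", 100, 200), ("x", 150, 350), ("b", 300, 400),
                      ("y", 390, 900), ("c", 500, 600)]},
        )
        prof = profile_instance(instance_of(g, ["a", "b", "c"]), g)
        # span 100..600; x (150-350) fully inside, y (390-900) sticks out
        assert prof.genes_in_span == 4

    def test_missing_member_is_error(self):
        g = make_genome("s", {"chr1": [("a", 1, 10), ("b", 20, 30), ("c", 40, 50)]})
        ghost = BlockInstance(
            "s", "chr1", (g.gene("a"), g.gene("b"), GeneRecord("zz", "s", "chr1", 60, 70)), 0
        )
        with pytest.raises(KeyError):
            profile_instance(ghost, g)

    def test_scale_invariance(self):
        layout = {"chr1": [(f"g{i}", 500 * i + 3, 500 * i + 400) for i in range(30)]}
        g1 = make_genome("s", layout, assembly_size=20_000)
        g2 = make_genome(
            "s",
            {"chr1": [(gid, (s - 1) * 7 + 1, e * 7) for gid, s, e in layout["chr1"]]},
            assembly_size=140_000,
        )
        ids = ["g3", "g5", "g9"]
        p1 = profile_instance(instance_of(g1, ids), g1)
        p2 = profile_instance(instance_of(g2, ids), g2)
        assert p2.normalized_density == pytest.approx(p1.normalized_density, rel=1e-6)


class TestParalogClassification:
    @pytest.mark.parametrize(
        "ogs,expected_frac,expected_flag",
        [
            (["O1", "O1", "O2", "O3", "O4"], 0.4, False),  # strict >
            (["O1", "O1", "O1", "O2", "O3"], 0.6, True),
            (["O1", "O2", "O3", "O4", "O5"], 0.2, False),
        ],
    )
    def test_fraction_rule(self, ogs, expected_frac, expected_flag):
        g = make_genome(
            "s",
            {"chr1": [(f"g{i}", 100 * i + 1, 100 * i + 50) for i in range(len(ogs))]},
            og_of={f"g{i}": og for i, og in enumerate(ogs)},
        )
        orth = OrthologyMap({f"g{i}": og for i, og in enumerate(ogs)})
        frac, flag = classify_paralogous(
            instance_of(g, [f"g{i}" for i in range(len(ogs))]), orth
        )
        assert frac == pytest.approx(expected_frac)
        assert flag is expected_flag

    def test_requires_three_members(self):
        g = make_genome("s", {"chr1": [("a", 1, 10), ("b", 20, 30)]})
        orth = OrthologyMap({"a": "O1", "b": "O2"})
        with pytest.raises(ValueError):
            classify_paralogous(instance_of(g, ["a", "b"]), orth)


class TestRandomSampling:
    def test_uniform_genome_concentrates_at_one(self):
        # abutting equal-footprint genes: every window has exactly the
        # genome-average density
        g = uniform_genome("s", 400, footprint=1000, gene_len=1000)
        inst = instance_of(g, [f"s_g{i}" for i in (50, 52, 54, 56)])
        rs = sample_random_blocks(inst, g, n=100, seed=4)
        se = rs.normalized_densities.std(ddof=1) / 10.0
        assert abs(rs.normalized_densities.mean() - 1.0) <= max(3 * se, 1e-12)

    def test_gap_pattern_fidelity(self, small_dataset):
        g = small_dataset.genomes["a1"]
        truth = next(p for p in small_dataset.truth.planted if "a1" in p.member_gene_ids)
        inst = instance_of(g, truth.member_gene_ids["a1"])
        obs_ords = [g.locate(x)[1] for x in inst.gene_ids()]
        obs_gaps = [b - a - 1 for a, b in zip(obs_ords, obs_ords[1:])]
        rs = sample_random_blocks(inst, g, n=50, seed=9)
        for slots in rs.gene_id_samples:
            ords = [g.locate(x)[1] for x in slots]
            gaps = [b - a - 1 for a, b in zip(ords, ords[1:])]
            assert gaps == obs_gaps
            assert len(slots) == len(inst.genes)

    def test_fixed_seed_reproducible(self):
        g = uniform_genome("s", 100, footprint=1000, gene_len=500)
        inst = instance_of(g, ["s_g10", "s_g12", "s_g13"])
        r1 = sample_random_blocks(inst, g, n=20, seed=5)
        r2 = sample_random_blocks(inst, g, n=20, seed=5)
        assert r1.gene_id_samples == r2.gene_id_samples
        assert np.array_equal(r1.normalized_densities, r2.normalized_densities)

    def test_window_equal_to_chromosome_forces_placement(self):
        g = uniform_genome("s", 6, footprint=1000, gene_len=500)
        inst = instance_of(g, [f"s_g{i}" for i in range(6)])
        rs = sample_random_blocks(inst, g, n=10, seed=1)
        assert all(s == tuple(f"s_g{i}" for i in range(6)) for s in rs.gene_id_samples)

    def test_placements_always_fit_chosen_chromosome(self):
        # the ordinal window can never exceed its host chromosome, so every
        # sampled placement must fit entirely
        g = uniform_genome("s", 30, footprint=1000, gene_len=500)
        inst = instance_of(g, ["s_g2", "s_g9", "s_g14"])
        rs = sample_random_blocks(inst, g, n=50, seed=3)
        for slots in rs.gene_id_samples:
            ords = sorted(g.locate(x)[1] for x in slots)
            assert 0 <= ords[0] and ords[-1] <= 29


class TestCngd:
    @pytest.mark.parametrize("obs,rand,expected", [(2.0, 1.0, 1.0), (1.0, 1.0, 0.0)])
    def test_analytic_identities(self, obs, rand, expected):
        assert cngd(obs, rand) == expected

    def test_half_density_under_the_relative_change_formula(self):
        # (obs - rand)/rand at half the random density; the formula's value
        # is -0.5 and -1 is approached only as obs -> 0
        assert cngd(0.5, 1.0) == -0.5
        assert cngd(1e-12, 1.0) == pytest.approx(-1.0)

    def test_nonpositive_random_median_is_error(self):
        with pytest.raises(ValueError):
            cngd(1.0, 0.0)

    def test_lower_bound_and_swap_identity(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            o, r = rng.uniform(0.01, 5.0, 2)
            v = cngd(o, r)
            assert v >= -1.0
            swapped = cngd(r, o)
            assert swapped == pytest.approx(1.0 / (1.0 + v) - 1.0)


class TestCompareToRandom:
    def _profiles(self, values):
        return [
            type("P", (), {"normalized_density": v, "median_intergenic_distance": v})()
            for v in values
        ]

    def _randset(self, values):
        arr = np.asarray(values, dtype=float)
        return type(
            "R", (), {"normalized_densities": arr, "intergenic_medians": arr}
        )()

    def test_identical_multisets_give_p_one(self):
        vals = [1.0, 2.0, 3.0, 4.0, 5.0]
        comp = compare_to_random(self._profiles(vals), [self._randset(vals)])
        assert comp.direction == "equal"
        assert comp.wilcoxon_p == 1.0

    def test_complete_separation_exact_p(self):
        comp = compare_to_random(
            self._profiles([10, 11, 12, 13, 14]),
            [self._randset([1, 2, 3, 4, 5])],
        )
        assert comp.direction == "higher"
        assert comp.wilcoxon_p == pytest.approx(2 / 252)

    def test_empty_random_pool_is_error(self):
        with pytest.raises(ValueError):
            compare_to_random(self._profiles([1.0]), [])


class TestRegimes:
    @pytest.mark.parametrize(
        "value,expected",
        [(0.8, "low"), (2.5, "high"), (1.0, "average"), (2.0, "average"), (1.5, "average")],
    )
    def test_thresholds(self, value, expected):
        assert regime_classify(value) == expected

    def test_species_specific_thresholds(self):
        assert regime_classify(1.4, low=1.47, high=1.84) == "low"
        assert regime_classify(1.9, low=1.34, high=1.98) == "average"


class TestCrossTaxonCngd:
    def test_identical_vectors_rho_one(self):
        recs = [
            CngdRecord(block_id=i, taxon=t, cngd=float(i) / 7)
            for t in ("T1", "T2")
            for i in range(12)
        ]
        out = cross_taxon_cngd(recs)
        assert out[("T1", "T2")]["rho"] == pytest.approx(1.0)
        assert out[("T1", "T2")]["n_shared"] == 12

    def test_below_min_shared_reported_missing(self):
        recs = [
            CngdRecord(block_id=i, taxon=t, cngd=float(i))
            for t in ("T1", "T2")
            for i in range(9)
        ]
        out = cross_taxon_cngd(recs)
        assert out[("T1", "T2")]["rho"] is None
        assert out[("T1", "T2")]["n_shared"] == 9

    def test_matches_rank_then_pearson_oracle(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=15)
        b = 0.5 * a + rng.normal(size=15)
        recs = [CngdRecord(i, "T1", a[i]) for i in range(15)] + [
            CngdRecord(i, "T2", b[i]) for i in range(15)
        ]
        out = cross_taxon_cngd(recs)
        ra = np.argsort(np.argsort(a)).astype(float)
        rb = np.argsort(np.argsort(b)).astype(float)
        manual = np.corrcoef(ra, rb)[0, 1]
        assert out[("T1", "T2")]["rho"] == pytest.approx(manual, abs=1e-12)


class TestMinOrthogroupPairDistance:
    def _block(self, genomes, member_map, ogs):
        instances = {
            sp: [instance_of(genomes[sp], ids)] for sp, ids in member_map.items()
        }
        return MultiSpeciesBlock(1, frozenset(ogs), instances)

    def test_direct_arithmetic_and_minimum_over_species(self):
        g1 = make_genome(
            "s1",
            {"chr1": [("a1", 1, 1000), ("b1", 11_001, 12_000), ("c1", 20_001, 21_000)]},
            assembly_size=1_000_000,
        )
        g2 = make_genome(
            "s2",
            {"chr1": [("a2", 1, 1000), ("b2", 2_001, 3_000), ("c2", 9_001, 10_000)]},
            assembly_size=1_000_000,
        )
        orth = OrthologyMap(
            {"a1": "O1", "b1": "O2", "c1": "O3", "a2": "O1", "b2": "O2", "c2": "O3"}
        )
        block = self._block(
            {"s1": g1, "s2": g2}, {"s1": ["a1", "b1", "c1"], "s2": ["a2", "b2", "c2"]},
            ["O1", "O2", "O3"],
        )
        edges = min_orthogroup_pair_distance(block, {"s1": g1, "s2": g2}, ["s1", "s2"], orth)
        assert edges[("O1", "O2")] == pytest.approx(1000 / 1_000_000)  # s2 is closer
        assert ("O1", "O1") not in edges  # single copy, no self-edge

    def test_self_edge_for_duplicated_orthogroup(self):
        g = make_genome(
            "s1",
            {"chr1": [("a", 1, 1000), ("a2", 6_001, 7_000), ("b", 9_001, 10_000)]},
            assembly_size=100_000,
        )
        orth = OrthologyMap({"a": "O1", "a2": "O1", "b": "O2"})
        block = self._block({"s1": g}, {"s1": ["a", "a2", "b"]}, ["O1", "O2"])
        edges = min_orthogroup_pair_distance(block, {"s1": g}, ["s1"], orth)
        assert edges[("O1", "O1")] == pytest.approx(5000 / 100_000)
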