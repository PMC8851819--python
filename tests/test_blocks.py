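"""Pairwise detection, fusion rules and shuffled-genome nulls."""

import numpy as np
import pytest

from syndense import (
    GeneRecord,
    OrthologyMap,
    PairwiseBlock,
    ShuffleSpec,
    build_genome_index,
    detect_blocks,
    find_pairwise_blocks,
    fuse_pairwise_blocks,
    shuffle_genome,
)

from conftest import make_genome
from oracles import block_signatures, exhaustive_detect, random_micro_genomes


def genome_from_ogs(species, og_sequence, chrom="chr1"):
    """Genome with one gene per symbol; None means an unlabeled gene."""
    records, og_of = [], {}
    for i, og in enumerate(og_sequence):
        gid = f"{species}_g{i}"
        records.append(GeneRecord(gid, species, chrom, 1000 * i + 1, 1000 * i + 500, "+", og))
        if og is not None:
            og_of[gid] = og
    return build_genome_index(records, 1000 * len(og_sequence) + 1000), og_of


class TestFindPairwiseBlocks:
    def test_hand_enumerated_chain(self):
        # A: O1 . O2 O3 ; B: O3 O1 . . O2  (. = gene with non-shared label)
        ga, ma = genome_from_ogs("A", ["O1", "X1", "O2", "O3"])
        gb, mb = genome_from_ogs("B", ["O3", "O1", "Y1", "Y2", "O2"])
        orth = OrthologyMap({**ma, **mb})
        blocks = find_pairwise_blocks(ga, gb, orth)
        assert len(blocks) == 1
        assert blocks[0].orthogroups == {"O1", "O2", "O3"}

    def test_two_shared_orthogroups_below_minimum(self):
        ga, ma = genome_from_ogs("A", ["O1", "O2", "X1"])
        gb, mb = genome_from_ogs("B", ["O1", "O2", "Y1"])
        orth = OrthologyMap({**ma, **mb})
        assert find_pairwise_blocks(ga, gb, orth) == []

    def test_self_identity_whole_chromosome(self):
        seq = [f"O{i}" for i in range(8)]
        ga, ma = genome_from_ogs("A", seq)
        gb, mb = genome_from_ogs("B", seq)
        orth = OrthologyMap({**ma, **mb})
        blocks = find_pairwise_blocks(ga, gb, orth)
        assert len(blocks) == 1
        assert len(blocks[0].genes_a) == 8 and len(blocks[0].genes_b) == 8

    def test_gap_above_limit_splits_block(self):
        # members separated by 6 interveners on A cannot chain
        seq_a = ["O1", "O2", "O3"] + ["X"] * 6 + ["O4", "O5", "O6"]
        ga, ma = genome_from_ogs("A", seq_a)
        gb, mb = genome_from_ogs("B", ["O1", "O2", "O3", "O4", "O5", "O6"])
        orth = OrthologyMap({**ma, **mb})
        blocks = find_pairwise_blocks(ga, gb, orth)
        assert sorted(sorted(b.orthogroups) for b in blocks) == [
            ["O1", "O2", "O3"], ["O4", "O5", "O6"],
        ]

    def test_symmetry(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            a, b, orth = random_micro_genomes(rng)
            fwd = find_pairwise_blocks(a, b, orth)
            rev = find_pairwise_blocks(b, a, orth)
            def sig(blocks, first_species):
                return {
                    (
                        frozenset(g.gene_id for g in blk.genes_of(first_species)),
                        frozenset(g.gene_id for g in blk.genes_of("y")),
                    )
                    for blk in blocks
                }
            assert sig(fwd, "x") == sig(rev, "x")

    def test_monotone_in_max_interveners(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            a, b, orth = random_micro_genomes(rng)
            counts = []
            for mi in (1, 3, 5, 8):
                blocks = find_pairwise_blocks(a, b, orth, max_interveners=mi)
                counts.append(sum(len(blk.genes_a) for blk in blocks))
            assert counts == sorted(counts)

    def test_monotone_in_min_genes(self):
        # total genes in blocks is non-increasing as min_genes rises (block
        # count itself is not: removing a small bridge block can split a
        # merged block into two)
        rng = np.random.default_rng(13)
        for _ in range(10):
            a, b, orth = random_micro_genomes(rng)
            totals = [
                sum(len(blk.genes_a) for blk in find_pairwise_blocks(a, b, orth, min_genes=k))
                for k in (2, 3, 4)
            ]
            assert totals == sorted(totals, reverse=True)

    def test_parameter_validation(self):
        ga, ma = genome_from_ogs("A", ["O1"])
        gb, mb = genome_from_ogs("B", ["O1"])
        orth = OrthologyMap({**ma, **mb})
        with pytest.raises(ValueError):
            find_pairwise_blocks(ga, gb, orth, min_genes=1)
        with pytest.raises(ValueError):
            find_pairwise_blocks(ga, gb, orth, max_interveners=-1)

    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(15):
            a, b, orth = random_micro_genomes(rng)
            got = block_signatures(detect_blocks({"x": a, "y": b}, orth))
            assert got == exhaustive_detect(a, b, orth)


def _pairwise(ogs_a, ogs_b=None, species=("A", "B")):
    """Minimal PairwiseBlock with given orthogroup identities."""
    ogs_b = ogs_b if ogs_b is not None else ogs_a
    genes_a = tuple(
        GeneRecord(f"{species[0]}_{og}", species[0], "c", i * 1000 + 1, i * 1000 + 500, "+", og)
        for i, og in enumerate(ogs_a)
    )
    genes_b = tuple(
        GeneRecord(f"{species[1]}_{og}", species[1], "c", i * 1000 + 1, i * 1000 + 500, "+", og)
        for i, og in enumerate(ogs_b)
    )
    return PairwiseBlock(
        species_a=species[0],
        species_b=species[1],
        genes_a=genes_a,
        genes_b=genes_b,
        ordinals_a=tuple(range(len(genes_a))),
        ordinals_b=tuple(range(len(genes_b))),
        orthogroups=frozenset(ogs_a) | frozenset(ogs_b),
    )


class TestFusion:
    def test_three_shared_orthogroups_fuse(self):
        b1 = _pairwise(["O1", "O2", "O3", "O7"], species=("A", "B"))
        b2 = _pairwise(["O1", "O2", "O3", "O8"], species=("C", "D"))
        fused = fuse_pairwise_blocks([b1, b2])
        assert len(fused) == 1
        assert fused[0].species_set == {"A", "B", "C", "D"}

    def test_half_of_smaller_block_fuses(self):
        # {O1..O4} vs {O3,O4,O9,O10}: intersection 2 = 50% of the smaller set
        b1 = _pairwise(["O1", "O2", "O3", "O4"], species=("A", "B"))
        b2 = _pairwise(["O3", "O4", "O9", "O10"], species=("C", "D"))
        assert len(fuse_pairwise_blocks([b1, b2])) == 1

    def test_single_shared_orthogroup_stays_separate(self):
        b1 = _pairwise(["O1", "O2", "O3", "O4"], species=("A", "B"))
        b2 = _pairwise(["O4", "O9", "O10", "O11"], species=("C", "D"))
        assert len(fuse_pairwise_blocks([b1, b2])) == 2

    def test_fifty_percent_rule_needs_more_than_three_ogs(self):
        # 2 of 3 shared is >=50% of the smaller set but both blocks must
        # have >3 orthogroups for the percentage criterion to apply
        b1 = _pairwise(["O1", "O2", "O3"], species=("A", "B"))
        b2 = _pairwise(["O2", "O3", "O9"], species=("C", "D"))
        assert len(fuse_pairwise_blocks([b1, b2])) == 2

    def test_block_ids_stable_and_ordered_by_species_count(self):
        b1 = _pairwise(["O1", "O2", "O3"], species=("A", "B"))
        b2 = _pairwise(["O1", "O2", "O3"], species=("C", "D"))
        b3 = _pairwise(["Z1", "Z2", "Z3"], species=("A", "B"))
        fused = fuse_pairwise_blocks([b1, b2, b3])
        assert [b.block_id for b in fused] == [1, 2]
        assert len(fused[0].species_set) >= len(fused[1].species_set)

    def test_empty_input(self):
        assert fuse_pairwise_blocks([]) == []


class TestShuffle:
    def test_single_gene_genome_unchanged(self):
        g = make_genome("s", {"chr1": [("g0", 10, 500)]})
        s = shuffle_genome(g, ShuffleSpec(seed=1))
        assert [x.gene_id for x in s.genes()] == ["g0"]

    def test_slots_and_multisets_conserved(self, small_dataset):
        g = small_dataset.genomes["a1"]
        s = shuffle_genome(g, ShuffleSpec(seed=5, replicate_index=2))
        slots = lambda gi: sorted(
            (x.chromosome_id, x.start, x.end) for x in gi.genes()
        )
        assert slots(s) == slots(g)
        assert sorted(x.gene_id for x in s.genes()) == sorted(
            x.gene_id for x in g.genes()
        )
        assert sorted(
            x.orthogroup_id for x in s.genes() if x.orthogroup_id
        ) == sorted(x.orthogroup_id for x in g.genes() if x.orthogroup_id)
        assert s.assembly_size == g.assembly_size

    def test_determinism_and_replicate_independence(self, small_dataset):
        g = small_dataset.genomes["b1"]
        order = lambda gi: [x.gene_id for x in gi.genes()]
        s1 = shuffle_genome(g, ShuffleSpec(seed=9, replicate_index=0))
        s2 = shuffle_genome(g, ShuffleSpec(seed=9, replicate_index=0))
        s3 = shuffle_genome(g, ShuffleSpec(seed=9, replicate_index=1))
        assert order(s1) == order(s2)
        assert order(s1) != order(s3)
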