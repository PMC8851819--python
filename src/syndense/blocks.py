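"""Microsyntenic block detection, fusion and shuffled-genome nulls.

A pairwise microsyntenic block is a set of at least three orthologous genes
found in both genomes of a species pair, with no more than five intervening
genes between consecutive members on either genome.  Collinearity (conserved
order/orientation) is NOT required.  Pairwise blocks are fused into
multi-species blocks when they share at least three orthogroups, or — for
blocks of more than three orthogroups — at least half of the smaller block's
orthogroup set.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io import GeneRecord, GenomeIndex, OrthologyMap

__all__ = [
    "BlockInstance",
    "PairwiseBlock",
    "MultiSpeciesBlock",
    "ShuffleSpec",
    "find_pairwise_blocks",
    "fuse_pairwise_blocks",
    "detect_blocks",
    "shuffle_genome",
    "detection_false_positive_run",
    "split_chain",
]

# A "seg" during chaining is a tuple of (chromosome, ordinal, GeneRecord, og)
# entries, ordinal-sorted within one chromosome.
_Entry = tuple[str, int, GeneRecord, str]


@dataclass(frozen=True)
class BlockInstance:
    """One chromosome-contiguous run of member genes of a block."""

    species_id: str
    chromosome_id: str
    genes: tuple[GeneRecord, ...]
    instance_index: int = 0

    def gene_ids(self) -> tuple[str, ...]:
        return tuple(g.gene_id for g in self.genes)


@dataclass
class PairwiseBlock:
    """A syntenic unit shared by one species pair.

    ``genes_a``/``genes_b`` are member genes sorted by (chromosome, ordinal);
    ``ordinals_a``/``ordinals_b`` are the members' ordinal positions in their
    genome, kept so that fusion can re-apply the intervener rule without the
    genome at hand.  After the final share-a-gene merge a side may in rare
    cases span more than one chromosome.
    """

    species_a: str
    species_b: str
    genes_a: tuple[GeneRecord, ...]
    genes_b: tuple[GeneRecord, ...]
    ordinals_a: tuple[int, ...]
    ordinals_b: tuple[int, ...]
    orthogroups: frozenset[str]

    def genes_of(self, species_id: str) -> tuple[GeneRecord, ...]:
        if species_id == self.species_a:
            return self.genes_a
        if species_id == self.species_b:
            return self.genes_b
        raise KeyError(species_id)

    @property
    def species_pair(self) -> tuple[str, str]:
        return (self.species_a, self.species_b)


@dataclass
class MultiSpeciesBlock:
    """Fusion of pairwise blocks: orthogroup union plus per-species instances."""

    block_id: int
    orthogroups: frozenset[str]
    instances: dict[str, list[BlockInstance]]
    provenance: tuple[int, ...] = ()

    @property
    def species_set(self) -> frozenset[str]:
        return frozenset(s for s, insts in self.instances.items() if insts)


@dataclass(frozen=True)
class ShuffleSpec:
    """Deterministic identity of one shuffled-genome replicate."""

    seed: int
    replicate_index: int = 0


def split_chain(
    entries: Sequence[_Entry], max_interveners: int
) -> list[list[_Entry]]:
    """Split an ordinal-sorted run wherever more than ``max_interveners``
    genes (of any kind) separate consecutive entries, or the chromosome
    changes."""
    out: list[list[_Entry]] = []
    cur: list[_Entry] = []
    for e in entries:
        if cur and (
            e[0] != cur[-1][0] or e[1] - cur[-1][1] - 1 > max_interveners
        ):
            out.append(cur)
            cur = []
        cur.append(e)
    if cur:
        out.append(cur)
    return out


def _candidate_segments(
    genome: GenomeIndex, shared: set[str], orth: OrthologyMap, max_interveners: int
) -> list[list[_Entry]]:
    segments: list[list[_Entry]] = []
    for chrom, genes in genome.chromosomes.items():
        entries = [
            (chrom, i, g, og)
            for i, g in enumerate(genes)
            if (og := orth.orthogroup(g.gene_id)) in shared
        ]
        segments.extend(split_chain(entries, max_interveners))
    return segments


def find_pairwise_blocks(
    a: GenomeIndex,
    b: GenomeIndex,
    orth: OrthologyMap,
    min_genes: int = 3,
    max_interveners: int = 5,
) -> list[PairwiseBlock]:
    """Detect pairwise microsyntenic blocks between two genomes.

    Fixed-point chaining: start from candidate segments of shared-orthogroup
    genes, then repeatedly restrict each candidate segment pair to its common
    orthogroups and re-split at gaps of more than ``max_interveners`` genes
    until stable.  Stable pairs with at least ``min_genes`` members on both
    sides are emitted, and emitted blocks sharing a gene on either side are
    merged.  The result is symmetric in (a, b) and independent of input
    order.
    """
    if min_genes < 2:
        raise ValueError("min_genes must be >= 2")
    if max_interveners < 0:
        raise ValueError("max_interveners must be >= 0")

    shared = orth.orthogroups_in(a) & orth.orthogroups_in(b)
    if not shared:
        return []
    segs_a = _candidate_segments(a, shared, orth, max_interveners)
    segs_b = _candidate_segments(b, shared, orth, max_interveners)

    def ogs(seg: Sequence[_Entry]) -> frozenset[str]:
        return frozenset(e[3] for e in seg)

    def key(seg_x: Sequence[_Entry], seg_y: Sequence[_Entry]) -> tuple:
        return (
            tuple(e[2].gene_id for e in seg_x),
            tuple(e[2].gene_id for e in seg_y),
        )

    queue: list[tuple[list[_Entry], list[_Entry]]] = [
        (sa, sb)
        for sa in segs_a
        for sb in segs_b
        if len(sa) >= min_genes and len(sb) >= min_genes and ogs(sa) & ogs(sb)
    ]
    seen: set[tuple] = set()
    stable: dict[tuple, tuple[list[_Entry], list[_Entry]]] = {}

    while queue:
        sa, sb = queue.pop()
        k = key(sa, sb)
        if k in seen:
            continue
        seen.add(k)
        common = ogs(sa) & ogs(sb)
        fa = [e for e in sa if e[3] in common]
        fb = [e for e in sb if e[3] in common]
        sub_a = split_chain(fa, max_interveners)
        sub_b = split_chain(fb, max_interveners)
        if len(sub_a) == 1 and len(sub_b) == 1 and len(fa) == len(sa) and len(
            fb
        ) == len(sb):
            if len(sa) >= min_genes and len(sb) >= min_genes:
                stable[k] = (sa, sb)
            continue
        for na, nb in itertools.product(sub_a, sub_b):
            if len(na) >= min_genes and len(nb) >= min_genes and ogs(na) & ogs(nb):
                queue.append((na, nb))

    # merge stable pairs sharing >=1 gene on either side (union-find)
    pairs = list(stable.values())
    parent = list(range(len(pairs)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj

    owner: dict[tuple[int, str], int] = {}
    for idx, (sa, sb) in enumerate(pairs):
        for side, seg in ((0, sa), (1, sb)):
            for e in seg:
                gk = (side, e[2].gene_id)
                if gk in owner:
                    union(idx, owner[gk])
                else:
                    owner[gk] = idx

    groups: dict[int, list[int]] = {}
    for idx in range(len(pairs)):
        groups.setdefault(find(idx), []).append(idx)

    blocks: list[PairwiseBlock] = []
    for members in groups.values():
        ga: dict[str, _Entry] = {}
        gb: dict[str, _Entry] = {}
        for idx in members:
            sa, sb = pairs[idx]
            for e in sa:
                ga[e[2].gene_id] = e
            for e in sb:
                gb[e[2].gene_id] = e
        ea = sorted(ga.values(), key=lambda e: (e[0], e[1]))
        eb = sorted(gb.values(), key=lambda e: (e[0], e[1]))
        blocks.append(
            PairwiseBlock(
                species_a=a.species_id,
                species_b=b.species_id,
                genes_a=tuple(e[2] for e in ea),
                genes_b=tuple(e[2] for e in eb),
                ordinals_a=tuple(e[1] for e in ea),
                ordinals_b=tuple(e[1] for e in eb),
                orthogroups=frozenset(e[3] for e in ea) | frozenset(e[3] for e in eb),
            )
        )
    blocks.sort(
        key=lambda blk: (
            blk.genes_a[0].chromosome_id,
            blk.genes_a[0].start,
            blk.genes_b[0].chromosome_id,
            blk.genes_b[0].start,
        )
    )
    return blocks


def _fusable(x: PairwiseBlock, y: PairwiseBlock) -> bool:
    inter = len(x.orthogroups & y.orthogroups)
    if inter >= 3:
        return True
    smaller = min(len(x.orthogroups), len(y.orthogroups))
    if len(x.orthogroups) > 3 and len(y.orthogroups) > 3:
        return inter >= 0.5 * smaller
    return False


def fuse_pairwise_blocks(
    blocks: Sequence[PairwiseBlock],
    min_genes: int = 3,
    max_interveners: int = 5,
) -> list[MultiSpeciesBlock]:
    """Fuse pairwise blocks into multi-species blocks.

    Blocks are nodes of an undirected graph with an edge when they share at
    least three orthogroups, or (both blocks having more than three
    orthogroups) at least 50% of the smaller block's orthogroup set.
    Connected components become multi-species blocks; per species the member
    genes of all contributing pairwise blocks are merged and re-split into
    chromosome-contiguous instances by the same intervener rule, dropping
    fragments below ``min_genes``.
    """
    n = len(blocks)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj

    # candidate edges via shared-orthogroup inverted index to avoid O(n^2)
    by_og: dict[str, list[int]] = {}
    for i, blk in enumerate(blocks):
        for og in blk.orthogroups:
            by_og.setdefault(og, []).append(i)
    candidates: set[tuple[int, int]] = set()
    for idxs in by_og.values():
        for i, j in itertools.combinations(sorted(idxs), 2):
            candidates.add((i, j))
    for i, j in candidates:
        if _fusable(blocks[i], blocks[j]):
            union(i, j)

    components: dict[int, list[int]] = {}
    for i in range(n):
        components.setdefault(find(i), []).append(i)

    fused: list[MultiSpeciesBlock] = []
    for members in components.values():
        # per species: gene_id -> (chrom, ordinal, record)
        per_species: dict[str, dict[str, tuple[str, int, GeneRecord]]] = {}
        orthogroups: set[str] = set()
        for i in members:
            blk = blocks[i]
            orthogroups |= blk.orthogroups
            for sp, genes, ordinals in (
                (blk.species_a, blk.genes_a, blk.ordinals_a),
                (blk.species_b, blk.genes_b, blk.ordinals_b),
            ):
                bucket = per_species.setdefault(sp, {})
                for g, o in zip(genes, ordinals):
                    bucket[g.gene_id] = (g.chromosome_id, o, g)
        instances: dict[str, list[BlockInstance]] = {}
        for sp in sorted(per_species):
            entries = sorted(per_species[sp].values(), key=lambda t: (t[0], t[1]))
            runs: list[list[tuple[str, int, GeneRecord]]] = []
            cur: list[tuple[str, int, GeneRecord]] = []
            for t in entries:
                if cur and (
                    t[0] != cur[-1][0] or t[1] - cur[-1][1] - 1 > max_interveners
                ):
                    runs.append(cur)
                    cur = []
                cur.append(t)
            if cur:
                runs.append(cur)
            insts = [run for run in runs if len(run) >= min_genes]
            if insts:
                instances[sp] = [
                    BlockInstance(sp, run[0][0], tuple(t[2] for t in run), k)
                    for k, run in enumerate(insts)
                ]
        if instances:
            fused.append(
                MultiSpeciesBlock(
                    block_id=-1,
                    orthogroups=frozenset(orthogroups),
                    instances=instances,
                    provenance=tuple(sorted(members)),
                )
            )

    fused.sort(key=lambda b: (-len(b.species_set), min(b.orthogroups)))
    for i, b in enumerate(fused):
        b.block_id = i + 1
    return fused


def detect_blocks(
    genomes: Mapping[str, GenomeIndex],
    orth: OrthologyMap,
    min_genes: int = 3,
    max_interveners: int = 5,
) -> list[MultiSpeciesBlock]:
    """All-against-all pairwise detection followed by fusion."""
    species = sorted(genomes)
    pairwise: list[PairwiseBlock] = []
    for sa, sb in itertools.combinations(species, 2):
        pairwise.extend(
            find_pairwise_blocks(
                genomes[sa], genomes[sb], orth, min_genes, max_interveners
            )
        )
    return fuse_pairwise_blocks(
        pairwise, min_genes=min_genes, max_interveners=max_interveners
    )


def shuffle_genome(g: GenomeIndex, spec: ShuffleSpec) -> GenomeIndex:
    """Permute gene identities over the genome's fixed position slots.

    Gene identities (ids, hence orthogroup labels) are assigned uniformly at
    random to the multiset of (chromosome, start, end) slots genome-wide;
    coordinates, chromosome structure and assembly size are unchanged.
    Deterministic per (seed, replicate_index).
    """
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=spec.seed, spawn_key=(spec.replicate_index,))
    )
    slots = [
        (chrom, gene.start, gene.end)
        for chrom in g.chromosomes
        for gene in g.chromosomes[chrom]
    ]
    genes = list(g.genes())
    perm = rng.permutation(len(genes))
    records = [
        GeneRecord(
            gene_id=genes[perm[i]].gene_id,
            species_id=genes[perm[i]].species_id,
            chromosome_id=slots[i][0],
            start=slots[i][1],
            end=slots[i][2],
            strand=genes[perm[i]].strand,
            orthogroup_id=genes[perm[i]].orthogroup_id,
        )
        for i in range(len(genes))
    ]
    return build_genome_index_like(g, records)


def build_genome_index_like(g: GenomeIndex, records: list[GeneRecord]) -> GenomeIndex:
    from .io import build_genome_index

    return build_genome_index(records, g.assembly_size)


def detection_false_positive_run(
    genomes: Mapping[str, GenomeIndex],
    orth: OrthologyMap,
    tree,
    seed: int,
    replicates: int = 3,
    min_genes: int = 3,
    max_interveners: int = 5,
):
    """Shuffle every genome, rerun detection+fusion+ancestry, count blocks.

    Returns a list (one entry per replicate) of per-node dicts
    ``{node: {"novel": int, "inherited": int}}`` — the chance-detection
    floor used to assess false positives.
    """
    from .ancestry import assign_emergence, node_block_counts

    if len(genomes) < 2:
        raise ValueError("need at least two species")
    out = []
    for rep in range(replicates):
        shuffled = {
            sp: shuffle_genome(g, ShuffleSpec(seed=seed, replicate_index=rep * 10007 + i))
            for i, (sp, g) in enumerate(sorted(genomes.items()))
        }
        blocks = detect_blocks(shuffled, orth, min_genes, max_interveners)
        assignment = assign_emergence(blocks, tree)
        out.append(node_block_counts(assignment, tree))
    return out
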