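"""Independent brute-force oracles used only by the test suite.

The detection oracle enumerates every orthogroup subset and every chain
pair explicitly, applies dominance filtering, then merges and fuses with
its own networkx-based logic — a deliberately different route from the
package's fixed-point chaining implementation.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np


def _chains_for_subset(genome, orth, subset, max_interveners):
    """All per-chromosome chains of subset-member genes whose orthogroup
    set covers the subset exactly."""
    chains = []
    for chrom, genes in genome.chromosomes.items():
        entries = [
            (i, g, orth.orthogroup(g.gene_id))
            for i, g in enumerate(genes)
            if orth.orthogroup(g.gene_id) in subset
        ]
        cur = []
        for e in entries:
            if cur and e[0] - cur[-1][0] - 1 > max_interveners:
                chains.append(cur)
                cur = []
            cur.append(e)
        if cur:
            chains.append(cur)
    return [
        c
        for c in chains
        if {e[2] for e in c} == set(subset)
    ]


def exhaustive_detect(genome_a, genome_b, orth, min_genes=3, max_interveners=5):
    """Exhaustive-search equivalent of detect-and-fuse for two genomes.

    Returns a set of block signatures: frozensets of (species, gene_id)
    over all member genes of each final multi-species block.
    """
    shared = sorted(orth.orthogroups_in(genome_a) & orth.orthogroups_in(genome_b))
    qualifying = []  # (frozenset genes_a_ids, frozenset genes_b_ids, og frozenset)
    for r in range(1, len(shared) + 1):
        for subset in itertools.combinations(shared, r):
            chains_a = _chains_for_subset(genome_a, orth, subset, max_interveners)
            chains_b = _chains_for_subset(genome_b, orth, subset, max_interveners)
            for ca, cb in itertools.product(chains_a, chains_b):
                if len(ca) >= min_genes and len(cb) >= min_genes:
                    qualifying.append(
                        (
                            frozenset(e[1].gene_id for e in ca),
                            frozenset(e[1].gene_id for e in cb),
                            frozenset(subset),
                        )
                    )
    # dominance filter: drop pairs contained in a larger qualifying pair
    keep = []
    for i, (ga, gb, og) in enumerate(qualifying):
        dominated = any(
            (ga <= ga2 and gb <= gb2 and (ga != ga2 or gb != gb2))
            for j, (ga2, gb2, _) in enumerate(qualifying)
            if j != i
        )
        if not dominated and (ga, gb, og) not in keep:
            keep.append((ga, gb, og))

    # merge pairs sharing a gene on either side
    g = nx.Graph()
    g.add_nodes_from(range(len(keep)))
    for i, j in itertools.combinations(range(len(keep)), 2):
        if keep[i][0] & keep[j][0] or keep[i][1] & keep[j][1]:
            g.add_edge(i, j)
    merged = []
    for comp in nx.connected_components(g):
        ga = frozenset().union(*(keep[i][0] for i in comp))
        gb = frozenset().union(*(keep[i][1] for i in comp))
        og = frozenset().union(*(keep[i][2] for i in comp))
        merged.append((ga, gb, og))

    # fusion rule between merged pairwise blocks
    f = nx.Graph()
    f.add_nodes_from(range(len(merged)))
    for i, j in itertools.combinations(range(len(merged)), 2):
        inter = len(merged[i][2] & merged[j][2])
        smaller = min(len(merged[i][2]), len(merged[j][2]))
        if inter >= 3 or (
            len(merged[i][2]) > 3 and len(merged[j][2]) > 3 and inter >= 0.5 * smaller
        ):
            f.add_edge(i, j)

    signatures = set()
    for comp in nx.connected_components(f):
        members = set()
        for side, genome in ((0, genome_a), (1, genome_b)):
            ids = set().union(*(merged[i][side] for i in comp))
            # re-split by the intervener rule, drop short fragments
            entries = sorted(
                (genome.locate(gid)[0], genome.locate(gid)[1], gid) for gid in ids
            )
            run = []
            runs = []
            for e in entries:
                if run and (e[0] != run[-1][0] or e[1] - run[-1][1] - 1 > max_interveners):
                    runs.append(run)
                    run = []
                run.append(e)
            if run:
                runs.append(run)
            for run in runs:
                if len(run) >= min_genes:
                    members |= {(genome.species_id, gid) for _, _, gid in run}
        if members:
            signatures.add(frozenset(members))
    return signatures


def random_micro_genomes(rng, orth_prob=0.75, n_shared_ogs=9):
    """Two random micro-genomes (<= 30 genes each) with overlapping
    orthogroup alphabets, for oracle-equivalence checks."""
    from syndense import GeneRecord, OrthologyMap, build_genome_index

    shared = [f"S{i}" for i in range(n_shared_ogs)]
    genomes = {}
    gene_to_og = {}
    for sp in ("x", "y"):
        private = [f"P_{sp}{i}" for i in range(4)]
        n_genes = int(rng.integers(18, 31))
        n_chrom = int(rng.integers(1, 3))
        records = []
        pos = {c: 0 for c in range(n_chrom)}
        for i in range(n_genes):
            c = int(rng.integers(n_chrom))
            start = pos[c] + int(rng.integers(50, 500))
            end = start + int(rng.integers(100, 2000))
            pos[c] = end
            gid = f"{sp}_g{i}"
            og = None
            if rng.random() < orth_prob:
                pool = shared if rng.random() < 0.8 else private
                og = pool[int(rng.integers(len(pool)))]
            records.append(GeneRecord(gid, sp, f"c{c}", start, end, "+", og))
            if og:
                gene_to_og[gid] = og
        genomes[sp] = build_genome_index(records, max(r.end for r in records) + 500)
    return genomes["x"], genomes["y"], OrthologyMap(gene_to_og)


def block_signatures(blocks):
    """Signature set of the package's multi-species blocks."""
    return {
        frozenset(
            (inst.species_id, g.gene_id)
            for insts in b.instances.values()
            for inst in insts
            for g in inst.genes
        )
        for b in blocks
    }
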