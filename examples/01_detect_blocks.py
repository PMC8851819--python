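"""Detect multi-species microsyntenic blocks in a small synthetic dataset.

Builds 8 genomes (4 clades x 2 species, 240 genes each) with 6 planted
syntenic blocks, then runs all-against-all pairwise detection (>= 3
orthologs per block, <= 5 intervening genes, no collinearity required)
followed by fusion into multi-species blocks.
"""

from syndense import default_config, detect_blocks, simulate_dataset

config = default_config(
    n_planted=6,
    n_clades=4,
    species_per_clade=2,
    genes_per_chromosome=120,
    n_chromosomes=2,
    n_orthogroups=100,
)
dataset = simulate_dataset(config, seed=7)
blocks = detect_blocks(dataset.genomes, dataset.orthology)

print(f"{len(blocks)} multi-species blocks detected")
b = blocks[0]
print(f"block {b.block_id}: {len(b.orthogroups)} orthogroups, "
      f"{len(b.species_set)} species")
for sp in sorted(b.instances)[:3]:
    inst = b.instances[sp][0]
    print(f"  {sp} {inst.chromosome_id}: {' '.join(inst.gene_ids())}")
# Each line is one species' instance of the block: the same orthogroups
# recur as a tight run of neighboring genes in every carrier genome.
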