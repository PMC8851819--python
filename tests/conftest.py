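import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from syndense import (
    GeneRecord,
    OrthologyMap,
    build_genome_index,
    default_config,
    simulate_dataset,
)

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_genome(species, layout, assembly_size=None, og_of=None):
    """Build a GenomeIndex from {chrom: [(gene_id, start, end), ...]}."""
    records = []
    for chrom, genes in layout.items():
        for gid, start, end in genes:
            records.append(
                GeneRecord(
                    gid,
                    species,
                    chrom,
                    start,
                    end,
                    "+",
                    (og_of or {}).get(gid),
                )
            )
    if assembly_size is None:
        assembly_size = max(r.end for r in records) + 1000
    return build_genome_index(records, assembly_size)


def uniform_genome(species, n_genes, footprint=1000, gene_len=1000, chrom="chr1",
                   og_prefix=None):
    """Genes at regular spacing; with gene_len == footprint they abut and every
    window has exactly genome-average density."""
    layout = {
        chrom: [
            (f"{species}_g{i}", i * footprint + 1, i * footprint + gene_len)
            for i in range(n_genes)
        ]
    }
    og_of = (
        {f"{species}_g{i}": f"{og_prefix}{i}" for i in range(n_genes)}
        if og_prefix
        else None
    )
    return make_genome(species, layout, assembly_size=n_genes * footprint, og_of=og_of)


@pytest.fixture(scope="session")
def default_dataset():
    """The default synthetic study conditions (12 species, 4 clades,
    2,000 genes per species, 40 planted blocks, full retention)."""
    return simulate_dataset(default_config(), seed=1)


@pytest.fixture(scope="session")
def small_dataset():
    cfg = default_config(
        n_planted=8,
        genes_per_chromosome=150,
        n_chromosomes=2,
        n_orthogroups=120,
    )
    return simulate_dataset(cfg, seed=3)
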