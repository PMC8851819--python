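"""Gene-density profiling of block instances and matched random nulls.

A block instance's span runs from the outermost coding bases of its member
genes; the gene count includes every gene (member or intervener) whose
start and end both fall inside the span.  Raw density (genes/bp) is
normalized by the whole-genome density (total genes / assembly bp), so a
normalized density of 1 means genome-average packing.  Each observed
instance is compared against randomly placed blocks that reproduce its
member count and per-gap intervener counts exactly.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .blocks import BlockInstance, MultiSpeciesBlock
from .io import GenomeIndex, OrthologyMap
from .stats import RankSumResult, rank_sum_test

__all__ = [
    "DensityProfile",
    "RandomSampleSet",
    "DensityComparison",
    "CngdRecord",
    "profile_instance",
    "classify_paralogous",
    "sample_random_blocks",
    "compare_to_random",
    "cngd",
    "block_cngd",
    "regime_classify",
    "cross_taxon_cngd",
    "min_orthogroup_pair_distance",
    "instance_seed",
]

LOW, AVERAGE, HIGH = "low", "average", "high"


@dataclass
class DensityProfile:
    block_id: int
    species_id: str
    instance_index: int
    span: int
    genes_in_span: int
    raw_density: float
    normalized_density: float
    median_intergenic_distance: float
    paralog_fraction: float = 0.0
    is_paralogous: bool = False


@dataclass
class RandomSampleSet:
    """Matched random blocks for one observed instance."""

    block_id: int
    species_id: str
    instance_index: int
    seed: int
    normalized_densities: np.ndarray
    intergenic_medians: np.ndarray
    gene_id_samples: list[tuple[str, ...]]  # the "syntenic" slot genes

    @property
    def n_samples(self) -> int:
        return len(self.normalized_densities)


@dataclass
class DensityComparison:
    grouping: tuple
    statistic: str
    n_obs: int
    n_rand: int
    median_obs: float
    median_rand: float
    direction: str  # higher / lower / equal
    u: float
    wilcoxon_p: float

    @property
    def significant(self) -> bool:
        return self.wilcoxon_p < 0.05


@dataclass(frozen=True)
class CngdRecord:
    block_id: int
    taxon: str
    cngd: float
    n_instances: int = 1


def _member_sorted(instance: BlockInstance, genome: GenomeIndex):
    members = sorted(instance.genes, key=lambda g: genome.locate(g.gene_id)[1])
    for g in members:
        genome.locate(g.gene_id)  # raises KeyError if missing
    return members


def _intergenic_median(members) -> float:
    gaps = [
        max(0, nxt.start - prev.end - 1)
        for prev, nxt in zip(members, members[1:])
    ]
    return float(np.median(gaps)) if gaps else 0.0


def profile_instance(
    instance: BlockInstance,
    genome: GenomeIndex,
    orth: OrthologyMap | None = None,
    paralog_threshold: float = 0.40,
    block_id: int = -1,
) -> DensityProfile:
    """Density statistics for one block instance.

    The span is the outermost member coordinates; genes_in_span counts every
    gene fully contained in the span (members and interveners); intergenic
    distances are taken between consecutive members, clamped at 0 for
    overlapping genes.
    """
    members = _member_sorted(instance, genome)
    chrom = instance.chromosome_id
    start = min(g.start for g in members)
    end = max(g.end for g in members)
    span = end - start + 1
    starts, ends = genome.coordinate_arrays(chrom)
    genes_in_span = int(np.count_nonzero((starts >= start) & (ends <= end)))
    raw = genes_in_span / span
    normalized = raw / genome.genome_density
    frac, is_par = (0.0, False)
    if orth is not None:
        frac, is_par = classify_paralogous(instance, orth, paralog_threshold)
    return DensityProfile(
        block_id=block_id,
        species_id=instance.species_id,
        instance_index=instance.instance_index,
        span=span,
        genes_in_span=genes_in_span,
        raw_density=raw,
        normalized_density=normalized,
        median_intergenic_distance=_intergenic_median(members),
        paralog_fraction=frac,
        is_paralogous=is_par,
    )


def classify_paralogous(
    instance: BlockInstance, orth: OrthologyMap, threshold: float = 0.40
) -> tuple[float, bool]:
    """Fraction of member genes in the largest same-orthogroup subset.

    A block is paralogous when strictly more than ``threshold`` of its
    member genes belong to one orthogroup (tandem-duplication signature).
    Computed over syntenic members only, not interveners.
    """
    if len(instance.genes) < 3:
        raise ValueError("paralogy classification needs >= 3 member genes")
    counts: dict[str, int] = {}
    for g in instance.genes:
        og = orth.orthogroup(g.gene_id)
        key = og if og is not None else f"__none_{g.gene_id}"
        counts[key] = counts.get(key, 0) + 1
    frac = max(counts.values()) / len(instance.genes)
    return frac, frac > threshold


def instance_seed(master_seed: int, block_id: int, species_id: str, instance_index: int) -> int:
    """Deterministic per-instance child seed below 2**31."""
    h = np.random.SeedSequence(
        entropy=int(master_seed) % (2**31),
        spawn_key=(
            int(block_id) % (2**31),
            abs(hash(species_id)) % (2**31),
            int(instance_index),
        ),
    )
    return int(h.generate_state(1, dtype=np.uint32)[0] % (2**31))


def sample_random_blocks(
    instance: BlockInstance,
    genome: GenomeIndex,
    n: int = 100,
    seed: int = 0,
    max_retries: int = 1000,
) -> RandomSampleSet:
    """Sample ``n`` random blocks matched to an observed instance.

    Each sample reproduces the instance's member count and per-gap
    intervener counts: a chromosome is chosen with probability proportional
    to its gene count, a start ordinal uniformly among placements that fit,
    and the member ("syntenic") slots follow the observed ordinal gap
    pattern.  Density statistics are computed on the slot genes exactly as
    for observed blocks.
    """
    members = _member_sorted(instance, genome)
    ordinals = [genome.locate(g.gene_id)[1] for g in members]
    gaps = [b - a - 1 for a, b in zip(ordinals, ordinals[1:])]
    window = len(members) + sum(gaps)  # ordinal footprint of the pattern

    chroms = sorted(genome.chromosomes)
    sizes = np.array([len(genome.chromosomes[c]) for c in chroms])
    if not np.any(sizes >= window):
        raise ValueError("block larger than any chromosome")
    weights = sizes / sizes.sum()
    offsets = np.cumsum([0] + [g + 1 for g in gaps])  # member offsets in window

    rng = np.random.default_rng(seed)
    dens = np.empty(n)
    medians = np.empty(n)
    slot_lists: list[tuple[str, ...]] = []
    wg_density = genome.genome_density
    for k in range(n):
        for attempt in range(max_retries + 1):
            ci = rng.choice(len(chroms), p=weights)
            genes = genome.chromosomes[chroms[ci]]
            if len(genes) < window:
                continue
            start_ord = int(rng.integers(0, len(genes) - window + 1))
            break
        else:
            raise ValueError("could not place random block (too many retries)")
        slots = [genes[start_ord + off] for off in offsets]
        s0 = min(g.start for g in slots)
        e0 = max(g.end for g in slots)
        span = e0 - s0 + 1
        starts, ends = genome.coordinate_arrays(chroms[ci])
        gis = int(np.count_nonzero((starts >= s0) & (ends <= e0)))
        dens[k] = (gis / span) / wg_density
        medians[k] = _intergenic_median(slots)
        slot_lists.append(tuple(g.gene_id for g in slots))
    return RandomSampleSet(
        block_id=-1,
        species_id=genome.species_id,
        instance_index=instance.instance_index,
        seed=seed,
        normalized_densities=dens,
        intergenic_medians=medians,
        gene_id_samples=slot_lists,
    )


def compare_to_random(
    obs: Sequence[DensityProfile],
    rand: Sequence[RandomSampleSet],
    statistic: str = "normalized_density",
    grouping: tuple = (),
) -> DensityComparison:
    """Pooled two-sided Wilcoxon rank-sum of observed vs random values."""
    if not obs:
        raise ValueError("no observed profiles")
    if statistic == "normalized_density":
        x = np.array([p.normalized_density for p in obs])
        pools = [r.normalized_densities for r in rand]
    elif statistic == "intergenic_median":
        x = np.array([p.median_intergenic_distance for p in obs])
        pools = [r.intergenic_medians for r in rand]
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    if not pools:
        raise ValueError("empty random pool")
    y = np.concatenate(pools)
    if y.size == 0:
        raise ValueError("empty random pool")
    res: RankSumResult = rank_sum_test(x, y)
    mo, mr = float(np.median(x)), float(np.median(y))
    direction = "equal" if mo == mr else ("higher" if mo > mr else "lower")
    return DensityComparison(
        grouping=grouping,
        statistic=statistic,
        n_obs=len(x),
        n_rand=len(y),
        median_obs=mo,
        median_rand=mr,
        direction=direction,
        u=res.u,
        wilcoxon_p=res.p_value,
    )


def cngd(median_obs: float, median_rand: float) -> float:
    """Change of normalized gene density relative to random.

    (median_obs - median_rand) / median_rand: 1 when observed blocks are
    twice as dense as random, -1 at half the random density, 0 when equal.
    """
    if median_rand <= 0:
        raise ValueError("median of random normalized densities must be > 0")
    return (median_obs - median_rand) / median_rand


def block_cngd(
    obs: Sequence[DensityProfile],
    rand: Sequence[RandomSampleSet],
    block_id: int,
    taxon: str,
) -> CngdRecord:
    """CNGD of one block within one taxon.

    Median over the taxon's observed instances of the block vs the median
    over all their random samples.
    """
    if not obs or not rand:
        raise ValueError("need observed and random values")
    m_obs = float(np.median([p.normalized_density for p in obs]))
    m_rand = float(np.median(np.concatenate([r.normalized_densities for r in rand])))
    return CngdRecord(
        block_id=block_id, taxon=taxon, cngd=cngd(m_obs, m_rand), n_instances=len(obs)
    )


def regime_classify(
    normalized_density: float, low: float = 1.0, high: float = 2.0
) -> str:
    """Tentative density regime from normalized density alone.

    Below 1 -> low regime; above 2 -> high regime; boundaries inclusive to
    average.  Species-specific thresholds (e.g. random-block quartiles) can
    be passed explicitly.
    """
    if normalized_density < 0:
        raise ValueError("normalized density must be >= 0")
    if normalized_density < low:
        return LOW
    if normalized_density > high:
        return HIGH
    return AVERAGE


def cross_taxon_cngd(
    records: Sequence[CngdRecord],
    taxon_pairs: Sequence[tuple[str, str]] | None = None,
    min_shared: int = 10,
) -> dict[tuple[str, str], dict]:
    """Spearman correlation of per-block CNGD between taxa.

    For each taxon pair sharing at least ``min_shared`` blocks, the Spearman
    rho over the shared blocks' CNGD values; pairs below the threshold are
    reported with rho and p set to None.
    """
    by_taxon: dict[str, dict[int, float]] = {}
    for rec in records:
        by_taxon.setdefault(rec.taxon, {})[rec.block_id] = rec.cngd
    if taxon_pairs is None:
        taxon_pairs = list(itertools.combinations(sorted(by_taxon), 2))
    out: dict[tuple[str, str], dict] = {}
    for ta, tb in taxon_pairs:
        shared = sorted(set(by_taxon.get(ta, {})) & set(by_taxon.get(tb, {})))
        if len(shared) < min_shared:
            out[(ta, tb)] = {"rho": None, "p": None, "n_shared": len(shared)}
            continue
        xa = [by_taxon[ta][b] for b in shared]
        xb = [by_taxon[tb][b] for b in shared]
        rho, p = sps.spearmanr(xa, xb)
        out[(ta, tb)] = {"rho": float(rho), "p": float(p), "n_shared": len(shared)}
    return out


def min_orthogroup_pair_distance(
    block: MultiSpeciesBlock,
    genomes: Mapping[str, GenomeIndex],
    taxon_species: Sequence[str],
    orth: OrthologyMap,
) -> dict[tuple[str, str], float]:
    """Minimum normalized distance between orthogroup pairs of a block.

    For every orthogroup pair (including self-pairs when an orthogroup has
    at least two member copies in a species) the minimum over all species of
    the taxon and all same-chromosome gene pairs of the bp gap between
    coding boundaries, normalized by that species' assembly size.
    """
    out: dict[tuple[str, str], float] = {}
    for sp in taxon_species:
        if sp not in block.instances or sp not in genomes:
            continue
        genome = genomes[sp]
        members = [g for inst in block.instances[sp] for g in inst.genes]
        labeled = [
            (og, g) for g in members if (og := orth.orthogroup(g.gene_id)) is not None
        ]
        for (og1, g1), (og2, g2) in itertools.combinations(labeled, 2):
            if g1.chromosome_id != g2.chromosome_id:
                continue
            gap = max(
                0, max(g1.start, g2.start) - min(g1.end, g2.end) - 1
            ) / genome.assembly_size
            key = tuple(sorted((og1, og2)))
            if key not in out or gap < out[key]:
                out[key] = gap
    return out
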