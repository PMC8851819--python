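"""Synthetic multi-species genome simulator with a machine-readable truth
manifest.

The generator emulates the input corpus of a comparative microsynteny
study: a clade-structured species tree, per-species gene orders on several
chromosomes with bp coordinates, many-to-one gene-to-orthogroup labels,
planted syntenic blocks with chosen emergence nodes, local density
multipliers, paralogy fractions and retention probabilities, and
latent-factor coexpression.  Background gene order is independent across
species, so any cross-species clustering outside the planted blocks is
chance-level — the same floor the shuffled-genome null measures.

Intergenic gaps are exponential (memoryless, so local density is a single
scale parameter); gene lengths are lognormal with fixed mean.  Gaps inside
a planted run with density multiplier m are exponential with scale
(F/m - mean gene length), F being the genome-average per-gene footprint:
multiplier-1 runs are therefore distributionally identical to background,
and multiplier-m runs have about m-fold local density.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .ancestry import NodeAssignment, SpeciesTree
from .blocks import MultiSpeciesBlock
from .density import regime_classify
from .io import ExpressionMatrix, GeneRecord, GenomeIndex, OrthologyMap, build_genome_index

__all__ = [
    "PlantedBlockSpec",
    "SimulationConfig",
    "PlantedTruth",
    "TruthManifest",
    "SimulatedDataset",
    "simulate_dataset",
    "simulate_expression",
    "evaluate_recovery",
    "default_config",
]


@dataclass(frozen=True)
class PlantedBlockSpec:
    """Ground-truth description of one block to plant."""

    name: str
    node: str  # emergence node (internal node label of the generated tree)
    n_members: int = 5
    gap_pattern: tuple[int, ...] = (1, 1, 1, 1)  # interveners per member gap
    density_multiplier: float = 1.0
    paralog_fraction: float = 0.0
    retention: float = 1.0  # per-leaf Bernoulli retention probability
    coexpression_loading: float = 0.0

    def __post_init__(self) -> None:
        if len(self.gap_pattern) != self.n_members - 1:
            raise ValueError(f"block {self.name}: gap_pattern length mismatch")
        if self.density_multiplier <= 0:
            raise ValueError("density multiplier must be > 0")
        if not (0.0 <= self.retention <= 1.0):
            raise ValueError("retention must be in [0, 1]")
        if not (0.0 <= self.coexpression_loading <= 1.0):
            raise ValueError("coexpression loading must be in [0, 1]")


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic dataset."""

    clades: dict[str, tuple[str, ...]]  # clade name -> species ids
    n_chromosomes: int = 4
    genes_per_chromosome: int = 500
    mean_gene_length: float = 1500.0
    mean_intergenic_gap: float = 3000.0
    n_orthogroups: int = 500
    og_presence_prob: float = 0.65
    planted: tuple[PlantedBlockSpec, ...] = ()
    n_expression_samples: int = 12
    noise_sd: float = 1.0

    @property
    def species(self) -> list[str]:
        return sorted(s for members in self.clades.values() for s in members)

    @property
    def genes_per_species(self) -> int:
        return self.n_chromosomes * self.genes_per_chromosome


@dataclass
class PlantedTruth:
    name: str
    node: str
    orthogroups: tuple[str, ...]
    retained_leaves: tuple[str, ...]
    member_gene_ids: dict[str, tuple[str, ...]]  # species -> member gene ids
    density_multiplier: float
    regime: str
    paralog_fraction: float
    coexpression_loading: float
    gap_pattern: tuple[int, ...]


@dataclass
class TruthManifest:
    planted: list[PlantedTruth]

    def to_json(self) -> str:
        return json.dumps({"planted": [asdict(p) for p in self.planted]}, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "TruthManifest":
        raw = json.loads(text)
        planted = []
        for p in raw["planted"]:
            p["orthogroups"] = tuple(p["orthogroups"])
            p["retained_leaves"] = tuple(p["retained_leaves"])
            p["gap_pattern"] = tuple(p["gap_pattern"])
            p["member_gene_ids"] = {
                k: tuple(v) for k, v in p["member_gene_ids"].items()
            }
            planted.append(PlantedTruth(**p))
        return cls(planted=planted)


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    seed: int
    genomes: dict[str, GenomeIndex]
    orthology: OrthologyMap
    newick: str
    recency: dict[str, float]
    truth: TruthManifest

    @property
    def tree(self) -> SpeciesTree:
        return SpeciesTree.from_newick(self.newick, self.recency)

    def write(self, outdir: str | Path) -> None:
        """Emit all files in the plain-text formats the readers accept."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for sp, genome in sorted(self.genomes.items()):
            with (outdir / f"{sp}.genes.tsv").open("w") as fh:
                for g in genome.genes():
                    fh.write(
                        f"{g.species_id}\t{g.chromosome_id}\t{g.gene_id}\t"
                        f"{g.start}\t{g.end}\t{g.strand}\n"
                    )
            with (outdir / f"{sp}.assembly.tsv").open("w") as fh:
                fh.write(f"__assembly__\t{genome.assembly_size}\n")
        with (outdir / "orthogroups.tsv").open("w") as fh:
            fh.write("orthogroup\tgene_id\n")
            for gene, og in sorted(self.orthology.gene_to_og.items()):
                fh.write(f"{og}\t{gene}\n")
        (outdir / "tree.nwk").write_text(self.newick + "\n")
        with (outdir / "recency.tsv").open("w") as fh:
            fh.write("node\trecency\n")
            for node, rec in sorted(self.recency.items()):
                fh.write(f"{node}\t{rec}\n")
        (outdir / "truth.json").write_text(self.truth.to_json())


def _build_tree(clades: Mapping[str, Sequence[str]]) -> tuple[str, dict[str, float]]:
    """Balanced newick over clades; internal nodes named by concatenation.

    Returns (newick string, recency map).  Recency is the node depth plus
    one: strictly increasing toward the present.
    """
    names = sorted(clades)

    def join(group: list[str]) -> tuple[str, str]:
        if len(group) == 1:
            cname = group[0]
            leaves = ",".join(sorted(clades[cname]))
            return f"({leaves}){cname}", cname
        half = (len(group) + 1) // 2
        left, lname = join(group[:half])
        right, rname = join(group[half:])
        label = lname + rname
        return f"({left},{right}){label}", label

    newick, _root = join(names)
    tree = SpeciesTree.from_newick(newick + ";")
    recency = {node: float(tree.depth(node) + 1) for node in tree.internal_nodes}
    return newick + ";", recency


def default_config(
    n_clades: int = 4,
    species_per_clade: int = 3,
    n_planted: int = 40,
    n_members: int = 5,
    density_multiplier: float = 1.0,
    paralog_fraction: float = 0.0,
    retention: float = 1.0,
    coexpression_loading: float = 0.0,
    **overrides,
) -> SimulationConfig:
    """The default study conditions: 4 clades x 3 species, 2,000 genes per
    species, 40 planted blocks spread over three nodes (root, the first
    clade pair, the first clade), full retention."""
    clade_names = [chr(ord("A") + i) for i in range(n_clades)]
    clades = {
        c: tuple(f"{c.lower()}{j + 1}" for j in range(species_per_clade))
        for c in clade_names
    }
    _, recency = _build_tree(clades)
    nodes = sorted(recency, key=lambda n: (recency[n], n))
    root = nodes[0]
    # three nodes: root, a mid-level node, one clade
    mids = [n for n in nodes if n not in clades and n != root]
    targets = [root, (mids[0] if mids else root), clade_names[0]]
    planted = []
    for i in range(n_planted):
        gap_pattern = tuple((i + j) % 3 for j in range(n_members - 1))
        planted.append(
            PlantedBlockSpec(
                name=f"PB{i:02d}",
                node=targets[i % len(targets)],
                n_members=n_members,
                gap_pattern=gap_pattern,
                density_multiplier=density_multiplier,
                paralog_fraction=paralog_fraction,
                retention=retention,
                coexpression_loading=coexpression_loading,
            )
        )
    return SimulationConfig(clades=clades, planted=tuple(planted), **overrides)


class _ProtoGene:
    __slots__ = ("og", "run", "member_of")

    def __init__(self, og: str | None, run: str | None = None, member_of: str | None = None):
        self.og = og
        self.run = run  # block name whose run this gene lies inside (gap scaling)
        self.member_of = member_of  # block name if a syntenic member


def simulate_dataset(config: SimulationConfig, seed: int) -> SimulatedDataset:
    """Generate genomes, orthology, tree and truth for one configuration."""
    newick, recency = _build_tree(config.clades)
    tree = SpeciesTree.from_newick(newick, recency)
    species = config.species
    for spec in config.planted:
        if not (tree.is_internal(spec.node) or spec.node in tree.leaves):
            raise ValueError(f"planted block {spec.name}: unknown node {spec.node!r}")

    ss = np.random.SeedSequence(seed)
    rng_global = np.random.default_rng(ss.spawn(1)[0])
    sp_seeds = {sp: s for sp, s in zip(species, np.random.SeedSequence(seed).spawn(len(species) + 1)[1:])}

    # member orthogroup labels per planted block (paralogy via repetition)
    block_ogs: dict[str, list[str]] = {}
    for spec in config.planted:
        n_same = max(1, round(spec.paralog_fraction * spec.n_members))
        labels = []
        for j in range(spec.n_members):
            labels.append(f"{spec.name}_m{0 if j < n_same else j}")
        block_ogs[spec.name] = labels

    # retained leaves per block
    retained: dict[str, list[str]] = {}
    for spec in config.planted:
        leaves = sorted(tree.leaves_under(spec.node))
        keep = [lf for lf in leaves if rng_global.random() < spec.retention]
        retained[spec.name] = keep

    # background orthogroup presence per species
    bg_ogs = [f"OG{i:04d}" for i in range(config.n_orthogroups)]
    presence: dict[str, list[str]] = {}
    for sp in species:
        rng = np.random.default_rng(sp_seeds[sp].spawn(1)[0])
        mask = rng.random(config.n_orthogroups) < config.og_presence_prob
        presence[sp] = [og for og, m in zip(bg_ogs, mask) if m]

    F = config.mean_gene_length + config.mean_intergenic_gap
    sigma = 0.5
    mu_len = math.log(config.mean_gene_length) - sigma**2 / 2

    genomes: dict[str, GenomeIndex] = {}
    gene_to_og: dict[str, str] = {}
    member_ids: dict[str, dict[str, list[str]]] = {
        spec.name: {} for spec in config.planted
    }

    for sp in species:
        rng = np.random.default_rng(sp_seeds[sp])
        my_blocks = [spec for spec in config.planted if sp in retained[spec.name]]
        n_members_total = sum(spec.n_members for spec in my_blocks)
        bg_total = config.genes_per_species - n_members_total
        if bg_total < sum(sum(s.gap_pattern) for s in my_blocks):
            raise ValueError("not enough background genes to host planted blocks")

        # background gene pool: labeled + unlabeled, shuffled
        bg: list[_ProtoGene] = [_ProtoGene(og) for og in presence[sp]]
        bg.extend(_ProtoGene(None) for _ in range(bg_total - len(bg)))
        if len(bg) != bg_total:
            raise ValueError("background orthogroup labels exceed gene budget")
        order = rng.permutation(len(bg))
        bg = [bg[i] for i in order]

        # split background across chromosomes as evenly as possible
        chrom_names = [f"chr{c + 1}" for c in range(config.n_chromosomes)]
        splits = np.array_split(np.arange(bg_total), config.n_chromosomes)
        chrom_bg = {c: [bg[i] for i in idx] for c, idx in zip(chrom_names, splits)}

        # choose a chromosome and a non-overlapping intervener window per run
        placements: dict[str, list[tuple[PlantedBlockSpec, int]]] = {
            c: [] for c in chrom_names
        }
        occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_names}
        for spec in my_blocks:
            need = sum(spec.gap_pattern)
            for _attempt in range(1000):
                c = chrom_names[int(rng.integers(config.n_chromosomes))]
                L = len(chrom_bg[c])
                if L < need + 1:
                    continue
                p = int(rng.integers(0, L - need + 1))
                window = (p, p + need)
                if all(
                    window[1] < s or window[0] > e for s, e in occupied[c]
                ):
                    occupied[c].append(window)
                    placements[c].append((spec, p))
                    break
            else:
                raise ValueError(
                    f"could not place planted block {spec.name} in {sp}"
                )

        # build final gene sequences with members interleaved at offsets
        records: list[GeneRecord] = []
        counter = 0
        for c in chrom_names:
            inserts: dict[int, list[tuple[PlantedBlockSpec, int]]] = {}
            for spec, p in placements[c]:
                cum = 0
                for j in range(spec.n_members):
                    inserts.setdefault(p + cum, []).append((spec, j))
                    if j < spec.n_members - 1:
                        cum += spec.gap_pattern[j]
            seq: list[_ProtoGene] = []
            bg_list = chrom_bg[c]
            for i in range(len(bg_list) + 1):
                for spec, j in inserts.get(i, []):
                    g = _ProtoGene(
                        block_ogs[spec.name][j], run=spec.name, member_of=spec.name
                    )
                    seq.append(g)
                if i < len(bg_list):
                    seq.append(bg_list[i])
            # mark genes lying inside each run for gap scaling
            run_bounds: dict[str, tuple[int, int]] = {}
            for i, g in enumerate(seq):
                if g.member_of:
                    lo, hi = run_bounds.get(g.member_of, (i, i))
                    run_bounds[g.member_of] = (min(lo, i), max(hi, i))
            scale_of = {}
            for spec, _p in placements[c]:
                scale_of[spec.name] = max(
                    1.0, F / spec.density_multiplier - config.mean_gene_length
                )
            in_run: dict[int, str] = {}
            for name, (lo, hi) in run_bounds.items():
                for i in range(lo + 1, hi + 1):
                    in_run[i] = name  # the gap BEFORE gene i is inside the run

            pos = 0
            for i, g in enumerate(seq):
                scale = (
                    scale_of[in_run[i]]
                    if i in in_run
                    else config.mean_intergenic_gap
                )
                gap = max(1, int(round(rng.exponential(scale))))
                length = max(1, int(round(rng.lognormal(mu_len, sigma))))
                start = pos + gap + 1
                end = start + length - 1
                pos = end
                counter += 1
                gid = f"{sp}_g{counter:05d}"
                records.append(
                    GeneRecord(gid, sp, c, start, end, "+", g.og)
                )
                if g.og is not None:
                    gene_to_og[gid] = g.og
                if g.member_of:
                    member_ids[g.member_of].setdefault(sp, []).append(gid)

        chrom_tail = {
            c: max(
                (r.end for r in records if r.chromosome_id == c), default=0
            )
            for c in chrom_names
        }
        assembly = sum(
            tail + int(round(rng.exponential(config.mean_intergenic_gap))) + 1
            for tail in chrom_tail.values()
        )
        genomes[sp] = build_genome_index(records, assembly)

    planted_truth = [
        PlantedTruth(
            name=spec.name,
            node=spec.node,
            orthogroups=tuple(dict.fromkeys(block_ogs[spec.name])),
            retained_leaves=tuple(retained[spec.name]),
            member_gene_ids={
                sp: tuple(ids) for sp, ids in sorted(member_ids[spec.name].items())
            },
            density_multiplier=spec.density_multiplier,
            regime=regime_classify(spec.density_multiplier),
            paralog_fraction=spec.paralog_fraction,
            coexpression_loading=spec.coexpression_loading,
            gap_pattern=spec.gap_pattern,
        )
        for spec in config.planted
    ]
    return SimulatedDataset(
        config=config,
        seed=seed,
        genomes=genomes,
        orthology=OrthologyMap(gene_to_og),
        newick=newick,
        recency=recency,
        truth=TruthManifest(planted=planted_truth),
    )


def simulate_expression(
    dataset: SimulatedDataset,
    n_samples: int | None = None,
    noise_sd: float | None = None,
    seed: int = 0,
) -> dict[str, ExpressionMatrix]:
    """TPM-like expression panels with latent-factor block coexpression.

    Each planted-block gene's log expression is
    ``loading * latent(block, sample) + (1 - loading) * noise``; background
    genes are pure noise.  Values are exponentiated onto a nonnegative
    TPM-like scale.  Columns are exchangeable samples (a developmental
    series and a tissue panel are treated identically).
    """
    cfg = dataset.config
    n_samples = n_samples if n_samples is not None else cfg.n_expression_samples
    noise_sd = noise_sd if noise_sd is not None else cfg.noise_sd
    if n_samples < 4:
        raise ValueError("need at least 4 expression samples")
    loading_of: dict[str, float] = {}
    block_of_gene: dict[str, str] = {}
    for p in dataset.truth.planted:
        loading_of[p.name] = p.coexpression_loading
        for sp, ids in p.member_gene_ids.items():
            for gid in ids:
                block_of_gene[gid] = p.name
    out: dict[str, ExpressionMatrix] = {}
    ss = np.random.SeedSequence(seed)
    for sp, child in zip(sorted(dataset.genomes), ss.spawn(len(dataset.genomes))):
        rng = np.random.default_rng(child)
        genome = dataset.genomes[sp]
        gene_ids = [g.gene_id for g in genome.genes()]
        latents = {
            p.name: rng.normal(0.0, 1.0, n_samples) for p in dataset.truth.planted
        }
        base = rng.normal(math.log(50.0), 1.0, len(gene_ids))
        values = np.empty((len(gene_ids), n_samples))
        for i, gid in enumerate(gene_ids):
            eps = rng.normal(0.0, noise_sd, n_samples)
            block = block_of_gene.get(gid)
            if block is not None:
                lam = loading_of[block]
                z = lam * latents[block] + (1.0 - lam) * eps
            else:
                z = eps
            values[i] = np.exp(base[i] + z)
        out[sp] = ExpressionMatrix(
            sp, gene_ids, [f"s{j + 1}" for j in range(n_samples)], values
        )
    return out


def evaluate_recovery(
    truth: TruthManifest,
    blocks: Sequence[MultiSpeciesBlock],
    assignment: NodeAssignment | None,
    tree: SpeciesTree | None = None,
    min_shared_ogs: int = 3,
) -> dict:
    """Match detected blocks against the planted truth.

    A planted block is *found* when some detected block shares at least
    ``min_shared_ogs`` orthogroups with it, and *recovered* when that block
    is additionally assigned the planted emergence node.  Detected blocks
    novel at a non-root node that match no planted block are counted as
    spurious.
    """
    matches: dict[str, int | None] = {}
    for p in truth.planted:
        pset = set(p.orthogroups)
        best = None
        best_overlap = 0
        for b in blocks:
            ov = len(pset & b.orthogroups)
            if ov > best_overlap:
                best, best_overlap = b.block_id, ov
        matches[p.name] = best if best_overlap >= min(min_shared_ogs, len(pset)) else None

    found = sum(1 for v in matches.values() if v is not None)
    recovered = 0
    if assignment is not None:
        for p in truth.planted:
            bid = matches[p.name]
            if bid is not None and assignment.emergence_node.get(bid) == p.node:
                recovered += 1

    spurious_nonroot = 0
    if assignment is not None and tree is not None:
        planted_ogs = [set(p.orthogroups) for p in truth.planted]
        root = tree.root
        for b in blocks:
            node = assignment.emergence_node.get(b.block_id)
            if node is None or node == root:
                continue
            if not any(len(pset & b.orthogroups) >= min_shared_ogs for pset in planted_ogs):
                spurious_nonroot += 1

    n = len(truth.planted)
    return {
        "n_planted": n,
        "n_found": found,
        "n_recovered": recovered,
        "found_fraction": found / n if n else float("nan"),
        "recovered_fraction": recovered / n if n else float("nan"),
        "n_spurious_nonroot": spurious_nonroot,
        "spurious_fraction": spurious_nonroot / n if n else float("nan"),
        "matches": matches,
    }
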