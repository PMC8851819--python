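"""One configured, logged run of the full analysis chain.

simulate/load -> pairwise detection -> fusion -> emergence assignment
(observed + shuffled-genome replicates) -> density profiling with matched
random nulls, Wilcoxon comparisons, CNGD and cross-taxon correlations ->
optional block coexpression.  Every stage is deterministic from the one
master seed; derived seeds are recorded in the run log.
"""

from __future__ import annotations

import itertools
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import ancestry, blocks as blk, coexpression as coex, density as dens
from .io import (
    ExpressionMatrix,
    GenomeIndex,
    OrthologyMap,
    build_genome_index,
    read_chrom_sizes,
    read_expression,
    read_gene_table,
    read_orthogroups,
    read_recency,
    write_blocks,
)
from .simulate import SimulatedDataset, SimulationConfig, default_config, simulate_dataset, simulate_expression

__all__ = ["RunConfig", "StageError", "run_full", "load_run_config"]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    outdir: str = "syndense_run"
    seed: int = 7
    # inputs: either a simulate section or explicit paths
    simulate: dict | None = None
    genes_dir: str | None = None
    orthogroups: str | None = None
    orthogroups_format: str = "long_tsv"
    tree: str | None = None
    recency: str | None = None
    expression_dir: str | None = None
    # stage parameters
    min_genes: int = 3
    max_interveners: int = 5
    n_random: int = 100
    shuffle_replicates: int = 3
    taxa: tuple[str, ...] = ()
    regime_low: float = 1.0
    regime_high: float = 2.0
    min_shared_blocks: int = 10
    with_expression: bool = False

    def validate(self) -> None:
        if self.min_genes < 2:
            raise ValueError("min_genes must be >= 2")
        if self.max_interveners < 0:
            raise ValueError("max_interveners must be >= 0")
        if self.n_random < 1:
            raise ValueError("n_random must be >= 1")
        if self.simulate is None and not (
            self.genes_dir and self.orthogroups and self.tree
        ):
            raise ValueError(
                "either a simulate section or genes_dir+orthogroups+tree paths"
            )


def load_run_config(path: str | Path) -> RunConfig:
    """Read a YAML run configuration."""
    import yaml

    raw = yaml.safe_load(Path(path).read_text()) or {}
    if "taxa" in raw:
        raw["taxa"] = tuple(raw["taxa"])
    return RunConfig(**raw)


def _load_inputs(config: RunConfig):
    if config.simulate is not None:
        sim_args = dict(config.simulate)
        sim_seed = int(sim_args.pop("seed", config.seed))
        cfg = default_config(**sim_args)
        dataset = simulate_dataset(cfg, sim_seed)
        expr = (
            simulate_expression(dataset, seed=sim_seed + 1)
            if config.with_expression
            else {}
        )
        taxa = config.taxa or tuple(sorted(dataset.config.clades))
        return dataset.genomes, dataset.orthology, dataset.tree, expr, taxa, dataset
    genomes: dict[str, GenomeIndex] = {}
    genes_dir = Path(config.genes_dir)
    for path in sorted(genes_dir.glob("*.genes.tsv")):
        sp = path.name[: -len(".genes.tsv")]
        records = read_gene_table(path, "tsv6")
        sizes = read_chrom_sizes(genes_dir / f"{sp}.assembly.tsv")
        genomes[sp] = build_genome_index(records, sum(sizes.values()))
    orth = read_orthogroups(config.orthogroups, config.orthogroups_format)
    recency = read_recency(config.recency) if config.recency else None
    tree = ancestry.SpeciesTree.from_newick(Path(config.tree), recency)
    expr: dict[str, ExpressionMatrix] = {}
    if config.with_expression and config.expression_dir:
        for path in sorted(Path(config.expression_dir).glob("*.expr.tsv")):
            sp = path.name[: -len(".expr.tsv")]
            if sp in genomes:
                expr[sp] = read_expression(path, sp).restrict_to(genomes[sp])
    taxa = config.taxa or tuple(tree.internal_nodes)
    return genomes, orth, tree, expr, taxa, None


def _taxon_of(species: str, taxa: Sequence[str], tree: ancestry.SpeciesTree) -> str | None:
    for t in taxa:
        if species in tree.leaves_under(t):
            return t
    return None


def run_full(config: RunConfig) -> dict:
    """Run every stage and write the report bundle to ``config.outdir``."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def log(msg: str) -> None:
        log_lines.append(f"[{time.strftime('%H:%M:%S')}] {msg}")

    def stage(name: str):
        class _Ctx:
            def __enter__(self):
                log(f"stage {name}: start")
                return self

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    log(f"stage {name}: FAILED ({exc})")
                    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
                    raise StageError(name, exc) from exc
                log(f"stage {name}: done")
                return False

        return _Ctx()

    results: dict = {}
    log(f"seed={config.seed} min_genes={config.min_genes} "
        f"max_interveners={config.max_interveners} n_random={config.n_random}")

    with stage("load"):
        genomes, orth, tree, expr, taxa, dataset = _load_inputs(config)
        log(f"loaded {len(genomes)} genomes, {len(orth)} orthology entries")

    with stage("detect"):
        ms_blocks = blk.detect_blocks(
            genomes, orth, config.min_genes, config.max_interveners
        )
        write_blocks(ms_blocks, outdir / "blocks.tsv")
        log(f"{len(ms_blocks)} multi-species blocks")

    with stage("assign"):
        assignment = ancestry.assign_emergence(ms_blocks, tree)
        counts = ancestry.node_block_counts(assignment, tree)
        rows = [
            {"node": node, "replicate": "observed", **c}
            for node, c in counts.items()
        ]
        if config.shuffle_replicates > 0:
            null_counts = blk.detection_false_positive_run(
                genomes,
                orth,
                tree,
                seed=config.seed,
                replicates=config.shuffle_replicates,
                min_genes=config.min_genes,
                max_interveners=config.max_interveners,
            )
            for rep, cc in enumerate(null_counts):
                rows.extend(
                    {"node": node, "replicate": f"shuffled_{rep}", **c}
                    for node, c in cc.items()
                )
        node_counts = pd.DataFrame(rows)
        node_counts.to_csv(outdir / "node_counts.tsv", sep="\t", index=False)
        retention = ancestry.retention_and_loss(assignment, ms_blocks, tree, taxa)
        retention.to_csv(outdir / "retention.tsv", sep="\t")
        results.update(
            blocks=ms_blocks, assignment=assignment, node_counts=node_counts,
            retention=retention,
        )
        log(f"assigned emergence for {len(ms_blocks)} blocks")

    with stage("density"):
        profile_rows = []
        profiles: dict[tuple, dens.DensityProfile] = {}
        samples: dict[tuple, dens.RandomSampleSet] = {}
        for b in ms_blocks:
            for sp, insts in b.instances.items():
                genome = genomes[sp]
                for inst in insts:
                    key = (b.block_id, sp, inst.instance_index)
                    prof = dens.profile_instance(
                        inst, genome, orth, block_id=b.block_id
                    )
                    child_seed = dens.instance_seed(
                        config.seed, b.block_id, sp, inst.instance_index
                    )
                    rs = dens.sample_random_blocks(
                        inst, genome, n=config.n_random, seed=child_seed
                    )
                    profiles[key] = prof
                    samples[key] = rs
                    profile_rows.append(
                        {
                            "block_id": b.block_id,
                            "species": sp,
                            "instance_index": inst.instance_index,
                            "emergence_node": assignment.emergence_node[b.block_id],
                            "taxon": _taxon_of(sp, taxa, tree),
                            "span": prof.span,
                            "genes_in_span": prof.genes_in_span,
                            "raw_density": prof.raw_density,
                            "normalized_density": prof.normalized_density,
                            "median_intergenic_distance": prof.median_intergenic_distance,
                            "paralog_fraction": prof.paralog_fraction,
                            "is_paralogous": prof.is_paralogous,
                            "regime": dens.regime_classify(
                                prof.normalized_density,
                                config.regime_low,
                                config.regime_high,
                            ),
                            "random_seed": child_seed,
                        }
                    )
        density_df = pd.DataFrame(profile_rows)
        density_df.to_csv(outdir / "density.tsv", sep="\t", index=False)
        log(f"profiled {len(profile_rows)} block instances")

        # grouped observed-vs-random comparisons
        comp_rows = []
        if not density_df.empty:
            for (taxon, node, paralog), grp in density_df.groupby(
                ["taxon", "emergence_node", "is_paralogous"], dropna=False
            ):
                keys = [
                    (r.block_id, r.species, r.instance_index)
                    for r in grp.itertuples()
                ]
                for statistic in ("normalized_density", "intergenic_median"):
                    comp = dens.compare_to_random(
                        [profiles[k] for k in keys],
                        [samples[k] for k in keys],
                        statistic=statistic,
                        grouping=(taxon, node, paralog),
                    )
                    comp_rows.append(
                        {
                            "taxon": taxon,
                            "emergence_node": node,
                            "is_paralogous": paralog,
                            "statistic": statistic,
                            "n_blocks": comp.n_obs,
                            "n_rand": comp.n_rand,
                            "median_obs": comp.median_obs,
                            "median_rand": comp.median_rand,
                            "direction": comp.direction,
                            "wilcoxon_p": comp.wilcoxon_p,
                            "significant": comp.significant,
                        }
                    )
        pd.DataFrame(comp_rows).to_csv(
            outdir / "comparisons.tsv", sep="\t", index=False
        )

        # per-block per-taxon CNGD
        cngd_records = []
        for b in ms_blocks:
            for taxon in taxa:
                t_species = tree.leaves_under(taxon)
                keys = [
                    (b.block_id, sp, inst.instance_index)
                    for sp, insts in b.instances.items()
                    if sp in t_species
                    for inst in insts
                ]
                if not keys:
                    continue
                rec = dens.block_cngd(
                    [profiles[k] for k in keys],
                    [samples[k] for k in keys],
                    block_id=b.block_id,
                    taxon=taxon,
                )
                cngd_records.append(rec)
        pd.DataFrame(
            [
                {
                    "block_id": r.block_id,
                    "taxon": r.taxon,
                    "cngd": r.cngd,
                    "n_instances": r.n_instances,
                }
                for r in cngd_records
            ]
        ).to_csv(outdir / "cngd.tsv", sep="\t", index=False)

        pairs = dens.cross_taxon_cngd(
            cngd_records, min_shared=config.min_shared_blocks
        )
        pd.DataFrame(
            [
                {"taxon_a": a, "taxon_b": b2, **vals}
                for (a, b2), vals in pairs.items()
            ]
        ).to_csv(outdir / "cngd_pairs.tsv", sep="\t", index=False)
        results.update(
            density=density_df,
            comparisons=pd.DataFrame(comp_rows),
            cngd=cngd_records,
            cngd_pairs=pairs,
        )
        log(f"{len(cngd_records)} CNGD records, {len(pairs)} taxon pairs")

    if expr:
        with stage("coexpress"):
            obs_rows = []
            obs_by_sp: dict[str, list[coex.BlockCoexpression]] = {}
            rand_by_sp: dict[str, list[coex.BlockCoexpression]] = {}
            for b in ms_blocks:
                for sp, insts in b.instances.items():
                    if sp not in expr:
                        continue
                    for inst in insts:
                        genes = coex.expressed_genes(inst, expr[sp])
                        if len(genes) < 3:
                            continue
                        bc = coex.block_coexpression(
                            genes, expr[sp], b.block_id, inst.instance_index
                        )
                        obs_by_sp.setdefault(sp, []).append(bc)
                        obs_rows.append(
                            {
                                "block_id": b.block_id,
                                "species": sp,
                                "instance_index": inst.instance_index,
                                "n_expressed": bc.n_expressed,
                                "coexpression": bc.mean_correlation,
                            }
                        )
                        key = (b.block_id, sp, inst.instance_index)
                        for slot_genes in samples[key].gene_id_samples:
                            rgenes = coex.expressed_genes(list(slot_genes), expr[sp])
                            if len(rgenes) < 3:
                                continue
                            rand_by_sp.setdefault(sp, []).append(
                                coex.block_coexpression(rgenes, expr[sp], -1)
                            )
            pd.DataFrame(obs_rows).to_csv(
                outdir / "coexpression.tsv", sep="\t", index=False
            )
            comp = {
                sp: coex.compare_block_coexpression(obs_by_sp[sp], rand_by_sp[sp])
                for sp in obs_by_sp
                if sp in rand_by_sp
            }
            results.update(coexpression=pd.DataFrame(obs_rows), coexpression_comparison=comp)
            log(f"coexpression for {len(obs_rows)} instances")

    if dataset is not None:
        results["dataset"] = dataset
    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
    results["log"] = log_lines
    return results
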