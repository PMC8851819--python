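"""Readers, writers and indexed in-memory genome representations.

All coordinates are 1-based inclusive (GFF3 convention); a gene's extent is
its annotated coding span and its length is ``end - start + 1``.  Genes with
no orthogroup label are kept: they count as intervening genes and enter the
gene-density numerators and denominators like any other gene.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GeneRecord",
    "GenomeIndex",
    "OrthologyMap",
    "ExpressionMatrix",
    "read_gene_table",
    "read_orthogroups",
    "read_chrom_sizes",
    "read_expression",
    "read_recency",
    "build_genome_index",
    "write_blocks",
    "read_blocks",
]

_STRANDS = {"+", "-", "."}


@dataclass(frozen=True)
class GeneRecord:
    """One annotated gene: coding span on a chromosome of one species."""

    gene_id: str
    species_id: str
    chromosome_id: str
    start: int
    end: int
    strand: str = "."
    orthogroup_id: str | None = None

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < 1:
            raise ValueError(
                f"gene {self.gene_id}: coordinates must be positive "
                f"(got {self.start}..{self.end})"
            )
        if self.start > self.end:
            raise ValueError(
                f"gene {self.gene_id}: start > end ({self.start} > {self.end})"
            )
        if self.strand not in _STRANDS:
            object.__setattr__(self, "strand", ".")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


class GenomeIndex:
    """One species' gene order: per-chromosome ordinal-sorted genes.

    Ordinals run 0..n-1 per chromosome, sorted by (start, end, gene_id).
    ``assembly_size`` is the total bp of the assembly and is always supplied
    externally (chrom-sizes file or config), never inferred from gene ends,
    because the whole-genome density denominator is the full assembly.
    """

    def __init__(
        self,
        species_id: str,
        chromosomes: Mapping[str, Sequence[GeneRecord]],
        assembly_size: int,
    ) -> None:
        self.species_id = species_id
        self.chromosomes: dict[str, tuple[GeneRecord, ...]] = {
            c: tuple(chromosomes[c]) for c in sorted(chromosomes)
        }
        self.assembly_size = int(assembly_size)
        self._locate: dict[str, tuple[str, int]] = {}
        max_end = 0
        for chrom, genes in self.chromosomes.items():
            for ordinal, g in enumerate(genes):
                if g.gene_id in self._locate:
                    raise ValueError(f"duplicate gene_id {g.gene_id!r} in {species_id}")
                self._locate[g.gene_id] = (chrom, ordinal)
                max_end = max(max_end, g.end)
        if max_end > self.assembly_size:
            raise ValueError(
                f"{species_id}: assembly_size {assembly_size} < max gene end {max_end}"
            )

    @property
    def total_gene_count(self) -> int:
        return len(self._locate)

    @property
    def genome_density(self) -> float:
        """Whole-genome gene density: total genes / assembly bp."""
        return self.total_gene_count / self.assembly_size

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._locate

    def locate(self, gene_id: str) -> tuple[str, int]:
        """Return (chromosome_id, ordinal) of a gene."""
        try:
            return self._locate[gene_id]
        except KeyError:
            raise KeyError(
                f"gene {gene_id!r} not in genome of {self.species_id}"
            ) from None

    def gene(self, gene_id: str) -> GeneRecord:
        chrom, ordinal = self.locate(gene_id)
        return self.chromosomes[chrom][ordinal]

    def genes(self) -> Iterable[GeneRecord]:
        for chrom in self.chromosomes:
            yield from self.chromosomes[chrom]

    def coordinate_arrays(self, chromosome_id: str) -> tuple[np.ndarray, np.ndarray]:
        """Cached (starts, ends) arrays of one chromosome, in ordinal order."""
        cache = getattr(self, "_coord_cache", None)
        if cache is None:
            cache = self._coord_cache = {}
        if chromosome_id not in cache:
            genes = self.chromosomes[chromosome_id]
            cache[chromosome_id] = (
                np.fromiter((g.start for g in genes), dtype=np.int64, count=len(genes)),
                np.fromiter((g.end for g in genes), dtype=np.int64, count=len(genes)),
            )
        return cache[chromosome_id]


def build_genome_index(
    records: Sequence[GeneRecord], assembly_size: int
) -> GenomeIndex:
    """Assign ordinal positions and build an index for one species."""
    species = {r.species_id for r in records}
    if len(species) > 1:
        raise ValueError(f"records from multiple species: {sorted(species)}")
    species_id = species.pop() if species else "unknown"
    by_chrom: dict[str, list[GeneRecord]] = {}
    for r in records:
        by_chrom.setdefault(r.chromosome_id, []).append(r)
    for genes in by_chrom.values():
        genes.sort(key=lambda g: (g.start, g.end, g.gene_id))
    return GenomeIndex(species_id, by_chrom, assembly_size)


class OrthologyMap:
    """Many-to-one gene -> orthogroup labeling, shared across species.

    Every gene belongs to at most one orthogroup; all genes of an orthogroup
    are treated as orthologs downstream.
    """

    def __init__(self, gene_to_og: Mapping[str, str]) -> None:
        self.gene_to_og: dict[str, str] = dict(gene_to_og)
        self.og_to_genes: dict[str, set[str]] = {}
        for gene, og in self.gene_to_og.items():
            self.og_to_genes.setdefault(og, set()).add(gene)

    def __len__(self) -> int:
        return len(self.gene_to_og)

    def orthogroup(self, gene_id: str) -> str | None:
        return self.gene_to_og.get(gene_id)

    def genes_of(self, orthogroup_id: str) -> set[str]:
        return set(self.og_to_genes.get(orthogroup_id, set()))

    def orthogroups_in(self, genome: GenomeIndex) -> set[str]:
        """Orthogroups with at least one gene in the given genome."""
        return {
            og
            for g in genome.genes()
            if (og := self.gene_to_og.get(g.gene_id)) is not None
        }


@dataclass
class ExpressionMatrix:
    """Genes x samples TPM matrix for one species."""

    species_id: str
    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray  # shape (n_genes, n_samples), TPM >= 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("expression matrix shape does not match labels")
        if np.any(self.values < 0):
            raise ValueError("negative TPM values")
        self._row = {g: i for i, g in enumerate(self.gene_ids)}
        if len(self._row) != len(self.gene_ids):
            raise ValueError("duplicate gene ids in expression matrix")

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._row

    def profile(self, gene_id: str) -> np.ndarray:
        return self.values[self._row[gene_id]]

    def restrict_to(self, genome: GenomeIndex) -> "ExpressionMatrix":
        """Drop rows whose gene ids do not resolve in the genome index."""
        keep = [i for i, g in enumerate(self.gene_ids) if g in genome]
        dropped = len(self.gene_ids) - len(keep)
        if dropped:
            import warnings

            warnings.warn(
                f"{self.species_id}: dropped {dropped} expression rows with "
                "gene ids absent from the genome index",
                stacklevel=2,
            )
        return ExpressionMatrix(
            self.species_id,
            [self.gene_ids[i] for i in keep],
            list(self.sample_ids),
            self.values[keep],
        )


# ---------------------------------------------------------------------------
# file formats
# ---------------------------------------------------------------------------

_GFF3_ID = re.compile(r"(?:^|;)\s*ID=([^;]+)")


def read_gene_table(
    path: str | Path, format: str = "tsv6", species_id: str | None = None
) -> list[GeneRecord]:
    """Read gene records from a 6-column TSV or a GFF3 file.

    tsv6 columns: species, chromosome, gene_id, start, end, strand.
    GFF3: only ``gene`` features are used; the ID attribute names the gene,
    and ``species_id`` must be given (GFF3 carries no species column).
    Records are returned sorted by (chromosome, start, end, gene_id) and
    duplicate gene ids are rejected.
    """
    path = Path(path)
    records: list[GeneRecord] = []
    if format == "tsv6":
        with path.open() as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 6:
                    raise ValueError(
                        f"{path}:{lineno}: expected 6 tab-separated columns, "
                        f"got {len(parts)}"
                    )
                sp, chrom, gid, start, end, strand = parts
                try:
                    rec = GeneRecord(gid, sp, chrom, int(start), int(end), strand)
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: {exc}") from None
                records.append(rec)
    elif format == "gff3":
        if species_id is None:
            raise ValueError("species_id is required for GFF3 input")
        with path.open() as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 9:
                    raise ValueError(f"{path}:{lineno}: malformed GFF3 line")
                seqid, _, ftype, start, end, _, strand, _, attrs = parts
                if ftype != "gene":
                    continue
                m = _GFF3_ID.search(attrs)
                if not m:
                    raise ValueError(f"{path}:{lineno}: gene feature without ID")
                try:
                    rec = GeneRecord(
                        m.group(1), species_id, seqid, int(start), int(end), strand
                    )
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: {exc}") from None
                records.append(rec)
    else:
        raise ValueError(f"unknown gene table format {format!r}")

    seen: dict[tuple[str, str], int] = {}
    for r in records:
        key = (r.species_id, r.gene_id)
        if key in seen:
            raise ValueError(f"{path}: duplicate gene_id {r.gene_id!r}")
        seen[key] = 1
    records.sort(key=lambda g: (g.chromosome_id, g.start, g.end, g.gene_id))
    return records


def read_orthogroups(path: str | Path, format: str = "orthofinder_tsv") -> OrthologyMap:
    """Read a gene -> orthogroup map.

    ``orthofinder_tsv``: the Orthogroups.tsv dialect — header row of species
    columns, one row per orthogroup, cells are comma-separated gene lists.
    ``long_tsv``: two columns (orthogroup_id, gene_id), no header required.
    A gene appearing in two orthogroups is an error; empty orthogroup rows
    are skipped with a warning.
    """
    import warnings

    path = Path(path)
    gene_to_og: dict[str, str] = {}

    def add(gene: str, og: str) -> None:
        prev = gene_to_og.get(gene)
        if prev is not None and prev != og:
            raise ValueError(
                f"gene {gene!r} assigned to two orthogroups ({prev}, {og})"
            )
        gene_to_og[gene] = og

    if format == "orthofinder_tsv":
        with path.open() as fh:
            header = fh.readline()
            if not header:
                raise ValueError(f"{path}: empty file")
            for lineno, line in enumerate(fh, 2):
                line = line.rstrip("\n")
                if not line:
                    continue
                cells = line.split("\t")
                og = cells[0].strip()
                genes = [
                    g.strip()
                    for cell in cells[1:]
                    for g in cell.split(",")
                    if g.strip()
                ]
                if not genes:
                    warnings.warn(
                        f"{path}:{lineno}: empty orthogroup {og!r} skipped",
                        stacklevel=2,
                    )
                    continue
                for g in genes:
                    add(g, og)
    elif format == "long_tsv":
        with path.open() as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise ValueError(f"{path}:{lineno}: expected 2 columns")
                og, gene = parts[0].strip(), parts[1].strip()
                if og.lower() in {"orthogroup", "orthogroup_id"} and lineno == 1:
                    continue
                add(gene, og)
    else:
        raise ValueError(f"unknown orthogroup format {format!r}")
    return OrthologyMap(gene_to_og)


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Read a chrom-sizes style TSV: chromosome_id, length."""
    sizes: dict[str, int] = {}
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            sizes[parts[0]] = int(parts[1])
    return sizes


def read_expression(path: str | Path, species_id: str) -> ExpressionMatrix:
    """Read a TPM TSV: first column gene_id, remaining columns samples."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(
        species_id,
        [str(g) for g in df.index],
        [str(c) for c in df.columns],
        df.to_numpy(dtype=float),
    )


def read_recency(path: str | Path) -> dict[str, float]:
    """Read a node recency TSV: node_id, recency (higher = younger node)."""
    recency: dict[str, float] = {}
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            if lineno == 1 and parts[0].lower() in {"node", "node_id"}:
                continue
            recency[parts[0]] = float(parts[1])
    return recency


# ---------------------------------------------------------------------------
# block serialization (TSV, mirrors the supplementary block tables)
# ---------------------------------------------------------------------------

_BLOCK_COLUMNS = [
    "block_id",
    "species",
    "chromosome",
    "instance_index",
    "gene_id",
    "ordinal",
    "orthogroup_id",
]


def write_blocks(blocks: Sequence, path: str | Path) -> None:
    """Write multi-species blocks to TSV, one row per member gene."""
    rows = []
    for b in blocks:
        for species in sorted(b.instances):
            for inst in b.instances[species]:
                for ordinal, gene in enumerate(inst.genes):
                    rows.append(
                        {
                            "block_id": b.block_id,
                            "species": species,
                            "chromosome": inst.chromosome_id,
                            "instance_index": inst.instance_index,
                            "gene_id": gene.gene_id,
                            "ordinal": ordinal,
                            "orthogroup_id": gene.orthogroup_id or "",
                        }
                    )
    pd.DataFrame(rows, columns=_BLOCK_COLUMNS).to_csv(path, sep="\t", index=False)


def read_blocks(path: str | Path, genomes: Mapping[str, GenomeIndex]) -> list:
    """Inverse of :func:`write_blocks`; gene records resolved via genomes."""
    from .blocks import BlockInstance, MultiSpeciesBlock

    df = pd.read_csv(path, sep="\t", dtype={"orthogroup_id": str}, keep_default_na=False)
    blocks: list[MultiSpeciesBlock] = []
    for block_id, bdf in df.groupby("block_id", sort=True):
        instances: dict[str, list[BlockInstance]] = {}
        orthogroups: set[str] = set()
        for (species, idx), idf in bdf.groupby(["species", "instance_index"], sort=True):
            if species not in genomes:
                raise ValueError(f"{path}: unknown species {species!r}")
            genome = genomes[species]
            genes = tuple(
                genome.gene(gid) for gid in idf.sort_values("ordinal")["gene_id"]
            )
            chrom = genes[0].chromosome_id
            instances.setdefault(species, []).append(
                BlockInstance(species, chrom, genes, int(idx))
            )
        orthogroups |= {og for og in bdf["orthogroup_id"] if og}
        blocks.append(
            MultiSpeciesBlock(
                block_id=int(block_id),
                orthogroups=frozenset(orthogroups),
                instances=instances,
            )
        )
    return blocks
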