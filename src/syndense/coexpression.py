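"""Block coexpression: Fisher-averaged pairwise Spearman correlations.

Block coexpression is defined for blocks with at least three expressed
genes as tanh(mean(atanh(rho))) over the Spearman correlations of every
unordered pair of expressed member genes, with correlations of exactly
+/-1 nudged to the next representable float toward zero before the
transform (their atanh is infinite).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

from .blocks import BlockInstance
from .io import ExpressionMatrix
from .stats import fisher_average, rank_sum_test

__all__ = [
    "BlockCoexpression",
    "expressed_genes",
    "block_coexpression",
    "compare_block_coexpression",
    "CoexpressionComparison",
]


@dataclass(frozen=True)
class BlockCoexpression:
    block_id: int
    species_id: str
    instance_index: int
    n_expressed: int
    mean_correlation: float


@dataclass
class CoexpressionComparison:
    n_obs: int
    n_rand: int
    median_obs: float
    median_rand: float
    direction: str
    u: float
    wilcoxon_p: float

    @property
    def significant(self) -> bool:
        return self.wilcoxon_p < 0.05


def expressed_genes(
    gene_ids: Sequence[str] | BlockInstance,
    expr: ExpressionMatrix,
    min_tpm: float = 0.0,
    min_samples: int = 1,
) -> list[str]:
    """Genes of an instance expressed above ``min_tpm`` in >= ``min_samples``
    samples (default: any nonzero TPM in at least one sample)."""
    if isinstance(gene_ids, BlockInstance):
        gene_ids = gene_ids.gene_ids()
    out = []
    for gid in gene_ids:
        if gid not in expr:
            continue
        if int((expr.profile(gid) > min_tpm).sum()) >= min_samples:
            out.append(gid)
    return out


def _pairwise_spearman(values: np.ndarray) -> np.ndarray:
    """Spearman rho matrix over rows (average ranks for ties)."""
    ranks = np.apply_along_axis(rankdata, 1, values)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.corrcoef(ranks)


def block_coexpression(
    gene_ids: Sequence[str],
    expr: ExpressionMatrix,
    block_id: int = -1,
    instance_index: int = 0,
) -> BlockCoexpression:
    """Fisher-averaged pairwise Spearman correlation of a gene set.

    Genes constant across all samples yield undefined correlations; their
    pairs are dropped with a warning.  Raises if fewer than three genes or
    two samples are given, or if no defined pair remains.
    """
    gene_ids = list(gene_ids)
    if len(gene_ids) < 3:
        raise ValueError("block coexpression requires at least 3 expressed genes")
    values = np.array([expr.profile(g) for g in gene_ids], dtype=float)
    if values.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    rho = _pairwise_spearman(values)
    iu = np.triu_indices(len(gene_ids), k=1)
    pair_rhos = rho[iu]
    defined = ~np.isnan(pair_rhos)
    if not np.all(defined):
        warnings.warn(
            f"dropped {int((~defined).sum())} gene pairs with undefined "
            "Spearman correlation (constant expression)",
            stacklevel=2,
        )
    pair_rhos = pair_rhos[defined]
    if pair_rhos.size < 1:
        raise ValueError("no defined gene pair correlations in block")
    return BlockCoexpression(
        block_id=block_id,
        species_id=expr.species_id,
        instance_index=instance_index,
        n_expressed=len(gene_ids),
        mean_correlation=fisher_average(pair_rhos),
    )


def compare_block_coexpression(
    obs: Sequence[BlockCoexpression], rand: Sequence[BlockCoexpression]
) -> CoexpressionComparison:
    """Two-sided Wilcoxon rank-sum of observed vs random block coexpression."""
    if not obs or not rand:
        raise ValueError("both observed and random sets must be non-empty")
    x = np.array([b.mean_correlation for b in obs])
    y = np.array([b.mean_correlation for b in rand])
    res = rank_sum_test(x, y)
    mo, mr = float(np.median(x)), float(np.median(y))
    direction = "equal" if mo == mr else ("higher" if mo > mr else "lower")
    return CoexpressionComparison(
        n_obs=len(x),
        n_rand=len(y),
        median_obs=mo,
        median_rand=mr,
        direction=direction,
        u=res.u,
        wilcoxon_p=res.p_value,
    )
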