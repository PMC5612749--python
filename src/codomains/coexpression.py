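"""Per-chromosome pairwise Pearson coexpression matrices.

One symmetric matrix per chromosome holds the Pearson correlation between the
expression profiles of every pair of genes, with genes indexed by their
5'->3' rank. Genes whose expression is constant across samples have no
defined correlation; they keep their rank (so domain coordinates never
shift) but are masked out of every average.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, chromosome_genes


@dataclass
class CoexpressionMatrix:
    """Symmetric gene-gene Pearson matrix for one chromosome.

    ``C[i, j]`` is the correlation between the expression vectors of the
    genes at ranks i and j; undefined entries (a zero-variance gene on either
    side) are NaN and ``valid_mask`` flags the genes with defined variance.
    """

    chromosome: str
    gene_ids: list[str]
    C: np.ndarray
    valid_mask: np.ndarray

    def __post_init__(self) -> None:
        self.C = np.asarray(self.C, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        n = len(self.gene_ids)
        if self.C.shape != (n, n):
            raise ValueError("matrix shape does not match gene list")
        if self.valid_mask.shape != (n,):
            raise ValueError("valid_mask length does not match gene list")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.C, index=self.gene_ids, columns=self.gene_ids)


def build_coexpression_matrix(
    expr: ExpressionMatrix,
    annotation: pd.DataFrame,
    chromosome: str,
) -> CoexpressionMatrix:
    """Pearson correlation matrix over the ranked genes of one chromosome.

    Requires at least 3 samples. Uses the sample (n-1) covariance
    convention; the correlation ratio is convention-independent.
    """
    if expr.n_samples < 3:
        raise ValueError(f"need >= 3 samples to correlate, got {expr.n_samples}")
    genes = chromosome_genes(annotation, chromosome)
    present = genes["gene_id"].isin(set(expr.genes))
    if not present.all():
        missing = genes.loc[~present, "gene_id"].tolist()
        raise ValueError(f"genes missing from expression matrix: {missing[:5]}...")
    ordered_ids = genes["gene_id"].tolist()
    X = expr.subset(ordered_ids).values
    sd = X.std(axis=1, ddof=1)
    valid = sd > 0
    C = np.full((len(ordered_ids), len(ordered_ids)), np.nan)
    if valid.sum() >= 2:
        sub = np.corrcoef(X[valid])
        C[np.ix_(valid, valid)] = sub
    elif valid.sum() == 1:
        i = int(np.flatnonzero(valid)[0])
        C[i, i] = 1.0
    np.fill_diagonal(C, np.where(valid, 1.0, np.nan))
    return CoexpressionMatrix(chromosome, ordered_ids, C, valid)


def build_all_coexpression_matrices(
    expr: ExpressionMatrix, annotation: pd.DataFrame
) -> dict[str, CoexpressionMatrix]:
    """One coexpression matrix per chromosome present in the annotation."""
    out = {}
    for chrom in annotation["chromosome"].unique():
        out[str(chrom)] = build_coexpression_matrix(expr, annotation, str(chrom))
    return out


def average_pairwise_coexpression(
    cm: CoexpressionMatrix,
    set_a: Sequence[int],
    set_b: Sequence[int] | None = None,
) -> tuple[float, int]:
    """Mean Pearson coefficient over gene pairs, with the pair count used.

    With one set: mean over all unordered within-set pairs (self-pairs
    excluded). With two sets: mean over the full cross product. Undefined
    entries are excluded from the mean; if every relevant entry is undefined
    the mean is NaN (never silently zero) with count 0.
    """
    a = np.asarray(sorted(set(int(i) for i in set_a)), dtype=int)
    if len(a) == 0 or (set_b is not None and len(set_b) == 0):
        raise ValueError("gene sets must be non-empty")
    if set_b is None:
        if len(a) < 2:
            return float("nan"), 0
        block = cm.C[np.ix_(a, a)]
        iu = np.triu_indices(len(a), k=1)
        vals = block[iu]
    else:
        b = np.asarray(sorted(set(int(i) for i in set_b)), dtype=int)
        vals = cm.C[np.ix_(a, b)].ravel()
    defined = vals[~np.isnan(vals)]
    if defined.size == 0:
        return float("nan"), 0
    return float(defined.mean()), int(defined.size)


def export_matrix_tsv(cm: CoexpressionMatrix, path) -> None:
    """Dense TSV export for external heat-map rendering."""
    cm.to_frame().to_csv(path, sep="\t")
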