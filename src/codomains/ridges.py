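"""RIDGE detection: Regions of Increased Gene Expression.

A RIDGE is a run of at least ``min_run`` consecutive genes (in chromosomal
order) whose moving-median expression — the median of each gene's mean
expression over a 39-gene window, 19 genes up- and 19 downstream — exceeds
``factor`` times the genome-wide median of per-gene mean expression
(strict inequality). The genomic median is computed once over all
chromosomes, not per chromosome; windows truncate at chromosome ends.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import Domain, DomainSet, ExpressionMatrix, chromosome_genes


def moving_median(values: np.ndarray, window: int = 39) -> np.ndarray:
    """Centered sliding median; the window truncates at the array ends."""
    if window % 2 != 1:
        raise ValueError("window must be odd (k up + k down + the gene itself)")
    half = window // 2
    n = len(values)
    out = np.empty(n)
    for i in range(n):
        out[i] = np.median(values[max(0, i - half) : min(n, i + half + 1)])
    return out


def call_ridges(
    expr: ExpressionMatrix,
    annotation: pd.DataFrame,
    window: int = 39,
    factor: float = 2.0,
    min_run: int = 10,
) -> dict[str, DomainSet]:
    """Call RIDGEs on every annotated chromosome.

    Returns one DomainSet (kind RIDGE) per chromosome; chromosomes shorter
    than ``min_run`` genes yield empty sets. Calls are invariant to sample
    order and to rescaling all expression by a positive constant.
    """
    mean_by_gene = dict(zip(expr.genes, expr.values.mean(axis=1)))
    chroms = list(annotation["chromosome"].unique())
    all_means = []
    per_chrom: dict[str, pd.DataFrame] = {}
    for chrom in chroms:
        genes = chromosome_genes(annotation, str(chrom))
        genes = genes[genes["gene_id"].isin(mean_by_gene)].reset_index(drop=True)
        per_chrom[str(chrom)] = genes
        all_means.extend(mean_by_gene[g] for g in genes["gene_id"])
    genomic_median = float(np.median(all_means)) if all_means else float("nan")
    cutoff = factor * genomic_median

    out: dict[str, DomainSet] = {}
    for chrom, genes in per_chrom.items():
        means = np.array([mean_by_gene[g] for g in genes["gene_id"]])
        domains: list[Domain] = []
        if len(means) >= min_run:
            med = moving_median(means, window)
            qualifies = med > cutoff
            start = None
            for i, q in enumerate(list(qualifies) + [False]):
                if q and start is None:
                    start = i
                elif not q and start is not None:
                    if i - start >= min_run:
                        first, last = start, i - 1
                        domains.append(
                            Domain(
                                int(genes.loc[first, "rank"]),
                                int(genes.loc[last, "rank"]),
                                int(genes.loc[first, "start"]),
                                int(genes.loc[last, "end"]),
                                tuple(genes.loc[first:last, "gene_id"]),
                                {"mean_moving_median": float(med[first : last + 1].mean())},
                            )
                        )
                    start = None
        out[chrom] = DomainSet(chrom, domains, kind="RIDGE")
    return out
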