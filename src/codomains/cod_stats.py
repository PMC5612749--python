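"""Intra-/inter-COD coexpression statistics and randomization null models.

Inter-COD coexpression between two domains is the mean Pearson coefficient
over every cross pair of their genes; |mean| >= 0.2 marks a strongly
co-regulated (positive) or anti-regulated (negative) domain pair. Null
domain sets preserve the real size and spacing structure either by
inverting all coordinates 5'-3' -> 3'-5' on the chromosome, or by shifting
every border a fixed distance (100 kb by default).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .coexpression import CoexpressionMatrix, average_pairwise_coexpression
from .io import DomainSet, attach_genes

SIGNIFICANCE_CUTOFF = 0.2


@dataclass
class CODPairStat:
    """Summary of one intra-chromosomal pair of domains."""

    index_a: int
    index_b: int
    avg_inter_coexpression: float
    n_pairs: int
    distance: float  # bp between domain midpoints (or edges, per config)
    classification: str  # positive / negative / neutral

    @staticmethod
    def classify(value: float, cutoff: float = SIGNIFICANCE_CUTOFF) -> str:
        if np.isnan(value):
            return "neutral"
        if value >= cutoff:
            return "positive"
        if value <= -cutoff:
            return "negative"
        return "neutral"


@dataclass
class CoexpressionPopulations:
    """The three pair populations of one chromosome's matrix."""

    intra: np.ndarray  # pairs within the same domain
    inter: np.ndarray  # pairs spanning two different domains
    rest: np.ndarray  # pairs involving at least one unassigned gene


def _domain_ranks(ds: DomainSet) -> list[np.ndarray]:
    out = []
    for d in ds.domains:
        if d.gene_ids:
            out.append(np.arange(d.first_rank, d.last_rank + 1))
        else:
            out.append(np.array([], dtype=int))
    return out


def cod_coexpression_summary(
    cods: DomainSet,
    cm: CoexpressionMatrix,
    *,
    distance: Literal["midpoint", "edge"] = "midpoint",
    cutoff: float = SIGNIFICANCE_CUTOFF,
) -> tuple[list[float], list[CODPairStat], CoexpressionPopulations]:
    """Per-domain intra averages, all domain-pair stats, and pair populations.

    The populations partition every defined upper-triangle coefficient of
    the matrix: intra (both genes in the same domain), inter (two different
    domains) and rest (anything touching an unassigned gene).
    """
    ranks = _domain_ranks(cods)
    intra_means = []
    for r in ranks:
        if len(r) >= 2:
            m, _ = average_pairwise_coexpression(cm, r)
        else:
            m = float("nan")
        intra_means.append(m)

    pair_stats: list[CODPairStat] = []
    for i in range(len(cods.domains)):
        for j in range(i + 1, len(cods.domains)):
            if len(ranks[i]) == 0 or len(ranks[j]) == 0:
                continue
            m, n_pairs = average_pairwise_coexpression(cm, ranks[i], ranks[j])
            a, b = cods.domains[i], cods.domains[j]
            if distance == "midpoint":
                dist = abs(b.midpoint - a.midpoint)
            else:
                dist = max(0.0, float(max(a.start_bp, b.start_bp) - min(a.end_bp, b.end_bp)))
            pair_stats.append(
                CODPairStat(i, j, m, n_pairs, dist, CODPairStat.classify(m, cutoff))
            )

    n = cm.n_genes
    label = np.full(n, -1, dtype=int)
    for k, r in enumerate(ranks):
        label[r] = k
    iu, ju = np.triu_indices(n, k=1)
    vals = cm.C[iu, ju]
    ok = ~np.isnan(vals)
    iu, ju, vals = iu[ok], ju[ok], vals[ok]
    same = (label[iu] == label[ju]) & (label[iu] >= 0)
    cross = (label[iu] >= 0) & (label[ju] >= 0) & (label[iu] != label[ju])
    rest = ~(same | cross)
    pops = CoexpressionPopulations(vals[same], vals[cross], vals[rest])
    return intra_means, pair_stats, pops


@dataclass
class DistanceBinning:
    """Equal-count bins of domain pairs ordered by genomic distance."""

    mean_distance: np.ndarray
    mean_coexpression: np.ndarray
    pair_count: np.ndarray

    @property
    def n_bins(self) -> int:
        return len(self.pair_count)


def distance_binned_coexpression(
    pairs: Sequence[CODPairStat], n_bins: int = 50
) -> DistanceBinning:
    """Bin domain pairs by distance into equal-count groups (counts +-1).

    Pairs are stably sorted by distance and split into ``n_bins`` groups
    (reduced to the pair count when there are fewer pairs); per-group mean
    distance and mean inter-domain coexpression are reported.
    """
    pairs = [p for p in pairs if not np.isnan(p.avg_inter_coexpression)]
    if not pairs:
        return DistanceBinning(np.array([]), np.array([]), np.array([], dtype=int))
    order = np.argsort([p.distance for p in pairs], kind="stable")
    d = np.array([pairs[k].distance for k in order])
    c = np.array([pairs[k].avg_inter_coexpression for k in order])
    n_bins = min(n_bins, len(pairs))
    groups = np.array_split(np.arange(len(pairs)), n_bins)
    md = np.array([d[g].mean() for g in groups])
    mc = np.array([c[g].mean() for g in groups])
    cnt = np.array([len(g) for g in groups])
    return DistanceBinning(md, mc, cnt)


def randomize_domains_by_inversion(
    domains: DomainSet,
    chrom_length: int | None = None,
    annotation: pd.DataFrame | None = None,
) -> DomainSet:
    """Mirror every interval: [s, e) -> [L - e, L - s) on a chromosome of length L.

    This preserves the multiset of domain lengths and inter-domain gaps
    exactly while scrambling gene content. When ``annotation`` is given the
    gene composition is reassigned by gene midpoint; applied twice the
    operation returns the original coordinates exactly. L defaults to the
    maximum annotated gene end (or domain end), under which the map is an
    isometry for any admissible L.
    """
    if chrom_length is None:
        ends = [d.end_bp for d in domains.domains]
        if annotation is not None:
            sub = annotation[annotation["chromosome"] == domains.chromosome]
            ends += [int(sub["end"].max())] if len(sub) else []
        chrom_length = max(ends) if ends else 0
    L = int(chrom_length)
    if domains.domains and L < max(d.end_bp for d in domains.domains):
        raise ValueError("chrom_length smaller than the maximum domain end")
    new = [
        replace(d, start_bp=L - d.end_bp, end_bp=L - d.start_bp, gene_ids=())
        for d in domains.domains
    ]
    ds = DomainSet(domains.chromosome, new, kind="random")
    if annotation is not None:
        ds = DomainSet(ds.chromosome, attach_genes(ds, annotation).domains, kind="random")
    return ds


def randomize_domains_by_shift(
    domains: DomainSet,
    shift: int = 100_000,
    direction: Literal["downstream", "upstream"] = "downstream",
    chrom_length: int | None = None,
    annotation: pd.DataFrame | None = None,
) -> DomainSet:
    """Shift every domain border by +-shift bp, clipping to [0, L).

    Interior domains keep their exact size; domains running off either end
    are truncated, and ones pushed entirely off-chromosome are dropped with
    a warning.
    """
    delta = shift if direction == "downstream" else -shift
    if chrom_length is None:
        ends = [d.end_bp + max(0, delta) for d in domains.domains]
        chrom_length = max(ends) if ends else 0
    L = int(chrom_length)
    new = []
    for d in domains.domains:
        s, e = d.start_bp + delta, d.end_bp + delta
        s2, e2 = max(0, s), min(L, e)
        if e2 <= 0 or s2 >= L or e2 <= s2:
            import logging

            logging.getLogger("codomains").warning(
                "domain [%d, %d) shifted off chromosome %s: dropped",
                d.start_bp, d.end_bp, domains.chromosome,
            )
            continue
        new.append(replace(d, start_bp=s2, end_bp=e2, gene_ids=()))
    ds = DomainSet(domains.chromosome, new, kind="random")
    if annotation is not None:
        ds = DomainSet(ds.chromosome, attach_genes(ds, annotation).domains, kind="random")
    return ds


def compare_distributions(
    groups: dict[str, np.ndarray],
    n_tests: int | None = None,
    *,
    comparisons: Sequence[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Pairwise two-sided Mann-Whitney tests with Bonferroni adjustment.

    ``comparisons`` defaults to every unordered pair of group labels;
    ``n_tests`` defaults to the number of comparisons performed. The exact
    null distribution is enumerated for small samples (scipy's policy below
    n = 8 without ties), the tie-corrected normal approximation otherwise.
    Adjusted p = min(1, p * n_tests).
    """
    labels = list(groups)
    if comparisons is None:
        comparisons = [(a, b) for i, a in enumerate(labels) for b in labels[i + 1 :]]
    if n_tests is None:
        n_tests = len(comparisons)
    rows = []
    for a, b in comparisons:
        x, y = np.asarray(groups[a], float), np.asarray(groups[b], float)
        x, y = x[~np.isnan(x)], y[~np.isnan(y)]
        if len(x) == 0 or len(y) == 0:
            raise ValueError(f"empty group in comparison {a} vs {b}")
        if np.ptp(np.concatenate([x, y])) == 0:
            u, p = len(x) * len(y) / 2.0, 1.0
        else:
            res = stats.mannwhitneyu(x, y, alternative="two-sided")
            u, p = float(res.statistic), float(res.pvalue)
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "n_a": len(x),
                "n_b": len(y),
                "U": u,
                "p_value": p,
                "p_bonferroni": min(1.0, p * n_tests),
            }
        )
    return pd.DataFrame(rows)
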