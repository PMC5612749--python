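"""Coincidence of domain sets and gene-set overlap statistics.

Implements the thresholded coincidence rules used to compare called
coexpression domains with TADs/contact domains and normal with cancer
domain sets: length coincidence (a domain A matches when one single domain
B covers >= 80% of A's length), boundary coincidence (any B boundary within
a tolerance expressed as a fraction of A's length, or of A's gene count),
and gene-composition coincidence (>= 80% of A's genes shared with one B).
Significance comes from hypergeometric gene-set tests and a 2x2 chi-square
on matched/unmatched boundary counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from .cod_stats import compare_distributions, randomize_domains_by_inversion
from .coexpression import CoexpressionMatrix
from .io import DomainSet, chromosome_genes


@dataclass
class MatchConfig:
    """Thresholds of the coincidence rules (all inclusive, i.e. >= / <=)."""

    min_length_frac: float = 0.80
    boundary_tol_frac: float = 0.10
    gene_frac: float = 0.80

    def __post_init__(self) -> None:
        for name in ("min_length_frac", "boundary_tol_frac", "gene_frac"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")


def _overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start))


def match_domains_by_length(
    a: DomainSet, b: DomainSet, cfg: MatchConfig | None = None
) -> pd.DataFrame:
    """Length-coincidence matching of every A domain against set B.

    A domain of A matches when some *single* domain of B overlaps at least
    ``min_length_frac`` of A's length. Not symmetric: run both directions
    for Venn-style summaries. Returns one row per A domain with the best
    overlap fraction and the index of the best B partner (-1 if none).
    """
    cfg = cfg or MatchConfig()
    rows = []
    for i, da in enumerate(a.domains):
        best_frac, best_j = 0.0, -1
        for j, db in enumerate(b.domains):
            frac = _overlap(da.start_bp, da.end_bp, db.start_bp, db.end_bp) / da.length_bp
            if frac > best_frac:
                best_frac, best_j = frac, j
        rows.append(
            {
                "index_a": i,
                "best_index_b": best_j,
                "overlap_frac": best_frac,
                "matched": best_frac >= cfg.min_length_frac,
            }
        )
    return pd.DataFrame(rows, columns=["index_a", "best_index_b", "overlap_frac", "matched"])


def match_boundaries(
    a: DomainSet,
    b: DomainSet,
    cfg: MatchConfig | None = None,
    *,
    tolerance_units: Literal["length", "genes"] = "length",
    annotation: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Boundary coincidence: every A boundary against every B boundary.

    Each domain contributes its two end coordinates. An A boundary matches
    when any B boundary lies within the tolerance — ``boundary_tol_frac`` of
    that A domain's length in bp (COD-vs-TAD style), or, with
    ``tolerance_units='genes'``, within that fraction of the domain's gene
    count converted to a rank distance against B boundary gene ranks
    (normal-vs-cancer style). Boundaries are matched independently; a single
    B boundary may satisfy several A boundaries.
    """
    cfg = cfg or MatchConfig()
    rows = []
    if tolerance_units == "length":
        b_bounds = np.array(
            [x for d in b.domains for x in (d.start_bp, d.end_bp)], dtype=float
        )
        for i, da in enumerate(a.domains):
            tol = cfg.boundary_tol_frac * da.length_bp
            for side, pos in (("start", da.start_bp), ("end", da.end_bp)):
                matched = bool(len(b_bounds)) and bool(np.min(np.abs(b_bounds - pos)) < tol)
                rows.append({"index_a": i, "side": side, "position": pos, "matched": matched})
    else:
        b_bounds = np.array(
            [x for d in b.domains if d.gene_ids for x in (d.first_rank, d.last_rank)],
            dtype=float,
        )
        for i, da in enumerate(a.domains):
            if not da.gene_ids:
                continue
            tol = cfg.boundary_tol_frac * da.n_genes
            for side, pos in (("start", da.first_rank), ("end", da.last_rank)):
                matched = bool(len(b_bounds)) and bool(np.min(np.abs(b_bounds - pos)) <= tol)
                rows.append({"index_a": i, "side": side, "position": pos, "matched": matched})
    return pd.DataFrame(rows, columns=["index_a", "side", "position", "matched"])


def match_domains_by_genes(
    a: DomainSet, b: DomainSet, cfg: MatchConfig | None = None
) -> pd.DataFrame:
    """Gene-composition matching: A matches if one B shares >= gene_frac of A's genes."""
    cfg = cfg or MatchConfig()
    for ds in (a, b):
        if any(not d.gene_ids for d in ds.domains):
            raise ValueError("every domain needs a gene list for gene matching")
    b_sets = [set(d.gene_ids) for d in b.domains]
    rows = []
    for i, da in enumerate(a.domains):
        ga = set(da.gene_ids)
        best_frac, best_j = 0.0, -1
        for j, gb in enumerate(b_sets):
            frac = len(ga & gb) / len(ga)
            if frac > best_frac:
                best_frac, best_j = frac, j
        rows.append(
            {
                "index_a": i,
                "best_index_b": best_j,
                "shared_frac": best_frac,
                "matched": best_frac >= cfg.gene_frac,
            }
        )
    return pd.DataFrame(rows, columns=["index_a", "best_index_b", "shared_frac", "matched"])


def assign_genes_to_domains(
    annotation: pd.DataFrame, domains: DomainSet
) -> pd.Series:
    """Map each gene of the chromosome to a domain index by midpoint containment.

    A gene belongs to domain k iff (start + end) / 2 falls in [start_bp,
    end_bp) of domain k; genes outside every domain get -1. Domains must be
    non-overlapping so each gene lands in at most one.
    """
    genes = chromosome_genes(annotation, domains.chromosome)
    for d1, d2 in zip(domains.domains, domains.domains[1:]):
        if d2.start_bp < d1.end_bp:
            raise ValueError("domains overlap in genomic coordinates")
    mid = (genes["start"].to_numpy() + genes["end"].to_numpy()) / 2.0
    assignment = np.full(len(genes), -1, dtype=int)
    for k, d in enumerate(domains.domains):
        assignment[(mid >= d.start_bp) & (mid < d.end_bp)] = k
    return pd.Series(assignment, index=genes["gene_id"], name="domain")


def gene_set_overlap_test(
    hits_in_set: int, set_size: int, category_size: int, universe: int
) -> float:
    """Upper-tail hypergeometric probability of >= hits category genes in the set."""
    if not (0 <= hits_in_set <= min(set_size, category_size) <= universe):
        raise ValueError(
            f"inconsistent counts: hits={hits_in_set}, set={set_size}, "
            f"category={category_size}, universe={universe}"
        )
    return float(stats.hypergeom.sf(hits_in_set - 1, universe, category_size, set_size))


def boundary_coincidence_chi2(
    real_matched: int,
    real_total: int,
    random_matched: int,
    random_total: int,
    *,
    correction: bool = False,
) -> tuple[float, float]:
    """Pearson chi-square on the 2x2 matched/unmatched table; returns (chi2, p)."""
    cells = [real_matched, real_total - real_matched, random_matched, random_total - random_matched]
    if any(c < 0 for c in cells):
        raise ValueError("negative cell in contingency table")
    table = np.array(cells, dtype=float).reshape(2, 2)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("zero margin in contingency table: test undefined")
    res = stats.chi2_contingency(table, correction=correction)
    return float(res.statistic), float(res.pvalue)


def intra_vs_inter_domain_coexpression(
    domains: DomainSet,
    cm: CoexpressionMatrix,
    annotation: pd.DataFrame,
    *,
    n_tests: int | None = None,
) -> tuple[dict[str, np.ndarray], pd.DataFrame]:
    """Intra-domain vs inter-domain vs randomized-intra coexpression.

    Genes are assigned to domains by midpoint; coefficients are split into
    intra (same domain), inter (two domains) and intra-random (same domain
    of the inversion-randomized set). Returns the distributions and the
    Bonferroni-corrected Mann-Whitney comparison table.
    """
    if not domains.domains:
        return {}, pd.DataFrame()
    assignment = assign_genes_to_domains(annotation, domains).to_numpy()
    rnd = randomize_domains_by_inversion(domains, annotation=annotation)
    rnd_assignment = assign_genes_to_domains(annotation, rnd).to_numpy()

    n = cm.n_genes
    iu, ju = np.triu_indices(n, k=1)
    vals = cm.C[iu, ju]
    ok = ~np.isnan(vals)
    iu, ju, vals = iu[ok], ju[ok], vals[ok]
    intra = (assignment[iu] >= 0) & (assignment[iu] == assignment[ju])
    inter = (assignment[iu] >= 0) & (assignment[ju] >= 0) & (assignment[iu] != assignment[ju])
    r_intra = (rnd_assignment[iu] >= 0) & (rnd_assignment[iu] == rnd_assignment[ju])
    groups = {
        "intra": vals[intra],
        "inter": vals[inter],
        "intra_random": vals[r_intra],
    }
    nonempty = {k: v for k, v in groups.items() if len(v)}
    table = (
        compare_distributions(nonempty, n_tests=n_tests) if len(nonempty) >= 2 else pd.DataFrame()
    )
    return groups, table
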