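"""Hi-C contact-matrix normalization and contact-profile correlation.

The pipeline mirrors the standard intra-chromosomal compartment analysis:
raw binned counts are balanced with Knight-Ruiz (KR) matrix scaling so all
included rows sum to a common constant; the balanced matrix is divided by
the mean contact at each genomic distance to give the observed/expected
(O/E) matrix; and the Pearson correlation between O/E rows ("profile
correlation", a.k.a. connectivity) measures how similar two loci's
genome-wide contact patterns are. Genes are mapped to bins by midpoint so
every gene pair inherits a connectivity value.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .coexpression import CoexpressionMatrix
from .cod_stats import CODPairStat, compare_distributions, randomize_domains_by_inversion
from .io import DomainSet, chromosome_genes


# ---------------------------------------------------------------------------
# KR balancing
# ---------------------------------------------------------------------------


class BalancingError(RuntimeError):
    pass


def _kr_newton(A: np.ndarray, tol: float, max_outer: int) -> np.ndarray:
    """Knight-Ruiz inner-outer Newton iteration with conjugate-gradient inner solves.

    Finds x > 0 with diag(x) A diag(x) e = e. Translated from the published
    algorithm; raises BalancingError on stagnation.
    """
    n = A.shape[0]
    e = np.ones(n)
    x = e.copy()
    delta, big_delta = 0.1, 3.0
    g, etamax = 0.9, 0.1
    eta = etamax
    rt = tol**2
    v = x * (A @ x)
    rk = 1.0 - v
    rho_km1 = float(rk @ rk)
    rout = rho_km1
    rold = rout
    outer = 0
    while rout > rt:
        outer += 1
        if outer > max_outer:
            raise BalancingError(f"KR did not converge in {max_outer} outer iterations")
        k = 0
        y = e.copy()
        innertol = max(eta**2 * rout, rt)
        rho_km2 = rho_km1
        while rho_km1 > innertol:
            k += 1
            if k == 1:
                Z = rk / v
                p = Z.copy()
                rho_km1 = float(rk @ Z)
            else:
                beta = rho_km1 / rho_km2
                p = Z + beta * p
            w = x * (A @ (x * p)) + v * p
            denom = float(p @ w)
            if denom <= 0:
                raise BalancingError("KR inner solve lost positive definiteness")
            alpha = rho_km1 / denom
            ap = alpha * p
            ynew = y + ap
            if ynew.min() <= delta:
                if delta == 0:
                    break
                ind = ap < 0
                gamma = float(np.min((delta - y[ind]) / ap[ind]))
                y = y + gamma * ap
                break
            if ynew.max() >= big_delta:
                ind = ynew > big_delta
                gamma = float(np.min((big_delta - y[ind]) / ap[ind]))
                y = y + gamma * ap
                break
            y = ynew
            rk = rk - alpha * w
            rho_km2 = rho_km1
            Z = rk / v
            rho_km1 = float(rk @ Z)
            if k > 10 * n:
                raise BalancingError("KR inner iteration stalled")
        x = x * y
        v = x * (A @ x)
        rk = 1.0 - v
        rho_km1 = float(rk @ rk)
        rout = rho_km1
        rat = rout / rold
        rold = rout
        eta = g * rat
        if g * eta**2 > 0.1:
            eta = max(eta, g * eta**2)
        eta = max(min(eta, etamax), 0.5 * tol / max(np.sqrt(rout), 1e-300))
    return x


def _sinkhorn(A: np.ndarray, tol: float, max_iter: int) -> np.ndarray:
    """Symmetric alternating scaling: x <- x / sqrt(rowsum). Slow but robust."""
    n = A.shape[0]
    x = np.ones(n)
    for _ in range(max_iter):
        s = x * (A @ x)
        if np.ptp(s) <= tol * max(s.max(), 1e-300):
            return x
        if np.any(s <= 0):
            raise BalancingError("zero row sum during Sinkhorn scaling")
        x = x / np.sqrt(s)
    raise BalancingError(f"Sinkhorn did not converge in {max_iter} iterations")


def kr_balance(
    counts: np.ndarray,
    tol: float = 1e-6,
    max_iter: int = 1000,
    min_nnz: int = 1,
    chromosome: str = "?",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Balance a symmetric nonnegative contact matrix.

    Returns ``(vector, balanced, included)`` where ``balanced[i, j] =
    vector[i] * counts[i, j] * vector[j]`` has equal row sums (= 1) over the
    included bins; bins with fewer than ``min_nnz`` nonzero entries are
    excluded (vector NaN, rows/columns NaN in the balanced matrix). Tries
    the Knight-Ruiz Newton scheme first and falls back to symmetric
    Sinkhorn scaling when it fails.
    """
    A = np.asarray(counts, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("counts must be a square matrix")
    if np.any(A < 0):
        raise ValueError("counts must be nonnegative")
    if not np.allclose(A, A.T):
        raise ValueError("counts must be symmetric")
    n = A.shape[0]
    nnz = (A > 0).sum(axis=1)
    included = nnz >= max(min_nnz, 1)
    sub = A[np.ix_(included, included)]
    m = sub.shape[0]
    vector = np.full(n, np.nan)
    balanced = np.full((n, n), np.nan)
    if m == 0:
        return vector, balanced, included
    if np.any(sub.sum(axis=1) == 0):
        # excluding sparse bins may strand others; drop them too
        keep = sub.sum(axis=1) > 0
        idx = np.flatnonzero(included)[keep]
        included = np.zeros(n, dtype=bool)
        included[idx] = True
        sub = A[np.ix_(included, included)]
        m = sub.shape[0]
    try:
        x = _kr_newton(sub, tol=tol, max_outer=max_iter)
    except BalancingError:
        try:
            x = _sinkhorn(sub, tol=tol, max_iter=max_iter * 100)
        except BalancingError as err:
            raise BalancingError(f"balancing failed for chromosome {chromosome}: {err}")
    # polish with a few Sinkhorn sweeps so the row-sum spread meets tol exactly
    B = x[:, None] * sub * x[None, :]
    for _ in range(100):
        s = B.sum(axis=1)
        if np.ptp(s) <= tol:
            break
        x = x / np.sqrt(s)
        B = x[:, None] * sub * x[None, :]
    vector[included] = x
    balanced[np.ix_(included, included)] = B
    return vector, balanced, included


# ---------------------------------------------------------------------------
# O/E and profile correlation
# ---------------------------------------------------------------------------


def observed_over_expected(normalized: np.ndarray) -> np.ndarray:
    """Divide each entry by the mean value at its genomic distance.

    expected(d) is the mean of defined entries on diagonal d; entries on
    diagonals with expected = 0 (or no data) are NaN. By construction the
    per-diagonal mean of the result is 1 wherever defined.
    """
    M = np.asarray(normalized, dtype=float)
    n = M.shape[0]
    oe = np.full_like(M, np.nan)
    for d in range(n):
        diag = np.diagonal(M, offset=d)
        defined = ~np.isnan(diag)
        if not defined.any():
            continue
        expected = diag[defined].mean()
        if expected == 0:
            continue
        idx = np.arange(n - d)
        oe[idx, idx + d] = diag / expected
        oe[idx + d, idx] = diag / expected
    return oe


def profile_correlation(oe: np.ndarray, min_defined: int = 3) -> np.ndarray:
    """Pearson correlation of O/E rows for every bin pair.

    For bins i and j the correlation runs over columns defined in both rows,
    excluding columns i and j themselves (the self-contact positions).
    Pairs with fewer than ``min_defined`` shared columns, or a constant row
    over them, are NaN. Symmetric with unit diagonal on defined bins.
    """
    M = np.asarray(oe, dtype=float)
    n = M.shape[0]
    out = np.full((n, n), np.nan)
    row_ok = (~np.isnan(M)).sum(axis=1) >= min_defined
    for i in range(n):
        if row_ok[i]:
            out[i, i] = 1.0
        for j in range(i + 1, n):
            if not (row_ok[i] and row_ok[j]):
                continue
            mask = ~np.isnan(M[i]) & ~np.isnan(M[j])
            mask[i] = mask[j] = False
            if mask.sum() < min_defined:
                continue
            a, b = M[i, mask], M[j, mask]
            sa, sb = a.std(), b.std()
            if sa == 0 or sb == 0:
                continue
            r = float(((a - a.mean()) * (b - b.mean())).mean() / (sa * sb))
            out[i, j] = out[j, i] = r
    return out


# ---------------------------------------------------------------------------
# Container tying the stages together
# ---------------------------------------------------------------------------


@dataclass
class HiCMatrix:
    """Binned intra-chromosomal contact matrix and its derived transforms."""

    chromosome: str
    resolution: int
    counts: np.ndarray
    balancing_vector: np.ndarray | None = None
    normalized: np.ndarray | None = None
    included: np.ndarray | None = None
    oe: np.ndarray | None = None
    profile_corr: np.ndarray | None = None

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]

    @classmethod
    def from_triplets(
        cls,
        path: str | Path,
        resolution: int,
        chromosome: str = "?",
        n_bins: int | None = None,
    ) -> "HiCMatrix":
        """Load 3-column triplet text (bin_i, bin_j, count); mirrored on load.

        Bin indices may be given either as 0-based bin numbers or as start
        coordinates in bp (multiples of the resolution; detected when values
        exceed the bin count range).
        """
        df = pd.read_csv(path, sep=r"\s+", header=None, names=["i", "j", "count"])
        bi, bj = df["i"].to_numpy(float), df["j"].to_numpy(float)
        if bi.size and (bi.max() >= resolution or bj.max() >= resolution):
            bi, bj = bi / resolution, bj / resolution
        bi, bj = bi.astype(int), bj.astype(int)
        n = n_bins or int(max(bi.max(), bj.max())) + 1
        M = np.zeros((n, n))
        for i, j, c in zip(bi, bj, df["count"].to_numpy(float)):
            M[i, j] = c
            M[j, i] = c
        return cls(chromosome, resolution, M)

    def process(self, tol: float = 1e-6, max_iter: int = 1000, min_nnz: int = 1) -> "HiCMatrix":
        """Run balancing, O/E and profile correlation in sequence."""
        self.balancing_vector, self.normalized, self.included = kr_balance(
            self.counts, tol=tol, max_iter=max_iter, min_nnz=min_nnz, chromosome=self.chromosome
        )
        self.oe = observed_over_expected(self.normalized)
        self.profile_corr = profile_correlation(self.oe)
        return self


# ---------------------------------------------------------------------------
# Gene-level connectivity
# ---------------------------------------------------------------------------


def gene_pair_connectivity(
    annotation: pd.DataFrame,
    profile_corr: np.ndarray,
    resolution: int,
    chromosome: str,
) -> np.ndarray:
    """Connectivity for every gene pair of a chromosome.

    Each gene maps to the bin containing its midpoint (integer division by
    the resolution); pairs inherit profile_corr of their bin pair. Two genes
    in the same bin share an identical contact profile, so their
    connectivity is 1 by convention. Genes whose midpoint falls beyond the
    matrix extent yield NaN rows (the pairs are skipped downstream).
    """
    genes = chromosome_genes(annotation, chromosome)
    mid = (genes["start"].to_numpy() + genes["end"].to_numpy()) / 2.0
    bins = (mid // resolution).astype(int)
    n_bins = profile_corr.shape[0]
    n = len(genes)
    conn = np.full((n, n), np.nan)
    inside = (bins >= 0) & (bins < n_bins)
    if not inside.all():
        import logging

        logging.getLogger("codomains").warning(
            "%d gene(s) beyond the Hi-C matrix extent on chromosome %s",
            int((~inside).sum()), chromosome,
        )
    for i in range(n):
        if not inside[i]:
            continue
        for j in range(i, n):
            if not inside[j]:
                continue
            v = 1.0 if bins[i] == bins[j] else profile_corr[bins[i], bins[j]]
            conn[i, j] = conn[j, i] = v
    return conn


@dataclass
class ConnectivityBinning:
    """Equal-count bins of gene pairs ranked by connectivity."""

    mean_connectivity: np.ndarray
    mean_coexpression: np.ndarray
    pair_count: np.ndarray

    @property
    def n_bins(self) -> int:
        return len(self.pair_count)


def binned_connectivity_vs_coexpression(
    connectivity: np.ndarray,
    cm: CoexpressionMatrix,
    n_bins: int = 20,
) -> ConnectivityBinning:
    """Rank gene pairs by connectivity, split into equal-count bins, average both.

    Only pairs with both a defined connectivity and a defined coexpression
    enter; bin counts differ by at most 1 (bins reduced when pairs are
    scarce).
    """
    n = cm.n_genes
    if connectivity.shape != (n, n):
        raise ValueError("connectivity and coexpression matrices disagree on gene count")
    iu, ju = np.triu_indices(n, k=1)
    conn = connectivity[iu, ju]
    coex = cm.C[iu, ju]
    ok = ~np.isnan(conn) & ~np.isnan(coex)
    conn, coex = conn[ok], coex[ok]
    if conn.size == 0:
        return ConnectivityBinning(np.array([]), np.array([]), np.array([], dtype=int))
    order = np.argsort(conn, kind="stable")
    conn, coex = conn[order], coex[order]
    n_bins = min(n_bins, conn.size)
    groups = np.array_split(np.arange(conn.size), n_bins)
    return ConnectivityBinning(
        np.array([conn[g].mean() for g in groups]),
        np.array([coex[g].mean() for g in groups]),
        np.array([len(g) for g in groups]),
    )


def cod_connectivity_comparison(
    cods: DomainSet,
    pair_stats: Sequence[CODPairStat],
    connectivity: np.ndarray,
    annotation: pd.DataFrame,
    *,
    n_tests: int | None = None,
) -> tuple[dict[str, np.ndarray], pd.DataFrame]:
    """Connectivity of intra-COD / coexpressed inter-COD pairs vs rest vs random.

    Builds the distributions behind the two standard comparisons: (i)
    gene pairs inside the same COD vs all remaining pairs vs pairs inside
    the same inversion-randomized COD; (ii) gene pairs spanning two
    *coexpressed* CODs (|average inter-COD coexpression| >= 0.2) vs the rest
    vs pairs spanning two different randomized CODs. Returns the labeled
    distributions and the Bonferroni-corrected Mann-Whitney table.
    """
    if not cods.domains:
        return {}, pd.DataFrame()
    n = connectivity.shape[0]
    label = np.full(n, -1, dtype=int)
    for k, d in enumerate(cods.domains):
        if d.gene_ids:
            label[d.first_rank : d.last_rank + 1] = k
    rnd = randomize_domains_by_inversion(cods, annotation=annotation)
    rlabel = np.full(n, -1, dtype=int)
    for k, d in enumerate(rnd.domains):
        if d.gene_ids:
            rlabel[d.first_rank : d.last_rank + 1] = k

    coupled = {
        frozenset((p.index_a, p.index_b))
        for p in pair_stats
        if p.classification in ("positive", "negative")
    }
    iu, ju = np.triu_indices(n, k=1)
    vals = connectivity[iu, ju]
    ok = ~np.isnan(vals)
    iu, ju, vals = iu[ok], ju[ok], vals[ok]
    li, lj = label[iu], label[ju]
    intra = (li >= 0) & (li == lj)
    inter_coex = np.array(
        [
            a >= 0 and b >= 0 and a != b and frozenset((a, b)) in coupled
            for a, b in zip(li, lj)
        ],
        dtype=bool,
    )
    rest = ~intra & ~inter_coex
    ri, rj = rlabel[iu], rlabel[ju]
    groups = {
        "intra": vals[intra],
        "rest": vals[rest],
        "intra_random": vals[(ri >= 0) & (ri == rj)],
        "inter_coexpressed": vals[inter_coex],
        "inter_random": vals[(ri >= 0) & (rj >= 0) & (ri != rj)],
    }
    nonempty = {k: v for k, v in groups.items() if len(v)}
    wanted = [
        ("intra", "rest"),
        ("intra", "intra_random"),
        ("inter_coexpressed", "rest"),
        ("inter_coexpressed", "inter_random"),
    ]
    comparisons = [(a, b) for a, b in wanted if a in nonempty and b in nonempty]
    table = (
        compare_distributions(nonempty, n_tests=n_tests, comparisons=comparisons)
        if comparisons
        else pd.DataFrame()
    )
    return groups, table
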