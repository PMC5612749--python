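"""Coexpression-domain (COD) calling from the binsignal track.

The calling statistic is a TopDom-style window average. For gene i with
window w, let U_i = {i-w+1, ..., i} and D_i = {i+1, ..., i+w}; then

    binsignal(i) = (1 / w^2) * sum_{l, m} C(U_i(l), D_i(m)),

the mean correlation between the w genes ending at i and the w genes that
follow — a measure of coexpression cohesion across the junction between
genes i and i+1. binsignal is high inside coexpression domains and dips
between them. CODs are maximal runs of junctions with binsignal >= threshold
(default 0.15, the genome-wide average in the reference breast cohort),
delimited on both sides by statistically significant low-binsignal boundary
regions (Student's t-test on flanking binsignal values, p < alpha) or by
chromosome ends. A run of above-threshold junctions at ranks [r0, r1] spans
the genes r0..r1+1, which are the genes reported for the COD. Single-gene
dips below the threshold are tolerated inside a COD; domains with fewer than
``min_cod_genes`` genes (default 4) are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .coexpression import CoexpressionMatrix, average_pairwise_coexpression
from .io import Domain, DomainSet, chromosome_genes


@dataclass
class CODCallConfig:
    """Tunable parameters of the COD caller (defaults are the reference ones)."""

    w: int = 4
    #: window (in binsignal values per side) of the boundary t-test; fixed at
    #: four independently of w, as the test is described with four values a side
    test_w: int = 4
    threshold: float = 0.15
    alpha: float = 0.05
    min_cod_genes: int = 4
    #: consecutive below-threshold junctions tolerated inside a COD
    max_internal_dip: int = 1
    #: minimum run length for a *reported* boundary region
    min_boundary_run: int = 4
    #: if True, only runs >= min_boundary_run may delimit CODs; otherwise any
    #: significant below-threshold run of >= 2 junctions qualifies
    strict_boundary_length: bool = False
    #: where in a below-threshold run the boundary t-test is evaluated:
    #: "edges" (both transition junctions; smaller p wins), "min"
    #: (minimum-binsignal junction) or "midpoint"
    anchor: str = "edges"

    def __post_init__(self) -> None:
        if self.w < 1:
            raise ValueError("w must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.min_cod_genes < 1:
            raise ValueError("min_cod_genes must be >= 1")
        if self.anchor not in ("edges", "min", "midpoint"):
            raise ValueError(f"unknown anchor {self.anchor!r}")


@dataclass
class BinSignalTrack:
    """Per-gene binsignal values for one chromosome (NaN where undefined)."""

    chromosome: str
    w: int
    values: np.ndarray
    threshold: float = 0.15

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


@dataclass
class BoundaryRegion:
    """A below-threshold run evaluated as a candidate COD boundary."""

    first_rank: int
    last_rank: int
    p_value: float
    significant: bool

    @property
    def run_length(self) -> int:
        return self.last_rank - self.first_rank + 1


def compute_binsignal(cm: CoexpressionMatrix, w: int = 4) -> BinSignalTrack:
    """Windowed mean coexpression across each inter-gene junction.

    At chromosome ends the windows truncate to the available genes and the
    mean runs over the existing block; entries involving invalid
    (zero-variance) genes are excluded, shrinking the divisor. The value is
    undefined (NaN) where either window is empty of valid genes — in
    particular at the last rank, whose downstream window is empty.
    """
    n = cm.n_genes
    if n <= w:
        raise ValueError(f"need more than w={w} genes, got {n}")
    vals = np.full(n, np.nan)
    C = cm.C
    for i in range(n):
        u0 = max(0, i - w + 1)
        d1 = min(n, i + 1 + w)
        if i + 1 >= n:
            continue
        block = C[u0 : i + 1, i + 1 : d1]
        defined = block[~np.isnan(block)]
        if defined.size:
            vals[i] = defined.mean()
    return BinSignalTrack(cm.chromosome, w, vals)


def boundary_test(track: BinSignalTrack, i: int, w: int | None = None) -> float:
    """Two-sided pooled-variance t-test of flanking binsignal windows.

    Compares the w binsignal values at ranks {i-w+1..i} against those at
    {i+1..i+w}. Returns NaN when either side has fewer than 2 defined
    values; identical constant windows give p = 1 by convention.
    """
    w = track.w if w is None else w
    n = len(track.values)
    up = track.values[max(0, i - w + 1) : i + 1]
    down = track.values[i + 1 : min(n, i + 1 + w)]
    up = up[~np.isnan(up)]
    down = down[~np.isnan(down)]
    if len(up) < 2 or len(down) < 2:
        return float("nan")
    if np.ptp(up) == 0 and np.ptp(down) == 0:
        return 1.0 if up[0] == down[0] else 0.0
    return float(stats.ttest_ind(up, down, equal_var=True).pvalue)


def _below_runs(above: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of False in a boolean above-threshold array."""
    runs, start = [], None
    for i, a in enumerate(above):
        if not a and start is None:
            start = i
        elif a and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(above) - 1))
    return runs


def _run_pvalue(track: BinSignalTrack, r0: int, r1: int, cfg: CODCallConfig) -> float:
    """Boundary p-value of a below-threshold run [r0, r1].

    "edges" tests the two transition junctions — i = r0 - 1 (upstream flank
    vs run) and i = r1 (run vs downstream flank) — and reports the smaller
    p; runs abutting a chromosome end use the remaining edge only.
    """
    tw = cfg.test_w
    if cfg.anchor == "edges":
        ps = []
        if r0 - 1 >= 0:
            ps.append(boundary_test(track, r0 - 1, tw))
        if r1 + 1 < len(track.values):
            ps.append(boundary_test(track, r1, tw))
        ps = [p for p in ps if not np.isnan(p)]
        return min(ps) if ps else float("nan")
    if cfg.anchor == "min":
        seg = track.values[r0 : r1 + 1]
        if np.all(np.isnan(seg)):
            anchor = (r0 + r1) // 2
        else:
            anchor = r0 + int(np.nanargmin(seg))
        p = boundary_test(track, anchor, tw)
        if np.isnan(p):
            p = boundary_test(track, (r0 + r1) // 2, tw)
        return p
    return boundary_test(track, (r0 + r1) // 2, tw)


def call_cods(
    cm: CoexpressionMatrix,
    annotation: pd.DataFrame | None = None,
    cfg: CODCallConfig | None = None,
) -> tuple[DomainSet, list[BoundaryRegion]]:
    """Call CODs on one chromosome.

    Segmentation: (1) junctions are classified above/below the binsignal
    threshold (undefined values count as below); (2) below-threshold runs no
    longer than ``max_internal_dip`` are absorbed into the surrounding
    domain; longer runs split the axis into candidate segments; (3) a
    candidate segment becomes a COD when both flanking runs are significant
    boundaries (p < alpha) or chromosome ends, and it spans at least
    ``min_cod_genes`` genes. A run of above-threshold junctions [r0, r1]
    spans genes r0..r1+1. Runs of length >= ``min_boundary_run`` are
    reported as BoundaryRegions regardless of the delimitation outcome.

    ``annotation`` (ranked genes of this chromosome) supplies genomic
    coordinates; without it coordinates fall back to gene ranks.
    """
    cfg = cfg or CODCallConfig()
    n = cm.n_genes
    if n < 2 * cfg.w + 1:
        import logging

        logging.getLogger("codomains").warning(
            "chromosome %s has %d genes (< 2w+1): no CODs called", cm.chromosome, n
        )
        return DomainSet(cm.chromosome, [], kind="COD"), []
    track = compute_binsignal(cm, cfg.w)
    # junctions 0..n-2; the one at n-1 has no downstream window by construction
    n_j = n - 1
    above = np.zeros(n_j, dtype=bool)
    defined = ~np.isnan(track.values[:n_j])
    above[defined] = track.values[:n_j][defined] >= cfg.threshold

    runs = _below_runs(above)
    boundaries: list[BoundaryRegion] = []
    min_delim = cfg.min_boundary_run if cfg.strict_boundary_length else 2
    # classify below-threshold runs: tolerated internal dip vs boundary candidate
    run_info = []  # (r0, r1, is_delimiter, p)
    for r0, r1 in runs:
        length = r1 - r0 + 1
        if length <= cfg.max_internal_dip and 0 < r0 and r1 < n_j - 1:
            continue  # internal dip, absorbed
        p = _run_pvalue(track, r0, r1, cfg)
        significant = bool(p < cfg.alpha) if not np.isnan(p) else False
        delim = significant and length >= min_delim
        run_info.append((r0, r1, delim, p))
        if length >= cfg.min_boundary_run:
            boundaries.append(BoundaryRegion(r0, r1, p, significant))

    genes = None
    if annotation is not None:
        genes = chromosome_genes(annotation, cm.chromosome)

    # candidate segments between consecutive splitting runs / chromosome ends
    cuts = [(-1, -1, True, np.nan)] + run_info + [(n_j, n_j, True, np.nan)]
    domains = []
    for (l0, l1, l_delim, l_p), (r0, r1, r_delim, r_p) in zip(cuts, cuts[1:]):
        seg_first, seg_last = l1 + 1, r0 - 1
        if seg_last < seg_first:
            continue
        if not (l_delim and r_delim):
            continue
        # junction run [seg_first, seg_last] spans genes seg_first .. seg_last + 1
        g_first, g_last = seg_first, min(seg_last + 1, n - 1)
        n_genes = g_last - g_first + 1
        if n_genes < cfg.min_cod_genes:
            continue
        ranks = np.arange(g_first, g_last + 1)
        avg_intra, n_pairs = average_pairwise_coexpression(cm, ranks)
        attrs = {
            "avg_intra_coexpression": avg_intra,
            "n_pairs": n_pairs,
            "p_left": None if np.isnan(l_p) else float(l_p),
            "p_right": None if np.isnan(r_p) else float(r_p),
        }
        if genes is not None:
            start_bp = int(genes.loc[g_first, "start"])
            end_bp = int(genes.loc[g_last, "end"])
            ids = tuple(genes.loc[g_first:g_last, "gene_id"])
        else:
            start_bp, end_bp = int(g_first), int(g_last) + 1
            ids = tuple(cm.gene_ids[g_first : g_last + 1])
        domains.append(
            Domain(int(g_first), int(g_last), start_bp, end_bp, ids, attrs)
        )
    return DomainSet(cm.chromosome, domains, kind="COD"), boundaries


def window_sweep(
    cm: CoexpressionMatrix,
    w_values: Sequence[int],
    annotation: pd.DataFrame | None = None,
    cfg: CODCallConfig | None = None,
) -> pd.DataFrame:
    """COD summary per window size: count, mean size, mean intra coexpression.

    Used to justify the default w = 4; nearby windows (3-6) should give very
    similar average intra-COD coexpression on well-structured data.
    """
    base = cfg or CODCallConfig()
    rows = []
    for w in w_values:
        c = CODCallConfig(
            w=int(w),
            test_w=base.test_w,
            threshold=base.threshold,
            alpha=base.alpha,
            min_cod_genes=base.min_cod_genes,
            max_internal_dip=base.max_internal_dip,
            min_boundary_run=base.min_boundary_run,
            strict_boundary_length=base.strict_boundary_length,
            anchor=base.anchor,
        )
        cods, _ = call_cods(cm, annotation, c)
        sizes = [d.n_genes for d in cods]
        intras = [
            d.attributes["avg_intra_coexpression"]
            for d in cods
            if not np.isnan(d.attributes["avg_intra_coexpression"])
        ]
        rows.append(
            {
                "w": int(w),
                "n_cods": len(cods),
                "mean_cod_size": float(np.mean(sizes)) if sizes else np.nan,
                "mean_intra_coexpression": float(np.mean(intras)) if intras else np.nan,
            }
        )
    return pd.DataFrame(rows, columns=["w", "n_cods", "mean_cod_size", "mean_intra_coexpression"])
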