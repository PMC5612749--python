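"""Synthetic cohorts with planted coexpression-domain structure.

The generator emulates the statistical skeleton the pipeline assumes in
real tumor/normal cohorts: collinear blocks of mutually correlated genes
(the planted domains), optional long-range coupling between designated
block pairs (planted inter-domain co-regulation), uncorrelated background
genes, and Hi-C contact maps with power-law distance decay plus a
compartment enrichment aligned to the coupled blocks. Every quantity is
produced by a single-factor model so the target correlations are analytic:
a gene in block b is

    x = sqrt(rho_intra) * F_b + sqrt(1 - rho_intra) * eps,

giving within-block correlation rho_intra exactly in expectation; a coupled
block pair shares a factor component sized so the cross-block gene
correlation is rho_inter. Values are mapped to a nonnegative RSEM-like
scale by an affine transform (never truncation), which leaves every Pearson
coefficient unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .compare import MatchConfig, match_domains_by_genes
from .io import Domain, DomainSet, ExpressionMatrix, make_annotation, order_genes


@dataclass
class HiCSpec:
    """Parameters of the synthetic contact map."""

    resolution: int = 100_000
    decay: float = 1.0  # power-law exponent of the distance decay
    compartment_boost: float = 1.0  # same-compartment contact multiplier
    depth: float = 100.0  # expected counts at distance 1


@dataclass
class SyntheticSpec:
    """Planted structure of one synthetic chromosome cohort.

    Defaults reproduce the generator's reference scenario: five 10-gene
    blocks at rho_intra = 0.6 separated by 6 background genes, 100 samples,
    one gene every 100 kb.
    """

    n_genes: int = 86
    n_samples: int = 100
    gene_spacing: int = 100_000
    gene_length: int = 50_000
    blocks: list[tuple[int, int, float]] = field(
        default_factory=lambda: blocks_with_gaps(5, 10, 6, 0.6)
    )
    coupled_block_pairs: list[tuple[int, int, float]] = field(default_factory=list)
    #: groups of blocks sharing one common factor: [(block indices, rho_inter)];
    #: every cross-block gene pair within a group correlates at rho_inter
    coupled_groups: list[tuple[tuple[int, ...], float]] = field(default_factory=list)
    background_sd: float = 1.0
    seed: int = 0
    chromosome: str = "1"
    base_expression: float = 100.0
    expression_scale: float = 20.0
    hic: HiCSpec = field(default_factory=HiCSpec)

    def __post_init__(self) -> None:
        last = -1
        for b0, b1, rho in sorted(self.blocks):
            if b0 <= last:
                raise ValueError("blocks must be disjoint in rank space")
            if not 0 <= rho < 1:
                raise ValueError("rho_intra must be in [0, 1)")
            if b1 >= self.n_genes:
                raise ValueError("block extends beyond n_genes")
            last = b1
        for a, b, rho in self.coupled_block_pairs:
            ra, rb = self.blocks[a][2], self.blocks[b][2]
            if not 0 <= rho <= min(ra, rb):
                raise ValueError("rho_inter must satisfy 0 <= rho_inter <= rho_intra")
        for members, rho in self.coupled_groups:
            if len(members) < 2:
                raise ValueError("a coupled group needs at least 2 blocks")
            if not 0 <= rho <= min(self.blocks[k][2] for k in members):
                raise ValueError("rho_inter must satisfy 0 <= rho_inter <= rho_intra")


def blocks_with_gaps(
    n_blocks: int, block_size: int, gap: int, rho: float
) -> list[tuple[int, int, float]]:
    """Blocks of ``block_size`` genes separated (and flanked) by ``gap`` genes."""
    out = []
    pos = gap
    for _ in range(n_blocks):
        out.append((pos, pos + block_size - 1, rho))
        pos += block_size + gap
    return out


def _annotation_for(spec: SyntheticSpec) -> pd.DataFrame:
    rows = [
        (
            f"g{i:05d}",
            spec.chromosome,
            i * spec.gene_spacing,
            i * spec.gene_spacing + spec.gene_length,
            "+",
        )
        for i in range(spec.n_genes)
    ]
    return order_genes(make_annotation(rows), chromosomes=[spec.chromosome])


def generate_expression(
    spec: SyntheticSpec,
) -> tuple[ExpressionMatrix, pd.DataFrame, DomainSet]:
    """Sample a cohort; returns (expression, ranked annotation, truth domains).

    The implied covariance is checked for feasibility: the shared-factor
    weights of each block must not exceed 1 in total (otherwise the target
    correlations are not jointly attainable) — enforced in the spec and
    here via the factor construction.
    """
    rng = np.random.default_rng(spec.seed)
    n, m = spec.n_genes, spec.n_samples
    annotation = _annotation_for(spec)

    # shared factors: one per coupled pair, one per coupled group
    couplings = [((a, b), rho) for a, b, rho in spec.coupled_block_pairs]
    couplings += [(tuple(members), rho) for members, rho in spec.coupled_groups]
    pair_factors = [rng.standard_normal(m) for _ in couplings]
    weights: dict[int, list[tuple[int, float]]] = {}
    for p, (members, rho_inter) in enumerate(couplings):
        for blk in members:
            rho_intra = spec.blocks[blk][2]
            if rho_intra == 0:
                raise ValueError("cannot couple a block with rho_intra = 0")
            weights.setdefault(blk, []).append((p, rho_inter / rho_intra))

    factors = []
    for k, (b0, b1, rho) in enumerate(spec.blocks):
        shared = weights.get(k, [])
        total = sum(c for _, c in shared)
        if total > 1 + 1e-12:
            raise ValueError(
                f"block {k}: coupled-factor weights sum to {total:.3f} > 1; "
                "the implied covariance is not positive semidefinite"
            )
        F = np.sqrt(max(0.0, 1.0 - total)) * rng.standard_normal(m)
        for p, c in shared:
            F = F + np.sqrt(c) * pair_factors[p]
        factors.append(F)

    Z = rng.standard_normal((n, m)) * spec.background_sd
    X = Z.copy()
    for (b0, b1, rho), F in zip(spec.blocks, factors):
        load = np.sqrt(rho)
        noise = np.sqrt(1.0 - rho)
        X[b0 : b1 + 1] = load * F[None, :] + noise * Z[b0 : b1 + 1] / spec.background_sd

    values = spec.base_expression + spec.expression_scale * X
    low = values.min()
    if low < 0:  # affine shift, not truncation: correlations untouched
        values = values - low
    gene_ids = annotation["gene_id"].tolist()
    expr = ExpressionMatrix(gene_ids, [f"s{j:04d}" for j in range(m)], values)

    truth_domains = []
    for b0, b1, rho in spec.blocks:
        truth_domains.append(
            Domain(
                b0,
                b1,
                int(annotation.loc[b0, "start"]),
                int(annotation.loc[b1, "end"]),
                tuple(gene_ids[b0 : b1 + 1]),
                {"rho_intra": rho},
            )
        )
    truth = DomainSet(spec.chromosome, truth_domains, kind="COD")
    return expr, annotation, truth


# ---------------------------------------------------------------------------
# Hi-C generation
# ---------------------------------------------------------------------------


def _compartments(spec: SyntheticSpec, n_bins: int) -> np.ndarray:
    """Bin compartment labels derived from the coupling structure.

    Each coupled pair/group of blocks is one compartment (labels 1, 2, ...);
    bins over background or uncoupled blocks keep label 0. Co-regulated
    blocks thereby share enriched contacts, the premise the
    profile-correlation stage tests.
    """
    labels = np.zeros(n_bins, dtype=int)
    couplings = [(a, b) for a, b, _ in spec.coupled_block_pairs]
    couplings += [tuple(members) for members, _ in spec.coupled_groups]
    for g, members in enumerate(couplings, start=1):
        for k in members:
            b0, b1, _ = spec.blocks[k]
            lo = (b0 * spec.gene_spacing) // spec.hic.resolution
            hi = (b1 * spec.gene_spacing + spec.gene_length) // spec.hic.resolution
            labels[lo : min(hi + 1, n_bins)] = g
    return labels


def generate_hic(
    spec: SyntheticSpec, coupling: str = "none"
) -> tuple[np.ndarray, np.ndarray]:
    """Sample a symmetric contact matrix; returns (counts, compartment labels).

    Expected contacts decay as |i - j| ** -decay, multiplied by
    ``compartment_boost`` when both bins share a compartment. With
    ``coupling='cod_coupled'`` the compartments are the bins covering the
    coupled planted blocks; with 'none' all bins share one compartment and
    the boost cancels from the O/E transform. Counts are independent
    Poisson draws, mirrored to a symmetric matrix; seeded from the spec.
    """
    if coupling not in ("none", "cod_coupled"):
        raise ValueError(f"unknown coupling {coupling!r}")
    if spec.hic.decay <= 0:
        raise ValueError("decay exponent must be > 0")
    rng = np.random.default_rng(spec.seed + 1_000_003)
    span = spec.n_genes * spec.gene_spacing
    n_bins = int(np.ceil(span / spec.hic.resolution))
    labels = (
        _compartments(spec, n_bins) if coupling == "cod_coupled" else np.zeros(n_bins, dtype=int)
    )
    i, j = np.meshgrid(np.arange(n_bins), np.arange(n_bins), indexing="ij")
    dist = np.maximum(np.abs(i - j), 1)
    lam = spec.hic.depth * dist.astype(float) ** (-spec.hic.decay)
    same = labels[i] == labels[j]
    lam = lam * np.where(same, spec.hic.compartment_boost, 1.0)
    counts = np.zeros((n_bins, n_bins))
    iu, ju = np.triu_indices(n_bins)
    draws = rng.poisson(lam[iu, ju])
    counts[iu, ju] = draws
    counts[ju, iu] = draws
    return counts, labels


def write_hic_triplets(counts: np.ndarray, path, resolution: int | None = None) -> None:
    """Dump the upper triangle as 'bin_i  bin_j  count' text (nonzero only)."""
    iu, ju = np.triu_indices(counts.shape[0])
    with open(path, "w") as fh:
        for i, j in zip(iu, ju):
            c = counts[i, j]
            if c:
                if resolution:
                    fh.write(f"{i * resolution}\t{j * resolution}\t{c:g}\n")
                else:
                    fh.write(f"{i}\t{j}\t{c:g}\n")


# ---------------------------------------------------------------------------
# Recovery scoring
# ---------------------------------------------------------------------------


@dataclass
class RecoveryResult:
    """How well a called domain set recovers the planted truth."""

    precision: float  # fraction of called domains matching a truth block
    recall: float  # fraction of truth blocks recovered (>= 80% gene coincidence)
    boundary_precision: float
    boundary_recall: float
    boundary_f1: float
    boundary_errors: np.ndarray  # per truth edge: rank offset to nearest called edge


def evaluate_recovery(
    called: DomainSet, truth: DomainSet, tol_genes: int = 1
) -> RecoveryResult:
    """Score called domains against planted blocks.

    Block-level recall uses >= 80% gene coincidence of the truth block with
    a single called domain (and precision the reverse direction). Boundary
    scores match each edge rank (domain first/last gene) to the other set
    within ``tol_genes``; F1 is the harmonic mean of boundary precision and
    recall. With no calls, recall is 0 and precision NaN.
    """
    nan = float("nan")
    if not called.domains:
        return RecoveryResult(nan, 0.0, nan, 0.0, 0.0, np.array([]))
    cfg = MatchConfig(gene_frac=0.80)
    recall = float(match_domains_by_genes(truth, called, cfg)["matched"].mean())
    precision = float(match_domains_by_genes(called, truth, cfg)["matched"].mean())

    t_edges = np.array([x for d in truth.domains for x in (d.first_rank, d.last_rank)])
    c_edges = np.array([x for d in called.domains for x in (d.first_rank, d.last_rank)])
    errors = np.array([int(c_edges[np.abs(c_edges - e).argmin()] - e) for e in t_edges])
    b_recall = float(np.mean(np.abs(errors) <= tol_genes)) if len(t_edges) else nan
    hit_called = [np.min(np.abs(t_edges - e)) <= tol_genes for e in c_edges]
    b_precision = float(np.mean(hit_called)) if len(c_edges) else nan
    if b_precision + b_recall > 0:
        f1 = 2 * b_precision * b_recall / (b_precision + b_recall)
    else:
        f1 = 0.0
    return RecoveryResult(precision, recall, b_precision, b_recall, f1, errors)
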