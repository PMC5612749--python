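"""Shared data model and file I/O.

Genes are ordered 5'->3' along each chromosome irrespective of strand, and
every downstream stage addresses them by *rank* — the 0-based position in
that order. Coordinates are 0-based half-open (BED convention) internally;
1-based inclusive input is converted on read when requested.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("codomains")

#: Default chromosome universe: autosomes 1-22 plus X (23 groups).
#: Y and MT are excluded by default but any universe may be passed instead.
DEFAULT_CHROMOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 23)) + ("X",)

ANNOTATION_COLUMNS = ["gene_id", "chromosome", "start", "end", "strand", "rank"]


def _norm_chrom(name: str) -> str:
    """Strip a leading 'chr' so 'chr1' and '1' compare equal."""
    return name[3:] if name.lower().startswith("chr") else name


# ---------------------------------------------------------------------------
# Expression matrix
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Genes x samples table of nonnegative normalized expression values.

    Rows follow ``genes``; columns follow ``samples``. Values are kept on
    their native nonnegative scale (RSEM-style units); an optional
    ``log2(x + 1)`` transform is available at read time.
    """

    genes: list[str]
    samples: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        if len(set(self.genes)) != len(self.genes):
            dupes = pd.Index(self.genes)[pd.Index(self.genes).duplicated()]
            raise ValueError(f"duplicated gene_id(s): {sorted(set(dupes))}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")
        if np.any(self.values < 0):
            raise ValueError("expression values must be >= 0")
        self._index = {g: i for i, g in enumerate(self.genes)}

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def row(self, gene_id: str) -> np.ndarray:
        return self.values[self._index[gene_id]]

    def subset(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        idx = [self._index[g] for g in gene_ids]
        return ExpressionMatrix(list(gene_ids), list(self.samples), self.values[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.samples)


def read_expression_table(
    path: str | Path,
    annotation: pd.DataFrame | None = None,
    *,
    log2: bool = False,
) -> ExpressionMatrix:
    """Read a tab-delimited expression table (gene_id column + sample columns).

    When ``annotation`` is given the matrix is restricted to annotated genes
    and the number of dropped rows is logged. Duplicated gene ids or
    non-numeric cells are hard errors.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    gene_col = df.columns[0]
    genes = df[gene_col].tolist()
    dup = df[gene_col][df[gene_col].duplicated()]
    if len(dup):
        raise ValueError(f"duplicated gene_id in {path}: {sorted(set(dup))}")
    sample_cols = list(df.columns[1:])
    values = np.empty((len(genes), len(sample_cols)), dtype=float)
    for j, col in enumerate(sample_cols):
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        if bad.any() or numeric.isna().any():
            row = df.loc[numeric.isna().idxmax(), gene_col]
            raise ValueError(f"non-numeric value at gene {row!r}, sample {col!r}")
        values[:, j] = numeric.to_numpy()
    if annotation is not None:
        keep = set(annotation["gene_id"])
        mask = [g in keep for g in genes]
        n_dropped = len(genes) - sum(mask)
        if n_dropped:
            logger.warning("dropped %d gene(s) absent from annotation", n_dropped)
        genes = [g for g, m in zip(genes, mask) if m]
        values = values[np.asarray(mask, dtype=bool)]
    if log2:
        values = np.log2(values + 1.0)
    return ExpressionMatrix(genes, sample_cols, values)


# ---------------------------------------------------------------------------
# Gene annotation
# ---------------------------------------------------------------------------


def make_annotation(
    records: Iterable[tuple],
    columns: Sequence[str] = ("gene_id", "chromosome", "start", "end", "strand"),
) -> pd.DataFrame:
    """Build an annotation frame from (gene_id, chromosome, start, end[, strand])."""
    records = list(records)
    ncol = len(records[0]) if records else len(columns)
    df = pd.DataFrame(records, columns=list(columns)[:ncol])
    if "strand" not in df.columns:
        df["strand"] = "."
    return _validate_annotation(df)


def _validate_annotation(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    df["chromosome"] = df["chromosome"].astype(str)
    if (df["start"] >= df["end"]).any():
        bad = df.loc[df["start"] >= df["end"], "gene_id"].tolist()
        raise ValueError(f"gene(s) with start >= end: {bad}")
    if df["gene_id"].duplicated().any():
        bad = df.loc[df["gene_id"].duplicated(), "gene_id"].tolist()
        raise ValueError(f"duplicated gene_id(s): {sorted(set(bad))}")
    return df


def read_annotation_bed(path: str | Path, *, one_based: bool = False) -> pd.DataFrame:
    """Read gene annotation from BED (chrom, start, end, name[, score, strand])."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 4:
        raise ValueError("annotation BED needs at least 4 columns (name in column 4)")
    out = pd.DataFrame(
        {
            "gene_id": df[3].astype(str),
            "chromosome": df[0].astype(str),
            "start": df[1].astype(int) - (1 if one_based else 0),
            "end": df[2].astype(int),
            "strand": df[5].astype(str) if df.shape[1] >= 6 else ".",
        }
    )
    return _validate_annotation(out)


def read_annotation_gtf(path: str | Path, feature: str = "gene") -> pd.DataFrame:
    """Read gene annotation from GTF; keeps rows of the given feature type.

    GTF is 1-based inclusive; converted to 0-based half-open.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != feature:
                continue
            attrs = dict(
                (kv.strip().split(" ", 1)[0], kv.strip().split(" ", 1)[1].strip('"'))
                for kv in f[8].rstrip(";").split(";")
                if " " in kv.strip()
            )
            gid = attrs.get("gene_id") or attrs.get("gene_name")
            if gid is None:
                raise ValueError(f"GTF row without gene_id attribute: {line[:80]}")
            rows.append((gid, f[0], int(f[3]) - 1, int(f[4]), f[6]))
    return make_annotation(rows)


def order_genes(
    annotation: pd.DataFrame,
    chromosomes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Assign 5'->3' ranks per chromosome, ignoring strand.

    Genes are sorted by ascending start; ties broken by end then gene_id so
    the ordering is deterministic and invariant to input row order. Returns
    the annotation restricted to the chromosome universe (default 1-22 + X)
    with a ``rank`` column.
    """
    universe = DEFAULT_CHROMOSOMES if chromosomes is None else tuple(chromosomes)
    norm_universe = {_norm_chrom(c) for c in universe}
    df = _validate_annotation(annotation)
    df = df[df["chromosome"].map(_norm_chrom).isin(norm_universe)].copy()
    df = df.sort_values(
        ["chromosome", "start", "end", "gene_id"], kind="mergesort"
    ).reset_index(drop=True)
    df["rank"] = df.groupby("chromosome", sort=False).cumcount()
    return df


def chromosome_genes(annotation: pd.DataFrame, chromosome: str) -> pd.DataFrame:
    """Ranked genes of one chromosome, sorted by rank."""
    if "rank" not in annotation.columns:
        raise ValueError("annotation has no ranks; call order_genes first")
    sub = annotation[annotation["chromosome"] == chromosome]
    return sub.sort_values("rank").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Domain sets
# ---------------------------------------------------------------------------


@dataclass
class Domain:
    """A called domain: a gene-rank interval with genomic coordinates."""

    first_rank: int
    last_rank: int
    start_bp: int
    end_bp: int
    gene_ids: tuple[str, ...] = ()
    attributes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.end_bp <= self.start_bp:
            raise ValueError(f"domain end {self.end_bp} <= start {self.start_bp}")
        if self.last_rank < self.first_rank:
            raise ValueError("last_rank < first_rank")
        self.gene_ids = tuple(self.gene_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids) if self.gene_ids else self.last_rank - self.first_rank + 1

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start_bp + self.end_bp)


@dataclass
class DomainSet:
    """Ordered, rank-disjoint domains of one chromosome.

    ``kind`` distinguishes called CODs from consumed TADs/contact domains,
    RIDGEs and randomized null sets. Random sets may contain domains with no
    assigned genes (rank fields then mirror the empty assignment and rank
    disjointness is not enforced).
    """

    chromosome: str
    domains: list[Domain]
    kind: str = "COD"

    VALID_KINDS = ("COD", "TAD", "contact_domain", "RIDGE", "random")

    def __post_init__(self) -> None:
        if self.kind not in self.VALID_KINDS:
            raise ValueError(f"unknown domain kind {self.kind!r}")
        self.domains = sorted(self.domains, key=lambda d: (d.start_bp, d.end_bp))
        if self.kind != "random":
            for a, b in zip(self.domains, self.domains[1:]):
                if b.first_rank <= a.last_rank and a.gene_ids and b.gene_ids:
                    raise ValueError(
                        f"overlapping domains in rank space: "
                        f"[{a.first_rank},{a.last_rank}] and [{b.first_rank},{b.last_rank}]"
                    )

    def __len__(self) -> int:
        return len(self.domains)

    def __iter__(self):
        return iter(self.domains)

    def gene_id_set(self) -> set[str]:
        return {g for d in self.domains for g in d.gene_ids}


def read_domains_bed(
    path: str | Path, kind: str = "TAD", *, one_based: bool = False
) -> dict[str, DomainSet]:
    """Read BED3+ domain intervals, one DomainSet per chromosome.

    Unsorted input is accepted and sorted. Rank fields are set to a dense
    per-chromosome index when no gene information is present.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df[1] = df[1].astype(int) - (1 if one_based else 0)
    df[2] = df[2].astype(int)
    if (df[1] >= df[2]).any():
        raise ValueError(f"interval with start >= end in {path}")
    out: dict[str, DomainSet] = {}
    for chrom, sub in df.groupby(0, sort=False):
        sub = sub.sort_values([1, 2])
        domains = []
        for i, (_, row) in enumerate(sub.iterrows()):
            attrs = {}
            if sub.shape[1] > 3 and not pd.isna(row[3]):
                attrs["name"] = str(row[3])
            domains.append(Domain(i, i, int(row[1]), int(row[2]), attributes=attrs))
        out[str(chrom)] = DomainSet(str(chrom), domains, kind=kind)
    return out


def write_domains(
    sets: dict[str, DomainSet] | DomainSet,
    path: str | Path,
    *,
    sidecar: str | Path | None = None,
) -> None:
    """Write domains as BED4; optionally a sidecar TSV with per-domain details.

    The sidecar mirrors a COD summary table: gene list, gene count, average
    intra-domain coexpression and boundary p-values where present in
    ``attributes``.
    """
    if isinstance(sets, DomainSet):
        sets = {sets.chromosome: sets}
    bed_rows, side_rows = [], []
    for chrom in sets:
        for i, d in enumerate(sets[chrom].domains):
            name = d.attributes.get("name", f"{sets[chrom].kind}_{chrom}_{i + 1}")
            bed_rows.append((chrom, d.start_bp, d.end_bp, name))
            side_rows.append(
                {
                    "chromosome": chrom,
                    "name": name,
                    "start": d.start_bp,
                    "end": d.end_bp,
                    "n_genes": d.n_genes,
                    "genes": ",".join(d.gene_ids),
                    "avg_intra_coexpression": d.attributes.get("avg_intra_coexpression", ""),
                    "p_left": d.attributes.get("p_left", ""),
                    "p_right": d.attributes.get("p_right", ""),
                }
            )
    pd.DataFrame(bed_rows).to_csv(path, sep="\t", header=False, index=False)
    if sidecar is not None:
        pd.DataFrame(side_rows).to_csv(sidecar, sep="\t", index=False)


def domains_from_intervals(
    chromosome: str,
    intervals: Sequence[tuple[int, int]],
    annotation: pd.DataFrame | None = None,
    kind: str = "TAD",
) -> DomainSet:
    """Build a DomainSet from (start, end) pairs, assigning genes by midpoint."""
    domains = [Domain(i, i, int(s), int(e)) for i, (s, e) in enumerate(sorted(intervals))]
    ds = DomainSet(chromosome, domains, kind=kind)
    if annotation is not None:
        ds = attach_genes(ds, annotation)
    return ds


def attach_genes(ds: DomainSet, annotation: pd.DataFrame) -> DomainSet:
    """Re-derive each domain's gene list (and ranks) by gene-midpoint containment."""
    genes = chromosome_genes(annotation, ds.chromosome)
    mid = (genes["start"].to_numpy() + genes["end"].to_numpy()) / 2.0
    new = []
    for d in ds.domains:
        inside = (mid >= d.start_bp) & (mid < d.end_bp)
        ids = tuple(genes.loc[inside, "gene_id"])
        ranks = genes.loc[inside, "rank"]
        if len(ids):
            nd = replace(d, gene_ids=ids, first_rank=int(ranks.min()), last_rank=int(ranks.max()))
        else:
            nd = replace(d, gene_ids=())
        new.append(nd)
    return DomainSet(ds.chromosome, new, kind=ds.kind)
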