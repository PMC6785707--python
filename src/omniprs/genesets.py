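"""SNP-to-gene mapping, gene-set SNP sets, overlap statistics and random sets.

A SNP is *genic* when it falls within a gene body or within 5 kb upstream /
1 kb downstream of it; upstream and downstream are strand-aware by default
(the upstream side of a minus-strand gene is its higher-coordinate side).
Random genic and non-genic SNP sets — the omnigenic "floor" sets — are drawn
from pools pruned to near-independence beforehand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd

from .core import GeneSet, SnpSet

logger = logging.getLogger("omniprs")


@dataclass(frozen=True)
class GenicMargins:
    """Genic window: gene body plus 5 kb upstream and 1 kb downstream."""

    upstream_bp: int = 5000
    downstream_bp: int = 1000

    def __post_init__(self):
        if self.upstream_bp < 0 or self.downstream_bp < 0:
            raise ValueError("genic margins must be >= 0")


@dataclass(frozen=True)
class RandomSetSpec:
    """How many random SNP sets to draw, from which pool, and at what size."""

    n_sets: int = 50
    set_size: int = 5000
    pool: str = "genic"  # "genic" | "nongenic"
    r2_max_pool: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.n_sets < 1 or self.set_size < 1:
            raise ValueError("n_sets and set_size must be >= 1")
        if self.pool not in ("genic", "nongenic"):
            raise ValueError(f"unknown pool '{self.pool}'")


def classify_genic(
    snps: pd.DataFrame,
    genes: pd.DataFrame,
    margins: GenicMargins = GenicMargins(),
    strand_aware: bool = True,
) -> tuple[np.ndarray, dict[str, list[str]]]:
    """Flag genic SNPs and record per-gene SNP assignments.

    Coordinates are 1-based inclusive on both sides; the margin boundaries are
    inclusive (a SNP exactly 5000 bp 5' of a plus-strand gene start is genic).
    Returns (boolean flags aligned to ``snps`` row order, gene_id -> snp_ids).
    """
    flags = np.zeros(len(snps), dtype=bool)
    assignments: dict[str, list[str]] = {}
    pos_by_chrom = {}
    for chrom, sub in snps.groupby("chrom", sort=False):
        sub = sub.sort_values("pos", kind="stable")
        pos_by_chrom[chrom] = (sub["pos"].to_numpy(), sub["snp_id"].to_numpy(), sub.index.to_numpy())
    row_pos = {idx: i for i, idx in enumerate(snps.index)}
    for gene in genes.itertuples(index=False):
        if gene.chrom not in pos_by_chrom:
            assignments[gene.gene_id] = []
            continue
        pos, ids, idx = pos_by_chrom[gene.chrom]
        if strand_aware and gene.strand == "-":
            lo = gene.start - margins.downstream_bp
            hi = gene.end + margins.upstream_bp
        else:
            lo = gene.start - margins.upstream_bp
            hi = gene.end + margins.downstream_bp
        a, b = np.searchsorted(pos, lo, side="left"), np.searchsorted(pos, hi, side="right")
        assignments[gene.gene_id] = list(ids[a:b])
        for j in idx[a:b]:
            flags[row_pos[j]] = True
    return flags, assignments


def snps_for_gene_set(gene_set: GeneSet, assignments: dict[str, list[str]]) -> SnpSet:
    """Union of SNPs assigned to any gene in the set (deduplicated)."""
    out: list[str] = []
    seen: set[str] = set()
    missing = 0
    for gene in gene_set.genes:
        if gene not in assignments:
            missing += 1
            continue
        for snp in assignments[gene]:
            if snp not in seen:
                seen.add(snp)
                out.append(snp)
    if missing:
        logger.warning("gene set '%s': %d genes absent from the annotation", gene_set.name, missing)
    return SnpSet(name=gene_set.name, snps=tuple(out), provenance=gene_set.provenance or "gene_set")


def overlap_stats(gene_sets: list[GeneSet]) -> pd.DataFrame:
    """Gene counts and percentages for every region of the intersection lattice.

    Each region is an exclusive membership pattern over the compared sets;
    percentages are of the union of all genes, so they sum to 100.
    """
    if len(gene_sets) < 2:
        raise ValueError("overlap_stats requires at least 2 gene sets")
    members = [set(gs.genes) for gs in gene_sets]
    union = set().union(*members)
    rows = []
    for pattern in product([True, False], repeat=len(gene_sets)):
        if not any(pattern):
            continue
        region = set(union)
        for inside, genes in zip(pattern, members):
            region &= genes if inside else (union - genes)
        rows.append(
            {
                "region": "&".join(gs.name for gs, inside in zip(gene_sets, pattern) if inside)
                + ("" if all(pattern) else " only" if sum(pattern) == 1 else ""),
                "pattern": "".join("1" if x else "0" for x in pattern),
                "n_genes": len(region),
                "pct_of_union": 100.0 * len(region) / len(union) if union else 0.0,
            }
        )
    return pd.DataFrame(rows)


def draw_random_sets(
    spec: RandomSetSpec,
    snp_ids: np.ndarray | pd.Series,
    genic_flags: np.ndarray,
    pruned_pool: set[str] | None = None,
) -> list[SnpSet]:
    """Sample random SNP sets from the (pruned) genic or non-genic pool.

    Sampling is without replacement within a set and independent across sets.
    Sets are truncated (with a warning) when the pool is smaller than the
    requested size.
    """
    snp_ids = np.asarray(snp_ids)
    in_pool = genic_flags.astype(bool) if spec.pool == "genic" else ~genic_flags.astype(bool)
    pool = snp_ids[in_pool]
    if pruned_pool is not None:
        pool = pool[np.isin(pool, sorted(pruned_pool))]
    if pool.size == 0:
        raise ValueError(f"empty {spec.pool} pool")
    size = min(spec.set_size, pool.size)
    if size < spec.set_size:
        logger.warning("%s pool has %d SNPs; truncating sets from %d", spec.pool, pool.size, spec.set_size)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed & 0x7FFFFFFF, 0x5E75]))
    return [
        SnpSet(
            name=f"{spec.pool}_{i:03d}",
            snps=tuple(rng.choice(pool, size=size, replace=False)),
            provenance=f"random_{spec.pool}",
        )
        for i in range(spec.n_sets)
    ]
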