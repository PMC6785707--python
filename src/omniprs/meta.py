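"""Stouffer's Z meta-analysis across held-out studies and related summaries.

Each held-out evaluation contributes a signed z-score reconstructed from its
two-sided p-value and the sign of the PRS coefficient; studies are weighted by
the square root of sample size (cases + controls, or an effective sample size
by option).  Also provides the nested-R² order statistics the reports quote,
p-value decile binning against the uniform null, and the equal-contribution
expected share of variance for a SNP set under a genome-wide score.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import norm

from .core import LooRecord, MetaResult

logger = logging.getLogger("omniprs")

_TINY_P = 1e-300  # p=0 is clamped here (smallest p keeping the normal quantile finite)


def _signed_z(p: float, direction: int) -> float:
    if p <= 0.0:
        logger.warning("p-value of 0 clamped to %.3g for Stouffer z", _TINY_P)
        p = _TINY_P
    return float(direction) * norm.isf(p / 2.0)


def stouffer(
    records: list[LooRecord],
    alpha: float = 0.05,
    weight: str = "total",
) -> MetaResult:
    """Sample-size-weighted Stouffer's Z over the held-out records.

    z_meta = Σ √n_i z_i / √Σ n_i with n_i = cases+controls ("total") or the
    effective size 4/(1/cases+1/controls) ("effective"); p_meta is two-sided.
    Flagged (degenerate-fit) records are excluded with a logged count.
    """
    if weight not in ("total", "effective"):
        raise ValueError(f"unknown weight scheme '{weight}'")
    usable = [r for r in records if not r.flagged]
    if not usable:
        raise ValueError("no usable records to meta-analyze")
    n_excluded = len(records) - len(usable)
    if n_excluded:
        logger.info("stouffer: excluding %d flagged records", n_excluded)
    if weight == "total":
        ns = np.array([r.n for r in usable], dtype=float)
    else:
        ns = np.array(
            [4.0 / (1.0 / max(r.n_cases, 1) + 1.0 / max(r.n_controls, 1)) for r in usable]
        )
    zs = np.array([_signed_z(r.p_value, r.direction) for r in usable])
    z_meta = float(np.sum(np.sqrt(ns) * zs) / np.sqrt(np.sum(ns)))
    p_meta = float(max(2.0 * norm.sf(abs(z_meta)), _TINY_P))
    r2s = np.array([r.nested_r2 for r in usable])
    q1, med, q3 = np.percentile(r2s, [25, 50, 75])
    return MetaResult(
        z_meta=z_meta,
        p_meta=p_meta,
        k_significant=int(np.sum(np.array([r.p_value for r in usable]) < alpha)),
        n_used=len(usable),
        n_excluded=n_excluded,
        r2_median=float(med),
        r2_iqr=float(q3 - q1),
        r2_range=(float(r2s.min()), float(r2s.max())),
    )


def summarize_r2(records: list[LooRecord]) -> tuple[float, float, tuple[float, float]]:
    """Median, IQR and range of nested R² across held-out studies.

    Quartiles use the linear-interpolation convention of ``numpy.percentile``.
    """
    if not records:
        raise ValueError("no records to summarize")
    r2s = np.array([r.nested_r2 for r in records])
    q1, med, q3 = np.percentile(r2s, [25, 50, 75])
    return float(med), float(q3 - q1), (float(r2s.min()), float(r2s.max()))


def decile_bins(stats: pd.DataFrame, snp_set=None) -> np.ndarray:
    """Proportion of SNP p-values in each decile bin [0,0.1), ..., [0.9,1].

    Under the uniform null every bin holds ~10%; signal shows up as an excess
    in the first bin.  Proportions sum to 1 exactly.
    """
    sel = stats
    if snp_set is not None:
        sel = stats[stats["snp_id"].isin(snp_set.snps)]
    p = sel["p"].to_numpy(dtype=float)
    if p.size == 0:
        raise ValueError("empty SNP set for decile binning")
    counts, _ = np.histogram(p, bins=np.linspace(0.0, 1.0, 11))
    return counts / p.size


def expected_share(r2_genomewide: float, n_snps_genomewide: int, n_snps_set: int) -> float:
    """Expected R² share of a SNP set if every SNP contributed equally.

    The equal-contribution "omnigenic floor": genome-wide R² scaled by the
    set's fraction of the genome-wide SNP count.
    """
    if n_snps_genomewide <= 0:
        raise ValueError("n_snps_genomewide must be positive")
    if n_snps_set < 0:
        raise ValueError("n_snps_set must be non-negative")
    return r2_genomewide * n_snps_set / n_snps_genomewide


def meta_table(results: dict[str, MetaResult]) -> pd.DataFrame:
    """One row per gene set: z, p, #significant held-out sets, R² summaries."""
    rows = []
    for name, mr in results.items():
        rows.append(
            {
                "set": name,
                "z_meta": mr.z_meta,
                "p_meta": mr.p_meta,
                "k_significant": mr.k_significant,
                "n_used": mr.n_used,
                "r2_median": mr.r2_median,
                "r2_iqr": mr.r2_iqr,
                "r2_min": mr.r2_range[0],
                "r2_max": mr.r2_range[1],
            }
        )
    return pd.DataFrame(rows)
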