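"""Pairwise linkage-disequilibrium (r²) computation and sliding-window pruning.

r² is the squared Pearson correlation of additive dosages over
pairwise-complete samples.  Pruning follows the standard indep-pairwise
procedure: slide a window of ``window_snps`` SNPs forward by ``step_snps``;
within each window, whenever a retained pair exceeds ``r2_max``, the
later-positioned SNP of the pair is removed.  The removal rule is
deterministic, so the kept list depends only on the data.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger("omniprs")


@dataclass(frozen=True)
class PruneParams:
    """Sliding-window pruning parameters (main analysis defaults)."""

    window_snps: int = 50
    step_snps: int = 5
    r2_max: float = 0.25

    def __post_init__(self):
        if self.step_snps < 1 or self.window_snps < 1:
            raise ValueError("window and step must be >= 1")
        if self.step_snps > self.window_snps:
            raise ValueError("step_snps must be <= window_snps")
        if not (0.0 < self.r2_max < 1.0):
            raise ValueError("r2_max must lie in (0, 1)")


def r2(dosages_a: np.ndarray, dosages_b: np.ndarray) -> float:
    """Squared Pearson correlation over pairwise-complete samples.

    Monomorphic input (zero variance over the complete pairs) is defined as
    r² = 0 with a warning: a monomorphic SNP cannot be in LD with anything.
    """
    a = np.asarray(dosages_a, dtype=float)
    b = np.asarray(dosages_b, dtype=float)
    ok = ~(np.isnan(a) | np.isnan(b))
    if ok.sum() < 2:
        raise ValueError("need at least 2 samples with both dosages non-missing")
    a, b = a[ok], b[ok]
    va, vb = a.var(), b.var()
    if va == 0.0 or vb == 0.0:
        warnings.warn("monomorphic SNP in r2 computation; returning 0", stacklevel=2)
        return 0.0
    c = np.mean((a - a.mean()) * (b - b.mean()))
    return float(c * c / (va * vb))


def _band_r2(X: np.ndarray, max_offset: int, block: int = 256) -> np.ndarray:
    """r² between columns i and i+d for d=1..max_offset, pairwise-complete.

    Returns R of shape (max_offset, m) with R[d-1, i] = r²(i, i+d) (nan-padded
    past the end).  Computed in column blocks via five matrix products so the
    cost is a handful of BLAS calls instead of per-pair loops.
    """
    n, m = X.shape
    mask = (~np.isnan(X)).astype(np.float64)
    X0 = np.nan_to_num(X, nan=0.0)
    X0sq = X0 * X0
    R = np.full((max_offset, m), np.nan)
    for a in range(0, m, block):
        b = min(a + block, m)
        hi = min(b + max_offset, m)
        Xs, Ms, Qs = X0[:, a:hi], mask[:, a:hi], X0sq[:, a:hi]
        S = Xs.T @ Xs  # sum x_i x_j over pairwise-complete (zeros elsewhere)
        N = Ms.T @ Ms  # pairwise-complete counts
        A = Xs.T @ Ms  # A[i, j] = sum of x_i over samples where j present
        Q = Qs.T @ Ms  # Q[i, j] = sum of x_i^2 over samples where j present
        w = hi - a
        for d in range(1, max_offset + 1):
            iend = min(b, m - d)
            if iend <= a:
                break
            i = np.arange(a, iend) - a
            j = i + d
            j = j[j < w]
            i = i[: j.size]
            nn = N[i, j]
            with np.errstate(invalid="ignore", divide="ignore"):
                cov = nn * S[i, j] - A[i, j] * A[j, i]
                vx = nn * Q[i, j] - A[i, j] ** 2
                vy = nn * Q[j, i] - A[j, i] ** 2
                rr = np.where((vx > 0) & (vy > 0) & (nn > 1), cov * cov / (vx * vy), 0.0)
            R[d - 1, a + i] = rr
    return R


def prune(
    dosage: np.ndarray,
    snp_ids: list[str] | np.ndarray,
    params: PruneParams = PruneParams(),
) -> list[str]:
    """Return the SNP IDs kept by sliding-window LD pruning, in genomic order.

    ``dosage`` is (n_samples, n_snps) with columns already ordered by
    (chrom, pos); ``nan`` marks missing calls.
    """
    snp_ids = list(np.asarray(snp_ids))
    n, m = dosage.shape
    if m != len(snp_ids):
        raise ValueError("snp_ids length does not match dosage columns")
    if m == 0:
        return []
    w = min(params.window_snps, m)
    band = _band_r2(dosage, max_offset=w - 1) if w > 1 else np.zeros((0, m))

    kept = np.ones(m, dtype=bool)
    starts = range(0, max(m - 1, 1), params.step_snps)
    for start in starts:
        end = min(start + w, m)
        if end - start < 2:
            continue
        idx = np.arange(start, end)
        for jj in idx[1:]:
            if not kept[jj]:
                continue
            earlier = idx[(idx < jj) & kept[idx]]
            if earlier.size == 0:
                continue
            r2s = band[jj - earlier - 1, earlier]
            if np.any(r2s > params.r2_max):
                kept[jj] = False
        if end == m:
            break
    kept_ids = [snp_ids[i] for i in range(m) if kept[i]]
    logger.debug("prune: kept %d / %d SNPs at r2<=%.3g", len(kept_ids), m, params.r2_max)
    return kept_ids
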