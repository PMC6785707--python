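"""Polygenic score computation and in-training p-value-threshold selection.

Scores are sums of risk-allele dosages weighted by training ln(odds ratios),
restricted to a SNP set and to SNPs whose training p-value falls below a
cutoff.  Nine cutoffs are tried on the training data only; the cutoff with the
largest covariate-adjusted likelihood-ratio statistic is the single score
carried to the held-out study, so no multiplicity accrues on test data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .assoc import fit_logistic, lrt, pooled_design
from .core import FitResult, GenotypeStudy, ScoreVector, SnpSet

logger = logging.getLogger("omniprs")


@dataclass(frozen=True)
class ThresholdGrid:
    """The nine training p-value cutoffs tried for each score."""

    p_cutoffs: tuple[float, ...] = (0.0001, 0.001, 0.01, 0.05, 0.10, 0.20, 0.30, 0.40, 0.50)

    def __post_init__(self):
        cuts = self.p_cutoffs
        if not cuts or any(not (0.0 < c <= 1.0) for c in cuts):
            raise ValueError("cutoffs must lie in (0, 1]")
        if any(a >= b for a, b in zip(cuts, cuts[1:])):
            raise ValueError("cutoffs must be strictly increasing")


def _scored_snps(stats: pd.DataFrame, snp_set: SnpSet | None, p_cutoff: float) -> pd.DataFrame:
    sel = stats[~stats["flag"].astype(bool)]
    if snp_set is not None:
        sel = sel[sel["snp_id"].isin(snp_set.snps)]
    return sel[sel["p"].to_numpy() < p_cutoff]


def score_matrix(
    dosage: np.ndarray,
    snps: pd.DataFrame,
    stats: pd.DataFrame,
    snp_set: SnpSet | None,
    p_cutoff: float,
) -> ScoreVector:
    """Score a dosage matrix (columns aligned to ``snps``) against oriented stats."""
    if np.any(stats["lnor"].to_numpy() < 0.0):
        raise ValueError("stats must be risk-oriented (all ln OR >= 0); apply orient_risk first")
    sel = _scored_snps(stats, snp_set, p_cutoff)
    n = dosage.shape[0]
    if sel.empty:
        logger.debug("empty scored set (cutoff %g); returning all-zero scores", p_cutoff)
        return ScoreVector(score=np.zeros(n), valid_count=np.zeros(n, dtype=int), n_snps_scored=0)
    col = pd.Series(np.arange(len(snps)), index=snps["snp_id"].to_numpy())
    idx = col[sel["snp_id"].to_numpy()].to_numpy()
    D = dosage[:, idx]
    panel_a1 = snps["a1"].to_numpy()[idx]
    flipped = sel["a1"].to_numpy() != panel_a1  # effect allele is the panel's A2
    risk = np.where(flipped[None, :], 2.0 - D, D)
    w = sel["lnor"].to_numpy()
    miss = np.isnan(risk)
    contrib = np.where(miss, 0.0, risk) * w[None, :]
    return ScoreVector(
        score=contrib.sum(axis=1),
        valid_count=(~miss).sum(axis=1).astype(int),
        n_snps_scored=int(len(sel)),
    )


def score(
    study: GenotypeStudy,
    stats: pd.DataFrame,
    snp_set: SnpSet | None,
    p_cutoff: float,
) -> ScoreVector:
    """Per-sample PRS for one study: Σ ln(OR) × risk-allele dosage.

    Missing genotypes contribute 0 to the sum and decrement the per-sample
    count of valid scored genotypes (carried downstream as a covariate).
    """
    return score_matrix(study.dosage, study.snps, stats, snp_set, p_cutoff)


def _nested_score_fit(
    y: np.ndarray, covars: pd.DataFrame, sv: ScoreVector
) -> tuple[float, float, FitResult, FitResult]:
    """LRT of covariates+valid_count+score vs covariates+valid_count."""
    base_X = covars.copy()
    base_X["valid_ct"] = sv.valid_count.astype(float)
    full_X = base_X.copy()
    full_X["score"] = sv.score
    base = fit_logistic(y, base_X)
    full = fit_logistic(y, full_X)
    if "score" in full.dropped or base.flagged or full.flagged:
        return 0.0, 1.0, full, base
    stat, p = lrt(full, base, df=1)
    return stat, p, full, base


def select_threshold(
    training_studies: list[GenotypeStudy],
    stats: pd.DataFrame,
    snp_set: SnpSet | None,
    grid: ThresholdGrid = ThresholdGrid(),
    kept_snps: set[str] | None = None,
    pooled: tuple[np.ndarray, pd.DataFrame, np.ndarray] | None = None,
) -> tuple[float, pd.DataFrame]:
    """Pick the cutoff whose training LRT statistic is largest.

    Each cutoff's score is refit on the pooled training samples against the
    covariates-only base model; ties go to the smallest cutoff.  Raises when
    every cutoff yields a degenerate (constant or non-converged) fit.
    ``pooled`` may carry a precomputed ``pooled_design(training_studies)``.
    """
    y, covars, dosage = pooled if pooled is not None else pooled_design(training_studies)
    use_stats = stats if kept_snps is None else stats[stats["snp_id"].isin(kept_snps)]
    rows = []
    any_ok = False
    for cutoff in grid.p_cutoffs:
        sv = score_matrix(dosage, training_studies[0].snps, use_stats, snp_set, cutoff)
        if sv.n_snps_scored == 0:
            rows.append({"cutoff": cutoff, "n_snps": 0, "lrt_stat": 0.0, "p": 1.0, "degenerate": True})
            continue
        stat, p, full, base = _nested_score_fit(y, covars, sv)
        degenerate = "score" in full.dropped or full.flagged or base.flagged
        any_ok = any_ok or not degenerate
        rows.append(
            {"cutoff": cutoff, "n_snps": sv.n_snps_scored, "lrt_stat": stat, "p": p, "degenerate": degenerate}
        )
    table = pd.DataFrame(rows)
    if not any_ok:
        name = snp_set.name if snp_set is not None else "<all SNPs>"
        raise RuntimeError(f"all cutoffs degenerate for SNP set '{name}'")
    stats_col = table["lrt_stat"].where(~table["degenerate"], -np.inf)
    best = float(table.loc[stats_col.idxmax(), "cutoff"])  # idxmax takes the first (smallest) on ties
    return best, table
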