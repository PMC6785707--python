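"""Logistic-model machinery: training GWAS, risk orientation, LRT, Nagelkerke R².

The per-SNP training GWAS is a pooled mega-regression: phenotype on additive
dosage plus covariates (PC surrogates and study indicators), one logistic fit
per SNP with Wald two-sided p-values.  Because the leave-one-out permutation
experiments refit the GWAS hundreds of times, the per-SNP fits run as a single
batched Newton–Raphson (IRLS) iteration vectorised across SNPs; the per-SNP
likelihood equations are identical to an ordinary logistic fit, and the test
suite cross-checks the batch path against statsmodels SNP by SNP.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from scipy.stats import chi2 as chi2_dist
from scipy.stats import norm

from .core import CASE, MISSING_PHENO, SUMSTAT_COLUMNS, FitResult, GenotypeStudy

logger = logging.getLogger("omniprs")

COEF_CAP = 30.0  # |coefficient| cap for separated / diverging fits


# ---------------------------------------------------------------------------
# single logistic fits (statsmodels-backed)
# ---------------------------------------------------------------------------

def _drop_rank_deficient(design: pd.DataFrame, tol: float = 1e-9) -> tuple[pd.DataFrame, tuple[str, ...]]:
    """Greedily drop columns that do not increase the design rank.

    Works on the full design (intercept included), so constant columns that
    merely duplicate the intercept are removed.  Rank tests run on the
    correlation-normalised Gram matrix, which is cheap at GWAS covariate
    widths.
    """
    arr = design.to_numpy(dtype=float)
    if arr.shape[1] <= 1:
        return design, ()
    G = arr.T @ arr
    scale = np.sqrt(np.diag(G))
    scale[scale == 0.0] = 1.0
    Gn = G / scale[:, None] / scale[None, :]
    keep: list[int] = [0]
    dropped: list[str] = []
    for i in range(1, arr.shape[1]):
        cand = keep + [i]
        eig = np.linalg.eigvalsh(Gn[np.ix_(cand, cand)])
        if eig[0] > tol:
            keep.append(i)
        else:
            dropped.append(design.columns[i])
    if dropped:
        logger.debug("dropping rank-deficient columns: %s", dropped)
    return design.iloc[:, keep], tuple(dropped)


def fit_logistic(y: np.ndarray, X: pd.DataFrame | None, add_intercept: bool = True) -> FitResult:
    """Maximum-likelihood logistic fit of binary y on X (plus intercept).

    Rank-deficient predictor columns are dropped with a record in
    ``FitResult.dropped``; perfect separation or non-convergence yields a
    flagged result with coefficients capped at ±COEF_CAP rather than a crash.
    Predictors are mean-centred before fitting for numerical stability: slope
    coefficients, log-likelihood and tests are unchanged, and the intercept
    refers to a sample at the predictor means.
    """
    y = np.asarray(y, dtype=float)
    if not np.all(np.isin(y, (0.0, 1.0))):
        raise ValueError("y must be binary 0/1")
    n = y.shape[0]
    if X is None or X.shape[1] == 0:
        # closed-form intercept-only fit
        phat = float(np.clip(y.mean(), 1e-12, 1 - 1e-12))
        llf = n * (phat * np.log(phat) + (1 - phat) * np.log(1 - phat))
        params = pd.Series({"const": float(np.log(phat / (1 - phat)))})
        return FitResult(params=params, llf=float(llf), n=n, converged=True)

    X = X.reset_index(drop=True)
    X = X - X.mean(axis=0)
    design = sm.add_constant(X, has_constant="add") if add_intercept else X
    design, dropped = _drop_rank_deficient(design)
    flagged = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, design).fit(disp=0, maxiter=200, warn_convergence=False)
            params = res.params
            llf = float(res.llf)
            converged = bool(res.mle_retvals.get("converged", True))
        except Exception as exc:  # separation or numerical failure
            logger.warning("logistic fit failed (%s); returning flagged capped fit", exc)
            params = pd.Series(0.0, index=design.columns)
            llf = float("nan")
            converged = False
    if not converged or np.any(np.abs(params) > COEF_CAP) or not np.isfinite(llf):
        flagged = True
        params = params.clip(-COEF_CAP, COEF_CAP)
    return FitResult(
        params=params, llf=llf, n=n, converged=converged, flagged=flagged, dropped=dropped
    )


def lrt(full: FitResult, base: FitResult, df: int) -> tuple[float, float]:
    """Likelihood-ratio test of nested logistic fits: 2Δll vs chi-square(df)."""
    if df <= 0:
        raise ValueError("df must be >= 1 for a nested comparison")
    delta = 2.0 * (full.llf - base.llf)
    if delta < -1e-6 * max(1.0, abs(base.llf)):
        raise RuntimeError(f"full model log-likelihood below base ({delta / 2:.4g}); fits not converged")
    stat = max(delta, 0.0)
    return float(stat), float(chi2_dist.sf(stat, df))


def nagelkerke(ll_model: float, ll_null: float, n: int) -> float:
    """Nagelkerke pseudo-R²: Cox–Snell rescaled to a [0, 1] maximum."""
    if n <= 0:
        raise ValueError("n must be positive")
    cox_snell = 1.0 - np.exp((2.0 / n) * (ll_null - ll_model))
    max_cs = 1.0 - np.exp((2.0 / n) * ll_null)
    if max_cs <= 0.0:
        return 0.0
    return float(cox_snell / max_cs)


# ---------------------------------------------------------------------------
# pooled training design
# ---------------------------------------------------------------------------

def pooled_design(studies: list[GenotypeStudy]) -> tuple[np.ndarray, pd.DataFrame, np.ndarray]:
    """Stack labeled samples of several studies into one regression design.

    Returns (y, covariate DataFrame with PC columns and study indicators
    [first study as reference], pooled dosage matrix).  Samples with a
    missing phenotype are excluded.
    """
    if not studies:
        raise ValueError("no studies supplied")
    ys, covs, doss = [], [], []
    for s in studies:
        keep = s.labeled_mask()
        ys.append((s.phenotype[keep] == CASE).astype(float))
        cov = s.covariates.loc[keep].reset_index(drop=True).copy()
        cov["study"] = s.study_id
        covs.append(cov)
        doss.append(s.dosage[keep])
    y = np.concatenate(ys)
    cov = pd.concat(covs, ignore_index=True)
    dummies = pd.get_dummies(cov.pop("study"), prefix="study", drop_first=True, dtype=float)
    cov = pd.concat([cov, dummies], axis=1)
    return y, cov, np.concatenate(doss)


# ---------------------------------------------------------------------------
# batched per-SNP GWAS
# ---------------------------------------------------------------------------

def _batched_logistic_gwas(
    y: np.ndarray,
    covars: np.ndarray,
    G: np.ndarray,
    max_iter: int = 25,
    tol: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-SNP logistic Newton–Raphson, vectorised across SNPs.

    For each SNP the model is y ~ intercept + covars + dosage with samples
    missing that SNP's dosage dropped (their IRLS weights zeroed, which yields
    the identical likelihood).  Each iteration only touches the SNPs that have
    not yet converged, and the Newton Hessian from a SNP's final step doubles
    as its observed information (the step is below ``tol``, so the difference
    is far inside the Wald approximation error).
    Returns (beta, se, n_used, converged, flagged).
    """
    n, m = G.shape
    base = np.column_stack([np.ones(n), covars])
    k1 = base.shape[1]
    d = k1 + 1
    mask = ~np.isnan(G)
    maskf = mask.astype(np.float64)
    Gm = np.nan_to_num(G, nan=0.0)
    n_used = mask.sum(axis=0)

    # polymorphism over the non-missing samples
    gsum = (Gm * maskf).sum(axis=0)
    gsq = (Gm * Gm * maskf).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        gvar = gsq / np.maximum(n_used, 1) - (gsum / np.maximum(n_used, 1)) ** 2
    poly = (gvar > 1e-12) & (n_used > k1 + 1)

    # warm start from the covariate-only fit on all samples (fit_logistic
    # centres predictors, so translate its intercept back to raw covariates)
    null_fit = fit_logistic(y, pd.DataFrame(covars, columns=[f"c{i}" for i in range(covars.shape[1])]))
    gamma0 = np.zeros(k1)
    for i in range(covars.shape[1]):
        gamma0[1 + i] = null_fit.params.get(f"c{i}", 0.0)
    gamma0[0] = null_fit.params.get("const", 0.0) - float(covars.mean(axis=0) @ gamma0[1:])

    theta = np.tile(np.append(gamma0, 0.0), (m, 1))  # (m, k1+1)
    iu, ju = np.triu_indices(k1)
    pair = (base[:, iu] * base[:, ju])  # packed symmetric products, (n, k1(k1+1)/2)
    converged = np.zeros(m, dtype=bool)
    Hlast = np.zeros((m, d, d))
    act = np.where(poly)[0]
    yv = y[:, None]
    diag = np.arange(d)

    for _ in range(max_iter):
        if act.size == 0:
            break
        Ga = Gm[:, act]
        Ma = maskf[:, act]
        eta = base @ theta[act, :k1].T + Ga * theta[act, k1][None, :]
        p = expit(eta)
        w = p * (1.0 - p) * Ma
        r = (yv - p) * Ma

        Bp = w.T @ pair  # (a, packed)
        WG = w * Ga
        cross = WG.T @ base
        gg = (WG * Ga).sum(axis=0)
        grad = np.concatenate([r.T @ base, (r * Ga).sum(axis=0)[:, None]], axis=1)

        H = np.empty((act.size, d, d))
        H[:, iu, ju] = Bp
        H[:, ju, iu] = Bp
        H[:, :k1, k1] = cross
        H[:, k1, :k1] = cross
        H[:, k1, k1] = gg
        # tiny ridge keeps near-singular (quasi-separated) systems solvable
        H[:, diag, diag] += 1e-10 * np.trace(H, axis1=1, axis2=2)[:, None]
        try:
            delta = np.linalg.solve(H, grad[..., None])[..., 0]
        except np.linalg.LinAlgError:
            delta = np.einsum("sij,sj->si", np.linalg.pinv(H), grad)
        theta[act] += delta
        np.clip(theta, -COEF_CAP, COEF_CAP, out=theta)
        Hlast[act] = H
        done = np.max(np.abs(delta), axis=1) < tol
        converged[act[done]] = True
        act = act[~done]

    se = np.full(m, np.nan)
    ok = np.where(poly)[0]
    try:
        Hinv = np.linalg.inv(Hlast[ok])
        se[ok] = np.sqrt(np.maximum(Hinv[:, k1, k1], 0.0))
    except np.linalg.LinAlgError:
        for i in ok:
            try:
                se[i] = np.sqrt(np.linalg.inv(Hlast[i])[k1, k1])
            except np.linalg.LinAlgError:
                se[i] = np.nan

    beta = theta[:, k1].copy()
    flagged = ~poly | ~converged | ~np.isfinite(se) | (se <= 0) | (np.abs(beta) >= COEF_CAP)
    beta[~poly] = 0.0
    return beta, se, n_used, converged, flagged


def gwas(studies: list[GenotypeStudy], max_iter: int = 25) -> pd.DataFrame:
    """Per-SNP training GWAS on the pooled studies.

    Returns a summary-statistics frame with columns ``SUMSTAT_COLUMNS``:
    effect allele A1, ln(odds ratio), Wald SE and two-sided p per SNP.
    Monomorphic SNPs get ln(OR)=0, p=1 and a flag.
    """
    y, cov, G = pooled_design(studies)
    beta, se, n_used, _, flagged = _batched_logistic_gwas(y, cov.to_numpy(dtype=float), G, max_iter=max_iter)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = beta / se
        p = 2.0 * norm.sf(np.abs(z))
    p = np.where(flagged | ~np.isfinite(p), 1.0, p)
    lnor = np.where(flagged, 0.0, beta)
    snps = studies[0].snps
    stats = pd.DataFrame(
        {
            "snp_id": snps["snp_id"].to_numpy(),
            "a1": snps["a1"].to_numpy(),
            "a2": snps["a2"].to_numpy(),
            "lnor": lnor,
            "se": se,
            "p": p,
            "n": n_used.astype(int),
            "flag": flagged,
        },
        columns=SUMSTAT_COLUMNS,
    )
    n_flag = int(flagged.sum())
    if n_flag:
        logger.info("gwas: %d/%d SNPs flagged (monomorphic or non-converged)", n_flag, len(stats))
    return stats


def orient_risk(stats: pd.DataFrame) -> pd.DataFrame:
    """Re-code every SNP so the effect allele is the risk allele (ln OR ≥ 0).

    SNPs with negative ln(OR) have their alleles swapped and the sign flipped;
    exact zeros keep A1.  Idempotent.
    """
    out = stats.copy()
    neg = out["lnor"].to_numpy() < 0.0
    a1 = out["a1"].to_numpy().copy()
    a2 = out["a2"].to_numpy().copy()
    out.loc[neg, "a1"] = a2[neg]
    out.loc[neg, "a2"] = a1[neg]
    out.loc[neg, "lnor"] = -out.loc[neg, "lnor"]
    return out
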