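"""Readers/writers for the text formats the pipeline touches, and genotype QC.

PLINK text dialects: ``.bim`` (chrom, id, cM=0, bp, A1, A2), ``.fam``
(FID, IID, 0, 0, sex=0, phenotype 1=control/2=case/0=missing) and a ``.traw``
additive dosage table (one row per SNP, counted allele = A1, missing = NA).
Gene annotation travels as 6-column BED (0-based half-open; internal
coordinates are 1-based inclusive), gene sets as GMT, summary statistics as a
``SNP A1 A2 LNOR SE P N`` TSV and SNP sets as one-ID-per-line text.

QC applies the standard consortium filters in their conventional order:
pre-sample SNP missingness, then sample missingness and |Fhet|, then post-
sample SNP missingness, case/control differential missingness, and
Hardy–Weinberg by affection status.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist

from .core import CASE, CONTROL, MISSING_PHENO, SUMSTAT_COLUMNS, GeneSet, GenotypeStudy, SnpSet

logger = logging.getLogger("omniprs")


class FormatError(ValueError):
    """Malformed input file."""


class DimensionMismatchError(FormatError):
    """Files disagree on sample or SNP dimensions."""


class PhenotypeCodeError(FormatError):
    """Unknown phenotype code in a .fam file."""


class DuplicateSnpError(FormatError):
    """Duplicate SNP identifier."""


class AlignmentError(FormatError):
    """SNP identifiers inconsistent across files."""


class EmptyPanelError(RuntimeError):
    """QC removed every SNP."""


# ---------------------------------------------------------------------------
# PLINK text study
# ---------------------------------------------------------------------------

def write_study(study: GenotypeStudy, prefix: str | Path) -> None:
    """Write .bim/.fam/.traw (plus a covariate TSV) under the given prefix."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    snps = study.snps
    bim = pd.DataFrame(
        {
            "chrom": snps["chrom"],
            "snp_id": snps["snp_id"],
            "cm": 0,
            "pos": snps["pos"],
            "a1": snps["a1"],
            "a2": snps["a2"],
        }
    )
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)

    pheno_code = np.where(
        study.phenotype == CASE, 2, np.where(study.phenotype == CONTROL, 1, 0)
    )
    fam = pd.DataFrame(
        {
            "fid": study.study_id,
            "iid": study.sample_ids,
            "pat": 0,
            "mat": 0,
            "sex": 0,
            "pheno": pheno_code,
        }
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)

    cols = [f"{study.study_id}_{iid}" for iid in study.sample_ids]
    traw = pd.DataFrame(
        {
            "CHR": snps["chrom"],
            "SNP": snps["snp_id"],
            "(C)M": 0,
            "POS": snps["pos"],
            "COUNTED": snps["a1"],
            "ALT": snps["a2"],
        }
    )
    body = pd.DataFrame(study.dosage.T, columns=cols)
    pd.concat([traw, body], axis=1).to_csv(
        prefix.with_suffix(".traw"), sep="\t", index=False, na_rep="NA", float_format="%g"
    )
    study.covariates.assign(IID=study.sample_ids)[
        ["IID"] + list(study.covariates.columns)
    ].to_csv(prefix.with_suffix(".cov"), sep="\t", index=False)


def read_study(
    bim_path: str | Path,
    fam_path: str | Path,
    traw_path: str | Path,
    cov_path: str | Path | None = None,
) -> GenotypeStudy:
    """Read a study back from PLINK text files.

    The dosage matrix is aligned to .fam sample order and .bim SNP order;
    phenotype codes 1/2/0 decode to control/case/missing.  Inconsistent
    dimensions, duplicate SNP IDs and SNPs missing from the .traw raise
    distinct named errors.
    """
    bim = pd.read_csv(
        bim_path, sep=r"\s+", header=None, names=["chrom", "snp_id", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str},
    )
    if bim["snp_id"].duplicated().any():
        dup = bim.loc[bim["snp_id"].duplicated(), "snp_id"].iloc[0]
        raise DuplicateSnpError(f"duplicate SNP ID in .bim: {dup}")
    fam = pd.read_csv(
        fam_path, sep=r"\s+", header=None, names=["fid", "iid", "pat", "mat", "sex", "pheno"],
        dtype={"fid": str, "iid": str},
    )
    bad = ~fam["pheno"].isin((0, 1, 2))
    if bad.any():
        raise PhenotypeCodeError(f"unknown phenotype code {fam.loc[bad, 'pheno'].iloc[0]!r} in .fam")

    traw = pd.read_csv(traw_path, sep="\t")
    meta_cols = ["CHR", "SNP", "(C)M", "POS", "COUNTED", "ALT"]
    if list(traw.columns[:6]) != meta_cols:
        raise FormatError(f".traw header must start with {meta_cols}")
    missing_snps = set(bim["snp_id"]) - set(traw["SNP"])
    if missing_snps:
        raise AlignmentError(f".bim SNP absent from .traw: {sorted(missing_snps)[0]}")
    if len(traw) != len(bim):
        raise DimensionMismatchError(f".traw has {len(traw)} SNPs but .bim has {len(bim)}")
    sample_cols = list(traw.columns[6:])
    expect = [f"{f}_{i}" for f, i in zip(fam["fid"], fam["iid"])]
    if set(sample_cols) != set(expect):
        raise DimensionMismatchError(".traw sample columns do not match the .fam")

    traw = traw.set_index("SNP").loc[bim["snp_id"]]
    dosage = traw[expect].to_numpy(dtype=float).T

    phenotype = np.where(
        fam["pheno"] == 2, CASE, np.where(fam["pheno"] == 1, CONTROL, MISSING_PHENO)
    )
    if cov_path is not None and Path(cov_path).exists():
        cov = pd.read_csv(cov_path, sep="\t").set_index("IID").loc[fam["iid"]].reset_index(drop=True)
    else:
        cov = pd.DataFrame(index=range(len(fam)))
    snps = bim[["snp_id", "chrom", "pos", "a1", "a2"]].reset_index(drop=True)
    study = GenotypeStudy(
        study_id=str(fam["fid"].iloc[0]),
        sample_ids=list(fam["iid"]),
        dosage=dosage,
        phenotype=phenotype,
        covariates=cov,
        snps=snps,
    )
    study.validate()
    return study


# ---------------------------------------------------------------------------
# GMT / BED / SNP sets / summary stats
# ---------------------------------------------------------------------------

def write_gmt(gene_sets: list[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in gene_sets:
            fh.write("\t".join([gs.name, gs.description or gs.provenance or "."] + list(gs.genes)) + "\n")


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read gene sets from GMT (name, description, genes...); dedups members."""
    sets: list[GeneSet] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{ln}: GMT line needs name, description and >=1 gene")
            name, desc, genes = fields[0], fields[1], fields[2:]
            uniq = list(dict.fromkeys(g for g in genes if g))
            if len(uniq) < len([g for g in genes if g]):
                logger.warning("GMT set '%s' contained duplicate genes; deduplicated", name)
            sets.append(GeneSet(name=name, genes=tuple(uniq), description=desc))
    return sets


def write_bed(genes: pd.DataFrame, path: str | Path) -> None:
    """Write gene intervals as BED6 (1-based inclusive -> 0-based half-open)."""
    out = pd.DataFrame(
        {
            "chrom": genes["chrom"],
            "start": genes["start"] - 1,
            "end": genes["end"],
            "name": genes["gene_id"],
            "score": 0,
            "strand": genes["strand"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read BED into 1-based inclusive gene intervals (missing strand -> '+')."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise FormatError(f"{path}:{ln}: BED line needs chrom, start, end")
            start0, end0 = int(f[1]), int(f[2])
            if end0 <= start0:
                raise FormatError(f"{path}:{ln}: BED end <= start")
            rows.append(
                {
                    "gene_id": f[3] if len(f) > 3 else f"interval{ln}",
                    "chrom": f[0],
                    "start": start0 + 1,
                    "end": end0,
                    "strand": f[5] if len(f) > 5 and f[5] in ("+", "-") else "+",
                }
            )
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])


def write_snp_set(snp_set: SnpSet, path: str | Path) -> None:
    Path(path).write_text("\n".join(snp_set.snps) + ("\n" if snp_set.snps else ""))


def read_snp_set(path: str | Path, name: str | None = None) -> SnpSet:
    ids = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    return SnpSet(name=name or Path(path).stem, snps=tuple(ids))


def write_sumstats(stats: pd.DataFrame, path: str | Path) -> None:
    out = stats.rename(
        columns={"snp_id": "SNP", "a1": "A1", "a2": "A2", "lnor": "LNOR", "se": "SE", "p": "P", "n": "N"}
    )[["SNP", "A1", "A2", "LNOR", "SE", "P", "N"]]
    out.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_sumstats(path: str | Path) -> pd.DataFrame:
    raw = pd.read_csv(path, sep="\t")
    stats = raw.rename(
        columns={"SNP": "snp_id", "A1": "a1", "A2": "a2", "LNOR": "lnor", "SE": "se", "P": "p", "N": "n"}
    )
    stats["flag"] = False
    return stats[SUMSTAT_COLUMNS]


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def snp_info(study: GenotypeStudy) -> pd.DataFrame:
    """Per-SNP QC quantities: folded minor-allele frequency and missingness.

    MAF is folded to [0, 0.5] regardless of which allele is counted;
    missingness is the fraction of samples without a call.
    """
    with np.errstate(invalid="ignore"):
        freq = np.nanmean(study.dosage, axis=0) / 2.0
    freq = np.nan_to_num(freq, nan=0.0)
    return study.snps.assign(
        maf=np.minimum(freq, 1.0 - freq),
        missingness=np.isnan(study.dosage).mean(axis=0),
    )


@dataclass(frozen=True)
class QcThresholds:
    """Retain-if-below thresholds for the standard consortium QC filters."""

    snp_miss_pre: float = 0.05
    subj_miss: float = 0.02
    fhet_abs: float = 0.2
    snp_miss_post: float = 0.02
    diff_miss_case_control: float = 0.02
    hwe_p_controls: float = 1e-6
    hwe_p_cases: float = 1e-10


def hwe_chisq_p(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Hardy–Weinberg 1-df Pearson chi-square p from genotype counts."""
    n = n_aa + n_ab + n_bb
    if n == 0:
        return 1.0
    p = (2 * n_bb + n_ab) / (2.0 * n)
    exp = np.array([n * (1 - p) ** 2, n * 2 * p * (1 - p), n * p * p])
    obs = np.array([n_aa, n_ab, n_bb], dtype=float)
    nz = exp > 0
    if nz.sum() <= 1:
        return 1.0
    stat = float(np.sum((obs[nz] - exp[nz]) ** 2 / exp[nz]))
    return float(chi2_dist.sf(stat, 1))


def _snp_missingness(dosage: np.ndarray) -> np.ndarray:
    return np.isnan(dosage).mean(axis=0) if dosage.shape[0] else np.zeros(dosage.shape[1])


def _hwe_p_vector(dosage: np.ndarray) -> np.ndarray:
    """Vectorised HWE chi-square p per SNP column."""
    n0 = np.nansum(dosage == 0, axis=0).astype(float)
    n1 = np.nansum(dosage == 1, axis=0).astype(float)
    n2 = np.nansum(dosage == 2, axis=0).astype(float)
    n = n0 + n1 + n2
    with np.errstate(invalid="ignore", divide="ignore"):
        p = (2 * n2 + n1) / (2 * n)
        e0, e1, e2 = n * (1 - p) ** 2, 2 * n * p * (1 - p), n * p * p
        stat = np.zeros_like(n)
        for obs, exp in ((n0, e0), (n1, e1), (n2, e2)):
            term = np.where(exp > 0, (obs - exp) ** 2 / np.where(exp > 0, exp, 1.0), 0.0)
            stat += term
        mono = (p <= 0) | (p >= 1) | (n == 0)
    out = chi2_dist.sf(stat, 1)
    out[mono | ~np.isfinite(stat)] = 1.0
    return out


def qc_filter(
    study: GenotypeStudy, thresholds: QcThresholds = QcThresholds()
) -> tuple[GenotypeStudy, pd.DataFrame]:
    """Apply the QC filters in order; return the filtered study and a report.

    Order: SNP missingness (pre-sample), sample missingness and |Fhet|,
    SNP missingness (post-sample), case/control differential missingness,
    HWE by affection status.  Raises EmptyPanelError when nothing survives.
    """
    thr = thresholds
    dosage = study.dosage
    snp_keep = np.ones(study.n_snps, dtype=bool)
    sample_keep = np.ones(study.n_samples, dtype=bool)
    counts: list[dict] = []

    miss = _snp_missingness(dosage)
    fail = miss >= thr.snp_miss_pre
    snp_keep &= ~fail
    counts.append({"filter": "snp_missingness_pre", "removed": int(fail.sum())})

    sub = dosage[:, snp_keep]
    subj_miss = np.isnan(sub).mean(axis=1) if sub.shape[1] else np.zeros(study.n_samples)
    # per-sample inbreeding-style het deviation over retained SNPs
    present = ~np.isnan(sub)
    obs_het = np.where(present.sum(axis=1) > 0, np.nansum(sub == 1, axis=1), 0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.nanmean(sub, axis=0) / 2.0
    exp_het_per_snp = 2.0 * freq * (1.0 - freq)
    exp_het = present @ np.nan_to_num(exp_het_per_snp)
    with np.errstate(invalid="ignore", divide="ignore"):
        fhet = np.where(exp_het > 0, 1.0 - obs_het / exp_het, 0.0)
    fail_s = (subj_miss >= thr.subj_miss) | (np.abs(fhet) >= thr.fhet_abs)
    sample_keep &= ~fail_s
    counts.append({"filter": "sample_missingness_or_fhet", "removed": int(fail_s.sum())})

    dos2 = dosage[sample_keep]
    miss2 = _snp_missingness(dos2)
    fail = snp_keep & (miss2 >= thr.snp_miss_post)
    snp_keep &= ~fail
    counts.append({"filter": "snp_missingness_post", "removed": int(fail.sum())})

    pheno = study.phenotype[sample_keep]
    is_case, is_ctrl = pheno == CASE, pheno == CONTROL
    if is_case.any() and is_ctrl.any():
        dmiss = np.abs(_snp_missingness(dos2[is_case]) - _snp_missingness(dos2[is_ctrl]))
        fail = snp_keep & (dmiss >= thr.diff_miss_case_control)
    else:
        fail = np.zeros_like(snp_keep)
    snp_keep &= ~fail
    counts.append({"filter": "differential_missingness", "removed": int(fail.sum())})

    hwe_ctrl = _hwe_p_vector(dos2[is_ctrl]) if is_ctrl.any() else np.ones(study.n_snps)
    hwe_case = _hwe_p_vector(dos2[is_case]) if is_case.any() else np.ones(study.n_snps)
    fail = snp_keep & ((hwe_ctrl <= thr.hwe_p_controls) | (hwe_case <= thr.hwe_p_cases))
    snp_keep &= ~fail
    counts.append({"filter": "hwe", "removed": int(fail.sum())})

    if not snp_keep.any():
        raise EmptyPanelError("QC removed every SNP (empty panel)")

    filtered = GenotypeStudy(
        study_id=study.study_id,
        sample_ids=[s for s, k in zip(study.sample_ids, sample_keep) if k],
        dosage=dosage[np.ix_(sample_keep, snp_keep)],
        phenotype=study.phenotype[sample_keep],
        covariates=study.covariates.loc[sample_keep].reset_index(drop=True),
        snps=study.snps.loc[snp_keep].reset_index(drop=True),
    )
    report = pd.DataFrame(counts)
    report["retained_snps"] = filtered.n_snps
    report["retained_samples"] = filtered.n_samples
    for row in counts:
        logger.info("qc %-28s removed %d", row["filter"], row["removed"])
    return filtered, report
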