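"""Shared domain containers for the leave-one-out gene-set PRS pipeline.

A *study* is one case-control cohort genotyped on a common SNP panel; the
pipeline pools all-but-one study for training and evaluates a single polygenic
score on the held-out study.  Dosages are additive counts of the A1 allele
(0/1/2) stored as floats with ``nan`` marking missing genotypes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger("omniprs")

#: column convention for per-SNP training-GWAS summary statistics
SUMSTAT_COLUMNS = ["snp_id", "a1", "a2", "lnor", "se", "p", "n", "flag"]

#: phenotype encoding used internally (PLINK .fam uses 1=control, 2=case, 0=missing)
CONTROL, CASE, MISSING_PHENO = 0, 1, -1


@dataclass
class GenotypeStudy:
    """One cohort: samples, additive dosage matrix, phenotype and covariates.

    dosage has shape (n_samples, n_snps), counts of the A1 allele with ``nan``
    for missing calls; phenotype is 1=case, 0=control, -1=missing; covariates
    is a (n_samples, k) DataFrame of quantitative columns (PC surrogates).
    snps is the shared panel table with columns snp_id, chrom, pos, a1, a2.
    """

    study_id: str
    sample_ids: list[str]
    dosage: np.ndarray
    phenotype: np.ndarray
    covariates: pd.DataFrame
    snps: pd.DataFrame

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosage.shape[1]

    @property
    def n_cases(self) -> int:
        return int(np.sum(self.phenotype == CASE))

    @property
    def n_controls(self) -> int:
        return int(np.sum(self.phenotype == CONTROL))

    def labeled_mask(self) -> np.ndarray:
        """Samples with a non-missing case/control phenotype."""
        return self.phenotype != MISSING_PHENO

    def copy(self) -> "GenotypeStudy":
        return GenotypeStudy(
            study_id=self.study_id,
            sample_ids=list(self.sample_ids),
            dosage=self.dosage.copy(),
            phenotype=self.phenotype.copy(),
            covariates=self.covariates.copy(),
            snps=self.snps,
        )

    def with_phenotype(self, phenotype: np.ndarray) -> "GenotypeStudy":
        out = replace(self, phenotype=np.asarray(phenotype))
        if out.phenotype.shape[0] != self.n_samples:
            raise ValueError("phenotype length does not match sample count")
        return out

    def validate(self) -> None:
        n, m = self.dosage.shape
        if len(self.sample_ids) != n:
            raise ValueError(f"{self.study_id}: {len(self.sample_ids)} sample ids for {n} dosage rows")
        if self.phenotype.shape[0] != n:
            raise ValueError(f"{self.study_id}: phenotype length mismatch")
        if len(self.covariates) != n:
            raise ValueError(f"{self.study_id}: covariate rows mismatch")
        if len(self.snps) != m:
            raise ValueError(f"{self.study_id}: {len(self.snps)} SNP records for {m} dosage columns")


@dataclass(frozen=True)
class GeneSet:
    """A named collection of gene identifiers."""

    name: str
    genes: tuple[str, ...]
    description: str = ""
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class SnpSet:
    """A named collection of SNP identifiers (target set, random genic, ...)."""

    name: str
    snps: tuple[str, ...]
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.snps)


@dataclass
class FitResult:
    """A converged (or flagged) maximum-likelihood logistic fit."""

    params: pd.Series
    llf: float
    n: int
    converged: bool
    flagged: bool = False
    dropped: tuple[str, ...] = ()

    def coef(self, name: str) -> float:
        return float(self.params[name])


@dataclass
class ScoreVector:
    """Per-sample polygenic score and count of non-missing scored genotypes."""

    score: np.ndarray
    valid_count: np.ndarray
    n_snps_scored: int


@dataclass
class LooRecord:
    """One held-out evaluation: the single score tested on the left-out study."""

    held_out_study: str
    selected_cutoff: float
    lrt_stat: float
    p_value: float
    nested_r2: float
    r2_full: float
    r2_base: float
    direction: int
    n_cases: int
    n_controls: int
    flagged: bool = False
    note: str = ""

    @property
    def n(self) -> int:
        return self.n_cases + self.n_controls


@dataclass
class MetaResult:
    """Stouffer's Z combination of held-out results plus nested-R² summaries."""

    z_meta: float
    p_meta: float
    k_significant: int
    n_used: int
    n_excluded: int
    r2_median: float
    r2_iqr: float
    r2_range: tuple[float, float]


def stage_rng(seed: int, *tokens) -> np.random.Generator:
    """Derive a stage-specific generator from the root seed.

    Every source of randomness in the package obtains its generator through
    this function with a stable token path (e.g. ``("study", 3)``), so a single
    root seed reproduces the entire experiment and stages stay independent.
    """
    import zlib

    entropy = [int(seed) & 0x7FFFFFFF]
    for t in tokens:
        entropy.append(zlib.crc32(str(t).encode("utf8")))
    return np.random.default_rng(np.random.SeedSequence(entropy))
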