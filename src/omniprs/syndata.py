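"""Synthetic multi-study case-control genotype generator.

Emulates the structure of a multi-cohort GWAS consortium at desk scale:
several case-control studies of unequal size on a shared autosomal SNP panel,
a liability-threshold disease model with an omnigenic effect-size background
(every SNP carries a nonzero effect unless h² = 0), optional variance
enrichment in a designated core gene set, Balding–Nichols allele-frequency
drift between studies, uniform genotype missingness, and study-correlated
Gaussian covariate columns standing in for ancestry principal components.

All randomness flows from ``SimConfig.seed`` through :func:`core.stage_rng`
with fixed stage tokens, so one seed reproduces the whole cohort bit-for-bit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .core import CASE, CONTROL, GeneSet, GenotypeStudy, stage_rng
from .genesets import GenicMargins, classify_genic, snps_for_gene_set

logger = logging.getLogger("omniprs")


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


@dataclass
class SimConfig:
    """Study conditions for one synthetic cohort.

    Defaults are the desk-scale conditions used throughout: six studies of
    200-500 samples with unequal case/control counts, 2000 SNPs across 300
    genes on a 20 Mb chromosome, liability-scale h² = 0.3 and prevalence 0.10,
    mild between-study drift (Wright's F = 0.02) and sparse missingness.
    """

    n_studies: int = 6
    cases_per_study: tuple[int, ...] = (150, 250, 100, 200, 120, 180)
    controls_per_study: tuple[int, ...] = (150, 250, 150, 200, 130, 170)
    n_snps: int = 2000
    n_genes: int = 300
    chrom_length: int = 20_000_000
    gene_length_range: tuple[int, int] = (2_000, 10_000)
    maf_range: tuple[float, float] = (0.05, 0.5)
    h2_liability: float = 0.3
    prevalence: float = 0.10
    core_set_name: str = "core"
    core_set_genes: int = 50
    n_control_sets: int = 2
    control_set_genes: int = 50
    set_overlap_fraction: float = 0.0
    core_enrichment: float = 1.0
    prop_causal_genic: float | None = None
    study_drift_f: float = 0.02
    missing_rate: float = 0.01
    n_covariates: int = 2
    seed: int = 0

    def validate(self) -> None:
        if self.n_studies < 1:
            raise ConfigurationError("n_studies must be >= 1")
        if len(self.cases_per_study) != self.n_studies or len(self.controls_per_study) != self.n_studies:
            raise ConfigurationError("cases_per_study and controls_per_study must have length n_studies")
        if self.n_genes < 1:
            raise ConfigurationError("at least 1 gene required")
        if self.n_snps < 1:
            raise ConfigurationError("at least 1 SNP required")
        if not (0.0 <= self.h2_liability < 1.0):
            raise ConfigurationError("h2_liability must lie in [0, 1)")
        if not (0.0 < self.prevalence < 1.0):
            raise ConfigurationError("prevalence must lie in (0, 1)")
        if self.core_enrichment < 1.0:
            raise ConfigurationError("core_enrichment must be >= 1")
        if not (0.0 <= self.study_drift_f <= 0.2):
            raise ConfigurationError("study_drift_f must lie in [0, 0.2]")
        if self.prop_causal_genic is not None and not (0.0 <= self.prop_causal_genic <= 1.0):
            raise ConfigurationError("prop_causal_genic must lie in [0, 1]")


@dataclass
class Annotation:
    """Gene intervals (1-based inclusive, stranded) and SNP panel positions."""

    genes: pd.DataFrame  # gene_id, chrom, start, end, strand
    snps: pd.DataFrame  # snp_id, chrom, pos, a1, a2
    n_genic: int = 0
    n_nongenic: int = 0


@dataclass
class TrueArchitecture:
    """Simulated truth: per-SNP liability effects and the disease threshold."""

    beta: np.ndarray
    core_member: np.ndarray
    genic: np.ndarray
    ancestral_maf: np.ndarray
    liability_threshold: float
    h2_liability: float


def simulate_annotation(cfg: SimConfig) -> Annotation:
    """Place non-overlapping stranded genes and uniform SNP positions.

    Gene lengths are uniform over ``cfg.gene_length_range``; the free sequence
    between genes is split by a Dirichlet draw so gene spacing varies.  Errors
    out when the requested genes cannot be packed on the chromosome.
    """
    cfg.validate()
    rng = stage_rng(cfg.seed, "annotation")
    lo, hi = cfg.gene_length_range
    lengths = rng.integers(lo, hi + 1, size=cfg.n_genes)
    total = int(lengths.sum())
    free = cfg.chrom_length - total
    if free < 0:
        raise ConfigurationError(
            f"cannot place {cfg.n_genes} genes totalling {total} bp on a {cfg.chrom_length} bp chromosome"
        )
    gaps = np.floor(rng.dirichlet(np.ones(cfg.n_genes + 1)) * free).astype(int)
    starts = np.cumsum(gaps[:-1]) + np.cumsum(np.concatenate([[0], lengths[:-1]])) + 1
    ends = starts + lengths - 1
    strands = rng.choice(["+", "-"], size=cfg.n_genes)
    genes = pd.DataFrame(
        {
            "gene_id": [f"gene{i:04d}" for i in range(cfg.n_genes)],
            "chrom": "1",
            "start": starts.astype(int),
            "end": ends.astype(int),
            "strand": strands,
        }
    )

    pos = np.sort(rng.choice(cfg.chrom_length, size=cfg.n_snps, replace=False)) + 1
    alleles = rng.choice(["A", "C", "G", "T"], size=(cfg.n_snps, 2))
    same = alleles[:, 0] == alleles[:, 1]
    alleles[same, 1] = np.where(alleles[same, 0] == "A", "G", "A")
    snps = pd.DataFrame(
        {
            "snp_id": [f"snp{i:05d}" for i in range(cfg.n_snps)],
            "chrom": "1",
            "pos": pos.astype(int),
            "a1": alleles[:, 0],
            "a2": alleles[:, 1],
        }
    )
    genic, _ = classify_genic(snps, genes, GenicMargins())
    ann = Annotation(genes=genes, snps=snps, n_genic=int(genic.sum()), n_nongenic=int((~genic).sum()))
    logger.info(
        "annotation: %d genes, %d SNPs (%d genic / %d non-genic)",
        cfg.n_genes, cfg.n_snps, ann.n_genic, ann.n_nongenic,
    )
    return ann


def make_gene_sets(annotation: Annotation, cfg: SimConfig) -> list[GeneSet]:
    """Draw the designated core set plus non-enriched control sets.

    Sets are sampled without replacement from the annotated genes; pairwise
    overlap is limited to ``cfg.set_overlap_fraction`` of each set (0 by
    default, i.e. disjoint sets).
    """
    cfg.validate()
    sizes = [cfg.core_set_genes] + [cfg.control_set_genes] * cfg.n_control_sets
    if max(sizes) > cfg.n_genes:
        raise ConfigurationError(f"requested set size {max(sizes)} exceeds n_genes={cfg.n_genes}")
    rng = stage_rng(cfg.seed, "gene_sets")
    all_genes = annotation.genes["gene_id"].to_numpy()
    names = [cfg.core_set_name] + [f"control_{i + 1}" for i in range(cfg.n_control_sets)]
    sets: list[GeneSet] = []
    used: set[str] = set()
    for name, size in zip(names, sizes):
        n_shared = int(round(cfg.set_overlap_fraction * size)) if used else 0
        shared = rng.choice(sorted(used), size=n_shared, replace=False) if n_shared else np.array([], dtype=object)
        fresh_pool = np.array([g for g in all_genes if g not in used])
        n_fresh = size - len(shared)
        if n_fresh > len(fresh_pool):
            raise ConfigurationError(f"not enough unused genes for set '{name}'")
        fresh = rng.choice(fresh_pool, size=n_fresh, replace=False)
        members = tuple(sorted(np.concatenate([shared, fresh]).tolist()))
        provenance = "core" if name == cfg.core_set_name else "control"
        sets.append(GeneSet(name=name, genes=members, provenance=provenance))
        used.update(members)
    return sets


def simulate_effects(
    cfg: SimConfig,
    annotation: Annotation,
    gene_sets: list[GeneSet] | None = None,
) -> TrueArchitecture:
    """Draw the omnigenic liability architecture.

    Betas are zero-mean Gaussian at every SNP; SNPs mapped to the core set get
    ``core_enrichment`` times the background variance.  When
    ``prop_causal_genic`` is set, genic SNPs carry exactly that fraction of h²
    (1.0 places all effects at genic SNPs).  After drawing, betas are rescaled
    so the liability-scale genetic variance Σ 2p(1−p)β² equals ``h2_liability``
    exactly.
    """
    cfg.validate()
    rng = stage_rng(cfg.seed, "effects")
    m = cfg.n_snps
    maf = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=m)

    genic, assignments = classify_genic(annotation.snps, annotation.genes, GenicMargins())
    core_member = np.zeros(m, dtype=bool)
    if cfg.core_enrichment > 1.0:
        if gene_sets is None:
            raise ConfigurationError("core_enrichment > 1 requires gene sets (none supplied)")
        by_name = {gs.name: gs for gs in gene_sets}
        if cfg.core_set_name not in by_name:
            raise ConfigurationError(f"no gene set named '{cfg.core_set_name}'")
        core_snps = set(snps_for_gene_set(by_name[cfg.core_set_name], assignments).snps)
        core_member = annotation.snps["snp_id"].isin(core_snps).to_numpy()
    elif gene_sets is not None:
        by_name = {gs.name: gs for gs in gene_sets}
        if cfg.core_set_name in by_name:
            core_snps = set(snps_for_gene_set(by_name[cfg.core_set_name], assignments).snps)
            core_member = annotation.snps["snp_id"].isin(core_snps).to_numpy()

    rel_var = np.ones(m)
    rel_var[core_member] *= cfg.core_enrichment
    beta = rng.normal(0.0, 1.0, size=m) * np.sqrt(rel_var)

    het = 2.0 * maf * (1.0 - maf)
    if cfg.h2_liability == 0.0:
        beta = np.zeros(m)
    elif cfg.prop_causal_genic is None:
        beta *= np.sqrt(cfg.h2_liability / np.sum(het * beta**2))
    else:
        # allocate h2 between the genic and non-genic partitions, then rescale
        # each partition so the split is exact
        for mask, share in ((genic, cfg.prop_causal_genic), (~genic, 1.0 - cfg.prop_causal_genic)):
            v = np.sum(het[mask] * beta[mask] ** 2)
            if share == 0.0 or mask.sum() == 0:
                beta[mask] = 0.0
            else:
                if v == 0.0:
                    raise ConfigurationError("cannot allocate h2 to an effect-free partition")
                beta[mask] *= np.sqrt(share * cfg.h2_liability / v)

    return TrueArchitecture(
        beta=beta,
        core_member=core_member,
        genic=genic,
        ancestral_maf=maf,
        liability_threshold=float(norm.isf(cfg.prevalence)),
        h2_liability=cfg.h2_liability,
    )


class RejectionCapError(RuntimeError):
    """Raised when case/control rejection sampling exceeds the batch cap."""


def _study_frequencies(arch: TrueArchitecture, drift_f: float, rng: np.random.Generator) -> np.ndarray:
    """Balding–Nichols per-study allele frequencies around the ancestral MAF."""
    p = arch.ancestral_maf
    if drift_f == 0.0:
        return p.copy()
    a = p * (1.0 - drift_f) / drift_f
    b = (1.0 - p) * (1.0 - drift_f) / drift_f
    return np.clip(rng.beta(a, b), 1e-6, 1.0 - 1e-6)


def _draw_population(
    arch: TrueArchitecture, p_study: np.ndarray, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw n unascertained individuals; return (genotypes, case flags)."""
    g = rng.binomial(2, p_study, size=(n, p_study.shape[0])).astype(np.float64)
    genetic = (g - 2.0 * arch.ancestral_maf) @ arch.beta
    noise_sd = np.sqrt(max(1.0 - arch.h2_liability, 0.0))
    liability = genetic + rng.normal(0.0, noise_sd, size=n)
    return g, liability > arch.liability_threshold


def simulate_study(
    arch: TrueArchitecture,
    snps: pd.DataFrame,
    study_id: str,
    n_case: int,
    n_control: int,
    drift_f: float,
    missing_rate: float,
    n_covariates: int,
    seed: int,
    study_index: int = 0,
    max_batches: int = 200,
) -> GenotypeStudy:
    """Sample one ascertained case-control cohort under the liability model.

    Individuals are drawn from the study's drifted allele frequencies and
    rejection-sampled until exactly ``n_case`` cases and ``n_control``
    controls are collected; the batch cap guards against prevalences too
    extreme for the requested counts.
    """
    if n_case < 1 or n_control < 1:
        raise ConfigurationError("n_case and n_control must be >= 1")
    rng = stage_rng(seed, "study", study_index)
    p_study = _study_frequencies(arch, drift_f, rng)

    prev = norm.sf(arch.liability_threshold)
    batch = int(min(max(n_case / max(prev, 1e-6), n_control / max(1.0 - prev, 1e-6)) * 1.3 + 50, 200_000))
    cases: list[np.ndarray] = []
    controls: list[np.ndarray] = []
    have_case = have_ctrl = 0
    for it in range(max_batches):
        g, is_case = _draw_population(arch, p_study, batch, rng)
        if have_case < n_case:
            cases.append(g[is_case])
            have_case += int(is_case.sum())
        if have_ctrl < n_control:
            controls.append(g[~is_case])
            have_ctrl += int((~is_case).sum())
        if have_case >= n_case and have_ctrl >= n_control:
            break
    else:
        raise RejectionCapError(
            f"{study_id}: rejection sampling exceeded the cap of {max_batches} batches "
            f"({have_case}/{n_case} cases, {have_ctrl}/{n_control} controls)"
        )

    g_case = np.concatenate(cases)[:n_case]
    g_ctrl = np.concatenate(controls)[:n_control]
    dosage = np.concatenate([g_case, g_ctrl])
    phenotype = np.concatenate([np.full(n_case, CASE), np.full(n_control, CONTROL)])

    # shuffle so cases and controls are interleaved like a real cohort file
    order = rng.permutation(n_case + n_control)
    dosage = dosage[order]
    phenotype = phenotype[order]

    if missing_rate > 0.0:
        miss = rng.random(dosage.shape) < missing_rate
        dosage[miss] = np.nan

    # PC-surrogate covariates: a study-specific mean shift plus unit noise
    mu = stage_rng(seed, "covariate_means", study_index).normal(0.0, 1.0, size=n_covariates)
    covars = mu + rng.normal(0.0, 1.0, size=(n_case + n_control, n_covariates))
    covariates = pd.DataFrame(covars, columns=[f"PC{i + 1}" for i in range(n_covariates)])

    sample_ids = [f"{study_id}_s{i:05d}" for i in range(n_case + n_control)]
    study = GenotypeStudy(
        study_id=study_id,
        sample_ids=sample_ids,
        dosage=dosage,
        phenotype=phenotype,
        covariates=covariates,
        snps=snps,
    )
    study.validate()
    return study


@dataclass
class Cohort:
    """Everything one simulated experiment needs, plus the generating truth."""

    config: SimConfig
    annotation: Annotation
    architecture: TrueArchitecture
    gene_sets: list[GeneSet]
    studies: list[GenotypeStudy]


def simulate_cohort(cfg: SimConfig) -> Cohort:
    """Generate annotation, gene sets, architecture and all studies."""
    cfg.validate()
    annotation = simulate_annotation(cfg)
    gene_sets = make_gene_sets(annotation, cfg)
    arch = simulate_effects(cfg, annotation, gene_sets)
    studies = [
        simulate_study(
            arch,
            annotation.snps,
            study_id=f"study{i + 1}",
            n_case=cfg.cases_per_study[i],
            n_control=cfg.controls_per_study[i],
            drift_f=cfg.study_drift_f,
            missing_rate=cfg.missing_rate,
            n_covariates=cfg.n_covariates,
            seed=cfg.seed,
            study_index=i,
        )
        for i in range(cfg.n_studies)
    ]
    return Cohort(config=cfg, annotation=annotation, architecture=arch, gene_sets=gene_sets, studies=studies)
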