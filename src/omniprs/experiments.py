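"""Canned validation experiments at desk scale.

These encode the package's standard study designs — a type-I calibration run,
a core-set parameter-recovery contrast against the genic floor, and the
genic vs non-genic floor-direction comparison — so the analysis drivers, the
test suite and the reproduction script all execute the identical conditions.

Problem sizes (chosen once as the desk-scale study design): six cohorts on a
2,000-SNP / 300-gene panel; the calibration run uses 100+100 samples per
study, the recovery and floor runs 250+250 for adequate power.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .genesets import classify_genic, snps_for_gene_set
from .pipeline import (
    PermutationResult,
    floor_analysis,
    loo_multi,
    loo_run,
    permutation_experiment,
    prepare_training,
)
from .genesets import RandomSetSpec, draw_random_sets
from .assoc import pooled_design
from .ldtools import PruneParams, prune
from .syndata import Cohort, SimConfig, simulate_cohort

logger = logging.getLogger("omniprs")


def _core_snps(cohort: Cohort):
    _, assignments = classify_genic(cohort.annotation.snps, cohort.annotation.genes)
    return snps_for_gene_set(cohort.gene_sets[0], assignments)


def type1_config(seed: int) -> SimConfig:
    """Null-calibration conditions: 6 equal studies, polygenic but unenriched."""
    return SimConfig(
        n_studies=6,
        cases_per_study=(100,) * 6,
        controls_per_study=(100,) * 6,
        n_snps=2000,
        n_genes=300,
        h2_liability=0.3,
        core_enrichment=1.0,
        seed=seed,
    )


def type1_experiment(
    seed: int, n_permutations: int = 100, refit_training: bool = False
) -> tuple[PermutationResult, list[float]]:
    """Experiment-wise rejection rate of the pipeline under phenotype permutation.

    The tested gene set has no enrichment beyond the omnigenic background, and
    permutation breaks even that, so rejections at α=0.05 should occur for
    about 5% of permutations when the pipeline is well calibrated.
    """
    cohort = simulate_cohort(type1_config(seed))
    core = _core_snps(cohort)
    return permutation_experiment(
        cohort.studies, core, n_permutations=n_permutations,
        seed=seed, refit_training=refit_training,
    )


def recovery_config(seed: int) -> SimConfig:
    """Parameter-recovery conditions: 10x core enrichment, generous samples."""
    return SimConfig(
        n_studies=6,
        cases_per_study=(250,) * 6,
        controls_per_study=(250,) * 6,
        n_snps=2000,
        n_genes=300,
        core_set_genes=50,
        h2_liability=0.3,
        core_enrichment=10.0,
        seed=seed,
    )


@dataclass
class RecoveryResult:
    core_p_meta: float
    core_r2_median: float
    random_p_metas: list[float]
    random_r2_medians: list[float]

    @property
    def beats_floor_p(self) -> bool:
        return self.core_p_meta < float(np.median(self.random_p_metas))

    @property
    def beats_floor_r2(self) -> bool:
        return self.core_r2_median > float(np.median(self.random_r2_medians))


def core_recovery_replicate(seed: int, n_random: int = 20) -> RecoveryResult:
    """One replicate of the core-set vs genic-floor contrast.

    The enriched core set is run through the leave-one-out pipeline alongside
    ``n_random`` random genic SNP sets of the same SNP count drawn from an
    independence-pruned (r² < 0.01) pool; a recovered enrichment shows up as a
    smaller meta p and larger median nested R² than the floor medians.
    """
    cohort = simulate_cohort(recovery_config(seed))
    core = _core_snps(cohort)
    snps = cohort.annotation.snps
    genic, _ = classify_genic(snps, cohort.annotation.genes)

    _, _, pooled_dosage = pooled_design(cohort.studies)
    pool_prune = PruneParams(r2_max=0.01)
    pruned = set(prune(pooled_dosage, snps["snp_id"].to_numpy(), pool_prune))
    spec = RandomSetSpec(n_sets=n_random, set_size=len(core), pool="genic",
                         r2_max_pool=0.01, seed=seed)
    random_sets = draw_random_sets(spec, snps["snp_id"].to_numpy(), genic, pruned_pool=pruned)

    artifacts = prepare_training(cohort.studies, keep_pooled=True)
    results = loo_multi(cohort.studies, [core] + random_sets, artifacts=artifacts)
    _, core_meta = results[core.name]
    random_metas = [results[s.name][1] for s in random_sets]
    return RecoveryResult(
        core_p_meta=core_meta.p_meta,
        core_r2_median=core_meta.r2_median,
        random_p_metas=[m.p_meta for m in random_metas],
        random_r2_medians=[m.r2_median for m in random_metas],
    )


def floor_config(seed: int) -> SimConfig:
    """Floor-direction conditions: liability effects at genic SNPs only."""
    return SimConfig(
        n_studies=6,
        cases_per_study=(250,) * 6,
        controls_per_study=(250,) * 6,
        n_snps=2000,
        n_genes=300,
        h2_liability=0.3,
        core_enrichment=1.0,
        prop_causal_genic=1.0,
        seed=seed,
    )


@dataclass
class FloorResult:
    genic_r2_median: float
    nongenic_r2_median: float
    genic_p_median: float
    nongenic_p_median: float

    @property
    def genic_above_nongenic(self) -> bool:
        return self.genic_r2_median > self.nongenic_r2_median


def floor_direction_replicate(seed: int, n_sets: int = 10, set_size: int = 200) -> FloorResult:
    """One replicate of the genic vs non-genic floor comparison.

    With all liability variance at genic SNPs, scores from random genic sets
    should explain more held-out variance than equally sized non-genic sets.
    """
    cohort = simulate_cohort(floor_config(seed))
    floor = floor_analysis(
        cohort.studies, cohort.annotation.genes,
        n_sets=n_sets, set_size=set_size, seed=seed,
    )
    g = [mr for _, mr in floor["genic"]]
    n = [mr for _, mr in floor["nongenic"]]
    return FloorResult(
        genic_r2_median=float(np.median([m.r2_median for m in g])),
        nongenic_r2_median=float(np.median([m.r2_median for m in n])),
        genic_p_median=float(np.median([m.p_meta for m in g])),
        nongenic_p_median=float(np.median([m.p_meta for m in n])),
    )
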