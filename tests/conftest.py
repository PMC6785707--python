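"""Shared fixtures: small synthetic cohorts reused across the test modules."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from omniprs.genesets import classify_genic, snps_for_gene_set
from omniprs.syndata import SimConfig, simulate_cohort


def small_config(**overrides) -> SimConfig:
    """A 4-study desk-scale configuration that keeps unit tests fast."""
    base = dict(
        n_studies=4,
        cases_per_study=(80, 80, 80, 80),
        controls_per_study=(80, 80, 80, 80),
        n_snps=600,
        n_genes=120,
        chrom_length=6_000_000,
        core_set_genes=30,
        control_set_genes=30,
        n_control_sets=1,
        seed=3,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def small_cohort():
    """Four equal studies, h² = 0.3, no core enrichment."""
    return simulate_cohort(small_config())


@pytest.fixture(scope="session")
def enriched_cohort():
    """Four equal studies with a 10x-enriched core gene set."""
    return simulate_cohort(small_config(seed=11, core_enrichment=10.0))


def core_snp_set(cohort):
    _, assignments = classify_genic(cohort.annotation.snps, cohort.annotation.genes)
    return snps_for_gene_set(cohort.gene_sets[0], assignments)


def correlated_panel(
    n: int, m: int, seed: int, missing_rate: float = 0.0
) -> tuple[np.ndarray, list[str]]:
    """Dosage panel with block-ish LD, for pruning tests.

    Latent Gaussian factors shared by neighbouring SNPs are thresholded into
    0/1/2 calls, giving realistic positive local correlation.
    """
    rng = np.random.default_rng(seed)
    z = rng.normal(size=(n, m))
    factors = rng.normal(size=(n, max(m // 4, 1)))
    for j in range(m):
        z[:, j] = 0.75 * factors[:, j % factors.shape[1]] + 0.66 * z[:, j]
    p = rng.uniform(0.2, 0.8, size=m)
    from scipy.stats import norm

    lo = norm.ppf((1 - p) ** 2)
    hi = norm.ppf(1 - p**2)
    dosage = np.where(z < lo, 0.0, np.where(z < hi, 1.0, 2.0))
    if missing_rate > 0:
        dosage[rng.random(dosage.shape) < missing_rate] = np.nan
    return dosage, [f"s{j:03d}" for j in range(m)]
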