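"""Generator checks: determinism, liability normalisation, enrichment, drift."""

import numpy as np
import pytest
from scipy.stats import norm

from omniprs.core import stage_rng
from omniprs.syndata import (
    ConfigurationError,
    RejectionCapError,
    SimConfig,
    TrueArchitecture,
    _draw_population,
    make_gene_sets,
    simulate_annotation,
    simulate_cohort,
    simulate_effects,
    simulate_study,
)

from conftest import small_config


class TestAnnotation:
    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ConfigurationError):
            simulate_annotation(small_config(n_genes=0))
        with pytest.raises(ConfigurationError):
            # 200 genes of >=2 kb cannot fit on 100 kb
            simulate_annotation(small_config(n_genes=200, chrom_length=100_000))

    def test_feasible_packing_is_disjoint_and_in_bounds(self):
        cfg = small_config(n_genes=10, gene_length_range=(10_000, 10_000), chrom_length=1_000_000)
        ann = simulate_annotation(cfg)
        genes = ann.genes.sort_values("start")
        assert len(genes) == 10
        assert (genes["start"] >= 1).all() and (genes["end"] <= 1_000_000).all()
        assert (genes["end"] - genes["start"] + 1 == 10_000).all()
        assert (genes["start"].to_numpy()[1:] > genes["end"].to_numpy()[:-1]).all()

    def test_rerun_is_byte_identical(self):
        a = simulate_annotation(small_config())
        b = simulate_annotation(small_config())
        assert a.genes.equals(b.genes)
        assert a.snps.equals(b.snps)

    def test_both_genic_and_nongenic_snps_exist(self, small_cohort):
        ann = small_cohort.annotation
        assert ann.n_genic > 0 and ann.n_nongenic > 0
        assert ann.n_genic + ann.n_nongenic == len(ann.snps)


class TestEffects:
    def test_null_architecture_has_zero_betas(self):
        cfg = small_config(h2_liability=0.0)
        ann = simulate_annotation(cfg)
        arch = simulate_effects(cfg, ann, make_gene_sets(ann, cfg))
        assert np.all(arch.beta == 0.0)

    def test_liability_variance_normalised_exactly(self, small_cohort):
        arch = small_cohort.architecture
        het = 2.0 * arch.ancestral_maf * (1.0 - arch.ancestral_maf)
        assert np.sum(het * arch.beta**2) == pytest.approx(0.3, abs=1e-12)

    def test_core_enrichment_variance_ratio(self):
        cfg = small_config(seed=21, n_snps=4000, n_genes=400, core_set_genes=120,
                           chrom_length=40_000_000, core_enrichment=9.0)
        ann = simulate_annotation(cfg)
        arch = simulate_effects(cfg, ann, make_gene_sets(ann, cfg))
        assert arch.core_member.sum() > 100
        ratio = arch.beta[arch.core_member].var() / arch.beta[~arch.core_member].var()
        # F-distributed sampling noise at these member counts: generous band
        assert 0.55 * 9.0 < ratio < 1.6 * 9.0

    def test_no_enrichment_ratio_near_one(self):
        cfg = small_config(seed=22, n_snps=4000, n_genes=400, core_set_genes=120,
                           chrom_length=40_000_000, core_enrichment=1.0)
        ann = simulate_annotation(cfg)
        arch = simulate_effects(cfg, ann, make_gene_sets(ann, cfg))
        core = arch.core_member if arch.core_member.any() else arch.genic
        ratio = arch.beta[core].var() / arch.beta[~core].var()
        assert 0.55 < ratio < 1.6

    def test_genic_only_allocation(self):
        cfg = small_config(prop_causal_genic=1.0)
        ann = simulate_annotation(cfg)
        arch = simulate_effects(cfg, ann, make_gene_sets(ann, cfg))
        assert np.all(arch.beta[~arch.genic] == 0.0)
        het = 2.0 * arch.ancestral_maf * (1.0 - arch.ancestral_maf)
        assert np.sum(het * arch.beta**2) == pytest.approx(cfg.h2_liability, rel=1e-9)

    def test_invalid_h2_rejected(self):
        with pytest.raises(ConfigurationError):
            small_config(h2_liability=1.5).validate()


class TestStudies:
    def test_population_case_fraction_matches_prevalence(self, small_cohort):
        arch = small_cohort.architecture
        rng = stage_rng(99, "popcheck")
        n = 20_000
        _, is_case = _draw_population(arch, arch.ancestral_maf, n, rng)
        prev = small_cohort.config.prevalence
        tol = 4.0 * np.sqrt(prev * (1 - prev) / n)
        assert abs(is_case.mean() - prev) < tol

    def test_exact_counts_and_no_missing_when_rate_zero(self, small_cohort):
        arch = small_cohort.architecture
        s = simulate_study(arch, small_cohort.annotation.snps, "t", 40, 55,
                           drift_f=0.0, missing_rate=0.0, n_covariates=2, seed=5)
        assert s.n_cases == 40 and s.n_controls == 55
        assert not np.isnan(s.dosage).any()

    def test_rejection_cap_raises_named_error(self):
        cfg = small_config(n_snps=10, n_genes=4, core_set_genes=1, control_set_genes=1)
        ann = simulate_annotation(cfg)
        arch = simulate_effects(cfg, ann, make_gene_sets(ann, cfg))
        # a liability threshold at ~6 SD makes cases essentially unreachable
        rare = TrueArchitecture(
            beta=arch.beta, core_member=arch.core_member, genic=arch.genic,
            ancestral_maf=arch.ancestral_maf, liability_threshold=float(norm.isf(1e-10)),
            h2_liability=arch.h2_liability,
        )
        with pytest.raises(RejectionCapError, match="cap"):
            simulate_study(rare, ann.snps, "t", 50, 10, drift_f=0.0,
                           missing_rate=0.0, n_covariates=1, seed=1, max_batches=2)

    def test_cohort_is_deterministic(self):
        a = simulate_cohort(small_config(n_studies=2, cases_per_study=(30, 40),
                                         controls_per_study=(30, 40), n_snps=200,
                                         n_genes=40, chrom_length=2_000_000,
                                         core_set_genes=10, control_set_genes=10))
        b = simulate_cohort(small_config(n_studies=2, cases_per_study=(30, 40),
                                         controls_per_study=(30, 40), n_snps=200,
                                         n_genes=40, chrom_length=2_000_000,
                                         core_set_genes=10, control_set_genes=10))
        for sa, sb in zip(a.studies, b.studies):
            np.testing.assert_array_equal(sa.dosage, sb.dosage)
            np.testing.assert_array_equal(sa.phenotype, sb.phenotype)
        assert [g.genes for g in a.gene_sets] == [g.genes for g in b.gene_sets]
        np.testing.assert_array_equal(a.architecture.beta, b.architecture.beta)


class TestGeneSets:
    def test_exact_sizes_and_disjoint_by_default(self, small_cohort):
        sets = small_cohort.gene_sets
        assert len(sets[0]) == 30
        assert not set(sets[0].genes) & set(sets[1].genes)

    def test_oversized_request_rejected(self):
        with pytest.raises(ConfigurationError):
            cfg = small_config(core_set_genes=500)
            make_gene_sets(simulate_annotation(cfg), cfg)

    def test_same_seed_same_membership(self):
        cfg = small_config()
        ann = simulate_annotation(cfg)
        assert make_gene_sets(ann, cfg) == make_gene_sets(ann, cfg)
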