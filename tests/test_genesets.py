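"""SNP-gene mapping, set construction, overlap lattice and random draws."""

import numpy as np
import pandas as pd
import pytest

from omniprs.core import GeneSet
from omniprs.genesets import (
    GenicMargins,
    RandomSetSpec,
    classify_genic,
    draw_random_sets,
    overlap_stats,
    snps_for_gene_set,
)


def panel(positions, chrom="1"):
    return pd.DataFrame(
        {
            "snp_id": [f"s{i}" for i in range(len(positions))],
            "chrom": chrom,
            "pos": positions,
            "a1": "A",
            "a2": "G",
        }
    )


def gene(gene_id, start, end, strand="+", chrom="1"):
    return {"gene_id": gene_id, "chrom": chrom, "start": start, "end": end, "strand": strand}


class TestClassifyGenic:
    def test_inside_gene_body_is_genic(self):
        snps = panel([15_000])
        genes = pd.DataFrame([gene("g", 10_000, 20_000)])
        flags, asg = classify_genic(snps, genes)
        assert flags[0] and asg["g"] == ["s0"]

    def test_upstream_boundary_inclusive_plus_strand(self):
        genes = pd.DataFrame([gene("g", 50_000, 60_000, "+")])
        flags, _ = classify_genic(panel([45_000, 44_999, 61_000, 61_001]), genes)
        # exactly 5 kb upstream genic, 5001 bp not; 1 kb downstream genic, 1001 bp not
        assert flags.tolist() == [True, False, True, False]

    def test_minus_strand_margins_are_mirrored(self):
        genes = pd.DataFrame([gene("g", 50_000, 60_000, "-")])
        flags, _ = classify_genic(panel([49_000, 48_999, 65_000, 65_001]), genes)
        # minus strand: 1 kb window on the low-coordinate (downstream) side,
        # 5 kb on the high-coordinate (upstream) side
        assert flags.tolist() == [True, False, True, False]

    def test_strand_unaware_mode_uses_plus_convention(self):
        genes = pd.DataFrame([gene("g", 50_000, 60_000, "-")])
        flags, _ = classify_genic(panel([45_000, 61_000, 65_000]), genes, strand_aware=False)
        assert flags.tolist() == [True, True, False]

    def test_matches_bruteforce_on_mixed_fixture(self):
        rng = np.random.default_rng(8)
        pos = np.sort(rng.choice(200_000, size=20, replace=False)) + 1
        snps = panel(pos)
        genes = pd.DataFrame(
            [gene("a", 30_000, 40_000, "+"), gene("b", 90_000, 95_000, "-"), gene("c", 150_000, 180_000, "+")]
        )
        m = GenicMargins()
        flags, asg = classify_genic(snps, genes, m)
        for i, p in enumerate(pos):
            expect = False
            for g in genes.itertuples(index=False):
                if g.strand == "-":
                    lo, hi = g.start - m.downstream_bp, g.end + m.upstream_bp
                else:
                    lo, hi = g.start - m.upstream_bp, g.end + m.downstream_bp
                if lo <= p <= hi:
                    expect = True
            assert flags[i] == expect, f"snp at {p}"

    def test_partition_property(self, small_cohort):
        flags, _ = classify_genic(small_cohort.annotation.snps, small_cohort.annotation.genes)
        assert flags.shape[0] == len(small_cohort.annotation.snps)
        assert flags.sum() + (~flags).sum() == len(flags)


class TestSnpsForGeneSet:
    def test_empty_set_and_dedup_and_count(self):
        snps = panel([10, 20, 30, 40, 50])
        genes = pd.DataFrame([gene("a", 5, 30), gene("b", 25, 45)])
        _, asg = classify_genic(snps, genes, GenicMargins(0, 0))
        assert len(snps_for_gene_set(GeneSet("e", ()), asg)) == 0
        # a covers {10,20,30}, b covers {30,40}; union has 4
        ss = snps_for_gene_set(GeneSet("ab", ("a", "b")), asg)
        assert len(ss) == 4
        assert len(set(ss.snps)) == len(ss.snps)

    def test_unknown_gene_warns_not_raises(self, caplog):
        snps = panel([10])
        genes = pd.DataFrame([gene("a", 5, 30)])
        _, asg = classify_genic(snps, genes, GenicMargins(0, 0))
        with caplog.at_level("WARNING", logger="omniprs"):
            ss = snps_for_gene_set(GeneSet("x", ("a", "phantom")), asg)
        assert ss.snps == ("s0",)
        assert "absent" in caplog.text


class TestOverlapStats:
    def test_disjoint_and_identical(self):
        a, b = GeneSet("a", ("g1", "g2")), GeneSet("b", ("g3", "g4"))
        tab = overlap_stats([a, b])
        both = tab[tab["pattern"] == "11"].iloc[0]
        assert both["n_genes"] == 0 and both["pct_of_union"] == 0.0
        tab2 = overlap_stats([a, GeneSet("a2", ("g1", "g2"))])
        assert tab2[tab2["pattern"] == "11"].iloc[0]["pct_of_union"] == 100.0

    def test_hand_counted_overlap(self):
        tab = overlap_stats([GeneSet("x", ("a", "b", "c")), GeneSet("y", ("b", "c", "d"))])
        by = tab.set_index("pattern")
        assert by.loc["11", "n_genes"] == 2
        assert by.loc["11", "pct_of_union"] == pytest.approx(50.0)
        assert by.loc["10", "n_genes"] == 1 and by.loc["01", "n_genes"] == 1

    def test_percentages_sum_to_100(self, small_cohort):
        tab = overlap_stats(small_cohort.gene_sets)
        assert tab["pct_of_union"].sum() == pytest.approx(100.0)

    def test_requires_two_sets(self):
        with pytest.raises(ValueError):
            overlap_stats([GeneSet("a", ("g",))])


class TestRandomSets:
    def setup_method(self):
        self.ids = np.array([f"s{i}" for i in range(40)])
        self.genic = np.array([i < 25 for i in range(40)])

    def test_pool_membership_and_disjoint_pools(self):
        spec_g = RandomSetSpec(n_sets=5, set_size=10, pool="genic", seed=1)
        spec_n = RandomSetSpec(n_sets=5, set_size=10, pool="nongenic", seed=1)
        genic_sets = draw_random_sets(spec_g, self.ids, self.genic)
        nong_sets = draw_random_sets(spec_n, self.ids, self.genic)
        genic_ids = set(self.ids[self.genic])
        for ss in genic_sets:
            assert set(ss.snps) <= genic_ids
            assert len(set(ss.snps)) == 10
        for ss in nong_sets:
            assert not set(ss.snps) & genic_ids

    def test_same_seed_identical_draws(self):
        spec = RandomSetSpec(n_sets=3, set_size=8, pool="genic", seed=42)
        a = draw_random_sets(spec, self.ids, self.genic)
        b = draw_random_sets(spec, self.ids, self.genic)
        assert [s.snps for s in a] == [s.snps for s in b]

    def test_pool_of_exactly_set_size(self):
        spec = RandomSetSpec(n_sets=2, set_size=25, pool="genic", seed=0)
        sets = draw_random_sets(spec, self.ids, self.genic)
        for ss in sets:
            assert sorted(ss.snps) == sorted(self.ids[self.genic])

    def test_truncation_warns_and_empty_pool_raises(self, caplog):
        spec = RandomSetSpec(n_sets=1, set_size=100, pool="genic", seed=0)
        with caplog.at_level("WARNING", logger="omniprs"):
            sets = draw_random_sets(spec, self.ids, self.genic)
        assert len(sets[0]) == 25 and "truncating" in caplog.text
        with pytest.raises(ValueError, match="empty"):
            draw_random_sets(
                RandomSetSpec(n_sets=1, set_size=5, pool="genic", seed=0),
                self.ids, np.zeros(40, dtype=bool),
            )

    def test_pruned_pool_restriction(self):
        pruned = {f"s{i}" for i in range(0, 40, 2)}
        spec = RandomSetSpec(n_sets=4, set_size=6, pool="genic", seed=3)
        for ss in draw_random_sets(spec, self.ids, self.genic, pruned_pool=pruned):
            assert set(ss.snps) <= pruned
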