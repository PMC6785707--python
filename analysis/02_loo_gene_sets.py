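#!/usr/bin/env python
"""Leave-one-out gene-set PRS analysis of an enriched cohort.

Simulates a cohort whose core gene set carries 10x the background effect
variance, runs the leave-one-out pipeline for the core set, the control sets
and the unrestricted genome-wide score, and writes per-study records and the
Stouffer meta-analysis under results/loo/.  The expected picture: the core set
meta-significant with the largest nested R², control sets near the omnigenic
floor, and the genome-wide score strongest of all in absolute R².
"""

import argparse
import logging
from pathlib import Path

from omniprs.experiments import recovery_config
from omniprs.genesets import classify_genic, snps_for_gene_set
from omniprs.meta import meta_table
from omniprs.pipeline import _records_frame, loo_multi, loo_run, prepare_training
from omniprs.syndata import simulate_cohort


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", default="results/loo")
    args = ap.parse_args()
    logging.basicConfig(level=logging.INFO, format="%(levelname)s %(message)s")

    cohort = simulate_cohort(recovery_config(args.seed))
    _, assignments = classify_genic(cohort.annotation.snps, cohort.annotation.genes)
    snp_sets = [snps_for_gene_set(gs, assignments) for gs in cohort.gene_sets]

    artifacts = prepare_training(cohort.studies, keep_pooled=True)
    results = loo_multi(cohort.studies, snp_sets, artifacts=artifacts)
    gw_records, gw_meta = loo_run(cohort.studies, None, prune_params=None)
    records = {name: recs for name, (recs, _) in results.items()}
    records["genomewide"] = gw_records
    metas = {name: mr for name, (_, mr) in results.items()}
    metas["genomewide"] = gw_meta

    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)
    _records_frame(records).to_csv(out / "loo_records.tsv", sep="\t", index=False)
    tab = meta_table(metas)
    tab.to_csv(out / "meta.tsv", sep="\t", index=False)

    print(tab.to_string(index=False, float_format=lambda v: f"{v:.3g}"))
    core = metas[cohort.config.core_set_name]
    print(f"\ncore set: Stouffer p = {core.p_meta:.3g}, "
          f"{core.k_significant}/{core.n_used} held-out studies significant, "
          f"median nested R2 = {core.r2_median:.4f}")


if __name__ == "__main__":
    main()
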