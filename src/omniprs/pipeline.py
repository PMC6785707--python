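"""Leave-one-out experiment orchestration, permutation null, and floor analysis.

For each study s the training set is every other study pooled; a training GWAS
is run, risk alleles oriented, the training panel LD-pruned, the score
restricted to the gene set under test, the p-value cutoff selected inside the
training data, and the single resulting score evaluated on s with a nested
likelihood-ratio test.  The held-out records are then combined with Stouffer's
Z.  Training stages only ever see the container of training studies, so the
held-out phenotypes cannot leak into weight estimation or threshold selection.

The permutation null re-runs this entire procedure (GWAS included) on
within-study phenotype permutations; the floor analysis runs it over random
genic and non-genic SNP sets drawn from independence-pruned pools.  Both reuse
phenotype-independent intermediates (LD prune lists; per-iteration GWAS across
gene sets) where re-computation would be bit-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import beta as beta_dist

from . import __version__
from .assoc import fit_logistic, gwas, lrt, nagelkerke, orient_risk, pooled_design
from .core import CASE, GenotypeStudy, LooRecord, MetaResult, SnpSet, stage_rng
from .genesets import RandomSetSpec, classify_genic, draw_random_sets, snps_for_gene_set
from .io_formats import QcThresholds, qc_filter
from .ldtools import PruneParams, prune
from .meta import meta_table, stouffer
from .prs import ThresholdGrid, score_matrix, select_threshold
from .syndata import Cohort, SimConfig, simulate_cohort

logger = logging.getLogger("omniprs")


class ConfigError(ValueError):
    """Unknown or invalid experiment-configuration key."""


@dataclass
class TrainingArtifacts:
    """Training-side outputs for one leave-one-out iteration."""

    held_out: str
    stats: pd.DataFrame  # risk-oriented summary statistics, pruned panel only
    kept: set[str]
    pooled: tuple[np.ndarray, pd.DataFrame, np.ndarray] | None = None  # (y, covars, dosage)


@dataclass
class PermutationResult:
    """Experiment-wise rejection fraction under phenotype permutation."""

    n_permutations: int
    n_rejected: int
    alpha: float
    ci_low: float
    ci_high: float

    @property
    def fraction(self) -> float:
        return self.n_rejected / self.n_permutations


def _clopper_pearson(k: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    a = (1.0 - conf) / 2.0
    lo = 0.0 if k == 0 else float(beta_dist.ppf(a, k, n - k + 1))
    hi = 1.0 if k == n else float(beta_dist.ppf(1.0 - a, k + 1, n - k))
    return lo, hi


def prepare_training(
    studies: list[GenotypeStudy],
    prune_params: PruneParams | None = PruneParams(),
    prune_cache: dict[str, set[str]] | None = None,
    keep_pooled: bool = False,
) -> list[TrainingArtifacts]:
    """Run the training GWAS + orientation + pruning for every held-out study.

    ``prune_params=None`` skips pruning (genome-wide mode).  ``prune_cache``
    maps held-out study id to a previously computed kept-SNP set; pruning
    depends only on training genotypes, so the cache is exact under phenotype
    permutation.
    """
    if len(studies) < 3:
        raise ValueError("leave-one-out needs at least 3 studies")
    arts = []
    for i, held in enumerate(studies):
        training = studies[:i] + studies[i + 1 :]
        stats = orient_risk(gwas(training))
        pooled = pooled_design(training)
        if prune_params is None:
            kept = set(stats["snp_id"])
        elif prune_cache is not None and held.study_id in prune_cache:
            kept = prune_cache[held.study_id]
        else:
            kept = set(prune(pooled[2], training[0].snps["snp_id"].to_numpy(), prune_params))
        arts.append(
            TrainingArtifacts(
                held_out=held.study_id,
                stats=stats[stats["snp_id"].isin(kept)].reset_index(drop=True),
                kept=kept,
                pooled=pooled if keep_pooled else None,
            )
        )
    return arts


def _failed_record(held: GenotypeStudy, note: str) -> LooRecord:
    return LooRecord(
        held_out_study=held.study_id, selected_cutoff=float("nan"), lrt_stat=0.0,
        p_value=1.0, nested_r2=0.0, r2_full=0.0, r2_base=0.0, direction=1,
        n_cases=held.n_cases, n_controls=held.n_controls, flagged=True, note=note,
    )


def _evaluate_held_out(
    held: GenotypeStudy,
    art: TrainingArtifacts,
    training: list[GenotypeStudy] | None,
    snp_set: SnpSet | None,
    grid: ThresholdGrid,
    cached: tuple[float, "object"] | None = None,
) -> LooRecord:
    """Select the cutoff in training, score the held-out study, nested LRT.

    ``cached`` may carry a previously selected (cutoff, held-out ScoreVector)
    pair — both are functions of training data and held-out genotypes only, so
    they are reusable across phenotype permutations of the held-out study.
    """
    if cached is not None:
        best, sv = cached
    else:
        pooled = art.pooled if art.pooled is not None else pooled_design(training)
        try:
            best, _ = select_threshold(training, art.stats, snp_set, grid, pooled=pooled)
        except RuntimeError as exc:
            logger.warning("%s: %s", held.study_id, exc)
            return _failed_record(held, "all training cutoffs degenerate")
        sv = None

    keep = held.labeled_mask()
    y = (held.phenotype[keep] == CASE).astype(float)
    if sv is None:
        sv = score_matrix(held.dosage[keep], held.snps, art.stats, snp_set, best)
    covars = held.covariates.loc[keep].reset_index(drop=True).copy()
    base_X = covars.copy()
    base_X["valid_ct"] = sv.valid_count.astype(float)
    full_X = base_X.copy()
    full_X["score"] = sv.score

    base = fit_logistic(y, base_X)
    full = fit_logistic(y, full_X)
    ll0 = fit_logistic(y, None).llf
    n = int(y.shape[0])

    flagged = base.flagged or full.flagged or "score" in full.dropped or sv.n_snps_scored == 0
    if flagged:
        stat, p, direction = 0.0, 1.0, 1
        r2_full = r2_base = nested = 0.0
    else:
        stat, p = lrt(full, base, df=1)
        direction = 1 if full.coef("score") >= 0.0 else -1
        r2_full = nagelkerke(full.llf, ll0, n)
        r2_base = nagelkerke(base.llf, ll0, n)
        nested = max(r2_full - r2_base, 0.0)

    return LooRecord(
        held_out_study=held.study_id,
        selected_cutoff=best,
        lrt_stat=stat,
        p_value=p,
        nested_r2=nested,
        r2_full=r2_full,
        r2_base=r2_base,
        direction=direction,
        n_cases=int(y.sum()),
        n_controls=int((1 - y).sum()),
        flagged=flagged,
    )


def loo_run(
    studies: list[GenotypeStudy],
    snp_set: SnpSet | None,
    prune_params: PruneParams | None = PruneParams(),
    grid: ThresholdGrid = ThresholdGrid(),
    alpha: float = 0.05,
    artifacts: list[TrainingArtifacts] | None = None,
) -> tuple[list[LooRecord], MetaResult]:
    """Full leave-one-out experiment for one SNP set.

    ``snp_set=None`` evaluates the unrestricted (genome-wide) score.  Failed
    held-out fits are flagged and excluded from the meta-analysis; the run
    continues.
    """
    if artifacts is None:
        artifacts = prepare_training(studies, prune_params, keep_pooled=True)
    records = []
    for i, held in enumerate(studies):
        training = studies[:i] + studies[i + 1 :]
        records.append(_evaluate_held_out(held, artifacts[i], training, snp_set, grid))
    return records, stouffer(records, alpha=alpha)


def loo_multi(
    studies: list[GenotypeStudy],
    snp_sets: list[SnpSet],
    prune_params: PruneParams | None = PruneParams(),
    grid: ThresholdGrid = ThresholdGrid(),
    alpha: float = 0.05,
    artifacts: list[TrainingArtifacts] | None = None,
) -> dict[str, tuple[list[LooRecord], MetaResult]]:
    """loo_run over several SNP sets, sharing the per-iteration training GWAS.

    The training GWAS and prune list do not depend on the gene set, so they
    are computed once per held-out study and reused — results are identical to
    independent loo_run calls.
    """
    if artifacts is None:
        artifacts = prepare_training(studies, prune_params, keep_pooled=True)
    return {
        ss.name: loo_run(studies, ss, prune_params, grid, alpha, artifacts=artifacts)
        for ss in snp_sets
    }


def permute_within_study(study: GenotypeStudy, rng: np.random.Generator) -> GenotypeStudy:
    """Shuffle case/control labels among the study's labeled samples."""
    pheno = study.phenotype.copy()
    idx = np.where(study.labeled_mask())[0]
    pheno[idx] = pheno[rng.permutation(idx)]
    return study.with_phenotype(pheno)


def permutation_experiment(
    studies: list[GenotypeStudy],
    snp_set: SnpSet | None,
    n_permutations: int = 100,
    alpha: float = 0.05,
    prune_params: PruneParams | None = PruneParams(),
    grid: ThresholdGrid = ThresholdGrid(),
    seed: int = 0,
    refit_training: bool = False,
) -> tuple[PermutationResult, list[float]]:
    """Experiment-wise type-I error of the pipeline under phenotype permutation.

    Each permutation shuffles case/control labels within every study
    (preserving per-study margins) and recomputes the meta statistic.  With the
    default ``refit_training=False`` the training side (GWAS weights, pruning,
    threshold selection) stays fixed at the observed phenotypes and only the
    held-out evaluations see permuted labels; the held-out z-scores are then
    independent and the test is calibrated.  ``refit_training=True`` re-runs
    the training GWAS and threshold selection on the permuted labels as well;
    because every study sits in the other K−1 training sets, the held-out
    z-scores pick up a pairwise correlation of about 1/(K−1) under that mode
    and the meta test becomes anti-conservative by construction (see the
    methods notes) — it is provided for studying exactly that behaviour.
    Returns the rejection fraction with an exact binomial 95% CI, plus the
    per-permutation meta p-values.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    base_arts = prepare_training(studies, prune_params, keep_pooled=not refit_training)
    meta_ps: list[float] = []

    if refit_training:
        prune_cache = {a.held_out: a.kept for a in base_arts}
        for b in range(n_permutations):
            rng = stage_rng(seed, "permutation", b)
            permuted = [permute_within_study(s, rng) for s in studies]
            arts = prepare_training(permuted, prune_params, prune_cache=prune_cache, keep_pooled=True)
            _, mr = loo_run(permuted, snp_set, prune_params, grid, alpha, artifacts=arts)
            meta_ps.append(mr.p_meta)
            logger.debug("permutation %d: meta p = %.3g", b, mr.p_meta)
    else:
        # training-side selection and held-out scores depend only on observed
        # training phenotypes and genotypes: compute once, reuse per permutation
        cached: list[tuple[float, object] | None] = []
        for i, held in enumerate(studies):
            training = studies[:i] + studies[i + 1 :]
            art = base_arts[i]
            try:
                best, _ = select_threshold(training, art.stats, snp_set, grid, pooled=art.pooled)
            except RuntimeError as exc:
                logger.warning("%s: %s", held.study_id, exc)
                cached.append(None)
                continue
            sv = score_matrix(held.dosage[held.labeled_mask()], held.snps, art.stats, snp_set, best)
            cached.append((best, sv))
        for b in range(n_permutations):
            rng = stage_rng(seed, "permutation", b)
            records = []
            for i, held in enumerate(studies):
                permuted = permute_within_study(held, rng)
                if cached[i] is None:
                    records.append(_failed_record(permuted, "all training cutoffs degenerate"))
                else:
                    records.append(
                        _evaluate_held_out(permuted, base_arts[i], None, snp_set, grid, cached=cached[i])
                    )
            mr = stouffer(records, alpha=alpha)
            meta_ps.append(mr.p_meta)
            logger.debug("permutation %d: meta p = %.3g", b, mr.p_meta)

    k = int(np.sum(np.array(meta_ps) < alpha))
    lo, hi = _clopper_pearson(k, n_permutations)
    return PermutationResult(n_permutations, k, alpha, lo, hi), meta_ps


def floor_analysis(
    studies: list[GenotypeStudy],
    genes: pd.DataFrame,
    n_sets: int = 50,
    set_size: int = 5000,
    r2_max_pool: float = 0.01,
    prune_params: PruneParams | None = PruneParams(),
    grid: ThresholdGrid = ThresholdGrid(),
    alpha: float = 0.05,
    seed: int = 0,
    artifacts: list[TrainingArtifacts] | None = None,
) -> dict[str, list[tuple[str, MetaResult]]]:
    """Omnigenic-floor estimate from random genic and non-genic SNP sets.

    SNPs are first pruned to near-independence (r² < ``r2_max_pool``) over the
    pooled studies, partitioned into genic/non-genic pools, and ``n_sets``
    random sets of ``set_size`` drawn from each pool; every set then goes
    through the standard leave-one-out pipeline.
    """
    snps = studies[0].snps
    genic, _ = classify_genic(snps, genes)
    _, _, pooled_dosage = pooled_design(studies)
    pool_window = PruneParams(
        window_snps=(prune_params or PruneParams()).window_snps,
        step_snps=(prune_params or PruneParams()).step_snps,
        r2_max=r2_max_pool,
    )
    pruned = set(prune(pooled_dosage, snps["snp_id"].to_numpy(), pool_window))
    out: dict[str, list[tuple[str, MetaResult]]] = {}
    if artifacts is None:
        artifacts = prepare_training(studies, prune_params, keep_pooled=True)
    for pool in ("genic", "nongenic"):
        spec = RandomSetSpec(n_sets=n_sets, set_size=set_size, pool=pool, r2_max_pool=r2_max_pool, seed=seed)
        sets = draw_random_sets(spec, snps["snp_id"].to_numpy(), genic, pruned_pool=pruned)
        results = loo_multi(studies, sets, prune_params, grid, alpha, artifacts=artifacts)
        out[pool] = [(name, mr) for name, (_, mr) in results.items()]
    return out


# ---------------------------------------------------------------------------
# config-driven experiment
# ---------------------------------------------------------------------------

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "alpha": 0.05,
    "simulate": {f: getattr(SimConfig(), f) for f in SimConfig.__dataclass_fields__},
    "qc": {"enabled": False},
    "gene_sets": None,  # null = every simulated gene set
    "prune": {"window_snps": 50, "step_snps": 5, "r2_max": 0.25},
    "grid": list(ThresholdGrid().p_cutoffs),
    "genomewide": {"enabled": False, "prune": False},
    "permutations": {"enabled": False, "n": 100, "gene_set": "core", "refit_training": False},
    "floor": {"enabled": False, "n_sets": 50, "set_size": 5000, "r2_max_pool": 0.01},
}


def _validate_config(cfg: dict, defaults: dict, path: str = "") -> dict:
    out = {k: (dict(v) if isinstance(v, dict) else v) for k, v in defaults.items()}
    for key, val in cfg.items():
        if key not in defaults:
            raise ConfigError(f"unknown configuration key '{path + key}'")
        if isinstance(defaults[key], dict) and not isinstance(val, dict):
            raise ConfigError(f"configuration key '{path + key}' must be a mapping")
        if isinstance(defaults[key], dict):
            out[key] = _validate_config(val, defaults[key], path + key + ".")
        else:
            out[key] = val
    return out


def load_config(source: dict | str | Path) -> dict:
    """Merge a user config (dict or YAML path) over defaults, validating keys."""
    import yaml

    if isinstance(source, (str, Path)):
        with open(source) as fh:
            source = yaml.safe_load(fh) or {}
    return _validate_config(source, DEFAULT_CONFIG)


def _records_frame(by_set: dict[str, list[LooRecord]]) -> pd.DataFrame:
    rows = []
    for name, records in by_set.items():
        for r in records:
            rows.append(
                {
                    "set": name,
                    "held_out_study": r.held_out_study,
                    "n_cases": r.n_cases,
                    "n_controls": r.n_controls,
                    "selected_cutoff": r.selected_cutoff,
                    "lrt_stat": r.lrt_stat,
                    "p_value": r.p_value,
                    "nested_r2": r.nested_r2,
                    "direction": r.direction,
                    "significant": (not r.flagged) and r.p_value < 0.05,
                    "flagged": r.flagged,
                }
            )
    return pd.DataFrame(rows)


def run_experiment(config: dict | str | Path, out_dir: str | Path) -> dict:
    """Simulate, optionally QC, and run LOO / permutation / floor analyses.

    Writes TSV reports and a manifest under ``out_dir`` and returns the report
    bundle in memory.
    """
    cfg = load_config(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    sim_cfg = SimConfig(**{**cfg["simulate"], "seed": cfg["simulate"]["seed"] or cfg["seed"]})
    cohort = simulate_cohort(sim_cfg)
    studies = cohort.studies
    if cfg["qc"]["enabled"]:
        studies = [qc_filter(s)[0] for s in studies]
        studies = harmonize_panels(studies)

    prune_params = PruneParams(**cfg["prune"])
    grid = ThresholdGrid(tuple(cfg["grid"]))
    alpha = cfg["alpha"]

    _, assignments = classify_genic(cohort.annotation.snps, cohort.annotation.genes)
    wanted = cfg["gene_sets"] or [gs.name for gs in cohort.gene_sets]
    by_name = {gs.name: gs for gs in cohort.gene_sets}
    missing = [w for w in wanted if w not in by_name]
    if missing:
        raise ConfigError(f"unknown gene set(s) {missing}")
    snp_sets = [snps_for_gene_set(by_name[w], assignments) for w in wanted]

    artifacts = prepare_training(studies, prune_params, keep_pooled=True)
    results = loo_multi(studies, snp_sets, prune_params, grid, alpha, artifacts=artifacts)
    by_set_records = {name: recs for name, (recs, _) in results.items()}
    metas = {name: mr for name, (_, mr) in results.items()}

    if cfg["genomewide"]["enabled"]:
        gw_prune = prune_params if cfg["genomewide"]["prune"] else None
        gw_records, gw_meta = loo_run(studies, None, gw_prune, grid, alpha)
        by_set_records["genomewide"] = gw_records
        metas["genomewide"] = gw_meta

    bundle: dict = {"records": by_set_records, "meta": metas}
    _records_frame(by_set_records).to_csv(out_dir / "loo_records.tsv", sep="\t", index=False)
    meta_table(metas).to_csv(out_dir / "meta.tsv", sep="\t", index=False)

    if cfg["permutations"]["enabled"]:
        target = cfg["permutations"]["gene_set"]
        if target not in {s.name for s in snp_sets}:
            raise ConfigError(f"permutation gene_set '{target}' not among analysed sets")
        snp_set = next(s for s in snp_sets if s.name == target)
        perm, meta_ps = permutation_experiment(
            studies, snp_set, n_permutations=cfg["permutations"]["n"], alpha=alpha,
            prune_params=prune_params, grid=grid, seed=cfg["seed"],
            refit_training=cfg["permutations"]["refit_training"],
        )
        pd.DataFrame(
            {"permutation": range(perm.n_permutations), "meta_p": meta_ps}
        ).to_csv(out_dir / "permutation.tsv", sep="\t", index=False)
        bundle["permutation"] = perm

    if cfg["floor"]["enabled"]:
        floor = floor_analysis(
            studies, cohort.annotation.genes,
            n_sets=cfg["floor"]["n_sets"], set_size=cfg["floor"]["set_size"],
            r2_max_pool=cfg["floor"]["r2_max_pool"], prune_params=prune_params,
            grid=grid, alpha=alpha, seed=cfg["seed"], artifacts=artifacts,
        )
        rows = [
            {"pool": pool, "set": name, "p_meta": mr.p_meta, "z_meta": mr.z_meta, "r2_median": mr.r2_median}
            for pool, pairs in floor.items()
            for name, mr in pairs
        ]
        pd.DataFrame(rows).to_csv(out_dir / "floor.tsv", sep="\t", index=False)
        bundle["floor"] = floor

    manifest = {
        "package": "omniprs",
        "version": __version__,
        "seed": cfg["seed"],
        "config": {k: v for k, v in cfg.items() if k != "simulate"} | {"simulate": dict(cfg["simulate"])},
        "n_studies": len(studies),
        "n_snps": int(studies[0].n_snps),
        "gene_sets": wanted,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    bundle["manifest"] = manifest
    return bundle


def harmonize_panels(studies: list[GenotypeStudy]) -> list[GenotypeStudy]:
    """Subset every study to the SNPs retained in all studies (post-QC)."""
    common = set(studies[0].snps["snp_id"])
    for s in studies[1:]:
        common &= set(s.snps["snp_id"])
    if not common:
        raise ValueError("no SNPs shared by all studies after QC")
    out = []
    for s in studies:
        keep = s.snps["snp_id"].isin(common).to_numpy()
        out.append(
            GenotypeStudy(
                study_id=s.study_id,
                sample_ids=s.sample_ids,
                dosage=s.dosage[:, keep],
                phenotype=s.phenotype,
                covariates=s.covariates,
                snps=s.snps.loc[keep].reset_index(drop=True),
            )
        )
    return out
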