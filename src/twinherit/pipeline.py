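"""Config-driven end-to-end pipeline.

Runs, in study order: simulation (or cohort loading), fingerprinting (self
and MZ-twin), classical Falconer heritability, bivariate genetic
correlation, the three classifier-weight methods, factor analysis with a
factor-level rerun of every heritability method (including the dual
regression+Bartlett score-set robustness run), and the cross-method /
domain statistics.  One global seed deterministically derives per-stage
seeds, so a config is a pure function to its report bundle.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import factors as fac
from . import fingerprint as fp
from . import genecorr as gc
from . import heritability as her
from . import mlweights as ml
from . import stats as st
from . import synthetic_data as sd
from .preprocess import PairFeatureSet, build_pair_features, zscore

log = logging.getLogger("twinherit")

STAGES = ("fingerprint", "heritability", "genecorr", "mlweights", "factors", "stats")


@dataclass
class PipelineConfig:
    """Either a cohort directory to load or a simulation recipe to run."""

    cohort_dir: str | None = None
    simulation: dict | None = None      # design + specs recipe (see from_yaml)
    stages: tuple = STAGES
    seed: int = 0
    out_dir: str = "twinherit_out"
    n_perm_identification: int = 1000
    n_perm_domain: int = 10_000
    ml: ml.RunConfig = field(default_factory=ml.RunConfig)
    n_factors: int | None = None        # None -> Kaiser rule

    def __post_init__(self) -> None:
        if self.cohort_dir is None and self.simulation is None:
            raise ValueError("config needs a cohort_dir or a simulation recipe")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "ml" in raw:
            raw["ml"] = ml.RunConfig(**{
                k: tuple(v) if k == "alpha_grid" else v
                for k, v in raw["ml"].items()})
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)


def _stage_seed(seed: int, stage: str) -> int:
    """Stable per-stage sub-seed below 2^31 (process-independent)."""
    ss = np.random.SeedSequence([seed, zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % 2**31)


def build_simulated_cohort(recipe: dict, seed: int) -> sd.Cohort:
    """Cohort from a plain-dict recipe (YAML-friendly).

    Recipe keys: ``design`` (CohortDesign kwargs minus seed) and ``specs``
    (list of VarianceSpec kwargs); ``genetic_corr`` may be a nested list.
    """
    specs = [sd.VarianceSpec(**s) for s in recipe["specs"]]
    design_kwargs = dict(recipe["design"])
    if design_kwargs.get("genetic_corr") is not None:
        design_kwargs["genetic_corr"] = np.asarray(design_kwargs["genetic_corr"], float)
    design = sd.CohortDesign(n_measures=len(specs), seed=seed, **design_kwargs)
    return sd.simulate_cohort(design, specs)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; returns the report dict and writes the
    TSV/JSON bundle under ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "stages": list(config.stages)}

    if config.simulation is not None:
        cohort = build_simulated_cohort(config.simulation,
                                        _stage_seed(config.seed, "simulate"))
        sd.write_cohort(cohort, out / "cohort")
    else:
        cohort = sd.read_cohort(config.cohort_dir)
    log.info("cohort: %d subjects, %d measures", len(cohort.phenotypes),
             len(cohort.measures))

    domains = None
    if cohort.truth is not None:
        domains = pd.Series({s["measure_id"]: s["domain"]
                             for s in cohort.truth["specs"]})

    rel = None
    if cohort.retest is not None and len(cohort.retest) >= 3:
        rel = her.reliability(cohort.phenotypes, cohort.retest)

    if "fingerprint" in config.stages:
        seed = _stage_seed(config.seed, "fingerprint")
        fp_report = {}
        if cohort.retest is not None and len(cohort.retest) >= 2:
            res = fp.identify_self(cohort, n_perm=config.n_perm_identification,
                                   seed=seed)
            res.to_tsv(out / "fingerprint_self_ranks.tsv")
            fp_report["self"] = res.summary()
        else:
            fp_report["self"] = None
            log.info("no retest data: self-identification skipped")
        res = fp.identify_twin(cohort, n_perm=config.n_perm_identification,
                               seed=seed + 1)
        res.to_tsv(out / "fingerprint_twin_ranks.tsv")
        fp_report["twin"] = res.summary()
        report["fingerprint"] = fp_report

    profiles: dict[str, her.HeritabilityProfile | ml.WeightProfile] = {}

    if "heritability" in config.stages:
        prof = her.falconer_profile(cohort, domains=domains, rel=rel)
        prof.to_tsv(out / "heritability_falconer.tsv")
        profiles["falconer"] = prof
        report["heritability"] = {"n_measures": len(prof.table),
                                  "models": prof.table["model"].value_counts().to_dict()}
        if rel is None:
            log.info("no retest data: disattenuation skipped")

    if "genecorr" in config.stages:
        gmat = gc.genetic_correlation_matrix(cohort)
        gmat.rho_G.to_csv(out / "rho_G.tsv", sep="\t")
        gmat.rho_E.to_csv(out / "rho_E.tsv", sep="\t")
        gmat.mask.to_csv(out / "rho_mask.tsv", sep="\t")
        gmat.to_long().to_csv(out / "rho_long.tsv", sep="\t", index=False)
        report["genecorr"] = {"n_defined": int(gmat.mask.to_numpy().sum()),
                              "n_clamped": len(gmat.clamped)}

    if "mlweights" in config.stages:
        pairset = build_pair_features(cohort)
        report["mlweights"] = _ml_stage(pairset, config, out, profiles, suffix="")

    if "factors" in config.stages:
        report["factors"] = _factor_stage(cohort, config, out)

    if "stats" in config.stages and len(profiles) >= 2:
        seed = _stage_seed(config.seed, "stats")
        values = {name: np.asarray(p.values if hasattr(p, "values") else p.mean)
                  for name, p in profiles.items()}
        spear = st.spearman_matrix(values)
        spear.to_csv(out / "spearman_profiles.tsv", sep="\t")
        stats_report = {"spearman": spear.to_dict()}
        if domains is not None:
            domain_tests = {}
            for name, vals in values.items():
                res = st.domain_permutation_test(
                    vals, domains.loc[cohort.measures].to_numpy(),
                    n_perm=config.n_perm_domain, seed=seed)
                domain_tests[name] = res.summary()
            k = len(domain_tests)
            for name, entry in domain_tests.items():
                entry["p_bonferroni"] = min(1.0, entry["p_value"] * k)
            stats_report["domain_tests"] = domain_tests
        report["stats"] = stats_report

    (out / "report.json").write_text(json.dumps(report, indent=1, default=str))
    return report


def _ml_stage(pairset: PairFeatureSet, config: PipelineConfig, out: Path,
              profiles: dict, suffix: str) -> dict:
    seed = _stage_seed(config.seed, f"mlweights{suffix}")
    cfg = ml.RunConfig(**{**asdict(config.ml), "seed": seed})
    stage: dict = {}
    uni = ml.univariate_weights(pairset)
    uni.to_tsv(out / f"weights_univariate{suffix}.tsv")
    profiles[f"univariate{suffix}" if suffix else "univariate"] = uni
    perf, ridge_w, alpha = ml.ridge_classify(pairset, cfg)
    ridge_w.to_tsv(out / f"weights_ridge{suffix}.tsv")
    profiles[f"ridge{suffix}" if suffix else "ridge"] = ridge_w
    stage["ridge"] = {**perf.summary(), "alpha": alpha}
    perf_rf, rf_w = ml.rf_classify(pairset, cfg)
    rf_w.to_tsv(out / f"weights_rf{suffix}.tsv")
    profiles[f"rf{suffix}" if suffix else "rf"] = rf_w
    stage["rf"] = perf_rf.summary()
    return stage


def _factor_stage(cohort: sd.Cohort, config: PipelineConfig, out: Path) -> dict:
    z = zscore(cohort.phenotypes)
    unrotated = fac.paf_extract(z.corr(), n_factors=config.n_factors)
    unrotated.eigen_table().to_csv(out / "factor_eigenvalues.tsv", sep="\t")
    stage: dict = {"n_factors": unrotated.n_factors,
                   "variance_explained": float(unrotated.variance_explained.sum())}
    if unrotated.n_factors == 0:
        return stage
    model = (fac.promax_rotate(unrotated) if unrotated.n_factors > 1 else unrotated)
    lam = model.loadings.copy()
    lam.index = z.columns
    lam.to_csv(out / "factor_loadings.tsv", sep="\t")
    model.display_loadings().to_csv(out / "factor_loadings_display.tsv", sep="\t")

    scores = {}
    for method in ("regression", "bartlett"):
        s = fac.factor_scores(z, model, method=method)
        s.to_csv(out / f"factor_scores_{method}.csv")
        scores[method] = s

    # factor-level heritability rerun on regression scores
    reg = zscore(scores["regression"])
    factor_profiles: dict = {}
    prof = her.falconer_profile(cohort, phenotypes=reg)
    prof.to_tsv(out / "heritability_falconer_factors.tsv")
    factor_profiles["falconer"] = prof
    pairset = build_pair_features(cohort, phenotypes=reg)
    stage["ml_factors"] = _ml_stage(pairset, config, out, factor_profiles,
                                    suffix="_factors")
    values = {n: np.asarray(p.values if hasattr(p, "values") else p.mean)
              for n, p in factor_profiles.items()}
    stage["spearman_factors"] = st.spearman_matrix(values).to_dict()

    # dual-score robustness: both score sets simultaneously as features
    both = pd.concat(
        [scores["regression"].add_suffix("_reg"),
         scores["bartlett"].add_suffix("_bart")], axis=1)
    pairset_dual = build_pair_features(cohort, phenotypes=zscore(both))
    dual_profiles: dict = {}
    stage["ml_dual_scores"] = _ml_stage(pairset_dual, config, out, dual_profiles,
                                        suffix="_dualscores")
    for name in ("ridge", "rf"):
        prof_d = dual_profiles[f"{name}_dualscores"]
        k = unrotated.n_factors
        reg_w = prof_d.mean.iloc[:k].to_numpy()
        bart_w = prof_d.mean.iloc[k:].to_numpy()
        stage[f"dual_{name}_weight_corr"] = float(np.corrcoef(reg_w, bart_w)[0, 1])
    return stage
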