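"""End-to-end assembly of the asymmetry-intelligence analysis.

Builds the hierarchical general-intelligence measurement model, regresses
g on global fluctuating-asymmetry scores (with nested equality-constraint
comparisons of effect sizes), contrasts P-FIT against non-P-FIT regions,
tests latent mediation of the childhood-SES -> g association by thickness
asymmetry, fits per-region association models, and computes default-prior
Bayes-factor correlations between extracted g factor scores and each
asymmetry variable.  ``run`` executes the whole suite on a synthetic or
file-based cohort and writes CSV mirrors of the result tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _version
from .atlas import RegionPartition, default_partition
from .asymmetry import (
    compare_methods,
    directional_ttests,
    fluctuating_asymmetry_equal,
    fluctuating_asymmetry_proportional,
    regional_summary,
    subset_scores,
)
from .bayes import DEFAULT_KAPPA, bf_correlation, factor_scores
from .cohort import CORTICAL_METRICS, Cohort, CohortConfig, default_config, generate_cohort
from .errors import NeuroasymError, ValidationError
from .io import PairedTable, pair_hemispheres, read_cognitive_csv, read_regional_csv, read_ses_csv
from .sem import ModelSpec, chisq_diff_test, fit, heywood_refit
from .sem.compare import ComparisonResult
from .sem.fit import FitResult

__all__ = [
    "COGNITIVE_TESTS",
    "DOMAINS",
    "PipelineConfig",
    "MediationResult",
    "build_g_model",
    "g_model_data",
    "fit_g_model",
    "global_asymmetry_model",
    "effect_size_difference",
    "pfit_model",
    "regional_association_models",
    "mediation_model",
    "wm_fa_model",
    "run",
]

DOMAINS = {
    "visuospatial": ["matrix_reasoning", "block_design", "spatial_span"],
    "crystallised": ["nart", "wtar", "verbal_fluency"],
    "verbal_memory": ["verbal_paired_associates", "logical_memory",
                      "digit_span_backwards"],
    "processing_speed": ["symbol_search", "digit_symbol", "inspection_time",
                         "four_choice_rt"],
}
COGNITIVE_TESTS = [t for tests in DOMAINS.values() for t in tests]
RESIDUAL_COVARIANCES = [("nart", "wtar"), ("verbal_paired_associates", "logical_memory")]
SES_INDICATORS = ["people_per_room", "toilet_type", "people_sharing_toilet",
                  "father_social_class"]


def build_g_model() -> ModelSpec:
    """Hierarchical model of general intelligence: 13 tests, 4 domains, g.

    The verbal-memory disturbance is fixed at zero (its estimate is
    inadmissibly negative when free: all verbal-memory variance is shared
    with g) and the two same-method test pairs get residual covariances.
    Latent (disturbance) variances are fixed at 1 for identification.
    """
    spec = ModelSpec(observed=list(COGNITIVE_TESTS),
                     latent=[*DOMAINS, "g"], name="g_hierarchical")
    for domain, tests in DOMAINS.items():
        for t in tests:
            spec.add_loading(domain, t)
        spec.add_loading("g", domain)
    for a, b in RESIDUAL_COVARIANCES:
        spec.add_covariance(a, b)
    spec.add_variance("g", free=False, value=1.0)
    for domain in DOMAINS:
        value = 0.0 if domain == "verbal_memory" else 1.0
        spec.add_variance(domain, free=False, value=value)
    return spec


def _zscore(s: pd.Series) -> pd.Series:
    sd = s.std(ddof=0)
    if not np.isfinite(sd) or sd == 0:
        raise ValidationError(f"cannot standardize constant column {s.name!r}")
    return (s - s.mean()) / sd


def g_model_data(cognitive: pd.DataFrame,
                 scores: dict[str, pd.Series] | None = None) -> pd.DataFrame:
    """Model frame: 13 tests plus z-scored asymmetry predictor columns.

    Asymmetry scores are standardized before entering the structural model
    so that equality constraints on their paths compare effect sizes rather
    than raw slopes on score-specific scales.
    """
    missing = [t for t in COGNITIVE_TESTS if t not in cognitive.columns]
    if missing:
        raise ValidationError(f"cognitive table lacks test column(s) {missing}")
    data = cognitive.set_index("participant_id")[COGNITIVE_TESTS].copy()
    for name, series in (scores or {}).items():
        data[name] = _zscore(series.reindex(data.index))
    return data


def fit_g_model(cognitive: pd.DataFrame, *, compute_se: bool = True) -> FitResult:
    """Fit the measurement model of g alone (no structural predictors)."""
    return fit(build_g_model(), g_model_data(cognitive), compute_se=compute_se)


def _structural_spec(predictors: list[str]) -> ModelSpec:
    spec = build_g_model()
    spec.observed.extend(predictors)
    for i, a in enumerate(predictors):
        spec.add_regression("g", a, label=f"b_{a}")
        for b in predictors[i + 1:]:
            spec.add_covariance(a, b)
    return spec


def global_asymmetry_model(cognitive: pd.DataFrame, scores: dict[str, pd.Series],
                           *, compute_se: bool = True
                           ) -> tuple[ModelSpec, FitResult]:
    """Regress g on the (freely correlated) global asymmetry scores."""
    names = [f"asym_{m}" for m in scores]
    spec = _structural_spec(names)
    data = g_model_data(cognitive, {f"asym_{m}": s for m, s in scores.items()})
    return spec, fit(spec, data, compute_se=compute_se)


def effect_size_difference(spec: ModelSpec, free_fit: FitResult,
                           data: pd.DataFrame, pair: tuple[str, str], *,
                           compute_se: bool = False) -> ComparisonResult:
    """Equate the g-paths of two predictors and test the loss of fit."""
    a, b = pair
    if a == b:
        raise ValidationError("cannot equate a structural path with itself")
    constrained = spec.equate([("path", "g", a), ("path", "g", b)],
                              label=f"b_eq_{a}_{b}")
    return chisq_diff_test(free_fit, fit(constrained, data, compute_se=compute_se))


def pfit_model(cognitive: pd.DataFrame, subset_score_map: dict[str, pd.Series],
               *, compute_se: bool = True
               ) -> tuple[FitResult, dict[str, ComparisonResult], pd.DataFrame]:
    """Six-predictor model (P-FIT and non-P-FIT per metric) plus contrasts.

    For each cortical metric an equality constraint on the P-FIT and
    non-P-FIT paths is tested against the free model.
    """
    names = list(subset_score_map)
    spec = _structural_spec(names)
    data = g_model_data(cognitive, subset_score_map)
    free_fit = fit(spec, data, compute_se=compute_se)
    comparisons = {}
    rows = []
    for metric in CORTICAL_METRICS:
        a, b = f"asym_{metric}_pfit", f"asym_{metric}_non_pfit"
        if a in names and b in names:
            comparisons[metric] = effect_size_difference(spec, free_fit, data, (a, b))
    for name in names:
        rows.append({"predictor": name,
                     "beta": free_fit.std_estimate("path", "g", name),
                     "se": free_fit.se("path", "g", name),
                     "p": float(free_fit._row("path", "g", name)["p"])})
    return free_fit, comparisons, pd.DataFrame(rows)


def regional_association_models(cognitive: pd.DataFrame, result, *,
                                regions: list[str] | None = None,
                                compute_se: bool = True) -> pd.DataFrame:
    """One structural model per region: its normalized absolute asymmetry -> g.

    ``result`` is an equal-method :class:`AsymmetryResult`; each region is
    fitted as a separate single-predictor model (a joint model over all
    regions would not be identified at cohort-scale n).
    """
    per_region = result.per_region
    use = regions or sorted(per_region["region"].unique())
    rows = []
    for region in use:
        sub = per_region[per_region["region"] == region]
        series = sub.set_index("participant_id")["normalized"]
        name = "regional_asym"
        spec = _structural_spec([name])
        data = g_model_data(cognitive, {name: series})
        res = fit(spec, data, compute_se=compute_se)
        row = res._row("path", "g", name)
        rows.append({"metric": result.metric, "region": region,
                     "beta": row["std_estimate"], "se": row["se"], "p": row["p"],
                     "n": int(series.notna().sum())})
    out = pd.DataFrame(rows)
    m = out["p"].notna().sum()
    out["p_bonferroni"] = np.minimum(out["p"] * m, 1.0)
    return out


@dataclass
class MediationResult:
    """Latent mediation of the SES -> g association by an asymmetry score."""

    a_std: float            # SES -> mediator
    b_std: float            # mediator -> g
    c_prime_std: float      # direct SES -> g
    indirect_std: float     # a * b
    total_std: float        # c' + a*b
    attenuation_pct: float  # 100 * (total - direct) / total
    indirect_raw: float
    indirect_se: float
    indirect_p: float
    fit: FitResult
    spec: ModelSpec


def _ses_block(spec: ModelSpec) -> ModelSpec:
    spec.observed.extend(SES_INDICATORS)
    spec.latent.append("ses")
    for ind in SES_INDICATORS:
        spec.add_loading("ses", ind)
    spec.add_covariance("toilet_type", "people_sharing_toilet")
    spec.add_variance("ses", free=False, value=1.0)
    return spec


def mediation_model(cognitive: pd.DataFrame, ses: pd.DataFrame,
                    mediator_scores: pd.Series, *,
                    mediator_name: str = "asym_thickness",
                    compute_se: bool = True) -> MediationResult:
    """SES -> thickness-asymmetry -> g mediation with delta-method inference.

    Inadmissible (negative) indicator residual variances are fixed at zero
    and the model refit before effects are computed.  The attenuation
    percentage compares the total standardized SES effect (direct plus
    indirect) with the direct path, on unrounded estimates.
    """
    spec = _ses_block(build_g_model())
    spec.observed.append(mediator_name)
    spec.add_regression(mediator_name, "ses", label="a_path")
    spec.add_regression("g", mediator_name, label="b_path")
    spec.add_regression("g", "ses", label="c_prime")
    data = g_model_data(cognitive, {mediator_name: mediator_scores})
    ses_idx = ses.set_index("participant_id")[SES_INDICATORS]
    data = data.join(ses_idx, how="left")
    result = fit(spec, data, compute_se=compute_se)
    spec, result = heywood_refit(spec, result, data, compute_se=compute_se)

    a = result.estimate("path", mediator_name, "ses")
    b = result.estimate("path", "g", mediator_name)
    a_std = result.std_estimate("path", mediator_name, "ses")
    b_std = result.std_estimate("path", "g", mediator_name)
    c_std = result.std_estimate("path", "g", "ses")
    indirect_raw = a * b
    se = p = float("nan")
    if result.vcov is not None:
        ia = result.labels.index("a_path")
        ib = result.labels.index("b_path")
        var = (b ** 2 * result.vcov[ia, ia] + a ** 2 * result.vcov[ib, ib]
               + 2 * a * b * result.vcov[ia, ib])
        if var > 0:
            from scipy.stats import norm
            se = float(np.sqrt(var))
            p = float(2 * norm.sf(abs(indirect_raw) / se))
    indirect_std = a_std * b_std
    total = c_std + indirect_std
    atten = 100.0 * indirect_std / total if total != 0 else float("nan")
    return MediationResult(a_std=a_std, b_std=b_std, c_prime_std=c_std,
                           indirect_std=indirect_std, total_std=total,
                           attenuation_pct=atten, indirect_raw=indirect_raw,
                           indirect_se=se, indirect_p=p, fit=result, spec=spec)


def wm_fa_model(cognitive: pd.DataFrame, fa_scores: pd.Series, *,
                compute_se: bool = True) -> tuple[ModelSpec, FitResult]:
    """Global white-matter fractional-anisotropy asymmetry -> g."""
    return global_asymmetry_model(cognitive, {"fa": fa_scores},
                                  compute_se=compute_se)


# ---------------------------------------------------------------------------
# pipeline driver


@dataclass
class PipelineConfig:
    """What to run and where to write it."""

    outdir: str | Path = "neuroasym_report"
    simulate: bool = True
    cohort: CohortConfig = field(default_factory=default_config)
    input_dir: str | Path | None = None   # expects regional_<metric>.csv etc.
    metrics: tuple = CORTICAL_METRICS
    methods: tuple = ("equal", "proportional")
    include_regional: bool = True
    include_mediation: bool = True
    include_wm: bool = True
    include_bayes: bool = True
    kappa: float = DEFAULT_KAPPA
    compute_se: bool = True

    def validate(self) -> None:
        if not self.metrics or not self.methods:
            raise ValidationError("select at least one metric and one method")
        unknown = set(self.methods) - {"equal", "proportional"}
        if unknown:
            raise ValidationError(f"unknown method(s) {sorted(unknown)}")


def _load_tables(config: PipelineConfig) -> Cohort:
    if config.simulate:
        return generate_cohort(config.cohort)
    base = Path(config.input_dir or ".")
    regional = {}
    for metric in (*config.metrics, *(["fa"] if config.include_wm else [])):
        path = base / f"regional_{metric}.csv"
        if not path.exists():
            raise ValidationError(f"missing regional table {path}")
        regional[metric] = read_regional_csv(path, metric)
    cog_path = base / "cognitive.csv"
    if not cog_path.exists():
        raise ValidationError(f"missing cognitive table {cog_path}")
    cognitive = read_cognitive_csv(cog_path)
    ses_path = base / "ses.csv"
    ses = read_ses_csv(ses_path) if ses_path.exists() else pd.DataFrame()
    return Cohort(config=config.cohort, regional=regional, cognitive=cognitive,
                  ses=ses, truth={})


def run(config: PipelineConfig | None = None) -> dict:
    """Execute simulate -> asymmetry -> models -> bayes -> report.

    Returns the report bundle (dict of DataFrames/objects) and writes CSV
    mirrors plus a YAML run manifest to ``config.outdir``.  Any stage error
    is re-raised with the stage name prefixed.
    """
    config = config or PipelineConfig()
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    partition = default_partition()
    bundle: dict = {}

    def stage(name):
        def wrap(fn, *args, **kw):
            try:
                return fn(*args, **kw)
            except NeuroasymError as exc:
                raise type(exc)(f"[stage: {name}] {exc}") from exc
        return wrap

    cohort = stage("load")(_load_tables, config)
    cognitive = cohort.cognitive

    paired = {m: pair_hemispheres(t, partition) for m, t in cohort.regional.items()}
    equal, proportional = {}, {}
    for m in config.metrics:
        equal[m] = stage("asymmetry")(fluctuating_asymmetry_equal, paired[m])
        if "proportional" in config.methods:
            proportional[m] = stage("asymmetry")(
                fluctuating_asymmetry_proportional, paired[m])
    if config.include_wm and "fa" in paired:
        equal["fa"] = stage("asymmetry")(fluctuating_asymmetry_equal, paired["fa"])

    ttest_frames = []
    summary_frames = []
    for m, res in equal.items():
        ttest_frames.append(stage("directional")(directional_ttests, paired[m])
                            .assign(metric=m))
        summary_frames.append(regional_summary(res).assign(metric=m))
    bundle["directional_ttests"] = pd.concat(ttest_frames, ignore_index=True)
    bundle["regional_asymmetry_summary"] = pd.concat(summary_frames, ignore_index=True)

    if "proportional" in config.methods and "equal" in config.methods:
        comp_rows = [compare_methods(equal[m], proportional[m]).__dict__
                     for m in config.metrics]
        bundle["method_comparison"] = pd.DataFrame(comp_rows)

    # global structural model and effect-size contrasts
    scores_equal = {m: equal[m].scores for m in config.metrics}
    spec, free_fit = stage("global_model")(
        global_asymmetry_model, cognitive, scores_equal, compute_se=config.compute_se)
    bundle["global_fit"] = free_fit
    data = g_model_data(cognitive, {f"asym_{m}": s for m, s in scores_equal.items()})
    t2 = [{"model": "i", "constraints": "none", "chisq": free_fit.chisq,
           "df": free_fit.df, "aic": free_fit.aic, "bic": free_fit.bic,
           "comparison": "", "d_chisq": np.nan, "d_df": np.nan, "p": np.nan}]
    pairs = [("ii", "asym_thickness", "asym_surface_area"),
             ("iii", "asym_thickness", "asym_volume")]
    for label, a, b in pairs:
        if a in data.columns and b in data.columns:
            cmp_ = stage("effect_size")(effect_size_difference, spec, free_fit,
                                        data, (a, b))
            t2.append({"model": label, "constraints": f"{a}={b}",
                       "chisq": cmp_.chisq_constrained, "df": cmp_.df_constrained,
                       "aic": cmp_.aic_constrained, "bic": cmp_.bic_constrained,
                       "comparison": "i", "d_chisq": cmp_.d_chisq,
                       "d_df": cmp_.d_df, "p": round(cmp_.p, 3)})
    bundle["effect_size_tests"] = pd.DataFrame(t2)

    if "proportional" in config.methods:
        _, prop_fit = stage("global_model")(
            global_asymmetry_model, cognitive,
            {m: proportional[m].scores for m in config.metrics},
            compute_se=config.compute_se)
        bundle["global_fit_proportional"] = prop_fit

    # P-FIT versus non-P-FIT
    subset_map = {}
    for m in config.metrics:
        for subset in ("pfit", "non_pfit"):
            res = stage("pfit")(subset_scores, paired[m], partition, subset, "equal")
            subset_map[f"asym_{m}_{subset}"] = res.scores
    pf_fit, pf_cmp, pf_table = stage("pfit")(
        pfit_model, cognitive, subset_map, compute_se=config.compute_se)
    bundle["pfit_fit"] = pf_fit
    bundle["pfit_paths"] = pf_table
    t4 = [{"model": "A", "constraints": "none", "chisq": pf_fit.chisq,
           "df": pf_fit.df, "aic": pf_fit.aic, "bic": pf_fit.bic,
           "comparison": "", "d_chisq": np.nan, "d_df": np.nan, "p": np.nan}]
    for label, metric in zip("BCD", CORTICAL_METRICS):
        if metric in pf_cmp:
            c = pf_cmp[metric]
            t4.append({"model": label,
                       "constraints": f"pfit={metric}=non_pfit",
                       "chisq": c.chisq_constrained, "df": c.df_constrained,
                       "aic": c.aic_constrained, "bic": c.bic_constrained,
                       "comparison": "A", "d_chisq": c.d_chisq,
                       "d_df": c.d_df, "p": round(c.p, 3)})
    bundle["pfit_tests"] = pd.DataFrame(t4)

    if config.include_regional:
        frames = [stage("regional")(regional_association_models, cognitive,
                                    equal[m], compute_se=config.compute_se)
                  for m in equal]
        bundle["regional_associations"] = pd.concat(frames, ignore_index=True)

    if config.include_mediation and len(cohort.ses):
        med = stage("mediation")(mediation_model, cognitive, cohort.ses,
                                 scores_equal.get("thickness"),
                                 compute_se=config.compute_se)
        bundle["mediation"] = med

    if config.include_wm and "fa" in equal:
        _, fa_fit = stage("wm_fa")(wm_fa_model, cognitive, equal["fa"].scores,
                                   compute_se=config.compute_se)
        bundle["wm_fa_fit"] = fa_fit

    if config.include_bayes:
        g_fit = stage("bayes")(fit_g_model, cognitive, compute_se=False)
        gs = factor_scores(g_fit, g_model_data(cognitive))
        rows = []
        against = {f"{m}_equal": equal[m].scores for m in equal}
        against.update({f"{m}_proportional": proportional[m].scores
                        for m in proportional})
        for name, s in against.items():
            aligned = s.reindex(g_model_data(cognitive).index)
            bf = stage("bayes")(bf_correlation, gs.to_numpy(),
                                aligned.to_numpy(), config.kappa)
            rows.append({"variable": name, "r": bf.r, "bf10": bf.bf10,
                         "bf01": bf.bf01, "n": bf.n, "kappa": bf.kappa})
        bundle["bayes_correlations"] = pd.DataFrame(rows)
        bundle["g_scores"] = gs

    # report files
    for key in ("directional_ttests", "regional_asymmetry_summary",
                "method_comparison", "effect_size_tests", "pfit_paths",
                "pfit_tests", "regional_associations", "bayes_correlations"):
        if key in bundle:
            bundle[key].to_csv(outdir / f"{key}.csv", index=False)
    if "global_fit" in bundle:
        bundle["global_fit"].to_csv(outdir / "global_model_parameters.csv")
    manifest = {
        "package_version": _version,
        "seed": config.cohort.seed if config.simulate else None,
        "n_participants": int(len(cognitive)),
        "metrics": list(config.metrics),
        "methods": list(config.methods),
        "kappa": config.kappa,
        "score_standardization": "z-scored asymmetry predictors",
        "identification": "latent variances fixed at 1",
        "chisq_convention": "likelihood ratio vs saturated (FIML)",
    }
    (outdir / "run_manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=False))
    bundle["manifest"] = manifest
    return bundle
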