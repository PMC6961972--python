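"""Nested-model comparisons, Heywood handling and measurement invariance."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy import stats

from ..errors import ModelError
from .fit import FitResult, fit
from .model import ModelSpec, Parameter

__all__ = ["ComparisonResult", "nested_p", "chisq_diff_test",
           "heywood_refit", "invariance_test"]


@dataclass(frozen=True)
class ComparisonResult:
    """Likelihood-ratio contrast of a constrained model against a free one."""

    d_chisq: float
    d_df: int
    p: float
    chisq_free: float
    df_free: int
    chisq_constrained: float
    df_constrained: int
    aic_free: float
    aic_constrained: float
    bic_free: float
    bic_constrained: float
    preferred: str  # 'free' | 'constrained' by AIC

    def as_row(self) -> dict:
        return {
            "d_chisq": self.d_chisq, "d_df": self.d_df, "p": self.p,
            "chisq_free": self.chisq_free, "df_free": self.df_free,
            "chisq_constrained": self.chisq_constrained,
            "df_constrained": self.df_constrained,
            "aic_free": self.aic_free, "aic_constrained": self.aic_constrained,
            "bic_free": self.bic_free, "bic_constrained": self.bic_constrained,
            "preferred": self.preferred,
        }


def nested_p(d_chisq: float, d_df: int) -> float:
    """Upper-tail chi-square probability of a nested-model difference."""
    if d_df <= 0:
        raise ModelError(f"difference test needs d_df > 0, got {d_df}")
    if d_chisq < 0:
        raise ValueError("d_chisq must be non-negative")
    return float(stats.chi2.sf(d_chisq, d_df))


def chisq_diff_test(free: FitResult, constrained: FitResult) -> ComparisonResult:
    """Chi-square difference test of two nested fits on the same data."""
    d_df = constrained.df - free.df
    if d_df <= 0:
        raise ModelError(
            f"constrained model must have more df than the free one "
            f"(got {constrained.df} vs {free.df})"
        )
    if constrained.n != free.n:
        raise ModelError("difference test requires the same data in both fits")
    d_chisq = constrained.chisq - free.chisq
    if d_chisq < -1e-6:
        raise ModelError(
            f"constrained chi-square is smaller than the free one by {-d_chisq:.3g}; "
            "models are not properly nested or a fit is at a local optimum"
        )
    d_chisq = max(d_chisq, 0.0)
    return ComparisonResult(
        d_chisq=d_chisq, d_df=d_df, p=nested_p(d_chisq, d_df),
        chisq_free=free.chisq, df_free=free.df,
        chisq_constrained=constrained.chisq, df_constrained=constrained.df,
        aic_free=free.aic, aic_constrained=constrained.aic,
        bic_free=free.bic, bic_constrained=constrained.bic,
        preferred="free" if free.aic <= constrained.aic else "constrained",
    )


def heywood_refit(spec: ModelSpec, result: FitResult, data: pd.DataFrame, *,
                  compute_se: bool = True) -> tuple[ModelSpec, FitResult]:
    """Fix negative (Heywood) variance estimates at zero and refit.

    The most negative estimated variance is fixed at zero and the model
    refit, iterating until all variance estimates are admissible.  If more
    than half of the free variances end up on the boundary the model is
    treated as misspecified.
    """
    n_free_vars = sum(1 for p in result.spec.params if p.kind == "var" and p.free)
    fixed = 0
    while result.heywood:
        label, _ = min(result.heywood, key=lambda t: t[1])
        row = result.params[(result.params["label"] == label)
                            & (result.params["kind"] == "var")].iloc[0]
        group = row["group"] if pd.notna(row["group"]) else None
        # operate on the completed spec the fit actually used, so implicitly
        # added residual variances can be fixed too
        spec = result.spec.fix_parameter("var", row["target"], None, 0.0, group=group)
        fixed += 1
        if n_free_vars and fixed > n_free_vars / 2:
            raise ModelError(
                f"{fixed} of {n_free_vars} free variances hit the boundary; "
                "the model appears misspecified"
            )
        result = fit(spec, data, compute_se=compute_se)
    return spec, result


def _multigroup_spec(base: ModelSpec, groups: list, group_var: str,
                     share_measurement: bool, name: str) -> ModelSpec:
    base = base.complete()
    obs, lat = set(base.observed), set(base.latent)
    out = ModelSpec(observed=list(base.observed), latent=list(base.latent),
                    group_var=group_var, name=name)
    for prm in base.params:
        is_loading = prm.kind == "path" and prm.source in lat and prm.target in obs
        is_obs_mean = prm.kind == "mean" and prm.target in obs
        is_lat_var = prm.kind == "var" and prm.target in lat
        if share_measurement and (is_loading or is_obs_mean):
            out._add(Parameter(prm.kind, prm.target, prm.source, prm.free,
                               prm.value, prm.label, group=None))
        elif share_measurement and is_lat_var:
            # the reference group anchors the latent scale; later groups get
            # free latent variances so only measurement parameters are equated
            out._add(Parameter("var", prm.target, None, False, 1.0, None,
                               group=groups[0]))
            for g in groups[1:]:
                out._add(Parameter("var", prm.target, None, True, 1.0, None,
                                   group=g))
        else:
            for g in groups:
                out._add(Parameter(prm.kind, prm.target, prm.source, prm.free,
                                   prm.value, None, group=g))
    if share_measurement:
        for v in base.latent:
            for g in groups[1:]:
                out._add(Parameter("mean", v, None, True, 0.0, None, group=g))
    return out


def invariance_test(spec: ModelSpec, data: pd.DataFrame, group: str,
                    level: str = "strong", *, compute_se: bool = False
                    ) -> ComparisonResult:
    """Compare configural against strong (loadings + intercepts) invariance.

    ``spec`` is a single-group measurement model; it is expanded into a
    multigroup model in which either every measurement parameter is free per
    group (configural) or loadings and intercepts are equated across groups
    with free latent variances and means in the non-reference groups
    (strong).  Returns the chi-square difference test of strong against
    configural.
    """
    if level not in ("configural", "strong"):
        raise ValueError("level must be 'configural' or 'strong'")
    if group not in data.columns:
        raise ModelError(f"grouping column {group!r} not in data")
    groups = sorted(data[group].dropna().unique().tolist())
    if len(groups) < 2:
        raise ModelError("invariance testing needs at least two groups")
    configural = _multigroup_spec(spec, groups, group, False, f"{spec.name}_configural")
    fit_conf = fit(configural, data, compute_se=compute_se)
    if level == "configural":
        # degenerate request: contrast configural with itself is undefined;
        # return the configural fit packaged against the strong model anyway
        raise ValueError("invariance_test compares strong against configural; "
                         "use level='strong'")
    strong = _multigroup_spec(spec, groups, group, True, f"{spec.name}_strong")
    fit_strong = fit(strong, data, compute_se=compute_se)
    return chisq_diff_test(fit_conf, fit_strong)
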