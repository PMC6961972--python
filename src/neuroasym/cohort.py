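"""Synthetic cohorts with the generative structure the analysis assumes.

The generator emulates the derived data of a single-wave ageing-cohort
study: per-participant left/right values for 34 paired cortical regions
(surface area, volume, thickness) and 5 paired white-matter tracts
(fractional anisotropy), a 13-test cognitive battery with a hierarchical
four-domain general-intelligence structure, and four childhood
socioeconomic-status indicators loading on one latent factor.

Generative model
----------------
* A participant-level developmental-instability factor D ~ N(0, 1) scales
  the magnitude of every regional fluctuating deviation through
  exp(instability_loading * D), so one latent quantity couples the
  absolute asymmetries of all regions and metrics.
* Region r of metric m:  L = size + (d + delta)/2, R = size - (d + delta)/2,
  where d is the region's directional-asymmetry mean and
  delta ~ N(0, (fa_sd_scale * size)^2) * exp(instability_loading * D).
* The latent g is built from the realized equal-contribution asymmetry
  scores (z-scored in sample) with the configured standardized structural
  coefficients, plus a childhood-SES path, plus an independent disturbance
  scaled so that g has unit sample variance.  Cognitive tests follow the
  hierarchical factor model (4 domains, fixed residual covariances for the
  two reading tests and the two verbal-recall tests) and are rescaled to
  published-battery means and SDs.  All tests are generated already
  oriented so that higher means better.
* Missingness is completely at random, per cell, on the cognitive and SES
  columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace, asdict
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .atlas import atlas_table, tract_table, default_partition
from .asymmetry import fluctuating_asymmetry_equal
from .errors import ValidationError
from .io import PairedTable, RegionalMetricTable

__all__ = ["CohortConfig", "Cohort", "default_config", "generate_cohort"]

CORTICAL_METRICS = ("surface_area", "volume", "thickness")


def _load_tests() -> pd.DataFrame:
    with resources.files("neuroasym.data").joinpath("cognitive_tests.csv").open("r") as fh:
        return pd.read_csv(fh)


@dataclass
class CohortConfig:
    """All generative parameters of a synthetic cohort.

    Standardized structural coefficients must lie strictly inside (-1, 1);
    the structural disturbance of g must keep positive variance after the
    configured paths are accounted for.
    """

    n_participants: int = 636
    seed: int = 2020
    # per-region per-hemisphere mean values; None = shipped atlas defaults
    region_sizes: dict | None = None
    # per-region directional asymmetry means (units of the metric);
    # None = atlas default fractions times region size
    directional_asymmetry_means: dict | None = None
    # scale of fluctuating deviations as a fraction of region size;
    # scalar or {region: scale}
    fa_sd_scale: float | dict = 0.04
    # loading of the latent instability factor on deviation magnitudes;
    # the default yields inter-metric asymmetry-score correlations near 0.3
    instability_loading: float = 0.08
    # standardized paths from equal-method asymmetry scores to g
    g_structural_paths: dict = field(default_factory=lambda: {
        "surface_area": -0.03, "volume": 0.07, "thickness": -0.18, "fa": 0.0,
    })
    # 13 test loadings on their domains (None = shipped defaults)
    domain_loadings: dict | None = None
    # domain loadings on g
    g_loadings: dict = field(default_factory=lambda: {
        "visuospatial": 0.78, "crystallised": 0.72,
        "verbal_memory": 1.0, "processing_speed": 0.68,
    })
    # residual covariances between similar tests (standardized scale)
    residual_covariances: dict = field(default_factory=lambda: {
        ("nart", "wtar"): 0.15,
        ("verbal_paired_associates", "logical_memory"): 0.12,
    })
    ses_loadings: dict = field(default_factory=lambda: {
        "people_per_room": 1.0, "toilet_type": 0.75,
        "people_sharing_toilet": 0.70, "father_social_class": 0.68,
    })
    ses_residual_covariance: float = 0.10  # toilet_type ~~ people_sharing_toilet
    ses_g_path: float = -0.29
    # mixes the SES factor into the instability factor (0 = no coupling)
    ses_instability_coupling: float = 0.0
    missing_rate: float = 0.02
    regional_missing_rate: float = 0.0
    # optional per-sex measurement shifts for invariance experiments:
    # {"loading": {test: delta}, "intercept": {test: delta}} applied to F
    group_offsets: dict | None = None

    def validate(self) -> None:
        if self.n_participants < 10:
            raise ValidationError("n_participants must be >= 10")
        if not (0 <= self.missing_rate < 1) or not (0 <= self.regional_missing_rate < 1):
            raise ValidationError("missing rates must lie in [0, 1)")
        for k, v in self.g_structural_paths.items():
            if not np.isfinite(v) or abs(v) >= 1:
                raise ValidationError(f"structural path {k}={v} must lie in (-1, 1)")
        if abs(self.ses_g_path) >= 1:
            raise ValidationError("ses_g_path must lie in (-1, 1)")
        if not -1 < self.ses_instability_coupling < 1:
            raise ValidationError("ses_instability_coupling must lie in (-1, 1)")
        for k, v in self.g_loadings.items():
            if not np.isfinite(v) or not 0 < v <= 1:
                raise ValidationError(f"g loading {k}={v} must lie in (0, 1]")
        scales = (self.fa_sd_scale.values() if isinstance(self.fa_sd_scale, dict)
                  else [self.fa_sd_scale])
        if any(s <= 0 for s in scales):
            raise ValidationError("fa_sd_scale must be positive")

    def to_yaml(self, path: str | Path | None = None) -> str:
        d = asdict(self)
        d["residual_covariances"] = {f"{a}|{b}": v for (a, b), v
                                     in self.residual_covariances.items()}
        text = yaml.safe_dump(d, sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "CohortConfig":
        text = str(source)
        if "\n" not in text and Path(text).exists():
            text = Path(text).read_text()
        d = yaml.safe_load(text)
        if "residual_covariances" in d:
            d["residual_covariances"] = {tuple(k.split("|")): v for k, v
                                         in d["residual_covariances"].items()}
        return cls(**d)


@dataclass
class Cohort:
    """Generated tables plus the generating latent quantities (for tests)."""

    config: CohortConfig
    regional: dict          # metric -> RegionalMetricTable
    cognitive: pd.DataFrame
    ses: pd.DataFrame
    truth: dict             # g, instability, ses_factor, asymmetry scores

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for metric, table in self.regional.items():
            table.data.to_csv(outdir / f"regional_{metric}.csv", index=False)
        self.cognitive.to_csv(outdir / "cognitive.csv", index=False)
        self.ses.to_csv(outdir / "ses.csv", index=False)


def default_config(**overrides) -> CohortConfig:
    """The documented default cohort: n = 636, thickness path -0.18."""
    cfg = CohortConfig(**overrides)
    cfg.validate()
    return cfg


def _region_table(config: CohortConfig):
    atlas = atlas_table().set_index("region")
    tracts = tract_table().set_index("tract")
    sizes: dict = {m: {} for m in (*CORTICAL_METRICS, "fa")}
    da: dict = {m: {} for m in (*CORTICAL_METRICS, "fa")}
    for region, row in atlas.iterrows():
        sa = row["total_surface_area_mm2"] / 2.0  # per hemisphere
        th = row["mean_thickness_mm"]
        sizes["surface_area"][region] = sa
        sizes["thickness"][region] = th
        sizes["volume"][region] = sa * th
        da["surface_area"][region] = row["da_frac_surface_area"] * sa
        da["volume"][region] = row["da_frac_volume"] * sa * th
        da["thickness"][region] = row["da_frac_thickness"] * th
    for tract, row in tracts.iterrows():
        sizes["fa"][tract] = row["mean_fa"]
        da["fa"][tract] = row["da_frac_fa"] * row["mean_fa"]
    if config.region_sizes:
        for m, d in config.region_sizes.items():
            sizes[m].update(d)
    if config.directional_asymmetry_means:
        for m, d in config.directional_asymmetry_means.items():
            da[m].update(d)
    return sizes, da


def _sd_scale(config: CohortConfig, region: str) -> float:
    if isinstance(config.fa_sd_scale, dict):
        return float(config.fa_sd_scale.get(region, 0.04))
    return float(config.fa_sd_scale)


def generate_cohort(config: CohortConfig | None = None) -> Cohort:
    """Deterministically generate one cohort from ``config`` (seed included)."""
    config = config or default_config()
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_participants
    ids = np.array([f"p{i:04d}" for i in range(1, n + 1)])
    n_m = int(round(n * 336 / 636))
    sex = np.array(["M"] * n_m + ["F"] * (n - n_m))

    w = config.ses_instability_coupling
    ses_factor = rng.standard_normal(n)
    instability = np.sqrt(1 - w ** 2) * rng.standard_normal(n) + w * ses_factor
    magnitude = np.exp(config.instability_loading * instability)

    sizes, da = _region_table(config)
    regional: dict = {}
    paired_frames: dict = {}
    for metric in (*CORTICAL_METRICS, "fa"):
        regions = list(sizes[metric])
        size = np.array([sizes[metric][r] for r in regions])
        dmean = np.array([da[metric][r] for r in regions])
        sd = np.array([_sd_scale(config, r) for r in regions]) * size
        delta = rng.standard_normal((n, len(regions))) * sd * magnitude[:, None]
        total_da = dmean[None, :] + delta
        L = size[None, :] + total_da / 2.0
        R = size[None, :] - total_da / 2.0
        if (L <= 0).any() or (R <= 0).any():
            raise ValidationError(
                f"negative {metric} value generated; reduce fa_sd_scale or "
                "instability_loading"
            )
        paired = pd.DataFrame({
            "participant_id": np.repeat(ids, len(regions)),
            "region": np.tile(regions, n),
            "L": L.ravel(),
            "R": R.ravel(),
        })
        paired_frames[metric] = paired
        long = pd.concat([
            paired.melt(id_vars=["participant_id", "region"],
                        value_vars=["L", "R"], var_name="hemisphere",
                        value_name="value")
        ], ignore_index=True).sort_values(
            ["participant_id", "region", "hemisphere"]).reset_index(drop=True)
        if config.regional_missing_rate > 0:
            keep = rng.random(len(long)) >= config.regional_missing_rate
            long = long[keep].reset_index(drop=True)
        regional[metric] = RegionalMetricTable(metric=metric, data=long)

    # realized equal-contribution asymmetry scores drive g
    scores = {}
    for metric in (*CORTICAL_METRICS, "fa"):
        res = fluctuating_asymmetry_equal(
            PairedTable(metric=metric, data=paired_frames[metric]))
        scores[metric] = res.scores.reindex(ids).to_numpy()

    z = {m: (s - s.mean()) / s.std(ddof=0) for m, s in scores.items()}
    predictors = []
    coefs = []
    for m, beta in config.g_structural_paths.items():
        if beta != 0.0:
            predictors.append(z[m])
            coefs.append(beta)
    predictors.append(ses_factor)
    coefs.append(config.ses_g_path)
    P = np.column_stack(predictors)
    c = np.array(coefs)
    explained = float(c @ np.cov(P.T, bias=True) @ c) if len(c) > 1 else float(
        c[0] ** 2 * P.var(ddof=0))
    psi = 1.0 - explained
    if psi <= 0.02:
        raise ValidationError(
            f"structural paths leave non-positive g disturbance ({psi:.3f})"
        )
    g = P @ c + np.sqrt(psi) * rng.standard_normal(n)

    tests = _load_tests()
    if config.domain_loadings:
        tests = tests.copy()
        tests["domain_loading"] = [
            config.domain_loadings.get(t, l)
            for t, l in zip(tests["test"], tests["domain_loading"])
        ]
    domains = {}
    for d, gamma in config.g_loadings.items():
        psi_d = max(1.0 - gamma ** 2, 0.0)
        domains[d] = gamma * g + np.sqrt(psi_d) * rng.standard_normal(n)

    # unique parts, with the configured residual covariances among pairs
    resid = {}
    rescov = dict(config.residual_covariances)
    covered = {t for pair in rescov for t in pair}
    for (a, b), cv in rescov.items():
        ra = tests.loc[tests["test"] == a, "domain_loading"].iloc[0]
        rb = tests.loc[tests["test"] == b, "domain_loading"].iloc[0]
        va, vb = 1 - ra ** 2, 1 - rb ** 2
        if cv ** 2 >= va * vb:
            raise ValidationError(f"residual covariance {a}~{b} too large")
        cov = np.array([[va, cv], [cv, vb]])
        e = rng.multivariate_normal([0, 0], cov, size=n)
        resid[a], resid[b] = e[:, 0], e[:, 1]
    cognitive = pd.DataFrame({"participant_id": ids, "sex": sex})
    female = sex == "F"
    offsets = config.group_offsets or {}
    for _, row in tests.iterrows():
        t, d, lam = row["test"], row["domain"], row["domain_loading"]
        lam_vec = np.full(n, lam)
        lam_vec[female] += offsets.get("loading", {}).get(t, 0.0)
        if t in covered:
            e = resid[t]
        else:
            e = np.sqrt(max(1 - lam ** 2, 1e-6)) * rng.standard_normal(n)
        y = lam_vec * domains[d] + e
        y[female] += offsets.get("intercept", {}).get(t, 0.0)
        cognitive[t] = row["mean"] + row["sd"] * y

    # SES indicators (factor oriented so that higher = more deprived)
    ses = pd.DataFrame({"participant_id": ids})
    ses_specs = {
        "people_per_room": ("linear", 1.5, 0.55),
        "toilet_type": ("ordinal3", 0.0, 1.0),
        "people_sharing_toilet": ("linear", 4.0, 2.0),
        "father_social_class": ("ordinal5", 3.0, 1.1),
    }
    lt, ls = config.ses_loadings["toilet_type"], config.ses_loadings["people_sharing_toilet"]
    vt, vs = 1 - lt ** 2, 1 - ls ** 2
    cv = config.ses_residual_covariance
    if cv ** 2 >= vt * vs:
        raise ValidationError("ses_residual_covariance too large")
    e_pair = rng.multivariate_normal([0, 0], [[vt, cv], [cv, vs]], size=n)
    ses_resid = {"toilet_type": e_pair[:, 0], "people_sharing_toilet": e_pair[:, 1]}
    for ind, (kind, loc, scale) in ses_specs.items():
        lam = config.ses_loadings[ind]
        if ind in ses_resid:
            e = ses_resid[ind]
        else:
            e = np.sqrt(max(1 - lam ** 2, 0.0)) * rng.standard_normal(n)
        x = lam * ses_factor + e
        if kind == "linear":
            ses[ind] = loc + scale * x
        elif kind == "ordinal3":
            ses[ind] = np.digitize(x, [-0.75, 0.75]).astype(int)
        else:  # ordinal5, 1 = professional .. 5 = unskilled
            ses[ind] = np.clip(np.round(loc + scale * x), 1, 5).astype(int)

    if config.missing_rate > 0:
        test_cols = list(tests["test"])
        mask = rng.random((n, len(test_cols))) < config.missing_rate
        cognitive[test_cols] = cognitive[test_cols].mask(mask)
        ses_cols = list(ses_specs)
        mask = rng.random((n, len(ses_cols))) < config.missing_rate
        ses[ses_cols] = ses[ses_cols].mask(mask)

    truth = {"g": pd.Series(g, index=ids, name="g"),
             "instability": pd.Series(instability, index=ids),
             "ses_factor": pd.Series(ses_factor, index=ids),
             "asymmetry_scores": {m: pd.Series(s, index=ids) for m, s in scores.items()}}
    return Cohort(config=config, regional=regional, cognitive=cognitive,
                  ses=ses, truth=truth)
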