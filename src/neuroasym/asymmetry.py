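"""Directional and fluctuating asymmetry of paired regional measures.

For a bilateral region, directional asymmetry is the signed left-minus-right
difference; its sample mean is the population-level directional component.
Fluctuating asymmetry is the participant's absolute deviation from that
sample mean, a proposed marker of developmental instability.  Two weighting
schemes are provided:

equal contribution
    Per region: DA = L - R; center on the sample mean DA of that region;
    take the absolute value; divide by the participant's bilateral mean
    (L + R)/2 for that region.  The participant's score is the mean of these
    normalized values over the regions available to them, so each region
    counts the same regardless of its size.

proportional contribution
    Per participant: hemispheric totals are summed over regions first
    (total_L - total_R), centered on the sample mean of that difference,
    the absolute value taken, and divided by the participant's bilateral
    mean total.  Large regions dominate in proportion to their size.

The proportional scheme is stated in the source analyses only up to the
subtraction of totals; the centering/absolute/normalization tail mirrors the
equal scheme so that both yield non-negative, dimensionless fluctuating
measures that can be correlated with each other.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .atlas import RegionPartition, default_partition
from .errors import DegenerateInputError, InsufficientSampleError
from .io import PairedTable

__all__ = [
    "AsymmetryResult",
    "MethodComparison",
    "fluctuating_asymmetry_equal",
    "fluctuating_asymmetry_proportional",
    "subset_scores",
    "regional_summary",
    "directional_ttests",
    "compare_methods",
]


@dataclass
class AsymmetryResult:
    """Per-region intermediates and per-participant fluctuating-asymmetry scores.

    ``per_region`` carries the audit trail of every computation step; for the
    proportional method it instead holds per-participant hemispheric totals.
    ``scores`` is indexed by participant_id.
    """

    metric: str
    method: str  # 'equal' | 'proportional'
    subset: str  # 'all' | 'pfit' | 'non_pfit'
    per_region: pd.DataFrame
    scores: pd.Series
    regions_used: tuple[str, ...]
    dropped_regions: tuple[str, ...] = ()

    @property
    def n_participants(self) -> int:
        return len(self.scores)


@dataclass(frozen=True)
class MethodComparison:
    """Pearson agreement between equal- and proportional-method scores."""

    metric: str
    r: float
    p: float
    n: int


def _prepare(paired: PairedTable, regions: tuple[str, ...] | None) -> pd.DataFrame:
    df = paired.data
    if regions is not None:
        df = df[df["region"].isin(regions)]
        if df.empty:
            raise InsufficientSampleError("no rows left after restricting to the subset")
    if df["participant_id"].nunique() < 2:
        raise InsufficientSampleError(
            "fluctuating asymmetry needs >= 2 participants (a sample mean is required)"
        )
    bilat = (df["L"] + df["R"]) / 2.0
    if (bilat == 0).any():
        bad = df.loc[bilat == 0, ["participant_id", "region"]].head(5).to_dict("records")
        raise DegenerateInputError(f"zero bilateral mean for rows {bad}")
    return df


def fluctuating_asymmetry_equal(paired: PairedTable,
                                regions: tuple[str, ...] | None = None,
                                subset_label: str = "all") -> AsymmetryResult:
    """Equal-contribution fluctuating asymmetry (steps: DA, center, abs, normalize, average)."""
    df = _prepare(paired, regions).copy()
    # a region observed in fewer than 2 participants has no usable sample mean
    counts = df.groupby("region")["participant_id"].nunique()
    dropped = tuple(counts.index[counts < 2])
    if dropped:
        df = df[~df["region"].isin(dropped)]
        if df.empty:
            raise InsufficientSampleError("every region has fewer than 2 participants")
    df["da"] = df["L"] - df["R"]
    df["centered"] = df["da"] - df.groupby("region")["da"].transform("mean")
    df["absolute"] = df["centered"].abs()
    df["normalized"] = df["absolute"] / ((df["L"] + df["R"]) / 2.0)
    scores = df.groupby("participant_id")["normalized"].mean()
    scores.name = f"{paired.metric}_{subset_label}_equal"
    return AsymmetryResult(
        metric=paired.metric, method="equal", subset=subset_label,
        per_region=df.reset_index(drop=True), scores=scores,
        regions_used=tuple(sorted(df["region"].unique())), dropped_regions=dropped,
    )


def fluctuating_asymmetry_proportional(paired: PairedTable,
                                       regions: tuple[str, ...] | None = None,
                                       subset_label: str = "all") -> AsymmetryResult:
    """Proportional-contribution fluctuating asymmetry from hemispheric totals."""
    df = _prepare(paired, regions)
    totals = df.groupby("participant_id")[["L", "R"]].sum()
    totals.columns = ["total_L", "total_R"]
    totals["n_regions"] = df.groupby("participant_id")["region"].nunique()
    totals["diff"] = totals["total_L"] - totals["total_R"]
    totals["centered"] = totals["diff"] - totals["diff"].mean()
    totals["absolute"] = totals["centered"].abs()
    bilat = (totals["total_L"] + totals["total_R"]) / 2.0
    if (bilat == 0).any():
        raise DegenerateInputError("zero bilateral total for at least one participant")
    totals["score"] = totals["absolute"] / bilat
    scores = totals["score"].copy()
    scores.name = f"{paired.metric}_{subset_label}_proportional"
    return AsymmetryResult(
        metric=paired.metric, method="proportional", subset=subset_label,
        per_region=totals.reset_index(), scores=scores,
        regions_used=tuple(sorted(df["region"].unique())),
    )


def subset_scores(paired: PairedTable, partition: RegionPartition | None = None,
                  subset: str = "all", method: str = "equal") -> AsymmetryResult:
    """Recompute fluctuating asymmetry within a region subset.

    Sample means (the centering step) are recomputed on the subset, not
    inherited from the all-region run.
    """
    partition = partition or default_partition()
    members = partition.members(subset, paired.metric)
    available = set(paired.data["region"])
    if not available & set(members):
        raise InsufficientSampleError(f"subset {subset!r} is empty after intersection")
    fn = {"equal": fluctuating_asymmetry_equal,
          "proportional": fluctuating_asymmetry_proportional}[method]
    return fn(paired, regions=members, subset_label=subset)


def regional_summary(result: AsymmetryResult) -> pd.DataFrame:
    """Per-region mean and SD of (normalized) absolute asymmetry.

    This is the tabular counterpart of the per-region asymmetry heatmaps:
    ``mean``/``sd`` summarize the size-normalized absolute asymmetry;
    ``mean_absolute``/``sd_absolute`` the un-normalized values in metric units.
    """
    if result.method != "equal":
        raise ValueError("regional summaries are defined for the equal (per-region) method")
    g = result.per_region.groupby("region")
    out = pd.DataFrame({
        "n": g["participant_id"].nunique(),
        "mean": g["normalized"].mean(),
        "sd": g["normalized"].std(ddof=1),
        "mean_absolute": g["absolute"].mean(),
        "sd_absolute": g["absolute"].std(ddof=1),
    }).reset_index()
    return out


def directional_ttests(paired: PairedTable,
                       regions: tuple[str, ...] | None = None) -> pd.DataFrame:
    """One-sample t-test of each region's directional asymmetry against zero."""
    df = _prepare(paired, regions).copy()
    df["da"] = df["L"] - df["R"]
    rows = []
    zero_sd = []
    for region, sub in df.groupby("region"):
        da = sub["da"].to_numpy()
        if len(da) < 2:
            continue
        if np.std(da, ddof=1) == 0:
            zero_sd.append(region)
            continue
        t, p = stats.ttest_1samp(da, 0.0)
        rows.append({"region": region, "n": len(da), "mean_da": da.mean(),
                     "sd_da": da.std(ddof=1), "t": t, "df": len(da) - 1, "p": p})
    if zero_sd:
        raise DegenerateInputError(
            f"zero sample SD of directional asymmetry for region(s) {zero_sd}; "
            "the t statistic is undefined"
        )
    return pd.DataFrame(rows)


def compare_methods(equal: AsymmetryResult, proportional: AsymmetryResult) -> MethodComparison:
    """Pairwise-complete Pearson correlation between the two scoring schemes."""
    if equal.metric != proportional.metric:
        raise ValueError("method comparison requires the same metric on both sides")
    merged = pd.concat([equal.scores.rename("e"), proportional.scores.rename("p")],
                       axis=1, join="inner").dropna()
    if len(merged) < 3:
        raise InsufficientSampleError("fewer than 3 complete score pairs")
    if merged["e"].nunique() < 2 or merged["p"].nunique() < 2:
        raise DegenerateInputError("constant score vector; correlation undefined")
    r, p = stats.pearsonr(merged["e"], merged["p"])
    return MethodComparison(metric=equal.metric, r=float(r), p=float(p), n=len(merged))
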