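"""Reading, validation and hemispheric pairing of regional tables.

Regional data arrive as long-format CSV (participant_id, region, hemisphere,
value), one file per metric.  Values are per-hemisphere summaries of a
paired region: cortical surface area (mm^2), cortical volume (mm^3), mean
cortical thickness (mm), or tract-averaged fractional anisotropy
(dimensionless, in (0, 1)).  A wide-format convenience reader accepts
``lh_<region>`` / ``rh_<region>`` columns and normalizes to long format.

Asymmetry is undefined when one hemisphere is missing, so pairing drops the
(participant, region) cell and reports it in ``PairedTable.flags`` instead
of imputing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import RegionPartition, default_partition
from .errors import SchemaError, UnknownRegionError, ValidationError

__all__ = [
    "METRICS",
    "RegionalMetricTable",
    "PairedTable",
    "read_regional_csv",
    "read_wide_regional_csv",
    "write_regional_csv",
    "validate_regional",
    "pair_hemispheres",
    "read_cognitive_csv",
    "read_ses_csv",
]

#: Supported metrics and their units.
METRICS = {
    "surface_area": "mm^2",
    "volume": "mm^3",
    "thickness": "mm",
    "fa": "1",
}

_REQUIRED_COLUMNS = ("participant_id", "region", "hemisphere", "value")
_SES_COLUMNS = (
    "participant_id",
    "people_per_room",
    "toilet_type",
    "people_sharing_toilet",
    "father_social_class",
)


@dataclass
class RegionalMetricTable:
    """Validated long-format hemispheric values for one metric."""

    metric: str
    data: pd.DataFrame  # columns: participant_id, region, hemisphere, value

    @property
    def participants(self) -> np.ndarray:
        return self.data["participant_id"].unique()

    @property
    def regions(self) -> np.ndarray:
        return self.data["region"].unique()


@dataclass
class PairedTable:
    """One row per (participant, region) with both hemispheres present.

    ``flags`` lists (participant, region) cells dropped because only one
    hemisphere was observed.
    """

    metric: str
    data: pd.DataFrame  # columns: participant_id, region, L, R
    flags: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["participant_id", "region", "reason"])
    )

    @property
    def n_pairs(self) -> int:
        return len(self.data)


def validate_regional(df: pd.DataFrame, metric: str,
                      partition: RegionPartition | None = None) -> pd.DataFrame:
    """Check schema and row invariants; raise with row-indexed messages."""
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; expected one of {sorted(METRICS)}")
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s) {missing} for metric {metric!r}")
    df = df.loc[:, list(_REQUIRED_COLUMNS)].copy()
    df["hemisphere"] = df["hemisphere"].astype(str).str.upper().str.strip()
    df["value"] = pd.to_numeric(df["value"], errors="coerce")

    problems: list[str] = []
    bad_hemi = ~df["hemisphere"].isin(["L", "R"])
    for idx in df.index[bad_hemi][:10]:
        problems.append(f"row {idx}: hemisphere {df.at[idx, 'hemisphere']!r} not in {{L, R}}")
    nonfinite = ~np.isfinite(df["value"].to_numpy(dtype=float))
    for idx in df.index[nonfinite][:10]:
        problems.append(f"row {idx}: non-numeric or non-finite value")
    if metric == "fa":
        bad = (df["value"] <= 0) | (df["value"] >= 1)
    else:
        bad = df["value"] <= 0
    bad &= ~nonfinite
    for idx in df.index[bad][:10]:
        bound = "(0, 1)" if metric == "fa" else "> 0"
        problems.append(f"row {idx}: {metric} value {df.at[idx, 'value']} violates {bound}")
    dup = df.duplicated(subset=["participant_id", "region", "hemisphere"], keep=False)
    for idx in df.index[dup][:10]:
        problems.append(
            f"row {idx}: duplicate (participant, region, hemisphere) "
            f"{tuple(df.loc[idx, ['participant_id', 'region', 'hemisphere']])}"
        )
    if partition is not None:
        canonical = set(partition.tract_regions if metric == "fa" else partition.cortical_regions)
        unknown = ~df["region"].isin(canonical)
        if unknown.any():
            labels = sorted(df.loc[unknown, "region"].unique())
            raise UnknownRegionError(
                f"region label(s) {labels} not in the canonical {metric} list"
            )
    if problems:
        raise ValidationError("invalid regional rows:\n  " + "\n  ".join(problems))
    return df


def read_regional_csv(path: str | Path, metric: str,
                      partition: RegionPartition | None = None) -> RegionalMetricTable:
    """Read one long-format metric file and validate it."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, float_precision="round_trip")
    return RegionalMetricTable(metric=metric, data=validate_regional(df, metric, partition))


def read_wide_regional_csv(path: str | Path, metric: str,
                           partition: RegionPartition | None = None) -> RegionalMetricTable:
    """Read a wide table with lh_<region>/rh_<region> columns; normalize to long."""
    df = pd.read_csv(path, float_precision="round_trip")
    if "participant_id" not in df.columns:
        raise SchemaError("wide regional table requires a participant_id column")
    records = []
    for col in df.columns:
        if col.startswith(("lh_", "rh_")):
            hemi = "L" if col.startswith("lh_") else "R"
            region = col[3:]
            sub = df[["participant_id", col]].dropna()
            records.append(pd.DataFrame({
                "participant_id": sub["participant_id"],
                "region": region,
                "hemisphere": hemi,
                "value": sub[col],
            }))
    if not records:
        raise SchemaError("no lh_/rh_ prefixed columns found in wide regional table")
    long = pd.concat(records, ignore_index=True)
    return RegionalMetricTable(metric=metric, data=validate_regional(long, metric, partition))


def write_regional_csv(table: RegionalMetricTable, path: str | Path) -> None:
    table.data.to_csv(path, index=False)


def pair_hemispheres(table: RegionalMetricTable,
                     partition: RegionPartition | None = None) -> PairedTable:
    """Pivot a validated long table into one L/R row per (participant, region).

    Cells with only one hemisphere observed are excluded for that participant
    and reported in ``flags``.  Unknown region labels raise.
    """
    partition = partition or default_partition()
    canonical = partition.tract_regions if table.metric == "fa" else partition.cortical_regions
    unknown = set(table.data["region"]) - set(canonical)
    if unknown:
        raise UnknownRegionError(
            f"region label(s) {sorted(unknown)} have no counterpart in the partition"
        )
    wide = table.data.pivot_table(
        index=["participant_id", "region"], columns="hemisphere", values="value",
        aggfunc="first",
    ).reset_index()
    for hemi in ("L", "R"):
        if hemi not in wide.columns:
            wide[hemi] = np.nan
    incomplete = wide["L"].isna() | wide["R"].isna()
    flags = wide.loc[incomplete, ["participant_id", "region"]].copy()
    flags["reason"] = np.where(
        wide.loc[incomplete, "L"].isna(), "missing L hemisphere", "missing R hemisphere"
    )
    paired = wide.loc[~incomplete, ["participant_id", "region", "L", "R"]].reset_index(drop=True)
    return PairedTable(metric=table.metric, data=paired, flags=flags.reset_index(drop=True))


def read_cognitive_csv(path: str | Path, orientation: dict[str, int] | None = None) -> pd.DataFrame:
    """Read the cognitive battery table; optionally flip reversed scores.

    ``orientation`` maps test column -> +1/-1; columns flagged -1 (e.g.
    reaction times, where a larger value is worse) are negated so that higher
    always means better downstream.  ``sex`` is carried through if present.
    """
    df = pd.read_csv(path)
    if "participant_id" not in df.columns:
        raise SchemaError("cognitive table requires a participant_id column")
    if orientation:
        for col, sign in orientation.items():
            if col not in df.columns:
                raise SchemaError(f"orientation flag for unknown column {col!r}")
            if sign == -1:
                df[col] = -df[col]
            elif sign != 1:
                raise ValidationError(f"orientation for {col!r} must be +1 or -1")
    return df


def read_ses_csv(path: str | Path) -> pd.DataFrame:
    """Read the four childhood socioeconomic-status indicators.

    Father's social class is the UK 1951 occupational classification, an
    ordinal 1 (professional) .. 5 (unskilled).
    """
    df = pd.read_csv(path)
    missing = [c for c in _SES_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"SES table missing column(s) {missing}")
    fsc = df["father_social_class"].dropna()
    if not fsc.isin([1, 2, 3, 4, 5]).all():
        bad = sorted(fsc[~fsc.isin([1, 2, 3, 4, 5])].unique())
        raise ValidationError(f"father_social_class values {bad} outside 1..5")
    return df
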