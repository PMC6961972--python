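"""Canonical region lists and the parieto-frontal (P-FIT) partition.

The cortical parcellation is the 34-region gyral Desikan-Killiany atlas
(lowercase FreeSurfer labels, one label per paired left/right region).  The
white-matter set is five bilaterally paired association/projection tracts
whose fractional anisotropy can be measured reliably with single-seed
probabilistic tractography.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

__all__ = [
    "DK_REGIONS",
    "PFIT_REGIONS",
    "NON_PFIT_REGIONS",
    "TRACTS",
    "RegionPartition",
    "default_partition",
    "atlas_table",
    "tract_table",
]


def _load_csv(name: str) -> pd.DataFrame:
    with resources.files("neuroasym.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


_ATLAS = _load_csv("dk_atlas.csv")
_TRACTS = _load_csv("tracts.csv")

#: The 34 paired cortical regions, atlas order.
DK_REGIONS: tuple[str, ...] = tuple(_ATLAS["region"])

#: The 10 frontoparietal regions singled out by the parieto-frontal
#: integration theory of intelligence.
PFIT_REGIONS: tuple[str, ...] = tuple(_ATLAS.loc[_ATLAS["pfit"] == 1, "region"])

#: The complementary 24 cortical regions.
NON_PFIT_REGIONS: tuple[str, ...] = tuple(_ATLAS.loc[_ATLAS["pfit"] == 0, "region"])

#: The 5 paired white-matter tracts with per-tract mean fractional anisotropy.
TRACTS: tuple[str, ...] = tuple(_TRACTS["tract"])


@dataclass(frozen=True)
class RegionPartition:
    """Cortical region list with its P-FIT / non-P-FIT split, plus tracts.

    Invariants: the P-FIT members are a subset of the cortical regions, the
    split is disjoint and exhaustive, and all label lists are duplicate-free.
    """

    cortical_regions: tuple[str, ...] = DK_REGIONS
    pfit_members: tuple[str, ...] = PFIT_REGIONS
    tract_regions: tuple[str, ...] = TRACTS

    def __post_init__(self) -> None:
        cort = set(self.cortical_regions)
        pfit = set(self.pfit_members)
        if len(cort) != len(self.cortical_regions):
            raise ValueError("duplicate cortical region labels")
        if not pfit <= cort:
            raise ValueError(f"P-FIT labels not in cortical list: {sorted(pfit - cort)}")
        if len(set(self.tract_regions)) != len(self.tract_regions):
            raise ValueError("duplicate tract labels")

    @property
    def non_pfit_members(self) -> tuple[str, ...]:
        return tuple(r for r in self.cortical_regions if r not in set(self.pfit_members))

    def members(self, subset: str, metric: str = "surface_area") -> tuple[str, ...]:
        """Region labels for ``subset`` in {'all', 'pfit', 'non_pfit'}.

        For the 'fa' metric 'all' means the tract list; the P-FIT split is
        defined for cortical metrics only.
        """
        if metric == "fa":
            if subset != "all":
                raise ValueError("P-FIT partition is defined for cortical regions only")
            return self.tract_regions
        if subset == "all":
            return self.cortical_regions
        if subset == "pfit":
            return self.pfit_members
        if subset == "non_pfit":
            return self.non_pfit_members
        raise ValueError(f"unknown subset {subset!r}")


def default_partition() -> RegionPartition:
    """The shipped 34-region atlas with its 10-region P-FIT subset."""
    return RegionPartition()


def atlas_table() -> pd.DataFrame:
    """Per-region defaults (sizes, directional-asymmetry fractions) as a copy."""
    return _ATLAS.copy()


def tract_table() -> pd.DataFrame:
    return _TRACTS.copy()
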