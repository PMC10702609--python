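"""Bilateral homolog parcellation of the mouse brain.

The analysis operates on a 72-region atlas: 36 regions per hemisphere, each
left region paired with its right-hemisphere homolog.  Regions are identified
externally by their abbreviation (``CA1``, ``RCOA``, ...) and internally by
their 0-based position in the region table, which also fixes the row/column
order of every connectivity matrix downstream.

Homolog pairing is positional: the i-th left region in the table is the
homolog of the i-th right region.  The packaged table lists both hemispheres
in matched order, so this resolves every irregular abbreviation pair
(``IntC`` ↔ ``RIC``, ``IC`` ↔ ``RInfC``, ``RA`` ↔ ``RRN``,
``MOB_gl`` ↔ ``RAOB_gl``) without string heuristics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

import pandas as pd

__all__ = [
    "Region",
    "RegionAtlas",
    "CompositeROI",
    "AtlasFormatError",
    "load_atlas",
    "packaged_atlas",
    "hemisphere_subset",
    "merge_rois",
]

HEMISPHERES = ("L", "R")


class AtlasFormatError(ValueError):
    """Raised when a region table violates the atlas format contract."""


@dataclass(frozen=True)
class Region:
    """One parcellation unit.

    index is the 0-based position in the atlas (and the matrix row/column),
    abbreviation is the unique external key, hemisphere is "L" or "R".
    """

    index: int
    name: str
    abbreviation: str
    hemisphere: str


@dataclass(frozen=True)
class CompositeROI:
    """A named, single-hemisphere union of atlas regions used as a seed scope.

    E.g. the hippocampus = {CA1, CA2, CA3, DG}, or a singleton such as the
    cortical amygdalar area {COA}.
    """

    name: str
    members: frozenset[str]
    hemisphere: str


@dataclass(frozen=True)
class RegionAtlas:
    """Ordered bilateral atlas with an L↔R homolog bijection."""

    regions: tuple[Region, ...]
    _index: dict[str, int] = field(repr=False, compare=False, default_factory=dict)
    _homolog: dict[str, str] = field(repr=False, compare=False, default_factory=dict)

    def __post_init__(self) -> None:
        abbrevs = [r.abbreviation for r in self.regions]
        if len(set(abbrevs)) != len(abbrevs):
            dupes = sorted({a for a in abbrevs if abbrevs.count(a) > 1})
            raise AtlasFormatError(f"duplicate abbreviations: {dupes}")
        for r in self.regions:
            if r.hemisphere not in HEMISPHERES:
                raise AtlasFormatError(
                    f"region {r.abbreviation!r}: hemisphere must be L or R, "
                    f"got {r.hemisphere!r}"
                )
        left = [r for r in self.regions if r.hemisphere == "L"]
        right = [r for r in self.regions if r.hemisphere == "R"]
        if len(left) != len(right):
            raise AtlasFormatError(
                f"hemispheres are unbalanced: {len(left)} L vs {len(right)} R"
            )
        object.__setattr__(self, "_index", {a: i for i, a in enumerate(abbrevs)})
        homolog: dict[str, str] = {}
        for lo, ro in zip(left, right):
            homolog[lo.abbreviation] = ro.abbreviation
            homolog[ro.abbreviation] = lo.abbreviation
        object.__setattr__(self, "_homolog", homolog)

    # -- basic queries ----------------------------------------------------

    def __len__(self) -> int:
        return len(self.regions)

    def __contains__(self, abbreviation: str) -> bool:
        return abbreviation in self._index

    @property
    def abbreviations(self) -> tuple[str, ...]:
        return tuple(r.abbreviation for r in self.regions)

    def index_of(self, abbreviation: str) -> int:
        try:
            return self._index[abbreviation]
        except KeyError:
            raise KeyError(f"unknown region abbreviation {abbreviation!r}") from None

    def region(self, abbreviation: str) -> Region:
        return self.regions[self.index_of(abbreviation)]

    def hemisphere_of(self, abbreviation: str) -> str:
        return self.region(abbreviation).hemisphere

    def homolog(self, abbreviation: str) -> str:
        """The contralateral homolog abbreviation (an involution)."""
        self.index_of(abbreviation)  # raise on unknown
        return self._homolog[abbreviation]

    def hemisphere_subset(self, side: str) -> tuple[Region, ...]:
        """All regions of one hemisphere, atlas order preserved."""
        if side not in HEMISPHERES:
            raise ValueError(f"hemisphere must be one of {HEMISPHERES}, got {side!r}")
        return tuple(r for r in self.regions if r.hemisphere == side)

    def hemisphere_indices(self, side: str) -> list[int]:
        return [r.index for r in self.hemisphere_subset(side)]

    # -- composite ROIs ---------------------------------------------------

    def merge_rois(self, members: Iterable[str], name: str) -> CompositeROI:
        """Build a composite seed ROI from same-hemisphere member regions.

        Downstream, counts to/from the composite are sums over member
        rows/columns, with edges internal to the composite summed once.
        """
        members = frozenset(members)
        if not members:
            raise ValueError("composite ROI needs at least one member region")
        unknown = sorted(m for m in members if m not in self)
        if unknown:
            raise ValueError(f"unknown member regions: {unknown}")
        hemis = {self.hemisphere_of(m) for m in members}
        if len(hemis) != 1:
            raise ValueError(
                f"composite ROI members must share a hemisphere, got {sorted(hemis)}"
            )
        return CompositeROI(name=name, members=members, hemisphere=hemis.pop())


def load_atlas(region_table: str | Path, expect_regions: int | None = 72) -> RegionAtlas:
    """Load a region table (TSV with name/abbreviation/hemisphere columns).

    Parameters
    ----------
    region_table:
        Path to a tab-separated file with header columns ``name``,
        ``abbreviation`` and ``hemisphere``; one row per region, file order
        defines matrix order.
    expect_regions:
        Required region count (72 for the packaged bilateral atlas).  Pass
        ``None`` to allow toy atlases of any (even) size.
    """
    # keep_default_na: "NA" is the nucleus accumbens, not a missing value
    df = pd.read_csv(region_table, sep="\t", dtype=str, keep_default_na=False,
                     na_values=[""])
    required = {"name", "abbreviation", "hemisphere"}
    missing = required - set(df.columns)
    if missing:
        raise AtlasFormatError(f"region table missing columns: {sorted(missing)}")
    if df[list(required)].isna().any().any():
        raise AtlasFormatError("region table contains empty cells")
    regions = tuple(
        Region(index=i, name=row["name"], abbreviation=row["abbreviation"],
               hemisphere=row["hemisphere"])
        for i, row in df.iterrows()
    )
    if expect_regions is not None and len(regions) != expect_regions:
        raise AtlasFormatError(
            f"expected {expect_regions} regions, found {len(regions)}"
        )
    return RegionAtlas(regions=regions)


def packaged_atlas() -> RegionAtlas:
    """The packaged 72-region bilateral homolog atlas."""
    with resources.as_file(resources.files("strucnet") / "data" / "regions.tsv") as p:
        return load_atlas(p, expect_regions=72)


# Named seed ROIs of the seeded-pathway analyses: hippocampus = Ammon's horn
# subfields + dentate gyrus; amygdala = cortical amygdalar area; caudate =
# caudoputamen.
STANDARD_SEED_ROIS: dict[str, tuple[str, ...]] = {
    "hippocampus-L": ("CA1", "CA2", "CA3", "DG"),
    "hippocampus-R": ("RCA1", "RCA2", "RCA3", "RDG"),
    "amygdala-L": ("COA",),
    "amygdala-R": ("RCOA",),
    "caudate-L": ("CP",),
    "caudate-R": ("RCP",),
}


def standard_composites(atlas: RegionAtlas) -> dict[str, CompositeROI]:
    """The named composite seed ROIs, built against an atlas."""
    return {name: atlas.merge_rois(members, name)
            for name, members in STANDARD_SEED_ROIS.items()}


def hemisphere_subset(atlas: RegionAtlas, side: str) -> tuple[Region, ...]:
    """Functional alias for :meth:`RegionAtlas.hemisphere_subset`."""
    return atlas.hemisphere_subset(side)


def merge_rois(atlas: RegionAtlas, members: Iterable[str], name: str) -> CompositeROI:
    """Functional alias for :meth:`RegionAtlas.merge_rois`."""
    return atlas.merge_rois(members, name)
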