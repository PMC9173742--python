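"""Canonical catalog of quantified input regions to VTA dopamine neurons.

Rabies-labeled input cells are binned into 57 anatomically defined brain
regions: 22 long-range (forebrain and distant hindbrain sites, more than
~1 mm from the injection site) and 35 local (ventral midbrain and nearby
hindbrain).  Each region carries a locality class, a midline flag (midline
nuclei are never split by hemisphere), a VTA-subnucleus flag (PBP, PN, IF,
Rli), and an optional serotonergic cell-group label (B3--B9).

The default catalog ships as a versioned CSV resource.  The long-range
membership is reconstructed from the published figure narratives and the
prior whole-brain mapping studies the quantification is anchored to; edits
belong in the CSV, not in code.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

__all__ = [
    "Region",
    "RegionCatalog",
    "UnknownRegionError",
    "load_default_catalog",
    "classify_locality",
    "serotonergic_regions",
]

#: Serotonergic cell groups that can appear in the catalog.
SEROTONERGIC_GROUPS = ("B3", "B5", "B6", "B7", "B8", "B9")

#: Alternate short labels seen in figure legends, mapped to catalog names.
DEFAULT_ALIASES = {
    "VTA PBP": "PBP",
    "VTA PN": "PN",
    "VTA IF": "IF",
    "VTA RLI": "Rli",
    "RLI": "Rli",
    "SEPTUM": "Septum",
    "CTX": "Cortex",
}


class UnknownRegionError(KeyError):
    """Raised when a region name cannot be resolved against the catalog."""


@dataclass(frozen=True)
class Region:
    """A single quantified input region.

    Parameters
    ----------
    name
        Short label used in count tables (e.g. ``"SNr"``, ``"NAcLat"``).
    full_name
        Human-readable anatomical name.
    locality
        ``"long_range"`` or ``"local"``; local means within ~1 mm of the
        injection site or in the posterior ventral midbrain.
    midline
        Whether the nucleus straddles the midline; midline regions are
        reported as a single column rather than split by hemisphere.
    vta_subnucleus
        Whether the region is one of the VTA subnuclei (PBP, PN, IF, Rli).
    serotonergic_group
        Optional raphe/reticular serotonergic group label (B3..B9).
    """

    name: str
    full_name: str
    locality: str
    midline: bool = False
    vta_subnucleus: bool = False
    serotonergic_group: Optional[str] = None

    def __post_init__(self) -> None:
        if self.locality not in ("long_range", "local"):
            raise ValueError(f"invalid locality {self.locality!r}")
        if self.serotonergic_group is not None and (
            self.serotonergic_group not in SEROTONERGIC_GROUPS
        ):
            raise ValueError(
                f"invalid serotonergic group {self.serotonergic_group!r}"
            )


class RegionCatalog:
    """Ordered collection of :class:`Region` with alias-tolerant lookup.

    The region order is stable so that every matrix built against a catalog
    (fraction matrices, distance matrices, heatmaps) is reproducible.
    Lookup is case-insensitive on the short label and accepts the aliases in
    :data:`DEFAULT_ALIASES` (e.g. ``"VTA PBP"`` resolves to ``"PBP"``).
    """

    def __init__(self, regions: Iterable[Region], version: str = "custom"):
        self.regions = tuple(regions)
        self.version = version
        names = [r.name for r in self.regions]
        if len(set(names)) != len(names):
            raise ValueError("region names must be unique within a catalog")
        self._by_key = {r.name.upper(): r for r in self.regions}
        for alias, target in DEFAULT_ALIASES.items():
            if target.upper() in self._by_key:
                self._by_key.setdefault(alias.upper(), self._by_key[target.upper()])

    # -- basic container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions)

    def __contains__(self, name: str) -> bool:
        try:
            self.get(name)
        except UnknownRegionError:
            return False
        return True

    def __eq__(self, other) -> bool:
        if not isinstance(other, RegionCatalog):
            return NotImplemented
        return self.regions == other.regions

    # -- lookup -------------------------------------------------------------------
    def get(self, name: str) -> Region:
        """Resolve ``name`` (case-insensitive, alias-tolerant) to a Region."""
        try:
            return self._by_key[str(name).upper()]
        except KeyError:
            raise UnknownRegionError(name) from None

    def resolve(self, name: str) -> str:
        """Return the canonical short label for ``name``."""
        return self.get(name).name

    # -- views --------------------------------------------------------------------
    @property
    def names(self) -> list[str]:
        return [r.name for r in self.regions]

    def long_range(self) -> list[Region]:
        return [r for r in self.regions if r.locality == "long_range"]

    def local(self) -> list[Region]:
        return [r for r in self.regions if r.locality == "local"]

    def midline_names(self) -> set[str]:
        return {r.name for r in self.regions if r.midline}

    def vta_subnuclei(self) -> list[Region]:
        return [r for r in self.regions if r.vta_subnucleus]

    def serotonergic(self) -> list[Region]:
        return [r for r in self.regions if r.serotonergic_group is not None]

    # -- (de)serialization --------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "name": [r.name for r in self.regions],
                "full_name": [r.full_name for r in self.regions],
                "locality": [r.locality for r in self.regions],
                "midline": [r.midline for r in self.regions],
                "vta_subnucleus": [r.vta_subnucleus for r in self.regions],
                "serotonergic_group": [
                    r.serotonergic_group or "" for r in self.regions
                ],
            }
        )

    def to_csv(self, path) -> None:
        df = self.to_frame()
        for col in ("midline", "vta_subnucleus"):
            df[col] = df[col].map({True: "true", False: "false"})
        df.to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, version: str = "custom") -> "RegionCatalog":
        regions = []
        for row in df.itertuples(index=False):
            group = getattr(row, "serotonergic_group", "")
            if pd.isna(group) or group == "":
                group = None
            regions.append(
                Region(
                    name=str(row.name),
                    full_name=str(row.full_name),
                    locality=str(row.locality),
                    midline=_as_bool(row.midline),
                    vta_subnucleus=_as_bool(row.vta_subnucleus),
                    serotonergic_group=group,
                )
            )
        return cls(regions, version=version)

    @classmethod
    def from_csv(cls, path, version: str = "custom") -> "RegionCatalog":
        return cls.from_frame(pd.read_csv(path), version=version)


def _as_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    return str(value).strip().lower() in ("true", "1", "yes")


def load_default_catalog() -> RegionCatalog:
    """Load the shipped 57-region catalog (22 long-range + 35 local).

    The long-range list is reconstructed from the published figures and the
    prior whole-brain mapping studies; the CSV resource is the authoritative,
    versioned form of that reconstruction.
    """
    text = (
        resources.files("vtatrace").joinpath("data/region_catalog.csv").read_text()
    )
    return RegionCatalog.from_frame(
        pd.read_csv(io.StringIO(text)), version="default-1"
    )


def classify_locality(region_name: str, catalog: RegionCatalog) -> str:
    """Return ``"long_range"`` or ``"local"`` for a region name.

    Raises :class:`UnknownRegionError` for names absent from the catalog.
    """
    return catalog.get(region_name).locality


def serotonergic_regions(catalog: RegionCatalog) -> list[Region]:
    """Regions carrying a serotonergic group annotation (B3..B9)."""
    return catalog.serotonergic()
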