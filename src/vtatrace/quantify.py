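"""Core counting stage: fractions, locality split, convergence index, summaries.

All operations count *input* cells only (``is_starter == False``); starter
cells are never inputs even though they are RABV-GFP+.  Midline nuclei are
always reported as a single ``midline`` column, never split by hemisphere.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .catalog import RegionCatalog, UnknownRegionError
from .synthetic import BrainDataset, Cohort

__all__ = [
    "FractionMatrix",
    "EllipseSummary",
    "TTestResult",
    "count_by_region",
    "fraction_matrix",
    "local_long_split",
    "convergence_index",
    "per_10k_normalization",
    "starter_composition",
    "starter_ellipse",
    "compare_groups",
]


@dataclass
class FractionMatrix:
    """Brains x regions matrix of fractional input counts.

    With ``denominator="all_inputs"`` every row sums to 1 (all 57 regions
    included); with ``denominator="long_range_only"`` fractions are taken
    over the long-range regions alone.
    """

    values: pd.DataFrame  # index = brain ids, columns = region names
    denominator: str = "all_inputs"

    @property
    def brain_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def region_names(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class EllipseSummary:
    """Center of mass and 1-SD radii of starter cells (um, ML and DV axes)."""

    center_ml: float
    center_dv: float
    radius_ml: float
    radius_dv: float


@dataclass
class TTestResult:
    t: float
    df: float
    p: float
    ci_low: float
    ci_high: float


def _validate_regions(regions: Iterable[str], catalog: RegionCatalog) -> None:
    for name in pd.unique(np.asarray(list(regions), dtype=object)):
        catalog.get(name)  # raises UnknownRegionError


def count_by_region(brain: BrainDataset, catalog: RegionCatalog,
                    hemispheres: str = "combined") -> pd.DataFrame:
    """Integer input-cell counts per region (x hemisphere if ``separate``).

    Midline regions are reported in a single ``midline`` column even in
    ``separate`` mode.  Starter cells are excluded by definition.
    """
    if hemispheres not in ("combined", "separate"):
        raise ValueError("hemispheres must be 'combined' or 'separate'")
    inputs = brain.inputs
    inputs = inputs[~inputs["is_starter"].astype(bool)]
    _validate_regions(inputs["region"], catalog)
    canonical = inputs["region"].map(catalog.resolve)
    names = catalog.names
    if hemispheres == "combined":
        counts = canonical.value_counts()
        out = pd.DataFrame({"count": [int(counts.get(n, 0)) for n in names]},
                           index=pd.Index(names, name="region"))
        return out
    midline = catalog.midline_names()
    hemi = np.where(canonical.isin(list(midline)), "midline",
                    brain.inputs.loc[canonical.index, "hemisphere"])
    tab = pd.crosstab(canonical, pd.Series(hemi, index=canonical.index))
    out = pd.DataFrame(0, index=pd.Index(names, name="region"),
                       columns=["ipsi", "contra", "midline"], dtype=int)
    for col in tab.columns:
        if col not in out.columns:
            raise ValueError(f"unexpected hemisphere label {col!r}")
        out.loc[tab.index, col] = tab[col]
    # midline regions must not carry ipsi/contra counts
    out.loc[list(midline), ["ipsi", "contra"]] = 0
    return out


def fraction_matrix(cohort: Cohort, catalog: RegionCatalog,
                    denominator: str = "all_inputs") -> FractionMatrix:
    """Per-brain fractional input counts over the catalog regions."""
    if denominator not in ("all_inputs", "long_range_only"):
        raise ValueError("invalid denominator mode")
    if denominator == "long_range_only":
        keep = [r.name for r in catalog.long_range()]
    else:
        keep = catalog.names
    rows = {}
    for brain in cohort:
        counts = count_by_region(brain, catalog)["count"]
        counts = counts.loc[keep]
        total = counts.sum()
        if total == 0:
            raise ValueError(f"brain {brain.brain_id} has zero input cells")
        rows[brain.brain_id] = counts / total
    values = pd.DataFrame(rows).T
    values.index.name = "brain_id"
    return FractionMatrix(values=values, denominator=denominator)


def local_long_split(fractions: FractionMatrix,
                     catalog: RegionCatalog) -> pd.DataFrame:
    """Per-brain (local, long_range) shares of all inputs, plus mean +/- SEM.

    Requires ``denominator="all_inputs"`` so the two shares sum to 1.
    """
    if fractions.denominator != "all_inputs":
        raise ValueError("local/long split requires all-inputs fractions")
    local_names = [r.name for r in catalog.local()
                   if r.name in fractions.values.columns]
    long_names = [r.name for r in catalog.long_range()
                  if r.name in fractions.values.columns]
    out = pd.DataFrame(
        {
            "local": fractions.values[local_names].sum(axis=1),
            "long_range": fractions.values[long_names].sum(axis=1),
        }
    )
    out.attrs["mean"] = out.mean().to_dict()
    n = len(out)
    out.attrs["sem"] = (
        (out.std(ddof=1) / np.sqrt(n)).to_dict() if n > 1 else {c: np.nan for c in out}
    )
    return out


def convergence_index(brain: BrainDataset, catalog: RegionCatalog) -> float:
    """Ratio of long-range input cells to starter cells."""
    n_starters = len(brain.starters)
    if n_starters == 0:
        raise ValueError("convergence index undefined for zero starter cells")
    counts = count_by_region(brain, catalog)["count"]
    long_names = [r.name for r in catalog.long_range()]
    return float(counts.loc[long_names].sum() / n_starters)


def per_10k_normalization(count: int, total_inputs: int) -> float:
    """Input count normalized per 10,000 RABV-labeled inputs."""
    if total_inputs <= 0:
        raise ValueError("total_inputs must be positive")
    if count > total_inputs:
        raise ValueError("count cannot exceed total_inputs")
    return count / total_inputs * 10_000.0


STARTER_SUBNUCLEI = ("PBP", "PN", "IF", "SNc", "Rli")


def starter_composition(brain: BrainDataset,
                        catalog: RegionCatalog) -> dict[str, float]:
    """Fractions of starter cells over {PBP, PN, IF, SNc, Rli, other}."""
    starters = brain.starters
    if len(starters) == 0:
        raise ValueError("no starter cells")
    canonical = starters["region"].map(catalog.resolve)
    counts = canonical.value_counts()
    out = {sub: float(counts.get(sub, 0)) / len(starters)
           for sub in STARTER_SUBNUCLEI}
    out["other"] = 1.0 - sum(out.values())
    return out


def starter_ellipse(starters: pd.DataFrame) -> EllipseSummary:
    """Center of mass and per-axis sample SD (1-SD radii) of starter cells."""
    coords = starters[["x_ml", "y_dv"]].dropna()
    if len(coords) == 0:
        raise ValueError("no starter cells with coordinates")
    center = coords.mean()
    if len(coords) == 1:
        radii = pd.Series({"x_ml": 0.0, "y_dv": 0.0})
    else:
        radii = coords.std(ddof=1)
    return EllipseSummary(
        center_ml=float(center["x_ml"]),
        center_dv=float(center["y_dv"]),
        radius_ml=float(radii["x_ml"]),
        radius_dv=float(radii["y_dv"]),
    )


def compare_groups(values_a, values_b, welch: bool = False,
                   alpha: float = 0.05) -> TTestResult:
    """Two-sided unpaired t-test with a CI for the difference of means.

    Default is the Student (pooled-variance) test; ``welch=True`` uses the
    Welch--Satterthwaite correction.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two observations")
    res = stats.ttest_ind(a, b, equal_var=not welch)
    diff = a.mean() - b.mean()
    if welch:
        se = np.sqrt(a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b))
        df = res.df
    else:
        df = len(a) + len(b) - 2
        sp2 = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / df
        se = np.sqrt(sp2 * (1 / len(a) + 1 / len(b)))
    tcrit = stats.t.ppf(1 - alpha / 2, df)
    return TTestResult(
        t=float(res.statistic),
        df=float(df),
        p=float(res.pvalue),
        ci_low=float(diff - tcrit * se),
        ci_high=float(diff + tcrit * se),
    )
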