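"""Marker-conditional input maps: GABAergic, dopaminergic and serotonergic.

Co-label rules are require/exclude sets over the boolean marker flags carried
by each cell record (GFP, TC66T/mCherry, GAD1/2, TH, Tph2).  TC66T is an
mCherry fusion, so "mCherry-negative" and "TC66T-negative" are the same flag.
Rules only ever select input cells; starter cells never pass.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .catalog import RegionCatalog
from .quantify import per_10k_normalization
from .synthetic import BrainDataset, Cohort

__all__ = [
    "ColabelRule",
    "GABA_RULE",
    "DA_RULE",
    "SEROTONIN_RULE",
    "apply_colabel_rule",
    "gaba_composition",
    "da_colabel_fraction",
    "da_total_estimate",
    "serotonin_summary",
    "DEFAULT_ROI_SPECS",
]

MARKER_FLAGS = ("gfp", "tc66t", "gad", "th", "tph2")


@dataclass(frozen=True)
class ColabelRule:
    """Markers that must be positive (``require``) and negative (``exclude``)."""

    require: frozenset = field(default_factory=frozenset)
    exclude: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        object.__setattr__(self, "require", frozenset(self.require))
        object.__setattr__(self, "exclude", frozenset(self.exclude))
        unknown = (self.require | self.exclude) - set(MARKER_FLAGS)
        if unknown:
            raise ValueError(f"unknown marker flags: {sorted(unknown)}")
        if self.require & self.exclude:
            raise ValueError("require and exclude sets overlap")


#: GABAergic input: RABV+ (GFP), GAD1/2+, TC66T-.
GABA_RULE = ColabelRule(require={"gfp", "gad"}, exclude={"tc66t"})
#: Dopaminergic input: GFP+, TH+, mCherry(TC66T)-.
DA_RULE = ColabelRule(require={"gfp", "th"}, exclude={"tc66t"})
#: Serotonergic input: GFP+, Tph2+.
SEROTONIN_RULE = ColabelRule(require={"gfp", "tph2"})


def apply_colabel_rule(brain: BrainDataset, rule: ColabelRule) -> pd.DataFrame:
    """Input cells satisfying the rule (starters never pass)."""
    cells = brain.inputs
    mask = ~cells["is_starter"].astype(bool)
    for flag in rule.require:
        mask &= cells[flag].astype(bool)
    for flag in rule.exclude:
        mask &= ~cells[flag].astype(bool)
    return cells[mask]


def _per_brain_region_shares(cohort, catalog, rule, region_names,
                             hemispheres="combined"):
    """Per-brain shares of rule-passing inputs over ``region_names``."""
    midline = catalog.midline_names()
    rows = {}
    for brain in cohort:
        passing = apply_colabel_rule(brain, rule)
        canonical = passing["region"].map(catalog.resolve)
        passing = passing[canonical.isin(region_names)]
        canonical = canonical[canonical.isin(region_names)]
        total = len(passing)
        if total == 0:
            raise ValueError(
                f"brain {brain.brain_id} has zero rule-passing inputs"
            )
        if hemispheres == "combined":
            counts = canonical.value_counts()
            rows[brain.brain_id] = pd.Series(
                {n: counts.get(n, 0) / total for n in region_names}
            )
        else:
            hemi = np.where(canonical.isin(list(midline)), "midline",
                            passing["hemisphere"])
            key = pd.Series(
                [f"{r}|{h}" for r, h in zip(canonical, hemi)],
                index=canonical.index,
            )
            counts = key.value_counts()
            rows[brain.brain_id] = counts / total
    out = pd.DataFrame(rows).T.fillna(0.0)
    out.index.name = "brain_id"
    return out


def gaba_composition(cohort: Cohort, catalog: RegionCatalog,
                     hemispheres: str = "combined",
                     pooled: bool = False) -> pd.DataFrame:
    """Region composition of local GABAergic input (% of GABAergic inputs).

    Default reporting is per brain then mean +/- SEM across brains; with
    ``pooled=True`` cells are pooled across brains before taking shares.
    Combined-mode shares sum to 100% over the local regions.
    """
    local_names = [r.name for r in catalog.local()]
    if pooled:
        frames = [apply_colabel_rule(b, GABA_RULE) for b in cohort]
        cells = pd.concat(frames, ignore_index=True)
        canonical = cells["region"].map(catalog.resolve)
        cells = cells[canonical.isin(local_names)]
        canonical = canonical[canonical.isin(local_names)]
        counts = canonical.value_counts()
        share = pd.Series({n: counts.get(n, 0) / len(cells) for n in local_names})
        return pd.DataFrame(
            {"mean_percent": share * 100.0, "sem_percent": np.nan}
        ).rename_axis("region")
    shares = _per_brain_region_shares(
        cohort, catalog, GABA_RULE, local_names, hemispheres
    )
    n = len(shares)
    out = pd.DataFrame(
        {
            "mean_percent": shares.mean() * 100.0,
            "sem_percent": (shares.std(ddof=1) / np.sqrt(n)) * 100.0
            if n > 1
            else np.nan,
        }
    )
    out.index.name = "region" if hemispheres == "combined" else "region|hemisphere"
    return out


#: Default midbrain regions of interest for DA--DA connectivity, as
#: coordinate predicates (region set, ML range in um) on the available axes.
DEFAULT_ROI_SPECS: dict[str, dict] = {
    "VTA_medial": {"regions": ("PBP", "PN", "IF", "Rli"), "ml_range": (None, 250.0)},
    "VTA_central": {"regions": ("PBP", "PN", "IF", "Rli"), "ml_range": (250.0, 500.0)},
    "VTA_lateral": {"regions": ("PBP", "PN", "IF", "Rli"), "ml_range": (500.0, None)},
    "RRF": {"regions": ("RRF",), "ml_range": (None, None)},
}


def da_colabel_fraction(
    cohort: Cohort,
    catalog: RegionCatalog,
    roi_specs: Optional[Mapping[str, Mapping]] = None,
    tva_center: Optional[Sequence[float]] = None,
    tva_radius: float = 500.0,
    return_per_brain: bool = False,
) -> pd.DataFrame:
    """TH+ fraction of eligible inputs per midbrain region of interest.

    The denominator is GFP+ / TC66T- input cells located outside the sphere
    of TVA spread (radius ``tva_radius`` um around ``tva_center``); the
    numerator is the TH+ subset.  ROIs with no eligible cells in a brain are
    missing, not zero, and are excluded from the cross-brain mean.
    """
    roi_specs = dict(roi_specs or DEFAULT_ROI_SPECS)
    denom_rule = ColabelRule(require={"gfp"}, exclude={"tc66t"})
    rows = {}
    for brain in cohort:
        eligible = apply_colabel_rule(brain, denom_rule).copy()
        eligible["region"] = eligible["region"].map(catalog.resolve)
        if tva_radius > 0:
            center = tva_center
            if center is None:
                center = (brain.injection["x_ml"], brain.injection["y_dv"])
            coords = eligible[["x_ml", "y_dv"]]
            if coords.isna().any().any():
                eligible = eligible[coords.notna().all(axis=1)]
                coords = eligible[["x_ml", "y_dv"]]
            dist = np.hypot(coords["x_ml"] - center[0], coords["y_dv"] - center[1])
            eligible = eligible[dist > tva_radius]
        row = {}
        for roi, spec in roi_specs.items():
            sel = eligible[eligible["region"].isin(spec["regions"])]
            lo, hi = spec.get("ml_range", (None, None))
            if lo is not None:
                sel = sel[sel["x_ml"] >= lo]
            if hi is not None:
                sel = sel[sel["x_ml"] < hi]
            row[roi] = (
                float(sel["th"].astype(bool).mean()) if len(sel) else np.nan
            )
        rows[brain.brain_id] = pd.Series(row)
    per_brain = pd.DataFrame(rows).T
    per_brain.index.name = "brain_id"
    n_obs = per_brain.notna().sum()
    summary = pd.DataFrame(
        {
            "mean_th_fraction": per_brain.mean(),
            "sem_th_fraction": per_brain.std(ddof=1) / np.sqrt(n_obs),
            "n_brains": n_obs,
        }
    )
    summary.index.name = "roi"
    if return_per_brain:
        return summary, per_brain
    return summary


def da_total_estimate(vta_rrf_input_share: float, th_fraction: float) -> float:
    """Percent of all inputs that are dopaminergic: share x TH+ fraction x 100."""
    for value in (vta_rrf_input_share, th_fraction):
        if not 0.0 <= value <= 1.0:
            raise ValueError("arguments must be fractions in [0, 1]")
    return vta_rrf_input_share * th_fraction * 100.0


def serotonin_summary(cohort: Cohort, catalog: RegionCatalog,
                      return_per_brain: bool = False) -> pd.DataFrame:
    """Per serotonergic region: Tph2+ fraction and Tph2+ count per 10,000 inputs.

    Hemispheres are reported separately except for the midline raphe groups
    (B3/B7/B8), which are merged.  Regions with zero inputs in a brain are
    missing, not zero, for the fraction; the per-10k count is 0 in that case.
    """
    sero = catalog.serotonergic()
    if not sero:
        raise ValueError("catalog has no serotonergic regions")
    midline = catalog.midline_names()
    keys = []
    for region in sero:
        if region.name in midline:
            keys.append((region.name, "midline"))
        else:
            keys.append((region.name, "ipsi"))
            keys.append((region.name, "contra"))
    frac_rows, per10k_rows = {}, {}
    for brain in cohort:
        inputs = brain.inputs[~brain.inputs["is_starter"].astype(bool)].copy()
        inputs["region"] = inputs["region"].map(catalog.resolve)
        total = len(inputs)
        if total == 0:
            raise ValueError(f"brain {brain.brain_id} has zero input cells")
        hemi = np.where(inputs["region"].isin(list(midline)), "midline",
                        inputs["hemisphere"])
        frac, per10k = {}, {}
        for name, h in keys:
            sel = inputs[(inputs["region"] == name) & (hemi == h)]
            label = f"{name}|{h}"
            n_pos = int(sel["tph2"].astype(bool).sum())
            frac[label] = n_pos / len(sel) if len(sel) else np.nan
            per10k[label] = per_10k_normalization(n_pos, total)
        frac_rows[brain.brain_id] = pd.Series(frac)
        per10k_rows[brain.brain_id] = pd.Series(per10k)
    frac_df = pd.DataFrame(frac_rows).T
    per10k_df = pd.DataFrame(per10k_rows).T
    n_frac = frac_df.notna().sum()
    n = len(frac_df)
    out = pd.DataFrame(
        {
            "tph2_fraction_mean": frac_df.mean(),
            "tph2_fraction_sem": frac_df.std(ddof=1) / np.sqrt(n_frac),
            "per_10k_mean": per10k_df.mean(),
            "per_10k_sem": per10k_df.std(ddof=1) / np.sqrt(n) if n > 1 else np.nan,
        }
    )
    out.index.name = "region|hemisphere"
    if return_per_brain:
        return out, frac_df, per10k_df
    return out
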