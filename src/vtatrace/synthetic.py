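"""Synthetic tracing cohorts with the statistical structure the pipeline assumes.

The generator emulates a monosynaptic rabies-tracing experiment targeting VTA
dopamine neurons:

* per brain, a starter-cell count uniform on 900--2,400, distributed over the
  ventral-midbrain subnuclei at the observed mix (58/27/5/8/2% in
  PBP/PN/IF/SNc/Rli);
* long-range input totals Poisson with mean ``convergence_index x starters``
  (default index 8) and a local input block sized so the expected local share
  of all inputs is ``local_fraction`` (default 0.46), giving ~23,000 inputs
  per brain at the defaults;
* region counts multinomial around a default composition whose anchors come
  from the published input map (VTA subnuclei ~10% of total inputs, SN ~6%,
  RPC+IPN ~4%, VTA+RRF ~11.5%, DR 12.5%);
* between-brain covariance planted through a per-brain Dirichlet mixture over
  three projection archetypes (lateral / uniform / medial), which is what the
  embedding stage is designed to recover;
* marker flags (GAD, TH, Tph2) drawn per cell from per-region rates anchored
  to the published co-label fractions, mutually exclusive within a cell;
* Cre-negative control brains with Poisson background labeling (mean 2.67
  cells for the attenuated TC66T receptor, 3,183 for wild-type TC-B);
* grayscale axon-projection images whose medial--lateral intensity profile is
  increasing (lateral archetype), flat (uniform) or decreasing (medial).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .catalog import RegionCatalog, load_default_catalog

__all__ = [
    "GeneratorConfig",
    "BrainDataset",
    "Cohort",
    "generate_cohort",
    "generate_control_brain",
    "generate_axon_image",
    "generate_two_dataset_scenario",
    "simulate_background_counts",
    "default_composition",
    "default_archetype_loadings",
    "default_colabel_rates",
    "CELL_COLUMNS",
]

#: Column schema for cell tables (one row per labeled cell).
CELL_COLUMNS = [
    "brain_id",
    "region",
    "hemisphere",
    "x_ml",
    "y_dv",
    "gfp",
    "tc66t",
    "gad",
    "th",
    "tph2",
    "is_starter",
]

#: Starter-cell mix over ventral-midbrain subnuclei (whole-brain mapping level).
STARTER_MIX = {"PBP": 0.58, "PN": 0.27, "IF": 0.05, "SNc": 0.08, "Rli": 0.02}

#: Published composition of local GABAergic input sources (% of GABAergic
#: inputs; the remainder is spread over the other local regions).
REFERENCE_GABA_SHARES = {
    "SNr": 20.1,
    "PBP": 19.3,
    "SNc": 10.5,
    "IF": 8.0,
    "PnO": 7.5,
    "PN": 6.2,
    "mRT": 5.5,
    "Rli": 4.8,
    "IPN": 2.8,
    "RRF": 2.5,
    "PPTg": 1.8,
    "PMnR": 1.6,
    "MnR": 1.2,
    "SuM": 1.2,
}
REFERENCE_GABA_OTHER = 6.6

#: Projection archetypes along the medial--lateral axis of the VTA.
ARCHETYPES = ("lateral", "uniform", "medial")

_ARCHETYPE_MEMBERS = {
    "lateral": [
        "SNr", "SNl", "mRT", "SPTg", "SubB", "PnC", "RI", "PT", "InC", "PAG",
        "DStr", "NAcLat", "GPe", "Cortex", "EP", "ZI", "DCN",
    ],
    "uniform": [
        "PSth", "IC", "RPC", "PBP", "PN", "IF", "MnR", "Rli", "SNc", "PMnR",
        "VTg", "MPL", "MM", "SuMx",
        "LH", "PVH", "BNST", "EAM", "CeA", "PBN", "DR",
    ],
    "medial": [
        "IPN", "SuM", "SC", "PnO", "ATg", "RMg", "PPTg", "RRF", "RtTg",
        "MiTg", "DLL",
        "MHb", "LHb", "Septum", "PO", "LDT", "NAcMed", "NAcCore", "VP",
    ],
}

# Mean lateral offset (um from midline) used when placing local input cells.
_LOCAL_ML_MEAN = {
    "PBP": 500.0, "PN": 250.0, "IF": 100.0, "Rli": 80.0, "SNc": 900.0,
    "SNr": 1100.0, "SNl": 1400.0, "RRF": 1200.0,
}
_LOCAL_ML_DEFAULT = 700.0
_LOCAL_ML_SD = 200.0
_DV_MEAN, _DV_SD = -4300.0, 200.0

#: Default injection site (right hemisphere), um from midline / bregma DV.
DEFAULT_INJECTION = {"hemisphere": "right", "x_ml": 400.0, "y_dv": -4300.0}


def default_composition(catalog: Optional[RegionCatalog] = None,
                        local_fraction: float = 0.46) -> dict[str, float]:
    """Default mean fractional composition over the 57 regions.

    Long-range weights sum to ``1 - local_fraction`` and local weights to
    ``local_fraction``.  Anchors: DR 12.5% of total inputs (so the default
    Tph2 rate reproduces the published per-10,000 serotonergic scale), VTA
    subnuclei 10%, substantia nigra 6%, RPC+IPN 4%, VTA+RRF 11.5%.
    """
    if catalog is None:
        catalog = load_default_catalog()
    long_raw = {
        "DR": 0.125, "NAcLat": 0.05, "NAcMed": 0.03, "NAcCore": 0.025,
        "DStr": 0.04, "Cortex": 0.035, "LH": 0.04, "GPe": 0.015, "EP": 0.015,
        "ZI": 0.02, "DCN": 0.01, "BNST": 0.015, "PVH": 0.015, "LHb": 0.025,
        "MHb": 0.01, "Septum": 0.015, "PO": 0.015, "LDT": 0.015, "EAM": 0.005,
        "VP": 0.01, "CeA": 0.005, "PBN": 0.005,
    }
    local_raw = {
        "PBP": 0.055, "PN": 0.025, "IF": 0.020, "SNr": 0.030, "SNc": 0.025,
        "SNl": 0.005, "RPC": 0.020, "IPN": 0.020, "Rli": 0.010, "RRF": 0.015,
        "mRT": 0.017, "MnR": 0.012, "RMg": 0.010, "PnO": 0.009, "PAG": 0.020,
    }
    rest = [r.name for r in catalog.local() if r.name not in local_raw]
    remainder = 0.46 - sum(local_raw.values())
    for name in rest:
        local_raw[name] = remainder / len(rest)
    # Renormalize each block exactly to the requested split.
    lsum = sum(local_raw.values())
    gsum = sum(long_raw.values())
    comp = {k: v * (1.0 - local_fraction) / gsum for k, v in long_raw.items()}
    comp.update({k: v * local_fraction / lsum for k, v in local_raw.items()})
    return {r.name: comp[r.name] for r in catalog}


def default_archetype_loadings(
    catalog: Optional[RegionCatalog] = None,
) -> dict[str, np.ndarray]:
    """One-hot loadings of each region on the three projection archetypes."""
    if catalog is None:
        catalog = load_default_catalog()
    member_of = {}
    for arch, names in _ARCHETYPE_MEMBERS.items():
        for name in names:
            member_of[name] = arch
    loadings = {}
    for region in catalog:
        vec = np.zeros(3)
        vec[ARCHETYPES.index(member_of[region.name])] = 1.0
        loadings[region.name] = vec
    return loadings


def default_colabel_rates(
    catalog: Optional[RegionCatalog] = None,
    composition: Optional[Mapping[str, float]] = None,
) -> dict[str, dict[str, float]]:
    """Per-region GAD/TH/Tph2 positivity rates.

    GAD rates are chosen so that region shares of GABAergic inputs reproduce
    the published composition of local inhibition (rate proportional to
    share/composition, scaled by K=0.08 so every per-cell categorical draw is
    feasible).  TH is 0.40 in the VTA subnuclei and RRF; Tph2 is ~0.30 in the
    serotonergic-group regions.
    """
    if catalog is None:
        catalog = load_default_catalog()
    if composition is None:
        composition = default_composition(catalog)
    gaba_share = {k: v / 100.0 for k, v in REFERENCE_GABA_SHARES.items()}
    named_comp = sum(composition[k] for k in gaba_share)
    other_local = [
        r.name for r in catalog.local() if r.name not in gaba_share
    ]
    other_comp = sum(composition[k] for k in other_local)
    other_ratio = (
        (REFERENCE_GABA_OTHER / 100.0) / other_comp if other_comp > 0 else 0.0
    )
    K = 0.08
    rates: dict[str, dict[str, float]] = {}
    tph2 = {"DR": 0.30, "mRT": 0.30, "MnR": 0.31, "RMg": 0.30,
            "PnO": 0.29, "SPTg": 0.25}
    th_regions = {"PBP", "PN", "IF", "Rli", "RRF"}
    for region in catalog:
        name = region.name
        gad = 0.0
        if region.locality == "local":
            if name in gaba_share and composition[name] > 0:
                gad = K * gaba_share[name] / composition[name]
            else:
                gad = K * other_ratio
        rates[name] = {
            "gad": min(gad, 0.75),
            "th": 0.40 if name in th_regions else 0.0,
            "tph2": tph2.get(name, 0.0),
        }
        total = sum(rates[name].values())
        if total > 1.0:  # keep the categorical draw feasible
            rates[name] = {k: v / total for k, v in rates[name].items()}
    return rates


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic cohort generator.

    Defaults are the conditions of the emulated experiment: 4 brains,
    900--2,400 starters, convergence index 8 long-range inputs per starter,
    46% of inputs local, background means 2.67 (TC66T) and 3,183 (TC-B)
    cells per Cre-negative brain.
    """

    n_brains: int = 4
    starter_range: tuple[int, int] = (900, 2400)
    convergence_index: float = 8.0
    local_fraction: float = 0.46
    composition: Optional[Mapping[str, float]] = None
    archetype_loadings: Optional[Mapping[str, Sequence[float]]] = None
    archetype_strength: float = 0.8
    colabel_rates: Optional[Mapping[str, Mapping[str, float]]] = None
    background_rate_tc66t: float = 2.67
    background_rate_tcb: float = 3183.0
    noise_scale: float = 0.1
    ipsi_fraction: float = 0.75
    seed: int = 0

    def resolved(self, catalog: RegionCatalog) -> "GeneratorConfig":
        """Return a copy with all defaultable fields filled in and validated."""
        comp = dict(
            self.composition
            if self.composition is not None
            else default_composition(catalog, self.local_fraction)
        )
        total = sum(comp.values())
        if any(v < 0 for v in comp.values()):
            raise ValueError("composition weights must be nonnegative")
        if abs(total - 1.0) > 1e-9:
            raise ValueError("composition weights must sum to 1")
        loadings = {
            k: np.asarray(v, dtype=float)
            for k, v in (
                self.archetype_loadings or default_archetype_loadings(catalog)
            ).items()
        }
        if any((v < 0).any() for v in loadings.values()):
            raise ValueError("archetype loadings must be nonnegative")
        rates = self.colabel_rates or default_colabel_rates(catalog, comp)
        for name, r in rates.items():
            if any(not (0.0 <= r.get(m, 0.0) <= 1.0) for m in ("gad", "th", "tph2")):
                raise ValueError(f"invalid co-label rates for {name}")
        if not 0.0 <= self.local_fraction <= 1.0:
            raise ValueError("local_fraction must be in [0, 1]")
        if self.convergence_index <= 0:
            raise ValueError("convergence_index must be positive")
        return dataclasses.replace(
            self, composition=comp, archetype_loadings=loadings, colabel_rates=rates
        )


@dataclass
class BrainDataset:
    """Starter and input cell tables for one brain."""

    brain_id: str
    starters: pd.DataFrame
    inputs: pd.DataFrame
    condition: str = "cre_pos_tc66t"
    injection: Mapping[str, object] = field(
        default_factory=lambda: dict(DEFAULT_INJECTION)
    )

    def cells(self) -> pd.DataFrame:
        return pd.concat([self.starters, self.inputs], ignore_index=True)


@dataclass
class Cohort:
    """A list of brains analyzed together."""

    brains: list[BrainDataset]
    config: Optional[GeneratorConfig] = None

    def __len__(self) -> int:
        return len(self.brains)

    def __iter__(self):
        return iter(self.brains)


def _empty_cells() -> pd.DataFrame:
    df = pd.DataFrame({c: pd.Series(dtype=t) for c, t in zip(
        CELL_COLUMNS,
        [str, str, str, float, float, bool, bool, bool, bool, bool, bool],
    )})
    return df


def _hemispheres(rng, n, regions, midline_names, ipsi_fraction, injection_hemi):
    contra_hemi = "left" if injection_hemi == "right" else "right"
    ipsi = rng.random(n) < ipsi_fraction
    hemi = np.where(ipsi, "ipsi", "contra")
    hemi = np.asarray(hemi, dtype=object)
    hemi[np.isin(regions, list(midline_names))] = "midline"
    return hemi


def _generate_brain(brain_id, cfg: GeneratorConfig, catalog: RegionCatalog,
                    rng: np.random.Generator) -> BrainDataset:
    comp = cfg.composition
    loadings = cfg.archetype_loadings
    names = catalog.names
    midline = catalog.midline_names()

    # --- starter cells ----------------------------------------------------------
    lo, hi = cfg.starter_range
    n_start = int(rng.integers(lo, hi + 1))
    sub_names = list(STARTER_MIX)
    sub_counts = rng.multinomial(n_start, list(STARTER_MIX.values()))
    s_regions = np.repeat(sub_names, sub_counts)
    s_x = rng.normal(DEFAULT_INJECTION["x_ml"], 150.0, n_start)
    s_y = rng.normal(DEFAULT_INJECTION["y_dv"], 150.0, n_start)
    starters = pd.DataFrame(
        {
            "brain_id": brain_id,
            "region": s_regions,
            "hemisphere": "ipsi",
            "x_ml": s_x,
            "y_dv": s_y,
            "gfp": True,
            "tc66t": True,
            "gad": False,
            "th": True,
            "tph2": False,
            "is_starter": True,
        }
    )

    # --- per-brain archetype mixture and region weights -------------------------
    w = rng.dirichlet([2.0, 2.0, 2.0])
    base = np.array([comp[n] for n in names])
    gain = np.array([float(np.dot(w, loadings[n])) for n in names])
    mult = 1.0 + cfg.archetype_strength * (3.0 * gain - 1.0)
    mult = np.clip(mult, 1e-12, None)
    jitter = np.exp(cfg.noise_scale * rng.standard_normal(len(names)))
    weights = base * mult * jitter

    is_local = np.array([catalog.get(n).locality == "local" for n in names])
    p_long = weights * ~is_local
    p_local = weights * is_local

    # --- input totals ------------------------------------------------------------
    n_long = int(rng.poisson(cfg.convergence_index * n_start))
    lf = cfg.local_fraction
    if lf >= 1.0:
        raise ValueError("local_fraction must be < 1 for a finite cohort")
    n_local = int(rng.poisson(cfg.convergence_index * n_start * lf / (1.0 - lf)))

    counts = np.zeros(len(names), dtype=int)
    if n_long > 0:
        if p_long.sum() <= 0:
            raise ValueError("no long-range composition mass")
        counts += rng.multinomial(n_long, p_long / p_long.sum())
    if n_local > 0:
        if p_local.sum() <= 0:
            raise ValueError("no local composition mass")
        counts += rng.multinomial(n_local, p_local / p_local.sum())

    regions = np.repeat(names, counts)
    n_inputs = int(counts.sum())
    hemi = _hemispheres(rng, n_inputs, regions, midline,
                        cfg.ipsi_fraction, DEFAULT_INJECTION["hemisphere"])

    # Coordinates only for local inputs (the co-label sphere filter needs them).
    local_mask = np.isin(regions, [r.name for r in catalog.local()])
    x = np.full(n_inputs, np.nan)
    y = np.full(n_inputs, np.nan)
    ml_mean = np.array(
        [_LOCAL_ML_MEAN.get(r, _LOCAL_ML_DEFAULT) for r in regions]
    )
    x[local_mask] = rng.normal(ml_mean[local_mask], _LOCAL_ML_SD)
    y[local_mask] = rng.normal(_DV_MEAN, _DV_SD, int(local_mask.sum()))

    # Mutually exclusive marker draw with the configured marginal rates.
    rates = cfg.colabel_rates
    p_gad = np.array([rates[r]["gad"] for r in regions])
    p_th = np.array([rates[r]["th"] for r in regions])
    p_tph2 = np.array([rates[r]["tph2"] for r in regions])
    u = rng.random(n_inputs)
    gad = u < p_gad
    th = (~gad) & (u < p_gad + p_th)
    tph2 = (~gad) & (~th) & (u < p_gad + p_th + p_tph2)

    inputs = pd.DataFrame(
        {
            "brain_id": brain_id,
            "region": regions,
            "hemisphere": hemi,
            "x_ml": x,
            "y_dv": y,
            "gfp": True,
            "tc66t": False,
            "gad": gad,
            "th": th,
            "tph2": tph2,
            "is_starter": False,
        }
    )
    return BrainDataset(brain_id=str(brain_id), starters=starters, inputs=inputs)


def generate_cohort(config: GeneratorConfig,
                    catalog: Optional[RegionCatalog] = None) -> Cohort:
    """Generate ``config.n_brains`` synthetic brains.

    Identical ``(config, seed)`` produce identical cohorts.
    """
    if catalog is None:
        catalog = load_default_catalog()
    if config.n_brains < 1:
        raise ValueError("n_brains must be >= 1")
    cfg = config.resolved(catalog)
    rng = np.random.default_rng(cfg.seed)
    brains = [
        _generate_brain(f"brain{i:03d}", cfg, catalog, rng)
        for i in range(cfg.n_brains)
    ]
    return Cohort(brains=brains, config=cfg)


CONTROL_CONDITIONS = ("cre_neg_tc66t", "cre_neg_tcb", "cre_neg_no_aav")


def simulate_background_counts(condition: str, n: int,
                               rng: np.random.Generator,
                               config: Optional[GeneratorConfig] = None) -> np.ndarray:
    """Vectorized Poisson draw of background labeled-cell counts for controls."""
    cfg = config or GeneratorConfig()
    if condition == "cre_neg_tc66t":
        mean = cfg.background_rate_tc66t
    elif condition == "cre_neg_tcb":
        mean = cfg.background_rate_tcb
    elif condition == "cre_neg_no_aav":
        mean = 0.0
    else:
        raise ValueError(f"not a Cre-negative control condition: {condition!r}")
    return rng.poisson(mean, size=n)


def generate_control_brain(condition: str,
                           config: Optional[GeneratorConfig] = None,
                           catalog: Optional[RegionCatalog] = None,
                           brain_id: str = "control000",
                           rng: Optional[np.random.Generator] = None) -> BrainDataset:
    """A Cre-negative control brain: no starters, Poisson background labeling.

    Background cells are placed uniformly over local regions; the condition
    sets the Poisson mean (2.67 for TC66T, 3,183 for TC-B, 0 without AAV).
    """
    if condition not in CONTROL_CONDITIONS:
        raise ValueError(f"not a Cre-negative control condition: {condition!r}")
    cfg = config or GeneratorConfig()
    if catalog is None:
        catalog = load_default_catalog()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n_cells = int(simulate_background_counts(condition, 1, rng, cfg)[0])
    local_names = [r.name for r in catalog.local()]
    regions = rng.choice(local_names, size=n_cells)
    midline = catalog.midline_names()
    hemi = _hemispheres(rng, n_cells, regions, midline, cfg.ipsi_fraction,
                        DEFAULT_INJECTION["hemisphere"])
    inputs = pd.DataFrame(
        {
            "brain_id": brain_id,
            "region": regions,
            "hemisphere": hemi,
            "x_ml": rng.normal(700.0, 400.0, n_cells),
            "y_dv": rng.normal(_DV_MEAN, _DV_SD, n_cells),
            "gfp": True,
            "tc66t": False,
            "gad": False,
            "th": False,
            "tph2": False,
            "is_starter": False,
        }
    ) if n_cells else _empty_cells()
    return BrainDataset(
        brain_id=brain_id,
        starters=_empty_cells(),
        inputs=inputs,
        condition=condition,
    )


def generate_axon_image(archetype: str, width: int, height: int,
                        noise: float = 0.0,
                        seed: Optional[int] = None) -> np.ndarray:
    """Grayscale projection image with a planted medial--lateral gradient.

    Columns run medial (left) to lateral (right).  The expected column mean
    is increasing for ``"lateral"``, flat for ``"uniform"`` and decreasing
    for ``"medial"``; ``noise`` applies multiplicative lognormal jitter.
    """
    if width <= 0 or height <= 0:
        raise ValueError("image dimensions must be positive")
    if archetype == "lateral":
        base = np.linspace(0.2, 1.0, width)
    elif archetype == "medial":
        base = np.linspace(1.0, 0.2, width)
    elif archetype == "uniform":
        base = np.full(width, 0.6)
    else:
        raise ValueError(f"unknown archetype {archetype!r}")
    image = np.tile(base, (height, 1))
    if noise > 0:
        rng = np.random.default_rng(seed)
        image = image * np.exp(noise * rng.standard_normal(image.shape))
    return image


def generate_two_dataset_scenario(
    shared: bool,
    config: Optional[GeneratorConfig] = None,
    catalog: Optional[RegionCatalog] = None,
) -> tuple[Cohort, Cohort]:
    """Two cohorts drawn from one composition (``shared``) or from divergent ones.

    With ``shared=False`` the second cohort's local-region composition is
    resampled (seeded permutation of the local weights plus a systematic
    lognormal perturbation), so region points segregate by dataset in the
    downstream mixing diagnostic while long-range structure stays comparable.
    """
    if catalog is None:
        catalog = load_default_catalog()
    cfg = (config or GeneratorConfig()).resolved(catalog)
    if cfg.n_brains < 1:
        raise ValueError("n_brains must be >= 1")
    cohort_a = generate_cohort(cfg, catalog)
    cfg_b = dataclasses.replace(cfg, seed=cfg.seed + 104729)
    if not shared:
        rng = np.random.default_rng(cfg.seed + 7919)
        comp = dict(cfg.composition)
        local_names = [r.name for r in catalog.local()]
        local_w = np.array([comp[n] for n in local_names])
        perm = rng.permutation(len(local_names))
        local_w = local_w[perm] * np.exp(rng.standard_normal(len(local_names)))
        local_w = local_w / local_w.sum() * cfg.local_fraction
        for name, wgt in zip(local_names, local_w):
            comp[name] = float(wgt)
        cfg_b = dataclasses.replace(cfg_b, composition=comp)
    cohort_b = generate_cohort(cfg_b, catalog)
    return cohort_a, cohort_b
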