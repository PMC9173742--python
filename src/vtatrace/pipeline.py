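"""End-to-end orchestration: simulate -> validate -> quantify -> colabel ->
embed/cluster -> profiles, with a machine-readable YAML report.

A run is fully determined by its configuration and seed: re-running with the
same config produces a byte-identical report.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import colabel as _colabel
from . import embedding as _embedding
from . import profiles as _profiles
from . import quantify as _quantify
from .catalog import RegionCatalog, UnknownRegionError, load_default_catalog
from .io import read_cohort, write_cohort
from .synthetic import (
    ARCHETYPES,
    Cohort,
    GeneratorConfig,
    generate_axon_image,
    generate_cohort,
)

__all__ = ["RunConfig", "run_pipeline", "validate_cohort", "PipelineError"]


class PipelineError(RuntimeError):
    """Stage-tagged pipeline failure."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Single configuration object for a pipeline run."""

    out_dir: str = "vtatrace_run"
    cohort_path: Optional[str] = None  # None -> simulate
    catalog_path: Optional[str] = None
    seed: int = 0
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    # stage toggles
    run_quantify: bool = True
    run_colabel: bool = True
    run_embedding: bool = True
    run_profiles: bool = True
    # embedding parameters
    n_embeddings: int = 20
    n_neighbors: int = 10
    min_dist: float = 0.1
    linkage: str = "average"
    k: Optional[int] = None
    # colabel parameters
    tva_radius: float = 500.0
    hemispheres: str = "combined"
    # profile parameters
    n_bins: int = 100
    images_per_archetype: int = 3
    image_size: tuple[int, int] = (120, 400)
    image_noise: float = 0.1

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        gen = GeneratorConfig(**raw.pop("generator", {}))
        if "image_size" in raw:
            raw["image_size"] = tuple(raw["image_size"])
        return cls(generator=gen, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        gen = d["generator"]
        # only echo scalar generator settings; big maps stay in code/config files
        d["generator"] = {
            k: gen[k]
            for k in (
                "n_brains", "starter_range", "convergence_index",
                "local_fraction", "archetype_strength", "noise_scale",
                "background_rate_tc66t", "background_rate_tcb",
                "ipsi_fraction", "seed",
            )
        }
        d["generator"]["starter_range"] = list(gen["starter_range"])
        d["image_size"] = list(d["image_size"])
        return d


def validate_cohort(cohort: Cohort,
                    catalog: Optional[RegionCatalog] = None) -> dict:
    """Schema and invariant checks; lists violations without aborting."""
    if catalog is None:
        catalog = load_default_catalog()
    violations: list[str] = []
    for brain in cohort:
        cells = brain.cells()
        missing = [c for c in ("region", "hemisphere", "is_starter") if c not in cells]
        if missing:
            violations.append(f"{brain.brain_id}: missing columns {missing}")
            continue
        for name in pd.unique(cells["region"]):
            try:
                catalog.get(name)
            except UnknownRegionError:
                violations.append(f"{brain.brain_id}: unknown region {name!r}")
        for flag in ("gfp", "tc66t", "gad", "th", "tph2"):
            if flag not in cells:
                violations.append(f"{brain.brain_id}: missing marker flag {flag!r}")
        starters = cells[cells["is_starter"].astype(bool)]
        if "gfp" in cells and not starters.empty:
            if not starters["gfp"].astype(bool).all():
                violations.append(f"{brain.brain_id}: starter with gfp=False")
            if not starters["tc66t"].astype(bool).all():
                violations.append(f"{brain.brain_id}: starter with tc66t=False")
        inputs = cells[~cells["is_starter"].astype(bool)]
        if "tc66t" in cells and not inputs.empty:
            if inputs["tc66t"].astype(bool).any():
                violations.append(f"{brain.brain_id}: input cell with tc66t=True")
    return {"n_brains": len(cohort.brains), "violations": violations}


def _round_floats(obj, ndigits=6):
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (float, np.floating)):
        return round(float(obj), ndigits)
    if isinstance(obj, (int, np.integer)):
        return int(obj)
    return obj


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and write outputs plus ``report.yaml``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    catalog = (
        RegionCatalog.from_csv(config.catalog_path)
        if config.catalog_path
        else load_default_catalog()
    )
    report: dict = {"config": config.to_dict(), "stages": []}

    # --- obtain cohort -----------------------------------------------------------
    try:
        if config.cohort_path:
            cohort = read_cohort(config.cohort_path)
        else:
            gen = dataclasses.replace(config.generator, seed=config.seed)
            cohort = generate_cohort(gen, catalog)
            write_cohort(cohort, out / "cohort")
        report["stages"].append("cohort")
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("cohort", str(exc)) from exc

    report["validation"] = validate_cohort(cohort, catalog)

    if config.run_quantify:
        try:
            fm = _quantify.fraction_matrix(cohort, catalog)
            fm.values.to_csv(out / "input_fractions.csv")
            split = _quantify.local_long_split(fm, catalog)
            split.to_csv(out / "local_long_split.csv")
            ci = {
                b.brain_id: _quantify.convergence_index(b, catalog) for b in cohort
            }
            pd.Series(ci, name="convergence_index").to_csv(
                out / "convergence_index.csv"
            )
            comp = {
                b.brain_id: _quantify.starter_composition(b, catalog)
                for b in cohort
                if len(b.starters)
            }
            report["quantify"] = {
                "n_regions": fm.values.shape[1],
                "convergence_index": ci,
                "mean_convergence_index": float(np.mean(list(ci.values()))),
                "local_share_mean": float(split["local"].mean()),
                "long_range_share_mean": float(split["long_range"].mean()),
                "starter_composition_mean": {
                    sub: float(np.mean([c[sub] for c in comp.values()]))
                    for sub in next(iter(comp.values()))
                }
                if comp
                else {},
            }
            report["stages"].append("quantify")
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("quantify", str(exc)) from exc

    if config.run_colabel:
        try:
            gaba = _colabel.gaba_composition(cohort, catalog,
                                             hemispheres=config.hemispheres)
            gaba.to_csv(out / "gaba_composition.csv")
            gaba_hemi = _colabel.gaba_composition(cohort, catalog,
                                                  hemispheres="separate")
            gaba_hemi.to_csv(out / "gaba_by_hemisphere.csv")
            da = _colabel.da_colabel_fraction(cohort, catalog,
                                              tva_radius=config.tva_radius)
            da.to_csv(out / "da_th_fractions.csv")
            sero = _colabel.serotonin_summary(cohort, catalog)
            sero.to_csv(out / "serotonin_summary.csv")
            vta_rrf = [r.name for r in catalog.vta_subnuclei()] + ["RRF"]
            fm = _quantify.fraction_matrix(cohort, catalog)
            share = float(fm.values[vta_rrf].sum(axis=1).mean())
            th_mean = float(da["mean_th_fraction"].mean())
            report["colabel"] = {
                "gaba_top_region": str(gaba["mean_percent"].idxmax()),
                "gaba_top_percent": float(gaba["mean_percent"].max()),
                "vta_rrf_input_share": share,
                "mean_th_fraction": th_mean,
                "da_total_estimate_percent": _colabel.da_total_estimate(
                    min(share, 1.0), min(th_mean, 1.0)
                ),
            }
            report["stages"].append("colabel")
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("colabel", str(exc)) from exc

    if config.run_embedding:
        try:
            fm = _quantify.fraction_matrix(cohort, catalog)
            z = _embedding.zscore_regions(fm)
            seeds = [config.seed * 1000 + i for i in range(config.n_embeddings)]
            embeddings = _embedding.embed_ensemble(
                z.values.to_numpy(),
                n_embeddings=config.n_embeddings,
                n_neighbors=config.n_neighbors,
                min_dist=config.min_dist,
                seeds=seeds,
            )
            mats = [_embedding.normalized_pairwise_distance(e) for e in embeddings]
            agg = _embedding.aggregate_distances(
                mats, region_names=z.region_names, seeds=seeds
            )
            agg.values.to_csv(out / "aggregated_distances.csv")
            clusters = _embedding.cluster_regions(
                agg, k=config.k, linkage=config.linkage
            )
            clusters.labels.rename("cluster").to_csv(out / "cluster_assignment.csv")
            report["embedding"] = {
                "n_embeddings": agg.n_embeddings,
                "k": clusters.k,
                "silhouette": float(clusters.silhouette),
                "linkage": clusters.linkage,
                "cluster_sizes": clusters.labels.value_counts().sort_index()
                .to_dict(),
            }
            report["stages"].append("embedding")
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("embedding", str(exc)) from exc

    if config.run_profiles:
        try:
            h, w = config.image_size
            line = _profiles.ProfileLine(
                start=(h / 2.0, 1.0), end=(h / 2.0, w - 2.0), thickness=min(h - 2, 100)
            )
            profile_table = {}
            for a_idx, archetype in enumerate(ARCHETYPES):
                per_image = []
                for i in range(config.images_per_archetype):
                    image = generate_axon_image(
                        archetype, width=w, height=h,
                        noise=config.image_noise,
                        seed=config.seed * 100 + a_idx * 10 + i,
                    )
                    per_image.append(
                        _profiles.profile_from_image(image, line, config.n_bins)
                    )
                avg = _profiles.average_profiles(per_image, level_out="cluster")
                profile_table[archetype] = avg.values
            df = pd.DataFrame(profile_table)
            df.index.name = "bin"
            df.to_csv(out / "innervation_profiles.csv")
            report["profiles"] = {
                "n_bins": int(df.shape[0]),
                "archetypes": list(df.columns),
            }
            report["stages"].append("profiles")
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("profiles", str(exc)) from exc

    report = _round_floats(report)
    with open(out / "report.yaml", "w") as fh:
        yaml.safe_dump(report, fh, sort_keys=True)
    return report
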