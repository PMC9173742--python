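"""Reading and writing cohorts: one cells CSV per brain plus a YAML manifest."""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .synthetic import BrainDataset, CELL_COLUMNS, Cohort

__all__ = ["write_cohort", "read_cohort"]


def write_cohort(cohort: Cohort, path) -> Path:
    """Write each brain's cells to CSV and a cohort manifest to YAML."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest = {"brains": []}
    for brain in cohort:
        fname = f"cells_{brain.brain_id}.csv"
        cells = brain.cells()[CELL_COLUMNS]
        cells.to_csv(path / fname, index=False)
        manifest["brains"].append(
            {
                "brain_id": brain.brain_id,
                "condition": brain.condition,
                "cells_file": fname,
                "injection": {k: v for k, v in brain.injection.items()},
            }
        )
    with open(path / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return path / "manifest.yaml"


def read_cohort(path) -> Cohort:
    """Load a cohort from a directory containing ``manifest.yaml``."""
    path = Path(path)
    manifest_path = path if path.is_file() else path / "manifest.yaml"
    with open(manifest_path) as fh:
        manifest = yaml.safe_load(fh)
    base = manifest_path.parent
    brains = []
    for entry in manifest["brains"]:
        cells = pd.read_csv(base / entry["cells_file"])
        for col in ("gfp", "tc66t", "gad", "th", "tph2", "is_starter"):
            cells[col] = cells[col].astype(bool)
        starters = cells[cells["is_starter"]].reset_index(drop=True)
        inputs = cells[~cells["is_starter"]].reset_index(drop=True)
        brains.append(
            BrainDataset(
                brain_id=str(entry["brain_id"]),
                starters=starters,
                inputs=inputs,
                condition=entry.get("condition", "cre_pos_tc66t"),
                injection=entry.get("injection", {}),
            )
        )
    return Cohort(brains=brains)
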