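"""TSV/JSON writers and run manifests.

All artifacts are plain text: per-nucleus snapshots, circumferentially
averaged profiles, weighted phase-point streams, survival curves, field
grids (matrix TSV plus axis metadata JSON) and a manifest recording the
configuration hash and seeds of every run directory.
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
import math
import os
from typing import Optional

import numpy as np
import pandas as pd

from .phase_analysis import FieldGrid, SurvivalCurve
from .ssa import LatticeState

__all__ = [
    "RunManifest",
    "write_snapshot_tsv",
    "write_profile_tsv",
    "write_phase_points_tsv",
    "write_survival_tsv",
    "write_field_grid",
]

GENE_NAMES = ("A", "B", "C", "D")


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        return "inf" if isinstance(obj, float) and math.isinf(obj) else float(obj)
    return obj


@dataclasses.dataclass
class RunManifest:
    """Provenance record written once per output directory."""

    command: str
    config: dict
    seed: int
    started: str = ""
    finished: str = ""
    outputs: list = dataclasses.field(default_factory=list)
    config_hash: str = ""

    def __post_init__(self):
        blob = json.dumps(_jsonable(self.config), sort_keys=True).encode()
        self.config_hash = hashlib.sha256(blob).hexdigest()[:16]
        if not self.started:
            self.started = datetime.datetime.now().isoformat(timespec="seconds")

    def finish(self, outputs: list[str]) -> None:
        self.finished = datetime.datetime.now().isoformat(timespec="seconds")
        self.outputs = sorted(outputs)

    def write(self, out_dir) -> str:
        path = os.path.join(out_dir, "manifest.json")
        with open(path, "w") as fh:
            json.dump(_jsonable(dataclasses.asdict(self)), fh, indent=2)
        return path


def write_snapshot_tsv(state: LatticeState, path) -> None:
    """Per-nucleus snapshot: time_s, z, phi, gene, monomers, dimers, bound_sites."""
    rows = []
    bound_per_rep = state.bound.astype(int).sum(axis=1)  # (n_nuc, rep)
    for z in range(state.N_z):
        for f in range(state.N_phi):
            n = z * state.N_phi + f
            for g, name in enumerate(GENE_NAMES):
                rows.append((state.time, z, f, name, state.mono[n, g],
                             state.dimr[n, g], bound_per_rep[n, g]))
    pd.DataFrame(rows, columns=["time_s", "z", "phi", "gene", "monomers",
                                "dimers", "bound_sites"]).to_csv(
        path, sep="\t", index=False)


def write_profile_tsv(states: list[LatticeState], path) -> None:
    """Circumference-summed total copies: time_s, z, gene, total_copies."""
    rows = []
    for st in states:
        per_row = st.totals_per_row()
        for z in range(st.N_z):
            for g, name in enumerate(GENE_NAMES):
                rows.append((st.time, z, name, per_row[z, g]))
    pd.DataFrame(rows, columns=["time_s", "z", "gene", "total_copies"]).to_csv(
        path, sep="\t", index=False)


def write_phase_points_tsv(samples: pd.DataFrame, path) -> None:
    """Weighted phase-point stream (reweighted sampler output)."""
    cols = [c for c in ["time", "lambda_AC", "lambda_BD", "delta_AC", "delta_BD",
                        "weight", "tree_id", "branch_id"] if c in samples.columns]
    samples[cols].rename(columns={"time": "time_s"}).to_csv(path, sep="\t", index=False)


def write_survival_tsv(curve: SurvivalCurve, path) -> None:
    pd.DataFrame({"t_s": curve.times, "S": curve.S}).to_csv(path, sep="\t", index=False)


def write_field_grid(grid: FieldGrid, prefix: str) -> list[str]:
    """Write each populated layer as a matrix TSV plus one axis-metadata JSON.

    Returns the list of files written.
    """
    written = []
    meta = {
        "x_edges": list(map(float, grid.x_edges)),
        "y_edges": list(map(float, grid.y_edges)),
        "layers": [],
        "empty_bins": "masked (blank cells), not zero",
    }
    layers = {"counts": grid.counts, "weight": grid.weight, "vx": grid.vx,
              "vy": grid.vy, "D_lambda": grid.D_lambda,
              "density": grid.density, "potential": grid.potential}
    for name, arr in layers.items():
        if arr is None:
            continue
        a = np.asarray(arr, dtype=float).copy()
        a[grid.mask] = np.nan
        path = f"{prefix}.{name}.tsv"
        pd.DataFrame(a).to_csv(path, sep="\t", index=False, header=False)
        meta["layers"].append(name)
        written.append(path)
    meta_path = f"{prefix}.axes.json"
    with open(meta_path, "w") as fh:
        json.dump(meta, fh, indent=2)
    written.append(meta_path)
    return written
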