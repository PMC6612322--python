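"""Output writers, run manifests, and deterministic test fixtures."""

from __future__ import annotations

import dataclasses
import datetime
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .config import Config, MutationProfile
from .orchestrator import SimulationState

__all__ = ["write_timeseries", "write_snapshot", "write_manifest", "make_fixture"]

ARTIFACT_VERSION = "0.1.0"


def write_timeseries(records: pd.DataFrame, path: str | Path) -> Path:
    """Write a tidy time-series frame as CSV (header, fixed column order)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    records.to_csv(path, index=False, float_format="%.10g")
    return path


def snapshot_frame(state: SimulationState) -> pd.DataFrame:
    """Point-cloud table of a simulation state: one row per living cell and
    per free EGF particle."""
    rows = []
    for c in state.cells:
        rows.append({
            "kind": "cell", "id": c.id,
            "x": c.pos[0], "y": c.pos[1], "z": c.pos[2],
            "radius": c.radius, "phase": c.phase, "active_tf": c.active_tf(),
        })
    for i in range(state.field.n_free):
        p = state.field.pos[i]
        rows.append({
            "kind": "egf", "id": i, "x": p[0], "y": p[1], "z": p[2],
            "radius": state.field.params.r_egf, "phase": "", "active_tf": 0,
        })
    cols = ["kind", "id", "x", "y", "z", "radius", "phase", "active_tf"]
    return pd.DataFrame(rows, columns=cols)


def write_snapshot(state: SimulationState, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    snapshot_frame(state).to_csv(path, index=False, float_format="%.10g")
    return path


def write_manifest(
    config: Config, seed: int, scenario: str, out_dir: str | Path,
    extra: dict | None = None,
) -> Path:
    """Record everything needed to bit-reproduce a run."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "scenario": scenario,
        "seed": int(seed),
        "artifact_version": ARTIFACT_VERSION,
        "written_at": datetime.datetime.now().isoformat(timespec="seconds"),
        "config": config.to_dict(),
    }
    if extra:
        manifest.update(extra)
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path


def make_fixture(kind: str, seed: int, config: Config | None = None) -> SimulationState:
    """Deterministic tiny states for the test suite.

    Kinds: 'single-cell' (one cell, empty field), 'two-cell-overlap' (two
    cells at a prescribed overlapping separation), 'cell-free-field'
    (particles only), 'mini-tumour' (one cell plus a populated field).
    """
    config = config or Config()
    state = SimulationState(config=config, master_seed=seed)
    rng = np.random.default_rng(seed)
    if kind == "single-cell":
        state.add_cell(np.zeros(3))
    elif kind == "two-cell-overlap":
        c1 = state.add_cell(np.zeros(3))
        # separation strictly between hard-core contact and touching
        h0 = 2.0 * config.cell.r_cell
        h1 = 2.0 * config.cell.r_nucleus
        h = (h0 - h1) + 0.75 * h1
        state.add_cell(np.array([h, 0.0, 0.0]))
        assert h0 - h1 < np.linalg.norm(state.cells[1].pos - c1.pos) < h0
    elif kind == "cell-free-field":
        n = rng.poisson(state.field.stationary_mean())
        u = rng.random(n) ** (1.0 / 3.0)
        v = rng.normal(size=(n, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        state.field.pos = config.domain.r_domain * u[:, None] * v
        state.field.degradation_time = rng.exponential(
            1.0 / config.field_.degradation_rate, size=n
        )
    elif kind == "mini-tumour":
        state.add_cell(np.zeros(3), MutationProfile(kras=True))
        n = 40
        u = rng.random(n) ** (1.0 / 3.0)
        v = rng.normal(size=(n, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        pos = config.domain.r_domain * u[:, None] * v
        # keep fixture particles outside the cell body
        outside = np.linalg.norm(pos, axis=1) > config.cell.r_cell + 0.5
        state.field.pos = pos[outside]
        state.field.degradation_time = 1.0 + rng.exponential(
            1.0 / config.field_.degradation_rate, size=int(outside.sum())
        )
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    return state
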