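"""Delimited-text readers/writers and run provenance records."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .bursts import Burst, PhotonTrace
from .exceptions import InvalidInputError
from .profiles import DiffusionProfile

PACKAGE_VERSION = "0.1.0"


def write_traces(traces: list[PhotonTrace], path: str | Path) -> None:
    """One CSV per scan: position_id, transverse_um, tick (16-ps units)."""
    rows = []
    for tr in traces:
        rows.append(pd.DataFrame({
            "position_id": tr.position_id,
            "transverse_um": tr.transverse_um,
            "duration_s": tr.duration_s,
            "tick": tr.timestamps_ticks,
        }))
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def read_traces(path: str | Path) -> list[PhotonTrace]:
    df = pd.read_csv(path)
    required = {"position_id", "transverse_um", "duration_s", "tick"}
    if not required.issubset(df.columns):
        raise InvalidInputError(f"trace file must have columns {sorted(required)}")
    traces = []
    for pid, g in df.groupby("position_id", sort=True):
        traces.append(PhotonTrace(
            np.asarray(g["tick"], dtype=np.int64),
            float(g["duration_s"].iloc[0]),
            int(pid),
            float(g["transverse_um"].iloc[0]),
        ))
    return traces


def write_bursts(bursts: list[Burst], path: str | Path) -> None:
    pd.DataFrame({
        "start_s": [b.start_s for b in bursts],
        "duration_ms": [b.duration_ms for b in bursts],
        "n_photons": [b.n_photons for b in bursts],
        "normalized_intensity": [b.normalized_intensity for b in bursts],
    }).to_csv(path, index=False)


def read_bursts(path: str | Path) -> list[Burst]:
    df = pd.read_csv(path)
    return [Burst(r.start_s, r.duration_ms, int(r.n_photons), r.normalized_intensity)
            for r in df.itertuples()]


def write_profile(profile: DiffusionProfile, path: str | Path) -> None:
    """CSV of coordinate, value, crossing index; JSON sidecar with metadata."""
    path = Path(path)
    pd.DataFrame({
        "coordinate_um": profile.coordinates_um,
        "value": profile.values,
        "crossing": profile.crossing_index(),
    }).to_csv(path, index=False)
    sidecar = {
        "mode": profile.mode,
        "crossing_boundaries": [list(b) for b in profile.crossing_boundaries],
        "metadata": profile.metadata,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_profile(path: str | Path) -> DiffusionProfile:
    path = Path(path)
    df = pd.read_csv(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    return DiffusionProfile(
        np.asarray(df["coordinate_um"], dtype=float),
        np.asarray(df["value"], dtype=float),
        sidecar["mode"],
        [tuple(b) for b in sidecar["crossing_boundaries"]],
        sidecar.get("metadata", {}),
    )


def provenance(config: dict, seed: int | None = None) -> dict:
    """Reproducibility record: config hash, code version, seed."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return {
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "package_version": PACKAGE_VERSION,
        "seed": seed,
    }


def write_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True, default=_jsonable))


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")
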