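"""Plain-text readers and writers.

Time series go to CSV (one column per sweep/channel plus time/command) with
a JSON sidecar of the same stem carrying protocol, parameters, seed and
event windows.  Floats are written with 17 significant digits so a
write/read round trip is bit-identical.  Unknown sidecar keys are preserved
on read and written back (forward compatibility).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import FluorescenceExperiment, MembraneProperties, Recording
from .errors import ParseError
from .params import CellParams, ProtocolSpec
from .survival_sim import SURVIVAL_COLUMNS

FLOAT_FMT = "%.17g"
FORMAT_VERSION = 1

_RECORDING_KEYS = {"format_version", "kind", "protocol", "cell", "cell_id",
                   "condition", "seed", "n_sweeps", "n_samples"}
_FLUOR_KEYS = {"format_version", "kind", "events", "cell_id", "condition",
               "seed", "n_frames", "channels"}


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def _load_sidecar(path: Path, expected_kind: str) -> dict:
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise ParseError(f"missing sidecar {sidecar}")
    try:
        meta = json.loads(sidecar.read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"sidecar {sidecar} is not valid JSON: {exc}") from exc
    if meta.get("kind") != expected_kind:
        raise ParseError(f"sidecar {sidecar}: kind {meta.get('kind')!r}, "
                         f"expected {expected_kind!r}")
    return meta


def write_recording(rec: Recording, path) -> Path:
    """Write a Recording as ``<path>.csv`` plus ``<path>.json``."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    csv_path = path.with_suffix(".csv")
    data = {"time": rec.time_base, "command": rec.command}
    for i, sweep in enumerate(rec.sweeps):
        data[f"sweep_{i:03d}"] = sweep
    pd.DataFrame(data).to_csv(csv_path, index=False, float_format=FLOAT_FMT)
    meta = {
        "format_version": FORMAT_VERSION,
        "kind": "recording",
        "protocol": rec.protocol.to_dict(),
        "cell_id": rec.cell_id,
        "condition": rec.condition,
        "seed": rec.seed,
        "n_sweeps": rec.n_sweeps,
        "n_samples": int(rec.command.size),
    }
    cell = rec.aux.get("cell")
    if isinstance(cell, CellParams):
        meta["cell"] = cell.to_dict()
    meta.update({k: v for k, v in rec.extra.items() if k not in meta})
    _sidecar_path(path).write_text(json.dumps(meta, indent=1, sort_keys=True))
    return csv_path


def read_recording(path) -> Recording:
    """Read a Recording written by :func:`write_recording`.

    A truncated or inconsistent file raises ParseError naming the problem;
    no partial object is returned.
    """
    path = Path(path)
    meta = _load_sidecar(path, "recording")
    csv_path = path.with_suffix(".csv")
    if not csv_path.exists():
        raise ParseError(f"missing data file {csv_path}")
    df = pd.read_csv(csv_path, float_precision="round_trip")
    for col in ("time", "command"):
        if col not in df.columns:
            raise ParseError(f"{csv_path}: missing column {col!r}")
    sweep_cols = sorted(c for c in df.columns if c.startswith("sweep_"))
    if len(sweep_cols) != meta.get("n_sweeps"):
        raise ParseError(f"{csv_path}: {len(sweep_cols)} sweep columns, sidecar "
                         f"declares {meta.get('n_sweeps')}")
    if len(df) != meta.get("n_samples"):
        raise ParseError(f"{csv_path}: {len(df)} samples, sidecar declares "
                         f"{meta.get('n_samples')} (truncated file?)")
    try:
        protocol = ProtocolSpec.from_dict(meta["protocol"])
    except KeyError:
        raise ParseError(f"sidecar for {path} lacks 'protocol'") from None
    aux = {}
    if "cell" in meta:
        aux["cell"] = CellParams.from_dict(meta["cell"])
    extra = {k: v for k, v in meta.items() if k not in _RECORDING_KEYS}
    return Recording(
        sweeps=[df[c].to_numpy() for c in sweep_cols],
        command=df["command"].to_numpy(), time_base=df["time"].to_numpy(),
        protocol=protocol, cell_id=meta.get("cell_id", ""),
        condition=meta.get("condition", ""), seed=meta.get("seed"),
        aux=aux, extra=extra,
    )


def write_fluorescence(expt: FluorescenceExperiment, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    csv_path = path.with_suffix(".csv")
    data = {"time": expt.frame_times, **expt.channels}
    if expt.true_ca is not None:
        data["true_ca"] = expt.true_ca
    pd.DataFrame(data).to_csv(csv_path, index=False, float_format=FLOAT_FMT)
    meta = {
        "format_version": FORMAT_VERSION,
        "kind": "fluorescence",
        "events": {k: list(v) for k, v in expt.events.items()},
        "channels": list(expt.channels.keys()),
        "cell_id": expt.cell_id,
        "condition": expt.condition,
        "seed": expt.seed,
        "n_frames": int(expt.frame_times.size),
    }
    meta.update({k: v for k, v in expt.extra.items() if k not in meta})
    _sidecar_path(path).write_text(json.dumps(meta, indent=1, sort_keys=True))
    return csv_path


def read_fluorescence(path) -> FluorescenceExperiment:
    path = Path(path)
    meta = _load_sidecar(path, "fluorescence")
    csv_path = path.with_suffix(".csv")
    if not csv_path.exists():
        raise ParseError(f"missing data file {csv_path}")
    df = pd.read_csv(csv_path, float_precision="round_trip")
    if "time" not in df.columns:
        raise ParseError(f"{csv_path}: missing column 'time'")
    if len(df) != meta.get("n_frames"):
        raise ParseError(f"{csv_path}: {len(df)} frames, sidecar declares "
                         f"{meta.get('n_frames')} (truncated file?)")
    channels = {}
    for name in meta.get("channels", []):
        if name not in df.columns:
            raise ParseError(f"{csv_path}: missing channel column {name!r}")
        channels[name] = df[name].to_numpy()
    true_ca = df["true_ca"].to_numpy() if "true_ca" in df.columns else None
    extra = {k: v for k, v in meta.items() if k not in _FLUOR_KEYS}
    return FluorescenceExperiment(
        frame_times=df["time"].to_numpy(), channels=channels,
        events={k: tuple(v) for k, v in meta.get("events", {}).items()},
        true_ca=true_ca, cell_id=meta.get("cell_id", ""),
        condition=meta.get("condition", ""), seed=meta.get("seed"), extra=extra,
    )


def write_survival(table: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table[SURVIVAL_COLUMNS].to_csv(path, index=False)
    return path


def read_survival(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"missing file {path}")
    df = pd.read_csv(path)
    missing = [c for c in SURVIVAL_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    return df


def write_properties(props: list, path) -> Path:
    """Per-cell MembraneProperties rows as delimited text."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = []
    for p in props:
        rows.append({
            "cell_id": p.cell_id, "condition": p.condition, "r_n": p.r_n,
            "v_rev": p.v_rev, "e_gaba": p.e_gaba, "driving_force": p.driving_force,
            "v_m": p.v_m, "junction_corrected": p.junction_corrected,
        })
    pd.DataFrame(rows).to_csv(path, index=False, float_format=FLOAT_FMT)
    return path


def read_properties(path) -> list:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"missing file {path}")
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        get = lambda k: None if pd.isna(row[k]) else float(row[k])
        out.append(MembraneProperties(
            r_n=get("r_n"), v_rev=get("v_rev"), e_gaba=get("e_gaba"),
            driving_force=get("driving_force"), v_m=get("v_m"),
            junction_corrected=bool(row["junction_corrected"]),
            cell_id=str(row["cell_id"]), condition=str(row["condition"]),
        ))
    return out
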