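"""Recording file I/O: CSV traces plus a JSON metadata sidecar."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .recording import Recording

__all__ = ["write_recording", "read_recording", "params_hash", "RecordingFormatError"]


class RecordingFormatError(ValueError):
    """Malformed recording CSV."""


def params_hash(params) -> str:
    """Stable short hash of an ElectricalParams set (sidecar provenance)."""
    d = dataclasses.asdict(params)
    blob = json.dumps(d, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def write_recording(rec: Recording, path) -> Path:
    """Write traces as CSV (17 significant digits, lossless float round trip)
    and the metadata as a JSON sidecar next to it."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    header = ",".join(["time_s"] + [f"probe_{p}_V" for p in rec.probes])
    with open(path, "w") as fh:
        fh.write(header + "\n")
        for i in range(rec.n_samples):
            row = [f"{rec.times[i]:.17g}"] + [f"{v:.17g}" for v in rec.V[i]]
            fh.write(",".join(row) + "\n")
    meta = dict(rec.metadata)
    meta["probes"] = list(map(int, rec.probes))
    meta["positions_m"] = [float(x) for x in rec.positions]
    with open(_sidecar(path), "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True, default=str)
    return path


def read_recording(path) -> Recording:
    """Read a recording written by :func:`write_recording`."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().strip()
    cols = header.split(",")
    if not cols or cols[0] != "time_s":
        raise RecordingFormatError(f"{path}:1: header must start with 'time_s'")
    probes = []
    for c in cols[1:]:
        if not (c.startswith("probe_") and c.endswith("_V")):
            raise RecordingFormatError(f"{path}:1: bad trace column {c!r}")
        probes.append(int(c[len("probe_"):-len("_V")]))
    try:
        df = pd.read_csv(path, dtype=float, float_precision="round_trip")
    except Exception as exc:
        lineno = getattr(exc, "lineno", "?")
        raise RecordingFormatError(f"{path}:{lineno}: {exc}") from None
    if df.shape[1] != len(cols):
        raise RecordingFormatError(f"{path}: inconsistent column count")
    meta: dict = {}
    positions = np.full(len(probes), np.nan)
    sc = _sidecar(path)
    if sc.exists():
        meta = json.loads(sc.read_text())
        if "positions_m" in meta:
            positions = np.asarray(meta["positions_m"], float)
    times = df.iloc[:, 0].to_numpy()
    V = df.iloc[:, 1:].to_numpy() if len(probes) else np.empty((len(df), 0))
    return Recording(times=times, V=V, probes=probes,
                     positions=positions, metadata=meta)
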