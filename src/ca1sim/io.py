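"""Trace/feature-table round-tripping and run manifests.

Traces are CSV (columns ``t_ms,v_mV``) with a JSON metadata sidecar; all
floating-point text output uses 6 significant digits for reproducible
diffs.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .simulator import VoltageTrace

__all__ = [
    "write_trace",
    "read_trace",
    "write_traces",
    "read_traces",
    "write_feature_table",
    "read_feature_table",
    "RunManifest",
]

_REQUIRED_META = ("amplitude", "delay", "duration", "protocol")
FLOAT_FMT = "%.6g"


def _fmt(x) -> str:
    return FLOAT_FMT % float(x)


def write_trace(trace: VoltageTrace, path) -> None:
    path = Path(path)
    rows = "\n".join(f"{_fmt(t)},{_fmt(v)}"
                     for t, v in zip(trace.time, trace.voltage))
    path.write_text("t_ms,v_mV\n" + rows + "\n")
    meta = {k: (float(v) if isinstance(v, (int, float, np.floating)) else v)
            for k, v in trace.meta.items()}
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1,
                                                    sort_keys=True))


def read_trace(path) -> VoltageTrace:
    path = Path(path)
    sidecar = path.with_suffix(".json")
    if not sidecar.exists():
        raise FileNotFoundError(f"missing metadata sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    for key in _REQUIRED_META:
        if key not in meta:
            raise ValueError(f"metadata missing required field {key!r}")
    data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    t = data[:, 0]
    if len(t) >= 3:
        dts = np.diff(t)
        if np.max(np.abs(dts - dts[0])) > 1e-3 * abs(dts[0]):
            raise ValueError("non-uniform time base")
    return VoltageTrace(time=t, voltage=data[:, 1], meta=meta)


def write_traces(traces, directory) -> list:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, tr in enumerate(traces):
        name = (f"{tr.meta.get('cell_id', 'cell')}_"
                f"{tr.meta.get('protocol', 'proto')}_{i:03d}.csv")
        write_trace(tr, directory / name)
        paths.append(directory / name)
    return paths


def read_traces(directory) -> list:
    directory = Path(directory)
    return [read_trace(p) for p in sorted(directory.glob("*.csv"))]


def write_feature_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_feature_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


@dataclass
class RunManifest:
    """Provenance record written once per pipeline output directory."""

    command: str
    seeds: dict
    config: dict = field(default_factory=dict)
    inputs: list = field(default_factory=list)
    outputs: list = field(default_factory=list)
    version: str = __version__
    timestamp: str = ""

    def config_hash(self) -> str:
        payload = json.dumps(self.config, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def write(self, directory) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        path = directory / "manifest.json"
        doc = dict(command=self.command, seeds=self.seeds,
                   config=self.config, config_hash=self.config_hash(),
                   inputs=[str(p) for p in self.inputs],
                   outputs=[str(p) for p in self.outputs],
                   version=self.version,
                   timestamp=self.timestamp or time.strftime(
                       "%Y-%m-%dT%H:%M:%S"))
        path.write_text(json.dumps(doc, indent=1, sort_keys=True))
        return path

    @staticmethod
    def read(directory) -> dict:
        return json.loads((Path(directory) / "manifest.json").read_text())
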