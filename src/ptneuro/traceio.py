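"""Reading and writing voltage traces.

Traces are stored as two-column delimited text (t_ms, V_mV) next to a JSON
sidecar with the injected current, sampling step, solver settings and any
parameter values. Values are written with 17 significant digits so the
round trip is bit-exact. An optional HDF5 container mirrors the schema for
multi-trace bundles.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np

from .neuron_models import SolverSettings, VoltageTrace

FORMAT_VERSION = "1"

__all__ = ["write_trace", "read_trace", "write_bundle_h5", "read_bundle_h5"]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_trace(path, trace: VoltageTrace, settings: SolverSettings = None,
                params: dict = None) -> None:
    path = Path(path)
    data = np.column_stack([trace.t, trace.v])
    np.savetxt(path, data, fmt="%.17g", delimiter="\t",
               header="t_ms\tV_mV", comments="# ")
    meta = {
        "format_version": FORMAT_VERSION,
        "i_inj": trace.i_inj,
        "dt": trace.dt,
        "n_samples": len(trace),
        "solver_settings": asdict(settings) if settings else None,
        "params": params,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def read_trace(path):
    """Returns ``(VoltageTrace, metadata dict)``."""
    path = Path(path)
    meta = json.loads(_sidecar_path(path).read_text())
    if meta.get("format_version") != FORMAT_VERSION:
        raise ValueError(f"unsupported trace format: {meta.get('format_version')}")
    data = np.loadtxt(path)
    trace = VoltageTrace(t=data[:, 0], v=data[:, 1],
                         i_inj=meta["i_inj"], dt=meta["dt"])
    return trace, meta


def write_bundle_h5(path, traces: dict, attrs: dict = None) -> None:
    """Write ``{label: VoltageTrace}`` into one HDF5 file."""
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        for k, v in (attrs or {}).items():
            f.attrs[k] = v
        for label, trace in traces.items():
            grp = f.create_group(str(label))
            grp.create_dataset("t", data=trace.t)
            grp.create_dataset("v", data=trace.v)
            grp.attrs["i_inj"] = trace.i_inj
            grp.attrs["dt"] = trace.dt


def read_bundle_h5(path) -> dict:
    import h5py

    traces = {}
    with h5py.File(path, "r") as f:
        for label in f:
            grp = f[label]
            traces[label] = VoltageTrace(
                t=grp["t"][:], v=grp["v"][:],
                i_inj=float(grp.attrs["i_inj"]), dt=float(grp.attrs["dt"]))
    return traces
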