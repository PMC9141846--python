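"""Serialization: array containers with JSON sidecars, delimited-text export.

Numeric artifacts are written as ``.npz`` containers next to a ``.json``
sidecar carrying the metadata needed to reproduce or reinterpret them
(sampling rates, units, seeds, lattice geometry).  Response curves and
phase-diagram matrices are additionally exportable as delimited text with
header rows naming the columns and units.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .ccml import LatticeFieldSeries, LatticeGeometry
from .critical_modes import MultiChannelSeries
from .hopf import ResponseCurve
from .spectra import PhaseDiagramGrid

__all__ = [
    "save_arrays",
    "load_arrays",
    "save_response_curve",
    "load_response_curve",
    "save_field_series",
    "load_field_series",
    "save_multichannel",
    "load_multichannel",
    "save_phase_diagram",
    "load_phase_diagram",
]


def _jsonify(obj):
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def save_arrays(path: str | Path, arrays: dict, meta: dict | None = None) -> None:
    """Write arrays to ``path.npz`` and metadata to ``path.json``."""
    path = Path(path)
    np.savez(path.with_suffix(".npz"), **arrays)
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(_jsonify(meta or {}), fh, indent=2)


def load_arrays(path: str | Path) -> tuple[dict, dict]:
    path = Path(path)
    with np.load(path.with_suffix(".npz")) as npz:
        arrays = {k: npz[k] for k in npz.files}
    sidecar = path.with_suffix(".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return arrays, meta


def save_response_curve(path: str | Path, curve: ResponseCurve) -> None:
    """Delimited-text export with a header naming abscissa and units."""
    label = "forcing_amplitude" if curve.sweep_kind == "forcing" else "omega_rad_per_time"
    header = f"{label}\tamplitude\n# meta: {json.dumps(_jsonify(curve.meta))}"
    np.savetxt(
        path,
        np.column_stack([curve.abscissa, curve.amplitude]),
        delimiter="\t",
        header=header,
    )


def load_response_curve(path: str | Path, sweep_kind: str = "frequency") -> ResponseCurve:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("# # meta:"):
                meta = json.loads(line.split("meta:", 1)[1])
    data = np.loadtxt(path)
    return ResponseCurve(data[:, 0], data[:, 1], sweep_kind, meta)


def save_field_series(path: str | Path, series: LatticeFieldSeries) -> None:
    save_arrays(
        path,
        {"values": series.values},
        {
            "geometry": {"kind": series.geometry.kind, "shape": list(series.geometry.shape),
                         "boundary": series.geometry.boundary},
            "params": series.params,
            "seed": series.seed,
            "units": {"values": "dimensionless field", "time": "map steps"},
        },
    )


def load_field_series(path: str | Path) -> LatticeFieldSeries:
    arrays, meta = load_arrays(path)
    g = meta["geometry"]
    geom = LatticeGeometry(g["kind"], tuple(g["shape"]), g.get("boundary", "periodic"))
    return LatticeFieldSeries(geom, arrays["values"], meta.get("params", {}), meta.get("seed"))


def save_multichannel(path: str | Path, series: MultiChannelSeries) -> None:
    save_arrays(
        path,
        {"data": series.data},
        {
            "fs": series.fs,
            "channel_names": series.channel_names,
            "provenance": {k: v for k, v in series.provenance.items() if k != "A_true"},
            "units": {"data": "arbitrary voltage", "fs": "Hz"},
        },
    )


def load_multichannel(path: str | Path) -> MultiChannelSeries:
    """Load a recording from an ``.npz`` container or delimited text.

    Text input is channels x samples (or samples x channels with
    ``"orientation": "samples_by_channels"`` in the sidecar); the ``.json``
    sidecar must give ``fs`` and may give ``channel_names``.
    """
    path = Path(path)
    if path.suffix in (".csv", ".tsv", ".txt"):
        delim = "," if path.suffix == ".csv" else None
        data = np.loadtxt(path, delimiter=delim)
        meta = json.loads(path.with_suffix(".json").read_text())
        if meta.get("orientation") == "samples_by_channels":
            data = data.T
        return MultiChannelSeries(data, meta["fs"], meta.get("channel_names"),
                                  {"file": str(path)})
    arrays, meta = load_arrays(path)
    return MultiChannelSeries(arrays["data"], meta["fs"], meta.get("channel_names"),
                              meta.get("provenance", {"file": str(path)}))


def save_phase_diagram(path: str | Path, grid: PhaseDiagramGrid) -> None:
    """Entropy and low-frequency-power matrices as TSV plus a JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    for name, mat in (("entropy", grid.entropy),
                      ("low_freq_power", grid.low_freq_power),
                      ("status", grid.status)):
        np.savetxt(path.parent / f"{path.name}_{name}.tsv", mat, delimiter="\t",
                   header="rows: c values; columns: lam values")
    with open(path.parent / f"{path.name}.json", "w") as fh:
        json.dump(_jsonify({
            "c_values": grid.c_values,
            "lam_values": grid.lam_values,
            "run_config": grid.run_config,
            "units": {"entropy": "bits", "low_freq_power": "fraction"},
        }), fh, indent=2)


def load_phase_diagram(path: str | Path) -> PhaseDiagramGrid:
    path = Path(path)
    meta = json.loads((path.parent / f"{path.name}.json").read_text())
    mats = {
        name: np.loadtxt(path.parent / f"{path.name}_{name}.tsv", delimiter="\t", ndmin=2)
        for name in ("entropy", "low_freq_power", "status")
    }
    return PhaseDiagramGrid(
        c_values=np.asarray(meta["c_values"], float),
        lam_values=np.asarray(meta["lam_values"], float),
        entropy=mats["entropy"],
        low_freq_power=mats["low_freq_power"],
        status=mats["status"].astype(int),
        run_config=meta.get("run_config", {}),
    )
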