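"""Readers and writers for sweep tables, HDF5 bundles, and (optionally) ABF.

Two on-disk representations are supported for a :class:`SweepSet`:

``csv``
    A human-inspectable long table with columns ``sweep_id, time_s, value``
    plus a JSON sidecar (``<path>.json``) holding dt, mode, units, holding
    potential and the per-sweep stimulus descriptors.  Floats are written
    with full round-trip precision.

``bundle``
    A single HDF5 file storing samples losslessly (float64), either one
    SweepSet or a whole cohort of neuron records with their truth table.

Axon ABF reading is a thin optional adapter: it maps an ABF file onto a
SweepSet when the ``pyabf`` package is importable and raises
:class:`~tgephys.sweeps.CapabilityError` otherwise.  There is no ABF writer.
"""

from __future__ import annotations

import importlib.util
import json
from io import StringIO
from pathlib import Path
from typing import Optional, Union

import h5py
import numpy as np
import pandas as pd

from .sweeps import (
    CapabilityError,
    NeuronRecord,
    RecordingMeta,
    Stimulus,
    Sweep,
    SweepSet,
    TraceError,
    TraceParseError,
)
from .synth import CohortBundle

FORMATS = ("csv", "bundle", "abf")


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def _stim_dict(s: Stimulus) -> dict:
    return {
        "onset_s": s.onset_s,
        "duration_s": s.duration_s,
        "amplitude_pa": s.amplitude_pa,
        "displacement_um": s.displacement_um,
    }


def write_traces(sweeps: SweepSet, path: Union[str, Path], format: str = "csv") -> Path:
    """Write a SweepSet; the file round-trips losslessly through read_traces."""
    path = Path(path)
    if format == "csv":
        header = {
            "dt": sweeps.dt,
            "mode": sweeps.mode,
            "units": sweeps.units,
            "time_units": "s",
            "holding_potential_mv": sweeps.holding_potential_mv,
            "stimuli": {str(s.sweep_id): _stim_dict(s.stimulus) for s in sweeps},
            "t0": {str(s.sweep_id): s.t0 for s in sweeps},
        }
        with open(path, "w") as fh:
            fh.write("sweep_id,time_s,value\n")
            for s in sweeps:
                t = s.t0 + sweeps.dt * np.arange(s.samples.size)
                for ti, vi in zip(t.tolist(), s.samples.tolist()):
                    fh.write(f"{s.sweep_id},{ti!r},{vi!r}\n")
        _sidecar(path).write_text(json.dumps(header, indent=1))
        return path
    if format == "bundle":
        with h5py.File(path, "w") as h5:
            _write_sweepset(h5, sweeps)
        return path
    raise TraceError(f"unsupported write format {format!r} (csv or bundle)")


def _write_sweepset(grp, sweeps: SweepSet) -> None:
    grp.attrs["dt"] = sweeps.dt
    grp.attrs["mode"] = sweeps.mode
    grp.attrs["units"] = sweeps.units
    if sweeps.holding_potential_mv is not None:
        grp.attrs["holding_potential_mv"] = sweeps.holding_potential_mv
    for s in sweeps:
        d = grp.create_dataset(f"sweep_{s.sweep_id:04d}", data=s.samples)
        d.attrs["sweep_id"] = s.sweep_id
        d.attrs["t0"] = s.t0
        for k, v in _stim_dict(s.stimulus).items():
            if v is not None:
                d.attrs[k] = v


def _read_sweepset(grp) -> SweepSet:
    sweeps = []
    for name in sorted(grp.keys()):
        d = grp[name]
        a = d.attrs
        stim = Stimulus(
            onset_s=float(a["onset_s"]),
            duration_s=float(a["duration_s"]),
            amplitude_pa=float(a["amplitude_pa"]) if "amplitude_pa" in a else None,
            displacement_um=(
                float(a["displacement_um"]) if "displacement_um" in a else None
            ),
        )
        sweeps.append(
            Sweep(int(a["sweep_id"]), d[...], stim, t0=float(a.get("t0", 0.0)))
        )
    hold = grp.attrs.get("holding_potential_mv")
    return SweepSet(
        dt=float(grp.attrs["dt"]),
        mode=str(grp.attrs["mode"]),
        sweeps=sweeps,
        holding_potential_mv=float(hold) if hold is not None else None,
    )


def _read_csv(path: Path) -> SweepSet:
    side = _sidecar(path)
    if not side.exists():
        raise TraceParseError(f"missing sidecar header {side}")
    header = json.loads(side.read_text())
    df = pd.read_csv(
        path,
        dtype={"sweep_id": int, "time_s": float, "value": object},
        float_precision="round_trip",
    )
    raw = df["value"].to_numpy()
    values = np.empty(raw.size, dtype=float)
    for i, v in enumerate(raw):  # float() preserves repr round-trip exactly
        try:
            values[i] = float(v)
        except (TypeError, ValueError):
            values[i] = np.nan
    bad = ~np.isfinite(values)
    if bad.any():
        i = int(np.flatnonzero(bad)[0])
        raise TraceParseError(
            f"non-numeric or non-finite value in sweep {df['sweep_id'].iloc[i]} "
            f"row {i + 2} of {path.name}"
        )
    values = pd.Series(values, index=df.index)
    sweeps = []
    for sid, sub in df.assign(value=values).groupby("sweep_id", sort=True):
        t = sub["time_s"].to_numpy()
        if t.size >= 2:
            steps = np.diff(t)
            if not np.allclose(steps, header["dt"], rtol=1e-9, atol=1e-12):
                raise TraceError(
                    f"sweep {sid}: sample interval differs from declared dt "
                    f"{header['dt']}"
                )
        stim = header["stimuli"].get(str(sid))
        if stim is None:
            raise TraceParseError(f"sweep {sid}: no stimulus in sidecar header")
        sweeps.append(
            Sweep(
                int(sid),
                sub["value"].to_numpy(),
                Stimulus(**stim),
                t0=float(header.get("t0", {}).get(str(sid), t[0] if t.size else 0.0)),
            )
        )
    return SweepSet(
        dt=float(header["dt"]),
        mode=header["mode"],
        sweeps=sweeps,
        holding_potential_mv=header.get("holding_potential_mv"),
    )


def _read_abf(path: Path) -> SweepSet:
    if importlib.util.find_spec("pyabf") is None:
        raise CapabilityError(
            "ABF reading requires the optional 'pyabf' package, which is not "
            "installed; install tgephys[abf] or convert the file to csv/bundle"
        )
    import pyabf  # pragma: no cover - exercised only when pyabf is present

    abf = pyabf.ABF(str(path))
    mode = "current_clamp" if "mV" in abf.adcUnits[0] else "voltage_clamp"
    sweeps = []
    for i in abf.sweepList:
        abf.setSweep(i)
        # ABF epochs are not interpreted; the whole sweep is the window.
        stim = Stimulus(onset_s=0.0, duration_s=len(abf.sweepY) / abf.dataRate)
        sweeps.append(Sweep(i, np.asarray(abf.sweepY, dtype=float), stim))
    return SweepSet(dt=1.0 / abf.dataRate, mode=mode, sweeps=sweeps)


def read_traces(path: Union[str, Path], format: str = "csv") -> SweepSet:
    """Read a SweepSet from ``csv``, ``bundle`` (HDF5) or ``abf``."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "csv":
        return _read_csv(path)
    if format == "bundle":
        with h5py.File(path, "r") as h5:
            return _read_sweepset(h5)
    if format == "abf":
        return _read_abf(path)
    raise TraceError(f"unsupported format {format!r}; expected one of {FORMATS}")


# ---------------------------------------------------------------------------
# cohort bundles


_META_FIELDS = (
    "capacitance_pf",
    "rmp_reported_mv",
    "rs_start_mohm",
    "rs_end_mohm",
    "leak_pa",
    "input_resistance_mohm",
)


def save_cohort(bundle: CohortBundle, path: Union[str, Path]) -> Path:
    """Write a whole cohort (all protocols + truth table) to one HDF5 file."""
    path = Path(path)
    with h5py.File(path, "w") as h5:
        h5.attrs["seed"] = bundle.seed
        h5.attrs["truth_json"] = bundle.truth_table.to_json(orient="table")
        neurons = h5.create_group("neurons")
        for rec in bundle.records:
            g = neurons.create_group(rec.neuron_id)
            for name in _META_FIELDS:
                g.attrs[name] = getattr(rec.meta, name)
            if rec.truth is not None:
                g.attrs["truth_json"] = json.dumps(rec.truth)
            _write_sweepset(g.create_group("ap"), rec.ap_sweeps)
            _write_sweepset(g.create_group("train"), rec.train_sweeps)
            _write_sweepset(g.create_group("ma"), rec.ma_sweeps)
    return path


def load_cohort(path: Union[str, Path]) -> CohortBundle:
    path = Path(path)
    with h5py.File(path, "r") as h5:
        seed = int(h5.attrs["seed"])
        truth = pd.read_json(StringIO(h5.attrs["truth_json"]), orient="table")
        records = []
        for nid in sorted(h5["neurons"].keys()):
            g = h5["neurons"][nid]
            meta = RecordingMeta(**{k: float(g.attrs[k]) for k in _META_FIELDS})
            rec_truth = (
                json.loads(g.attrs["truth_json"]) if "truth_json" in g.attrs else None
            )
            records.append(
                NeuronRecord(
                    neuron_id=nid,
                    meta=meta,
                    ap_sweeps=_read_sweepset(g["ap"]),
                    train_sweeps=_read_sweepset(g["train"]),
                    ma_sweeps=_read_sweepset(g["ma"]),
                    truth=rec_truth,
                )
            )
    return CohortBundle(records=records, truth_table=truth, seed=seed)
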