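"""Sampled-trace data model for whole-cell patch-clamp sweeps.

A :class:`SweepSet` is the substrate every analysis stage operates on: a set
of uniformly sampled sweeps recorded in one clamp mode, each carrying its own
stimulus descriptor (injected current for current clamp, probe displacement
for the piezo-indentation protocol under voltage clamp).  Voltage sweeps are
in mV, current sweeps in pA, time in seconds throughout; readers and writers
never rescale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

CURRENT_CLAMP = "current_clamp"
VOLTAGE_CLAMP = "voltage_clamp"
_MODES = (CURRENT_CLAMP, VOLTAGE_CLAMP)


class TraceError(ValueError):
    """Invalid trace data or violated SweepSet invariant."""


class TraceParseError(TraceError):
    """A sweep file could not be parsed; the message names sweep and row."""


class CapabilityError(RuntimeError):
    """An optional capability (e.g. ABF reading) is unavailable at runtime."""


@dataclass(frozen=True)
class Stimulus:
    """Per-sweep stimulus descriptor.

    ``onset_s``/``duration_s`` delimit the stimulus window within the sweep
    (t = 0 at sweep start).  ``amplitude_pa`` is the injected current for
    current-clamp steps; ``displacement_um`` the probe depth for piezo sweeps.
    """

    onset_s: float
    duration_s: float
    amplitude_pa: Optional[float] = None
    displacement_um: Optional[float] = None

    @property
    def end_s(self) -> float:
        return self.onset_s + self.duration_s


@dataclass
class Sweep:
    sweep_id: int
    samples: np.ndarray  # mV (current clamp) or pA (voltage clamp)
    stimulus: Stimulus
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise TraceError(f"sweep {self.sweep_id}: samples must be 1-D")
        if not np.all(np.isfinite(self.samples)):
            bad = int(np.flatnonzero(~np.isfinite(self.samples))[0])
            raise TraceParseError(
                f"sweep {self.sweep_id}: non-finite sample at row {bad}"
            )
        if self.stimulus is None:
            raise TraceError(f"sweep {self.sweep_id}: missing stimulus descriptor")


@dataclass
class SweepSet:
    """Uniformly sampled sweeps sharing one dt and one clamp mode."""

    dt: float
    mode: str
    sweeps: list[Sweep] = field(default_factory=list)
    holding_potential_mv: Optional[float] = None

    def __post_init__(self) -> None:
        if not (self.dt > 0):
            raise TraceError(f"dt must be positive, got {self.dt}")
        if self.mode not in _MODES:
            raise TraceError(f"mode must be one of {_MODES}, got {self.mode!r}")
        ids = [s.sweep_id for s in self.sweeps]
        if len(set(ids)) != len(ids):
            raise TraceError("duplicate sweep_id in SweepSet")

    def __len__(self) -> int:
        return len(self.sweeps)

    def __iter__(self):
        return iter(self.sweeps)

    def __getitem__(self, i: int) -> Sweep:
        return self.sweeps[i]

    @property
    def units(self) -> str:
        return "mV" if self.mode == CURRENT_CLAMP else "pA"

    def times(self, sweep: Sweep) -> np.ndarray:
        return sweep.t0 + self.dt * np.arange(sweep.samples.size)

    def equal_lengths(self) -> bool:
        ns = {s.samples.size for s in self.sweeps}
        return len(ns) <= 1


@dataclass
class RecordingMeta:
    """Whole-cell recording metadata used for QC and current density."""

    capacitance_pf: float
    rmp_reported_mv: float
    rs_start_mohm: float
    rs_end_mohm: float
    leak_pa: float
    input_resistance_mohm: float

    def __post_init__(self) -> None:
        if not (self.capacitance_pf > 0):
            raise ValueError(f"capacitance must be > 0 pF, got {self.capacitance_pf}")
        for name in ("rs_start_mohm", "rs_end_mohm", "input_resistance_mohm"):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")


@dataclass
class NeuronRecord:
    """One recorded neuron: metadata plus the three protocol sweep sets.

    ``truth`` carries the generating parameters for synthetic neurons and is
    None for imported recordings.
    """

    neuron_id: str
    meta: RecordingMeta
    ap_sweeps: SweepSet
    train_sweeps: SweepSet
    ma_sweeps: SweepSet
    truth: Optional[dict] = None

    def __post_init__(self) -> None:
        if self.ap_sweeps.mode != CURRENT_CLAMP:
            raise TraceError("ap_sweeps must be current clamp")
        if self.train_sweeps.mode != CURRENT_CLAMP:
            raise TraceError("train_sweeps must be current clamp")
        if self.ma_sweeps.mode != VOLTAGE_CLAMP:
            raise TraceError("ma_sweeps must be voltage clamp")


def sweepsets_equal(a: SweepSet, b: SweepSet) -> bool:
    """Field-by-field equality, samples compared element-wise (bit-exact)."""
    if (a.dt, a.mode, a.holding_potential_mv, len(a)) != (
        b.dt,
        b.mode,
        b.holding_potential_mv,
        len(b),
    ):
        return False
    for sa, sb in zip(a.sweeps, b.sweeps):
        if sa.sweep_id != sb.sweep_id or sa.t0 != sb.t0:
            return False
        if sa.stimulus != sb.stimulus:
            return False
        if sa.samples.size != sb.samples.size:
            return False
        if not np.array_equal(sa.samples, sb.samples):
            return False
    return True
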