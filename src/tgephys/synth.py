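"""Synthetic cohort generator.

Generates the three patch-clamp protocols used throughout the package — a
single-AP protocol (brief 1–5 nA pulses), 1-s current-step trains, and a
stepped piezo-indentation protocol under voltage clamp — for single neurons
or whole cohorts parameterized from the packaged nine-group table.  Every
generated neuron retains its drawn ground-truth parameters so that feature
extraction and classification can be scored against the truth.

The AP waveform model is phenomenological (see :mod:`tgephys.waveforms`):
baseline, half-cosine upstroke, a falling phase solved to hit the requested
width at base (dB) and dV/dt hump metric, and an exponential AHP recovery
with time constant AHP80 / ln 5 so that 80% recovery occurs at AHP80.
Mechanically activated (MA) currents decay monoexponentially from their peak
(I = dI * exp(-t/tau)); peak amplitude ramps linearly with probe displacement
from the threshold step to the deepest step.

Trace noise is band-limited Gaussian noise (white noise smoothed over 0.5 ms
and rescaled), emulating the low-pass character of filtered recordings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

from . import _tables
from .sweeps import (
    CURRENT_CLAMP,
    VOLTAGE_CLAMP,
    NeuronRecord,
    RecordingMeta,
    Stimulus,
    Sweep,
    SweepSet,
)
from .waveforms import (
    DEFLECTION,
    DOUBLE_PEAK,
    LINEAR,
    LN5,
    SHAPE_CLASSES,
    ShapeError,
    _total_drop_coeffs,
    rise_voltage,
    solve_falling_phase,
)

DEFAULT_DT = 5e-5  # 20 kHz
DEFAULT_NOISE_MV = 0.3
DEFAULT_NOISE_PA = 2.0
DEFAULT_PRE_S = 0.1  # pre-stimulus baseline in every generated sweep
AP_PULSE_S = 5e-4  # 0.5 ms brief pulse of the single-AP protocol
STEP_DURATION_S = 1.0
STEP_GRID_PA = tuple(range(50, 551, 100))
HOLDING_MV = -60.0


class ParameterError(ValueError):
    """Invalid or unreachable generator parameters."""


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class PiezoProtocol:
    """Stepped piezo-indentation protocol: displacement of sweep k is
    k * step_um (k = 1..n_steps), each held for hold_ms with inter_step_s of
    rest between sweeps."""

    n_steps: int = 10
    step_um: float = 1.5
    hold_ms: float = 300.0
    inter_step_s: float = 10.0

    def __post_init__(self) -> None:
        if int(self.n_steps) != self.n_steps or self.n_steps < 1:
            raise ParameterError(f"n_steps must be a positive integer, got {self.n_steps}")
        if not (self.step_um > 0):
            raise ParameterError(f"step_um must be > 0, got {self.step_um}")
        if not (self.hold_ms > 0):
            raise ParameterError(f"hold_ms must be > 0, got {self.hold_ms}")

    @property
    def displacements_um(self) -> np.ndarray:
        return self.step_um * np.arange(1, self.n_steps + 1)

    @property
    def max_displacement_um(self) -> float:
        return float(self.n_steps * self.step_um)


def make_piezo_protocol(
    n_steps: int = 10,
    step_um: float = 1.5,
    hold_ms: float = 300.0,
    inter_step_s: float = 10.0,
) -> PiezoProtocol:
    """Build a piezo protocol; the default is 10 pokes of 1.5 µm reaching 15 µm."""
    return PiezoProtocol(n_steps, step_um, hold_ms, inter_step_s)


@dataclass(frozen=True)
class APShapeParams:
    """Target action-potential morphology for one neuron.

    ``hump_metric`` (mV/ms, <= 0) is used for the double_peak and deflection
    shape classes; ``ahp_peak`` is the AHP undershoot relative to RMP (<= 0);
    ``ahp80`` the 80%-recovery time in ms.  ``rheobase`` / ``train_rate``
    control the current-step protocol (None = the neuron does not fire to
    1-s steps / does not fire trains).
    """

    rmp: float = -60.0
    peak_v: float = 30.0
    rise_ms: float = 0.7
    target_db: float = 5.0
    shape_class: str = LINEAR
    hump_metric: float = 0.0
    ahp_peak: float = -8.0
    ahp80: float = 20.0
    rheobase: Optional[float] = None
    train_rate: Optional[float] = None

    def __post_init__(self) -> None:
        if self.shape_class not in SHAPE_CLASSES:
            raise ParameterError(f"unknown shape_class {self.shape_class!r}")
        if not (self.target_db > 0):
            raise ParameterError(f"target_db must be > 0 ms, got {self.target_db}")
        if self.ahp80 < 0:
            raise ParameterError(f"ahp80 must be >= 0 ms, got {self.ahp80}")
        if self.ahp_peak > 0:
            raise ParameterError(f"ahp_peak must be <= 0 mV, got {self.ahp_peak}")
        if self.shape_class == DOUBLE_PEAK and self.hump_metric > 0:
            raise ParameterError(
                "double_peak requires hump_metric <= 0 (second dV/dt minimum "
                f"below the intervening maximum), got {self.hump_metric}"
            )
        if not (self.rise_ms > 0):
            raise ParameterError(f"rise_ms must be > 0, got {self.rise_ms}")
        if self.target_db <= self.rise_ms:
            raise ParameterError(
                f"target_db ({self.target_db} ms) must exceed rise_ms ({self.rise_ms} ms)"
            )


@dataclass(frozen=True)
class MAParams:
    """Mechanical-response ground truth for one neuron."""

    responsive: bool = True
    threshold_um: float = 18.0
    max_amp_pa: float = 500.0
    tau_ms: float = 60.0
    rise_ms: float = 2.0
    noise_sd_pa: float = DEFAULT_NOISE_PA
    plateau_frac: float = 0.0  # sustained fraction left after full decay

    def __post_init__(self) -> None:
        if self.responsive:
            if not (self.threshold_um > 0):
                raise ParameterError("responsive neuron needs threshold_um > 0")
            if not (self.max_amp_pa > 0):
                raise ParameterError("responsive neuron needs max_amp_pa > 0")
            if not (self.tau_ms > 0):
                raise ParameterError("responsive neuron needs tau_ms > 0")
        if not (0 <= self.plateau_frac < 1):
            raise ParameterError("plateau_frac must be in [0, 1)")


@dataclass
class GroupSpec:
    """Generating specification for one electrophysiological group."""

    label: str
    n: int
    ap: APShapeParams
    ma: MAParams
    capacitance_pf: float = 80.0
    sem: dict = field(default_factory=dict)  # per-parameter SEM of the mean
    sd_n: int = 1  # N used to convert SEM -> SD (SD = SEM * sqrt(N))
    clip: dict = field(default_factory=dict)  # per-parameter (lo, hi) bounds
    train_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ParameterError(f"group size must be >= 0, got {self.n}")
        for k, (lo, hi) in self.clip.items():
            if lo > hi:
                raise ParameterError(f"clip bounds reversed for {k}")


@dataclass
class NoiseLevels:
    mv: float = DEFAULT_NOISE_MV
    pa: float = DEFAULT_NOISE_PA

    def __post_init__(self) -> None:
        if self.mv < 0 or self.pa < 0:
            raise ParameterError("noise SDs must be >= 0")


@dataclass
class CohortBundle:
    """Synthetic cohort: neuron records plus the generating truth table."""

    records: list
    truth_table: pd.DataFrame
    seed: int

    def __len__(self) -> int:
        return len(self.records)

    @property
    def truth_labels(self) -> pd.Series:
        return self.truth_table.set_index("neuron_id")["label"]


@dataclass
class IHCCounts:
    """Per-section immunohistochemistry counts by joint marker class."""

    table: pd.DataFrame  # columns: section_id, replicate_id, <classes...>, total
    class_names: tuple

    def __post_init__(self) -> None:
        sums = self.table[list(self.class_names)].sum(axis=1)
        if not np.array_equal(sums.to_numpy(), self.table["total"].to_numpy()):
            raise ParameterError("class counts must sum to the section total")
        if (self.table[list(self.class_names)].to_numpy() < 0).any():
            raise ParameterError("counts must be >= 0")


# ---------------------------------------------------------------------------
# noise


def band_noise(rng: np.random.Generator, n: int, sd: float, dt: float,
               smooth_s: float = 5e-4) -> np.ndarray:
    """Band-limited Gaussian noise with the requested sample SD."""
    if sd == 0 or n == 0:
        return np.zeros(n)
    w = max(1, int(round(smooth_s / dt)))
    x = rng.standard_normal(n)
    if w > 1:
        x = uniform_filter1d(x, w, mode="nearest")
        x /= np.sqrt(np.mean(x**2) + 1e-300)
    return sd * x


# ---------------------------------------------------------------------------
# single-trace simulators


def _ap_waveform(params: APShapeParams, dt: float, pre_s: float) -> np.ndarray:
    """Noise-free single-AP sweep samples (adaptive length)."""
    rmp, peak = params.rmp, params.peak_v
    tau_ahp_ms = params.ahp80 / LN5 if params.ahp80 > 0 else 0.0
    if peak <= rmp:  # no spike requested: flat trace at RMP
        n = int(round((pre_s + 0.2) / dt))
        return np.full(n, rmp, dtype=float)
    trough = rmp + params.ahp_peak
    fall = solve_falling_phase(
        params.shape_class,
        peak,
        rmp,
        trough,
        params.target_db - params.rise_ms,
        abs(params.hump_metric),
    )
    post_s = (params.target_db + fall.duration_ms + 6.0 * tau_ahp_ms) / 1e3 + 0.03
    n = int(round((pre_s + params.rise_ms / 1e3 + post_s) / dt))
    t = dt * np.arange(n)
    v = np.full(n, rmp, dtype=float)
    t_on = pre_s
    t_pk = t_on + params.rise_ms / 1e3
    t_tr = t_pk + fall.duration_ms / 1e3
    m = (t >= t_on) & (t < t_pk)
    v[m] = rise_voltage((t[m] - t_on) * 1e3, params.rise_ms, rmp, peak)
    m = (t >= t_pk) & (t < t_tr)
    v[m] = fall.voltage((t[m] - t_pk) * 1e3, peak)
    m = t >= t_tr
    if params.ahp_peak < 0 and tau_ahp_ms > 0:
        v[m] = rmp + params.ahp_peak * np.exp(-(t[m] - t_tr) * 1e3 / tau_ahp_ms)
    else:
        v[m] = trough if params.ahp_peak < 0 else rmp
    return v


def simulate_ap(
    params: APShapeParams,
    dt: float = DEFAULT_DT,
    noise_sd_mv: float = 0.0,
    seed: int = 0,
    pre_s: float = DEFAULT_PRE_S,
    pulse_pa: float = 1000.0,
) -> SweepSet:
    """Simulate one single-AP sweep (brief suprathreshold current pulse).

    With ``noise_sd_mv`` = 0 the waveform is exact: feature extraction
    recovers RMP, dB, shape class, AHP peak and AHP80 to within its stated
    round-trip tolerances.
    """
    if not (5e-5 <= dt <= 5e-4):
        raise ParameterError(f"dt must be within the 2-20 kHz range, got {dt}")
    rng = np.random.default_rng(seed)
    v = _ap_waveform(params, dt, pre_s)
    v = v + band_noise(rng, v.size, noise_sd_mv, dt)
    stim = Stimulus(onset_s=pre_s, duration_s=AP_PULSE_S, amplitude_pa=pulse_pa)
    return SweepSet(dt=dt, mode=CURRENT_CLAMP, sweeps=[Sweep(0, v, stim)])


def simulate_ap_protocol(
    params: APShapeParams,
    dt: float = DEFAULT_DT,
    noise_sd_mv: float = 0.0,
    seed: int = 0,
    pulses_na: Sequence[float] = (1, 2, 3, 4, 5),
    pre_s: float = DEFAULT_PRE_S,
) -> SweepSet:
    """The full single-AP protocol: separate sweeps at 1–5 nA brief pulses."""
    rng = np.random.default_rng(seed)
    base = _ap_waveform(params, dt, pre_s)
    sweeps = []
    for k, i_na in enumerate(pulses_na):
        v = base + band_noise(rng, base.size, noise_sd_mv, dt)
        stim = Stimulus(onset_s=pre_s, duration_s=AP_PULSE_S, amplitude_pa=1e3 * i_na)
        sweeps.append(Sweep(k, v, stim))
    return SweepSet(dt=dt, mode=CURRENT_CLAMP, sweeps=sweeps)


def _spike_template(params: APShapeParams, dt: float) -> np.ndarray:
    """A single spike returning to RMP (no AHP tail), for train insertion."""
    fall = solve_falling_phase(
        params.shape_class,
        params.peak_v,
        params.rmp,
        params.rmp,
        params.target_db - params.rise_ms,
        abs(params.hump_metric),
    )
    n = int(round(params.target_db / 1e3 / dt)) + 1
    t_ms = dt * 1e3 * np.arange(n)
    v = np.where(
        t_ms < params.rise_ms,
        rise_voltage(t_ms, params.rise_ms, params.rmp, params.peak_v),
        fall.voltage(t_ms - params.rise_ms, params.peak_v),
    )
    return v


def simulate_step_responses(
    params: APShapeParams,
    steps_pa: Sequence[float] = STEP_GRID_PA,
    dt: float = DEFAULT_DT,
    seed: int = 0,
    noise_sd_mv: float = 0.0,
    pre_s: float = DEFAULT_PRE_S,
    step_s: float = STEP_DURATION_S,
    tail_s: float = 0.05,
) -> SweepSet:
    """Simulate the 1-s current-step protocol.

    Sweeps at injected currents >= rheobase contain spikes; neurons with a
    ``train_rate`` fire round(train_rate) spikes in the maximal sweep, with
    the count interpolating down to a single spike at rheobase.  Neurons
    without a rheobase stay subthreshold in every sweep.
    """
    steps = [float(s) for s in steps_pa]
    if not steps or any(b <= a for a, b in zip(steps, steps[1:])):
        raise ParameterError("steps_pa must be a nonempty ascending sequence")
    rng = np.random.default_rng(seed)
    n = int(round((pre_s + step_s + tail_s) / dt))
    t = dt * np.arange(n)
    in_step = (t >= pre_s) & (t < pre_s + step_s)
    rheo = params.rheobase
    template = None
    i_max = steps[-1]
    sweeps = []
    for k, i_pa in enumerate(steps):
        v = np.full(n, params.rmp, dtype=float)
        # passive subthreshold depolarization during the step (~8 mV at max)
        v[in_step] += 8.0 * i_pa / i_max
        if rheo is not None and i_pa >= rheo and params.peak_v > params.rmp:
            if template is None:
                template = _spike_template(params, dt)
            if params.train_rate is not None:
                frac = (i_pa - rheo) / (i_max - rheo) if i_max > rheo else 1.0
                n_spikes = max(1, int(round(params.train_rate * frac)))
            else:
                n_spikes = 1
            first = pre_s + 0.02
            interval = step_s / max(n_spikes, 1)
            for j in range(n_spikes):
                i0 = int(round((first + j * interval) / dt))
                i1 = min(i0 + template.size, n)
                if i0 >= n:
                    break
                v[i0:i1] = np.maximum(v[i0:i1], template[: i1 - i0])
        v = v + band_noise(rng, n, noise_sd_mv, dt)
        stim = Stimulus(onset_s=pre_s, duration_s=step_s, amplitude_pa=i_pa)
        sweeps.append(Sweep(k, v, stim))
    return SweepSet(dt=dt, mode=CURRENT_CLAMP, sweeps=sweeps)


def simulate_ma_sweeps(
    params: MAParams,
    protocol: PiezoProtocol,
    dt: float = DEFAULT_DT,
    seed: int = 0,
    pre_s: float = DEFAULT_PRE_S,
    tail_s: float = 0.05,
) -> SweepSet:
    """Simulate the voltage-clamp piezo protocol for one neuron.

    Sweeps below the displacement threshold carry baseline noise only.  At
    and above threshold an inward (negative) current rises within
    ``rise_ms``, peaks at an amplitude ramping linearly with displacement up
    to ``max_amp_pa`` at the deepest step, and decays monoexponentially with
    ``tau_ms`` toward ``plateau_frac`` of the peak; the current returns to
    baseline at stimulus offset.  The amplitude at the threshold step is
    max(6 * noise SD, 10% of the maximal amplitude) so that the fivefold
    positivity rule detects the first responsive sweep.
    """
    rng = np.random.default_rng(seed)
    disps = protocol.displacements_um
    hold_s = protocol.hold_ms / 1e3
    n = int(round((pre_s + hold_s + tail_s) / dt))
    t = dt * np.arange(n)
    responsive = params.responsive
    if responsive and params.threshold_um > protocol.max_displacement_um:
        warnings.warn(
            f"threshold {params.threshold_um} µm beyond the deepest displacement "
            f"{protocol.max_displacement_um} µm: neuron realized as a nonresponder",
            stacklevel=2,
        )
        responsive = False
    amp_at = {}
    if responsive:
        d_thr = disps[disps >= params.threshold_um][0]
        d_max = disps[-1]
        a_thr = min(
            params.max_amp_pa,
            max(6.0 * params.noise_sd_pa, 0.1 * params.max_amp_pa),
        )
        for d in disps:
            if d < d_thr:
                continue
            if d_max > d_thr:
                amp_at[d] = a_thr + (params.max_amp_pa - a_thr) * (d - d_thr) / (d_max - d_thr)
            else:
                amp_at[d] = params.max_amp_pa
    rise_s = params.rise_ms / 1e3
    sweeps = []
    for k, d in enumerate(disps):
        i_trace = np.zeros(n)
        amp = amp_at.get(d)
        if amp is not None:
            t_pk = pre_s + rise_s
            m = (t >= pre_s) & (t < t_pk)
            i_trace[m] = -amp * 0.5 * (1.0 - np.cos(np.pi * (t[m] - pre_s) / rise_s))
            m = (t >= t_pk) & (t < pre_s + hold_s)
            decay = np.exp(-(t[m] - t_pk) * 1e3 / params.tau_ms)
            i_trace[m] = -amp * (params.plateau_frac + (1 - params.plateau_frac) * decay)
        i_trace += band_noise(rng, n, params.noise_sd_pa, dt)
        stim = Stimulus(onset_s=pre_s, duration_s=hold_s, displacement_um=float(d))
        sweeps.append(Sweep(k, i_trace, stim))
    return SweepSet(
        dt=dt, mode=VOLTAGE_CLAMP, sweeps=sweeps, holding_potential_mv=HOLDING_MV
    )


# ---------------------------------------------------------------------------
# cohort generation


def default_group_specs(
    n_scale: float = 1.0,
    noise_pa: float = DEFAULT_NOISE_PA,
) -> list[GroupSpec]:
    """GroupSpecs transcribing the packaged nine-group parameter table."""
    specs = []
    for label, row in _tables.GROUP_TABLE.items():
        shape = row["shape"]
        hump = row["hump"][0] if row["hump"] is not None else 0.0
        if shape == DEFLECTION:
            hump = -max(abs(hump), 0.2)
        ap = APShapeParams(
            rmp=row["rmp"][0],
            peak_v=30.0,
            target_db=row["db"][0],
            shape_class=shape,
            hump_metric=min(hump, 0.0),
            ahp_peak=row["ahp_peak"][0],
            ahp80=row["ahp80"][0],
            rheobase=row["rheobase"][0] if row["rheobase"] else None,
            train_rate=row["train"][0] if row["train"] else None,
        )
        if row["ma"] is not None:
            ma = MAParams(
                responsive=True,
                threshold_um=row["ma"]["threshold"][0],
                max_amp_pa=row["ma"]["max_amp"][0],
                tau_ms=row["ma"]["tau"][0],
                noise_sd_pa=noise_pa,
            )
        else:
            ma = MAParams(responsive=False, noise_sd_pa=noise_pa)
        sem = dict(
            cap=row["cap"][1],
            rmp=row["rmp"][1],
            db=row["db"][1],
            ahp80=row["ahp80"][1],
            ahp_peak=row["ahp_peak"][1],
            peak_v=1.0,
        )
        if row["hump"] is not None:
            sem["hump"] = row["hump"][1]
        if row["rheobase"]:
            sem["rheobase"] = row["rheobase"][1]
        if row["train"]:
            sem["train"] = row["train"][1]
        if row["ma"] is not None:
            sem.update(
                threshold=row["ma"]["threshold"][1],
                max_amp=row["ma"]["max_amp"][1],
                tau=row["ma"]["tau"][1],
            )
        clip = dict(_tables.COMMON_CLIPS)
        clip.update(_tables.GROUP_CLIPS[label])
        clip.setdefault("peak_v", (22.0, 42.0))
        specs.append(
            GroupSpec(
                label=label,
                n=int(round(row["n"] * n_scale)),
                ap=ap,
                ma=ma,
                capacitance_pf=row["cap"][0],
                sem=sem,
                sd_n=row["n"],
                clip=clip,
                train_fraction=row["train_fraction"],
            )
        )
    return specs


def _draw(rng, mean, sem, sd_n, clip):
    if sem is None:
        return mean
    sd = sem * np.sqrt(sd_n)
    x = rng.normal(mean, sd)
    if clip is not None:
        x = float(np.clip(x, *clip))
    return float(x)


def _draw_neuron(spec: GroupSpec, rng: np.random.Generator) -> dict:
    """Draw one neuron's ground-truth parameters around the group means."""
    g = lambda name, mean: _draw(rng, mean, spec.sem.get(name), spec.sd_n, spec.clip.get(name))
    d = dict(label=spec.label)
    d["cap"] = g("cap", spec.capacitance_pf)
    d["rmp"] = g("rmp", spec.ap.rmp)
    d["peak_v"] = g("peak_v", spec.ap.peak_v)
    d["db"] = g("db", spec.ap.target_db)
    d["shape_class"] = spec.ap.shape_class
    d["ahp80"] = g("ahp80", spec.ap.ahp80)
    d["ahp_peak"] = min(g("ahp_peak", spec.ap.ahp_peak), 0.0)
    if spec.ap.shape_class == LINEAR:
        d["hump"] = 0.0
    else:
        hump = g("hump", spec.ap.hump_metric)
        lo, hi = spec.clip.get("hump", (-40.0, 0.0))
        if spec.ap.shape_class == DOUBLE_PEAK:
            # geometric feasibility: keep the main dV/dt lobe at least as
            # deep as the hump so both falling-phase peaks stay resolvable,
            # and keep dB short enough to host a detectable hump within the
            # available peak-to-trough drop
            drop = d["peak_v"] - (d["rmp"] + d["ahp_peak"])
            c1, c0 = _total_drop_coeffs(DOUBLE_PEAK)
            db_cap = spec.ap.rise_ms + drop / (1.3 * (c0 + c1) * abs(hi))
            d["db"] = min(d["db"], db_cap)
            t_fall = d["db"] - spec.ap.rise_ms
            lo = max(lo, -drop / (1.3 * (c0 + c1) * t_fall))
        d["hump"] = float(np.clip(-abs(hump), lo, hi))
    d["rheobase"] = (
        g("rheobase", spec.ap.rheobase) if spec.ap.rheobase is not None else None
    )
    fires = spec.ap.train_rate is not None and rng.random() < spec.train_fraction
    d["train_rate"] = g("train", spec.ap.train_rate) if fires else None
    if d["train_rate"] is not None and d["rheobase"] is None:
        d["rheobase"] = 150.0
    d["responsive"] = spec.ma.responsive
    if spec.ma.responsive:
        d["threshold_um"] = g("threshold", spec.ma.threshold_um)
        d["max_amp_pa"] = g("max_amp", spec.ma.max_amp_pa)
        d["tau_ms"] = g("tau", spec.ma.tau_ms)
    else:
        d["threshold_um"] = None
        d["max_amp_pa"] = None
        d["tau_ms"] = None
    return d


def _params_from_draw(d: dict, noise: NoiseLevels) -> tuple[APShapeParams, MAParams]:
    ap = APShapeParams(
        rmp=d["rmp"],
        peak_v=d["peak_v"],
        target_db=d["db"],
        shape_class=d["shape_class"],
        hump_metric=d["hump"],
        ahp_peak=d["ahp_peak"],
        ahp80=d["ahp80"],
        rheobase=d["rheobase"],
        train_rate=d["train_rate"],
    )
    if d["responsive"]:
        ma = MAParams(
            responsive=True,
            threshold_um=d["threshold_um"],
            max_amp_pa=d["max_amp_pa"],
            tau_ms=d["tau_ms"],
            noise_sd_pa=noise.pa,
        )
    else:
        ma = MAParams(responsive=False, noise_sd_pa=noise.pa)
    return ap, ma


def simulate_cohort(
    specs: Optional[Sequence[GroupSpec]] = None,
    dt: float = DEFAULT_DT,
    noise: Optional[NoiseLevels] = None,
    seed: int = 0,
    protocol: Optional[PiezoProtocol] = None,
) -> CohortBundle:
    """Generate a full cohort: all three protocols per neuron, truth retained.

    ``specs`` defaults to the packaged nine-group table (185 neurons).  The
    piezo protocol defaults to 20 steps of 1.5 µm so that every group's
    displacement threshold lies inside the protocol range.  Reproducible:
    identical seeds yield identical bundles.
    """
    if specs is None:
        specs = default_group_specs()
    noise = noise if noise is not None else NoiseLevels()
    protocol = protocol or PiezoProtocol(n_steps=20)
    rng = np.random.default_rng(seed)
    records, rows = [], []
    idx = 0
    for spec in specs:
        for _ in range(spec.n):
            d = _draw_neuron(spec, rng)
            ap, ma = _params_from_draw(d, noise)
            nid = f"{spec.label}_{idx:04d}"
            sub = rng.integers(0, 2**31 - 1, size=3)
            ap_sweeps = simulate_ap_protocol(ap, dt, noise.mv, int(sub[0]))
            train = simulate_step_responses(
                ap, STEP_GRID_PA, dt, int(sub[1]), noise_sd_mv=noise.mv
            )
            ma_sweeps = simulate_ma_sweeps(ma, protocol, dt, int(sub[2]))
            rs_start = float(rng.uniform(4.0, 8.0))
            meta = RecordingMeta(
                capacitance_pf=d["cap"],
                rmp_reported_mv=d["rmp"],
                rs_start_mohm=rs_start,
                rs_end_mohm=rs_start * float(rng.uniform(1.0, 1.15)),
                leak_pa=float(rng.uniform(0.0, 60.0)),
                input_resistance_mohm=float(rng.uniform(150.0, 500.0)),
            )
            records.append(
                NeuronRecord(
                    neuron_id=nid,
                    meta=meta,
                    ap_sweeps=ap_sweeps,
                    train_sweeps=train,
                    ma_sweeps=ma_sweeps,
                    truth=d,
                )
            )
            rows.append(dict(neuron_id=nid, **d))
            idx += 1
    truth = pd.DataFrame(
        rows,
        columns=[
            "neuron_id", "label", "cap", "rmp", "peak_v", "db", "shape_class",
            "hump", "ahp80", "ahp_peak", "rheobase", "train_rate", "responsive",
            "threshold_um", "max_amp_pa", "tau_ms",
        ],
    )
    return CohortBundle(records=records, truth_table=truth, seed=seed)


# ---------------------------------------------------------------------------
# immunohistochemistry


def simulate_ihc_sections(
    joint_probs: dict,
    cells_per_section: int,
    n_sections: int,
    seed: int = 0,
    n_replicates: int = 1,
) -> IHCCounts:
    """Multinomial per-section cell counts by joint marker class.

    Sections are assigned round-robin to ``n_replicates`` biological
    replicates (one replicate = one animal's ganglion).
    """
    names = tuple(joint_probs)
    p = np.array([joint_probs[k] for k in names], dtype=float)
    if abs(p.sum() - 1.0) > 1e-9:
        raise ParameterError(f"joint probabilities must sum to 1, got {p.sum()!r}")
    if (p < 0).any():
        raise ParameterError("probabilities must be >= 0")
    if cells_per_section <= 0 or n_sections <= 0 or n_replicates <= 0:
        raise ParameterError("counts must be positive")
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(cells_per_section, p, size=n_sections)
    df = pd.DataFrame(counts, columns=list(names))
    df.insert(0, "replicate_id", [i % n_replicates for i in range(n_sections)])
    df.insert(0, "section_id", np.arange(n_sections))
    df["total"] = cells_per_section
    return IHCCounts(table=df, class_names=names)


def default_ihc_probs() -> dict:
    """Packaged joint CGRP x trpV1 composition as probabilities."""
    return {k: v / 100.0 for k, v in _tables.IHC_JOINT_PERCENT.items()}
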