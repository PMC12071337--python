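"""Mechanically activated (MA) current analysis.

Operationalizes the MA measurements of the piezo-indentation protocol:
baseline noise estimation, the fivefold-noise positivity rule per sweep, the
displacement threshold (first responsive sweep), peak amplitude and current
density, and monoexponential decay fitting I = dI * exp(-t / tau) from the
current peak to the stimulus offset.

Amplitudes are reported as magnitudes (positive pA) of inward currents; raw
traces keep the physiological sign (inward = negative).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import linregress
from sklearn.base import BaseEstimator, TransformerMixin

from .sweeps import NeuronRecord, Sweep, SweepSet, TraceError, VOLTAGE_CLAMP
from .synth import PiezoProtocol


class MAError(ValueError):
    """MA measurement cannot be performed on the given sweep."""


class NoDecayError(MAError):
    """The post-peak segment does not decay; no exponential was fitted."""


@dataclass
class ResponseCall:
    """Positivity call for one piezo sweep (fivefold-noise rule)."""

    sweep_id: int
    responsive: bool
    peak_pa: float  # magnitude of the inward peak, baseline-subtracted
    peak_time: float  # s, absolute within the sweep
    noise_sd: float
    displacement_um: Optional[float] = None


@dataclass
class DecayFit:
    delta_i: float  # dI, pA
    tau_ms: float
    rmse: float
    fit_window: tuple

    def __post_init__(self) -> None:
        if not (self.tau_ms > 0):
            raise MAError(f"fitted tau must be > 0, got {self.tau_ms}")


@dataclass
class MAFeatures:
    """Per-neuron mechanical-response record (None fields for nonresponders)."""

    responsive: bool
    threshold_um: Optional[float] = None
    max_peak_pa: Optional[float] = None
    density_pa_per_pf: Optional[float] = None
    tau_ms: Optional[float] = None


def estimate_noise(sweep: Sweep, dt: float, min_baseline_s: float = 0.05) -> float:
    """Baseline noise SD (pA) after removing a linear trend.

    Uses the declared pre-stimulus window; slow drift (e.g. leak creep) is
    removed by least squares so it does not inflate the noise estimate that
    the fivefold positivity rule divides by.
    """
    n = int(round(sweep.stimulus.onset_s / dt))
    if n * dt < min_baseline_s:
        raise MAError(
            f"baseline window {n * dt * 1e3:.1f} ms is shorter than "
            f"{min_baseline_s * 1e3:.0f} ms"
        )
    y = sweep.samples[:n]
    t = np.arange(n, dtype=float)
    resid = y - np.polyval(np.polyfit(t, y, 1), t)
    return float(np.std(resid))


def sweep_response(
    sweep: Sweep,
    dt: float,
    noise_sd: float,
    fold: float = 5.0,
) -> ResponseCall:
    """Call one sweep responsive iff its inward peak is >= fold * noise SD.

    The peak is the largest negative-going excursion within the stimulus
    hold window, relative to the pre-stimulus baseline mean; the boundary is
    inclusive.  A strictly positive peak is additionally required so that a
    perfectly flat (noise-free) baseline sweep is never called responsive.
    """
    stim = sweep.stimulus
    i0 = int(round(stim.onset_s / dt))
    i1 = int(round(stim.end_s / dt))
    base = float(np.mean(sweep.samples[:i0])) if i0 > 0 else 0.0
    window = sweep.samples[i0:i1]
    if window.size == 0:
        raise MAError(f"sweep {sweep.sweep_id}: empty stimulus window")
    k = int(np.argmin(window))
    peak = base - float(window[k])  # inward magnitude
    peak = max(peak, 0.0)
    responsive = (peak >= fold * noise_sd) and (peak > 0.0)
    return ResponseCall(
        sweep_id=sweep.sweep_id,
        responsive=bool(responsive),
        peak_pa=peak,
        peak_time=(i0 + k) * dt,
        noise_sd=noise_sd,
        displacement_um=stim.displacement_um,
    )


def ma_threshold(
    calls: Sequence[ResponseCall], protocol: PiezoProtocol
) -> Optional[float]:
    """Displacement (µm) of the first responsive sweep; None if none is."""
    if len(calls) != protocol.n_steps:
        raise MAError(
            f"{len(calls)} response calls for a {protocol.n_steps}-step protocol"
        )
    for call, disp in zip(calls, protocol.displacements_um):
        if call.responsive:
            return float(disp)
    return None


def fit_decay(
    sweep: Sweep,
    dt: float,
    peak_time: float,
    stim_end: Optional[float] = None,
    min_samples: int = 20,
) -> DecayFit:
    """Least-squares monoexponential fit I = dI * exp(-t/tau) after the peak.

    Fitted on the baseline-subtracted inward magnitude from the current peak
    to the stimulus offset.  Initialized from a log-domain linear regression;
    raises :class:`NoDecayError` when the window shows no decaying trend.
    """
    stim_end = stim_end if stim_end is not None else sweep.stimulus.end_s
    i0 = int(round(peak_time / dt))
    i1 = int(round(stim_end / dt))
    if i1 - i0 < min_samples:
        raise MAError(f"fit window has {i1 - i0} samples, need >= {min_samples}")
    nbase = int(round(sweep.stimulus.onset_s / dt))
    base = float(np.mean(sweep.samples[:nbase])) if nbase > 0 else 0.0
    y = base - sweep.samples[i0:i1]  # inward magnitude
    t = dt * np.arange(y.size)
    slope = linregress(t, y).slope
    if slope >= 0 or y[0] <= 0:
        raise NoDecayError("no decay detected in the post-peak window")
    pos = y > max(1e-12, 1e-6 * y[0])
    if pos.sum() >= 2:
        lr = linregress(t[pos], np.log(y[pos]))
        tau0 = -1.0 / lr.slope if lr.slope < 0 else t[-1]
        a0 = float(np.exp(lr.intercept))
    else:
        tau0, a0 = t[-1] / 3, float(y[0])
    tau0 = float(np.clip(tau0, dt, 100 * t[-1]))
    popt, _ = curve_fit(
        lambda tt, a, tau: a * np.exp(-tt / tau),
        t,
        y,
        p0=(a0, tau0),
        bounds=([0.0, dt / 10.0], [np.inf, np.inf]),
        maxfev=10000,
    )
    a, tau = float(popt[0]), float(popt[1])
    if tau <= 0 or a <= 0:
        raise NoDecayError("exponential fit did not converge to a decay")
    rmse = float(np.sqrt(np.mean((y - a * np.exp(-t / tau)) ** 2)))
    return DecayFit(
        delta_i=a, tau_ms=tau * 1e3, rmse=rmse, fit_window=(peak_time, stim_end)
    )


def persistent_threshold(
    calls: Sequence[ResponseCall],
    protocol: PiezoProtocol,
    min_responsive: int = 2,
) -> Optional[float]:
    """Displacement of the first *persistently* responsive sweep.

    A genuine mechanical response persists: every sweep at and above the
    threshold displacement exceeds the fivefold-noise criterion, whereas a
    noise excursion trips a single sweep.  The neuron is a responder only if
    at least ``min_responsive`` sweeps are responsive, and the threshold is
    the first responsive sweep that is followed by another responsive sweep
    (or is the deepest sweep).  On noise-free or single-sweep data this
    reduces to the plain first-responsive-sweep rule.
    """
    if len(calls) != protocol.n_steps:
        raise MAError(
            f"{len(calls)} response calls for a {protocol.n_steps}-step protocol"
        )
    flags = [c.responsive for c in calls]
    if sum(flags) < min(min_responsive, len(calls)):
        return None
    disps = protocol.displacements_um
    for i, flag in enumerate(flags):
        if flag and (i + 1 == len(flags) or flags[i + 1]):
            return float(disps[i])
    return None


def summarize_ma(
    sweeps: SweepSet,
    protocol: PiezoProtocol,
    capacitance_pf: float,
    fold: float = 5.0,
    min_responsive: int = 2,
) -> MAFeatures:
    """Threshold, peak amplitude, current density and decay tau for one neuron.

    Responsiveness requires persistence (see :func:`persistent_threshold`).
    The maximal amplitude and the decay tau are measured on the deepest
    responsive sweep (largest signal-to-noise); density is the per-neuron
    ratio amplitude / capacitance.  Nonresponders yield an all-None record.
    """
    if sweeps.mode != VOLTAGE_CLAMP:
        raise TraceError("MA analysis requires voltage-clamp sweeps")
    if capacitance_pf <= 0:
        raise MAError(f"capacitance must be > 0 pF, got {capacitance_pf}")
    dt = sweeps.dt
    calls = []
    for sweep in sweeps:
        noise_sd = estimate_noise(sweep, dt)
        calls.append(sweep_response(sweep, dt, noise_sd, fold))
    threshold = persistent_threshold(calls, protocol, min_responsive)
    if threshold is None:
        return MAFeatures(responsive=False)
    deepest = max(
        (c for c in calls if c.responsive), key=lambda c: c.displacement_um
    )
    sweep = next(s for s in sweeps if s.sweep_id == deepest.sweep_id)
    try:
        tau = fit_decay(sweep, dt, deepest.peak_time).tau_ms
    except NoDecayError:
        tau = None
    return MAFeatures(
        responsive=True,
        threshold_um=threshold,
        max_peak_pa=deepest.peak_pa,
        density_pa_per_pf=deepest.peak_pa / capacitance_pf,
        tau_ms=tau,
    )


def response_table(sweeps: SweepSet, fold: float = 5.0) -> pd.DataFrame:
    """Per-sweep diagnostics: displacement, peak, responsiveness."""
    dt = sweeps.dt
    rows = []
    for sweep in sweeps:
        call = sweep_response(sweep, dt, estimate_noise(sweep, dt), fold)
        rows.append(
            dict(
                sweep_id=call.sweep_id,
                displacement_um=call.displacement_um,
                peak_pa=call.peak_pa,
                noise_sd_pa=call.noise_sd,
                responsive=call.responsive,
            )
        )
    return pd.DataFrame(rows)


class MAFeatureExtractor(BaseEstimator, TransformerMixin):
    """Transformer mapping neuron records to the MA feature table."""

    def __init__(self, fold: float = 5.0, protocol: Optional[PiezoProtocol] = None):
        self.fold = fold
        self.protocol = protocol

    def fit(self, X=None, y=None):
        return self

    def _protocol_for(self, record: NeuronRecord) -> PiezoProtocol:
        if self.protocol is not None:
            return self.protocol
        disps = [s.stimulus.displacement_um for s in record.ma_sweeps]
        if not disps or any(d is None for d in disps):
            raise MAError(f"{record.neuron_id}: piezo sweeps lack displacements")
        step = disps[0]
        hold_ms = record.ma_sweeps[0].stimulus.duration_s * 1e3
        return PiezoProtocol(n_steps=len(disps), step_um=step, hold_ms=hold_ms)

    def transform(self, X: Sequence[NeuronRecord]) -> pd.DataFrame:
        records = getattr(X, "records", X)
        rows = []
        for rec in records:
            f = summarize_ma(
                rec.ma_sweeps,
                self._protocol_for(rec),
                rec.meta.capacitance_pf,
                self.fold,
            )
            rows.append(
                dict(
                    neuron_id=rec.neuron_id,
                    MA_responsive=f.responsive,
                    MA_threshold_um=f.threshold_um,
                    MA_max_current_pA=f.max_peak_pa,
                    MA_current_density_pA_per_pF=f.density_pa_per_pf,
                    MA_tau_ms=f.tau_ms,
                )
            )
        return pd.DataFrame(rows)
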