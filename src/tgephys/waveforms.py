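"""Parametric action-potential waveform construction.

The waveform family is deliberately minimal: a resting baseline, a
half-cosine upstroke, a repolarization whose time derivative (dV/dt) is a
piecewise cosine-blended profile, and an exponential afterhyperpolarization
(AHP) recovery.  The repolarization profile template fixes the *shape* of the
falling-phase dV/dt curve — a single lobe (``linear``), two lobes separated
by a saddle (``double_peak``, the classic "hump"/"bow"), or a flat-bottomed
plateau with a shallow internal dip (``deflection``) — while two free scale
parameters (total falling duration T and profile depth p) are solved
numerically so that

* the total voltage drop runs from the AP peak to the AHP trough, and
* the falling phase crosses resting potential exactly at the requested AP
  width at base (dB).

The hump metric (second dV/dt minimum minus the intervening maximum) is hit
exactly by construction because it enters the template as an absolute offset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

DOUBLE_PEAK = "double_peak"
DEFLECTION = "deflection"
LINEAR = "linear"
SHAPE_CLASSES = (DOUBLE_PEAK, DEFLECTION, LINEAR)

# ln 5: an exponential recovery has decayed by 80% after tau * ln 5.
LN5 = float(np.log(5.0))


class ShapeError(ValueError):
    """Requested AP geometry is unreachable within the waveform family."""


def _template(shape_class: str, p: float, h: float):
    """Knot values (mV/ms) and u-axis weights of the dV/dt profile.

    ``p`` > 0 is the main profile depth, ``h`` >= 0 the hump offset.  Knots
    are joined by half-cosine blends, so profile extrema sit exactly on the
    knots and the profile is continuously differentiable.
    """
    if shape_class == LINEAR:
        return [0.0, -p, 0.0], [0.5, 0.5]
    if shape_class == DOUBLE_PEAK:
        # first lobe to -p, saddle at -p/4, second lobe h below the saddle
        return (
            [0.0, -p, -0.25 * p, -0.25 * p - h, 0.0],
            [0.15, 0.30, 0.25, 0.30],
        )
    if shape_class == DEFLECTION:
        # wide flat plateau at -p with a shallow internal dip of depth h
        return [0.0, -p, -p - h, -p, 0.0], [0.10, 0.40, 0.40, 0.10]
    raise ShapeError(f"unknown shape class {shape_class!r}")


def _piece_integral(va: float, vb: float, s: np.ndarray) -> np.ndarray:
    """∫_0^s of the cosine blend between va and vb (s in [0, 1], unit width)."""
    s = np.asarray(s, dtype=float)
    return va * s + 0.5 * (vb - va) * (s - np.sin(np.pi * s) / np.pi)


def _cumulative_drop(values, weights, u: np.ndarray) -> np.ndarray:
    """-∫_0^u g(u') du' for the normalized profile (positive = voltage drop)."""
    u = np.atleast_1d(np.asarray(u, dtype=float))
    edges = np.concatenate([[0.0], np.cumsum(weights)])
    out = np.zeros_like(u)
    base = 0.0
    for i, w in enumerate(weights):
        va, vb = values[i], values[i + 1]
        lo, hi = edges[i], edges[i + 1]
        inside = u > lo
        s = np.clip((u[inside] - lo) / w, 0.0, 1.0)
        out[inside] = base - w * _piece_integral(va, vb, s)
        base -= w * _piece_integral(va, vb, np.array(1.0))
        out[u >= hi] = base
    return out


def _total_drop_coeffs(shape_class: str):
    """Total normalized drop is c1*p + c0*h (linear in the two scales)."""
    v1, w = _template(shape_class, 1.0, 0.0)
    c1 = -sum(wi * (v1[i] + v1[i + 1]) / 2.0 for i, wi in enumerate(w))
    v0, w = _template(shape_class, 0.0, 1.0)
    c0 = -sum(wi * (v0[i] + v0[i + 1]) / 2.0 for i, wi in enumerate(w))
    return c1, c0


def _crossing_u(values, weights, frac: float) -> float:
    """u at which the cumulative drop reaches ``frac`` of the total drop."""
    total = float(_cumulative_drop(values, weights, np.array([1.0]))[0])
    target = frac * total
    edges = np.concatenate([[0.0], np.cumsum(weights)])
    cum = _cumulative_drop(values, weights, edges)
    for i in range(len(weights)):
        if cum[i + 1] >= target - 1e-12 * total:
            w = weights[i]
            va, vb = values[i], values[i + 1]
            need = target - cum[i]

            # g(s) = drop accumulated within this piece minus what is needed
            def g(s):
                return -w * float(_piece_integral(va, vb, np.array(s))) - need

            if abs(g(1.0)) < 1e-14:
                s = 1.0
            else:
                s = brentq(g, 0.0, 1.0, xtol=1e-14)
            return float(edges[i] + s * w)
    return 1.0


@dataclass(frozen=True)
class FallingPhase:
    """Solved falling-phase geometry (time in ms, voltages in mV)."""

    shape_class: str
    duration_ms: float  # AP peak -> AHP trough
    depth: float  # p, profile scale in mV/ms
    hump: float  # h, >= 0
    values: tuple
    weights: tuple

    def voltage(self, t_ms: np.ndarray, peak_v: float) -> np.ndarray:
        u = np.clip(np.asarray(t_ms, dtype=float) / self.duration_ms, 0.0, 1.0)
        drop = _cumulative_drop(list(self.values), list(self.weights), u)
        return peak_v - self.duration_ms * drop


def solve_falling_phase(
    shape_class: str,
    peak_v: float,
    rmp: float,
    trough_v: float,
    fall_to_rmp_ms: float,
    hump: float = 0.0,
) -> FallingPhase:
    """Solve (T, p) so the repolarization hits dB and the trough exactly.

    ``fall_to_rmp_ms`` is the time from the AP peak to the downward RMP
    crossing (dB minus the upstroke rise time).  ``hump`` is the magnitude
    (>= 0) of the hump/dip offset in mV/ms; ignored for ``linear``.
    """
    if shape_class not in SHAPE_CLASSES:
        raise ShapeError(f"unknown shape class {shape_class!r}")
    h = 0.0 if shape_class == LINEAR else float(abs(hump))
    d_tot = peak_v - trough_v
    d1 = peak_v - rmp
    if d_tot <= 0 or d1 <= 0:
        raise ShapeError("AP peak must lie above RMP and trough")
    if trough_v > rmp:
        raise ShapeError("AHP trough cannot sit above RMP")
    if fall_to_rmp_ms <= 0:
        raise ShapeError("dB leaves no time for the falling phase")
    c1, c0 = _total_drop_coeffs(shape_class)

    if trough_v == rmp:
        # no undershoot: the profile ends exactly at the RMP crossing
        T = fall_to_rmp_ms
        p = (d_tot / T - c0 * h) / c1
        if p <= 0:
            raise ShapeError("hump too deep for the requested dB and amplitudes")
        v, w = _template(shape_class, p, h)
        return FallingPhase(shape_class, T, p, h, tuple(v), tuple(w))

    frac = d1 / d_tot

    def crossing_time(T: float) -> float:
        p = (d_tot / T - c0 * h) / c1
        if p <= 0:
            return np.inf
        v, w = _template(shape_class, p, h)
        return T * _crossing_u(v, w, frac)

    t_lo = fall_to_rmp_ms * 1.0001
    t_hi = d_tot / (c0 * h + 1e-9) if h > 0 else 60.0 * fall_to_rmp_ms
    t_hi = min(t_hi * 0.999, 60.0 * fall_to_rmp_ms)
    if t_hi <= t_lo:
        raise ShapeError("hump too deep for the requested dB and amplitudes")
    grid = np.geomspace(t_lo, t_hi, 80)
    vals = np.array([crossing_time(T) - fall_to_rmp_ms for T in grid])
    ok = np.isfinite(vals)
    sign_change = None
    for i in range(len(grid) - 1):
        if ok[i] and ok[i + 1] and vals[i] * vals[i + 1] <= 0:
            sign_change = (grid[i], grid[i + 1])
            break
    if sign_change is None:
        raise ShapeError(
            f"no feasible {shape_class} falling phase for peak {peak_v} mV, "
            f"RMP {rmp} mV, trough {trough_v} mV, dB segment {fall_to_rmp_ms} ms, "
            f"hump {hump} mV/ms"
        )
    T = brentq(
        lambda T: crossing_time(T) - fall_to_rmp_ms, *sign_change, xtol=1e-12
    )
    p = (d_tot / T - c0 * h) / c1
    v, w = _template(shape_class, p, h)
    return FallingPhase(shape_class, float(T), float(p), h, tuple(v), tuple(w))


def rise_voltage(t_ms: np.ndarray, rise_ms: float, rmp: float, peak_v: float):
    """Half-cosine upstroke from RMP to the AP peak."""
    s = np.clip(np.asarray(t_ms, dtype=float) / rise_ms, 0.0, 1.0)
    return rmp + (peak_v - rmp) * 0.5 * (1.0 - np.cos(np.pi * s))
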