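"""Action-potential feature extraction from current-clamp sweeps.

Implements the per-neuron AP morphology measurements used for grouping:
resting membrane potential (RMP), AP width at the RMP level (dB), the
falling-phase dV/dt profile and its shape class (double_peak / deflection /
linear) with the signed hump metric, afterhyperpolarization peak and 80%
recovery time (AHP80), and the current-step train analysis (rheobase, train
firing, maximal rate).

Shape classification works on a smoothed falling-phase derivative.  Local
dV/dt minima are detected with a prominence threshold; when two minima exist
the hump metric is the refined value of the later minimum minus the
intervening local maximum (<= 0 when a genuine hump exists).  Profiles with
a single minimum are split into ``deflection`` (a wide, flat-bottomed
plateau) and ``linear`` (a narrow single lobe) by the fraction of the
falling phase spent below half of the profile minimum: a single smooth lobe
spends two thirds of its duration there, a plateau nearly all of it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d
from scipy.signal import find_peaks, savgol_filter
from sklearn.base import BaseEstimator, TransformerMixin

from .sweeps import CURRENT_CLAMP, NeuronRecord, Sweep, SweepSet, TraceError
from .waveforms import DEFLECTION, DOUBLE_PEAK, LINEAR


class FeatureError(ValueError):
    """A feature cannot be measured from the given trace."""


@dataclass(frozen=True)
class APPeak:
    index: int
    time_s: float
    voltage_mv: float


@dataclass
class DvdtProfile:
    """Falling-phase dV/dt between the AP peak and the AHP trough.

    ``dvdt`` is the lightly smoothed derivative used for reported hump
    values; ``dvdt_detect`` is a heavily smoothed copy used only to locate
    extrema robustly under recording noise.
    """

    t_ms: np.ndarray  # time from AP peak
    v_mv: np.ndarray
    dvdt: np.ndarray  # lightly smoothed derivative, mV/ms
    dvdt_detect: np.ndarray  # heavily smoothed derivative for detection
    minima_idx: np.ndarray  # prominence-thresholded dV/dt minima (detect)
    minima_val: np.ndarray  # refined values at the minima (light profile)
    prominences: np.ndarray


@dataclass
class AHPResult:
    peak_mv: float  # trough voltage minus RMP, <= 0
    ahp80_ms: float
    censored: bool = False


@dataclass
class TrainResult:
    rheobase_pa: Optional[float]
    fires_train: bool
    train_rate_hz: Optional[float]


@dataclass
class APFeatures:
    """Per-neuron AP morphology record."""

    rmp: float
    ap_peak: Optional[float]
    db_ms: Optional[float]
    shape_class: Optional[str]
    hump_metric: Optional[float]
    ahp_peak: float = 0.0
    ahp80_ms: float = 0.0
    ahp_censored: bool = False
    rheobase_pa: Optional[float] = None
    fires_train: bool = False
    train_rate_hz: Optional[float] = None


# ---------------------------------------------------------------------------
# elementary measurements


def estimate_rmp(sweep: Sweep, dt: float, min_baseline_s: float = 0.01) -> float:
    """Mean voltage over the declared pre-stimulus baseline window."""
    n = int(round(sweep.stimulus.onset_s / dt))
    if n * dt < min_baseline_s:
        raise FeatureError(
            f"baseline window {n * dt * 1e3:.1f} ms is shorter than "
            f"{min_baseline_s * 1e3:.0f} ms"
        )
    return float(np.mean(sweep.samples[:n]))


def detect_ap(
    sweep: Sweep,
    dt: float,
    rmp: float,
    excursion_mv: float = 40.0,
    overshoot_mv: float = 0.0,
) -> Optional[APPeak]:
    """Locate the earliest spike peak, or None.

    A spike is an excursion beyond ``rmp + excursion_mv`` or beyond
    ``overshoot_mv`` absolute, whichever level is reached first.  The peak is
    the voltage maximum of the first above-level region.
    """
    level = min(rmp + excursion_mv, overshoot_mv)
    above = sweep.samples > level
    if not above.any():
        return None
    start = int(np.argmax(above))
    below = np.flatnonzero(~above[start:])
    end = start + (int(below[0]) if below.size else above.size - start)
    i = start + int(np.argmax(sweep.samples[start:end]))
    return APPeak(index=i, time_s=i * dt, voltage_mv=float(sweep.samples[i]))


def _interp_crossing(t0, t1, v0, v1, level):
    if v1 == v0:
        return t1
    return t0 + (level - v0) * (t1 - t0) / (v1 - v0)


def measure_db(sweep: Sweep, dt: float, rmp: float, ap: APPeak) -> float:
    """AP width at the RMP level (ms), with linear interpolation.

    Duration between the last upward crossing of RMP before the peak and the
    first downward crossing after it.
    """
    v = sweep.samples
    eps = 1e-6  # guards against RMP estimates a float ULP off the baseline
    before = np.flatnonzero(v[: ap.index] <= rmp + eps)
    if before.size == 0:
        raise FeatureError("no upward RMP crossing before the AP peak")
    i = int(before[-1])
    t_up = _interp_crossing(i * dt, (i + 1) * dt, v[i], v[i + 1], rmp)
    after = np.flatnonzero(v[ap.index :] <= rmp + eps)
    if after.size == 0:
        raise FeatureError("unterminated AP: trace never returns to RMP")
    j = ap.index + int(after[0])
    t_dn = _interp_crossing((j - 1) * dt, j * dt, v[j - 1], v[j], rmp)
    return (t_dn - t_up) * 1e3


def _refine(y: np.ndarray, i: int) -> float:
    """Parabolic sub-sample refinement of an extremum value at index i."""
    if i <= 0 or i >= y.size - 1:
        return float(y[i])
    denom = y[i + 1] - 2 * y[i] + y[i - 1]
    if denom == 0:
        return float(y[i])
    return float(y[i] - (y[i + 1] - y[i - 1]) ** 2 / (8 * denom))


def _find_trough(v: np.ndarray, dt: float, rmp: float, ap: APPeak,
                 smooth_s: float = 1e-3, tol_mv: float = 0.5) -> int:
    """Index of the AHP trough (or RMP-return sample if no undershoot).

    Returns the earliest entry into the trough basin (first sample within
    ``tol_mv`` of the post-AP minimum of a smoothed copy): slow AHPs are
    nearly flat around their minimum, so a plain argmin would jitter by
    milliseconds under recording noise.
    """
    after = np.flatnonzero(v[ap.index :] <= rmp + 1e-6)
    if after.size == 0:
        raise FeatureError("unterminated AP: trace never returns to RMP")
    j = ap.index + int(after[0])
    w = max(1, int(round(smooth_s / dt)))
    seg = uniform_filter1d(v[j:], w, mode="nearest") if w > 1 else v[j:]
    return j + int(np.flatnonzero(seg <= seg.min() + tol_mv)[0])


def _savgol_deriv(seg: np.ndarray, dt: float, w: int) -> np.ndarray:
    n = seg.size
    w = min(w if w % 2 == 1 else w + 1, n if n % 2 == 1 else n - 1)
    w = max(w, 3)
    return savgol_filter(seg, w, min(3, w - 1), deriv=1, delta=dt) / 1e3


def falling_phase_profile(
    sweep: Sweep,
    dt: float,
    rmp: float,
    ap: APPeak,
    trough_index: Optional[int] = None,
    smooth_divisor: int = 16,
    detect_divisor: int = 4,
    min_window: int = 5,
    prominence: float = 2.5,
    rel_prominence: float = 0.12,
) -> DvdtProfile:
    """Smoothed dV/dt (mV/ms) between the AP peak and the AHP trough.

    Savitzky-Golay derivative windows scale with the falling-phase duration
    (1/``smooth_divisor`` of its samples for the reported profile,
    1/``detect_divisor`` for extremum detection), so shape measures are
    invariant to uniform time rescaling of the sweep.  The extremum
    prominence threshold is the larger of ``prominence`` (mV/ms) and
    ``rel_prominence`` times the profile depth, which keeps spurious
    noise dips subcritical on fast, steep repolarizations.
    """
    v = sweep.samples
    j = trough_index if trough_index is not None else _find_trough(v, dt, rmp, ap)
    seg = v[ap.index : j + 1]
    n = seg.size
    if n < 5:
        raise FeatureError("falling phase too short to differentiate")
    dvdt = _savgol_deriv(seg, dt, max(min_window, n // smooth_divisor))
    detect = _savgol_deriv(seg, dt, max(min_window, n // detect_divisor))
    prom = max(prominence, rel_prominence * float(-detect.min()))
    idx, props = find_peaks(-detect, prominence=prom)
    # report extremum values from the light profile, searched near the
    # detected locations
    half = max(2, n // (2 * detect_divisor))
    vals = []
    for i in idx:
        lo, hi = max(0, i - half), min(n, i + half + 1)
        k = lo + int(np.argmin(dvdt[lo:hi]))
        vals.append(_refine(dvdt, k))
    return DvdtProfile(
        t_ms=dt * 1e3 * np.arange(n),
        v_mv=seg,
        dvdt=dvdt,
        dvdt_detect=detect,
        minima_idx=idx,
        minima_val=np.asarray(vals),
        prominences=props.get("prominences", np.array([])),
    )


def classify_falling_phase(
    profile: DvdtProfile,
    h_cut: float = -5.0,
    flat_cut: float = 0.68,
    rel_depth: float = 0.25,
) -> tuple[str, Optional[float]]:
    """Shape class and hump metric from a falling-phase dV/dt profile.

    A double peak requires two detected minima whose hump (second minimum
    minus intervening maximum, on the detection profile) is both below
    ``h_cut`` and at least ``rel_depth`` of the second minimum's depth — a
    genuine hump rises well toward zero between the two dV/dt peaks,
    whereas differentiation ripple on a steep plateau does not.  Returns
    ``(shape_class, hump_metric)``; the hump metric is None for the linear
    class and ~0 for plateau-only deflections.
    """
    dvdt = profile.dvdt
    detect = profile.dvdt_detect
    n = dvdt.size
    hump = None
    if profile.minima_idx.size >= 2:
        order = np.argsort(profile.prominences)[::-1][:2]
        pair = np.sort(profile.minima_idx[order])
        i1, i2 = int(pair[0]), int(pair[1])
        k = i1 + int(np.argmax(detect[i1 : i2 + 1]))
        # the class decision uses the heavily smoothed profile (robust to
        # noise); the reported metric comes from the light profile, searched
        # near the robust locations
        m2_detect = _refine(detect, i2)
        h_detect = m2_detect + _refine(-detect, k)
        half = max(2, n // 8)
        lo, hi = max(i1, i2 - half), min(n, i2 + half + 1)
        j2 = lo + int(np.argmin(dvdt[lo:hi]))
        m2 = _refine(dvdt, j2)
        lo, hi = max(i1, k - half), min(i2 + 1, k + half + 1)
        jk = lo + int(np.argmax(dvdt[lo:hi]))
        mid = -_refine(-dvdt, jk)
        hump = m2 - mid
        if h_detect <= h_cut and abs(h_detect) >= rel_depth * abs(m2_detect):
            return DOUBLE_PEAK, float(hump)
    vmin = float(dvdt.min())
    if vmin >= 0:
        return LINEAR, None
    flat_frac = float(np.mean(dvdt <= 0.5 * vmin))
    if flat_frac >= flat_cut:
        return DEFLECTION, float(hump) if hump is not None else 0.0
    return LINEAR, None


def _ahp_pass(seg: np.ndarray, dt: float, rmp: float, w: int) -> AHPResult:
    s = uniform_filter1d(seg, w, mode="nearest") if w > 1 else seg
    k = int(np.argmin(s))
    trough_v = _refine(s, k)
    # sub-sample trough time: the falling phase enters the trough with zero
    # slope while the recovery leaves it with finite slope, so the kink is
    # located by extrapolating the early rising branch back to the trough
    # level.  Keeps AHP80 accurate when the recovery spans few samples.
    t_k = float(k)
    i1 = k + max(2, w // 2 + 1)
    i2 = i1 + max(2, w)
    if i2 < s.size and s[i2] > s[i1] > trough_v:
        slope = (s[i2] - s[i1]) / (i2 - i1)
        t0 = i1 - (s[i1] - trough_v) / slope
        t_k = float(np.clip(t0, k - 1.0, k + 1.0))
    depth = trough_v - rmp
    level = trough_v + 0.8 * (rmp - trough_v)
    rec = np.flatnonzero(s[k:] >= level)
    if rec.size == 0:
        return AHPResult(float(depth), (s.size - 1 - t_k) * dt * 1e3, censored=True)
    r = k + int(rec[0])
    if r == k:
        t80 = 0.0
    else:
        t_c = _interp_crossing((r - 1) * dt, r * dt, s[r - 1], s[r], level)
        t80 = max(t_c - t_k * dt, 0.0)
    return AHPResult(float(depth), float(t80 * 1e3))


def measure_ahp(
    sweep: Sweep,
    dt: float,
    rmp: float,
    ap: APPeak,
    min_undershoot_mv: float = 1.0,
    max_smooth_s: float = 2e-3,
) -> AHPResult:
    """AHP peak (mV below RMP) and 80% recovery time (ms).

    Both are 0 when the trace does not undershoot RMP by at least
    ``min_undershoot_mv`` after the AP.  The post-AP segment is smoothed
    before the trough and recovery crossing are located; the window adapts
    to the recovery duration (a rough unsmoothed pass sets the scale) so
    short AHPs are not blurred and long noisy recoveries are denoised.  If
    the 80% level is not reached within the sweep, AHP80 is censored at the
    sweep end.
    """
    v = sweep.samples
    after = np.flatnonzero(v[ap.index :] <= rmp + 1e-6)
    if after.size == 0:
        return AHPResult(0.0, 0.0)
    seg = v[ap.index + int(after[0]) :]
    rough = _ahp_pass(seg, dt, rmp, max(1, int(round(2.5e-4 / dt))))
    if rough.peak_mv > -min_undershoot_mv:
        return AHPResult(0.0, 0.0)
    w = int(round(max(rough.ahp80_ms, 0.5) / 40.0 * 1e-3 / dt))
    w = int(np.clip(w, 1, max(1, round(max_smooth_s / dt))))
    res = _ahp_pass(seg, dt, rmp, w)
    if res.peak_mv > -min_undershoot_mv:
        return AHPResult(0.0, 0.0)
    return res


def count_spikes(
    sweep: Sweep,
    dt: float,
    threshold_mv: float = 0.0,
    refractory_ms: float = 1.0,
) -> int:
    """Upward crossings of ``threshold_mv`` with a refractory lockout."""
    v = sweep.samples
    up = np.flatnonzero((v[1:] > threshold_mv) & (v[:-1] <= threshold_mv)) + 1
    if up.size == 0:
        return 0
    lock = max(1, int(round(refractory_ms / 1e3 / dt)))
    count, last = 0, -lock - 1
    for i in up:
        if i - last > lock:
            count += 1
            last = i
    return count


def analyze_train(
    step_sweeps: SweepSet,
    threshold_mv: float = 0.0,
    refractory_ms: float = 1.0,
    train_min_spikes: int = 3,
) -> TrainResult:
    """Rheobase, train firing and maximal rate from the current-step protocol."""
    if step_sweeps.mode != CURRENT_CLAMP:
        raise TraceError("train analysis requires current-clamp sweeps")
    if not step_sweeps.equal_lengths():
        raise TraceError("step sweeps have unequal durations")
    rheobase = None
    max_count = 0
    best_duration = None
    for sweep in step_sweeps:
        if sweep.stimulus.amplitude_pa is None:
            raise TraceError(f"sweep {sweep.sweep_id} lacks an injected-current value")
        c = count_spikes(sweep, step_sweeps.dt, threshold_mv, refractory_ms)
        if c >= 1 and (
            rheobase is None or sweep.stimulus.amplitude_pa < rheobase
        ):
            rheobase = float(sweep.stimulus.amplitude_pa)
        if c > max_count:
            max_count = c
            best_duration = sweep.stimulus.duration_s
    if max_count == 0:
        return TrainResult(None, False, None)
    rate = max_count / best_duration
    return TrainResult(rheobase, max_count >= train_min_spikes, float(rate))


# ---------------------------------------------------------------------------
# per-neuron extraction


def extract_ap_features(
    ap_sweeps: SweepSet,
    train_sweeps: Optional[SweepSet] = None,
    *,
    excursion_mv: float = 40.0,
    overshoot_mv: float = 0.0,
    smooth_divisor: int = 16,
    detect_divisor: int = 4,
    prominence: float = 2.5,
    rel_prominence: float = 0.12,
    h_cut: float = -5.0,
    flat_cut: float = 0.68,
    refractory_ms: float = 1.0,
    train_min_spikes: int = 3,
) -> APFeatures:
    """All AP features for one neuron.

    The measured sweep is the lowest-amplitude single-AP sweep that elicits
    a spike; the train metrics come from the step protocol.
    """
    dt = ap_sweeps.dt
    ordered = sorted(
        ap_sweeps,
        key=lambda s: s.stimulus.amplitude_pa if s.stimulus.amplitude_pa else 0.0,
    )
    rmp = None
    chosen, peak = None, None
    for sweep in ordered:
        r = estimate_rmp(sweep, dt)
        p = detect_ap(sweep, dt, r, excursion_mv, overshoot_mv)
        if p is not None:
            rmp, chosen, peak = r, sweep, p
            break
    if chosen is None:
        rmp = estimate_rmp(ordered[0], dt)
        feats = APFeatures(rmp=rmp, ap_peak=None, db_ms=None, shape_class=None,
                           hump_metric=None)
    else:
        db = measure_db(chosen, dt, rmp, peak)
        trough = _find_trough(chosen.samples, dt, rmp, peak)
        profile = falling_phase_profile(
            chosen, dt, rmp, peak, trough,
            smooth_divisor=smooth_divisor, detect_divisor=detect_divisor,
            prominence=prominence, rel_prominence=rel_prominence,
        )
        shape, hump = classify_falling_phase(profile, h_cut, flat_cut)
        ahp = measure_ahp(chosen, dt, rmp, peak)
        feats = APFeatures(
            rmp=rmp,
            ap_peak=peak.voltage_mv,
            db_ms=db,
            shape_class=shape,
            hump_metric=hump,
            ahp_peak=ahp.peak_mv,
            ahp80_ms=ahp.ahp80_ms,
            ahp_censored=ahp.censored,
        )
    if train_sweeps is not None and len(train_sweeps):
        tr = analyze_train(train_sweeps, refractory_ms=refractory_ms,
                           train_min_spikes=train_min_spikes)
        feats.rheobase_pa = tr.rheobase_pa
        feats.fires_train = tr.fires_train
        feats.train_rate_hz = tr.train_rate_hz
    return feats


class APFeatureExtractor(BaseEstimator, TransformerMixin):
    """Transformer mapping neuron records to an AP feature table.

    Stateless (fit is a no-op); parameters are the measurement tunables.
    Output columns follow the reporting convention of the per-group feature
    tables (Cap_pF, RMP_mV, dB_ms, dVdt_mV_per_ms, AHP80_ms, AHPpeak_mV,
    APThresh_pA, APTrain_Hz) plus ``shape_class`` and ``fires_train``.
    """

    def __init__(
        self,
        smooth_divisor: int = 16,
        detect_divisor: int = 4,
        prominence: float = 2.5,
        rel_prominence: float = 0.12,
        h_cut: float = -5.0,
        flat_cut: float = 0.68,
        excursion_mv: float = 40.0,
        overshoot_mv: float = 0.0,
        refractory_ms: float = 1.0,
        train_min_spikes: int = 3,
    ):
        self.smooth_divisor = smooth_divisor
        self.detect_divisor = detect_divisor
        self.prominence = prominence
        self.rel_prominence = rel_prominence
        self.h_cut = h_cut
        self.flat_cut = flat_cut
        self.excursion_mv = excursion_mv
        self.overshoot_mv = overshoot_mv
        self.refractory_ms = refractory_ms
        self.train_min_spikes = train_min_spikes

    def fit(self, X=None, y=None):
        return self

    def transform(self, X: Sequence[NeuronRecord]) -> pd.DataFrame:
        records = getattr(X, "records", X)
        rows = []
        for rec in records:
            f = extract_ap_features(
                rec.ap_sweeps,
                rec.train_sweeps,
                excursion_mv=self.excursion_mv,
                overshoot_mv=self.overshoot_mv,
                smooth_divisor=self.smooth_divisor,
                detect_divisor=self.detect_divisor,
                prominence=self.prominence,
                rel_prominence=self.rel_prominence,
                h_cut=self.h_cut,
                flat_cut=self.flat_cut,
                refractory_ms=self.refractory_ms,
                train_min_spikes=self.train_min_spikes,
            )
            rows.append(
                dict(
                    neuron_id=rec.neuron_id,
                    Cap_pF=rec.meta.capacitance_pf,
                    RMP_mV=f.rmp,
                    dB_ms=f.db_ms,
                    shape_class=f.shape_class,
                    dVdt_mV_per_ms=f.hump_metric,
                    AHP80_ms=f.ahp80_ms,
                    AHPpeak_mV=f.ahp_peak,
                    APThresh_pA=f.rheobase_pa,
                    fires_train=f.fires_train,
                    APTrain_Hz=f.train_rate_hz,
                )
            )
        return pd.DataFrame(rows)
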