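"""AP feature measurements: RMP, dB, falling-phase shape, AHP, trains."""

import numpy as np
import pytest

import tgephys as tg
from tgephys.ap import (
    analyze_train,
    classify_falling_phase,
    count_spikes,
    detect_ap,
    estimate_rmp,
    extract_ap_features,
    falling_phase_profile,
    measure_ahp,
    measure_db,
    FeatureError,
)
from tgephys.sweeps import Stimulus, Sweep, SweepSet
from tgephys.waveforms import LN5

DT = 5e-5


def _sweep(samples, onset_s=0.02, amplitude_pa=1000.0):
    return Sweep(0, np.asarray(samples, float),
                 Stimulus(onset_s=onset_s, duration_s=5e-4, amplitude_pa=amplitude_pa))


def _hat_trace(rmp=-60.0, peak=20.0, up_ms=22.0, down_ms=32.0, total_ms=60.0):
    """Triangular spike crossing RMP at exactly up_ms and down_ms."""
    t = np.arange(int(total_ms * 1e-3 / DT)) * DT * 1e3
    apex = (up_ms + down_ms) / 2
    tri = np.maximum(0.0, 1.0 - np.abs(t - apex) / (apex - up_ms))
    return rmp + (peak - rmp) * tri


class TestRMP:
    def test_constant_baseline(self):
        sw = _sweep(np.full(2000, -60.0))
        assert estimate_rmp(sw, DT) == -60.0

    def test_short_baseline_rejected(self):
        sw = _sweep(np.full(2000, -60.0), onset_s=0.005)
        with pytest.raises(FeatureError, match="baseline"):
            estimate_rmp(sw, DT)

    def test_noisy_baseline_matches_sample_mean(self):
        rng = np.random.default_rng(5)
        base = -56.4 + 0.3 * rng.standard_normal(2000)
        sw = _sweep(np.concatenate([base, np.full(100, -56.4)]), onset_s=0.1)
        # the estimator IS the arithmetic mean of the baseline samples
        assert estimate_rmp(sw, DT) == pytest.approx(base.mean(), abs=1e-12)
        assert estimate_rmp(sw, DT) == pytest.approx(-56.4, abs=3 * 0.3 / np.sqrt(2000))


class TestDetect:
    def test_flat_trace_none(self):
        assert detect_ap(_sweep(np.full(1000, -60.0)), DT, -60.0) is None

    def test_peak_at_voltage_maximum(self):
        v = _hat_trace(peak=35.0)
        ap = detect_ap(_sweep(v), DT, -60.0)
        assert ap is not None
        assert ap.index == int(np.argmax(v))

    def test_two_spike_sweep_returns_earliest(self):
        v1 = _hat_trace(peak=20.0, up_ms=22, down_ms=26, total_ms=40)
        v2 = _hat_trace(peak=35.0, up_ms=10, down_ms=14, total_ms=40)
        v = np.maximum(v1, v2 - 0)  # second (later) hump is taller
        v = np.maximum(_hat_trace(peak=20.0, up_ms=10, down_ms=14, total_ms=60),
                       _hat_trace(peak=35.0, up_ms=30, down_ms=34, total_ms=60))
        ap = detect_ap(_sweep(v), DT, -60.0)
        assert ap.time_s < 20e-3  # earliest spike, not the global maximum
        assert ap.voltage_mv == pytest.approx(20.0, abs=0.5)


class TestDB:
    def test_constructed_crossings(self):
        sw = _sweep(_hat_trace())
        ap = detect_ap(sw, DT, -60.0)
        assert measure_db(sw, DT, -60.0, ap) == pytest.approx(10.0, abs=DT * 1e3)

    @pytest.mark.parametrize("db,label", [(10.2, "broad"), (2.3, "narrow")])
    def test_generated_widths(self, db, label):
        shape = "double_peak" if db > 5 else "linear"
        hump = -12.3 if shape == "double_peak" else 0.0
        params = tg.APShapeParams(
            rmp=-55.0, target_db=db, shape_class=shape, hump_metric=hump,
            ahp_peak=-8.0, ahp80=20.0,
        )
        f = extract_ap_features(tg.simulate_ap_protocol(params, DT, 0.0, 1))
        assert f.db_ms == pytest.approx(db, rel=0.02)

    def test_unterminated_ap(self):
        v = np.concatenate([np.full(500, -60.0), np.linspace(-60, 30, 500)])
        sw = _sweep(v)
        ap = detect_ap(sw, DT, -60.0)
        with pytest.raises(FeatureError, match="unterminated"):
            measure_db(sw, DT, -60.0, ap)


class TestFallingPhase:
    def _profile(self, params, seed=1, noise=0.0, dt=DT):
        ss = tg.simulate_ap_protocol(params, dt, noise, seed)
        sw = ss[0]
        rmp = estimate_rmp(sw, dt)
        ap = detect_ap(sw, dt, rmp)
        return falling_phase_profile(sw, dt, rmp, ap)

    def test_linear_ramp_constant_derivative(self):
        # pure -10 mV/ms ramp from +20 down through RMP to a trough
        n_ramp = int(9e-3 / DT)
        v = np.concatenate([
            np.full(400, -60.0),
            np.linspace(-60, 20, 100),
            np.linspace(20, -70, n_ramp),
            np.full(400, -70.0),
        ])
        sw = _sweep(v)
        ap = detect_ap(sw, DT, -60.0)
        prof = falling_phase_profile(sw, DT, -60.0, ap)
        mid = prof.dvdt[10:-10]
        assert np.allclose(mid, -10.0, atol=0.3)

    def test_single_segment_has_one_minimum(self):
        params = tg.APShapeParams(rmp=-60, target_db=4.0, shape_class="linear",
                                  ahp_peak=-8.0, ahp80=15.0)
        prof = self._profile(params)
        assert prof.minima_idx.size == 1

    def test_double_peak_exhaustive_extrema_scan(self):
        params = tg.APShapeParams(rmp=-55, target_db=9.0, shape_class="double_peak",
                                  hump_metric=-10.0, ahp_peak=-9.0, ahp80=25.0)
        prof = self._profile(params)
        # oracle: exhaustive scan of strict sign changes of the derivative
        d = np.diff(prof.dvdt_detect)
        interior_minima = np.flatnonzero((d[:-1] < 0) & (d[1:] > 0)) + 1
        assert prof.minima_idx.size == 2
        assert set(prof.minima_idx).issubset(set(interior_minima))
        cls, hump = classify_falling_phase(prof)
        assert cls == "double_peak"
        assert hump == pytest.approx(-10.0, rel=0.1)

    @pytest.mark.parametrize("dt", [5e-5, 1e-4])
    def test_class_invariant_to_time_rescaling(self, group_specs, dt):
        for spec in group_specs:
            params = spec.ap
            f = extract_ap_features(tg.simulate_ap_protocol(params, dt, 0.0, 2))
            assert f.shape_class == params.shape_class, (spec.label, dt)


class TestAHP:
    def test_no_undershoot_gives_zeros(self):
        params = tg.APShapeParams(rmp=-60, target_db=4.0, shape_class="linear",
                                  ahp_peak=0.0, ahp80=0.0)
        ss = tg.simulate_ap_protocol(params, DT, 0.0, 1)
        sw = ss[0]
        ap = detect_ap(sw, DT, -60.0)
        res = measure_ahp(sw, DT, -60.0, ap)
        assert res.peak_mv == 0.0 and res.ahp80_ms == 0.0

    def test_exponential_recovery_closed_form(self):
        # 80% recovery of an exponential occurs at tau * ln 5
        tau = 10.0
        params = tg.APShapeParams(rmp=-60, target_db=4.0, shape_class="linear",
                                  ahp_peak=-9.0, ahp80=tau * LN5)
        ss = tg.simulate_ap_protocol(params, DT, 0.0, 1)
        sw = ss[0]
        ap = detect_ap(sw, DT, -60.0)
        res = measure_ahp(sw, DT, -60.0, ap)
        assert res.ahp80_ms == pytest.approx(10.0 * np.log(5.0), rel=0.01)

    def test_m4_archetype_recovery(self):
        params = tg.APShapeParams(rmp=-64.4, target_db=2.6, shape_class="linear",
                                  ahp_peak=-7.8, ahp80=41.9)
        f = extract_ap_features(tg.simulate_ap_protocol(params, DT, 0.0, 1))
        assert f.ahp_peak == pytest.approx(-7.8, rel=0.05)
        assert f.ahp80_ms == pytest.approx(41.9, rel=0.05)

    def test_censored_recovery_flagged(self):
        # slow AHP cut off by a short sweep
        n = int(0.05 / DT)
        t = np.arange(n) * DT * 1e3
        v = np.full(n, -60.0)
        v[400:500] = np.linspace(-60, 30, 100)
        v[500:600] = np.linspace(30, -72, 100)
        tail = t[600:] - t[600]
        v[600:] = -60.0 - 12.0 * np.exp(-tail / 200.0)  # tau 200 ms >> sweep
        sw = _sweep(v)
        ap = detect_ap(sw, DT, -60.0)
        res = measure_ahp(sw, DT, -60.0, ap)
        assert res.censored and res.ahp80_ms > 0


class TestTrain:
    def test_all_spikeless(self):
        params = tg.APShapeParams(rmp=-60, target_db=5.0, rheobase=None)
        ss = tg.simulate_step_responses(params, dt=DT, seed=1)
        tr = analyze_train(ss)
        assert (tr.rheobase_pa, tr.fires_train, tr.train_rate_hz) == (None, False, None)

    def test_eight_spikes_is_a_train_at_8_hz(self):
        params = tg.APShapeParams(rmp=-60, target_db=5.0, rheobase=100.0,
                                  train_rate=8.0)
        ss = tg.simulate_step_responses(params, dt=DT, seed=1)
        tr = analyze_train(ss)
        assert tr.fires_train and tr.train_rate_hz == pytest.approx(8.0)

    def test_two_spikes_not_a_train(self):
        params = tg.APShapeParams(rmp=-60, target_db=4.0, rheobase=100.0,
                                  train_rate=2.0)
        ss = tg.simulate_step_responses(params, dt=DT, seed=1)
        tr = analyze_train(ss)
        assert not tr.fires_train and tr.train_rate_hz == pytest.approx(2.0)

    def test_unequal_sweep_durations_rejected(self):
        params = tg.APShapeParams(rmp=-60, target_db=5.0, rheobase=100.0)
        ss = tg.simulate_step_responses(params, dt=DT, seed=1)
        ss.sweeps[1] = Sweep(
            ss.sweeps[1].sweep_id,
            ss.sweeps[1].samples[:-100],
            ss.sweeps[1].stimulus,
        )
        with pytest.raises(tg.TraceError, match="unequal"):
            analyze_train(ss)

    def test_refractory_lockout_merges_adjacent_crossings(self):
        v = np.full(2000, -60.0)
        v[100:105] = 10.0
        v[106:110] = 10.0  # re-crossing within 1 ms is not a second spike
        v[800:805] = 10.0
        assert count_spikes(_sweep(v), DT) == 2


class TestNoiseRobustShapes:
    def test_shape_stability_under_default_noise(self, group_specs):
        """Shape class must survive 0.3 mV voltage noise almost always."""
        flips = 0
        total = 0
        for spec in group_specs:
            for seed in range(20):
                f = extract_ap_features(
                    tg.simulate_ap_protocol(spec.ap, DT, 0.3, 3000 + seed)
                )
                total += 1
                flips += f.shape_class != spec.ap.shape_class
        assert flips / total <= 0.05
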