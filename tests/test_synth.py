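"""Synthetic generator: protocols, waveform round-trips, cohorts, IHC."""

import numpy as np
import pytest

import tgephys as tg
from tgephys.ap import extract_ap_features
from tgephys.ma import summarize_ma

DT = 5e-5


class TestPiezoProtocol:
    def test_default_reaches_15_um(self):
        p = tg.make_piezo_protocol()
        assert p.n_steps == 10 and p.step_um == 1.5
        assert p.max_displacement_um == 15.0

    def test_twenty_steps_reach_30_um(self):
        assert tg.make_piezo_protocol(20, 1.5, 300, 10).max_displacement_um == 30.0

    @pytest.mark.parametrize("n,step", [(0, 1.5), (-3, 1.5), (5, 0.0), (5, -1.0)])
    def test_degenerate_arguments_rejected(self, n, step):
        with pytest.raises(tg.ParameterError):
            tg.make_piezo_protocol(n, step, 300, 10)


class TestSimulateAP:
    def test_flat_trace_when_peak_equals_rmp(self):
        params = tg.APShapeParams(rmp=-50.0, peak_v=-50.0, target_db=10.0)
        ss = tg.simulate_ap(params, DT, 0.0, 1)
        v = ss[0].samples
        assert np.allclose(v, -50.0)
        rmp = tg.estimate_rmp(ss[0], DT)
        assert tg.detect_ap(ss[0], DT, rmp) is None

    def test_determinism_and_seed_sensitivity(self):
        params = tg.APShapeParams(rmp=-55, target_db=6.0, ahp80=20.0)
        a = tg.simulate_ap(params, DT, 0.3, seed=42)
        b = tg.simulate_ap(params, DT, 0.3, seed=42)
        c = tg.simulate_ap(params, DT, 0.3, seed=43)
        assert np.array_equal(a[0].samples, b[0].samples)
        assert not np.array_equal(a[0].samples, c[0].samples)

    def test_positive_hump_for_double_peak_rejected(self):
        with pytest.raises(tg.ParameterError):
            tg.APShapeParams(
                shape_class="double_peak", hump_metric=3.0, target_db=8.0
            )

    def test_dt_outside_sampling_range_rejected(self):
        params = tg.APShapeParams(target_db=6.0)
        with pytest.raises(tg.ParameterError):
            tg.simulate_ap(params, dt=1e-3)

    def test_s1_archetype_roundtrip(self):
        params = tg.APShapeParams(
            rmp=-50.0, peak_v=30.0, target_db=10.2, shape_class="double_peak",
            hump_metric=-12.3, ahp_peak=-9.3, ahp80=28.7,
        )
        f = extract_ap_features(tg.simulate_ap_protocol(params, DT, 0.0, 1))
        assert f.shape_class == "double_peak"
        assert f.db_ms == pytest.approx(10.2, rel=0.02)
        assert f.hump_metric == pytest.approx(-12.3, rel=0.05)


class TestNoiseFreeRoundTrips:
    """Feature extraction must invert the generator on clean traces."""

    def test_all_nine_groups(self, group_specs, quiet):
        for spec in group_specs:
            ss = tg.simulate_ap_protocol(spec.ap, DT, 0.0, seed=7)
            f = extract_ap_features(ss)
            assert f.rmp == pytest.approx(spec.ap.rmp, abs=0.1), spec.label
            assert f.db_ms == pytest.approx(spec.ap.target_db, rel=0.02), spec.label
            assert f.shape_class == spec.ap.shape_class, spec.label
            assert f.ahp_peak == pytest.approx(spec.ap.ahp_peak, rel=0.05), spec.label
            assert f.ahp80_ms == pytest.approx(spec.ap.ahp80, rel=0.05), spec.label

    def test_ma_roundtrip_threshold_amp_tau(self, group_specs):
        protocol = tg.PiezoProtocol(n_steps=20)
        for spec in group_specs:
            if not spec.ma.responsive:
                continue
            params = tg.MAParams(
                responsive=True,
                threshold_um=spec.ma.threshold_um,
                max_amp_pa=spec.ma.max_amp_pa,
                tau_ms=spec.ma.tau_ms,
                noise_sd_pa=0.0,
            )
            ss = tg.simulate_ma_sweeps(params, protocol, DT, seed=3)
            f = summarize_ma(ss, protocol, 80.0)
            disps = protocol.displacements_um
            expected_thr = disps[disps >= spec.ma.threshold_um][0]
            assert f.threshold_um == expected_thr, spec.label
            assert f.max_peak_pa == pytest.approx(spec.ma.max_amp_pa, rel=0.01)
            assert f.tau_ms == pytest.approx(spec.ma.tau_ms, rel=1e-3)


class TestSimulateSteps:
    def test_rheobase_grid_alignment(self):
        params = tg.APShapeParams(rmp=-60, target_db=5.0, rheobase=120.0)
        ss = tg.simulate_step_responses(params, dt=DT, seed=1)
        tr = tg.analyze_train(ss)
        assert tr.rheobase_pa == 150.0  # first grid step >= 120
        from tgephys.ap import count_spikes

        assert count_spikes(ss[0], DT) == 0  # 50 pA sweep stays subthreshold

    def test_train_rate_realized_in_maximal_sweep(self):
        params = tg.APShapeParams(
            rmp=-60, target_db=5.0, rheobase=120.0, train_rate=8.0
        )
        ss = tg.simulate_step_responses(params, dt=DT, seed=1)
        tr = tg.analyze_train(ss)
        assert tr.fires_train and tr.train_rate_hz == pytest.approx(8.0)

    def test_rheobase_above_grid_yields_silence(self):
        params = tg.APShapeParams(rmp=-60, target_db=5.0, rheobase=900.0)
        ss = tg.simulate_step_responses(params, dt=DT, seed=1)
        tr = tg.analyze_train(ss)
        assert tr == tg.ap.TrainResult(None, False, None) or (
            tr.rheobase_pa is None and not tr.fires_train
        )


class TestSimulateMA:
    def test_threshold_beyond_protocol_warns_and_silences(self):
        params = tg.MAParams(
            responsive=True, threshold_um=24.0, max_amp_pa=100.0, tau_ms=50.0,
            noise_sd_pa=0.0,
        )
        with pytest.warns(UserWarning, match="nonresponder"):
            ss = tg.simulate_ma_sweeps(params, tg.PiezoProtocol(), DT, 1)
        assert all(np.allclose(s.samples, 0.0) for s in ss)

    def test_peak_magnitudes_monotone_in_displacement(self):
        params = tg.MAParams(
            responsive=True, threshold_um=6.0, max_amp_pa=800.0, tau_ms=60.0,
            noise_sd_pa=0.0,
        )
        protocol = tg.PiezoProtocol(n_steps=10)
        ss = tg.simulate_ma_sweeps(params, protocol, DT, 1)
        peaks = [-s.samples.min() for s in ss]
        assert np.all(np.diff(peaks) >= -1e-9)
        assert peaks[-1] == pytest.approx(800.0, rel=1e-6)

    def test_nonresponder_all_baseline(self):
        params = tg.MAParams(responsive=False, noise_sd_pa=0.0)
        ss = tg.simulate_ma_sweeps(params, tg.PiezoProtocol(), DT, 1)
        from tgephys.ma import sweep_response

        for s in ss:
            assert not sweep_response(s, DT, 0.0).responsive


class TestCohort:
    def test_packaged_specs_sum_to_185(self, group_specs):
        assert sum(s.n for s in group_specs) == 185

    def test_empty_specs_empty_bundle(self):
        bundle = tg.simulate_cohort([], seed=1)
        assert len(bundle) == 0 and bundle.truth_table.empty

    def test_same_seed_identical_bundles(self, quiet):
        specs = tg.default_group_specs(n_scale=0.03)
        a = tg.simulate_cohort(specs, noise=quiet, seed=9)
        b = tg.simulate_cohort(specs, noise=quiet, seed=9)
        assert a.truth_table.equals(b.truth_table)
        for ra, rb in zip(a.records, b.records):
            assert np.array_equal(
                ra.ma_sweeps[0].samples, rb.ma_sweeps[0].samples
            )
            assert np.array_equal(ra.ap_sweeps[0].samples, rb.ap_sweeps[0].samples)

    def test_truth_table_covers_all_records(self, tiny_cohort):
        ids = {r.neuron_id for r in tiny_cohort.records}
        assert set(tiny_cohort.truth_table["neuron_id"]) == ids

    def test_metadata_passes_qc_by_construction(self, tiny_cohort):
        report = tg.QCFilter().report(tiny_cohort)
        assert report["passed"].all()


class TestIHCSimulation:
    def test_counts_sum_to_section_total(self):
        counts = tg.simulate_ihc_sections(tg.default_ihc_probs(), 400, 9, seed=1)
        assert (counts.table["total"] == 400).all()

    def test_law_of_large_numbers(self):
        probs = tg.default_ihc_probs()
        counts = tg.simulate_ihc_sections(probs, 10_000, 100, seed=2)
        frac = counts.table[list(probs)].sum() / counts.table["total"].sum()
        for k, p in probs.items():
            assert frac[k] == pytest.approx(p, abs=0.01)

    def test_bad_probabilities_rejected(self):
        with pytest.raises(tg.ParameterError):
            tg.simulate_ihc_sections({"a": 0.5, "b": 0.4}, 100, 3, seed=1)
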