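import numpy as np
import pytest

from pcxdend.ephys import (SweepSet, apv_comparison, epsp_metrics,
                           passive_properties, spike_features)
from pcxdend.synth import (EphysSpec, gen_epsp_sweep, gen_rc_sweep,
                           gen_spike_step)


class TestPassiveProperties:
    def test_ideal_rc_recovered_exactly(self):
        sweep, truth = gen_rc_sweep(EphysSpec(r_mohm=200, tau_ms=20, step_pa=-80))
        p = passive_properties(sweep)
        assert p.vm_mv == pytest.approx(truth["vm_mv"])
        assert p.rin_mohm == pytest.approx(200.0, rel=1e-6)
        assert p.tau_ms == pytest.approx(20.0, rel=1e-6)
        assert p.cm_pf == pytest.approx(100.0, rel=1e-6)

    @pytest.mark.parametrize("r, tau, i", [(120, 12, -50), (350, 35, -80),
                                           (80, 8, -120)])
    def test_exact_over_physiological_range(self, r, tau, i):
        sweep, _ = gen_rc_sweep(EphysSpec(r_mohm=r, tau_ms=tau, step_pa=i))
        p = passive_properties(sweep)
        assert p.rin_mohm == pytest.approx(r, rel=1e-5)
        assert p.tau_ms == pytest.approx(tau, rel=1e-4)
        assert p.cm_pf == pytest.approx(tau / r * 1e3, rel=1e-4)

    def test_noisy_recovery_within_one_percent(self):
        for seed in range(10):
            sweep, _ = gen_rc_sweep(EphysSpec(noise_sd_mv=0.2), seed=seed)
            p = passive_properties(sweep)
            assert abs(p.rin_mohm - 200) / 200 < 0.01
            assert abs(p.tau_ms - 20) / 20 < 0.01

    def test_zero_step_amplitude_rejected(self):
        sweep, _ = gen_rc_sweep(EphysSpec())
        sweep.step_amplitude_pa = 0.0
        with pytest.raises(ValueError, match="non-zero"):
            passive_properties(sweep)


class TestSpikeFeatures:
    def test_threshold_at_constructed_one_percent_sample(self):
        sweep, truth = gen_spike_step()
        f = spike_features([sweep])
        assert f.ap_threshold_mv == pytest.approx(truth["threshold_mv"], abs=1e-9)
        assert f.chosen_step == 0

    def test_fahp_is_threshold_minus_trough(self):
        sweep, truth = gen_spike_step(fahp_mv=8.0)
        f = spike_features([sweep])
        assert f.fahp_mv == pytest.approx(truth["fahp_mv"], abs=1e-9)

    def test_instant_frequency_from_first_isi(self):
        sweep, _ = gen_spike_step(first_isi_ms=25.0)
        f = spike_features([sweep])
        assert f.instant_freq_hz == pytest.approx(40.0)

    def test_first_qualifying_step_chosen(self):
        weak, _ = gen_spike_step(n_aps=3)
        strong, truth = gen_spike_step(n_aps=10)
        f = spike_features([weak, strong])
        assert f.chosen_step == 1
        f = spike_features([weak])
        assert f.status.startswith("no step") and f.ap_threshold_mv is None

    def test_dc_offset_invariance_of_threshold_location(self):
        sweep, _ = gen_spike_step()
        shifted = SweepSet(voltage=sweep.voltage + 7.5,
                           sampling_rate=sweep.sampling_rate,
                           step_amplitude_pa=sweep.step_amplitude_pa,
                           step_onset_s=sweep.step_onset_s,
                           step_duration_s=sweep.step_duration_s)
        f0, f1 = spike_features([sweep]), spike_features([shifted])
        assert f1.ap_threshold_mv == pytest.approx(f0.ap_threshold_mv + 7.5)
        assert f1.fahp_mv == pytest.approx(f0.fahp_mv)


class TestEpsp:
    def test_flat_trace_zero_metrics(self):
        sweep, _ = gen_epsp_sweep(amplitudes_mv=(0, 0, 0), shape="square")
        m = epsp_metrics(sweep)
        assert m.amplitude_mv == pytest.approx(0.0)
        assert m.auc_mv_ms == pytest.approx(0.0)
        assert not m.has_ap

    def test_square_two_mv_spanning_window(self):
        sweep, _ = gen_epsp_sweep(amplitudes_mv=(0, 0, 2.0), shape="square",
                                  square_ms=60.0)
        m = epsp_metrics(sweep)
        assert m.amplitude_mv == pytest.approx(2.0)
        assert m.auc_mv_ms == pytest.approx(120.0)

    def test_auc_additivity(self):
        a, _ = gen_epsp_sweep(amplitudes_mv=(0.5, 0.7, 1.1), shape="alpha")
        b, _ = gen_epsp_sweep(amplitudes_mv=(0.2, 0.4, 0.9), shape="alpha")
        summed = SweepSet(voltage=a.voltage + b.voltage - (-70.0),
                          sampling_rate=a.sampling_rate,
                          stim_times_s=a.stim_times_s)
        assert epsp_metrics(summed).auc_mv_ms == pytest.approx(
            epsp_metrics(a).auc_mv_ms + epsp_metrics(b).auc_mv_ms, abs=1e-9)

    def test_apv_comparison_skips_ap_sweeps(self):
        def with_ap(sweep):
            v = sweep.voltage.copy()
            i = sweep.index(sweep.stim_times_s[2]) + 100
            v[i:i + 10] = 20.0                      # AP inside the window
            return SweepSet(voltage=v, sampling_rate=sweep.sampling_rate,
                            stim_times_s=sweep.stim_times_s)
        s1, _ = gen_epsp_sweep(amplitudes_mv=(0, 0, 1.0), shape="square")
        s2, _ = gen_epsp_sweep(amplitudes_mv=(0, 0, 2.0), shape="square")
        s3, _ = gen_epsp_sweep(amplitudes_mv=(0, 0, 3.0), shape="square")
        pre = [(10.0, s1), (20.0, s2), (30.0, with_ap(s3))]
        post = [(10.0, s1), (20.0, s2)]
        out = apv_comparison(pre, post)
        assert out["pre"]["intensity"] == 20.0      # next-largest without AP
        assert out["pre"]["amplitude_mv"] == pytest.approx(2.0)
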