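"""Compartmental model: integrator correctness and filtering protocols."""

import numpy as np
import pytest

from flickersync.cable import (
    CompartmentalNeuron,
    DriveConfig,
    SynapseSpec,
    build_neuron,
    burst_transfer_impedance,
    capacitance_sweep,
    default_drive,
    fit_modulation,
    input_population_ppc,
    rhythmic_drive,
    scale_dendritic_cm,
    simulate,
    site_at_distance,
    transfer_impedance,
)


def _single_rc(r_mohm=100.0, c_nf=0.1):
    """One isopotential compartment with the requested R (MOhm) and C (nF)."""
    area = np.pi * 50 * 50 * 1e-8  # cm^2 for a 50x50 um cylinder
    gl = (1.0 / r_mohm) * 1e-3 / area  # mS/cm^2 giving 1/R uS total
    cm = c_nf * 1e-3 / area  # uF/cm^2 giving C nF total
    return CompartmentalNeuron(
        length_um=[50.0], diam_um=[50.0], cm_uf_cm2=[cm], gl_ms_cm2=[gl]
    )


class TestNeuronConstruction:
    def test_archetype_time_constants_ordered(self):
        pyr, pv = build_neuron("pyramidal"), build_neuron("pv")
        assert pv.tau_m_ms < pyr.tau_m_ms
        assert pv.total_dendritic_capacitance_nf < pyr.total_dendritic_capacitance_nf

    def test_membrane_area_is_cylinder_sum(self):
        n = build_neuron("pv")
        expected = np.pi * n.diam_um * n.length_um * 1e-8 * n.n_parallel
        assert np.allclose(n.area_cm2, expected)

    def test_identical_config_gives_identical_neuron(self):
        a, b = build_neuron("pyramidal"), build_neuron("pyramidal")
        assert np.array_equal(a.c_nf, b.c_nf)
        assert np.array_equal(a.g_axial_us, b.g_axial_us)

    def test_site_lookup_near_150_um(self):
        pyr = build_neuron("pyramidal")
        site = site_at_distance(pyr, 150.0)
        assert abs(pyr.distance_um[site] - 150.0) <= pyr.length_um[site] / 2

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            CompartmentalNeuron(
                length_um=[10.0], diam_um=[-1.0], cm_uf_cm2=[1.0], gl_ms_cm2=[0.1]
            )


class TestSimulate:
    def test_rests_at_leak_reversal_without_input(self):
        res = simulate(build_neuron("pv"), duration_s=0.1)
        assert np.allclose(res.v_soma, -65.0, atol=1e-9)

    def test_ohmic_steady_state(self):
        neuron = _single_rc(r_mohm=100.0)
        n_total = int(round(0.7 * 1e3 / 0.025))
        i_ext = np.full(n_total, 0.05)  # nA -> 5 mV on 100 MOhm
        res = simulate(neuron, duration_s=0.5, prerun_s=0.2, i_ext_na=i_ext)
        assert res.v_soma[-1] == pytest.approx(-65.0 + 5.0, abs=0.01)

    def test_subthreshold_linearity(self):
        neuron = build_neuron("pyramidal")
        site = site_at_distance(neuron, 150.0)
        n_total = int(round(0.5 * 1e3 / 0.025))
        base = np.zeros(n_total)
        base[8000:] = 0.02
        r1 = simulate(neuron, 0.3, prerun_s=0.2, i_ext_na=base, elec_comp=site)
        r2 = simulate(neuron, 0.3, prerun_s=0.2, i_ext_na=2 * base, elec_comp=site)
        d1 = r1.v_soma - (-65.0)
        d2 = r2.v_soma - (-65.0)
        assert np.allclose(d2, 2 * d1, rtol=1e-6, atol=1e-9)

    def test_dt_self_convergence(self):
        neuron = build_neuron("pv")
        site = site_at_distance(neuron, 150.0)
        out = {}
        for dt in (0.025, 0.0125):
            n_total = int(round(0.5 * 1e3 / dt))
            t = (np.arange(n_total) + 1) * dt * 1e-3
            i_ext = 0.1 * np.sin(2 * np.pi * 40.0 * t)
            res = simulate(neuron, 0.3, dt_ms=dt, prerun_s=0.2, i_ext_na=i_ext,
                           elec_comp=site)
            out[dt] = res.v_soma[:: int(round(0.05 / dt))][:5000]
        rms = np.sqrt(np.mean((out[0.025] - out[0.0125]) ** 2))
        scale = np.sqrt(np.mean((out[0.0125] + 65.0) ** 2))
        assert rms / scale < 0.005

    def test_threshold_reset_spiking(self):
        neuron = _single_rc(r_mohm=100.0)
        n_total = int(round(0.5 * 1e3 / 0.025))
        i_ext = np.full(n_total, 0.5)  # 50 mV drive: well above threshold
        res = simulate(neuron, 0.3, prerun_s=0.2, i_ext_na=i_ext, spiking=True)
        assert res.spike_times.size > 3
        isis = np.diff(res.spike_times)
        assert np.all(isis >= neuron.refractory_ms * 1e-3 - 1e-9)
        assert res.v_soma.max() <= neuron.v_th_mv + 1e-9

    def test_divergence_aborts_with_diagnostics(self):
        neuron = _single_rc()
        n_total = int(round(0.3 * 1e3 / 0.025))
        with pytest.raises(RuntimeError, match="diverged"):
            simulate(neuron, 0.1, prerun_s=0.2, i_ext_na=np.full(n_total, 50.0))


class TestTransferImpedance:
    def test_single_compartment_matches_rc_closed_form(self):
        neuron = _single_rc(r_mohm=100.0, c_nf=0.1)
        freqs = [2.0, 10.0, 40.0, 100.0]
        spec = transfer_impedance(neuron, frequencies=freqs, site_um=0.0, dt_ms=0.005)
        f = np.asarray(freqs)
        closed = 100.0 / np.sqrt(1 + (2 * np.pi * f * 100e6 * 0.1e-9) ** 2)
        assert np.allclose(spec.magnitude_mohm, closed, rtol=0.01)

    def test_low_frequency_limit_equals_dc_resistance(self):
        # brute-force DC oracle: steady-state soma deflection / current
        neuron = build_neuron("pv")
        site = site_at_distance(neuron, 150.0)
        n_total = int(round(1.2 * 1e3 / 0.025))
        i_ext = np.full(n_total, 0.01)
        res = simulate(neuron, 1.0, prerun_s=0.2, i_ext_na=i_ext, elec_comp=site)
        dc = (res.v_soma[-1] + 65.0) / 0.01
        spec = transfer_impedance(neuron, frequencies=[0.5], site_um=150.0,
                                  duration_s=6.0)
        assert spec.magnitude_mohm[0] == pytest.approx(dc, rel=0.01)

    def test_passive_impedance_monotone_decreasing(self):
        for arch in ("pyramidal", "pv"):
            spec = transfer_impedance(build_neuron(arch))
            assert np.all(np.diff(spec.magnitude_mohm) < 0)

    def test_ei_ratio_monotone_non_increasing(self):
        zp = transfer_impedance(build_neuron("pyramidal"))
        zv = transfer_impedance(build_neuron("pv"))
        ratio = zp.magnitude_mohm / zv.magnitude_mohm
        assert ratio[0] > 1.0  # pyramidal wins at low frequency
        assert np.all(np.diff(ratio) <= 1e-9)


class TestBurstProtocol:
    def test_zero_weight_synapse_gives_zero_response(self):
        neuron = build_neuron("pv")
        site = site_at_distance(neuron, 150.0)
        ev = (np.array([0.25]), np.array([site]), np.array([0.0]))
        res = simulate(neuron, 0.3, prerun_s=0.2, syn_events=ev)
        assert np.allclose(res.v_soma, -65.0, atol=1e-12)

    def test_synaptic_events_superpose_in_linear_regime(self):
        # response to two weak events equals the sum of single-event responses
        neuron = build_neuron("pyramidal")
        site = site_at_distance(neuron, 150.0)
        w = 1e-5
        kw = dict(duration_s=0.4, prerun_s=0.2)
        r1 = simulate(neuron, syn_events=(np.array([0.25]), np.array([site]), np.array([w])), **kw)
        r2 = simulate(neuron, syn_events=(np.array([0.30]), np.array([site]), np.array([w])), **kw)
        r12 = simulate(
            neuron,
            syn_events=(np.array([0.25, 0.30]), np.array([site, site]), np.array([w, w])),
            **kw,
        )
        lhs = r12.v_soma + 65.0
        rhs = (r1.v_soma + 65.0) + (r2.v_soma + 65.0)
        assert np.abs(lhs - rhs).max() < 1e-3 * np.abs(lhs).max() + 1e-9

    def test_burst_ratio_consistent_with_sinusoidal_impedance(self):
        # weak-synapse burst magnitudes reproduce |Z(f)| of the current probe
        neuron = build_neuron("pv")
        syn = SynapseSpec(weight_us=1e-5)
        burst = burst_transfer_impedance(neuron, syn, rates=[10.0, 40.0])
        sine = transfer_impedance(neuron, frequencies=[10.0, 40.0])
        assert np.allclose(burst.magnitude_mohm, sine.magnitude_mohm, rtol=0.02)

    def test_ei_burst_ratio_monotone_non_increasing(self):
        rates = np.arange(5.0, 101.0, 10.0)
        bp = burst_transfer_impedance(build_neuron("pyramidal"), rates=rates)
        bv = burst_transfer_impedance(build_neuron("pv"), rates=rates)
        ratio = bp.magnitude_mohm / bv.magnitude_mohm
        assert np.all(np.diff(ratio) <= 1e-9)


class TestCapacitance:
    def test_unit_scale_is_identity(self):
        neuron = build_neuron("pyramidal")
        assert np.array_equal(scale_dendritic_cm(neuron, 1.0).c_nf, neuron.c_nf)

    def test_halving_cm_raises_impedance_everywhere(self):
        neuron = build_neuron("pyramidal")
        freqs = [2.0, 10.0, 40.0, 100.0]
        sweep = capacitance_sweep(
            neuron, [0.5, 1.0],
            protocol=lambda n: transfer_impedance(n, frequencies=freqs),
        )
        assert np.all(sweep[0.5].magnitude_mohm > sweep[1.0].magnitude_mohm)


class TestRhythmicDrive:
    def test_unmodulated_drive_gives_no_locking(self):
        neuron = build_neuron("pv")
        drive = default_drive("pv", 40.0, 0.0, repetitions=15, duration_s=2.0, seed=2)
        res = rhythmic_drive(neuron, drive)
        assert res.n_spikes > 100
        # no locking to the (absent) rhythm; locking to the input
        # population's own fluctuations may stay slightly positive
        sem = np.sqrt(2.0) / res.phases.size
        assert abs(res.stimulus_ppc) < max(3 * sem, 0.01)

    def test_locking_decreases_from_10_to_60_hz(self):
        neuron = build_neuron("pyramidal")
        vals = []
        for f in (10.0, 60.0):
            drive = default_drive("pyramidal", f, 0.8, repetitions=6,
                                  duration_s=2.0, seed=3)
            vals.append(rhythmic_drive(neuron, drive).ppc)
        assert vals[0] > vals[1]


class TestFitModulation:
    def test_zero_target_gives_zero_depth(self):
        drive = default_drive("pyramidal", 10.0, 0.5, duration_s=5.0, seed=0)
        fit = fit_modulation(0.0, drive)
        assert fit.depth == 0.0 and fit.converged

    def test_round_trip_recovers_generating_depth(self):
        drive = default_drive("pyramidal", 10.0, 0.5, duration_s=5.0, seed=1)
        target = input_population_ppc(drive, 0.6, n_reps=20, seed=99)
        fit = fit_modulation(target, drive, tolerance=0.005, n_reps=10, seed=7)
        assert fit.converged
        assert abs(fit.depth - 0.6) < 0.08

    def test_unreachable_target_reports_maximum(self):
        drive = default_drive("pv", 10.0, 0.5, duration_s=5.0, seed=2)
        fit = fit_modulation(0.9, drive)
        assert fit.at_maximum and not fit.converged
        assert fit.depth == 1.0

    def test_input_ppc_tracks_squared_half_depth(self):
        drive = default_drive("pyramidal", 10.0, 0.5, duration_s=5.0, seed=3)
        for depth in (0.4, 0.8):
            got = input_population_ppc(drive, depth, n_reps=20, seed=5)
            assert got == pytest.approx((depth / 2) ** 2, abs=0.01)
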