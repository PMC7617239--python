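"""Generator contracts: stimulus timing, Poisson structure, determinism."""

import numpy as np
import pytest
from scipy import stats

from flickersync import locking, synthgen
from flickersync.core import wrap_phase


class TestMakeFlicker:
    def test_square_wave_period_and_cycles(self):
        protocol = synthgen.FlickerProtocol(
            frequency=40.0, sampling_rate=10000.0, n_trials=3
        )
        stim, trials = synthgen.make_flicker(protocol, seed=0)
        onset = trials["onset"].iloc[0]
        i0 = int(round(onset * stim.fs))
        # one flicker period spans fs/f = 250 samples: 125 on, 125 off
        cycle = stim.samples[i0 : i0 + 250]
        assert cycle[:125].sum() == 125 and cycle[125:].sum() == 0
        # 2 s trial at 40 Hz carries 80 full cycles
        trial = stim.samples[i0 : i0 + int(2.0 * stim.fs)]
        rising = np.sum(np.diff(trial) > 0.5)
        assert rising == 79  # 80 cycles -> 79 internal rising edges

    def test_isi_range_respected(self):
        protocol = synthgen.FlickerProtocol(frequency=10.0, n_trials=1000)
        _, trials = synthgen.make_flicker(protocol, seed=3)
        isis = trials["onset"].to_numpy()[1:] - trials["offset"].to_numpy()[:-1]
        assert isis.size == 999
        assert np.all(isis >= 4.0) and np.all(isis <= 10.0)

    def test_rejects_undersampled_stimulus(self):
        protocol = synthgen.FlickerProtocol(frequency=200.0, sampling_rate=1200.0)
        with pytest.raises(ValueError, match="sampling_rate"):
            synthgen.make_flicker(protocol, seed=0)

    @pytest.mark.parametrize("bad", [
        dict(frequency=-1.0), dict(duty_cycle=1.0), dict(isi_range=(5.0, 4.0)),
    ])
    def test_protocol_validation(self, bad):
        with pytest.raises(ValueError):
            synthgen.FlickerProtocol(**{"frequency": 40.0, **bad})


class TestLockedTrain:
    def test_unmodulated_train_has_uniform_phases(self, flicker_40hz):
        stim, trials = flicker_40hz
        spec = synthgen.LockedTrainSpec(base_rate=25.0, mod_depth=0.0, seed=1)
        train = synthgen.simulate_locked_train(spec, trials, 40.0)
        phases = locking.spike_phases(stim, train, 40.0)
        n = phases.size
        sem = np.sqrt(2.0 / (n * (n - 1)))  # PPC SE under uniformity ~ sqrt(2)/n
        assert abs(locking.ppc(phases)) < 3 * max(sem, 1.0 / n)

    def test_rate_conservation(self, flicker_40hz):
        # realized counts match base_rate x in-trial time within Poisson error
        _, trials = flicker_40hz
        total_time = (trials["offset"] - trials["onset"]).sum()
        counts = []
        for s in range(100):
            spec = synthgen.LockedTrainSpec(
                base_rate=10.0, mod_depth=0.5, refractory=0.0, seed=s
            )
            counts.append(synthgen.simulate_locked_train(spec, trials, 40.0).n_spikes)
        expected = 10.0 * total_time
        sem = np.sqrt(expected / 100)
        assert abs(np.mean(counts) - expected) < 4 * sem

    def test_phase_density_matches_rectified_cosine(self, flicker_40hz):
        # chi-square goodness of fit of spike phases against the target
        # density (1 + m cos(theta)) / 2pi, using the analytic phase
        _, trials = flicker_40hz
        m = 0.6
        spec = synthgen.LockedTrainSpec(base_rate=40.0, mod_depth=m, refractory=0.0, seed=5)
        train = synthgen.simulate_locked_train(spec, trials, 40.0)
        phases = synthgen.flicker_fundamental_phase(trials, 40.0, train.spike_times)
        edges = np.linspace(-np.pi, np.pi, 13)
        obs, _ = np.histogram(phases, bins=edges)
        centers = (edges[:-1] + edges[1:]) / 2
        expected = phases.size * (1 + m * np.cos(centers)) * np.diff(edges)[0] / (2 * np.pi)
        chi2 = np.sum((obs - expected) ** 2 / expected)
        assert stats.chi2.sf(chi2, df=obs.size - 1) > 0.01

    def test_ppc_matches_phase_density_oracle(self, flicker_40hz):
        # Monte-Carlo oracle: draw phases directly from the rectified-cosine
        # density (rejection sampling) and compare PPC of generated spikes
        stim, trials = flicker_40hz
        m = 0.8
        spec = synthgen.LockedTrainSpec(base_rate=40.0, mod_depth=m, refractory=0.0, seed=6)
        train = synthgen.simulate_locked_train(spec, trials, 40.0)
        phases = synthgen.flicker_fundamental_phase(trials, 40.0, train.spike_times)
        rng = np.random.default_rng(0)
        cand = rng.uniform(-np.pi, np.pi, 200_000)
        oracle = cand[rng.uniform(size=cand.size) < (1 + m * np.cos(cand)) / (1 + m)]
        got, want = locking.ppc(phases), locking.ppc(oracle)
        assert abs(got - want) < 5 * np.sqrt(2.0 / phases.size)

    def test_refractory_enforced(self, flicker_40hz):
        _, trials = flicker_40hz
        spec = synthgen.LockedTrainSpec(base_rate=200.0, mod_depth=0.0, refractory=0.002, seed=2)
        train = synthgen.simulate_locked_train(spec, trials, 40.0)
        in_trial_isis = train.spike_times[1:][np.diff(train.trial_ids) == 0] \
            - train.spike_times[:-1][np.diff(train.trial_ids) == 0]
        assert np.all(in_trial_isis >= 0.002 - 1e-12)


class TestPopulation:
    def test_same_seed_is_bit_identical(self):
        pop = synthgen.area_gradient_population(n_per_area=3, frequencies=(10.0, 40.0))
        pop.protocol_kwargs = {"n_trials": 3}
        a = synthgen.simulate_population(pop, seed=9)
        b = synthgen.simulate_population(pop, seed=9)
        for f in (10.0, 40.0):
            assert np.array_equal(a.sessions[f].stimulus.samples, b.sessions[f].stimulus.samples)
            for ta, tb in zip(a.sessions[f].trains, b.sessions[f].trains):
                assert np.array_equal(ta.spike_times, tb.spike_times)

    def test_empty_area_list_rejected(self):
        with pytest.raises(ValueError):
            synthgen.PopulationSpec(n_units={}, mod_depth={})

    def test_gradient_preset_monotone_depth_chain(self):
        pop = synthgen.area_gradient_population()
        for f in pop.frequencies:
            assert pop.mod_depth[("LGN", f)] > pop.mod_depth[("V1", f)] > pop.mod_depth[("CA1", f)]
            assert pop.mod_depth[("CA1", f)] == 0.0


class TestLaminarFlash:
    def test_too_few_channels_rejected(self):
        with pytest.raises(ValueError, match="5 channels"):
            synthgen.simulate_laminar_flash(4, 50.0, np.array([0.5]), seed=0)

    def test_zero_amplitude_gives_no_assignment(self):
        from flickersync import anatomy

        flashes = 0.5 + 2.1 * np.arange(10)
        rec, _ = synthgen.simulate_laminar_flash(
            16, 50.0, flashes, seed=4, sink_amplitude=0.0
        )
        csd = anatomy.compute_csd(rec, flashes)
        assert not anatomy.assign_layers(csd).assigned


class TestRippleLfp:
    def test_overlapping_bursts_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            synthgen.simulate_ripple_lfp(
                10.0, 1250.0, np.array([1.0, 1.05]), 0, 1, seed=0
            )

    def test_burst_sits_in_ripple_band(self):
        from flickersync.sigproc import bandpass

        rec, truth = synthgen.simulate_ripple_lfp(
            10.0, 1250.0, np.array([5.0]), 0, 1, seed=1, amplitude_sd=10.0
        )
        band = bandpass(rec.data[0], 1250.0, 130.0, 200.0)
        i0 = int(5.0 * 1250)
        inside = np.abs(band[i0 : i0 + 100]).max()
        outside = np.abs(band[: i0 - 1250]).std()
        assert inside > 5 * outside


class TestWaveforms:
    def test_noise_free_templates_identical_within_class(self):
        bank = synthgen.simulate_waveforms(
            "narrow", 5, seed=3, noise_sd=0.0, width_jitter=0.0
        )
        assert bank.waveforms.shape == (5, 84)
        assert np.allclose(bank.waveforms, bank.waveforms[0])

    def test_inverted_polarity_flagged_for_discard(self):
        from flickersync import celltypes

        bank = synthgen.simulate_waveforms("broad", 3, seed=4, invert=True)
        entries = [celltypes.mean_waveform(w) for w in bank.waveforms]
        assert all(e.discarded for e in entries)
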