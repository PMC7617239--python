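"""PPC estimator, spike-phase extraction, sLFP and group statistics."""

import cmath
import itertools

import numpy as np
import pytest
from scipy.special import iv

from flickersync import locking, synthgen
from flickersync.core import ContinuousSignal, SpikeTrain


class TestPpc:
    @pytest.mark.parametrize(
        "phases, expected",
        [
            (np.zeros(100), 1.0),
            (np.array([0.0, np.pi]), -1.0),
            (np.array([0.0, np.pi / 2, np.pi, 3 * np.pi / 2]), -1.0 / 3.0),
        ],
    )
    def test_analytic_phase_sets(self, phases, expected):
        assert locking.ppc(phases) == pytest.approx(expected, abs=1e-12)

    def test_equals_average_pairwise_cosine(self):
        rng = np.random.default_rng(0)
        phases = rng.uniform(-np.pi, np.pi, 40)
        pairs = [np.cos(a - b) for a, b in itertools.combinations(phases, 2)]
        assert locking.ppc(phases) == pytest.approx(np.mean(pairs), abs=1e-12)

    def test_undefined_below_two_phases(self):
        assert np.isnan(locking.ppc(np.array([0.3])))

    def test_unbiased_under_uniform_phases(self):
        rng = np.random.default_rng(1)
        vals = [locking.ppc(rng.uniform(-np.pi, np.pi, 200)) for _ in range(1000)]
        sem = np.std(vals) / np.sqrt(len(vals))
        assert abs(np.mean(vals)) < 3 * sem

    @pytest.mark.parametrize("kappa", [0.5, 1.0, 2.0, 4.0])
    def test_von_mises_closed_form(self, kappa):
        # E[PPC] equals the squared mean resultant length (I1/I0)^2
        rng = np.random.default_rng(int(kappa * 10))
        vals = [locking.ppc(rng.vonmises(0.0, kappa, 2000)) for _ in range(50)]
        expected = (iv(1, kappa) / iv(0, kappa)) ** 2
        sem = np.std(vals) / np.sqrt(len(vals))
        assert abs(np.mean(vals) - expected) < 4 * sem


class TestSpikePhases:
    def test_cosine_convention_at_peak_and_rising_zero(self):
        f, fs = 40.0, 1200.0
        t = np.arange(int(10 * fs)) / fs
        sig = ContinuousSignal(np.cos(2 * np.pi * f * t), fs=fs)
        at_peak = SpikeTrain(0, np.array([5.0]))  # 200 full cycles
        assert locking.spike_phases(sig, at_peak, f)[0] == pytest.approx(0.0, abs=1e-3)
        rising = SpikeTrain(0, np.array([5.0 - 1 / (4 * f)]))
        assert locking.spike_phases(sig, rising, f)[0] == pytest.approx(-np.pi / 2, abs=1e-3)

    def test_matches_bruteforce_windowed_dft(self):
        # sample-by-sample oracle with the same Hann/convention contract
        rng = np.random.default_rng(2)
        fs, f, window = 1200.0, 36.0, 0.25
        sig = ContinuousSignal(rng.normal(size=int(fs * 8)), fs=fs)
        times = rng.uniform(0.5, 7.5, 100)
        train = SpikeTrain(0, np.sort(times))
        got = locking.spike_phases(sig, train, f, window=window)

        n_win = int(round(window * fs))
        if n_win % 2 == 0:
            n_win += 1
        half = n_win // 2
        h = np.hanning(n_win)
        expected = []
        for t_s in np.sort(times):
            c = int(round(t_s * fs))
            wmean = 0.0
            for j in range(-half, half + 1):
                wmean += sig.samples[c + j] * h[j + half]
            wmean /= h.sum()
            acc = 0j
            for j in range(-half, half + 1):
                acc += (
                    (sig.samples[c + j] - wmean)
                    * h[j + half]
                    * cmath.exp(-2j * np.pi * f * j / fs)
                )
            acc *= cmath.exp(2j * np.pi * f * (t_s - c / fs))
            expected.append(cmath.phase(acc))
        err = np.angle(np.exp(1j * (got - np.array(expected))))
        assert np.abs(err).max() < 1e-6

    def test_edge_spikes_dropped(self):
        sig = ContinuousSignal(np.zeros(1200) + 1.0, fs=1200.0)
        train = SpikeTrain(0, np.array([0.01, 0.5, 0.99]))
        assert locking.spike_phases(sig, train, 10.0).size == 1


class TestLockingSpectrum:
    def test_low_spike_count_marked_invalid(self, flicker_40hz):
        stim, trials = flicker_40hz
        spec40 = synthgen.LockedTrainSpec(base_rate=2.0, mod_depth=0.5, seed=3)
        train = synthgen.simulate_locked_train(spec40, trials, 40.0)
        assert train.n_spikes < 150
        spec = locking.locking_spectrum(train, stim, [10.0, 40.0, 80.0])
        assert not spec.valid.any()
        assert np.isnan(spec.value_at(40.0))

    def test_spectrum_peaks_at_locked_frequency(self, flicker_40hz, locked_train_40hz):
        # measured against a noisy photodiode trace: on a noiseless square
        # wave, carrier leakage is phase-coherent across locked spikes and
        # would inflate off-target PPC (phase carries no amplitude floor)
        stim, _ = flicker_40hz
        rng = np.random.default_rng(0)
        photodiode = ContinuousSignal(
            stim.samples + rng.normal(0, 0.05, stim.samples.size), fs=stim.fs
        )
        spec = locking.locking_spectrum(
            locked_train_40hz, photodiode, [10.0, 20.0, 40.0, 60.0, 80.0]
        )
        assert spec.valid.all()
        assert spec.frequencies[np.argmax(spec.ppc)] == 40.0
        off = spec.ppc[spec.frequencies != 40.0]
        assert spec.value_at(40.0) > 10 * np.abs(off).max()


class TestSurrogateLfp:
    def test_no_spikes_gives_zero_signal(self):
        slfp = locking.build_slfp([SpikeTrain(0, np.empty(0))], duration=2.0)
        assert np.allclose(slfp.samples, 0.0)

    def test_additivity(self, flicker_40hz):
        _, trials = flicker_40hz
        trains = [
            synthgen.simulate_locked_train(
                synthgen.LockedTrainSpec(base_rate=15.0, mod_depth=0.5, seed=s),
                trials, 40.0, unit_id=s,
            )
            for s in range(4)
        ]
        dur = trials["offset"].iloc[-1] + 1.0
        whole = locking.build_slfp(trains, duration=dur)
        parts = locking.build_slfp(trains[:2], duration=dur).samples + \
            locking.build_slfp(trains[2:], duration=dur).samples
        assert np.allclose(whole.samples, parts, atol=1e-9)

    def test_population_slfp_peaks_at_flicker_frequency(self, flicker_40hz):
        _, trials = flicker_40hz
        trains = [
            synthgen.simulate_locked_train(
                synthgen.LockedTrainSpec(base_rate=20.0, mod_depth=0.9, seed=s),
                trials, 40.0, unit_id=s,
            )
            for s in range(20)
        ]
        slfp = locking.build_slfp(trains, duration=trials["offset"].iloc[-1] + 1.0)
        spec = np.abs(np.fft.rfft(slfp.samples)) ** 2
        freqs = np.fft.rfftfreq(len(slfp), 1 / slfp.fs)
        band = (freqs > 2) & (freqs < 100)
        peak_f = freqs[band][np.argmax(spec[band])]
        assert abs(peak_f - 40.0) < 1.0

    def test_locking_to_slfp_mirrors_locking_to_stimulus(self, flicker_40hz):
        # a unit locked to the stimulus is also locked to the population
        # surrogate LFP built from the same generator
        stim, trials = flicker_40hz
        trains = [
            synthgen.simulate_locked_train(
                synthgen.LockedTrainSpec(base_rate=20.0, mod_depth=0.8, seed=40 + s),
                trials, 40.0, unit_id=s,
            )
            for s in range(30)
        ]
        slfp = locking.build_slfp(trains, duration=trials["offset"].iloc[-1] + 1.0)
        probe = trains[0]
        ppc_stim = locking.ppc(locking.spike_phases(stim, probe, 40.0))
        ppc_slfp = locking.ppc(locking.spike_phases(slfp, probe, 40.0))
        assert ppc_slfp > 0.5 * ppc_stim > 0


class TestEiRatio:
    def _spectra(self, values):
        return [
            locking.LockingSpectrum(
                unit_id=i,
                frequencies=np.array([10.0, 40.0]),
                ppc=np.asarray(v, dtype=float),
                n_spikes=np.array([500, 500]),
                valid=np.array([True, True]),
            )
            for i, v in enumerate(values)
        ]

    def test_identical_groups_give_unit_ratio(self):
        specs = self._spectra([[0.2, 0.1], [0.4, 0.3]])
        curve = locking.ei_ratio(specs, specs)
        assert np.allclose(curve.ratio, 1.0)

    def test_weaker_broad_group_gives_ratio_below_one(self):
        broad = self._spectra([[0.1, 0.05], [0.2, 0.15]])
        narrow = self._spectra([[0.2, 0.1], [0.4, 0.3]])
        curve = locking.ei_ratio(broad, narrow)
        assert np.all(curve.ratio < 1.0)

    def test_nonpositive_narrow_mean_is_undefined(self):
        broad = self._spectra([[0.1, 0.1]])
        narrow = self._spectra([[0.2, -0.01]])
        curve = locking.ei_ratio(broad, narrow)
        assert np.isfinite(curve.ratio[0]) and np.isnan(curve.ratio[1])


class TestGroupStats:
    def test_null_calibration(self):
        rng = np.random.default_rng(3)
        false_pos = 0
        for s in range(200):
            a = rng.normal(size=10)
            b = rng.normal(size=10)
            if locking.group_permutation_test(a, b, n_perm=199, seed=s) < 0.05:
                false_pos += 1
        assert false_pos / 200 <= 0.095  # 0.05 + ~3 binomial SEs

    def test_extreme_separation_attains_floor(self):
        a = np.zeros(10) + 10.0
        b = np.zeros(10)
        p = locking.group_permutation_test(a + 0.01 * np.arange(10), b, n_perm=999, seed=0)
        assert p == pytest.approx(1.0 / 1000.0)

    def test_matches_exhaustive_enumeration(self):
        a = np.array([0.1, 0.5, 0.9, 1.3])
        b = np.array([0.0, 0.2, 0.4, 0.6])
        pooled = np.concatenate([a, b])
        obs = abs(a.mean() - b.mean())
        count = total = 0
        for idx in itertools.combinations(range(8), 4):
            sel = np.zeros(8, dtype=bool)
            sel[list(idx)] = True
            diff = abs(pooled[sel].mean() - pooled[~sel].mean())
            count += diff >= obs - 1e-12
            total += 1
        exact = count / total
        p = locking.group_permutation_test(a, b, n_perm=20000, seed=1)
        assert abs(p - exact) < 4 * np.sqrt(exact * (1 - exact) / 20000) + 1e-4

    def test_degenerate_input_gives_p_one(self):
        assert locking.group_permutation_test([1.0, 1.0], [1.0, 1.0]) == 1.0

    def test_fdr_monotone_and_bounded(self):
        p = [0.001, 0.02, 0.04, 0.2, 0.9]
        reject, p_adj = locking.fdr_correct(p)
        assert reject[0] and not reject[-1]
        assert np.all(p_adj >= np.asarray(p) - 1e-15)

    def test_sign_permutation_detects_offset_and_calibrates(self):
        rng = np.random.default_rng(4)
        assert locking.sign_permutation_test(rng.normal(1.0, 0.1, 20), seed=0) < 0.01
        nulls = [
            locking.sign_permutation_test(rng.normal(0.0, 1.0, 20), n_perm=199, seed=s)
            for s in range(200)
        ]
        assert np.mean(np.asarray(nulls) < 0.05) <= 0.095
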