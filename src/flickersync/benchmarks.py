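"""End-to-end validation benchmarks on synthetic data.

Each function regenerates its inputs from a seed, runs the relevant part of
the pipeline, and returns a dict of plain numbers. They back both the
acceptance test suite and the ``scripts/acceptance.py`` reporting script,
so every number is recomputed from scratch on each run.
"""

from __future__ import annotations

import cmath
from typing import Dict, Sequence

import numpy as np
from scipy.special import iv

from . import anatomy, celltypes, locking, phasereg, respond, synthgen
from .cable import (
    build_neuron,
    default_drive,
    fit_modulation,
    input_population_ppc,
    rhythmic_drive,
    scale_dendritic_cm,
    transfer_impedance,
)
from .cable.neuron import CompartmentalNeuron
from .core import ContinuousSignal, LaminarRecording, PhaseSeries, SpikeTrain, trial_table, wrap_phase

__all__ = [
    "ppc_estimator_benchmark",
    "spike_phase_oracle_benchmark",
    "gradient_benchmark",
    "ripple_benchmark",
    "csd_benchmark",
    "classifier_benchmark",
    "zeta_benchmark",
    "regression_benchmark",
    "cable_benchmark",
    "modulation_roundtrip_benchmark",
]


# ---------------------------------------------------------------------- 1

def ppc_estimator_benchmark(seed: int) -> Dict:
    """Exactness on analytic phase sets, bias under uniformity, and the
    von Mises closed form (I1(k)/I0(k))^2."""
    exact_err = max(
        abs(locking.ppc(np.zeros(100)) - 1.0),
        abs(locking.ppc(np.array([0.0, np.pi])) + 1.0),
        abs(locking.ppc(np.array([0.0, np.pi / 2, np.pi, 3 * np.pi / 2])) + 1.0 / 3.0),
    )
    rng = np.random.default_rng(seed)
    uniform = np.array(
        [locking.ppc(rng.uniform(-np.pi, np.pi, 200)) for _ in range(1000)]
    )
    bias = float(np.mean(uniform))
    sem = float(np.std(uniform) / np.sqrt(uniform.size))
    vm = {}
    for kappa in (0.5, 1.0, 2.0, 4.0):
        vals = np.array([locking.ppc(rng.vonmises(0.0, kappa, 2000)) for _ in range(60)])
        expected = (iv(1, kappa) / iv(0, kappa)) ** 2
        vm[kappa] = {
            "mean": float(vals.mean()),
            "expected": float(expected),
            "z": float((vals.mean() - expected) / (vals.std() / np.sqrt(vals.size))),
        }
    return {
        "exact_error": float(exact_err),
        "uniform_bias": bias,
        "uniform_bias_sem": sem,
        "von_mises": vm,
    }


# ---------------------------------------------------------------------- 2

def spike_phase_oracle_benchmark(seed: int, n_cases: int = 100) -> Dict:
    """Max |difference| against a sample-by-sample windowed-DFT oracle."""
    rng = np.random.default_rng(seed)
    fs, window = 1200.0, 0.25
    sig = ContinuousSignal(rng.normal(size=int(fs * 10)), fs=fs)
    times = np.sort(rng.uniform(0.5, 9.5, n_cases))
    freq = 36.0
    got = locking.spike_phases(sig, SpikeTrain(0, times), freq, window=window)

    n_win = int(round(window * fs))
    if n_win % 2 == 0:
        n_win += 1
    half = n_win // 2
    h = np.hanning(n_win)
    worst = 0.0
    for k, t_s in enumerate(times):
        c = int(round(t_s * fs))
        wmean = sum(sig.samples[c + j] * h[j + half] for j in range(-half, half + 1))
        wmean /= h.sum()
        acc = 0j
        for j in range(-half, half + 1):
            acc += (
                (sig.samples[c + j] - wmean)
                * h[j + half]
                * cmath.exp(-2j * np.pi * freq * j / fs)
            )
        acc *= cmath.exp(2j * np.pi * freq * (t_s - c / fs))
        diff = abs(np.angle(np.exp(1j * (got[k] - cmath.phase(acc)))))
        worst = max(worst, diff)
    return {"max_error_rad": float(worst), "n_cases": n_cases}


# ---------------------------------------------------------------------- 3

def gradient_benchmark(seed: int, n_per_area: int = 50) -> Dict:
    """Gradient recovery on the multi-area preset: mean PPC per area and
    frequency, ordering flag, and CA1-vs-zero / LGN-vs-CA1 statistics."""
    pop = synthgen.area_gradient_population(n_per_area=n_per_area)
    rec = synthgen.simulate_population(pop, seed=seed)
    means: Dict[str, Dict[float, float]] = {a: {} for a in pop.n_units}
    p_ca1_zero, p_lgn_ca1 = [], []
    for f in pop.frequencies:
        sess = rec.sessions[f]
        by_area = {a: [] for a in pop.n_units}
        counts = {a: [] for a in pop.n_units}
        for tr in sess.trains:
            spec = locking.locking_spectrum(tr, sess.stimulus, [f])
            v = spec.value_at(f)
            if np.isfinite(v):
                by_area[tr.area].append(v)
                counts[tr.area].append(int(spec.n_spikes[0]))
        for a in by_area:
            means[a][f] = float(np.mean(by_area[a]))
        p_ca1_zero.append(
            locking.uniform_phase_null_test(
                by_area["CA1"], counts["CA1"], seed=seed + int(f)
            )
        )
        p_lgn_ca1.append(
            locking.group_permutation_test(
                by_area["LGN"], by_area["CA1"], seed=seed + int(f)
            )
        )
    ca1_reject, ca1_adj = locking.fdr_correct(p_ca1_zero)
    lgn_reject, _ = locking.fdr_correct(p_lgn_ca1)
    ordering = bool(
        all(means["LGN"][f] > means["V1"][f] > means["CA1"][f] for f in pop.frequencies)
    )
    return {
        "frequencies": list(pop.frequencies),
        "mean_ppc": {a: [means[a][f] for f in pop.frequencies] for a in means},
        "ordering_holds": ordering,
        "ca1_fdr_p": [float(p) for p in ca1_adj],
        "ca1_significant_any": bool(ca1_reject.any()),
        "lgn_vs_ca1_significant_all": bool(lgn_reject.all()),
    }


# ---------------------------------------------------------------------- 4

def ripple_benchmark(seed: int, n_events: int = 100) -> Dict:
    """Detector sensitivity / false positives on calibrated synthetic LFP."""
    starts = 1.0 + 1.19 * np.arange(n_events)
    duration = float(starts[-1]) + 1.0
    rec, truth = synthgen.simulate_ripple_lfp(
        duration, 1250.0, starts, 0, 1, seed=seed, amplitude_sd=10.0
    )
    events = anatomy.detect_ripples(rec.channel(0))
    hits = sum(
        any(e.start < t0 + 0.08 and e.stop > t0 for e in events) for t0 in starts
    )
    false = len(events) - sum(
        any(e.start < t0 + 0.08 and e.stop > t0 for t0 in starts) for e in events
    )
    out = {
        "sensitivity": hits / n_events,
        "false_per_min": false / (duration / 60.0),
    }
    for dur, key in ((0.010, "short_burst_detected"), (0.300, "long_burst_detected")):
        rec2, _ = synthgen.simulate_ripple_lfp(
            20.0, 1250.0, np.array([5.0]), 0, 1, seed=seed + 1,
            ripple_durations=np.array([dur]), amplitude_sd=15.0,
        )
        ev = anatomy.detect_ripples(rec2.channel(0))
        out[key] = bool(any(e.start < 5.0 + dur and e.stop > 5.0 for e in ev))
    return out


# ---------------------------------------------------------------------- 5

def csd_benchmark(seed: int) -> Dict:
    """Linear-field annihilation and sink localization accuracy."""
    lin = LaminarRecording(
        np.outer(3.0 * np.arange(24) + 2.0, np.ones(500)), fs=1250.0, spacing_um=50.0
    )
    lin_err = float(np.abs(anatomy.compute_csd(lin, np.array([0.2])).values).max())
    flashes = 1.0 + 2.1 * np.arange(20)
    rec, truth = synthgen.simulate_laminar_flash(24, 50.0, flashes, seed=seed)
    assignment = anatomy.assign_layers(anatomy.compute_csd(rec, flashes))
    return {
        "linear_field_max_abs": lin_err,
        "sink_error_channels": abs(assignment.sink_channel - truth["granular_channel"])
        if assignment.assigned
        else np.inf,
    }


# ---------------------------------------------------------------------- 6

def classifier_benchmark(seed: int, n_per_class: int = 200) -> Dict:
    """Accuracy on the separable benchmark and cross-seed label stability."""
    broad = synthgen.simulate_waveforms("broad", n_per_class, seed=seed)
    narrow = synthgen.simulate_waveforms("narrow", n_per_class, seed=seed + 1)
    wfs = np.vstack([broad.waveforms, narrow.waveforms])
    entries = [celltypes.mean_waveform(w, unit_id=i) for i, w in enumerate(wfs)]
    truth = np.array(["broad"] * n_per_class + ["narrow"] * n_per_class, dtype=object)
    labels = [
        celltypes.classify_waveforms(entries, seed=seed + s).labels for s in range(5)
    ]
    accuracy = float(np.mean(labels[0] == truth))
    stability = float(
        min(np.mean(labels[s] == labels[0]) for s in range(1, 5))
    )
    return {"accuracy": accuracy, "stability": stability, "n_units": 2 * n_per_class}


# ---------------------------------------------------------------------- 7

def zeta_benchmark(seed: int, n_sims: int = 1000) -> Dict:
    """Type-I calibration of the responsiveness test plus the tagging rules."""
    rates = (1.0, 5.0, 20.0)
    events = np.arange(50) * 4.0 + 1.0
    type1 = {}
    for rate in rates:
        rej = 0
        for s in range(n_sims):
            rng = np.random.default_rng(seed * 7919 + s)
            n = rng.poisson(rate * 205.0)
            train = SpikeTrain(0, np.sort(rng.uniform(0, 205.0, n)))
            res = respond.zeta_like_test(train, events, n_perm=199, seed=s)
            if res.testable and res.p < 0.05:
                rej += 1
        type1[rate] = rej / n_sims
    cases = {
        "tagged_significant_3ms": respond.classify_optotagged(
            respond.ResponsivenessResult(0, True, 0.5, 0.01, 0.003, 0.004, 100, 50)
        ),
        "rejected_early_latency": not respond.classify_optotagged(
            respond.ResponsivenessResult(0, True, 0.5, 0.01, 0.0005, 0.001, 100, 50)
        ),
        "rejected_nonsignificant": not respond.classify_optotagged(
            respond.ResponsivenessResult(0, True, 0.5, 0.2, 0.003, 0.004, 100, 50)
        ),
    }
    return {"type_one": type1, "rules_hold": bool(all(cases.values())), "cases": cases}


# ---------------------------------------------------------------------- 8

def regression_benchmark(seed: int) -> Dict:
    """Parameter recovery at ~1e5 bins, phase-shift equivariance, and
    held-out prediction for a strongly modulated unit."""
    truth = (1.0, 0.8, -2.0)
    f = 40.0
    rng = np.random.default_rng(seed)

    def simulate(beta, n_trials, shift=0.0, sub_seed=0):
        b0, b1, b2 = beta
        local = np.random.default_rng(seed * 31 + sub_seed)
        trials = trial_table(np.arange(n_trials) * 2.5, 2.0, f)
        fs = 1000.0
        t = np.arange(int((n_trials * 2.5 + 2) * fs)) / fs
        ps = PhaseSeries(
            wrap_phase(2 * np.pi * f * t + shift), fs=fs, t0=0.0, carrier_frequency=f
        )
        bin_s = 1.0 / phasereg.BIN_RATE
        spikes = []
        for _, tr in trials.iterrows():
            centers = tr["onset"] + np.arange(int(2.0 * phasereg.BIN_RATE)) * bin_s + bin_s / 2
            lam = np.exp(b0 * np.sin(ps.at(centers) + b1) + b2)
            for c, k in zip(centers, local.poisson(lam)):
                spikes.extend(local.uniform(c - bin_s / 2, c + bin_s / 2, k))
        return SpikeTrain(0, np.sort(np.asarray(spikes))), ps, trials

    train, ps, trials = simulate(truth, n_trials=400)
    model, _ = phasereg.fit_phase_model(train, ps, trials, seed=seed)
    recovery = {
        "beta0": {"estimate": model.beta0, "z": (model.beta0 - truth[0]) / model.se_beta0},
        "beta1": {
            "estimate": model.beta1,
            "z": float(wrap_phase(model.beta1 - truth[1])) / model.se_beta1,
        },
        "beta2": {"estimate": model.beta2, "z": (model.beta2 - truth[2]) / model.se_beta2},
    }

    delta = 0.9
    train_s, ps0, trials_s = simulate(truth, n_trials=60, sub_seed=1)
    _, ps1, _ = simulate(truth, n_trials=60, shift=delta, sub_seed=1)
    m0, _ = phasereg.fit_phase_model(train_s, ps0, trials_s, seed=seed)
    m1, _ = phasereg.fit_phase_model(train_s, ps1, trials_s, seed=seed)
    equiv_err = float(abs(wrap_phase(m1.beta1 - (m0.beta1 - delta))))

    strong, ps_s, trials_strong = simulate((1.5, 0.3, 0.0), n_trials=200, sub_seed=2)
    m_s, held = phasereg.fit_phase_model(strong, ps_s, trials_strong, seed=seed)
    heldout_r = float(phasereg.evaluate_model(m_s, held))
    return {
        "n_bins_train": model.n_bins_train,
        "recovery": recovery,
        "equivariance_error_rad": equiv_err,
        "heldout_r_strong": heldout_r,
    }


# ---------------------------------------------------------------------- 9

def _single_rc(r_mohm: float = 100.0, c_nf: float = 0.1) -> CompartmentalNeuron:
    area = np.pi * 50 * 50 * 1e-8
    return CompartmentalNeuron(
        length_um=[50.0],
        diam_um=[50.0],
        cm_uf_cm2=[c_nf * 1e-3 / area],
        gl_ms_cm2=[(1.0 / r_mohm) * 1e-3 / area],
    )


def _ppc_se(ppc_val: float, n: int) -> float:
    """Propagated Monte-Carlo SE of a PPC estimate from n pooled phases."""
    r = np.sqrt(max(ppc_val, 1e-12))
    se_r = np.sqrt((1 - min(r * r, 1.0)) / (2 * max(n, 2)))
    return float(2 * r * se_r)


def cable_benchmark(
    seed: int,
    drive_frequencies: Sequence[float] = (10.0, 20.0, 40.0, 60.0),
    repetitions: int = 200,
    duration_s: float = 2.5,
) -> Dict:
    """Impedance correctness and the cell-type filtering orderings."""
    rc = _single_rc()
    freqs = [2.0, 10.0, 40.0, 100.0]
    spec = transfer_impedance(rc, frequencies=freqs, site_um=0.0, dt_ms=0.005)
    closed = 100.0 / np.sqrt(1 + (2 * np.pi * np.asarray(freqs) * 100e6 * 0.1e-9) ** 2)
    rc_err = float(np.max(np.abs(spec.magnitude_mohm - closed) / closed))

    pyr, pv = build_neuron("pyramidal"), build_neuron("pv")
    zp = transfer_impedance(pyr)
    zv = transfer_impedance(pv)
    z_ratio = zp.magnitude_mohm / zv.magnitude_mohm
    z_mono = bool(
        np.all(np.diff(zp.magnitude_mohm) < 0) and np.all(np.diff(zv.magnitude_mohm) < 0)
    )

    half = scale_dendritic_cm(pyr, 0.5)
    z_half = transfer_impedance(half, frequencies=[2.0, 10.0, 40.0, 100.0])
    z_base = transfer_impedance(pyr, frequencies=[2.0, 10.0, 40.0, 100.0])
    cm_half_increases = bool(np.all(z_half.magnitude_mohm > z_base.magnitude_mohm))

    ppc_out = {"pyramidal": [], "pv": []}
    ns = {"pyramidal": [], "pv": []}
    slfp_out = {"pyramidal": [], "pv": []}
    for arch, neuron in (("pyramidal", pyr), ("pv", pv)):
        for f in drive_frequencies:
            drive = default_drive(
                arch, f, 0.5, repetitions=repetitions, duration_s=duration_s,
                seed=seed,
            )
            res = rhythmic_drive(neuron, drive)
            ppc_out[arch].append(res.stimulus_ppc)
            slfp_out[arch].append(res.ppc)
            ns[arch].append(res.n_spikes)
    ratio = np.asarray(ppc_out["pyramidal"]) / np.asarray(ppc_out["pv"])
    ratio_se = np.array(
        [
            abs(r)
            * np.sqrt(
                (_ppc_se(p, n1) / max(p, 1e-9)) ** 2
                + (_ppc_se(v, n2) / max(v, 1e-9)) ** 2
            )
            for r, p, v, n1, n2 in zip(
                ratio, ppc_out["pyramidal"], ppc_out["pv"],
                ns["pyramidal"], ns["pv"],
            )
        ]
    )
    # monotone at the Monte-Carlo resolution of the ratio estimates
    tol = 2 * np.sqrt(ratio_se[1:] ** 2 + ratio_se[:-1] ** 2)
    ppc_ratio_mono = bool(np.all(np.diff(ratio) <= tol))
    return {
        "rc_max_rel_error": rc_err,
        "z_monotone_decreasing": z_mono,
        "z_ratio": [float(x) for x in z_ratio],
        "z_ratio_monotone": bool(np.all(np.diff(z_ratio) <= 1e-9)),
        "cm_half_increases_z": cm_half_increases,
        "drive_frequencies": list(drive_frequencies),
        "ppc_pyramidal": [float(x) for x in ppc_out["pyramidal"]],
        "ppc_pv": [float(x) for x in ppc_out["pv"]],
        "slfp_ppc_pyramidal": [float(x) for x in slfp_out["pyramidal"]],
        "slfp_ppc_pv": [float(x) for x in slfp_out["pv"]],
        "ppc_ratio": [float(x) for x in ratio],
        "ppc_ratio_se": [float(x) for x in ratio_se],
        "ppc_ratio_monotone": ppc_ratio_mono,
    }


# --------------------------------------------------------------------- 10

def modulation_roundtrip_benchmark(
    seed: int, depths: Sequence[float] = (0.3, 0.5, 0.7)
) -> Dict:
    """Round-trip: depth -> input-population PPC -> fitted depth."""
    out = {}
    for d in depths:
        drive = default_drive("pyramidal", 10.0, d, duration_s=5.0, seed=seed)
        target = input_population_ppc(drive, d, n_reps=20, seed=seed + 1)
        fit = fit_modulation(target, drive, tolerance=0.005, n_reps=10, seed=seed + 2)
        out[d] = {
            "target_ppc": float(target),
            "recovered_depth": float(fit.depth),
            "error": float(abs(fit.depth - d)),
            "converged": bool(fit.converged),
        }
    return {"roundtrips": out, "max_depth_error": max(v["error"] for v in out.values())}
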