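"""Ball-and-stick neuron archetypes.

Geometry is a chain of cylinders: compartment 0 is the soma, compartments
1..n the dendrite, ordered by distance from the soma. Electrical unit
conventions (consistent throughout the solver): voltage mV, time ms,
current nA, conductance uS, capacitance nF; the usual specific constants
(Ra in Ohm*cm, Cm in uF/cm^2, g_leak in mS/cm^2) are converted on
construction.

The two archetypes capture the features that matter for dendritic
filtering: the pyramidal-like cell has a longer, wider dendrite (larger
total dendritic capacitance) and a slower membrane time constant than the
PV-like cell, so it low-pass filters dendritic input more strongly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Tuple

import numpy as np

__all__ = ["CompartmentalNeuron", "build_neuron", "site_at_distance", "scale_dendritic_cm"]


@dataclass(frozen=True)
class CompartmentalNeuron:
    """Passive cable chain with a threshold-reset spike mechanism at the soma."""

    length_um: np.ndarray
    diam_um: np.ndarray
    cm_uf_cm2: np.ndarray
    gl_ms_cm2: np.ndarray
    n_parallel: Optional[np.ndarray] = None
    ra_ohm_cm: float = 150.0
    e_leak_mv: float = -65.0
    v_th_mv: float = -50.0
    v_reset_mv: float = -65.0
    refractory_ms: float = 2.0
    archetype: str = "custom"

    def __post_init__(self) -> None:
        for name in ("length_um", "diam_um", "cm_uf_cm2", "gl_ms_cm2"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.n_parallel is None:
            object.__setattr__(self, "n_parallel", np.ones_like(self.length_um))
        else:
            object.__setattr__(self, "n_parallel", np.asarray(self.n_parallel, dtype=float))
        n = self.length_um.size
        if not (
            self.diam_um.size == self.cm_uf_cm2.size == self.gl_ms_cm2.size
            == self.n_parallel.size == n
        ):
            raise ValueError("per-compartment arrays must have equal length")
        if n < 1:
            raise ValueError("need at least one compartment")
        if (
            np.any(self.length_um <= 0)
            or np.any(self.diam_um <= 0)
            or np.any(self.cm_uf_cm2 <= 0)
            or np.any(self.gl_ms_cm2 <= 0)
            or self.ra_ohm_cm <= 0
        ):
            raise ValueError("all geometric/electrical constants must be positive")

    @property
    def n_compartments(self) -> int:
        return self.length_um.size

    @property
    def area_cm2(self) -> np.ndarray:
        """Lateral cylinder area per compartment (cm^2).

        ``n_parallel`` lumps N identical parallel branches into one
        compartment chain (membrane area and axial conductance both scale
        by N); by symmetry and superposition the somatic response to
        current entering the lumped chain equals the response to the same
        current entering a single branch, so somatic transfer impedances
        are exact.
        """
        return np.pi * self.diam_um * self.length_um * 1e-8 * self.n_parallel

    @property
    def c_nf(self) -> np.ndarray:
        """Membrane capacitance per compartment (nF)."""
        return self.cm_uf_cm2 * self.area_cm2 * 1e3

    @property
    def g_leak_us(self) -> np.ndarray:
        """Leak conductance per compartment (uS)."""
        return self.gl_ms_cm2 * self.area_cm2 * 1e3

    @property
    def g_axial_us(self) -> np.ndarray:
        """Axial conductance between adjacent compartments (uS), length n-1.

        Series resistance of the two half-cylinders joining the centers.
        """
        L_cm = self.length_um * 1e-4
        a_cm2 = np.pi * (self.diam_um * 1e-4) ** 2 / 4 * self.n_parallel
        r_half = self.ra_ohm_cm * (L_cm / 2) / a_cm2  # Ohm
        r_link = r_half[:-1] + r_half[1:]
        return 1e6 / r_link

    @property
    def distance_um(self) -> np.ndarray:
        """Path distance of each compartment center from the soma center."""
        d = np.zeros(self.n_compartments)
        if self.n_compartments > 1:
            # soma-edge to dendrite centers
            cum = np.cumsum(self.length_um[1:])
            d[1:] = cum - self.length_um[1:] / 2
        return d

    @property
    def tau_m_ms(self) -> float:
        """Membrane time constant Cm / g_leak (uniform-membrane value)."""
        return float(np.mean(self.cm_uf_cm2 / self.gl_ms_cm2))

    @property
    def total_dendritic_capacitance_nf(self) -> float:
        return float(self.c_nf[1:].sum())


_ARCHETYPES = {
    # soma L=d (um), dendrite length (um), n dend comps, dend diam (um),
    # n parallel dendrites, dendritic Cm (uF/cm^2), tau_m (ms), V_th (mV)
    "pyramidal": (20.0, 600.0, 20, 0.8, 3, 2.5, 20.0, -50.0),
    "pv": (15.0, 300.0, 10, 1.2, 5, 0.9, 5.0, -55.0),
}


def build_neuron(archetype: str, ra_ohm_cm: float = 150.0) -> CompartmentalNeuron:
    """Construct a ball-and-stick archetype ('pyramidal' or 'pv').

    Pyramidal-like: three parallel thin (0.8 um) 600 um dendrites with
    spiny-membrane capacitance 2.5 uF/cm^2 and a 20 ms membrane time
    constant. PV-like: five parallel smooth 300 um dendrites (1.2 um) at
    0.9 uF/cm^2, a fast 5 ms time constant and a lower spike threshold
    (fast-spiking cells are more excitable). The leak conductance follows
    from Cm and the target time constant, so the pyramidal cell carries
    both the larger total dendritic capacitance and the slower membrane --
    the two properties that make it the stronger dendritic low-pass filter.
    """
    if archetype not in _ARCHETYPES:
        raise ValueError(f"unknown archetype {archetype!r}; choose from {sorted(_ARCHETYPES)}")
    soma, dend_len, n_dend, dend_diam, n_par, cm_dend, tau_m, v_th = _ARCHETYPES[archetype]
    n = 1 + n_dend
    length = np.full(n, dend_len / n_dend)
    diam = np.full(n, dend_diam)
    cm = np.full(n, cm_dend)
    npar = np.full(n, float(n_par))
    length[0] = soma
    diam[0] = soma
    cm[0] = 1.0
    npar[0] = 1.0
    return CompartmentalNeuron(
        length_um=length,
        diam_um=diam,
        cm_uf_cm2=cm,
        gl_ms_cm2=cm / tau_m,
        n_parallel=npar,
        ra_ohm_cm=ra_ohm_cm,
        v_th_mv=v_th,
        archetype=archetype,
    )


def site_at_distance(neuron: CompartmentalNeuron, distance_um: float) -> int:
    """Index of the dendritic compartment whose center is nearest a path
    distance from the soma (e.g. the standard 150 um injection site)."""
    if neuron.n_compartments < 2:
        raise ValueError("neuron has no dendrite")
    d = neuron.distance_um
    return int(1 + np.argmin(np.abs(d[1:] - distance_um)))


def scale_dendritic_cm(neuron: CompartmentalNeuron, factor: float) -> CompartmentalNeuron:
    """Scale the membrane capacitance of all dendritic compartments."""
    if factor <= 0:
        raise ValueError("scale factor must be positive")
    cm = neuron.cm_uf_cm2.copy()
    cm[1:] *= factor
    return replace(neuron, cm_uf_cm2=cm)
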