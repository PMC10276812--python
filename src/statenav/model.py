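"""Two-state coupled-equilibrium (modulated-receptor) model of channel block.

Voltage-gated sodium channels distribute between resting (R) and inactivated
(I) conformations according to a Boltzmann equilibrium set by the membrane
potential.  A drug that binds the two conformations with different
dissociation constants (K_r to resting, K_i to inactivated) pulls that
equilibrium toward the higher-affinity conformation.  At binding equilibrium
the availability curve keeps its shape but its midpoint moves by

    dV = -k * ln[(1 + D/K_i) / (1 + D/K_r)]

where k is the Boltzmann slope factor (mV) and D the drug concentration.
Tighter binding to inactivated states (K_i < K_r) gives a hyperpolarizing
(negative) shift.  This module holds that algebra; the kinetic realization
lives in :mod:`statenav.kinetics` and the inverse problem (curve -> K_i) in
:mod:`statenav.inference`.

Units: voltages mV, concentrations nM, throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BoltzmannParams",
    "StateBindingModel",
    "boltzmann_availability",
    "coupled_shift",
    "apparent_kd",
]


@dataclass(frozen=True)
class BoltzmannParams:
    """Parameters of a steady-state availability (inactivation) curve.

    Availability decreases with depolarization:
    ``h(V) = amplitude / (1 + exp((V - v_half) / slope))`` with ``slope > 0``.

    Parameters
    ----------
    v_half : float
        Midpoint voltage V_1/2 (mV).
    slope : float
        Slope factor k (mV), strictly positive; the voltage change producing
        an e-fold change in the resting/inactivated equilibrium.
    amplitude : float
        Maximal availability (dimensionless), default 1.
    """

    v_half: float
    slope: float
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.v_half):
            raise ValueError("v_half must be finite")
        if not (np.isfinite(self.slope) and self.slope > 0):
            raise ValueError(f"slope must be strictly positive, got {self.slope}")
        if not (np.isfinite(self.amplitude) and self.amplitude >= 0):
            raise ValueError(f"amplitude must be non-negative, got {self.amplitude}")


@dataclass(frozen=True)
class StateBindingModel:
    """Drug concentration plus state-specific dissociation constants.

    ``kd_rest`` may be ``math.inf`` to represent no measurable resting-state
    binding.  ``slope`` is shared with the control availability curve; the
    two-state model assumes a common slope factor for control and drug.
    """

    drug_conc: float
    kd_rest: float
    kd_inact: float
    slope: float

    def __post_init__(self) -> None:
        if self.drug_conc < 0:
            raise ValueError("drug_conc must be >= 0")
        if not self.kd_rest > 0:
            raise ValueError("kd_rest must be > 0 (may be inf)")
        if not (np.isfinite(self.kd_inact) and self.kd_inact > 0):
            raise ValueError("kd_inact must be finite and > 0")
        if not (np.isfinite(self.slope) and self.slope > 0):
            raise ValueError("slope must be strictly positive")

    @property
    def resting_block(self) -> float:
        """Fraction of current remaining at strongly hyperpolarized holding,
        1 / (1 + D/K_r): occupancy of unbound resting channels among resting
        channels at binding equilibrium."""
        return 1.0 / (1.0 + self.drug_conc / self.kd_rest)


def boltzmann_availability(v, p: BoltzmannParams):
    """Steady-state availability at voltage(s) ``v`` (mV).

    Returns ``amplitude / (1 + exp((v - v_half)/slope))``; monotonically
    decreasing in ``v`` and approaching ``amplitude`` as ``v -> -inf``.
    Accepts scalars or arrays.
    """
    v = np.asarray(v, dtype=float)
    out = p.amplitude / (1.0 + np.exp((v - p.v_half) / p.slope))
    return float(out) if out.ndim == 0 else out


def coupled_shift(m: StateBindingModel) -> float:
    """Midpoint shift dV_1/2 (mV) predicted by the coupled-equilibrium model.

    ``-slope * ln[(1 + D/K_i) / (1 + D/K_r)]``; zero when D = 0 or when the
    two affinities are equal, negative (hyperpolarizing) when K_i < K_r.
    """
    d = m.drug_conc
    if d == 0.0:
        return 0.0
    return -m.slope * math.log((1.0 + d / m.kd_inact) / (1.0 + d / m.kd_rest))


def apparent_kd(h: float, m: StateBindingModel) -> float:
    """Apparent dissociation constant at availability ``h``.

    The standard coupled-equilibrium harmonic combination
    ``1/K_app = h/K_r + (1 - h)/K_i``: with fast gating, binding relaxes as a
    single site whose affinity interpolates between K_r (all channels resting,
    h = 1) and K_i (all inactivated, h = 0).
    """
    if not (0.0 <= h <= 1.0):
        raise ValueError(f"availability h must lie in [0, 1], got {h}")
    inv = h / m.kd_rest + (1.0 - h) / m.kd_inact
    if inv == 0.0:
        return math.inf
    return 1.0 / inv
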