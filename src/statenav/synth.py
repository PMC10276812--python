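"""Seeded generators for every input the analysis pipeline consumes.

All generators are deterministic under a fixed seed: a single global integer
seed is expanded into independent per-curve substreams with
``numpy.random.default_rng([seed, stream])``, so changing the seed changes
only the noise and two runs with identical parameters are bit-identical.
Noise is additive Gaussian on the normalized current (roughly uniform error
bars across an availability curve), clipped at zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .model import BoltzmannParams, StateBindingModel, boltzmann_availability, coupled_shift
from .kinetics import (
    KineticScheme,
    VoltageProtocol,
    simulate_protocol,
    slowly_recovering_fraction,
)
from .inference import AvailabilityCurve, DoseResponseCurve
from . import structure as st

__all__ = [
    "NoiseSpec",
    "gen_availability",
    "gen_paired_availability",
    "gen_dose_response",
    "gen_kinetic_dataset",
    "gen_structure_fixtures",
    "DEFAULT_VOLTAGE_GRID",
    "DEFAULT_DOSE_GRID",
]

#: prepulse grid used in the steady-state availability protocol
DEFAULT_VOLTAGE_GRID = np.arange(-130.0, -15.0, 5.0)
#: five-point log-spaced assay grid, nM ({0.3, 1, 3, 10, 30} uM)
DEFAULT_DOSE_GRID = np.array([300.0, 1000.0, 3000.0, 10000.0, 30000.0])


@dataclass(frozen=True)
class NoiseSpec:
    """Gaussian measurement noise: sd on normalized current, plus a seed."""

    sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("noise sd must be >= 0")

    def rng(self, stream: int = 0) -> np.random.Generator:
        """Independent substream of the global seed."""
        return np.random.default_rng([self.seed, stream])

    def apply(self, y: np.ndarray, stream: int = 0) -> np.ndarray:
        if self.sd == 0.0:
            return np.array(y, dtype=float)
        out = y + self.rng(stream).normal(0.0, self.sd, size=np.shape(y))
        return np.clip(out, 0.0, None)


NOISELESS = NoiseSpec(0.0, 0)


def gen_availability(
    params: BoltzmannParams,
    voltages: Sequence[float] = DEFAULT_VOLTAGE_GRID,
    noise: NoiseSpec = NOISELESS,
    stream: int = 0,
    drug_conc: float = 0.0,
    label: str = "",
) -> AvailabilityCurve:
    """Availability curve sampled from a Boltzmann with measurement noise."""
    voltages = np.asarray(voltages, dtype=float)
    if voltages.size == 0:
        raise ValueError("voltage grid must not be empty")
    y = boltzmann_availability(voltages, params)
    return AvailabilityCurve(
        prepulse_v=voltages,
        current_norm=noise.apply(y, stream),
        drug_conc=drug_conc,
        label=label,
    )


def gen_paired_availability(
    model: StateBindingModel,
    control: BoltzmannParams,
    voltages: Sequence[float] = DEFAULT_VOLTAGE_GRID,
    noise: NoiseSpec = NOISELESS,
) -> tuple[AvailabilityCurve, AvailabilityCurve, float]:
    """Control/drug availability pair under the coupled-equilibrium model.

    The drug curve is the control Boltzmann shifted by ``coupled_shift`` and
    scaled by the resting block ``1/(1 + D/K_r)``; the resting block is
    returned as the third element for the inference chain.  Substreams 0 and
    1 of the seed carry the control and drug noise respectively.
    """
    shift = coupled_shift(model)
    block = model.resting_block
    drug_params = BoltzmannParams(
        control.v_half + shift, control.slope, control.amplitude * block
    )
    ctl = gen_availability(control, voltages, noise, stream=0, label="control")
    drg = gen_availability(
        drug_params, voltages, noise, stream=1,
        drug_conc=model.drug_conc, label="drug",
    )
    return ctl, drg, block


def gen_dose_response(
    ic50: float,
    hill_n: float = 1.0,
    concs: Sequence[float] = DEFAULT_DOSE_GRID,
    noise: NoiseSpec = NOISELESS,
    stream: int = 0,
    label: str = "",
) -> DoseResponseCurve:
    """Hill-shaped dose-inhibition data (concentrations in nM)."""
    concs = np.asarray(concs, dtype=float)
    if concs.size == 0:
        raise ValueError("concentration grid must not be empty")
    if ic50 <= 0:
        raise ValueError("ic50 must be positive")
    y = 1.0 / (1.0 + (ic50 / concs) ** hill_n)
    y = noise.apply(y, stream)
    return DoseResponseCurve(conc=concs, inhibition=np.clip(y, 0.0, 1.0), label=label)


def gen_kinetic_dataset(
    scheme: KineticScheme,
    drug_conc: float = 0.0,
    conditioning_ms: Sequence[float] = (1.0, 3.0, 10.0, 20.0, 50.0, 100.0, 300.0),
    recovery_ms: Sequence[float] | None = None,
    conditioning_v: float = -40.0,
    recovery_v: float = -100.0,
    holding: float = -100.0,
    noise: NoiseSpec = NOISELESS,
) -> dict[str, pd.DataFrame]:
    """Recovery and slow-entry time-course tables from the simulator.

    ``recovery``: availability vs. recovery interval at ``recovery_v`` after
    a 300-ms conditioning step (recovery-from-inactivation protocol);
    ``entry``: fraction of slowly-recovering channels vs. conditioning
    duration (entry-into-slow-states protocol, 100-ms recovery criterion).
    Recovery intervals default to 25 points log-spaced from 1 ms to 3 s.
    """
    if recovery_ms is None:
        recovery_ms = np.geomspace(1.0, 3000.0, 25)
    rec_rows = []
    for t in recovery_ms:
        proto = VoltageProtocol(
            epochs=((holding, 0.0), (conditioning_v, 300.0), (recovery_v, float(t))),
            measure_epochs=(2,),
            label="recovery",
        )
        traj = simulate_protocol(scheme, proto, drug_conc)
        rec_rows.append({"recovery_ms": float(t), "availability": traj.readouts[0][1]})
    recovery = pd.DataFrame(rec_rows)
    recovery["availability"] = noise.apply(
        recovery["availability"].to_numpy(), stream=0
    )

    ent_rows = []
    for dur in conditioning_ms:
        frac = slowly_recovering_fraction(
            scheme, drug_conc, float(dur), conditioning_v, recovery_v,
            criterion_time=100.0, holding=holding,
        )
        ent_rows.append({"conditioning_ms": float(dur), "slow_fraction": frac})
    entry = pd.DataFrame(ent_rows)
    entry["slow_fraction"] = noise.apply(entry["slow_fraction"].to_numpy(), stream=1)
    return {"recovery": recovery, "entry": entry}


# ---------------------------------------------------------------------------
# structural fixtures with planted geometry
# ---------------------------------------------------------------------------

def _ring(center: np.ndarray, normal: np.ndarray, radius: float = 1.39,
          n: int = 6, phase: float = 0.0) -> np.ndarray:
    """Coordinates of a planar regular ring with the given normal."""
    normal = np.asarray(normal, float)
    normal = normal / np.linalg.norm(normal)
    # orthonormal in-plane basis
    a = np.array([1.0, 0.0, 0.0])
    if abs(normal @ a) > 0.9:
        a = np.array([0.0, 1.0, 0.0])
    u = np.cross(normal, a)
    u /= np.linalg.norm(u)
    w = np.cross(normal, u)
    ang = phase + 2 * np.pi * np.arange(n) / n
    return center + radius * (np.outer(np.cos(ang), u) + np.outer(np.sin(ang), w))


def gen_structure_fixtures() -> dict:
    """Synthetic toy coordinate sets with planted interactions.

    Returns a dict of synthetic :class:`~statenav.structure.Structure`
    objects (these are constructed stand-ins, not deposited coordinates):

    ``hbond``
        A serine hydroxyl donor 2.8 A from a ligand oxygen with a 170 deg
        CB-OG...O angle, plus a decoy ligand oxygen at 4.5 A from a second
        serine (beyond the heavy-atom H-bond cutoff).
    ``pistack``
        A phenylalanine ring and a parallel ligand six-membered ring at
        4.0 A centroid separation.
    ``chain`` / ``chain_rotated`` / ``rotation`` / ``translation``
        A 12-atom chain and a copy transformed by a known proper rotation
        (30 deg about z) plus translation, for superposition round trips.
    """
    mk = st.Atom

    # (a) + (d): donor-acceptor triad and decoy, one structure
    atoms = []
    # SER 10: CB at 1.43 A from OG (covalent), OG at origin
    og = np.zeros(3)
    cb = np.array([0.0, 0.0, 1.43])
    acc_dir = np.array([math.sin(math.radians(170.0)), 0.0,
                        math.cos(math.radians(170.0))])
    o1 = 2.8 * acc_dir  # 170 deg angle CB-OG...O1
    atoms += [
        mk("A", 10, "SER", "CB", "C", *cb),
        mk("A", 10, "SER", "OG", "O", *og),
        mk("L", 90, "CBD", "O1", "O", *o1),
    ]
    # decoy: SER 20 OG 4.5 A from ligand O2, far from the first triad
    base = np.array([20.0, 0.0, 0.0])
    atoms += [
        mk("A", 20, "SER", "CB", "C", *(base + np.array([0.0, 0.0, 1.43]))),
        mk("A", 20, "SER", "OG", "O", *base),
        mk("L", 91, "CBD", "O2", "O", *(base + np.array([0.0, 4.5, 0.0]))),
    ]
    hbond = st.Structure(atoms, source="synthetic-hbond-fixture")

    # (b): parallel six-membered rings at 4.0 A centroid distance
    phe_names = ["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]
    lig_names = ["C1", "C2", "C3", "C4", "C5", "C6"]
    ring1 = _ring(np.zeros(3), [0, 0, 1])
    ring2 = _ring(np.array([0.0, 0.0, 4.0]), [0, 0, 1], phase=np.pi / 6)
    patoms = [
        mk("A", 387, "PHE", nm, "C", *xyz) for nm, xyz in zip(phe_names, ring1)
    ] + [
        mk("L", 90, "CBD", nm, "C", *xyz) for nm, xyz in zip(lig_names, ring2)
    ]
    pistack = st.Structure(patoms, source="synthetic-pistack-fixture")

    # (c): 12-atom chain and a rotated+translated copy
    rng = np.random.default_rng(7)
    xyz = np.cumsum(rng.normal(0.0, 1.5, size=(12, 3)), axis=0)
    theta = math.radians(30.0)
    rot = np.array([
        [math.cos(theta), -math.sin(theta), 0.0],
        [math.sin(theta), math.cos(theta), 0.0],
        [0.0, 0.0, 1.0],
    ])
    trans = np.array([5.0, -3.0, 2.0])
    xyz2 = xyz @ rot.T + trans
    chain = st.Structure(
        [mk("A", i + 1, "GLY", "CA", "C", *p) for i, p in enumerate(xyz)],
        source="synthetic-chain-fixture",
    )
    chain_rot = st.Structure(
        [mk("A", i + 1, "GLY", "CA", "C", *p) for i, p in enumerate(xyz2)],
        source="synthetic-chain-fixture-rotated",
    )
    return {
        "hbond": hbond,
        "pistack": pistack,
        "chain": chain,
        "chain_rotated": chain_rot,
        "rotation": rot,
        "translation": trans,
    }
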