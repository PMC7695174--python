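"""Langevin dynamics in reduced units.

Reduced-unit conventions: the contact energy scale epsilon is the energy
unit, lengths are nm, all atoms have unit mass by default, and the time
unit follows from these.  The production reduced temperature default is
0.582 (the regime where molecular fluctuations are representative of
cellular conditions for this model class); disordered-tail generation
runs at reduced temperature 1.0.

The integrator is a BAOAB-splitting Langevin velocity-Verlet: with
friction = 0 the O-step is the identity and the scheme reduces to plain
symplectic velocity-Verlet (NVE).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .kernels import _SKIN, pack_topology, run_langevin_loop
from .structures import MolecularStructure, radius_of_gyration
from .topology import ForceFieldTopology
from .trajectory import Trajectory

__all__ = ["LangevinParams", "SimulationState", "RestraintSpec",
           "SimulationBlowUpError", "initialize_velocities", "run_langevin",
           "generate_disordered_tails",
           "PRODUCTION_TEMPERATURE", "TAIL_GENERATION_TEMPERATURE"]

PRODUCTION_TEMPERATURE = 0.582
TAIL_GENERATION_TEMPERATURE = 1.0


class SimulationBlowUpError(RuntimeError):
    """Raised when coordinates become non-finite; reports the step number."""

    def __init__(self, step: int):
        self.step = step
        super().__init__(f"simulation blew up at step {step}")


@dataclass(frozen=True)
class LangevinParams:
    """Integration parameters (reduced units).

    reduced_temperature : production default 0.582
    timestep : default 0.002
    friction : inverse reduced time, default 1.0; 0 gives NVE
    """

    reduced_temperature: float = PRODUCTION_TEMPERATURE
    timestep: float = 0.002
    friction: float = 1.0
    n_steps: int = 0
    seed: int = 0
    save_interval: int = 500

    def __post_init__(self) -> None:
        if self.timestep <= 0:
            raise ValueError("timestep must be positive")
        if self.friction < 0:
            raise ValueError("friction must be non-negative")
        if self.n_steps < 0:
            raise ValueError("n_steps must be non-negative")
        if self.reduced_temperature < 0:
            raise ValueError("temperature must be non-negative")
        if self.save_interval < 1:
            raise ValueError("save_interval must be >= 1")


@dataclass
class SimulationState:
    positions: np.ndarray
    velocities: np.ndarray
    time: float = 0.0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.velocities = np.asarray(self.velocities, dtype=float)
        if self.positions.shape != self.velocities.shape:
            raise ValueError("positions/velocities shape mismatch")
        if not (np.all(np.isfinite(self.positions))
                and np.all(np.isfinite(self.velocities))):
            raise ValueError("non-finite state")


@dataclass(frozen=True)
class RestraintSpec:
    """Harmonic position restraints on an atom selection.

    ``atom_indices`` must be non-empty; ``reference_positions`` has one
    row per restrained atom; ``spring_constant`` is in reduced energy
    per nm^2.
    """

    atom_indices: np.ndarray
    reference_positions: np.ndarray
    spring_constant: float

    def __post_init__(self) -> None:
        idx = np.asarray(self.atom_indices, dtype=np.int64)
        ref = np.asarray(self.reference_positions, dtype=float)
        object.__setattr__(self, "atom_indices", idx)
        object.__setattr__(self, "reference_positions", ref)
        if len(idx) == 0:
            raise ValueError("restraint selection is empty")
        if ref.shape != (len(idx), 3):
            raise ValueError("reference positions must be (n_restrained, 3)")
        if self.spring_constant <= 0:
            raise ValueError("spring constant must be positive")


def initialize_velocities(n_atoms_or_state, temperature: float, seed: int,
                          masses: np.ndarray | None = None) -> np.ndarray:
    """Maxwell-Boltzmann velocities at the given reduced temperature.

    Deterministic given the seed; ``temperature = 0`` yields zeros.
    """
    if temperature < 0:
        raise ValueError("temperature must be non-negative")
    if isinstance(n_atoms_or_state, SimulationState):
        n = len(n_atoms_or_state.positions)
    else:
        n = int(n_atoms_or_state)
    masses = np.ones(n) if masses is None else np.asarray(masses, dtype=float)
    rng = np.random.default_rng(seed)
    return rng.standard_normal((n, 3)) * np.sqrt(temperature / masses)[:, None]


def run_langevin(topology: ForceFieldTopology,
                 state0: SimulationState,
                 params: LangevinParams,
                 restraints: RestraintSpec | None = None) -> Trajectory:
    """Integrate Langevin dynamics; frames saved every ``save_interval`` steps.

    ``n_steps = 0`` returns a trajectory holding only the initial frame.
    Identical (seed, params, topology, state) reproduce the trajectory
    bitwise on one execution configuration (single-threaded kernels).
    Raises :class:`SimulationBlowUpError` with the step number if
    coordinates go non-finite.
    """
    if state0.positions.shape != (topology.n_atoms, 3):
        raise ValueError("state does not match topology atom count")
    packed = pack_topology(topology)
    if restraints is not None:
        rest_idx = restraints.atom_indices
        rest_ref = np.ascontiguousarray(restraints.reference_positions)
        rest_k = float(restraints.spring_constant)
    else:
        rest_idx = np.empty(0, dtype=np.int64)
        rest_ref = np.empty((0, 3))
        rest_k = 0.0
    pos = np.ascontiguousarray(state0.positions, dtype=np.float64).copy()
    vel = np.ascontiguousarray(state0.velocities, dtype=np.float64).copy()
    out = run_langevin_loop(
        pos, vel, np.ascontiguousarray(topology.masses, dtype=np.float64),
        np.float64(params.timestep), np.float64(params.friction),
        np.float64(params.reduced_temperature),
        np.int64(params.n_steps), np.int64(params.save_interval),
        np.int64(params.seed),
        *packed, rest_idx, rest_ref, np.float64(rest_k), np.float64(_SKIN))
    saved_pos, saved_vel, times, pe, ke, blowup = out
    if blowup >= 0:
        raise SimulationBlowUpError(int(blowup))
    return Trajectory(
        positions=saved_pos, times=times + state0.time, velocities=saved_vel,
        metadata={
            "seed": params.seed,
            "temperature": params.reduced_temperature,
            "timestep": params.timestep,
            "friction": params.friction,
            "n_steps": params.n_steps,
            "save_interval": params.save_interval,
            "potential_energy": pe.tolist(),
            "kinetic_energy": ke.tolist(),
        },
    )


def _autocorrelation_time(series: np.ndarray) -> float:
    """Integrated autocorrelation time (in sample strides) of a scalar series."""
    x = np.asarray(series, dtype=float)
    x = x - x.mean()
    var = float(np.mean(x * x))
    if var == 0 or len(x) < 4:
        return 0.0
    tau = 0.5
    for lag in range(1, len(x) // 2):
        rho = float(np.mean(x[:-lag] * x[lag:])) / var
        if rho < 0.05:
            break
        tau += rho
    return tau


def generate_disordered_tails(compact: MolecularStructure,
                              topology: ForceFieldTopology,
                              n_samples: int,
                              high_temperature: float = TAIL_GENERATION_TEMPERATURE,
                              restraint_k: float = 500.0,
                              seed: int = 0,
                              equilibration_steps: int = 5000,
                              stride_steps: int = 5000,
                              timestep: float = 0.002,
                              tail_ranges: dict | None = None,
                              ) -> tuple[list[MolecularStructure], dict]:
    """Sample disordered tail conformations by restrained high-T dynamics.

    A high-temperature (reduced T = 1 by default) simulation starts from
    the compact conformation with every non-tail atom harmonically
    restrained to its compact position, so the tails sample a fully
    disordered ensemble while the shell body stays put.  ``n_samples``
    conformations are taken at a fixed stride after an equilibration
    stride.

    Returns ``(samples, manifest)``; the manifest records the seed,
    parameters and a decorrelation warning if the sampling stride is
    shorter than the measured tail-Rg autocorrelation time.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    tail_idx: list[np.ndarray] = []
    for ann in compact.chains:
        rng_ = tail_ranges.get(ann.chain_id, ann.tail_range) if tail_ranges \
            else ann.tail_range
        idx = compact.atom_indices(ann.chain_id, rng_)
        if len(idx) == 0:
            raise ValueError(f"chain {ann.chain_id}: empty tail range {rng_}")
        tail_idx.append(idx)
    tail_mask = np.zeros(compact.n_atoms, dtype=bool)
    for idx in tail_idx:
        tail_mask[idx] = True
    body_idx = np.flatnonzero(~tail_mask)
    restraint = RestraintSpec(body_idx, compact.positions[body_idx], restraint_k)

    n_steps = equilibration_steps + n_samples * stride_steps
    params = LangevinParams(reduced_temperature=high_temperature,
                            timestep=timestep, friction=1.0,
                            n_steps=n_steps, seed=seed,
                            save_interval=max(1, stride_steps // 10))
    state = SimulationState(
        positions=compact.positions.copy(),
        velocities=initialize_velocities(compact.n_atoms, high_temperature, seed,
                                         topology.masses))
    traj = run_langevin(topology, state, params, restraints=restraint)

    sample_times = [(equilibration_steps + (s + 1) * stride_steps) * timestep
                    for s in range(n_samples)]
    samples = []
    for t_target in sample_times:
        frame = int(np.argmin(np.abs(traj.times - t_target)))
        samples.append(compact.with_positions(traj.positions[frame]))

    # decorrelation check on the tail radius of gyration
    all_tail = np.flatnonzero(tail_mask)
    rg_series = np.array([radius_of_gyration(fr[all_tail])
                          for fr in traj.positions])
    tau_strides = _autocorrelation_time(rg_series)
    stride_in_saves = stride_steps / params.save_interval
    manifest = {
        "seed": seed, "high_temperature": high_temperature,
        "restraint_k": restraint_k, "n_samples": n_samples,
        "equilibration_steps": equilibration_steps, "stride_steps": stride_steps,
        "tail_rg_autocorrelation_strides": tau_strides,
        "warnings": [],
    }
    if tau_strides > stride_in_saves:
        msg = ("sampling stride is shorter than the measured tail-Rg "
               f"autocorrelation time ({tau_strides:.1f} saves)")
        warnings.warn(msg)
        manifest["warnings"].append(msg)
    return samples, manifest
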