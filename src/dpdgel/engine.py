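"""DPD equations of motion under periodic boundary conditions.

Pairwise forces (all zero beyond the cutoff rc = 1 in reduced units):

* conservative: F^C = fmax_ij (1 - r) r_hat — the linear soft repulsion,
  the exact negative gradient of the quadratic DPD potential;
* dissipative: F^D = -gamma (r_hat . v_ij) r_hat with the constant weight
  function w^D = 1 inside the cutoff;
* random: F^R = sigma theta_ij r_hat / sqrt(dt), theta_ij a zero-mean,
  unit-variance uniform variate drawn once per pair (same magnitude,
  opposite sign on the partner), which together with F^D realizes the
  momentum-conserving DPD thermostat at kB*T = 1 when sigma^2 = 2 gamma.

Bonded beads additionally feel the harmonic bond force and are *not*
excluded from the non-bonded sums (soft potentials need no exclusions).

Integration is velocity Verlet with one force evaluation per step; the
protocol runs an optional Langevin-thermostatted pre-thermalization
(conservative + bond forces with per-particle friction and noise), then DPD
thermalization, then production with periodic snapshots.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .errors import DomainError, GeometryError, BlowUpError
from .forcefield import DPDForceField
from .topology import BondParams, InitialConfiguration
from .trajectory import Trajectory

__all__ = [
    "SimulationState",
    "Protocol",
    "conservative_force",
    "dissipative_force",
    "random_force",
    "bond_force",
    "maxwell_boltzmann_velocities",
    "state_from_configuration",
    "compute_forces",
    "integrate_step",
    "run_simulation",
    "neighbor_search",
    "instantaneous_temperature",
]


@dataclass
class SimulationState:
    """Mutable core of a running simulation (reduced units).

    ``positions`` are wrapped into [0, box_side); ``images`` count the
    periodic wraps per bead so ``unwrapped_positions`` recovers continuous
    coordinates.  ``types``: 0 = water, 1 = monomer.
    """

    positions: np.ndarray
    velocities: np.ndarray
    images: np.ndarray
    types: np.ndarray
    masses: np.ndarray
    box_side: float
    step: int = 0

    @property
    def n_beads(self) -> int:
        return len(self.positions)

    def unwrapped_positions(self) -> np.ndarray:
        return self.positions + self.images * self.box_side


@dataclass(frozen=True)
class Protocol:
    """Simulation schedule in reduced time steps.

    Defaults follow the full production protocol: dt = 0.01, 1e6 Langevin
    pre-thermalization steps, 1e6 DPD thermalization steps, 5e6 production
    steps.  ``snapshot_interval`` controls trajectory output during
    production; ``langevin_gamma`` is the friction of the pre-thermalization
    bath; ``skin`` the neighbour-list skin.
    """

    dt: float = 0.01
    pre_thermalization_steps: int = 1_000_000
    thermalization_steps: int = 1_000_000
    production_steps: int = 5_000_000
    snapshot_interval: int = 1_000
    seed: int = 0
    langevin_gamma: float = 1.0
    skin: float = 0.3

    def __post_init__(self):
        if self.dt <= 0:
            raise DomainError("dt must be positive")
        for name in ("pre_thermalization_steps", "thermalization_steps",
                     "production_steps"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be >= 0")
        if self.snapshot_interval < 1:
            raise DomainError("snapshot_interval must be >= 1")


def conservative_force(r: float, fmax: float, rc: float = 1.0) -> float:
    """Scalar soft repulsion along r_hat: fmax (1 - r/rc), zero beyond rc."""
    if r < 0:
        raise DomainError("r must be non-negative")
    if r >= rc:
        return 0.0
    return fmax * (1.0 - r / rc)


def dissipative_force(r: float, rhat: np.ndarray, v_rel: np.ndarray,
                      gamma: float, rc: float = 1.0) -> np.ndarray:
    """Pair drag -gamma (r_hat . v_ij) r_hat for r < rc, else zero."""
    if r == 0:
        raise DomainError("dissipative force undefined at zero separation")
    rhat = np.asarray(rhat, dtype=float)
    if r >= rc:
        return np.zeros(3)
    return -gamma * float(rhat @ np.asarray(v_rel, dtype=float)) * rhat


def random_force(r: float, rhat: np.ndarray, sigma: float, dt: float,
                 rng: np.random.Generator, rc: float = 1.0) -> np.ndarray:
    """Pair noise sigma theta r_hat / sqrt(dt), theta ~ U[-sqrt3, sqrt3).

    The same draw with opposite sign acts on the partner bead, so each pair
    contributes zero net momentum.
    """
    if r == 0:
        raise DomainError("random force undefined at zero separation")
    rhat = np.asarray(rhat, dtype=float)
    if r >= rc:
        return np.zeros(3)
    theta = (2.0 * rng.random() - 1.0) * np.sqrt(3.0)
    return sigma * theta / np.sqrt(dt) * rhat


def bond_force(r: float, params_reduced: tuple[float, float]) -> float:
    """Scalar harmonic bond force -K (r - r0) along the bond direction."""
    if r < 0:
        raise DomainError("r must be non-negative")
    K, r0 = params_reduced
    return -K * (r - r0)


def maxwell_boltzmann_velocities(masses: np.ndarray, seed: int,
                                 T: float = 1.0) -> np.ndarray:
    """Equilibrium velocities at reduced temperature T, zero total momentum."""
    rng = np.random.default_rng(seed)
    v = rng.normal(size=(len(masses), 3)) * np.sqrt(T / masses)[:, None]
    p = (masses[:, None] * v).sum(axis=0) / masses.sum()
    return v - p


def state_from_configuration(init: InitialConfiguration, ff: DPDForceField,
                             seed: int) -> SimulationState:
    masses = ff.mass_by_type()[init.types]
    return SimulationState(
        positions=init.positions.copy().astype(float),
        velocities=maxwell_boltzmann_velocities(masses, seed),
        images=np.zeros_like(init.positions, dtype=np.int64),
        types=init.types.astype(np.int64),
        masses=masses,
        box_side=init.box_side,
    )


def compute_forces(state: SimulationState, ff: DPDForceField,
                   bonds: np.ndarray | None = None,
                   bond_params_reduced: tuple[float, float] = (0.0, 0.0),
                   dt: float = 0.01, seed: int = 0,
                   include_random: bool = True) -> np.ndarray:
    """Evaluate all DPD forces at the current state (cell-list path).

    With ``include_random=False`` only the deterministic conservative,
    dissipative and bond contributions are returned, which is the quantity
    that can be compared against an independent all-pairs evaluation.
    """
    if bonds is None:
        bonds = np.empty((0, 2), dtype=np.int64)
    bonds = np.asarray(bonds, dtype=np.int64)
    n = state.n_beads
    box = state.box_side
    rng = np.empty(1, dtype=np.uint64)
    rng[0] = np.uint64(max(seed, 1))
    sigma_dt = (ff.sigma / np.sqrt(dt)) if include_random else 0.0
    f = np.zeros((n, 3))
    ncell = int(box)
    if ncell >= 3:
        ncell3 = ncell**3
        cell_of = np.empty(n, dtype=np.int64)
        counts = np.zeros(ncell3 + 1, dtype=np.int64)
        order = np.empty(n, dtype=np.int64)
        _kernels._assign_cells(state.positions, box, ncell, cell_of, counts,
                               order)
        stencil = np.array([[sx, sy, sz]
                            for sx in (-1, 0, 1) for sy in (-1, 0, 1)
                            for sz in (-1, 0, 1)
                            if sx * 9 + sy * 3 + sz > 0
                            or (sx, sy, sz) == (0, 0, 0)], dtype=np.int64)
        scratch = (np.empty((n, 3)), np.empty((n, 3)),
                   np.empty(n, dtype=np.int64), np.empty((n, 3)))
        _kernels.dpd_forces_cells(
            state.positions, state.velocities, state.types, box,
            ff.fmax_matrix(), ff.gamma, sigma_dt, bonds,
            bond_params_reduced[0], bond_params_reduced[1], f, rng,
            _kernels.MODE_DPD, 0.0, 1.0, state.masses, counts, order, ncell,
            stencil, *scratch)
    else:
        pi, pj = _kernels.build_pairs(state.positions, box, 1.0)
        _kernels.dpd_forces(
            state.positions, state.velocities, state.types, box,
            ff.fmax_matrix(), ff.gamma, sigma_dt, pi, pj, bonds,
            bond_params_reduced[0], bond_params_reduced[1], f, rng,
            _kernels.MODE_DPD, 0.0, 1.0, state.masses)
    return f


def _advance(state: SimulationState, ff: DPDForceField, bonds: np.ndarray,
             kbond: float, r0: float, dt: float, nsteps: int, seed: int,
             mode: int, langevin_gamma: float, skin: float) -> None:
    bad = _kernels.run_dpd_block(
        state.positions, state.images, state.velocities, state.types,
        state.masses, state.box_side, ff.fmax_matrix(), ff.gamma, ff.sigma,
        bonds, kbond, r0, dt, nsteps, state.step, seed, mode,
        langevin_gamma, skin,
    )
    if bad >= 0:
        raise BlowUpError(bad)
    state.step += nsteps


def integrate_step(state: SimulationState, ff: DPDForceField,
                   bonds: np.ndarray | None = None,
                   bond_params_reduced: tuple[float, float] = (0.0, 0.0),
                   dt: float = 0.01, seed: int = 0,
                   mode: int = _kernels.MODE_DPD,
                   langevin_gamma: float = 1.0, skin: float = 0.3) -> SimulationState:
    """Advance one velocity-Verlet step in place and return the state."""
    if bonds is None:
        bonds = np.empty((0, 2), dtype=np.int64)
    _advance(state, ff, np.asarray(bonds, dtype=np.int64),
             bond_params_reduced[0], bond_params_reduced[1], dt, 1, seed,
             mode, langevin_gamma, skin)
    return state


def run_simulation(init: InitialConfiguration, ff: DPDForceField,
                   protocol: Protocol,
                   bond_params: BondParams = BondParams(),
                   log_callback=None,
                   log_interval: int = 10_000) -> Trajectory:
    """Execute pre-thermalization, thermalization and production.

    Snapshots (unwrapped positions) are taken at the end of thermalization
    and every ``snapshot_interval`` production steps.  Deterministic given
    ``protocol.seed``.  Raises ``BlowUpError`` (with the step index) if the
    integrator destabilizes.
    """
    kbond, r0 = bond_params.reduced(ff.units)
    bonds = np.asarray(init.bonds, dtype=np.int64)
    state = state_from_configuration(init, ff, protocol.seed)
    traj = Trajectory(metadata={
        "temperature": ff.temperature,
        "engine": "dpd",
        "seed": protocol.seed,
        "rc_angstrom": ff.units.rc_angstrom,
        "dt": protocol.dt,
    })

    def _log():
        if log_callback is not None:
            log_callback(state.step, instantaneous_temperature(state),
                         _rg_of_state(state))

    def _run_phase(nsteps: int, mode: int):
        done = 0
        while done < nsteps:
            chunk = min(log_interval, nsteps - done)
            _advance(state, ff, bonds, kbond, r0, protocol.dt, chunk,
                     protocol.seed, mode, protocol.langevin_gamma,
                     protocol.skin)
            done += chunk
            _log()

    _run_phase(protocol.pre_thermalization_steps, _kernels.MODE_LANGEVIN)
    _run_phase(protocol.thermalization_steps, _kernels.MODE_DPD)
    traj.append(state.step, state.box_side, state.unwrapped_positions(),
                state.types)

    done = 0
    while done < protocol.production_steps:
        chunk = min(protocol.snapshot_interval,
                    protocol.production_steps - done)
        _advance(state, ff, bonds, kbond, r0, protocol.dt, chunk,
                 protocol.seed, _kernels.MODE_DPD, protocol.langevin_gamma,
                 protocol.skin)
        done += chunk
        traj.append(state.step, state.box_side, state.unwrapped_positions(),
                    state.types)
        if done % log_interval < protocol.snapshot_interval:
            _log()

    traj.metadata["final_state"] = state
    return traj


def _rg_of_state(state: SimulationState) -> float:
    poly = state.types == 1
    if poly.sum() < 2:
        return 0.0
    x = state.unwrapped_positions()[poly]
    return float(np.sqrt(((x - x.mean(axis=0)) ** 2).sum(axis=1).mean()))


def neighbor_search(state: SimulationState | np.ndarray, cutoff: float,
                    box_side: float | None = None) -> set[tuple[int, int]]:
    """Exact set of minimum-image pairs with r < cutoff.

    Accepts a state or a bare (N, 3) position array (then ``box_side`` is
    required).  Raises ``GeometryError`` if cutoff exceeds half the box.
    """
    if isinstance(state, SimulationState):
        pos, box = state.positions, state.box_side
    else:
        pos, box = np.asarray(state, dtype=float), box_side
        if box is None:
            raise GeometryError("box_side required with bare positions")
    if cutoff > box / 2:
        raise GeometryError("cutoff exceeds half the box side")
    if len(pos) == 0:
        return set()
    pi, pj = _kernels.build_pairs(np.mod(pos, box), box, cutoff)
    return {(int(a), int(b)) for a, b in zip(pi, pj)}


def instantaneous_temperature(state: SimulationState) -> float:
    """Kinetic temperature 2 KE / (3 (N-1)) with centre-of-mass motion removed."""
    n = state.n_beads
    if n < 2:
        raise DomainError("temperature needs at least two beads")
    m = state.masses
    v = state.velocities
    vcom = (m[:, None] * v).sum(axis=0) / m.sum()
    ke = 0.5 * float((m * ((v - vcom) ** 2).sum(axis=1)).sum())
    return 2.0 * ke / (3.0 * (n - 1))
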