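"""Implicit-solvent Langevin dynamics of the bare polymer network.

Comparison mode for the explicit-solvent DPD model: only the 439 polymer
beads are simulated.  Excluded volume is the purely repulsive
Weeks-Chandler-Andersen (WCA) potential (Lennard-Jones truncated at its
minimum 2^(1/6) sigma and shifted to zero); the hydrophobic effect, which
in DPD emerges from the chi-dependent water-monomer repulsion, must here be
put in by hand as a temperature-dependent attraction between monomer beads:
a flat well of depth eps_h(T) out to r1, smoothly closed by a cos^2 ramp
between r1 and the outer cutoff r2.  The well depth grows linearly with
temperature above an onset temperature, so the network is swollen (athermal)
at low T and collapses once the attraction overcomes the entropic spring
pressure of the chains.

Reduced units: length = wca_sigma (set equal to the 6.5 A bond length),
energy = kB*T, mass = one monomer bead.  The Langevin bath (friction gamma
on absolute velocities plus matched Gaussian noise) thermostats to reduced
temperature 1; unlike DPD it does not conserve momentum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .errors import BlowUpError, DomainError, GeometryError
from .forcefield import KB, ReducedUnitSystem, BeadSpec
from .engine import Protocol, maxwell_boltzmann_velocities
from .topology import BondParams, NanogelTopology, _embed_polymer
from .trajectory import Trajectory

__all__ = [
    "LangevinForceField",
    "langevin_units",
    "wca_force",
    "hydrophobic_potential",
    "hydrophobic_force",
    "langevin_step",
    "run_langevin",
]

WCA_CUTOFF = 2.0 ** (1.0 / 6.0)


@dataclass(frozen=True)
class LangevinForceField:
    """Polymer-only force field (reduced units, length = wca_sigma).

    hydro_depth(T) = hydro_slope * max(0, T - hydro_onset) in kB*T units;
    the attraction plateau runs from hydro_r1 to where the cos^2 ramp
    starts, vanishing smoothly at hydro_range.  ``damping`` is the reduced
    Langevin friction (per unit mass, 1/time); ``fcap`` caps the WCA force
    at tiny separations.
    """

    wca_epsilon: float = 1.0
    wca_sigma_A: float = 6.5
    hydro_onset: float = 295.0   # K
    hydro_slope: float = 0.1     # kB*T per K
    hydro_r1: float = WCA_CUTOFF
    hydro_range: float = 1.8
    damping: float = 1.0
    fcap: float = 1e4

    def __post_init__(self):
        if self.hydro_range <= self.hydro_r1:
            raise DomainError("hydro_range must exceed hydro_r1")
        if self.wca_epsilon < 0 or self.damping < 0:
            raise DomainError("wca_epsilon and damping must be >= 0")

    def hydro_depth(self, T: float) -> float:
        """Attraction depth in kB*T at temperature T (K); non-decreasing."""
        return self.hydro_slope * max(0.0, T - self.hydro_onset)


def langevin_units(T: float, ff: LangevinForceField = LangevinForceField(),
                   beads: BeadSpec = BeadSpec()) -> ReducedUnitSystem:
    """Reduced-unit system of the polymer-only model at temperature T."""
    return ReducedUnitSystem(rc=ff.wca_sigma_A * 1e-10,
                             mass_unit=beads.monomer_bead_mass,
                             energy_unit=KB * T, rho_reduced=0.0)


def wca_force(r: float, eps: float = 1.0, sigma: float = 1.0,
              fcap: float = 1e4) -> float:
    """Scalar WCA repulsion along r_hat; zero at and beyond 2^(1/6) sigma.

    The 1/r^13 divergence is guarded: values above ``fcap`` are clamped
    (the capped-force flag of the engine counts such events).
    """
    if r <= 0:
        raise DomainError("r must be positive")
    if r >= WCA_CUTOFF * sigma:
        return 0.0
    s6 = (sigma / r) ** 6
    f = 24.0 * eps * (2.0 * s6 * s6 - s6) / r
    return min(f, fcap)


def hydrophobic_potential(r: float, T: float,
                          ff: LangevinForceField = LangevinForceField()) -> float:
    """Smooth square-well attraction between monomer beads, kB*T units."""
    if r <= 0:
        raise DomainError("r must be positive")
    eps_h = ff.hydro_depth(T)
    if eps_h == 0.0 or r >= ff.hydro_range:
        return 0.0
    if r <= ff.hydro_r1:
        return -eps_h
    u = 0.5 * np.pi * (r - ff.hydro_r1) / (ff.hydro_range - ff.hydro_r1)
    return -eps_h * np.cos(u) ** 2


def hydrophobic_force(r: float, T: float,
                      ff: LangevinForceField = LangevinForceField()) -> float:
    """Scalar force -dU/dr of the hydrophobic well (negative = attractive)."""
    if r <= 0:
        raise DomainError("r must be positive")
    eps_h = ff.hydro_depth(T)
    if eps_h == 0.0 or r >= ff.hydro_range or r <= ff.hydro_r1:
        return 0.0
    width = ff.hydro_range - ff.hydro_r1
    u = 0.5 * np.pi * (r - ff.hydro_r1) / width
    return -eps_h * np.pi * np.cos(u) * np.sin(u) / width


def polymer_configuration(topo: NanogelTopology, box_side: float,
                          nn_distance: float | None = None) -> np.ndarray:
    """Embed the network at the centre of an otherwise empty box.

    Bond lengths start near the reduced equilibrium length 1 (= 6.5 A).
    Unlike the DPD case, beads have a hard core of diameter ~1, so the
    default embedding stretches the chains almost straight (crosslinker
    spacing 0.95 per bond); the network contracts to its equilibrium size
    during thermalization.

    Raises
    ------
    GeometryError
        If the extended network does not fit in the box.
    """
    if nn_distance is None:
        nn_distance = 0.95 * (topo.chain_length + 1)
    pos = _embed_polymer(topo, 1.0, nn_distance)
    pos = pos - pos.mean(axis=0)
    extent = 2.0 * float(np.linalg.norm(pos, axis=1).max()) + 1.0
    if extent >= box_side:
        raise GeometryError(
            f"extended network (~{extent:.1f} sigma) does not fit in box "
            f"of {box_side} sigma")
    return pos + box_side / 2.0


def _bond_reduced(bond: BondParams, T: float,
                  ff: LangevinForceField) -> tuple[float, float]:
    sigma_m = ff.wca_sigma_A * 1e-10
    k_red = bond.K * sigma_m**2 / (KB * T)
    r0_red = bond.r0 * 1e-10 / sigma_m
    return k_red, r0_red


def langevin_step(positions, images, velocities, masses, box_side, ff,
                  T, dt, nsteps=1, step0=0, seed=0,
                  bonds=None, bond_reduced=(0.0, 0.0), skin=0.3):
    """Advance Langevin dynamics in place; returns the capped-force count.

    Deterministic given (seed, step0).  Raises ``BlowUpError`` on
    instability.  With damping = 0 and eps_h = 0 this reduces to plain NVE
    velocity Verlet with WCA + bonds.
    """
    if bonds is None:
        bonds = np.empty((0, 2), dtype=np.int64)
    bad, ncap = _kernels.run_polymer_block(
        positions, images, velocities, masses, box_side,
        ff.wca_epsilon, 1.0, ff.hydro_depth(T), ff.hydro_r1, ff.hydro_range,
        ff.fcap, np.asarray(bonds, dtype=np.int64), bond_reduced[0],
        bond_reduced[1], dt, nsteps, step0, seed, ff.damping, skin,
    )
    if bad >= 0:
        raise BlowUpError(bad)
    return ncap


def run_langevin(topo: NanogelTopology, T: float, protocol: Protocol,
                 ff: LangevinForceField = LangevinForceField(),
                 bond: BondParams = BondParams(),
                 box_side: float = 100.0,
                 log_callback=None,
                 pushoff_steps: int = 5_000) -> Trajectory:
    """Thermalize and run production Langevin dynamics of the nanogel.

    A short push-off phase (small time step, strong damping) first relaxes
    residual hard-core overlaps of the constructed configuration; then the
    thermalization and production stages run at ``protocol.dt``.  Snapshot
    and format conventions match the DPD engine, so every analysis routine
    is engine-agnostic.  ``protocol.pre_thermalization_steps`` is ignored
    (there is no separate pre-thermalization stage here).
    """
    n = topo.n_beads
    masses = np.ones(n)
    positions = np.mod(polymer_configuration(topo, box_side), box_side)
    images = np.zeros((n, 3), dtype=np.int64)
    velocities = maxwell_boltzmann_velocities(masses, protocol.seed)
    types = np.ones(n, dtype=np.int64)
    kred = _bond_reduced(bond, T, ff)
    units = langevin_units(T, ff)

    traj = Trajectory(metadata={
        "temperature": T, "engine": "langevin", "seed": protocol.seed,
        "rc_angstrom": units.rc_angstrom, "dt": protocol.dt,
    })
    step = 0

    def advance(nsteps):
        nonlocal step
        langevin_step(positions, images, velocities, masses, box_side, ff,
                      T, protocol.dt, nsteps, step, protocol.seed,
                      topo.bonds, kred, protocol.skin)
        step += nsteps

    if pushoff_steps > 0:
        from dataclasses import replace as _replace
        push_ff = _replace(ff, damping=max(ff.damping, 5.0))
        langevin_step(positions, images, velocities, masses, box_side,
                      push_ff, T, protocol.dt / 20.0, pushoff_steps, 0,
                      protocol.seed, topo.bonds, kred, protocol.skin)

    advance(protocol.thermalization_steps)
    traj.append(step, box_side, positions + images * box_side, types)
    done = 0
    while done < protocol.production_steps:
        chunk = min(protocol.snapshot_interval,
                    protocol.production_steps - done)
        advance(chunk)
        done += chunk
        traj.append(step, box_side, positions + images * box_side, types)
        if log_callback is not None and done % 10_000 < protocol.snapshot_interval:
            ke = 0.5 * float((masses * (velocities**2).sum(axis=1)).sum())
            log_callback(step, 2 * ke / (3 * (n - 1)), None)
    return traj
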