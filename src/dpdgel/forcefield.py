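"""Temperature-dependent DPD force-field parameterization for unequal bead volumes.

The model maps experimental inputs at temperature T — the density and
isothermal compressibility of water, the pure density of the polymer, and a
fitted Flory-Huggins interaction parameter chi(T) — onto the three maximum
repulsion parameters of a two-component DPD fluid (water-water,
monomer-monomer, water-monomer), following the unequal-bead-volume scheme of
Kacar and co-workers on top of the classic Groot-Warren parameterization.

The chain of definitions, all in reduced units (kB*T = 1, rc = 1, water-bead
mass = 1, reduced density rho~ = 3):

* chi(T) = 0.5 + A*(1 - Theta/T), fitted to PNIPAM microgel data
  (A = 35.2, Theta = 308.3 K).  chi crosses the athermal value 0.5 exactly
  at the theta temperature and grows with T: the solvent turns poor.
* rc = (rho~ * Nm * m_w / rho_w)^(1/3): one water bead aggregates Nm = 5
  water molecules; imposing rho~ = 3 fixes the cutoff, which therefore
  varies (weakly) with temperature through the water density.
* k_inv = 1 / (rho_w,pure * kB*T * kappa_T): dimensionless inverse
  compressibility of water (about 16 at ambient conditions).
* fmax_ww = (Nm * k_inv - 1) / (2 * alpha * rho~), the Groot-Warren water
  repulsion generalized to Nm molecules per bead, with alpha = 0.101 the
  excess-pressure scaling constant of the quadratic DPD equation of state.
* The matching pressure p solves the equation of state for the water bead:
  p = rho~ + alpha * fmax_ww * rho~^2.  It is an auxiliary parameter, not
  the physical pressure of the simulated system.
* fmax_ii = (p - rho_i,pure) / (alpha * rho_i,pure^2) for each pure
  component at its own reduced pure density (this is where the unequal bead
  volumes enter).
* fmax_ij = sqrt(fmax_ii * fmax_jj) + 0.0454 * p * chi * (rho_i + rho_j)/2:
  geometric-mean baseline plus a chi-linear excess.  For two identical
  water-like beads at rho~ = 3 the excess reduces to
  0.0454 * p * rho~ * chi = 3.50 chi, recovering the Groot-Warren
  proportionality Delta_a = chi / 0.286 to within its published uncertainty.

The friction gamma = 4.5 and noise sigma = sqrt(2*gamma) (fluctuation-
dissipation with kB*T = 1) are global, identical for every pair type.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math

import numpy as np

from .errors import DomainError, ParameterizationError
from .water import water_properties

__all__ = [
    "KB",
    "AVOGADRO",
    "ALPHA_EOS",
    "CHI_EXCESS_CONST",
    "FloryHugginsModel",
    "BeadSpec",
    "ReducedUnitSystem",
    "DPDForceField",
    "chi_of_temperature",
    "cutoff_radius",
    "inverse_compressibility",
    "fmax_water",
    "matching_pressure",
    "fmax_self",
    "fmax_cross",
    "reduced_units",
    "build_forcefield",
]

KB = 1.380649e-23  # J/K
AVOGADRO = 6.02214076e23  # 1/mol

#: Scaling constant alpha of the DPD equation of state p = rho + alpha*a*rho^2.
ALPHA_EOS = 0.101

#: Proportionality constant of the chi-linear excess repulsion.
CHI_EXCESS_CONST = 0.0454


@dataclass(frozen=True)
class FloryHugginsModel:
    """Fitted temperature law chi(T) = 0.5 + A*(1 - Theta/T).

    A is the dimensionless fit amplitude, Theta the theta temperature in
    kelvin at which chi equals the athermal constant 0.5 exactly.
    """

    A: float = 35.2
    Theta: float = 308.3

    def __post_init__(self):
        if self.Theta <= 0:
            raise DomainError("theta temperature must be positive")


@dataclass(frozen=True)
class BeadSpec:
    """Coarse-graining specification of the two bead species.

    Nm
        Water molecules aggregated into one water bead (5 in all default
        simulations; chosen so the two bead volumes are as similar as
        possible).
    m_w
        Molar mass of one water molecule, g/mol.
    monomer_molar_mass
        Molar mass of one NIPAM monomer (one monomer bead), g/mol.
    monomer_mass_density
        Bulk mass density of the pure polymer, kg/m^3; 1100 kg/m^3 gives a
        monomer bead volume of about 171 A^3, close to the 5-water bead
        (about 150 A^3).
    rho_pure_water, rho_pure_monomer
        Optional explicit pure *number* densities (beads/m^3).  When None,
        water is taken from the packaged reference table at T and the
        monomer from monomer_mass_density / monomer mass.
    """

    Nm: int = 5
    m_w: float = 18.01528
    monomer_molar_mass: float = 113.16
    monomer_mass_density: float = 1100.0
    rho_pure_water: float | None = None
    rho_pure_monomer: float | None = None

    def __post_init__(self):
        if self.Nm < 1:
            raise DomainError("Nm must be >= 1")
        for name in ("m_w", "monomer_molar_mass", "monomer_mass_density"):
            if getattr(self, name) <= 0:
                raise DomainError(f"{name} must be positive")

    @property
    def water_molecule_mass(self) -> float:
        """Mass of one water molecule, kg."""
        return self.m_w * 1e-3 / AVOGADRO

    @property
    def water_bead_mass(self) -> float:
        """Mass of one water bead (= mass unit of the reduced system), kg."""
        return self.Nm * self.water_molecule_mass

    @property
    def monomer_bead_mass(self) -> float:
        """Mass of one monomer bead, kg."""
        return self.monomer_molar_mass * 1e-3 / AVOGADRO

    @property
    def monomer_mass_reduced(self) -> float:
        """Monomer bead mass in units of the water bead mass."""
        return self.monomer_bead_mass / self.water_bead_mass

    def monomer_number_density(self) -> float:
        """Pure number density of monomer beads, beads/m^3."""
        if self.rho_pure_monomer is not None:
            return self.rho_pure_monomer
        return self.monomer_mass_density / self.monomer_bead_mass


@dataclass(frozen=True)
class ReducedUnitSystem:
    """Conversion factors between reduced (dimensionless) and SI units.

    Base quantities: length = cutoff rc, mass = one water bead, energy =
    kB*T at the simulation temperature.  The derived time unit is
    rc*sqrt(mass/energy).
    """

    rc: float  # m
    mass_unit: float  # kg
    energy_unit: float  # J
    rho_reduced: float = 3.0

    @property
    def time_unit(self) -> float:
        """Derived time scale, s."""
        return self.rc * math.sqrt(self.mass_unit / self.energy_unit)

    @property
    def rc_angstrom(self) -> float:
        return self.rc * 1e10

    def length_to_reduced(self, x_si: float) -> float:
        return x_si / self.rc

    def spring_to_reduced(self, k_si: float) -> float:
        """Convert an elastic constant from N/m to reduced force/length."""
        return k_si * self.rc**2 / self.energy_unit


@dataclass(frozen=True)
class DPDForceField:
    """Complete pairwise DPD force field at one temperature (reduced units)."""

    temperature: float  # K
    fmax_ww: float
    fmax_mm: float
    fmax_wm: float
    gamma: float
    sigma: float
    p_match: float
    k_inv: float
    kappa_T: float  # 1/Pa, SI
    chi: float
    rho_w_reduced: float
    rho_m_reduced: float
    units: ReducedUnitSystem
    monomer_mass_reduced: float
    alpha: float = ALPHA_EOS
    cutoff: float = 1.0

    def fmax_matrix(self) -> np.ndarray:
        """2x2 repulsion matrix indexed by bead type (0 = water, 1 = monomer)."""
        return np.array(
            [[self.fmax_ww, self.fmax_wm], [self.fmax_wm, self.fmax_mm]]
        )

    def mass_by_type(self) -> np.ndarray:
        """Reduced bead masses by type (0 = water, 1 = monomer)."""
        return np.array([1.0, self.monomer_mass_reduced])


def chi_of_temperature(T: float, model: FloryHugginsModel = FloryHugginsModel()) -> float:
    """Flory-Huggins water-monomer interaction parameter at temperature T (K).

    chi(T) = 0.5 + A*(1 - Theta/T); strictly increasing in T, equal to the
    athermal constant 0.5 at the theta temperature.
    """
    if T <= 0:
        raise DomainError(f"temperature must be positive, got {T}")
    return 0.5 + model.A * (1.0 - model.Theta / T)


def cutoff_radius(T: float, Nm: int = 5, rho_reduced: float = 3.0,
                  m_w_kg: float | None = None,
                  rho_water: float | None = None) -> float:
    """Interaction cutoff rc in metres from the imposed reduced density.

    rc = (rho~ * Nm * m_w / rho_w)^(1/3), so that a box at reduced density
    rho~ holds exactly the experimental mass of water.  rho_water defaults
    to the reference density at T.
    """
    if Nm <= 0 or rho_reduced <= 0:
        raise DomainError("Nm and rho_reduced must be positive")
    if m_w_kg is None:
        m_w_kg = 18.01528e-3 / AVOGADRO
    if rho_water is None:
        rho_water = water_properties(T)[0]
    if m_w_kg <= 0 or rho_water <= 0:
        raise DomainError("masses and densities must be positive")
    return (rho_reduced * Nm * m_w_kg / rho_water) ** (1.0 / 3.0)


def inverse_compressibility(T: float, rho_number_water: float,
                            kappa_T: float) -> float:
    """Dimensionless inverse isothermal compressibility of water.

    k_inv = 1 / (rho_w,pure * kB*T * kappa_T) with rho_w,pure the number
    density of water *molecules* (1/m^3) and kappa_T in 1/Pa.  About 16 for
    ambient water, the Groot-Warren value.
    """
    if T <= 0 or rho_number_water <= 0 or kappa_T <= 0:
        raise DomainError("all arguments must be positive")
    return 1.0 / (rho_number_water * KB * T * kappa_T)


def fmax_water(Nm: int, k_inv: float, rho_reduced: float = 3.0,
               alpha: float = ALPHA_EOS) -> float:
    """Water-water maximum repulsion, reduced units.

    fmax_ww = (Nm*k_inv - 1) / (2*alpha*rho~); the Nm = 1, k_inv = 16
    limit recovers the classic Groot-Warren a = 25 at rho~ = 3.
    """
    if Nm * k_inv <= 1.0:
        raise ParameterizationError(
            f"Nm*k_inv = {Nm * k_inv:.3g} <= 1: no positive repulsion exists"
        )
    return (Nm * k_inv - 1.0) / (2.0 * alpha * rho_reduced)


def matching_pressure(fmax_ww: float, rho_pure_water_reduced: float = 3.0,
                      alpha: float = ALPHA_EOS) -> float:
    """Auxiliary matching pressure p, reduced units.

    Inverts the self-repulsion relation for the water bead:
    p = rho~ + alpha * fmax_ww * rho~^2, so that
    ``fmax_self(p, rho~) == fmax_ww`` exactly.
    """
    if fmax_ww < 0:
        raise ParameterizationError("fmax_ww must be non-negative")
    rho = rho_pure_water_reduced
    return rho + alpha * fmax_ww * rho**2


def fmax_self(p: float, rho_pure_i: float, alpha: float = ALPHA_EOS) -> float:
    """Self-repulsion of component i at the matching pressure, reduced units.

    fmax_ii = (p - rho_i,pure) / (alpha * rho_i,pure^2).
    """
    if p < rho_pure_i:
        raise ParameterizationError(
            f"matching pressure {p:.4g} below pure density {rho_pure_i:.4g}: "
            "negative repulsion"
        )
    return (p - rho_pure_i) / (alpha * rho_pure_i**2)


def fmax_cross(fmax_ii: float, fmax_jj: float, chi: float, p: float,
               rho_i: float, rho_j: float,
               excess_const: float = CHI_EXCESS_CONST) -> float:
    """Cross repulsion between unlike beads, reduced units.

    Geometric-mean baseline plus a chi-linear excess with pure-density
    weighting:

        fmax_ij = sqrt(fmax_ii*fmax_jj)
                  + excess_const * p * chi * (rho_i + rho_j) / 2

    At chi = 0 the cross term is exactly the geometric mean; for identical
    water-like beads at rho~ = 3 the excess slope is 0.0454*p*rho~ = 3.50
    per unit chi, the Groot-Warren Delta_a-chi proportionality.  The whole
    excess expression is isolated here so the functional form can be
    amended in one place.
    """
    if fmax_ii < 0 or fmax_jj < 0:
        raise ParameterizationError("self repulsions must be non-negative")
    baseline = math.sqrt(fmax_ii * fmax_jj)
    excess = excess_const * p * chi * 0.5 * (rho_i + rho_j)
    return baseline + excess


def reduced_units(T: float, beads: BeadSpec = BeadSpec(),
                  rho_reduced: float = 3.0) -> ReducedUnitSystem:
    """Reduced-unit system (rc, water-bead mass, kB*T) at temperature T."""
    rc = cutoff_radius(T, beads.Nm, rho_reduced, beads.water_molecule_mass)
    return ReducedUnitSystem(
        rc=rc, mass_unit=beads.water_bead_mass, energy_unit=KB * T,
        rho_reduced=rho_reduced,
    )


def build_forcefield(T: float, beads: BeadSpec = BeadSpec(),
                     fh: FloryHugginsModel = FloryHugginsModel(),
                     rho_reduced: float = 3.0,
                     gamma: float = 4.5) -> DPDForceField:
    """Assemble the full DPD force field at temperature T (kelvin).

    Composes the reference water properties, the reduced-unit system, the
    Groot-Warren water repulsion, the pressure matching, the unequal-volume
    self terms and the chi-dependent cross term.  sigma is fixed by the
    fluctuation-dissipation theorem, sigma^2 = 2*gamma (kB*T = 1).
    """
    rho_w_mass, kappa_T = water_properties(T)
    units = reduced_units(T, beads, rho_reduced)
    rc = units.rc

    # number densities
    n_water_molecules = rho_w_mass / beads.water_molecule_mass  # molecules/m^3
    n_water_beads = n_water_molecules / beads.Nm
    n_monomer = beads.monomer_number_density()
    if beads.rho_pure_water is not None:
        n_water_beads = beads.rho_pure_water
        n_water_molecules = n_water_beads * beads.Nm

    rho_w_red = n_water_beads * rc**3  # == rho_reduced by construction
    rho_m_red = n_monomer * rc**3

    k_inv = inverse_compressibility(T, n_water_molecules, kappa_T)
    f_ww = fmax_water(beads.Nm, k_inv, rho_reduced)
    p = matching_pressure(f_ww, rho_w_red)
    f_mm = fmax_self(p, rho_m_red)
    chi = chi_of_temperature(T, fh)
    f_wm = fmax_cross(f_ww, f_mm, chi, p, rho_w_red, rho_m_red)
    if f_wm < 0:
        raise ParameterizationError(
            f"cross repulsion fmax_wm = {f_wm:.4g} < 0 at T = {T} K"
        )

    return DPDForceField(
        temperature=T,
        fmax_ww=f_ww, fmax_mm=f_mm, fmax_wm=f_wm,
        gamma=gamma, sigma=math.sqrt(2.0 * gamma),
        p_match=p, k_inv=k_inv, kappa_T=kappa_T, chi=chi,
        rho_w_reduced=rho_w_red, rho_m_reduced=rho_m_red,
        units=units, monomer_mass_reduced=beads.monomer_mass_reduced,
    )
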