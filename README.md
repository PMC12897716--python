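# dpdgel

Coarse-grained simulation toolkit for the temperature-driven volume phase
transition (VPT) of a neutral PNIPAM nanogel in water, built around
dissipative particle dynamics (DPD) with **unequal bead volumes** and an
implicit-solvent Langevin comparison mode.

## The scientific problem

Thermoresponsive PNIPAM gels swell in cold water and collapse abruptly above
their lower critical solution temperature (~305 K): warm water stops being a
good solvent, hydration shells become unfavourable, and the network expels
its solvent. `dpdgel` models an isolated nanogel — a diamond-topology
network of 439 monomer/crosslinker beads in explicit coarse-grained water —
and asks whether the collapse *emerges* from a temperature-dependent
solvent–polymer interaction alone, with no ad hoc attraction between
monomers.

## The model

**Interactions.** DPD beads interact through the soft linear repulsion
F(r) = F^max_ij (1 − r/r_c) for r < r_c, plus pairwise dissipative and
random forces forming a momentum-conserving thermostat
(σ² = 2γk_BT, γ = 4.5). Bonded beads add a harmonic spring
U = K/2 (r − r₀)² with K = 0.4 N/m, r₀ = 6.5 Å.

**Parameterization.** One water bead aggregates N_m = 5 water molecules;
imposing reduced density ρ̃ = 3 fixes the cutoff
r_c = (ρ̃ N_m m_w / ρ_w)^{1/3} ≈ 7.7 Å from the experimental water density
at each temperature. The water self-repulsion follows from the isothermal
compressibility, F^max_ww = (N_m k̃⁻¹ − 1)/(2αρ̃) with α = 0.101; a matching
pressure p = ρ̃ + α F^max_ww ρ̃² then sets each component's self-repulsion at
its **own** pure density — this is where unequal bead volumes enter
(monomer bead ≈ 171 Å³ vs water bead ≈ 150 Å³). The water–monomer cross
term couples to the solvent quality through the Flory–Huggins parameter

    chi(T) = 0.5 + A (1 − Θ/T),   A = 35.2, Θ = 308.3 K
    F^max_wm = sqrt(F^max_ww F^max_mm) + 0.0454 p chi (ρ_w + ρ_m)/2

so chi = 0.5 exactly at the theta temperature and the cross repulsion grows
past the geometric-mean baseline as the solvent turns poor.

**Observables.** Radius of gyration Rg (nanogel size), swelling ratio
Rg(T)/Rg(T_ref), radial distribution functions (monomer–water,
monomer–monomer, nanogel-centre-of-mass–water), transition bracket (the
steepest Rg drop between consecutive temperatures), and blocking
(binned-correlated-data) standard errors.

## Worked example

```bash
python examples/01_parameterize_forcefield.py
```

prints the force field across the studied range (abridged):

```
   T/K    rc/A      chi  fmax_ww  fmax_mm  fmax_wm geom.mean
 280.0   7.656   -3.058   129.65   169.61   101.09    148.29
 305.0   7.668    0.119   130.32   168.81   150.17    148.32
 330.0   7.695    2.815   122.38   155.26   179.21    137.84
```

Below the theta temperature the water–monomer repulsion (101) sits far
below the geometric mean of the self terms (148): water happily wets the
polymer and the gel swells. By 330 K the ordering has reversed
(179 vs 138): contact with water costs energy, the hydration layer is
expelled, and the network collapses. `examples/03_dpd_collapse_quick.py`
runs a miniature gel at both ends of the range and prints the resulting
Rg drop; `examples/04_langevin_comparison.py` does the same with the
implicit-solvent model, where the collapse instead comes from an explicit
temperature-dependent monomer–monomer attraction.

Other entry points: `examples/02_build_nanogel.py` (the 439-bead network
and a solvated box), `examples/05_analyze_observables.py` (blocking SEM and
the 305–310 K transition bracket), and a four-verb CLI
(`dpdgel parameterize | build | simulate | analyze`) over the same library.

## Layout

- `src/dpdgel/forcefield.py` — chi(T), reduced units, repulsion parameters
- `src/dpdgel/water.py` — reference water density / compressibility (1 atm)
- `src/dpdgel/topology.py` — diamond network builder, solvated initial box
- `src/dpdgel/engine.py`, `_kernels.py` — DPD velocity-Verlet engine (numba)
- `src/dpdgel/langevin.py` — WCA + hydrophobic-well implicit-solvent mode
- `src/dpdgel/analysis.py` — Rg, RDFs, blocking SEM, swelling, transition
- `src/dpdgel/io.py`, `cli.py` — configs, annotated-XYZ trajectories, CLI
- `docs/methods.md` — model details, defaults, numerical choices, limits
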