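# Methods

## Model and assumptions

The system is a single neutral PNIPAM nanogel in explicit coarse-grained
water under NVT periodic boundary conditions. Each monomer bead is one
NIPAM unit (113.16 g/mol); each water bead aggregates five water molecules,
a coarse-graining chosen so the two bead volumes are as similar as
possible (~171 ų vs ~150 ų). Crosslinkers are chemically identical to
monomers except for their bond count. Electrostatics, hydrogen-bond
specific potentials, transport-matched per-pair friction, and structure
factors are out of scope.

All simulation-facing quantities are reduced: length by the cutoff r_c,
energy by k_BT at the simulation temperature, mass by one water bead
(monomer beads weigh 113.16/90.08 = 1.256). The derived time unit
t̃ = r_c sqrt(m/k_BT) is ≈ 4.6 ps at ambient conditions. Because r_c is
fixed by the experimental water density at each temperature, the length
conversion varies (weakly) with T: 7.66 Å at 280 K to 7.70 Å at 330 K.

## Force-field parameterization

Inputs at temperature T: water density and isothermal compressibility at
1 atm, the pure polymer density, and the fitted solvent-quality law
chi(T) = 0.5 + 35.2 (1 − 308.3/T). The chain of definitions (reduced
units, ρ̃ = 3, α = 0.101):

1. k̃⁻¹ = 1/(ρ_w k_BT κ_T) — dimensionless inverse compressibility
   (≈ 16.1 at 298 K);
2. F^max_ww = (N_m k̃⁻¹ − 1)/(2αρ̃) (≈ 131; the N_m = 1, k̃⁻¹ = 16 limit
   recovers the classic a ≈ 25 water repulsion);
3. matching pressure p = ρ̃ + α F^max_ww ρ̃² (an auxiliary construct, not
   the virial pressure of the simulated box);
4. F^max_ii = (p − ρ_i)/(α ρ_i²) at each component's own reduced pure
   density — the unequal-volume step;
5. F^max_ij = sqrt(F^max_ii F^max_jj) + 0.0454 p chi (ρ_i + ρ_j)/2.

The cross-term excess (step 5) deserves comment because the available
rendering of its source expression is typographically corrupted. We adopt
the geometric-mean baseline plus a chi-linear excess weighted by the
arithmetic mean of the pure densities, and validate it against the one
limit that is unambiguous: for two identical water-like beads at ρ̃ = 3
with a = 25 the excess slope is 0.0454·p·ρ̃ = 3.504 per unit chi, matching
the classic Groot–Warren proportionality Δa = chi/0.286 within its stated
uncertainty. The whole expression lives in a single function
(`fmax_cross`) with the constant exposed, so a corrected algebra would
touch one place. For this system the ambiguity is mild: the two candidate
density weightings differ only through ρ_m ≈ 2.64 vs ρ_w = 3.

Friction is global, γ = 4.5, σ = sqrt(2γ) = 3 exactly (fluctuation–
dissipation at k_BT = 1), identical for all pair types — adequate because
no transport properties are targeted.

Water reference data: density from the Kell (1975) 1-atm correlation,
compressibility from Kell's 1-atm table with cubic-spline interpolation,
both valid 273–373 K. Any standard source agrees with these to well below
the precision that matters here (they enter F^max through k̃⁻¹ at the
percent level). Pure polymer density defaults to 1.10 g/cm³ (bulk PNIPAM);
it is exposed in `BeadSpec` because it is the least certain input — it
shifts F^max_mm by (p−ρ_m)/αρ_m², roughly −1.5 % per +1 % density.

## Nanogel construction

The generator replicates a diamond lattice of crosslinker sites, joins
nearest-neighbour sites with 8-monomer chains, keeps beads within a
pruning radius of the lattice origin, retains the largest connected
component, and then trims the outermost dangling monomers (farthest
first, deterministic tie-break) to an exact bead-count target. The
packaged defaults (extent 2, radius 0.95 cells, target 439) give
29 crosslinkers (27 four-coordinated), 40 complete inner chains of exactly
8 monomers, and 34 dangling chains of ≤ 4 monomers. The trimming step is
what makes an exact 439 reachable: radius pruning alone jumps between 349
and 451 beads. The result is committed as a plain-text fixture
(`src/dpdgel/data/`) and the builder is tested against it.

Initial configurations embed the network with crosslinker spacing
2.4 r₀ and the chain beads wound in a 120° helix about each chain axis,
which keeps every monomer–monomer bond at r₀ and second neighbours no
closer than a bond length; the box is then filled with water by uniform
insertion, rejecting positions within 0.3 r_c of the polymer (soft cores
tolerate the rest; thermalization relaxes it). Water count defaults to
round(ρ̃ L³) − N_polymer and is exposed as an override, because at the
full-scale box the density-derived count (33,733) and the published
composition (33,620) differ by ~0.3 %, suggesting an unstated volume
correction in the original setup; the default stays density-derived.

For the implicit-solvent model the same network is embedded with chains
stretched nearly straight (0.95 bond lengths per segment) instead: WCA
cores of diameter one bond length simply do not fit a compact embedding,
and the extended start plus a push-off phase (dt/20, strong damping,
5,000 steps) is the standard preparation; the network then contracts to
its thermal size during thermalization.

## Integration and thermostats

Velocity Verlet with one force evaluation per step; the dissipative force
uses mid-step velocities (the common DPD-VV scheme — its small temperature
bias at dt = 0.01 is measured, not assumed: the 500-bead pure-water box
holds ⟨T⟩ = 1.00 ± 0.02). The random pair force carries the 1/sqrt(dt)
scaling required for step-size-independent temperature, and θ is uniform
on [−√3, √3) (zero mean, unit variance). Bonded pairs are not excluded
from non-bonded sums. Pre-thermalization runs the same conservative system
under a per-particle Langevin bath (γ_L = 1), which removes initial-
configuration stress without coupling to the momentum-conserving DPD
thermostat.

Forces are evaluated by direct linked-cell traversal (cell size = r_c)
in a numba kernel; bead data are copied into cell-sorted scratch each step
so inner loops touch contiguous memory. Interior cells skip periodic
wrapping and minimum-image branches. Noise comes from an in-kernel
xorshift64* stream seeded from (run seed, step block) and consumed in the
deterministic traversal order, so trajectories are bit-reproducible for a
given seed; on ≤ 300-bead systems the cell forces are verified against an
independent all-pairs evaluation to ~1e-10. Blow-up (per-step displacement
beyond half the box) aborts with the step index.

Unwrapped coordinates (per-bead image counters) are used for all polymer
geometry; wrapped ones for force evaluation and RDFs.

## Implicit-solvent comparison mode

Polymer-only Langevin dynamics: WCA repulsion (ε = 1 k_BT, σ = 6.5 Å — the
bond length scale, so the reduced bond length is 1), the same harmonic
bonds, and a hydrophobic flat-bottomed well between monomers closed by a
cos² ramp from r₁ = 2^{1/6} σ to 1.8 σ. The well depth is zero below an
onset temperature and grows linearly above it:
ε_h(T) = 0.1 k_BT/K · max(0, T − 295 K), giving ≈ 1 k_BT near the
transition range and 3.5 k_BT at 330 K. These constants are package
defaults, exposed in `LangevinForceField`: the original Appendix values
for this mode are not available, so the implicit-solvent branch is
calibrated only to reproduce the qualitative collapse (and does; Rg drops
between 280 K and 330 K in the desk-scale test), not the quantitative
reference radii. The WCA 1/r¹³ divergence is clamped at a configurable cap
and capped evaluations are counted. The bath is velocity Verlet with
friction and matched Gaussian noise; momentum is deliberately *not*
conserved (asserted as a contrast test against DPD).

## Analysis

* Rg: equal-mass root-mean-square distance from the centroid, unwrapped
  coordinates mandatory (a bond longer than half the box raises an error).
* Blocking SEM: the series is split into k equal blocks for
  k = 12 … 25 and the SEM of block means is averaged over that window.
  On iid data this reproduces σ/√N; on AR(1) data it recovers the inflated
  true error of the mean — both are test oracles.
* RDFs: shell histograms with minimum-image distances normalized by the
  ideal-gas expectation; distinct-pair convention when groups overlap;
  default bin 0.1 r_c; frames weighted equally. The centre-of-mass RDF
  computes the polymer COM on unwrapped coordinates and minimum-images it
  to each water bead, avoiding periodic COM artefacts for a compact
  cluster.
* First-peak position: parabolic interpolation through the first local
  maximum above g = 1 (sentinel None when no such peak exists).
* Transition bracket: the consecutive temperature pair with the strictly
  largest Rg drop; flat, increasing, or uniformly sloped curves return the
  no-transition sentinel.
* Maximum-diameter estimate: the largest r with monomer–monomer
  g(r) > 10⁻³ (threshold configurable).

## Problem sizes used in the shipped tests

The default suite exercises the full physics at reduced scale, chosen as
the smallest sizes at which every effect is unambiguous: the engine
property checks use a 500-bead pure fluid (5×10⁴ thermostat steps); the
collapse experiment uses the complete 439-bead nanogel in a 12 r_c box
(5,184 beads) with 5×10³ pre-thermalization, 1.5×10⁴ thermalization and
2×10⁵ production steps at 280 K and 330 K. At that scale the production
mean Rg comes out ≈ 44 Å swollen vs ≈ 20 Å collapsed, already very close
to the full-scale reference values, and the water-exclusion signatures
(centre-of-mass–water RDF at small r, first solvation shell of the
monomer–water RDF) are far outside noise. The full protocol — 22.5 r_c
box, 34k beads, 10⁶ + 10⁶ + 5×10⁶ steps per temperature, nine
temperatures — is implemented verbatim in `scripts/longrun_reproduction.py`
and is the configuration the quantitative reference table, the 6.5 Å
high-temperature monomer–monomer peak and the 305–310 K bracket refer to.

## What the synthetic conditions do and do not show

The scaled-down box confines the swollen gel (the extended network spans
most of the 12 r_c box), so low-temperature Rg values there are mildly
box-limited and production lengths are too short for fully converged
blocking plateaus; the tests therefore assert orderings and qualitative
structure, not absolute values, at that scale. Conversely, everything
analytic (parameterization chain, topology counts, estimator oracles) is
exact and scale-free. No claim is made about transport coefficients
(global γ), about charged or copolymer gels, or about hydrogen-bond-level
collapse mechanisms, which this level of coarse-graining cannot resolve.

## Numerical choices and degenerate inputs

dt = 0.01 t̃ throughout; neighbour structures are rebuilt every step (cell
traversal) or on skin/2 displacement (pair lists for the polymer-only
engine, skin 0.3). Coincident beads (r < 10⁻¹²) are skipped in pair loops;
zero-length chain axes raise geometry errors; empty topologies, duplicate
or self bonds, disconnected networks, monomers with more than two bonds,
and inner chains of the wrong length are rejected by `validate_topology`
with named errors. Config files reject unknown keys with their full key
path. The trajectory dialect prints six decimals; round-tripping is exact
to that precision.
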