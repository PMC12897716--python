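"""Construct the diamond-topology nanogel and a solvated starting box.

The default configuration prunes a diamond lattice of crosslinkers joined
by 8-monomer chains down to exactly 439 polymer beads — inner crosslinkers
carry four chains, rim crosslinkers fewer, outermost chains may be short.
The box is then filled with water beads to reduced density 3.

The printed degree histogram counts beads by bond count: monomers have
degree 1-2, crosslinkers up to 4.
"""

from dpdgel import (build_forcefield, build_nanogel, initial_configuration,
                    validate_topology)

topo = build_nanogel()
report = validate_topology(topo)
for key, val in report.items():
    print(f"{key}: {val}")

ff = build_forcefield(298.15)
init = initial_configuration(topo, box_side=12.0, units=ff.units, seed=1)
print(f"\nbox 12 rc at reduced density 3: {init.n_polymer} polymer beads + "
      f"{init.n_water} water beads = {init.n_beads} "
      f"(3 * 12^3 = {3 * 12**3})")

init_paper = initial_configuration(topo, box_side=22.5, units=ff.units,
                                   seed=1)
print(f"full-scale box 22.5 rc: {init_paper.n_water} water beads "
      "(density-derived default)")
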