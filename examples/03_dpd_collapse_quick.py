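"""Quick DPD demonstration of the volume phase transition (~1 minute).

Runs a deliberately small system — a 9 rc box with a miniature nanogel
(2-monomer chains) and heavily shortened protocol — at 280 K and 330 K and
prints the production-mean radius of gyration.  The gel must come out
smaller at 330 K: above the theta temperature the water-monomer repulsion
exceeds the geometric-mean baseline and water is expelled from the network.

For the full-scale protocol (22.5 rc box, 7e6 steps per temperature) see
scripts/longrun_reproduction.py.
"""

import numpy as np

from dpdgel import build_forcefield, build_nanogel, initial_configuration
from dpdgel.analysis import rg_series
from dpdgel.engine import Protocol, run_simulation

topo = build_nanogel(chain_length=2, lattice_extent=1, pruning_radius=0.75,
                     target_beads=None)
print(f"miniature nanogel: {topo.n_beads} beads, {topo.n_bonds} bonds")

protocol = Protocol(pre_thermalization_steps=2_000,
                    thermalization_steps=5_000,
                    production_steps=20_000,
                    snapshot_interval=500, seed=7)

rg = {}
for T in (280.0, 330.0):
    ff = build_forcefield(T)
    init = initial_configuration(topo, box_side=9.0, units=ff.units, seed=7)
    traj = run_simulation(init, ff, protocol)
    series = rg_series(traj)          # angstrom, one value per snapshot
    rg[T] = float(np.mean(series[10:]))
    print(f"T = {T:5.1f} K: chi = {ff.chi:+.3f}, fmax_wm = {ff.fmax_wm:6.1f},"
          f" production mean Rg = {rg[T]:.2f} A")

ratio = rg[330.0] / rg[280.0]
print(f"\nRg(330 K) / Rg(280 K) = {ratio:.3f}  "
      f"({'collapse' if ratio < 1 else 'no collapse'} at high temperature)")
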