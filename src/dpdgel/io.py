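"""Run configuration and trajectory file I/O.

Configs are plain-text YAML mappings (``key: value``); unknown keys are
rejected with the offending key path so typos fail loudly.  Trajectories
use an annotated XYZ dialect: the comment line of every frame carries the
step index, box side (reduced), temperature, cutoff in angstrom, engine
and seed, and each bead record is ``<W|M> x y z`` with *unwrapped* reduced
coordinates printed to six decimals.
"""

from __future__ import annotations

from dataclasses import dataclass


import numpy as np
import yaml

from .errors import ConfigError, TrajectoryParseError
from .forcefield import BeadSpec, FloryHugginsModel, build_forcefield
from .engine import Protocol, run_simulation
from .langevin import LangevinForceField, run_langevin
from .topology import (BondParams, build_nanogel, initial_configuration,
                       load_default_topology_fixture)
from .trajectory import Trajectory

__all__ = [
    "RunConfig",
    "read_config",
    "write_trajectory",
    "read_trajectory",
]

_TYPE_LABELS = {0: "W", 1: "M"}
_TYPE_CODES = {"W": 0, "M": 1}


@dataclass
class RunConfig:
    """Validated simulation run description."""

    engine: str
    temperature_K: float
    seed: int
    box_side: float
    water_count: int | None
    beads: BeadSpec
    fh: FloryHugginsModel
    bond: BondParams
    topology_config: dict
    use_fixture: bool
    protocol: Protocol
    langevin_ff: LangevinForceField
    nn_distance: float | None = None

    def build_topology(self):
        if self.use_fixture:
            return load_default_topology_fixture()
        return build_nanogel(**self.topology_config)

    def run(self, log_callback=None) -> Trajectory:
        """Build everything from the config and run the selected engine."""
        topo = self.build_topology()
        if self.engine == "langevin":
            return run_langevin(topo, self.temperature_K, self.protocol,
                                self.langevin_ff, self.bond, self.box_side,
                                log_callback=log_callback)
        ff = build_forcefield(self.temperature_K, self.beads, self.fh)
        init = initial_configuration(
            topo, self.box_side, ff.units, self.bond, ff.units.rho_reduced,
            seed=self.seed, water_count=self.water_count,
            nn_distance=self.nn_distance,
        )
        return run_simulation(init, ff, self.protocol, self.bond,
                              log_callback=log_callback)


def _take(section: dict, path: str, known: dict) -> dict:
    """Pop known keys with defaults; reject unknown ones with their path."""
    out = {}
    for key, default in known.items():
        out[key] = section.pop(key, default)
    if section:
        bad = next(iter(section))
        raise ConfigError(f"{path}.{bad}" if path else bad, "unknown key")
    return out


def read_config(path_or_stream) -> RunConfig:
    """Parse and validate a run configuration file.

    Missing optional keys receive the packaged defaults (dt = 0.01,
    reduced density 3, gamma = 4.5, 22.5 rc DPD box, ...); unknown keys and
    out-of-range values raise ``ConfigError`` naming the key path.
    """
    if hasattr(path_or_stream, "read"):
        raw = yaml.safe_load(path_or_stream.read())
    else:
        with open(path_or_stream) as fh:
            raw = yaml.safe_load(fh.read())
    if not isinstance(raw, dict):
        raise ConfigError("", "config must be a key: value mapping")

    top = _take(dict(raw), "", {
        "engine": "dpd", "temperature_K": None, "seed": 0,
        "box_side": None, "water_count": None, "nn_distance": None,
        "bead": {}, "flory_huggins": {}, "bond": {}, "topology": {},
        "protocol": {}, "langevin": {},
    })
    engine = top["engine"]
    if engine not in ("dpd", "langevin"):
        raise ConfigError("engine", f"must be 'dpd' or 'langevin', got {engine!r}")
    T = top["temperature_K"]
    if T is None:
        raise ConfigError("temperature_K", "required")
    if not isinstance(T, (int, float)) or T <= 0:
        raise ConfigError("temperature_K", f"must be a positive number, got {T!r}")
    seed = top["seed"]
    if not isinstance(seed, int) or seed < 0:
        raise ConfigError("seed", "must be a non-negative integer")

    box_side = top["box_side"]
    if box_side is None:
        box_side = 22.5 if engine == "dpd" else 100.0
    if box_side <= 0:
        raise ConfigError("box_side", "must be positive")

    try:
        beads = BeadSpec(**_take(dict(top["bead"] or {}), "bead", {
            "Nm": 5, "m_w": 18.01528, "monomer_molar_mass": 113.16,
            "monomer_mass_density": 1100.0, "rho_pure_water": None,
            "rho_pure_monomer": None}))
        fh_model = FloryHugginsModel(**_take(dict(top["flory_huggins"] or {}),
                                             "flory_huggins",
                                             {"A": 35.2, "Theta": 308.3}))
        bond = BondParams(**_take(dict(top["bond"] or {}), "bond",
                                  {"K": 0.4, "r0": 6.5}))
    except (TypeError, ValueError) as exc:
        if isinstance(exc, ConfigError):
            raise
        raise ConfigError("bead/bond/flory_huggins", str(exc)) from exc

    topo_raw = dict(top["topology"] or {})
    use_fixture = bool(topo_raw.pop("use_fixture", False))
    topo_cfg = _take(topo_raw, "topology", {
        "chain_length": 8, "lattice_extent": 2,
        "pruning_radius": 0.95, "target_beads": 439})

    proto_cfg = _take(dict(top["protocol"] or {}), "protocol", {
        "dt": 0.01, "pre_thermalization_steps": 1_000_000,
        "thermalization_steps": 1_000_000, "production_steps": 5_000_000,
        "snapshot_interval": 1_000, "langevin_gamma": 1.0, "skin": 0.3})
    try:
        protocol = Protocol(seed=seed, **proto_cfg)
    except ValueError as exc:
        raise ConfigError("protocol", str(exc)) from exc

    try:
        lang_ff = LangevinForceField(**_take(dict(top["langevin"] or {}),
                                             "langevin", {
            "wca_epsilon": 1.0, "wca_sigma_A": 6.5, "hydro_onset": 295.0,
            "hydro_slope": 0.1, "hydro_r1": 2.0 ** (1 / 6),
            "hydro_range": 1.8, "damping": 1.0, "fcap": 1e4}))
    except ValueError as exc:
        raise ConfigError("langevin", str(exc)) from exc

    return RunConfig(
        engine=engine, temperature_K=float(T), seed=seed,
        box_side=float(box_side), water_count=top["water_count"],
        beads=beads, fh=fh_model, bond=bond, topology_config=topo_cfg,
        use_fixture=use_fixture, protocol=protocol, langevin_ff=lang_ff,
        nn_distance=top["nn_distance"],
    )


def write_trajectory_frame(stream, frame, metadata: dict) -> None:
    """Append one frame in the annotated XYZ dialect."""
    n = len(frame.positions)
    stream.write(f"{n}\n")
    stream.write(
        f"step={frame.step} box={frame.box_side:.8g} "
        f"temperature={metadata.get('temperature', 0.0):.6g} "
        f"rc_angstrom={metadata.get('rc_angstrom', 1.0):.8g} "
        f"engine={metadata.get('engine', 'dpd')} "
        f"seed={metadata.get('seed', 0)}\n"
    )
    for t, (x, y, z) in zip(frame.types, frame.positions):
        stream.write(f"{_TYPE_LABELS[int(t)]} {x:.6f} {y:.6f} {z:.6f}\n")


def write_trajectory(path_or_stream, traj: Trajectory) -> None:
    if hasattr(path_or_stream, "write"):
        for frame in traj.frames:
            write_trajectory_frame(path_or_stream, frame, traj.metadata)
        return
    with open(path_or_stream, "w") as fh:
        for frame in traj.frames:
            write_trajectory_frame(fh, frame, traj.metadata)


def read_trajectory(path_or_stream) -> Trajectory:
    """Parse an annotated XYZ trajectory.

    An empty file yields an empty Trajectory; malformed content raises
    ``TrajectoryParseError`` with the offending line number.
    """
    if hasattr(path_or_stream, "read"):
        lines = path_or_stream.read().splitlines()
    else:
        with open(path_or_stream) as fh:
            lines = fh.read().splitlines()

    traj = Trajectory()
    ln = 0
    while ln < len(lines):
        if lines[ln].strip() == "":
            ln += 1
            continue
        try:
            n = int(lines[ln].strip())
        except ValueError:
            raise TrajectoryParseError(ln + 1, "expected bead count")
        if ln + 1 >= len(lines):
            raise TrajectoryParseError(ln + 2, "missing comment line")
        meta = {}
        for tok in lines[ln + 1].split():
            if "=" not in tok:
                raise TrajectoryParseError(ln + 2, f"bad token {tok!r}")
            k, v = tok.split("=", 1)
            meta[k] = v
        try:
            step = int(meta["step"])
            box = float(meta["box"])
        except (KeyError, ValueError):
            raise TrajectoryParseError(ln + 2, "comment line needs step= and box=")
        if not traj.metadata:
            traj.metadata = {
                "temperature": float(meta.get("temperature", 0.0)),
                "rc_angstrom": float(meta.get("rc_angstrom", 1.0)),
                "engine": meta.get("engine", "dpd"),
                "seed": int(meta.get("seed", 0)),
            }
        pos = np.empty((n, 3))
        types = np.empty(n, dtype=np.int64)
        for i in range(n):
            lno = ln + 2 + i
            if lno >= len(lines):
                raise TrajectoryParseError(lno + 1, "truncated frame")
            parts = lines[lno].split()
            if len(parts) != 4 or parts[0] not in _TYPE_CODES:
                raise TrajectoryParseError(lno + 1, f"bad bead record {lines[lno]!r}")
            types[i] = _TYPE_CODES[parts[0]]
            try:
                pos[i] = [float(parts[1]), float(parts[2]), float(parts[3])]
            except ValueError:
                raise TrajectoryParseError(lno + 1, "non-numeric coordinate")
        traj.append(step, box, pos, types)
        ln += 2 + n
    return traj
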