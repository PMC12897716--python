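"""Observables of the volume phase transition.

All structural measures of the nanogel reduce to a handful of estimators:

* the radius of gyration Rg (root-mean-square distance of the polymer
  beads from their centroid, equal masses), the proxy for nanogel size;
* radial distribution functions g(r): monomer-water and monomer-monomer
  pair RDFs, plus the RDF between the nanogel centre of mass and the water
  beads, which diagnoses solvent exclusion from the collapsed core;
* the swelling ratio Rg(T)/Rg(T_ref) with the lowest temperature as
  reference;
* the transition-temperature bracket — the consecutive pair of simulated
  temperatures with the steepest drop in Rg;
* the standard error of the mean of correlated time series by blocking
  (binned correlated data): the series is grouped into progressively fewer
  blocks and the SEM estimate is averaged over the flat 12-25 block window.

Rg requires unwrapped coordinates; RDFs re-wrap into the periodic box and
use minimum-image distances, normalized by the ideal-gas expectation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import (CoordinateError, DomainError, InsufficientDataError)
from .trajectory import Trajectory

__all__ = [
    "Trajectory",
    "AnalysisResult",
    "radius_of_gyration",
    "rg_series",
    "block_sem",
    "rdf_pair",
    "rdf_from_point",
    "swelling_ratio",
    "first_peak_position",
    "transition_temperature",
    "max_diameter",
]


@dataclass
class AnalysisResult:
    """Bundle of per-temperature observables (lengths in angstrom)."""

    rg_series: np.ndarray
    rg_mean: float
    rg_sem: float
    rdf_curves: dict = field(default_factory=dict)
    swelling: dict = field(default_factory=dict)


def radius_of_gyration(positions: np.ndarray,
                       indices: np.ndarray | None = None,
                       box_side: float | None = None,
                       bonds: np.ndarray | None = None) -> float:
    """Rg of the selected beads: sqrt(mean |r_i - centroid|^2), equal masses.

    Coordinates must be unwrapped.  If ``bonds`` and ``box_side`` are given,
    a bond longer than half the box is taken as evidence of wrapped input
    and raises ``CoordinateError``.
    """
    pos = np.asarray(positions, dtype=float)
    if indices is not None:
        sel = pos[np.asarray(indices)]
    else:
        sel = pos
    if len(sel) < 2:
        raise DomainError("radius of gyration needs at least two beads")
    if bonds is not None and box_side is not None and len(bonds):
        bl = np.linalg.norm(pos[np.asarray(bonds)[:, 0]]
                            - pos[np.asarray(bonds)[:, 1]], axis=1)
        if bl.max() > box_side / 2:
            raise CoordinateError(
                "bond longer than half the box: positions look wrapped"
            )
    d = sel - sel.mean(axis=0)
    return float(np.sqrt((d * d).sum(axis=1).mean()))


def rg_series(traj: Trajectory, in_angstrom: bool = True) -> np.ndarray:
    """Per-frame polymer Rg; in angstrom when rc is known from metadata."""
    poly = traj.polymer_indices()
    out = np.array([radius_of_gyration(f.positions, poly,
                                       box_side=f.box_side)
                    for f in traj.frames])
    if in_angstrom:
        out = out * traj.metadata.get("rc_angstrom", 1.0)
    return out


def block_sem(series, min_blocks: int = 12, max_blocks: int = 25
              ) -> tuple[float, float]:
    """Mean and blocking SEM of a (possibly correlated) series.

    For each block count k in [min_blocks, max_blocks] the series is cut
    into k equal blocks and the SEM estimated from the scatter of block
    means; the reported SEM averages these estimates over the window, which
    for well-sampled data falls on the plateau of the blocking curve.
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    if n < 2 * max_blocks:
        raise InsufficientDataError(
            f"series of length {n} too short for {max_blocks}-block analysis"
        )
    sems = []
    for k in range(min_blocks, max_blocks + 1):
        size = n // k
        bm = x[:k * size].reshape(k, size).mean(axis=1)
        sems.append(bm.std(ddof=1) / np.sqrt(k))
    return float(x.mean()), float(np.mean(sems))


def _wrap(pos: np.ndarray, box: float) -> np.ndarray:
    return np.mod(pos, box)


def rdf_pair(traj: Trajectory, group_a, group_b,
             bin_width: float = 0.1, r_max: float | None = None
             ) -> tuple[np.ndarray, np.ndarray]:
    """Radial distribution function between two bead groups.

    Shell counts (minimum image, periodic) averaged over frames and
    normalized by the ideal-gas expectation at the groups' densities;
    self-pairs are excluded where the groups overlap.  Returns
    ``(r_centers, g)`` in reduced units.
    """
    if bin_width <= 0:
        raise DomainError("bin_width must be positive")
    if traj.n_frames == 0:
        raise InsufficientDataError("empty trajectory")
    box = traj.frames[0].box_side
    if r_max is None:
        r_max = box / 2
    if r_max > box / 2 + 1e-9:
        raise DomainError("r_max exceeds half the box side")
    ga = np.asarray(group_a, dtype=np.int64)
    gb = np.asarray(group_b, dtype=np.int64)
    n_overlap = len(np.intersect1d(ga, gb))
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    edges = edges[edges <= r_max + 1e-12]
    counts = np.zeros(len(edges) - 1)
    for f in traj.frames:
        pa = _wrap(f.positions[ga], box)
        pb = _wrap(f.positions[gb], box)
        ta = cKDTree(pa, boxsize=box)
        tb = cKDTree(pb, boxsize=box)
        cum = ta.count_neighbors(tb, edges)  # ordered pairs, cumulative
        cum = cum - n_overlap                # distance-0 self pairs
        counts += np.diff(cum)
    vol = box**3
    shells = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    expected = (len(ga) * len(gb) - n_overlap) * shells / vol
    g = counts / (traj.n_frames * expected)
    centers = 0.5 * (edges[1:] + edges[:-1])
    return centers, g


def rdf_from_point(traj: Trajectory, group,
                   bin_width: float = 0.1, r_max: float | None = None,
                   reference: str = "polymer_com"
                   ) -> tuple[np.ndarray, np.ndarray]:
    """RDF between a per-frame reference point and a bead group.

    The default reference is the polymer centre of mass, computed on the
    unwrapped polymer coordinates (robust for a compact cluster) and then
    minimum-imaged to each group bead.  Low g(r) at small r at high
    temperature signals water exclusion from the collapsed core.
    """
    if bin_width <= 0:
        raise DomainError("bin_width must be positive")
    if traj.n_frames == 0:
        raise InsufficientDataError("empty trajectory")
    box = traj.frames[0].box_side
    if r_max is None:
        r_max = box / 2
    if r_max > box / 2 + 1e-9:
        raise DomainError("r_max exceeds half the box side")
    gi = np.asarray(group, dtype=np.int64)
    poly = traj.polymer_indices()
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    edges = edges[edges <= r_max + 1e-12]
    counts = np.zeros(len(edges) - 1)
    for f in traj.frames:
        if reference == "polymer_com":
            point = f.positions[poly].mean(axis=0)
        else:
            point = np.asarray(reference, dtype=float)
        d = _wrap(f.positions[gi], box) - _wrap(point[None, :], box)
        d -= box * np.rint(d / box)
        r = np.sqrt((d * d).sum(axis=1))
        h, _ = np.histogram(r, bins=edges)
        counts += h
    vol = box**3
    shells = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    expected = len(gi) * shells / vol
    g = counts / (traj.n_frames * expected)
    centers = 0.5 * (edges[1:] + edges[:-1])
    return centers, g


def swelling_ratio(rg_by_T: dict, T_ref: float | None = None) -> dict:
    """Rg(T)/Rg(T_ref) per temperature; T_ref defaults to the lowest T."""
    if not rg_by_T:
        raise DomainError("empty Rg map")
    if T_ref is None:
        T_ref = min(rg_by_T)
    if T_ref not in rg_by_T:
        raise KeyError(f"reference temperature {T_ref} not in Rg map")
    ref = rg_by_T[T_ref]
    if ref <= 0:
        raise DomainError("reference Rg must be positive")
    return {T: rg / ref for T, rg in sorted(rg_by_T.items())}


def first_peak_position(r: np.ndarray, g: np.ndarray) -> float | None:
    """Location of the first local maximum of g above 1.

    Refined by parabolic interpolation through the maximum bin and its
    neighbours; returns None (no-peak sentinel) if g never develops a peak
    above the homogeneous baseline.
    """
    r = np.asarray(r, dtype=float)
    g = np.asarray(g, dtype=float)
    if len(r) < 3:
        raise DomainError("curve needs at least three bins")
    for i in range(1, len(g) - 1):
        if g[i] > 1.0 and g[i] >= g[i - 1] and g[i] >= g[i + 1]:
            denom = g[i - 1] - 2.0 * g[i] + g[i + 1]
            if denom >= 0:  # flat top: fall back to the bin centre
                return float(r[i])
            shift = 0.5 * (g[i - 1] - g[i + 1]) / denom
            shift = float(np.clip(shift, -0.5, 0.5))
            return float(r[i] + shift * (r[1] - r[0]))
    return None


def transition_temperature(rg_by_T: dict) -> tuple[float, float] | None:
    """Bracket of the volume phase transition: the consecutive temperature
    pair with the largest drop in Rg.

    Returns None (no-transition sentinel) when Rg never decreases or when
    no drop stands out (flat or uniformly sloped data).
    """
    if len(rg_by_T) < 4:
        raise DomainError("need at least four temperatures")
    items = sorted(rg_by_T.items())
    temps = np.array([t for t, _ in items])
    rgs = np.array([v for _, v in items])
    drops = rgs[:-1] - rgs[1:]
    if drops.max() <= 0:
        return None
    order = np.sort(drops)[::-1]
    if len(order) > 1 and order[0] - order[1] <= 1e-9 * max(1.0, order[0]):
        return None  # degenerate: no unique steepest segment
    i = int(np.argmax(drops))
    return float(temps[i]), float(temps[i + 1])


def max_diameter(r: np.ndarray, g: np.ndarray,
                 threshold: float = 1e-3) -> float | None:
    """Largest r at which g exceeds the threshold (tail criterion).

    Estimates the maximum nanogel diameter from the monomer-monomer g(r)
    tail; None if the curve never exceeds the threshold.
    """
    mask = np.asarray(g) > threshold
    if not mask.any():
        return None
    return float(np.asarray(r)[mask].max())
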