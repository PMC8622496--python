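"""Synthetic swimmer trajectories and detection-count tables.

The generator is the stochastic twin of the boundary-modified diffusion
model: independent cells perform a random walk on the J imaging sites with
departure rate from site j proportional to the exodus coefficient m_j
(boundary sites exit in one direction only, interior sites in two).  Detailed
balance then gives the stationary occupancy pi ∝ 1/m, matching the analytic
steady state of the population equation, so every downstream estimator can be
tested against exact ground truth without any experimental download.

The observation model turns cell positions into slice detection counts the
way the microscope does: each cell is in focus in ~3 consecutive slices
(mode 3; configurable 1..6), so raw totals are inflated threefold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import (
    ChamberGeometry,
    DetectionModel,
    EvaporationSchedule,
    ZStackCounts,
    snapshot_times,
)
from .diffusion import map_alpha_to_m, steady_state_analytic

__all__ = [
    "AgentSimSpec",
    "AgentSnapshots",
    "simulate_agents",
    "apply_observation_model",
    "make_benchmark_dataset",
]


@dataclass
class AgentSimSpec:
    """Configuration of the agent-based stochastic twin.

    ``hop_rate_scale`` (per second) plays the role of D/dz^2: the rate at
    which a bulk cell hops to a given neighbouring site.  The default 0.1/s
    lets a cell explore a few slices between 30 s snapshots, in keeping with
    continuously swimming cells.  ``m_vector`` has one entry per site
    (interior entries 1 by convention).
    """

    n_cells: int
    m_vector: np.ndarray
    hop_rate_scale: float = 0.1
    t_burnin: float = 300.0
    snapshot_times: np.ndarray = field(default_factory=snapshot_times)
    seed: int = 0

    def __post_init__(self) -> None:
        self.m_vector = np.asarray(self.m_vector, dtype=float)
        self.snapshot_times = np.asarray(self.snapshot_times, dtype=float)
        if self.n_cells < 0:
            raise ValueError("n_cells must be non-negative")
        if (self.m_vector <= 0).any():
            raise ValueError("all exodus coefficients m must be positive")
        if self.hop_rate_scale <= 0:
            raise ValueError("hop_rate_scale must be positive")
        if self.t_burnin < 0:
            raise ValueError("t_burnin must be non-negative")
        if self.snapshot_times.size == 0 or np.any(np.diff(self.snapshot_times) <= 0):
            raise ValueError("snapshot_times must be non-empty and strictly increasing")


@dataclass
class AgentSnapshots:
    """Cell slice-site indices at each snapshot time."""

    times: np.ndarray
    sites: list  # list of int arrays, one per snapshot
    J: int
    z_top: np.ndarray = None  # type: ignore[assignment]

    def positions_um(self, geom: ChamberGeometry) -> list:
        """Continuous z positions (site centres) in micrometres."""
        return [s * geom.slice_interval for s in self.sites]

    def occupancy(self) -> np.ndarray:
        """Site-occupancy histogram pooled over snapshots, normalized."""
        h = np.zeros(self.J)
        for s in self.sites:
            h += np.bincount(s, minlength=self.J)
        total = h.sum()
        if total == 0:
            return h
        return h / total


def _evolve(sites: np.ndarray, m: np.ndarray, rate: float, duration: float,
            rng: np.random.Generator, J: int) -> np.ndarray:
    """Advance the walkers by ``duration`` seconds.

    Fixed-step chain with per-direction move probability rate*m_j*dt
    (dt chosen so the total exit probability stays <= 1/2); this chain has
    exactly the stationary law pi ∝ 1/m by detailed balance.
    """
    if duration <= 0 or sites.size == 0:
        return sites
    m_max = float(m[:J].max())
    dt = min(0.25 / (rate * m_max), duration)
    n_steps = max(int(np.ceil(duration / dt)), 1)
    dt = duration / n_steps
    for _ in range(n_steps):
        p_dir = rate * m[sites] * dt  # per-direction move probability
        u = rng.random(sites.size)
        up = u < p_dir
        down = (u >= p_dir) & (u < 2 * p_dir)
        # boundary sites have a single exit direction
        at_bottom = sites == 0
        at_top = sites == J - 1
        move = np.where(up & ~at_top, 1, 0) + np.where(down & ~at_bottom, -1, 0)
        # a boundary cell uses its single exit with probability rate*m*dt
        move[at_bottom & up] = 1
        move[at_top & down] = -1
        sites = sites + move
    return sites


def simulate_agents(
    spec: AgentSimSpec,
    geom: ChamberGeometry,
    evaporation: EvaporationSchedule | None = None,
    init: str = "uniform",
) -> AgentSnapshots:
    """Run the stochastic twin and record cell sites at each snapshot.

    ``init`` may be "uniform" (burn-in required for stationarity) or
    "stationary" (cells drawn from pi ∝ 1/m, so every snapshot is already at
    equilibrium).  Under evaporation the top site index falls with z_top and
    cells stranded above it are re-injected at the new top site (mass is
    conserved; the microscopic rule is a modelling choice).
    """
    J = geom.n_slices
    m = np.asarray(spec.m_vector, dtype=float)
    if m.size != J:
        raise ValueError(f"m_vector length {m.size} != n_slices {J}")
    rng = np.random.default_rng(spec.seed)
    if spec.n_cells == 0:
        times = spec.snapshot_times
        return AgentSnapshots(times, [np.empty(0, dtype=int) for _ in times], J,
                              z_top=np.full(times.size, geom.depth))

    if init == "stationary":
        pi = steady_state_analytic(m)
        sites = rng.choice(J, size=spec.n_cells, p=pi)
    elif init == "uniform":
        sites = rng.integers(0, J, size=spec.n_cells)
    else:
        raise ValueError(f"unknown init {init!r}")

    evap = evaporation or EvaporationSchedule()
    z_tops = evap.z_top(np.arange(spec.snapshot_times.size), geom.depth)

    sites = _evolve(sites, m, spec.hop_rate_scale, spec.t_burnin, rng, J)
    out, t_prev = [], 0.0
    for i, t in enumerate(spec.snapshot_times):
        J_now = int(np.floor(z_tops[i] / geom.slice_interval)) + 1
        J_now = min(J_now, J)
        sites = np.minimum(sites, J_now - 1)  # re-inject stranded cells at top
        m_now = m[:J_now].copy()
        m_now[-1] = m[-1]  # the air-interface coefficient follows the surface
        sites = _evolve(sites, m_now, spec.hop_rate_scale, t - t_prev, rng, J_now)
        out.append(sites.copy())
        t_prev = t
    return AgentSnapshots(spec.snapshot_times, out, J, z_top=z_tops)


def _detection_windows(z: np.ndarray, k: np.ndarray, det: DetectionModel,
                       geom: ChamberGeometry, n_avail: int) -> list:
    """Slice indices detected for each cell (z in micrometres)."""
    dz = geom.slice_interval
    windows = []
    if det.kernel_rule == "nearest-3-clipped-inward":
        centre = np.rint(z / dz).astype(int)
        for c, ki in zip(centre, k):
            ki = min(int(ki), n_avail)
            start = min(max(c - (ki - 1) // 2, 0), n_avail - ki)
            windows.append(np.arange(start, start + ki))
    elif det.kernel_rule == "half-width-threshold":
        half = 1.5 * dz
        slice_z = np.arange(n_avail) * dz
        for zi in z:
            windows.append(np.nonzero(np.abs(slice_z - zi) <= half)[0])
    else:  # pragma: no cover - validated in DetectionModel
        raise ValueError(det.kernel_rule)
    return windows


def apply_observation_model(
    snapshots,
    det: DetectionModel,
    geom: ChamberGeometry,
    seed: int = 0,
) -> ZStackCounts:
    """Convert cell positions into a raw z-stack count table.

    ``snapshots`` is an :class:`AgentSnapshots` or a list of per-snapshot z
    arrays (micrometres; a companion ``times`` attribute is then synthesised
    at 30 s spacing).  Each cell contributes one detection to each of k
    consecutive slices, k drawn from the multiplicity distribution (default:
    deterministic 3); the window is shifted inward at the stack edges so
    interface cells are also detected k times.
    """
    rng = np.random.default_rng(seed)
    if isinstance(snapshots, AgentSnapshots):
        zs = snapshots.positions_um(geom)
        times = snapshots.times
        z_tops = snapshots.z_top
    else:
        zs = [np.asarray(z, dtype=float) for z in snapshots]
        times = np.arange(len(zs)) * 30.0
        z_tops = np.full(len(zs), geom.depth)

    J = geom.n_slices
    counts = np.zeros((len(zs), J))
    for i, z in enumerate(zs):
        z = np.asarray(z, dtype=float)
        bad = np.nonzero((z < 0) | (z > z_tops[i] + 1e-9))[0]
        if bad.size:
            raise ValueError(
                f"snapshot {i}: cell index {bad[0]} at z={z[bad[0]]:.1f} um "
                f"outside chamber [0, {z_tops[i]:.1f}]"
            )
        n_avail = min(int(np.floor(z_tops[i] / geom.slice_interval)) + 1, J)
        k = det.sample_multiplicities(z.size, rng)
        for window in _detection_windows(z, k, det, geom, n_avail):
            counts[i, window] += 1
    return ZStackCounts(counts, geom.slice_z, times, z_top=z_tops)


def make_benchmark_dataset(
    alpha_solid: float,
    alpha_air: float,
    concentration: float,
    geom: ChamberGeometry = ChamberGeometry(),
    det: DetectionModel = DetectionModel(),
    evaporation: EvaporationSchedule | None = None,
    seed: int = 0,
    times: np.ndarray | None = None,
    hop_rate_scale: float = 0.1,
) -> tuple[ZStackCounts, dict]:
    """End-to-end fixture: a count table shaped like the experiment.

    The physical occupancy is the stationary law of exodus coefficients
    m = 1/alpha (normalized [alpha_solid, 1, ..., 1, alpha_air]); cells start
    at equilibrium and evolve through the default 21 x 30 s snapshot
    schedule; the observation model then produces raw counts.  Returns the
    table plus a ground-truth sidecar (true alpha, m, n_cells, seed).
    """
    if alpha_solid <= 0 or alpha_air <= 0:
        raise ValueError("accumulation coefficients must be positive")
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    m = map_alpha_to_m(alpha_solid, alpha_air, geom.n_slices)
    n_cells = int(round(concentration * geom.effective_volume_ml))
    if n_cells < 1:
        raise ValueError("requested concentration yields zero cells in the field of view")
    spec = AgentSimSpec(
        n_cells=n_cells,
        m_vector=m,
        hop_rate_scale=hop_rate_scale,
        t_burnin=0.0,
        snapshot_times=times if times is not None else snapshot_times(),
        seed=seed,
    )
    snaps = simulate_agents(spec, geom, evaporation=evaporation, init="stationary")
    counts = apply_observation_model(snaps, det, geom, seed=seed + 1)
    truth = {
        "alpha_solid": float(alpha_solid),
        "alpha_air": float(alpha_air),
        "m_solid": float(m[0]),
        "m_air": float(m[-1]),
        "n_cells": n_cells,
        "concentration_cells_per_ml": float(n_cells / geom.effective_volume_ml),
        "seed": int(seed),
    }
    counts.metadata["ground_truth"] = truth
    return counts, truth
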