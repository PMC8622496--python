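"""Core data containers shared across the pipeline.

The experimental observable is a z-stack count table N(z, t): for each of a
series of time snapshots, the number of in-focus detections in each imaging
slice of a shallow cylindrical chamber.  Everything downstream (probability
profiles, accumulation coefficients, diffusion-model fits) is computed from
this table, so the containers here are deliberately plain: validated NumPy
arrays plus the chamber/imaging geometry needed to interpret them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ChamberGeometry",
    "DetectionModel",
    "EvaporationSchedule",
    "ZStackCounts",
    "ProbabilityProfile",
    "detectable_depth",
    "snapshot_times",
]


@dataclass(frozen=True)
class ChamberGeometry:
    """Physical chamber and imaging grid.

    The chamber is a 12 mm diameter, 1 mm deep well imaged from the solid
    glass bottom (z = 0) to the air-liquid interface at the top.  The camera
    sees a square field of view whose corners fall outside the image circle,
    so the effective imaged volume is the inscribed cylinder:
    ``fov_side**2 * depth * pi / 4``.

    Parameters
    ----------
    depth : float
        Water column depth in micrometres (default 1000).
    fov_side : float
        Side of the square camera field of view, in millimetres
        (default 6.75).
    slice_interval : float
        Spacing of the imaging z-slices in micrometres (default 50).
    n_slices : int
        Number of slices; defaults to ``depth / slice_interval + 1`` so the
        stack spans both interfaces inclusively (21 for the defaults).
    """

    depth: float = 1000.0
    fov_side: float = 6.75
    slice_interval: float = 50.0
    n_slices: int = 0

    def __post_init__(self) -> None:
        if self.depth <= 0 or self.fov_side <= 0 or self.slice_interval <= 0:
            raise ValueError("depth, fov_side and slice_interval must be positive")
        if self.n_slices == 0:
            ratio = self.depth / self.slice_interval
            if not math.isclose(ratio, round(ratio)):
                raise ValueError(
                    "depth is not an integer multiple of slice_interval; "
                    "pass n_slices explicitly"
                )
            object.__setattr__(self, "n_slices", int(round(ratio)) + 1)
        if self.n_slices < 2:
            raise ValueError("need at least two slices")

    @property
    def slice_z(self) -> np.ndarray:
        """Slice positions in micrometres: {0, dz, ..., depth}."""
        return np.arange(self.n_slices) * self.slice_interval

    @property
    def effective_volume_ml(self) -> float:
        """Imaged volume in millilitres (inscribed image circle)."""
        volume_mm3 = self.fov_side**2 * (self.depth / 1000.0) * math.pi / 4.0
        return volume_mm3 / 1000.0


# A single physical cell is in focus over ~140 um of the column, so it is
# detected in about three consecutive 50-um slices.  The categorical option
# models the looser multiplicities seen for cells swimming in bulk.
@dataclass(frozen=True)
class DetectionModel:
    """Observation model: how one cell turns into slice detections.

    ``kernel_rule`` choices:

    - ``"nearest-3-clipped-inward"`` (default): the ``k`` slices nearest the
      cell, with the window shifted inward at the stack edges so a cell
      sitting exactly on an interface is still detected in ``k`` slices.
    - ``"half-width-threshold"``: detect in every slice within
      1.5 * slice_interval of the cell.

    ``counting_factor`` is the divisor applied to raw totals when estimating
    absolute cell numbers or concentrations (default 3, the modal
    multiplicity).
    """

    multiplicity_mode: int = 3
    multiplicity_distribution: "str | dict[int, float]" = "deterministic-3"
    kernel_rule: str = "nearest-3-clipped-inward"
    counting_factor: int = 3

    def __post_init__(self) -> None:
        if self.multiplicity_mode < 1:
            raise ValueError("multiplicity_mode must be >= 1")
        if self.counting_factor < 1:
            raise ValueError("counting_factor must be >= 1")
        if self.kernel_rule not in ("nearest-3-clipped-inward", "half-width-threshold"):
            raise ValueError(f"unknown kernel_rule {self.kernel_rule!r}")
        dist = self.multiplicity_distribution
        if isinstance(dist, dict):
            if not dist:
                raise ValueError("empty multiplicity distribution")
            ks = np.array(sorted(dist))
            ps = np.array([dist[int(k)] for k in ks], dtype=float)
            if (ks < 1).any() or (ks > 6).any():
                raise ValueError("multiplicities must lie in {1..6}")
            if (ps < 0).any() or not math.isclose(ps.sum(), 1.0, abs_tol=1e-9):
                raise ValueError("multiplicity probabilities must sum to 1")
        elif dist != "deterministic-3":
            raise ValueError(
                "multiplicity_distribution must be 'deterministic-3' or a dict"
            )

    def sample_multiplicities(self, n: int, rng: np.random.Generator) -> np.ndarray:
        dist = self.multiplicity_distribution
        if dist == "deterministic-3":
            return np.full(n, 3, dtype=int)
        ks = np.array(sorted(dist))
        ps = np.array([dist[int(k)] for k in ks], dtype=float)
        ps = ps / ps.sum()
        return rng.choice(ks, size=n, p=ps)

    def effective_slice_thickness(self, geom: ChamberGeometry) -> float:
        """Effective detectable thickness of one slice, in micrometres."""
        return self.multiplicity_mode * geom.slice_interval


@dataclass(frozen=True)
class EvaporationSchedule:
    """Slow lowering of the top (air-liquid) surface during acquisition.

    ``rate`` is in micrometres per snapshot; the top surface height is
    ``z_top(i) = depth - rate * i`` for snapshot index ``i``.
    """

    rate: float = 0.0

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError("evaporation rate must be non-negative (z_top non-increasing)")

    def z_top(self, snapshot_index: "int | np.ndarray", depth: float) -> np.ndarray:
        z = depth - self.rate * np.asarray(snapshot_index, dtype=float)
        if np.any(z <= 0):
            raise ValueError("evaporation schedule empties the chamber")
        return z


@dataclass
class ZStackCounts:
    """Raw detection counts per slice per time snapshot, N(z, t).

    Attributes
    ----------
    counts : ndarray, shape (n_snapshots, n_slices)
        Non-negative detection counts (float to allow averaged tables).
    slice_z : ndarray, shape (n_slices,)
        Slice heights in micrometres, z = 0 at the solid bottom.
    times : ndarray, shape (n_snapshots,)
        Snapshot times in seconds.
    z_top : ndarray, shape (n_snapshots,)
        Height of the air-liquid interface at each snapshot (micrometres);
        defaults to the top slice height.
    metadata : dict
        Free-form provenance (extra CSV columns, generator ground truth...).
    """

    counts: np.ndarray
    slice_z: np.ndarray
    times: np.ndarray
    z_top: np.ndarray = None  # type: ignore[assignment]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.slice_z = np.asarray(self.slice_z, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2D (snapshots x slices)")
        S, J = self.counts.shape
        if self.slice_z.shape != (J,):
            raise ValueError("slice_z length does not match counts")
        if self.times.shape != (S,):
            raise ValueError("times length does not match counts")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if self.z_top is None:
            self.z_top = np.full(S, self.slice_z[-1])
        else:
            self.z_top = np.asarray(self.z_top, dtype=float)
            if self.z_top.shape != (S,):
                raise ValueError("z_top length does not match counts")

    @property
    def n_snapshots(self) -> int:
        return self.counts.shape[0]

    @property
    def n_slices(self) -> int:
        return self.counts.shape[1]

    def total_per_snapshot(self) -> np.ndarray:
        return self.counts.sum(axis=1)


@dataclass
class ProbabilityProfile:
    """Per-slice probability mass of the cell distribution along z.

    ``z_axis`` holds the abscissa (raw micrometres, or z/z_top in [0, 1] when
    ``normalized_height`` is True).  The mass convention follows the counting
    procedure: entries sum to 1 over slices, they are not densities per um.
    """

    p: np.ndarray
    z_axis: np.ndarray
    normalized_height: bool = False

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        self.z_axis = np.asarray(self.z_axis, dtype=float)
        if self.p.shape != self.z_axis.shape:
            raise ValueError("p and z_axis must have equal shapes")
        if (self.p < 0).any():
            raise ValueError("probabilities must be non-negative")
        if abs(self.p.sum() - 1.0) > 1e-9:
            raise ValueError("probabilities must sum to 1")


def detectable_depth(focal_depth: float = 90.0, cell_thickness: float = 50.0) -> float:
    """Axial range over which one cell is detected as in focus (um).

    The focal depth of the low-NA objective plus the physical thickness of
    the cell: 90 + 50 = 140 um for the defaults, i.e. 2-3 slices at 50 um
    spacing.
    """
    return focal_depth + cell_thickness


def snapshot_times(interval_s: float = 30.0, total_s: float = 600.0) -> np.ndarray:
    """Acquisition schedule: snapshots every ``interval_s`` over ``total_s``
    inclusive of both endpoints (21 snapshots for 30 s over 10 min)."""
    n = int(round(total_s / interval_s)) + 1
    return np.arange(n) * interval_s
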