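"""Distribution statistics of z-stack count tables.

Turns raw detection counts N(z, t) into the quantities the analysis rests
on: the time-averaged profile with its snapshot-to-snapshot dispersion, the
per-slice probability profile (mass convention: entries sum to 1), profiles
on the evaporation-corrected normalized height z/z_top, and the absolute
cell concentration via the multiple-counting correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import (
    ChamberGeometry,
    DetectionModel,
    ProbabilityProfile,
    ZStackCounts,
)

__all__ = [
    "TimeAverage",
    "ConcentrationEstimate",
    "time_average",
    "to_probability",
    "normalize_height",
    "rebin_profile",
    "estimate_concentration",
]


@dataclass
class TimeAverage:
    """Per-slice mean and dispersion of N(z) over snapshots."""

    mean: np.ndarray
    sd: np.ndarray
    n_snapshots: int


def time_average(counts: ZStackCounts) -> TimeAverage:
    """Time-averaged profile with per-slice sample standard deviation.

    A single snapshot yields zero dispersion by convention.
    """
    c = counts.counts
    mean = c.mean(axis=0)
    sd = c.std(axis=0, ddof=1) if c.shape[0] > 1 else np.zeros(c.shape[1])
    return TimeAverage(mean, sd, c.shape[0])


def to_probability(n_z, z=None) -> ProbabilityProfile:
    """Normalize a count vector to per-slice probability mass, p = n / sum(n).

    The multiple-counting factor cancels in this normalization, so raw
    counts can be used directly.
    """
    n = np.asarray(n_z, dtype=float)
    if n.ndim != 1:
        raise ValueError("expected a 1D count vector")
    if (n < 0).any():
        raise ValueError("counts must be non-negative")
    total = n.sum()
    if total <= 0:
        raise ValueError("cannot normalize an all-zero count vector")
    z = np.arange(n.size, dtype=float) if z is None else np.asarray(z, dtype=float)
    return ProbabilityProfile(n / total, z)


def normalize_height(profile: ProbabilityProfile, z_top: float,
                     grid: np.ndarray | None = None) -> ProbabilityProfile:
    """Re-express a profile on the relative height z/z_top in [0, 1].

    With evaporation the water column shrinks; normalizing each snapshot by
    its own surface height puts profiles from different times (or samples of
    different depth) on a common abscissa.  Pass ``grid`` to additionally
    rebin (mass-preserving) onto a shared axis for averaging.
    """
    if z_top <= 0:
        raise ValueError("z_top must be positive")
    occupied = profile.z_axis[profile.p > 0]
    if occupied.size and occupied.max() > z_top + 1e-9:
        raise ValueError("z_top is below the highest occupied slice")
    x = profile.z_axis / z_top
    p = profile.p
    if grid is not None:
        p = rebin_profile(p, x, np.asarray(grid, dtype=float))
        x = np.asarray(grid, dtype=float)
    return ProbabilityProfile(p, x, normalized_height=True)


def rebin_profile(p: np.ndarray, x_src: np.ndarray, x_dst: np.ndarray) -> np.ndarray:
    """Mass-preserving rebin of per-bin probability mass onto a new axis.

    Interpolates the cumulative mass at the midpoints between destination
    bins, so the total stays exactly 1 regardless of grid mismatch.
    """
    p = np.asarray(p, dtype=float)
    cum = np.concatenate([[0.0], np.cumsum(p)])
    # source bin edges: midpoints, extended at the ends
    edges_src = np.concatenate([
        [x_src[0] - (x_src[1] - x_src[0]) / 2],
        (x_src[:-1] + x_src[1:]) / 2,
        [x_src[-1] + (x_src[-1] - x_src[-2]) / 2],
    ])
    edges_dst = np.concatenate([
        [x_dst[0] - (x_dst[1] - x_dst[0]) / 2],
        (x_dst[:-1] + x_dst[1:]) / 2,
        [x_dst[-1] + (x_dst[-1] - x_dst[-2]) / 2],
    ])
    cum_at = np.interp(edges_dst, edges_src, cum, left=0.0, right=cum[-1])
    out = np.diff(cum_at)
    # clamp tiny negatives from interpolation and restore exact unit mass
    out = np.clip(out, 0.0, None)
    return out / out.sum()


@dataclass
class ConcentrationEstimate:
    """Absolute cell concentration with snapshot dispersion (cells/mL)."""

    mean: float
    sd: float
    per_snapshot: np.ndarray


def estimate_concentration(counts: ZStackCounts, det: DetectionModel,
                           geom: ChamberGeometry) -> ConcentrationEstimate:
    """Cells per millilitre from raw totals.

    concentration = (raw detections summed over slices) / counting_factor
    / effective imaged volume, evaluated per snapshot and averaged with its
    sample standard deviation.
    """
    volume = geom.effective_volume_ml
    if volume <= 0:
        raise ValueError("effective volume must be positive")
    per = counts.total_per_snapshot() / det.counting_factor / volume
    sd = per.std(ddof=1) if per.size > 1 else 0.0
    return ConcentrationEstimate(float(per.mean()), float(sd), per)
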