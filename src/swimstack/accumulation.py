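"""Accumulation-coefficient estimation from measured profiles.

The accumulation coefficients quantify how strongly cells gather at the two
interfaces relative to the bulk:

    alpha_solid = N_solid / N_bulk,    alpha_air = N_air / N_bulk

where N_solid and N_air are the raw peak detection counts at the bottom and
top interface slices and N_bulk is the spatially averaged bulk count divided
by the multiple-counting factor.  The asymmetry is deliberate: a stationary
interface cell appears exactly once in the peak slice, whereas a bulk cell
inflates the bulk slices by the factor (~3).  Note the raw peak also collects
detections spilling over from the first bulk layers, so this direct estimator
overestimates alpha for broad peaks; the kernel-aware least-squares fit in
:mod:`swimstack.diffusion` removes that bias.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import DetectionModel, ZStackCounts

__all__ = [
    "PeakLocation",
    "AccumulationCoefficients",
    "locate_interface_peaks",
    "bulk_average",
    "estimate_alphas",
]


@dataclass(frozen=True)
class PeakLocation:
    """Indices of the interface peaks with distinctness flags."""

    bottom: int
    top: int
    bottom_distinct: bool = True
    top_distinct: bool = True


def locate_interface_peaks(n_z, bottom_window: int = 4,
                           top_window: int = 5) -> PeakLocation:
    """Find the interface peaks of a profile.

    The bottom peak is the argmax within the lowest ``bottom_window`` slices;
    the top peak the argmax within the highest ``top_window`` slices (one
    wider by default, to absorb the downward drift of the surface peak under
    evaporation).  A window whose maximum does not exceed the mean of the
    slices outside both windows is flagged as not distinct and the boundary
    index is returned for it.
    """
    n = np.asarray(n_z, dtype=float)
    J = n.size
    if J < 5:
        raise ValueError("profile too short to locate interface peaks")
    b_win = np.arange(min(bottom_window, J))
    t_win = np.arange(max(J - top_window, 0), J)
    interior = np.setdiff1d(np.arange(J), np.concatenate([b_win, t_win]))
    baseline = n[interior].mean() if interior.size else n.mean()
    b_idx = int(b_win[np.argmax(n[b_win])])
    t_idx = int(t_win[np.argmax(n[t_win])])
    b_ok = n[b_idx] > baseline
    t_ok = n[t_idx] > baseline
    if not b_ok:
        b_idx = 0
    if not t_ok:
        t_idx = J - 1
    return PeakLocation(b_idx, t_idx, b_ok, t_ok)


def bulk_average(n_z, peak_indices, exclusion: int = 3) -> float:
    """Mean raw count over the interior (bulk) slices.

    ``exclusion`` slices on each side of each peak are dropped (default 3,
    covering the ~150 um detection spill of interface cells) and the
    arithmetic mean of what remains is returned.  At least three interior
    slices must survive.
    """
    n = np.asarray(n_z, dtype=float)
    J = n.size
    mask = np.ones(J, dtype=bool)
    for p in peak_indices:
        lo, hi = max(p - exclusion, 0), min(p + exclusion, J - 1)
        mask[lo:hi + 1] = False
    if mask.sum() < 3:
        raise ValueError(
            f"only {int(mask.sum())} bulk slices remain after exclusion; "
            "need at least 3 (reduce `exclusion` or use a taller stack)"
        )
    return float(n[mask].mean())


@dataclass
class AccumulationCoefficients:
    """Accumulation coefficients with uncertainty over snapshots.

    ``sd_*`` is the dispersion (sample standard deviation) over snapshots —
    the error-bar convention of the time-resolved analysis — and ``se_*`` the
    standard error of the mean.  ``flagged`` marks snapshots without a
    distinct peak or with a degenerate bulk; snapshots whose bulk is zero
    have NaN alphas and are excluded from the averages.
    """

    alpha_solid: float
    alpha_air: float
    sd_solid: float
    sd_air: float
    se_solid: float
    se_air: float
    n_snapshots: int
    per_snapshot_solid: np.ndarray
    per_snapshot_air: np.ndarray
    peaks: list
    flagged: np.ndarray


def _peak_value(n: np.ndarray, idx: int, estimator: str, factor: int) -> float:
    if estimator == "peak":
        return float(n[idx])
    if estimator == "sum3":
        lo, hi = max(idx - 1, 0), min(idx + 1, n.size - 1)
        return float(n[lo:hi + 1].sum() / factor)
    raise ValueError(f"unknown peak estimator {estimator!r}")


def estimate_alphas(
    counts: ZStackCounts,
    det: DetectionModel = DetectionModel(),
    bottom_window: int = 4,
    top_window: int = 5,
    exclusion: int = 3,
    peak_estimator: str = "peak",
) -> AccumulationCoefficients:
    """Estimate alpha_solid and alpha_air from a count table.

    Per snapshot: locate the interface peaks, take the raw peak values
    (or, with ``peak_estimator="sum3"``, the 3-slice sum divided by the
    counting factor — less biased for broad peaks), divide the bulk mean by
    the counting factor, and form the two ratios.  Reported values are the
    mean over snapshots with dispersion (sd) and standard error (se).
    """
    S = counts.n_snapshots
    if S < 1:
        raise ValueError("need at least one snapshot")
    a_solid = np.full(S, np.nan)
    a_air = np.full(S, np.nan)
    flagged = np.zeros(S, dtype=bool)
    peaks = []
    for i in range(S):
        n = counts.counts[i]
        loc = locate_interface_peaks(n, bottom_window, top_window)
        peaks.append(loc)
        try:
            bulk = bulk_average(n, (loc.bottom, loc.top), exclusion)
        except ValueError:
            flagged[i] = True
            continue
        bulk_corr = bulk / det.counting_factor
        if bulk_corr <= 0 or not (loc.bottom_distinct and loc.top_distinct):
            flagged[i] = True
        if bulk_corr > 0:
            a_solid[i] = _peak_value(n, loc.bottom, peak_estimator,
                                     det.counting_factor) / bulk_corr
            a_air[i] = _peak_value(n, loc.top, peak_estimator,
                                   det.counting_factor) / bulk_corr

    valid_s = a_solid[~np.isnan(a_solid)]
    valid_a = a_air[~np.isnan(a_air)]
    if valid_s.size == 0 or valid_a.size == 0:
        raise ValueError("alpha undefined for every snapshot (zero bulk everywhere)")

    def _stats(v):
        sd = float(v.std(ddof=1)) if v.size > 1 else 0.0
        return float(v.mean()), sd, sd / np.sqrt(v.size)

    ms, sds, ses = _stats(valid_s)
    ma, sda, sea = _stats(valid_a)
    return AccumulationCoefficients(
        alpha_solid=ms, alpha_air=ma,
        sd_solid=sds, sd_air=sda,
        se_solid=ses, se_air=sea,
        n_snapshots=S,
        per_snapshot_solid=a_solid, per_snapshot_air=a_air,
        peaks=peaks, flagged=flagged,
    )
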