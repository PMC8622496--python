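"""Model/Results interface tying the pipeline together.

:class:`InterfaceAccumulation` is built from a z-stack count table (from the
synthetic generator, a CSV export, or a detection run on images) and its
:meth:`~InterfaceAccumulation.fit` returns an
:class:`InterfaceAccumulationResults` carrying the accumulation coefficients
with their snapshot dispersion, the matching exodus coefficients of the
diffusion model, the concentration estimate, fit diagnostics and a
``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import accumulation, distributions
from .containers import ChamberGeometry, DetectionModel, ZStackCounts
from .diffusion import DetectionKernel, fit_from_observed, steady_state_analytic

__all__ = ["InterfaceAccumulation", "InterfaceAccumulationResults"]


class InterfaceAccumulation:
    """Interface-accumulation model for a measured N(z, t) table.

    Parameters
    ----------
    counts : ZStackCounts
        Raw detection counts per slice per snapshot.
    detection : DetectionModel, optional
        Observation model (counting factor, kernel); defaults to the
        triple-counting setup.
    geometry : ChamberGeometry, optional
        Chamber/imaging geometry; inferred from the table's slice axis when
        omitted.
    """

    def __init__(self, counts: ZStackCounts,
                 detection: DetectionModel | None = None,
                 geometry: ChamberGeometry | None = None):
        self.counts = counts
        self.detection = detection or DetectionModel()
        if geometry is None:
            dz = float(np.diff(counts.slice_z).mean()) if counts.n_slices > 1 else 50.0
            geometry = ChamberGeometry(depth=float(counts.slice_z[-1]) or 1000.0,
                                       slice_interval=dz,
                                       n_slices=counts.n_slices)
        self.geometry = geometry

    @classmethod
    def from_csv(cls, path, **kwargs) -> "InterfaceAccumulation":
        from .io import read_counts

        return cls(read_counts(path), **kwargs)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "InterfaceAccumulation":
        from .io import counts_from_dataframe

        return cls(counts_from_dataframe(df), **kwargs)

    def fit(self, method: str = "both", exclusion: int = 3,
            bottom_window: int = 4, top_window: int = 5,
            kernel: DetectionKernel | None = None,
            peak_estimator: str = "peak") -> "InterfaceAccumulationResults":
        """Estimate the accumulation coefficients.

        ``method`` is ``"peak-ratio"`` (the direct peak-over-bulk estimator,
        evaluated per snapshot with dispersion), ``"profile-lsq"`` (kernel-
        aware least squares of the convolved steady profile against the
        time-averaged probability profile) or ``"both"`` (default).
        """
        if method not in ("peak-ratio", "profile-lsq", "both"):
            raise ValueError(f"unknown method {method!r}")
        if kernel is None:
            kernel = DetectionKernel(rule=self.detection.kernel_rule
                                     if self.detection.kernel_rule == "nearest-3-clipped-inward"
                                     else None)
        avg = distributions.time_average(self.counts)
        profile = distributions.to_probability(avg.mean, z=self.counts.slice_z)
        conc = distributions.estimate_concentration(self.counts, self.detection,
                                                    self.geometry)
        coeffs = None
        if method in ("peak-ratio", "both"):
            coeffs = accumulation.estimate_alphas(
                self.counts, self.detection, bottom_window=bottom_window,
                top_window=top_window, exclusion=exclusion,
                peak_estimator=peak_estimator)
        lsq = None
        if method in ("profile-lsq", "both"):
            lsq = fit_from_observed(profile, kernel=kernel,
                                    counting_factor=self.detection.counting_factor,
                                    peak_window=bottom_window, exclusion=exclusion)
        return InterfaceAccumulationResults(
            model=self, method=method, coefficients=coeffs, lsq_fit=lsq,
            profile=profile, time_avg=avg, concentration=conc)


@dataclass
class InterfaceAccumulationResults:
    """Fitted accumulation coefficients and diagnostics."""

    model: InterfaceAccumulation
    method: str
    coefficients: "accumulation.AccumulationCoefficients | None"
    lsq_fit: object  # DiffusionFit | None
    profile: object  # ProbabilityProfile
    time_avg: object  # TimeAverage
    concentration: object  # ConcentrationEstimate
    _cache: dict = field(default_factory=dict, repr=False)

    @property
    def alpha_solid(self) -> float:
        if self.coefficients is not None:
            return self.coefficients.alpha_solid
        return self.lsq_fit.alpha_lsq[0]

    @property
    def alpha_air(self) -> float:
        if self.coefficients is not None:
            return self.coefficients.alpha_air
        return self.lsq_fit.alpha_lsq[1]

    @property
    def m_solid(self) -> float:
        return 1.0 / self.alpha_solid

    @property
    def m_air(self) -> float:
        return 1.0 / self.alpha_air

    def fitted_profile(self) -> np.ndarray:
        """Convolved analytic steady profile implied by the fit (normalized)."""
        from .diffusion import convolve_detection, map_alpha_to_m

        J = self.model.counts.n_slices
        if self.lsq_fit is not None:
            m = np.ones(J)
            m[0], m[-1] = self.lsq_fit.m_lsq
        else:
            m = map_alpha_to_m(self.alpha_solid, self.alpha_air, J)
        kernel = DetectionKernel(rule="nearest-3-clipped-inward"
                                 if self.model.detection.kernel_rule
                                 == "nearest-3-clipped-inward" else None)
        return convolve_detection(steady_state_analytic(m), kernel, normalize=True)

    def to_dict(self) -> dict:
        d = {
            "method": self.method,
            "concentration_cells_per_ml": self.concentration.mean,
            "concentration_sd": self.concentration.sd,
            "n_snapshots": self.model.counts.n_snapshots,
        }
        if self.coefficients is not None:
            c = self.coefficients
            d["peak_ratio"] = {
                "alpha_solid": c.alpha_solid, "alpha_air": c.alpha_air,
                "sd_solid": c.sd_solid, "sd_air": c.sd_air,
                "se_solid": c.se_solid, "se_air": c.se_air,
                "n_flagged": int(c.flagged.sum()),
                "peak_bottom": int(c.peaks[0].bottom),
                "peak_top": int(c.peaks[0].top),
            }
        if self.lsq_fit is not None:
            f = self.lsq_fit
            d["profile_lsq"] = {
                "alpha_solid": f.alpha_lsq[0], "alpha_air": f.alpha_lsq[1],
                "m_solid": f.m_lsq[0], "m_air": f.m_lsq[1],
                "residual": f.residual_lsq, "flat": f.flat,
            }
        return d

    def summary(self) -> str:
        """Human-readable summary table."""
        lines = [
            "Interface Accumulation Results",
            "=" * 46,
            f"snapshots: {self.model.counts.n_snapshots:>4d}   "
            f"slices: {self.model.counts.n_slices:>4d}   "
            f"counting factor: {self.model.detection.counting_factor}",
            f"concentration: {self.concentration.mean:.3e} +/- "
            f"{self.concentration.sd:.1e} cells/mL",
            "-" * 46,
        ]
        if self.coefficients is not None:
            c = self.coefficients
            lines += [
                "peak-ratio estimator (per-snapshot mean +/- sd):",
                f"  alpha_solid = {c.alpha_solid:7.3f} +/- {c.sd_solid:.3f}"
                f"  (se {c.se_solid:.3f})",
                f"  alpha_air   = {c.alpha_air:7.3f} +/- {c.sd_air:.3f}"
                f"  (se {c.se_air:.3f})",
            ]
        if self.lsq_fit is not None:
            f = self.lsq_fit
            lines += [
                "profile least-squares fit (kernel-aware):",
                f"  alpha_solid = {f.alpha_lsq[0]:7.3f}   m_solid = {f.m_lsq[0]:.4f}",
                f"  alpha_air   = {f.alpha_lsq[1]:7.3f}   m_air   = {f.m_lsq[1]:.4f}",
                f"  residual L2 = {f.residual_lsq:.3e}",
            ]
        lines.append("=" * 46)
        return "\n".join(lines)

    def plot(self, ax=None):
        """Measured time-averaged probability profile vs the fitted one."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        z = self.model.counts.slice_z
        ax.plot(z, self.profile.p, "o-", label="measured (time avg)")
        ax.plot(z, self.fitted_profile(), "--", label="fitted apparent profile")
        ax.set_xlabel("z (um)")
        ax.set_ylabel("probability")
        ax.legend()
        return ax
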