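"""Synthetic bright-field z-stacks and in-focus cell detection.

Stands in for the machine-learning segmentation + particle analysis used on
the real micrographs.  Cells are rendered as dark Gaussian blobs on a bright
background; contrast falls and width grows with defocus distance, so a cell
is only detectable in the few slices nearest its true height — the origin of
the multiple-counting factor.  Detection is deterministic thresholding plus
connected components with an area filter, and the multiplicity factor is
estimated by linking detections across adjacent slices.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass

import numpy as np
from skimage import measure

from .containers import ChamberGeometry

__all__ = [
    "OpticsSpec",
    "DetectionSettings",
    "SliceDetections",
    "MultiplicityEstimate",
    "render_stack",
    "detect_cells",
    "estimate_multiplicity_factor",
]


@dataclass(frozen=True)
class OpticsSpec:
    """Rendering parameters of the synthetic microscope.

    ``focal_depth`` (um) controls how fast contrast decays with defocus: the
    blob amplitude is ``peak_contrast / (1 + (defocus/focal_depth)^2)`` and
    its radius grows by the same factor's square root.  With the defaults a
    cell drops below the detection threshold beyond ~70 um of defocus, i.e.
    it is detectable over ~140 um — three slices at 50 um spacing.
    """

    image_size: int = 512
    pixel_size_um: float = 13.18  # 6.75 mm field of view / 512 px
    focal_depth: float = 90.0
    cell_radius_px: float = 2.0
    peak_contrast: float = 0.5
    background_level: float = 0.85
    background_gradient: float = 0.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.image_size < 8:
            raise ValueError("image_size too small")
        if self.focal_depth <= 0 or self.cell_radius_px <= 0:
            raise ValueError("focal_depth and cell_radius_px must be positive")
        if not 0 < self.peak_contrast <= self.background_level:
            raise ValueError("peak_contrast must lie in (0, background_level]")

    def contrast(self, defocus_um: float) -> float:
        """Blob amplitude at a given defocus distance (monotone decreasing)."""
        return self.peak_contrast / (1.0 + (defocus_um / self.focal_depth) ** 2)


@dataclass(frozen=True)
class DetectionSettings:
    """Threshold / connected-component settings of the detector."""

    intensity_threshold: float = 0.3  # fraction of full dynamic range
    min_area_px: int = 3
    max_area_px: int = 400
    link_radius_px: float = 5.0

    def __post_init__(self) -> None:
        if not 0 < self.intensity_threshold < 1:
            raise ValueError("intensity_threshold must be in (0, 1)")
        if not 0 < self.min_area_px < self.max_area_px:
            raise ValueError("need 0 < min_area_px < max_area_px")


def render_stack(cells, optics: OpticsSpec, geom: ChamberGeometry,
                 seed: int = 0) -> np.ndarray:
    """Render one 2D frame per imaging slice for cells at (x_px, y_px, z_um).

    Returns a float32 array of shape (n_slices, H, W) in [0, 1].  Each cell
    appears as a dark blob whose contrast and sharpness decay with the
    distance between its height and the slice's focal plane.  Deterministic
    under ``seed`` (used only for the optional noise floor).
    """
    if optics is None:
        raise ValueError("optics parameters are required")
    cells = np.asarray(cells, dtype=float)
    if cells.size and cells.ndim != 2:
        raise ValueError("cells must be an (n, 3) array of (x_px, y_px, z_um)")
    n = optics.image_size
    if cells.size:
        if ((cells[:, 0] < 0) | (cells[:, 0] >= n)
                | (cells[:, 1] < 0) | (cells[:, 1] >= n)).any():
            raise ValueError("cell x/y outside the field of view")
        if ((cells[:, 2] < 0) | (cells[:, 2] > geom.depth)).any():
            raise ValueError("cell z outside the chamber")
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:n, 0:n]
    stack = np.empty((geom.n_slices, n, n), dtype=np.float32)
    for i, z_slice in enumerate(geom.slice_z):
        frame = np.full((n, n), optics.background_level, dtype=float)
        if optics.background_gradient:
            frame *= 1.0 + optics.background_gradient * (xx / n - 0.5)
        for x, y, z in cells:
            d = abs(z - z_slice)
            amp = optics.contrast(d)
            if amp < 1e-3:
                continue
            sigma = optics.cell_radius_px * np.sqrt(1.0 + (d / optics.focal_depth) ** 2)
            r2 = (xx - x) ** 2 + (yy - y) ** 2
            local = r2 < (6 * sigma) ** 2
            frame[local] -= amp * np.exp(-r2[local] / (2 * sigma**2))
        if optics.noise_sd:
            frame += rng.normal(0.0, optics.noise_sd, frame.shape)
        stack[i] = np.clip(frame, 0.0, 1.0)
    return stack


@dataclass
class SliceDetections:
    """Detections of one slice: centroids (n, 2) in (x, y) px and areas."""

    centroids: np.ndarray
    areas: np.ndarray

    @property
    def count(self) -> int:
        return len(self.areas)


def detect_cells(stack: np.ndarray, settings: DetectionSettings = DetectionSettings()
                 ) -> list[SliceDetections]:
    """Threshold + connected components + area filter, per slice.

    A pixel is foreground when it is darker than the frame background by
    more than ``intensity_threshold`` of the full dynamic range.  Saturated
    (flat) frames yield a warning and zero detections.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3 or stack.shape[0] == 0:
        raise ValueError("stack must be a non-empty (slices, H, W) array")
    out = []
    for i, frame in enumerate(stack):
        background = np.median(frame)
        if np.ptp(frame) < 1e-9:
            if background >= 1.0 - 1e-9:
                warnings.warn(f"slice {i}: saturated frame, no detections")
            out.append(SliceDetections(np.empty((0, 2)), np.empty(0, dtype=int)))
            continue
        mask = (background - frame) > settings.intensity_threshold
        labels = measure.label(mask, connectivity=2)
        cents, areas = [], []
        for region in measure.regionprops(labels):
            if settings.min_area_px <= region.area <= settings.max_area_px:
                cy, cx = region.centroid
                cents.append((cx, cy))
                areas.append(region.area)
        out.append(SliceDetections(
            np.asarray(cents, dtype=float).reshape(-1, 2),
            np.asarray(areas, dtype=int),
        ))
    return out


@dataclass
class MultiplicityEstimate:
    """Histogram and mode of per-cell slice-detection counts."""

    mode: int | None
    histogram: dict
    n_tracks: int

    @property
    def defined(self) -> bool:
        return self.mode is not None


def estimate_multiplicity_factor(detections: list[SliceDetections],
                                 link_radius_px: float = 5.0) -> MultiplicityEstimate:
    """Estimate the multiple-counting factor from per-slice detections.

    Detections in adjacent slices closer than ``link_radius_px`` are greedily
    linked into per-cell tracks (nearest first); the mode of the track
    lengths estimates how many consecutive slices detect one physical cell.
    Returns an undefined mode (flagged) when there are no detections.
    """
    track_lengths: list[int] = []
    open_tracks: list[tuple[np.ndarray, int]] = []  # (centroid, length)
    for det in detections:
        cents = det.centroids
        new_open: list[tuple[np.ndarray, int]] = []
        unmatched = set(range(len(cents)))
        if open_tracks and len(cents):
            prev = np.array([t[0] for t in open_tracks])
            dist = np.linalg.norm(prev[:, None, :] - cents[None, :, :], axis=2)
            pairs = sorted(
                ((dist[i, j], i, j) for i in range(len(open_tracks))
                 for j in range(len(cents)) if dist[i, j] <= link_radius_px),
            )
            used_t, used_d = set(), set()
            for _, i, j in pairs:
                if i in used_t or j in used_d:
                    continue
                used_t.add(i)
                used_d.add(j)
                new_open.append((cents[j], open_tracks[i][1] + 1))
                unmatched.discard(j)
            for i, t in enumerate(open_tracks):
                if i not in used_t:
                    track_lengths.append(t[1])
        else:
            track_lengths.extend(t[1] for t in open_tracks)
        for j in unmatched:
            new_open.append((cents[j], 1))
        open_tracks = new_open
    track_lengths.extend(t[1] for t in open_tracks)
    if not track_lengths:
        return MultiplicityEstimate(None, {}, 0)
    hist = dict(sorted(Counter(track_lengths).items()))
    # mode; ties broken toward the smaller factor for a conservative estimate
    mode = max(hist, key=lambda k: (hist[k], -k))
    return MultiplicityEstimate(int(mode), hist, len(track_lengths))
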