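"""Tracer-front pseudo-ADC (ADC*) from serial contrast-enhanced T1WI.

The estimator tracks the expanding hyperintense front of an infused
high-molecular-weight tracer: inside a rough ROI each volume is split by
Otsu's threshold into tracer and non-tracer tissue, the 6-connected boundary
voxels of the tracer region form a surface, and the nearest-point travel
distance from each point of an earlier surface to the next surface enters

    ADC* = dist^2 / (2 d t),    d = 3,

whose per-point values are averaged into the pooled estimate.  ADC* is a
front-speed surrogate: it responds to both diffusion and bulk flow, which is
exactly what makes the comparison against a diffusion-only DTI estimate
informative.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .types import AdcStarResult, RoiMask, Surface, VolumeSeries

__all__ = [
    "otsu_threshold",
    "refine_roi",
    "extract_surface",
    "surface_distances",
    "adc_star",
    "adcstar_pipeline",
    "register_series",
]


def otsu_threshold(intensities, nbins: int = 256) -> float:
    """Between-class-variance-maximizing threshold of an intensity sample.

    The sample is histogrammed into ``nbins`` equal bins spanning
    ``[min, max]`` and every interior bin edge is scored by the between-class
    variance ``w0 w1 (mu0 - mu1)^2`` of the split it induces; the best edge
    is returned.  Values strictly above the threshold form the bright
    ("tracer") class.

    Raises
    ------
    ValueError
        If fewer than two distinct values are present
        ("degenerate intensity distribution").
    """
    x = np.asarray(intensities, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty intensity sample")
    lo, hi = float(x.min()), float(x.max())
    if lo == hi:
        raise ValueError("degenerate intensity distribution: all values equal")
    counts, edges = np.histogram(x, bins=nbins, range=(lo, hi))
    p = counts / counts.sum()
    centers = 0.5 * (edges[:-1] + edges[1:])
    w0 = np.cumsum(p)[:-1]            # weight of class <= edge k, k = 1..nbins-1
    w1 = 1.0 - w0
    m = np.cumsum(p * centers)
    mu_total = m[-1]
    with np.errstate(invalid="ignore", divide="ignore"):
        mu0 = m[:-1] / w0
        mu1 = (mu_total - m[:-1]) / w1
        between = w0 * w1 * (mu0 - mu1) ** 2
    between = np.where((w0 > 0) & (w1 > 0), between, -np.inf)
    best = int(np.argmax(between))    # ties -> lowest edge
    return float(edges[best + 1])


def refine_roi(volume: np.ndarray, rough_roi: RoiMask) -> RoiMask:
    """Keep only the bright (tracer) class inside a rough manual ROI.

    The returned mask is a subset of ``rough_roi``: the voxels whose
    intensity exceeds the Otsu threshold of the ROI-interior intensities.
    """
    volume = np.asarray(volume, dtype=float)
    if volume.shape != rough_roi.voxels.shape:
        raise ValueError(
            f"volume shape {volume.shape} != ROI shape {rough_roi.voxels.shape}")
    thr = otsu_threshold(volume[rough_roi.voxels])
    refined = rough_roi.voxels & (volume > thr)
    # Otsu guarantees a non-empty bright class: at least the max is above thr.
    assert refined.any(), "unreachable: Otsu bright class is empty"
    return RoiMask(voxels=refined, label=f"{rough_roi.label}/otsu")


# 6-connectivity structuring element for boundary detection.
_STRUCT6 = ndimage.generate_binary_structure(3, 1)


def extract_surface(mask: RoiMask, spacing_mm, time_ms: float) -> Surface:
    """Boundary voxels of a mask, as physical points.

    A mask voxel belongs to the surface when at least one of its six face
    neighbours is outside the mask; voxels beyond the grid edge count as
    outside.  Points are voxel centres, ``index * spacing`` in mm.
    """
    m = mask.voxels
    interior = ndimage.binary_erosion(m, structure=_STRUCT6, border_value=0)
    boundary = m & ~interior
    idx = np.argwhere(boundary)
    points = idx * np.asarray(spacing_mm, dtype=float)
    return Surface(points=points, source_time_ms=time_ms)


def surface_distances(earlier: Surface, later: Surface) -> np.ndarray:
    """Nearest-point distance (mm) from each earlier-surface point to the
    later surface."""
    tree = cKDTree(later.points)
    dists, _ = tree.query(earlier.points, k=1)
    return np.asarray(dists, dtype=float)


def adc_star(distances_mm, delta_t_ms: float, d: int = 3):
    """Per-point and mean pseudo-ADC from travel distances.

    ``adc* = dist^2 / (2 d delta_t)`` per point; the summary is the
    arithmetic mean with standard error ``sd / sqrt(N)``.

    Returns
    -------
    per_point : ndarray, mm^2/ms
    mean : float
    se : float
    """
    if delta_t_ms <= 0:
        raise ValueError(f"delta_t must be positive, got {delta_t_ms}")
    if d < 1:
        raise ValueError("dimensionality d must be >= 1")
    dist = np.asarray(distances_mm, dtype=float)
    if np.any(dist < 0):
        raise ValueError("distances must be non-negative")
    per_point = dist**2 / (2.0 * d * delta_t_ms)
    mean = float(per_point.mean())
    se = float(per_point.std(ddof=1) / np.sqrt(per_point.size)) \
        if per_point.size > 1 else 0.0
    return per_point, mean, se


def register_series(series: VolumeSeries, reference: int = 0) -> VolumeSeries:
    """Motion-correction hook.

    Synthetic series are motion-free, so the shipped implementation is the
    identity transform; the hook marks where a rigid registration would sit
    for in-vivo data.
    """
    return series


def adcstar_pipeline(series: VolumeSeries, rough_rois: list[RoiMask],
                     d: int = 3, pooling: str = "points") -> AdcStarResult:
    """Full front-tracking chain on a T1WI series.

    For each volume the rough ROI is Otsu-refined and the tracer surface
    extracted; consecutive surface pairs yield per-point travel distances
    and per-point ADC* values.  ``pooling="points"`` (default) averages all
    per-point values across pairs with equal weight; ``pooling="pairs"``
    averages the per-pair means.

    A non-increasing surface size emits a warning (an expanding tracer
    region should satisfy N1 < N2 < ...), never an error: noise can shrink
    the segmented front.
    """
    if len(series) < 2:
        raise ValueError("surface tracking needs at least 2 volumes")
    if len(rough_rois) != len(series):
        raise ValueError(f"{len(series)} volumes but {len(rough_rois)} ROIs")
    if pooling not in ("points", "pairs"):
        raise ValueError(f"unknown pooling rule {pooling!r}")

    surfaces = []
    for i, (vol, roi) in enumerate(zip(series.volumes, rough_rois)):
        try:
            refined = refine_roi(vol, roi)
            surfaces.append(extract_surface(refined, series.spacing_mm,
                                            series.times_ms[i]))
        except ValueError as err:
            raise ValueError(f"volume {i}: {err}") from err

    sizes = [s.n_points for s in surfaces]
    if any(b <= a for a, b in zip(sizes, sizes[1:])):
        warnings.warn(
            f"surface sizes {sizes} are not strictly increasing; the tracer "
            "region is expected to grow between scans", stacklevel=2)

    per_pair_dists: list[np.ndarray] = []
    delta_ts: list[float] = []
    per_pair_means: list[float] = []
    pooled_vals: list[np.ndarray] = []
    for k in range(len(surfaces) - 1):
        dt = series.times_ms[k + 1] - series.times_ms[k]
        dists = surface_distances(surfaces[k], surfaces[k + 1])
        per_point, mean, _ = adc_star(dists, dt, d=d)
        per_pair_dists.append(dists)
        delta_ts.append(dt)
        per_pair_means.append(mean)
        pooled_vals.append(per_point)

    if pooling == "points":
        allvals = np.concatenate(pooled_vals)
        pooled_mean = float(allvals.mean())
        pooled_se = float(allvals.std(ddof=1) / np.sqrt(allvals.size)) \
            if allvals.size > 1 else 0.0
    else:
        means = np.asarray(per_pair_means)
        pooled_mean = float(means.mean())
        pooled_se = float(means.std(ddof=1) / np.sqrt(means.size)) \
            if means.size > 1 else 0.0

    return AdcStarResult(
        per_point_distances_mm=per_pair_dists,
        delta_t_ms=delta_ts,
        d=d,
        per_pair_adcstar=per_pair_means,
        pooled_adcstar_mean=pooled_mean,
        pooled_adcstar_se=pooled_se,
        surface_sizes=sizes,
        pooling=pooling,
    )
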