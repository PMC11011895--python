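"""Shared data containers for the tracer-transport analysis pipeline.

Conventions used throughout the package:

* voxel indices are 0-based; a voxel's physical position is ``index * spacing``
  (voxel-centre convention), in millimetres;
* all times are in milliseconds, so diffusivities are in mm^2/ms
  (1e-3 mm^2/ms == 1e-3 mm^2/s in the more common s-based unit);
* 3-D arrays are indexed ``(x, y, z)`` with spacing ``(dx, dy, dz)``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "VolumeSeries",
    "RoiMask",
    "Surface",
    "AdcStarResult",
    "TensorField",
    "ScalarMaps",
    "TortuosityParams",
    "ConcentrationSeries",
    "DwiProtocol",
    "SimulationConfig",
    "GroupComparison",
    "FREE_DIFFUSION_WATER",
    "FREE_DIFFUSION_BSA",
]

#: Free diffusion coefficient of water at body temperature, mm^2/ms.
FREE_DIFFUSION_WATER = 3.0e-6

#: Free diffusion coefficient of bovine serum albumin (66 kD), mm^2/ms,
#: used as a stand-in for the 70 kD Gd-albumin tracer.
FREE_DIFFUSION_BSA = 8.29e-8


def _as_float_volume(a) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if a.ndim != 3:
        raise ValueError(f"expected a 3-D volume, got shape {a.shape}")
    return a


@dataclass
class VolumeSeries:
    """A time-ordered set of 3-D scalar volumes on one grid.

    Parameters
    ----------
    volumes : list of (X, Y, Z) float arrays sharing one shape.
    spacing_mm : voxel spacing along each axis, mm.
    times_ms : acquisition time of each volume, ms, strictly increasing.
    """

    volumes: list[np.ndarray]
    spacing_mm: tuple[float, float, float]
    times_ms: list[float]

    def __post_init__(self) -> None:
        self.volumes = [_as_float_volume(v) for v in self.volumes]
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        self.times_ms = [float(t) for t in self.times_ms]
        if not self.volumes:
            raise ValueError("VolumeSeries needs at least one volume")
        if len(self.volumes) != len(self.times_ms):
            raise ValueError(
                f"{len(self.volumes)} volumes but {len(self.times_ms)} times"
            )
        shapes = {v.shape for v in self.volumes}
        if len(shapes) > 1:
            raise ValueError(f"volumes have mismatched shapes: {sorted(shapes)}")
        if any(s <= 0 for s in self.spacing_mm) or len(self.spacing_mm) != 3:
            raise ValueError(f"spacing must be 3 positive reals, got {self.spacing_mm}")
        if np.any(np.diff(self.times_ms) <= 0):
            raise ValueError(f"times must be strictly increasing, got {self.times_ms}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.volumes[0].shape

    def __len__(self) -> int:
        return len(self.volumes)


@dataclass
class RoiMask:
    """A binary region-of-interest mask on the analysis grid."""

    voxels: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.voxels)
        if v.ndim != 3:
            raise ValueError(f"ROI mask must be 3-D, got shape {v.shape}")
        uniq = np.unique(v)
        if not np.isin(uniq, (0, 1)).all():
            raise ValueError("mask must be binary")
        self.voxels = v.astype(bool)
        if not self.voxels.any():
            raise ValueError(f"ROI mask {self.label!r} is empty")

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.sum())


@dataclass
class Surface:
    """Boundary points of a segmented tracer region, in physical mm."""

    points: np.ndarray  # (N, 3) physical coordinates, mm
    source_time_ms: float

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError(f"points must be (N, 3), got {self.points.shape}")
        if self.points.shape[0] < 1:
            raise ValueError("surface needs at least one point")
        self.source_time_ms = float(self.source_time_ms)

    @property
    def n_points(self) -> int:
        return self.points.shape[0]


@dataclass
class AdcStarResult:
    """Output of the tracer-front pseudo-ADC (ADC*) pipeline.

    ``per_point_distances_mm[k]`` holds the nearest-point travel distances
    from surface k to surface k+1; ``per_pair_adcstar`` the mean ADC* of each
    pair; the pooled fields the final estimate with its standard error.
    """

    per_point_distances_mm: list[np.ndarray]
    delta_t_ms: list[float]
    d: int
    per_pair_adcstar: list[float]
    pooled_adcstar_mean: float
    pooled_adcstar_se: float
    surface_sizes: list[int] = field(default_factory=list)
    pooling: str = "points"


@dataclass
class TensorField:
    """Per-voxel symmetric diffusion tensor with sorted eigensystem.

    ``tensor`` is ``(X, Y, Z, 3, 3)`` in mm^2/ms; ``eigenvalues`` are sorted
    descending (lambda1 >= lambda2 >= lambda3); ``eigenvectors[..., :, i]``
    is the unit eigenvector of ``eigenvalues[..., i]``.  ``valid`` marks
    voxels where the tensor is meaningful (e.g. S0 > 0 in a fit).
    """

    tensor: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    valid: np.ndarray

    @classmethod
    def from_tensor_array(cls, tensor: np.ndarray, valid: np.ndarray | None = None
                          ) -> "TensorField":
        """Build the field from a ``(..., 3, 3)`` symmetric tensor array."""
        tensor = np.asarray(tensor, dtype=float)
        if tensor.shape[-2:] != (3, 3):
            raise ValueError(f"tensor array must end in (3, 3), got {tensor.shape}")
        if not np.allclose(tensor, np.swapaxes(tensor, -1, -2), atol=1e-10):
            raise ValueError("tensor field has non-symmetric entries")
        evals, evecs = np.linalg.eigh(tensor)  # ascending
        order = np.argsort(-evals, axis=-1, kind="stable")
        evals = np.take_along_axis(evals, order, axis=-1)
        evecs = np.take_along_axis(evecs, order[..., None, :], axis=-1)
        if valid is None:
            valid = np.ones(tensor.shape[:-2], dtype=bool)
        return cls(tensor=tensor, eigenvalues=evals, eigenvectors=evecs,
                   valid=np.asarray(valid, dtype=bool))

    @property
    def grid_shape(self) -> tuple[int, ...]:
        return self.tensor.shape[:-2]


@dataclass
class ScalarMaps:
    """DTI scalar maps: FA (dimensionless), ADC, D_axi, D_rad (mm^2/ms)."""

    fa: np.ndarray
    adc: np.ndarray
    d_axi: np.ndarray
    d_rad: np.ndarray
    valid: np.ndarray


@dataclass
class TortuosityParams:
    """Free diffusivities and the tortuosity hindrance factor lambda.

    ``lambda^2 = D_free / ADC``; lambda >= 1 in hindered media.
    """

    free_diffusion_water: float = FREE_DIFFUSION_WATER
    free_diffusion_tracer: float = FREE_DIFFUSION_BSA
    tortuosity: float = 1.0

    def __post_init__(self) -> None:
        if self.free_diffusion_water <= 0 or self.free_diffusion_tracer <= 0:
            raise ValueError("free diffusion coefficients must be positive")


@dataclass
class ConcentrationSeries:
    """Ground-truth tracer concentration snapshots from the simulator."""

    volumes: list[np.ndarray]
    times_ms: list[float]
    spacing_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.volumes = [_as_float_volume(v) for v in self.volumes]
        if len(self.volumes) != len(self.times_ms):
            raise ValueError("volumes/times length mismatch")
        for v in self.volumes:
            if np.any(v < 0):
                raise ValueError("concentrations must be non-negative")

    def total_mass(self, index: int) -> float:
        """Discrete integral (sum * voxel volume) of snapshot ``index``."""
        return float(self.volumes[index].sum() * np.prod(self.spacing_mm))


@dataclass
class DwiProtocol:
    """A diffusion-weighting scheme: b-values (s/mm^2) and unit directions."""

    bvalues: np.ndarray
    directions: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.bvalues = np.asarray(self.bvalues, dtype=float).ravel()
        self.directions = np.asarray(self.directions, dtype=float)
        if self.directions.shape != (self.bvalues.size, 3):
            raise ValueError(
                f"directions shape {self.directions.shape} does not match "
                f"{self.bvalues.size} b-values"
            )
        weighted = self.bvalues > 0
        if not (~weighted).any():
            raise ValueError("protocol needs at least one b=0 entry")
        if weighted.sum() < 6:
            raise ValueError("protocol needs at least 6 diffusion-weighted entries")
        norms = np.linalg.norm(self.directions[weighted], axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("weighted gradient directions must be unit vectors")
        # Non-collinearity <=> the 6-element quadratic design has full rank.
        g = self.directions[weighted]
        design = np.column_stack([
            g[:, 0] ** 2, g[:, 1] ** 2, g[:, 2] ** 2,
            2 * g[:, 0] * g[:, 1], 2 * g[:, 0] * g[:, 2], 2 * g[:, 1] * g[:, 2],
        ])
        if np.linalg.matrix_rank(design) < 6:
            raise ValueError(
                "gradient directions are collinear/degenerate; the tensor design "
                f"built from them is rank-deficient: {g.tolist()}"
            )

    def __len__(self) -> int:
        return self.bvalues.size


@dataclass
class SimulationConfig:
    """Configuration of the advection-diffusion tracer-transport simulation.

    Defaults emulate the study conditions: a 20-minute constant-rate
    intra-striatal infusion on a 64x64x48 grid at the acquisition's
    interpolated spacing, with post-infusion snapshots 4.5 and 28.5 minutes
    after the end of infusion, and a tracer diffusivity on the scale of a
    70 kD protein in tissue (2e-8 mm^2/ms).
    """

    grid_shape: tuple[int, int, int] = (64, 64, 48)
    voxel_spacing_mm: tuple[float, float, float] = (0.125, 0.125, 0.167)
    diffusion_coefficient: float = 2.0e-8  # mm^2/ms
    velocity: tuple[float, float, float] | np.ndarray = (0.0, 0.0, 0.0)  # mm/ms
    infusion_center: tuple[int, int, int] | None = None  # default: grid centre
    infusion_rate: float = 1.0e-6  # concentration units / ms
    infusion_duration_ms: float = 20.0 * 60e3
    source_sigma_mm: float = 0.3  # spatial deposition kernel width
    snapshot_times_ms: tuple[float, ...] = (24.5 * 60e3, 48.5 * 60e3)
    cfl_safety: float = 0.5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(n) for n in self.grid_shape)
        if len(self.grid_shape) != 3 or any(n < 3 for n in self.grid_shape):
            raise ValueError(f"grid_shape must be 3 ints >= 3, got {self.grid_shape}")
        self.voxel_spacing_mm = tuple(float(s) for s in self.voxel_spacing_mm)
        if any(s <= 0 for s in self.voxel_spacing_mm):
            raise ValueError("voxel spacing must be positive")
        if self.diffusion_coefficient < 0:
            raise ValueError("diffusion coefficient must be >= 0")
        if self.infusion_center is None:
            self.infusion_center = tuple(n // 2 for n in self.grid_shape)
        self.infusion_center = tuple(int(i) for i in self.infusion_center)
        if any(not (0 <= i < n) for i, n in zip(self.infusion_center, self.grid_shape)):
            raise ValueError("infusion centre lies outside the grid")
        times = np.asarray(self.snapshot_times_ms, dtype=float)
        if times.size == 0 or np.any(np.diff(times) <= 0) or times[0] <= 0:
            raise ValueError("snapshot times must be positive and strictly increasing")
        self.snapshot_times_ms = tuple(times)
        if not 0 < self.cfl_safety <= 0.5:
            raise ValueError("cfl_safety must be in (0, 0.5]")

    def velocity_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis velocity components broadcastable to the grid."""
        v = self.velocity
        if isinstance(v, np.ndarray) and v.ndim == 4:
            if v.shape != (*self.grid_shape, 3):
                raise ValueError(
                    f"velocity field shape {v.shape} != {(*self.grid_shape, 3)}"
                )
            return v[..., 0], v[..., 1], v[..., 2]
        v = np.asarray(v, dtype=float).ravel()
        if v.size != 3:
            raise ValueError("uniform velocity must be a 3-vector")
        return (np.full((), v[0]), np.full((), v[1]), np.full((), v[2]))

    def max_speed(self) -> float:
        vx, vy, vz = self.velocity_arrays()
        return float(np.sqrt(np.max(vx**2 + vy**2 + vz**2)))


@dataclass
class GroupComparison:
    """Two-group comparison of per-subject ADC values (mm^2/ms)."""

    group_a_values: np.ndarray
    group_b_values: np.ndarray
    label_a: str
    label_b: str
    mean_a: float
    se_a: float
    mean_b: float
    se_b: float
    t_statistic: float
    degrees_freedom: float
    p_value: float
    percent_difference: float
    roi_label: str = ""

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["group_a_values"] = list(map(float, self.group_a_values))
        d["group_b_values"] = list(map(float, self.group_b_values))
        return d
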