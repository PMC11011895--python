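"""Diffusion-tensor estimation, scalar maps, and tortuosity scaling.

The tensor is fit voxelwise by log-linear ordinary least squares on the
monoexponential model ``S = S0 exp(-b g^T D g)``; scalar maps follow the
standard definitions

    FA    = sqrt(1/2) sqrt(((l1-l2)^2 + (l1-l3)^2 + (l2-l3)^2)
                            / (l1^2 + l2^2 + l3^2))
    ADC   = (l1 + l2 + l3) / 3
    D_axi = l1
    D_rad = (l2 + l3) / 2

with l1 >= l2 >= l3 the sorted eigenvalues.  The extracellular-space
tortuosity lambda links the water ADC measured by DTI to the effective
diffusivity of a high-molecular-weight tracer in the same tissue through

    lambda^2 = D_free / ADC

applied once with the free-water coefficient (3e-6 mm^2/ms) to obtain
lambda, and once, inverted, with the free coefficient of bovine serum
albumin (8.29e-8 mm^2/ms) to predict the tracer's tissue ADC.
"""

from __future__ import annotations

import warnings

import numpy as np

from .types import (
    FREE_DIFFUSION_BSA,
    FREE_DIFFUSION_WATER,
    DwiProtocol,
    RoiMask,
    ScalarMaps,
    TensorField,
    VolumeSeries,
)

__all__ = [
    "design_matrix",
    "fit_tensor",
    "scalar_maps",
    "roi_mean_adc",
    "tortuosity_from_water",
    "scale_adc_to_tracer",
    "water_adc_from_tracer",
]

# Signal floor applied before the log, as a fraction of S0.
_SIGNAL_FLOOR_FRAC = 1e-6


def design_matrix(protocol: DwiProtocol) -> np.ndarray:
    """Rows ``b * [gx^2, gy^2, gz^2, 2 gx gy, 2 gx gz, 2 gy gz]`` for the
    weighted protocol entries (b converted from s/mm^2 to ms/mm^2 so the
    product with a mm^2/ms tensor is dimensionless), so that
    ``row . dvec = b g^T D g``."""
    from .simulate import MS_PER_S

    weighted = protocol.bvalues > 0
    g = protocol.directions[weighted]
    b = protocol.bvalues[weighted][:, None] * MS_PER_S
    return b * np.column_stack([
        g[:, 0] ** 2, g[:, 1] ** 2, g[:, 2] ** 2,
        2 * g[:, 0] * g[:, 1], 2 * g[:, 0] * g[:, 2], 2 * g[:, 1] * g[:, 2],
    ])


def _dvec_to_tensor(dvec: np.ndarray) -> np.ndarray:
    """(..., 6) [Dxx, Dyy, Dzz, Dxy, Dxz, Dyz] -> (..., 3, 3) symmetric."""
    t = np.empty((*dvec.shape[:-1], 3, 3))
    t[..., 0, 0] = dvec[..., 0]
    t[..., 1, 1] = dvec[..., 1]
    t[..., 2, 2] = dvec[..., 2]
    t[..., 0, 1] = t[..., 1, 0] = dvec[..., 3]
    t[..., 0, 2] = t[..., 2, 0] = dvec[..., 4]
    t[..., 1, 2] = t[..., 2, 1] = dvec[..., 5]
    return t


def fit_tensor(dwi: VolumeSeries, protocol: DwiProtocol) -> TensorField:
    """Voxelwise log-linear OLS diffusion-tensor fit.

    ``S0`` is the mean of the b=0 volumes; signals are floored at
    ``1e-6 * S0`` before the log; voxels with ``S0 <= 0`` are marked
    invalid (their tensor is set to zero).
    """
    if len(dwi) != len(protocol):
        raise ValueError(
            f"{len(dwi)} DWI volumes but protocol has {len(protocol)} entries")
    M = design_matrix(protocol)  # validity of the direction set is checked
    if np.linalg.matrix_rank(M) < 6:
        bad = protocol.directions[protocol.bvalues > 0]
        raise ValueError(
            f"rank-deficient tensor design; offending directions: {bad.tolist()}")

    data = np.stack(dwi.volumes, axis=-1)  # (X, Y, Z, n)
    b0 = data[..., protocol.bvalues == 0].mean(axis=-1)
    valid = b0 > 0
    s0 = np.where(valid, b0, 1.0)
    sig = data[..., protocol.bvalues > 0]
    floor = _SIGNAL_FLOOR_FRAC * s0[..., None]
    sig = np.maximum(sig, floor)
    y = np.log(s0[..., None]) - np.log(sig)  # b g^T D g per weighted volume

    # One shared least-squares solve for every voxel: pinv(M) @ y.
    dvec = np.einsum("km,...m->...k", np.linalg.pinv(M), y)
    dvec[~valid] = 0.0
    tensor = _dvec_to_tensor(dvec)
    return TensorField.from_tensor_array(tensor, valid=valid)


def scalar_maps(tensors: TensorField) -> ScalarMaps:
    """FA / ADC / D_axi / D_rad maps from a tensor field.

    Negative eigenvalues (noise artefacts of the log-linear fit) are
    clamped to 0 before map evaluation; voxels whose eigenvalues are all
    zero get FA = 0 by convention so background never produces NaNs.
    """
    lam = np.maximum(tensors.eigenvalues, 0.0)
    l1, l2, l3 = lam[..., 0], lam[..., 1], lam[..., 2]
    sumsq = l1**2 + l2**2 + l3**2
    num = (l1 - l2) ** 2 + (l1 - l3) ** 2 + (l2 - l3) ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(0.5) * np.sqrt(num / sumsq)
    fa = np.where(sumsq > 0, fa, 0.0)
    fa = np.clip(fa, 0.0, 1.0)
    return ScalarMaps(
        fa=fa,
        adc=(l1 + l2 + l3) / 3.0,
        d_axi=l1,
        d_rad=(l2 + l3) / 2.0,
        valid=tensors.valid,
    )


def roi_mean_adc(maps: ScalarMaps, roi: RoiMask) -> tuple[float, float]:
    """Mean and standard error of the ADC map over valid ROI voxels."""
    sel = roi.voxels & maps.valid
    n = int(sel.sum())
    if n == 0:
        raise ValueError(f"ROI {roi.label!r} has no valid voxels")
    vals = maps.adc[sel]
    mean = float(vals.mean())
    se = float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return mean, se


def tortuosity_from_water(adc_water: float,
                          free_diffusion_water: float = FREE_DIFFUSION_WATER
                          ) -> float:
    """Tortuosity ``lambda = sqrt(D_free_water / ADC_water)``.

    ``lambda < 1`` (tissue water apparently faster than free water) is
    physically implausible and triggers a warning, not an error.
    """
    if adc_water <= 0:
        raise ValueError(f"water ADC must be positive, got {adc_water}")
    lam = float(np.sqrt(free_diffusion_water / adc_water))
    if lam < 1.0:
        warnings.warn(
            f"computed tortuosity {lam:.3f} < 1: water ADC exceeds the free "
            "diffusion coefficient", stacklevel=2)
    return lam


def scale_adc_to_tracer(tortuosity: float,
                        free_diffusion_tracer: float = FREE_DIFFUSION_BSA
                        ) -> float:
    """Tissue ADC of the tracer, ``D_free_tracer / lambda^2`` (mm^2/ms).

    Assumes the tracer experiences the same extracellular tortuosity as
    water — a conservative assumption: a larger true tortuosity would only
    lower this diffusion-only prediction.
    """
    if tortuosity <= 0:
        raise ValueError(f"tortuosity must be positive, got {tortuosity}")
    if tortuosity < 1.0:
        warnings.warn(f"tortuosity {tortuosity:.3f} < 1 is physically "
                      "implausible", stacklevel=2)
    return float(free_diffusion_tracer / tortuosity**2)


def water_adc_from_tracer(adc_tracer: float,
                          free_diffusion_water: float = FREE_DIFFUSION_WATER,
                          free_diffusion_tracer: float = FREE_DIFFUSION_BSA
                          ) -> float:
    """Inverse of the water -> tracer composition: the water ADC that would
    rescale to ``adc_tracer`` under a shared tortuosity."""
    if adc_tracer <= 0:
        raise ValueError("tracer ADC must be positive")
    return float(adc_tracer * free_diffusion_water / free_diffusion_tracer)
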