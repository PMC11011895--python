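"""Readers and writers for the pipeline's on-disk dialects.

Volumes travel as NIfTI (one 4-D file or a list of 3-D files) with voxel
spacing in the header and acquisition times in a JSON sidecar; diffusion
protocols as FSL-style ``bvals``/``bvecs`` text files; analysis results as
JSON.  Volumes are treated in voxel-index space: orientation matrices are
preserved on write but never used for resampling, since every input of one
analysis shares a single grid by contract.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from . import __version__
from .types import DwiProtocol, RoiMask, VolumeSeries

__all__ = [
    "write_volume_series",
    "read_volume_series",
    "write_mask",
    "read_mask",
    "write_protocol",
    "read_protocol",
    "PipelineConfig",
    "read_config",
    "provenance",
    "write_json",
]


def _affine(spacing_mm) -> np.ndarray:
    return np.diag([*spacing_mm, 1.0])


def write_volume_series(series: VolumeSeries, path, sidecar_path=None) -> None:
    """Write a series as one 4-D NIfTI plus a ``times_ms`` JSON sidecar."""
    path = Path(path)
    data = np.stack(series.volumes, axis=-1)
    nib.save(nib.Nifti1Image(data, _affine(series.spacing_mm)), str(path))
    if sidecar_path is None:
        sidecar_path = path.with_suffix("").with_suffix(".json") \
            if path.suffix == ".gz" else path.with_suffix(".json")
    Path(sidecar_path).write_text(
        json.dumps({"times_ms": series.times_ms}, indent=2))


def read_volume_series(paths, sidecar_path=None,
                       times_ms=None) -> VolumeSeries:
    """Load a series from one 4-D NIfTI or a list of 3-D NIfTI files.

    Spacing comes from the NIfTI header (mm); acquisition times from the
    sidecar JSON (``{"times_ms": [...]}``) or the ``times_ms`` argument.
    Mixed grids are rejected with the offending files named.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    volumes: list[np.ndarray] = []
    spacings: list[tuple] = []
    for p in paths:
        img = nib.load(str(p))
        zooms = tuple(round(float(z), 6) for z in img.header.get_zooms()[:3])
        data = np.asarray(img.dataobj, dtype=float)
        if data.ndim == 4:
            volumes.extend(data[..., k] for k in range(data.shape[-1]))
        elif data.ndim == 3:
            volumes.append(data)
        else:
            raise ValueError(f"{p}: expected 3-D or 4-D NIfTI, got {data.ndim}-D")
        spacings.append(zooms)
    if len({v.shape for v in volumes}) > 1 or len(set(spacings)) > 1:
        detail = ", ".join(f"{p}: shape={nib.load(str(p)).shape} "
                           f"spacing={s}" for p, s in zip(paths, spacings))
        raise ValueError(f"mismatched geometry across volumes: {detail}")
    if times_ms is None:
        if sidecar_path is None:
            raise ValueError("acquisition times required: pass a sidecar "
                             "path or times_ms")
        times_ms = json.loads(Path(sidecar_path).read_text())["times_ms"]
    return VolumeSeries(volumes=volumes, spacing_mm=spacings[0],
                        times_ms=list(times_ms))


def write_mask(mask: RoiMask, path) -> None:
    spacing = (1.0, 1.0, 1.0)
    nib.save(nib.Nifti1Image(mask.voxels.astype(np.uint8), _affine(spacing)),
             str(path))


def read_mask(path, label: str | None = None) -> RoiMask:
    data = np.asarray(nib.load(str(path)).dataobj)
    return RoiMask(voxels=data, label=label or Path(path).stem)


def write_protocol(protocol: DwiProtocol, bvals_path, bvecs_path) -> None:
    """FSL dialect: bvals on one space-separated line; bvecs as three rows
    (x, y, z components)."""
    Path(bvals_path).write_text(
        " ".join(f"{b:g}" for b in protocol.bvalues) + "\n")
    rows = [" ".join(f"{v:.6f}" for v in protocol.directions[:, ax])
            for ax in range(3)]
    Path(bvecs_path).write_text("\n".join(rows) + "\n")


def _parse_numeric_lines(path, expected_rows: int | None = None
                         ) -> list[list[float]]:
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    out = []
    for i, ln in enumerate(lines, start=1):
        row = []
        for tok in ln.split():
            try:
                row.append(float(tok))
            except ValueError as err:
                raise ValueError(
                    f"{path}, line {i}: non-numeric token {tok!r}") from err
        out.append(row)
    if expected_rows is not None and len(out) != expected_rows:
        raise ValueError(f"{path}: expected {expected_rows} rows, "
                         f"got {len(out)}")
    return out


def read_protocol(bvals_path, bvecs_path) -> DwiProtocol:
    """Parse FSL-dialect bvals/bvecs into a validated protocol.

    Directions are re-normalised; a zero direction vector is allowed only
    where b = 0.
    """
    bval_rows = _parse_numeric_lines(bvals_path, expected_rows=1)
    bvals = np.asarray(bval_rows[0])
    bvec_rows = _parse_numeric_lines(bvecs_path, expected_rows=3)
    lens = {len(r) for r in bvec_rows}
    if lens != {bvals.size}:
        raise ValueError(
            f"{bvecs_path}: direction count {sorted(lens)} does not match "
            f"{bvals.size} b-values in {bvals_path}")
    dirs = np.asarray(bvec_rows).T  # (n, 3)
    norms = np.linalg.norm(dirs, axis=1)
    zero = norms < 1e-12
    if np.any(zero & (bvals > 0)):
        idx = np.nonzero(zero & (bvals > 0))[0]
        raise ValueError(f"zero gradient vector at weighted entries {idx.tolist()}")
    dirs = np.where(zero[:, None], 0.0, dirs / np.where(zero, 1.0, norms)[:, None])
    return DwiProtocol(bvalues=bvals, directions=dirs)


@dataclass
class PipelineConfig:
    """Flat configuration for the end-to-end synthetic experiment."""

    n_subjects: int = 5
    diffusion_coefficient: float = 2.0e-8  # mm^2/ms, tracer in tissue
    flow_speed: float = 1.5e-7             # mm/ms, bulk-flow arm
    flow_direction: tuple[float, float, float] = (1.0, 0.0, 0.0)
    t1wi_noise_sd: float = 2.0
    dwi_noise_sd: float = 50.0
    adcstar_pooling: str = "points"
    ttest_variant: str = "pooled"
    rng_seed: int = 0
    output_dir: str = "results"

    @classmethod
    def from_mapping(cls, mapping: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(mapping)
        if "flow_direction" in kwargs:
            kwargs["flow_direction"] = tuple(kwargs["flow_direction"])
        return cls(**kwargs)


def read_config(path) -> PipelineConfig:
    """Load a flat YAML key-value config; unknown keys are errors."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    mapping = yaml.safe_load(path.read_text())
    if mapping is None:
        mapping = {}
    if not isinstance(mapping, dict):
        raise ValueError(f"{path}: config must be a flat key-value mapping")
    return PipelineConfig.from_mapping(mapping)


def provenance(config_obj, seeds) -> dict:
    """Config hash, seed list and package version, embedded in every output."""
    if dataclasses.is_dataclass(config_obj):
        config_obj = dataclasses.asdict(config_obj)
    blob = json.dumps(config_obj, sort_keys=True, default=str).encode()
    return {
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seeds": [int(s) for s in np.atleast_1d(seeds)],
        "version": __version__,
    }


def write_json(obj: dict, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(obj, indent=2, default=float))
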