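"""NIfTI volume I/O and sequence-parameter configuration files."""

from __future__ import annotations

import os

import numpy as np
import yaml

import nibabel as nib

from .relaxometry import SequenceParams

__all__ = [
    "read_volume",
    "write_volume",
    "check_same_geometry",
    "load_sequence_config",
    "DEFAULT_SEQUENCE",
]

#: Protocol defaults (post-contrast cardiac PSIR at 60 bpm).
DEFAULT_SEQUENCE = {
    "rr_ms": 1000.0,
    "t_inv_ms": 300.0,
    "tr_ms": 9.4,
    "flip_deg": 18.0,
    "tfe_factor": 23,
    "inversion_deg": 180.0,
    "kernel_rr": 2,
}


def read_volume(path: str | os.PathLike) -> tuple[np.ndarray, np.ndarray]:
    """Load a NIfTI volume as (float array, 4x4 affine).

    Single-slice 2-D images are promoted to one-slice 3-D; higher-dimensional
    data are rejected.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such volume: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several format-specific types
        raise ValueError(f"could not read {path} as a NIfTI volume: {exc}") from exc
    data = np.asarray(img.get_fdata(), dtype=float)
    if data.ndim == 2:
        data = data[..., np.newaxis]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 2-D or 3-D volume, got shape {data.shape}")
    return data, np.asarray(img.affine, dtype=float)


def write_volume(data: np.ndarray, path: str | os.PathLike, affine: np.ndarray | None = None) -> None:
    """Write a volume to NIfTI, preserving the given geometry."""
    data = np.asarray(data, dtype=np.float64)
    if data.ndim == 2:
        data = data[..., np.newaxis]
    if data.ndim != 3:
        raise ValueError(f"expected a 2-D or 3-D volume, got shape {data.shape}")
    if affine is None:
        affine = np.eye(4)
    nib.save(nib.Nifti1Image(data, np.asarray(affine, dtype=float)), str(path))


def check_same_geometry(
    shape_a, affine_a, shape_b, affine_b, names: tuple[str, str] = ("first", "second")
) -> None:
    """Raise if two volumes are not on the same grid."""
    if tuple(shape_a) != tuple(shape_b):
        raise ValueError(
            f"volume shapes differ: {names[0]} {tuple(shape_a)} vs {names[1]} {tuple(shape_b)}"
        )
    if not np.allclose(affine_a, affine_b, atol=1e-4):
        raise ValueError(f"volume affines differ between {names[0]} and {names[1]}")


def load_sequence_config(path: str | os.PathLike | None, **overrides) -> SequenceParams:
    """Build SequenceParams from a flat YAML config plus explicit overrides.

    Keys mirror the SequenceParams field names; overrides with value None are
    ignored so command-line flags can be layered on top of the file.
    """
    values = dict(DEFAULT_SEQUENCE)
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"{path}: config must be a flat mapping")
        unknown = set(loaded) - set(DEFAULT_SEQUENCE)
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        values.update(loaded)
    values.update({k: v for k, v in overrides.items() if v is not None})
    values["tfe_factor"] = int(values["tfe_factor"])
    values["kernel_rr"] = int(values["kernel_rr"])
    return SequenceParams(**values)
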