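"""NIfTI, CSV and YAML I/O shared by all commands.

Scalar volumes and integer label maps are stored as 3-D NIfTI-1; velocity
and displacement fields as 4-D NIfTI with the last axis holding the vector
component (voxel-unit convention recorded in the header description).
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .fields import Diffeo, Image3D, InvalidInputError, LabelMap3D, VelocityField

__all__ = [
    "load_volume", "save_volume", "load_vector_field", "save_vector_field",
    "load_cohort_csv", "save_label_key", "load_label_key",
    "load_yaml_config", "save_run_config",
]

_VEC_DESC = b"svfatlas vector field; voxel-unit components on last axis"


def _affine(spacing: np.ndarray, origin: np.ndarray) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(spacing)
    aff[:3, 3] = origin
    return aff


def _grid_from(img: nib.Nifti1Image):
    zooms = np.asarray(img.header.get_zooms()[:3], dtype=float)
    origin = np.asarray(img.affine[:3, 3], dtype=float)
    return zooms, origin


def load_volume(path, as_labels: bool = False):
    """Read a 3-D NIfTI volume as Image3D, or LabelMap3D if ``as_labels``."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[-1] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise InvalidInputError(f"{path}: expected a 3-D volume, got shape {data.shape}")
    spacing, origin = _grid_from(img)
    if as_labels or np.issubdtype(data.dtype, np.integer):
        if as_labels:
            return LabelMap3D(np.rint(data).astype(np.int32), spacing, origin)
        return Image3D(data.astype(float), spacing, origin)
    return Image3D(np.asarray(data, dtype=float), spacing, origin)


def save_volume(obj, path) -> None:
    """Write an Image3D (float32) or LabelMap3D (int16/int32) to NIfTI."""
    if isinstance(obj, LabelMap3D):
        data = obj.labels
        dtype = np.int16 if data.max(initial=0) < 2 ** 15 else np.int32
        arr = data.astype(dtype)
    elif isinstance(obj, Image3D):
        arr = obj.values.astype(np.float32)
    else:
        raise InvalidInputError(f"cannot save object of type {type(obj).__name__}")
    img = nib.Nifti1Image(arr, _affine(obj.spacing, obj.origin))
    img.header.set_zooms(tuple(obj.spacing))
    nib.save(img, str(path))


def save_vector_field(obj, path) -> None:
    """Write a VelocityField or Diffeo as a 4-D NIfTI (last axis = component)."""
    if isinstance(obj, VelocityField):
        arr = obj.vectors
    elif isinstance(obj, Diffeo):
        arr = obj.displacement
    else:
        raise InvalidInputError(f"cannot save vector field of type {type(obj).__name__}")
    img = nib.Nifti1Image(arr.astype(np.float32), _affine(obj.spacing, obj.origin))
    img.header["descrip"] = _VEC_DESC
    nib.save(img, str(path))


def load_vector_field(path, as_diffeo: bool = False):
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(float)
    if data.ndim != 4 or data.shape[-1] != 3:
        raise InvalidInputError(f"{path}: expected (X, Y, Z, 3) vector field, got {data.shape}")
    spacing, origin = _grid_from(img)
    if as_diffeo:
        return Diffeo(data, spacing, origin)
    return VelocityField(data, spacing, origin)


def load_cohort_csv(path):
    """Read a cohort table with columns subject_id, age_weeks, image_path.

    Returns a list of (subject_id, age, image_path) tuples; paths are resolved
    relative to the CSV's directory.
    """
    import pandas as pd

    df = pd.read_csv(path)
    required = {"subject_id", "age_weeks", "image_path"}
    if not required.issubset(df.columns):
        raise InvalidInputError(f"cohort CSV must have columns {sorted(required)}")
    base = Path(path).parent
    rows = []
    for _, row in df.iterrows():
        p = Path(row["image_path"])
        if not p.is_absolute():
            p = base / p
        rows.append((str(row["subject_id"]), float(row["age_weeks"]), p))
    return rows


def save_label_key(key: dict, path) -> None:
    """One 'id name' pair per line (the released-atlas label-key layout)."""
    with open(path, "w") as fh:
        for lab in sorted(key):
            fh.write(f"{lab} {key[lab]}\n")


def load_label_key(path) -> dict:
    key = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            lab, name = line.split(maxsplit=1)
            key[int(lab)] = name
    return key


def load_yaml_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise InvalidInputError(f"{path}: config must be a mapping")
    return cfg


def save_run_config(config: dict, out_dir) -> Path:
    """Write the resolved run configuration beside the outputs (JSON)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "run_config.json"
    with open(path, "w") as fh:
        json.dump(config, fh, indent=2, sort_keys=True, default=str)
    return path
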