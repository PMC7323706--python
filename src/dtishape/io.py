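"""NIfTI / gradient-table / report readers and writers.

Conventions: NIfTI-1 volumes (compressed, ``.nii.gz``); FSL-dialect
bval/bvec with directions in the image coordinate frame; NaN as the
on-disk sentinel for invalid voxels; CSV (UTF-8, header row) for tables;
JSON for manifests.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

from .gradients import GradientScheme, read_bvals_bvecs, write_bvals_bvecs
from .tissue import LABEL_NAMES

__all__ = [
    "DwiDataset",
    "LabelVolume",
    "read_dwi",
    "write_dwi",
    "read_labels",
    "write_labels",
    "write_metric_maps",
    "read_metric_map",
    "CountMismatchError",
    "GridMismatchError",
]

METRIC_MAP_NAMES = ("fa", "cl", "cp", "cs", "md")


class CountMismatchError(ValueError):
    """Volume count disagrees with gradient-table length."""


class GridMismatchError(ValueError):
    """Volumes expected on a shared grid have different shapes."""


@dataclass
class DwiDataset:
    """A 4D DWI stack with its affine and gradient scheme."""

    data: np.ndarray
    affine: np.ndarray
    scheme: GradientScheme
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.data.ndim != 4:
            raise ValueError(f"DWI data must be 4D; got shape {self.data.shape}")
        if self.data.shape[-1] != self.scheme.n:
            raise CountMismatchError(
                f"DWI has {self.data.shape[-1]} volumes but gradient table "
                f"has {self.scheme.n} entries"
            )
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine is singular")


@dataclass
class LabelVolume:
    """3D integer labels with an affine and a label → name map."""

    data: np.ndarray
    affine: np.ndarray
    names: dict[int, str]

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError(f"label volume must be 3D; got {self.data.shape}")
        if np.any(self.data < 0):
            raise ValueError("labels must be non-negative integers")


def read_dwi(
    nifti_path: str | Path,
    bval_path: str | Path,
    bvec_path: str | Path,
) -> DwiDataset:
    """Read a DWI NIfTI plus its FSL-dialect gradient table pair."""
    img = nib.load(str(nifti_path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim == 3:
        data = data[..., None]
    scheme = read_bvals_bvecs(bval_path, bvec_path)
    if data.shape[-1] != scheme.n:
        raise CountMismatchError(
            f"{nifti_path}: {data.shape[-1]} volumes vs {scheme.n} "
            "gradient-table entries"
        )
    return DwiDataset(data=data, affine=img.affine, scheme=scheme)


def write_dwi(
    data: np.ndarray,
    affine: np.ndarray,
    scheme: GradientScheme,
    prefix: str | Path,
) -> dict[str, Path]:
    """Write ``<prefix>.nii.gz`` plus ``<prefix>.bval``/``<prefix>.bvec``."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "nifti": prefix.with_suffix(".nii.gz"),
        "bval": prefix.with_suffix(".bval"),
        "bvec": prefix.with_suffix(".bvec"),
    }
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine)
    nib.save(img, str(paths["nifti"]))
    write_bvals_bvecs(scheme, paths["bval"], paths["bvec"])
    return paths


def read_labels(path: str | Path) -> LabelVolume:
    """Read an integer label volume (with optional JSON name sidecar)."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if not np.issubdtype(data.dtype, np.integer):
        rounded = np.rint(data)
        if not np.allclose(data, rounded):
            raise ValueError(f"{path}: label volume has non-integer values")
        data = rounded.astype(np.int32)
    sidecar = Path(str(path).replace(".nii.gz", "").replace(".nii", "") + ".json")
    names = dict(LABEL_NAMES)
    if sidecar.exists():
        import json

        with open(sidecar) as fh:
            names = {int(k): v for k, v in json.load(fh).items()}
    return LabelVolume(data=data, affine=img.affine, names=names)


def write_labels(
    data: np.ndarray,
    affine: np.ndarray,
    path: str | Path,
    names: dict[int, str] | None = None,
) -> Path:
    """Write labels as int16 NIfTI plus a JSON label-name sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(np.asarray(data, dtype=np.int16), affine)
    nib.save(img, str(path))
    import json

    if names is None:
        present = {int(l) for l in np.unique(data) if l != 0}
        names = {l: LABEL_NAMES.get(l, str(l)) for l in present}
    sidecar = Path(str(path).replace(".nii.gz", "").replace(".nii", "") + ".json")
    with open(sidecar, "w") as fh:
        json.dump({str(k): v for k, v in names.items()}, fh, indent=2,
                  sort_keys=True)
    return path


def write_metric_maps(
    metrics: dict[str, np.ndarray],
    affine: np.ndarray,
    out_prefix: str | Path,
) -> dict[str, Path]:
    """Write one float32 NIfTI per metric map (``<prefix>_<metric>.nii.gz``).

    Invalid voxels must already be NaN-encoded; NaN round-trips as the
    sentinel.  All maps must share one grid.
    """
    shapes = {m: np.asarray(v).shape for m, v in metrics.items()}
    if len(set(shapes.values())) > 1:
        raise GridMismatchError(f"metric grids differ: {shapes}")
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, vol in metrics.items():
        p = out_prefix.parent / f"{out_prefix.name}_{name}.nii.gz"
        nib.save(nib.Nifti1Image(np.asarray(vol, dtype=np.float32), affine), str(p))
        paths[name] = p
    return paths


def read_metric_map(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a metric map; returns ``(data, affine)`` with NaN sentinels."""
    img = nib.load(str(path))
    return np.asarray(img.dataobj, dtype=np.float64), img.affine
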