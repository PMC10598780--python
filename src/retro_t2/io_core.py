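"""Volume containers and NIfTI I/O.

Two carriers move through the whole pipeline: :class:`ImageVolume` for
scalar images (weighted images in arbitrary units, T2 maps in ms) and
:class:`LabelVolume` for integer tissue / ROI label maps.  Both are thin
wrappers over a 3D numpy array plus the geometry metadata the pipeline
needs (voxel spacing in mm, a units tag, and the through-plane axis).

Conventions
-----------
* Voxel indices are 0-based and the through-plane (slice) axis is the
  last axis; every per-slice operation iterates over it.
* Weighted images carry ``units="arbitrary"``; T2 maps carry
  ``units="ms"``.  The units tag and the label legend travel in a JSON
  sidecar next to the ``.nii``/``.nii.gz`` file.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "ImageVolume",
    "LabelVolume",
    "VolumeIOError",
    "read_volume",
    "write_volume",
    "read_labels",
    "write_labels",
]

#: Units an ImageVolume may carry.
UNITS = ("arbitrary", "ms")


class VolumeIOError(ValueError):
    """Raised when a volume fails ingest validation."""


@dataclass
class ImageVolume:
    """A scalar 3D grid with voxel spacing and a units tag.

    Parameters
    ----------
    data
        Scalar grid, shape (X, Y, Z).  Stored as float.
    spacing
        Voxel size in mm per axis, all positive.
    units
        ``"arbitrary"`` for weighted/echo images, ``"ms"`` for T2 maps.
    slice_axis
        Index of the through-plane axis (always 2 by convention).
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    units: str = "arbitrary"
    slice_axis: int = 2

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise VolumeIOError(
                f"expected 3D payload, got {self.data.ndim}D shape {self.data.shape}"
            )
        if any(s < 1 for s in self.data.shape):
            raise VolumeIOError(f"all dimensions must be >= 1, got {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise VolumeIOError(f"spacing must be 3 positive floats, got {self.spacing}")
        if self.units not in UNITS:
            raise VolumeIOError(f"units must be one of {UNITS}, got {self.units!r}")
        if self.slice_axis != 2:
            raise VolumeIOError("through-plane axis must be the last axis (2)")

    # -- convenience -------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape)

    @property
    def n_slices(self) -> int:
        return self.data.shape[self.slice_axis]

    def slices(self):
        """Iterate 2D slices along the through-plane axis."""
        for k in range(self.n_slices):
            yield self.data[:, :, k]

    def with_data(self, data: np.ndarray, units: str | None = None) -> "ImageVolume":
        """New volume with the same geometry but different voxel data."""
        return replace(self, data=np.asarray(data), units=units or self.units)


@dataclass
class LabelVolume:
    """Non-negative integer label grid with a label -> name legend."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    legend: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise VolumeIOError(
                f"expected 3D payload, got {self.data.ndim}D shape {self.data.shape}"
            )
        if not np.issubdtype(self.data.dtype, np.integer):
            as_int = self.data.astype(np.int32)
            if not np.array_equal(as_int, self.data):
                raise VolumeIOError("label data must be integer-valued")
            self.data = as_int
        if (self.data < 0).any():
            raise VolumeIOError("labels must be non-negative")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.legend = {int(k): str(v) for k, v in self.legend.items()}
        present = set(np.unique(self.data).tolist()) - {0}
        missing = present - set(self.legend)
        if missing:
            raise VolumeIOError(f"labels {sorted(missing)} missing from legend")

    def mask(self, name: str) -> np.ndarray:
        """Boolean mask of the label with the given legend name."""
        for lab, nm in self.legend.items():
            if nm == name:
                return self.data == lab
        raise KeyError(f"no label named {name!r} in legend {self.legend}")


# ---------------------------------------------------------------------------
# NIfTI round-trip.  Geometry is encoded in the affine (diagonal spacing);
# units and legend go in a JSON sidecar because NIfTI has no native slot.
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suf in (".nii.gz", ".nii"):
        if name.endswith(suf):
            return path.with_name(name[: -len(suf)] + ".json")
    return path.with_suffix(".json")


def write_volume(vol: ImageVolume, path: str | Path) -> None:
    """Write a volume as NIfTI plus a JSON sidecar carrying the units tag."""
    path = Path(path)
    affine = np.diag(list(vol.spacing) + [1.0])
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=np.float64), affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))
    _sidecar_path(path).write_text(json.dumps({"units": vol.units}))


def read_volume(path: str | Path) -> ImageVolume:
    """Load a NIfTI volume; units default to arbitrary unless the sidecar says ms.

    Raises
    ------
    VolumeIOError
        For a missing file, a non-3D payload, or non-finite voxels (the
        error names the offending voxel count).
    """
    path = Path(path)
    if not path.exists():
        raise VolumeIOError(f"no such file: {path}")
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata())
    if data.ndim != 3:
        raise VolumeIOError(f"expected 3D payload, got {data.ndim}D in {path}")
    bad = int(np.count_nonzero(~np.isfinite(data)))
    if bad:
        raise VolumeIOError(f"{bad} non-finite voxel(s) in {path}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    units = "arbitrary"
    sc = _sidecar_path(path)
    if sc.exists():
        units = json.loads(sc.read_text()).get("units", "arbitrary")
    return ImageVolume(data=data, spacing=spacing, units=units)


def write_labels(lab: LabelVolume, path: str | Path) -> None:
    path = Path(path)
    affine = np.diag(list(lab.spacing) + [1.0])
    img = nib.Nifti1Image(lab.data.astype(np.int16), affine)
    img.header.set_zooms(lab.spacing)
    nib.save(img, str(path))
    _sidecar_path(path).write_text(
        json.dumps({"legend": {str(k): v for k, v in lab.legend.items()}})
    )


def read_labels(path: str | Path) -> LabelVolume:
    path = Path(path)
    if not path.exists():
        raise VolumeIOError(f"no such file: {path}")
    img = nib.load(str(path))
    data = np.asarray(img.dataobj).astype(np.int32)
    if data.ndim != 3:
        raise VolumeIOError(f"expected 3D payload, got {data.ndim}D in {path}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    legend: dict[int, str] = {}
    sc = _sidecar_path(path)
    if sc.exists():
        raw = json.loads(sc.read_text()).get("legend", {})
        legend = {int(k): v for k, v in raw.items()}
    return LabelVolume(data=data, spacing=spacing, legend=legend)
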