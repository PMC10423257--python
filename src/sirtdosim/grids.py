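"""Image containers and NIfTI I/O.

Everything downstream works on plain 3D scalar grids with a physical voxel
spacing.  The coordinate convention is voxel-center: world position of voxel
``(i, j, k)`` is ``origin + (index + 0.5) * spacing``, with axis 2 taken as
the axial (cranio-caudal, z) direction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np

#: grid provenance tags
MODALITIES = ("truth", "spect_like", "pet_like", "suv")

#: VOI roles understood by the dosimetry layer
ROLES = ("lesion", "liver", "background", "sphere_insert", "body")


def _as_triplet(x) -> tuple[float, float, float]:
    arr = np.broadcast_to(np.asarray(x, dtype=float), (3,))
    return (float(arr[0]), float(arr[1]), float(arr[2]))


@dataclass
class ImageGrid:
    """A 3D scalar image on a regular grid with physical spacing.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Voxel values. Interpreted according to ``units``.
    spacing_mm : 3 floats
        Strictly positive voxel edge lengths in mm.
    origin_mm : 3 floats
        World coordinate of the corner of voxel (0, 0, 0).
    modality : str
        One of ``truth | spect_like | pet_like | suv``.
    units : str
        ``kBq/mL`` for activity concentration, ``Gy`` for dose,
        ``g/mL`` for SUV, or ``arbitrary``.
    """

    values: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    modality: str = "truth"
    units: str = "arbitrary"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3D grid, got ndim={self.values.ndim}")
        self.spacing_mm = _as_triplet(self.spacing_mm)
        self.origin_mm = _as_triplet(self.origin_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing_mm}")
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("grid contains non-finite values")
        if self.units == "kBq/mL" and np.any(self.values < 0):
            raise ValueError("activity concentration grid has negative values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mL(self) -> float:
        """Volume of one voxel in mL (1 mL = 1000 mm^3)."""
        return float(np.prod(self.spacing_mm)) / 1000.0

    def axis_centers_mm(self, axis: int) -> np.ndarray:
        """World coordinates of voxel centers along ``axis``."""
        n = self.values.shape[axis]
        return self.origin_mm[axis] + (np.arange(n) + 0.5) * self.spacing_mm[axis]

    def with_values(self, values: np.ndarray, *, modality: str | None = None,
                    units: str | None = None) -> "ImageGrid":
        """New grid on the same lattice with different values."""
        return replace(self, values=values,
                       modality=self.modality if modality is None else modality,
                       units=self.units if units is None else units)

    # -- NIfTI round trip ---------------------------------------------------
    def _affine(self) -> np.ndarray:
        aff = np.diag(list(self.spacing_mm) + [1.0])
        aff[:3, 3] = np.asarray(self.origin_mm) + 0.5 * np.asarray(self.spacing_mm)
        return aff

    def to_nifti(self, path: str | Path) -> Path:
        path = Path(path)
        img = nib.Nifti1Image(self.values, affine=self._affine())
        img.header.set_zooms(self.spacing_mm)
        nib.save(img, path)
        return path

    @classmethod
    def from_nifti(cls, path: str | Path, *, modality: str = "truth",
                   units: str = "arbitrary") -> "ImageGrid":
        img = nib.load(str(path))
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        origin = tuple(np.asarray(img.affine[:3, 3], dtype=float)
                       - 0.5 * np.asarray(spacing))
        return cls(np.asarray(img.dataobj, dtype=np.float64), spacing,
                   origin, modality=modality, units=units)


@dataclass
class VOILabel:
    """Metadata for one label id in a :class:`VOISet`."""

    name: str
    role: str
    diameter_mm: float | None = None

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown VOI role {self.role!r}")


@dataclass
class VOISet:
    """Integer label map plus label metadata, aligned with an :class:`ImageGrid`."""

    label_map: np.ndarray
    spacing_mm: tuple[float, float, float]
    labels: dict[int, VOILabel] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.label_map = np.asarray(self.label_map)
        if self.label_map.ndim != 3:
            raise ValueError("label map must be 3D")
        if not np.issubdtype(self.label_map.dtype, np.integer):
            self.label_map = self.label_map.astype(np.int32)
        self.spacing_mm = _as_triplet(self.spacing_mm)
        if self.label_map.min() < 0:
            raise ValueError("label ids must be non-negative")
        present = set(np.unique(self.label_map).tolist())
        missing = present - set(self.labels)
        if missing:
            raise ValueError(f"label ids {sorted(missing)} missing from label table")

    @property
    def voxel_volume_mL(self) -> float:
        return float(np.prod(self.spacing_mm)) / 1000.0

    def mask(self, label_id: int) -> np.ndarray:
        return self.label_map == label_id

    def volume_mL(self, label_id: int) -> float:
        return float(np.count_nonzero(self.label_map == label_id)) * self.voxel_volume_mL

    def ids_by_role(self, role: str) -> list[int]:
        return sorted(i for i, lab in self.labels.items() if lab.role == role)

    def check_alignment(self, grid: ImageGrid) -> None:
        if grid.values.shape != self.label_map.shape:
            raise ValueError("grid and label map shapes differ")
        if not np.allclose(grid.spacing_mm, self.spacing_mm):
            raise ValueError("grid and label map spacings differ")

    # -- I/O: NIfTI label map + JSON sidecar for the label table ------------
    def to_nifti(self, path: str | Path) -> Path:
        path = Path(path)
        aff = np.diag(list(self.spacing_mm) + [1.0])
        nib.save(nib.Nifti1Image(self.label_map.astype(np.int16), aff), path)
        sidecar = {str(i): {"name": lab.name, "role": lab.role,
                            "diameter_mm": lab.diameter_mm}
                   for i, lab in self.labels.items()}
        _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
        return path

    @classmethod
    def from_nifti(cls, path: str | Path) -> "VOISet":
        path = Path(path)
        img = nib.load(str(path))
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        labels: dict[int, VOILabel] = {}
        sidecar = _sidecar_path(path)
        if sidecar.exists():
            for key, meta in json.loads(sidecar.read_text()).items():
                labels[int(key)] = VOILabel(meta["name"], meta["role"],
                                            meta.get("diameter_mm"))
        else:
            for i in np.unique(np.asarray(img.dataobj)).astype(int):
                labels[int(i)] = VOILabel(f"label_{i}", "background")
        return cls(np.asarray(img.dataobj).astype(np.int32), spacing, labels)


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".labels.json")
    return path.with_suffix(".labels.json")
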