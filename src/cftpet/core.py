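"""Shared containers and conventions.

Conventions used throughout the package:

* World coordinates are millimetres in RAS orientation (+X right, +Y
  anterior, +Z superior).  "Anterior" always means the +Y direction.
* Voxel indexing is 0-based; the affine maps voxel indices to world mm.
* All randomness flows from a single global seed through named
  substreams (see :func:`derive_seed`).
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

# ---------------------------------------------------------------------------
# Region coding
# ---------------------------------------------------------------------------

#: Anatomical ROI codes shared by every label map in the package.
#: 0 is background.  L/R refer to the subject's left/right (RAS: +X = right).
REGION_CODES: dict[int, tuple[str, str]] = {
    1: ("caudate", "L"),
    2: ("caudate", "R"),
    3: ("putamen", "L"),
    4: ("putamen", "R"),
    5: ("pallidum", "L"),
    6: ("pallidum", "R"),
    7: ("midbrain", "L"),
    8: ("midbrain", "R"),
    9: ("occipital", "L"),
    10: ("occipital", "R"),
}

#: Subregion codes: caudate and putamen split into anterior/middle/posterior
#: thirds; pallidum, midbrain and the occipital reference pass through.
SUBREGION_CODES: dict[int, tuple[str, str]] = {
    1: ("anterior_caudate", "L"),
    2: ("anterior_caudate", "R"),
    3: ("middle_caudate", "L"),
    4: ("middle_caudate", "R"),
    5: ("posterior_caudate", "L"),
    6: ("posterior_caudate", "R"),
    7: ("anterior_putamen", "L"),
    8: ("anterior_putamen", "R"),
    9: ("middle_putamen", "L"),
    10: ("middle_putamen", "R"),
    11: ("posterior_putamen", "L"),
    12: ("posterior_putamen", "R"),
    13: ("pallidum", "L"),
    14: ("pallidum", "R"),
    15: ("midbrain", "L"),
    16: ("midbrain", "R"),
    17: ("occipital", "L"),
    18: ("occipital", "R"),
}

#: The 14 striatal feature names in their fixed column order.
STRIATAL_FEATURES: tuple[str, ...] = tuple(
    f"{name}_{side}" for code, (name, side) in SUBREGION_CODES.items() if code <= 14
)
#: Midbrain feature names (the optional 2-feature add-on).
MIDBRAIN_FEATURES: tuple[str, ...] = ("midbrain_L", "midbrain_R")

#: Subregion pairs that carry a bilateral asymmetry index.
ASYMMETRY_SUBREGIONS: tuple[str, ...] = (
    "anterior_caudate",
    "middle_caudate",
    "posterior_caudate",
    "anterior_putamen",
    "middle_putamen",
    "posterior_putamen",
)

DIAGNOSES = ("PD", "MSA", "PSP")
GROUPS = ("PD", "MSA", "PSP", "NC")
STAGES = ("ES", "AS")


def subregion_code(name: str, side: str) -> int:
    for code, (n, s) in SUBREGION_CODES.items():
        if n == name and s == side:
            return code
    raise KeyError(f"unknown subregion {name}_{side}")


# ---------------------------------------------------------------------------
# Volumes
# ---------------------------------------------------------------------------


@dataclass
class VolumeImage:
    """A 3D scalar grid with a voxel-to-world (RAS mm) affine."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("VolumeImage data must be 3D")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def spacing(self) -> np.ndarray:
        """Voxel spacing (mm) per axis."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        """Map Nx3 voxel indices to Nx3 world mm coordinates."""
        ijk = np.atleast_2d(ijk).astype(float)
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.atleast_2d(xyz).astype(float)
        inv = np.linalg.inv(self.affine)
        return xyz @ inv[:3, :3].T + inv[:3, 3]

    def same_grid(self, other: "VolumeImage", tol: float = 1e-4) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=tol
        )


@dataclass
class LabelMap:
    """Integer-coded ROI volume sharing a :class:`VolumeImage` grid."""

    grid: np.ndarray
    affine: np.ndarray
    code_table: dict[int, tuple[str, str]] = field(
        default_factory=lambda: dict(REGION_CODES)
    )

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        self.affine = np.asarray(self.affine, dtype=float)
        if not np.issubdtype(self.grid.dtype, np.integer):
            self.grid = np.rint(self.grid).astype(np.int16)
        extra = set(np.unique(self.grid)) - set(self.code_table) - {0}
        if extra:
            raise ValueError(f"grid contains codes absent from code_table: {extra}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape  # type: ignore[return-value]

    def mask(self, code: int) -> np.ndarray:
        return self.grid == code

    def code_of(self, name: str, side: str) -> int:
        for code, (n, s) in self.code_table.items():
            if n == name and s == side:
                return code
        raise KeyError(f"unknown region {name}_{side}")

    def present_codes(self) -> set[int]:
        return set(np.unique(self.grid)) - {0}

    def as_volume(self) -> VolumeImage:
        return VolumeImage(self.grid.astype(np.float32), self.affine)


def centered_affine(shape: tuple[int, int, int], voxel_size_mm: float) -> np.ndarray:
    """RAS affine with isotropic spacing and the grid centred on the origin."""
    aff = np.eye(4)
    aff[:3, :3] = np.eye(3) * voxel_size_mm
    aff[:3, 3] = -(np.asarray(shape) - 1) / 2.0 * voxel_size_mm
    return aff


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------


def save_volume(vol: VolumeImage, path) -> None:
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=np.float32), vol.affine)
    nib.save(img, str(path))


def load_volume(path) -> VolumeImage:
    img = nib.load(str(path))
    return VolumeImage(np.asarray(img.dataobj, dtype=np.float32), img.affine)


def save_labels(labels: LabelMap, path, sidecar: bool = True) -> None:
    img = nib.Nifti1Image(labels.grid.astype(np.int16), labels.affine)
    nib.save(img, str(path))
    if sidecar:
        import json
        from pathlib import Path

        side = Path(str(path).replace(".nii.gz", "").replace(".nii", "") + ".json")
        side.write_text(
            json.dumps({str(k): list(v) for k, v in labels.code_table.items()})
        )


def load_labels(path, code_table: dict[int, tuple[str, str]] | None = None) -> LabelMap:
    import json
    from pathlib import Path

    img = nib.load(str(path))
    if code_table is None:
        side = Path(str(path).replace(".nii.gz", "").replace(".nii", "") + ".json")
        if side.exists():
            raw = json.loads(side.read_text())
            code_table = {int(k): (v[0], v[1]) for k, v in raw.items()}
        else:
            code_table = dict(REGION_CODES)
    return LabelMap(
        np.asarray(img.dataobj).astype(np.int16), img.affine, code_table
    )


def check_paired_grids(a: VolumeImage, b: VolumeImage, what: str = "volumes",
                       tol: float = 1e-3) -> None:
    """Fail loudly on orientation/affine mismatch between paired volumes."""
    if a.shape != b.shape or not np.allclose(a.affine, b.affine, atol=tol):
        raise ValueError(
            f"paired {what} disagree in grid/affine; no silent reorientation is "
            f"performed (shapes {a.shape} vs {b.shape})"
        )


# ---------------------------------------------------------------------------
# Seeding
# ---------------------------------------------------------------------------


def derive_seed(global_seed: int, *names) -> int:
    """Derive a per-stage / per-subject seed below 2**31.

    Hashing (seed, stage, subject) means inserting or removing one subject
    does not perturb any other subject's draws.
    """
    key = ":".join([str(int(global_seed))] + [str(n) for n in names])
    digest = hashlib.sha256(key.encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


def warn(msg: str) -> None:
    warnings.warn(msg, stacklevel=3)
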