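"""Rigid multimodal registration and label propagation.

The anatomical volume is aligned to the PET volume with a rigid transform
(Mattes mutual information, 3-level multiresolution, regular gradient
descent) and the resulting transform carries the ROI labels onto the PET
grid by nearest-neighbour interpolation.  PET intensities are never
resampled: features are always read on the native PET grid.

Transforms are stored fixed<-moving: :meth:`RigidTransform.apply` maps
points from moving-world to fixed-world coordinates (RAS mm).  SimpleITK
works in LPS internally; the conversion is handled here and never leaks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import SimpleITK as sitk
from scipy.ndimage import map_coordinates
from scipy.spatial.transform import Rotation

from .core import LabelMap, VolumeImage, warn

__all__ = ["RigidTransform", "register_rigid", "resample_labels"]

_FLIP = np.diag([-1.0, -1.0, 1.0])  # RAS <-> LPS


@dataclass
class RigidTransform:
    """Rigid map from moving-world to fixed-world RAS mm coordinates.

    ``rotation`` holds extrinsic x-y-z Euler angles (radians); the rotation
    is applied about ``center``.
    """

    rotation: tuple[float, float, float]
    translation: tuple[float, float, float]
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    converged: bool = True

    @property
    def matrix(self) -> np.ndarray:
        """Homogeneous 4x4 matrix realizing the map."""
        R = Rotation.from_euler("xyz", self.rotation).as_matrix()
        c = np.asarray(self.center)
        t = np.asarray(self.translation)
        m = np.eye(4)
        m[:3, :3] = R
        m[:3, 3] = c - R @ c + t
        return m

    @classmethod
    def from_matrix(
        cls, m: np.ndarray, center=(0.0, 0.0, 0.0), converged: bool = True
    ) -> "RigidTransform":
        R = np.asarray(m)[:3, :3]
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-6):
            raise ValueError("matrix is not a proper rotation")
        angles = Rotation.from_matrix(R).as_euler("xyz")
        c = np.asarray(center, dtype=float)
        t = np.asarray(m)[:3, 3] - (c - R @ c)
        return cls(tuple(angles), tuple(t), tuple(c), converged)

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(points)
        m = self.matrix
        return pts @ m[:3, :3].T + m[:3, 3]

    def inverse(self) -> "RigidTransform":
        return RigidTransform.from_matrix(
            np.linalg.inv(self.matrix), self.center, self.converged
        )

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls((0.0, 0.0, 0.0), (0.0, 0.0, 0.0))

    def save_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "convention": "fixed<-moving, RAS mm, extrinsic xyz Euler",
                    "rotation_rad": list(self.rotation),
                    "translation_mm": list(self.translation),
                    "center_mm": list(self.center),
                    "converged": bool(self.converged),
                },
                indent=2,
            )
        )

    @classmethod
    def load_json(cls, path) -> "RigidTransform":
        raw = json.loads(Path(path).read_text())
        return cls(
            tuple(raw["rotation_rad"]),
            tuple(raw["translation_mm"]),
            tuple(raw["center_mm"]),
            raw.get("converged", True),
        )


# ---------------------------------------------------------------------------
# SimpleITK bridge
# ---------------------------------------------------------------------------


def _to_sitk(vol: VolumeImage) -> sitk.Image:
    """Convert a RAS VolumeImage to a SimpleITK (LPS) image."""
    img = sitk.GetImageFromArray(
        np.ascontiguousarray(np.transpose(np.asarray(vol.data, dtype=np.float64), (2, 1, 0)))
    )
    A = vol.affine[:3, :3]
    spacing = np.linalg.norm(A, axis=0)
    direction_ras = A / spacing
    direction_lps = _FLIP @ direction_ras
    origin_lps = _FLIP @ vol.affine[:3, 3]
    img.SetSpacing(tuple(spacing))
    img.SetDirection(tuple(direction_lps.ravel()))
    img.SetOrigin(tuple(origin_lps))
    return img


def register_rigid(
    moving: VolumeImage,
    fixed: VolumeImage,
    config: dict | None = None,
) -> RigidTransform:
    """Estimate the rigid transform aligning ``moving`` onto ``fixed``.

    Mutual-information metric (Mattes, 48 bins) over a 3-level pyramid,
    full dense sampling for determinism.  Returns the best transform found
    with ``converged=False`` if the optimizer hit its iteration cap.
    """
    config = config or {}
    for name, vol in (("moving", moving), ("fixed", fixed)):
        arr = np.asarray(vol.data)
        if not np.isfinite(arr).all() or arr.max() == arr.min():
            raise ValueError(f"{name} volume is constant or non-finite; cannot register")

    # byte-identical volumes on the same grid are already aligned; MI has a
    # noisy gradient at the exact-overlap point, so short-circuit to identity
    if moving.same_grid(fixed) and np.array_equal(
        np.asarray(moving.data), np.asarray(fixed.data)
    ):
        return RigidTransform.identity()

    f_img, m_img = _to_sitk(fixed), _to_sitk(moving)

    init = sitk.CenteredTransformInitializer(
        f_img,
        m_img,
        sitk.Euler3DTransform(),
        sitk.CenteredTransformInitializerFilter.GEOMETRY,
    )

    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMattesMutualInformation(
        numberOfHistogramBins=int(config.get("histogram_bins", 48))
    )
    reg.SetMetricSamplingStrategy(reg.NONE)  # dense sampling: deterministic
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=float(config.get("learning_rate", 0.5)),
        minStep=float(config.get("min_step", 1e-5)),
        numberOfIterations=int(config.get("max_iterations", 300)),
        relaxationFactor=0.5,
        gradientMagnitudeTolerance=1e-6,
    )
    reg.SetOptimizerScalesFromPhysicalShift()
    # keep the coarsest pyramid level at >= 16 voxels per axis: coarser
    # levels of small volumes create spurious MI basins
    min_dim = min(moving.shape + fixed.shape)
    shrink = [s for s in (4, 2, 1) if min_dim // s >= 16] or [1]
    reg.SetShrinkFactorsPerLevel(shrink)
    reg.SetSmoothingSigmasPerLevel([s / 2.0 if s > 1 else 0.0 for s in shrink])
    reg.SmoothingSigmasAreSpecifiedInPhysicalUnitsOn()
    reg.SetInitialTransform(init, inPlace=True)

    final = reg.Execute(f_img, m_img)
    stop = reg.GetOptimizerStopConditionDescription()
    converged = "Maximum number of iterations" not in stop
    if not converged:
        warn(f"rigid registration did not converge: {stop}; returning best-so-far")

    euler = sitk.Euler3DTransform(final)
    # sitk transform maps fixed-LPS points to moving-LPS points (resampling
    # convention); our stored transform maps moving-world -> fixed-world RAS.
    R_lps = np.asarray(euler.GetMatrix()).reshape(3, 3)
    c_lps = np.asarray(euler.GetCenter())
    t_lps = np.asarray(euler.GetTranslation())
    M_lps = np.eye(4)
    M_lps[:3, :3] = R_lps
    M_lps[:3, 3] = c_lps - R_lps @ c_lps + t_lps
    F4 = np.eye(4)
    F4[:3, :3] = _FLIP
    M_ras_fixed_to_moving = F4 @ M_lps @ F4
    M = np.linalg.inv(M_ras_fixed_to_moving)
    return RigidTransform.from_matrix(M, center=tuple(_FLIP @ c_lps), converged=converged)


def resample_labels(
    labels: LabelMap, transform: RigidTransform, target_grid: VolumeImage | LabelMap
) -> LabelMap:
    """Carry a label map through a rigid transform onto a target grid.

    Nearest-neighbour interpolation (labels are categorical); the code
    table is preserved and no new codes can appear.  Regions that vanish
    entirely are flagged with a warning.
    """
    tgt_aff = np.asarray(target_grid.affine, dtype=float)
    tgt_shape = target_grid.shape

    ii, jj, kk = np.meshgrid(*[np.arange(n) for n in tgt_shape], indexing="ij")
    idx = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3).astype(float)
    world_fixed = idx @ tgt_aff[:3, :3].T + tgt_aff[:3, 3]
    world_moving = transform.inverse().apply(world_fixed)
    inv = np.linalg.inv(labels.affine)
    src_idx = world_moving @ inv[:3, :3].T + inv[:3, 3]

    out = map_coordinates(
        labels.grid.astype(np.float32),
        src_idx.T,
        order=0,
        mode="constant",
        cval=0.0,
    )
    out = np.rint(out).astype(np.int16).reshape(tgt_shape)

    result = LabelMap(out, tgt_aff, dict(labels.code_table))
    for code in labels.present_codes():
        if code not in result.present_codes():
            name, side = labels.code_table[code]
            warn(f"region {name}_{side} vanished during label resampling")
    return result
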