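"""Synthetic paired MRI/PET phantoms with parkinsonian uptake structure.

The generator emulates the statistical structure the downstream classifier
assumes: per-group subregional striatal-to-occipital ratios (SOR) with
bilateral asymmetry.  Each subject is a pair of 3D volumes on a shared RAS
grid:

* an "MRI" whose regions carry distinct intensity bands (region code x a
  fixed step plus Gaussian noise) so a segmenter can learn them, and
* a "PET" whose mean uptake in subregion *s* is
  ``occipital_uptake * (1 + SOR_s)``, with SOR_s drawn per subject from the
  group profile.

Asymmetry realization: a drawn level ``s`` and asymmetry index ``a`` give
side SORs ``s*(1 + a/2)`` and ``s*(1 - a/2)``; which hemisphere gets the
higher side is a fair coin from the subject RNG.  The subregional uptake
gradient is piecewise-constant over the three anatomical thirds of each
caudate/putamen, defined by the same balanced tripartition used at feature
extraction, so a noise-free phantom round-trips its planted values exactly.

Default group profiles carry the published cohort means/SDs for the six
caudate/putamen subregions; pallidum and midbrain levels (for which no
group table exists) are package defaults with midbrain kept nearly
group-invariant.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .core import (
    ASYMMETRY_SUBREGIONS,
    GROUPS,
    LabelMap,
    REGION_CODES,
    VolumeImage,
    centered_affine,
    derive_seed,
    save_labels,
    save_volume,
    warn,
)
from .subregions import build_subregion_map

__all__ = [
    "PhantomSpec",
    "GroupProfile",
    "CohortManifest",
    "default_spec",
    "default_profiles",
    "generate_subject",
    "planted_values",
    "generate_cohort",
]

_SOR_FLOOR = -1.0 + 0.01  # tracer concentration must stay nonnegative

#: Default ellipsoid geometry (world mm, RAS, grid centred on the origin).
#: Mirror pairs share |x|; anterior is +Y.
_DEFAULT_GEOMETRY: dict[str, tuple[tuple[float, float, float], tuple[float, float, float]]] = {
    "caudate": ((10.0, 12.0, 8.0), (5.0, 16.0, 6.0)),
    "putamen": ((22.0, 2.0, 2.0), (6.0, 18.0, 7.0)),
    "pallidum": ((12.0, 0.0, 0.0), (4.0, 6.0, 5.0)),
    "midbrain": ((4.0, -14.0, -14.0), (4.0, 7.0, 8.0)),
    "occipital": ((16.0, -38.0, 0.0), (10.0, 12.0, 16.0)),
}


@dataclass
class PhantomSpec:
    """Geometry and acquisition parameters for one phantom."""

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size_mm: float = 2.0
    #: region name -> ((|x|, y, z) centre, (ax, ay, az) semi-axes), mm.
    #: The left/right pair is produced by mirroring the centre about x=0.
    roi_geometry: dict = field(default_factory=lambda: dict(_DEFAULT_GEOMETRY))
    background_uptake: float = 0.3
    occipital_uptake: float = 1.0
    noise_sd: float = 0.05
    mri_step: float = 10.0
    mri_noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.occipital_uptake <= 0:
            raise ValueError("occipital_uptake must be positive")
        if self.background_uptake < 0 or self.noise_sd < 0:
            raise ValueError("background_uptake and noise_sd must be nonnegative")
        half = np.asarray(self.grid_shape) * self.voxel_size_mm / 2.0
        for name, (center, axes) in self.roi_geometry.items():
            c, a = np.abs(np.asarray(center)), np.asarray(axes)
            if np.any(c + a > half):
                raise ValueError(f"ellipsoid {name} extends outside the grid")

    @property
    def affine(self) -> np.ndarray:
        return centered_affine(tuple(self.grid_shape), self.voxel_size_mm)

    @classmethod
    def from_yaml(cls, path) -> "PhantomSpec":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "grid_shape" in raw:
            raw["grid_shape"] = tuple(raw["grid_shape"])
        if "roi_geometry" in raw:
            raw["roi_geometry"] = {
                k: (tuple(v[0]), tuple(v[1])) for k, v in raw["roi_geometry"].items()
            }
        return cls(**raw)


@dataclass
class GroupProfile:
    """Per-group subregional SOR and asymmetry distribution parameters."""

    group: str
    sor_mean: dict[str, float]
    sor_sd: dict[str, float]
    asym_mean: dict[str, float]
    asym_sd: dict[str, float]

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group}")
        for k, v in self.sor_mean.items():
            if v <= -1:
                raise ValueError(f"sor_mean[{k}] must exceed -1")
        for k, v in self.asym_mean.items():
            if not 0 <= v <= 2:
                raise ValueError(f"asym_mean[{k}] must lie in [0, 2]")


# Published cohort subregional SOR means/SDs (PD, MSA, PSP, NC) and
# asymmetry indexes; pallidum/midbrain rows are package defaults.
_SOR_TABLE = {
    "anterior_caudate": ((0.90, 0.53), (1.02, 0.83), (0.58, 0.40), (1.65, 0.65)),
    "middle_caudate": ((0.52, 0.44), (0.62, 0.59), (0.25, 0.22), (1.26, 0.77)),
    "posterior_caudate": ((0.25, 0.25), (0.32, 0.36), (0.14, 0.13), (0.70, 0.55)),
    "anterior_putamen": ((1.13, 0.48), (1.26, 0.88), (1.03, 0.37), (2.25, 0.74)),
    "middle_putamen": ((0.65, 0.34), (1.06, 0.93), (0.67, 0.29), (1.98, 0.91)),
    "posterior_putamen": ((0.46, 0.30), (0.77, 0.86), (0.55, 0.29), (1.50, 0.88)),
    "pallidum": ((0.40, 0.30), (0.55, 0.35), (0.45, 0.30), (0.90, 0.40)),
    "midbrain": ((0.35, 0.25), (0.33, 0.25), (0.30, 0.25), (0.55, 0.30)),
}
_AI_TABLE = {
    "anterior_caudate": ((1.06, 0.84), (1.00, 0.71), (0.97, 0.71), (0.74, 0.66)),
    "middle_caudate": ((1.28, 0.90), (1.50, 0.91), (1.57, 0.83), (0.89, 0.82)),
    "posterior_caudate": ((1.41, 0.72), (1.78, 0.86), (1.54, 0.71), (1.24, 0.84)),
    "anterior_putamen": ((0.63, 0.38), (0.40, 0.41), (0.31, 0.22), (0.25, 0.23)),
    "middle_putamen": ((0.76, 0.50), (0.45, 0.47), (0.39, 0.40), (0.29, 0.28)),
    "posterior_putamen": ((0.67, 0.55), (0.59, 0.44), (0.52, 0.56), (0.45, 0.36)),
}


def default_profiles() -> dict[str, GroupProfile]:
    """Group profiles seeded from the published cohort table."""
    out = {}
    for gi, group in enumerate(GROUPS):
        out[group] = GroupProfile(
            group=group,
            sor_mean={k: v[gi][0] for k, v in _SOR_TABLE.items()},
            sor_sd={k: v[gi][1] for k, v in _SOR_TABLE.items()},
            asym_mean={k: v[gi][0] for k, v in _AI_TABLE.items()},
            asym_sd={k: v[gi][1] for k, v in _AI_TABLE.items()},
        )
    return out


def default_spec(grid: int = 64, **overrides) -> PhantomSpec:
    """Default phantom spec on a ``grid^3`` lattice covering a 128 mm FOV."""
    voxel = 128.0 / grid
    return PhantomSpec(grid_shape=(grid, grid, grid), voxel_size_mm=voxel, **overrides)


# ---------------------------------------------------------------------------
# Geometry rasterization
# ---------------------------------------------------------------------------


def build_truth_labels(spec: PhantomSpec) -> LabelMap:
    """Rasterize the ellipsoid geometry into the 10-region label map."""
    shape = tuple(spec.grid_shape)
    aff = spec.affine
    ii, jj, kk = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    xyz = np.stack([ii, jj, kk], axis=-1) @ aff[:3, :3].T + aff[:3, 3]

    grid = np.zeros(shape, dtype=np.int16)
    for code, (name, side) in REGION_CODES.items():
        center, axes = spec.roi_geometry[name]
        c = np.asarray(center, dtype=float)
        if side == "L":
            c = c * np.array([-1.0, 1.0, 1.0])
        d = (xyz - c) / np.asarray(axes, dtype=float)
        mask = np.sum(d * d, axis=-1) < 1.0
        if np.any(grid[mask] != 0):
            raise ValueError(f"ellipsoid {name}_{side} overlaps another region")
        grid[mask] = code
    return LabelMap(grid, aff, dict(REGION_CODES))


# ---------------------------------------------------------------------------
# Subject generation
# ---------------------------------------------------------------------------


def _truncated_normal(rng, mean, sd, lo, hi=np.inf, what=""):
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo < x < hi:
            return x
    warn(f"truncated draw for {what} fell back to the bound")
    return float(np.clip(mean, lo + 1e-6, hi - 1e-6))


def _draw_subject(profile: GroupProfile, rng: np.random.Generator):
    """Draw per-side SORs and asymmetry indexes for one subject.

    Returns (side_sor: dict 'name_side' -> SOR, planted_ai: dict name -> AI).
    Asymmetry is only realizable when the drawn level is positive; for
    near-zero levels the sides are left symmetric and AI = 0 is recorded.
    """
    side_sor: dict[str, float] = {}
    planted_ai: dict[str, float] = {}
    for name in ASYMMETRY_SUBREGIONS:
        level = _truncated_normal(
            rng, profile.sor_mean[name], profile.sor_sd[name], _SOR_FLOOR, what=name
        )
        a = float(
            np.clip(rng.normal(profile.asym_mean[name], profile.asym_sd[name]), 0.0, 2.0)
        )
        left_high = bool(rng.integers(0, 2))
        if level > 0.02:
            hi, lo = level * (1 + a / 2), level * (1 - a / 2)
            planted_ai[name] = a
        else:
            hi = lo = level
            planted_ai[name] = 0.0
        side_sor[f"{name}_L"] = hi if left_high else lo
        side_sor[f"{name}_R"] = lo if left_high else hi
    for name in ("pallidum", "midbrain"):
        level = _truncated_normal(
            rng, profile.sor_mean[name], profile.sor_sd[name], _SOR_FLOOR, what=name
        )
        side_sor[f"{name}_L"] = side_sor[f"{name}_R"] = level
    return side_sor, planted_ai


def planted_values(
    spec: PhantomSpec, profile: GroupProfile, subject_seed: int
) -> tuple[dict[str, float], dict[str, float]]:
    """Reproduce the exact per-side SORs / AIs a subject seed generates."""
    rng = np.random.default_rng(int(subject_seed))
    return _draw_subject(profile, rng)


# geometry is identical across a cohort; cache the rasterized truth/submap
_GEOMETRY_CACHE: dict[str, tuple[LabelMap, LabelMap]] = {}


def _truth_and_submap(spec: PhantomSpec) -> tuple[LabelMap, LabelMap]:
    key = repr((spec.grid_shape, spec.voxel_size_mm, sorted(spec.roi_geometry.items())))
    if key not in _GEOMETRY_CACHE:
        truth = build_truth_labels(spec)
        _GEOMETRY_CACHE[key] = (truth, build_subregion_map(truth, seed=0))
        if len(_GEOMETRY_CACHE) > 8:
            _GEOMETRY_CACHE.pop(next(iter(_GEOMETRY_CACHE)))
    return _GEOMETRY_CACHE[key]


def generate_subject(
    spec: PhantomSpec, profile: GroupProfile, subject_seed: int
) -> tuple[VolumeImage, VolumeImage, LabelMap]:
    """Generate one (MRI, PET, truth-labels) phantom triple.

    Deterministic given ``subject_seed``: two calls with the same seed
    yield bit-identical volumes.
    """
    rng = np.random.default_rng(int(subject_seed))
    side_sor, _ = _draw_subject(profile, rng)

    truth, submap = _truth_and_submap(spec)

    pet = np.full(truth.shape, spec.background_uptake, dtype=np.float64)
    for code, (name, side) in submap.code_table.items():
        mask = submap.grid == code
        if name == "occipital":
            pet[mask] = spec.occipital_uptake
        else:
            pet[mask] = spec.occipital_uptake * (1.0 + side_sor[f"{name}_{side}"])

    mri = truth.grid.astype(np.float64) * spec.mri_step
    if spec.mri_noise_sd > 0:
        mri = mri + rng.normal(0.0, spec.mri_noise_sd, size=truth.shape)
    if spec.noise_sd > 0:
        pet = pet + rng.normal(0.0, spec.noise_sd, size=truth.shape)

    aff = spec.affine
    return (
        VolumeImage(mri.astype(np.float32), aff),
        VolumeImage(pet.astype(np.float32), aff),
        truth,
    )


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

#: Published cohort sizes and early-stage fractions.
DEFAULT_N_PER_GROUP = {"PD": 50, "MSA": 37, "PSP": 20, "NC": 22}
DEFAULT_ES_FRACTIONS = {"PD": 0.22, "MSA": 0.459, "PSP": 0.40}


@dataclass
class CohortManifest:
    """Rows of (subject_id, group, stage, mri_path, pet_path, labels_path, seed)."""

    rows: list[dict]

    HEADER = ("subject_id", "group", "stage", "mri_path", "pet_path", "labels_path", "seed")

    def __post_init__(self) -> None:
        ids = [r["subject_id"] for r in self.rows]
        if len(ids) != len(set(ids)):
            raise ValueError("subject_ids must be unique")

    def __len__(self) -> int:
        return len(self.rows)

    def write_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.DictWriter(fh, fieldnames=self.HEADER)
            w.writeheader()
            for r in self.rows:
                w.writerow({k: r[k] for k in self.HEADER})

    @classmethod
    def read_csv(cls, path) -> "CohortManifest":
        with open(path, newline="") as fh:
            rows = [dict(r) for r in csv.DictReader(fh)]
        for r in rows:
            r["seed"] = int(r["seed"])
        return cls(rows)


def _assign_stages(group: str, n: int, fraction: float | None, rng) -> list[str]:
    """Exact-count early/advanced stage assignment via a seeded permutation."""
    if fraction is None:
        return ["NA"] * n
    n_es = int(round(fraction * n))
    stages = np.array(["ES"] * n_es + ["AS"] * (n - n_es))
    rng.shuffle(stages)
    return list(stages)


def generate_cohort(
    out_dir,
    spec: PhantomSpec | None = None,
    profiles: dict[str, GroupProfile] | None = None,
    n_per_group: dict[str, int] | None = None,
    stage_fractions: dict[str, float] | None = None,
    seed: int = 0,
    write_volumes: bool = True,
) -> CohortManifest:
    """Generate a phantom cohort and write volumes + manifest CSV.

    Stage labels use exact per-group early-stage counts (round(fraction*n))
    assigned by a seeded permutation, so the default cohort reproduces the
    published ES/AS composition exactly.
    """
    spec = spec or default_spec()
    profiles = profiles or default_profiles()
    n_per_group = n_per_group or dict(DEFAULT_N_PER_GROUP)
    stage_fractions = (
        dict(DEFAULT_ES_FRACTIONS) if stage_fractions is None else stage_fractions
    )
    if any(n <= 0 for n in n_per_group.values()):
        raise ValueError("n_per_group entries must be positive")

    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:  # pragma: no cover - filesystem dependent
        raise OSError(f"output directory {out} is not writable: {exc}") from exc

    rows = []
    for group in sorted(n_per_group):
        n = n_per_group[group]
        stage_rng = np.random.default_rng(derive_seed(seed, "stage", group))
        stages = _assign_stages(group, n, stage_fractions.get(group), stage_rng)
        for i in range(n):
            sid = f"{group}{i:03d}"
            sseed = derive_seed(seed, "subject", sid)
            row = {
                "subject_id": sid,
                "group": group,
                "stage": stages[i],
                "mri_path": str(out / f"{sid}_mri.nii.gz"),
                "pet_path": str(out / f"{sid}_pet.nii.gz"),
                "labels_path": str(out / f"{sid}_labels.nii.gz"),
                "seed": sseed,
            }
            if write_volumes:
                mri, pet, truth = generate_subject(spec, profiles[group], sseed)
                save_volume(mri, row["mri_path"])
                save_volume(pet, row["pet_path"])
                save_labels(truth, row["labels_path"])
            rows.append(row)

    manifest = CohortManifest(rows)
    manifest.write_csv(out / "manifest.csv")
    return manifest
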