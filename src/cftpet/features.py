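"""SOR feature extraction and bilateral asymmetry indexes.

The striatal-to-occipital ratio (SOR) normalizes regional tracer uptake to
the occipital cortex, a region with negligible specific dopamine-
transporter binding.  The default formula is the specific binding ratio

    SOR = (mean ROI uptake - mean occipital uptake) / mean occipital uptake

with both occipital sides pooled into one reference.  A ``plain_ratio``
variant (ROI / occipital) is available via the ``sor_formula`` config key.

The asymmetry index of a left/right subregion pair is

    AI = (SOR_high - SOR_low) / mean(SOR_left, SOR_right),

zero for perfectly symmetric uptake and 2 at the boundary where one side
has no specific binding at all (both sides nonnegative).

Feature sets: ``striatum`` (14 SORs: 12 caudate/putamen subregions +
pallidum L/R), ``midbrain`` (2 SORs), ``striatum+midbrain`` (16 SORs).
Asymmetry indexes are computed for the six caudate/putamen subregion
pairs; whether they join the classifier's feature vector is a config
switch (``include_asymmetry``, default off).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    ASYMMETRY_SUBREGIONS,
    LabelMap,
    MIDBRAIN_FEATURES,
    STRIATAL_FEATURES,
    VolumeImage,
    subregion_code,
    warn,
)

__all__ = [
    "SubjectFeatures",
    "compute_sor",
    "compute_asymmetry",
    "extract_subject",
    "cohort_feature_table",
    "feature_columns",
    "group_summary",
    "write_feature_table",
    "read_feature_table",
]

def write_feature_table(table: pd.DataFrame, path) -> None:
    """Write a feature table so that reading it back is bit-exact."""
    table.to_csv(path, index=False)


def read_feature_table(path) -> pd.DataFrame:
    """Read a feature table with round-trip float parsing (pandas' default
    fast parser is not bit-exact)."""
    return pd.read_csv(path, float_precision="round_trip")

FEATURE_SETS = ("striatum", "midbrain", "striatum+midbrain")


def feature_columns(feature_set: str = "striatum+midbrain") -> tuple[str, ...]:
    """Fixed SOR column order for a feature set."""
    if feature_set == "striatum":
        return STRIATAL_FEATURES
    if feature_set == "midbrain":
        return MIDBRAIN_FEATURES
    if feature_set == "striatum+midbrain":
        return STRIATAL_FEATURES + MIDBRAIN_FEATURES
    raise ValueError(f"unknown feature_set {feature_set!r}; choose from {FEATURE_SETS}")


@dataclass
class SubjectFeatures:
    """Per-subject SOR features, asymmetry indexes and metadata."""

    subject_id: str
    group: str
    stage: str
    sor: dict[str, float]
    asym: dict[str, float | None]
    occipital_mean: float
    feature_set: str = "striatum+midbrain"

    def row(self) -> dict:
        out: dict = {
            "subject_id": self.subject_id,
            "group": self.group,
            "stage": self.stage,
        }
        for col in feature_columns(self.feature_set):
            out[f"sor_{col}"] = self.sor[col]
        for name in ASYMMETRY_SUBREGIONS:
            v = self.asym.get(name)
            out[f"ai_{name}"] = math.nan if v is None else v
        out["occipital_mean"] = self.occipital_mean
        return out


def _occipital_mean(pet: VolumeImage, submap: LabelMap) -> float:
    mask = np.zeros(submap.shape, dtype=bool)
    for side in ("L", "R"):
        mask |= submap.grid == submap.code_of("occipital", side)
    if not mask.any():
        raise ValueError("occipital reference regions are empty")
    return float(np.asarray(pet.data)[mask].mean())


def compute_sor(
    pet: VolumeImage,
    submap: LabelMap,
    code: int,
    sor_formula: str = "sbr",
    occ_mean: float | None = None,
) -> float:
    """SOR of one subregion against the pooled occipital reference."""
    if occ_mean is None:
        occ_mean = _occipital_mean(pet, submap)
    if occ_mean <= 0:
        raise ValueError(f"occipital reference mean {occ_mean} is not positive")
    mask = submap.grid == code
    if not mask.any():
        name, side = submap.code_table.get(code, ("?", "?"))
        raise ValueError(f"subregion {name}_{side} (code {code}) is empty")
    roi = float(np.asarray(pet.data)[mask].mean())
    if sor_formula == "sbr":
        return (roi - occ_mean) / occ_mean
    if sor_formula == "plain_ratio":
        return roi / occ_mean
    raise ValueError(f"unknown sor_formula {sor_formula!r}")


def compute_asymmetry(sor_left: float, sor_right: float) -> float | None:
    """Bilateral asymmetry index (higher - lower) / mean; None when the
    mean is not positive (undefined, recorded as missing)."""
    if not (np.isfinite(sor_left) and np.isfinite(sor_right)):
        raise ValueError("side SORs must be finite")
    mean = (sor_left + sor_right) / 2.0
    if mean <= 0:
        return None
    return (max(sor_left, sor_right) - min(sor_left, sor_right)) / mean


def extract_subject(
    pet: VolumeImage,
    submap: LabelMap,
    metadata: dict,
    feature_set: str = "striatum+midbrain",
    sor_formula: str = "sbr",
) -> SubjectFeatures:
    """Assemble the per-subject feature vector from PET and subregion map."""
    cols = feature_columns(feature_set)
    occ = _occipital_mean(pet, submap)
    sor = {
        col: compute_sor(
            pet, submap, subregion_code(*col.rsplit("_", 1)), sor_formula, occ
        )
        for col in cols
    }
    asym: dict[str, float | None] = {}
    for name in ASYMMETRY_SUBREGIONS:
        if f"{name}_L" in sor and f"{name}_R" in sor:
            asym[name] = compute_asymmetry(sor[f"{name}_L"], sor[f"{name}_R"])
    return SubjectFeatures(
        subject_id=str(metadata.get("subject_id", "")),
        group=str(metadata.get("group", "")),
        stage=str(metadata.get("stage", "NA")),
        sor=sor,
        asym=asym,
        occipital_mean=occ,
        feature_set=feature_set,
    )


def cohort_feature_table(
    manifest,
    segmenter=None,
    config: dict | None = None,
) -> pd.DataFrame:
    """One feature row per manifest subject.

    With ``segmenter=None`` the supplied ground-truth label maps are used
    directly (they already live on the PET grid for phantoms).  With a
    segmenter, the MRI is segmented, rigidly registered to the PET and the
    labels carried over before subregioning.

    Per-subject failures are logged and the subject excluded.
    """
    from .core import load_labels, load_volume
    from .subregions import build_subregion_map

    config = config or {}
    feature_set = config.get("feature_set", "striatum+midbrain")
    sor_formula = config.get("sor_formula", "sbr")
    sub_seed = int(config.get("subregion_seed", 0))

    rows, failures = [], []
    for rec in manifest.rows:
        try:
            pet = load_volume(rec["pet_path"])
            if segmenter is None:
                labels = load_labels(rec["labels_path"])
            else:
                from .registration import register_rigid, resample_labels
                from .segmentation import segment

                mri = load_volume(rec["mri_path"])
                # occipital delineations, when supplied, are ground truth
                supplied = None
                if rec.get("labels_path"):
                    try:
                        supplied = load_labels(rec["labels_path"])
                    except FileNotFoundError:
                        supplied = None
                labels = segment(segmenter, mri, supplied_labels=supplied)
                tf = register_rigid(mri, pet, config.get("registration"))
                labels = resample_labels(labels, tf, pet)
            submap = build_subregion_map(labels, seed=sub_seed)
            feats = extract_subject(pet, submap, rec, feature_set, sor_formula)
            rows.append(feats.row())
        except Exception as exc:  # noqa: BLE001 - per-subject isolation
            failures.append((rec.get("subject_id", "?"), str(exc)))
            warn(f"subject {rec.get('subject_id')} failed: {exc}")
    if failures:
        warn(f"{len(failures)} of {len(manifest.rows)} subjects failed extraction")
    df = pd.DataFrame(rows)
    df.attrs["failures"] = failures
    return df


def group_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Per-group mean +/- SD of bilaterally averaged SORs and AIs.

    Matches the layout of the published cohort table: SOR rows average the
    two sides; AI rows are the per-pair asymmetry indexes.
    """
    recs = []
    pairs = sorted({c[len("sor_"):].rsplit("_", 1)[0] for c in table if c.startswith("sor_")})
    for group, sub in table.groupby("group"):
        for name in pairs:
            cl, cr = f"sor_{name}_L", f"sor_{name}_R"
            if cl in sub and cr in sub:
                both = (sub[cl] + sub[cr]) / 2.0
                recs.append(
                    {
                        "group": group,
                        "measure": "SOR",
                        "region": name,
                        "mean": both.mean(),
                        "sd": both.std(ddof=1),
                    }
                )
        for name in ASYMMETRY_SUBREGIONS:
            col = f"ai_{name}"
            if col in sub:
                recs.append(
                    {
                        "group": group,
                        "measure": "AI",
                        "region": name,
                        "mean": sub[col].mean(),
                        "sd": sub[col].std(ddof=1),
                    }
                )
    return pd.DataFrame(recs)
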