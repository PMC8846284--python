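import numpy as np
import pandas as pd
import pytest

from cftpet import phantom
from cftpet.core import STRIATAL_FEATURES
from cftpet.features import cohort_feature_table


@pytest.fixture(scope="session")
def profiles():
    return phantom.default_profiles()


@pytest.fixture(scope="session")
def spec32():
    """Default phantom geometry on a 32^3 grid (4 mm voxels)."""
    return phantom.default_spec(32)


@pytest.fixture(scope="session")
def spec32_clean():
    """Noise-free variant for exact round-trip checks."""
    return phantom.default_spec(32, noise_sd=0.0, mri_noise_sd=0.0)


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory, spec32):
    """8-subject cohort (2 per group) with volumes on disk."""
    out = tmp_path_factory.mktemp("cohort8")
    manifest = phantom.generate_cohort(
        out, spec=spec32, n_per_group={"PD": 2, "MSA": 2, "PSP": 2, "NC": 2}, seed=5
    )
    return manifest


@pytest.fixture(scope="session")
def patient_table(tmp_path_factory, spec32):
    """Feature table of a full-size phantom patient cohort (107 + 22 NC)."""
    out = tmp_path_factory.mktemp("cohort_full")
    manifest = phantom.generate_cohort(out, spec=spec32, seed=1)
    return cohort_feature_table(manifest)


@pytest.fixture(scope="session")
def trained_segmenter(spec32, profiles):
    """Learned-backend segmenter trained on 10 phantoms (shared: training
    is the most expensive fixture in the suite)."""
    from cftpet.segmentation import train_segmenter

    groups = ("PD", "MSA", "PSP", "NC")
    pairs = []
    for i in range(10):
        mri, _, truth = phantom.generate_subject(spec32, profiles[groups[i % 4]], 100 + i)
        pairs.append((mri, truth))
    return train_segmenter(pairs, {"epochs": 20, "seed": 3})


def make_feature_table(
    rng: np.random.Generator,
    n_per_group: int = 20,
    planted: str | None = None,
    shift: float = 1.5,
    with_stage: bool = False,
) -> pd.DataFrame:
    """Synthetic feature-level cohort: i.i.d. standard-normal striatal SORs,
    optionally shifting one bilateral subregion pair between groups."""
    rows = []
    for gi, group in enumerate(("PD", "MSA", "PSP")):
        for i in range(n_per_group):
            feat = {f"sor_{f}": rng.normal() for f in STRIATAL_FEATURES}
            feat["sor_midbrain_L"] = rng.normal()
            feat["sor_midbrain_R"] = rng.normal()
            if planted is not None:
                feat[f"sor_{planted}_L"] += gi * shift
                feat[f"sor_{planted}_R"] += gi * shift
            rows.append(
                {
                    "subject_id": f"{group}{i:03d}",
                    "group": group,
                    "stage": ("ES" if i % 3 == 0 else "AS") if with_stage else "NA",
                }
                | feat
            )
    return pd.DataFrame(rows)
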