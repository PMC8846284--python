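import json

import numpy as np
import pandas as pd
import pytest
import yaml
from click.testing import CliRunner

from cftpet import phantom
from cftpet.cli import main as cli_main
from cftpet.core import (
    LabelMap,
    REGION_CODES,
    VolumeImage,
    centered_affine,
    check_paired_grids,
    derive_seed,
    load_labels,
    load_volume,
    save_labels,
    save_volume,
)
from cftpet.interface import PipelineConfig, run_pipeline


def test_volume_nifti_round_trip(tmp_path):
    rng = np.random.default_rng(0)
    vol = VolumeImage(rng.normal(size=(8, 8, 8)).astype(np.float32),
                      centered_affine((8, 8, 8), 2.0))
    save_volume(vol, tmp_path / "v.nii.gz")
    back = load_volume(tmp_path / "v.nii.gz")
    np.testing.assert_array_equal(back.data, vol.data)
    np.testing.assert_allclose(back.affine, vol.affine, atol=1e-5)


def test_label_map_round_trip_is_exact(tmp_path):
    grid = np.zeros((8, 8, 8), np.int16)
    grid[2:4, 2:4, 2:4] = 3
    lab = LabelMap(grid, centered_affine((8, 8, 8), 1.0), dict(REGION_CODES))
    save_labels(lab, tmp_path / "l.nii.gz")
    back = load_labels(tmp_path / "l.nii.gz")
    assert np.array_equal(back.grid, lab.grid)
    assert back.code_table == lab.code_table


def test_mismatched_grids_fail_loudly():
    a = VolumeImage(np.zeros((8, 8, 8)), centered_affine((8, 8, 8), 1.0))
    b = VolumeImage(np.zeros((8, 8, 8)), centered_affine((8, 8, 8), 2.0))
    with pytest.raises(ValueError, match="no silent reorientation"):
        check_paired_grids(a, b)


def test_derived_seeds_are_stable_and_independent():
    s1 = derive_seed(17, "stage", "PD000")
    assert s1 == derive_seed(17, "stage", "PD000")
    assert s1 != derive_seed(17, "stage", "PD001")
    assert 0 <= s1 < 2**31


def test_config_schema_rejects_unknown_and_missing_fields(tmp_path):
    path = tmp_path / "cfg.yaml"
    path.write_text(yaml.safe_dump({"seed": 1, "grid": 32, "bogus_field": 1}))
    with pytest.raises(ValueError, match="bogus_field"):
        PipelineConfig.from_yaml(path)
    path.write_text(yaml.safe_dump({"seed": 1, "grid": 32}))
    with pytest.raises(ValueError, match="segmentation_backend"):
        PipelineConfig.from_yaml(path)


def test_config_validates_backend():
    with pytest.raises(ValueError, match="segmentation_backend"):
        PipelineConfig(segmentation_backend="magic")


@pytest.fixture(scope="module")
def smoke_run(tmp_path_factory):
    """8-subject end-to-end pipeline run with the atlas backend."""
    out = tmp_path_factory.mktemp("run")
    cfg = PipelineConfig(
        seed=17,
        grid=32,
        n_per_group={"PD": 2, "MSA": 2, "PSP": 2, "NC": 2},
        classifier={"c_grid": (1.0,)},
        importance={"n_rep": 2, "n_trees": 100},
        run_strategies=False,  # 2 subjects/group cannot fill the ES pools
    )
    return cfg, run_pipeline(cfg, out / "a")


def test_pipeline_end_to_end_outputs(smoke_run):
    _, out = smoke_run
    for name in (
        "cohort/manifest.csv",
        "features.csv",
        "metrics.json",
        "confusion_matrix.csv",
        "importance.json",
        "contribution_map.nii.gz",
        "provenance.json",
    ):
        assert (out / name).exists(), name
    prov = json.loads((out / "provenance.json").read_text())
    assert "failed_stage" not in prov
    assert prov["stages"]["simulate"]["n_subjects"] == 8
    features = pd.read_csv(out / "features.csv")
    assert len(features) == 8


def test_pipeline_rerun_is_bit_identical(smoke_run, tmp_path):
    cfg, first = smoke_run
    second = run_pipeline(cfg, tmp_path / "b")
    a = (first / "features.csv").read_text()
    b = (second / "features.csv").read_text()
    assert a == b


def test_feature_matrix_tolerates_extra_columns():
    from cftpet.classification import feature_matrix
    from conftest import make_feature_table

    table = make_feature_table(np.random.default_rng(0), n_per_group=3)
    table["extra_metadata"] = "x"
    X, y = feature_matrix(table, "striatum")
    assert X.shape == (9, 14)


def test_cli_simulate_extract_classify(tmp_path):
    runner = CliRunner()
    out = tmp_path / "cohort"
    res = runner.invoke(
        cli_main,
        ["simulate", "--out", str(out), "--seed", "3",
         "--n-per-group", "PD=2,MSA=2,PSP=2,NC=2"],
    )
    assert res.exit_code == 0, res.output
    res = runner.invoke(
        cli_main,
        ["extract", "--manifest", str(out / "manifest.csv"),
         "--out", str(tmp_path / "features.csv")],
    )
    assert res.exit_code == 0, res.output
    res = runner.invoke(
        cli_main,
        ["classify", "--features", str(tmp_path / "features.csv"),
         "--task", "multiclass", "--out", str(tmp_path / "cls")],
    )
    assert res.exit_code == 0, res.output
    assert (tmp_path / "cls" / "predictions.csv").exists()


def test_cli_user_error_exit_code(tmp_path):
    runner = CliRunner()
    bad = tmp_path / "cfg.yaml"
    bad.write_text(yaml.safe_dump({"seed": 1, "grid": 32, "bogus": True}))
    res = runner.invoke(
        cli_main, ["run", "--config", str(bad), "--out", str(tmp_path / "r")]
    )
    assert res.exit_code == 1
    assert "bogus" in res.output
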