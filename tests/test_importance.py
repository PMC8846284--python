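import numpy as np
import pytest
from scipy.stats import binom

from cftpet.classification import ClassifierConfig, feature_matrix
from cftpet.importance import (
    aggregate_contributions,
    feature_contributions,
    mcnemar_chi2,
    mcnemar_exact,
    midbrain_addon_test,
)
from conftest import make_feature_table

# Published per-feature contributions of the 14 striatal features.
PRINTED = {
    "anterior_caudate_R": 0.113, "anterior_caudate_L": 0.072,
    "middle_caudate_R": 0.099, "middle_caudate_L": 0.064,
    "posterior_caudate_R": 0.067, "posterior_caudate_L": 0.077,
    "anterior_putamen_R": 0.048, "anterior_putamen_L": 0.053,
    "middle_putamen_R": 0.092, "middle_putamen_L": 0.076,
    "posterior_putamen_R": 0.075, "posterior_putamen_L": 0.072,
    "pallidum_R": 0.038, "pallidum_L": 0.054,
}


def test_printed_contributions_aggregate_to_quoted_percentages():
    table = aggregate_contributions(PRINTED)
    pct = table.percent()
    assert pct["nucleus"] == {"caudate": 49.2, "putamen": 41.6, "pallidum": 9.2}
    assert pct["bilateral"]["anterior_caudate"] == 18.5
    assert pct["bilateral"]["middle_putamen"] == 16.8
    assert pct["bilateral"]["middle_caudate"] == 16.3
    assert pct["bilateral"]["posterior_putamen"] == 14.7
    assert pct["bilateral"]["posterior_caudate"] == 14.4
    assert pct["bilateral"]["anterior_putamen"] == 10.1


def test_aggregation_degenerate_single_key():
    per = {k: 0.0 for k in PRINTED}
    per["pallidum_L"] = 1.0
    table = aggregate_contributions(per)
    assert table.nucleus == {"caudate": 0.0, "putamen": 0.0, "pallidum": 1.0}


def test_aggregation_rejects_unknown_keys():
    with pytest.raises(KeyError, match="unknown"):
        aggregate_contributions({"thalamus_L": 1.0})


def test_aggregation_is_linear():
    a = aggregate_contributions(PRINTED)
    doubled = aggregate_contributions({k: 2 * v for k, v in PRINTED.items()})
    for k in a.bilateral:
        assert doubled.bilateral[k] == pytest.approx(2 * a.bilateral[k])


def test_fitted_contributions_normalize_and_recover_planted_signal():
    """Only the anterior-caudate pair differs between groups; its bilateral
    aggregate must dominate, and contributions must sum to one."""
    rng = np.random.default_rng(0)
    table = make_feature_table(rng, n_per_group=25, planted="anterior_caudate")
    X, y = feature_matrix(table, "striatum")
    imp = feature_contributions(X, y, {"n_rep": 3, "n_trees": 200, "seed": 0})
    assert sum(imp.per_feature.values()) == pytest.approx(1.0, abs=1e-9)
    assert max(imp.bilateral, key=imp.bilateral.get) == "anterior_caudate"


def test_null_features_show_no_spurious_dominance():
    """Identically distributed features: averaged over many forest seeds,
    no bilateral aggregate dominates another by more than 2x."""
    rng = np.random.default_rng(1)
    table = make_feature_table(rng, n_per_group=25, planted=None)
    X, y = feature_matrix(table, "striatum")
    imp = feature_contributions(X, y, {"n_rep": 20, "n_trees": 200, "seed": 0})
    vals = list(imp.bilateral.values())
    assert max(vals) <= 2.0 * min(vals)


@pytest.mark.parametrize(
    "b,c,expected",
    [(5, 5, 1.0), (0, 0, 1.0), (9, 1, 2 * binom.cdf(1, 10, 0.5))],
)
def test_mcnemar_exact_values(b, c, expected):
    assert mcnemar_exact(b, c) == pytest.approx(expected, rel=1e-12)


def test_mcnemar_exact_matches_tail_enumeration():
    """Exact binomial p equals direct two-sided tail enumeration for every
    discordant split with b + c <= 12."""
    for n in range(1, 13):
        for b in range(n + 1):
            c = n - b
            k = min(b, c)
            # two-sided: sum of both tails at least as extreme as k
            p_enum = min(1.0, binom.cdf(k, n, 0.5) + binom.sf(n - k - 1, n, 0.5))
            assert mcnemar_exact(b, c) == pytest.approx(p_enum, rel=1e-10)


def test_mcnemar_chi2_variant():
    assert mcnemar_chi2(0, 0) == 1.0
    assert 0.0 < mcnemar_chi2(9, 1) < 0.05


def test_midbrain_addon_comparison():
    """Identical subjects across feature-set arms; groups separated only in
    striatal features, so the midbrain-only arm should do worst and the
    16- vs 14-feature McNemar p should be large."""
    rng = np.random.default_rng(3)
    table = make_feature_table(rng, n_per_group=10, planted="middle_putamen", shift=3.0)
    out = midbrain_addon_test(table, ClassifierConfig(c_grid=(1.0,), seed=0))
    acc = out["accuracy"]
    assert set(acc) == {"striatum+midbrain", "striatum", "midbrain"}
    assert acc["midbrain"] < acc["striatum"]
    assert 0.0 <= out["mcnemar_p"] <= 1.0


def test_midbrain_addon_identical_arms_gives_p_one():
    assert mcnemar_exact(0, 0) == 1.0
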