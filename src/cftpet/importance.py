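"""Random-forest region-contribution analysis and the midbrain add-on test.

Each of the 14 striatal SOR features gets a relative contribution from
impurity-based (mean decrease in impurity) random-forest importances,
averaged over several seeded forest fits and normalized to sum to one.
Contributions aggregate bilaterally (7 subregion values) and by nucleus
(caudate, putamen, pallidum).  A permutation-importance switch exists for
users wary of impurity bias.

The value of adding the midbrain features is tested by comparing
per-subject LOOCV correctness of the 16-feature and 14-feature models
with McNemar's exact test (binomial on discordant pairs).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import binomtest
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance

from .core import STRIATAL_FEATURES
from .evaluation import round_half_up

__all__ = [
    "ImportanceTable",
    "feature_contributions",
    "aggregate_contributions",
    "mcnemar_exact",
    "midbrain_addon_test",
    "contribution_map",
]

#: bilateral aggregation: subregion name -> its two feature keys
BILATERAL_PAIRS: dict[str, tuple[str, str]] = {
    name: (f"{name}_L", f"{name}_R")
    for name in (
        "anterior_caudate",
        "middle_caudate",
        "posterior_caudate",
        "anterior_putamen",
        "middle_putamen",
        "posterior_putamen",
        "pallidum",
    )
}
NUCLEUS_MEMBERS: dict[str, tuple[str, ...]] = {
    "caudate": ("anterior_caudate", "middle_caudate", "posterior_caudate"),
    "putamen": ("anterior_putamen", "middle_putamen", "posterior_putamen"),
    "pallidum": ("pallidum",),
}


@dataclass
class ImportanceTable:
    """Normalized per-feature contributions with bilateral/nucleus sums."""

    per_feature: dict[str, float]
    bilateral: dict[str, float]
    nucleus: dict[str, float]

    def percent(self, decimals: int = 1) -> dict[str, dict[str, float]]:
        return {
            level: {k: round_half_up(100 * v, decimals) for k, v in d.items()}
            for level, d in (
                ("per_feature", self.per_feature),
                ("bilateral", self.bilateral),
                ("nucleus", self.nucleus),
            )
        }

    def save(self, path_prefix) -> None:
        p = Path(path_prefix)
        pd.Series(self.per_feature).rename("contribution").to_csv(
            p.with_suffix(".csv"), index_label="feature"
        )
        p.with_suffix(".json").write_text(json.dumps(
            {
                "per_feature": self.per_feature,
                "bilateral": self.bilateral,
                "nucleus": self.nucleus,
            },
            indent=2,
        ))


def aggregate_contributions(per_feature: dict[str, float]) -> ImportanceTable:
    """Bilateral and nucleus sums of 14 per-feature contributions."""
    unknown = set(per_feature) - set(STRIATAL_FEATURES)
    if unknown:
        raise KeyError(f"unknown feature keys: {sorted(unknown)}")
    if any(v < 0 for v in per_feature.values()):
        raise ValueError("contributions must be nonnegative")
    bilateral = {
        name: sum(per_feature.get(k, 0.0) for k in keys)
        for name, keys in BILATERAL_PAIRS.items()
    }
    nucleus = {
        nuc: sum(bilateral[m] for m in members)
        for nuc, members in NUCLEUS_MEMBERS.items()
    }
    return ImportanceTable(dict(per_feature), bilateral, nucleus)


def feature_contributions(
    X: pd.DataFrame,
    y,
    config: dict | None = None,
) -> ImportanceTable:
    """Averaged, normalized random-forest contributions of the 14 striatal
    features.

    ``config`` keys: ``n_trees`` (default 500), ``n_rep`` seeded fits to
    average (default 10), ``seed``, ``method`` = ``impurity`` |
    ``permutation``.
    """
    config = config or {}
    n_trees = int(config.get("n_trees", 500))
    n_rep = int(config.get("n_rep", 10))
    seed = int(config.get("seed", 0))
    method = config.get("method", "impurity")

    X = pd.DataFrame(X)
    cols = [c[len("sor_"):] if c.startswith("sor_") else c for c in X.columns]
    missing = [f for f in STRIATAL_FEATURES if f not in cols]
    if missing:
        raise ValueError(f"missing striatal features: {missing}")
    order = [cols.index(f) for f in STRIATAL_FEATURES]
    Xv = X.values[:, order]
    y = np.asarray(y)
    if len(set(y)) < 2:
        raise ValueError("need at least two classes")

    acc = np.zeros(len(STRIATAL_FEATURES))
    for rep in range(n_rep):
        rf = RandomForestClassifier(n_estimators=n_trees, random_state=seed + rep)
        rf.fit(Xv, y)
        if method == "impurity":
            imp = rf.feature_importances_
        elif method == "permutation":
            imp = permutation_importance(
                rf, Xv, y, n_repeats=5, random_state=seed + rep
            ).importances_mean
            imp = np.clip(imp, 0.0, None)
        else:
            raise ValueError(f"unknown importance method {method!r}")
        total = imp.sum()
        if total > 0:
            acc += imp / total
    acc /= n_rep
    acc /= acc.sum()  # exact normalization after averaging
    per_feature = dict(zip(STRIATAL_FEATURES, acc.tolist()))
    return aggregate_contributions(per_feature)


def mcnemar_exact(b: int, c: int) -> float:
    """Exact two-sided McNemar p-value from discordant counts (b, c).

    Binomial test of min(b, c) successes in b+c trials at p = 1/2; p = 1
    when there are no discordant pairs.
    """
    if b < 0 or c < 0:
        raise ValueError("discordant counts must be nonnegative")
    n = b + c
    if n == 0:
        return 1.0
    return float(binomtest(min(b, c), n, 0.5, alternative="two-sided").pvalue)


def mcnemar_chi2(b: int, c: int) -> float:
    """Continuity-corrected chi-square variant of McNemar's test."""
    from scipy.stats import chi2

    n = b + c
    if n == 0:
        return 1.0
    stat = (abs(b - c) - 1) ** 2 / n
    return float(chi2.sf(stat, df=1))


def midbrain_addon_test(
    table: pd.DataFrame,
    config=None,
    exact: bool = True,
) -> dict:
    """LOOCV accuracy of striatum+midbrain vs striatum vs midbrain feature
    sets, with McNemar's test on the 16- vs 14-feature per-subject
    correctness."""
    from .classification import ClassifierConfig, feature_matrix, loocv

    config = config or ClassifierConfig()
    results = {}
    correctness = {}
    for fs in ("striatum+midbrain", "striatum", "midbrain"):
        X, y = feature_matrix(table, fs)
        res = loocv(X, y, config)
        results[fs] = res
        correctness[fs] = res.correct()

    a16, a14 = correctness["striatum+midbrain"], correctness["striatum"]
    if list(a16.index) != list(a14.index):
        raise ValueError("subject sets differ between feature-set arms")
    b = int((a16 & ~a14).sum())  # add-on fixes
    c = int((~a16 & a14).sum())  # add-on breaks
    p = mcnemar_exact(b, c) if exact else mcnemar_chi2(b, c)
    return {
        "accuracy": {fs: results[fs].accuracy for fs in results},
        "results": results,
        "discordant": (b, c),
        "mcnemar_p": p,
    }


def contribution_map(submap, table: ImportanceTable):
    """Voxelwise map painting each subregion with its bilateral aggregate
    (the data behind region-contribution renderings)."""
    from .core import VolumeImage

    out = np.zeros(submap.shape, dtype=np.float32)
    for code, (name, side) in submap.code_table.items():
        if name in table.bilateral:
            out[submap.grid == code] = table.bilateral[name]
    return VolumeImage(out, submap.affine)
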