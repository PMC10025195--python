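"""Feature screening: Mann–Whitney, per-feature CV AUC, redundancy pruning."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tugait.errors import FoldError
from tugait.metrics import roc_auc
from tugait.parameters import FeatureTable
from tugait.selection import (
    cv_auc_filter,
    mann_whitney_feature,
    mann_whitney_screen,
    redundancy_filter,
    select_feature_groups,
)

from conftest import gaussian_feature_table


def u_statistic_oracle(x, y):
    """Exhaustive pairwise enumeration of the rank-sum U statistic."""
    u = 0.0
    for a in x:
        for b in y:
            u += 1.0 if a > b else (0.5 if a == b else 0.0)
    return u


def test_u_statistic_matches_enumeration_on_4v4():
    x = np.array([3.1, 5.0, 2.2, 5.0])
    y = np.array([1.0, 5.0, 2.9, 0.4])
    u, p = mann_whitney_feature(x, y)
    assert u == pytest.approx(u_statistic_oracle(x, y), abs=1e-12)
    assert 0.0 < p <= 1.0


def test_null_feature_excluded_at_nominal_rate():
    """Type-I error: an uninformative feature survives alpha=0.05 screening
    in at most ~6 % of repetitions (n=60/group)."""
    rng = np.random.default_rng(0)
    excluded = 0
    reps = 500
    for _ in range(reps):
        _, p = mann_whitney_feature(rng.normal(size=60), rng.normal(size=60))
        excluded += p >= 0.05
    assert excluded / reps >= 0.94


def test_shifted_feature_almost_always_included():
    """Power: a 2-SD group shift at n=60/group is detected essentially always."""
    rng = np.random.default_rng(1)
    included = 0
    reps = 300
    for _ in range(reps):
        _, p = mann_whitney_feature(rng.normal(2.0, 1.0, 60), rng.normal(size=60))
        included += p < 0.05
    assert included / reps >= 0.99


def test_screen_keeps_shifted_drops_null_and_constant():
    table = gaussian_feature_table(
        40,
        {
            "strong": ("straight_walk", 2.0),
            "null": ("turning", 0.0),
        },
        seed=5,
    )
    table.data["flat"] = 1.0
    table.components["flat"] = "sitting"
    fg1 = mann_whitney_screen(table)
    assert "strong" in fg1.features
    assert "flat" not in fg1.features
    assert fg1.stats.loc["flat", "p"] == 1.0


def test_cv_auc_keeps_separable_feature():
    table = gaussian_feature_table(20, {"sep": ("straight_walk", 0.0)}, seed=2)
    table.data["sep"] = (table.labels == "PD").astype(float)
    group = mann_whitney_screen(table)
    fg3 = cv_auc_filter(table, group, seed=0)
    assert fg3.stats.loc["sep", "auc5fold"] == pytest.approx(1.0)
    assert "sep" in fg3.features


def test_cv_auc_null_feature_near_chance():
    """Folded CV AUC of pure noise averages in [0.5, 0.58] over 200 seeds."""
    aucs = []
    for seed in range(200):
        rng = np.random.default_rng(10_000 + seed)
        table = gaussian_feature_table(60, {"noise": ("turning", 0.0)}, seed=seed)
        group = mann_whitney_screen(table, alpha=1.1)  # keep regardless of p
        fg3 = cv_auc_filter(table, group, seed=seed, threshold=0.6)
        aucs.append(fg3.stats.loc["noise", "auc5fold"])
    assert 0.5 <= np.mean(aucs) <= 0.58
    assert np.mean([a >= 0.6 for a in aucs]) < 0.5  # typically dropped


def test_in_sample_auc_equals_normalized_u():
    table = gaussian_feature_table(5, {"f": ("standing", 1.0)}, seed=3)
    x = table.data["f"].to_numpy()
    y = table.labels.to_numpy()
    u = u_statistic_oracle(x[y == "PD"], x[y == "ET"])
    assert roc_auc(x, y) == pytest.approx(u / 25.0, abs=1e-12)


def test_cv_auc_fold_error_when_class_too_small():
    table = gaussian_feature_table(3, {"f": ("standing", 1.0)}, seed=4)
    group = mann_whitney_screen(table, alpha=1.1)
    with pytest.raises(FoldError):
        cv_auc_filter(table, group, folds=5)


def test_cv_auc_invariant_to_row_order():
    table = gaussian_feature_table(
        25, {"a": ("standing", 0.8), "b": ("turning", 0.5), "c": ("sitting", 0.0)}
    )
    group = mann_whitney_screen(table, alpha=1.1)
    fg3 = cv_auc_filter(table, group, seed=9)
    perm = np.random.default_rng(0).permutation(len(table.data))
    shuffled = FeatureTable(
        data=table.data.iloc[perm],
        labels=table.labels.iloc[perm],
        components=table.components,
    )
    fg3_shuffled = cv_auc_filter(shuffled, mann_whitney_screen(shuffled, alpha=1.1), seed=9)
    assert fg3.features == fg3_shuffled.features


def test_redundancy_duplicate_features_keep_one():
    table = gaussian_feature_table(30, {"a": ("standing", 1.0)}, seed=6)
    table.data["b"] = table.data["a"]
    table.components["b"] = "standing"
    group = mann_whitney_screen(table)
    fg2 = redundancy_filter(table, group)
    assert fg2.features == ["a"]  # tie on p broken by name order


def test_redundancy_uncorrelated_features_all_kept():
    table = gaussian_feature_table(
        40, {"a": ("standing", 0.9), "b": ("turning", 0.7), "c": ("sitting", 0.5)}
    )
    group = mann_whitney_screen(table, alpha=1.1)
    fg2 = redundancy_filter(table, group)
    assert sorted(fg2.features) == ["a", "b", "c"]


def test_redundancy_matches_hand_enumerated_greedy():
    rng = np.random.default_rng(7)
    n = 50
    base = rng.normal(size=2 * n)
    table = gaussian_feature_table(n, {}, seed=7)
    shift = (table.labels == "PD").to_numpy().astype(float)
    cols = {
        "f1": base + 1.2 * shift,
        "f2": 2.0 * base + 2.4 * shift + 0.01 * rng.normal(size=2 * n),
        "f3": rng.normal(size=2 * n) + 0.8 * shift,
        "f4": rng.normal(size=2 * n) + 0.4 * shift,
    }
    for name, x in cols.items():
        table.data[name] = x
        table.components[name] = "straight_walk"
    group = mann_whitney_screen(table, alpha=1.1)
    # independent greedy enumeration with scipy, mirroring the declared rule
    ps = {f: mann_whitney_feature(
        table.data[f][table.labels == "PD"].to_numpy(),
        table.data[f][table.labels == "ET"].to_numpy(),
    )[1] for f in cols}
    order = sorted(cols, key=lambda f: (ps[f], f))
    kept = []
    for f in order:
        if all(abs(stats.spearmanr(table.data[f], table.data[k]).statistic) <= 0.9 for k in kept):
            kept.append(f)
    fg2 = redundancy_filter(table, group, rho_max=0.9)
    assert fg2.features == kept
    assert len(kept) == 3  # f2 is an affine copy of f1


def test_group_nesting_invariants():
    table = gaussian_feature_table(
        30,
        {
            "a": ("standing", 1.5),
            "b": ("turning", 1.0),
            "c": ("sitting", 0.7),
            "d": ("straight_walk", 0.0),
        },
        seed=8,
    )
    groups = select_feature_groups(table, seed=1)
    assert set(groups["FG_II"].features) <= set(groups["FG_I"].features)
    assert set(groups["FG_III"].features) <= set(groups["FG_I"].features)
    for g in groups.values():
        assert len(g.features) == len(set(g.features))
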