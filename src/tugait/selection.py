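"""Training-set feature screening into the three feature groups.

* FG I  — Mann–Whitney U screen: keep features whose two-sided,
  tie-corrected p value (normal approximation with continuity correction)
  is below alpha (default 0.05, uncorrected).
* FG II — redundancy pruning of FG I: features ordered by ascending p are
  kept greedily unless their |Spearman rho| against an already-kept
  feature exceeds rho_max (default 0.9).
* FG III — per-feature discriminability: a single-feature threshold
  classifier's stratified 5-fold CV AUC, folded for orientation
  (AUC' = max(AUC, 1-AUC)), must reach the threshold (default 0.6).

All selectors operate on the training table only; fold assignment is keyed
on sorted subject ids so results are invariant to row order.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .errors import FoldError
from .metrics import roc_auc
from .parameters import FeatureTable

log = logging.getLogger(__name__)

GROUP_NAMES = ("FG_I", "FG_II", "FG_III")


@dataclasses.dataclass
class FeatureGroup:
    name: str  # "FG_I" | "FG_II" | "FG_III"
    features: list[str]
    provenance: dict
    stats: pd.DataFrame | None = None  # per-feature statistic/p/auc

    def __len__(self) -> int:
        return len(self.features)

    def per_component_counts(self, table: FeatureTable) -> dict[str, int]:
        counts: dict[str, int] = {}
        for f in self.features:
            comp = table.components[f]
            counts[comp] = counts.get(comp, 0) + 1
        return counts


def mann_whitney_feature(x_pd: np.ndarray, x_et: np.ndarray) -> tuple[float, float]:
    """(U statistic for the PD sample, two-sided p) for one feature.

    Tie-corrected normal approximation with continuity correction; a
    constant feature is reported as p = 1.
    """
    if np.all(x_pd == x_pd[0]) and np.all(x_et == x_pd[0]):
        return float(len(x_pd) * len(x_et) / 2.0), 1.0
    res = stats.mannwhitneyu(
        x_pd, x_et, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)


def _feature_stats(table: FeatureTable) -> pd.DataFrame:
    y = table.labels.to_numpy()
    rows = []
    for name in table.feature_names:
        x = table.data[name].to_numpy(dtype=float)
        ok = np.isfinite(x)
        x_pd, x_et = x[ok & (y == "PD")], x[ok & (y == "ET")]
        if x_pd.size == 0 or x_et.size == 0:
            u, p = np.nan, 1.0
        elif np.unique(np.concatenate([x_pd, x_et])).size == 1:
            u, p = len(x_pd) * len(x_et) / 2.0, 1.0
            log.warning("constant feature %s excluded (p set to 1)", name)
        else:
            u, p = mann_whitney_feature(x_pd, x_et)
        rows.append({"feature": name, "component": table.components[name], "U": u, "p": p})
    return pd.DataFrame(rows).set_index("feature")


def mann_whitney_screen(table: FeatureTable, alpha: float = 0.05) -> FeatureGroup:
    """FG I: features that differ between PD and ET at two-sided p < alpha."""
    if set(table.labels) != {"PD", "ET"}:
        raise ValueError("screen needs both PD and ET rows")
    st = _feature_stats(table)
    kept = st[st["p"] < alpha]
    # deterministic order: ascending p, then feature name
    kept = kept.sort_values(["p"], kind="mergesort")
    order = sorted(kept.index, key=lambda f: (kept.loc[f, "p"], f))
    return FeatureGroup(
        name="FG_I",
        features=order,
        provenance={"method": "mann_whitney", "alpha": alpha},
        stats=st,
    )


def redundancy_filter(
    table: FeatureTable, group: FeatureGroup, rho_max: float = 0.9
) -> FeatureGroup:
    """FG II: greedy correlation pruning of FG I.

    Features are visited in ascending-p order (ties broken by name); a
    feature is dropped if its |Spearman rho| with any already-kept feature
    exceeds ``rho_max``.
    """
    st = group.stats if group.stats is not None else _feature_stats(table)
    order = sorted(group.features, key=lambda f: (st.loc[f, "p"], f))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant columns yield NaN rho
        rho = table.data[order].corr(method="spearman").abs()
    kept: list[str] = []
    for f in order:
        if all(not (rho.loc[f, k] > rho_max) for k in kept):
            kept.append(f)
    return FeatureGroup(
        name="FG_II",
        features=kept,
        provenance={"method": "redundancy", "rho_max": rho_max, "parent": group.name},
        stats=st,
    )


def assign_folds(subject_ids: list[str], labels: pd.Series, folds: int, seed: int) -> dict[str, int]:
    """Stratified fold ids keyed on subject id (row-order invariant)."""
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xF01D)))
    assignment: dict[str, int] = {}
    for cls in ("PD", "ET"):
        ids = sorted(s for s in subject_ids if labels[s] == cls)
        if len(ids) < folds:
            raise FoldError(f"class {cls} has {len(ids)} subjects < {folds} folds")
        perm = rng.permutation(len(ids))
        for pos, idx in enumerate(perm):
            assignment[ids[idx]] = pos % folds
    return assignment


def cv_auc_filter(
    table: FeatureTable,
    group: FeatureGroup,
    folds: int = 5,
    threshold: float = 0.6,
    seed: int = 0,
) -> FeatureGroup:
    """FG III: features whose folded 5-fold CV AUC reaches the threshold.

    The single-feature classifier is a threshold rule on the raw value;
    the per-fold held-out AUCs are averaged and folded for orientation,
    AUC' = max(AUC, 1 - AUC).
    """
    missing = [f for f in group.features if f not in table.data.columns]
    if missing:
        raise ValueError(f"group features absent from table: {missing}")
    fold_of = assign_folds(list(table.data.index), table.labels, folds, seed)
    fold_ids = np.array([fold_of[s] for s in table.data.index])
    y = table.labels.to_numpy()

    st = group.stats if group.stats is not None else _feature_stats(table)
    aucs: dict[str, float] = {}
    for name in group.features:
        x = table.data[name].to_numpy(dtype=float)
        per_fold = []
        for k in range(folds):
            test = fold_ids == k
            ok = test & np.isfinite(x)
            if len(set(y[ok])) < 2:
                continue
            per_fold.append(roc_auc(x[ok], y[ok]))
        mean_auc = float(np.mean(per_fold)) if per_fold else 0.5
        aucs[name] = max(mean_auc, 1.0 - mean_auc)
    kept = [f for f in group.features if aucs[f] >= threshold]
    kept = sorted(kept, key=lambda f: (-aucs[f], f))
    st = st.copy()
    st["auc5fold"] = pd.Series(aucs)
    return FeatureGroup(
        name="FG_III",
        features=kept,
        provenance={
            "method": "cv_auc",
            "folds": folds,
            "threshold": threshold,
            "seed": seed,
            "parent": group.name,
        },
        stats=st,
    )


def select_feature_groups(
    train_table: FeatureTable,
    alpha: float = 0.05,
    rho_max: float = 0.9,
    folds: int = 5,
    auc_threshold: float = 0.6,
    seed: int = 0,
) -> dict[str, FeatureGroup]:
    """Run all three selection methods on the training table."""
    fg1 = mann_whitney_screen(train_table, alpha=alpha)
    fg2 = redundancy_filter(train_table, fg1, rho_max=rho_max)
    fg3 = cv_auc_filter(
        train_table, fg1, folds=folds, threshold=auc_threshold, seed=seed
    )
    return {"FG_I": fg1, "FG_II": fg2, "FG_III": fg3}


def write_groups_csv(groups: dict[str, FeatureGroup], table: FeatureTable, path) -> None:
    rows = []
    for gname, group in groups.items():
        st = group.stats
        for f in group.features:
            rows.append(
                {
                    "group": gname,
                    "feature": f,
                    "component": table.components[f],
                    "method": group.provenance.get("method"),
                    "U": None if st is None else st.loc[f, "U"],
                    "p": None if st is None else st.loc[f, "p"],
                    "auc5fold": (
                        st.loc[f, "auc5fold"]
                        if st is not None and "auc5fold" in st.columns
                        else None
                    ),
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)
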