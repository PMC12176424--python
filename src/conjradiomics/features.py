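"""Feature-table assembly, participant-level splitting, imputation,
normalization, and stability-based feature selection.

Every fitted transform (imputer, scalers, feature ranking) sees training
rows only; test tables are transformed with the training fit. Splitting is
at participant level so photos of one child never straddle the split.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.impute import KNNImputer

__all__ = [
    "METADATA_COLUMNS",
    "SelectionResult",
    "build_feature_table",
    "feature_columns",
    "split_cohort",
    "impute_knn",
    "zscore_standardize",
    "minmax_scale",
    "stability_select_features",
]

#: Non-feature columns of an assembled analysis table.
METADATA_COLUMNS = (
    "participant_id", "eye", "device", "region",
    "age_years", "sex", "hgb_g_dl", "anemia",
)


def feature_columns(table: pd.DataFrame) -> list[str]:
    """All columns of an analysis table that are radiomic features."""
    return [c for c in table.columns if c not in METADATA_COLUMNS]


def build_feature_table(photos, participants, config=None,
                        errors: list | None = None) -> pd.DataFrame:
    """Extract features for every photo and join the participant metadata."""
    from conjradiomics.texture import extract_feature_vector

    by_id = {p.id: p for p in participants}
    rows = []
    for ph in photos:
        feats = extract_feature_vector(ph, config, errors=errors)
        p = by_id[ph.participant_id]
        rows.append({
            "participant_id": ph.participant_id, "eye": ph.eye,
            "device": ph.device, "region": ph.region,
            "age_years": p.age_years, "sex": p.sex,
            "hgb_g_dl": p.hgb, "anemia": int(p.anemia),
            **feats,
        })
    return pd.DataFrame(rows)


def split_cohort(table: pd.DataFrame, train_fraction: float = 0.7,
                 seed: int = 0, max_prevalence_gap: float = 0.03,
                 max_tries: int = 200) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Participant-level stratified split of an analysis table.

    Participants (not photos) are split ``train_fraction`` / rest,
    stratified by anemia label; photos follow their participant, so no
    participant id appears in both subsets. Within the seeded stream the
    split is redrawn until the anemia prevalence difference between subsets
    is at most ``max_prevalence_gap`` (3 percentage points by default).
    With 565 participants at 0.70 this yields 395 train / 170 test.

    For very small cohorts the tolerance can be structurally unattainable
    (one participant moves the test prevalence by 1/n_test); the
    best-balanced draw seen is then returned instead.
    """
    parts = table[["participant_id", "anemia"]].drop_duplicates("participant_id")
    labels = parts.set_index("participant_id")["anemia"]
    if labels.sum() < 10 or (1 - labels).sum() < 10:
        raise ValueError("need at least 10 participants per class to split")
    n = len(labels)
    n_train = int(np.floor(n * train_fraction + 1e-9))
    n_test = n - n_train
    rng = np.random.default_rng(seed)
    ids = labels.index.to_numpy()
    y = labels.to_numpy()
    best = None
    for _ in range(max_tries):
        # stratified draw: allocate test count per class proportionally,
        # with randomized rounding so odd counts can still balance
        test_ids = []
        remaining = n_test
        classes = [1, 0]
        for ci, cls in enumerate(classes):
            cls_ids = ids[y == cls]
            if ci == len(classes) - 1:
                k = remaining
            else:
                exact = cls_ids.size * n_test / n
                k = int(np.floor(exact)) + int(rng.random() < exact % 1.0)
                k = min(k, remaining)
            take = rng.choice(cls_ids, size=k, replace=False)
            test_ids.extend(take)
            remaining -= k
        test_set = set(test_ids)
        train_ids = [i for i in ids if i not in test_set]
        prev_train = labels.loc[train_ids].mean()
        prev_test = labels.loc[list(test_set)].mean()
        gap = abs(prev_train - prev_test)
        if best is None or gap < best[0]:
            best = (gap, test_set)
        if gap <= max_prevalence_gap:
            break
    _, test_set = best
    train_ids = [i for i in ids if i not in test_set]
    tr = table[table["participant_id"].isin(train_ids)].reset_index(drop=True)
    te = table[table["participant_id"].isin(test_set)].reset_index(drop=True)
    return tr, te


def impute_knn(train: pd.DataFrame, test: pd.DataFrame | None = None,
               k: int = 5) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """k-nearest-neighbor imputation of missing feature values.

    Neighbors are found among training rows only (test rows are imputed
    from their training-set neighbors); distances are computed on
    min-max-scaled features so no single feature's scale dominates. Columns
    fully missing in train raise an error naming them.
    """
    cols = feature_columns(train)
    Xtr = train[cols].to_numpy(dtype=float)
    fully_missing = [c for c, bad in zip(cols, np.isnan(Xtr).all(axis=0)) if bad]
    if fully_missing:
        raise ValueError(f"columns fully missing in train: {fully_missing}")
    miss_frac = np.isnan(Xtr).mean(axis=0)
    if (miss_frac >= 0.5).any():
        bad = [c for c, m in zip(cols, miss_frac) if m >= 0.5]
        raise ValueError(f"missingness >= 50% in columns: {bad}")
    if not np.isnan(Xtr).any() and (test is None or
                                    not test[cols].isna().any().any()):
        return train, test

    lo = np.nanmin(Xtr, axis=0)
    hi = np.nanmax(Xtr, axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)

    def _scale(X):
        return (X - lo) / span

    def _unscale(X):
        return X * span + lo

    imputer = KNNImputer(n_neighbors=k)
    imputer.fit(_scale(Xtr))
    train = train.copy()
    train[cols] = _unscale(imputer.transform(_scale(Xtr)))
    if test is not None:
        test = test.copy()
        Xte = test[cols].to_numpy(dtype=float)
        test[cols] = _unscale(imputer.transform(_scale(Xte)))
    return train, test


def zscore_standardize(train: pd.DataFrame, test: pd.DataFrame | None = None
                       ) -> tuple[pd.DataFrame, pd.DataFrame | None, list[str]]:
    """Z-score features using train mean/SD; zero-variance columns map to 0.

    Returns (train, test, flagged) where ``flagged`` lists the
    zero-variance columns."""
    cols = feature_columns(train)
    mu = train[cols].mean()
    sd = train[cols].std(ddof=0)
    flagged = [c for c in cols if sd[c] == 0 or not np.isfinite(sd[c])]
    sd = sd.replace(0, 1.0)
    train = train.copy()
    train[cols] = (train[cols] - mu) / sd
    train[flagged] = 0.0
    if test is not None:
        test = test.copy()
        test[cols] = (test[cols] - mu) / sd
        test[flagged] = 0.0
    return train, test, flagged


def minmax_scale(train: pd.DataFrame, test: pd.DataFrame | None = None
                 ) -> tuple[pd.DataFrame, pd.DataFrame | None, list[str]]:
    """Scale features to [0, 1] using train min/max.

    Zero-range train columns map to 0 and are flagged. Test values outside
    the train range map outside [0, 1] and are preserved, not clipped."""
    cols = feature_columns(train)
    lo = train[cols].min()
    hi = train[cols].max()
    span = hi - lo
    flagged = [c for c in cols if span[c] == 0 or not np.isfinite(span[c])]
    span = span.replace(0, 1.0)
    train = train.copy()
    train[cols] = (train[cols] - lo) / span
    train[flagged] = 0.0
    if test is not None:
        test = test.copy()
        test[cols] = (test[cols] - lo) / span
        test[flagged] = 0.0
    return train, test, flagged


@dataclass
class SelectionResult:
    """Outcome of stability selection: per-seed ranks and the final set."""

    selected: list[str]
    stability_counts: dict[str, int]
    median_ranks: dict[str, float]
    seeds: list[int]
    per_seed_rankings: dict[int, list[str]] = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "selected": self.selected,
                    "stability_counts": self.stability_counts,
                    "median_ranks": self.median_ranks,
                    "seeds": self.seeds,
                    "per_seed_rankings": {
                        str(k): v for k, v in self.per_seed_rankings.items()
                    },
                },
                fh,
                indent=2,
            )


def stability_select_features(
    train: pd.DataFrame,
    n_select: int = 20,
    n_seeds: int = 20,
    top_k: int = 30,
    threshold: float = 0.8,
    n_estimators: int = 100,
    base_seed: int = 0,
    target: str = "anemia",
) -> SelectionResult:
    """Select features that rank consistently high across seeded forests.

    For each of ``n_seeds`` seeds a random-forest classifier is fitted on
    the training features against the anemia label and features are ranked
    by mean decrease in impurity (Gini importance). A feature is *stable*
    if it lands in the top ``top_k`` in at least ``threshold * n_seeds``
    runs. The ``n_select`` stable features with the best median rank are
    returned (ties broken by median rank then name). If fewer than
    ``n_select`` features are stable the threshold is halved once; if still
    short, an error reports the stability histogram.
    """
    cols = feature_columns(train)
    usable = [c for c in cols if train[c].nunique() > 1]
    if len(usable) < n_select:
        raise ValueError(
            f"only {len(usable)} non-constant features; need {n_select}")
    X = train[usable].to_numpy(dtype=float)
    y = train[target].to_numpy(dtype=int)
    # canonical row order: forest bootstraps depend on row order, so sort
    # rows lexicographically to make selection invariant to permutations
    order = np.lexsort(tuple(X[:, c] for c in range(X.shape[1] - 1, -1, -1)))
    X, y = X[order], y[order]
    seeds = [int(base_seed) + s for s in range(n_seeds)]
    counts = {c: 0 for c in usable}
    ranks: dict[str, list[int]] = {c: [] for c in usable}
    rankings: dict[int, list[str]] = {}
    for s in seeds:
        rf = RandomForestClassifier(
            n_estimators=n_estimators, random_state=s, n_jobs=1)
        rf.fit(X, y)
        order = np.argsort(-rf.feature_importances_, kind="stable")
        ranking = [usable[i] for i in order]
        rankings[s] = ranking[:top_k]
        for r, name in enumerate(ranking):
            ranks[name].append(r)
            if r < top_k:
                counts[name] += 1

    def _pick(thr: float):
        need = thr * n_seeds
        stable = [c for c in usable if counts[c] >= need]
        if len(stable) < n_select:
            return None
        med = {c: float(np.median(ranks[c])) for c in stable}
        stable.sort(key=lambda c: (med[c], c))
        return stable[:n_select], med

    picked = _pick(threshold) or _pick(threshold / 2)
    if picked is None:
        hist = dict(sorted(counts.items(), key=lambda kv: -kv[1])[:50])
        raise RuntimeError(
            f"fewer than {n_select} stable features; top stability counts: {hist}")
    selected, med = picked
    return SelectionResult(
        selected=selected,
        stability_counts={c: counts[c] for c in usable if counts[c] > 0},
        median_ranks={c: float(np.median(ranks[c])) for c in selected},
        seeds=seeds,
        per_seed_rankings=rankings,
    )
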