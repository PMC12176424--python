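"""ROC/AUC machinery, DeLong test, Kruskal-Wallis, WHO labels, regressions."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from conjradiomics.stats import (
    auc_mann_whitney,
    association_regressions,
    contingency_test,
    delong_test,
    delong_test_unpaired,
    kruskal_wallis_auc,
    subgroup_rocs,
    who_anemia_label,
)
from oracles import auc_pairwise


@pytest.mark.parametrize(
    "age,sex,hgb,expected",
    [
        (8, "male", 11.4, True),      # below the 5-11 y cutoff
        (8, "male", 11.5, False),     # strict inequality at the boundary
        (8, "female", 11.49, True),
        (12, "female", 11.9, True),   # 12-14 y cutoff 12.0
        (14, "male", 12.0, False),
        (15, "male", 12.5, True),     # 15 y male cutoff 13.0
        (15, "male", 13.0, False),
        (15, "female", 12.5, False),  # 15 y female cutoff 12.0
        (15, "female", 11.9, True),
        (5, "F", 11.4, True),         # short sex codes accepted
    ],
)
def test_who_cutoffs(age, sex, hgb, expected):
    assert who_anemia_label(age, sex, hgb) is expected


def test_who_label_rejects_out_of_range():
    with pytest.raises(ValueError):
        who_anemia_label(4, "male", 11.0)
    with pytest.raises(ValueError):
        who_anemia_label(16, "male", 11.0)
    with pytest.raises(ValueError):
        who_anemia_label(8, "male", -1.0)


def test_auc_perfect_separation():
    res = auc_mann_whitney([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])
    assert res.auc == 1.0
    assert res.ci95[1] <= 1.0


def test_auc_matches_pairwise_oracle(rng):
    """Rank-statistic AUC equals exhaustive pairwise win counting,
    including with ties, on 100 random score/label vectors."""
    for _ in range(100):
        n = int(rng.integers(10, 60))
        scores = rng.choice(np.linspace(0, 1, 11), size=n)  # force ties
        labels = rng.random(n) < 0.5
        if labels.all() or not labels.any():
            continue
        res = auc_mann_whitney(scores, labels)
        assert res.auc == pytest.approx(auc_pairwise(scores, labels), abs=1e-12)


def test_auc_trapezoid_equals_rank_statistic(rng):
    """The trapezoidal area under the ROC curve equals the rank AUC."""
    for _ in range(20):
        scores = rng.choice(np.linspace(0, 1, 15), size=80)
        labels = rng.random(80) < 0.4
        if labels.all() or not labels.any():
            continue
        res = auc_mann_whitney(scores, labels)
        fpr, tpr = res.curve
        assert np.trapezoid(tpr, fpr) == pytest.approx(res.auc, abs=1e-12)


def test_auc_single_class_errors():
    with pytest.raises(ValueError):
        auc_mann_whitney([0.1, 0.2], [1, 1])


def test_wald_ci_width_shrinks_with_n(rng):
    widths = []
    for n in (50, 200, 800):
        scores = np.concatenate([rng.normal(1, 1, n), rng.normal(0, 1, n)])
        labels = np.r_[np.ones(n), np.zeros(n)].astype(bool)
        res = auc_mann_whitney(scores, labels)
        widths.append(res.ci95[1] - res.ci95[0])
    assert widths[0] > widths[1] > widths[2]


def test_delong_self_comparison_p_is_one(rng):
    scores = rng.normal(size=50)
    labels = rng.random(50) < 0.5
    labels[0], labels[1] = True, False
    res = delong_test(scores, scores, labels)
    assert res.p == 1.0
    assert res.auc_a == res.auc_b


def test_delong_variance_nonnegative_and_detects_difference(rng):
    n = 300
    y = rng.random(n) < 0.5
    y[:2] = [True, False]
    good = y + rng.normal(0, 0.5, n)
    bad = rng.normal(0, 1, n)
    res = delong_test(good, bad, y)
    assert res.var_diff >= 0
    assert res.p < 0.01
    assert res.auc_a > res.auc_b


def test_delong_variance_matches_bootstrap(rng):
    """DeLong AUC variance agrees with a bootstrap oracle within 15%."""
    n = 400
    y = rng.random(n) < 0.5
    y[:2] = [True, False]
    scores = y + rng.normal(0, 1.2, n)
    res = auc_mann_whitney(scores, y)
    boot = []
    for _ in range(2000):
        idx = rng.integers(0, n, n)
        yb = y[idx]
        if yb.all() or not yb.any():
            continue
        boot.append(auc_mann_whitney(scores[idx], yb).auc)
    assert res.se**2 == pytest.approx(np.var(boot), rel=0.15)


def test_kruskal_identical_groups():
    g = [0.7, 0.71, 0.72]
    h, p = kruskal_wallis_auc([g, g, g])
    assert h == 0.0 and p == 1.0


def test_kruskal_matches_textbook_formula():
    """H statistic checked against an explicit rank-sum computation."""
    groups = [[0.61, 0.65, 0.70], [0.55, 0.58, 0.60], [0.72, 0.75, 0.80]]
    h, p = kruskal_wallis_auc(groups)
    pooled = np.concatenate(groups)
    ranks = sps.rankdata(pooled)
    n = pooled.size
    offset = 0
    h_direct = 0.0
    for g in groups:
        r = ranks[offset:offset + len(g)]
        h_direct += r.sum() ** 2 / len(g)
        offset += len(g)
    h_direct = 12.0 / (n * (n + 1)) * h_direct - 3 * (n + 1)
    assert h == pytest.approx(h_direct, abs=1e-10)


def test_kruskal_requires_three_groups():
    with pytest.raises(ValueError, match="delong"):
        kruskal_wallis_auc([[0.7, 0.8], [0.6, 0.65]])


def test_contingency_homogeneous_table():
    name, p = contingency_test([[10, 10], [10, 10]])
    assert p == pytest.approx(1.0)


def test_contingency_small_cells_use_fisher():
    name, p = contingency_test([[2, 8], [3, 7]])
    assert name == "fisher"
    assert 0 <= p <= 1


def test_logistic_regression_recovers_known_odds_ratios(rng):
    """ORs estimated on synthetic tabular data sit near exp(beta)."""
    n, k = 4000, 4
    beta = np.array([0.5, -0.4, 0.0, 0.8])
    X = rng.normal(size=(n, k))
    logits = X @ beta - 0.2
    y = rng.random(n) < 1 / (1 + np.exp(-logits))
    hgb = 11.0 - y + rng.normal(0, 1, n)
    feats = pd.DataFrame(X, columns=[f"f{i}" for i in range(k)])
    res = association_regressions(feats, hgb, y)
    tab = res["logistic"].table
    for i, b in enumerate(beta):
        assert tab.loc[f"f{i}", "or_ci_lo"] <= np.exp(b) * 1.25
        assert tab.loc[f"f{i}", "or_ci_hi"] >= np.exp(b) * 0.8
    # null-coefficient feature: CI contains OR = 1
    assert tab.loc["f2", "or_ci_lo"] <= 1 <= tab.loc["f2", "or_ci_hi"]
    # linear fits exist per class with CIs bracketing the point estimate
    lin = res["linear_anemic"].table
    assert ((lin["ci_lo"] <= lin["coef"]) & (lin["coef"] <= lin["ci_hi"])).all()


def test_subgroup_rocs_structure(rng):
    n = 600
    y = rng.random(n) < 0.5
    y[:2] = [True, False]
    scores = y + rng.normal(0, 1, n)
    meta = pd.DataFrame({
        "device": rng.choice(["a", "b", "c"], n),
        "eye": rng.choice(["left", "right"], n),
        "sex": rng.choice(["male", "female"], n),
    })
    out = subgroup_rocs(scores, y, meta, n_boot=50, seed=0)
    assert set(out) == {"device", "eye", "sex"}
    assert out["eye"]["comparison"]["test"] == "delong_unpaired"
    assert out["device"]["comparison"]["test"] == "kruskal_wallis_bootstrap"
    for factor in out:
        for entry in out[factor]["auc"].values():
            assert 0 <= entry["auc"] <= 1


def test_sex_dependent_effect_yields_higher_female_auc(rng):
    """A constructed subgroup effect (stronger score separation for
    females) must surface as a higher female AUC with a significant
    unpaired DeLong comparison."""
    n = 800
    sex = np.where(rng.random(n) < 0.5, "female", "male")
    y = rng.random(n) < 0.5
    y[:2] = [True, False]
    sep = np.where(sex == "female", 2.0, 0.6)
    scores = y * sep + rng.normal(0, 1, n)
    meta = pd.DataFrame({"sex": sex})
    out = subgroup_rocs(scores, y, meta, factors=("sex",), seed=1)
    assert out["sex"]["auc"]["female"]["auc"] > out["sex"]["auc"]["male"]["auc"]
    assert out["sex"]["comparison"]["p"] < 0.01


def test_identical_eyes_rarely_differ(rng):
    """With no eye effect, the left-vs-right comparison stays null in at
    least 90% of runs."""
    ok = 0
    n_runs = 100
    for _ in range(n_runs):
        n = 300
        eye = np.where(rng.random(n) < 0.5, "left", "right")
        y = rng.random(n) < 0.5
        y[:2] = [True, False]
        scores = y + rng.normal(0, 1, n)
        out = subgroup_rocs(scores, y, pd.DataFrame({"eye": eye}),
                            factors=("eye",), seed=0)
        ok += out["eye"]["comparison"]["p"] > 0.05
    assert ok >= 0.9 * n_runs


def test_unpaired_delong_null_is_calibrated(rng):
    """Disjoint-subset DeLong comparison keeps its size under the null."""
    rejections = 0
    n_rep = 200
    for _ in range(n_rep):
        n = 120
        y = rng.random(n) < 0.5
        y[:2] = [True, False]
        s = rng.normal(size=n)
        res = delong_test_unpaired(s[: n // 2], y[: n // 2],
                                   s[n // 2 :], y[n // 2 :])
        rejections += res.p < 0.05
    assert rejections / n_rep < 0.12
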