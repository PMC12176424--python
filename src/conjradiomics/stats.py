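"""Evaluation statistics for photo-level anemia classification.

WHO hemoglobin cutoffs for school-age children, ROC/AUC machinery with
Wald confidence intervals, the DeLong test for correlated ROC curves,
Kruskal-Wallis comparisons of AUC replicates across more than two models,
categorical-table tests, subgroup ROC analyses, and the multivariate
linear/logistic regressions that relate selected radiomic features to
hemoglobin and anemia status.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "who_anemia_label",
    "AucResult",
    "DeLongResult",
    "RegressionResult",
    "auc_mann_whitney",
    "delong_test",
    "delong_test_unpaired",
    "kruskal_wallis_auc",
    "contingency_test",
    "association_regressions",
    "subgroup_rocs",
]

# WHO hemoglobin cutoffs (g/dL) for the 5-15 y study population.
# 5-11 y: 11.5; 12-14 y: 12.0; 15 y: 12.0 (female) / 13.0 (male).
_CUTOFF_5_11 = 11.5
_CUTOFF_12_14 = 12.0
_CUTOFF_15_FEMALE = 12.0
_CUTOFF_15_MALE = 13.0


def who_anemia_label(age_years: int, sex: str, hgb: float) -> bool:
    """Return True if the hemoglobin level is anemic under WHO cutoffs.

    Anemia is defined by a strict ``hgb < cutoff`` comparison, with
    age-banded cutoffs: <11.5 g/dL for ages 5-11, <12.0 for ages 12-14,
    and at age 15, <12.0 for females and <13.0 for males.

    Parameters
    ----------
    age_years : int
        Age in completed years; must lie in [5, 15] (the study population).
    sex : str
        ``"male"`` or ``"female"`` (case-insensitive; ``"M"``/``"F"`` accepted).
    hgb : float
        Blood hemoglobin concentration in g/dL; must be positive.
    """
    if not 5 <= age_years <= 15:
        raise ValueError(f"age {age_years} outside the supported range [5, 15]")
    if hgb <= 0:
        raise ValueError(f"non-positive hemoglobin {hgb}")
    s = str(sex).strip().lower()
    if s in ("male", "m"):
        male = True
    elif s in ("female", "f"):
        male = False
    else:
        raise ValueError(f"unrecognized sex label {sex!r}")
    if age_years <= 11:
        cutoff = _CUTOFF_5_11
    elif age_years <= 14:
        cutoff = _CUTOFF_12_14
    else:
        cutoff = _CUTOFF_15_MALE if male else _CUTOFF_15_FEMALE
    return bool(hgb < cutoff)


@dataclass
class AucResult:
    """ROC summary: AUC, DeLong standard error, Wald 95% CI, curve points."""

    auc: float
    se: float
    ci95: tuple[float, float]
    n_pos: int
    n_neg: int
    curve: tuple[np.ndarray, np.ndarray]  # (fpr, tpr)

    def as_dict(self) -> dict:
        return {
            "auc": self.auc,
            "se": self.se,
            "ci95": list(self.ci95),
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
        }


@dataclass
class DeLongResult:
    """Paired (or unpaired) comparison of two ROC AUCs."""

    auc_a: float
    auc_b: float
    var_diff: float
    z: float
    p: float
    paired: bool = True


@dataclass
class RegressionResult:
    """Per-feature coefficients with Wald 95% CIs and p-values.

    For the logistic case ``odds_ratios`` holds exp(coefficients) and the
    CI columns are on the odds-ratio scale as well.
    """

    table: pd.DataFrame
    kind: str  # "linear" | "logistic"
    flags: list[str] = field(default_factory=list)


def _validate_scores_labels(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D arrays")
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present to compute an ROC")
    return scores, labels


def _placements(scores: np.ndarray, labels: np.ndarray):
    """Structural components (placement values) of the Mann-Whitney AUC.

    Returns (auc, v10, v01): v10[i] is the probability that positive case i
    outscores a random negative (ties half), v01 analogously per negative.
    Midrank-based, O(n log n).
    """
    pos = scores[labels]
    neg = scores[~labels]
    m, n = pos.size, neg.size
    all_scores = np.concatenate([pos, neg])
    ranks = sps.rankdata(all_scores)  # midranks over pooled sample
    ranks_pos = sps.rankdata(pos)
    ranks_neg = sps.rankdata(neg)
    v10 = (ranks[:m] - ranks_pos) / n
    v01 = 1.0 - (ranks[m:] - ranks_neg) / m
    auc = float(v10.mean())
    return auc, v10, v01


def _roc_curve(scores: np.ndarray, labels: np.ndarray):
    """ROC points from all score thresholds, highest threshold first."""
    order = np.argsort(-scores, kind="mergesort")
    s, y = scores[order], labels[order]
    # thresholds at distinct score values
    distinct = np.r_[np.nonzero(np.diff(s))[0], s.size - 1]
    tps = np.cumsum(y)[distinct]
    fps = (distinct + 1) - tps
    tpr = np.r_[0.0, tps / y.sum()]
    fpr = np.r_[0.0, fps / (~labels).sum()]
    return fpr, tpr


def auc_mann_whitney(scores, labels) -> AucResult:
    """AUC as the Mann-Whitney rank statistic with a DeLong Wald 95% CI.

    The AUC equals the fraction of (positive, negative) pairs where the
    positive scores higher, counting ties as one half. The standard error
    comes from the DeLong structural-component variance; the CI is
    ``auc +/- 1.96 se`` truncated to [0, 1].
    """
    scores, labels = _validate_scores_labels(scores, labels)
    auc, v10, v01 = _placements(scores, labels)
    m, n = v10.size, v01.size
    var = 0.0
    if m > 1:
        var += np.var(v10, ddof=1) / m
    if n > 1:
        var += np.var(v01, ddof=1) / n
    se = float(np.sqrt(var))
    lo = max(0.0, auc - 1.96 * se)
    hi = min(1.0, auc + 1.96 * se)
    fpr, tpr = _roc_curve(scores, labels)
    return AucResult(auc=auc, se=se, ci95=(lo, hi), n_pos=m, n_neg=n, curve=(fpr, tpr))


def delong_test(scores_a, scores_b, labels) -> DeLongResult:
    """DeLong test for two correlated ROC curves scored on the same cases.

    Uses per-case placement values; the variance of the AUC difference
    includes the covariance term induced by the shared cases. Two-sided
    normal p-value. Identical scores (zero variance of the difference and
    equal AUCs) return p = 1 by convention.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    if scores_a.shape != scores_b.shape:
        raise ValueError("paired DeLong requires both models to score the same rows")
    _, labels = _validate_scores_labels(scores_a, labels)
    auc_a, v10_a, v01_a = _placements(scores_a, labels)
    auc_b, v10_b, v01_b = _placements(scores_b, labels)
    m, n = v10_a.size, v01_a.size
    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1) if n > 1 else np.zeros((2, 2))
    var_diff = float(
        (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    )
    diff = auc_a - auc_b
    if var_diff <= 0:
        z = 0.0 if diff == 0 else np.inf * np.sign(diff)
        p = 1.0 if diff == 0 else 0.0
    else:
        z = diff / np.sqrt(var_diff)
        p = float(2 * sps.norm.sf(abs(z)))
    return DeLongResult(auc_a=auc_a, auc_b=auc_b, var_diff=var_diff, z=float(z), p=p)


def delong_test_unpaired(scores_a, labels_a, scores_b, labels_b) -> DeLongResult:
    """DeLong-style comparison of AUCs from disjoint case subsets.

    Subgroup comparisons (left vs right eye, male vs female) score different
    rows, so the covariance term vanishes and the variance of the difference
    is the sum of the two DeLong variances.
    """
    ra = auc_mann_whitney(scores_a, labels_a)
    rb = auc_mann_whitney(scores_b, labels_b)
    var_diff = ra.se**2 + rb.se**2
    diff = ra.auc - rb.auc
    if var_diff <= 0:
        z = 0.0 if diff == 0 else np.inf * np.sign(diff)
        p = 1.0 if diff == 0 else 0.0
    else:
        z = diff / np.sqrt(var_diff)
        p = float(2 * sps.norm.sf(abs(z)))
    return DeLongResult(
        auc_a=ra.auc, auc_b=rb.auc, var_diff=float(var_diff), z=float(z), p=p,
        paired=False,
    )


def kruskal_wallis_auc(per_group_auc_samples) -> tuple[float, float]:
    """Kruskal-Wallis H test across >=3 groups of AUC replicates.

    Each group is a sequence of AUC values (e.g. bootstrap resamples of the
    test set restricted to one device). Returns (H, p) with tie correction.
    For two groups the DeLong test is the appropriate tool and a ValueError
    says so.
    """
    groups = [np.asarray(g, dtype=float) for g in per_group_auc_samples]
    if len(groups) < 3:
        raise ValueError("fewer than 3 groups: use delong_test for pairwise comparison")
    if any(g.size < 2 for g in groups):
        raise ValueError("each group needs at least 2 AUC replicates")
    if all(np.array_equal(g, groups[0]) for g in groups[1:]):
        return 0.0, 1.0  # identical samples: no rank separation
    h, p = sps.kruskal(*groups)
    return float(h), float(p)


def contingency_test(table) -> tuple[str, float]:
    """Chi-square test of a contingency table, or Fisher's exact for 2x2
    tables with any expected cell below 5. Returns (test_name, p)."""
    table = np.asarray(table, dtype=float)
    chi2, p, dof, expected = sps.chi2_contingency(table, correction=False)
    if table.shape == (2, 2) and (expected < 5).any():
        _, p = sps.fisher_exact(table)
        return "fisher", float(p)
    return "chi2", float(p)


def association_regressions(
    features: pd.DataFrame,
    hgb,
    anemia_labels,
) -> dict[str, RegressionResult]:
    """Multivariate association models between selected features and anemia.

    Fits (a) linear regressions of hemoglobin on the (Z-scored) selected
    features, separately within the anemic and nonanemic groups, reporting
    slope coefficients with Wald 95% CIs; and (b) a multivariate logistic
    regression of anemia status on all features jointly, reporting odds
    ratios with Wald 95% CIs. Perfect separation in the logistic fit falls
    back to an L2-penalized fit (flagged; no CIs in that case).

    Returns a dict with keys ``linear_anemic``, ``linear_nonanemic``,
    ``logistic``.
    """
    X = pd.DataFrame(features).astype(float)
    if X.isna().any().any():
        raise ValueError("features must be imputed before regression")
    hgb = np.asarray(hgb, dtype=float)
    y = np.asarray(anemia_labels).astype(int)

    out: dict[str, RegressionResult] = {}
    for name, sel in (("linear_anemic", y == 1), ("linear_nonanemic", y == 0)):
        Xg = sm.add_constant(X.loc[sel], has_constant="add")
        fit = sm.OLS(hgb[sel], Xg).fit()
        ci = fit.conf_int(alpha=0.05)
        tab = pd.DataFrame(
            {
                "coef": fit.params,
                "ci_lo": ci[0],
                "ci_hi": ci[1],
                "p": fit.pvalues,
            }
        ).drop(index="const")
        out[name] = RegressionResult(table=tab, kind="linear")

    Xl = sm.add_constant(X, has_constant="add")
    flags: list[str] = []
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, Xl).fit(disp=0, maxiter=200)
        if not fit.mle_retvals.get("converged", True):
            raise sps.FitError("logistic MLE did not converge")
        ci = fit.conf_int(alpha=0.05)
        tab = pd.DataFrame(
            {
                "coef": fit.params,
                "odds_ratio": np.exp(fit.params),
                "or_ci_lo": np.exp(ci[0]),
                "or_ci_hi": np.exp(ci[1]),
                "p": fit.pvalues,
            }
        ).drop(index="const")
    except Exception:
        # Perfect separation or non-convergence: penalized likelihood fallback.
        flags.append("logistic fit fell back to L2-penalized likelihood")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, Xl).fit_regularized(
                disp=0, alpha=1.0, L1_wt=0.0, maxiter=500
            )
        params = pd.Series(np.asarray(fit.params).ravel(), index=Xl.columns)
        tab = pd.DataFrame(
            {
                "coef": params,
                "odds_ratio": np.exp(params),
                "or_ci_lo": np.nan,
                "or_ci_hi": np.nan,
                "p": np.nan,
            }
        ).drop(index="const")
    out["logistic"] = RegressionResult(table=tab, kind="logistic", flags=flags)
    return out


def _bootstrap_aucs(scores, labels, n_boot, rng):
    scores = np.asarray(scores, float)
    labels = np.asarray(labels).astype(bool)
    n = scores.size
    aucs = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        y = labels[idx]
        if y.all() or not y.any():
            continue
        auc, _, _ = _placements(scores[idx], y)
        aucs.append(auc)
    return np.asarray(aucs)


def subgroup_rocs(
    scores,
    labels,
    metadata: pd.DataFrame,
    factors: tuple[str, ...] = ("device", "eye", "sex"),
    n_boot: int = 200,
    seed: int = 0,
) -> dict:
    """Per-subgroup AUCs with the matching comparison for each factor.

    Two-level factors (eye, sex) are compared with the unpaired DeLong
    variant on the disjoint subsets; factors with three or more levels
    (device) are compared with a Kruskal-Wallis test over seeded bootstrap
    AUC replicates of each level's test rows. Subgroups containing a single
    class are skipped with a warning entry.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    rng = np.random.default_rng(seed)
    results: dict = {}
    for factor in factors:
        if factor not in metadata.columns:
            continue
        levels = sorted(metadata[factor].astype(str).unique())
        per_level: dict[str, AucResult] = {}
        skipped: list[str] = []
        for lev in levels:
            sel = (metadata[factor].astype(str) == lev).to_numpy()
            y = labels[sel]
            if y.all() or not y.any():
                skipped.append(lev)
                continue
            per_level[lev] = auc_mann_whitney(scores[sel], y)
        entry: dict = {"auc": {k: v.as_dict() for k, v in per_level.items()}}
        if skipped:
            entry["skipped_single_class"] = skipped
        usable = list(per_level)
        if len(usable) == 2:
            a, b = usable
            sel_a = (metadata[factor].astype(str) == a).to_numpy()
            sel_b = (metadata[factor].astype(str) == b).to_numpy()
            res = delong_test_unpaired(
                scores[sel_a], labels[sel_a], scores[sel_b], labels[sel_b]
            )
            entry["comparison"] = {
                "test": "delong_unpaired",
                "levels": [a, b],
                "p": res.p,
                "z": res.z,
            }
        elif len(usable) >= 3:
            boots = []
            for lev in usable:
                sel = (metadata[factor].astype(str) == lev).to_numpy()
                boots.append(_bootstrap_aucs(scores[sel], labels[sel], n_boot, rng))
            h, p = kruskal_wallis_auc(boots)
            entry["comparison"] = {
                "test": "kruskal_wallis_bootstrap",
                "levels": usable,
                "H": h,
                "p": p,
                "n_boot": n_boot,
            }
        results[factor] = entry
    return results
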