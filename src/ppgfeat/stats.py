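"""Group comparison, stepwise-forward feature ranking and incremental
logistic-regression evaluation.

Feature importance follows the two-cohort design this pipeline serves:
within each of 7 repeats of a 7-fold stratified cross-validation, greedy
forward selection adds at every step the feature that maximizes the mean
left-out-fold AUROC of an (effectively unpenalized) logistic model with
training-fold z-scoring; a Borda-count popularity vote across the repeats'
rankings picks the final top-10.  Incremental evaluation then reports the
AUROC mean and sd over the 7x7 left-out folds as the ranked features are
added one by one, either treating segments as independent or grouping all of
a participant's segments into the same fold.

Candidate pools: ``"hrv"`` (30 features), ``"morph"`` (37 minus PWD — PWD is
the reciprocal of mean heart rate in disguise and is excluded from ranking),
``"combined"`` (66).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold

from .hrv import HRV_FEATURE_NAMES
from .morphology import MORPH_FEATURE_NAMES

__all__ = [
    "EffectSizeResult",
    "RankingResult",
    "candidate_pool",
    "cohens_d",
    "group_compare",
    "rank_features",
    "evaluate_incremental",
    "age_trend",
    "condition_compare",
]

N_FOLDS = 7
N_REPEATS = 7
TOP_K = 10


def candidate_pool(feature_set: str) -> list:
    """Feature names eligible for ranking in a given set."""
    fs = feature_set.lower()
    if fs == "hrv":
        return list(HRV_FEATURE_NAMES)
    if fs == "morph":
        return [f for f in MORPH_FEATURE_NAMES if f != "pwd"]
    if fs == "combined":
        return list(HRV_FEATURE_NAMES) + [f for f in MORPH_FEATURE_NAMES if f != "pwd"]
    raise ValueError(f"unknown feature set: {feature_set!r}")


# ---------------------------------------------------------------- group stats

@dataclass
class EffectSizeResult:
    feature: str
    cohens_d: float
    ci_low: float
    ci_high: float
    mann_whitney_p: float
    median_a: float
    iqr_a: tuple
    median_b: float
    iqr_b: tuple


def cohens_d(x: np.ndarray, y: np.ndarray) -> float:
    """Standardized mean difference with the pooled (n-1) sd."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    nx, ny = len(x), len(y)
    pooled = math.sqrt(
        ((nx - 1) * np.var(x, ddof=1) + (ny - 1) * np.var(y, ddof=1)) / (nx + ny - 2)
    )
    if pooled == 0:
        return math.nan
    return float((np.mean(x) - np.mean(y)) / pooled)


def group_compare(
    df: pd.DataFrame,
    features: list,
    label_col: str = "group",
    groups: tuple = ("A", "B"),
    n_boot: int = 2000,
    seed: int = 0,
) -> list:
    """Per-feature Mann-Whitney U (two-sided) and Cohen's d with bootstrap CI.

    The 95% CI is a percentile bootstrap over segments (``n_boot``
    resamples, seeded).  Features with zero pooled sd or an empty group come
    back with NaN effect size.
    """
    rng = np.random.default_rng(seed)
    out = []
    for feat in features:
        a = df.loc[df[label_col] == groups[0], feat].dropna().to_numpy()
        b = df.loc[df[label_col] == groups[1], feat].dropna().to_numpy()
        if len(a) == 0 or len(b) == 0:
            raise ValueError(f"empty group for feature {feat!r}")
        d = cohens_d(a, b)
        if len(a) > 1 and len(b) > 1 and (np.std(a) > 0 or np.std(b) > 0):
            p = float(sstats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
        else:
            p = math.nan
        if math.isfinite(d):
            boots = np.empty(n_boot)
            for i in range(n_boot):
                boots[i] = cohens_d(
                    a[rng.integers(0, len(a), len(a))], b[rng.integers(0, len(b), len(b))]
                )
            ci_low, ci_high = np.nanpercentile(boots, [2.5, 97.5])
        else:
            ci_low = ci_high = math.nan
        qa = np.percentile(a, [25, 50, 75])
        qb = np.percentile(b, [25, 50, 75])
        out.append(
            EffectSizeResult(
                feature=feat, cohens_d=d, ci_low=float(ci_low), ci_high=float(ci_high),
                mann_whitney_p=p, median_a=float(qa[1]), iqr_a=(float(qa[0]), float(qa[2])),
                median_b=float(qb[1]), iqr_b=(float(qb[0]), float(qb[2])),
            )
        )
    return out


def condition_compare(
    df_first: pd.DataFrame, df_second: pd.DataFrame, features: list, **kwargs
) -> list:
    """Two-condition comparison (e.g. first vs second recording night).

    Same machinery and output schema as :func:`group_compare`, with the two
    conditions standing in for the two groups.
    """
    a = df_first.copy()
    b = df_second.copy()
    a["_condition"] = "first"
    b["_condition"] = "second"
    merged = pd.concat([a, b], ignore_index=True)
    return group_compare(
        merged, features, label_col="_condition", groups=("first", "second"), **kwargs
    )


# ------------------------------------------------------------------- ranking

@dataclass
class RankingResult:
    feature_set: str
    rankings: list  # one ordered list of feature names per repeat
    popularity: dict = field(default_factory=dict)  # Borda points per feature
    top: list = field(default_factory=list)  # final ordered top-10


def _prepared(df: pd.DataFrame, features: list, label_col: str, pos_label):
    """Drop rows with missing candidate features; return X, y and subjects."""
    sub = df.dropna(subset=features)
    X = sub[features].to_numpy(dtype=float)
    y = (sub[label_col] == pos_label).to_numpy(dtype=int)
    subjects = sub["subject"].to_numpy() if "subject" in sub else np.arange(len(sub))
    return X, y, subjects


def _fold_auroc(X, y, cols, train, test) -> float:
    """AUROC of a logistic model on one fold, z-scored on the training fold."""
    Xtr, Xte = X[np.ix_(train, cols)], X[np.ix_(test, cols)]
    mu = Xtr.mean(axis=0)
    sd = Xtr.std(axis=0)
    sd[sd == 0] = 1.0
    clf = LogisticRegression(C=1e6, max_iter=1000)
    clf.fit((Xtr - mu) / sd, y[train])
    if len(np.unique(y[test])) < 2:
        return math.nan
    return roc_auc_score(y[test], clf.decision_function((Xte - mu) / sd))


def rank_features(
    df: pd.DataFrame,
    feature_set: str = "combined",
    label_col: str = "group",
    pos_label: str = "B",
    n_folds: int = N_FOLDS,
    n_repeats: int = N_REPEATS,
    depth: int = TOP_K,
    seed: int = 0,
    features: list | None = None,
) -> RankingResult:
    """Stepwise-forward feature ranking with a popularity vote across repeats.

    Each repeat reshuffles its stratified folds with a distinct seed, runs
    greedy forward selection to ``depth`` features (score = mean left-out
    AUROC over the folds), and contributes a Borda vote
    (``depth - position`` points per ranked feature).  Ties in the final
    popularity break by mean rank, then name.
    """
    if features is None:
        features = candidate_pool(feature_set)
    X, y, _ = _prepared(df, features, label_col, pos_label)
    if len(np.unique(y)) < 2:
        raise ValueError("need both classes present")
    depth = min(depth, len(features))

    rankings = []
    for rep in range(n_repeats):
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed + rep)
        folds = list(skf.split(X, y))
        selected: list = []
        remaining = list(range(len(features)))
        for _ in range(depth):
            best_j, best_score = None, -np.inf
            for j in remaining:
                cols = selected + [j]
                scores = [_fold_auroc(X, y, cols, tr, te) for tr, te in folds]
                score = float(np.nanmean(scores))
                if score > best_score:
                    best_j, best_score = j, score
            selected.append(best_j)
            remaining.remove(best_j)
        rankings.append([features[j] for j in selected])

    popularity: dict = {}
    positions: dict = {}
    for ranking in rankings:
        for pos, feat in enumerate(ranking):
            popularity[feat] = popularity.get(feat, 0) + (depth - pos)
            positions.setdefault(feat, []).append(pos)
    ordered = sorted(
        popularity,
        key=lambda f: (-popularity[f], float(np.mean(positions[f])), f),
    )
    return RankingResult(
        feature_set=feature_set,
        rankings=rankings,
        popularity=popularity,
        top=ordered[:TOP_K],
    )


def evaluate_incremental(
    df: pd.DataFrame,
    ranked_features: list,
    label_col: str = "group",
    pos_label: str = "B",
    stratification: str = "segment",
    n_folds: int = N_FOLDS,
    n_repeats: int = N_REPEATS,
    seed: int = 0,
) -> pd.DataFrame:
    """AUROC-vs-feature-count curve over the 7x7 left-out folds.

    ``stratification='segment'`` treats every segment as independent;
    ``'participant'`` keeps each subject's segments in the same fold
    (grouped, class-stratified splits).  Folds whose test set is
    single-class are skipped in the mean.  Returns a DataFrame with columns
    ``k``, ``feature``, ``auroc_mean``, ``auroc_sd``.
    """
    X, y, subjects = _prepared(df, list(ranked_features), label_col, pos_label)
    rows = []
    for k in range(1, len(ranked_features) + 1):
        cols = list(range(k))
        scores = []
        for rep in range(n_repeats):
            if stratification == "participant":
                sgkf = StratifiedGroupKFold(n_splits=n_folds, shuffle=True, random_state=seed + rep)
                folds = sgkf.split(X, y, groups=subjects)
            elif stratification == "segment":
                skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed + rep)
                folds = skf.split(X, y)
            else:
                raise ValueError("stratification must be 'segment' or 'participant'")
            for tr, te in folds:
                scores.append(_fold_auroc(X, y, cols, tr, te))
        scores = np.asarray(scores, dtype=float)
        rows.append(
            {
                "k": k,
                "feature": ranked_features[k - 1],
                "auroc_mean": float(np.nanmean(scores)),
                "auroc_sd": float(np.nanstd(scores)),
                "stratification": stratification,
            }
        )
    return pd.DataFrame(rows)


# ----------------------------------------------------------------- age trend

def age_trend(df: pd.DataFrame, features: list, age_col: str = "age") -> pd.DataFrame:
    """Per-feature OLS of the subject-averaged feature on age.

    Multiple segments per subject are first averaged so each subject
    contributes one value.  Returns slope, intercept and the two-sided p of
    the slope per feature.
    """
    per_subject = df.groupby("subject").agg({age_col: "first", **{f: "mean" for f in features}})
    if len(per_subject) < 3:
        raise ValueError("need at least 3 subjects")
    ages = per_subject[age_col].to_numpy(dtype=float)
    if np.std(ages) == 0:
        raise ValueError("ages are constant; regression undefined")
    rows = []
    for feat in features:
        vals = per_subject[feat].to_numpy(dtype=float)
        good = np.isfinite(vals)
        if good.sum() < 3:
            rows.append({"feature": feat, "slope": math.nan, "intercept": math.nan, "p": math.nan})
            continue
        res = sstats.linregress(ages[good], vals[good])
        rows.append(
            {"feature": feat, "slope": float(res.slope), "intercept": float(res.intercept),
             "p": float(res.pvalue)}
        )
    return pd.DataFrame(rows)
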