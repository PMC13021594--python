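"""Cohort-level statistics: stratification, balancing, cross-validated
sex/age models, group-difference indicator tables and Romberg-quotient
analyses.

The protocol mirrors a large posturographic cohort study design:

* subjects are stratified into five age groups (65–69, 70–74, 75–79, 80–84,
  ≥85);
* the sexes are balanced by selecting, per age stratum, a seeded random
  subset of females matching the male count;
* balanced subjects are shuffled within sex, paired, arranged in an
  alternating male/female sequence and split into 10 mutually exclusive
  folds of whole pairs (leftover pairs stay in training for every round);
* a binary classification tree predicts sex from log-transformed features;
  linear models and regression trees predict age per sex;
* per-feature group differences use the two-sample rank-sum
  (Wilcoxon–Mann–Whitney) test at α = 0.05 with no multiplicity correction,
  reported as 0/1 indicator tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.linear_model import LinearRegression, LogisticRegression
from sklearn.model_selection import GridSearchCV, KFold
from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor, export_text

from .exceptions import BalanceError, InputError, SwaylabError

__all__ = [
    "stratify_age_groups",
    "balance_by_age",
    "interleave_and_fold",
    "sex_classification_cv",
    "age_prediction",
    "group_difference_tests",
    "correlation_table",
    "rq_cohort_analysis",
    "ClassificationReport",
    "AgeModelReport",
    "GroupComparisonTable",
]

SEX_FEATURES = ["cy", "m_my", "zcr_vx", "cri_t", "st_n"]
AGE_FEATURES = ["cy", "zcr_y", "cri_t", "st_n"]
SIX_FEATURES = ["cy", "m_my", "zcr_y", "zcr_vx", "cri_t", "st_n"]

#: Numeric sex coding used for correlation and logistic analyses.
SEX_CODE = {"male": 0, "female": 1}


def stratify_age_groups(ages) -> np.ndarray:
    """Map ages (years, ≥65) to group labels 1–5.

    Bins: 65–69 → 1, 70–74 → 2, 75–79 → 3, 80–84 → 4, ≥85 → 5 (inclusive
    boundaries as printed: 70 is group 2, 85 is group 5).
    """
    ages = np.asarray(ages, dtype=float)
    if np.any(ages < 65):
        bad = ages[ages < 65]
        raise SwaylabError(f"ages below 65 are out of range: {bad[:5]}")
    return np.minimum((ages - 65) // 5, 4).astype(int) + 1


def balance_by_age(
    cohort: pd.DataFrame, seed: int, age_col: str = "age", sex_col: str = "sex"
) -> pd.DataFrame:
    """Select females matching the male age distribution, stratum by stratum.

    All males are kept; within each age group a seeded random subset of
    females of exactly the male count is drawn without replacement. The
    result has equal sex totals and per-stratum counts.
    """
    df = cohort.copy()
    df["_age_group"] = stratify_age_groups(df[age_col].to_numpy())
    rng = np.random.default_rng(seed)
    keep = []
    for grp, sub in df.groupby("_age_group", sort=True):
        males = sub[sub[sex_col] == "male"]
        females = sub[sub[sex_col] == "female"]
        if len(females) < len(males):
            raise BalanceError(
                f"age group {grp}: {len(females)} females < {len(males)} males"
            )
        keep.append(males)
        chosen = rng.choice(females.index.to_numpy(), size=len(males), replace=False)
        keep.append(females.loc[np.sort(chosen)])
    out = pd.concat(keep).drop(columns="_age_group")
    return out.sort_index()


def interleave_and_fold(
    balanced: pd.DataFrame, k: int = 10, seed: int = 0, sex_col: str = "sex"
) -> pd.Series:
    """Alternating male/female fold assignment for k-fold cross-validation.

    Males and females are shuffled independently, paired positionally, and
    the pair sequence is cut into ``k`` mutually exclusive folds. Pairs left
    over when the total is not divisible by ``k`` are assigned fold −1 and
    stay in the training set of every round, so each test fold holds exactly
    ``n_pairs // k`` subjects of each sex.

    Returns a fold id per input row (index-aligned), −1 marking
    permanent-training rows.
    """
    males = balanced.index[balanced[sex_col] == "male"].to_numpy()
    females = balanced.index[balanced[sex_col] == "female"].to_numpy()
    if len(males) != len(females):
        raise InputError(
            f"sex counts must be equal, got {len(males)} males, {len(females)} females"
        )
    rng = np.random.default_rng(seed)
    rng.shuffle(males)
    rng.shuffle(females)
    n_pairs = len(males)
    per_fold = n_pairs // k
    if per_fold == 0:
        raise InputError(f"{n_pairs} pairs cannot fill {k} folds")
    fold = pd.Series(-1, index=balanced.index, dtype=int, name="fold")
    for f in range(k):
        sel = slice(f * per_fold, (f + 1) * per_fold)
        fold.loc[males[sel]] = f
        fold.loc[females[sel]] = f
    return fold


@dataclass
class ClassificationReport:
    fold_accuracies: list
    mean_accuracy: float  # percent
    sd_accuracy: float  # percent
    male_as_female_rate: float  # percent of males misclassified
    female_as_male_rate: float  # percent of females misclassified
    tree_text: str = ""
    confusion: dict = field(default_factory=dict)


def _log_design(df: pd.DataFrame, features: Sequence[str]) -> np.ndarray:
    """Natural-log transform of strictly positive feature columns.

    Non-positive or missing values are replaced per-column by the log of the
    smallest positive value (they cannot be log-transformed; the replacement
    keeps the row usable while flagging nothing upstream).
    """
    X = df[list(features)].to_numpy(dtype=float)
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        col = X[:, j]
        pos = col > 0
        if not np.any(pos):
            out[:, j] = 0.0
            continue
        floor = np.log(col[pos].min())
        out[:, j] = np.where(pos, np.log(np.where(pos, col, 1.0)), floor)
    return out


def _prune_tree(X, y, seed, classifier=True, min_leaf=20):
    """Cost-complexity-pruned tree, alpha chosen by a small inner CV."""
    cls = DecisionTreeClassifier if classifier else DecisionTreeRegressor
    base = cls(min_samples_leaf=min_leaf, random_state=seed)
    path = base.cost_complexity_pruning_path(X, y)
    alphas = np.unique(path.ccp_alphas)
    alphas = alphas[alphas >= 0]
    if len(alphas) > 8:
        alphas = np.quantile(alphas, np.linspace(0, 0.9, 8))
    gs = GridSearchCV(
        cls(min_samples_leaf=min_leaf, random_state=seed),
        {"ccp_alpha": alphas},
        cv=3,
        n_jobs=None,
    )
    gs.fit(X, y)
    return gs.best_estimator_


def sex_classification_cv(
    features: pd.DataFrame,
    folds: pd.Series,
    feature_cols: Sequence[str] = tuple(SEX_FEATURES),
    sex_col: str = "sex",
    log_transform: bool = True,
    seed: int = 0,
    min_leaf: int = 20,
) -> ClassificationReport:
    """K-fold cross-validated decision-tree sex classification.

    Trains a pruned binary classification tree on the training folds of each
    round (including permanent-training rows) and evaluates on the held-out
    fold; reports mean ± SD accuracy and the directional misclassification
    rates, plus a text export of the final round's tree.
    """
    df = features.loc[folds.index]
    X = _log_design(df, feature_cols) if log_transform else df[
        list(feature_cols)
    ].to_numpy(dtype=float)
    y = df[sex_col].map(SEX_CODE).to_numpy()
    accs, tree_text = [], ""
    conf = np.zeros((2, 2), dtype=int)  # rows: true sex code, cols: predicted
    for f in sorted(folds[folds >= 0].unique()):
        test = (folds == f).to_numpy()
        train = ~test
        tree = _prune_tree(X[train], y[train], seed=seed, min_leaf=min_leaf)
        pred = tree.predict(X[test])
        accs.append(float(np.mean(pred == y[test])))
        for t, p in zip(y[test], pred):
            conf[t, p] += 1
        tree_text = export_text(tree, feature_names=list(feature_cols))
    accs = [a * 100.0 for a in accs]
    m2f = 100.0 * conf[0, 1] / max(conf[0].sum(), 1)
    f2m = 100.0 * conf[1, 0] / max(conf[1].sum(), 1)
    return ClassificationReport(
        fold_accuracies=accs,
        mean_accuracy=float(np.mean(accs)),
        sd_accuracy=float(np.std(accs, ddof=1)) if len(accs) > 1 else 0.0,
        male_as_female_rate=float(m2f),
        female_as_male_rate=float(f2m),
        tree_text=tree_text,
        confusion={
            "male_correct": int(conf[0, 0]), "male_as_female": int(conf[0, 1]),
            "female_as_male": int(conf[1, 0]), "female_correct": int(conf[1, 1]),
        },
    )


@dataclass
class AgeModelReport:
    model_type: str
    cv_residual_sd: float  # years
    in_sample_residual_sd: float
    r_squared: float
    f_statistic: float
    f_pvalue: float
    n: int


def age_prediction(
    features: pd.DataFrame,
    feature_cols: Sequence[str] = tuple(AGE_FEATURES),
    age_col: str = "age",
    model: str = "linear",
    k: int = 10,
    seed: int = 0,
    log_transform: bool = True,
) -> AgeModelReport:
    """Cross-validated age prediction from sway features (one sex at a time).

    The headline number is the SD of the cross-validated prediction error in
    years; R² and the F statistic come from the in-sample OLS fit. ``model``
    selects a linear model or a pruned regression tree.
    """
    if model not in ("linear", "tree"):
        raise SwaylabError(f"model must be 'linear' or 'tree', got {model!r}")
    df = features.dropna(subset=list(feature_cols) + [age_col])
    n = len(df)
    if n < 30:
        import warnings

        warnings.warn(f"only {n} subjects; age model estimates will be unstable")
    X = _log_design(df, feature_cols) if log_transform else df[
        list(feature_cols)
    ].to_numpy(dtype=float)
    y = df[age_col].to_numpy(dtype=float)

    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    cv_resid = np.empty(n)
    for train, test in kf.split(X):
        if model == "linear":
            est = LinearRegression().fit(X[train], y[train])
        else:
            est = _prune_tree(X[train], y[train], seed=seed, classifier=False)
        cv_resid[test] = y[test] - est.predict(X[test])

    ols = sm.OLS(y, sm.add_constant(X)).fit()
    return AgeModelReport(
        model_type=model,
        cv_residual_sd=float(np.std(cv_resid, ddof=1)),
        in_sample_residual_sd=float(np.std(ols.resid, ddof=1)),
        r_squared=float(ols.rsquared),
        f_statistic=float(ols.fvalue),
        f_pvalue=float(ols.f_pvalue),
        n=n,
    )


@dataclass
class GroupComparisonTable:
    """0/1 significance indicators (and p-values) per comparison × feature."""

    indicators: pd.DataFrame
    p_values: pd.DataFrame
    test_name: str = "rank-sum"
    alpha: float = 0.05


def group_difference_tests(
    features: pd.DataFrame,
    grouping: str,
    feature_cols: Sequence[str] = tuple(SIX_FEATURES),
    alpha: float = 0.05,
    sex_col: str = "sex",
    age_col: str = "age",
    sex: Optional[str] = None,
) -> GroupComparisonTable:
    """Rank-sum indicator tables of group differences.

    ``grouping='sex_within_age_group'`` compares males vs females inside each
    of the five age groups (rows 1–5). ``grouping='successive_age_groups'``
    compares consecutive age groups (rows "1-2" … "4-5"), optionally within
    one sex. Indicator is 1 iff the two-sided Mann–Whitney p-value is below
    ``alpha``; no multiple-testing correction is applied. Comparisons with
    fewer than 3 subjects on either side are skipped (NaN) with a warning.
    """
    import warnings

    df = features.copy()
    df["_age_group"] = stratify_age_groups(df[age_col].to_numpy())
    if sex is not None:
        df = df[df[sex_col] == sex]

    if grouping == "sex_within_age_group":
        comparisons = [
            (str(g), df[(df._age_group == g) & (df[sex_col] == "male")],
             df[(df._age_group == g) & (df[sex_col] == "female")])
            for g in range(1, 6)
        ]
    elif grouping == "successive_age_groups":
        comparisons = [
            (f"{g}-{g + 1}", df[df._age_group == g], df[df._age_group == g + 1])
            for g in range(1, 5)
        ]
    else:
        raise SwaylabError(f"unknown grouping {grouping!r}")

    ind = pd.DataFrame(index=[c[0] for c in comparisons], columns=list(feature_cols),
                       dtype=float)
    pvals = ind.copy()
    for label, a, b in comparisons:
        for col in feature_cols:
            va = pd.to_numeric(a[col], errors="coerce").dropna()
            vb = pd.to_numeric(b[col], errors="coerce").dropna()
            if len(va) < 3 or len(vb) < 3:
                warnings.warn(f"comparison {label}/{col} skipped: group too small")
                continue
            p = stats.mannwhitneyu(va, vb, alternative="two-sided").pvalue
            pvals.loc[label, col] = p
            ind.loc[label, col] = float(p < alpha)
    return GroupComparisonTable(indicators=ind, p_values=pvals, alpha=alpha)


def correlation_table(
    features: pd.DataFrame,
    feature_cols: Sequence[str] = tuple(SIX_FEATURES),
    age_col: str = "age",
    sex_col: str = "sex",
) -> pd.DataFrame:
    """Pairwise Pearson correlations of the six features, age and sex.

    Sex is coded male = 0, female = 1. Constant columns yield NaN entries.
    """
    df = features.copy()
    cols = list(feature_cols) + [age_col]
    mat = df[cols].apply(pd.to_numeric, errors="coerce")
    mat["sex"] = df[sex_col].map(SEX_CODE)
    if len(mat.dropna()) < 3:
        raise InputError("need at least 3 complete rows")
    return mat.corr()


def rq_cohort_analysis(
    rq_table: pd.DataFrame,
    path_col: str = "rq_path",
    vel_col: str = "rq_velocity",
    sex_col: str = "sex",
    age_col: str = "age",
    k: int = 10,
    seed: int = 0,
) -> dict:
    """The Romberg-quotient benchmark battery.

    Computes, per cohort: the correlation between the path- and velocity-based
    RQ variants; the rank-sum sex comparison per variant; cross-validated
    logistic-regression sex-classification accuracy from both RQs; one-way
    ANOVA of each RQ across the five age groups; and a cross-validated
    decision-tree age-group (5-class) accuracy.
    """
    df = rq_table.dropna(subset=[path_col, vel_col]).copy()
    df["_age_group"] = stratify_age_groups(df[age_col].to_numpy())
    X = np.log(df[[path_col, vel_col]].to_numpy(dtype=float))
    y_sex = df[sex_col].map(SEX_CODE).to_numpy()
    corr = float(np.corrcoef(df[path_col], df[vel_col])[0, 1])

    sex_p = {
        name: float(
            stats.mannwhitneyu(
                df.loc[df[sex_col] == "male", col],
                df.loc[df[sex_col] == "female", col],
                alternative="two-sided",
            ).pvalue
        )
        for name, col in [("path", path_col), ("velocity", vel_col)]
    }

    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    logit_acc, tree_acc = [], []
    y_grp = df["_age_group"].to_numpy()
    for train, test in kf.split(X):
        lr = LogisticRegression(max_iter=1000).fit(X[train], y_sex[train])
        logit_acc.append(float(np.mean(lr.predict(X[test]) == y_sex[test])))
        tr = DecisionTreeClassifier(min_samples_leaf=20, random_state=seed).fit(
            X[train], y_grp[train]
        )
        tree_acc.append(float(np.mean(tr.predict(X[test]) == y_grp[test])))

    anova = {}
    for name, col in [("path", path_col), ("velocity", vel_col)]:
        groups = [g[col].to_numpy() for _, g in df.groupby("_age_group")]
        f, p = stats.f_oneway(*groups)
        anova[name] = {"F": float(f), "p": float(p)}

    return {
        "n": int(len(df)),
        "rq_correlation": corr,
        "sex_ranksum_p": sex_p,
        "logistic_sex_accuracy_pct": 100.0 * float(np.mean(logit_acc)),
        "age_group_tree_accuracy_pct": 100.0 * float(np.mean(tree_acc)),
        "age_group_anova": anova,
    }
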