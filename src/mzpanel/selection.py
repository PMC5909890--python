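"""Multi-method biomarker feature ranking and panel assembly.

Each selector consumes an annotated, autoscaled feature table with a
binary case/control assignment and returns a :class:`RankedFeatureList`;
the top-k (default 10) becomes a candidate :class:`PanelDefinition`.

Methods mirror the complementary approaches used for metabolomic panel
discovery: univariate statistics (per-feature ROC AUC, Welch t, fold
change), LASSO selection frequency over stratified subsamples
(stability selection), linear-SVM recursive feature elimination, PLS-DA
variable importance in projection (VIP), and random-forest importance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import RFE
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.svm import LinearSVC
from scipy import stats as sps

from .io import FeatureTable
from .stats import mann_whitney_auc

SELECTION_METHODS = (
    "univariate_auc", "ttest", "fold_change",
    "lasso_frequency", "linear_svm", "plsda_vip", "random_forest",
)


@dataclass
class RankedFeatureList:
    """Feature labels with scores, sorted non-increasing by score."""

    method: str
    entries: list[tuple[str, float]]
    seed: int | None = None

    def __post_init__(self):
        labels = [l for l, _ in self.entries]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate labels in ranked list")
        self.entries = sorted(self.entries, key=lambda e: -e[1])

    @property
    def labels(self) -> list[str]:
        return [l for l, _ in self.entries]

    def to_series(self) -> pd.Series:
        return pd.Series(dict(self.entries), name=self.method)


@dataclass
class PanelDefinition:
    """An ordered list of annotated analyte labels from one selector."""

    labels: list[str]
    method: str = ""
    k: int = 10

    def __post_init__(self):
        if len(self.labels) > self.k:
            raise ValueError(f"panel has {len(self.labels)} labels but k={self.k}")

    def __len__(self) -> int:
        return len(self.labels)


# ----------------------------------------------------------------------


def binary_labels(table: FeatureTable, positive: str = "case") -> np.ndarray:
    """0/1 outcome vector from the table's group column."""
    groups = table.groups().astype(str)
    classes = sorted(groups.unique())
    if len(classes) != 2:
        raise ValueError(f"need exactly two groups, found {classes}")
    if positive not in classes:
        raise ValueError(f"positive class {positive!r} not among groups {classes}")
    return (groups == positive).to_numpy().astype(int)


def _check_two_groups(y: np.ndarray, min_per_class: int = 2) -> None:
    n1, n0 = int(y.sum()), int((1 - y).sum())
    if n1 < min_per_class or n0 < min_per_class:
        raise ValueError(f"each group needs >= {min_per_class} samples (got {n1}/{n0})")


def univariate_stats(
    table: FeatureTable,
    y: np.ndarray | None = None,
    raw_table: FeatureTable | None = None,
    positive: str = "case",
) -> dict[str, RankedFeatureList]:
    """Per-feature ROC AUC, Welch t, and log2 fold change rankings.

    AUC and t statistics are computed on the (autoscaled) ``table``;
    fold change uses raw abundances from ``raw_table`` when supplied.
    AUCs are folded to >= 0.5 for ranking so that down- and up-regulated
    features rank comparably; t and fold change rank by magnitude.
    """
    if y is None:
        y = binary_labels(table, positive)
    _check_two_groups(y)
    X = table.abundances
    aucs, tstats = {}, {}
    for label in X.columns:
        x = X[label].to_numpy(dtype=float)
        a = mann_whitney_auc(x, y)
        aucs[label] = max(a, 1.0 - a)
        t = sps.ttest_ind(x[y == 1], x[y == 0], equal_var=False).statistic
        tstats[label] = abs(float(t)) if np.isfinite(t) else 0.0
    out = {
        "univariate_auc": RankedFeatureList("univariate_auc", list(aucs.items())),
        "ttest": RankedFeatureList("ttest", list(tstats.items())),
    }
    fc_source = raw_table if raw_table is not None else table
    Xr = fc_source.abundances
    fcs = {}
    for label in Xr.columns:
        x = Xr[label].to_numpy(dtype=float)
        if fc_source.transform_state == "raw":
            with np.errstate(divide="ignore", invalid="ignore"):
                fc = np.log2(x[y == 1].mean()) - np.log2(x[y == 0].mean())
        else:  # already log-scale: difference of means
            fc = x[y == 1].mean() - x[y == 0].mean()
        fcs[label] = abs(float(fc)) if np.isfinite(fc) else 0.0
    out["fold_change"] = RankedFeatureList("fold_change", list(fcs.items()))
    return out


# ----------------------------------------------------------------------
# LASSO selection frequency (stability selection)

_C_GRID = np.logspace(-2, 2, 10)


def _lasso_fit_one_se(X: np.ndarray, y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """L1 logistic fit with penalty chosen by 3-fold CV and the 1-SE rule."""
    cv = StratifiedKFold(n_splits=3, shuffle=True, random_state=int(rng.integers(2**31 - 1)))
    state = int(rng.integers(2**31 - 1))  # liblinear is stochastic unless seeded
    means, ses = [], []
    for C in _C_GRID:
        clf = LogisticRegression(l1_ratio=1.0, solver="liblinear", C=C, max_iter=200, random_state=state)
        scores = cross_val_score(clf, X, y, cv=cv, scoring="accuracy")
        means.append(scores.mean())
        ses.append(scores.std(ddof=1) / np.sqrt(len(scores)))
    means = np.asarray(means)
    best = int(np.argmax(means))
    cutoff = means[best] - ses[best]
    # smallest C (strongest penalty) whose CV accuracy is within 1 SE of the best
    chosen = next(i for i in range(len(_C_GRID)) if means[i] >= cutoff)
    clf = LogisticRegression(l1_ratio=1.0, solver="liblinear", C=_C_GRID[chosen], max_iter=200, random_state=state)
    clf.fit(X, y)
    return clf.coef_.ravel()


def lasso_selection_frequency(
    table: FeatureTable,
    y: np.ndarray | None = None,
    n_subsamples: int = 100,
    subsample_fraction: float = 0.8,
    seed: int = 0,
    positive: str = "case",
) -> RankedFeatureList:
    """Selection frequency (0-100%) of each feature under L1 logistic fits.

    For each of ``n_subsamples`` stratified draws of
    ``subsample_fraction`` of the samples, an L1-penalized logistic
    regression is fitted with the penalty chosen by internal
    cross-validation (1-SE rule); a feature's frequency is the
    percentage of subsamples in which its coefficient is nonzero.
    """
    if y is None:
        y = binary_labels(table, positive)
    _check_two_groups(y)
    if n_subsamples < 10:
        raise ValueError("n_subsamples must be >= 10")
    X = table.abundances.to_numpy(dtype=float)
    labels = table.abundances.columns
    rng = np.random.default_rng(seed)
    idx1, idx0 = np.nonzero(y == 1)[0], np.nonzero(y == 0)[0]
    k1 = max(2, int(round(subsample_fraction * len(idx1))))
    k0 = max(2, int(round(subsample_fraction * len(idx0))))
    counts = np.zeros(X.shape[1])
    for _ in range(n_subsamples):
        for _retry in range(10):
            sel = np.concatenate([rng.choice(idx1, k1, replace=False), rng.choice(idx0, k0, replace=False)])
            ysub = y[sel]
            if 0 < ysub.sum() < len(ysub):
                break
        coef = _lasso_fit_one_se(X[sel], ysub, rng)
        counts += coef != 0
    freq = 100.0 * counts / n_subsamples
    return RankedFeatureList("lasso_frequency", list(zip(labels, freq)), seed=seed)


# ----------------------------------------------------------------------


def linear_svm_ranking(
    table: FeatureTable,
    y: np.ndarray | None = None,
    seed: int = 0,
    n_repeats: int = 15,
    subsample_fraction: float = 0.8,
    positive: str = "case",
) -> RankedFeatureList:
    """Ensembled linear-SVM recursive feature elimination ranking.

    The cost parameter is fixed once by 3-fold internal
    cross-validation. RFE (10% of the remaining features eliminated per
    step, so elimination grows finer toward the end) is then repeated on
    ``n_repeats`` stratified subsamples of ``subsample_fraction`` of the
    samples; a feature's score is its negated mean elimination rank
    across repeats. Aggregating ranks tames the variance of a single
    RFE run when features far outnumber samples, the same way the LASSO
    selector aggregates over subsamples. With fewer than 10 samples RFE
    is skipped and |coefficient| of one full-data fit ranks directly.
    """
    if y is None:
        y = binary_labels(table, positive)
    _check_two_groups(y)
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    X = table.abundances.to_numpy(dtype=float)
    labels = table.abundances.columns
    cv = StratifiedKFold(n_splits=3, shuffle=True, random_state=seed)
    best_C, best_score = 1.0, -np.inf
    for C in (0.01, 0.1, 1.0, 10.0):
        clf = LinearSVC(C=C, dual="auto", max_iter=5000)
        score = cross_val_score(clf, X, y, cv=cv, scoring="accuracy").mean()
        if score > best_score:
            best_C, best_score = C, score
    est = LinearSVC(C=best_C, dual="auto", max_iter=5000)
    if len(y) < 10:
        warnings.warn("fewer than 10 samples: ranking by |coef| of a single SVM fit")
        est.fit(X, y)
        scores = np.abs(est.coef_.ravel())
        return RankedFeatureList("linear_svm", list(zip(labels, scores)), seed=seed)
    rng = np.random.default_rng(seed)
    idx1, idx0 = np.nonzero(y == 1)[0], np.nonzero(y == 0)[0]
    k1 = max(2, int(round(subsample_fraction * len(idx1))))
    k0 = max(2, int(round(subsample_fraction * len(idx0))))
    rank_sum = np.zeros(X.shape[1])
    for _ in range(n_repeats):
        sel = np.concatenate([rng.choice(idx1, k1, replace=False), rng.choice(idx0, k0, replace=False)])
        rfe = RFE(est, n_features_to_select=1, step=0.1)
        rfe.fit(X[sel], y[sel])
        rank_sum += rfe.ranking_.astype(float)  # rank 1 = kept longest = best
    scores = -rank_sum / n_repeats
    return RankedFeatureList("linear_svm", list(zip(labels, scores)), seed=seed)


def plsda_vip(
    table: FeatureTable,
    y: np.ndarray | None = None,
    n_components: int = 2,
    positive: str = "case",
) -> RankedFeatureList:
    """PLS-DA VIP (variable importance in projection) ranking.

    VIP_j = sqrt( p * sum_a SSY_a (w_ja / ||w_a||)^2 / sum_a SSY_a ),
    where SSY_a is the outcome variance explained by component a; the
    mean of squared VIPs equals 1.
    """
    if y is None:
        y = binary_labels(table, positive)
    _check_two_groups(y)
    X = table.abundances.to_numpy(dtype=float)
    max_comp = min(X.shape[0] - 1, X.shape[1])
    if n_components > max_comp:
        warnings.warn(f"reducing PLS components {n_components} -> {max_comp}")
        n_components = max_comp
    pls = PLSRegression(n_components=n_components, scale=False)
    pls.fit(X, y.astype(float))
    T = pls.x_scores_           # (n, a)
    W = pls.x_weights_          # (p, a)
    Q = pls.y_loadings_         # (1, a)
    p = X.shape[1]
    ssy = (Q.ravel() ** 2) * np.einsum("ij,ij->j", T, T)  # per-component explained SS of y
    Wn = W / np.linalg.norm(W, axis=0, keepdims=True)
    vip = np.sqrt(p * (Wn**2 @ ssy) / ssy.sum())
    labels = table.abundances.columns
    return RankedFeatureList("plsda_vip", list(zip(labels, vip)))


def random_forest_importance(
    table: FeatureTable,
    y: np.ndarray | None = None,
    n_trees: int = 500,
    seed: int = 0,
    positive: str = "case",
) -> RankedFeatureList:
    """Random-forest (impurity) importance ranking; seed-deterministic."""
    if y is None:
        y = binary_labels(table, positive)
    _check_two_groups(y)
    X = table.abundances.to_numpy(dtype=float)
    rf = RandomForestClassifier(n_estimators=n_trees, random_state=seed, n_jobs=1)
    rf.fit(X, y)
    labels = table.abundances.columns
    return RankedFeatureList("random_forest", list(zip(labels, rf.feature_importances_)), seed=seed)


def build_panel(ranked: RankedFeatureList, k: int = 10) -> PanelDefinition:
    """Top-k labels of a ranking, in rank order."""
    if k < 1:
        raise ValueError("k must be >= 1")
    labels = ranked.labels
    if k > len(labels):
        warnings.warn(f"k={k} exceeds {len(labels)} ranked features; using all")
    return PanelDefinition(labels=labels[:k], method=ranked.method, k=k)
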