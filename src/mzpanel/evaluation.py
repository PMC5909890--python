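"""Logistic-regression panel evaluation with ROC analysis.

The central objects follow the model/results convention: a
:class:`PanelLogit` model is built from an annotated, autoscaled
:class:`~mzpanel.io.FeatureTable` and a :class:`~mzpanel.selection.PanelDefinition`;
``fit()`` returns a :class:`PanelEvaluation` results object carrying the
coefficient estimates, their standard errors, the training/discovery
:class:`ROCResult` and a ``summary()`` table. Internal validation
(``fit_cv10``) refits the model per stratified fold and pools
out-of-fold probabilities into one ROC; external replication refits the
panel on the held-out cohort.

AUCs are Mann-Whitney statistics (ties at 1/2); AUC standard errors and
default confidence intervals use the Hanley-McNeil closed form, with a
stratified-bootstrap CI available as an option.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import StratifiedKFold

from .io import FeatureTable
from .selection import PanelDefinition, binary_labels
from .stats import hanley_mcneil_se, mann_whitney_auc

Z95 = 1.959963984540054


@dataclass
class ROCResult:
    """A ROC AUC with Hanley-McNeil uncertainty and operating point."""

    auc: float
    se: float
    ci95: tuple[float, float]
    sensitivity: float
    specificity: float
    n_cases: int
    n_controls: int
    mode: str  # "discovery" | "cv10" | "replication"
    curve: np.ndarray = field(repr=False, default=None)  # (k, 2) of (FPR, TPR)
    youden_threshold: float = float("nan")
    ridge_stabilized: bool = False

    def __post_init__(self):
        lo, hi = self.ci95
        if not (0.0 <= self.auc <= 1.0 and lo <= self.auc <= hi):
            raise ValueError(f"inconsistent AUC/CI: auc={self.auc}, ci={self.ci95}")

    def summary_line(self) -> str:
        lo, hi = self.ci95
        return (
            f"{self.mode:<11s} AUC {self.auc:.3f} (95% CI {lo:.3f}-{hi:.3f}) "
            f"sens/spec {self.sensitivity:.3f}/{self.specificity:.3f} "
            f"[n={self.n_cases}+{self.n_controls}]"
        )


def roc_curve_auc(
    scores: np.ndarray,
    y: np.ndarray,
    mode: str = "discovery",
    bootstrap_ci: bool = False,
    n_boot: int = 500,
    seed: int = 0,
    ridge_stabilized: bool = False,
) -> ROCResult:
    """ROC curve, Mann-Whitney AUC, Hanley-McNeil SE/CI, Youden point.

    The operating point maximizes Youden's J = sensitivity +
    specificity - 1; exact ties resolve toward higher specificity.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y).astype(int)
    n1, n0 = int(y.sum()), int((1 - y).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    auc = mann_whitney_auc(scores, y)
    se = hanley_mcneil_se(auc, n1, n0)
    if bootstrap_ci:
        lo, hi = _bootstrap_auc_ci(scores, y, n_boot=n_boot, seed=seed)
        lo, hi = min(lo, auc), max(hi, auc)
    else:
        lo, hi = max(0.0, auc - Z95 * se), min(1.0, auc + Z95 * se)
    fpr, tpr, thresholds = _sk_roc_curve(y, scores)
    j = tpr - fpr
    best = int(np.argmax(j))  # fpr ascending -> first max has highest specificity
    curve = np.column_stack([fpr, tpr])
    return ROCResult(
        auc=auc,
        se=se,
        ci95=(lo, hi),
        sensitivity=float(tpr[best]),
        specificity=float(1.0 - fpr[best]),
        n_cases=n1,
        n_controls=n0,
        mode=mode,
        curve=curve,
        youden_threshold=float(thresholds[best]),
        ridge_stabilized=ridge_stabilized,
    )


def _bootstrap_auc_ci(scores, y, n_boot: int = 500, seed: int = 0) -> tuple[float, float]:
    """Percentile CI of the AUC under stratified resampling."""
    rng = np.random.default_rng(seed)
    i1, i0 = np.nonzero(y == 1)[0], np.nonzero(y == 0)[0]
    aucs = np.empty(n_boot)
    for b in range(n_boot):
        sel = np.concatenate([rng.choice(i1, len(i1)), rng.choice(i0, len(i0))])
        aucs[b] = mann_whitney_auc(scores[sel], y[sel])
    lo, hi = np.percentile(aucs, [2.5, 97.5])
    return float(lo), float(hi)


# ----------------------------------------------------------------------


def _fit_logistic(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray | None, bool]:
    """MLE logistic fit; ridge-stabilized fallback on separation.

    Returns (params incl. intercept first, standard errors or None, ridge flag).
    """
    Xc = sm.add_constant(X, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
            params = np.asarray(res.params, dtype=float)
            bse = np.asarray(res.bse, dtype=float)
            # treat exploding estimates/SEs as (quasi-)separation
            if np.all(np.isfinite(params)) and np.all(np.isfinite(bse)) and np.max(np.abs(params)) < 50:
                return params, bse, False
        except Exception:
            pass
    # weak ridge stabilization (large C = light penalty) keeps scores defined
    clf = LogisticRegression(C=100.0, max_iter=2000)
    clf.fit(X, y)
    params = np.concatenate([clf.intercept_, clf.coef_.ravel()])
    return params, None, True


def _predict(params: np.ndarray, X: np.ndarray) -> np.ndarray:
    eta = params[0] + X @ params[1:]
    return 1.0 / (1.0 + np.exp(-eta))


def logistic_scores(
    table: FeatureTable, panel: PanelDefinition, y: np.ndarray | None = None, positive: str = "case"
) -> tuple[np.ndarray, pd.Series, bool]:
    """Fitted case probabilities from a logistic fit on panel features.

    Returns ``(probabilities, coefficients, ridge_flag)``; the ridge
    flag reports that a weakly penalized fit replaced the MLE because of
    (quasi-)separation.
    """
    if y is None:
        y = binary_labels(table, positive)
    missing = [l for l in panel.labels if l not in table.features.index]
    if missing:
        raise KeyError(
            f"panel label(s) {missing} absent from table; run intersect_common against "
            "this cohort first"
        )
    X = table.abundances[panel.labels].to_numpy(dtype=float)
    params, _bse, ridge = _fit_logistic(X, y)
    coefs = pd.Series(params, index=["const"] + list(panel.labels))
    return _predict(params, X), coefs, ridge


class PanelLogit:
    """Logistic-regression model of case/control status on a panel.

    Parameters
    ----------
    table : FeatureTable
        Annotated, autoscaled cohort table.
    panel : PanelDefinition
        Ordered analyte labels; all must exist in ``table``.
    positive : str
        Group label treated as the case (outcome 1).
    """

    def __init__(self, table: FeatureTable, panel: PanelDefinition, positive: str = "case"):
        missing = [l for l in panel.labels if l not in table.features.index]
        if missing:
            raise KeyError(
                f"panel label(s) {missing} absent from table; run intersect_common "
                "against this cohort first"
            )
        if len(panel) == 0:
            raise ValueError("empty panel")
        self.table = table
        self.panel = panel
        self.positive = positive
        self.endog = binary_labels(table, positive)
        self.exog = table.abundances[panel.labels].to_numpy(dtype=float)

    # -- training/discovery -------------------------------------------------

    def fit(self, mode: str = "discovery", bootstrap_ci: bool = False, seed: int = 0) -> "PanelEvaluation":
        params, bse, ridge = _fit_logistic(self.exog, self.endog)
        probs = _predict(params, self.exog)
        roc = roc_curve_auc(
            probs, self.endog, mode=mode, bootstrap_ci=bootstrap_ci, seed=seed,
            ridge_stabilized=ridge,
        )
        names = ["const"] + list(self.panel.labels)
        return PanelEvaluation(
            model=self,
            params=pd.Series(params, index=names),
            bse=pd.Series(bse, index=names) if bse is not None else None,
            fittedvalues=probs,
            roc=roc,
            ridge_stabilized=ridge,
        )

    # -- internal validation ------------------------------------------------

    def fit_cv10(self, seed: int = 0, n_folds: int = 10, bootstrap_ci: bool = False) -> ROCResult:
        """Stratified 10-fold CV; out-of-fold probabilities pooled into one ROC."""
        y = self.endog
        n_min = min(int(y.sum()), int((1 - y).sum()))
        folds = n_folds
        if n_min < folds:
            warnings.warn(f"smallest class has {n_min} samples; reducing folds {folds} -> {n_min}")
            folds = n_min
        if folds < 2:
            raise ValueError("need at least 2 samples per class for cross-validation")
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        oof = np.full(len(y), np.nan)
        any_ridge = False
        for train, test in skf.split(self.exog, y):
            params, _bse, ridge = _fit_logistic(self.exog[train], y[train])
            any_ridge |= ridge
            oof[test] = _predict(params, self.exog[test])
        return roc_curve_auc(
            oof, y, mode="cv10", bootstrap_ci=bootstrap_ci, seed=seed, ridge_stabilized=any_ridge
        )


@dataclass
class PanelEvaluation:
    """Results of a fitted :class:`PanelLogit`."""

    model: PanelLogit
    params: pd.Series
    bse: pd.Series | None
    fittedvalues: np.ndarray
    roc: ROCResult
    ridge_stabilized: bool = False

    @property
    def auc(self) -> float:
        return self.roc.auc

    def summary(self) -> str:
        lines = [
            "Panel logistic regression",
            "=" * 68,
            f"method: {self.model.panel.method or '-':<20s} analytes: {len(self.model.panel)}",
            f"groups: {int(self.model.endog.sum())} {self.model.positive} / "
            f"{int((1 - self.model.endog).sum())} other",
            self.roc.summary_line(),
        ]
        if self.ridge_stabilized:
            lines.append("note: ridge-stabilized fit (separation detected); no Wald SEs")
        lines.append("-" * 68)
        lines.append(f"{'term':<24s}{'coef':>12s}{'std err':>12s}")
        for name, value in self.params.items():
            se = f"{self.bse[name]:12.4f}" if self.bse is not None else " " * 12
            lines.append(f"{name:<24s}{value:12.4f}{se}")
        lines.append("=" * 68)
        return "\n".join(lines)


# ----------------------------------------------------------------------
# module-level convenience wrappers


def evaluate_discovery(
    table: FeatureTable, panel: PanelDefinition, positive: str = "case", **kwargs
) -> ROCResult:
    """Training/discovery ROC from a full-data logistic fit."""
    return PanelLogit(table, panel, positive).fit(mode="discovery", **kwargs).roc


def evaluate_cv10(
    table: FeatureTable, panel: PanelDefinition, seed: int = 0, positive: str = "case", **kwargs
) -> ROCResult:
    """Internal validation: pooled out-of-fold ROC under stratified 10-fold CV."""
    return PanelLogit(table, panel, positive).fit_cv10(seed=seed, **kwargs)


def evaluate_replication(
    table_external: FeatureTable,
    panel: PanelDefinition,
    positive: str = "case",
    discovery_fit: PanelEvaluation | None = None,
    **kwargs,
) -> ROCResult:
    """External replication ROC.

    By default the panel's logistic coefficients are refitted on the
    external cohort (same procedure as training/discovery). Passing a
    ``discovery_fit`` instead applies the fitted discovery model to the
    external data without refitting (sensitivity analysis).
    """
    if discovery_fit is None:
        return PanelLogit(table_external, panel, positive).fit(mode="replication", **kwargs).roc
    missing = [l for l in panel.labels if l not in table_external.features.index]
    if missing:
        raise KeyError(f"panel label(s) {missing} absent from external table")
    X = table_external.abundances[panel.labels].to_numpy(dtype=float)
    y = binary_labels(table_external, positive)
    probs = _predict(discovery_fit.params.to_numpy(), X)
    return roc_curve_auc(probs, y, mode="replication", **kwargs)
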