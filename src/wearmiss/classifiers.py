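"""Missingness classifiers: cluster-bootstrap random forest and GEE logistic.

Both models predict the night-level binary missingness indicator (positive
class = "data missing", coded 1) from six observed predictors: night index,
household size, education level, employment, marital status, and the
heart-rate-presence indicator for the prior day.  Repeated measures from the
same participant are correlated, so neither model may treat nights as
independent:

* the random forest grows every tree on a *cluster bootstrap* that
  resamples whole participants (all five nights travel together), and its
  out-of-bag predictions for a night use only trees whose resample excluded
  that night's participant;
* the logistic model is estimated by generalized estimating equations with
  a working correlation structure over nights within participant (default
  exchangeable) and robust sandwich standard errors; QIC compares working
  structures.

An out-of-bag AUC clearly above 0.5 is evidence that missingness is
predictable from observed variables, i.e. consistent with MAR.

The estimators follow the scikit-learn protocol (``fit``/``predict``/
``predict_proba``, fitted attributes suffixed ``_``) and accept a
:class:`~wearmiss.data_model.LongitudinalDataset` through the module-level
``fit_rf``/``fit_gee`` convenience wrappers.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import roc_auc_score
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_is_fitted
from statsmodels.genmod.cov_struct import (
    Autoregressive,
    Exchangeable,
    Independence,
    Unstructured,
)

from .data_model import LongitudinalDataset, make_dataset

logger = logging.getLogger(__name__)

#: The six predictors of night-level missingness, in default entry order
#: for forward selection.
DEFAULT_PREDICTORS = [
    "night_index",
    "hr_present_prior_day",
    "employed",
    "married",
    "education_level",
    "household_size",
]

CORR_STRUCTURES = ("independence", "exchangeable", "ar1", "unstructured")


# ---------------------------------------------------------------------------
# metrics


@dataclass
class ConfusionMatrix:
    """2x2 classification counts; positive class = "data missing" (1)."""

    tn: int
    fp: int
    fn: int
    tp: int

    @property
    def total(self) -> int:
        return self.tn + self.fp + self.fn + self.tp

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ConfusionMatrix":
        y_true = np.asarray(y_true).astype(int)
        y_pred = np.asarray(y_pred).astype(int)
        return cls(
            tn=int(((y_true == 0) & (y_pred == 0)).sum()),
            fp=int(((y_true == 0) & (y_pred == 1)).sum()),
            fn=int(((y_true == 1) & (y_pred == 0)).sum()),
            tp=int(((y_true == 1) & (y_pred == 1)).sum()),
        )


def confusion_metrics(cm: ConfusionMatrix) -> dict:
    """Accuracy, sensitivity (recall of "missing") and specificity.

    Returned both as raw fractions and rounded to 2 decimals; an empty class
    yields NaN for the affected rate rather than an error.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    acc = (cm.tn + cm.tp) / cm.total
    sens = cm.tp / (cm.tp + cm.fn) if (cm.tp + cm.fn) else float("nan")
    spec = cm.tn / (cm.tn + cm.fp) if (cm.tn + cm.fp) else float("nan")
    return {
        "accuracy": round(acc, 2),
        "sensitivity": round(sens, 2) if sens == sens else sens,
        "specificity": round(spec, 2) if spec == spec else spec,
        "accuracy_raw": acc,
        "sensitivity_raw": sens,
        "specificity_raw": spec,
    }


def auc(scores, labels) -> float:
    """Rank-based (Mann-Whitney) area under the ROC curve; ties count 0.5."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC undefined: only one class present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


# ---------------------------------------------------------------------------
# cluster bootstrap


def cluster_bootstrap(ds: LongitudinalDataset, seed=None) -> LongitudinalDataset:
    """Resample whole participants with replacement.

    Draws ``n_participants`` participant IDs with replacement and keeps all
    nights of each drawn participant; a participant drawn k times appears k
    times under fresh IDs (``<pid>#b<j>``) so clusters stay distinct.
    """
    rng = np.random.default_rng(seed)
    ids, nights_df, new_cov = _cluster_bootstrap_frames(ds, rng)
    out = make_dataset(nights_df, new_cov, n_nights=ds.n_nights)
    out.meta = {**ds.meta, "bootstrap_source_ids": ids.tolist()}
    return out


def _cluster_bootstrap_frames(ds: LongitudinalDataset, rng: np.random.Generator):
    pids = ds.participants.to_numpy()
    ids = rng.choice(pids, size=len(pids), replace=True)
    night_groups = {pid: g for pid, g in ds.nights.groupby("participant_id", sort=False)}
    nights, covs = [], []
    for j, pid in enumerate(ids):
        g = night_groups[pid].copy()
        new_id = f"{pid}#b{j}"
        g["participant_id"] = new_id
        nights.append(g)
        c = ds.covariates.loc[[pid]].copy()
        c.index = pd.Index([new_id], name="participant_id")
        covs.append(c)
    return ids, pd.concat(nights, ignore_index=True), pd.concat(covs)


# ---------------------------------------------------------------------------
# random forest with cluster-adjusted bootstrap


class ClusterBootstrapForest(BaseEstimator, ClassifierMixin):
    """Random forest for clustered binary outcomes.

    Each tree is grown on a bootstrap resample of whole clusters
    (participants), not individual rows, preserving within-subject
    correlation in the resampling distribution.  Predicted probability is
    the fraction of trees voting for the positive class; out-of-bag
    probabilities use only trees whose resample excluded the row's cluster.

    Parameters
    ----------
    n_trees : int
        Ensemble size (default 500).
    max_features : int or str
        Features considered per split; default 2 = floor(sqrt(6)) for the
        six-predictor missingness model.
    random_state : int or None
        Seed for the cluster bootstrap and tree growing.

    Attributes
    ----------
    trees_ : list of DecisionTreeClassifier
    oob_mask_ : ndarray of shape (n_trees, n_clusters)
        True where the cluster was absent from the tree's resample.
    feature_names_in_ : ndarray of str
    """

    def __init__(self, n_trees: int = 500, max_features=2, random_state=None):
        self.n_trees = n_trees
        self.max_features = max_features
        self.random_state = random_state

    def fit(self, X, y, groups=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y).astype(int)
        if X.ndim != 2 or len(X) != len(y):
            raise ValueError("X must be 2-D with one label per row")
        if len(np.unique(y)) < 2:
            raise ValueError("outcome has a single class; AUC would be undefined")
        groups = np.arange(len(y)) if groups is None else np.asarray(groups)
        clusters, cluster_idx = np.unique(groups, return_inverse=True)
        n_clusters = len(clusters)
        rng = np.random.default_rng(self.random_state)

        self.classes_ = np.array([0, 1])
        self.n_features_in_ = X.shape[1]
        self.trees_ = []
        self.oob_mask_ = np.zeros((self.n_trees, n_clusters), dtype=bool)
        rows_of = [np.flatnonzero(cluster_idx == c) for c in range(n_clusters)]
        for b in range(self.n_trees):
            draw = rng.integers(0, n_clusters, size=n_clusters)
            rows = np.concatenate([rows_of[c] for c in draw])
            tree = DecisionTreeClassifier(
                max_features=self.max_features,
                random_state=int(rng.integers(0, 2**31 - 1)),
            )
            tree.fit(X[rows], y[rows])
            self.trees_.append(tree)
            in_bag = np.zeros(n_clusters, dtype=bool)
            in_bag[draw] = True
            self.oob_mask_[b] = ~in_bag

        self._cluster_idx_fit = cluster_idx
        votes = self._votes(X)
        self.oob_decision_function_ = self._oob_proba(votes, cluster_idx)
        self.feature_importances_ = np.mean(
            [t.feature_importances_ for t in self.trees_], axis=0
        )
        return self

    def _votes(self, X) -> np.ndarray:
        """(n_trees, n_rows) binary votes for the positive class."""
        X = np.asarray(X, dtype=float)
        return np.stack([t.predict(X) for t in self.trees_])

    def _oob_proba(self, votes: np.ndarray, cluster_idx: np.ndarray) -> np.ndarray:
        out = np.full(votes.shape[1], np.nan)
        oob_by_row = self.oob_mask_[:, cluster_idx]  # (n_trees, n_rows)
        counts = oob_by_row.sum(axis=0)
        ok = counts > 0
        out[ok] = (votes * oob_by_row).sum(axis=0)[ok] / counts[ok]
        return out

    def predict_proba(self, X):
        check_is_fitted(self, "trees_")
        p1 = self._votes(X).mean(axis=0)
        return np.column_stack([1 - p1, p1])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


@dataclass
class RFFit:
    """Fitted cluster-bootstrap forest with its evaluation summaries."""

    model: ClusterBootstrapForest
    auc: float
    oob_auc: float
    confusion: ConfusionMatrix
    oob_confusion: ConfusionMatrix
    variable_importances: pd.Series
    predictions: pd.DataFrame  # participant, night, prob, oob_prob, pred, true
    n_trees: int
    seed: object

    @property
    def metrics(self) -> dict:
        return confusion_metrics(self.confusion)


def _design(ds: LongitudinalDataset, predictors) -> tuple[pd.DataFrame, pd.Series]:
    merged = ds.merged()
    missing = [t for t in predictors if t not in merged.columns]
    if missing:
        raise ValueError(f"predictor(s) not in dataset: {missing}")
    return merged[list(predictors)].astype(float), merged["missing"].astype(int)


def fit_rf(
    ds: LongitudinalDataset,
    n_trees: int = 500,
    seed=None,
    predictors=None,
) -> RFFit:
    """Fit the cluster-bootstrap random forest missingness classifier.

    In-sample and out-of-bag AUCs and 0.5-threshold confusion matrices are
    both reported; the OOB figures are the less optimistic and are what the
    mechanism decision consumes.
    """
    predictors = DEFAULT_PREDICTORS if predictors is None else list(predictors)
    merged = ds.merged()
    X, y = _design(ds, predictors)
    model = ClusterBootstrapForest(n_trees=n_trees, random_state=seed)
    model.fit(X.to_numpy(), y.to_numpy(), groups=merged["participant_id"].to_numpy())
    prob = model.predict_proba(X.to_numpy())[:, 1]
    oob_prob = model.oob_decision_function_
    pred = (prob >= 0.5).astype(int)
    oob_pred = (np.nan_to_num(oob_prob) >= 0.5).astype(int)
    preds = pd.DataFrame(
        {
            "participant_id": merged["participant_id"],
            "night_index": merged["night_index"],
            "prob_missing": prob,
            "oob_prob_missing": oob_prob,
            "predicted": pred,
            "true": y,
        }
    )
    ok = ~np.isnan(oob_prob)
    return RFFit(
        model=model,
        auc=auc(prob, y),
        oob_auc=auc(oob_prob[ok], y[ok]),
        confusion=ConfusionMatrix.from_predictions(y, pred),
        oob_confusion=ConfusionMatrix.from_predictions(y, oob_pred),
        variable_importances=pd.Series(model.feature_importances_, index=predictors),
        predictions=preds,
        n_trees=n_trees,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# GEE logistic model


def _cov_struct(name: str):
    try:
        return {
            "independence": Independence,
            "exchangeable": Exchangeable,
            "ar1": lambda: Autoregressive(grid=True),
            "unstructured": Unstructured,
        }[name]()
    except KeyError:
        raise ValueError(
            f"unknown working correlation {name!r}; expected one of {CORR_STRUCTURES}"
        ) from None


class GEEMissingnessModel(BaseEstimator, ClassifierMixin):
    """Marginal logistic missingness model fit by GEE.

    Estimation uses iterated weighted scoring with working covariance
    A^(1/2) R(alpha) A^(1/2); the exchangeable correlation parameter is a
    moment estimator from Pearson residuals, and inference uses the robust
    sandwich covariance (all via statsmodels' GEE machinery).  QIC is the
    quasi-likelihood under the independence model criterion used to compare
    working structures.

    Parameters
    ----------
    terms : list of str or None
        Predictor columns; None = the six standard missingness predictors.
    corstr : str
        Working correlation: independence, exchangeable (default), ar1 or
        unstructured.

    Attributes
    ----------
    result_ : statsmodels GEEResults
    params_ : pd.Series of coefficients (with intercept ``const``)
    robust_se_ : pd.Series
    alpha_ : float, working-correlation parameter (0 for independence)
    qic_ : float
    """

    def __init__(self, terms=None, corstr: str = "exchangeable"):
        self.terms = terms
        self.corstr = corstr

    def fit(self, X, y, groups, time=None):
        X = pd.DataFrame(X)
        if self.terms is not None:
            X = X[list(self.terms)]
        exog = sm.add_constant(X.astype(float), has_constant="add")
        # collinearity check with names, before statsmodels sees it
        arr = exog.to_numpy()
        if np.linalg.matrix_rank(arr) < arr.shape[1]:
            constant = [
                c for c in exog.columns[1:] if exog[c].nunique() <= 1
            ]
            with np.errstate(invalid="ignore", divide="ignore"):
                corr = np.corrcoef(arr, rowvar=False)
            pairs = [
                (exog.columns[i], exog.columns[j])
                for i in range(1, len(exog.columns))
                for j in range(i + 1, len(exog.columns))
                if abs(corr[i, j]) > 0.999999
            ]
            raise ValueError(
                f"singular design; constant terms: {constant}; "
                f"collinear pairs: {pairs}"
            )
        cov = _cov_struct(self.corstr)
        kwargs = {}
        if self.corstr in ("ar1", "unstructured"):
            t = np.asarray(time)
            kwargs["time"] = (t - t.min()).astype(int)
        model = sm.GEE(
            np.asarray(y, dtype=float),
            exog,
            groups=np.asarray(groups),
            family=sm.families.Binomial(),
            cov_struct=cov,
            **kwargs,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self.result_ = model.fit(maxiter=100)
        self.converged_ = bool(getattr(self.result_, "converged", True))
        if not self.converged_:
            logger.warning("GEE scoring iterations did not converge")
        self.params_ = pd.Series(self.result_.params, index=exog.columns)
        self.robust_se_ = pd.Series(self.result_.bse, index=exog.columns)
        self.p_values_ = pd.Series(self.result_.pvalues, index=exog.columns)
        dep = cov.dep_params
        if dep is None or np.size(dep) == 0:
            self.alpha_ = 0.0
        else:
            self.alpha_ = float(np.atleast_1d(np.asarray(dep, dtype=float)).ravel()[0])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self.qic_ = float(self.result_.qic(scale=1.0)[0])
        self.feature_names_in_ = np.asarray(X.columns)
        self.classes_ = np.array([0, 1])
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "result_")
        X = pd.DataFrame(X)
        if self.terms is not None:
            X = X[list(self.terms)]
        exog = sm.add_constant(X.astype(float), has_constant="add")
        p1 = np.asarray(self.result_.predict(exog))
        return np.column_stack([1 - p1, p1])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    def odds_ratios(self) -> pd.DataFrame:
        """exp(estimate) with 95% Wald CIs from the robust SEs."""
        check_is_fitted(self, "result_")
        est, se = self.params_, self.robust_se_
        return pd.DataFrame(
            {
                "estimate": est,
                "robust_se": se,
                "odds_ratio": np.exp(est),
                "or_ci_low": np.exp(est - 1.96 * se),
                "or_ci_high": np.exp(est + 1.96 * se),
                "p_value": self.p_values_,
            }
        )


@dataclass
class GEEFit:
    """Fitted GEE missingness model with its evaluation summaries."""

    model: GEEMissingnessModel
    coefficients: pd.DataFrame  # estimate, robust_se, OR, CI, p
    alpha: float
    qic: float
    confusion: ConfusionMatrix
    auc: float
    predictions: pd.DataFrame
    selected_terms: list = field(default_factory=list)
    converged: bool = True
    step_trace: list = field(default_factory=list)

    @property
    def metrics(self) -> dict:
        return confusion_metrics(self.confusion)


def fit_gee(
    ds: LongitudinalDataset,
    terms=None,
    corstr: str = "exchangeable",
) -> GEEFit:
    """Fit the GEE logistic missingness model on a dataset.

    Clusters are participants; within-cluster order is the night index.
    """
    terms = DEFAULT_PREDICTORS if terms is None else list(terms)
    merged = ds.merged()
    X, y = _design(ds, terms)  # terms=[] gives an intercept-only model
    model = GEEMissingnessModel(terms=None, corstr=corstr)
    model.fit(
        X,
        y,
        groups=merged["participant_id"].to_numpy(),
        time=merged["night_index"].to_numpy(),
    )
    prob = model.predict_proba(X)[:, 1]
    pred = (prob >= 0.5).astype(int)
    preds = pd.DataFrame(
        {
            "participant_id": merged["participant_id"],
            "night_index": merged["night_index"],
            "prob_missing": prob,
            "predicted": pred,
            "true": y,
        }
    )
    auc_val = auc(prob, y) if y.nunique() > 1 else float("nan")
    return GEEFit(
        model=model,
        coefficients=model.odds_ratios(),
        alpha=model.alpha_,
        qic=model.qic_,
        confusion=ConfusionMatrix.from_predictions(y, pred),
        auc=auc_val,
        predictions=preds,
        selected_terms=terms,
        converged=model.converged_,
    )


def select_corstr(
    ds: LongitudinalDataset,
    terms=None,
    candidates=CORR_STRUCTURES,
) -> tuple[str, pd.DataFrame]:
    """Choose the working correlation structure by minimum QIC.

    Fits the model under each candidate structure; failed fits are excluded
    from the comparison (and logged).  Returns the winning structure and the
    full QIC table.
    """
    rows = []
    for c in candidates:
        try:
            fit = fit_gee(ds, terms=terms, corstr=c)
            rows.append({"corstr": c, "qic": fit.qic, "alpha": fit.alpha})
        except Exception as exc:  # noqa: BLE001 - per-structure isolation
            logger.warning("working structure %s failed: %s", c, exc)
            rows.append({"corstr": c, "qic": float("nan"), "alpha": float("nan")})
    table = pd.DataFrame(rows)
    valid = table.dropna(subset=["qic"])
    if valid.empty:
        raise RuntimeError("every candidate working structure failed to fit")
    best = valid.loc[valid["qic"].idxmin(), "corstr"]
    return str(best), table


def forward_select(
    ds: LongitudinalDataset,
    candidate_terms=None,
    alpha: float = 0.05,
    corstr: str = "exchangeable",
) -> GEEFit:
    """Sequential (forward) entry of predictors, then a significance prune.

    Terms are added one at a time in the given order, fitting a model at
    each step; after the last step, terms whose robust Wald p-value is at or
    above ``alpha`` are dropped and the reduced model refit.  The step trace
    (terms, coefficients, p-values, QIC per step) is attached to the result.
    """
    candidates = DEFAULT_PREDICTORS if candidate_terms is None else list(candidate_terms)
    if not candidates:
        raise ValueError("candidate term list is empty")
    trace = []
    fit = None
    for k in range(1, len(candidates) + 1):
        step_terms = candidates[:k]
        fit = fit_gee(ds, terms=step_terms, corstr=corstr)
        trace.append(
            {
                "step": k,
                "terms": list(step_terms),
                "qic": fit.qic,
                "p_values": fit.model.p_values_.to_dict(),
            }
        )
    keep = [
        t for t in candidates if fit.model.p_values_.get(t, 1.0) < alpha
    ]
    final = fit_gee(ds, terms=keep, corstr=corstr)
    final.selected_terms = keep
    final.step_trace = trace + [{"step": "final", "terms": keep, "qic": final.qic}]
    return final
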