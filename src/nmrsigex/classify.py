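"""Repeated stratified k-fold cross-validated classification.

The evaluation scheme: stratified three-fold cross-validation repeated 333
times (999 classifier fits).  For binning features, in-fold univariate
selection keeps the top-k features by absolute moderated t-statistic — the
empirical-Bayes two-sample t with variance shrunk toward a prior estimated
across features.  Deconvolution feature sets are used without selection.
Metrics per held-out fold: classification error, sensitivity (correctly
classified cases; predicted case iff probability > 0.5) and specificity.
"""
from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import digamma, polygamma
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .binning import FeatureMatrix

__all__ = ["CvConfig", "CvResult", "ModeratedTResult", "moderated_t",
           "stratified_folds", "run_repeated_cv", "summarize",
           "probability_histogram", "top_feature_frequency", "make_classifier"]

CASE_LABEL = "case"


# ------------------------------------------------------- moderated t-statistic

def _trigamma(x):
    return polygamma(1, x)


def _trigamma_inverse(y: float, max_iter: int = 50) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iteration on 1/x scale)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = _trigamma(x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x += dif
        if abs(dif) / x < 1e-8:
            break
    return float(x)


@dataclass
class ModeratedTResult:
    """Per-feature moderated and ordinary two-sample statistics."""

    t_moderated: pd.Series
    t_ordinary: pd.Series
    s2: pd.Series              # pooled sample variances
    s2_shrunk: pd.Series
    d0: float                  # prior degrees of freedom (may be inf)
    s0_2: float                # prior variance
    df_residual: int
    rank: pd.Series            # 1 = most discriminative (largest |t~|)


def moderated_t(X: pd.DataFrame | np.ndarray,
                labels: Sequence[str] | np.ndarray,
                case_label: str = CASE_LABEL,
                d0_override: float | None = None) -> ModeratedTResult:
    """Empirical-Bayes moderated two-sample t-statistic per feature.

    Pooled per-feature variances s_g^2 (d = n1+n2-2 df) are shrunk toward a
    prior (d0, s0^2) estimated by method of moments on log s_g^2:
    s~^2 = (d0*s0^2 + d*s_g^2) / (d0 + d).  With d0 = 0 the ordinary t is
    recovered; with d0 = inf all variances equal s0^2.  ``d0_override``
    forces the prior degrees of freedom (used for the limiting cases).
    """
    Xv = X.values if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    cols = list(X.columns) if isinstance(X, pd.DataFrame) else \
        [f"f{i}" for i in range(Xv.shape[1])]
    lab = np.asarray(labels)
    is_case = lab == case_label
    n1, n2 = int(is_case.sum()), int((~is_case).sum())
    if n1 < 2 or n2 < 2:
        raise ValueError(f"each class needs n >= 2 (got {n1} cases, {n2} controls)")
    x1, x2 = Xv[is_case], Xv[~is_case]
    m1, m2 = x1.mean(axis=0), x2.mean(axis=0)
    d = n1 + n2 - 2
    s2 = (((x1 - m1) ** 2).sum(axis=0) + ((x2 - m2) ** 2).sum(axis=0)) / d
    s2 = np.maximum(s2, 1e-300)
    se_factor = np.sqrt(1.0 / n1 + 1.0 / n2)
    t_ord = (m1 - m2) / (np.sqrt(s2) * se_factor)

    if d0_override is not None:
        d0 = float(d0_override)
        if d0 == 0:
            s0_2 = float(np.exp(np.mean(np.log(s2))))
        else:
            s0_2 = _prior_variance(s2, d, d0)
    else:
        d0, s0_2 = _fit_f_dist(s2, d)
    if np.isinf(d0):
        s2_shrunk = np.full_like(s2, s0_2)
    else:
        s2_shrunk = (d0 * s0_2 + d * s2) / (d0 + d)
    t_mod = (m1 - m2) / (np.sqrt(s2_shrunk) * se_factor)
    order = np.argsort(-np.abs(t_mod), kind="stable")
    rank = np.empty(len(cols), dtype=int)
    rank[order] = np.arange(1, len(cols) + 1)
    idx = pd.Index(cols)
    return ModeratedTResult(
        t_moderated=pd.Series(t_mod, index=idx),
        t_ordinary=pd.Series(t_ord, index=idx),
        s2=pd.Series(s2, index=idx),
        s2_shrunk=pd.Series(s2_shrunk, index=idx),
        d0=d0, s0_2=s0_2, df_residual=d,
        rank=pd.Series(rank, index=idx))


def _fit_f_dist(s2: np.ndarray, d: int) -> tuple[float, float]:
    """Method-of-moments fit of the scaled-F prior on {log s_g^2}."""
    z = np.log(s2)
    e = z - digamma(d / 2.0) + np.log(d / 2.0)
    emean = float(np.mean(e))
    n = e.size
    if n < 2:
        return np.inf, float(np.exp(emean))
    evar = float(np.var(e, ddof=1)) - float(_trigamma(d / 2.0))
    if evar <= 0:
        return np.inf, float(np.exp(emean))
    half_d0 = _trigamma_inverse(evar)
    d0 = 2.0 * half_d0
    s0_2 = float(np.exp(emean + digamma(half_d0) - np.log(half_d0)))
    return d0, s0_2


def _prior_variance(s2: np.ndarray, d: int, d0: float) -> float:
    z = np.log(s2)
    e = z - digamma(d / 2.0) + np.log(d / 2.0)
    if np.isinf(d0):
        return float(np.exp(np.mean(e)))  # digamma(x) - log(x) -> 0
    return float(np.exp(np.mean(e) + digamma(d0 / 2.0) - np.log(d0 / 2.0)))


# --------------------------------------------------------------------- folds

def stratified_folds(labels: Sequence[str], k: int,
                     rng: np.random.Generator | int) -> np.ndarray:
    """Random stratified fold assignment; per-class counts balanced to +/-1."""
    lab = np.asarray(labels)
    if k < 2:
        raise ValueError("k must be >= 2")
    counts = pd.Series(lab).value_counts()
    if k > counts.min():
        raise ValueError(f"k={k} exceeds the smallest class count {counts.min()}")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    folds = np.empty(lab.size, dtype=int)
    for cls in counts.index:
        idx = np.flatnonzero(lab == cls)
        rng.shuffle(idx)
        folds[idx] = np.arange(idx.size) % k
    return folds


# --------------------------------------------------------------- classifiers

class _AdaptiveStratifiedCV:
    """Stratified k-fold whose fold count adapts to the smallest class."""

    def __init__(self, max_splits: int = 5):
        self.max_splits = max_splits

    def _n(self, y) -> int:
        _, counts = np.unique(y, return_counts=True)
        return max(2, min(self.max_splits, int(counts.min())))

    def split(self, X, y, groups=None):
        from sklearn.model_selection import StratifiedKFold
        return StratifiedKFold(self._n(y)).split(X, y)

    def get_n_splits(self, X=None, y=None, groups=None) -> int:
        return self.max_splits if y is None else self._n(y)


def make_classifier(name: str, params: dict | None = None):
    """Factory for the plug-in classifier contract (fit / predict_proba).

    "elastic_net" is the reference implementation: a penalized logistic
    regression with mixing parameter l1_ratio (default 0.5); "lasso" is the
    same with l1_ratio = 1.  Features are standardized inside the pipeline so
    scaling happens on training folds only.
    """
    params = dict(params or {})
    if name in ("elastic_net", "lasso"):
        l1_ratio = params.pop("l1_ratio", 1.0 if name == "lasso" else 0.5)
        C = params.pop("C", None)
        if C is None:
            # small inner CV over the regularization strength; fold count
            # shrinks with the smallest class so tiny training sets still fit
            from sklearn.linear_model import LogisticRegressionCV
            clf = LogisticRegressionCV(
                Cs=params.pop("Cs", [0.01, 0.1, 1.0, 10.0]),
                cv=params.pop("cv", _AdaptiveStratifiedCV(5)),
                solver="saga", l1_ratios=[l1_ratio],
                max_iter=params.pop("max_iter", 2000), **params)
        else:
            clf = LogisticRegression(
                solver="saga", l1_ratio=l1_ratio, C=C,
                max_iter=params.pop("max_iter", 2000), **params)
    elif name == "logistic":
        clf = LogisticRegression(max_iter=params.pop("max_iter", 1000), **params)
    elif name == "random_forest":
        clf = RandomForestClassifier(**{"n_estimators": 200, **params})
    elif name == "svm":
        clf = SVC(probability=True, **params)
    elif name == "plsda":
        clf = _PlsDa(**params)
    else:
        raise ValueError(f"unknown classifier {name!r}")
    return Pipeline([("scale", StandardScaler()), ("clf", clf)])


class _PlsDa(ClassifierMixin, BaseEstimator):
    """Minimal PLS-DA front end satisfying the fit/predict_proba contract."""

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X, y):
        from sklearn.cross_decomposition import PLSRegression
        self.classes_ = np.unique(y)
        target = (np.asarray(y) == self.classes_[1]).astype(float)
        ncomp = min(self.n_components, X.shape[1], X.shape[0] - 1)
        self._pls = PLSRegression(n_components=ncomp)
        self._pls.fit(X, target)
        return self

    def predict_proba(self, X):
        p = np.clip(self._pls.predict(X).ravel(), 0.0, 1.0)
        return np.column_stack([1 - p, p])


# ------------------------------------------------------------------ CV harness

@dataclass
class CvConfig:
    """Configuration of the repeated stratified k-fold evaluation."""

    k_folds: int = 3
    repetitions: int = 333
    selector: str = "none"              # or "moderated_t_top_k"
    top_k: int = 15
    classifier: str = "elastic_net"
    classifier_params: dict = dataclass_field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")
        if self.selector not in ("none", "moderated_t_top_k"):
            raise ValueError(f"unknown selector {self.selector!r}")


@dataclass
class CvResult:
    """Per-iteration metrics, pooled probabilities and selection logs."""

    metrics: pd.DataFrame        # columns repetition, fold, error, sens, spec
    probabilities: pd.DataFrame  # columns repetition, sample_id, label, p_case
    selected: list[list[str]]    # per classifier fit, features used
    config: CvConfig
    n_fits: int


def run_repeated_cv(features: FeatureMatrix, config: CvConfig) -> CvResult:
    """Repeated stratified k-fold CV with in-fold selection and training.

    The selector and the classifier see training folds only; each held-out
    fold contributes one (error, sensitivity, specificity) record, so a run
    makes exactly k_folds x repetitions classifier fits.  A master seed
    spawns per-repetition substreams, making repetitions independent but
    reproducible.
    """
    if features.labels is None:
        raise ValueError("feature matrix has no labels")
    X = features.values
    y = features.labels.to_numpy()
    n_features = X.shape[1]
    if config.selector == "moderated_t_top_k" and config.top_k > n_features:
        raise ValueError(
            f"top_k={config.top_k} exceeds feature count {n_features}")
    streams = np.random.SeedSequence(config.seed).spawn(config.repetitions)
    met_rows = []
    prob_rows = []
    selected: list[list[str]] = []
    for rep, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        folds = stratified_folds(y, config.k_folds, rng)
        for fold in range(config.k_folds):
            test = folds == fold
            train = ~test
            Xtr, ytr = X.iloc[train], y[train]
            if config.selector == "moderated_t_top_k":
                mt = moderated_t(Xtr, ytr)
                keep = list(mt.rank.sort_values().index[: config.top_k])
            else:
                keep = list(X.columns)
            selected.append(keep)
            clf = make_classifier(config.classifier, config.classifier_params)
            clf.fit(Xtr[keep].values, ytr)
            classes = list(clf.classes_)
            p = clf.predict_proba(X.iloc[test][keep].values)
            p_case = p[:, classes.index(CASE_LABEL)]
            ytest = y[test]
            pred_case = p_case > 0.5
            is_case = ytest == CASE_LABEL
            err = float(np.mean(pred_case != is_case))
            sens = float(np.mean(pred_case[is_case])) if is_case.any() else np.nan
            spec = float(np.mean(~pred_case[~is_case])) if (~is_case).any() else np.nan
            met_rows.append({"repetition": rep, "fold": fold, "error": err,
                             "sensitivity": sens, "specificity": spec})
            for sid, lab_i, pc in zip(X.index[test], ytest, p_case):
                prob_rows.append({"repetition": rep, "sample_id": sid,
                                  "label": lab_i, "p_case": float(pc)})
    metrics = pd.DataFrame(met_rows)
    probs = pd.DataFrame(prob_rows)
    return CvResult(metrics=metrics, probabilities=probs, selected=selected,
                    config=config, n_fits=len(met_rows))


def summarize(result: CvResult) -> pd.DataFrame:
    """Mean and standard error (SD/sqrt(iterations)) of each metric."""
    rows = []
    n = len(result.metrics)
    for metric in ("error", "sensitivity", "specificity"):
        vals = result.metrics[metric].to_numpy(float)
        rows.append({"metric": metric, "mean": float(np.nanmean(vals)),
                     "se": float(np.nanstd(vals, ddof=1) / np.sqrt(n))
                     if n > 1 else 0.0})
    return pd.DataFrame(rows).set_index("metric")


def probability_histogram(result: CvResult, bins: int = 20) -> pd.DataFrame:
    """Per-class histogram of pooled out-of-fold case probabilities."""
    edges = np.linspace(0.0, 1.0, bins + 1)
    out = []
    for lab, grp in result.probabilities.groupby("label"):
        counts, _ = np.histogram(grp["p_case"], bins=edges)
        for lo, hi, c in zip(edges[:-1], edges[1:], counts):
            out.append({"label": lab, "bin_lo": lo, "bin_hi": hi, "count": int(c)})
    return pd.DataFrame(out)


def top_feature_frequency(result: CvResult | None = None,
                          features: FeatureMatrix | None = None,
                          config: CvConfig | None = None,
                          n_top: int = 15) -> pd.Series:
    """Frequency of appearance among the top-n features by |moderated t|.

    With a CV result carrying selection logs, the logged selections are
    re-ranked; otherwise the moderated t is applied per CV iteration to the
    supplied feature matrix (the univariate check used for feature sets that
    are classified without selection).
    """
    if result is not None and result.selected and \
            result.config.selector == "moderated_t_top_k":
        counts: dict[str, int] = {}
        for sel in result.selected:
            for f in sel[:n_top]:
                counts[f] = counts.get(f, 0) + 1
        total = len(result.selected)
        return pd.Series(counts).sort_values(ascending=False) / total
    if features is None:
        raise ValueError("need either a CV result with selection logs or a "
                         "feature matrix")
    cfg = config or (result.config if result is not None else CvConfig())
    X, y = features.values, features.labels.to_numpy()
    streams = np.random.SeedSequence(cfg.seed).spawn(cfg.repetitions)
    counts = {}
    total = 0
    for ss in streams:
        rng = np.random.default_rng(ss)
        folds = stratified_folds(y, cfg.k_folds, rng)
        for fold in range(cfg.k_folds):
            train = folds != fold
            mt = moderated_t(X.iloc[train], y[train])
            for f in mt.rank.sort_values().index[:n_top]:
                counts[f] = counts.get(f, 0) + 1
            total += 1
    return pd.Series(counts).sort_values(ascending=False) / total
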