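"""ALN-status classifiers on promoter-profiling features.

Workflow mirrors the study design: rank features (SVM-RFE with a Welch-t
tie-break, or a fast one-shot |weight| mode), keep the top 100, backward-
eliminate along the ranking to maximize leave-one-out cross-validated AUC,
and evaluate with DeLong AUC confidence intervals and paired/unpaired AUC
comparison tests. Three linear models are supported: linear-kernel SVM
(cost 1), unpenalized logistic regression, and LDA — each standardized on
training-fold statistics and scored by its continuous decision value.

The high-level entry point is :class:`AlnClassifier` (a model bound to a
training matrix and labels) whose :meth:`~AlnClassifier.fit` returns an
:class:`AlnClassifierResults` carrying the selection path, LOOCV scores,
training evaluation and a frozen linear model for validation scoring.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .profiling import PromoterProfileMatrix
from .simulate import NEGATIVE, POSITIVE

MODEL_TYPES = ("svm", "lr", "lda")


class ClassifierError(ValueError):
    pass


def _as_binary(labels) -> np.ndarray:
    y = np.asarray(labels)
    if y.dtype.kind in "biu" or set(np.unique(y)) <= {0, 1, True, False}:
        return y.astype(int)
    classes = set(np.unique(y))
    if classes <= {POSITIVE, NEGATIVE}:
        return (y == POSITIVE).astype(int)
    raise ClassifierError(f"labels must be 0/1 or {POSITIVE!r}/{NEGATIVE!r}; got {sorted(classes)}")


def _new_estimator(model_type: str):
    if model_type == "svm":
        return SVC(kernel="linear", C=1.0)
    if model_type == "lr":
        # unpenalized, matching a plain GLM fit
        return LogisticRegression(C=np.inf, solver="lbfgs", max_iter=2000)
    if model_type == "lda":
        return LinearDiscriminantAnalysis()
    raise ClassifierError(f"model_type must be one of {MODEL_TYPES}, got {model_type!r}")


# ----------------------------------------------------------- DeLong / ROC


def _placements(pos: np.ndarray, neg: np.ndarray):
    """AUC and DeLong placement values via midranks."""
    m, n = len(pos), len(neg)
    r_all = stats.rankdata(np.concatenate([pos, neg]))
    v10 = (r_all[:m] - stats.rankdata(pos)) / n
    v01 = 1.0 - (r_all[m:] - stats.rankdata(neg)) / m
    return float(v10.mean()), v10, v01


def auc_mann_whitney(scores, labels) -> float:
    """AUC as the Mann–Whitney concordance statistic (ties count ½)."""
    y = _as_binary(labels)
    s = np.asarray(scores, float)
    if y.sum() == 0 or y.sum() == len(y):
        raise ClassifierError("both classes must be present")
    auc, _, _ = _placements(s[y == 1], s[y == 0])
    return auc


@dataclass
class ClassifierEvaluation:
    """ROC summary of one score vector: AUC with DeLong CI + Youden point."""

    model_type: str
    features: list[str] = field(default_factory=list)
    scores: pd.Series | None = field(default=None, repr=False)
    auc: float = np.nan
    delong_se: float = np.nan
    ci95: tuple[float, float] = (np.nan, np.nan)
    threshold: float = np.nan
    sensitivity: float = np.nan
    specificity: float = np.nan
    accuracy: float = np.nan
    cohort: str = ""

    def as_row(self) -> dict:
        return {
            "cohort": self.cohort,
            "model_type": self.model_type,
            "n_features": len(self.features),
            "auc": self.auc,
            "delong_se": self.delong_se,
            "ci95_lo": self.ci95[0],
            "ci95_hi": self.ci95[1],
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
        }


def roc_with_delong(
    scores, labels, model_type: str = "", features: list[str] | None = None, cohort: str = ""
) -> ClassifierEvaluation:
    """AUC, DeLong SE and 95% CI, and Youden-optimal operating point.

    The operating threshold maximizes sensitivity + specificity − 1
    (ties resolved toward higher specificity); sensitivity, specificity
    and accuracy are reported at that threshold.
    """
    y = _as_binary(labels)
    s = np.asarray(scores, float)
    if y.sum() == 0 or y.sum() == len(y):
        raise ClassifierError("both classes must be present")
    pos, neg = s[y == 1], s[y == 0]
    auc, v10, v01 = _placements(pos, neg)
    var = 0.0
    if len(pos) > 1:
        var += np.var(v10, ddof=1) / len(pos)
    if len(neg) > 1:
        var += np.var(v01, ddof=1) / len(neg)
    se = float(np.sqrt(var))
    ci = (max(0.0, auc - 1.96 * se), min(1.0, auc + 1.96 * se))

    best = (-np.inf, -np.inf, np.nan)  # (youden, specificity, threshold)
    for t in np.unique(s):
        pred = s >= t
        sens = float(np.mean(pred[y == 1]))
        spec = float(np.mean(~pred[y == 0]))
        key = (sens + spec - 1, spec, t)
        if key[:2] > best[:2]:
            best = key
    youden, spec, thr = best
    pred = s >= thr
    sens = float(np.mean(pred[y == 1]))
    acc = float(np.mean(pred == (y == 1)))
    idx = scores.index if isinstance(scores, pd.Series) else None
    return ClassifierEvaluation(
        model_type=model_type,
        features=list(features or []),
        scores=pd.Series(s, index=idx),
        auc=auc,
        delong_se=se,
        ci95=ci,
        threshold=float(thr),
        sensitivity=sens,
        specificity=spec,
        accuracy=acc,
        cohort=cohort,
    )


def compare_auc_delong(scores_a, scores_b, labels) -> tuple[float, float]:
    """Paired DeLong test for the AUC difference of two score vectors.

    Both score vectors must be over the same samples. Returns ``(z, p)``
    with a two-sided normal p; identical scores give p = 1.
    """
    sa = np.asarray(scores_a, float)
    sb = np.asarray(scores_b, float)
    if sa.shape != sb.shape:
        raise ClassifierError("paired comparison requires scores on identical samples")
    y = _as_binary(labels)
    auc_a, v10a, v01a = _placements(sa[y == 1], sa[y == 0])
    auc_b, v10b, v01b = _placements(sb[y == 1], sb[y == 0])
    m, n = int(y.sum()), int(len(y) - y.sum())
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1)
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1)
    var = s10[0, 0] / m + s01[0, 0] / n + s10[1, 1] / m + s01[1, 1] / n
    var -= 2 * (s10[0, 1] / m + s01[0, 1] / n)
    if var <= 0:
        return 0.0, 1.0
    z = (auc_a - auc_b) / np.sqrt(var)
    return float(z), float(2 * stats.norm.sf(abs(z)))


def compare_auc_unpaired(eval_a: ClassifierEvaluation, eval_b: ClassifierEvaluation) -> tuple[float, float]:
    """Normal-theory AUC comparison between independent cohorts/strata."""
    var = eval_a.delong_se**2 + eval_b.delong_se**2
    if var <= 0:
        return 0.0, 1.0
    z = (eval_a.auc - eval_b.auc) / np.sqrt(var)
    return float(z), float(2 * stats.norm.sf(abs(z)))


# -------------------------------------------------------- feature ranking


@dataclass
class FeatureRanking:
    """Features ordered best-first with importance scores."""

    table: pd.DataFrame = field(repr=False)  # columns: feature_id, importance
    method: str = "rfe"

    @property
    def features(self) -> list[str]:
        return list(self.table["feature_id"])

    def top(self, k: int) -> list[str]:
        return self.features[:k]


def _welch_p(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(X[y == 1], X[y == 0], equal_var=False)
    return np.where(np.isfinite(res.pvalue), res.pvalue, 1.0)


def rank_features(
    matrix: PromoterProfileMatrix, labels, method: str = "rfe"
) -> FeatureRanking:
    """Rank features by linear-SVM recursive elimination.

    ``method='rfe'``: repeatedly fit a standardized linear SVM on the
    remaining features and eliminate the one with the smallest absolute
    weight (ties broken by eliminating the larger Welch-t p-value first);
    the rank is the reverse elimination order. ``method='weight'`` is a
    one-shot ranking by |weight| from a single fit. Constant features are
    ranked last with a warning.
    """
    y = _as_binary(labels)
    if min((y == 1).sum(), (y == 0).sum()) < 2 or len(y) <= 2:
        raise ClassifierError("need at least 2 samples per class")
    X = matrix.values.to_numpy(float)
    feats = np.array(matrix.feature_ids)
    const = X.std(axis=0) == 0
    if const.any():
        warnings.warn(f"{int(const.sum())} constant features ranked last")
    Xs = StandardScaler().fit_transform(X)
    welch = _welch_p(X, y)

    if method == "weight":
        w = np.abs(_fit_weights(Xs, y))
        order = np.lexsort((welch, -w))  # |w| desc, then smaller Welch p first
        imp = w[order]
        order_feats = feats[order]
    elif method == "rfe":
        remaining = list(range(X.shape[1]))
        eliminated: list[int] = []
        while len(remaining) > 1:
            w = np.abs(_fit_weights(Xs[:, remaining], y))
            # eliminate smallest |weight|; tie → larger Welch p goes first
            cand = np.lexsort((-welch[remaining], w))[0]
            eliminated.append(remaining.pop(cand))
        ranked_idx = remaining + eliminated[::-1]
        order_feats = feats[ranked_idx]
        imp = np.arange(len(feats), 0, -1, dtype=float)
    else:
        raise ClassifierError(f"unknown ranking method {method!r}")
    table = pd.DataFrame({"feature_id": order_feats, "importance": imp})
    return FeatureRanking(table=table, method=method)


def _fit_weights(Xs: np.ndarray, y: np.ndarray) -> np.ndarray:
    clf = SVC(kernel="linear", C=1.0)
    clf.fit(Xs, y)
    return clf.coef_[0]


# ------------------------------------------------------------------ LOOCV


def loocv_scores(
    matrix: PromoterProfileMatrix, labels, feature_subset, model_type: str = "svm"
) -> pd.Series:
    """Leave-one-out decision scores for one feature subset.

    Each sample is scored by a model standardized and fitted on all other
    samples; the pooled scores feed a single ROC.
    """
    subset = list(feature_subset)
    if not subset:
        raise ClassifierError("feature subset must be non-empty")
    y = _as_binary(labels)
    if len(y) < 3:
        raise ClassifierError("need at least 3 samples for LOOCV")
    if min((y == 1).sum(), (y == 0).sum()) < 2:
        raise ClassifierError("leaving one sample out must keep both classes present")
    X = matrix.values[subset].to_numpy(float)
    scores = np.empty(len(y))
    mask = np.ones(len(y), bool)
    for i in range(len(y)):
        mask[i] = False
        scaler = StandardScaler().fit(X[mask])
        est = _new_estimator(model_type)
        est.fit(scaler.transform(X[mask]), y[mask])
        scores[i] = est.decision_function(scaler.transform(X[i : i + 1]))[0]
        mask[i] = True
    return pd.Series(scores, index=matrix.sample_ids, name=f"loocv_{model_type}")


def backward_select(
    matrix: PromoterProfileMatrix,
    labels,
    ranking: FeatureRanking,
    k_top: int = 100,
    model_type: str = "svm",
    mode: str = "rank",
) -> tuple[list[str], pd.DataFrame]:
    """Backward elimination maximizing LOOCV AUC.

    Default ``mode='rank'``: start from the top ``k_top`` ranked features
    and drop the lowest-ranked one at a time, recording the LOOCV AUC at
    every size; the returned subset maximizes AUC (ties favour the
    smallest subset). ``mode='greedy'`` removes whichever feature best
    improves the AUC and stops when no removal improves it.
    """
    if k_top < 1:
        raise ClassifierError("k_top must be >= 1")
    k_top = min(k_top, len(ranking.features))
    start = ranking.top(k_top)
    path_rows = []
    if mode == "rank":
        best_auc, best_subset = -np.inf, start
        for k in range(k_top, 0, -1):
            subset = start[:k]
            auc = auc_mann_whitney(loocv_scores(matrix, labels, subset, model_type), labels)
            path_rows.append({"k": k, "auc": auc, "dropped": start[k] if k < k_top else ""})
            if auc >= best_auc:  # ties → smaller subset (we scan large→small)
                best_auc, best_subset = auc, subset
        return list(best_subset), pd.DataFrame(path_rows)
    if mode == "greedy":
        subset = list(start)
        cur = auc_mann_whitney(loocv_scores(matrix, labels, subset, model_type), labels)
        path_rows.append({"k": len(subset), "auc": cur, "dropped": ""})
        while len(subset) > 1:
            trials = []
            for f in subset:
                trial = [g for g in subset if g != f]
                auc = auc_mann_whitney(loocv_scores(matrix, labels, trial, model_type), labels)
                trials.append((auc, f))
            best_removal = max(trials)
            if best_removal[0] <= cur:
                break
            cur = best_removal[0]
            subset.remove(best_removal[1])
            path_rows.append({"k": len(subset), "auc": cur, "dropped": best_removal[1]})
        return subset, pd.DataFrame(path_rows)
    raise ClassifierError(f"unknown backward-selection mode {mode!r}")


# -------------------------------------------------------- frozen classifier


@dataclass
class FittedClassifier:
    """A trained linear decision rule frozen for validation scoring.

    All three model types are linear in the standardized features, so the
    decision value is ``w · (x − mean) / scale + b`` with constants frozen
    from the training cohort.
    """

    model_type: str
    features: list[str]
    mean: np.ndarray
    scale: np.ndarray
    coef: np.ndarray
    intercept: float
    threshold: float = np.nan

    def decision(self, matrix: PromoterProfileMatrix) -> pd.Series:
        missing = [f for f in self.features if f not in matrix.values.columns]
        if missing:
            raise ClassifierError(f"validation matrix lacks features: {missing[:10]}")
        X = matrix.values[self.features].to_numpy(float)
        z = (X - self.mean) / self.scale
        return pd.Series(z @ self.coef + self.intercept, index=matrix.sample_ids)

    def to_json(self, path) -> None:
        payload = {
            "model_type": self.model_type,
            "features": self.features,
            "mean": self.mean.tolist(),
            "scale": self.scale.tolist(),
            "coef": self.coef.tolist(),
            "intercept": self.intercept,
            "threshold": self.threshold,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "FittedClassifier":
        with open(path) as fh:
            p = json.load(fh)
        return cls(
            model_type=p["model_type"],
            features=p["features"],
            mean=np.asarray(p["mean"], float),
            scale=np.asarray(p["scale"], float),
            coef=np.asarray(p["coef"], float),
            intercept=float(p["intercept"]),
            threshold=float(p["threshold"]),
        )


def fit_frozen(
    matrix: PromoterProfileMatrix, labels, features, model_type: str = "svm"
) -> FittedClassifier:
    """Fit once on the full training cohort and freeze the linear rule."""
    features = list(features)
    y = _as_binary(labels)
    X = matrix.values[features].to_numpy(float)
    scaler = StandardScaler().fit(X)
    est = _new_estimator(model_type)
    est.fit(scaler.transform(X), y)
    return FittedClassifier(
        model_type=model_type,
        features=features,
        mean=scaler.mean_,
        scale=scaler.scale_,
        coef=np.asarray(est.coef_[0] if est.coef_.ndim == 2 else est.coef_, float),
        intercept=float(np.atleast_1d(est.intercept_)[0]),
    )


def evaluate_on_validation(
    fitted: FittedClassifier, matrix: PromoterProfileMatrix, labels
) -> ClassifierEvaluation:
    """Score a frozen training-cohort model on an untouched validation set."""
    scores = fitted.decision(matrix)
    return roc_with_delong(
        scores, labels, model_type=fitted.model_type, features=fitted.features, cohort="validation"
    )


# ------------------------------------------------- strata and covariates


def stratified_evaluation(scores, labels, covariate) -> tuple[pd.DataFrame, dict]:
    """Per-stratum ROC evaluation plus pairwise unpaired DeLong p-values.

    Strata missing a class are excluded with a warning.
    """
    scores = pd.Series(np.asarray(scores, float))
    y = _as_binary(labels)
    cov = np.asarray(covariate)
    evals = {}
    for level in pd.unique(cov):
        m = cov == level
        if len(set(y[m])) < 2:
            warnings.warn(f"stratum {level!r} lacks both classes; excluded")
            continue
        evals[level] = roc_with_delong(scores[m].to_numpy(), y[m], cohort=str(level))
    rows = pd.DataFrame([e.as_row() for e in evals.values()])
    pvals = {}
    levels = list(evals)
    for i in range(len(levels)):
        for j in range(i + 1, len(levels)):
            _, p = compare_auc_unpaired(evals[levels[i]], evals[levels[j]])
            pvals[(levels[i], levels[j])] = p
    return rows, pvals


def combine_with_covariates(
    matrix: PromoterProfileMatrix,
    selected_subset,
    covariates: pd.DataFrame,
    labels,
    model_type: str = "svm",
) -> pd.DataFrame:
    """LOOCV evaluation of gene features plus every covariate combination.

    Appends each non-empty subset of the covariate columns (2^m − 1
    combinations) to the selected gene features, re-evaluates with LOOCV,
    and returns one row per combination plus the gene-only baseline,
    sorted by AUC (descending).
    """
    from itertools import combinations

    if covariates.isna().any().any():
        bad = covariates.columns[covariates.isna().any()].tolist()
        raise ClassifierError(f"missing covariate values in {bad}; no imputation performed")
    selected_subset = list(selected_subset)
    cols = list(covariates.columns)
    aug = matrix.values.join(covariates.set_axis(matrix.values.index))
    rows = []
    combos = [()] + [c for r in range(1, len(cols) + 1) for c in combinations(cols, r)]
    for combo in combos:
        feats = selected_subset + list(combo)
        scores = loocv_scores(_wrap(aug[feats], matrix.level), labels, feats, model_type)
        ev = roc_with_delong(scores, labels, model_type=model_type, features=feats)
        row = ev.as_row()
        row["covariates"] = "+".join(combo) if combo else "(baseline)"
        rows.append(row)
    out = pd.DataFrame(rows).sort_values("auc", ascending=False).reset_index(drop=True)
    return out[["covariates"] + [c for c in out.columns if c != "covariates"]]


def _wrap(df: pd.DataFrame, level: str) -> PromoterProfileMatrix:
    m = object.__new__(PromoterProfileMatrix)
    m.values = df
    m.level = level
    return m


def enrichment_pvalue(selected, truth_positive, universe) -> float:
    """Hypergeometric over-representation p of truth genes in a selection."""
    universe = set(universe)
    selected = set(selected) & universe
    truth_positive = set(truth_positive) & universe
    k = len(selected & truth_positive)
    return float(
        stats.hypergeom.sf(k - 1, len(universe), len(truth_positive), len(selected))
    )


# --------------------------------------------------- model/results façade


class AlnClassifier:
    """Lymph-node-status classifier bound to a training profile matrix.

    Parameters
    ----------
    matrix
        Training-cohort :class:`PromoterProfileMatrix`.
    labels
        Per-sample class labels (``ALN-positive``/``ALN-negative`` or 0/1),
        aligned with the matrix rows.
    model_type
        ``'svm'`` (linear kernel, cost 1), ``'lr'`` or ``'lda'``.
    """

    def __init__(self, matrix: PromoterProfileMatrix, labels, model_type: str = "svm"):
        if model_type not in MODEL_TYPES:
            raise ClassifierError(f"model_type must be one of {MODEL_TYPES}")
        self.matrix = matrix
        self.labels = pd.Series(_as_binary(labels), index=matrix.sample_ids)
        self.model_type = model_type

    @classmethod
    def from_dataframe(
        cls, data: pd.DataFrame, label_col: str = "label", model_type: str = "svm", level: str = "gene"
    ) -> "AlnClassifier":
        """Build from a tidy frame with one label column + feature columns."""
        features = data.drop(columns=[label_col])
        return cls(PromoterProfileMatrix(features, level=level), data[label_col], model_type)

    def fit(
        self,
        k_top: int = 100,
        ranking_method: str = "rfe",
        selection_mode: str = "rank",
        ranking: FeatureRanking | None = None,
    ) -> "AlnClassifierResults":
        """Rank → top-k → backward-eliminate → LOOCV-evaluate → freeze."""
        if ranking is None:
            ranking = rank_features(self.matrix, self.labels, method=ranking_method)
        subset, path = backward_select(
            self.matrix, self.labels, ranking, k_top=k_top,
            model_type=self.model_type, mode=selection_mode,
        )
        scores = loocv_scores(self.matrix, self.labels, subset, self.model_type)
        train_eval = roc_with_delong(
            scores, self.labels, model_type=self.model_type, features=subset, cohort="training"
        )
        frozen = fit_frozen(self.matrix, self.labels, subset, self.model_type)
        frozen.threshold = train_eval.threshold
        return AlnClassifierResults(
            model=self, ranking=ranking, selected_features=list(subset),
            auc_path=path, loocv_scores_=scores, train_eval=train_eval, fitted=frozen,
        )


@dataclass
class AlnClassifierResults:
    """Fit results: selection path, LOOCV scores, evaluations, frozen rule."""

    model: AlnClassifier
    ranking: FeatureRanking
    selected_features: list[str]
    auc_path: pd.DataFrame = field(repr=False)
    loocv_scores_: pd.Series = field(repr=False)
    train_eval: ClassifierEvaluation = field(repr=False)
    fitted: FittedClassifier = field(repr=False)

    @property
    def auc(self) -> float:
        return self.train_eval.auc

    @property
    def informative(self) -> bool:
        """False when even the best subset barely beats chance (AUC < 0.6)."""
        return self.train_eval.auc >= 0.6

    def evaluate(self, matrix: PromoterProfileMatrix, labels) -> ClassifierEvaluation:
        """Score the frozen training model on a validation cohort."""
        return evaluate_on_validation(self.fitted, matrix, labels)

    def pooled_evaluation(self, matrix: PromoterProfileMatrix, labels) -> ClassifierEvaluation:
        """One ROC over training LOOCV scores pooled with validation scores."""
        val_scores = self.fitted.decision(matrix)
        scores = pd.concat([self.loocv_scores_, val_scores])
        y = pd.concat([self.model.labels, pd.Series(_as_binary(labels), index=matrix.sample_ids)])
        ev = roc_with_delong(
            scores, y, model_type=self.model.model_type,
            features=self.selected_features, cohort="pooled",
        )
        return ev

    def summary(self) -> str:
        e = self.train_eval
        lines = [
            "ALN-status promoter-profiling classifier",
            "=" * 48,
            f"model:            {self.model.model_type} (linear, standardized)",
            f"training samples: {len(self.model.labels)} "
            f"({int(self.model.labels.sum())} ALN-positive)",
            f"features ranked:  {len(self.ranking.features)} ({self.ranking.method})",
            f"selected subset:  {len(self.selected_features)} features",
            f"LOOCV AUC:        {e.auc:.3f} (DeLong 95% CI {e.ci95[0]:.3f}-{e.ci95[1]:.3f})",
            f"operating point:  sens {e.sensitivity:.3f}, spec {e.specificity:.3f}, "
            f"acc {e.accuracy:.3f} (Youden)",
            f"informative:      {self.informative}",
        ]
        return "\n".join(lines)
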