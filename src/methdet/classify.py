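"""Cross-validated model comparison, PLS-VIP gene selection and accuracy.

Six model families are compared by stratified 5-fold cross-validation
repeated over ten runs, scoring each run by the area under the ROC curve of
the pooled out-of-fold scores; the family with the highest mean AUC wins
(ties broken by the fixed listing order). Gene importance uses the PLS
Variable Importance in Projection (VIP) statistic, whose squared values
average to 1 across genes, so VIP > 1 marks above-average contributors.
Panel accuracy is reported both by resubstitution (whole-data fit, the
optimistic "whole-model fit" convention) and by cross-validation.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.cross_decomposition import PLSRegression
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.tree import DecisionTreeClassifier

from .preprocess import MethylationMatrix, impute_median
from .synthetic import RELAPSE

MODEL_FAMILIES = ("pls", "knn", "logistic", "discriminant", "tree", "glm_forward")


@dataclass(frozen=True)
class ModelSpec:
    family: str
    hyperparams: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in MODEL_FAMILIES:
            raise ValueError(f"unknown model family {self.family!r}")


@dataclass
class CVResult:
    model: ModelSpec
    auc_per_run: List[float]
    auc_mean: float
    fold_scheme: Tuple[int, int, int]  # (k, runs, seed)


@dataclass
class GeneRanking:
    scores: pd.Series  # gene -> mean VIP over CV fits
    selection_rule: str


@dataclass
class PanelMetrics:
    """Confusion counts and derived accuracy of a gene panel or single gene."""

    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    auc: float
    threshold: float
    scope: str  # "panel" or "single_gene:<id>"
    evaluation: str  # "resubstitution" or "cross_validated"


def encode_labels(labels: pd.Series) -> np.ndarray:
    """Relapse = positive class = 1."""
    y = (labels == RELAPSE).to_numpy().astype(int)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("both classes must be present")
    return y


def auc_score(y: np.ndarray, scores: np.ndarray) -> float:
    """AUC by the rank (Mann-Whitney) construction, ties counted 1/2.

    Equals the probability that a random positive outscores a random
    negative, with ties contributing half.
    """
    y = np.asarray(y)
    scores = np.asarray(scores, dtype=float)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined with a single class")
    ranks = rankdata(scores)
    return float(
        (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    )


def _design(matrix: MethylationMatrix, labels: pd.Series, genes=None):
    common = [s for s in matrix.samples if s in labels.index]
    if not common:
        raise ValueError("no overlap between matrix samples and labels")
    values = matrix.values[common]
    if genes is not None:
        missing = [g for g in genes if g not in values.index]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing}")
        values = values.loc[list(genes)]
    X = impute_median(values).to_numpy().T  # samples x genes
    y = encode_labels(labels.loc[common])
    return X, y, common, list(values.index)


def _clip_proba(p: np.ndarray) -> np.ndarray:
    return np.clip(p, 1e-10, 1 - 1e-10)


def _pls_components(requested: int, n_train: int, n_feat: int) -> int:
    return max(1, min(requested, n_train - 1, n_feat))


def _fit_score(spec: ModelSpec, X_tr, y_tr, X_te) -> np.ndarray:
    """Fit one model family on the training split and score the test split
    with a continuous relapse score (higher = more relapse-like)."""
    hp = spec.hyperparams
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        if spec.family == "pls":
            ncomp = _pls_components(hp.get("n_components", 2), len(y_tr), X_tr.shape[1])
            model = PLSRegression(n_components=ncomp).fit(X_tr, y_tr.astype(float))
            return model.predict(X_te).ravel()
        if spec.family == "knn":
            model = KNeighborsClassifier(n_neighbors=hp.get("k", 3)).fit(X_tr, y_tr)
            return model.predict_proba(X_te)[:, 1]
        if spec.family == "logistic":
            model = LogisticRegression(max_iter=hp.get("max_iter", 2000)).fit(X_tr, y_tr)
            return model.predict_proba(X_te)[:, 1]
        if spec.family == "discriminant":
            model = LinearDiscriminantAnalysis().fit(X_tr, y_tr)
            return model.decision_function(X_te)
        if spec.family == "tree":
            model = DecisionTreeClassifier(
                random_state=0, min_samples_leaf=hp.get("min_samples_leaf", 2)
            ).fit(X_tr, y_tr)
            return model.predict_proba(X_te)[:, 1]
        if spec.family == "glm_forward":
            return _forward_aic_logistic(
                X_tr, y_tr, X_te, max_features=hp.get("max_features", 10)
            )
    raise AssertionError(spec.family)


def _logistic_aic(X, y, cols) -> tuple[float, Optional[LogisticRegression]]:
    if cols:
        model = LogisticRegression(penalty=None, max_iter=500).fit(X[:, cols], y)
        p = _clip_proba(model.predict_proba(X[:, cols])[:, 1])
    else:
        model = None
        p = np.full(len(y), _clip_proba(np.array([y.mean()]))[0])
    loglik = float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))
    return 2 * (len(cols) + 1) - 2 * loglik, model


def _forward_aic_logistic(X_tr, y_tr, X_te, max_features: int = 10) -> np.ndarray:
    """General-linear-model selection: forward stepwise logistic regression
    by AIC, scored with the selected model's predicted probabilities."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        best_aic, _ = _logistic_aic(X_tr, y_tr, [])
        selected: List[int] = []
        remaining = list(range(X_tr.shape[1]))
        model = None
        while remaining and len(selected) < max_features:
            trials = [
                (_logistic_aic(X_tr, y_tr, selected + [j])[0], j) for j in remaining
            ]
            aic, j = min(trials)
            if aic >= best_aic - 1e-9:
                break
            best_aic = aic
            selected.append(j)
            remaining.remove(j)
        if not selected:
            return np.full(X_te.shape[0], y_tr.mean())
        _, model = _logistic_aic(X_tr, y_tr, selected)
        return model.predict_proba(X_te[:, selected])[:, 1]


def default_model_specs() -> List[ModelSpec]:
    return [ModelSpec(f) for f in MODEL_FAMILIES]


def cross_validate_models(
    matrix: MethylationMatrix,
    labels: pd.Series,
    specs: Optional[Sequence[ModelSpec]] = None,
    k: int = 5,
    runs: int = 10,
    seed: int = 0,
) -> Tuple[List[CVResult], ModelSpec]:
    """Compare model families by repeated stratified k-fold CV.

    Per run, out-of-fold scores of all folds are pooled into a single AUC;
    the best model maximizes the mean AUC over runs (ties resolved by the
    order of ``specs``). Deterministic given ``seed``.
    """
    specs = list(specs) if specs is not None else default_model_specs()
    X, y, _, _ = _design(matrix, labels)
    run_seeds = np.random.SeedSequence(seed).generate_state(runs) % (2**31)
    results = [
        CVResult(model=s, auc_per_run=[], auc_mean=np.nan, fold_scheme=(k, runs, seed))
        for s in specs
    ]
    for run_seed in run_seeds:
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=int(run_seed))
        folds = list(skf.split(X, y))
        for res in results:
            oof = np.empty(len(y))
            for tr, te in folds:
                oof[te] = _fit_score(res.model, X[tr], y[tr], X[te])
            res.auc_per_run.append(auc_score(y, oof))
    for res in results:
        res.auc_mean = float(np.mean(res.auc_per_run))
    best = max(results, key=lambda r: r.auc_mean)  # first max wins ties
    return results, best.model


def vip_scores(X: np.ndarray, y: np.ndarray, n_components: int = 2) -> np.ndarray:
    """Variable Importance in Projection for a PLS fit of y on X.

    VIP_j^2 = p * sum_a [SSY_a * (w_ja / ||w_a||)^2] / sum_a SSY_a with
    SSY_a = q_a^2 * t_a't_a, so that mean_j VIP_j^2 = 1.
    """
    ncomp = _pls_components(n_components, len(y), X.shape[1])
    pls = PLSRegression(n_components=ncomp).fit(X, np.asarray(y, dtype=float))
    W = pls.x_weights_  # p x a
    T = pls.x_scores_  # n x a
    q = pls.y_loadings_.ravel()  # a
    ssy = (q**2) * (T**2).sum(axis=0)
    wnorm = (W**2).sum(axis=0)
    p = X.shape[1]
    vip2 = p * ((W**2) / wnorm) @ ssy / ssy.sum()
    return np.sqrt(vip2)


def rank_and_select_panel(
    matrix: MethylationMatrix,
    labels: pd.Series,
    candidate_genes: Optional[Sequence[str]] = None,
    vip_min: float = 1.0,
    top_k: Optional[int] = None,
    n_components: int = 2,
    cv_k: int = 5,
    cv_runs: int = 10,
    seed: int = 0,
) -> Tuple[GeneRanking, List[str]]:
    """Rank genes by fold-averaged PLS-VIP and select the panel.

    VIP is computed on all genes of the matrix (the full probe background
    keeps the VIP > 1 rule on its natural scale, with null probes as the
    internal reference); the panel is the subset of ``candidate_genes``
    (default: all genes) whose mean VIP exceeds ``vip_min``, or the top-k
    candidates if ``top_k`` is given. Scores are averaged over the folds of
    ``cv_runs`` repeats of stratified ``cv_k``-fold splits.
    """
    X, y, _, genes = _design(matrix, labels)
    candidates = list(candidate_genes) if candidate_genes is not None else list(genes)
    if len(candidates) < 2:
        raise ValueError("need at least 2 candidate genes")
    missing = [g for g in candidates if g not in genes]
    if missing:
        raise KeyError(f"candidate genes absent from matrix: {missing}")
    run_seeds = np.random.SeedSequence(seed).generate_state(cv_runs) % (2**31)
    vips = np.zeros(len(genes))
    n_fits = 0
    for run_seed in run_seeds:
        skf = StratifiedKFold(n_splits=cv_k, shuffle=True, random_state=int(run_seed))
        for tr, _te in skf.split(X, y):
            vips += vip_scores(X[tr], y[tr], n_components)
            n_fits += 1
    scores = pd.Series(vips / n_fits, index=genes, name="vip").sort_values(
        ascending=False
    )
    if top_k is not None:
        rule = f"top_{top_k}"
        selected = [g for g in scores.index if g in candidates][:top_k]
    else:
        rule = f"vip>{vip_min}"
        selected = [g for g in scores.index if g in candidates and scores[g] > vip_min]
    return GeneRanking(scores=scores, selection_rule=rule), selected


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def metrics_from_scores(
    y: np.ndarray,
    scores: np.ndarray,
    threshold: float,
    scope: str,
    evaluation: str,
) -> PanelMetrics:
    """Confusion-matrix metrics at a score cutoff (predict positive at
    score >= threshold); undefined ratios are reported as NaN."""
    pred = np.asarray(scores) >= threshold
    y = np.asarray(y).astype(bool)
    tp = int((pred & y).sum())
    fp = int((pred & ~y).sum())
    tn = int((~pred & ~y).sum())
    fn = int((~pred & y).sum())
    return PanelMetrics(
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        sensitivity=_safe_div(tp, tp + fn),
        specificity=_safe_div(tn, tn + fp),
        ppv=_safe_div(tp, tp + fp),
        npv=_safe_div(tn, tn + fn),
        auc=auc_score(y.astype(int), scores),
        threshold=float(threshold),
        scope=scope,
        evaluation=evaluation,
    )


def youden_threshold(y: np.ndarray, scores: np.ndarray) -> float:
    """Score cutoff maximizing Youden's J = sensitivity + specificity - 1;
    ties resolved toward the higher (more specific) cutoff."""
    y = np.asarray(y).astype(bool)
    best_j, best_thr = -np.inf, None
    for thr in np.unique(scores)[::-1]:
        pred = scores >= thr
        sens = (pred & y).sum() / y.sum()
        spec = (~pred & ~y).sum() / (~y).sum()
        j = sens + spec - 1.0
        if j > best_j + 1e-12:
            best_j, best_thr = j, thr
    return float(best_thr)


def roc_points(y: np.ndarray, scores: np.ndarray) -> pd.DataFrame:
    """ROC coordinates over all observed score cutoffs."""
    y = np.asarray(y).astype(bool)
    rows = [{"threshold": np.inf, "fpr": 0.0, "tpr": 0.0}]
    for thr in np.unique(scores)[::-1]:
        pred = scores >= thr
        rows.append(
            {
                "threshold": float(thr),
                "fpr": float((pred & ~y).sum() / (~y).sum()),
                "tpr": float((pred & y).sum() / y.sum()),
            }
        )
    return pd.DataFrame(rows)


def evaluate_panel(
    matrix: MethylationMatrix,
    labels: pd.Series,
    panel: Sequence[str],
    mode: str = "resubstitution",
    n_components: int = 2,
    k: int = 5,
    seed: int = 0,
) -> Tuple[PanelMetrics, pd.DataFrame]:
    """Accuracy of a PLS score built from the panel genes.

    ``mode="resubstitution"`` fits and scores on all samples (the whole-data
    "whole-model fit" convention; optimistically biased);
    ``mode="cross_validated"`` pools out-of-fold scores from a stratified
    k-fold split. The classification threshold maximizes Youden's J on the
    resulting scores. Returns the metrics and the ROC coordinates.
    """
    if not panel:
        raise ValueError("panel must be non-empty")
    if mode not in ("resubstitution", "cross_validated"):
        raise ValueError(f"unknown mode {mode!r}")
    X, y, _, _ = _design(matrix, labels, genes=panel)
    spec = ModelSpec("pls", {"n_components": n_components})
    if mode == "resubstitution":
        scores = _fit_score(spec, X, y, X)
    else:
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        scores = np.empty(len(y))
        for tr, te in skf.split(X, y):
            scores[te] = _fit_score(spec, X[tr], y[tr], X[te])
    thr = youden_threshold(y, scores)
    scope = "panel" if len(panel) > 1 else f"single_gene:{panel[0]}"
    return metrics_from_scores(y, scores, thr, scope, mode), roc_points(y, scores)


def evaluate_single_genes(
    matrix: MethylationMatrix,
    labels: pd.Series,
    panel: Sequence[str],
    mode: str = "resubstitution",
    k: int = 5,
    seed: int = 0,
) -> List[PanelMetrics]:
    """Per-gene accuracy: a one-feature PLS score (equivalent to thresholding
    the oriented gene value), one metrics row per panel gene."""
    if not panel:
        raise ValueError("panel must be non-empty")
    return [
        evaluate_panel(matrix, labels, [g], mode=mode, k=k, seed=seed)[0]
        for g in panel
    ]


def metrics_to_frame(metrics: Sequence[PanelMetrics]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "scope": m.scope,
                "evaluation": m.evaluation,
                "sensitivity": m.sensitivity,
                "specificity": m.specificity,
                "ppv": m.ppv,
                "npv": m.npv,
                "auc": m.auc,
                "tp": m.tp,
                "fp": m.fp,
                "tn": m.tn,
                "fn": m.fn,
                "threshold": m.threshold,
            }
            for m in metrics
        ]
    )
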