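"""Cross-validated evaluation of the single-trial classifiers.

Per subject: a stratified 10-fold plan, per-fold fitting (with optional
inner-CV hyperparameter search and fold-local channel selection/scaling),
and six generalization metrics — classification accuracy (CA), area under
the ROC curve (AUC), sensitivity (SE), specificity (SP), Cohen's kappa and
computational time (CT).  Across subjects: Table-style summaries (mean ±
SD) and paired-t comparisons with a winner ranking.

Metric definitions, with TP/TN/FP/FN the confusion counts over evaluated
trials (positive-emotion trials are the positive class):

    CA    = (TP + TN) / (TP + TN + FP + FN)
    SE    = TP / (TP + FN)
    SP    = TN / (TN + FP)
    AUC   = P(score(random positive) > score(random negative)), ties 1/2
    Kappa = (P(O) - P(E)) / (1 - P(E)),  P(O) = CA,
            P(E) = [(TP+FN)(TP+FP) + (TN+FP)(TN+FN)] / N^2
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from . import features as feat
from .classifiers import CLASSIFIER_NAMES, L1Logit, fit_classifier
from .containers import EpochSet
from .stats import DegenerateDataError, paired_t

__all__ = [
    "ConfusionCounts", "FoldPlan", "SubjectResult",
    "kfold_split", "confusion",
    "metric_ca", "metric_se", "metric_sp", "metric_auc", "metric_kappa",
    "crossvalidate", "crossvalidate_epochs", "summarize", "compare_classifiers",
    "UndefinedMetricError", "DegenerateFoldError",
    "METRICS", "HIGHER_IS_BETTER",
]

METRICS = ("CA", "AUC", "SE", "SP", "Kappa", "CT")
#: orientation per metric for rankings (CT: smaller is better)
HIGHER_IS_BETTER = {m: m != "CT" for m in METRICS}


class UndefinedMetricError(ZeroDivisionError):
    """A metric's denominator is zero for these counts."""


class DegenerateFoldError(ValueError):
    """A fold's training set lacks one of the two classes."""


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class FoldPlan:
    """Assignment of each trial to one of k test folds."""

    k: int
    assignment: np.ndarray        # per-trial fold index in 0..k-1
    seed: int
    stratified: bool

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignment == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignment != fold)


def kfold_split(n: int, labels, k: int = 10, seed: int = 0,
                stratified: bool = True) -> FoldPlan:
    """Deterministic (seeded) k-fold partition, stratified by default so
    each fold preserves the class ratio within one trial."""
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    assignment = np.empty(n, dtype=int)
    if stratified:
        for cls in np.unique(labels):
            idx = np.flatnonzero(labels == cls)
            rng.shuffle(idx)
            assignment[idx] = np.arange(idx.size) % k
    else:
        idx = rng.permutation(n)
        assignment[idx] = np.arange(n) % k
    plan = FoldPlan(k=k, assignment=assignment, seed=seed, stratified=stratified)
    for fold in range(k):
        train_labels = labels[plan.train_indices(fold)]
        if np.unique(train_labels).size < np.unique(labels).size:
            raise DegenerateFoldError(
                f"fold {fold}: a class is absent from the training set"
            )
    return plan


def confusion(y_true, y_pred) -> ConfusionCounts:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred lengths differ")
    for arr, name in ((y_true, "y_true"), (y_pred, "y_pred")):
        if not np.isin(arr, (-1, 1)).all():
            raise ValueError(f"{name} contains labels outside {{+1, -1}}")
    return ConfusionCounts(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        tn=int(np.sum((y_true == -1) & (y_pred == -1))),
        fp=int(np.sum((y_true == -1) & (y_pred == 1))),
        fn=int(np.sum((y_true == 1) & (y_pred == -1))),
    )


def metric_ca(c: ConfusionCounts) -> float:
    if c.total == 0:
        raise UndefinedMetricError("no evaluated trials")
    return (c.tp + c.tn) / c.total


def metric_se(c: ConfusionCounts) -> float:
    if c.tp + c.fn == 0:
        raise UndefinedMetricError("no positive trials")
    return c.tp / (c.tp + c.fn)


def metric_sp(c: ConfusionCounts) -> float:
    if c.tn + c.fp == 0:
        raise UndefinedMetricError("no negative trials")
    return c.tn / (c.tn + c.fp)


def metric_kappa(c: ConfusionCounts) -> float:
    n = c.total
    if n == 0:
        raise UndefinedMetricError("no evaluated trials")
    p_o = (c.tp + c.tn) / n
    p_e = ((c.tp + c.fn) * (c.tp + c.fp) + (c.tn + c.fp) * (c.tn + c.fn)) / n ** 2
    if p_e == 1.0:
        raise UndefinedMetricError("chance agreement is 1; kappa undefined")
    return (p_o - p_e) / (1.0 - p_e)


def metric_auc(scores, y_true) -> float:
    """AUC as the normalized concordant-pair count with ties counted 1/2
    (midrank / Mann-Whitney formulation)."""
    scores = np.asarray(scores, dtype=float)
    y_true = np.asarray(y_true)
    pos = scores[y_true == 1]
    neg = scores[y_true == -1]
    if pos.size == 0 or neg.size == 0:
        raise UndefinedMetricError("both classes required for AUC")
    ranks = rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


# ---------------------------------------------------------------------------
# hyperparameter search
# ---------------------------------------------------------------------------

def _inner_cv_accuracy(name: str, X, y, hyper: dict, k: int, seed: int) -> float:
    plan = kfold_split(len(y), y, k=k, seed=seed)
    correct = 0
    for fold in range(plan.k):
        tr, te = plan.train_indices(fold), plan.test_indices(fold)
        res = fit_classifier(name, X[tr], y[tr], **hyper)
        correct += int(np.sum(res.predict(X[te]) == y[te]))
    return correct / len(y)


def search_hyperparameters(name: str, X, y, seed: int = 0,
                           inner_k: int = 5) -> dict:
    """Inner-CV grid search.

    l1lr: 20-point log grid on lam from 1e-4*lambda_max to lambda_max;
    rbfsvm: C in {0.1, 1, 10, 100} x gamma in {0.01, 0.1, 1, 10}/n_features;
    lda: automatic shrinkage, nothing to search.
    Grids are scored by inner-CV accuracy; ties go to the first (most
    regularized) candidate.
    """
    if name == "lda":
        return {"shrinkage": "auto"}
    if name == "l1lr":
        lam_max = L1Logit(y, X).lambda_max()
        grid = [{"lam": float(l)} for l in
                np.geomspace(lam_max, 1e-4 * lam_max, 20)]
    elif name == "rbfsvm":
        p = X.shape[1]
        grid = [{"C": c, "gamma": g / p}
                for c in (0.1, 1.0, 10.0, 100.0)
                for g in (0.01, 0.1, 1.0, 10.0)]
    else:
        raise ValueError(f"unknown classifier {name!r}")
    best, best_acc = grid[0], -1.0
    for hyper in grid:
        acc = _inner_cv_accuracy(name, X, y, hyper, inner_k, seed)
        if acc > best_acc:
            best, best_acc = hyper, acc
    return best


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

@dataclass
class SubjectResult:
    """Six-metric generalization result for one subject and classifier."""

    subject: str
    classifier: str
    ca: float
    auc: float
    se: float
    sp: float
    kappa: float
    ct: float                     # summed train+test wall time, seconds
    pooling: str = "pooled"
    foldmean: dict = field(default_factory=dict)
    hyper: dict = field(default_factory=dict)
    seed: int = 0

    def as_row(self) -> dict:
        return {
            "Subject": self.subject, "CA": self.ca, "AUC": self.auc,
            "SE": self.se, "SP": self.sp, "Kappa": self.kappa, "CT": self.ct,
        }


def _metrics_from(y_true, y_pred, scores) -> dict:
    c = confusion(y_true, y_pred)
    return {
        "CA": metric_ca(c), "SE": metric_se(c), "SP": metric_sp(c),
        "Kappa": metric_kappa(c), "AUC": metric_auc(scores, y_true),
    }


def crossvalidate(features: feat.FeatureMatrix, classifier: str,
                  plan: FoldPlan, hyper: dict | str | None = None,
                  scale_in_fold: bool = True, subject: str = "S0") -> SubjectResult:
    """k-fold cross-validation on a prepared feature matrix.

    Per fold the classifier is fitted on the training rows (after fitting
    min-max scaling bounds on those rows when ``scale_in_fold``; inner-CV
    hyperparameter search when ``hyper='search'``) and scored on the test
    rows.  All test-fold predictions are pooled into one confusion table /
    ROC for the headline metrics; fold-averaged variants are kept in
    ``foldmean``.  CT is the summed train+test wall time.
    """
    if classifier not in CLASSIFIER_NAMES:
        raise ValueError(f"unknown classifier {classifier!r}")
    if plan.assignment.shape[0] != features.n_trials:
        raise ValueError("fold plan does not match feature rows")
    y = features.y
    pooled_pred = np.empty_like(y)
    pooled_score = np.empty(features.n_trials, dtype=float)
    fold_rows = []
    ct = 0.0
    used_hyper: dict = {}
    for fold in range(plan.k):
        tr, te = plan.train_indices(fold), plan.test_indices(fold)
        if np.unique(y[tr]).size < 2:
            raise DegenerateFoldError(f"fold {fold} training set single-class")
        if scale_in_fold:
            scaled = feat.minmax_scale(features, fit_rows=tr)
            X = scaled.X
        else:
            X = features.X
        t0 = time.perf_counter()
        if hyper == "search":
            used_hyper = search_hyperparameters(classifier, X[tr], y[tr],
                                                seed=plan.seed)
        else:
            used_hyper = dict(hyper or {})
        res = fit_classifier(classifier, X[tr], y[tr], **used_hyper)
        pooled_pred[te] = res.predict(X[te])
        pooled_score[te] = res.decision_score(X[te])
        ct += time.perf_counter() - t0
        try:
            fold_rows.append(_metrics_from(y[te], pooled_pred[te], pooled_score[te]))
        except UndefinedMetricError:
            pass                  # tiny fold without both classes: skip in foldmean
    pooled = _metrics_from(y, pooled_pred, pooled_score)
    foldmean = {
        m: float(np.mean([r[m] for r in fold_rows])) for m in pooled
    } if fold_rows else {}
    return SubjectResult(
        subject=subject, classifier=classifier,
        ca=pooled["CA"], auc=pooled["AUC"], se=pooled["SE"],
        sp=pooled["SP"], kappa=pooled["Kappa"], ct=ct,
        pooling="pooled", foldmean=foldmean, hyper=used_hyper, seed=plan.seed,
    )


def crossvalidate_epochs(epochs: EpochSet, classifier: str,
                         k: int = 10, seed: int = 0,
                         window: tuple[float, float] = feat.DEFAULT_WINDOW,
                         n_channels: int = 5, mode: str = "samples",
                         hyper: dict | str | None = None,
                         paper_mode: bool = False) -> SubjectResult:
    """Full per-subject pipeline under cross-validation.

    Default (leakage-controlled): channel selection and scaling bounds are
    re-fitted on each fold's training trials only.  ``paper_mode`` instead
    performs one global channel selection and scaling on all trials before
    the fold loop — the per-subject procedure as commonly described, which
    lets test trials influence selection/scaling and is provided, labeled,
    for comparison.
    """
    all_features = feat.extract_features(
        epochs, list(epochs.channels), window=window, mode=mode)
    y = all_features.y
    plan = kfold_split(all_features.n_trials, y, k=k, seed=seed)
    if paper_mode:
        ranking = feat.select_channels(epochs, window=window, k=n_channels)
        fm = feat.extract_features(epochs, ranking.selected, window=window,
                                   mode=mode)
        fm = feat.minmax_scale(fm)
        result = crossvalidate(fm, classifier, plan, hyper=hyper,
                               scale_in_fold=False, subject=epochs.subject_id)
        result.hyper["paper_mode"] = True
        result.hyper["channels"] = ranking.selected
        return result

    pooled_pred = np.empty_like(y)
    pooled_score = np.empty(y.size, dtype=float)
    fold_rows = []
    ct = 0.0
    used_hyper: dict = {}
    trial_pos = {tid: i for i, tid in enumerate(all_features.trial_ids)}
    for fold in range(plan.k):
        tr, te = plan.train_indices(fold), plan.test_indices(fold)
        train_ids = all_features.trial_ids[tr]
        train_epochs = epochs.select_trials(
            np.isin(epochs.trial_ids, train_ids))
        ranking = feat.select_channels(train_epochs, window=window, k=n_channels)
        fm = feat.extract_features(epochs, ranking.selected, window=window,
                                   mode=mode)
        # extract_features preserves trial order, so fold indices carry over
        assert np.array_equal(fm.trial_ids, all_features.trial_ids)
        t0 = time.perf_counter()
        scaled = feat.minmax_scale(fm, fit_rows=tr)
        if hyper == "search":
            used_hyper = search_hyperparameters(classifier, scaled.X[tr], y[tr],
                                                seed=seed)
        else:
            used_hyper = dict(hyper or {})
        res = fit_classifier(classifier, scaled.X[tr], y[tr], **used_hyper)
        pooled_pred[te] = res.predict(scaled.X[te])
        pooled_score[te] = res.decision_score(scaled.X[te])
        ct += time.perf_counter() - t0
        try:
            fold_rows.append(_metrics_from(y[te], pooled_pred[te], pooled_score[te]))
        except UndefinedMetricError:
            pass
    pooled = _metrics_from(y, pooled_pred, pooled_score)
    foldmean = {m: float(np.mean([r[m] for r in fold_rows])) for m in pooled} \
        if fold_rows else {}
    return SubjectResult(
        subject=epochs.subject_id, classifier=classifier,
        ca=pooled["CA"], auc=pooled["AUC"], se=pooled["SE"],
        sp=pooled["SP"], kappa=pooled["Kappa"], ct=ct,
        pooling="pooled", foldmean=foldmean, hyper=used_hyper, seed=seed,
    )


# ---------------------------------------------------------------------------
# group summaries and comparisons
# ---------------------------------------------------------------------------

def summarize(results) -> pd.DataFrame:
    """Mean and SD (n-1) of each metric across subjects, rounded to 3
    decimals for reporting.

    ``results`` is a list of :class:`SubjectResult` (one classifier) or a
    DataFrame with the Table columns ``Subject, CA, AUC, SE, SP, Kappa, CT``.
    """
    if isinstance(results, pd.DataFrame):
        table = results
    else:
        names = {r.classifier for r in results}
        if len(names) > 1:
            raise ValueError(f"mixed classifiers in one summary: {sorted(names)}")
        table = pd.DataFrame([r.as_row() for r in results])
    if len(table) < 2:
        raise ValueError("need >= 2 subjects to summarize")
    rows = []
    for m in METRICS:
        rows.append({
            "metric": m,
            "mean": round(float(table[m].mean()), 3),
            "sd": round(float(table[m].std(ddof=1)), 3),
        })
    return pd.DataFrame(rows)


def compare_classifiers(tables: dict[str, pd.DataFrame],
                        alpha: float = 0.05) -> dict:
    """Paired-t comparison of classifiers across subjects, per metric.

    ``tables`` maps classifier name -> per-subject metric table (columns
    ``Subject, CA, AUC, SE, SP, Kappa, CT``; same subjects, same order).
    Returns ``{"tests": DataFrame(metric, pair, t, df, p), "ranking":
    DataFrame(metric, rank, classifier), "winner": str}``.  Per metric,
    classifiers are ordered by mean (CT: smaller is better) and adjacent
    pairs with p >= alpha share a rank (an n.s. tie); the overall winner is
    the classifier with the most first-rank finishes.
    """
    names = list(tables)
    if len(names) < 2:
        raise ValueError("need at least two classifiers to compare")
    subjects = [tuple(t["Subject"]) for t in tables.values()]
    if len(set(subjects)) != 1:
        raise ValueError("classifier tables cover different subjects")

    test_rows, ranking_rows = [], []
    first_rank_count = {n: 0 for n in names}
    for m in METRICS:
        pvals = {}
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                try:
                    res = paired_t(tables[a][m].to_numpy(),
                                   tables[b][m].to_numpy())
                    t, df, p = res.statistic, res.df, res.p_value
                except DegenerateDataError:
                    t, df, p = 0.0, float(len(tables[a]) - 1), 1.0
                pvals[frozenset((a, b))] = p
                test_rows.append({
                    "metric": m, "pair": f"{a} vs {b}",
                    "t": t, "df": df, "p": p,
                })
        means = {n: tables[n][m].mean() for n in names}
        order = sorted(names, key=lambda n: means[n],
                       reverse=HIGHER_IS_BETTER[m])
        # tier assignment: join the current tier when n.s. vs all its members
        tiers: list[list[str]] = [[order[0]]]
        for n in order[1:]:
            if all(pvals[frozenset((n, other))] >= alpha
                   for other in tiers[-1]):
                tiers[-1].append(n)
            else:
                tiers.append([n])
        for rank, tier in enumerate(tiers, start=1):
            for n in tier:
                ranking_rows.append({"metric": m, "rank": rank, "classifier": n})
                if rank == 1:
                    first_rank_count[n] += 1
    winner = max(first_rank_count, key=first_rank_count.get)
    return {
        "tests": pd.DataFrame(test_rows),
        "ranking": pd.DataFrame(ranking_rows),
        "winner": winner,
        "first_rank_count": first_rank_count,
    }
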