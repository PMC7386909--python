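"""Repeated k-fold evaluation, ROC/AUC, optimal ROC point, ranking, and
nonparametric model comparison.

Per run, the dataset is randomly partitioned into k folds; out-of-fold
scores are pooled across folds and a single AUC, optimal-ROC-point (ORP)
FPR/TPR and accuracy are computed on the pooled predictions (fold-level
metrics on ~7 samples are ill-defined when a fold lacks a class; a per-fold
averaging mode is available).  Aggregation over runs reports the mean and
sample standard deviation of each metric and their "mean std".

The ORP is the ROC vertex found by sliding a line of slope
S = (Cost(P|N) - Cost(N|N)) / (Cost(N|P) - Cost(P|P)) * N/P down from the
(FPR=0, TPR=1) corner, i.e. the vertex maximizing TPR - S*FPR, ties broken
toward the smaller FPR.  With the default unit misclassification costs,
S = N/P.

Model comparison uses Friedman's rank test on the runs x conditions AUC
matrix, followed by pairwise mean-rank z-tests with Bonferroni adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve

from . import ensemble as ens
from .cohort import Cohort
from .registry import PSA_ID

__all__ = [
    "ConfusionCounts",
    "CostSpec",
    "RunReport",
    "ComparisonResult",
    "CONDITIONS",
    "kfold_partitions",
    "confusion_metrics",
    "roc_and_auc",
    "optimal_roc_point",
    "repeated_cv",
    "rank_and_best",
    "friedman_compare",
    "posthoc_bonferroni",
]

#: The named feature-set conditions compared in the detection experiment.
CONDITIONS: dict[str, list[int]] = {
    "GA": [2, 20, 27, 28],
    "STAT": [14, 15, 16, 17],
    "GA+STAT": [2, 14, 15, 16, 17, 20, 27, 28],
    "PSA+GA+STAT": [PSA_ID, 2, 14, 15, 16, 17, 20, 27, 28],
    "PSA": [PSA_ID],
    "ALL": list(range(1, 33)),
}


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def p(self) -> int:
        return self.tp + self.fn

    @property
    def n(self) -> int:
        return self.fp + self.tn


@dataclass(frozen=True)
class CostSpec:
    """Misclassification cost structure for the ORP slope."""

    cost_fn: float = 1.0  # Cost(N|P): positive called negative
    cost_fp: float = 1.0  # Cost(P|N): negative called positive
    cost_tp: float = 0.0  # Cost(P|P)
    cost_tn: float = 0.0  # Cost(N|N)

    def slope(self, p: int, n: int) -> float:
        denom = self.cost_fn - self.cost_tp
        numer = self.cost_fp - self.cost_tn
        if denom <= 0 or numer <= 0:
            raise ValueError(
                "degenerate costs: misclassification must cost more than "
                "correct classification"
            )
        if p == 0:
            raise ValueError("positive class is empty")
        return numer / denom * (n / p)


def kfold_partitions(
    n: int, k: int, seed: int, stratify: np.ndarray | None = None
) -> list[np.ndarray]:
    """Random disjoint folds covering 0..n-1 with sizes differing by <= 1.

    With ``stratify`` given, each class is spread across folds as evenly as
    possible (unstratified partitioning is the default elsewhere).
    """
    if k > n or k < 2:
        raise ValueError(f"cannot split n={n} into k={k} folds")
    rng = np.random.default_rng(seed)
    if stratify is None:
        perm = rng.permutation(n)
        return [np.sort(f) for f in np.array_split(perm, k)]
    folds: list[list[int]] = [[] for _ in range(k)]
    start = 0
    for cls in np.unique(stratify):
        idx = rng.permutation(np.flatnonzero(stratify == cls))
        for i, v in enumerate(idx):
            folds[(start + i) % k].append(int(v))
        start += len(idx)
    return [np.sort(np.asarray(f, dtype=int)) for f in folds]


def confusion_metrics(c: ConfusionCounts) -> dict[str, float]:
    """Accuracy and the four rates; empty-class rates are reported as NaN."""
    total = c.tp + c.tn + c.fp + c.fn
    acc = (c.tp + c.tn) / total if total else np.nan
    tpr = c.tp / c.p if c.p else np.nan
    tnr = c.tn / c.n if c.n else np.nan
    return {
        "accuracy": acc,
        "tpr": tpr,
        "tnr": tnr,
        "fnr": 1.0 - tpr if c.p else np.nan,
        "fpr": 1.0 - tnr if c.n else np.nan,
    }


def roc_and_auc(
    scores: np.ndarray, labels: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC vertices (fpr, tpr arrays) and trapezoid AUC.

    Thresholds at each distinct score with ties grouped; the trapezoid AUC
    equals the Mann-Whitney U statistic / (P*N) with half-credit for ties.
    """
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC needs both classes present")
    fpr, tpr, _ = roc_curve(labels, np.asarray(scores, dtype=float),
                            drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, auc


def optimal_roc_point(
    fpr: np.ndarray,
    tpr: np.ndarray,
    costs: CostSpec,
    p: int,
    n: int,
) -> tuple[float, float]:
    """The ROC vertex first touched by a slope-S line descending from the
    (0, 1) corner: argmax of tpr - S*fpr, smaller fpr on ties."""
    if len(fpr) == 0:
        raise ValueError("empty ROC curve")
    s = costs.slope(p, n)
    objective = tpr - s * fpr
    best = np.flatnonzero(objective >= objective.max() - 1e-12)
    i = best[np.argmin(fpr[best])]
    return float(fpr[i]), float(tpr[i])


@dataclass
class RunReport:
    """Per-run and aggregate cross-validation metrics for one condition."""

    condition: str
    feature_set: list[int]
    runs: pd.DataFrame  # columns: auc, orp_fpr, orp_tpr, accuracy
    k: int

    @property
    def means(self) -> pd.Series:
        return self.runs.mean()

    @property
    def stds(self) -> pd.Series:
        return self.runs.std(ddof=1)

    @property
    def mean_std(self) -> float:
        """Mean of the four metrics' standard deviations."""
        return float(self.stds.mean())

    @property
    def best_run(self) -> pd.Series:
        return self.runs.loc[self.runs["auc"].idxmax()]


def _model_scores(
    X: np.ndarray,
    y: np.ndarray,
    folds: list[np.ndarray],
    model: "ens.EnsembleConfig | str",
    fold_seed: int,
) -> np.ndarray:
    """Pooled out-of-fold scores (each sample scored exactly once)."""
    scores = np.full(len(y), np.nan)
    for fi, probe_idx in enumerate(folds):
        train_idx = np.setdiff1d(np.arange(len(y)), probe_idx)
        if isinstance(model, str):
            s = ens.baseline_models(X[train_idx], y[train_idx], X[probe_idx], model)
        else:
            cfg = ens.EnsembleConfig(
                **{**model.__dict__, "seed": (fold_seed + fi) % 2**31}
            )
            mdl = ens.train(X[train_idx], y[train_idx], cfg)
            s = ens.score(mdl, X[probe_idx])
        scores[probe_idx] = s
    return scores


def _run_metrics(
    scores: np.ndarray, y: np.ndarray, costs: CostSpec
) -> dict[str, float]:
    fpr, tpr, auc = roc_and_auc(scores, y)
    p, n = int((y == 1).sum()), int((y == 0).sum())
    ofpr, otpr = optimal_roc_point(fpr, tpr, costs, p, n)
    pred = ens.classify(scores, 0.5)
    acc = float((pred == y).mean())
    return {"auc": auc, "orp_fpr": ofpr, "orp_tpr": otpr, "accuracy": acc}


def repeated_cv(
    cohort: Cohort,
    feature_set: list[int],
    model: "ens.EnsembleConfig | str | None" = None,
    k: int = 10,
    runs: int = 30,
    master_seed: int = 0,
    costs: CostSpec | None = None,
    stratify: bool = False,
    condition: str = "custom",
    mode: str = "pooled",
) -> RunReport:
    """k-fold cross-validation repeated ``runs`` times with fresh partition
    seeds; per-run metrics on pooled out-of-fold predictions (default) or
    averaged over per-fold metrics (``mode='per-fold'``)."""
    if not feature_set:
        raise ValueError("feature_set must be non-empty")
    model = model if model is not None else ens.EnsembleConfig()
    costs = costs or CostSpec()
    X = cohort.predictor_matrix(feature_set)
    y = cohort.labels
    rows = []
    for r in range(runs):
        seed = (master_seed * 1000 + r) % 2**31
        folds = kfold_partitions(
            cohort.n, k, seed, stratify=y if stratify else None
        )
        if mode == "pooled":
            scores = _model_scores(X, y, folds, model, seed)
            rows.append(_run_metrics(scores, y, costs))
        elif mode == "per-fold":
            per_fold = []
            scores = _model_scores(X, y, folds, model, seed)
            for probe_idx in folds:
                yf = y[probe_idx]
                if len(np.unique(yf)) < 2:
                    continue
                per_fold.append(_run_metrics(scores[probe_idx], yf, costs))
            rows.append(pd.DataFrame(per_fold).mean().to_dict())
        else:
            raise ValueError(f"unknown mode {mode!r}")
    return RunReport(
        condition=condition,
        feature_set=list(feature_set),
        runs=pd.DataFrame(rows),
        k=k,
    )


def rank_and_best(reports: list[RunReport]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Aggregate table with ranks (by mean AUC, ties by higher accuracy then
    lower ORP FPR) and the best single run per condition."""
    if len(reports) < 2:
        raise ValueError("need at least two reports to rank")
    agg = pd.DataFrame(
        {
            "condition": [r.condition for r in reports],
            "auc": [r.means["auc"] for r in reports],
            "orp_fpr": [r.means["orp_fpr"] for r in reports],
            "orp_tpr": [r.means["orp_tpr"] for r in reports],
            "accuracy": [r.means["accuracy"] for r in reports],
            "auc_std": [r.stds["auc"] for r in reports],
            "orp_fpr_std": [r.stds["orp_fpr"] for r in reports],
            "orp_tpr_std": [r.stds["orp_tpr"] for r in reports],
            "accuracy_std": [r.stds["accuracy"] for r in reports],
            "mean_std": [r.mean_std for r in reports],
        }
    )
    order = agg.sort_values(
        ["auc", "accuracy", "orp_fpr"], ascending=[False, False, True]
    ).index
    agg["rank"] = 0
    for pos, i in enumerate(order, start=1):
        agg.loc[i, "rank"] = pos
    best = pd.DataFrame(
        [dict(condition=r.condition, **r.best_run.to_dict()) for r in reports]
    )
    border = best.sort_values("auc", ascending=False).index
    best["rank"] = 0
    for pos, i in enumerate(border, start=1):
        best.loc[i, "rank"] = pos
    return agg, best


@dataclass
class ComparisonResult:
    chi_sq: float
    dof: int
    p: float
    mean_ranks: dict[str, float]
    posthoc: pd.DataFrame = field(default_factory=pd.DataFrame)


def friedman_compare(
    c_matrix: pd.DataFrame | np.ndarray, conditions: list[str] | None = None
) -> ComparisonResult:
    """Friedman rank test on a runs x conditions matrix (mid-ranks on ties,
    tie-corrected chi-square with conditions-1 degrees of freedom)."""
    if isinstance(c_matrix, pd.DataFrame):
        conditions = conditions or list(c_matrix.columns)
        C = c_matrix.to_numpy(dtype=float)
    else:
        C = np.asarray(c_matrix, dtype=float)
        conditions = conditions or [f"cond{j}" for j in range(C.shape[1])]
    n, k = C.shape
    if k < 2 or n < 2:
        raise ValueError("need >= 2 conditions and >= 2 runs")
    R = np.apply_along_axis(stats.rankdata, 1, C)
    Rj = R.sum(axis=0)
    ss = np.sum(Rj**2)
    # tie correction: 1 - sum(t^3 - t) / (n k (k^2 - 1))
    tie_sum = 0.0
    for row in C:
        _, counts = np.unique(row, return_counts=True)
        tie_sum += float(np.sum(counts**3 - counts))
    correction = 1.0 - tie_sum / (n * k * (k**2 - 1))
    if correction <= 0:
        chi = 0.0
    else:
        chi = (12.0 / (n * k * (k + 1)) * ss - 3.0 * n * (k + 1)) / correction
        chi = max(chi, 0.0)
    dof = k - 1
    p = float(stats.chi2.sf(chi, dof)) if chi > 0 else 1.0
    mean_ranks = dict(zip(conditions, (Rj / n).tolist()))
    return ComparisonResult(chi_sq=float(chi), dof=dof, p=p, mean_ranks=mean_ranks)


def posthoc_bonferroni(
    c_matrix: pd.DataFrame | np.ndarray, conditions: list[str] | None = None
) -> pd.DataFrame:
    """All pairwise mean-rank differences with Bonferroni-adjusted normal
    z-tests and simultaneous 95% confidence intervals."""
    base = friedman_compare(c_matrix, conditions)
    names = list(base.mean_ranks)
    if isinstance(c_matrix, pd.DataFrame):
        n, k = c_matrix.shape
    else:
        n, k = np.asarray(c_matrix).shape
    se = np.sqrt(k * (k + 1) / (6.0 * n))
    pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
    crit = stats.norm.ppf(1.0 - 0.05 / (2 * len(pairs)))
    rows = []
    for i, j in pairs:
        diff = base.mean_ranks[names[i]] - base.mean_ranks[names[j]]
        z = diff / se
        raw = 2.0 * stats.norm.sf(abs(z))
        rows.append(
            {
                "group_1": names[i],
                "group_2": names[j],
                "ci_lower": diff - crit * se,
                "diff": diff,
                "ci_upper": diff + crit * se,
                "p_adjusted": min(1.0, raw * len(pairs)),
            }
        )
    return pd.DataFrame(rows)
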