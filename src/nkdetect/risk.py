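"""D'Amico risk-group prediction experiment.

A stratified hold-out (5 low/intermediate + 5 high-risk records by default)
is drawn once and never enters training.  The remaining records (44 for the
default 54-patient cohort) are evaluated by 10-fold cross-validation over 30
iterations (300 fold-level fits); per iteration, a model trained on the full
remainder also scores the hold-out ("mini clinical trial" surface).  All 32
phenotypic features are used; PSA is deliberately excluded as a predictor —
the point of the experiment is risk prediction without PSA/Gleason/stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import ensemble as ens
from .cohort import Cohort
from .evaluation import CostSpec, _model_scores, _run_metrics, kfold_partitions

__all__ = ["RiskExperimentConfig", "RiskReport", "risk_experiment"]


@dataclass
class RiskExperimentConfig:
    holdout_per_class: int = 5
    iterations: int = 30
    folds: int = 10
    ensemble: ens.EnsembleConfig = field(
        default_factory=lambda: ens.EnsembleConfig(n_learners=30, subspace_dim=16)
    )
    seed: int = 0


@dataclass
class RiskReport:
    validation: pd.DataFrame  # per-iteration pooled CV metrics
    test: pd.DataFrame  # per-iteration hold-out metrics
    holdout_ids: list[str]
    remainder_ids: list[str]
    fold_fits: int

    def summary(self) -> pd.DataFrame:
        rows = {}
        for name, df in (("validation", self.validation), ("test", self.test)):
            rows[name] = {
                **{f"{c}_mean": df[c].mean() for c in df.columns},
                **{f"{c}_std": df[c].std(ddof=1) for c in df.columns},
            }
        return pd.DataFrame(rows).T


def risk_experiment(cohort: Cohort, config: RiskExperimentConfig | None = None) -> RiskReport:
    """Run the hold-out + repeated-CV risk experiment on a risk cohort."""
    config = config or RiskExperimentConfig()
    if cohort.task != "risk":
        raise ValueError("risk_experiment expects a risk-task cohort")
    y = cohort.labels
    h = config.holdout_per_class
    for cls in (0, 1):
        if (y == cls).sum() <= h:
            raise ValueError(
                f"class {cls} has too few records for a hold-out of {h} per class"
            )

    rng = np.random.default_rng(config.seed)
    holdout_idx = np.sort(
        np.concatenate(
            [rng.choice(np.flatnonzero(y == cls), h, replace=False) for cls in (0, 1)]
        )
    )
    rest_idx = np.setdiff1d(np.arange(cohort.n), holdout_idx)

    X = cohort.predictor_matrix(list(range(1, 33)))  # all 32 features, no PSA
    Xr, yr = X[rest_idx], y[rest_idx]
    Xh, yh = X[holdout_idx], y[holdout_idx]
    costs = CostSpec()

    val_rows, test_rows = [], []
    fold_fits = 0
    for it in range(config.iterations):
        seed = (config.seed * 1000 + it + 1) % 2**31
        folds = kfold_partitions(len(yr), config.folds, seed)
        fold_fits += len(folds)
        scores = _model_scores(Xr, yr, folds, config.ensemble, seed)
        val_rows.append(_run_metrics(scores, yr, costs))

        cfg = ens.EnsembleConfig(**{**config.ensemble.__dict__, "seed": seed})
        model = ens.train(Xr, yr, cfg)
        s = ens.score(model, Xh)
        test_rows.append(_run_metrics(s, yh, costs))

    return RiskReport(
        validation=pd.DataFrame(val_rows),
        test=pd.DataFrame(test_rows),
        holdout_ids=[cohort.patient_ids[i] for i in holdout_idx],
        remainder_ids=[cohort.patient_ids[i] for i in rest_idx],
        fold_fits=fold_fits,
    )
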