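"""End-to-end orchestration: simulate -> features -> rank -> select -> evaluate."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from beetlecast import learners
from beetlecast.evaluation import (
    LearnerReport,
    auc,
    build_config_grid,
    compare_estimators,
    estimate_performance,
    select_best_config,
)
from beetlecast.features import COVARIATES, build_feature_matrix, cv_folds, year_based_split
from beetlecast.learners import LearnerSpec
from beetlecast.mrmr import CovariateRanking, rank_covariates


def rank_on_training_data(
    table: pd.DataFrame, r: int, criterion: str = "MID", n_test_years: int = 2
) -> CovariateRanking:
    """mRMR ranking of the 14 covariates on the h=1 training rows for one r.

    One ranking is computed per prediction length; the current-year (h=1)
    covariate columns are ranked against the future target.
    """
    fm = build_feature_matrix(table, r=r, h=1, c=len(COVARIATES))
    plan = year_based_split(fm, n_test_years=n_test_years)
    X = fm.features(plan.train_idx)
    X = X.rename(columns={f"{cv}_lag0": cv for cv in COVARIATES})
    y = fm.target(plan.train_idx).astype(int)
    return rank_covariates(X, y, criterion=criterion)


@dataclass
class ExperimentResult:
    """All per-learner reports for one prediction length r."""

    r: int
    ranking: CovariateRanking
    reports: list[LearnerReport] = field(default_factory=list)

    def estimator_errors(self) -> dict[str, float]:
        return compare_estimators(self.reports)

    def best_learner(self) -> LearnerReport:
        scored = [rep for rep in self.reports if rep.s_test is not None]
        return max(scored, key=lambda rep: rep.s_test)

    def to_dict(self) -> dict:
        return {
            "r": self.r,
            "ranking": self.ranking.to_dict(),
            "reports": [rep.to_dict() for rep in self.reports],
            "estimator_error_sums": self.estimator_errors(),
        }


def split_protocol_experiment(
    seed: int,
    n_rows: int = 12,
    n_cols: int = 12,
    years: tuple[int, int] = (2005, 2018),
    r: int = 1,
    specs: list[LearnerSpec] | None = None,
) -> list[LearnerReport]:
    """One replicate of the random- vs year-based-split comparison.

    Simulates a survey under the default outbreak conditions, builds the
    h=1 full-covariate feature matrix for prediction length ``r``, trains
    every learner on the year-based training set, measures actual AUC on
    the held-out final years, and computes the three estimators on the
    training data.  Estimates that cannot be computed (e.g., the last
    training year holds a single class) are reported as ``None``.
    """
    from beetlecast.synthetic_data import default_survey

    specs = specs if specs is not None else learners.default_specs()
    table = default_survey(n_rows, n_cols, years, seed=seed)
    fm = build_feature_matrix(table, r=r, h=1)
    plan = year_based_split(fm)
    folds = cv_folds(fm, plan)
    reports = []
    for spec in specs:
        est = estimate_performance(spec, fm, plan, seed=seed, folds=folds)
        try:
            model = learners.train(spec, fm, seed=seed, rows=plan.train_idx, folds=folds)
            p = learners.predict(model, fm, plan.test_idx)
            y_test = fm.target(plan.test_idx).astype(int)
            s_test = auc(p, y_test) if len(np.unique(y_test)) > 1 else None
        except (learners.SingleClassError, ValueError):
            s_test = None
        reports.append(
            LearnerReport(
                name=spec.name, r=r, c_star=fm.c, h_star=1,
                cv_auc=est["average-fold"], fold_aucs=est["fold_aucs"],
                s_test=s_test, s_random=est["random"],
                s_average_fold=est["average-fold"], s_last_fold=est["last-fold"],
            )
        )
    return reports


def run_experiment(
    table: pd.DataFrame,
    r: int,
    specs: list[LearnerSpec] | None = None,
    c_values=None,
    h_values=None,
    seed: int | None = 0,
    n_test_years: int = 2,
    criterion: str = "MID",
) -> ExperimentResult:
    """Full protocol for one prediction length.

    1. rank covariates by mRMR on the h=1 training data;
    2. grid-search (c, h) per learner by year-fold cross-validated AUC;
    3. retrain each learner at its (c*, h*) on the whole training set and
       score it on the held-out test years (s_L);
    4. compute the three performance estimators for comparison.
    """
    specs = specs if specs is not None else learners.default_specs()
    ranking = rank_on_training_data(table, r, criterion=criterion, n_test_years=n_test_years)
    n_ranked = len(ranking.order)
    c_values = list(c_values) if c_values is not None else list(range(1, n_ranked + 1))
    c_values = [c for c in c_values if c <= n_ranked]
    h_values = list(h_values) if h_values is not None else [1, 2, 3, 4, 5]

    grid = build_config_grid(
        table, r, ranking.order, c_values, h_values, n_test_years=n_test_years
    )

    result = ExperimentResult(r=r, ranking=ranking)
    for spec in specs:
        c_star, h_star, cv_auc, _ = select_best_config(spec, grid, seed=seed)
        entry = grid[(c_star, h_star)]
        fm, plan = entry.fm, entry.plan
        folds = entry.folds
        est = estimate_performance(spec, fm, plan, seed=seed, folds=folds)
        model = learners.train(spec, fm, seed=seed, rows=plan.train_idx, folds=folds)
        p = learners.predict(model, fm, plan.test_idx)
        y_test = fm.target(plan.test_idx).astype(int)
        s_test = auc(p, y_test) if len(np.unique(y_test)) > 1 else None
        result.reports.append(
            LearnerReport(
                name=spec.name,
                r=r,
                c_star=c_star,
                h_star=h_star,
                cv_auc=cv_auc,
                fold_aucs=est["fold_aucs"],
                s_test=s_test,
                s_random=est["random"],
                s_average_fold=est["average-fold"],
                s_last_fold=est["last-fold"],
            )
        )
    return result
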