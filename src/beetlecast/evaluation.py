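"""AUC scoring, (c*, h*) selection, performance estimators, threshold maps.

The central question these tools answer: which estimate of a forecaster's
future skill can be trusted?  Three estimators computed on the training
data — a random 70/30 split, the year-fold cross-validated mean, and the
last training year held out — are compared against the model's actual AUC
on the temporally held-out test years.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from beetlecast import learners
from beetlecast.features import (
    FeatureMatrix,
    SplitPlan,
    build_feature_matrix,
    cv_folds,
    random_split,
    year_based_split,
)
from beetlecast.learners import LearnerSpec

ESTIMATORS = ("random", "average-fold", "last-fold")


def auc(scores, labels) -> float:
    """Rank-based (Mann-Whitney) AUC with ties counted one half.

    Equals the probability that a random positive outranks a random
    negative, with ties contributing 1/2.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same length")
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes present")
    ranks = rankdata(scores)  # average ranks handle ties as 1/2
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


# ---------------------------------------------------------------------------
# Cross-validation and model selection
# ---------------------------------------------------------------------------

def cross_val_aucs(
    spec: LearnerSpec,
    fm: FeatureMatrix,
    folds,
    seed: int | None = 0,
) -> list[tuple[int, float | None]]:
    """Per-year-fold AUCs; single-class folds are skipped with a warning.

    For the mixed model the base learners' out-of-fold probabilities are
    computed once and reused, so its fold scores come from stackers fitted
    on the *other* folds' out-of-fold probabilities — still leak-free.
    """
    out = []
    if spec.name == "MM":
        rows = np.concatenate([hold for (_, hold, _) in folds])
        base_specs = [
            LearnerSpec(n, spec.params.get(n, {})) for n in learners.BASE_LEARNERS
        ]
        probs, y_all, _ = learners.out_of_fold_probabilities(
            base_specs, fm, rows, seed=seed, folds=folds
        )
        probs = probs.dropna(axis=1)
        pos = {r: i for i, r in enumerate(rows)}
        from sklearn.linear_model import LogisticRegression

        for year, hold, rest in folds:
            yh = fm.target(hold).astype(int)
            if len(np.unique(yh)) < 2:
                warnings.warn(f"fold {year} has a single class; skipped")
                out.append((year, None))
                continue
            ir = [pos[r] for r in rest]
            ih = [pos[r] for r in hold]
            Xr, yr = probs.to_numpy()[ir], y_all[ir]
            kept = [j for j in range(Xr.shape[1]) if len(np.unique(Xr[:, j])) > 1]
            if not kept or len(np.unique(yr)) < 2:
                out.append((year, None))
                continue
            stk = LogisticRegression(max_iter=2000)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                stk.fit(Xr[:, kept], yr)
            p = stk.predict_proba(probs.to_numpy()[ih][:, kept])[:, 1]
            out.append((year, auc(p, yh)))
        return out

    for year, hold, rest in folds:
        yh = fm.target(hold).astype(int)
        if len(np.unique(yh)) < 2:
            warnings.warn(f"fold {year} has a single class; skipped")
            out.append((year, None))
            continue
        try:
            model = learners.train(spec, fm, seed=seed, rows=rest)
        except (learners.SingleClassError, ValueError) as exc:
            warnings.warn(f"{spec.name} failed on fold {year}: {exc}")
            out.append((year, None))
            continue
        p = learners.predict(model, fm, hold)
        out.append((year, auc(p, yh)))
    return out


@dataclass
class ConfigGridEntry:
    c: int
    h: int
    fm: FeatureMatrix
    plan: SplitPlan
    folds: list


def build_config_grid(
    table: pd.DataFrame,
    r: int,
    ranking: list[str],
    c_values,
    h_values,
    n_test_years: int = 2,
) -> dict[tuple[int, int], ConfigGridEntry]:
    """Feature matrix + year split + folds for each (c, h) configuration."""
    from beetlecast.features import ZeroTrainingInstancesError

    grid = {}
    for c in c_values:
        for h in h_values:
            try:
                fm = build_feature_matrix(table, r=r, h=h, c=c, ranking=ranking)
                plan = year_based_split(fm, n_test_years=n_test_years)
            except (ValueError, ZeroTrainingInstancesError) as exc:
                # e.g. r=7 with h=5 leaves no training target years at all
                warnings.warn(f"configuration (c={c}, h={h}) skipped: {exc}")
                continue
            grid[(c, h)] = ConfigGridEntry(
                c=c, h=h, fm=fm, plan=plan, folds=cv_folds(fm, plan)
            )
    if not grid:
        raise ValueError("no (c, h) configuration is constructible for this span")
    return grid


def select_best_config(
    spec: LearnerSpec,
    grid: dict[tuple[int, int], ConfigGridEntry],
    seed: int | None = 0,
) -> tuple[int, int, float, dict]:
    """Pick (c*, h*) maximizing the mean year-fold AUC over the grid.

    Ties break toward smaller c, then smaller h.  Configurations with no
    valid (two-class) fold are excluded.
    """
    best = None
    all_scores: dict[tuple[int, int], float | None] = {}
    for (c, h) in sorted(grid.keys()):
        entry = grid[(c, h)]
        fold_aucs = cross_val_aucs(spec, entry.fm, entry.folds, seed=seed)
        vals = [a for _, a in fold_aucs if a is not None]
        if not vals:
            all_scores[(c, h)] = None
            continue
        mean_auc = float(np.mean(vals))
        all_scores[(c, h)] = mean_auc
        if best is None or mean_auc > best[2]:
            best = (c, h, mean_auc)
    if best is None:
        raise ValueError("no (c, h) configuration produced a valid fold AUC")
    return best[0], best[1], best[2], all_scores


# ---------------------------------------------------------------------------
# The three performance estimators
# ---------------------------------------------------------------------------

def _fit_and_score(spec, fm, train_rows, test_rows, seed):
    model = learners.train(spec, fm, seed=seed, rows=train_rows)
    p = learners.predict(model, fm, test_rows)
    return auc(p, fm.target(test_rows).astype(int))


def estimate_performance(
    spec: LearnerSpec,
    fm: FeatureMatrix,
    plan: SplitPlan,
    seed: int | None = 0,
    folds=None,
) -> dict:
    """The three training-data estimates of a learner's actual skill.

    * ``random``: train on a seeded random 70% of the training rows, score
      on the remaining 30% (year structure ignored).
    * ``average-fold``: mean AUC over the year folds.
    * ``last-fold``: AUC on the latest training target year, with the model
      trained on the earlier years.
    """
    folds = folds if folds is not None else cv_folds(fm, plan)
    fold_aucs = cross_val_aucs(spec, fm, folds, seed=seed)
    vals = [a for _, a in fold_aucs if a is not None]
    s_avg = float(np.mean(vals)) if vals else None
    s_last = fold_aucs[-1][1] if fold_aucs else None

    sub = random_split(plan.train_idx, fraction=0.7, seed=seed)
    try:
        s_random = _fit_and_score(spec, fm, sub.train_idx, sub.test_idx, seed)
    except (learners.SingleClassError, ValueError) as exc:
        warnings.warn(f"random-split estimate failed for {spec.name}: {exc}")
        s_random = None
    return {
        "random": s_random,
        "average-fold": s_avg,
        "last-fold": s_last,
        "fold_aucs": fold_aucs,
    }


@dataclass
class LearnerReport:
    """Evaluation of one learner for one prediction length."""

    name: str
    r: int
    c_star: int
    h_star: int
    cv_auc: float
    fold_aucs: list
    s_test: float | None
    s_random: float | None
    s_average_fold: float | None
    s_last_fold: float | None

    def estimate(self, which: str) -> float | None:
        return {
            "random": self.s_random,
            "average-fold": self.s_average_fold,
            "last-fold": self.s_last_fold,
        }[which]

    def to_dict(self) -> dict:
        return asdict(self)


def compare_estimators(reports: list[LearnerReport]) -> dict[str, float]:
    """Summed absolute AUC estimation error of each estimator over learners.

    ``sum_L | s-hat_L - s_L |`` for each of random / average-fold /
    last-fold; the estimator with the smallest sum tracks actual
    forecasting skill best.
    """
    sums = {}
    for which in ESTIMATORS:
        total = 0.0
        for rep in reports:
            est = rep.estimate(which)
            if est is None or rep.s_test is None:
                continue
            total += abs(est - rep.s_test)
        sums[which] = total
    return sums


# ---------------------------------------------------------------------------
# Thresholding
# ---------------------------------------------------------------------------

@dataclass
class ThresholdReport:
    cutoff: float
    sensitivity: float
    specificity: float
    objective: float
    specificity_weight: float
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n_predicted_infested(self) -> int:
        return self.tp + self.fp

    def to_dict(self) -> dict:
        return asdict(self)


def youden_threshold(
    scores, labels, specificity_weight: float = 1.0
) -> ThresholdReport:
    """Cutoff maximizing sensitivity + w * specificity over observed scores.

    With w = 1 this is Youden's optimal cutoff; management applications that
    must avoid over-predicting infestations weight specificity more heavily
    (e.g., w = 10), which can only push the cutoff upward and shrinks the
    predicted-infested area.  Candidates are the unique score values plus 0
    and 1; ties break toward the higher cutoff (fewer predicted infested).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("threshold selection needs both classes present")
    candidates = np.unique(np.concatenate([scores, [0.0, 1.0]]))
    best = None
    for cut in candidates:  # ascending; >= keeps the highest tied cutoff
        pred = scores >= cut
        tp = int(np.sum(pred & (labels == 1)))
        fp = int(np.sum(pred & (labels == 0)))
        fn = n_pos - tp
        tn = n_neg - fp
        sens = tp / n_pos
        spec = tn / n_neg
        obj = sens + specificity_weight * spec
        if best is None or obj >= best.objective:
            best = ThresholdReport(
                cutoff=float(cut), sensitivity=sens, specificity=spec,
                objective=obj, specificity_weight=specificity_weight,
                tp=tp, fp=fp, tn=tn, fn=fn,
            )
    return best


def binary_map(
    probabilities: np.ndarray,
    cutoff: float,
    park_mask: np.ndarray | None = None,
) -> tuple[np.ndarray, int]:
    """Turn a probability raster into a binary infestation map.

    A pixel is marked infested iff its probability >= cutoff; increasing
    the cutoff can only shrink the infested set.  Returns (0/1 grid,
    infested pixel count).
    """
    probabilities = np.asarray(probabilities, dtype=float)
    pred = (probabilities >= cutoff).astype(int)
    if park_mask is not None:
        pred = pred * np.asarray(park_mask, dtype=int)
    return pred, int(pred.sum())
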