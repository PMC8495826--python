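"""Covariate engineering: dispersal kernel, lagged feature matrices, data splits.

The survey table is long-format with one row per (pixel, year).  The
infestation indicator columns ``I_missed`` / ``I_managed`` follow survey
semantics: the value stored at year ``t`` records whether the pixel held a
missed / managed infestation in year ``t - 1`` (they are "last year"
covariates).  The outcome column ``I`` records infestation presence at year
``t`` itself, so the forecasting target ``I_{g,t+r}`` is the ``I`` value of
row ``(g, t + r)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import convolve2d

#: The 14 covariates measured at year t, in canonical (input) column order.
COVARIATES = [
    "N", "E", "B", "D", "Tmin", "Tmax", "W", "R", "C", "O",
    "IN_missed", "IN_managed", "I_missed", "I_managed",
]

#: Covariates constant in time (topography).
STATIC_COVARIATES = ("N", "E", "B")

#: Covariates that are binary indicators and are never discretized.
BINARY_COVARIATES = ("I_missed", "I_managed")

KEY_COLUMNS = ["pixel_id", "row", "col", "year"]

#: Outcome column: infestation presence at the row's own year.
OUTCOME = "I"


class ZeroTrainingInstancesError(ValueError):
    """A split plan left no rows to train on (temporal gap ate the data)."""


# ---------------------------------------------------------------------------
# Short-distance dispersal kernel
# ---------------------------------------------------------------------------

def _ring_offsets(ring: int) -> list[tuple[int, int]]:
    """Cell offsets whose center distance rounds to ``ring`` x 100 m.

    Ring membership is the annulus [ring - 0.5, ring + 0.5) in cell units,
    which yields 8, 12 and 16 cells for rings 1-3 of an interior pixel.
    """
    offsets = []
    reach = ring + 1
    for dr in range(-reach, reach + 1):
        for dc in range(-reach, reach + 1):
            if dr == 0 and dc == 0:
                continue
            d = float(np.hypot(dr, dc))
            if ring - 0.5 <= d < ring + 0.5:
                offsets.append((dr, dc))
    return offsets


@dataclass(frozen=True)
class RingKernel:
    """Ring-weighted neighbor kernel for the missed/managed dispersal index.

    Ring ``i`` (i = 1, 2, 3) carries weight ``2**-i``; with ring sizes
    8 / 12 / 16 the raw maximum is 8/2 + 12/4 + 16/8 = 9, so the scale
    ``kappa = 2/3`` pins the maximal attainable index at exactly 6.
    """

    n_rings: int = 3
    kappa: float = 2.0 / 3.0
    _offsets: tuple = field(init=False, repr=False)

    def __post_init__(self):
        object.__setattr__(
            self,
            "_offsets",
            tuple(tuple(_ring_offsets(i + 1)) for i in range(self.n_rings)),
        )

    def weight(self, ring: int) -> float:
        return 2.0 ** (-ring)

    def offsets(self, ring: int) -> tuple[tuple[int, int], ...]:
        return self._offsets[ring - 1]

    @property
    def max_index(self) -> float:
        return self.kappa * sum(
            self.weight(i) * len(self.offsets(i))
            for i in range(1, self.n_rings + 1)
        )

    def footprint(self, ring: int) -> np.ndarray:
        """Dense 0/1 convolution footprint of one ring."""
        reach = self.n_rings + 1
        size = 2 * reach + 1
        fp = np.zeros((size, size))
        for dr, dc in self.offsets(ring):
            fp[reach + dr, reach + dc] = 1.0
        return fp


DEFAULT_KERNEL = RingKernel()


def compute_neighbor_index(
    indicator: np.ndarray,
    kernel: RingKernel | None = None,
    park_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Ring-weighted count of indicator-positive pixels around each pixel.

    ``index_g = kappa * sum_i 2**-i * |{g' in ring_i(g) ∩ park : x_g' = 1}|``

    Pixels outside the park never contribute; rings truncated by the park
    or grid boundary are *not* renormalized, so boundary pixels can only
    attain smaller values.

    Parameters
    ----------
    indicator : 2-D binary array (the pixel grid).
    kernel : ring kernel; defaults to three 100 m rings with weights 2**-i.
    park_mask : optional 2-D boolean array; False cells are ignored.

    Returns
    -------
    2-D float array of indices in [0, 6].
    """
    kernel = kernel or DEFAULT_KERNEL
    indicator = np.asarray(indicator)
    if indicator.ndim != 2:
        raise ValueError("indicator must be a 2-D grid")
    vals = np.unique(indicator)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValueError("indicator must be binary (0/1)")
    x = indicator.astype(float)
    if park_mask is not None:
        x = x * np.asarray(park_mask, dtype=float)
    index = np.zeros_like(x)
    for ring in range(1, kernel.n_rings + 1):
        counts = convolve2d(x, kernel.footprint(ring), mode="same", fillvalue=0.0)
        index += kernel.weight(ring) * counts
    return kernel.kappa * index


# ---------------------------------------------------------------------------
# Lagged feature matrices
# ---------------------------------------------------------------------------

@dataclass
class FeatureMatrix:
    """Dataset for one (r, h, c) configuration.

    ``df`` holds key columns, ``c*h`` feature columns and the ``target``
    column ``I_{g,t+r}``; the row's ``year`` is the most recent covariate
    year ``t`` and ``target_year`` is ``t + r``.
    """

    df: pd.DataFrame
    r: int
    h: int
    c: int
    ranking: list[str]
    feature_cols: list[str]
    target_col: str = "target"

    @property
    def covariates(self) -> list[str]:
        return self.ranking[: self.c]

    def features(self, rows=None) -> pd.DataFrame:
        d = self.df if rows is None else self.df.loc[rows]
        return d[self.feature_cols]

    def target(self, rows=None) -> np.ndarray:
        d = self.df if rows is None else self.df.loc[rows]
        return d[self.target_col].to_numpy()

    def target_years(self, rows=None) -> np.ndarray:
        d = self.df if rows is None else self.df.loc[rows]
        return d["target_year"].to_numpy()


def lag_column(covariate: str, lag: int) -> str:
    return f"{covariate}_lag{lag}"


def build_feature_matrix(
    table: pd.DataFrame,
    r: int,
    h: int,
    c: int | None = None,
    ranking: list[str] | None = None,
) -> FeatureMatrix:
    """Assemble the dataset D^{r,h,c} of lagged features and future targets.

    A row exists for every (pixel, t) whose full covariate history
    t-h+1 .. t lies inside the table's year span and whose target year
    t + r is observed.  For a rectangular table of N pixels over Y
    consecutive years this gives N * (Y + 1 - r - h) rows.

    Parameters
    ----------
    table : long-format survey table (one row per pixel and year).
    r : prediction length in years (how far ahead the target lies).
    h : history length, number of consecutive covariate years supplied.
    c : number of top-ranked covariates to keep (default: all 14).
    ranking : covariate ordering; defaults to the canonical input order.
    """
    ranking = list(ranking) if ranking is not None else list(COVARIATES)
    c = len(ranking) if c is None else c
    if r < 1:
        raise ValueError(f"prediction length r must be >= 1, got {r}")
    if h < 1:
        raise ValueError(f"history length h must be >= 1, got {h}")
    if not 1 <= c <= len(ranking):
        raise ValueError(f"number of covariates c={c} outside 1..{len(ranking)}")
    missing = [col for col in ranking if col not in table.columns]
    if missing:
        raise ValueError(f"table lacks covariate columns: {missing}")
    if OUTCOME not in table.columns:
        raise ValueError(f"table lacks outcome column {OUTCOME!r}")

    years = np.sort(table["year"].unique())
    if len(years) < r + h:
        raise ValueError(
            f"table spans {len(years)} years; need at least r+h = {r + h}"
        )

    covs = ranking[:c]
    base = table[KEY_COLUMNS].copy()
    out = base
    for lag in range(h):
        shifted = table[["pixel_id", "year"] + covs].copy()
        shifted["year"] = shifted["year"] + lag  # value from year t-lag lands at t
        shifted = shifted.rename(columns={cv: lag_column(cv, lag) for cv in covs})
        out = out.merge(shifted, on=["pixel_id", "year"], how="inner")
    tgt = table[["pixel_id", "year", OUTCOME]].copy()
    tgt["year"] = tgt["year"] - r  # outcome at year t+r lands at t
    tgt = tgt.rename(columns={OUTCOME: "target"})
    out = out.merge(tgt, on=["pixel_id", "year"], how="inner")
    out["target_year"] = out["year"] + r
    out = out.sort_values(["year", "pixel_id"], kind="stable").reset_index(drop=True)

    feature_cols = [lag_column(cv, lag) for cv in covs for lag in range(h)]
    out = out[KEY_COLUMNS + feature_cols + ["target", "target_year"]]
    return FeatureMatrix(
        df=out, r=r, h=h, c=c, ranking=ranking, feature_cols=feature_cols
    )


# ---------------------------------------------------------------------------
# Split plans
# ---------------------------------------------------------------------------

@dataclass
class SplitPlan:
    """Assignment of feature-matrix rows to train / test / gap roles."""

    kind: str
    train_idx: np.ndarray
    test_idx: np.ndarray
    train_target_years: list[int] = field(default_factory=list)
    test_target_years: list[int] = field(default_factory=list)
    gap_target_years: list[int] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "train_target_years": [int(y) for y in self.train_target_years],
            "test_target_years": [int(y) for y in self.test_target_years],
            "gap_target_years": [int(y) for y in self.gap_target_years],
            "n_train": int(len(self.train_idx)),
            "n_test": int(len(self.test_idx)),
        }


def year_based_split(fm: FeatureMatrix, n_test_years: int = 2) -> SplitPlan:
    """Temporal split: the latest ``n_test_years`` target years are the test set.

    Train and test rows are yearly disjoint by construction, so no target
    year contributes to both sides.
    """
    tyears = np.sort(fm.df["target_year"].unique())
    if len(tyears) <= n_test_years:
        raise ZeroTrainingInstancesError(
            f"only {len(tyears)} target years available; cannot hold out "
            f"{n_test_years} for testing"
        )
    test_years = set(int(y) for y in tyears[-n_test_years:])
    is_test = fm.df["target_year"].isin(test_years).to_numpy()
    return SplitPlan(
        kind="year-based",
        train_idx=fm.df.index[~is_test].to_numpy(),
        test_idx=fm.df.index[is_test].to_numpy(),
        train_target_years=sorted(int(y) for y in tyears[:-n_test_years]),
        test_target_years=sorted(test_years),
    )


def cv_folds(fm: FeatureMatrix, plan: SplitPlan) -> list[tuple[int, np.ndarray, np.ndarray]]:
    """Year folds of a training set: one fold per distinct target year.

    Returns ``(held_out_year, holdout_idx, remaining_idx)`` triples, sorted
    by year.  Folds partition the training rows.
    """
    train = fm.df.loc[plan.train_idx]
    folds = []
    for year in sorted(train["target_year"].unique()):
        mask = (train["target_year"] == year).to_numpy()
        folds.append(
            (int(year), plan.train_idx[mask], plan.train_idx[~mask])
        )
    return folds


def random_split(
    train_idx: np.ndarray, fraction: float = 0.7, seed: int | None = 0
) -> SplitPlan:
    """Row-wise i.i.d. 70/30 partition that ignores year structure.

    This is the conventional machine-learning split; on temporally
    autocorrelated data it lets the same survey year appear on both sides
    and therefore over-states forecasting skill.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    idx = np.asarray(train_idx)
    perm = rng.permutation(len(idx))
    n_train = int(round(fraction * len(idx)))
    return SplitPlan(
        kind="random-70/30",
        train_idx=np.sort(idx[perm[:n_train]]),
        test_idx=np.sort(idx[perm[n_train:]]),
    )


def gap_split(fm: FeatureMatrix, n_test_years: int = 1) -> SplitPlan:
    """Temporal-gap split honoring real forecasting constraints.

    When predicting year t+r from covariates up to year t, none of the
    intervening years t+1 .. t+r-1 would be observed yet; their rows are
    marked as the gap and excluded from training and validation.  For long
    prediction lengths combined with long histories this can leave zero
    training rows, which raises :class:`ZeroTrainingInstancesError`.
    """
    r = fm.r
    tyears = np.sort(fm.df["target_year"].unique())
    test_year = int(tyears[-1])
    t_latest = test_year - r  # latest usable covariate year
    gap_years = [y for y in range(t_latest + 1, test_year) if y in set(map(int, tyears))]
    ty = fm.df["target_year"].to_numpy()
    train_mask = ty <= t_latest
    test_mask = ty == test_year
    if n_test_years != 1:
        raise ValueError("gap plans test a single target year")
    if not train_mask.any():
        raise ZeroTrainingInstancesError(
            f"gap split for r={r}, h={fm.h} leaves zero training instances: "
            f"no rows have target year <= {t_latest}"
        )
    return SplitPlan(
        kind="gap-honoring",
        train_idx=fm.df.index[train_mask].to_numpy(),
        test_idx=fm.df.index[test_mask].to_numpy(),
        train_target_years=sorted(int(y) for y in np.unique(ty[train_mask])),
        test_target_years=[test_year],
        gap_target_years=gap_years,
    )


# ---------------------------------------------------------------------------
# Discretization
# ---------------------------------------------------------------------------

def _is_binary(x: np.ndarray) -> bool:
    vals = np.unique(x[~np.isnan(x)])
    return len(vals) <= 2 and np.all(np.isin(vals, (0.0, 1.0)))


@dataclass
class Discretizer:
    """Equal-width binning of non-binary columns, fitted on training rows only.

    Each non-binary column is cut into ``n_levels`` equal-width bins over
    its training range; out-of-range values at prediction time are clipped
    into the end bins.  Binary 0/1 columns pass through untouched.  Levels
    are integers 1..n_levels (binary columns keep their 0/1 values).
    """

    n_levels: int = 5
    edges: dict = field(default_factory=dict)       # col -> interior cut points
    binary_cols: list = field(default_factory=list)
    columns: list = field(default_factory=list)

    def fit(self, df: pd.DataFrame) -> "Discretizer":
        self.columns = list(df.columns)
        self.edges = {}
        self.binary_cols = []
        for col in df.columns:
            x = df[col].to_numpy(dtype=float)
            if _is_binary(x):
                self.binary_cols.append(col)
                continue
            lo, hi = np.nanmin(x), np.nanmax(x)
            if hi <= lo:  # constant column: a single level
                self.edges[col] = np.array([])
            else:
                self.edges[col] = lo + (hi - lo) * np.arange(
                    1, self.n_levels
                ) / self.n_levels
        return self

    def transform(self, df: pd.DataFrame) -> pd.DataFrame:
        out = df.copy()
        for col, cuts in self.edges.items():
            if col not in out.columns:
                continue
            x = out[col].to_numpy(dtype=float)
            lev = np.digitize(x, cuts) + 1 if len(cuts) else np.ones(len(x), dtype=int)
            lev = np.asarray(lev, dtype=float)
            lev[np.isnan(x)] = np.nan
            out[col] = lev
        return out

    def level_values(self, col: str) -> np.ndarray:
        """The full set of levels a column can take after transform."""
        if col in self.binary_cols:
            return np.array([0.0, 1.0])
        return np.arange(1, self.n_levels + 1, dtype=float)

    def edges_dict(self) -> dict:
        return {col: [float(e) for e in cuts] for col, cuts in self.edges.items()}


def discretize(
    fm: FeatureMatrix, n_levels: int = 5, fit_rows=None
) -> tuple[FeatureMatrix, Discretizer]:
    """Discretize a feature matrix's non-binary columns into equal levels.

    ``fit_rows`` restricts edge fitting to training rows (mandatory for any
    honest evaluation); the transform is applied to all rows.
    """
    disc = Discretizer(n_levels=n_levels)
    disc.fit(fm.features(fit_rows))
    df = fm.df.copy()
    df[fm.feature_cols] = disc.transform(fm.features())
    out = FeatureMatrix(
        df=df, r=fm.r, h=fm.h, c=fm.c, ranking=fm.ranking,
        feature_cols=fm.feature_cols, target_col=fm.target_col,
    )
    return out, disc


def check_no_leakage(plan: SplitPlan) -> bool:
    """True when every training target year precedes every test target year."""
    if not plan.train_target_years or not plan.test_target_years:
        warnings.warn("plan has no recorded target years; cannot audit leakage")
        return False
    return max(plan.train_target_years) < min(plan.test_target_years)
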