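"""Synthetic survey data with the spatiotemporal structure of a beetle outbreak.

The generator emulates the statistical features the downstream analysis
relies on: a bounded park on a 100 m pixel grid, static topography,
yearly spatially smooth weather, an exogenous three-phase outbreak
trajectory (increase, peak, decline), and an infestation process driven by
short-range neighbor pressure in which detected ("managed") infestations
are removed from the spread dynamics while "missed" ones seed next year's
attacks.  The result is strong spatial and temporal autocorrelation — the
property that makes random train/test splits of such data misleading.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.special import expit

from beetlecast.features import DEFAULT_KERNEL, RingKernel, compute_neighbor_index

CELL_KM = 0.1  # pixel side length: 100 m


# ---------------------------------------------------------------------------
# Landscape
# ---------------------------------------------------------------------------

@dataclass
class Landscape:
    """Static terrain of the study area.

    northerness/easterness are cos/sin of one smoothly varying aspect angle
    per pixel; ``border_distance`` is the within-park shortest-path distance
    (km) to the initially infested border, which is zero exactly on the
    designated border cells.
    """

    n_rows: int
    n_cols: int
    park_mask: np.ndarray
    northerness: np.ndarray
    easterness: np.ndarray
    border_distance: np.ndarray
    border_mask: np.ndarray

    @property
    def n_pixels(self) -> int:
        return int(self.park_mask.sum())

    def pixel_ids(self) -> np.ndarray:
        """Row-major integer label of every park pixel."""
        rows, cols = np.nonzero(self.park_mask)
        return rows * self.n_cols + cols


def _smooth_field(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    """Unit-variance spatially smooth Gaussian field."""
    f = gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="nearest")
    sd = f.std()
    return f / sd if sd > 0 else np.zeros(shape)


def _bfs_distance(park: np.ndarray, sources: np.ndarray) -> np.ndarray:
    """4-connected breadth-first-search step counts from source cells."""
    n_rows, n_cols = park.shape
    dist = np.full(park.shape, np.inf)
    q: deque = deque()
    for r, c in zip(*np.nonzero(sources)):
        dist[r, c] = 0
        q.append((r, c))
    while q:
        r, c = q.popleft()
        for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            rr, cc = r + dr, c + dc
            if 0 <= rr < n_rows and 0 <= cc < n_cols and park[rr, cc]:
                if dist[rr, cc] > dist[r, c] + 1:
                    dist[rr, cc] = dist[r, c] + 1
                    q.append((rr, cc))
    return dist


def generate_landscape(n_rows: int, n_cols: int, seed: int | None = 0) -> Landscape:
    """Generate a rectangular park with smooth aspect and border distances.

    The initially infested border is the park's western edge (its smallest
    occupied column); all infestation seeding starts there.  Deterministic
    given the seed.
    """
    if n_rows < 1 or n_cols < 1:
        raise ValueError(f"grid dimensions must be positive, got {n_rows}x{n_cols}")
    rng = np.random.default_rng(seed)
    shape = (n_rows, n_cols)
    park = np.ones(shape, dtype=bool)

    sigma = max(1.0, min(n_rows, n_cols) / 8.0)
    u = _smooth_field(rng, shape, sigma)
    v = _smooth_field(rng, shape, sigma)
    angle = np.arctan2(v, u)

    west_col = int(np.nonzero(park.any(axis=0))[0][0])
    border = park & (np.arange(n_cols)[None, :] == west_col)
    dist = _bfs_distance(park, border) * CELL_KM

    return Landscape(
        n_rows=n_rows,
        n_cols=n_cols,
        park_mask=park,
        northerness=np.cos(angle),
        easterness=np.sin(angle),
        border_distance=dist,
        border_mask=border,
    )


# ---------------------------------------------------------------------------
# Weather
# ---------------------------------------------------------------------------

@dataclass
class WeatherSeries:
    """Yearly weather fields plus the exogenous regional outbreak phase.

    All per-pixel arrays have shape (n_years, n_rows, n_cols).  Cold
    tolerance C is a survival index in [0, 1] that increases with the
    winter minimum temperature (milder winters let more larvae survive).
    """

    years: list[int]
    degree_days: np.ndarray
    winter_min_temp: np.ndarray
    summer_max_temp: np.ndarray
    wind: np.ndarray
    humidity: np.ndarray
    cold_tolerance: np.ndarray
    phase: np.ndarray  # int in {1, 2, 3} per year, weakly increasing


def phase_schedule(n_years: int, lengths: tuple[int, int, int] | None = None) -> np.ndarray:
    """Fixed increase / peak / decline segments (near-equal thirds by default)."""
    if lengths is None:
        third = n_years // 3
        lengths = (n_years - 2 * third, third, third)
    if sum(lengths) != n_years or any(l < 0 for l in lengths):
        raise ValueError(f"phase lengths {lengths} do not partition {n_years} years")
    return np.repeat([1, 2, 3], lengths)


def generate_weather(
    landscape: Landscape,
    years: list[int],
    seed: int | None = 0,
    phase_lengths: tuple[int, int, int] | None = None,
) -> WeatherSeries:
    """Simulate smooth weather fields for each year of the outbreak.

    Each covariate is a yearly regional anomaly plus a spatially smooth
    field (Gaussian noise smoothed at a ~3-pixel scale), so neighboring
    pixels are far more correlated than distant ones.  Cold tolerance is a
    logistic function of the winter minimum temperature.
    """
    years = [int(y) for y in years]
    if not years:
        raise ValueError("year span is empty")
    if list(years) != list(range(years[0], years[0] + len(years))):
        raise ValueError("years must be contiguous and increasing")
    rng = np.random.default_rng(seed)
    shape = (landscape.n_rows, landscape.n_cols)
    n = len(years)

    def yearly_field(scale_year: float, scale_space: float, base: float) -> np.ndarray:
        out = np.empty((n,) + shape)
        for k in range(n):
            out[k] = (
                base
                + scale_year * rng.normal()
                + scale_space * _smooth_field(rng, shape, sigma=3.0)
            )
        return out

    D = np.clip(yearly_field(120.0, 60.0, 900.0), 0.0, None)
    Tmin = yearly_field(6.0, 2.0, -32.0)
    Tmax = yearly_field(2.5, 1.5, 28.0)
    W = np.clip(yearly_field(1.5, 2.0, 10.0), 0.0, None)
    R = np.clip(yearly_field(5.0, 10.0, 55.0), 0.0, 100.0)
    C = expit((Tmin + 30.0) / 5.0)

    return WeatherSeries(
        years=years,
        degree_days=D,
        winter_min_temp=Tmin,
        summer_max_temp=Tmax,
        wind=W,
        humidity=R,
        cold_tolerance=C,
        phase=phase_schedule(n, phase_lengths),
    )


# ---------------------------------------------------------------------------
# Infestation process
# ---------------------------------------------------------------------------

@dataclass
class SimulationParams:
    """Coefficients of the logistic infestation-spread process.

    The per-pixel, per-year probability of a new infestation is
    ``logistic(intercept + beta_neighbor * IN + beta_self * I_prev
    + beta_border * B + beta_cold * C + beta_degree_days * zD + phase_effect)``
    where IN is the ring-weighted missed-neighbor index of the previous
    year, I_prev flags the pixel's own missed infestation last year, B the
    border distance in km and zD the standardized degree days.  Each new
    infestation is detected and managed with probability ``p_detect``;
    only missed infestations drive next year's neighbor pressure.
    Initial seeds are placed on border cells (each with probability
    ``seed_fraction``) and count as missed by convention — they are the
    undetected source of the outbreak.
    """

    intercept: float = -4.5
    beta_neighbor: float = 4.0
    beta_self: float = 2.0
    beta_border: float = -0.3
    beta_cold: float = 1.5
    beta_degree_days: float = 0.25
    phase_effect: tuple[float, float, float] = (0.0, 1.0, -1.5)
    p_detect: float = 0.5
    seed_fraction: float = 0.6
    seed: int | None = 0

    def validate(self) -> None:
        if not 0.0 <= self.p_detect <= 1.0:
            raise ValueError(f"p_detect must be in [0, 1], got {self.p_detect}")
        if not 0.0 <= self.seed_fraction <= 1.0:
            raise ValueError(
                f"seed_fraction must be in [0, 1], got {self.seed_fraction}"
            )
        if len(self.phase_effect) != 3:
            raise ValueError("phase_effect needs one value per outbreak phase")

    def with_seed(self, seed: int) -> "SimulationParams":
        return replace(self, seed=seed)


# reference anchors used to standardize degree days inside the simulator
_DD_CENTER, _DD_SCALE = 900.0, 150.0


def simulate_infestation(
    landscape: Landscape,
    weather: WeatherSeries,
    params: SimulationParams,
    kernel: RingKernel | None = None,
) -> pd.DataFrame:
    """Run the outbreak and emit a long-format survey table.

    The first weather year seeds the outbreak and is not emitted; every
    later year produces one row per park pixel.  Indicator columns follow
    survey semantics: ``I_missed`` / ``I_managed`` at year t record the
    previous year's infestation events, ``IN_missed`` / ``IN_managed`` are
    their ring-weighted neighbor indices, and the outcome column ``I``
    records infestation presence (missed or managed) at year t itself.
    """
    params.validate()
    kernel = kernel or DEFAULT_KERNEL
    if len(weather.years) < 2:
        raise ValueError("need at least two weather years (seed year + one survey year)")
    rng = np.random.default_rng(params.seed)
    park = landscape.park_mask
    shape = park.shape
    n_years = len(weather.years)

    ev_missed = np.zeros((n_years,) + shape, dtype=bool)
    ev_managed = np.zeros((n_years,) + shape, dtype=bool)

    # seed year: undetected infestations on the initially infested border
    seeds = landscape.border_mask & (rng.random(shape) < params.seed_fraction)
    ev_missed[0] = seeds & park

    zD = (weather.degree_days - _DD_CENTER) / _DD_SCALE
    phase_eff = np.asarray(params.phase_effect, dtype=float)

    for k in range(1, n_years):
        pressure = compute_neighbor_index(
            ev_missed[k - 1].astype(int), kernel, park
        )
        eta = (
            params.intercept
            + params.beta_neighbor * pressure
            + params.beta_self * ev_missed[k - 1]
            + params.beta_border * landscape.border_distance
            + params.beta_cold * weather.cold_tolerance[k]
            + params.beta_degree_days * zD[k]
            + phase_eff[weather.phase[k] - 1]
        )
        p = expit(eta)
        infested = park & (rng.random(shape) < p)
        managed = infested & (rng.random(shape) < params.p_detect)
        ev_managed[k] = managed
        ev_missed[k] = infested & ~managed

    rows_idx, cols_idx = np.nonzero(park)
    pixel_ids = rows_idx * landscape.n_cols + cols_idx
    frames = []
    for k in range(1, n_years):
        year = weather.years[k]
        in_missed = compute_neighbor_index(ev_missed[k - 1].astype(int), kernel, park)
        in_managed = compute_neighbor_index(ev_managed[k - 1].astype(int), kernel, park)
        frames.append(
            pd.DataFrame(
                {
                    "pixel_id": pixel_ids,
                    "row": rows_idx,
                    "col": cols_idx,
                    "year": year,
                    "N": landscape.northerness[rows_idx, cols_idx],
                    "E": landscape.easterness[rows_idx, cols_idx],
                    "B": landscape.border_distance[rows_idx, cols_idx],
                    "D": weather.degree_days[k][rows_idx, cols_idx],
                    "Tmin": weather.winter_min_temp[k][rows_idx, cols_idx],
                    "Tmax": weather.summer_max_temp[k][rows_idx, cols_idx],
                    "W": weather.wind[k][rows_idx, cols_idx],
                    "R": weather.humidity[k][rows_idx, cols_idx],
                    "C": weather.cold_tolerance[k][rows_idx, cols_idx],
                    # the phase covariate refers to the regional stage of the
                    # outbreak in the year the surveyed beetles flew (t - 1)
                    "O": int(weather.phase[k - 1]),
                    "I_missed": ev_missed[k - 1][rows_idx, cols_idx].astype(int),
                    "I_managed": ev_managed[k - 1][rows_idx, cols_idx].astype(int),
                    "IN_missed": in_missed[rows_idx, cols_idx],
                    "IN_managed": in_managed[rows_idx, cols_idx],
                    "I": (ev_missed[k] | ev_managed[k])[rows_idx, cols_idx].astype(int),
                }
            )
        )
    table = pd.concat(frames, ignore_index=True)
    return table.sort_values(["year", "pixel_id"], kind="stable").reset_index(drop=True)


def default_survey(
    n_rows: int = 24,
    n_cols: int = 24,
    years: tuple[int, int] = (2005, 2018),
    seed: int | None = 0,
    params: SimulationParams | None = None,
) -> pd.DataFrame:
    """One-call synthetic survey under the default study conditions.

    The default emulates a 13-season survey (emitted years 2006-2018, the
    first year only seeds the outbreak) on a 24 x 24 pixel park.  All
    randomness is split from the single ``seed``.
    """
    ss = np.random.SeedSequence(seed)
    s_land, s_weather, s_sim = (int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(3))
    land = generate_landscape(n_rows, n_cols, seed=s_land)
    weather = generate_weather(land, list(range(years[0], years[1] + 1)), seed=s_weather)
    params = params or SimulationParams()
    params = params.with_seed(s_sim)
    return simulate_infestation(land, weather, params)
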