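"""Environmental covariates for the metapopulation analysis.

This module derives the four covariates that drive brown bear extinction
risk in the occupancy model -- human land use (LU), winter temperature
(WT), net primary productivity (NPP) and elevation (ELE) -- from raw
climate, land-use and terrain inputs:

* the Miami model, an empirical first-order NPP model taking the minimum
  of a temperature-limited and a precipitation-limited productivity rate;
* the wintering-season temperature, the mean of monthly mean temperatures
  over months whose maximum monthly temperature is below 0 degC (matching
  bear denning phenology);
* anomaly calibration of pollen-based climate reconstructions against a
  31-year running mean of a recent annual series (baseline 1850 CE);
* weighted aggregation of time-interval data onto the analysis periods,
  with half weight for intervals at period margins;
* least-cost-path (LCP) dispersal distances between grid cells over a
  terrain grid with impassable water.

Calendar convention: years are signed numbers on a continuous axis, BCE
negative and CE positive, with no year-zero adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

__all__ = [
    "ClimateSeries",
    "MonthlyClimate",
    "TerrainGrid",
    "PeriodScheme",
    "DEFAULT_PERIOD_BOUNDARIES",
    "miami_npp",
    "wintering_temperature",
    "aggregate_to_periods",
    "calibrate_anomalies",
    "lcp_distances",
    "period_scheme_from_boundaries",
]

#: The seven analysis periods, as (start, end) calendar years (BCE negative).
DEFAULT_PERIOD_BOUNDARIES: tuple[tuple[float, float], ...] = (
    (-10000, -7000),
    (-7000, -3000),
    (-3000, 0),
    (0, 1500),
    (1500, 1800),
    (1950, 1970),
    (2010, 2015),
)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class ClimateSeries:
    """An annual climate series for one grid cell.

    Attributes
    ----------
    cell_id : int
    times : array of calendar years (CE positive, BCE negative), strictly
        increasing.
    mean_annual_temp : degC, same length as ``times``.
    total_annual_precip : mm/yr, non-negative.
    winter_temp : degC mean winter temperature.
    """

    cell_id: int
    times: np.ndarray
    mean_annual_temp: np.ndarray
    total_annual_precip: np.ndarray
    winter_temp: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.mean_annual_temp = np.asarray(self.mean_annual_temp, dtype=float)
        self.total_annual_precip = np.asarray(self.total_annual_precip, dtype=float)
        self.winter_temp = np.asarray(self.winter_temp, dtype=float)
        n = len(self.times)
        for name in ("mean_annual_temp", "total_annual_precip", "winter_temp"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length differs from times length {n}")
        if n > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.total_annual_precip < 0):
            raise ValueError("total_annual_precip must be >= 0")


@dataclass
class MonthlyClimate:
    """Twelve monthly climate normals at one location."""

    mean_temp: np.ndarray  # degC, 12 entries
    max_temp: np.ndarray   # degC, 12 entries
    precip: np.ndarray     # mm, 12 entries

    def __post_init__(self) -> None:
        self.mean_temp = np.asarray(self.mean_temp, dtype=float)
        self.max_temp = np.asarray(self.max_temp, dtype=float)
        self.precip = np.asarray(self.precip, dtype=float)
        for name in ("mean_temp", "max_temp", "precip"):
            if getattr(self, name).shape != (12,):
                raise ValueError(f"{name} must have exactly 12 entries")
        if np.any(self.max_temp < self.mean_temp):
            raise ValueError("max_temp must be >= mean_temp for every month")


@dataclass
class TerrainGrid:
    """A regular lattice of cells with elevation and a water mask.

    The lattice doubles as the dispersal substrate: least-cost-path
    distances are computed on its 8-neighbour graph.  ``spacing_km`` is
    the lattice spacing; ``coarse_km`` is the analysis cell size that
    distances are expressed in (grid units of ``coarse_km``).
    """

    x_km: np.ndarray          # (n_cells,) cell-centre x
    y_km: np.ndarray          # (n_cells,) cell-centre y
    elevation_m: np.ndarray   # (n_cells,)
    is_water: np.ndarray      # (n_cells,) bool
    nx: int
    ny: int
    spacing_km: float = 100.0
    coarse_km: float = 100.0

    def __post_init__(self) -> None:
        self.x_km = np.asarray(self.x_km, dtype=float)
        self.y_km = np.asarray(self.y_km, dtype=float)
        self.elevation_m = np.asarray(self.elevation_m, dtype=float)
        self.is_water = np.asarray(self.is_water, dtype=bool)
        n = self.nx * self.ny
        for name in ("x_km", "y_km", "elevation_m", "is_water"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} must have nx*ny = {n} entries")
        if self.spacing_km <= 0 or self.coarse_km <= 0:
            raise ValueError("cell sizes must be positive")
        if not np.all(np.isfinite(self.elevation_m[~self.is_water])):
            raise ValueError("elevation must be finite on land cells")

    @property
    def n_cells(self) -> int:
        return self.nx * self.ny

    @property
    def land(self) -> np.ndarray:
        return ~self.is_water


@dataclass
class PeriodScheme:
    """Ordered, non-overlapping analysis periods and the interval lengths
    between consecutive period midpoints."""

    boundaries: tuple[tuple[float, float], ...]
    midpoints: np.ndarray = field(init=False)
    dt: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        b = [(float(s), float(e)) for s, e in self.boundaries]
        for s, e in b:
            if e <= s:
                raise ValueError(f"period ({s}, {e}) has non-positive length")
        for (s0, e0), (s1, e1) in zip(b, b[1:]):
            if s1 < e0:
                raise ValueError(
                    f"periods ({s0}, {e0}) and ({s1}, {e1}) overlap or are unordered"
                )
        self.boundaries = tuple(b)
        self.midpoints = np.array([(s + e) / 2.0 for s, e in b])
        self.dt = np.diff(self.midpoints)
        if len(self.dt) and not np.all(self.dt > 0):
            raise ValueError("midpoints must be strictly increasing")

    @property
    def n_periods(self) -> int:
        return len(self.boundaries)


def period_scheme_from_boundaries(boundaries) -> PeriodScheme:
    """Build a :class:`PeriodScheme` from ordered (start, end) boundaries.

    For the seven default Holocene periods this yields
    dt = (3500, 3500, 2250, 900, 310, 52.5) years.
    """
    return PeriodScheme(tuple((float(s), float(e)) for s, e in boundaries))


# ---------------------------------------------------------------------------
# Covariate derivation
# ---------------------------------------------------------------------------

def miami_npp(temp_c, precip_mm):
    """Net primary productivity (g dry matter m^-2 a^-1) from the Miami model.

    NPP = min(NPP_T, NPP_P) with
    NPP_T = 3000 / (1 + exp(1.315 - 0.119 T)) and
    NPP_P = 3000 (1 - exp(-0.000664 P)).

    Both limiting rates saturate at 3000, so 0 <= NPP < 3000 for finite
    inputs; the result is monotone non-decreasing in both arguments.

    Parameters
    ----------
    temp_c : mean annual temperature, degC (scalar or array).
    precip_mm : total annual precipitation, mm/yr, >= 0.
    """
    t = np.asarray(temp_c, dtype=float)
    p = np.asarray(precip_mm, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("non-finite mean annual temperature")
    if not np.all(np.isfinite(p)):
        raise ValueError("non-finite total annual precipitation")
    if np.any(p < 0):
        raise ValueError("total annual precipitation must be >= 0")
    npp_t = 3000.0 / (1.0 + np.exp(1.315 - 0.119 * t))
    npp_p = 3000.0 * (-np.expm1(-0.000664 * p))
    out = np.minimum(npp_t, npp_p)
    return float(out) if out.ndim == 0 else out


def wintering_temperature(mc: MonthlyClimate) -> tuple[float, bool]:
    """Mean temperature of the wintering season, T_ws.

    T_ws is the mean of the monthly mean temperatures over the months
    whose maximum monthly temperature is below 0 degC.  When no month
    qualifies (a "no-winter" climate) the coldest monthly mean is
    returned instead and the second element of the result is True, so
    downstream analyses can drop or keep such populations explicitly.

    Returns
    -------
    (t_ws, no_winter_flag)
    """
    winter = mc.max_temp < 0.0
    if not winter.any():
        return float(mc.mean_temp.min()), True
    return float(mc.mean_temp[winter].mean()), False


def aggregate_to_periods(times, values, scheme: PeriodScheme) -> np.ndarray:
    """Aggregate time-interval data to period means with margin weighting.

    Each nominal timestamp falling inside a period contributes with
    weight 1; a timestamp lying exactly on a period boundary (a "margin"
    interval, shared between two adjacent periods) contributes with
    weight 0.5.  Weights are renormalized to sum to one within each
    period.

    Raises
    ------
    ValueError
        If some period is covered by no timestamp (named in the message).
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.shape != values.shape:
        raise ValueError("times and values must have the same shape")
    out = np.empty(scheme.n_periods)
    for k, (start, end) in enumerate(scheme.boundaries):
        inside = (times >= start) & (times <= end)
        if not inside.any():
            raise ValueError(
                f"period {k} ({start}, {end}) is covered by no time interval"
            )
        w = np.where((times[inside] == start) | (times[inside] == end), 0.5, 1.0)
        out[k] = np.average(values[inside], weights=w)
    return out


def calibrate_anomalies(years, values, anomalies, baseline_year: float = 1850,
                        window: int = 31):
    """Convert anomalies to absolute values via a running-mean baseline.

    The baseline is the ``window``-year (default 31) running mean of the
    annual series ``(years, values)`` centred on ``baseline_year``; each
    anomaly is returned as ``anomaly + baseline``.

    Raises
    ------
    ValueError
        If the series does not fully cover the running-mean window.
    """
    years = np.asarray(years, dtype=float)
    values = np.asarray(values, dtype=float)
    half = (window - 1) // 2
    lo, hi = baseline_year - half, baseline_year + half
    inside = (years >= lo) & (years <= hi)
    if inside.sum() < window:
        raise ValueError(
            f"series covers only {int(inside.sum())} of the {window} years "
            f"[{lo}, {hi}] needed for the baseline at {baseline_year}"
        )
    baseline = float(values[inside].mean())
    out = np.asarray(anomalies, dtype=float) + baseline
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Least-cost-path dispersal distances
# ---------------------------------------------------------------------------

def _lcp_edges(terrain: TerrainGrid):
    """Edges of the 8-neighbour lattice graph with terrain-penalized costs.

    Edge cost = planar step length * (1 + |d elevation| / planar step),
    with elevation and step length in the same unit (m).  Water cells
    have no edges (infinite cost).
    """
    nx, ny = terrain.nx, terrain.ny
    elev = terrain.elevation_m.reshape(ny, nx)
    water = terrain.is_water.reshape(ny, nx)
    step_m = terrain.spacing_km * 1000.0
    rows, cols, costs = [], [], []
    offsets = [(0, 1, 1.0), (1, 0, 1.0), (1, 1, np.sqrt(2.0)), (1, -1, np.sqrt(2.0))]
    for dy, dx, mult in offsets:
        y0 = np.arange(max(0, -dy), min(ny, ny - dy))
        x0 = np.arange(max(0, -dx), min(nx, nx - dx))
        yy, xx = np.meshgrid(y0, x0, indexing="ij")
        y1, x1 = yy + dy, xx + dx
        ok = ~water[yy, xx] & ~water[y1, x1]
        planar = mult * step_m
        de = np.abs(elev[y1, x1] - elev[yy, xx])
        cost = planar * (1.0 + de / planar)
        i = (yy * nx + xx)[ok]
        j = (y1 * nx + x1)[ok]
        rows.append(i)
        cols.append(j)
        costs.append(cost[ok])
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    costs = np.concatenate(costs)
    return rows, cols, costs


def lcp_distances(terrain: TerrainGrid) -> np.ndarray:
    """Symmetric least-cost-path distance matrix between land cells.

    Moves are on the 8-neighbour lattice; water is impassable; the cost
    of a move is its planar length inflated by the relative elevation
    change, so on flat terrain the LCP equals the graph geometric
    distance.  Distances are returned for every cell pair (water rows /
    columns and disconnected land components are +inf; diagonal 0) in
    multiples of ``terrain.coarse_km``.
    """
    n = terrain.n_cells
    if int(terrain.land.sum()) < 2:
        raise ValueError("terrain must contain at least 2 land cells")
    rows, cols, costs = _lcp_edges(terrain)
    graph = coo_matrix(
        (np.concatenate([costs, costs]),
         (np.concatenate([rows, cols]), np.concatenate([cols, rows]))),
        shape=(n, n),
    ).tocsr()
    d_m = dijkstra(graph, directed=False)
    d = d_m / (terrain.coarse_km * 1000.0)
    np.fill_diagonal(d, 0.0)
    d[terrain.is_water, :] = np.inf
    d[:, terrain.is_water] = np.inf
    np.fill_diagonal(d, 0.0)
    return d
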