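"""Readers, writers, run configuration and derived map products.

All tabular interchange is plain CSV with documented schemas; every
writer's output is readable by the matching reader without warnings.
The derived map products are numeric surfaces (the cartography of the
original maps is out of scope): the net trend log10(extinction rate /
colonization rate) per cell-period (0 = balance, positive = net
extinction) and the posterior occurrence probability P(z = 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .enviro import TerrainGrid, PeriodScheme, period_scheme_from_boundaries
from .metapop import SITE_TYPES, UNKNOWN_TYPE, RANGE_MAP_TYPE, CovariateStack
from .inference import MCMCConfig, PosteriorDraws
from .paths import bayes_factor

__all__ = [
    "RunConfig",
    "net_trend",
    "occurrence_surface",
    "read_records", "write_records",
    "read_covariates", "write_covariates",
    "read_terrain", "write_terrain",
    "read_population_table", "write_population_table",
    "write_effect_summary",
    "write_draws", "read_draws_long",
    "write_diagnostics",
]


# ---------------------------------------------------------------------------
# Derived surfaces
# ---------------------------------------------------------------------------

def net_trend(r_phi, r_gamma):
    """log10(extinction rate / colonization rate) per cell-period.

    Zero marks balance between extinction and colonization; positive
    values mark net range loss.  Summarize per posterior draw and take
    the median for a point surface.
    """
    r_phi = np.asarray(r_phi, dtype=float)
    r_gamma = np.asarray(r_gamma, dtype=float)
    if np.any(r_phi <= 0) or np.any(r_gamma <= 0):
        raise ValueError("rates must be strictly positive")
    out = np.log10(r_phi / r_gamma)
    return float(out) if out.ndim == 0 else out


def occurrence_surface(z_draws: np.ndarray) -> np.ndarray:
    """Posterior occurrence probability P(z[s, t] = 1).

    ``z_draws`` has shape (..., S, T) with leading draw dimensions
    (chains, draws); the mean is over all leading axes, so pooled
    scenario draws average with equal weight.
    """
    z_draws = np.asarray(z_draws, dtype=float)
    return z_draws.reshape(-1, *z_draws.shape[-2:]).mean(axis=0)


# ---------------------------------------------------------------------------
# CSV schemas
# ---------------------------------------------------------------------------

_RECORD_COLS = ["record_id", "site_id", "site_type", "period", "cell_id",
                "nsp_total", "detected"]


def write_records(records: pd.DataFrame, path) -> None:
    records[_RECORD_COLS].to_csv(path, index=False)


def read_records(path, allow_unknown_types: bool = False) -> pd.DataFrame:
    """Read and validate a detection-history table.

    Unrecognized site-type strings are rejected with the offending row
    unless ``allow_unknown_types`` maps them to "unknown" explicitly.
    """
    df = pd.read_csv(path)
    missing = set(_RECORD_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"records file lacks columns {sorted(missing)}")
    allowed = set(SITE_TYPES) | {UNKNOWN_TYPE, RANGE_MAP_TYPE}
    for i, row in df.iterrows():
        if row["nsp_total"] < 1:
            raise ValueError(
                f"row {i}: nsp_total = {row['nsp_total']} violates the "
                "NSP >= 1 invariant (every record has at least one bone)")
        if row["detected"] not in (0, 1):
            raise ValueError(f"row {i}: detected must be 0 or 1")
        if row["site_type"] not in allowed:
            if allow_unknown_types:
                df.at[i, "site_type"] = UNKNOWN_TYPE
            else:
                raise ValueError(
                    f"row {i}: unknown site type {row['site_type']!r} "
                    "(pass allow_unknown_types=True to map it to 'unknown')")
    return df


def write_covariates(cov: CovariateStack, path) -> None:
    n_cells, n_periods = cov.shape
    cell, period = np.meshgrid(np.arange(n_cells), np.arange(n_periods),
                               indexing="ij")
    pd.DataFrame({
        "cell_id": cell.ravel(), "period": period.ravel(),
        "lu": cov.lu.ravel(), "wt": cov.wt.ravel(),
        "npp": cov.npp.ravel(), "ele": cov.ele.ravel(),
    }).to_csv(path, index=False)


def read_covariates(path) -> CovariateStack:
    df = pd.read_csv(path)
    need = {"cell_id", "period", "lu", "wt", "npp", "ele"}
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"covariate file lacks columns {sorted(missing)}")
    cells = np.sort(df["cell_id"].unique())
    periods = np.sort(df["period"].unique())
    n_cells, n_periods = len(cells), len(periods)
    if len(df) != n_cells * n_periods:
        raise ValueError("covariate table is not a complete cell x period grid")
    df = df.sort_values(["cell_id", "period"])
    arrs = {c: df[c].to_numpy(dtype=float).reshape(n_cells, n_periods)
            for c in ("lu", "wt", "npp", "ele")}
    return CovariateStack(**arrs)


def write_terrain(terrain: TerrainGrid, path) -> None:
    pd.DataFrame({
        "cell_id": np.arange(terrain.n_cells),
        "x_km": terrain.x_km, "y_km": terrain.y_km,
        "elevation_m": terrain.elevation_m,
        "is_water": terrain.is_water.astype(int),
    }).to_csv(path, index=False)


def read_terrain(path, nx: int, ny: int, spacing_km: float = 100.0,
                 coarse_km: float = 100.0) -> TerrainGrid:
    df = pd.read_csv(path)
    need = {"cell_id", "x_km", "y_km", "elevation_m", "is_water"}
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"terrain file lacks columns {sorted(missing)}")
    df = df.sort_values("cell_id")
    return TerrainGrid(x_km=df["x_km"].to_numpy(), y_km=df["y_km"].to_numpy(),
                       elevation_m=df["elevation_m"].to_numpy(),
                       is_water=df["is_water"].to_numpy().astype(bool),
                       nx=nx, ny=ny, spacing_km=spacing_km, coarse_km=coarse_km)


_POP_COLS = ["population", "continent", "ls", "li", "fm_kg",
             "n_ls", "n_li", "n_fm", "lon", "lat", "npp", "t_ws"]


def write_population_table(table: pd.DataFrame, path) -> None:
    table[_POP_COLS].to_csv(path, index=False)


def read_population_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(_POP_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"population table lacks columns {sorted(missing)}")
    for i, row in df.iterrows():
        for c in ("ls", "li", "fm_kg"):
            if not row[c] > 0:
                raise ValueError(f"row {i}: {c} must be positive")
        for c in ("n_ls", "n_li", "n_fm"):
            if pd.notna(row[c]) and row[c] < 1:
                raise ValueError(f"row {i}: {c} must be >= 1 when present")
    return df


def write_effect_summary(decomp, inclusion_probs: dict, n_draws: int,
                         path, prior_inclusion: float = 0.5) -> None:
    """Effect-decomposition CSV: one row per direct/indirect/dampening
    effect with its posterior mean, 95% interval, and (for direct paths)
    the SSVS inclusion probability and Bayes factor."""
    rows = decomp.summary.copy()
    incl, bf = [], []
    for name in rows["effect_name"]:
        path_name = None
        if name.startswith("direct_"):
            path_name = "phi~" + name[len("direct_"):]
        if path_name and path_name in inclusion_probs:
            p = inclusion_probs[path_name]
            incl.append(p)
            bf.append(bayes_factor(p, prior_inclusion, n_draws=n_draws))
        else:
            incl.append(np.nan)
            bf.append(np.nan)
    rows["inclusion_prob"] = incl
    rows["bayes_factor"] = bf
    rows.to_csv(path, index=False)


def write_draws(draws: PosteriorDraws, path_long, path_wide=None) -> None:
    long = draws.to_long_dataframe()
    if draws.scenario_labels is not None:
        lab = np.array(draws.scenario_labels)
        long["scenario"] = lab[long["chain"].to_numpy()]
    elif draws.scenario is not None:
        long["scenario"] = draws.scenario
    long.to_csv(path_long, index=False)
    if path_wide is not None:
        wide = long.pivot_table(index=["chain", "iter"], columns="parameter",
                                values="value").reset_index()
        wide.to_csv(path_wide, index=False)


def read_draws_long(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    need = {"chain", "iter", "parameter", "value"}
    if need - set(df.columns):
        raise ValueError("draws file lacks required columns")
    return df


def write_diagnostics(diag: pd.DataFrame, path) -> None:
    diag.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Versioned run configuration loaded from a YAML file.

    Defaults mirror the study settings (seven Holocene periods, 10
    chains x 4,500 iterations, burn-in 2,000, thinning 25, Gamma(3,1)
    dispersal prior).
    """

    records_path: str | None = None
    covariates_path: str | None = None
    terrain_path: str | None = None
    population_path: str | None = None
    out_dir: str = "out"
    period_boundaries: list = field(default_factory=lambda: [
        [-10000, -7000], [-7000, -3000], [-3000, 0], [0, 1500],
        [1500, 1800], [1950, 1970], [2010, 2015]])
    mcmc: dict = field(default_factory=dict)
    scenarios: list = field(default_factory=lambda: [
        {"land_use_intensity": lu, "asian_colonization": asia}
        for lu in ("constant", "decreasing") for asia in ("yes", "no")])
    grid_scale: str = "desk"    # "desk" (12x12) or "full" (789-cell scale)
    verbosity: int = 1
    version: int = 1

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        bad = sorted(set(raw) - known)
        if bad:
            raise ValueError(f"unknown config keys: {bad}")
        cfg = cls(**raw)
        missing = [p for p in (cfg.records_path, cfg.covariates_path,
                               cfg.terrain_path, cfg.population_path)
                   if p is not None and not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"configured input files not found: {missing}")
        return cfg

    def scheme(self) -> PeriodScheme:
        return period_scheme_from_boundaries(self.period_boundaries)

    def mcmc_config(self, seed: int | None = None) -> MCMCConfig:
        kwargs = dict(self.mcmc)
        if seed is not None:
            kwargs["seed"] = seed
        return MCMCConfig(**kwargs)

    def to_yaml(self, path) -> None:
        from dataclasses import asdict
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
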