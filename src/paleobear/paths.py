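"""Bayesian path analysis and spike-and-slab variable selection.

The path model embeds three Gaussian regressions among the standardized
covariates -- WT on ELE; NPP on WT and ELE; LU on NPP, WT and ELE --
each with a grid-cell random effect, alongside the four extinction-rate
slopes of the occupancy model.  Together these give 10 candidate causal
paths.  Each path slope carries a spike-and-slab mixture prior

    P(beta_j | I_j) = (1 - I_j) Normal(0, precision tau_beta)
                    +      I_j  Normal(0, sd sigma_beta)

with binary inclusion indicators I_j (prior inclusion probability 0.5),
a fixed spike precision tau_beta = 3600 (spike sd 1/60), and a single
slab sd sigma_beta ~ Uniform(0, 20) shared by all 10 slopes ("global
adaptation": the slab scale adapts to the included coefficients jointly,
shrinking each towards the region supported by the others).

Inclusion is summarized by Bayes factors (posterior odds over prior
odds) and effects are decomposed per posterior draw into direct effects
on the extinction rate and indirect effects mediated by land use (and,
for winter temperature, by NPP).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PATH_NAMES",
    "PathModel",
    "SSVSConfig",
    "EffectDecomposition",
    "path_means",
    "ssvs_prior_density",
    "update_inclusion_indicator",
    "bayes_factor",
    "enumerate_model_space",
    "decompose_effects",
]

#: The 10 candidate paths, named response~predictor.
PATH_NAMES = (
    "wt~ele",
    "npp~wt", "npp~ele",
    "lu~npp", "lu~wt", "lu~ele",
    "phi~lu", "phi~npp", "phi~wt", "phi~ele",
)

SPIKE_PRECISION = 3600.0  # spike part: Normal(0, precision 3600), sd 1/60
SLAB_SD_MAX = 20.0        # slab sd ~ Uniform(0, 20)


@dataclass
class SSVSConfig:
    prior_inclusion: float = 0.5
    spike_precision: float = SPIKE_PRECISION
    slab_sd_max: float = SLAB_SD_MAX
    report_threshold: float = 0.95  # posterior inclusion for a "selected" path

    def __post_init__(self) -> None:
        if not 0.0 < self.prior_inclusion < 1.0:
            raise ValueError("prior inclusion probability must lie in (0, 1)")
        if self.spike_precision <= 0:
            raise ValueError("spike precision must be positive")

    @property
    def spike_sd(self) -> float:
        return self.spike_precision ** -0.5


@dataclass
class PathModel:
    """Parameters of the path system: 10 path slopes, three regression
    intercepts, residual precisions, cell random effects and the binary
    inclusion indicators."""

    slopes: dict = field(default_factory=lambda: {k: 0.0 for k in PATH_NAMES})
    intercepts: dict = field(default_factory=lambda: {"wt": 0.0, "npp": 0.0, "lu": 0.0})
    precisions: dict = field(default_factory=lambda: {"wt": 1.0, "npp": 1.0, "lu": 1.0})
    cell_effects: dict = field(default_factory=dict)   # eq -> (S,) arrays
    cell_precisions: dict = field(default_factory=lambda: {"wt": 1.0, "npp": 1.0, "lu": 1.0})
    indicators: dict = field(default_factory=lambda: {k: 1 for k in PATH_NAMES})

    def __post_init__(self) -> None:
        missing = set(PATH_NAMES) - set(self.slopes)
        if missing:
            raise ValueError(f"missing path slopes: {sorted(missing)}")
        if any(v not in (0, 1) for v in self.indicators.values()):
            raise ValueError("indicators must be binary")
        if any(v <= 0 for v in self.precisions.values()):
            raise ValueError("residual precisions must be positive")


@dataclass
class EffectDecomposition:
    """Per-draw direct/indirect effects on the extinction rate and their
    summaries (mean and central 95% interval)."""

    draws: pd.DataFrame          # one column per effect, one row per draw
    summary: pd.DataFrame        # effect_name, kind, mean, ci_low, ci_high
    n_dampening_excluded: int    # draws dropped because the direct WT effect was 0


def path_means(cov, params: PathModel) -> dict:
    """Gaussian mean surfaces of the three covariate regressions.

    Returns {"wt": mu_WT, "npp": mu_NPP, "lu": mu_LU}, each of shape
    (S, T):

        mu_WT  = b_WT,0  + b_WT,ELE  ELE + cell_WT
        mu_NPP = b_NPP,0 + b_NPP,WT  WT  + b_NPP,ELE ELE + cell_NPP
        mu_LU  = b_LU,0  + b_LU,NPP  NPP + b_LU,WT  WT + b_LU,ELE ELE + cell_LU
    """
    s = params.slopes
    ele, wt, npp = cov.ele, cov.wt, cov.npp
    n_cells = ele.shape[0]
    cells = {}
    for eq in ("wt", "npp", "lu"):
        c = params.cell_effects.get(eq)
        c = np.zeros(n_cells) if c is None else np.asarray(c, dtype=float)
        if len(c) != n_cells:
            raise ValueError(f"cell effect for {eq!r} has wrong length")
        cells[eq] = c[:, None]
    mu_wt = params.intercepts["wt"] + s["wt~ele"] * ele + cells["wt"]
    mu_npp = (params.intercepts["npp"] + s["npp~wt"] * wt
              + s["npp~ele"] * ele + cells["npp"])
    mu_lu = (params.intercepts["lu"] + s["lu~npp"] * npp + s["lu~wt"] * wt
             + s["lu~ele"] * ele + cells["lu"])
    return {"wt": mu_wt, "npp": mu_npp, "lu": mu_lu}


def _normal_logpdf(x, sd):
    return -0.5 * np.log(2.0 * np.pi) - np.log(sd) - 0.5 * (x / sd) ** 2


def ssvs_prior_density(beta_j: float, indicator: int, slab_sd: float,
                       config: SSVSConfig | None = None) -> float:
    """Density of the spike-and-slab prior at ``beta_j`` given I_j.

    I_j = 0: Normal(0, sd = spike_precision^-1/2 = 1/60);
    I_j = 1: Normal(0, sd = slab_sd).
    """
    config = config or SSVSConfig()
    if not 0.0 < slab_sd <= config.slab_sd_max:
        raise ValueError(f"slab sd must lie in (0, {config.slab_sd_max}]")
    sd = config.spike_sd if indicator == 0 else slab_sd
    return float(np.exp(_normal_logpdf(beta_j, sd)))


def update_inclusion_indicator(beta_j: float, slab_sd: float,
                               rng: np.random.Generator,
                               prior_inclusion: float = 0.5,
                               config: SSVSConfig | None = None) -> int:
    """Gibbs draw of the inclusion indicator given the current slope.

    P(I_j = 1 | beta_j) = p N(beta_j; 0, slab) /
                          (p N(beta_j; 0, slab) + (1-p) N(beta_j; 0, spike)).
    Computed on log scale so huge density ratios do not overflow.
    """
    config = config or SSVSConfig()
    if prior_inclusion >= 1.0:
        return 1
    if prior_inclusion <= 0.0:
        return 0
    log_slab = _normal_logpdf(beta_j, slab_sd) + np.log(prior_inclusion)
    log_spike = _normal_logpdf(beta_j, config.spike_sd) + np.log1p(-prior_inclusion)
    m = max(log_slab, log_spike)
    p1 = np.exp(log_slab - m) / (np.exp(log_slab - m) + np.exp(log_spike - m))
    return int(rng.random() < p1)


def inclusion_posterior(beta_j: float, slab_sd: float,
                        prior_inclusion: float = 0.5,
                        config: SSVSConfig | None = None) -> float:
    """P(I_j = 1 | beta_j), the exact Bernoulli conditional of the Gibbs step."""
    config = config or SSVSConfig()
    log_slab = _normal_logpdf(beta_j, slab_sd) + np.log(prior_inclusion)
    log_spike = _normal_logpdf(beta_j, config.spike_sd) + np.log1p(-prior_inclusion)
    m = max(log_slab, log_spike)
    return float(np.exp(log_slab - m) / (np.exp(log_slab - m) + np.exp(log_spike - m)))


def bayes_factor(posterior_inclusion: float, prior_inclusion: float = 0.5,
                 n_draws: int | None = None) -> float:
    """Bayes factor for a path: posterior odds over prior odds.

    ``posterior_inclusion`` is clipped to [1/(2M), 1 - 1/(2M)] when the
    number of posterior draws M is given, so an indicator that never (or
    always) switched yields a finite factor.
    """
    p = float(posterior_inclusion)
    if not 0.0 <= p <= 1.0:
        raise ValueError("posterior inclusion probability must lie in [0, 1]")
    if n_draws is not None:
        lo = 1.0 / (2.0 * n_draws)
        p = min(max(p, lo), 1.0 - lo)
    prior_odds = prior_inclusion / (1.0 - prior_inclusion)
    return (p / (1.0 - p)) / prior_odds


def enumerate_model_space(n_paths: int = 10) -> int:
    """Number of candidate models: every subset of the paths, 2**n."""
    if n_paths < 0:
        raise ValueError("n_paths must be >= 0")
    return 2 ** n_paths


def decompose_effects(draws: pd.DataFrame,
                      dampening: str = "vs_direct") -> EffectDecomposition:
    """Decompose posterior path-slope draws into direct/indirect effects.

    ``draws`` has one column per path (named as in :data:`PATH_NAMES`)
    and one row per posterior draw.  Per draw:

    * direct(X) = beta_phi,X for X in {LU, WT, NPP, ELE};
    * indirect(X via LU) = beta_LU,X * beta_phi,LU for X in {WT, NPP, ELE};
    * indirect(WT via NPP) = beta_NPP,WT * beta_phi,NPP;
    * dampening% of the WT effect by NPP, either
      100 |indirect via NPP| / |direct WT|            (``vs_direct``) or
      100 |indirect via NPP| / |direct + indirect WT| (``vs_total``).

    Draws with a zero direct WT effect have no defined dampening and are
    excluded from its summary; the count is reported.
    """
    if dampening not in ("vs_direct", "vs_total"):
        raise ValueError("dampening must be 'vs_direct' or 'vs_total'")
    d = draws
    out = pd.DataFrame(index=d.index)
    for x in ("lu", "wt", "npp", "ele"):
        out[f"direct_{x}"] = d[f"phi~{x}"]
    for x in ("wt", "npp", "ele"):
        out[f"indirect_{x}_via_lu"] = d[f"lu~{x}"] * d["phi~lu"]
    out["indirect_wt_via_npp"] = d["npp~wt"] * d["phi~npp"]

    direct_wt = out["direct_wt"].to_numpy()
    ind = out["indirect_wt_via_npp"].to_numpy()
    denom = np.abs(direct_wt) if dampening == "vs_direct" else np.abs(direct_wt + ind)
    ok = denom > 0
    damp = np.full(len(out), np.nan)
    damp[ok] = 100.0 * np.abs(ind[ok]) / denom[ok]
    out["dampening_pct"] = damp
    n_excluded = int((~ok).sum())

    rows = []
    for col in out.columns:
        vals = out[col].dropna().to_numpy()
        kind = ("dampening" if col == "dampening_pct"
                else "indirect" if col.startswith("indirect") else "direct")
        rows.append({
            "effect_name": col, "kind": kind,
            "mean": float(np.mean(vals)),
            "ci_low": float(np.percentile(vals, 2.5)),
            "ci_high": float(np.percentile(vals, 97.5)),
        })
    summary = pd.DataFrame(rows)
    return EffectDecomposition(draws=out, summary=summary,
                               n_dampening_excluded=n_excluded)
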