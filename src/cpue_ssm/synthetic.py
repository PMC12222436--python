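"""Seeded generative emulation of the multi-taxon fishery panel.

Runs the state-space model forward with known parameters: latent log-CPUE
random walks with period-switching drift and a temperature-anomaly term,
Poisson effort counts on a latent log random walk (with designated missing
years), and a trending annual temperature series.  Every latent quantity is
retained in a truth record so downstream estimates can be checked against
the generating values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import covariates as cov
from .io import FisheryPanel

__all__ = [
    "SimulationConfig",
    "SyntheticPanel",
    "simulate_effort",
    "simulate_temperature",
    "simulate_community",
    "group_structured_config",
]


@dataclass
class SimulationConfig:
    """All knobs of the generative model.

    ``theta_means`` rows are per-taxon means of ``(beta1, beta2, beta3,
    gamma)``; per-replicate taxon coefficients are drawn around them with
    covariance ``theta_cov`` (set to zeros for fixed coefficients).
    ``beta4`` is NaN for taxa without a restoration period.
    """

    taxa: tuple[str, ...]
    theta_means: np.ndarray          # (n_taxa, 4)
    beta4: np.ndarray                # (n_taxa,), NaN where absent
    sigma_x: np.ndarray              # (n_taxa,) process SD of log CPUE
    sigma_y: np.ndarray              # (n_taxa,) observation SD of log catch
    sigma_lambda: float = 0.05       # process SD of log expected effort
    lambda1: float = 120.0           # initial expected effort (fishers)
    theta_cov: np.ndarray = field(default_factory=lambda: np.zeros((4, 4)))
    year_start: int = cov.DEFAULT_YEAR_START
    year_end: int = cov.DEFAULT_YEAR_END
    period4_starts: Mapping[str, int] = field(default_factory=dict)
    effort_missing_years: tuple[int, ...] = ()
    temp_base: float = 14.0          # temperature in the first year (deg C)
    temp_trend: float = 0.03         # deg C per year
    temp_noise_sd: float = 0.35
    log_cpue_init: np.ndarray | None = None  # (n_taxa,) initial log CPUE
    zero_years: Mapping[str, Sequence[int]] = field(default_factory=dict)
    zero_floor: float = 50.0

    def __post_init__(self) -> None:
        self.taxa = tuple(str(t) for t in self.taxa)
        n = len(self.taxa)
        self.theta_means = np.asarray(self.theta_means, dtype=float)
        self.beta4 = np.asarray(self.beta4, dtype=float)
        self.sigma_x = np.broadcast_to(np.asarray(self.sigma_x, float), (n,)).copy()
        self.sigma_y = np.broadcast_to(np.asarray(self.sigma_y, float), (n,)).copy()
        self.theta_cov = np.asarray(self.theta_cov, dtype=float)
        if self.theta_means.shape != (n, 4):
            raise ValueError(f"theta_means must have shape ({n}, 4)")
        if self.beta4.shape != (n,):
            raise ValueError(f"beta4 must have shape ({n},)")
        for name, arr in (("sigma_x", self.sigma_x), ("sigma_y", self.sigma_y)):
            if (arr < 0).any() or not np.isfinite(arr).all():
                raise ValueError(f"{name} must be finite and >= 0")
        if self.sigma_lambda < 0:
            raise ValueError("sigma_lambda must be >= 0")
        if self.lambda1 <= 0:
            raise ValueError("lambda1 must be > 0")
        if not np.allclose(self.theta_cov, self.theta_cov.T):
            raise ValueError("theta_cov must be symmetric")
        if np.linalg.eigvalsh(self.theta_cov).min() < -1e-10:
            raise ValueError("theta_cov must be positive semi-definite")
        if not np.isfinite(self.theta_means).all():
            raise ValueError("theta_means must be finite")
        years = set(self.years())
        bad = [y for y in self.effort_missing_years if y not in years]
        if bad:
            raise ValueError(f"missing-effort years outside range: {bad}")
        if self.log_cpue_init is None:
            self.log_cpue_init = np.full(n, 7.0)
        self.log_cpue_init = np.broadcast_to(
            np.asarray(self.log_cpue_init, float), (n,)
        ).copy()

    def years(self) -> np.ndarray:
        return np.arange(self.year_start, self.year_end + 1)

    def schemes(self) -> list[cov.PeriodScheme]:
        out = []
        for t in self.taxa:
            if t in self.period4_starts:
                out.append(
                    cov.restoration_scheme(
                        t, self.period4_starts[t], self.year_start, self.year_end
                    )
                )
            else:
                out.append(cov.default_scheme(t, self.year_start, self.year_end))
        return out


@dataclass
class SyntheticPanel:
    """A generated panel plus the latent truth behind it."""

    panel: FisheryPanel
    truth: dict

    def truth_json(self) -> str:
        import json

        def _default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.integer, np.floating)):
                return o.item()
            raise TypeError(type(o))

        return json.dumps(self.truth, default=_default, indent=1)


def simulate_temperature(config: SimulationConfig, rng: np.random.Generator) -> pd.Series:
    """Annual temperature: linear trend plus iid Gaussian noise."""
    years = config.years()
    t = years - years[0]
    temp = config.temp_base + config.temp_trend * t
    if config.temp_noise_sd > 0:
        temp = temp + rng.normal(0.0, config.temp_noise_sd, size=len(years))
    return pd.Series(temp, index=years, name="temp_c")


def simulate_effort(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[pd.Series, dict]:
    """Poisson effort on a latent log random walk.

    Returns the observed series (NaN at the configured missing years) and a
    truth dict holding the full latent intensity and count series.
    """
    years = config.years()
    n = len(years)
    log_lam = np.empty(n)
    log_lam[0] = np.log(config.lambda1)
    if n > 1:
        steps = rng.normal(0.0, config.sigma_lambda, size=n - 1)
        log_lam[1:] = log_lam[0] + np.cumsum(steps)
    lam = np.exp(log_lam)
    z = rng.poisson(lam).astype(float)
    z = np.maximum(z, 1.0)  # a recorded fishery year implies >= 1 fisher
    observed = pd.Series(z.copy(), index=years, name="n_fishers")
    for y in config.effort_missing_years:
        observed.loc[y] = np.nan
    truth = {"log_lambda": log_lam, "lambda": lam, "z_full": z}
    return observed, truth


def simulate_community(config: SimulationConfig, seed: int | np.random.Generator) -> SyntheticPanel:
    """Generate a full synthetic panel from the exact generative model."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    years = config.years()
    n_i, n_t = len(config.taxa), len(years)

    temp = simulate_temperature(config, rng)
    effort, effort_truth = simulate_effort(config, rng)
    schemes = config.schemes()
    U = cov.design_matrix(schemes, temp, years)

    # per-replicate taxon coefficients around the configured means
    if np.any(config.theta_cov):
        theta4 = config.theta_means + rng.multivariate_normal(
            np.zeros(4), config.theta_cov, size=n_i, method="cholesky"
        )
    else:
        theta4 = config.theta_means.copy()
    theta = np.zeros((n_i, 5))
    theta[:, :4] = theta4
    theta[:, 4] = np.where(np.isnan(config.beta4), 0.0, config.beta4)

    drift = np.einsum("itk,ik->it", U, theta)  # drift[:, 0] is zero
    log_x = np.empty((n_i, n_t))
    log_x[:, 0] = config.log_cpue_init
    shocks = rng.normal(0.0, 1.0, size=(n_i, n_t - 1)) * config.sigma_x[:, None]
    for t in range(1, n_t):
        log_x[:, t] = log_x[:, t - 1] + drift[:, t] + shocks[:, t - 1]

    z_full = effort_truth["z_full"]
    obs_noise = rng.normal(0.0, 1.0, size=(n_i, n_t)) * config.sigma_y[:, None]
    log_y = log_x + np.log(z_full)[None, :] + obs_noise
    catch = np.exp(log_y)

    catch_df = pd.DataFrame(catch.T, index=years, columns=list(config.taxa))
    for taxon, zyears in config.zero_years.items():
        for y in zyears:
            catch_df.loc[int(y), taxon] = 0.0

    panel = FisheryPanel(catch=catch_df, effort=effort, temperature=temp)
    truth = {
        "taxa": list(config.taxa),
        "years": years,
        "theta": theta,                      # columns beta1,beta2,beta3,gamma,beta4
        "beta4_mask": (~np.isnan(config.beta4)).astype(int),
        "sigma_x": config.sigma_x,
        "sigma_y": config.sigma_y,
        "sigma_lambda": config.sigma_lambda,
        "log_cpue": log_x,
        "log_lambda": effort_truth["log_lambda"],
        "z_full": z_full,
        "theta_means": config.theta_means,
        "mu_beta_true": config.theta_means.mean(axis=0),
    }
    return SyntheticPanel(panel=panel, truth=truth)


def group_structured_config(
    n_group1: int = 5,
    n_group2: int = 3,
    within_sd: Sequence[float] = (0.02, 0.02, 0.02, 0.015),
    sigma_x: float = 0.10,
    sigma_y: float = 0.25,
    **overrides,
) -> SimulationConfig:
    """Default preset with two decline-timing groups.

    Group 1 taxa decline from period 2 onwards (beta2 and beta3 negative);
    group 2 taxa decline only in period 3 (beta3 negative).  One taxon per
    group carries a restoration period 4 with positive beta4.  Taxon order:
    group 1 first.
    """
    g1 = np.array([0.05, -0.30, -0.30, -0.04])
    g2 = np.array([0.04, 0.02, -0.30, -0.04])
    n = n_group1 + n_group2
    taxa = tuple(f"taxon_{i + 1}" for i in range(n))
    theta_means = np.vstack([np.tile(g1, (n_group1, 1)), np.tile(g2, (n_group2, 1))])
    beta4 = np.full(n, np.nan)
    period4_starts: dict[str, int] = {}
    if n_group1 >= 2:
        beta4[1] = 0.35                    # restoration taxon in group 1
        period4_starts[taxa[1]] = 2009
    if n_group2 >= 1:
        beta4[n_group1] = 0.35             # restoration taxon in group 2
        period4_starts[taxa[n_group1]] = 2012
    defaults = dict(
        taxa=taxa,
        theta_means=theta_means,
        beta4=beta4,
        sigma_x=np.full(n, sigma_x),
        sigma_y=np.full(n, sigma_y),
        theta_cov=np.diag(np.square(within_sd)),
        period4_starts=period4_starts,
        effort_missing_years=(1969, 1970, 1994),
        log_cpue_init=7.0 + 0.4 * np.linspace(-1, 1, n),
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)
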