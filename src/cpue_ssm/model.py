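"""Joint probability model: observation, process, effort, and prior layers.

Layers (all logs natural; catch in grams, effort in fishers):

* observation (t >= 2):   log y_it ~ N(log x_it + log z_t, sigma_y_i^2)
* process     (t >= 2):   log x_it ~ N(log x_{i,t-1} + R_it + S_it, sigma_x_i^2)
* effort count(t >= 1):   z_t ~ Poisson(lambda_t)   (zero-truncated when latent)
* effort walk (t >= 2):   log lambda_t ~ N(log lambda_{t-1}, sigma_lambda^2)
* community prior:        (beta1,beta2,beta3,gamma)_i ~ MVN(mu_beta, Sigma_beta)
* restoration effect:     beta4_i ~ N(0, beta4_sd^2) for restoration taxa

with R_it = beta1 + beta2*P2(t-1) + beta3*P3(t-1) [+ beta4*P4(t-1)] and
S_it = gamma * T_i(t-1).  Initial states carry vague Normal priors centred
on empirical proxies; hyperpriors are weakly informative (Normal mean,
inverse-Wishart covariance, uniform-on-SD scales).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, multigammaln

from . import covariates as cov
from .io import FisheryPanel

__all__ = [
    "PreparedData",
    "SSMParams",
    "LatentStates",
    "Priors",
    "preprocess_catch",
    "growth_mean",
    "climate_term",
    "log_joint",
    "prepare",
]

LOG_2PI = float(np.log(2.0 * np.pi))


def preprocess_catch(catch, floor: float = 50.0) -> np.ndarray:
    """Log-transform catch after replacing exact zeros with ``floor`` grams.

    Non-zero entries are unchanged before logging; negative entries raise.
    """
    arr = np.asarray(catch, dtype=float)
    if not np.isfinite(arr).all():
        raise ValueError("catch contains non-finite values")
    if (arr < 0).any():
        raise ValueError("catch contains negative values")
    out = np.where(arr == 0.0, float(floor), arr)
    return np.log(out)


def growth_mean(coefs: Sequence[float], indicators: Sequence[int]) -> float:
    """Period-specific drift R from coefficients ``(b1, b2, b3[, b4])``.

    ``indicators`` is the (P2, P3, P4) row of the *lagged* year.  Requesting
    a period-4 contribution from a taxon without ``b4`` raises.
    """
    coefs = [float(c) for c in coefs]
    p2, p3, p4 = (int(v) for v in indicators)
    if p2 + p3 + p4 > 1:
        raise ValueError("at most one period indicator may be 1")
    if len(coefs) not in (3, 4):
        raise ValueError("coefs must be (b1,b2,b3) or (b1,b2,b3,b4)")
    if p4 and len(coefs) < 4:
        raise ValueError("period-4 indicator set but taxon has no beta4")
    r = coefs[0] + coefs[1] * p2 + coefs[2] * p3
    if p4:
        r += coefs[3]
    return r


def climate_term(gamma: float, anomaly: float) -> float:
    """Temperature contribution S = gamma * anomaly (lagged year)."""
    if not np.isfinite(anomaly):
        raise ValueError("anomaly must be finite")
    return float(gamma) * float(anomaly)


@dataclass
class PreparedData:
    """Validated model inputs on the transformed scale."""

    taxa: tuple[str, ...]
    years: np.ndarray
    log_catch: np.ndarray        # (n_taxa, n_years)
    effort: np.ndarray           # (n_years,), NaN at missing years
    U: np.ndarray                # (n_taxa, n_years, 5) lagged drift design
    restoration: np.ndarray      # (n_taxa,) bool
    schemes: tuple[cov.PeriodScheme, ...]
    temperature: pd.Series

    def __post_init__(self) -> None:
        if not np.isfinite(self.log_catch).all():
            raise ValueError("log catch must be finite (apply the zero floor)")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_years(self) -> int:
        return len(self.years)

    @property
    def observed_mask(self) -> np.ndarray:
        return ~np.isnan(self.effort)

    @property
    def missing_years(self) -> np.ndarray:
        return self.years[~self.observed_mask]

    def effort_filled(self) -> np.ndarray:
        """Effort with missing years filled by linear interpolation."""
        obs = self.observed_mask
        if obs.all():
            return self.effort.copy()
        idx = np.arange(self.n_years)
        return np.interp(idx, idx[obs], self.effort[obs])


def prepare(
    panel: FisheryPanel,
    schemes: Sequence[cov.PeriodScheme] | None = None,
    floor: float = 50.0,
    period4_starts: dict[str, int] | None = None,
) -> PreparedData:
    """Build `PreparedData` from a validated panel."""
    taxa = panel.taxa
    years = panel.years
    if schemes is None:
        period4_starts = period4_starts or {}
        schemes = [
            cov.restoration_scheme(t, period4_starts[t], years[0], years[-1])
            if t in period4_starts
            else cov.default_scheme(t, years[0], years[-1])
            for t in taxa
        ]
    by_id = {s.taxon_id: s for s in schemes}
    missing = [t for t in taxa if t not in by_id]
    if missing:
        raise ValueError(f"no period scheme for taxa {missing}")
    schemes = tuple(by_id[t] for t in taxa)
    log_catch = preprocess_catch(panel.catch.to_numpy().T, floor=floor)
    U = cov.design_matrix(schemes, panel.temperature, years)
    restoration = np.array([s.has_period4 for s in schemes])
    return PreparedData(
        taxa=taxa,
        years=np.asarray(years),
        log_catch=log_catch,
        effort=panel.effort.to_numpy(dtype=float),
        U=U,
        restoration=restoration,
        schemes=schemes,
        temperature=panel.temperature,
    )


@dataclass
class SSMParams:
    """All non-state unknowns.

    ``theta`` columns are ``(beta1, beta2, beta3, gamma, beta4)``; the
    ``beta4`` column is ignored for non-restoration taxa.
    """

    theta: np.ndarray            # (n_taxa, 5)
    sigma_y: np.ndarray          # (n_taxa,)
    sigma_x: np.ndarray          # (n_taxa,)
    sigma_lambda: float
    mu_beta: np.ndarray          # (4,)
    Sigma_beta: np.ndarray       # (4, 4)

    def validate(self) -> None:
        if (np.asarray(self.sigma_y) <= 0).any() or (np.asarray(self.sigma_x) <= 0).any():
            raise ValueError("sigma_y and sigma_x must be > 0")
        if self.sigma_lambda <= 0:
            raise ValueError("sigma_lambda must be > 0")
        S = np.asarray(self.Sigma_beta)
        if not np.allclose(S, S.T):
            raise ValueError("Sigma_beta must be symmetric")
        if np.linalg.eigvalsh(S).min() <= 0:
            raise ValueError("Sigma_beta must be positive definite")


@dataclass
class LatentStates:
    """Latent trajectories and missing effort counts."""

    log_cpue: np.ndarray         # (n_taxa, n_years)
    log_lambda: np.ndarray       # (n_years,)
    z_missing: np.ndarray        # counts at missing-effort years, >= 1

    def validate(self) -> None:
        if not (np.isfinite(self.log_cpue).all() and np.isfinite(self.log_lambda).all()):
            raise ValueError("latent states must be finite")
        if (np.asarray(self.z_missing) < 1).any():
            raise ValueError("latent effort counts must be >= 1")


@dataclass
class Priors:
    """Hyperprior and initial-condition settings (all configurable)."""

    mu0: np.ndarray = field(default_factory=lambda: np.zeros(4))
    tau0: float = 10.0           # prior SD of each mu_beta component
    nu0: float = 6.0             # inverse-Wishart dof (p + 2 -> mean = Psi0)
    Psi0: np.ndarray = field(default_factory=lambda: 0.01 * np.eye(4))
    beta4_sd: float = 10.0
    sd_max: float = 5.0          # uniform-on-SD upper bound for all sigmas
    init_sd: float = 10.0        # SD of the vague initial-state priors


def _norm_logpdf(x, mean, sd):
    z = (np.asarray(x) - mean) / sd
    return -0.5 * z * z - np.log(sd) - 0.5 * LOG_2PI


def _mvn_logpdf(x, mean, covariance):
    d = np.asarray(x, float) - np.asarray(mean, float)
    sign, logdet = np.linalg.slogdet(covariance)
    if sign <= 0:
        raise ValueError("covariance must be positive definite")
    sol = np.linalg.solve(covariance, d)
    return -0.5 * (len(d) * LOG_2PI + logdet + d @ sol)


def _invwishart_logpdf(X, df, scale):
    p = X.shape[0]
    sign_x, logdet_x = np.linalg.slogdet(X)
    sign_s, logdet_s = np.linalg.slogdet(scale)
    if sign_x <= 0 or sign_s <= 0:
        raise ValueError("inverse-Wishart arguments must be positive definite")
    tr = np.trace(np.linalg.solve(X, scale))
    return (
        0.5 * df * logdet_s
        - 0.5 * (df * p) * np.log(2.0)
        - multigammaln(0.5 * df, p)
        - 0.5 * (df + p + 1) * logdet_x
        - 0.5 * tr
    )


def log_joint(
    params: SSMParams,
    states: LatentStates,
    data: PreparedData,
    priors: Priors | None = None,
) -> float:
    """Evaluate the full log joint density (model + priors).

    Additive over taxa and years; finite on the valid domain.  Parameter
    validity is enforced at the boundary (validation error), the density
    itself is evaluated only on the interior.
    """
    priors = priors or Priors()
    params.validate()
    states.validate()
    n_i, n_t = data.n_taxa, data.n_years
    a = states.log_cpue
    ell = states.log_lambda
    obs_mask = data.observed_mask

    for arr, sd_name in ((params.sigma_y, "sigma_y"), (params.sigma_x, "sigma_x")):
        if (np.asarray(arr) >= priors.sd_max).any():
            return -np.inf
    if params.sigma_lambda >= priors.sd_max:
        return -np.inf

    z = np.where(obs_mask, data.effort, 0.0)
    z[~obs_mask] = states.z_missing
    log_z = np.log(z)
    lam = np.exp(ell)

    total = 0.0
    # observation layer, t >= 2
    mu_obs = a[:, 1:] + log_z[None, 1:]
    total += _norm_logpdf(data.log_catch[:, 1:], mu_obs, params.sigma_y[:, None]).sum()
    # process layer, t >= 2
    drift = np.einsum("itk,ik->it", data.U, params.theta)
    mu_proc = a[:, :-1] + drift[:, 1:]
    total += _norm_logpdf(a[:, 1:], mu_proc, params.sigma_x[:, None]).sum()
    # effort count layer (Poisson; zero-truncated where latent)
    total += float(np.sum(z * ell - lam - gammaln(z + 1.0)))
    if (~obs_mask).any():
        total -= float(np.sum(np.log(-np.expm1(-lam[~obs_mask]))))
    # effort walk, t >= 2
    total += _norm_logpdf(ell[1:], ell[:-1], params.sigma_lambda).sum()
    # initial conditions (vague, empirically centred)
    z_fill = data.effort_filled()
    m0 = data.log_catch[:, 0] - np.log(z_fill[0])
    total += _norm_logpdf(a[:, 0], m0, priors.init_sd).sum()
    first_obs = data.effort[obs_mask][0]
    total += float(_norm_logpdf(ell[0], np.log(first_obs), priors.init_sd))
    # community prior on (beta1, beta2, beta3, gamma)
    for i in range(n_i):
        total += _mvn_logpdf(params.theta[i, :4], params.mu_beta, params.Sigma_beta)
    # restoration effects
    for i in np.flatnonzero(data.restoration):
        total += float(_norm_logpdf(params.theta[i, 4], 0.0, priors.beta4_sd))
    # hyperpriors
    total += _norm_logpdf(params.mu_beta, priors.mu0, priors.tau0).sum()
    total += _invwishart_logpdf(params.Sigma_beta, priors.nu0, priors.Psi0)
    # uniform-on-SD priors contribute a constant
    n_sd = 2 * n_i + 1
    total += -n_sd * np.log(priors.sd_max)
    return float(total)
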