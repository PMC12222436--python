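"""Blocked Gibbs sampler for the hierarchical CPUE state-space model.

All chains are advanced simultaneously (leading batch axis = chain), which
keeps the per-iteration Python overhead independent of the chain count.

Update blocks per sweep:

1. taxon coefficient vectors — conjugate Gaussian regression update
   (forward-shifted first differences of latent log CPUE on the lagged
   period/anomaly design);
2. latent log-CPUE paths — forward-filter backward-sample (FFBS), exact
   because the model is conditionally linear-Gaussian given effort;
3. variances — conjugate (truncated) inverse-gamma under uniform-on-SD
   priors;
4. community hyper-mean and covariance — conjugate Normal and
   inverse-Wishart (Bartlett) updates;
5. latent log effort intensity — even/odd adaptive Metropolis (the Poisson
   layer breaks conjugacy); latent effort counts at missing years —
   integer random-walk Metropolis.

The zero-truncation correction of the latent Poisson counts is omitted
from the intensity update: for the intensities in scope (tens to hundreds
of fishers) the term is below double precision.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.special import gammaln

from .model import PreparedData, Priors

__all__ = ["SamplerConfig", "run_gibbs"]


@dataclass
class SamplerConfig:
    """MCMC schedule and update switches."""

    n_chains: int = 4
    n_warmup: int = 1000
    n_draws: int = 4000
    thin: int = 1
    update_coefs: bool = True
    update_states: bool = True
    update_variances: bool = True
    update_hyper: bool = True
    update_effort: bool = True

    def __post_init__(self) -> None:
        if self.n_chains < 1 or self.n_draws < 1 or self.thin < 1:
            raise ValueError("invalid sampler schedule")


def _sample_trunc_invgamma(rng, shape, rate, upper, out_shape):
    """Inverse-gamma(shape, rate) truncated to values <= upper."""
    val = rate / rng.gamma(shape, 1.0, size=out_shape)
    bad = val > upper
    tries = 0
    while bad.any():
        val[bad] = (rate[bad] if np.ndim(rate) else rate) / rng.gamma(
            shape[bad] if np.ndim(shape) else shape, 1.0, size=int(bad.sum())
        )
        bad = val > upper
        tries += 1
        if tries > 1000:  # prior truncation nearly never binds in practice
            val = np.minimum(val, upper)
            break
    return val


def _sample_invwishart(rng, df, scale):
    """Batched inverse-Wishart draws via the Bartlett decomposition.

    ``scale`` has shape (C, p, p); returns (C, p, p).
    """
    C, p, _ = scale.shape
    L = np.linalg.cholesky(np.linalg.inv(scale))
    A = np.zeros((C, p, p))
    rows, cols = np.tril_indices(p, k=-1)
    A[:, rows, cols] = rng.standard_normal((C, len(rows)))
    dfs = df - np.arange(p)
    A[:, np.arange(p), np.arange(p)] = np.sqrt(
        rng.chisquare(np.broadcast_to(dfs, (C, p)))
    )
    LA = L @ A
    W = LA @ LA.transpose(0, 2, 1)
    return np.linalg.inv(W)


def _ffbs(rng, d, drift, sig2x, sig2y, m0, s0sq):
    """Exact draw of the latent log-CPUE paths given everything else.

    ``d`` is log catch minus log effort, shape (C, I, T); the observation
    layer applies from the second year on, the first year carries only the
    vague initial prior centred at ``m0``.
    """
    C, I, T = d.shape
    ms = np.empty((T, C, I))
    Ps = np.empty((T, C, I))
    m = np.broadcast_to(m0, (C, I)).astype(float).copy()
    P = np.full((C, I), float(s0sq))
    ms[0], Ps[0] = m, P
    for t in range(1, T):
        mp = m + drift[:, :, t]
        Pp = P + sig2x
        K = Pp / (Pp + sig2y)
        m = mp + K * (d[:, :, t] - mp)
        P = (1.0 - K) * Pp
        ms[t], Ps[t] = m, P
    a = np.empty((C, I, T))
    eps = rng.standard_normal((T, C, I))
    a[:, :, T - 1] = ms[T - 1] + np.sqrt(Ps[T - 1]) * eps[T - 1]
    for t in range(T - 2, -1, -1):
        denom = Ps[t] + sig2x
        J = Ps[t] / denom
        mean = ms[t] + J * (a[:, :, t + 1] - drift[:, :, t + 1] - ms[t])
        var = Ps[t] * sig2x / denom
        a[:, :, t] = mean + np.sqrt(var) * eps[t]
    return a


def _kalman_loglik(d, drift, sig2x, sig2y, m0, s0sq):
    """Marginal log likelihood of the observation rows given variances.

    Integrates the latent log-CPUE path out of the conditionally
    linear-Gaussian model by a forward Kalman pass; shapes as in `_ffbs`.
    Returns (C, I).
    """
    C, I, T = d.shape
    m = np.broadcast_to(m0, (C, I)).astype(float).copy()
    P = np.full((C, I), float(s0sq))
    ll = np.zeros((C, I))
    for t in range(1, T):
        mp = m + drift[:, :, t]
        Pp = P + sig2x
        S = Pp + sig2y
        v = d[:, :, t] - mp
        ll += -0.5 * (np.log(2.0 * np.pi * S) + v * v / S)
        K = Pp / S
        m = mp + K * v
        P = Pp - K * Pp
    return ll


def _update_theta_group(rng, theta, a_diff, U, G, idx, sig2x, prior_prec, prior_b, k):
    """Conjugate update of coefficient vectors for one taxon group.

    ``prior_prec``: (C, k, k); ``prior_b``: (C, k) = prior_prec @ prior_mean.
    """
    C = sig2x.shape[0]
    w = a_diff[:, idx]                                # (C, g, T-1)
    Uw = np.einsum("gtk,cgt->cgk", U[idx, 1:, :k], w)
    inv_s2 = 1.0 / sig2x[:, idx]
    Prec = prior_prec[:, None] + G[None] * inv_s2[:, :, None, None]
    b = Uw * inv_s2[:, :, None] + prior_b[:, None, :]
    V = np.linalg.inv(Prec)
    mean = np.einsum("cgkl,cgl->cgk", V, b)
    Lv = np.linalg.cholesky(V)
    eps = rng.standard_normal(mean.shape)
    theta[:, idx, :k] = mean + np.einsum("cgkl,cgl->cgk", Lv, eps)


def run_gibbs(
    data: PreparedData,
    priors: Priors,
    config: SamplerConfig,
    rng: np.random.Generator,
    fixed: Mapping[str, np.ndarray] | None = None,
) -> dict[str, np.ndarray]:
    """Run the sampler; returns draws keyed by quantity, shaped (C, D, ...).

    ``fixed`` may pin ``theta`` (I, 5), ``sigma_y``/``sigma_x`` (I,), or
    ``sigma_lambda`` (scalar) at known values (their updates are skipped).
    """
    fixed = dict(fixed or {})
    C = config.n_chains
    I, T = data.n_taxa, data.n_years
    U = data.U
    log_catch = data.log_catch
    obs_mask = data.observed_mask
    m_idx = np.flatnonzero(~obs_mask)
    M = len(m_idx)
    z_obs = np.where(obs_mask, data.effort, 1.0)

    idxR = np.flatnonzero(data.restoration)
    idxN = np.flatnonzero(~data.restoration)
    G_N = np.einsum("itk,itl->ikl", U[idxN, 1:, :4], U[idxN, 1:, :4]) if len(idxN) else None
    G_R = np.einsum("itk,itl->ikl", U[idxR, 1:, :5], U[idxR, 1:, :5]) if len(idxR) else None

    z_fill = data.effort_filled()
    m0 = log_catch[:, 0] - np.log(z_fill[0])
    s0sq = priors.init_sd**2
    ell0_mean = float(np.log(data.effort[obs_mask][0]))
    sd2_max = priors.sd_max**2

    # ---- initial state (overdispersed across chains) --------------------
    a = log_catch[None] - np.log(z_fill)[None, None, :] + 0.2 * rng.standard_normal((C, I, T))
    theta = 0.05 * rng.standard_normal((C, I, 5))
    theta[:, idxN, 4] = 0.0
    sig2x = (0.1 * np.exp(0.3 * rng.standard_normal((C, I)))) ** 2
    sig2y = (0.2 * np.exp(0.3 * rng.standard_normal((C, I)))) ** 2
    sig2lam = (0.05 * np.exp(0.3 * rng.standard_normal(C))) ** 2
    mu = 0.05 * rng.standard_normal((C, 4))
    Sigma = np.broadcast_to(0.01 * np.eye(4), (C, 4, 4)).copy()
    ell = np.log(z_fill)[None, :] + 0.05 * rng.standard_normal((C, T))
    zmis = np.maximum(np.round(z_fill[m_idx]), 1.0)[None, :].repeat(C, axis=0)
    scales = np.full((C, T), 0.1)
    var_scales = np.full((C, I), 0.2)

    if "theta" in fixed:
        theta = np.broadcast_to(np.asarray(fixed["theta"], float), (C, I, 5)).copy()
    if "sigma_y" in fixed:
        sig2y = np.broadcast_to(np.asarray(fixed["sigma_y"], float) ** 2, (C, I)).copy()
    if "sigma_x" in fixed:
        sig2x = np.broadcast_to(np.asarray(fixed["sigma_x"], float) ** 2, (C, I)).copy()
    if "sigma_lambda" in fixed:
        sig2lam = np.full(C, float(fixed["sigma_lambda"]) ** 2)

    even = np.arange(0, T, 2)
    odd = np.arange(1, T, 2)
    inv_tau0sq = 1.0 / priors.tau0**2
    inv_b4sq = 1.0 / priors.beta4_sd**2

    n_keep = config.n_draws
    out = {
        "theta": np.empty((C, n_keep, I, 5)),
        "sigma_y": np.empty((C, n_keep, I)),
        "sigma_x": np.empty((C, n_keep, I)),
        "sigma_lambda": np.empty((C, n_keep)),
        "mu_beta": np.empty((C, n_keep, 4)),
        "Sigma_beta": np.empty((C, n_keep, 4, 4)),
        "log_cpue": np.empty((C, n_keep, I, T)),
        "log_lambda": np.empty((C, n_keep, T)),
        "z_missing": np.empty((C, n_keep, M)),
    }

    def ell_block(idx_block, warmup):
        """Even/odd adaptive Metropolis on the log effort intensity."""
        nonlocal ell, scales
        lam_cur = ell[:, idx_block]
        z_blk = z_full[:, idx_block]
        prop = lam_cur + scales[:, idx_block] * rng.standard_normal(lam_cur.shape)

        def logt(x):
            lt = z_blk * x - np.exp(x)
            left = idx_block > 0
            lt[:, left] += -0.5 * (x[:, left] - ell[:, idx_block[left] - 1]) ** 2 / sig2lam[:, None]
            if idx_block[0] == 0:
                lt[:, 0] += -0.5 * (x[:, 0] - ell0_mean) ** 2 / s0sq
            right = idx_block < T - 1
            lt[:, right] += -0.5 * (ell[:, idx_block[right] + 1] - x[:, right]) ** 2 / sig2lam[:, None]
            return lt

        delta = logt(prop) - logt(lam_cur)
        accept = np.log(rng.random(delta.shape)) < delta
        ell[:, idx_block] = np.where(accept, prop, lam_cur)
        if warmup:
            scales[:, idx_block] *= np.exp(0.05 * (accept.astype(float) - 0.44))

    total_iters = config.n_warmup + config.n_draws * config.thin
    keep = 0
    for it in range(total_iters):
        warmup = it < config.n_warmup
        z_full = np.broadcast_to(z_obs, (C, T)).copy()
        if M:
            z_full[:, m_idx] = zmis
        log_z = np.log(z_full)

        # -- coefficient vectors -----------------------------------------
        if config.update_coefs:
            invSig = np.linalg.inv(Sigma)
            a_diff = a[:, :, 1:] - a[:, :, :-1]
            if len(idxN):
                prior_b = np.einsum("ckl,cl->ck", invSig, mu)
                _update_theta_group(rng, theta, a_diff, U, G_N, idxN, sig2x, invSig, prior_b, 4)
                theta[:, idxN, 4] = 0.0
            if len(idxR):
                pp = np.zeros((C, 5, 5))
                pp[:, :4, :4] = invSig
                pp[:, 4, 4] = inv_b4sq
                pb = np.zeros((C, 5))
                pb[:, :4] = np.einsum("ckl,cl->ck", invSig, mu)
                _update_theta_group(rng, theta, a_diff, U, G_R, idxR, sig2x, pp, pb, 5)

        drift = np.einsum("itk,cik->cit", U, theta)
        d = log_catch[None] - log_z[:, None, :]

        # -- variances, states-marginal Metropolis -------------------------
        # Joint log-scale random walk on (sigma_x, sigma_y) accepted with
        # the Kalman-marginal likelihood (latent paths integrated out);
        # breaks the strong coupling between the two variances and the
        # states.  Valid because the paths are redrawn by FFBS just below.
        if (
            config.update_variances
            and config.update_states
            and "sigma_x" not in fixed
            and "sigma_y" not in fixed
        ):
            lx, ly = 0.5 * np.log(sig2x), 0.5 * np.log(sig2y)
            step = var_scales * rng.standard_normal((2, C, I))
            lx_p, ly_p = lx + step[0], ly + step[1]
            s2x_p, s2y_p = np.exp(2 * lx_p), np.exp(2 * ly_p)
            ll_cur = _kalman_loglik(d, drift, sig2x, sig2y, m0, s0sq)
            ll_prop = _kalman_loglik(d, drift, s2x_p, s2y_p, m0, s0sq)
            # uniform-on-SD prior => density exp(u) in u = log(sd)
            delta = ll_prop - ll_cur + (lx_p - lx) + (ly_p - ly)
            delta = np.where((s2x_p > sd2_max) | (s2y_p > sd2_max), -np.inf, delta)
            accept = np.log(rng.random((C, I))) < delta
            sig2x = np.where(accept, s2x_p, sig2x)
            sig2y = np.where(accept, s2y_p, sig2y)
            if warmup:
                var_scales *= np.exp(0.05 * (accept.astype(float) - 0.3))

        # -- latent log CPUE ---------------------------------------------
        if config.update_states:
            a = _ffbs(rng, d, drift, sig2x, sig2y, m0, s0sq)

        # -- variances ----------------------------------------------------
        if config.update_variances:
            resid_x = a[:, :, 1:] - a[:, :, :-1] - drift[:, :, 1:]
            if "sigma_x" not in fixed:
                SSx = np.einsum("cit,cit->ci", resid_x, resid_x)
                sig2x = _sample_trunc_invgamma(rng, (T - 2) / 2.0, SSx / 2.0, sd2_max, (C, I))
            if "sigma_y" not in fixed:
                resid_y = d[:, :, 1:] - a[:, :, 1:]
                SSy = np.einsum("cit,cit->ci", resid_y, resid_y)
                sig2y = _sample_trunc_invgamma(rng, (T - 2) / 2.0, SSy / 2.0, sd2_max, (C, I))

        # -- community hyper-parameters -----------------------------------
        if config.update_hyper:
            invSig = np.linalg.inv(Sigma)
            theta4 = theta[:, :, :4]
            P = I * invSig + inv_tau0sq * np.eye(4)[None]
            b = np.einsum("ckl,cl->ck", invSig, theta4.sum(axis=1)) + inv_tau0sq * priors.mu0[None]
            V = np.linalg.inv(P)
            mean = np.einsum("ckl,cl->ck", V, b)
            Lv = np.linalg.cholesky(V)
            mu = mean + np.einsum("ckl,cl->ck", Lv, rng.standard_normal((C, 4)))
            dev = theta4 - mu[:, None, :]
            S = np.einsum("cik,cil->ckl", dev, dev)
            Sigma = _sample_invwishart(rng, priors.nu0 + I, priors.Psi0[None] + S)

        # -- effort layer --------------------------------------------------
        if config.update_effort:
            if "sigma_lambda" not in fixed:
                de = np.diff(ell, axis=1)
                SSl = np.einsum("ct,ct->c", de, de)
                sig2lam = _sample_trunc_invgamma(rng, (T - 2) / 2.0, SSl / 2.0, sd2_max, (C,))
            ell_block(even, warmup)
            ell_block(odd, warmup)
            if M:
                lam_m = np.exp(ell[:, m_idx])
                step = rng.integers(1, 6, size=(C, M)) * rng.choice((-1.0, 1.0), size=(C, M))
                z_new = zmis + step
                e = log_catch[None, :, m_idx] - a[:, :, m_idx]  # (C, I, M)
                inv2sy = 0.5 / sig2y  # (C, I)

                def z_logt(zv):
                    lt = zv * ell[:, m_idx] - gammaln(zv + 1.0)
                    lz = np.log(zv)
                    obs_t = -(inv2sy[:, :, None] * (e - lz[:, None, :]) ** 2).sum(axis=1)
                    # the first year carries no catch observation layer
                    if M and m_idx[0] == 0:
                        obs_t[:, 0] = 0.0
                    return lt + obs_t

                with np.errstate(divide="ignore", invalid="ignore"):
                    delta = np.where(z_new >= 1, z_logt(np.maximum(z_new, 1.0)) - z_logt(zmis), -np.inf)
                accept = np.log(rng.random(delta.shape)) < delta
                zmis = np.where(accept, np.maximum(z_new, 1.0), zmis)

        if not warmup and (it - config.n_warmup) % config.thin == 0:
            out["theta"][:, keep] = theta
            out["sigma_y"][:, keep] = np.sqrt(sig2y)
            out["sigma_x"][:, keep] = np.sqrt(sig2x)
            out["sigma_lambda"][:, keep] = np.sqrt(sig2lam)
            out["mu_beta"][:, keep] = mu
            out["Sigma_beta"][:, keep] = Sigma
            out["log_cpue"][:, keep] = a
            out["log_lambda"][:, keep] = ell
            out["z_missing"][:, keep] = zmis
            keep += 1

    assert keep == n_keep
    return out
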