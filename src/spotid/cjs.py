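"""Bayesian Cormack-Jolly-Seber survival estimation.

The model: conditional on first capture, an individual alive at occasion
t-1 survives to t with probability phi, and a live individual is captured
with probability p.  The latent alive states are marginalized analytically
by a forward recursion over the alive/dead chain, so the likelihood of a
capture history needs no latent sampling.  Posterior sampling uses
random-walk Metropolis on (logit phi, logit p) with the Jacobian
correction, 4 chains, and the first half of each chain discarded as
warm-up; uniform(0, 1) priors on both parameters.  A latent-state Gibbs
sampler (forward-filter/backward-sample of the death time plus conjugate
Beta draws) is available as an alternative.

A classical caveat: with time-constant parameters the product of survival
and capture in the final interval is only weakly identified; simulations
here use enough occasions (>= 10) that recovery is stable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .histories import CaptureHistoryMatrix

__all__ = ["cjs_log_likelihood", "fit_cjs", "hpd_interval",
           "PosteriorSummary"]


def _grouped(y: CaptureHistoryMatrix):
    rows, counts = np.unique(y.y, axis=0, return_counts=True)
    return rows, counts


def _loglik_rows(rows: np.ndarray, counts: np.ndarray,
                 phi: float, p: float) -> float:
    """Forward recursion marginalizing alive/dead, per unique history."""
    n, T = rows.shape
    first = rows.argmax(axis=1)
    pa = np.ones(n)          # P(data so far, alive at t)
    pd = np.zeros(n)         # P(data so far, dead at t)
    for t in range(1, T):
        active = first < t
        cap = rows[:, t] == 1
        pa_new = np.where(cap, pa * phi * p, pa * phi * (1 - p))
        pd_new = np.where(cap, 0.0, pd + pa * (1 - phi))
        pa = np.where(active, pa_new, pa)
        pd = np.where(active, pd_new, pd)
    lik = pa + pd
    if np.any(lik <= 0):
        return -np.inf
    return float(counts @ np.log(lik))


def cjs_log_likelihood(y: CaptureHistoryMatrix, phi: float, p: float) -> float:
    """Marginal log-likelihood of all capture histories.

    Latent alive states are summed out with a forward recursion; each
    history is conditioned on its first capture.  Returns ``-inf`` when
    the data are impossible under the parameters (e.g. a missed capture
    with phi = p = 1).
    """
    if not (0.0 <= phi <= 1.0 and 0.0 <= p <= 1.0):
        raise ValueError("phi and p must lie in [0, 1]")
    rows, counts = _grouped(y)
    return _loglik_rows(rows, counts, phi, p)


def hpd_interval(samples, mass: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing the requested posterior mass."""
    samples = np.sort(np.asarray(samples, dtype=float).ravel())
    n = len(samples)
    if n == 0:
        raise ValueError("need at least one sample")
    if not 0 < mass <= 1:
        raise ValueError("mass must lie in (0, 1]")
    m = max(int(np.ceil(mass * n)), 1)
    if m >= n:
        return float(samples[0]), float(samples[-1])
    widths = samples[m:] - samples[:-m]
    k = int(np.argmin(widths))
    return float(samples[k]), float(samples[k + m])


@dataclass
class PosteriorSummary:
    """Posterior means, 95% HPD intervals and raw draws for (phi, p)."""

    phi_mean: float
    p_mean: float
    phi_hpd: tuple[float, float]
    p_hpd: tuple[float, float]
    samples: np.ndarray            # (n, 2) columns (phi, p)
    diagnostics: dict = field(default_factory=dict)


def _logit(x):
    return np.log(x) - np.log1p(-x)


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


def _metropolis(rows, counts, n_keep: int, rng, n_chains: int = 4,
                proposal_sd: float = 0.18):
    keep_per_chain = max(n_keep // n_chains, 1)
    draws = []
    accept = 0
    total = 0
    for c in range(n_chains):
        theta = rng.normal(0.0, 0.5, size=2)   # logit-space start
        phi, p = _expit(theta)
        lp = (_loglik_rows(rows, counts, phi, p)
              + np.log(phi * (1 - phi)) + np.log(p * (1 - p)))
        chain = np.empty((2 * keep_per_chain, 2))
        for i in range(2 * keep_per_chain):
            prop = theta + rng.normal(0.0, proposal_sd, size=2)
            phi_n, p_n = _expit(prop)
            lp_n = (_loglik_rows(rows, counts, phi_n, p_n)
                    + np.log(phi_n * (1 - phi_n)) + np.log(p_n * (1 - p_n)))
            total += 1
            if np.log(rng.random()) < lp_n - lp:
                theta, lp = prop, lp_n
                accept += 1
            chain[i] = _expit(theta)
        draws.append(chain[keep_per_chain:])   # discard warm-up half
    return np.vstack(draws), accept / max(total, 1)


def _gibbs(y: CaptureHistoryMatrix, n_keep: int, rng):
    """Latent-death-time Gibbs sampler (alternative to marginalization).

    Between first and last capture an individual is certainly alive; only
    the death time after the last capture is latent, and its full
    conditional is a small categorical distribution, so the latent pass
    samples death times directly and phi, p have conjugate Beta updates
    under the uniform priors.
    """
    Y = y.y
    n, T = Y.shape
    first = y.first_capture
    last = T - 1 - Y[:, ::-1].argmax(axis=1)
    n_cap_after_first = Y[np.arange(n), :].sum(axis=1) - 1  # excl. first
    groups = {l: np.nonzero(last == l)[0] for l in np.unique(last)}
    phi, p = 0.5, 0.5
    n_warm = n_keep
    out = np.empty((n_keep, 2))
    death_time = np.empty(n, dtype=int)
    for it in range(n_warm + n_keep):
        # death interval per individual: alive occasions last..j; the
        # conditional over j is categorical and depends only on last
        for l, idx in groups.items():
            js = np.arange(l, T)
            logw = (js - l) * (np.log(phi) + np.log1p(-p))
            logw[js < T - 1] += np.log1p(-phi)
            w = np.exp(logw - logw.max())
            cdf = np.cumsum(w / w.sum())
            u = rng.random(len(idx))
            death_time[idx] = js[np.searchsorted(cdf, u)]
        surv_intervals = float((death_time - first).sum())
        deaths = float(np.count_nonzero(death_time < T - 1))
        captures = float(n_cap_after_first.sum())
        alive_uncaptured = surv_intervals - captures
        phi = rng.beta(1.0 + surv_intervals, 1.0 + deaths)
        p = rng.beta(1.0 + captures, 1.0 + alive_uncaptured)
        if it >= n_warm:
            out[it - n_warm] = (phi, p)
    return out


def fit_cjs(y: CaptureHistoryMatrix, n_samples: int = 8000,
            seed: int = 0, sampler: str = "metropolis",
            n_chains: int = 4, proposal_sd: float = 0.18
            ) -> PosteriorSummary:
    """Sample the posterior of (phi, p) given capture histories.

    ``n_samples`` is the total number of retained draws across chains.
    Reproducible given ``seed``.
    """
    if n_samples < 1000:
        raise ValueError("n_samples must be at least 1000")
    rng = np.random.default_rng(seed)
    diagnostics: dict = {"sampler": sampler, "n_chains": n_chains}
    if not (y.y.sum(axis=1) > 1).any():
        warnings.warn("no recaptures: posterior will be close to the prior",
                      stacklevel=2)
        diagnostics["no_recaptures"] = True
    if sampler == "metropolis":
        rows, counts = _grouped(y)
        samples, acc = _metropolis(rows, counts, n_samples, rng,
                                   n_chains=n_chains,
                                   proposal_sd=proposal_sd)
        diagnostics["acceptance_rate"] = acc
    elif sampler == "gibbs":
        samples = _gibbs(y, n_samples, rng)
    else:
        raise ValueError(f"unknown sampler '{sampler}'")
    return PosteriorSummary(
        phi_mean=float(samples[:, 0].mean()),
        p_mean=float(samples[:, 1].mean()),
        phi_hpd=hpd_interval(samples[:, 0]),
        p_hpd=hpd_interval(samples[:, 1]),
        samples=samples,
        diagnostics=diagnostics)
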