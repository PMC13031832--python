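"""Metropolis-Hastings benchmark on the emulated likelihood.

Gold-standard posterior sampling used to validate the ensemble Kalman
calibrator.  The target is the same emulated posterior the calibrator
approximates: a flat prior on the box, and a Gaussian likelihood whose
covariance is the observation noise R plus the (diagonal) emulator
predictive variance at theta, so emulator uncertainty widens the
likelihood exactly as it widens the Kalman innovation covariance.

The reference sampler is adaptive random-walk Metropolis: independent
chains from dispersed uniform starts, a diagonal Gaussian proposal whose
scale adapts towards a 20-40% acceptance rate during burn-in and is then
frozen (so the post-burn-in chain is a valid Metropolis chain).
Post-processing drops burn-in, thins, concatenates chains and reports
split-chain R-hat.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from mmscalib.design import PriorBox
from mmscalib.observables import ObservationVector

__all__ = [
    "McmcConfig",
    "log_posterior",
    "run_mcmc",
    "run_metropolis",
    "postprocess_chains",
    "split_rhat",
]

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass
class McmcConfig:
    """Chain bookkeeping and proposal adaptation settings.

    Defaults mirror a heavyweight reference run: 10 chains of 40,000
    samples, 10,000 burn-in, thinning 10 — leaving 30,000 retained samples.
    """

    n_chains: int = 10
    n_samples: int = 40_000
    burn_in: int = 10_000
    thinning: int = 10
    initial_scale: float = 0.1  # proposal sd as a fraction of prior range
    target_acceptance: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.burn_in < self.n_samples:
            raise ValueError("require 0 <= burn_in < n_samples")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")
        if self.n_chains < 1:
            raise ValueError("need at least one chain")


def log_posterior(
    theta: np.ndarray,
    y: ObservationVector,
    emulators,
    prior: PriorBox,
) -> np.ndarray:
    """Emulated log-posterior, vectorised over a batch of parameter vectors.

    -inf outside the prior box; inside, the Gaussian log-likelihood of y
    with mean m_bar(theta) and diagonal covariance R + k_bar(theta, theta),
    plus the (constant) flat log-prior.  Non-finite emulator output maps to
    -inf with a warning.
    """
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    n = theta.shape[0]
    out = np.full(n, -np.inf)
    inside = prior.contains(theta)
    if not np.any(inside):
        return out if theta.ndim > 1 else out[0]
    mu, var = emulators.predict(theta[inside])
    total_var = var + y.noise_var
    resid = y.values - mu
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = -0.5 * np.sum(
            resid**2 / total_var + np.log(total_var) + _LOG_2PI, axis=1
        )
    bad = ~np.isfinite(ll)
    if np.any(bad):
        warnings.warn("non-finite emulator output mapped to log-density -inf")
        ll[bad] = -np.inf
    out[inside] = ll
    return out


def run_metropolis(
    log_prob,
    prior: PriorBox,
    config: McmcConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Adaptive random-walk Metropolis on an arbitrary batched log-density.

    ``log_prob`` maps an (n, d) batch to n log-densities.  All chains are
    advanced in lock-step so batched (e.g. emulator-backed) densities are
    evaluated efficiently.  Returns ``(chains, acceptance)`` with chains of
    shape (n_chains, n_samples, d) and post-adaptation acceptance rates per
    chain; a chain accepting < 1% is flagged with a warning.
    """
    rng = np.random.default_rng(config.seed)
    d = prior.dim
    nc, ns = config.n_chains, config.n_samples
    current = prior.sample(nc, rng)
    current_lp = log_prob(current)
    scales = np.full((nc, d), config.initial_scale) * prior.range
    chains = np.empty((nc, ns, d))
    adapt_until = max(config.burn_in, 1)
    adapt_window = 50
    accepted_window = np.zeros(nc)
    accepted_post = np.zeros(nc)
    for t in range(ns):
        proposal = current + scales * rng.standard_normal((nc, d))
        prop_lp = log_prob(proposal)
        logu = np.log(rng.uniform(size=nc))
        accept = logu < (prop_lp - current_lp)
        current = np.where(accept[:, None], proposal, current)
        current_lp = np.where(accept, prop_lp, current_lp)
        chains[:, t] = current
        accepted_window += accept
        if t >= adapt_until:
            accepted_post += accept
        elif (t + 1) % adapt_window == 0:
            rate = accepted_window / adapt_window
            scales *= np.exp(rate - config.target_acceptance)[:, None]
            accepted_window[:] = 0.0
    n_post = max(ns - adapt_until, 1)
    acceptance = accepted_post / n_post
    stuck = acceptance < 0.01
    if np.any(stuck):
        warnings.warn(
            f"chains {np.nonzero(stuck)[0].tolist()} appear stuck "
            f"(acceptance < 1% after adaptation)"
        )
    return chains, acceptance


def run_mcmc(
    y: ObservationVector,
    emulators,
    prior: PriorBox,
    config: McmcConfig,
    use_likelihood: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample the emulated posterior (or, with ``use_likelihood=False``,
    the flat prior — a sampler self-check) with adaptive random-walk
    Metropolis.  Returns raw chains and per-chain acceptance rates."""

    if use_likelihood:

        def log_prob(theta):
            return log_posterior(theta, y, emulators, prior)

    else:

        def log_prob(theta):
            return np.where(prior.contains(np.atleast_2d(theta)), 0.0, -np.inf)

    return run_metropolis(log_prob, prior, config)


def split_rhat(chain_values: np.ndarray) -> float:
    """Split-chain potential scale reduction factor for one parameter.

    ``chain_values`` has shape (n_chains, n_samples); each chain is split
    in half, and R-hat compares between-half and within-half variances.
    """
    x = np.asarray(chain_values, dtype=float)
    nc, ns = x.shape
    half = ns // 2
    halves = np.concatenate([x[:, :half], x[:, half : 2 * half]], axis=0)
    m, n = halves.shape
    means = halves.mean(axis=1)
    b = n * np.var(means, ddof=1)
    w = np.mean(np.var(halves, axis=1, ddof=1))
    if w == 0:
        return 1.0
    var_plus = (n - 1) / n * w + b / n
    return float(np.sqrt(var_plus / w))


def postprocess_chains(
    chains: np.ndarray, config: McmcConfig, rhat_warn: float = 1.05
) -> tuple[np.ndarray, np.ndarray]:
    """Drop burn-in, thin, concatenate; report split R-hat per parameter.

    The retained count is n_chains * floor((n_samples - burn_in) /
    thinning).  A parameter with R-hat above ``rhat_warn`` triggers a
    convergence warning.
    """
    chains = np.asarray(chains, dtype=float)
    nc, ns, d = chains.shape
    n_keep = (ns - config.burn_in) // config.thinning
    kept = chains[:, config.burn_in :, :][:, : n_keep * config.thinning : config.thinning, :]
    rhats = np.array([split_rhat(kept[:, :, j]) for j in range(d)]) if nc > 1 else np.full(d, np.nan)
    if nc > 1 and np.any(rhats > rhat_warn):
        warnings.warn(
            f"split R-hat above {rhat_warn} for parameters "
            f"{np.nonzero(rhats > rhat_warn)[0].tolist()}: chains may not have mixed"
        )
    return kept.reshape(nc * n_keep, d), rhats
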