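"""Shared independent oracles and property-check helpers.

These implement textbook/closed-form references (conjugate Gaussian
posteriors, a plain static ensemble Kalman update, analytic gate dynamics)
that the package's own code paths are compared against.  They deliberately
avoid calling into mmscalib's update internals.
"""

from __future__ import annotations

import numpy as np

from mmscalib.design import PriorBox
from mmscalib.emulator import CallableEmulator
from mmscalib.enkf import EnkfConfig, calibrate
from mmscalib.observables import ObservationVector


def make_linear_observation(H: np.ndarray, truth: np.ndarray, noise_sd: np.ndarray):
    """Noise-free observation y = H truth with declared noise covariance."""
    H = np.atleast_2d(np.asarray(H, dtype=float))
    values = H @ np.asarray(truth, dtype=float)
    labels = tuple((i, "out") for i in range(H.shape[0]))
    return ObservationVector(
        values=values,
        labels=labels,
        noise_sd=np.broadcast_to(np.asarray(noise_sd, dtype=float), (H.shape[0],)).copy(),
    )


def linear_emulator(H: np.ndarray, variance: float = 0.0) -> CallableEmulator:
    H = np.atleast_2d(np.asarray(H, dtype=float))
    return CallableEmulator(fn=lambda th: th @ H.T, n_outputs=H.shape[0], variance=variance)


def conjugate_posterior(H, R_diag, y, m0, C0):
    """Exact Gaussian posterior for y = H theta + eps with prior N(m0, C0)."""
    H = np.atleast_2d(np.asarray(H, dtype=float))
    R_inv = np.diag(1.0 / np.asarray(R_diag, dtype=float))
    C0 = np.atleast_2d(C0)
    prec = np.linalg.inv(C0) + H.T @ R_inv @ H
    cov = np.linalg.inv(prec)
    mean = cov @ (np.linalg.solve(C0, np.atleast_1d(m0)) + H.T @ R_inv @ y)
    return mean, cov


def reference_static_enkf_step(particles, y_values, noise_sd, k_total, h_fn, rng):
    """Textbook perturbed-observation EnKF update for a static problem.

    Consumes the generator in the same order as the package's step
    (pseudo-dynamics increments first, then observation perturbations) so a
    sigma_theta = 0 run can be compared draw for draw, but computes the
    update entirely from the standard formulas.
    """
    n, d = particles.shape
    p = len(y_values)
    rng.standard_normal((n, d))  # sigma_theta = 0: increments are zeroed out
    predictions = h_fn(particles)
    perturbed = y_values + np.sqrt(k_total) * noise_sd * rng.standard_normal((n, p))
    dth = particles - particles.mean(axis=0)
    dh = predictions - predictions.mean(axis=0)
    c_tm = dth.T @ dh / (n - 1)
    c_hh = dh.T @ dh / (n - 1)
    s = c_hh + k_total * np.diag(noise_sd**2)
    gain = c_tm @ np.linalg.inv(s)
    return particles + (perturbed - predictions) @ gain.T


def run_linear_calibration(
    H,
    truth,
    noise_sd,
    box: PriorBox,
    n_particles: int,
    n_steps: int,
    sigma_theta,
    seed: int,
    emulator_variance: float = 0.0,
):
    """Full calibrate() run on an exactly-known linear measurement map."""
    y = make_linear_observation(H, truth, noise_sd)
    em = linear_emulator(H, variance=emulator_variance)
    cfg = EnkfConfig(
        n_particles=n_particles,
        n_steps=n_steps,
        sigma_theta=sigma_theta,
        seed=seed,
    )
    return calibrate(y, em, cfg, box)


def moment_matched_prior(box: PriorBox):
    """Gaussian moment match of the uniform box prior."""
    return box.midpoint, np.diag(box.range**2 / 12.0)
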