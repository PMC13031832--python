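"""Synthetic calibration studies at desk scale.

Three studies mirror the questions a clinical calibration workflow must
answer:

* **identifiability** — which tissue parameters do S1S2 measurements
  actually constrain?  Ground truths are drawn from the stored training
  ensemble (so synthetic data come from the true simulator, not the
  emulator), noisy observations are built for each measurement combination
  (S1 only; S1+S2; S1+S2+APD) and calibrated with the ensemble Kalman
  scheme; truth-vs-estimate correlations and posterior/prior contraction
  ratios are aggregated per parameter.
* **field RMSE** — how well do calibrated parameters reproduce the full
  spatial activation/repolarisation fields, including everywhere no sensor
  was placed?
* **reentry probability** — the motivating application: the posterior
  probability of sustained reentrant activity (the model's stand-in for
  AF sustaining) as a Monte-Carlo average of a binary simulation outcome
  over posterior parameter samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from mmscalib.design import PriorBox, TrainingEnsemble
from mmscalib.enkf import CalibrationResult, EnkfConfig, calibrate
from mmscalib.forward_model import (
    GridSpec,
    PacingProtocol,
    StimulusWindow,
    TissueParameters,
    default_sheet_grid,
    default_stim_region,
    run_stimuli,
    simulate,
)
from mmscalib.observables import (
    OUTPUT_TYPES,
    add_noise,
    build_observation,
    extract_apd,
    extract_lat,
    beat_windows,
)

__all__ = [
    "MEASUREMENT_COMBOS",
    "IdentifiabilityReport",
    "IndicatorFunction",
    "EventProbability",
    "run_identifiability_study",
    "compute_field_rmse",
    "posterior_event_probability",
    "spiral_sustain_indicator",
    "find_s2_timing",
]

#: The three measurement combinations studied, keyed by display name.
MEASUREMENT_COMBOS: dict[str, tuple[str, ...]] = {
    "S1": ("S1",),
    "S1+S2": ("S1", "S2"),
    "S1+S2+APD": ("S1", "S2", "APD"),
}


@dataclass
class IdentifiabilityReport:
    """Per-instance calibration records plus per-parameter aggregates.

    ``records`` has one row per (truth, combo) instance with the posterior
    mean/sd and convergence iteration; ``correlation`` and ``contraction``
    are (parameter x combo) tables of truth-vs-estimate Pearson correlation
    and median posterior-sd / prior-sd ratios.
    """

    records: pd.DataFrame
    correlation: pd.DataFrame
    contraction: pd.DataFrame
    truths: np.ndarray  # (n_truths, 5)
    combos: tuple[str, ...]


@dataclass(frozen=True)
class IndicatorFunction:
    """Deterministic binary event classifier g(theta) in {0, 1}."""

    fn: object  # callable theta (5,) -> int
    description: str = ""

    def __call__(self, theta: np.ndarray) -> int:
        return int(self.fn(np.asarray(theta, dtype=float)))


@dataclass
class EventProbability:
    probability: float
    standard_error: float
    n_samples: int
    n_events: int
    n_failed: int
    outcomes: np.ndarray


def run_identifiability_study(
    ensemble: TrainingEnsemble,
    emulators,
    n_truths: int = 10,
    combos: tuple[str, ...] = tuple(MEASUREMENT_COMBOS),
    enkf_config: EnkfConfig | None = None,
    noise_sd: float | None = None,
    seed: int = 0,
) -> IdentifiabilityReport:
    """Calibrate against every measurement combo for each synthetic truth.

    Truths are ensemble rows (chosen without replacement), so the noise-free
    observation is the stored simulator output.  Non-converged calibrations
    are flagged in the records, never dropped.
    """
    bad = [c for c in combos if c not in MEASUREMENT_COMBOS]
    if bad:
        raise ValueError(f"unknown measurement combos {bad}")
    if n_truths < 1 or n_truths > ensemble.M:
        raise ValueError("n_truths must lie in [1, ensemble size]")
    enkf_config = enkf_config or EnkfConfig()
    rng = np.random.default_rng(seed)
    truth_rows = rng.choice(ensemble.M, size=n_truths, replace=False)

    names = ensemble.box.names
    prior_sd = ensemble.box.range / np.sqrt(12.0)
    rows = []
    for row in truth_rows:
        truth = ensemble.params[row]
        clean = ensemble.observation(row)
        if noise_sd is not None:
            clean.noise_sd = np.full(clean.p, float(noise_sd))
        noisy = add_noise(clean, rng)
        for combo in combos:
            types = MEASUREMENT_COMBOS[combo]
            y = noisy.subset(types)
            gpe = emulators.subset_types(types)
            cfg_seed = int(rng.integers(2**31 - 1))
            cfg = EnkfConfig(
                n_particles=enkf_config.n_particles,
                n_steps=enkf_config.n_steps,
                sigma_theta=enkf_config.sigma_theta,
                seed=cfg_seed,
                boundary_policy=enkf_config.boundary_policy,
                conv_tol=enkf_config.conv_tol,
            )
            result = calibrate(y, gpe, cfg, ensemble.box)
            rec = {
                "truth_row": int(row),
                "combo": combo,
                "convergence_iteration": result.convergence_iteration,
                "converged": result.convergence_iteration is not None,
                "diverged": result.diverged,
            }
            for i, name in enumerate(names):
                rec[f"truth_{name}"] = truth[i]
                rec[f"mean_{name}"] = result.posterior_mean[i]
                rec[f"sd_{name}"] = result.posterior_sd[i]
            rows.append(rec)
    records = pd.DataFrame(rows)

    corr = pd.DataFrame(index=names, columns=list(combos), dtype=float)
    contr = pd.DataFrame(index=names, columns=list(combos), dtype=float)
    for combo in combos:
        sub = records[records.combo == combo]
        for i, name in enumerate(names):
            t = sub[f"truth_{name}"].to_numpy()
            m = sub[f"mean_{name}"].to_numpy()
            if len(sub) >= 2 and np.std(t) > 0 and np.std(m) > 0:
                corr.loc[name, combo] = float(np.corrcoef(t, m)[0, 1])
            else:
                corr.loc[name, combo] = np.nan
            contr.loc[name, combo] = float(
                np.median(sub[f"sd_{name}"]) / prior_sd[i]
            )
    return IdentifiabilityReport(
        records=records,
        correlation=corr,
        contraction=contr,
        truths=ensemble.params[truth_rows],
        combos=tuple(combos),
    )


def compute_field_rmse(
    true_params: TissueParameters,
    estimated_params: TissueParameters,
    grid: GridSpec,
    protocol: PacingProtocol | None = None,
    dt: float = 0.05,
    sampling_interval: float = 0.25,
) -> dict:
    """RMSE of S1 LAT, S2 LAT and S2 APD over *all* grid nodes.

    Both parameter sets are simulated on the full grid; a node where either
    run lacks a feature is excluded from that output's RMSE and counted in
    the exclusion fraction.
    """
    protocol = protocol or PacingProtocol()
    all_nodes = tuple(range(grid.n_nodes))
    recs = [
        simulate(p, grid, protocol, dt=dt, sites=all_nodes,
                 sampling_interval=sampling_interval)
        for p in (true_params, estimated_params)
    ]
    windows = beat_windows(recs[0])
    out: dict = {}
    for typ in OUTPUT_TYPES:
        window = windows[typ]
        onset = window[0]
        diffs = []
        n_excluded = 0
        for node in all_nodes:
            vals = []
            for rec in recs:
                trace = rec.trace(node)
                if typ == "APD":
                    v = extract_apd(trace, rec.times, window)
                else:
                    lat = extract_lat(trace, rec.times, window)
                    v = None if lat is None else lat - onset
                vals.append(v)
            if any(v is None for v in vals):
                n_excluded += 1
                continue
            diffs.append(vals[0] - vals[1])
        out[f"rmse_{typ}"] = (
            float(np.sqrt(np.mean(np.square(diffs)))) if diffs else np.nan
        )
        out[f"excluded_fraction_{typ}"] = n_excluded / len(all_nodes)
    return out


def posterior_event_probability(
    samples: np.ndarray, indicator: IndicatorFunction
) -> EventProbability:
    """Monte-Carlo estimate of P(event | y) = mean of g(theta) over samples.

    A sample on which the indicator raises is excluded and counted; the
    standard error is the binomial one.
    """
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    if samples.shape[0] == 0:
        raise ValueError("need at least one posterior sample")
    outcomes = []
    n_failed = 0
    for theta in samples:
        try:
            outcomes.append(int(indicator(theta)))
        except Exception:
            n_failed += 1
    if not outcomes:
        raise RuntimeError("indicator failed on every sample")
    outcomes = np.asarray(outcomes)
    n = len(outcomes)
    prob = float(outcomes.mean())
    se = float(np.sqrt(max(prob * (1.0 - prob), 0.0) / n))
    return EventProbability(
        probability=prob,
        standard_error=se,
        n_samples=n,
        n_events=int(outcomes.sum()),
        n_failed=n_failed,
        outcomes=outcomes,
    )


# ---------------------------------------------------------------------------
# Reentry (spiral-wave) indicator on a 2D sheet via cross-field stimulation
# ---------------------------------------------------------------------------

#: Default S2 timing (ms) for the cross-field protocol, computed once with
#: :func:`find_s2_timing` at the default prior-box midpoint parameters on
#: the default 50 x 50 mm sheet, then held fixed across indicator calls.
DEFAULT_SPIRAL_S2_TIME = 322.0

SPIRAL_TOTAL_MS = 2000.0
SPIRAL_QUIESCENT_TAIL_MS = 200.0
SPIRAL_MIN_CENTRE_ACTIVATIONS = 3


def _sheet_stimuli(
    grid: GridSpec, protocol_amp: float, duration_ms: float, s2_time: float | None
) -> list[StimulusWindow]:
    ny, nx = grid.shape
    s1_nodes = default_stim_region(grid)  # left-edge line electrode
    stimuli = [StimulusWindow(0.0, duration_ms, s1_nodes, protocol_amp)]
    if s2_time is not None:
        half = tuple(
            r * nx + c for r in range(ny // 2) for c in range(nx)
        )  # bottom half-plane, orthogonal to the S1 wavefront
        stimuli.append(
            StimulusWindow(s2_time, s2_time + duration_ms, half, protocol_amp)
        )
    return stimuli


def spiral_sustain_indicator(
    params: TissueParameters,
    sheet: GridSpec | None = None,
    s2_time: float | None = DEFAULT_SPIRAL_S2_TIME,
    seed: int = 0,
    dt: float = 0.05,
    total_ms: float = SPIRAL_TOTAL_MS,
) -> int:
    """1 if cross-field stimulation sustains reentrant activity, else 0.

    An S1 plane wave is launched from the left edge; at ``s2_time`` a
    half-plane S2 covering the bottom of the sheet fires into the
    repolarising tail, creating a wavebreak that can curl into a spiral.
    The run counts as sustained iff (a) any node is above the excitation
    threshold during the final 200 ms of a 2,000 ms run and (b) the sheet
    centre activates at least 3 times after the S2.  Deterministic given
    ``params`` (``seed`` is part of the interface for indicator functions
    but unused here).  Pass ``s2_time=None`` to disable the S2 — a single
    plane wave always terminates.
    """
    sheet = sheet or default_sheet_grid()
    if sheet.dimensionality != 2:
        raise ValueError("reentry induction requires a 2D sheet")
    ny, nx = sheet.shape
    centre = (ny // 2) * nx + nx // 2
    stimuli = _sheet_stimuli(sheet, 1.0, 2.0, s2_time)
    record, vmax = run_stimuli(
        params,
        sheet,
        stimuli,
        duration=total_ms,
        dt=dt,
        sites=(centre,),
        sampling_interval=1.0,
    )
    times = record.times
    tail = times >= total_ms - SPIRAL_QUIESCENT_TAIL_MS
    active_at_end = bool(np.any(vmax[tail] > params.v_gate))
    if not active_at_end:
        return 0
    if s2_time is None:
        return 0
    trace = record.site_traces[0]
    after = times >= s2_time
    v = trace[after]
    crossings = int(np.sum((v[:-1] < 0.75) & (v[1:] >= 0.75)))
    return int(active_at_end and crossings >= SPIRAL_MIN_CENTRE_ACTIVATIONS)


def find_s2_timing(
    params: TissueParameters,
    sheet: GridSpec | None = None,
    dt: float = 0.05,
    probe_ms: float = 400.0,
    tol_ms: float = 2.0,
) -> float:
    """Locate the vulnerable window for the cross-field S2 by bisection.

    The earliest S2 timing that captures anywhere in the recovering sheet
    (too early: fully refractory; later: progressively recovered) marks the
    lower edge of the vulnerable window.  The returned timing adds a small
    offset so the S2 lands where part of the sheet is recovered and part is
    still refractory — the configuration that breaks the S2 wavefront.
    """
    sheet = sheet or default_sheet_grid()
    ny, nx = sheet.shape
    probe = nx // 4  # bottom-left quadrant probe, inside the S2 half-plane

    def s2_captures(t_s2: float) -> bool:
        stimuli = _sheet_stimuli(sheet, 1.0, 2.0, t_s2)
        record, _ = run_stimuli(
            params,
            sheet,
            stimuli,
            duration=t_s2 + probe_ms,
            dt=dt,
            sites=(probe,),
            sampling_interval=1.0,
        )
        lat = extract_lat(
            record.site_traces[0], record.times, (t_s2, t_s2 + probe_ms)
        )
        return lat is not None

    lo, hi = 50.0, 800.0
    if not s2_captures(hi):
        raise RuntimeError("S2 never captures: sheet may not repolarise in time")
    while hi - lo > tol_ms:
        mid = 0.5 * (lo + hi)
        if s2_captures(mid):
            hi = mid
        else:
            lo = mid
    return hi + 20.0  # just inside the recovered-but-heterogeneous window
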