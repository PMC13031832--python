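"""Feasibility-filtered space-filling designs for emulator training.

The training ensemble E = {theta_m, h(theta_m)} is built in stages:

1. an (approximately maximin) Latin hypercube over the prior box,
   oversampled relative to the target size;
2. cheap cell-level (0D) rejection of non-physiological parameters —
   either by running the cell model directly, or via a probabilistic
   classifier trained on cell-model labels;
3. tissue simulation of the survivors and rejection of any run with an
   absent output (failed capture or recovery at any sensor site).

A parameter vector is cell-feasible when every paced beat activates, the S2
beat captures at the 500 ms coupling interval, and the S2 APD does not
exceed 500 ms (longer APDs are treated as non-physiological).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist
from scipy.stats import qmc

from mmscalib.forward_model import (
    PARAM_NAMES,
    GridSpec,
    PacingProtocol,
    TissueParameters,
    default_cable_grid,
    default_sensor_sites,
    simulate,
    simulate_cell,
)
from mmscalib.observables import (
    DEFAULT_NOISE_SD,
    OUTPUT_TYPES,
    ObservationVector,
    build_observation,
    extract_apd,
    extract_lat,
    beat_windows,
)

__all__ = [
    "PriorBox",
    "TrainingEnsemble",
    "CellFeasibility",
    "FeasibilityClassifier",
    "lhs_design",
    "cell_feasible",
    "fit_feasibility_classifier",
    "build_training_ensemble",
]

#: Maximum physiological S2 APD (ms); longer values are rejected.
APD_MAX_MS = 500.0


@dataclass(frozen=True)
class PriorBox:
    """Axis-aligned uniform prior box.

    For tissue calibration the bounds follow
    :data:`~mmscalib.forward_model.PARAM_NAMES` ordering (5 parameters);
    the class itself supports any dimension so toy inverse problems can use
    the same machinery.
    """

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "lower", np.atleast_1d(np.asarray(self.lower, dtype=float))
        )
        object.__setattr__(
            self, "upper", np.atleast_1d(np.asarray(self.upper, dtype=float))
        )
        if self.lower.shape != self.upper.shape or self.lower.ndim != 1:
            raise ValueError("bounds must be 1-D arrays of equal length")
        if not np.all(self.lower < self.upper):
            raise ValueError("require lower < upper for every parameter")

    @property
    def dim(self) -> int:
        return len(self.lower)

    @classmethod
    def default(cls) -> "PriorBox":
        """Desk-scale default bracketing standard mMS values.

        Produces S2 APDs spanning roughly 60-500+ ms on the cable model, so
        the 500 ms feasibility cut is active.  Units: ms for the four time
        constants, mm^2/ms for D.
        """
        return cls(
            lower=np.array([0.1, 2.0, 80.0, 80.0, 0.05]),
            upper=np.array([0.5, 12.0, 200.0, 200.0, 0.4]),
        )

    @property
    def names(self) -> tuple[str, ...]:
        if self.dim != 5:
            return tuple(f"theta_{i}" for i in range(self.dim))
        return PARAM_NAMES

    @property
    def range(self) -> np.ndarray:
        return self.upper - self.lower

    @property
    def midpoint(self) -> np.ndarray:
        return 0.5 * (self.lower + self.upper)

    def contains(self, theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(theta)
        return np.all((theta >= self.lower) & (theta <= self.upper), axis=1)

    def to_unit(self, theta: np.ndarray) -> np.ndarray:
        return (np.asarray(theta, dtype=float) - self.lower) / self.range

    def from_unit(self, u: np.ndarray) -> np.ndarray:
        return self.lower + np.asarray(u, dtype=float) * self.range

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """n independent uniform draws (n x dim, physical units)."""
        return self.from_unit(rng.uniform(size=(n, self.dim)))


@dataclass(frozen=True)
class CellFeasibility:
    feasible: bool
    reasons: tuple[str, ...] = ()

    def __bool__(self) -> bool:
        return self.feasible


def lhs_design(
    n: int,
    box: PriorBox,
    seed: int,
    n_candidates: int = 20,
) -> np.ndarray:
    """Approximately maximin Latin hypercube design mapped into the box.

    ``n_candidates`` seeded Latin hypercubes are drawn and the one with the
    largest minimum pairwise distance (in the unit cube) is kept, so the
    result is never worse than the plain design at the same seed.  Each
    parameter's values occupy ``n`` distinct strata of its range.
    """
    if n < 2:
        raise ValueError("a design needs at least 2 points")
    best, best_score = None, -np.inf
    for i in range(max(n_candidates, 1)):
        sampler = qmc.LatinHypercube(d=box.dim, seed=seed + i)
        u = sampler.random(n)
        score = pdist(u).min()
        if score > best_score:
            best, best_score = u, score
    return box.from_unit(best)


def _beat_capture_times(record) -> list[float | None]:
    """LAT (relative to its own stimulus) for every paced beat in a record."""
    stim = list(record.stimulus_times)
    edges = stim + [float(record.times[-1])]
    times = record.times
    trace = record.site_traces[0]
    lats = []
    for k, onset in enumerate(stim):
        lat = extract_lat(trace, times, (onset, edges[k + 1]))
        lats.append(None if lat is None else lat - onset)
    return lats


def cell_feasible(
    params: TissueParameters,
    protocol: PacingProtocol | None = None,
    dt: float = 0.05,
    apd_max: float = APD_MAX_MS,
) -> CellFeasibility:
    """Cheap 0D screen for non-physiological parameters.

    Feasible iff every S1 beat activates, the S2 beat captures at the
    coupling interval, and neither the final S1 beat nor the S2 beat has an
    APD exceeding ``apd_max`` (or a failed recovery).
    """
    record = simulate_cell(params, protocol, dt=dt)
    lats = _beat_capture_times(record)
    reasons: list[str] = []
    if any(lat is None for lat in lats[:-1]):
        reasons.append("no-capture")
    if lats[-1] is None:
        reasons.append("no-capture-s2")
    windows = beat_windows(record)
    trace, times = record.site_traces[0], record.times
    apd_ok = True
    for window in (windows["S1"], windows["S2"]):
        lat = extract_lat(trace, times, window)
        if lat is None:
            continue  # capture failures already recorded above
        apd = extract_apd(trace, times, window)

        if apd is None:
            reasons.append("no-recovery")
        elif apd > apd_max:
            apd_ok = False
    if not apd_ok:
        reasons.append("APD>500")
    return CellFeasibility(feasible=not reasons, reasons=tuple(reasons))


@dataclass
class FeasibilityClassifier:
    """Probabilistic cell-feasibility classifier over the prior box."""

    model: object
    box: PriorBox
    heldout_accuracy: float

    def predict_proba(self, thetas: np.ndarray) -> np.ndarray:
        u = self.box.to_unit(np.atleast_2d(thetas))
        return self.model.predict_proba(u)[:, 1]

    def predict(self, thetas: np.ndarray, threshold: float = 0.5) -> np.ndarray:
        return self.predict_proba(thetas) >= threshold


def fit_feasibility_classifier(
    params: np.ndarray,
    flags: np.ndarray,
    box: PriorBox,
    seed: int = 0,
    test_fraction: float = 0.2,
) -> FeasibilityClassifier:
    """Fit a gradient-boosted probabilistic classifier on labelled cell runs.

    Requires at least 200 labelled points with both classes present; a
    single-class label set raises (use direct rejection instead).
    """
    from sklearn.ensemble import HistGradientBoostingClassifier
    from sklearn.model_selection import train_test_split

    params = np.asarray(params, dtype=float)
    flags = np.asarray(flags, dtype=bool)
    if len(params) < 200:
        raise ValueError("need at least 200 labelled points")
    if len(np.unique(flags)) < 2:
        raise ValueError(
            "labels contain a single class; use direct rejection (cell_feasible) "
            "instead of a classifier"
        )
    u = box.to_unit(params)
    u_tr, u_te, f_tr, f_te = train_test_split(
        u, flags, test_size=test_fraction, random_state=seed, stratify=flags
    )
    model = HistGradientBoostingClassifier(random_state=seed)
    model.fit(u_tr, f_tr)
    acc = float(model.score(u_te, f_te))
    return FeasibilityClassifier(model=model, box=box, heldout_accuracy=acc)


@dataclass
class TrainingEnsemble:
    """The filtered design: parameters, simulator outputs and stage log."""

    params: np.ndarray  # (M, 5)
    outputs: np.ndarray  # (M, p)
    labels: tuple[tuple[int, str], ...]
    noise_sd: np.ndarray  # (p,) default observation noise carried alongside
    box: PriorBox
    grid: GridSpec
    protocol: PacingProtocol
    sites: tuple[int, ...]
    stage_log: dict[str, int]
    seed: int
    dt: float = 0.05
    sampling_interval: float = 0.25

    @property
    def M(self) -> int:
        return self.params.shape[0]

    @property
    def p(self) -> int:
        return self.outputs.shape[1]

    def observation(self, row: int) -> ObservationVector:
        """Noise-free observation vector for a stored ensemble member."""
        return ObservationVector(
            values=self.outputs[row].copy(),
            labels=self.labels,
            noise_sd=self.noise_sd.copy(),
        )


def build_training_ensemble(
    box: PriorBox | None = None,
    target_m: int = 200,
    grid: GridSpec | None = None,
    protocol: PacingProtocol | None = None,
    sites: tuple[int, ...] | None = None,
    types: tuple[str, ...] = OUTPUT_TYPES,
    seed: int = 0,
    oversample: float = 2.5,
    dt: float = 0.05,
    sampling_interval: float = 0.25,
    noise_sd: float | dict[str, float] = DEFAULT_NOISE_SD,
    classifier: FeasibilityClassifier | None = None,
    min_m: int | None = None,
) -> TrainingEnsemble:
    """Design, filter and simulate the training ensemble.

    Stage 1 rejects cell-infeasible design points (directly by default, or
    with ``classifier`` if given); stage 2 simulates survivors on the tissue
    grid and drops any run with an absent output.  If more than ``target_m``
    rows survive, the first ``target_m`` (in design order) are kept.
    """
    box = box or PriorBox.default()
    grid = grid or default_cable_grid()
    protocol = protocol or PacingProtocol()
    if sites is None:
        sites = default_sensor_sites(grid)
    min_m = max(2, target_m // 4) if min_m is None else min_m

    n_design = math.ceil(target_m * oversample)
    design = lhs_design(n_design, box, seed=seed)

    # stage 1: cell-level rejection
    if classifier is not None:
        keep1 = classifier.predict(design)
    else:
        keep1 = np.array(
            [bool(cell_feasible(TissueParameters.from_array(t), protocol, dt=dt))
             for t in design]
        )
    survivors1 = design[keep1]

    # stage 2: tissue simulation + rejection of absent outputs.  Stops early
    # once the target size is reached (design order preserved).
    rows_theta, rows_y = [], []
    labels = None
    sd_vec = None
    n_simulated = 0
    for theta in survivors1:
        n_simulated += 1
        record = simulate(
            TissueParameters.from_array(theta),
            grid,
            protocol,
            dt=dt,
            sites=sites,
            sampling_interval=sampling_interval,
        )
        obs = build_observation(record, types=types, noise_sd=noise_sd)
        if labels is None:
            labels, sd_vec = obs.labels, obs.noise_sd
        if obs.feasible:
            rows_theta.append(theta)
            rows_y.append(obs.values)
        if len(rows_theta) >= target_m:
            break

    n_final = len(rows_theta)
    if n_final < min_m:
        rate = n_final / max(n_simulated, 1)
        raise RuntimeError(
            f"only {n_final} feasible rows (tissue acceptance rate {rate:.2f}); "
            f"increase oversampling or revisit the prior box"
        )
    stage_log = {
        "design": int(n_design),
        "cell_pass": int(keep1.sum()),
        "tissue_simulated": int(n_simulated),
        "final": int(n_final),
    }
    return TrainingEnsemble(
        params=np.array(rows_theta),
        outputs=np.array(rows_y),
        labels=labels,
        noise_sd=np.asarray(sd_vec),
        box=box,
        grid=grid,
        protocol=protocol,
        sites=tuple(sites),
        stage_log=stage_log,
        seed=seed,
        dt=dt,
        sampling_interval=sampling_interval,
    )
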