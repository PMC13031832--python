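"""Measurement extraction: LAT, APD and noisy observation vectors.

Three output types are measured from an S1S2-paced run at a set of sensor
sites:

* ``S1``  — local activation time (LAT) of the final S1 beat,
* ``S2``  — LAT of the premature S2 beat,
* ``APD`` — action potential duration of the S2 beat.

LAT is the first time the normalised voltage crosses 0.75 from below
(positive time derivative), linearly interpolated between samples and
reported relative to the onset of the beat's own stimulus.  The local
recovery time (LRT) is the first time after the beat's peak at which the
voltage falls back to 10% of the beat's maximum amplitude; APD = LRT - LAT.
A site where a feature cannot be extracted (failed capture, no recovery)
yields an *absent* value, which marks the whole observation infeasible —
this is a valid outcome consumed by design-stage rejection, not an error.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from mmscalib.forward_model import SimulationRecord

__all__ = [
    "OUTPUT_TYPES",
    "LAT_THRESHOLD",
    "RECOVERY_FRACTION",
    "DEFAULT_NOISE_SD",
    "ObservationVector",
    "extract_lat",
    "extract_apd",
    "build_observation",
    "add_noise",
]

#: Canonical output-type ordering of the observation vector.
OUTPUT_TYPES = ("S1", "S2", "APD")

LAT_THRESHOLD = 0.75
RECOVERY_FRACTION = 0.10

#: Default observation-noise standard deviation (ms) for every output type.
DEFAULT_NOISE_SD = 1.0


@dataclass
class ObservationVector:
    """Ordered measurement vector y with labels and diagonal noise covariance.

    Canonical ordering: all S1 entries by site, then all S2, then all APD.
    ``noise_sd`` holds per-entry standard deviations (ms); the covariance R
    is diagonal with entries ``noise_sd**2``.  Absent features are stored as
    NaN with ``feasible=False``.
    """

    values: np.ndarray  # (p,) ms
    labels: tuple[tuple[int, str], ...]  # (site index, output type)
    noise_sd: np.ndarray  # (p,) ms
    feasible: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.noise_sd = np.asarray(self.noise_sd, dtype=float)
        if not (len(self.values) == len(self.labels) == len(self.noise_sd)):
            raise ValueError("values, labels and noise_sd must have equal length")
        # zero is tolerated as a noise-free test mode; negative is invalid
        if np.any(self.noise_sd < 0):
            raise ValueError("noise standard deviations must be non-negative")

    @property
    def p(self) -> int:
        return len(self.values)

    @property
    def R(self) -> np.ndarray:
        """Diagonal noise covariance matrix (p x p, ms^2)."""
        return np.diag(self.noise_sd**2)

    @property
    def noise_var(self) -> np.ndarray:
        return self.noise_sd**2

    def subset(self, types: tuple[str, ...]) -> "ObservationVector":
        """Restrict to a measurement combination, keeping canonical order."""
        types = _validate_types(types)
        keep = [i for i, (_, t) in enumerate(self.labels) if t in types]
        return ObservationVector(
            values=self.values[keep],
            labels=tuple(self.labels[i] for i in keep),
            noise_sd=self.noise_sd[keep],
            feasible=self.feasible and bool(np.all(np.isfinite(self.values[keep]))),
        )


def _validate_types(types) -> tuple[str, ...]:
    types = tuple(types)
    if len(types) == 0:
        raise ValueError("at least one output type is required")
    bad = [t for t in types if t not in OUTPUT_TYPES]
    if bad:
        raise ValueError(f"unknown output types {bad}; valid: {OUTPUT_TYPES}")
    # canonical order
    return tuple(t for t in OUTPUT_TYPES if t in types)


def _interp_crossing(t0, t1, v0, v1, level):
    if v1 == v0:
        return t0
    return t0 + (level - v0) / (v1 - v0) * (t1 - t0)


def extract_lat(
    trace: np.ndarray,
    times: np.ndarray,
    window: tuple[float, float],
    threshold: float = LAT_THRESHOLD,
) -> float | None:
    """First upward crossing of ``threshold`` inside ``window`` (absolute ms).

    Linear interpolation between samples; a sample landing exactly on the
    threshold counts as a crossing.  Returns ``None`` when the trace never
    crosses from below inside the window (failed capture).
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    t_start, t_end = window
    idx = np.nonzero((times >= t_start) & (times <= t_end))[0]
    if len(idx) < 2:
        return None
    for i in idx[:-1]:
        v0, v1 = trace[i], trace[i + 1]
        if v0 < threshold <= v1:
            return float(_interp_crossing(times[i], times[i + 1], v0, v1, threshold))
    return None


def extract_apd(
    trace: np.ndarray,
    times: np.ndarray,
    window: tuple[float, float],
    threshold: float = LAT_THRESHOLD,
    recovery_fraction: float = RECOVERY_FRACTION,
) -> float | None:
    """APD = LRT - LAT for the single beat inside ``window``.

    The beat's maximum amplitude is the peak voltage in the window; LRT is
    the first (interpolated) time after the peak at which the voltage drops
    to ``recovery_fraction`` of that maximum.  Absent if the beat never
    activates or never recovers inside the window.
    """
    lat = extract_lat(trace, times, window, threshold)
    if lat is None:
        return None
    t_start, t_end = window
    idx = np.nonzero((times >= t_start) & (times <= t_end))[0]
    seg = trace[idx]
    i_max = int(np.argmax(seg))
    v_max = float(seg[i_max])
    level = recovery_fraction * v_max
    for j in range(i_max, len(idx) - 1):
        v0, v1 = seg[j], seg[j + 1]
        if v0 > level >= v1:
            lrt = _interp_crossing(
                times[idx[j]], times[idx[j + 1]], v0, v1, level
            )
            return float(lrt - lat)
    return None


def beat_windows(record: SimulationRecord) -> dict[str, tuple[float, float]]:
    """Analysis windows: the final S1 beat spans its stimulus to the S2
    stimulus; the S2 beat spans the S2 stimulus to the end of the trace."""
    stim = record.stimulus_times
    if len(stim) < 2:
        raise ValueError("record must contain at least one S1 and the S2 stimulus")
    last_s1, s2 = stim[-2], stim[-1]
    t_end = float(record.times[-1])
    return {"S1": (last_s1, s2), "S2": (s2, t_end), "APD": (s2, t_end)}


def build_observation(
    record: SimulationRecord,
    sites: tuple[int, ...] | None = None,
    types: tuple[str, ...] = OUTPUT_TYPES,
    noise_sd: float | dict[str, float] = DEFAULT_NOISE_SD,
) -> ObservationVector:
    """Assemble the canonical observation vector from a simulation record.

    LATs are reported relative to the onset of their own stimulus.  Any
    absent feature at any site marks the observation infeasible (values NaN)
    so that design-stage rejection can act on it.
    """
    types = _validate_types(types)
    if sites is None:
        sites = record.sites
    windows = beat_windows(record)
    onsets = {"S1": windows["S1"][0], "S2": windows["S2"][0], "APD": None}
    times = record.times

    values, labels, sds = [], [], []
    feasible = True
    for typ in types:
        for site in sites:
            trace = record.trace(site)
            if typ == "APD":
                val = extract_apd(trace, times, windows["APD"])
            else:
                lat = extract_lat(trace, times, windows[typ])
                val = None if lat is None else lat - onsets[typ]
            if val is None:
                feasible = False
                val = np.nan
            values.append(val)
            labels.append((int(site), typ))
            if isinstance(noise_sd, dict):
                sds.append(float(noise_sd[typ]))
            else:
                sds.append(float(noise_sd))
    return ObservationVector(
        values=np.array(values),
        labels=tuple(labels),
        noise_sd=np.array(sds),
        feasible=feasible,
    )


def add_noise(
    obs: ObservationVector, seed: int | np.random.Generator
) -> ObservationVector:
    """Return a copy with zero-mean Gaussian noise eta ~ N(0, R) added to y."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    noisy = obs.values + rng.normal(0.0, obs.noise_sd)
    return replace(obs, values=noisy)
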