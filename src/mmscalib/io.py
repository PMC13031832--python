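"""Serialisation: HDF5 for simulation/ensemble/emulator/calibration artefacts,
CSV/JSON for observation vectors, YAML for configuration.

Emulator sets are stored as training data plus fitted kernel
hyperparameters; loading re-solves the GP linear systems with the optimiser
disabled, which restores predictions exactly without pickling estimator
internals.
"""

from __future__ import annotations

import json

import h5py
import numpy as np
import pandas as pd
import yaml

from mmscalib.design import PriorBox, TrainingEnsemble
from mmscalib.enkf import CalibrationResult, EnkfConfig, ParticleEnsemble
from mmscalib.forward_model import (
    GridSpec,
    PacingProtocol,
    SimulationRecord,
    TissueParameters,
)
from mmscalib.observables import ObservationVector

__all__ = [
    "save_record",
    "load_record",
    "save_ensemble",
    "load_ensemble",
    "save_emulators",
    "load_emulators",
    "save_calibration",
    "load_calibration",
    "observation_to_csv",
    "observation_from_csv",
    "observation_to_json",
    "observation_from_json",
    "load_yaml_config",
]


def _grid_attrs(g: h5py.Group, grid: GridSpec) -> None:
    g.attrs["dimensionality"] = grid.dimensionality
    g.attrs["node_counts"] = np.asarray(grid.node_counts)
    g.attrs["dx"] = grid.dx


def _grid_from_attrs(g: h5py.Group) -> GridSpec:
    return GridSpec(
        dimensionality=int(g.attrs["dimensionality"]),
        node_counts=tuple(int(n) for n in np.atleast_1d(g.attrs["node_counts"])),
        dx=float(g.attrs["dx"]),
    )


def _protocol_attrs(g: h5py.Group, protocol: PacingProtocol) -> None:
    g.attrs["n_s1"] = protocol.n_s1
    g.attrs["s1_interval"] = protocol.s1_interval
    g.attrs["s2_coupling"] = protocol.s2_coupling
    g.attrs["stim_amplitude"] = protocol.stim_amplitude
    g.attrs["stim_duration"] = protocol.stim_duration
    if protocol.stim_region is not None:
        g.attrs["stim_region"] = np.asarray(protocol.stim_region)


def _protocol_from_attrs(g: h5py.Group) -> PacingProtocol:
    region = g.attrs.get("stim_region")
    return PacingProtocol(
        n_s1=int(g.attrs["n_s1"]),
        s1_interval=float(g.attrs["s1_interval"]),
        s2_coupling=float(g.attrs["s2_coupling"]),
        stim_region=None if region is None else tuple(int(i) for i in region),
        stim_amplitude=float(g.attrs["stim_amplitude"]),
        stim_duration=float(g.attrs["stim_duration"]),
    )


def save_record(path: str, record: SimulationRecord) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("site_traces", data=record.site_traces)
        f.create_dataset("stimulus_times", data=np.asarray(record.stimulus_times))
        f.create_dataset("sites", data=np.asarray(record.sites))
        if record.full_field_snapshots is not None:
            f.create_dataset("full_field_snapshots", data=record.full_field_snapshots)
        f.attrs["sampling_interval"] = record.sampling_interval
        f.attrs["dt"] = record.dt
        f.attrs["params"] = record.params.to_array()
        f.attrs["v_gate"] = record.params.v_gate
        _grid_attrs(f, record.grid)
        if record.protocol is not None:
            _protocol_attrs(f.create_group("protocol"), record.protocol)


def load_record(path: str) -> SimulationRecord:
    with h5py.File(path, "r") as f:
        protocol = (
            _protocol_from_attrs(f["protocol"]) if "protocol" in f else None
        )
        return SimulationRecord(
            site_traces=f["site_traces"][...],
            sites=tuple(int(s) for s in f["sites"][...]),
            sampling_interval=float(f.attrs["sampling_interval"]),
            stimulus_times=tuple(float(t) for t in f["stimulus_times"][...]),
            grid=_grid_from_attrs(f),
            params=TissueParameters.from_array(
                f.attrs["params"], v_gate=float(f.attrs["v_gate"])
            ),
            protocol=protocol,
            dt=float(f.attrs["dt"]),
            full_field_snapshots=(
                f["full_field_snapshots"][...]
                if "full_field_snapshots" in f
                else None
            ),
        )


def _labels_to_arrays(labels):
    sites = np.asarray([s for s, _ in labels], dtype=np.int64)
    types = np.asarray([t for _, t in labels], dtype="S8")
    return sites, types


def _labels_from_arrays(sites, types):
    return tuple(
        (int(s), t.decode() if isinstance(t, bytes) else str(t))
        for s, t in zip(sites, types)
    )


def save_ensemble(path: str, ensemble: TrainingEnsemble) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("params", data=ensemble.params)
        f.create_dataset("outputs", data=ensemble.outputs)
        sites, types = _labels_to_arrays(ensemble.labels)
        f.create_dataset("label_sites", data=sites)
        f.create_dataset("label_types", data=types)
        f.create_dataset("noise_sd", data=ensemble.noise_sd)
        f.create_dataset("sites", data=np.asarray(ensemble.sites))
        f.attrs["box_lower"] = ensemble.box.lower
        f.attrs["box_upper"] = ensemble.box.upper
        f.attrs["seed"] = ensemble.seed
        f.attrs["dt"] = ensemble.dt
        f.attrs["sampling_interval"] = ensemble.sampling_interval
        f.attrs["stage_log"] = json.dumps(ensemble.stage_log)
        _grid_attrs(f.create_group("grid"), ensemble.grid)
        _protocol_attrs(f.create_group("protocol"), ensemble.protocol)


def load_ensemble(path: str) -> TrainingEnsemble:
    with h5py.File(path, "r") as f:
        return TrainingEnsemble(
            params=f["params"][...],
            outputs=f["outputs"][...],
            labels=_labels_from_arrays(f["label_sites"][...], f["label_types"][...]),
            noise_sd=f["noise_sd"][...],
            box=PriorBox(f.attrs["box_lower"], f.attrs["box_upper"]),
            grid=_grid_from_attrs(f["grid"]),
            protocol=_protocol_from_attrs(f["protocol"]),
            sites=tuple(int(s) for s in f["sites"][...]),
            stage_log=json.loads(f.attrs["stage_log"]),
            seed=int(f.attrs["seed"]),
            dt=float(f.attrs["dt"]),
            sampling_interval=float(f.attrs["sampling_interval"]),
        )


def save_emulators(path: str, emulators) -> None:
    """Store kernel hyperparameters + training data (not pickled estimators)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("train_X", data=emulators.train_X)
        f.create_dataset("train_Y", data=emulators.train_Y)
        f.create_dataset("y_mean", data=emulators.y_mean)
        f.create_dataset("y_std", data=emulators.y_std)
        f.create_dataset("log_scale", data=emulators.log_scale.astype(np.int8))
        sites, types = _labels_to_arrays(emulators.labels)
        f.create_dataset("label_sites", data=sites)
        f.create_dataset("label_types", data=types)
        f.attrs["box_lower"] = emulators.box.lower
        f.attrs["box_upper"] = emulators.box.upper
        f.attrs["unreliable"] = np.asarray(emulators.unreliable, dtype=np.int64)
        theta = np.array([gp.kernel_.theta for gp in emulators.gps])
        f.create_dataset("kernel_log_hyperparameters", data=theta)


def load_emulators(path: str):
    from sklearn.gaussian_process import GaussianProcessRegressor

    from mmscalib.emulator import EmulatorSet, _default_kernel

    with h5py.File(path, "r") as f:
        train_X = f["train_X"][...]
        train_Y = f["train_Y"][...]
        y_mean = f["y_mean"][...]
        y_std = f["y_std"][...]
        log_scale = f["log_scale"][...].astype(bool)
        labels = _labels_from_arrays(f["label_sites"][...], f["label_types"][...])
        box = PriorBox(f.attrs["box_lower"], f.attrs["box_upper"])
        unreliable = tuple(int(i) for i in f.attrs["unreliable"])
        thetas = f["kernel_log_hyperparameters"][...]
    u = box.to_unit(train_X)
    gps = []
    for j in range(train_Y.shape[1]):
        kernel = _default_kernel(box.dim).clone_with_theta(thetas[j])
        gp = GaussianProcessRegressor(kernel=kernel, alpha=1e-10, optimizer=None)
        T = np.log(train_Y[:, j]) if log_scale[j] else train_Y[:, j]
        gp.fit(u, (T - y_mean[j]) / y_std[j])
        gps.append(gp)
    return EmulatorSet(
        gps=gps,
        box=box,
        y_mean=y_mean,
        y_std=y_std,
        log_scale=log_scale,
        labels=labels,
        train_X=train_X,
        train_Y=train_Y,
        unreliable=unreliable,
    )


def save_calibration(path: str, result: CalibrationResult) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("particles", data=result.ensemble.particles)
        f.create_dataset("mean_trajectory", data=result.mean_trajectory)
        f.create_dataset("cov_trajectory", data=result.cov_trajectory)
        f.create_dataset("gain_norms", data=result.gain_norms)
        f.attrs["iteration"] = result.ensemble.iteration
        f.attrs["convergence_iteration"] = (
            -1
            if result.convergence_iteration is None
            else result.convergence_iteration
        )
        f.attrs["diverged"] = result.diverged
        f.attrs["box_lower"] = result.box.lower
        f.attrs["box_upper"] = result.box.upper
        cfg = result.config
        f.attrs["config"] = json.dumps(
            {
                "n_particles": cfg.n_particles,
                "n_steps": cfg.n_steps,
                "sigma_theta": (
                    None
                    if cfg.sigma_theta is None
                    else np.asarray(cfg.sigma_theta).tolist()
                ),
                "seed": cfg.seed,
                "boundary_policy": cfg.boundary_policy,
                "conv_tol": cfg.conv_tol,
                "sample_emulator": cfg.sample_emulator,
            }
        )


def load_calibration(path: str) -> CalibrationResult:
    with h5py.File(path, "r") as f:
        cfg_d = json.loads(f.attrs["config"])
        sigma = cfg_d.pop("sigma_theta")
        cfg = EnkfConfig(
            sigma_theta=None if sigma is None else np.asarray(sigma), **cfg_d
        )
        conv = int(f.attrs["convergence_iteration"])
        return CalibrationResult(
            ensemble=ParticleEnsemble(
                particles=f["particles"][...], iteration=int(f.attrs["iteration"])
            ),
            mean_trajectory=f["mean_trajectory"][...],
            cov_trajectory=f["cov_trajectory"][...],
            gain_norms=f["gain_norms"][...],
            convergence_iteration=None if conv < 0 else conv,
            diverged=bool(f.attrs["diverged"]),
            config=cfg,
            box=PriorBox(f.attrs["box_lower"], f.attrs["box_upper"]),
        )


def observation_to_csv(path: str, obs: ObservationVector) -> None:
    df = pd.DataFrame(
        {
            "site": [s for s, _ in obs.labels],
            "type": [t for _, t in obs.labels],
            "value_ms": obs.values,
            "noise_sd_ms": obs.noise_sd,
        }
    )
    df.to_csv(path, index=False)


def observation_to_json(path: str, obs: ObservationVector) -> None:
    payload = {
        "labels": [[int(s), t] for s, t in obs.labels],
        "values_ms": obs.values.tolist(),
        "noise_sd_ms": obs.noise_sd.tolist(),
        "feasible": bool(obs.feasible),
    }
    with open(path, "w") as f:
        json.dump(payload, f, indent=2)


def observation_from_json(path: str) -> ObservationVector:
    with open(path) as f:
        payload = json.load(f)
    return ObservationVector(
        values=np.asarray(payload["values_ms"], dtype=float),
        labels=tuple((int(s), str(t)) for s, t in payload["labels"]),
        noise_sd=np.asarray(payload["noise_sd_ms"], dtype=float),
        feasible=bool(payload["feasible"]),
    )


def observation_from_csv(path: str) -> ObservationVector:
    df = pd.read_csv(path)
    values = df["value_ms"].to_numpy(dtype=float)
    return ObservationVector(
        values=values,
        labels=tuple((int(s), str(t)) for s, t in zip(df["site"], df["type"])),
        noise_sd=df["noise_sd_ms"].to_numpy(dtype=float),
        feasible=bool(np.all(np.isfinite(values))),
    )


def load_yaml_config(path: str) -> dict:
    with open(path) as f:
        return yaml.safe_load(f) or {}
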