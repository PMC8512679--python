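"""Trial and result I/O: HDF5 and flat CSV dialects, YAML configuration.

HDF5 layout (one group per trial)::

    /<trial_name>/
        attrs: fs, fs_emg, mass, bw, seed
        theta/<joint>, omega/<joint>, alpha_ang/<joint>
        joint_centres/<joint>/<pos|vel|acc>      (n, 2)
        heel_pos                                  (n, 2)
        emg_env                                   (8, n)
        emg_raw                                   (8, n_emg)  [own rate fs_emg]
        grf                                       (3, n)  AP/ML/V, N
        cop                                       (2, n)  AP/ML, mm

The flat CSV dialect has one row per sample of the common kinematic
grid and one column per channel; the raw EMG block runs at its own
sampling rate and therefore lives in a sidecar ``<stem>_emg_raw.csv``.
Both dialects round-trip losslessly (up to float64 text precision for
CSV) except for the in-memory ground-truth block, which is a
generator-only object.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .synthetic import EMG_CHANNELS, JOINTS, StanceTrial

__all__ = [
    "write_trial_hdf5",
    "read_trial_hdf5",
    "write_trial_csv",
    "read_trial_csv",
    "write_torques_csv",
    "write_estimates_csv",
    "write_selection_csv",
    "load_config",
    "DEFAULT_CONFIG",
]

DEFAULT_CONFIG: dict = {
    "cohort": {
        "n_subjects": 5,
        "n_trials": 4,
        "seed": 0,
        "anthropometry_ranges": {"mass": [55.0, 90.0], "height": [1.55, 1.85]},
        "noise": {"angle_sd": 0.003, "marker_sd": 0.002, "grf_sd": 3.0,
                  "cop_sd": 2.0, "emg_sd": 0.02},
    },
    "pipeline": {
        "reduced": True,
        "seed": 0,
    },
}


def load_config(path: str | Path | None) -> dict:
    """Read a YAML config, merged over the defaults (shallow per section)."""
    cfg = {k: dict(v) for k, v in DEFAULT_CONFIG.items()}
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for section, values in user.items():
            cfg.setdefault(section, {}).update(values or {})
    return cfg


# ---------------------------------------------------------------------------
# HDF5
# ---------------------------------------------------------------------------

def write_trial_hdf5(path: str | Path, trial: StanceTrial, name: str = "trial",
                     mode: str = "a") -> None:
    """Append one trial as a group to an HDF5 file."""
    with h5py.File(path, mode) as fh:
        if name in fh:
            del fh[name]
        g = fh.create_group(name)
        g.attrs["fs"] = trial.fs
        g.attrs["fs_emg"] = trial.fs_emg
        g.attrs["mass"] = trial.mass
        g.attrs["bw"] = trial.bw
        g.attrs["seed"] = trial.seed
        g.create_dataset("t", data=trial.t)
        for block_name in ("theta", "omega", "alpha_ang"):
            sub = g.create_group(block_name)
            for j, v in getattr(trial, block_name).items():
                sub.create_dataset(j, data=v)
        jc = g.create_group("joint_centres")
        for j, d in trial.joint_centres.items():
            gj = jc.create_group(j)
            for key, v in d.items():
                gj.create_dataset(key, data=v)
        g.create_dataset("heel_pos", data=trial.heel_pos)
        g.create_dataset("emg_raw", data=trial.emg_raw)
        g.create_dataset("emg_env", data=trial.emg_env)
        g.create_dataset("grf", data=trial.grf)
        g.create_dataset("cop", data=trial.cop)


def read_trial_hdf5(path: str | Path, name: str = "trial") -> StanceTrial:
    """Read one trial group back into a :class:`StanceTrial` (no truth block)."""
    with h5py.File(path, "r") as fh:
        g = fh[name]
        blocks = {}
        for block_name in ("theta", "omega", "alpha_ang"):
            blocks[block_name] = {j: np.asarray(g[block_name][j]) for j in g[block_name]}
        jc = {
            j: {key: np.asarray(g["joint_centres"][j][key]) for key in g["joint_centres"][j]}
            for j in g["joint_centres"]
        }
        return StanceTrial(
            fs=float(g.attrs["fs"]), t=np.asarray(g["t"]),
            theta=blocks["theta"], omega=blocks["omega"],
            alpha_ang=blocks["alpha_ang"], joint_centres=jc,
            heel_pos=np.asarray(g["heel_pos"]),
            emg_raw=np.asarray(g["emg_raw"]), emg_env=np.asarray(g["emg_env"]),
            grf=np.asarray(g["grf"]), cop=np.asarray(g["cop"]),
            mass=float(g.attrs["mass"]), bw=float(g.attrs["bw"]),
            fs_emg=float(g.attrs["fs_emg"]), seed=int(g.attrs["seed"]),
        )


# ---------------------------------------------------------------------------
# flat CSV
# ---------------------------------------------------------------------------

def _trial_frame(trial: StanceTrial) -> pd.DataFrame:
    cols: dict[str, np.ndarray] = {"t": trial.t}
    for block_name in ("theta", "omega", "alpha_ang"):
        for j, v in getattr(trial, block_name).items():
            cols[f"{block_name}_{j}"] = v
    for j, d in trial.joint_centres.items():
        for key, v in d.items():
            for ax, axname in enumerate(("x", "y")):
                cols[f"jc_{j}_{key}_{axname}"] = v[:, ax]
    for ax, axname in enumerate(("x", "y")):
        cols[f"heel_pos_{axname}"] = trial.heel_pos[:, ax]
    for ci, ch in enumerate(EMG_CHANNELS):
        cols[f"emg_env_{ch}"] = trial.emg_env[ci]
    for row, nm in zip(trial.grf, ("ap", "ml", "v")):
        cols[f"grf_{nm}"] = row
    for row, nm in zip(trial.cop, ("ap", "ml")):
        cols[f"cop_{nm}"] = row
    return pd.DataFrame(cols)


def write_trial_csv(path: str | Path, trial: StanceTrial) -> None:
    """Write the common-grid channels as flat CSV + raw EMG sidecar.

    The header comment row carries fs/mass metadata.
    """
    path = Path(path)
    frame = _trial_frame(trial)
    with open(path, "w") as fh:
        fh.write(f"# fs={trial.fs} fs_emg={trial.fs_emg} mass={trial.mass!r} "
                 f"bw={trial.bw!r} seed={trial.seed}\n")
        frame.to_csv(fh, index=False, float_format="%.12g")
    raw = pd.DataFrame({f"emg_raw_{ch}": trial.emg_raw[ci]
                        for ci, ch in enumerate(EMG_CHANNELS)})
    raw.to_csv(path.with_name(path.stem + "_emg_raw.csv"), index=False,
               float_format="%.12g")


def read_trial_csv(path: str | Path) -> StanceTrial:
    """Read a flat-CSV trial (written by :func:`write_trial_csv`)."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().lstrip("# ").split()
        meta = {k: float(v) for k, v in (item.split("=") for item in header)}
        frame = pd.read_csv(fh)
    raw = pd.read_csv(path.with_name(path.stem + "_emg_raw.csv"))
    theta = {j: frame[f"theta_{j}"].to_numpy() for j in JOINTS}
    omega = {j: frame[f"omega_{j}"].to_numpy() for j in JOINTS}
    alpha = {j: frame[f"alpha_ang_{j}"].to_numpy() for j in JOINTS}
    jc = {}
    for j in ("ankle", "knee", "hip"):
        jc[j] = {key: np.stack([frame[f"jc_{j}_{key}_x"].to_numpy(),
                                frame[f"jc_{j}_{key}_y"].to_numpy()], axis=-1)
                 for key in ("pos", "vel", "acc")}
    return StanceTrial(
        fs=meta["fs"], t=frame["t"].to_numpy(),
        theta=theta, omega=omega, alpha_ang=alpha, joint_centres=jc,
        heel_pos=np.stack([frame["heel_pos_x"].to_numpy(),
                           frame["heel_pos_y"].to_numpy()], axis=-1),
        emg_raw=np.stack([raw[f"emg_raw_{ch}"].to_numpy() for ch in EMG_CHANNELS]),
        emg_env=np.stack([frame[f"emg_env_{ch}"].to_numpy() for ch in EMG_CHANNELS]),
        grf=np.stack([frame[f"grf_{nm}"].to_numpy() for nm in ("ap", "ml", "v")]),
        cop=np.stack([frame[f"cop_{nm}"].to_numpy() for nm in ("ap", "ml")]),
        mass=meta["mass"], bw=meta["bw"], fs_emg=meta["fs_emg"],
        seed=int(meta["seed"]),
    )


# ---------------------------------------------------------------------------
# result writers
# ---------------------------------------------------------------------------

def write_torques_csv(path: str | Path, torques: dict[str, np.ndarray]) -> None:
    """Phase-normalised torque series (Nm/kg): columns phase, hip, knee, ankle."""
    n = len(next(iter(torques.values())))
    frame = pd.DataFrame({"phase_pct": np.linspace(0, 100, n),
                          **{j: torques[j] for j in JOINTS}})
    frame.to_csv(path, index=False, float_format="%.8g")


def write_estimates_csv(path: str | Path, measured: dict[str, np.ndarray],
                        estimated: dict[str, np.ndarray]) -> None:
    """Measured and estimated target channels on the phase grid."""
    n = len(next(iter(measured.values())))
    cols = {"phase_pct": np.linspace(0, 100, n)}
    for key in measured:
        cols[f"{key}_measured"] = measured[key]
        if key in estimated:
            cols[f"{key}_estimated"] = estimated[key]
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.8g")


def write_selection_csv(path: str | Path, target: str, table: list[dict]) -> None:
    """NCA selection table: target, feature, squared weight, selected flag."""
    frame = pd.DataFrame([{"target": target, **row} for row in table])
    frame.to_csv(path, index=False, float_format="%.8g")
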