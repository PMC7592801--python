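"""Trial file formats: tidy CSV + JSON sidecar, and MAT-file ingestion.

A trial is stored as a directory of tidy CSV files (one per signal category,
columns ``time_s, channel, value``) plus ``meta.json`` holding the sampling
rate, participant, condition and trial metadata.  Numeric output uses 9
significant digits so repeated runs diff byte-stable.

MAT-file containers holding the same signals can be read through a
user-editable key map that names the variable path of every field, because
the internal layout of such containers varies between laboratories.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import ConditionSpec, GaitTrial, ParticipantSpec

FLOAT_FMT = "%.9g"

_CATEGORIES = ("joint_angles", "joint_moments", "grf", "emg")


def _tidy(time, channels: dict):
    frames = [pd.DataFrame({"time_s": time, "channel": name, "value": series})
              for name, series in channels.items()]
    return pd.concat(frames, ignore_index=True)


def write_trial(trial: GaitTrial, path):
    """Write a trial as a directory of tidy CSVs plus a JSON sidecar."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    t = trial.time
    tables = {
        "joint_angles": trial.joint_angles,
        "joint_moments": trial.joint_moments,
        "grf": {"ipsi": trial.grf_vertical_ipsi, "contra": trial.grf_vertical_contra},
        "emg": trial.emg_envelope,
    }
    for name, channels in tables.items():
        _tidy(t, channels).to_csv(path / f"{name}.csv", index=False,
                                  float_format=FLOAT_FMT)
    meta = {
        "sampling_rate": trial.sampling_rate,
        "n_samples": int(len(t)),
        "participant": {
            "id": trial.participant.id,
            "body_mass": trial.participant.body_mass,
            "stride_period": trial.participant.stride_period,
            "stance_fraction": trial.participant.stance_fraction,
            "template_scales": trial.participant.template_scales,
            "mvc": trial.participant.mvc,
        },
        "condition": {
            "grade_deg": trial.condition.grade_deg,
            "shoe_inclination_deg": trial.condition.shoe_inclination_deg,
            "speed": trial.condition.speed,
        },
        "meta": {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                 for k, v in trial.meta.items()},
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=1, sort_keys=True))
    return path


def _read_tidy(path: Path, n_samples: int):
    if not path.exists():
        raise FileNotFoundError(f"missing trial file {path}")
    df = pd.read_csv(path)
    out = {}
    for name, grp in df.groupby("channel", sort=False):
        series = grp.value.to_numpy(dtype=float)
        if len(series) != n_samples:
            raise ValueError(f"{path}: channel {name} has {len(series)} samples, "
                             f"expected {n_samples}")
        out[name] = series
    return out


def read_trial(path) -> GaitTrial:
    """Read a trial directory written by :func:`write_trial`."""
    path = Path(path)
    meta_path = path / "meta.json"
    if not meta_path.exists():
        raise FileNotFoundError(f"missing trial sidecar {meta_path}")
    meta = json.loads(meta_path.read_text())
    n = int(meta["n_samples"])
    angles = _read_tidy(path / "joint_angles.csv", n)
    moments = _read_tidy(path / "joint_moments.csv", n)
    grf = _read_tidy(path / "grf.csv", n)
    emg = _read_tidy(path / "emg.csv", n)
    p = meta["participant"]
    participant = ParticipantSpec(
        id=p["id"], body_mass=p["body_mass"], stride_period=p["stride_period"],
        stance_fraction=p["stance_fraction"],
        template_scales=p.get("template_scales", {}), mvc=p["mvc"])
    c = meta["condition"]
    condition = ConditionSpec(grade_deg=c["grade_deg"],
                              shoe_inclination_deg=c["shoe_inclination_deg"],
                              speed=c.get("speed", 1.0))
    for muscle in participant.mvc:
        if muscle not in emg:
            raise ValueError(f"{path}: missing EMG channel for muscle {muscle!r}")
    extras = {k: (np.asarray(v) if isinstance(v, list) else v)
              for k, v in meta.get("meta", {}).items()}
    fs = float(meta["sampling_rate"])
    return GaitTrial(
        sampling_rate=fs, time=np.arange(n) / fs,
        joint_angles=angles, joint_moments=moments,
        grf_vertical_ipsi=grf["ipsi"], grf_vertical_contra=grf["contra"],
        emg_envelope=emg, condition=condition, participant=participant,
        meta=extras)


#: Template key map for MAT ingestion: our field -> variable path in the file.
#: Paths are dot-separated struct fields; per-channel fields map a dict of
#: channel name -> path.  Edit a copy of this to match a given container.
DEFAULT_MAT_KEYMAP = {
    "sampling_rate": "fs",
    "joint_angles": {"hip": "angles.hip", "knee": "angles.knee", "ankle": "angles.ankle"},
    "joint_moments": {"hip": "moments.hip", "knee": "moments.knee", "ankle": "moments.ankle"},
    "grf_vertical_ipsi": "grf.ipsi",
    "grf_vertical_contra": "grf.contra",
    "emg_envelope": {},   # muscle -> path
    "body_mass": "participant.mass",
    "participant_id": "participant.id",
    "stride_period": "participant.stride_period",
    "stance_fraction": "participant.stance_fraction",
    "mvc": {},            # muscle -> path
    "grade_deg": "condition.grade",
    "shoe_inclination_deg": "condition.shoe",
}


def _resolve(container, dotted: str, origin: str):
    node = container
    for key in dotted.split("."):
        try:
            node = node[key]
        except (KeyError, IndexError, TypeError):
            raise KeyError(f"{origin}: key path {dotted!r} not found (failed at {key!r})")
    return node


def read_trial_mat(path, keymap: dict) -> GaitTrial:
    """Read a trial from a MAT container using an explicit key map."""
    from scipy.io import loadmat

    path = str(path)
    data = loadmat(path, simplify_cells=True)

    def scalar(field, default=None):
        dotted = keymap.get(field)
        if dotted is None:
            if default is None:
                raise KeyError(f"{path}: key map lacks required field {field!r}")
            return default
        return float(np.squeeze(_resolve(data, dotted, path)))

    def series_map(field):
        return {name: np.asarray(_resolve(data, dotted, path), dtype=float).ravel()
                for name, dotted in keymap.get(field, {}).items()}

    fs = scalar("sampling_rate")
    angles = series_map("joint_angles")
    moments = series_map("joint_moments")
    emg = series_map("emg_envelope")
    grf_i = np.asarray(_resolve(data, keymap["grf_vertical_ipsi"], path), dtype=float).ravel()
    grf_c = np.asarray(_resolve(data, keymap["grf_vertical_contra"], path), dtype=float).ravel()
    mvc = {name: float(np.squeeze(_resolve(data, dotted, path)))
           for name, dotted in keymap.get("mvc", {}).items()}
    if not mvc:
        mvc = {name: 1.0 for name in emg}
    pid = keymap.get("participant_id")
    pid = str(np.squeeze(_resolve(data, pid, path))) if pid else "mat"
    participant = ParticipantSpec(
        id=pid, body_mass=scalar("body_mass"),
        stride_period=scalar("stride_period", 1.12),
        stance_fraction=scalar("stance_fraction", 0.65), mvc=mvc)
    condition = ConditionSpec(grade_deg=scalar("grade_deg", 0.0),
                              shoe_inclination_deg=scalar("shoe_inclination_deg", 0.0))
    n = len(grf_i)
    return GaitTrial(
        sampling_rate=fs, time=np.arange(n) / fs, joint_angles=angles,
        joint_moments=moments, grf_vertical_ipsi=grf_i,
        grf_vertical_contra=grf_c, emg_envelope=emg,
        condition=condition, participant=participant,
        meta={"source": path})
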