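"""HDF5 containers for sessions, predictions and model checkpoints.

Session layout::

    /meta                 attrs: fs, n_trials, schema_version
    /trials/<k>/fine      (n_fine, T) float64
    /trials/<k>/coarse    (n_coarse, T) float64
    /trials/<k>           attrs: target_direction, movement_onset, trial_id
    /channels/name|role|region   string datasets

Model checkpoints store the architecture as a JSON string attribute and
one dataset per weight tensor; round trips are bit-exact.
"""

from __future__ import annotations

import tomllib
from dataclasses import fields as dc_fields
from pathlib import Path

import h5py
import numpy as np

from .errors import SchemaError
from .network import NBGNetArch, NBGNetParams, _WEIGHT_FIELDS
from .synthetic import ChannelInfo, RecordingSession, SimConfig, TrialLabel

__all__ = [
    "SCHEMA_VERSION",
    "write_session",
    "read_session",
    "write_predictions",
    "read_predictions",
    "save_model",
    "load_model",
    "load_config",
]

SCHEMA_VERSION = 1

_NORM_FIELDS = ("in_mean", "in_std", "out_mean", "out_std")


def write_session(session: RecordingSession, path: str | Path) -> None:
    """Serialize a session; deterministic layout, bit-exact round trip."""
    with h5py.File(path, "w", track_order=True) as f:
        meta = f.create_group("meta")
        meta.attrs["fs"] = float(session.fs)
        meta.attrs["n_trials"] = session.n_trials
        meta.attrs["schema_version"] = SCHEMA_VERSION
        trials = f.create_group("trials")
        for k in range(session.n_trials):
            g = trials.create_group(str(k))
            g.create_dataset("fine", data=session.fine[k])
            g.create_dataset("coarse", data=session.coarse[k])
            lab = session.labels[k]
            g.attrs["target_direction"] = lab.target_direction
            g.attrs["movement_onset"] = lab.movement_onset
            g.attrs["trial_id"] = lab.trial_id
        ch = f.create_group("channels")
        enc = h5py.string_dtype("utf-8")
        ch.create_dataset("name", data=[c.name for c in session.channel_meta], dtype=enc)
        ch.create_dataset("role", data=[c.role for c in session.channel_meta], dtype=enc)
        ch.create_dataset("region", data=[c.region for c in session.channel_meta], dtype=enc)


def read_session(path: str | Path) -> RecordingSession:
    with h5py.File(path, "r") as f:
        if "meta" not in f:
            raise SchemaError(f"{path}: missing /meta group; not a session container")
        version = int(f["meta"].attrs.get("schema_version", -1))
        if version != SCHEMA_VERSION:
            raise SchemaError(f"{path}: schema version {version}, expected {SCHEMA_VERSION}")
        n_trials = int(f["meta"].attrs["n_trials"])
        fs = float(f["meta"].attrs["fs"])
        fine, coarse, labels = [], [], []
        for k in range(n_trials):
            key = f"trials/{k}"
            if key not in f:
                raise SchemaError(f"{path}: missing dataset path /{key}")
            g = f[key]
            fine.append(g["fine"][()])
            coarse.append(g["coarse"][()])
            labels.append(
                TrialLabel(
                    target_direction=int(g.attrs["target_direction"]),
                    movement_onset=int(g.attrs["movement_onset"]),
                    trial_id=int(g.attrs["trial_id"]),
                )
            )
        meta = []
        if "channels" in f:
            names = [s.decode() if isinstance(s, bytes) else s for s in f["channels/name"][()]]
            roles = [s.decode() if isinstance(s, bytes) else s for s in f["channels/role"][()]]
            regions = [s.decode() if isinstance(s, bytes) else s for s in f["channels/region"][()]]
            meta = [ChannelInfo(n, r, g) for n, r, g in zip(names, roles, regions)]
    return RecordingSession(
        fine=np.stack(fine), coarse=np.stack(coarse), fs=fs, labels=labels, channel_meta=meta
    )


def write_predictions(path: str | Path, pred: np.ndarray, fs: float) -> None:
    pred = np.asarray(pred, dtype=float)
    with h5py.File(path, "w") as f:
        f.attrs["fs"] = float(fs)
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.create_dataset("pred", data=pred)


def read_predictions(path: str | Path) -> tuple[np.ndarray, float]:
    with h5py.File(path, "r") as f:
        if "pred" not in f:
            raise SchemaError(f"{path}: missing /pred dataset")
        return f["pred"][()], float(f.attrs["fs"])


def save_model(params: NBGNetParams, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["arch"] = params.arch.to_json()
        f.attrs["schema_version"] = SCHEMA_VERSION
        for name in _WEIGHT_FIELDS:
            f.create_dataset(name, data=getattr(params, name))
        for name in _NORM_FIELDS:
            arr = getattr(params, name)
            if arr is not None:
                f.create_dataset(name, data=arr)


def load_model(path: str | Path) -> NBGNetParams:
    with h5py.File(path, "r") as f:
        if "arch" not in f.attrs:
            raise SchemaError(f"{path}: missing architecture attribute")
        arch = NBGNetArch.from_json(f.attrs["arch"])
        kw = {name: f[name][()] for name in _WEIGHT_FIELDS}
        for name in _NORM_FIELDS:
            kw[name] = f[name][()] if name in f else None
    return NBGNetParams(arch=arch, **kw)


def load_config(path: str | Path) -> dict:
    """Load a TOML run configuration, rejecting unknown sections and keys."""
    from ._training import TrainConfig

    section_types = {
        "sim": SimConfig,
        "train": TrainConfig,
        "evaluate": None,
        "decode": None,
    }
    with open(path, "rb") as fh:
        doc = tomllib.load(fh)
    for section, content in doc.items():
        if section not in section_types:
            raise SchemaError(f"unknown config section [{section}]")
        cls = section_types[section]
        if cls is not None:
            allowed = {f.name for f in dc_fields(cls)}
            unknown = set(content) - allowed
            if unknown:
                raise SchemaError(f"unknown keys in [{section}]: {sorted(unknown)}")
    return doc
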