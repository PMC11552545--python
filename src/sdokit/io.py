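"""File I/O: signals, spike trains, SDO matrices and analysis configs.

Formats are deliberately plain: delimited text for signals (time, amplitude)
and spikes (trial, unit, time), HDF5 for large signal containers, JSON for
matrices and results, YAML for configuration.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import yaml

from .core import SDOMatrix, SpikeTrain
from .quantize import Signal

__all__ = [
    "read_signal_text",
    "write_signal_text",
    "read_signal_hdf5",
    "write_signal_hdf5",
    "read_spikes_text",
    "write_spikes_text",
    "sdo_to_json",
    "sdo_from_json",
    "load_config",
    "DEFAULT_CONFIG",
]

DEFAULT_CONFIG = {
    "n_states": 20,
    "scheme": "linear",
    "pre_bins": 20,
    "post_bins": 20,
    "n_shuffles": 1000,
    "shuffle_method": "isi_shuffle",
    "alpha": 0.05,
    "seed": 0,
    "notch_hz": 60.0,
    "notch_harmonics": 8,
    "hp_hz": 10.0,
    "hp_order": 4,
    "rms_points": 20,
    "kernel_width_ms": 50.0,
    "h2_sigma": 1.0,
}


def read_signal_text(path, fs: float | None = None, channel_id: str = "") -> Signal:
    """Read a two-column (time_s, amplitude) delimited text signal.

    If ``fs`` is not given it is inferred from the median time step.
    """
    data = np.loadtxt(path, delimiter=None)
    if data.ndim != 2 or data.shape[1] < 2:
        raise ValueError("expected two columns: time_s, amplitude")
    t, x = data[:, 0], data[:, 1]
    if fs is None:
        dt = np.median(np.diff(t))
        if dt <= 0:
            raise ValueError("non-increasing time column")
        fs = 1.0 / dt
    return Signal(samples=x, fs=fs, channel_id=channel_id or Path(path).stem)


def write_signal_text(path, sig: Signal) -> None:
    t = np.arange(sig.n_samples) / sig.fs
    np.savetxt(path, np.column_stack([t, sig.samples]), fmt="%.9g", header="time_s amplitude")


def write_signal_hdf5(path, sig: Signal) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("samples", data=sig.samples)
        f.attrs["fs"] = sig.fs
        f.attrs["channel_id"] = sig.channel_id


def read_signal_hdf5(path) -> Signal:
    with h5py.File(path, "r") as f:
        return Signal(
            samples=f["samples"][:],
            fs=float(f.attrs["fs"]),
            channel_id=str(f.attrs.get("channel_id", "")),
        )


def read_spikes_text(path) -> list[SpikeTrain]:
    """Read (trial_id, unit_id, time_s) delimited text into spike trains."""
    trains: dict[tuple[str, str], list[float]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            trial, unit, t = line.split()[:3]
            trains.setdefault((trial, unit), []).append(float(t))
    return [
        SpikeTrain(times=np.sort(ts), unit_id=unit, trial_id=trial)
        for (trial, unit), ts in sorted(trains.items())
    ]


def write_spikes_text(path, trains: list[SpikeTrain]) -> None:
    with open(path, "w") as fh:
        fh.write("# trial_id unit_id time_s\n")
        for tr in trains:
            for t in tr.times:
                fh.write(f"{tr.trial_id or 'trial0'} {tr.unit_id or 'unit0'} {t:.9g}\n")


def sdo_to_json(path, sdo, h_id: str | None = None) -> None:
    L = sdo.L
    payload = {
        "n_states": int(L.shape[0]),
        "form": getattr(sdo, "form", "raw"),
        "L": np.asarray(L).ravel().tolist(),  # row-major
        "p0_bar": None
        if getattr(sdo, "p0_bar", None) is None
        else np.asarray(sdo.p0_bar).tolist(),
        "n_spikes": int(getattr(sdo, "n_spikes", 0)),
    }
    if h_id or hasattr(sdo, "h_id"):
        payload["h_id"] = h_id or sdo.h_id
    with open(path, "w") as fh:
        json.dump(payload, fh)


def sdo_from_json(path) -> SDOMatrix:
    with open(path) as fh:
        d = json.load(fh)
    n = d["n_states"]
    return SDOMatrix(
        L=np.asarray(d["L"], dtype=float).reshape(n, n),
        form=d.get("form", "raw"),
        n_spikes=d.get("n_spikes", 0),
        p0_bar=None if d.get("p0_bar") is None else np.asarray(d["p0_bar"]),
    )


def load_config(path=None) -> dict:
    """Merge a YAML config over the defaults."""
    cfg = dict(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        unknown = set(user) - set(cfg)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg.update(user)
    return cfg
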