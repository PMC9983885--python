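"""Flat key-value configuration files and CSV/JSON artifact output.

Config files are ``key = value`` lines (``#`` comments allowed); values
are parsed as int, float, or left as strings.  Frequency responses are
written as ``freq_hz,re,im``, PSDs as ``freq_hz,power``, signals as
``t_s,value`` and spike trains as ``spike_time_s``.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Union

import numpy as np

__all__ = [
    "read_config",
    "write_response_csv",
    "write_psd_csv",
    "read_psd_csv",
    "write_signal_csv",
    "read_signal_csv",
    "write_spikes_csv",
    "write_json",
]

PathLike = Union[str, Path]


def _parse_value(raw: str):
    raw = raw.strip()
    for cast in (int, float):
        try:
            return cast(raw)
        except ValueError:
            continue
    if raw.lower() in ("true", "false"):
        return raw.lower() == "true"
    return raw


def read_config(path: PathLike) -> Dict[str, object]:
    """Read a flat ``key = value`` config file."""
    cfg: Dict[str, object] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        stripped = line.split("#", 1)[0].strip()
        if not stripped:
            continue
        if "=" not in stripped:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {line!r}")
        key, raw = stripped.split("=", 1)
        cfg[key.strip()] = _parse_value(raw)
    return cfg


def write_response_csv(path: PathLike, freqs: np.ndarray, response: np.ndarray) -> None:
    arr = np.column_stack([freqs, np.real(response), np.imag(response)])
    np.savetxt(path, arr, delimiter=",", header="freq_hz,re,im", comments="")


def write_psd_csv(path: PathLike, freqs: np.ndarray, power: np.ndarray) -> None:
    np.savetxt(
        path, np.column_stack([freqs, power]), delimiter=",",
        header="freq_hz,power", comments="",
    )


def read_psd_csv(path: PathLike):
    arr = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    return arr[:, 0], arr[:, 1]


def write_signal_csv(path: PathLike, t: np.ndarray, values: np.ndarray) -> None:
    np.savetxt(
        path, np.column_stack([t, values]), delimiter=",",
        header="t_s,value", comments="",
    )


def read_signal_csv(path: PathLike):
    arr = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    return arr[:, 0], arr[:, 1]


def write_spikes_csv(path: PathLike, times_s: np.ndarray) -> None:
    np.savetxt(path, np.asarray(times_s), header="spike_time_s", comments="")


def write_json(path: PathLike, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default) + "\n")


def _json_default(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    raise TypeError(f"not JSON serializable: {type(o)}")
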