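"""Session-bundle persistence: plain CSV + JSON, losslessly round-tripping.

A session bundle is a directory holding ``meta.json`` (sampling rates,
channel registry, intervention timestamps, seed, units, config hash),
one two-column ``time_s,value`` CSV per channel, ``hypnogram.csv``
(``epoch_start_s,label`` with labels W/N/R) and, for simulated sessions,
``ground_truth.json``. Floats are written with full repr precision so a
read-back reproduces every numeric array bit-exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import Hypnogram, Trace


@dataclass
class SessionBundle:
    """An on-disk session: channels, optional hypnogram, optional truth."""

    path: Path
    meta: dict
    traces: dict[str, Trace] = field(default_factory=dict)
    hypnogram: Hypnogram | None = None
    truth: dict | None = None


def _fmt(x: float) -> str:
    return repr(float(x))


def write_trace_csv(trace: Trace, path: Path, config_hash: str | None = None) -> None:
    with open(path, "w") as fh:
        if config_hash:
            fh.write(f"# config_hash: {config_hash}\n")
        fh.write("time_s,value,unit\n")
        t = trace.times
        for i in range(trace.n):
            fh.write(f"{_fmt(t[i])},{_fmt(trace.values[i])},{trace.unit}\n")


def read_trace_csv(path: Path) -> Trace:
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
    except Exception as exc:  # noqa: BLE001 - rewrap with the file name
        raise ValueError(f"{path}: cannot parse CSV ({exc})") from exc
    for col in ("time_s", "value"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
        bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
        if len(bad):
            raise ValueError(f"{path}: malformed value in line {bad[0] + 2}")
    t = df["time_s"].to_numpy(dtype=float)
    if t.size < 2:
        raise ValueError(f"{path}: need at least two samples")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise ValueError(f"{path}: time column is not uniformly sampled")
    unit = str(df["unit"].iloc[0]) if "unit" in df.columns else "raw_F"
    return Trace(df["value"].to_numpy(dtype=float), fs=1.0 / dt[0], t0=float(t[0]),
                 unit=unit)


def write_hypnogram_csv(hyp: Hypnogram, path: Path,
                        config_hash: str | None = None) -> None:
    with open(path, "w") as fh:
        if config_hash:
            fh.write(f"# config_hash: {config_hash}\n")
        fh.write("epoch_start_s,label\n")
        for t, lab in zip(hyp.epoch_starts, hyp.labels):
            fh.write(f"{_fmt(t)},{lab}\n")


def read_hypnogram_csv(path: Path) -> Hypnogram:
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    for col in ("epoch_start_s", "label"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    starts = df["epoch_start_s"].to_numpy(dtype=float)
    if starts.size < 2:
        epoch_len = 5.0
    else:
        d = np.diff(starts)
        if not np.allclose(d, d[0], rtol=1e-6, atol=1e-9):
            raise ValueError(f"{path}: epochs are not on a uniform grid")
        epoch_len = float(d[0])
    return Hypnogram(df["label"].to_numpy(dtype="U1"), epoch_len=epoch_len,
                     start_time=float(starts[0]))


def write_session(session, path: Path, config_hash: str | None = None) -> Path:
    """Persist a simulated :class:`~photosleep.simulate.Session` or a
    :class:`SessionBundle` to a bundle directory."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    if isinstance(session, SessionBundle):
        traces = dict(session.traces)
        hyp = session.hypnogram
        meta = dict(session.meta)
        truth = session.truth
    else:
        traces = dict(session.photo)
        if session.eeg is not None:
            traces["eeg"] = session.eeg
        if session.emg is not None:
            traces["emg"] = session.emg
        hyp = session.hypnogram
        meta = {
            "seed": session.cfg.seed,
            "interventions": session.interventions,
            "epoch_len": hyp.epoch_len,
            "background": session.cfg.background,
        }
        truth = None
        if session.truth is not None:
            tr = session.truth
            truth = {
                "events_a": tr.events_a,
                "events_b": tr.events_b,
                "lag": tr.lag,
                "slope": tr.slope,
                "bleach": list(tr.bleach),
                "seed": tr.seed,
            }
    meta = dict(meta)
    meta["channels"] = {
        name: {"fs": tr.fs, "t0": tr.t0, "unit": tr.unit,
               "file": f"{_channel_file(name)}"}
        for name, tr in traces.items()
    }
    if config_hash:
        meta["config_hash"] = config_hash
    for name, tr in traces.items():
        write_trace_csv(tr, path / _channel_file(name), config_hash)
    if hyp is not None:
        write_hypnogram_csv(hyp, path / "hypnogram.csv", config_hash)
    with open(path / "meta.json", "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)
    if truth is not None:
        with open(path / "ground_truth.json", "w") as fh:
            json.dump(truth, fh, sort_keys=True)
    return path


def _channel_file(name: str) -> str:
    return f"{name}.csv" if name in ("eeg", "emg") else f"photo_{name}.csv"


def read_session(path: Path) -> SessionBundle:
    """Read a bundle; missing hypnogram is allowed, missing channels are not."""
    path = Path(path)
    meta_path = path / "meta.json"
    if not meta_path.exists():
        raise ValueError(f"{path}: no meta.json found")
    with open(meta_path) as fh:
        meta = json.load(fh)
    traces = {}
    for name, info in meta.get("channels", {}).items():
        f = path / info["file"]
        if not f.exists():
            raise ValueError(f"missing channel file {f}")
        tr = read_trace_csv(f)
        if info.get("unit") and tr.unit != info["unit"]:
            raise ValueError(
                f"{f}: unit {tr.unit!r} does not match meta {info['unit']!r}"
            )
        traces[name] = tr
    hyp = None
    if (path / "hypnogram.csv").exists():
        hyp = read_hypnogram_csv(path / "hypnogram.csv")
    truth = None
    if (path / "ground_truth.json").exists():
        with open(path / "ground_truth.json") as fh:
            truth = json.load(fh)
    return SessionBundle(path=path, meta=meta, traces=traces, hypnogram=hyp,
                         truth=truth)
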