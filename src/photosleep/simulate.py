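"""Synthetic polysomnography + fiber-photometry sessions with ground truth.

The generator emulates the statistical structure the downstream analyses
assume: a semi-Markov vigilance-state sequence quantised to 5-s epochs,
state-dependent EEG band power and EMG amplitude, and one or two photometry
channels carrying state-dependent tonic levels, Poisson transient events
convolved with a rise/decay kernel, a slow two-exponential photobleaching
trend, constant background autofluorescence and white measurement noise.
Channel B repeats channel A's events at a fixed lag with amplitudes scaled
by a coupling slope plus noise, so lag and coupling estimators can be
validated by parameter recovery. An optional isosbestic channel carries the
bleach, background and a shared motion artifact but no sensor signal.

All randomness flows from a single integer seed through
``numpy.random.SeedSequence`` fan-out, so identical configurations produce
byte-identical sessions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
from scipy import signal as sps

from .core import STATES, Hypnogram, Trace

# ---------------------------------------------------------------------------
# configuration


def _default_state_mean_bout() -> dict[str, float]:
    return {"W": 120.0, "N": 120.0, "R": 60.0}


def _default_transition_weights() -> dict[str, dict[str, float]]:
    # REM is entered only from NREM; REM always exits to wake.
    return {
        "W": {"W": 0.0, "N": 1.0, "R": 0.0},
        "N": {"W": 0.6, "N": 0.0, "R": 0.4},
        "R": {"W": 1.0, "N": 0.0, "R": 0.0},
    }


def _default_band_gains() -> dict[str, dict[str, float]]:
    # relative power per state for the three synthesis components
    return {
        "W": {"delta": 1.0, "theta": 1.5, "broad": 1.0},
        "N": {"delta": 8.0, "theta": 1.0, "broad": 1.0},
        "R": {"delta": 0.5, "theta": 6.0, "broad": 1.0},
    }


def _default_emg_gain() -> dict[str, float]:
    return {"W": 4.0, "N": 1.0, "R": 0.6}


def _default_event_rate() -> dict[str, float]:
    # events per minute; quiescent during NREM, active in wake and REM
    return {"W": 2.0, "N": 0.3, "R": 2.0}


def _default_tonic_level() -> dict[str, float]:
    # ΔF/F offsets; elevated in wake and REM relative to NREM
    return {"W": 0.08, "N": 0.0, "R": 0.10}


@dataclass
class SimConfig:
    """Parameters of a synthetic session.

    Durations and time constants are in seconds, rates in events/min,
    photometry amplitudes in ΔF/F units, bleach amplitudes and background in
    raw fluorescence units.
    """

    duration: float = 3600.0
    epoch_len: float = 5.0
    seed: int = 0
    initial_state: str = "W"
    state_mean_bout: dict[str, float] = field(default_factory=_default_state_mean_bout)
    transition_weights: dict[str, dict[str, float]] = field(
        default_factory=_default_transition_weights
    )
    eeg_fs: float = 1525.0
    photo_fs: float = 1017.0
    band_gains: dict[str, dict[str, float]] = field(default_factory=_default_band_gains)
    emg_gain: dict[str, float] = field(default_factory=_default_emg_gain)
    event_rate: dict[str, float] = field(default_factory=_default_event_rate)
    event_amp: tuple[float, float] = (-1.6, 0.4)  # lognormal (mu, sigma) of ΔF/F
    kernel_rise: float = 2.0
    kernel_decay: float = 8.0
    tonic_level: dict[str, float] = field(default_factory=_default_tonic_level)
    coupling_lag: float = 23.0
    coupling_slope: float = 0.8
    coupling_noise_sd: float = 0.02
    bleach: tuple[float, float, float, float] = (30.0, 300.0, 70.0, 10000.0)
    background: float = 10.0
    artifact_sd: float = 0.0
    white_noise_sd: float = 0.05
    isosbestic: bool = False

    def validate(self) -> None:
        if self.duration <= 0 or self.epoch_len <= 0:
            raise ValueError("duration and epoch_len must be positive")
        n_epochs = self.duration / self.epoch_len
        if abs(n_epochs - round(n_epochs)) > 1e-9:
            raise ValueError(
                f"duration ({self.duration} s) must be a multiple of "
                f"epoch_len ({self.epoch_len} s)"
            )
        for name, m in [
            ("event_rate", self.event_rate),
            ("emg_gain", self.emg_gain),
            ("state_mean_bout", self.state_mean_bout),
        ]:
            if any(v < 0 for v in m.values()):
                raise ValueError(f"{name} entries must be non-negative")
        a1, t1, a2, t2 = self.bleach
        if t1 <= 0 or t2 <= 0:
            raise ValueError("bleach time constants must be positive")
        if self.coupling_noise_sd < 0 or self.white_noise_sd < 0 or self.artifact_sd < 0:
            raise ValueError("noise SDs must be non-negative")
        for s in STATES:
            row = self.transition_weights.get(s, {})
            off = [w for t, w in row.items() if t != s and w > 0]
            if not off:
                raise ValueError(f"state {s} has no allowed exit transition")
            if any(w < 0 for w in row.values()):
                raise ValueError("transition weights must be non-negative")


@dataclass
class GroundTruth:
    """The simulator's hidden parameters, used as the oracle in tests."""

    hypnogram: Hypnogram
    events_a: list[tuple[float, float]]
    events_b: list[tuple[float, float]]
    lag: float
    slope: float
    bleach: tuple[float, float, float, float]
    seed: int
    clean_a: np.ndarray | None = None  # ΔF/F of channel A without artifact/noise
    artifact: np.ndarray | None = None


@dataclass
class Session:
    """A simulated recording: raw channels plus the generating truth."""

    cfg: SimConfig
    hypnogram: Hypnogram
    eeg: Trace | None
    emg: Trace | None
    photo: dict[str, Trace]
    truth: GroundTruth | None
    interventions: list[dict] = field(default_factory=list)


# ---------------------------------------------------------------------------
# hypnogram


def _seeds(cfg: SimConfig) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(cfg.seed).spawn(3)
    return {
        "hyp": np.random.default_rng(children[0]),
        "eeg": np.random.default_rng(children[1]),
        "photo": np.random.default_rng(children[2]),
    }


def simulate_hypnogram(cfg: SimConfig, rng: np.random.Generator | None = None) -> Hypnogram:
    """Draw a semi-Markov state sequence quantised to scoring epochs.

    Bout lengths are geometric in epoch counts with mean
    ``state_mean_bout[state] / epoch_len``; the successor state is drawn
    from ``transition_weights`` with the self-transition excluded.
    """
    cfg.validate()
    if cfg.duration < 10 * cfg.epoch_len:
        raise ValueError("duration must cover at least 10 epochs")
    rng = rng if rng is not None else _seeds(cfg)["hyp"]
    n_epochs = int(round(cfg.duration / cfg.epoch_len))
    labels: list[str] = []
    state = cfg.initial_state
    while len(labels) < n_epochs:
        mean_epochs = max(cfg.state_mean_bout.get(state, cfg.epoch_len) / cfg.epoch_len, 1.0)
        bout = int(rng.geometric(1.0 / mean_epochs))
        labels.extend([state] * min(bout, n_epochs - len(labels)))
        row = cfg.transition_weights[state]
        nxt = [s for s in STATES if s != state]
        w = np.array([row.get(s, 0.0) for s in nxt], dtype=float)
        state = nxt[int(rng.choice(len(nxt), p=w / w.sum()))]
    return Hypnogram(np.array(labels), epoch_len=cfg.epoch_len)


# ---------------------------------------------------------------------------
# EEG / EMG


def _per_sample_state_values(
    hyp: Hypnogram, fs: float, mapping: dict[str, float], n: int
) -> np.ndarray:
    per_epoch = np.array([mapping[s] for s in hyp.labels], dtype=float)
    spe = int(round(hyp.epoch_len * fs))  # samples per epoch
    out = np.repeat(per_epoch, spe)
    if out.size < n:
        out = np.concatenate([out, np.full(n - out.size, per_epoch[-1])])
    return out[:n]


def simulate_eeg_emg(
    hyp: Hypnogram, cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple[Trace, Trace]:
    """Synthesise EEG and EMG matching the scoring criteria.

    The EEG is a sum of three Gaussian-noise components — delta-band
    (0.5–4 Hz), theta-band (6–10 Hz) and broadband — whose power is scaled
    per state; the EMG is white noise with a per-state amplitude, so wake
    shows desynchronised EEG with high EMG, NREM high delta with low EMG
    and REM theta dominance with muscle atonia.
    """
    if cfg.eeg_fs < 64:
        raise ValueError("eeg_fs below 64 Hz cannot support band synthesis")
    rng = rng if rng is not None else _seeds(cfg)["eeg"]
    fs = cfg.eeg_fs
    n = int(round(hyp.duration * fs))
    nyq = fs / 2.0

    sos_delta = sps.butter(4, [0.5 / nyq, 4.0 / nyq], btype="band", output="sos")
    sos_theta = sps.butter(4, [6.0 / nyq, 10.0 / nyq], btype="band", output="sos")
    comp = {
        "delta": sps.sosfiltfilt(sos_delta, rng.standard_normal(n)),
        "theta": sps.sosfiltfilt(sos_theta, rng.standard_normal(n)),
        "broad": rng.standard_normal(n) * 0.15,
    }
    # band-filtered unit white noise loses power to the stopband; renormalise
    for k in ("delta", "theta"):
        comp[k] = comp[k] / comp[k].std()

    eeg = np.zeros(n)
    for band, x in comp.items():
        gains = {s: cfg.band_gains[s][band] for s in STATES}
        eeg += np.sqrt(_per_sample_state_values(hyp, fs, gains, n)) * x

    emg_noise = rng.standard_normal(n)
    emg = _per_sample_state_values(hyp, fs, cfg.emg_gain, n) * emg_noise
    return (
        Trace(eeg, fs=fs, t0=hyp.start_time, unit="raw_F"),
        Trace(emg, fs=fs, t0=hyp.start_time, unit="raw_F"),
    )


# ---------------------------------------------------------------------------
# photometry


def event_kernel(fs: float, rise: float, decay: float) -> np.ndarray:
    """Difference-of-exponentials transient kernel, normalised to unit peak."""
    if decay <= 0:
        raise ValueError("kernel_decay must be positive")
    if rise <= 0 or rise >= decay:
        raise ValueError("kernel_rise must satisfy 0 < rise < decay")
    t = np.arange(0.0, 8.0 * decay, 1.0 / fs)
    k = np.exp(-t / decay) - np.exp(-t / rise)
    return k / k.max()


def _draw_events(
    hyp: Hypnogram, cfg: SimConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Inhomogeneous Poisson events with per-state rate, plus amplitudes."""
    times = []
    for start, label in zip(hyp.epoch_starts, hyp.labels):
        lam = cfg.event_rate.get(label, 0.0) / 60.0 * hyp.epoch_len
        k = int(rng.poisson(lam))
        if k:
            times.extend(start + rng.uniform(0.0, hyp.epoch_len, size=k))
    times = np.sort(np.array(times, dtype=float))
    mu, sigma = cfg.event_amp
    amps = rng.lognormal(mean=mu, sigma=sigma, size=times.size)
    return times, amps


def bleach_trend(t: np.ndarray, bleach: tuple[float, float, float, float]) -> np.ndarray:
    a1, t1, a2, t2 = bleach
    return a1 * np.exp(-t / t1) + a2 * np.exp(-t / t2)


def _events_to_dff(
    times: np.ndarray, amps: np.ndarray, n: int, fs: float, kernel: np.ndarray, t0: float
) -> np.ndarray:
    train = np.zeros(n)
    idx = np.round((times - t0) * fs).astype(int)
    keep = (idx >= 0) & (idx < n)
    np.add.at(train, idx[keep], amps[keep])
    return sps.fftconvolve(train, kernel)[:n]


def simulate_photometry_pair(
    hyp: Hypnogram,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
    amp_modifier: Callable[[np.ndarray, np.ndarray], np.ndarray] | None = None,
    modify_channel: str = "a",
) -> tuple[Trace, Trace, Trace | None, GroundTruth]:
    """Generate the raw lag-coupled photometry pair and its ground truth.

    Channel A carries the per-state tonic ΔF/F level plus the convolved
    event train; channel B repeats the events at ``coupling_lag`` with
    amplitudes ``slope·a + ε``. Both are wrapped in the measurement model
    ``F(t) = F0(t)·(1 + ΔF/F(t)) + background + white noise`` with the
    two-exponential bleach trend F0. ``amp_modifier(times, amps)`` rescales
    event amplitudes (used for simulated interventions) after the random
    draws, so the same seed yields the same event times and noise.
    """
    if cfg.coupling_lag < 0:
        raise ValueError("coupling_lag must be non-negative")
    if cfg.photo_fs < 1:
        raise ValueError("photo_fs must be at least 1 Hz")
    if cfg.kernel_decay <= 0:
        raise ValueError("kernel_decay must be positive")
    rng = rng if rng is not None else _seeds(cfg)["photo"]
    fs = cfg.photo_fs
    n = int(round(hyp.duration * fs))
    t = np.arange(n) / fs + hyp.start_time

    times_a, amps_a = _draw_events(hyp, cfg, rng)
    eps = rng.normal(0.0, cfg.coupling_noise_sd, size=times_a.size)
    noise_a = rng.normal(0.0, cfg.white_noise_sd, size=n)
    noise_b = rng.normal(0.0, cfg.white_noise_sd, size=n)
    noise_iso = rng.normal(0.0, cfg.white_noise_sd, size=n)
    artifact_raw = rng.standard_normal(n)

    times_b = times_a + cfg.coupling_lag
    amps_b = cfg.coupling_slope * amps_a + eps
    if amp_modifier is not None:
        if modify_channel in ("a", "both"):
            amps_a = amp_modifier(times_a, amps_a)
            amps_b = cfg.coupling_slope * amps_a + eps
        if modify_channel == "b":
            amps_b = amp_modifier(times_b, amps_b)

    kernel = event_kernel(fs, cfg.kernel_rise, cfg.kernel_decay)
    tonic = _per_sample_state_values(hyp, fs, cfg.tonic_level, n)
    dff_a = tonic + _events_to_dff(times_a, amps_a, n, fs, kernel, hyp.start_time)
    dff_b = tonic + _events_to_dff(times_b, amps_b, n, fs, kernel, hyp.start_time)

    if cfg.artifact_sd > 0:
        sos = sps.butter(2, min(0.5 / (fs / 2.0), 0.99), btype="low", output="sos")
        artifact = sps.sosfiltfilt(sos, artifact_raw)
        artifact = cfg.artifact_sd * artifact / artifact.std()
    else:
        artifact = np.zeros(n)

    f0 = bleach_trend(t - hyp.start_time, cfg.bleach)
    raw_a = f0 * (1.0 + dff_a + artifact) + cfg.background + noise_a
    raw_b = f0 * (1.0 + dff_b) + cfg.background + noise_b
    iso = None
    if cfg.isosbestic:
        iso = Trace(
            f0 * (1.0 + artifact) + cfg.background + noise_iso,
            fs=fs,
            t0=hyp.start_time,
            unit="raw_F",
        )

    truth = GroundTruth(
        hypnogram=hyp,
        events_a=list(zip(times_a.tolist(), amps_a.tolist())),
        events_b=list(zip(times_b.tolist(), amps_b.tolist())),
        lag=cfg.coupling_lag,
        slope=cfg.coupling_slope,
        bleach=cfg.bleach,
        seed=cfg.seed,
        clean_a=dff_a,
        artifact=artifact if cfg.artifact_sd > 0 else None,
    )
    return (
        Trace(raw_a, fs=fs, t0=hyp.start_time, unit="raw_F"),
        Trace(raw_b, fs=fs, t0=hyp.start_time, unit="raw_F"),
        iso,
        truth,
    )


# ---------------------------------------------------------------------------
# whole sessions and interventions


def simulate_session(
    cfg: SimConfig, with_eeg: bool = True, with_photometry: bool = True
) -> Session:
    """Generate a full session from one seed."""
    cfg.validate()
    rngs = _seeds(cfg)
    hyp = simulate_hypnogram(cfg, rngs["hyp"])
    eeg = emg = None
    if with_eeg:
        eeg, emg = simulate_eeg_emg(hyp, cfg, rngs["eeg"])
    photo: dict[str, Trace] = {}
    truth = None
    if with_photometry:
        a, b, iso, truth = simulate_photometry_pair(hyp, cfg, rngs["photo"])
        photo = {"a": a, "b": b}
        if iso is not None:
            photo["iso"] = iso
    return Session(cfg=cfg, hypnogram=hyp, eeg=eeg, emg=emg, photo=photo, truth=truth)


def apply_intervention(
    session: Session, t_inject: float, effect: float, which_channel: str = "a"
) -> Session:
    """Scale post-injection event amplitudes, emulating a drug effect.

    Events with time > ``t_inject`` on the chosen channel have their
    amplitude multiplied by ``effect`` before kernel convolution; the
    session is regenerated from the same seed so all random draws are
    unchanged and ``effect = 1`` reproduces the input bitwise.
    """
    cfg = session.cfg
    if effect < 0:
        raise ValueError("effect must be non-negative")
    if not (0 < t_inject < cfg.duration):
        raise ValueError("t_inject must fall inside the session")

    def modifier(times: np.ndarray, amps: np.ndarray) -> np.ndarray:
        return np.where(times > t_inject, amps * effect, amps)

    rngs = _seeds(cfg)
    hyp = session.hypnogram
    a, b, iso, truth = simulate_photometry_pair(
        hyp, cfg, rngs["photo"], amp_modifier=modifier, modify_channel=which_channel
    )
    photo = {"a": a, "b": b}
    if iso is not None:
        photo["iso"] = iso
    out = replace(session, photo=photo, truth=truth)
    out.interventions = session.interventions + [
        {"time": t_inject, "effect": effect, "channel": which_channel}
    ]
    return out
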