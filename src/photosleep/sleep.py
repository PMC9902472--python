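"""EEG/EMG sleep scoring and sleep-architecture statistics.

States are scored on 5-s epochs from an FFT spectrogram (~0.18 Hz
resolution) and the epoch EMG root-mean-square, following the standard
rodent criteria: wake = desynchronised EEG with high EMG; NREM =
high-amplitude delta (0.5-4 Hz) with low EMG; REM = theta dominance
(6-10 Hz) with muscle atonia. Thresholds are data-driven by default
(deterministic two-class splits of the per-epoch features) and can be
overridden, standing in for the manual validation step of semi-automatic
scoring.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from sklearn.base import BaseEstimator, ClassifierMixin

from .core import STATES, Hypnogram, Trace

#: Scoring bands (Hz): delta and the REM-scoring theta range.
SCORING_DELTA = (0.5, 4.0)
SCORING_THETA = (6.0, 10.0)
#: Total-power normalisation range for reported spectra.
NORM_RANGE = (0.5, 30.0)


@dataclass(frozen=True)
class BandDefinition:
    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (0 < self.lo < self.hi):
            raise ValueError("band edges must satisfy 0 < lo < hi")


#: Reporting bands. Theta is 4-8 Hz in band-power reports (the common
#: reporting convention) while REM *scoring* uses 6-10 Hz; sigma/beta follow
#: conventional rodent definitions.
DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 0.5, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("sigma", 10.0, 15.0),
    BandDefinition("beta", 15.0, 30.0),
)


@dataclass
class Spectrogram:
    """Per-epoch power spectra (epochs x frequency bins, power density)."""

    times: np.ndarray  # epoch centers, s
    freqs: np.ndarray  # Hz
    power: np.ndarray  # epochs x freqs
    epoch_len: float = 5.0
    t0: float = 0.0  # left edge of the first epoch

    @property
    def n_epochs(self) -> int:
        return int(self.power.shape[0])

    def band_power(self, lo: float, hi: float) -> np.ndarray:
        """Summed power per epoch over bins with lo <= f < hi."""
        m = (self.freqs >= lo) & (self.freqs < hi)
        return self.power[:, m].sum(axis=1)


def _nfft_for(fs: float, max_df: float = 0.19) -> int:
    """Smallest power of two whose bin width fs/nfft is <= max_df."""
    nfft = 1
    while fs / nfft > max_df:
        nfft *= 2
    return nfft


def compute_spectrogram(eeg: Trace, epoch_len: float = 5.0) -> Spectrogram:
    """Per-epoch Hann-tapered FFT power spectra at ~0.18 Hz resolution.

    Each epoch window is zero-padded to the smallest power of two giving a
    bin width of at most 0.19 Hz at the trace's sampling rate (0.186 Hz for
    a 1525-Hz recording).
    """
    if eeg.fs < 64:
        raise ValueError("sampling rate below 64 Hz is not supported")
    spe = int(round(epoch_len * eeg.fs))
    n_epochs = eeg.n // spe
    if n_epochs < 1:
        raise ValueError("trace shorter than one scoring epoch")
    nfft = _nfft_for(eeg.fs)
    x = eeg.values[: n_epochs * spe].reshape(n_epochs, spe)
    freqs, power = sps.periodogram(
        x, fs=eeg.fs, window="hann", nfft=nfft, detrend=False, axis=-1
    )
    times = eeg.t0 + epoch_len * (np.arange(n_epochs) + 0.5)
    return Spectrogram(times=times, freqs=freqs, power=power,
                       epoch_len=epoch_len, t0=eeg.t0)


# ---------------------------------------------------------------------------
# scoring


def _otsu_threshold(values: np.ndarray, nbins: int = 256) -> float:
    """Deterministic two-class threshold maximising between-class variance."""
    v = np.asarray(values, dtype=float)
    lo, hi = v.min(), v.max()
    if hi - lo < 1e-12:
        return float(lo)
    hist, edges = np.histogram(v, bins=nbins, range=(lo, hi))
    centers = (edges[:-1] + edges[1:]) / 2.0
    w = hist.astype(float)
    p = w / w.sum()
    omega = np.cumsum(p)
    mu = np.cumsum(p * centers)
    mu_t = mu[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = (mu_t * omega - mu) ** 2 / (omega * (1.0 - omega))
    sigma_b[~np.isfinite(sigma_b)] = -1.0
    return float(centers[int(np.argmax(sigma_b))])


def epoch_features(spec: Spectrogram, emg: Trace) -> np.ndarray:
    """Per-epoch feature matrix [EMG RMS, delta fraction, theta/delta ratio].

    The delta fraction is delta-band power over total 0.5-30 Hz power; the
    ratio uses the 6-10 Hz REM-scoring theta band. Both EEG features are
    scale-free, so scoring is invariant to EEG amplitude rescaling.
    """
    t_end = spec.t0 + spec.n_epochs * spec.epoch_len
    if emg.t0 > spec.t0 + 1e-6 or emg.t0 + emg.duration < t_end - 1e-6:
        raise ValueError("EMG does not cover the spectrogram time span")
    spe = int(round(spec.epoch_len * emg.fs))
    off = int(round((spec.t0 - emg.t0) * emg.fs))
    seg = emg.values[off : off + spec.n_epochs * spe].reshape(spec.n_epochs, spe)
    emg_rms = np.sqrt((seg**2).mean(axis=1))
    delta = spec.band_power(*SCORING_DELTA)
    theta = spec.band_power(*SCORING_THETA)
    total = spec.band_power(*NORM_RANGE)
    delta_frac = delta / np.maximum(total, 1e-300)
    ratio = theta / np.maximum(delta, 1e-300)
    return np.column_stack([emg_rms, delta_frac, ratio])


class SleepScorer(BaseEstimator, ClassifierMixin):
    """Rule-based epoch scorer with data-driven thresholds.

    Operates on the per-epoch feature matrix of :func:`epoch_features`.
    ``fit`` learns an EMG-RMS threshold (two-class split of the log RMS)
    separating wake from sleep and a delta-fraction threshold (split over
    the low-EMG epochs) separating NREM from the rest; the theta/delta
    ratio threshold defaults to 1 (theta power exceeding delta power marks
    REM). Any threshold may be fixed in the constructor.

    Attributes
    ----------
    emg_threshold_, delta_threshold_, ratio_threshold_ : float
        Thresholds actually used by :meth:`predict`.
    """

    def __init__(
        self,
        emg_threshold: float | None = None,
        delta_threshold: float | None = None,
        ratio_threshold: float | None = 1.0,
    ) -> None:
        self.emg_threshold = emg_threshold
        self.delta_threshold = delta_threshold
        self.ratio_threshold = ratio_threshold

    def fit(self, X: np.ndarray, y=None) -> "SleepScorer":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 3:
            raise ValueError("expected an (n_epochs, 3) feature matrix")
        emg_rms, delta_frac = X[:, 0], X[:, 1]
        self.emg_degenerate_ = bool(emg_rms.max() - emg_rms.min() < 1e-12)
        if self.emg_threshold is not None:
            self.emg_threshold_ = float(self.emg_threshold)
        elif self.emg_degenerate_:
            warnings.warn(
                "EMG is constant; falling back to EEG-only scoring rules",
                stacklevel=2,
            )
            self.emg_threshold_ = np.inf
        else:
            self.emg_threshold_ = float(
                np.exp(_otsu_threshold(np.log(np.maximum(emg_rms, 1e-300))))
            )
        if self.delta_threshold is not None:
            self.delta_threshold_ = float(self.delta_threshold)
        else:
            low_emg = delta_frac[emg_rms <= self.emg_threshold_]
            pool = low_emg if low_emg.size >= 10 else delta_frac
            self.delta_threshold_ = _otsu_threshold(pool)
        self.ratio_threshold_ = float(
            self.ratio_threshold if self.ratio_threshold is not None else 1.0
        )
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        emg_rms, delta_frac, ratio = X[:, 0], X[:, 1], X[:, 2]
        labels = np.full(X.shape[0], "N", dtype="U1")
        wake = emg_rms > self.emg_threshold_
        nrem = ~wake & (delta_frac > self.delta_threshold_)
        rem = ~wake & ~nrem & (ratio > self.ratio_threshold_)
        labels[wake] = "W"
        labels[rem] = "R"
        if getattr(self, "emg_degenerate_", False) and self.emg_threshold is None:
            # EEG-only fallback: epochs with neither delta nor theta
            # dominance are called wake (desynchronised EEG).
            rest = ~nrem & ~rem
            labels[rest] = "W"
        return labels


def score_epochs(
    spec: Spectrogram, emg: Trace, thresholds: dict[str, float] | None = None
) -> Hypnogram:
    """Score every epoch of the spectrogram; see :class:`SleepScorer`."""
    X = epoch_features(spec, emg)
    kw = {}
    if thresholds:
        kw = {
            "emg_threshold": thresholds.get("emg_rms"),
            "delta_threshold": thresholds.get("delta_frac"),
            "ratio_threshold": thresholds.get("theta_delta", 1.0),
        }
    scorer = SleepScorer(**kw).fit(X)
    return Hypnogram(scorer.predict(X), epoch_len=spec.epoch_len, start_time=spec.t0)


# ---------------------------------------------------------------------------
# architecture


@dataclass
class ArchitectureStats:
    """Per-state time percentage, bout count and mean bout duration."""

    window: tuple[float, float]
    percent_time: dict[str, float] = field(default_factory=dict)
    bout_count: dict[str, int] = field(default_factory=dict)
    mean_bout_duration: dict[str, float] = field(default_factory=dict)


def _runs(labels: np.ndarray) -> list[tuple[int, int, str]]:
    """Run-length encoding: (start epoch, length, label)."""
    out = []
    start = 0
    for i in range(1, labels.size + 1):
        if i == labels.size or labels[i] != labels[start]:
            out.append((start, i - start, str(labels[start])))
            start = i
    return out


def architecture_stats(hyp: Hypnogram, window: tuple[float, float] | None = None) -> ArchitectureStats:
    """Sleep-architecture summary over a time window.

    A bout is a maximal run of identical labels, clipped to the window;
    runs truncated by the window count as bouts of their clipped duration.
    Percent time sums to 100 over the three states.
    """
    if window is None:
        window = (hyp.start_time, hyp.end_time)
    w0, w1 = window
    if w1 <= w0:
        raise ValueError("empty analysis window")
    if w0 < hyp.start_time - 1e-9 or w1 > hyp.end_time + 1e-9:
        raise ValueError("window extends beyond the hypnogram span")
    total = {s: 0.0 for s in STATES}
    counts = {s: 0 for s in STATES}
    for start, length, label in _runs(hyp.labels):
        r0 = hyp.start_time + start * hyp.epoch_len
        r1 = r0 + length * hyp.epoch_len
        dur = min(r1, w1) - max(r0, w0)
        if dur > 1e-12:
            total[label] += dur
            counts[label] += 1
    span = w1 - w0
    return ArchitectureStats(
        window=window,
        percent_time={s: 100.0 * total[s] / span for s in STATES},
        bout_count=dict(counts),
        mean_bout_duration={
            s: (total[s] / counts[s] if counts[s] else 0.0) for s in STATES
        },
    )


def state_band_power(
    spec: Spectrogram,
    hyp: Hypnogram,
    state: str,
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
) -> dict[str, float]:
    """Normalised band power (% of 0.5-30 Hz total) for one state's spectrum."""
    centers = spec.times
    mask = hyp.mask_for_samples(centers, state)
    if not mask.any():
        warnings.warn(f"state {state!r} absent from hypnogram", stacklevel=2)
        return {}
    mean_spec = spec.power[mask].mean(axis=0)
    norm = (spec.freqs >= NORM_RANGE[0]) & (spec.freqs < NORM_RANGE[1])
    total = mean_spec[norm].sum()
    if total <= 0:
        raise ValueError("zero total power in the normalisation range")
    out = {}
    for b in bands:
        m = norm & (spec.freqs >= b.lo) & (spec.freqs < b.hi)
        out[b.name] = 100.0 * mean_spec[m].sum() / total
    return out


def circadian_wake_profile(hyp: Hypnogram, zt0: float = 0.0) -> dict:
    """Wake percentage per Zeitgeber-hour bin plus phase aggregates.

    ``zt0`` is the Zeitgeber time (hours after lights-on) at the start of
    the hypnogram. Returns hourly bins covered by the hypnogram plus
    epoch-weighted aggregates for the light phase (ZT0-12), dark phase
    (ZT12-24) and the early (ZT13-17) / late (ZT18-24) night windows.
    """
    if hyp.duration < 3600.0:
        raise ValueError("hypnogram shorter than one Zeitgeber-hour bin")
    zt = (zt0 + (hyp.epoch_starts - hyp.start_time) / 3600.0) % 24.0
    hour = np.floor(zt).astype(int)
    wake = hyp.labels == "W"

    def agg(mask: np.ndarray) -> float:
        return float(100.0 * wake[mask].mean()) if mask.any() else float("nan")

    hourly = {int(h): agg(hour == h) for h in np.unique(hour)}
    return {
        "hourly": hourly,
        "day": agg((zt >= 0) & (zt < 12)),
        "night": agg((zt >= 12) & (zt < 24)),
        "zt13_17": agg((zt >= 13) & (zt < 17)),
        "zt18_24": agg((zt >= 18) & (zt < 24)),
    }


#: The transition classes analysed around state changes.
TRANSITION_KINDS = ("W→N", "N→W", "N→R", "R→W")


def list_transitions(hyp: Hypnogram) -> list[tuple[float, str, str, str]]:
    """All state changes as (boundary time, from, to, kind).

    ``kind`` is one of W→N, N→W, N→R, R→W or ``"other"``.
    """
    out = []
    for i in range(1, hyp.n_epochs):
        a, b = hyp.labels[i - 1], hyp.labels[i]
        if a != b:
            kind = f"{a}→{b}"
            if kind not in TRANSITION_KINDS:
                kind = "other"
            out.append(
                (hyp.start_time + i * hyp.epoch_len, str(a), str(b), kind)
            )
    return out
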