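"""Transient detection and cross-signal timing/coupling analysis.

Events are local maxima exceeding k·SD of the (z-scored or detrended)
trace; onset and offset are the 10%-of-amplitude crossings around the
peak, the per-event baseline is the mean of the signal over the 100 s
preceding the onset, and the event magnitude Σ_fluor is the area under the
baseline-subtracted curve between onset and offset.

Timing between two signals is estimated from event-aligned peri-event time
histograms (PETHs), min-max normalised to [0, 1]; the C₅₀ of a PETH is the
time at which its rising phase first crosses half of the peak, and the
difference in C₅₀ between two signals estimates their average lag.
Coupling strength is the Pearson correlation of per-event AUC pairs, the
partner-signal AUC being evaluated over the lag-shifted event window; its
null distribution comes from circularly shifting the partner trace.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps, stats
from sklearn.base import BaseEstimator

from .core import STATES, Event, EventSet, Hypnogram, Trace

#: Units on which SD-relative event detection is meaningful.
DETECTABLE_UNITS = ("zscore", "norm_zscore", "detrended", "dFF")

#: Pre-onset window over which the per-event baseline is averaged, seconds.
BASELINE_WINDOW = 100.0


# ---------------------------------------------------------------------------
# detection and delineation


class TransientDetector(BaseEstimator):
    """Supra-threshold transient detector with SD-relative height.

    ``fit`` computes the trace SD (over the whole trimmed trace) and the
    detection threshold ``mean + k·SD``; ``detect`` returns the delineated
    :class:`~photosleep.core.EventSet`. The threshold being SD-relative
    makes detection invariant to affine rescaling of the input.

    Parameters
    ----------
    k : float
        SD multiplier; events must exceed ``k`` standard deviations.
    min_separation : float
        Minimum peak-to-peak distance in seconds.
    frac : float
        Onset/offset are the crossings of ``frac`` of the peak amplitude
        (0.1 = the 10% criterion).
    """

    def __init__(self, k: float = 2.0, min_separation: float = 10.0,
                 frac: float = 0.1) -> None:
        self.k = k
        self.min_separation = min_separation
        self.frac = frac

    def fit(self, X: np.ndarray, y=None) -> "TransientDetector":
        if self.k <= 0:
            raise ValueError("k must be positive")
        x = np.asarray(X, dtype=float).ravel()
        self.sd_ = float(x.std())
        if self.sd_ == 0:
            raise ValueError("trace has zero variance")
        self.mean_ = float(x.mean())
        self.threshold_ = self.mean_ + self.k * self.sd_
        return self

    def detect(self, trace: Trace, delineate: bool = True) -> EventSet:
        self.fit(trace.values)
        distance = max(int(round(self.min_separation * trace.fs)), 1)
        idx, _ = sps.find_peaks(trace.values, height=self.threshold_,
                                distance=distance)
        events = [Event(peak_time=float(trace.t0 + i / trace.fs),
                        peak_amp=float(trace.values[i] - self.mean_))
                  for i in idx]
        es = EventSet(events=events, threshold=self.threshold_, sd=self.sd_)
        if delineate:
            es.events = self._delineate_and_merge(trace, es.events)
        return es

    def _delineate_and_merge(self, trace: Trace, events: list[Event]) -> list[Event]:
        """Delineate all events, merging peaks whose windows overlap.

        A noisy event top can produce several local maxima further apart
        than ``min_separation``; after delineation such duplicates share
        one onset-offset window, so only the tallest peak is kept and the
        remainder re-delineated until the windows are disjoint.
        """

        def run(evs: list[Event]) -> list[Event]:
            out = []
            for j, e in enumerate(evs):
                prev_t = evs[j - 1].peak_time if j > 0 else None
                next_t = evs[j + 1].peak_time if j + 1 < len(evs) else None
                out.append(delineate_event(trace, e, frac=self.frac,
                                           prev_peak=prev_t, next_peak=next_t))
            return out

        evs = run(events)
        while True:
            drop = None
            for j in range(len(evs) - 1):
                # duplicates overlap, or one window was bounded at the
                # inter-peak midpoint because no 10% crossing separates the
                # two peaks (a noise bump on the other event's envelope)
                mid = (evs[j].peak_time + evs[j + 1].peak_time) / 2.0
                midbound = (
                    (evs[j].truncated and abs(evs[j].offset - mid) < 1e-6)
                    or (evs[j + 1].truncated and abs(evs[j + 1].onset - mid) < 1e-6)
                )
                if evs[j + 1].onset < evs[j].offset - 1e-9 or midbound:
                    hj = trace.values[trace.index_of(evs[j].peak_time)]
                    hj1 = trace.values[trace.index_of(evs[j + 1].peak_time)]
                    drop = j if hj < hj1 else j + 1
                    break
            if drop is None:
                return evs
            del evs[drop]
            evs = run([Event(e.peak_time, e.peak_amp) for e in evs])


def detect_events(trace: Trace, k: float = 2.0, min_separation: float = 10.0,
                  delineate: bool = True) -> EventSet:
    """Detect supra-``k``·SD transients; see :class:`TransientDetector`."""
    if trace.unit not in DETECTABLE_UNITS:
        raise ValueError(
            f"event detection expects a normalised trace, got unit {trace.unit!r}"
        )
    return TransientDetector(k=k, min_separation=min_separation).detect(
        trace, delineate=delineate
    )


def _cross_time(t0: float, v0: float, t1: float, v1: float, level: float) -> float:
    """Linear-interpolated time at which the segment crosses ``level``."""
    if v1 == v0:
        return t1
    return t0 + (level - v0) / (v1 - v0) * (t1 - t0)


def auc_between(trace: Trace, start: float, end: float, baseline: float) -> float:
    """Σ (x − baseline) · dt over samples with start <= t < end.

    The half-open convention makes the AUC additive over adjacent windows.
    """
    seg = trace.slice_time(start, end)
    return float((seg.values - baseline).sum() / trace.fs)


def delineate_event(trace: Trace, peak: Event, frac: float = 0.1,
                    baseline_window: float = BASELINE_WINDOW,
                    prev_peak: float | None = None,
                    next_peak: float | None = None) -> Event:
    """Complete an event with onset, offset, baseline and AUC.

    Amplitude is measured from the pre-peak local baseline (the trace
    minimum over the approach to the peak, bounded by the previous event);
    onset is the last crossing of ``frac``·amplitude before the peak and
    offset the first crossing after. If a crossing is not found before the
    neighbouring event, the bound is placed at the midpoint between the two
    peaks and the event flagged truncated. The reported ``baseline`` is the
    trace mean over the 100 s preceding the onset (clipped to the trace
    start) and the AUC integrates ``x − baseline`` over [onset, offset).
    """
    fs, t0 = trace.fs, trace.t0
    ip = trace.index_of(peak.peak_time)
    left_t = prev_peak if prev_peak is not None else max(
        t0, peak.peak_time - 2 * baseline_window
    )
    il = trace.index_of(left_t)
    local_base = float(trace.values[il : ip + 1].min())
    amp = float(trace.values[ip] - local_base)
    level = local_base + frac * amp
    truncated = False

    # last sample at or below the 10% line before the peak
    below = np.nonzero(trace.values[il:ip] <= level)[0]
    if below.size:
        j = il + int(below[-1])
        onset = _cross_time(t0 + j / fs, trace.values[j],
                            t0 + (j + 1) / fs, trace.values[j + 1], level)
    else:
        onset = None
    if onset is None:
        if prev_peak is not None:
            onset = (prev_peak + peak.peak_time) / 2.0
        else:
            onset = t0 + il / fs
        truncated = True

    right_t = next_peak if next_peak is not None else trace.t0 + (trace.n - 1) / fs
    ir = trace.index_of(right_t)
    # first sample at or below the 10% line after the peak
    below = np.nonzero(trace.values[ip + 1 : ir + 1] <= level)[0]
    if below.size:
        j = ip + 1 + int(below[0])
        offset = _cross_time(t0 + (j - 1) / fs, trace.values[j - 1],
                             t0 + j / fs, trace.values[j], level)
    else:
        offset = None
    if offset is None:
        if next_peak is not None:
            offset = (peak.peak_time + next_peak) / 2.0
        else:
            offset = t0 + ir / fs
        truncated = True

    base_start = onset - baseline_window
    if base_start < t0:
        base_start = t0
        truncated = True
    if onset - base_start >= 1.0 / fs:
        baseline = float(trace.slice_time(base_start, onset).values.mean())
    else:
        baseline = local_base
        truncated = True
    auc = auc_between(trace, onset, max(offset, onset + 1.0 / fs), baseline)
    ev = Event(peak_time=peak.peak_time, peak_amp=amp, onset=onset,
               offset=offset, auc=auc, baseline=baseline, truncated=truncated)
    ev.validate()
    return ev


# ---------------------------------------------------------------------------
# PETH and lag


@dataclass
class PETH:
    """Min-max-normalised event-aligned average."""

    lags: np.ndarray
    mean: np.ndarray  # normalised to [0, 1]
    sem: np.ndarray  # scaled by the same normalisation factor
    n_events: int
    reference: str = "onset"
    raw_mean: np.ndarray | None = None


@dataclass
class LagEstimate:
    c50_a: float
    c50_b: float

    @property
    def lag(self) -> float:
        return self.c50_b - self.c50_a


@dataclass
class CorrelationResult:
    r: float
    p: float
    slope: float
    intercept: float
    n_events: int
    n_dropped: int = 0


def _extract_segments(trace: Trace, ref_times, window: tuple[float, float]
                      ) -> tuple[np.ndarray, np.ndarray]:
    w0, w1 = window
    if w1 <= w0:
        raise ValueError("window end must exceed window start")
    k0 = int(np.ceil(w0 * trace.fs - 1e-9))
    k1 = int(np.floor(w1 * trace.fs + 1e-9))
    lags = np.arange(k0, k1 + 1) / trace.fs
    segs = []
    for t in ref_times:
        i = int(round((t - trace.t0) * trace.fs))
        if i + k0 < 0 or i + k1 >= trace.n:
            continue  # partial windows are dropped
        segs.append(trace.values[i + k0 : i + k1 + 1])
    return lags, np.array(segs, dtype=float)


def build_peth(trace: Trace, ref_times, window: tuple[float, float],
               reference: str = "onset") -> PETH:
    """Event-aligned mean ± SEM, min-max normalised to [0, 1]."""
    lags, segs = _extract_segments(trace, ref_times, window)
    if segs.shape[0] < 3:
        raise ValueError(
            f"need >= 3 events with complete windows, got {segs.shape[0]}"
        )
    m = segs.mean(axis=0)
    sem = segs.std(axis=0, ddof=1) / np.sqrt(segs.shape[0])
    rng = m.max() - m.min()
    if rng == 0:
        raise ValueError("flat PETH cannot be normalised")
    return PETH(lags=lags, mean=(m - m.min()) / rng, sem=sem / rng,
                n_events=int(segs.shape[0]), reference=reference, raw_mean=m)


def c50(peth: PETH) -> float:
    """First upward 0.5-crossing on the rising phase, linearly interpolated.

    The rising phase runs from the PETH minimum preceding the global
    maximum up to that maximum.
    """
    m = peth.mean
    i_max = int(np.argmax(m))
    if i_max == 0:
        raise ValueError("PETH peaks at the window start; no rising phase")
    i_min = int(np.argmin(m[: i_max + 1]))
    for i in range(i_min + 1, i_max + 1):
        if m[i - 1] < 0.5 <= m[i]:
            return _cross_time(peth.lags[i - 1], m[i - 1], peth.lags[i], m[i], 0.5)
    raise ValueError("PETH does not cross 0.5 on its rising phase")


def estimate_lag(peth_a: PETH, peth_b: PETH) -> LagEstimate:
    """Lag between two signals as the difference of their PETH C₅₀ times."""
    if peth_a.lags.shape != peth_b.lags.shape or not np.allclose(
        peth_a.lags, peth_b.lags
    ):
        raise ValueError("PETHs must share the same lag grid")
    if peth_a.reference != peth_b.reference:
        raise ValueError("PETHs must share the same reference")
    return LagEstimate(c50_a=c50(peth_a), c50_b=c50(peth_b))


# ---------------------------------------------------------------------------
# coupling correlation and shuffle null


def _auc_on_partner(trace_b: Trace, onset: float, offset: float,
                    baseline_window: float = BASELINE_WINDOW) -> float | None:
    t_lo, t_hi = trace_b.t0, trace_b.t0 + trace_b.duration
    if onset - baseline_window < t_lo or offset >= t_hi or onset >= offset:
        return None
    base = float(trace_b.slice_time(onset - baseline_window, onset).values.mean())
    return auc_between(trace_b, onset, offset, base)


def paired_auc_correlation(events_a: EventSet, trace_b: Trace, lag: float
                           ) -> tuple[CorrelationResult, np.ndarray]:
    """Pearson correlation of per-event AUC pairs across two signals.

    For each delineated event of signal A, the partner AUC is the integral
    of ``trace_b`` over the lag-shifted event window [onset+lag, offset+lag)
    relative to trace B's own 100-s pre-window mean. Returns the
    correlation summary and the (n, 2) array of AUC pairs.
    """
    if not np.isfinite(lag):
        raise ValueError("lag must be finite")
    pairs = []
    dropped = 0
    for e in events_a:
        if not (np.isfinite(e.onset) and np.isfinite(e.offset)):
            dropped += 1
            continue
        auc_b = _auc_on_partner(trace_b, e.onset + lag, e.offset + lag)
        if auc_b is None:
            dropped += 1
            continue
        pairs.append((e.auc, auc_b))
    pairs = np.array(pairs, dtype=float)
    if pairs.shape[0] < 3:
        raise ValueError("fewer than 3 usable event pairs")
    r, p = stats.pearsonr(pairs[:, 0], pairs[:, 1])
    slope, intercept = np.polyfit(pairs[:, 0], pairs[:, 1], 1)
    return (
        CorrelationResult(r=float(r), p=float(p), slope=float(slope),
                          intercept=float(intercept), n_events=pairs.shape[0],
                          n_dropped=dropped),
        pairs,
    )


@dataclass
class ShuffleNull:
    null_r: np.ndarray
    observed_r: float
    mean_abs_r: float
    p_empirical: float
    n_perm: int


def shuffle_null(events_a: EventSet, trace_b: Trace, lag: float,
                 n_perm: int = 100, seed: int = 0,
                 min_shift: float = 200.0) -> ShuffleNull:
    """Null distribution of the coupling r under circular shifts of B.

    Each permutation rotates ``trace_b`` by a uniform random offset at
    least ``min_shift`` seconds away from zero (preserving the trace's
    autocorrelation), recomputes the paired AUCs and their Pearson r, and
    the empirical p-value is the add-one rank of |observed r| in the null.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    spans = [e.offset - e.onset for e in events_a
             if np.isfinite(e.onset) and np.isfinite(e.offset)]
    if not spans or trace_b.duration < 2 * max(spans):
        raise ValueError("trace too short relative to the event spans")
    if trace_b.duration <= 2 * min_shift:
        raise ValueError("trace too short for the requested minimum shift")
    obs, _ = paired_auc_correlation(events_a, trace_b, lag)
    rng = np.random.default_rng(seed)
    null = []
    for _ in range(n_perm):
        shift = rng.uniform(min_shift, trace_b.duration - min_shift)
        k = int(round(shift * trace_b.fs))
        rolled = trace_b.with_values(np.roll(trace_b.values, k))
        try:
            res, _ = paired_auc_correlation(events_a, rolled, lag)
            null.append(res.r)
        except ValueError:
            continue
    null = np.array(null, dtype=float)
    p_emp = (1 + int((np.abs(null) >= abs(obs.r)).sum())) / (null.size + 1)
    return ShuffleNull(null_r=null, observed_r=obs.r,
                       mean_abs_r=float(np.abs(null).mean()),
                       p_empirical=float(p_emp), n_perm=int(null.size))


# ---------------------------------------------------------------------------
# intervention quantification


def _window_amplitude(trace: Trace, onset: float, offset: float,
                      baseline_window: float = BASELINE_WINDOW) -> float | None:
    """Peak of the trace in [onset, offset) relative to its 100-s pre mean."""
    t_lo = trace.t0
    if onset <= t_lo or offset > trace.t0 + trace.duration or offset <= onset:
        return None
    base_start = max(t_lo, onset - baseline_window)
    if onset - base_start < 1.0 / trace.fs:
        return None
    base = float(trace.slice_time(base_start, onset).values.mean())
    seg = trace.slice_time(onset, offset)
    return float(seg.values.max() - base)


@dataclass
class HemisphereRatios:
    times: np.ndarray
    ratios: np.ndarray
    pre_mean: float  # nan when no usable events in the window
    post_mean: float
    n_pre: int
    n_post: int


def hemisphere_ratio(trace_ref: Trace, trace_test: Trace, t_inject: float,
                     pre_window: tuple[float, float] | None = None,
                     post_window: tuple[float, float] | None = None,
                     k: float = 2.0, min_separation: float = 10.0
                     ) -> HemisphereRatios:
    """Per-event test/reference amplitude ratios around an injection.

    Events are detected on the reference channel at ``k``·SD; for each, the
    "corresponding" test-channel amplitude is evaluated over the same
    onset–offset window (peak relative to the test channel's own 100-s
    pre-window mean) and the ratio test/ref is formed. Means are reported
    for a pre window (default [trace start, t_inject)) and a post window
    (default [t_inject + 120 s, t_inject + 3600 s), the 2-min-to-1-h
    post-injection convention).
    """
    events = detect_events(trace_ref, k=k, min_separation=min_separation)
    if pre_window is None:
        pre_window = (trace_ref.t0, t_inject)
    if post_window is None:
        post_window = (t_inject + 120.0, t_inject + 3600.0)
    times, ratios = [], []
    for e in events:
        if not (np.isfinite(e.onset) and np.isfinite(e.offset)):
            continue
        ref_amp = _window_amplitude(trace_ref, e.onset, e.offset)
        test_amp = _window_amplitude(trace_test, e.onset, e.offset)
        if ref_amp is None or test_amp is None or ref_amp == 0:
            continue
        times.append(e.peak_time)
        ratios.append(test_amp / ref_amp)
    times = np.array(times)
    ratios = np.array(ratios)

    def window_mean(w):
        m = (times >= w[0]) & (times < w[1])
        return (float(ratios[m].mean()) if m.any() else float("nan")), int(m.sum())

    pre_mean, n_pre = window_mean(pre_window)
    post_mean, n_post = window_mean(post_window)
    return HemisphereRatios(times=times, ratios=ratios, pre_mean=pre_mean,
                            post_mean=post_mean, n_pre=n_pre, n_post=n_post)


@dataclass
class InterventionEffect:
    pre_mean_amp: float  # nan when undefined
    post_mean_amp: float
    n_pre: int
    n_post: int

    @property
    def ratio(self) -> float:
        return self.post_mean_amp / self.pre_mean_amp


def intervention_effect(trace: Trace, t_drug: float, post_delay: float = 600.0,
                        k: float = 2.0, min_separation: float = 10.0
                        ) -> InterventionEffect:
    """Mean supra-threshold event amplitude before vs after a drug.

    The pre window is [trace start, t_drug) and the post window
    [t_drug + post_delay, trace end) — by default the 10-min post-injection
    convention. Event size is the mean amplitude of supra-``k``·SD events.
    """
    events = detect_events(trace, k=k, min_separation=min_separation)
    amps = events.peak_amps
    times = events.peak_times
    pre = amps[(times >= trace.t0) & (times < t_drug)]
    post = amps[times >= t_drug + post_delay]
    return InterventionEffect(
        pre_mean_amp=float(pre.mean()) if pre.size else float("nan"),
        post_mean_amp=float(post.mean()) if post.size else float("nan"),
        n_pre=int(pre.size), n_post=int(post.size),
    )


# ---------------------------------------------------------------------------
# state means and aligned averages


def state_mean(trace: Trace, hyp: Hypnogram) -> dict[str, float]:
    """Mean trace value within the epochs of each state (absent states omitted)."""
    out = {}
    times = trace.times
    for s in STATES:
        m = hyp.mask_for_samples(times, s)
        if m.any():
            out[s] = float(trace.values[m].mean())
    return out


@dataclass
class AlignedAverage:
    lags: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    n_events: int


def aligned_average(trace: Trace, ref_times, window: tuple[float, float]
                    ) -> AlignedAverage:
    """Un-normalised event-aligned mean ± SEM (transitions, stimulation)."""
    lags, segs = _extract_segments(trace, ref_times, window)
    if segs.shape[0] < 1:
        raise ValueError("no reference time has a complete window")
    sem = (segs.std(axis=0, ddof=1) / np.sqrt(segs.shape[0])
           if segs.shape[0] > 1 else np.zeros(segs.shape[1]))
    return AlignedAverage(lags=lags, mean=segs.mean(axis=0), sem=sem,
                          n_events=int(segs.shape[0]))
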