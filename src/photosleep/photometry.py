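"""Raw photometry to analysis-ready normalised traces.

The processing order is fixed and documented: 1-Hz binning → background
subtraction → two-exponential bleach baseline and ΔF/F₀ → initial-segment
trim (~10 min) → optional isosbestic unmixing → z-scoring → either slow
drift removal or NREM-SD normalisation depending on the analysis.

The photobleaching baseline is the usual sum of two exponentials plus an
offset, F₀(t) = A₁e^(−t/τ₁) + A₂e^(−t/τ₂) + C, fitted to the
background-subtracted fluorescence by nonlinear least squares; ΔF/F₀ is
(F − F₀)/F₀. Slow drift is removed either with a zero-phase Butterworth
high-pass at a signal-class-specific cutoff (0.00035 cycles/sample for
adenosine/ATP sensors, 0.001 for calcium indicators at the 1-Hz analysis
rate) or with a sparsity-assisted asymmetric-least-squares baseline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize, signal as sps, sparse
from scipy.sparse.linalg import spsolve
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .core import Hypnogram, Trace

#: High-pass cutoffs in cycles/sample at the 1-Hz analysis rate.
DRIFT_CUTOFFS: dict[str, float] = {"ado": 0.00035, "atp": 0.00035, "ca": 0.001}

#: Default initial-segment trim, seconds (~10 min of fast autofluorescence
#: bleaching at the start of a recording).
DEFAULT_TRIM = 600.0


def default_cutoff(signal_class: str) -> float:
    try:
        return DRIFT_CUTOFFS[signal_class]
    except KeyError:
        raise ValueError(
            f"unknown signal class {signal_class!r}; expected one of "
            f"{sorted(DRIFT_CUTOFFS)}"
        ) from None


# ---------------------------------------------------------------------------
# binning and trimming


def bin_to_1hz(raw: Trace) -> Trace:
    """Average non-overlapping 1-s blocks; the trailing partial block drops."""
    if raw.n == 0:
        raise ValueError("empty trace")
    if raw.fs < 1.0:
        raise ValueError("sampling rate below 1 Hz cannot be binned to 1 Hz")
    spb = int(round(raw.fs))
    n_blocks = raw.n // spb
    if n_blocks == 0:
        raise ValueError("trace shorter than one 1-s block")
    vals = raw.values[: n_blocks * spb].reshape(n_blocks, spb).mean(axis=1)
    return Trace(vals, fs=1.0, t0=raw.t0, unit=raw.unit)


def trim_initial(trace: Trace, trim: float = DEFAULT_TRIM) -> Trace:
    """Drop the first ``trim`` seconds of a trace and advance its t0."""
    if trim < 0:
        raise ValueError("trim must be non-negative")
    if trim == 0:
        return replace(trace, values=trace.values.copy())
    if trace.duration <= trim:
        raise ValueError("trace is not longer than the requested trim")
    k = int(round(trim * trace.fs))
    return replace(trace, values=trace.values[k:], t0=trace.t0 + k / trace.fs)


# ---------------------------------------------------------------------------
# bleach baseline / ΔF/F₀


@dataclass
class BaselineFit:
    """Fitted photobleaching baseline F₀(t) = A₁e^(−t/τ₁) + A₂e^(−t/τ₂) + C."""

    a1: float
    tau1: float
    a2: float
    tau2: float
    offset: float
    residual_rms: float
    converged: bool

    def __call__(self, t: np.ndarray) -> np.ndarray:
        return (
            self.a1 * np.exp(-np.asarray(t, dtype=float) / self.tau1)
            + self.a2 * np.exp(-np.asarray(t, dtype=float) / self.tau2)
            + self.offset
        )


def _double_exp(t, a1, tau1, a2, tau2, c):
    return a1 * np.exp(-t / tau1) + a2 * np.exp(-t / tau2) + c


def _single_exp(t, a1, tau1, c):
    return a1 * np.exp(-t / tau1) + c


class BleachCorrector(BaseEstimator, TransformerMixin):
    """ΔF/F₀ transformer based on a two-exponential bleach baseline.

    ``fit`` subtracts the constant ``background`` fluorescence and fits the
    baseline by bounded nonlinear least squares (initialised with
    A₁ = A₂ = half the decaying amplitude, τ₁ = span/10, τ₂ = span,
    C = final value). On non-convergence a single exponential plus offset
    is fitted instead and ``converged_`` is set False. ``transform``
    returns ΔF/F₀ = (F − background − F₀)/F₀.

    Parameters
    ----------
    background : float
        Constant autofluorescence measured before the recording, in the
        same units as the input.
    dt : float
        Sample interval of the input, seconds.
    """

    def __init__(self, background: float = 0.0, dt: float = 1.0) -> None:
        self.background = background
        self.dt = dt

    def fit(self, X: np.ndarray, y=None) -> "BleachCorrector":
        y_ = self._column(X) - self.background
        if y_.size * self.dt < 60.0:
            raise ValueError("need at least 60 s of data to fit a baseline")
        t = np.arange(y_.size) * self.dt
        span = t[-1] if t[-1] > 0 else 1.0
        c0 = float(y_[-1])
        amp = max(float(y_[0]) - c0, 1e-6)
        p0 = [amp / 2, span / 10, amp / 2, span, max(c0, 0.0)]
        lb = [0.0, 1e-6, 0.0, 1e-6, 0.0]
        ub = [np.inf] * 5
        converged = True
        try:
            popt, _ = optimize.curve_fit(
                _double_exp, t, y_, p0=p0, bounds=(lb, ub), maxfev=20000
            )
        except (RuntimeError, ValueError):
            popt = None
            converged = False
        if popt is not None:
            f0 = _double_exp(t, *popt)
            if f0.min() <= 0:
                popt, converged = None, False
        if popt is None:
            try:
                ps, _ = optimize.curve_fit(
                    _single_exp, t, y_, p0=[amp, span / 4, max(c0, 0.0)],
                    bounds=([0.0, 1e-6, 0.0], [np.inf] * 3), maxfev=20000,
                )
                popt = [ps[0], ps[1], 0.0, 1.0, ps[2]]
            except (RuntimeError, ValueError):
                # last resort: constant baseline at the mean
                popt = [0.0, 1.0, 0.0, 1.0, max(float(y_.mean()), 1e-12)]
        f0 = _double_exp(t, *popt)
        if f0.min() <= 0:
            raise ValueError("fitted baseline is not positive over the trace")
        self.baseline_ = BaselineFit(
            a1=float(popt[0]), tau1=float(popt[1]), a2=float(popt[2]),
            tau2=float(popt[3]), offset=float(popt[4]),
            residual_rms=float(np.sqrt(np.mean((y_ - f0) ** 2))),
            converged=converged,
        )
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        y_ = self._column(X) - self.background
        t = np.arange(y_.size) * self.dt
        f0 = self.baseline_(t)
        return (y_ - f0) / f0

    @staticmethod
    def _column(X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 2 and X.shape[1] == 1:
            X = X[:, 0]
        if X.ndim != 1:
            raise ValueError("expected a single-channel input")
        return X


def fit_bleach_baseline(trace: Trace, background: float = 0.0) -> tuple[BaselineFit, Trace]:
    """Background-subtract, fit the bleach baseline and return ΔF/F₀."""
    if background < 0:
        raise ValueError("background must be non-negative")
    est = BleachCorrector(background=background, dt=1.0 / trace.fs).fit(trace.values)
    dff = est.transform(trace.values)
    return est.baseline_, trace.with_values(dff, unit="dFF")


# ---------------------------------------------------------------------------
# normalisation


class TraceNormalizer(BaseEstimator, TransformerMixin):
    """z-score a trace, optionally re-scaled by its NREM-restricted SD.

    ``mode="zscore"`` standardises by the full-trace mean and SD.
    ``mode="nrem_sd"`` additionally divides the z-scored values by their
    SD over NREM-labelled samples (passed as a boolean mask to ``fit``),
    expressing the signal in units of its quiescent-period fluctuation so
    sessions can be averaged across animals.
    """

    def __init__(self, mode: str = "zscore") -> None:
        self.mode = mode

    def fit(self, X: np.ndarray, y=None, nrem_mask: np.ndarray | None = None) -> "TraceNormalizer":
        x = np.asarray(X, dtype=float).ravel()
        self.mean_ = float(x.mean())
        self.sd_ = float(x.std())
        if self.sd_ == 0:
            raise ValueError("trace has zero variance")
        if self.mode == "nrem_sd":
            if nrem_mask is None:
                raise ValueError("nrem_sd mode requires an NREM sample mask")
            nrem_mask = np.asarray(nrem_mask, dtype=bool)
            z = (x - self.mean_) / self.sd_
            sd = float(z[nrem_mask].std())
            if sd == 0:
                raise ValueError("zero variance over NREM samples")
            self.nrem_sd_ = sd
        elif self.mode != "zscore":
            raise ValueError(f"unknown mode {self.mode!r}")
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        z = (np.asarray(X, dtype=float).ravel() - self.mean_) / self.sd_
        if self.mode == "nrem_sd":
            z = z / self.nrem_sd_
        return z


def normalize_trace(trace: Trace, mode: str = "zscore", hyp: Hypnogram | None = None) -> Trace:
    """z-score (``mode="zscore"``) or NREM-SD-normalise (``mode="nrem_sd"``)."""
    nrem_mask = None
    if mode == "nrem_sd":
        if hyp is None:
            raise ValueError("nrem_sd normalisation requires a hypnogram")
        n_nrem = int((hyp.labels == "N").sum())
        if n_nrem < 10:
            raise ValueError(
                f"nrem_sd normalisation needs >= 10 NREM epochs, got {n_nrem}"
            )
        nrem_mask = hyp.mask_for_samples(trace.times, "N")
        if nrem_mask.sum() < 2:
            raise ValueError("trace has too few samples inside NREM epochs")
    est = TraceNormalizer(mode=mode).fit(trace.values, nrem_mask=nrem_mask)
    unit = "zscore" if mode == "zscore" else "norm_zscore"
    return trace.with_values(est.transform(trace.values), unit=unit)


# ---------------------------------------------------------------------------
# drift removal


def _asls_baseline(x: np.ndarray, lam: float, p: float = 0.01, n_iter: int = 10) -> np.ndarray:
    """Asymmetric-least-squares baseline (Whittaker smoother, asym. weights)."""
    n = x.size
    d = sparse.diags([1.0, -2.0, 1.0], [0, -1, -2], shape=(n, n - 2))
    dd = lam * (d @ d.T)
    w = np.ones(n)
    z = x
    for _ in range(n_iter):
        W = sparse.diags(w)
        z = spsolve((W + dd).tocsc(), w * x)
        w = np.where(x > z, p, 1.0 - p)
    return z


class DriftRemover(BaseEstimator, TransformerMixin):
    """Remove slow baseline drift below a cutoff given in cycles/sample.

    ``method="butter"`` applies a zero-phase 4th-order Butterworth
    high-pass (forward-backward). ``method="asls"`` subtracts a
    sparsity-assisted asymmetric-least-squares baseline whose smoothing
    parameter is matched to the same cutoff; the asymmetric penalty keeps
    positive transients out of the baseline.
    """

    def __init__(self, cutoff: float = DRIFT_CUTOFFS["ca"], method: str = "butter") -> None:
        self.cutoff = cutoff
        self.method = method

    def fit(self, X=None, y=None) -> "DriftRemover":
        if not (0 < self.cutoff < 0.5):
            raise ValueError("cutoff must lie in (0, 0.5) cycles/sample")
        if self.method not in ("butter", "asls"):
            raise ValueError(f"unknown method {self.method!r}")
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        self.fit()
        x = np.asarray(X, dtype=float).ravel()
        if self.method == "butter":
            sos = sps.butter(4, 2.0 * self.cutoff, btype="high", output="sos")
            return sps.sosfiltfilt(sos, x)
        # Whittaker 2nd-difference smoother: effective cutoff
        # fc ≈ (1/2π)·λ^(−1/4) cycles/sample  ⇒  λ = (2π·fc)^(−4)
        lam = (2.0 * np.pi * self.cutoff) ** -4
        return x - _asls_baseline(x, lam=lam)


def remove_drift(trace: Trace, cutoff: float | None = None,
                 signal_class: str = "ca", method: str = "butter") -> Trace:
    """High-pass a trace above the class-specific slow-drift cutoff."""
    if cutoff is None:
        cutoff = default_cutoff(signal_class)
    out = DriftRemover(cutoff=cutoff, method=method).fit().transform(trace.values)
    return trace.with_values(out, unit="detrended")


# ---------------------------------------------------------------------------
# isosbestic unmixing


class IsosbesticUnmixer(BaseEstimator, TransformerMixin):
    """Remove the shared motion artifact using the isosbestic channel.

    A two-source ICA is run on the {signal, isosbestic} pair; the source
    more correlated (in absolute value) with the isosbestic channel is
    designated the artifact and the signal is reconstructed without it,
    re-scaled to its original variance. If ICA does not converge, the
    isosbestic channel is regressed out of the signal instead.
    """

    def __init__(self, random_state: int = 0, max_iter: int = 1000) -> None:
        self.random_state = random_state
        self.max_iter = max_iter

    def fit(self, X: np.ndarray, y=None) -> "IsosbesticUnmixer":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("expected a two-column [signal, isosbestic] matrix")
        self.used_ica_ = True
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            ica = FastICA(
                n_components=2, random_state=self.random_state,
                max_iter=self.max_iter, whiten="unit-variance",
            )
            S = ica.fit_transform(X)
            if any(issubclass(w.category, ConvergenceWarning) for w in caught):
                self.used_ica_ = False
        if self.used_ica_:
            iso = X[:, 1]
            corr = [abs(np.corrcoef(S[:, k], iso)[0, 1]) for k in range(2)]
            self.artifact_component_ = int(np.argmax(corr))
            self._ica = ica
        else:
            warnings.warn(
                "ICA did not converge; regressing the isosbestic channel out "
                "of the signal instead",
                stacklevel=2,
            )
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        sig, iso = X[:, 0], X[:, 1]
        if self.used_ica_:
            S = self._ica.transform(X)
            S[:, self.artifact_component_] = 0.0
            clean = self._ica.inverse_transform(S)[:, 0]
        else:
            beta = np.cov(sig, iso)[0, 1] / max(np.var(iso), 1e-300)
            clean = sig - beta * (iso - iso.mean())
        sd = clean.std()
        if sd > 0:
            clean = (clean - clean.mean()) * (sig.std() / sd) + sig.mean()
        return clean


def unmix_isosbestic(signal: Trace, iso: Trace, random_state: int = 0) -> Trace:
    """ICA-unmix the shared artifact captured by the isosbestic channel."""
    if signal.n != iso.n or abs(signal.fs - iso.fs) > 1e-9:
        raise ValueError("signal and isosbestic traces must share length and fs")
    X = np.column_stack([signal.values, iso.values])
    est = IsosbesticUnmixer(random_state=random_state).fit(X)
    return signal.with_values(est.transform(X))


# ---------------------------------------------------------------------------
# the canonical preprocessing chain


def preprocess(
    raw: Trace,
    background: float = 0.0,
    hyp: Hypnogram | None = None,
    iso: Trace | None = None,
    trim: float = DEFAULT_TRIM,
    normalize: str = "zscore",
    drift: str | None = None,
    ica_seed: int = 0,
) -> Trace:
    """Run the standard chain: bin → ΔF/F₀ → trim → (unmix) → normalise.

    ``normalize`` is ``"zscore"`` or ``"nrem_sd"`` (the latter needs a
    hypnogram); ``drift`` optionally names a signal class ("ca", "ado",
    "atp") whose slow-drift cutoff is applied after z-scoring.
    """
    x = bin_to_1hz(raw) if raw.fs > 1.0 else raw
    _, dff = fit_bleach_baseline(x, background=background)
    if trim and dff.duration > trim:
        dff = trim_initial(dff, trim)
    if iso is not None:
        iso1 = bin_to_1hz(iso) if iso.fs > 1.0 else iso
        _, iso_dff = fit_bleach_baseline(iso1, background=background)
        iso_dff = iso_dff.slice_time(dff.t0, dff.t0 + dff.duration)
        dff = unmix_isosbestic(dff, iso_dff, random_state=ica_seed)
    out = normalize_trace(dff, mode=normalize, hyp=hyp)
    if drift is not None:
        out = remove_drift(out, signal_class=drift)
    return out
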