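"""System-level entropy from the eigenvalue spectrum of phase covariance.

The collective order of N coupled oscillators over a short time window is
summarized by the covariance of their instantaneous phases.  Its
eigendecomposition yields N covariance modes; each eigenvalue is the
variance ("energy") captured by one mode.  Normalizing the eigenvalues to
sum to one turns the spectrum into a probability distribution p over
modes, whose Shannon entropy

    H = -sum_n p_n ln p_n

ranges from 0 (all energy trapped in a single collective mode: full
order) to ln N (energy spread evenly over all modes: full disorder).
Computed in sliding windows (200 ms, 50% overlap by default), H(t) tracks
the system's itinerancy between ordered and disordered states.

Phases are circular, so "covariance of phase angles" is computed by
default on the unit-modulus phase factors e^{i theta}: their Hermitian
covariance is positive semi-definite, rotation-invariant and insensitive
to angle wrapping.  A real covariance of cos(theta) is available as an
alternative.  Phases are extracted once globally from the signals
low-pass filtered below 30 Hz (where the delay-induced collective
oscillations live), not per window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.signal

from .simulation import SignalSet

__all__ = [
    "EntropySeries",
    "instantaneous_phase",
    "windowed_phase_covariance",
    "eigenvalue_distribution",
    "shannon_entropy",
    "entropy_timeseries",
]


@dataclass
class EntropySeries:
    """Windowed eigenvalue distributions and Shannon entropy H(t)."""

    window_starts: np.ndarray  # (W,) seconds
    start_indices: np.ndarray  # (W,) sample index of each window start
    window_samples: int  # window length in samples
    window_length: float  # seconds
    overlap: float
    sampling_rate: float
    t0: float
    eigen_dist: np.ndarray  # (W, N) normalized eigenvalues, descending
    entropy: np.ndarray  # (W,) nats
    method: str = "complex_phase"
    f_cut: float = 30.0

    @property
    def n_windows(self) -> int:
        return self.entropy.shape[0]


def _lowpass(values: np.ndarray, fs: float, f_cut: float) -> np.ndarray:
    """FFT bin-zeroing low-pass: keep 0 < f <= f_cut (DC removed)."""
    T = values.shape[-1]
    spec = np.fft.rfft(values, axis=-1)
    freqs = np.fft.rfftfreq(T, d=1.0 / fs)
    keep = freqs <= f_cut
    keep[0] = False
    spec[..., ~keep] = 0.0
    return np.fft.irfft(spec, n=T, axis=-1)


def instantaneous_phase(signals: SignalSet, f_cut: float = 30.0) -> np.ndarray:
    """Per-node instantaneous phase (radians) of the low-passed signals."""
    if f_cut >= signals.sampling_rate / 2:
        raise ValueError(
            f"f_cut {f_cut} Hz at or above Nyquist {signals.sampling_rate / 2} Hz"
        )
    values = signals.real
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite input to instantaneous_phase")
    filt = _lowpass(values, signals.sampling_rate, f_cut)
    return np.angle(scipy.signal.hilbert(filt, axis=-1))


def windowed_phase_covariance(
    phases: np.ndarray,
    sampling_rate: float,
    window_length: float = 0.2,
    overlap: float = 0.5,
    method: str = "complex_phase",
) -> tuple[np.ndarray, np.ndarray, int]:
    """Sliding-window covariance matrices of the node phases.

    Windows are left-aligned, wholly inside the record, starting every
    ``window_samples * (1 - overlap)`` samples; a partial trailing window
    is dropped.  Returns ``(covs, start_indices, window_samples)`` where
    ``covs`` has shape (W, N, N) and is Hermitian PSD for the default
    ``complex_phase`` method (covariance of mean-subtracted e^{i theta})
    or real symmetric for ``cosine_phase`` (covariance of cos theta).
    """
    phases = np.asarray(phases)
    if phases.ndim != 2:
        raise ValueError("phases must be an (N, T) matrix")
    n, T = phases.shape
    w_s = int(round(window_length * sampling_rate))
    if w_s < 2:
        raise ValueError("window_length shorter than 2 samples")
    if w_s > T:
        raise ValueError(f"window of {w_s} samples longer than record ({T})")
    if not 0.0 <= overlap < 1.0:
        raise ValueError("overlap must lie in [0, 1)")
    step = int(round(w_s * (1.0 - overlap)))
    if step < 1:
        raise ValueError("overlap too high: window step below one sample")
    starts = np.arange(0, T - w_s + 1, step)
    if method == "complex_phase":
        z = np.exp(1j * phases)
        covs = np.empty((starts.size, n, n), dtype=np.complex128)
        for i, s in enumerate(starts):
            seg = z[:, s : s + w_s]
            seg = seg - seg.mean(axis=1, keepdims=True)
            covs[i] = seg @ seg.conj().T / w_s
    elif method == "cosine_phase":
        x = np.cos(phases)
        covs = np.empty((starts.size, n, n), dtype=np.float64)
        for i, s in enumerate(starts):
            seg = x[:, s : s + w_s]
            seg = seg - seg.mean(axis=1, keepdims=True)
            covs[i] = seg @ seg.T / w_s
    else:
        raise ValueError(f"unknown method {method!r}")
    return covs, starts, w_s


def eigenvalue_distribution(cov: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Normalized eigenvalue spectrum of a Hermitian PSD matrix.

    Eigenvalues are clipped at zero (numerical negatives), sorted in
    descending order and divided by their sum, yielding a probability
    distribution over covariance modes.
    """
    cov = np.asarray(cov)
    if cov.ndim != 2 or cov.shape[0] != cov.shape[1]:
        raise ValueError("covariance must be a square matrix")
    herm_err = np.abs(cov - cov.conj().T).max()
    scale = max(np.abs(cov).max(), 1.0)
    if herm_err > tol * scale:
        raise ValueError(f"matrix not Hermitian within tolerance ({herm_err:.3g})")
    lam = np.linalg.eigvalsh(cov)
    lam = np.clip(lam.real, 0.0, None)[::-1]
    total = lam.sum()
    if total <= 0:
        raise ValueError("zero-trace covariance: eigenvalue distribution undefined")
    return lam / total


def shannon_entropy(p: np.ndarray, tol: float = 1e-6) -> float:
    """Shannon entropy -sum p ln p (nats) of a probability vector.

    Zero entries contribute nothing (0 ln 0 = 0 by continuity); the result
    lies in [0, ln len(p)].
    """
    p = np.asarray(p, dtype=float)
    if np.any(p < 0):
        raise ValueError("probabilities must be non-negative")
    if abs(p.sum() - 1.0) > tol:
        raise ValueError(f"probabilities sum to {p.sum():.8f}, not 1")
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def entropy_timeseries(
    signals: SignalSet,
    window_length: float = 0.2,
    overlap: float = 0.5,
    method: str = "complex_phase",
    f_cut: float = 30.0,
) -> EntropySeries:
    """H(t): windowed eigenvalue-spectrum Shannon entropy of the signals."""
    phases = instantaneous_phase(signals, f_cut=f_cut)
    covs, starts, w_s = windowed_phase_covariance(
        phases,
        signals.sampling_rate,
        window_length=window_length,
        overlap=overlap,
        method=method,
    )
    n = phases.shape[0]
    eigen_dist = np.empty((starts.size, n))
    entropy = np.empty(starts.size)
    for i in range(starts.size):
        eigen_dist[i] = eigenvalue_distribution(covs[i])
        entropy[i] = shannon_entropy(eigen_dist[i])
    return EntropySeries(
        window_starts=signals.t0 + starts / signals.sampling_rate,
        start_indices=starts,
        window_samples=w_s,
        window_length=window_length,
        overlap=overlap,
        sampling_rate=signals.sampling_rate,
        t0=signals.t0,
        eigen_dist=eigen_dist,
        entropy=entropy,
        method=method,
        f_cut=f_cut,
    )
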