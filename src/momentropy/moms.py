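"""Detection of metastable oscillatory modes (MOMs).

A MOM is a transient collective oscillation: a coalition of nodes whose
band-limited amplitude envelope rises far above a noise baseline at the
same time, persists briefly, then dissolves.  Detection proceeds band by
band over the four canonical sub-gamma frequency bands:

1. band-pass filter each node signal by FFT bin zeroing;
2. amplitude envelope = magnitude of the analytic (Hilbert) signal;
3. baseline = per-node, per-band envelope mean and SD from a twin
   simulation with all conduction delays set to zero (where collective
   slow oscillations cannot form, so sub-gamma power is noise-level);
4. a node is "active" when its envelope exceeds mean + n_std * SD
   (n_std = 5 by default);
5. the coalition size is the number of simultaneously active nodes; runs
   of coalition size >= min_coalition (default 5) are classified as MOM
   events.

Coalition-size series are kept raw (no minimum-size masking): the minimum
size applies to event classification only, while the continuous series —
including sub-threshold regimes where it hovers near zero — is what is
correlated with the system entropy downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.signal

from .connectome import Connectome
from .simulation import SignalSet, SimulationParams, integrate_network

__all__ = [
    "BandSpec",
    "DEFAULT_BANDS",
    "BaselineStats",
    "CoalitionSeries",
    "MOMEvent",
    "DetectionError",
    "bandpass_fft",
    "hilbert_envelope",
    "band_envelopes",
    "compute_baseline",
    "coalition_counts",
    "detect_mom_events",
]

#: duration (s) at each record edge flagged as filter-edge-affected
EDGE_GUARD_S = 0.1


class DetectionError(ValueError):
    pass


@dataclass(frozen=True)
class BandSpec:
    name: str
    f_lo: float  # Hz
    f_hi: float  # Hz

    def __post_init__(self) -> None:
        if not 0 < self.f_lo < self.f_hi:
            raise DetectionError(f"invalid band {self.name}: [{self.f_lo}, {self.f_hi}]")


#: canonical sub-gamma bands
DEFAULT_BANDS: tuple[BandSpec, ...] = (
    BandSpec("delta", 0.5, 4.0),
    BandSpec("theta", 4.0, 8.0),
    BandSpec("alpha", 8.0, 13.0),
    BandSpec("beta", 13.0, 30.0),
)


@dataclass
class BaselineStats:
    """Per-(band, node) envelope statistics from the no-delay twin run."""

    bands: tuple[BandSpec, ...]
    mean_amp: np.ndarray  # (B, N)
    std_amp: np.ndarray  # (B, N)
    n_std: float
    threshold_formula: str = "mean_plus_sd"  # or "sd_only"
    thresholds: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if self.n_std <= 0:
            raise DetectionError("n_std must be positive")
        if self.threshold_formula == "mean_plus_sd":
            self.thresholds = self.mean_amp + self.n_std * self.std_amp
        elif self.threshold_formula == "sd_only":
            self.thresholds = self.n_std * self.std_amp
        else:
            raise DetectionError(
                f"unknown threshold_formula {self.threshold_formula!r}"
            )


@dataclass(frozen=True)
class MOMEvent:
    band: str
    start: float  # seconds
    duration: float  # seconds
    peak_size: int
    node_set: tuple[int, ...]


@dataclass
class CoalitionSeries:
    """Per-band coalition-size series with the supra-threshold node masks."""

    bands: tuple[BandSpec, ...]
    counts: np.ndarray  # (B, T) int
    total: np.ndarray  # (T,) int, sum over bands
    above: np.ndarray  # (B, N, T) bool
    sampling_rate: float
    t0: float = 0.0
    events: list[MOMEvent] = field(default_factory=list)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    @property
    def edge_mask(self) -> np.ndarray:
        """True for samples within the filter-edge guard at either end."""
        guard = int(round(EDGE_GUARD_S * self.sampling_rate))
        mask = np.zeros(self.n_samples, dtype=bool)
        if guard > 0:
            mask[:guard] = True
            mask[-guard:] = True
        return mask


def _as_values(signals) -> tuple[np.ndarray, float]:
    if isinstance(signals, SignalSet):
        return signals.real, signals.sampling_rate
    raise TypeError("expected a SignalSet")


def _fft_band_filter(values: np.ndarray, fs: float, f_lo: float, f_hi: float) -> np.ndarray:
    """FFT bin-zeroing band-pass: keep f_lo <= |f| <= f_hi, drop DC."""
    if f_lo >= fs / 2:
        raise DetectionError(
            f"band low edge {f_lo} Hz at or above Nyquist {fs / 2} Hz"
        )
    values = np.asarray(values, dtype=float)
    T = values.shape[-1]
    spec = np.fft.rfft(values, axis=-1)
    freqs = np.fft.rfftfreq(T, d=1.0 / fs)
    keep = (freqs >= f_lo) & (freqs <= f_hi)
    keep[0] = False
    spec[..., ~keep] = 0.0
    return np.fft.irfft(spec, n=T, axis=-1)


def bandpass_fft(signals: SignalSet, band: BandSpec) -> SignalSet:
    """Band-pass a SignalSet by zeroing FFT bins outside [f_lo, f_hi]."""
    values, fs = _as_values(signals)
    if band.f_hi > fs / 2:
        raise DetectionError(
            f"band {band.name} upper edge {band.f_hi} Hz above Nyquist {fs / 2} Hz"
        )
    filt = _fft_band_filter(values, fs, band.f_lo, band.f_hi)
    meta = dict(signals.meta)
    meta["band"] = {"name": band.name, "f_lo": band.f_lo, "f_hi": band.f_hi}
    return SignalSet(values=filt, sampling_rate=fs, t0=signals.t0, meta=meta)


def hilbert_envelope(signals) -> np.ndarray:
    """Instantaneous amplitude: magnitude of the analytic signal, per node."""
    if isinstance(signals, SignalSet):
        values = signals.real
    else:
        values = np.asarray(signals, dtype=float)
    if not np.all(np.isfinite(values)):
        raise DetectionError("non-finite input to hilbert_envelope")
    return np.abs(scipy.signal.hilbert(values, axis=-1))


def band_envelopes(
    signals: SignalSet, bands: tuple[BandSpec, ...] = DEFAULT_BANDS
) -> np.ndarray:
    """Stack of per-band amplitude envelopes, shape (B, N, T)."""
    return np.stack([hilbert_envelope(bandpass_fft(signals, b)) for b in bands])


def compute_baseline(
    params: SimulationParams,
    connectome: Connectome,
    bands: tuple[BandSpec, ...] = DEFAULT_BANDS,
    n_std: float = 5.0,
    *,
    threshold_formula: str = "mean_plus_sd",
    baseline_seed: int | None = None,
) -> BaselineStats:
    """Envelope baseline from a twin run with conduction delays removed.

    Without delays the network cannot sustain collective sub-gamma
    oscillations, so each band envelope reflects the noise floor; its mean
    and SD per node define the detection threshold mean + n_std * SD.  By
    default the twin run reuses the main run's seed (paired noise).
    """
    p0 = replace(
        params,
        mean_delay=0.0,
        store_complex=False,
        seed=params.seed if baseline_seed is None else baseline_seed,
    )
    signals = integrate_network(p0, connectome)
    envs = band_envelopes(signals, bands)
    mean_amp = envs.mean(axis=-1)
    std_amp = envs.std(axis=-1)
    bad = np.argwhere(std_amp <= 0)
    if bad.size:
        b, n = bad[0]
        raise DetectionError(
            f"degenerate (zero-variance) baseline envelope: band "
            f"{bands[b].name!r}, node {n}"
        )
    return BaselineStats(
        bands=tuple(bands),
        mean_amp=mean_amp,
        std_amp=std_amp,
        n_std=n_std,
        threshold_formula=threshold_formula,
    )


def coalition_counts(
    envelopes: np.ndarray,
    baseline: BaselineStats,
    sampling_rate: float,
    t0: float = 0.0,
) -> CoalitionSeries:
    """Count supra-threshold nodes per band and per sample.

    ``envelopes`` has shape (B, N, T) matching the baseline's bands and
    nodes.  Counts are raw coalition sizes; no minimum-size masking is
    applied here (the minimum applies to event classification only).
    """
    envelopes = np.asarray(envelopes)
    if envelopes.ndim != 3 or envelopes.shape[:2] != baseline.thresholds.shape:
        raise DetectionError(
            f"envelope shape {envelopes.shape} inconsistent with baseline "
            f"{baseline.thresholds.shape}"
        )
    above = envelopes > baseline.thresholds[:, :, None]
    counts = above.sum(axis=1).astype(np.int64)
    return CoalitionSeries(
        bands=baseline.bands,
        counts=counts,
        total=counts.sum(axis=0),
        above=above,
        sampling_rate=sampling_rate,
        t0=t0,
    )


def detect_mom_events(
    series: CoalitionSeries, min_coalition: int = 5
) -> list[MOMEvent]:
    """Classify maximal runs of coalition size >= min_coalition as events.

    Each event records its band, onset time, duration, peak coalition size
    and the active node set at the peak sample (earliest sample on ties).
    """
    if min_coalition < 1:
        raise DetectionError("min_coalition must be >= 1")
    events: list[MOMEvent] = []
    dt = 1.0 / series.sampling_rate
    for b, band in enumerate(series.bands):
        mask = series.counts[b] >= min_coalition
        if not mask.any():
            continue
        padded = np.diff(np.concatenate(([0], mask.view(np.int8), [0])))
        starts = np.flatnonzero(padded == 1)
        ends = np.flatnonzero(padded == -1)  # exclusive
        for s, e in zip(starts, ends):
            seg = series.counts[b, s:e]
            peak_off = int(np.argmax(seg))  # argmax returns the earliest tie
            peak_idx = s + peak_off
            node_set = tuple(np.flatnonzero(series.above[b, :, peak_idx]))
            events.append(
                MOMEvent(
                    band=band.name,
                    start=series.t0 + s * dt,
                    duration=(e - s) * dt,
                    peak_size=int(seg[peak_off]),
                    node_set=node_set,
                )
            )
    events.sort(key=lambda ev: (ev.start, ev.band))
    return events
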