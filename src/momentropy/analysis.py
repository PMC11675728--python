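"""Coupling MOM coalition dynamics to system entropy.

The central claim tested here is an *anti-correlation*: when a large
coalition of nodes engages in a metastable oscillatory mode, the system's
energy concentrates in few covariance modes and the eigenvalue-spectrum
entropy drops.  The pipeline therefore

1. simulates the network,
2. detects coalition sizes against the no-delay baseline,
3. computes the windowed eigenvalue-spectrum entropy H(t),
4. averages the total coalition size over the same windows, and
5. reports the Pearson correlation between the two series.

A (K, <tau>) parameter sweep repeats the pipeline per grid cell with
Bonferroni correction over the cells, and a window-size robustness mode
re-analyzes one simulation at several window lengths.

The t-based Pearson p-value treats windows as independent although 50%
overlapping windows are autocorrelated, so it is anti-conservative; an
optional circular-shift permutation p-value is provided for honest
inference.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.stats

from .connectome import Connectome
from .entropy import EntropySeries, entropy_timeseries
from .moms import (
    DEFAULT_BANDS,
    BandSpec,
    BaselineStats,
    CoalitionSeries,
    band_envelopes,
    coalition_counts,
    compute_baseline,
    detect_mom_events,
)
from .simulation import SignalSet, SimulationParams, integrate_network

__all__ = [
    "DegenerateSeriesError",
    "PipelineError",
    "PipelineResult",
    "SweepResult",
    "window_average",
    "pearson_correlation",
    "bonferroni_adjust",
    "permutation_pvalue",
    "run_pipeline",
    "run_parameter_sweep",
    "run_window_robustness",
    "derive_cell_seed",
]


class DegenerateSeriesError(ValueError):
    """A correlation input has zero variance; r is undefined (NA, not 0)."""


class PipelineError(RuntimeError):
    """Failure in a named pipeline stage."""


def window_average(series: np.ndarray, windows: EntropySeries) -> np.ndarray:
    """Average a sample-rate series over the entropy windows.

    ``series`` must live on the same sampling grid as the signals behind
    ``windows``; each output value is the arithmetic mean of the samples in
    [start, start + window_length).
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 1:
        raise ValueError("series must be one-dimensional")
    last = windows.start_indices[-1] + windows.window_samples
    if series.size < last:
        raise ValueError(
            f"series of {series.size} samples shorter than window span {last}"
        )
    w_s = windows.window_samples
    return np.array(
        [series[s : s + w_s].mean() for s in windows.start_indices]
    )


def pearson_correlation(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Product-moment r with a two-sided t-based p (W - 2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be one-dimensional and equally long")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in correlation input")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DegenerateSeriesError("zero-variance series: correlation undefined")
    res = scipy.stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def bonferroni_adjust(p_values, m: int) -> np.ndarray:
    """Multiply each p by the family size m, capping at 1."""
    p = np.asarray(p_values, dtype=float)
    if m < p.size:
        raise ValueError("family size m smaller than the number of p-values")
    finite = p[np.isfinite(p)]
    if np.any((finite < 0) | (finite > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return np.minimum(1.0, m * p)


def permutation_pvalue(
    x: np.ndarray, y: np.ndarray, n_perm: int = 1000, seed: int = 0
) -> float:
    """Circular-shift permutation p for the Pearson r of two series.

    Shifting one series by a random circular offset preserves its
    autocorrelation while destroying the pairing, giving a null that is
    honest under overlapping-window dependence.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    r_obs, _ = pearson_correlation(x, y)
    rng = np.random.default_rng(seed)
    shifts = rng.integers(1, x.size, size=n_perm)
    exceed = 0
    for s in shifts:
        r_p = np.corrcoef(x, np.roll(y, s))[0, 1]
        if abs(r_p) >= abs(r_obs):
            exceed += 1
    return (exceed + 1) / (n_perm + 1)


@dataclass
class PipelineResult:
    """Everything one pipeline run produced, statsmodels-results style.

    The headline numbers are ``r`` (Pearson correlation between the
    window-averaged total coalition size and the entropy H(t)) and its
    t-based two-sided ``p_raw``.  ``na_reason`` is set (and r/p are NaN)
    when a series was degenerate.
    """

    params: SimulationParams
    baseline: BaselineStats
    coalition: CoalitionSeries
    entropy: EntropySeries
    coalition_windowed: np.ndarray  # (W,) total coalition size per window
    r: float
    p_raw: float
    na_reason: str | None = None
    signals: SignalSet | None = None
    min_coalition: int = 5

    @property
    def n_windows(self) -> int:
        return self.entropy.n_windows

    @property
    def events(self):
        return self.coalition.events

    @property
    def mean_entropy(self) -> float:
        return float(self.entropy.entropy.mean())

    @property
    def mean_coalition(self) -> float:
        return float(self.coalition_windowed.mean())

    def permutation_p(self, n_perm: int = 1000, seed: int = 0) -> float:
        if self.na_reason:
            return float("nan")
        return permutation_pvalue(
            self.coalition_windowed, self.entropy.entropy, n_perm=n_perm, seed=seed
        )

    def summary(self) -> str:
        p = self.params
        lines = [
            "Metastable oscillatory modes vs. eigen-spectrum entropy",
            "=" * 58,
            f"nodes: {self.baseline.mean_amp.shape[1]:>5d}    "
            f"K: {p.K:<8g} mean delay: {p.mean_delay * 1e3:g} ms",
            f"duration: {p.duration:g} s @ {1 / p.output_interval:g} Hz, "
            f"seed {p.seed}",
            f"windows: {self.n_windows} x {self.entropy.window_length * 1e3:g} ms "
            f"({self.entropy.overlap:.0%} overlap), log base e",
            "-" * 58,
            f"Pearson r (coalition vs entropy): {self.r: .4f}",
            f"p (two-sided, t, {self.n_windows - 2} df):  {self.p_raw:.3g}",
            f"mean entropy H:          {self.mean_entropy:.4f} nats "
            f"(max ln N = {np.log(self.baseline.mean_amp.shape[1]):.4f})",
            f"mean total coalition:    {self.mean_coalition:.4f} nodes",
            f"MOM events (size >= {self.min_coalition}): {len(self.events)}",
        ]
        if self.na_reason:
            lines.append(f"NOTE: correlation undefined ({self.na_reason})")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Diagnostic twin-axis plot of coalition size and entropy."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(9, 3))
        t = self.entropy.window_starts
        ax.plot(t, self.coalition_windowed, color="tab:blue", label="coalition size")
        ax.set_xlabel("time (s)")
        ax.set_ylabel("window-mean coalition size", color="tab:blue")
        ax2 = ax.twinx()
        ax2.plot(t, self.entropy.entropy, color="tab:orange", label="entropy")
        ax2.set_ylabel("H(t) (nats)", color="tab:orange")
        ax.set_title(f"r = {self.r:.3f}")
        return ax


def run_pipeline(
    params: SimulationParams,
    connectome: Connectome,
    *,
    bands: tuple[BandSpec, ...] = DEFAULT_BANDS,
    n_std: float = 5.0,
    min_coalition: int = 5,
    window_length: float = 0.2,
    overlap: float = 0.5,
    phase_method: str = "complex_phase",
    lowpass_hz: float = 30.0,
    threshold_formula: str = "mean_plus_sd",
    baseline_seed: int | None = None,
    keep_signals: bool = False,
) -> PipelineResult:
    """Simulate, detect coalitions, compute H(t) and correlate the two."""

    def stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except (DegenerateSeriesError, PipelineError):
            raise
        except Exception as exc:  # re-raise with the failing stage named
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc

    signals = stage("simulate", integrate_network, params, connectome)
    baseline = stage(
        "baseline",
        compute_baseline,
        params,
        connectome,
        bands,
        n_std,
        threshold_formula=threshold_formula,
        baseline_seed=baseline_seed,
    )
    envs = stage("envelopes", band_envelopes, signals, bands)
    coalition = stage(
        "coalitions",
        coalition_counts,
        envs,
        baseline,
        signals.sampling_rate,
        signals.t0,
    )
    coalition.events = stage("events", detect_mom_events, coalition, min_coalition)
    ent = stage(
        "entropy",
        entropy_timeseries,
        signals,
        window_length=window_length,
        overlap=overlap,
        method=phase_method,
        f_cut=lowpass_hz,
    )
    coal_win = stage("window_average", window_average, coalition.total, ent)
    na_reason = None
    try:
        r, p = pearson_correlation(coal_win, ent.entropy)
    except DegenerateSeriesError as exc:
        r, p, na_reason = float("nan"), float("nan"), str(exc)
    return PipelineResult(
        params=params,
        baseline=baseline,
        coalition=coalition,
        entropy=ent,
        coalition_windowed=coal_win,
        r=r,
        p_raw=p,
        na_reason=na_reason,
        signals=signals if keep_signals else None,
        min_coalition=min_coalition,
    )


def derive_cell_seed(master_seed: int, cell_index: int) -> int:
    """Deterministic, well-separated per-cell seed from a master seed."""
    ss = np.random.SeedSequence([int(master_seed), int(cell_index)])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class SweepResult:
    """Per-cell correlations over the (K, mean delay) grid."""

    frame: pd.DataFrame
    m: int  # Bonferroni family size (number of cells)
    master_seed: int
    results: list[PipelineResult] = field(default_factory=list, repr=False)

    def summary(self) -> str:
        cols = [
            "K",
            "tau_ms",
            "r",
            "p_raw",
            "p_adj",
            "mean_entropy",
            "mean_coalition",
            "seed",
        ]
        body = self.frame[cols].to_string(
            index=False, float_format=lambda v: f"{v:.4g}"
        )
        return (
            f"(K, <tau>) sweep: {self.m} cells, Bonferroni m = {self.m}, "
            f"master seed {self.master_seed}\n{body}"
        )

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def run_parameter_sweep(
    K_values,
    delay_values,
    base_params: SimulationParams,
    connectome: Connectome,
    master_seed: int = 0,
    keep_results: bool = False,
    **pipeline_kwargs,
) -> SweepResult:
    """One pipeline run per (K, mean delay) cell with Bonferroni over cells.

    Per-cell seeds are derived deterministically from ``master_seed`` and
    the cell index.  A failing cell is recorded (status column) and the
    sweep continues.
    """
    K_values = list(K_values)
    delay_values = list(delay_values)
    if not K_values or not delay_values:
        raise ValueError("empty parameter grid")
    cells = list(itertools.product(K_values, delay_values))
    m = len(cells)
    rows = []
    results: list[PipelineResult] = []
    for idx, (K, tau) in enumerate(cells):
        seed = derive_cell_seed(master_seed, idx)
        params = replace(base_params, K=float(K), mean_delay=float(tau), seed=seed)
        row = {
            "K": float(K),
            "tau_ms": float(tau) * 1e3,
            "seed": seed,
            "status": "ok",
            "r": float("nan"),
            "p_raw": float("nan"),
            "mean_entropy": float("nan"),
            "mean_coalition": float("nan"),
            "n_windows": 0,
            "n_events": 0,
        }
        try:
            res = run_pipeline(params, connectome, **pipeline_kwargs)
            row.update(
                r=res.r,
                p_raw=res.p_raw,
                mean_entropy=res.mean_entropy,
                mean_coalition=res.mean_coalition,
                n_windows=res.n_windows,
                n_events=len(res.events),
            )
            if res.na_reason:
                row["status"] = f"NA: {res.na_reason}"
            if keep_results:
                results.append(res)
        except PipelineError as exc:
            row["status"] = f"failed: {exc}"
        rows.append(row)
    frame = pd.DataFrame(rows)
    frame["p_adj"] = bonferroni_adjust(frame["p_raw"].to_numpy(), m)
    return SweepResult(frame=frame, m=m, master_seed=master_seed, results=results)


def run_window_robustness(
    params: SimulationParams,
    connectome: Connectome,
    window_lengths=(0.2, 0.3, 0.4, 0.5, 0.6),
    overlap: float = 0.5,
    **pipeline_kwargs,
) -> pd.DataFrame:
    """Re-analyze one simulation at several entropy window lengths.

    The simulation and coalition detection are shared across window
    lengths; only the windowing (entropy + coalition averaging +
    correlation) is repeated.  Returns one row per window length.
    """
    first = run_pipeline(
        params,
        connectome,
        window_length=window_lengths[0],
        overlap=overlap,
        keep_signals=True,
        **pipeline_kwargs,
    )
    rows = [
        {
            "window_ms": window_lengths[0] * 1e3,
            "r": first.r,
            "p_raw": first.p_raw,
            "n_windows": first.n_windows,
        }
    ]
    for wl in window_lengths[1:]:
        ent = entropy_timeseries(
            first.signals,
            window_length=wl,
            overlap=overlap,
            method=pipeline_kwargs.get("phase_method", "complex_phase"),
            f_cut=pipeline_kwargs.get("lowpass_hz", 30.0),
        )
        coal = window_average(first.coalition.total, ent)
        try:
            r, p = pearson_correlation(coal, ent.entropy)
        except DegenerateSeriesError:
            r, p = float("nan"), float("nan")
        rows.append(
            {"window_ms": wl * 1e3, "r": r, "p_raw": p, "n_windows": ent.n_windows}
        )
    return pd.DataFrame(rows)
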