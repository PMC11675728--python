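"""Model facade: build once, then simulate, fit and sweep.

``MetastableOscillationModel`` bundles a connectome with the dynamical and
analysis settings the way a statsmodels model bundles data with a design:
``fit()`` runs the full simulate -> detect -> entropy -> correlate
pipeline and returns a results object carrying the coalition/entropy
series, the Pearson r with its p-value, and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import replace

from .analysis import (
    PipelineResult,
    SweepResult,
    run_parameter_sweep,
    run_pipeline,
    run_window_robustness,
)
from .connectome import Connectome, generate_synthetic_connectome
from .moms import DEFAULT_BANDS, BandSpec
from .simulation import SignalSet, SimulationParams, integrate_network

__all__ = ["MetastableOscillationModel", "MOMEntropyResults"]

#: results class returned by :meth:`MetastableOscillationModel.fit`
MOMEntropyResults = PipelineResult


class MetastableOscillationModel:
    """Delay-coupled oscillator network with MOM/entropy analysis settings."""

    #: default (K, <tau>) grid explored by :meth:`sweep`
    DEFAULT_K_GRID = (0.1, 10.0, 50.0)
    DEFAULT_DELAY_GRID = (0.0, 0.003, 0.010)

    def __init__(
        self,
        connectome: Connectome,
        params: SimulationParams | None = None,
        *,
        bands: tuple[BandSpec, ...] = DEFAULT_BANDS,
        n_std: float = 5.0,
        min_coalition: int = 5,
        window_length: float = 0.2,
        overlap: float = 0.5,
        phase_method: str = "complex_phase",
        lowpass_hz: float = 30.0,
        threshold_formula: str = "mean_plus_sd",
    ):
        self.connectome = connectome
        self.params = params if params is not None else SimulationParams()
        self.bands = tuple(bands)
        self.n_std = n_std
        self.min_coalition = min_coalition
        self.window_length = window_length
        self.overlap = overlap
        self.phase_method = phase_method
        self.lowpass_hz = lowpass_hz
        self.threshold_formula = threshold_formula

    @classmethod
    def from_synthetic(
        cls,
        n_nodes: int = 90,
        density: float = 0.3,
        connectome_seed: int = 0,
        params: SimulationParams | None = None,
        **kwargs,
    ) -> "MetastableOscillationModel":
        """Model on a generated connectome with diffusion-MRI-like structure."""
        conn = generate_synthetic_connectome(
            n_nodes=n_nodes, density=density, seed=connectome_seed
        )
        return cls(conn, params=params, **kwargs)

    def _pipeline_kwargs(self) -> dict:
        return dict(
            bands=self.bands,
            n_std=self.n_std,
            min_coalition=self.min_coalition,
            window_length=self.window_length,
            overlap=self.overlap,
            phase_method=self.phase_method,
            lowpass_hz=self.lowpass_hz,
            threshold_formula=self.threshold_formula,
        )

    def _params_with_seed(self, seed: int | None) -> SimulationParams:
        return self.params if seed is None else replace(self.params, seed=seed)

    def simulate(self, seed: int | None = None) -> SignalSet:
        """Integrate the network once (no detection or entropy analysis)."""
        return integrate_network(self._params_with_seed(seed), self.connectome)

    def fit(self, seed: int | None = None, keep_signals: bool = False) -> MOMEntropyResults:
        """Run the full pipeline; returns results with r, p and summary()."""
        return run_pipeline(
            self._params_with_seed(seed),
            self.connectome,
            keep_signals=keep_signals,
            **self._pipeline_kwargs(),
        )

    def sweep(
        self,
        K_values=DEFAULT_K_GRID,
        delay_values=DEFAULT_DELAY_GRID,
        master_seed: int = 0,
        keep_results: bool = False,
    ) -> SweepResult:
        """Pipeline per (K, <tau>) cell, Bonferroni-corrected over cells."""
        return run_parameter_sweep(
            K_values,
            delay_values,
            self.params,
            self.connectome,
            master_seed=master_seed,
            keep_results=keep_results,
            **self._pipeline_kwargs(),
        )

    def window_robustness(
        self, window_lengths=(0.2, 0.3, 0.4, 0.5, 0.6), seed: int | None = None
    ):
        """Correlation stability across entropy window lengths (one cell)."""
        kwargs = self._pipeline_kwargs()
        kwargs.pop("window_length")
        kwargs.pop("overlap")
        return run_window_robustness(
            self._params_with_seed(seed),
            self.connectome,
            window_lengths=window_lengths,
            overlap=self.overlap,
            **kwargs,
        )
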