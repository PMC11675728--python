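# Methods

This note documents the model, the numerical and statistical choices, and
the known limitations of `momentropy`.  It is written for users who want
to understand *why* the pipeline is built the way it is, not just how to
call it.

## 1. Dynamical model

Each of N units carries a complex state Z_n obeying the Stuart–Landau
(Hopf normal form) equation with diffusive delayed coupling and additive
complex white noise:

    dZ_n/dt = Z_n (a + iω − |Z_n|²)
              + K Σ_{p≠n} C_np [Z_p(t − τ_np) − Z_n(t)]
              + β (η₁ + i η₂).

Assumptions: all units share the same natural frequency ω and bifurcation
parameter a; heterogeneity enters only through the coupling weights C_np
and delays τ_np; noise is uncorrelated across units and over time.

Key parameters (defaults in parentheses):

| parameter | units | default | role |
|---|---|---|---|
| ω/2π | Hz | 40 | natural (gamma) frequency of each unit |
| a | – | −5 | subcritical: damped 40 Hz response, stable origin |
| K | – | 10 | global coupling scale |
| ⟨τ⟩ | s | 0.003 | mean conduction delay over connected pairs |
| β | – | 10⁻³ | noise scale |
| dt | s | 10⁻⁴ | integration step (≈ 250 steps per 40 Hz cycle) |
| output interval | s | 0.002 | sampling period of stored signals (500 Hz) |
| duration / transient | s | 40 / 1 | analyzed length / discarded warm-up |

Delays are τ_np = D_np · ⟨τ⟩ / ⟨D⟩, where ⟨D⟩ is the mean distance over
*connected* pairs (zero-weight pairs carry no delay and are excluded from
the mean), so the realized mean delay over connected pairs equals ⟨τ⟩
exactly.

### Coupling normalization

The weight matrix is normalized before multiplication by K.  The default
divides by the mean over **all** off-diagonal entries (zeros included),
so the mean row sum of the normalized matrix is N − 1 and the per-node
coupling gain is K·(N − 1) independent of graph density.  The alternative
(`normalize="mean_nonzero"`, nonzero mean 1, gain ∝ density; and
`"none"`) is available in the configuration.

The choice matters only for sparse matrices and is fixed by the physics
of the delayed system.  The frequency of delay-locked collective modes
follows Ω ≈ ω − K·S·sin(Ω⟨τ⟩) (S = row gain): pulling 40 Hz units down to
alpha-band collective oscillations at K = 10, ⟨τ⟩ = 3 ms requires
K·S ≈ 900, which is exactly the mean-all convention at N = 90 (S = 89).
Simulations confirm a collective spectral peak at ≈ 11 Hz at that
operating point under mean-all, versus overdamped, featureless dynamics
(no coalition events at all) under mean-nonzero on a density-0.3 graph.
On near-dense empirical connectomes the two conventions coincide, which
is why the distinction is invisible there.

### Linear stability and what a "MOM" is here

With the diffusive coupling form, Gershgorin row dominance bounds every
characteristic root by a < 0: the delayed gain row sum can never exceed
the instantaneous leak K·S, so the origin is linearly stable for **all**
K and ⟨τ⟩, and no finite-amplitude limit cycle exists.  MOMs in this
model are therefore *noise-sustained, weakly damped slow collective
modes*: conduction delays create covariance modes at sub-gamma
frequencies whose damping approaches zero from below as K grows, and
noise excites them into intermittent, narrow-band amplitude excursions
far above what the same noise produces in the zero-delay network.
Detection is correspondingly *relative* — thresholds are calibrated
against the no-delay twin — so the absolute amplitude scale (set by β)
cancels throughout.

## 2. Numerical integration

The integrator is an integrating-factor (exponential) Euler–Maruyama
scheme:

    Z ← e^{(a+iω)dt} · [Z + dt·(coupling − |Z|² Z)] + σ·(η₁ + i η₂).

The stiff linear rotation/decay is propagated exactly; the cubic and
coupling terms are first-order explicit.  A fully explicit Euler step is
avoided deliberately: the rotation factor |1 + iω dt| exceeds 1 by
(ω dt)²/2 per step, which at dt = 10⁻⁴ and ω = 2π·40 shifts the effective
bifurcation parameter by ≈ +3.2 and visibly corrupts the amplitude decay
(measured radial error 0.167 against the closed form below; the
exponential scheme achieves 2.4·10⁻⁶).

* **Delays** are rounded to the nearest integer step and served from a
  ring buffer of length max-delay + 1.
* **History** for t ≤ 0 is the fixed point plus noise at the per-step
  scale (or exactly the user-supplied initial state for oracle runs).
  The first `transient` second is discarded; a warning is raised if the
  maximum delay exceeds the transient.
* **Noise**: σ = β·√dt by default (dt-invariant diffusion); the
  convention σ = β per step is available as `noise_mode="per_step"`.
  Because all detection is relative to a baseline driven by the same
  noise, this choice does not affect the pipeline's statistics.
* **Determinism**: one integer seed drives the JIT-compiled kernel's RNG;
  identical inputs give bit-identical outputs.
* **Divergence** (non-finite state) is detected at sampling times and
  raised with the failing step index.

The single-unit oracle is the closed-form radial solution of
dr/dt = r(a − r²):

    r(t)² = a r0² e^{2at} / (a + r0² (e^{2at} − 1)),   a < 0,

against which the integrator is tested to < 10⁻³ (max-abs over 1 s), with
the phase slope checked against ω to 10⁻³ relative.

## 3. MOM detection

* **Band filtering** by FFT bin zeroing (delta 0.5–4, theta 4–8, alpha
  8–13, beta 13–30 Hz; DC removed), applied to the full record to avoid
  per-window edge artifacts; the first and last 100 ms are flagged as
  edge-affected in the coalition series.
* **Envelopes**: magnitude of the analytic (Hilbert) signal.
* **Baseline**: a twin simulation with ⟨τ⟩ = 0 and otherwise identical
  parameters — by default the *same seed* (paired noise), overridable.
  Mean and SD are computed per node and band over time (per-node, not
  pooled: each node's threshold reflects its own connectivity).
* **Threshold**: mean + 5·SD by default; the variant 5·SD alone is
  selectable (`threshold_formula="sd_only"`) since both readings appear
  in the literature on this detection rule.
* **Coalition series are raw counts.** The minimum coalition size
  (default 5) classifies *events* only; the continuous series correlated
  with entropy is never masked.  This is required for the weak-coupling
  regimes, where window-averaged coalition sizes hover between 0 and 1 —
  values only possible without masking.

## 4. Eigenvalue-spectrum entropy

* **Phases** are extracted once globally from the signals low-pass
  filtered below `f_cut` (default 30 Hz, where the delay-induced
  collective modes live), not per window.
* **"Covariance of phase angles"** is computed on the unit-modulus phase
  factors e^{iθ}: their Hermitian covariance (within-window mean
  subtracted) is positive semi-definite, rotation-invariant and immune to
  angle wrapping, unlike a covariance of raw angles.  A real covariance
  of cos θ is available (`method="cosine_phase"`).
* **Windows** are left-aligned, wholly inside the record, starting every
  window·(1 − overlap) samples; a partial trailing window is dropped.
  40 s at 500 Hz with 200 ms windows and 50% overlap gives exactly
  (20000 − 100)/50 + 1 = 399 windows.
* **Spectrum → distribution → entropy**: eigenvalues (numerical negatives
  clipped to 0) are sorted descending and normalized to sum to 1;
  H = −Σ p ln p in natural log (nats), with 0·ln 0 ≡ 0, so
  0 ≤ H ≤ ln N.
* **Choice of f_cut per question.** For the zero-delay order/disorder
  contrast (small all-to-all network, K = 0 vs K = 50), synchrony lives
  at the 40 Hz carrier itself; the cut must sit *above* ω (45 Hz is used
  in the tests) or the filter discards the very rhythm whose rank-1
  dominance is being measured.  The entropy drop under strong coupling is
  visible under either cut; the dominance of the leading eigenvalue is
  carrier-specific (measured: 85% of windows above 0.8 at 45 Hz vs 0% at
  30 Hz).

## 5. Coalition–entropy analysis

* The total (band-summed) coalition series is averaged over exactly the
  entropy windows; both series share window metadata by construction.
* **Pearson p-values** use the t approximation with W − 2 df, which
  treats overlapping windows as independent and is therefore
  anti-conservative; a circular-shift permutation p (1000 shifts,
  seeded) is provided for honest inference.
* **Bonferroni family** = the grid cells (m = 9 for the default 3×3
  sweep).  Zero-variance series yield NA cells with a reason string,
  never r = 0.
* **Per-cell seeds** derive deterministically from the master seed and
  cell index via `numpy.random.SeedSequence`, so sweeps are reproducible
  cell by cell.

## 6. Synthetic connectome

The generator emulates the statistics of diffusion-MRI connectomes:
node positions uniform in a 140×170×120 mm box (distances are Euclidean,
hence metric and with the right-skewed unimodal delay histogram
characteristic of fiber-length data); a fraction `density` (default
0.30, in the range of thresholded 90-region structural matrices) of
pairs connected; nonzero weights log-normal with σ = 1.5 (streamline
counts span several decades).

What it does **not** emulate: hemispheric symmetry and strong homotopic
connections, community/modular structure, the empirical anticorrelation
between weight and distance, and spatially clustered hubs.  Consequences:
collective modes are less differentiated than on a real connectome, MOM
coalitions are smaller (tens of nodes rather than the ~200 band-summed
units reachable empirically), and regime boundaries in the (K, ⟨τ⟩)
plane shift somewhat.  Passing tests therefore demonstrate the
*mechanism* (delay-induced slow collective modes whose formation lowers
the eigenvalue-spectrum entropy) and the *sign and magnitude class* of
the correlation, not cell-exact reproduction of any particular empirical
connectome.

## 7. Problem sizes used by the test suite and acceptance script

Unit tests run seconds-long simulations on 2–30 node graphs.  The
end-to-end checks use: one 40 s run at the optimal point (K = 10,
⟨τ⟩ = 3 ms, N = 90); five independent 20 s runs for sign stability; a
20 s no-delay null; 20 s order/disorder runs at N = 10; and a 3×3 sweep
at 10 s per cell.  These lengths were chosen so the full suite completes
in a few minutes on one core while keeping ≥ 199 analysis windows per
run; the 40 s headline run matches the published record length exactly.

## 8. Known limitations

* The (K = 50, ⟨τ⟩ = 10 ms) corner of the default grid pulls the
  collective mode below ~1 Hz on the synthetic connectome.  A 200 ms
  window then covers a small fraction of the mode's period: within-window
  phase spread is *smallest* precisely when the slow mode is coherent,
  so windowed entropy rises during MOMs and the coalition–entropy
  correlation can invert.  This is a window/timescale mismatch of the
  method at that operating point, not an integration artifact; longer
  windows (the 200–600 ms robustness range) mitigate it.
* First-order (weak order 1.0) treatment of the nonlinear and coupling
  terms; no adaptive stepping; delays rounded to dt.
* MOMs here are noise-sustained linear excursions (see §1); regimes
  requiring genuinely multistable large-amplitude attractors are outside
  this model class with a < 0 and diffusive coupling.
* The t-based p-values in the sweep table are anti-conservative under
  window overlap; use the permutation p for inference.
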