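# Methods

## The observable

Terminal orientational relaxation of a polymer molecule is measured through
the time autocorrelation function (TACF) of a unit vector **u** directed
along the molecule's longest dimension:

    C(t) = ⟨ u(t₀ + t) · u(t₀) ⟩

averaged over all admissible time origins t₀ (equilibrium dynamics depend on
time differences only) and over all tracer vectors of a molecule. For a
linear chain the tracer is the end-to-end vector; for a ring of N beads it
is the family of diameter vectors — bead pairs N/2 − 1 bonds apart along the
contour. All N cyclic offsets, pair (i, (i + N/2 − 1) mod N) for
i = 0..N−1, are enumerated as directed tracers. The enumeration convention
(N vectors rather than N/2 − 1 or N/2) is a documented choice: each tracer
correlates only with itself over time, so the near-duplication of
antipodal directions cannot bias the average, and using every offset
maximizes statistics. Odd N is rejected rather than rounded, since rounding
would silently change the observable. Rings require even N ≥ 4; vectors of
(numerically) zero length raise rather than normalize.

Units are fixed package-wide: nm for length, ns for time, kBT for energy.
Coordinates must be unwrapped; there is no periodic-image handling anywhere.

## TACF estimation

`molecule_tacf` computes the direct multi-origin sum — no FFT — so the
per-lag sample count (origins × tracers) is exact and carried with the
curve. The lag grid is the native frame grid; defaults are
`origin_stride = 1` (every origin) and `max_lag_fraction = 0.5` (longer lags
average too few origins to be useful). Two equivalent direct-sum code paths
exist (a sliced lag loop and a `numpy.correlate` path, O(n_lags·T) vs
O(T²)); the cheaper one is chosen and they are tested for equality.
`C(0) = 1` is structural (unit tracers), not imposed by division.

## Decay laws

**Stretched exponential (KWW).** C(t) = exp[−(t/τ_KWW)^β]. Its time
integral has the closed form τ₀ = τ_KWW · Γ(1/β)/β, which every returned
fit satisfies to machine precision by construction. β = 1 is the
homogeneous (single-exponential) limit; β < 1 signals a distribution of
underlying relaxation times, i.e. dynamic heterogeneity — the narrower β,
the broader the spectrum.

**Constrained multi-exponential.** C(t) = Σᵢ Aᵢ exp(−t/τᵢ) with Aᵢ ≥ 0 and
Σ Aᵢ = 1 (the unit-sum constraint is built into the parameterization:
n_m − 1 free amplitudes, the last a remainder, negative remainders
penalized). Modes are returned τ-ascending. `select_num_modes` fits
n_m = 1, 2, … and keeps the smallest count for which one more exponential
improves the RMS residual by less than 10 % relative (configurable), or the
residual is already at the noiseless floor (1e-8); ties resolve to fewer
modes. The threshold makes the qualitative notion "smallest number of modes
needed" reproducible.

**Fit window and weighting.** Both fits run on the window from t = 0 to the
curve's first negative crossing, log-thinned to at most 200 points uniform
in log-lag (t = 0 always kept) so that every decade contributes comparable
weight; equal weights by default, count-proportional optionally. Multistart
(5 log-spaced τ guesses × β ∈ {0.4, 0.7, 1.0} for KWW; log-spaced τ ladders
at three spans, jittered by a fixed seed 20200330, for the
multi-exponential) guards against local minima; non-convergence returns a
flagged best-effort fit, never an exception. Bounds: β ∈ (0.05, 1],
τ ∈ (10⁻³·dt, 10⁴·window).

**Model-free terminal time.** Per molecule, τ₀ is also measured directly as
the trapezoidal integral of C(t) from 0 to its first negative crossing
(t_max); curves that never cross zero inside the window are integrated in
full and flagged `truncated` — they are *kept* in population statistics,
because dropping them would bias exactly the slow tail the analysis is
about. Truncation-first (integrate/fit only up to t_max) is the default
ordering.

## Heterogeneity statistics

Per-molecule terminal times are normalized by the mean terminal time of a
designated reference system (e.g. the pure ring melt) and summarized as a
probability histogram (default bin width 0.1 in normalized time, range
auto-extended), the sample median (midpoint convention), and slow-tail
fractions: the share of molecules with normalized time *strictly* above a
threshold (default thresholds 1 and 2). Whether the reference is the
ensemble-KWW τ₀ or the mean of per-molecule integrals is configurable; the
pipeline defaults to the ensemble-KWW value, while the blend-series
analysis scripts use the mean of per-molecule integrals, which is the
quantity the normalization is meant to remove.

## Synthetic data and what it does (not) show

All tests run on generators with analytically known ground truth; no
atomistic trajectories are shipped or required.

**Rotational diffusion.** Each tracer performs an isotropic random walk on
the sphere: per frame it rotates by a Gaussian angle θ ~ N(0, 4·D_r·dt)
about a uniformly random tangent direction. Because the walk is isotropic,
its l = 1 correlation is exactly Π E[cos θ] = exp(−2·D_r·t) *at any step
size* — spherical harmonics diagonalize isotropic walks — while the
small-step limit is the familiar tangent-plane Gaussian step of variance
2·D_r·dt per component. (A renormalized tangent-step walk, by contrast,
carries an O(D·dt) rate bias that is material at coarse sampling.) A guard
rejects dt·D_r > 0.05 as a physicality bound on per-step angles.

**Bead-spring chains and rings.** Overdamped (free-draining) Langevin
dynamics of harmonic springs, Euler–Maruyama with stability bound
dt < ζ/(4k) enforced, warm-up of 10× the slowest mode time discarded.
There are no excluded-volume or hydrodynamic interactions — deliberately:
the model's normal modes are exact, giving closed-form ground truth. For a
ring, mode p relaxes with τ_p = ζ/(4k sin²(pπ/N)), and the diameter-vector
correlation is the mode sum ρ(t) = Σ c_p e^(−t/τ_p)/Σ c_p with
c_p = sin²(πph/N)/(N sin²(πp/N)), h = N/2 − 1 (validated against a
brute-force matrix-exponential covariance computation on an N = 6 ring).
Because the analysis normalizes vectors to unit length, the measured TACF
is not ρ itself but the exact unit-vector map for isotropic jointly
Gaussian 3-vectors,

    ⟨u(t)·u(0)⟩ = (8/3π) ρ ₂F₁(½, ½; 5⁄2; ρ²),

which equals ρ at 0 and 1 and deviates by up to ~0.08 in between — the
simulation test resolves this difference and confirms the map.

**Mixtures.** Molecules draw a population (weight, decay law, τ) by a
seeded draw; exponential populations diffuse with D_r = 1/(2τ). KWW
populations use the exact mixture representation of the stretched
exponential: each tracer draws a static rate R = S/τ with S one-sided
stable of index β (Kanter's sampler; Laplace transform E[e^(−uS)] =
e^(−u^β) verified directly), so the ensemble TACF is exp[−(t/τ)^β] as a
*stationary* process. A deterministically time-dilated diffusion clock was
rejected: it is non-stationary, and under multi-origin averaging its
measured TACF ages far away from the stretched exponential. Each molecule
can carry several independent tracers (`n_tracers`) — the counterpart of a
ring's diameter family — which per-molecule integral estimates need to
converge at desk scale.

What the generators do **not** emulate: chain connectivity between tracers
of one molecule (mixture tracers are independent), excluded volume,
entanglement or actual threading geometry, and chemistry-specific detail.
Passing tests therefore demonstrate that the estimators and fitters recover
known relaxation structure from trajectory-like data of realistic length
and noise — not that any particular chemistry is reproduced.

## Study conditions used by tests and analysis scripts

Chosen once, a priori, so that estimator noise is small against the designed
population separations:

- rotational-diffusion calibration: 400 tracers, D_r = 0.1 ns⁻¹, dt = 0.01 ns,
  3000 frames;
- ring oracle: 8 independent N = 8 rings, k = 10 kBT/nm², ζ = 40 kBT·ns/nm²,
  dt = 0.05 ns, 2000 ns observed at 0.5 ns resolution;
- mixture recovery: 200 molecules × 8 tracers, 80 %/20 % at τ = 1/2.5 ns,
  dt = 0.1 ns, 600 ns, 30 ns TACF window, reference time 1.25 ns (designed
  slow population at 2× the reference, designed median 0.8);
- blend-emulation sweep (analysis/): threaded weights 5/12/18/20 % at a
  5× slowdown, 200 molecules × 8 tracers per composition. The 5× factor
  keeps the free-population peak well below the τ₀/τ_ref = 1 threshold, so
  tail fractions report the designed threaded weight rather than estimator
  noise.

## Numerical notes and limitations

- The first-negative-crossing truncation interacts with noise: per-molecule
  curves with too few tracers/origins truncate near their noise floor with
  a positive bias; the per-molecule machinery should be given tracer
  families or long observations (the mixture defaults above do).
- Printed-precision inputs propagate: a β quoted to ±0.01 moves the
  closed-form τ₀ by up to ~4 % at β ≈ 0.5.
- Multistart is deterministic given the config seed; reports contain no
  timestamps, so a pipeline rerun with the same config and seed is
  byte-identical.
- No bootstrap error bars; residual-based diagnostics only. No Laplace
  inversion/continuous relaxation spectra; the multi-exponential mode count
  is capped (default 6).
- XYZ I/O is plain multi-frame XYZ at fixed decimal precision; the native
  archive (npz, schema-versioned) is lossless.
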