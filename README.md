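# ringhet

Dynamic heterogeneity of orientational relaxation in ring/linear polymer
blends: per-molecule time autocorrelation functions (TACFs), stretched-
exponential and multi-exponential decay fits, and relaxation-time
population statistics — with synthetic trajectory generators whose ground
truth is known analytically.

## The problem

In a melt, a ring polymer loses memory of its orientation as its diameter
vectors **R**_d (bead pairs half a contour apart) decorrelate; a linear
chain does so through its end-to-end vector **R**_ee. Blending rings with
linear chains lets linear chains *thread* rings. Threaded — especially
multiply-threaded — rings relax far slower than free ones, so one number
("the" relaxation time) hides the physics: the population splits into
fast and slow subpopulations. This package quantifies that splitting.

For each molecule the TACF C(t) = ⟨u(t)·u(0)⟩ is computed over all time
origins and tracer vectors. Ensemble curves are fitted with

- the KWW stretched exponential C(t) = exp[−(t/τ_KWW)^β], whose integral
  is τ₀ = τ_KWW·Γ(1/β)/β — β < 1 measures the breadth of the underlying
  relaxation spectrum;
- a constrained sum of exponentials C(t) = Σ Aᵢ exp(−t/τᵢ), Aᵢ ≥ 0,
  Σ Aᵢ = 1, with the smallest adequate mode count selected automatically —
  separating fast loop dynamics, loop migration, whole-molecule diffusion
  and (in blends) threading release.

Per molecule, τ₀ is also measured model-free as the integral of C(t) up to
its first negative crossing; the ensemble of per-molecule times, normalized
by the reference melt time, yields histograms, medians and slow-tail
fractions — the quantitative face of dynamic heterogeneity.

Who it is for: simulators analyzing coarse-grained or atomistic polymer
trajectories who need per-molecule relaxation statistics with honest
sampling diagnostics, and method developers who need generators with exact
ground truth to validate fitting pipelines.

## Worked example

```python
import numpy as np
import ringhet as rh

# 200 molecules, 80% free (tau = 1 ns) / 20% threaded-like (tau = 2.5 ns),
# 8 tracer vectors per molecule, 600 ns at 0.1 ns resolution
spec = rh.MixtureSpec(
    populations=(rh.MixturePopulation(0.8, "exponential", 1.0),
                 rh.MixturePopulation(0.2, "exponential", 2.5)),
    n_molecules=200, dt=0.1, n_frames=6000, seed=42, n_tracers=8)
series, truth = rh.generate_mixture_ensemble(spec)

curves = [rh.molecule_tacf(s, max_lag_fraction=0.05) for s in series]
kww = rh.fit_kww(rh.ensemble_tacf(curves))
print(f"beta = {kww.beta:.3f}, tau0 = {kww.tau0:.3f} ns")

ens = rh.build_ensemble([rh.tau0_numeric(c) for c in curves],
                        reference_time=1.25)
print(f"median tau0/tau_ref = {rh.ensemble_median(ens):.3f}, "
      f"slow tail (>1) = {rh.tail_fraction(ens, 1.0):.3f}")
```

prints

```
beta = 0.924, tau0 = 1.225 ns
median tau0/tau_ref = 0.809, slow tail (>1) = 0.175
```

β ≈ 0.92 < 1 flags the hidden two-population structure of the ensemble
curve; the median sits at the designed fast-population time (0.8 × the
reference) and the slow-tail fraction recovers the designed 20 % threaded
weight (the seeded draw realized 17.5 %).

## Analysis scripts

`analysis/01_simulate_blend_series.py` … `04_figures.py` run a four-
composition blend emulation (threaded weight growing 5 → 20 %), fit the
decay laws, and tabulate heterogeneity statistics under
`results/blend_series/`. Each script prints what it found; run them in
order.

## Command line

`ringhet run <config.toml>` executes simulate → tacf → fit → heterogeneity
from one TOML config and writes CSV artifacts plus a deterministic
`report.json` (same config + seed ⇒ byte-identical report). Subcommands:
`simulate`, `tacf`, `fit-kww`, `fit-multiexp`, `heterogeneity`, `run`,
`validate`. Exit codes: 0 ok, 2 config error, 3 stage failure.
Trajectories must contain **unwrapped** coordinates; no periodic-image
reconstruction is performed.

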