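"""Synthetic trajectory and orientation-series generators with known truth.

Three generators feed the analysis stages:

* **Rotational diffusion** — ensembles of unit vectors performing isotropic
  diffusion on the sphere with coefficient ``D_r``; the exact l = 1
  orientational TACF is ``C(t) = exp(-2 D_r t)``.
* **Bead-spring (Rouse) chains and rings** — overdamped Langevin dynamics of
  harmonic springs (free-draining: no hydrodynamics, no excluded volume).
  The normal-mode decomposition is exact, so the diameter/end-to-end vector
  correlation is an analytically known sum of exponentials — the ground
  truth the multi-exponential fitter is tested against.
* **Relaxation-time mixtures** — molecule populations with prescribed
  exponential or stretched-exponential (KWW) TACFs, emulating the
  phenomenology of ring/linear blends where unthreaded rings relax like the
  pure melt while multiply-threaded rings relax far slower.

Energies are measured in kBT (so spring constants are kBT/nm^2 and
frictions kBT*ns/nm^2), lengths in nm, times in ns. All generators are
bit-reproducible from their integer seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import hyp2f1

from .orientation import OrientationSeries
from .trajectory_io import MoleculeRecord, SystemSpec, Trajectory

__all__ = [
    "RotDiffSpec",
    "RouseChainSpec",
    "MixturePopulation",
    "MixtureSpec",
    "generate_rotational_diffusion",
    "generate_rouse_chain",
    "generate_mixture_ensemble",
    "ring_relaxation_times",
    "ring_diameter_mode_weights",
    "ring_diameter_normalized_correlation",
    "gaussian_unit_vector_tacf",
    "analytic_ring_diameter_tacf",
]

#: discretization-bias bound for the spherical random walk: per-step angular
#: variance 2*D_r*dt must stay below this
MAX_STEP_VARIANCE = 0.1


# ---------------------------------------------------------------------------
# specs


@dataclass(frozen=True)
class RotDiffSpec:
    """Ensemble of independently diffusing unit vectors.

    D_r is the rotational diffusion coefficient in 1/ns, either one value
    for all molecules or one per molecule.
    """

    n_molecules: int
    D_r: float | tuple[float, ...]
    dt: float
    n_frames: int
    seed: int

    def __post_init__(self) -> None:
        if self.n_molecules < 1:
            raise ValueError("n_molecules must be >= 1")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.dt <= 0:
            raise ValueError("dt must be > 0 ns")
        d = self.d_per_molecule
        if d.size != self.n_molecules:
            raise ValueError("per-molecule D_r list length must equal n_molecules")
        if np.any(d <= 0):
            raise ValueError("D_r must be > 0 (all entries)")
        if np.any(self.dt * d > MAX_STEP_VARIANCE / 2):
            raise ValueError(
                f"dt * D_r = {float((self.dt * d).max()):.3g} exceeds the discretization "
                f"bound {MAX_STEP_VARIANCE / 2}; reduce dt"
            )

    @property
    def d_per_molecule(self) -> np.ndarray:
        if np.isscalar(self.D_r):
            return np.full(self.n_molecules, float(self.D_r))
        return np.asarray(self.D_r, dtype=float)


@dataclass(frozen=True)
class RouseChainSpec:
    """Free-draining bead-spring chain or ring under overdamped Langevin dynamics.

    k is the harmonic spring constant (kBT/nm^2), zeta the bead friction
    (kBT*ns/nm^2). ``n_steps`` integration steps follow a warm-up of
    ``warmup_mode_times`` multiples of the slowest normal-mode time; every
    ``save_stride``-th step is stored. ``n_molecules`` independent replicas
    are simulated in one trajectory for statistics.
    """

    topology: str  # "ring" | "linear"
    n_beads: int
    k: float
    zeta: float
    dt: float
    n_steps: int
    save_stride: int
    seed: int
    n_molecules: int = 1
    warmup_mode_times: float = 10.0

    def __post_init__(self) -> None:
        if self.topology not in ("ring", "linear"):
            raise ValueError(f"topology must be 'ring' or 'linear', got {self.topology!r}")
        min_beads = 3 if self.topology == "ring" else 2
        if self.n_beads < min_beads:
            raise ValueError(f"{self.topology} needs >= {min_beads} beads")
        if self.k <= 0 or self.zeta <= 0:
            raise ValueError("k and zeta must be > 0")
        bound = self.zeta / (4.0 * self.k)
        if not self.dt < bound:
            raise ValueError(
                f"unstable time step: dt = {self.dt} violates dt < zeta/(4k) = {bound:.6g} ns"
            )
        if self.n_steps < self.save_stride:
            raise ValueError("n_steps must cover at least one save_stride")
        if self.save_stride < 1 or self.n_molecules < 1:
            raise ValueError("save_stride and n_molecules must be >= 1")

    @property
    def slowest_mode_time(self) -> float:
        """zeta / (4 k sin^2(pi p* / N')) for the slowest internal mode."""
        if self.topology == "ring":
            s = math.sin(math.pi / self.n_beads)
        else:
            s = math.sin(math.pi / (2 * self.n_beads))
        return self.zeta / (4.0 * self.k * s * s)


@dataclass(frozen=True)
class MixturePopulation:
    """One mixture component: weight plus its prescribed TACF shape."""

    weight: float
    decay_kind: str  # "exponential" | "kww"
    tau: float  # ns; for "kww" this is tau_KWW
    beta: float = 1.0

    def __post_init__(self) -> None:
        if self.weight <= 0:
            raise ValueError("population weight must be > 0")
        if self.decay_kind not in ("exponential", "kww"):
            raise ValueError(f"decay_kind must be 'exponential' or 'kww', got {self.decay_kind!r}")
        if self.tau <= 0:
            raise ValueError("tau must be > 0 ns")
        if not 0.0 < self.beta <= 1.0:
            raise ValueError("beta must lie in (0, 1]")


@dataclass(frozen=True)
class MixtureSpec:
    """Finite mixture of relaxation populations (threaded/unthreaded emulation).

    ``n_tracers`` independent unit vectors are generated per molecule, all
    relaxing with the molecule's population parameters — the counterpart of
    a ring's diameter-vector family, whose members the per-molecule TACF
    averages over.
    """

    populations: tuple[MixturePopulation, ...]
    n_molecules: int
    dt: float
    n_frames: int
    seed: int
    n_tracers: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "populations", tuple(self.populations))
        if not self.populations:
            raise ValueError("at least one population required")
        total = sum(p.weight for p in self.populations)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"population weights must sum to 1, got {total}")
        if self.n_molecules < 1 or self.n_frames < 2 or self.dt <= 0:
            raise ValueError("invalid n_molecules / n_frames / dt")
        if self.n_tracers < 1:
            raise ValueError("n_tracers must be >= 1")


# ---------------------------------------------------------------------------
# spherical random walk core


def _diffuse_unit_vectors(rng: np.random.Generator, n_mol: int, step_var: np.ndarray) -> np.ndarray:
    """Isotropic diffusion of unit vectors on the sphere.

    step_var[j] = 2 D dt is the tangent-plane angular variance per component
    for the step from frame j to j+1 (1-D: shared by all walkers; 2-D
    (n_steps, n_mol): per walker). Each step rotates u by a Gaussian
    angle theta ~ N(0, 2 * step_var) about a uniformly random tangent
    direction. Because the walk is isotropic, the l = 1 correlation after
    any number of steps is exactly prod_j E[cos theta_j] =
    exp(-sum_j step_var_j) — i.e. exp(-2 D t) with no time-step bias; in
    the small-step limit this is the familiar tangent-plane Gaussian step
    of variance 2 D dt per component, renormalized. Returns
    (n_frames, n_mol, 3) unit vectors with isotropic initial orientations.
    """
    step_var = np.asarray(step_var, dtype=float)
    if step_var.ndim == 1:  # shared schedule -> broadcast per walker
        step_var = step_var[:, None] * np.ones((1, n_mol))
    n_frames = step_var.shape[0] + 1
    u = rng.normal(size=(n_mol, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    out = np.empty((n_frames, n_mol, 3))
    out[0] = u
    angle_sd = np.sqrt(2.0 * step_var)
    for j in range(n_frames - 1):
        sd = angle_sd[j]
        theta = rng.normal(size=n_mol) * sd
        g = rng.normal(size=(n_mol, 3))
        g -= np.einsum("ij,ij->i", g, u)[:, None] * u  # tangent-plane direction
        g /= np.maximum(np.linalg.norm(g, axis=1, keepdims=True), 1e-300)
        u = np.cos(theta)[:, None] * u + np.sin(theta)[:, None] * g
        u /= np.linalg.norm(u, axis=1, keepdims=True)  # float drift only
        out[j + 1] = u
    return out


def generate_rotational_diffusion(spec: RotDiffSpec) -> list[OrientationSeries]:
    """Unit-vector ensembles whose exact TACF is exp(-2 D_r t).

    Each molecule's vector performs an isotropic spherical random walk:
    a Gaussian tangent-plane step of per-component variance 2 D_r dt,
    renormalized to the sphere, per frame.
    """
    rng = np.random.default_rng(spec.seed)
    d = spec.d_per_molecule
    series: list[OrientationSeries] = []
    width = len(str(spec.n_molecules - 1))
    # group molecules sharing one D_r to vectorize; preserve per-molecule ids
    for value in dict.fromkeys(d.tolist()):
        idx = np.nonzero(d == value)[0]
        step_var = np.full(spec.n_frames - 1, 2.0 * value * spec.dt)
        vecs = _diffuse_unit_vectors(rng, idx.size, step_var)
        for col, mol in enumerate(idx):
            series.append(
                OrientationSeries(
                    molecule_id=f"rd{mol:0{width}d}",
                    vectors=vecs[:, col : col + 1, :],
                    vector_kind="end_to_end",
                    dt_frame=spec.dt,
                )
            )
    series.sort(key=lambda s: s.molecule_id)
    return series


# ---------------------------------------------------------------------------
# bead-spring Brownian dynamics


def _spring_force(coords: np.ndarray, k: float, topology: str) -> np.ndarray:
    """-k * L r for the chain/ring connectivity Laplacian L; coords (..., N, 3)."""
    if topology == "ring":
        return k * (np.roll(coords, -1, axis=-2) + np.roll(coords, 1, axis=-2) - 2.0 * coords)
    f = np.zeros_like(coords)
    f[..., :-1, :] += k * (coords[..., 1:, :] - coords[..., :-1, :])
    f[..., 1:, :] += k * (coords[..., :-1, :] - coords[..., 1:, :])
    return f


def generate_rouse_chain(spec: RouseChainSpec) -> Trajectory:
    """Euler-Maruyama integration of the free-draining bead-spring model.

    dr = (F/zeta) dt + sqrt(2 dt / zeta) xi, F = -k L r. A warm-up of
    ``warmup_mode_times`` x the slowest mode time is integrated and
    discarded before frames are stored.
    """
    rng = np.random.default_rng(spec.seed)
    n_mol, N = spec.n_molecules, spec.n_beads
    coords = rng.normal(scale=1.0 / math.sqrt(spec.k), size=(n_mol, N, 3))
    coords -= coords.mean(axis=1, keepdims=True)
    dt_over_zeta = spec.dt / spec.zeta
    noise_scale = math.sqrt(2.0 * spec.dt / spec.zeta)
    n_warmup = int(math.ceil(spec.warmup_mode_times * spec.slowest_mode_time / spec.dt))

    def step(r: np.ndarray) -> np.ndarray:
        return (
            r
            + dt_over_zeta * _spring_force(r, spec.k, spec.topology)
            + noise_scale * rng.normal(size=r.shape)
        )

    for _ in range(n_warmup):
        coords = step(coords)
    n_frames = spec.n_steps // spec.save_stride + 1
    frames = np.empty((n_frames, n_mol, N, 3))
    frames[0] = coords
    for i in range(1, n_frames):
        for _ in range(spec.save_stride):
            coords = step(coords)
        frames[i] = coords
    width = len(str(n_mol - 1))
    system = SystemSpec(
        molecules=tuple(
            MoleculeRecord(f"{spec.topology}{m:0{width}d}", spec.topology, N) for m in range(n_mol)
        ),
        dt_frame=spec.dt * spec.save_stride,
        label=f"bead-spring {spec.topology} N={N} k={spec.k} zeta={spec.zeta} seed={spec.seed}",
    )
    return Trajectory(frames.reshape(n_frames, n_mol * N, 3), system)


# ---------------------------------------------------------------------------
# analytic normal-mode oracle for the harmonic ring


def ring_relaxation_times(n_beads: int, k: float, zeta: float) -> np.ndarray:
    """Normal-mode relaxation times tau_p = zeta / (4 k sin^2(p pi / N)), p = 1..N-1."""
    p = np.arange(1, n_beads)
    return zeta / (4.0 * k * np.sin(np.pi * p / n_beads) ** 2)


def ring_diameter_mode_weights(n_beads: int) -> np.ndarray:
    """Relative weight of mode p in the diameter-vector correlation.

    For d = r_{i+h} - r_i with h = N/2 - 1 bonds, the equilibrium modal
    decomposition of the harmonic ring gives
    c_p = sin^2(pi p h / N) / (N sin^2(pi p / N)), p = 1..N-1 (any offset i;
    the family average equals each member by ring symmetry).
    """
    if n_beads % 2 != 0:
        raise ValueError("diameter vectors require even N")
    h = n_beads // 2 - 1
    p = np.arange(1, n_beads)
    return np.sin(np.pi * p * h / n_beads) ** 2 / (n_beads * np.sin(np.pi * p / n_beads) ** 2)


def ring_diameter_normalized_correlation(
    t: np.ndarray, n_beads: int, k: float, zeta: float
) -> np.ndarray:
    """rho(t) = <d(t).d(0)> / <|d|^2> for the harmonic ring: an exact mode sum."""
    taus = ring_relaxation_times(n_beads, k, zeta)
    c = ring_diameter_mode_weights(n_beads)
    t = np.asarray(t, dtype=float)
    return (np.exp(-t[:, None] / taus[None, :]) @ c) / c.sum()


def gaussian_unit_vector_tacf(rho: np.ndarray) -> np.ndarray:
    """<u(t).u(0)> of an isotropic 3-D Gaussian vector with correlation rho.

    For jointly Gaussian d(0), d(t) with per-component correlation rho, the
    unit-vector correlation has the closed form
    (8 / (3 pi)) * rho * 2F1(1/2, 1/2; 5/2; rho^2); it equals rho at both
    rho = 0 and rho = 1 and deviates by at most a few percent in between.
    """
    rho = np.asarray(rho, dtype=float)
    return (8.0 / (3.0 * np.pi)) * rho * hyp2f1(0.5, 0.5, 2.5, rho**2)


def analytic_ring_diameter_tacf(t: np.ndarray, n_beads: int, k: float, zeta: float) -> np.ndarray:
    """Exact unit diameter-vector TACF of the harmonic ring (oracle curve)."""
    return gaussian_unit_vector_tacf(ring_diameter_normalized_correlation(t, n_beads, k, zeta))


# ---------------------------------------------------------------------------
# mixtures


def _sample_positive_stable(rng: np.random.Generator, alpha: float, size: int) -> np.ndarray:
    """One-sided stable variates S with Laplace transform E[e^(-u S)] = e^(-u^alpha).

    Kanter's construction: V ~ U(0, pi), W ~ Exp(1),
    S = [sin(alpha V) / (sin V)^(1/alpha)] * [sin((1-alpha) V) / W]^((1-alpha)/alpha).
    alpha = 1 degenerates to S = 1.
    """
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must lie in (0, 1]")
    if alpha == 1.0:
        return np.ones(size)
    v = rng.uniform(0.0, np.pi, size)
    w = rng.exponential(1.0, size)
    return (
        np.sin(alpha * v) / np.sin(v) ** (1.0 / alpha)
        * (np.sin((1.0 - alpha) * v) / w) ** ((1.0 - alpha) / alpha)
    )


def generate_mixture_ensemble(spec: MixtureSpec) -> tuple[list[OrientationSeries], list[dict]]:
    """Orientation ensembles from a designed mixture of relaxation populations.

    Each molecule is assigned a population by a seeded draw. Exponential
    populations diffuse with D_r = 1 / (2 tau). KWW populations exploit the
    exact mixture representation of the stretched exponential: every tracer
    draws a static rate R = S / tau with S one-sided stable of index beta,
    so that E[exp(-R t)] = exp[-(t/tau)^beta] holds as a *stationary*
    process — correct under multi-time-origin averaging, which a
    deterministically time-dilated clock is not. (A surrogate for
    heterogeneous relaxation, not a physical model.)

    Returns the series list and a per-molecule ground-truth record
    (population index, decay kind, tau, beta, and the exact tau0).
    """
    from .decay_fitting import tau0_from_kww  # local import avoids a cycle

    rng = np.random.default_rng(spec.seed)
    weights = np.array([p.weight for p in spec.populations])
    assignment = rng.choice(len(spec.populations), size=spec.n_molecules, p=weights)
    width = len(str(spec.n_molecules - 1))
    series: list[OrientationSeries] = [None] * spec.n_molecules  # type: ignore[list-item]
    truth: list[dict] = [None] * spec.n_molecules  # type: ignore[list-item]
    m = spec.n_tracers
    for pop_idx, pop in enumerate(spec.populations):
        members = np.nonzero(assignment == pop_idx)[0]
        if members.size == 0:
            continue
        n_walkers = members.size * m
        if pop.decay_kind == "exponential":
            d_r = 1.0 / (2.0 * pop.tau)
            if spec.dt * d_r > MAX_STEP_VARIANCE / 2:
                raise ValueError(
                    f"population tau = {pop.tau} ns too fast for dt = {spec.dt} ns "
                    f"(dt/(2 tau) exceeds {MAX_STEP_VARIANCE / 2})"
                )
            step_var = np.full((spec.n_frames - 1, n_walkers), 2.0 * d_r * spec.dt)
        else:
            # per-tracer static rate from the stable mixture behind the KWW law
            s = _sample_positive_stable(rng, pop.beta, n_walkers)
            step_var = np.broadcast_to(
                (s / pop.tau) * spec.dt, (spec.n_frames - 1, n_walkers)
            ).copy()
        vecs = _diffuse_unit_vectors(rng, n_walkers, step_var)
        vecs = vecs.reshape(vecs.shape[0], members.size, m, 3)
        for col, mol in enumerate(members):
            mol_id = f"mix{mol:0{width}d}"
            series[mol] = OrientationSeries(
                molecule_id=mol_id,
                vectors=vecs[:, col, :, :],
                vector_kind="diameter" if m > 1 else "end_to_end",
                dt_frame=spec.dt,
            )
            truth[mol] = {
                "molecule_id": mol_id,
                "population": pop_idx,
                "decay_kind": pop.decay_kind,
                "tau_ns": pop.tau,
                "beta": pop.beta,
                "tau0_ns": pop.tau
                if pop.decay_kind == "exponential"
                else tau0_from_kww(pop.tau, pop.beta),
            }
    return series, truth
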