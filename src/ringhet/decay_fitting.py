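"""Decay-law fits of orientational TACF curves.

Two complementary descriptions of terminal relaxation are implemented:

* the stretched-exponential (KWW) law ``C(t) = exp[-(t/tau_KWW)^beta]``,
  whose time integral has the closed form
  ``tau0 = tau_KWW * Gamma(1/beta) / beta``; a stretching exponent
  beta < 1 signals a distribution of underlying relaxation times, i.e.
  dynamic heterogeneity;
* a constrained finite sum of simple exponentials
  ``C(t) = sum_i A_i exp(-t/tau_i)`` with ``A_i >= 0`` and ``sum_i A_i = 1``,
  whose mode count and weights resolve distinct relaxation mechanisms
  (fast loop dynamics, loop migration, whole-molecule diffusion, and — in
  ring/linear blends — threading release).

Per-molecule terminal times are additionally measured model-free as the
trapezoidal integral of the TACF up to its first negative crossing.

Fits are weighted nonlinear least squares on a log-thinned lag grid
(decades contribute evenly), with deterministic multistart.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.special import gamma as gamma_fn

from .tacf import TACFCurve, first_negative_crossing

__all__ = [
    "FitConfig",
    "KWWFit",
    "MultiExpFit",
    "MoleculeRelaxation",
    "tau0_from_kww",
    "fit_kww",
    "tau0_numeric",
    "fit_multiexp",
    "select_num_modes",
    "kww_curve",
    "multiexp_curve",
]

_BETA_MIN = 0.05
_BETA_MAX = 1.0


@dataclass(frozen=True)
class FitConfig:
    """Shared fitting knobs.

    max_points: size cap of the log-thinned fit grid (t = 0 always kept).
    noise_floor: lags with C(t) <= noise_floor are excluded from fits.
    min_count: lags with fewer averaged products than this are excluded.
    weighting: "equal" on the thinned grid, or "counts" (count-proportional).
    max_modes: hard cap on the multi-exponential mode count.
    mode_improvement_threshold: relative RMS-residual gain below which an
        extra exponential mode is judged unnecessary.
    seed: RNG seed for multistart jitter (deterministic fits).
    """

    max_points: int = 200
    noise_floor: float = 0.0
    min_count: int = 1
    weighting: str = "equal"
    max_modes: int = 6
    mode_improvement_threshold: float = 0.10
    seed: int = 20200330

    def __post_init__(self) -> None:
        if self.weighting not in ("equal", "counts"):
            raise ValueError(f"weighting must be 'equal' or 'counts', got {self.weighting!r}")
        if self.max_points < 10:
            raise ValueError("max_points must be >= 10")


@dataclass(frozen=True)
class KWWFit:
    """Stretched-exponential fit result; tau0 is the Eq-closed-form integral."""

    tau_kww: float
    beta: float
    tau0: float
    rms_residual: float
    fit_window: tuple[float, float]
    converged: bool
    beta_pinned: bool = False

    def __post_init__(self) -> None:
        if self.tau_kww <= 0:
            raise ValueError("tau_kww must be > 0")
        if not 0.0 < self.beta <= 1.0:
            raise ValueError("beta must lie in (0, 1]")
        expected = tau0_from_kww(self.tau_kww, self.beta)
        if abs(self.tau0 - expected) > 1e-12 * max(1.0, abs(expected)):
            raise ValueError("tau0 inconsistent with tau_kww * Gamma(1/beta) / beta")


@dataclass(frozen=True)
class MultiExpFit:
    """Constrained multi-exponential fit: modes (tau_i, A_i), tau ascending."""

    modes: tuple[tuple[float, float], ...]
    rms_residual: float
    converged: bool

    def __post_init__(self) -> None:
        taus = np.array([t for t, _ in self.modes])
        amps = np.array([a for _, a in self.modes])
        if np.any(taus <= 0):
            raise ValueError("all tau_i must be > 0")
        if np.any(np.diff(taus) <= 0):
            raise ValueError("modes must be strictly tau-ascending")
        if np.any(amps < -1e-12):
            raise ValueError("all A_i must be >= 0")
        if abs(amps.sum() - 1.0) > 1e-6:
            raise ValueError(f"amplitudes must sum to 1 within 1e-6, got {amps.sum()!r}")

    @property
    def n_modes(self) -> int:
        return len(self.modes)

    @property
    def taus(self) -> np.ndarray:
        return np.array([t for t, _ in self.modes])

    @property
    def amplitudes(self) -> np.ndarray:
        return np.array([a for _, a in self.modes])

    @property
    def mean_relaxation_time(self) -> float:
        """sum_i A_i tau_i — the fit's own TACF time integral."""
        return float(np.dot(self.taus, self.amplitudes))


@dataclass(frozen=True)
class MoleculeRelaxation:
    """Model-free per-molecule terminal time: integral of C(t) to t_max."""

    molecule_id: str
    tau0_numeric: float
    t_max: float | None
    truncated: bool

    def __post_init__(self) -> None:
        if self.tau0_numeric <= 0:
            raise ValueError("tau0_numeric must be > 0")


def tau0_from_kww(tau_kww: float, beta: float) -> float:
    """Closed-form time integral of exp[-(t/tau_KWW)^beta].

    tau0 = tau_KWW * Gamma(1/beta) / beta, in the units of tau_kww (ns).
    """
    if tau_kww <= 0:
        raise ValueError(f"tau_kww must be > 0, got {tau_kww}")
    if not 0.0 < beta <= 1.0:
        raise ValueError(f"beta must lie in (0, 1], got {beta}")
    return tau_kww * gamma_fn(1.0 / beta) / beta


def kww_curve(t: np.ndarray, tau_kww: float, beta: float) -> np.ndarray:
    """Evaluate the KWW law on lag times t (ns); exact 1 at t = 0."""
    t = np.asarray(t, dtype=float)
    out = np.ones_like(t)
    pos = t > 0
    out[pos] = np.exp(-((t[pos] / tau_kww) ** beta))
    return out


def multiexp_curve(t: np.ndarray, taus: np.ndarray, amps: np.ndarray) -> np.ndarray:
    """Evaluate sum_i A_i exp(-t/tau_i) on lag times t (ns)."""
    t = np.asarray(t, dtype=float)
    return np.exp(-t[:, None] / np.asarray(taus)[None, :]) @ np.asarray(amps)


# ---------------------------------------------------------------------------
# fit-window selection


def _fit_window_indices(curve: TACFCurve, config: FitConfig) -> np.ndarray:
    """Indices of the log-thinned fit grid (always includes lag 0).

    The window runs from t = 0 up to the first negative crossing (or the full
    curve if none), drops lags at or below the noise floor or with too few
    samples, then thins to <= max_points approximately uniform in log-lag.
    """
    t_cross = first_negative_crossing(curve)
    mask = np.ones(curve.n_lags, dtype=bool)
    if t_cross is not None:
        mask &= curve.lags < t_cross
    mask &= curve.values > config.noise_floor
    mask &= curve.counts >= config.min_count
    mask[0] = True
    idx = np.nonzero(mask)[0]
    pos = idx[idx > 0]
    if pos.size + 1 <= config.max_points or pos.size == 0:
        return idx
    logs = np.log(curve.lags[pos])
    targets = np.linspace(logs[0], logs[-1], config.max_points - 1)
    chosen = pos[np.unique(np.searchsorted(logs, targets).clip(0, pos.size - 1))]
    return np.concatenate(([0], chosen))


def _weights(curve: TACFCurve, idx: np.ndarray, config: FitConfig) -> np.ndarray:
    if config.weighting == "counts":
        w = np.sqrt(curve.counts[idx].astype(float))
        return w / w.mean()
    return np.ones(idx.size)


# ---------------------------------------------------------------------------
# KWW fitting


def fit_kww(curve: TACFCurve, config: FitConfig | None = None) -> KWWFit:
    """Weighted least-squares KWW fit of a TACF curve.

    Multistart over log-spaced tau guesses and beta in {0.4, 0.7, 1.0};
    never raises on non-convergence — returns best-effort parameters with
    ``converged=False`` instead. A beta estimate pinned at a bound is
    reported via ``beta_pinned``.
    """
    config = config or FitConfig()
    idx = _fit_window_indices(curve, config)
    if idx.size < 10:
        raise ValueError(
            f"KWW fit needs >= 10 usable lags above the noise floor, got {idx.size}"
        )
    t = curve.lags[idx]
    y = curve.values[idx]
    w = _weights(curve, idx, config)
    window = float(t[-1])
    dt = float(curve.lags[1] - curve.lags[0])
    lo_tau, hi_tau = dt * 1e-3, 1e4 * window

    def resid(p: np.ndarray) -> np.ndarray:
        log_tau, beta = p
        return w * (kww_curve(t, math.exp(log_tau), beta) - y)

    # crude moment guess: integral of the curve sets the tau scale
    tau_scale = max(float(np.trapezoid(np.clip(y, 0, None), t)), dt)
    tau_guesses = np.exp(
        np.linspace(math.log(max(lo_tau * 10, tau_scale / 30)),
                    math.log(min(hi_tau / 10, tau_scale * 30)), 5)
    )
    best = None
    for tau_g in tau_guesses:
        for beta_g in (0.4, 0.7, 1.0):
            sol = least_squares(
                resid,
                x0=[math.log(tau_g), min(beta_g, _BETA_MAX)],
                bounds=([math.log(lo_tau), _BETA_MIN], [math.log(hi_tau), _BETA_MAX]),
                xtol=1e-14, ftol=1e-14, gtol=1e-14,
            )
            if best is None or sol.cost < best.cost - 1e-15:
                best = sol
    tau_fit = math.exp(best.x[0])
    beta_fit = float(best.x[1])
    rms = float(np.sqrt(np.mean((resid(best.x) / w) ** 2)))
    pinned = bool(
        abs(beta_fit - _BETA_MIN) < 1e-9
        or (abs(beta_fit - _BETA_MAX) < 1e-9 and rms > 1e-6)
    )
    beta_fit = min(max(beta_fit, _BETA_MIN), _BETA_MAX)
    return KWWFit(
        tau_kww=tau_fit,
        beta=beta_fit,
        tau0=tau0_from_kww(tau_fit, beta_fit),
        rms_residual=rms,
        fit_window=(float(t[0]), window),
        converged=bool(best.success),
        beta_pinned=pinned,
    )


# ---------------------------------------------------------------------------
# model-free per-molecule terminal time


def tau0_numeric(curve: TACFCurve) -> MoleculeRelaxation:
    """Trapezoidal integral of C(t) from 0 to its first negative crossing.

    If the curve never crosses zero inside its window, the full window is
    integrated and the result is flagged ``truncated``.
    """
    if curve.n_lags < 2:
        raise ValueError("tau0_numeric needs a curve with >= 2 lags")
    t_cross = first_negative_crossing(curve)
    if t_cross is None:
        hi = curve.n_lags - 1
        truncated = True
    else:
        hi = int(np.searchsorted(curve.lags, t_cross))
        truncated = False
    hi = max(hi, 1)
    value = float(np.trapezoid(curve.values[: hi + 1], curve.lags[: hi + 1]))
    return MoleculeRelaxation(
        molecule_id=curve.molecule_id or "",
        tau0_numeric=value,
        t_max=t_cross,
        truncated=truncated,
    )


# ---------------------------------------------------------------------------
# constrained multi-exponential fitting


def _multiexp_residual_factory(t, y, w, n_m, penalty=1e3):
    """Residuals over (log_tau_1..n, a_1..a_{n-1}); A_n is the remainder.

    The unit-sum constraint is built in by construction; a negative
    remainder is discouraged by a linear penalty term.
    """

    def resid(p: np.ndarray) -> np.ndarray:
        log_taus = p[:n_m]
        free_amps = p[n_m:]
        a_last = 1.0 - free_amps.sum()
        amps = np.concatenate([free_amps, [a_last]])
        model = np.exp(-t[:, None] * np.exp(-log_taus)[None, :]) @ amps
        res = w * (model - y)
        return np.concatenate([res, [penalty * max(0.0, -a_last)]])

    return resid


def fit_multiexp(curve: TACFCurve, n_m: int, config: FitConfig | None = None) -> MultiExpFit:
    """Fit C(t) = sum_{i=1..n_m} A_i exp(-t/tau_i), A_i >= 0, sum A_i = 1.

    Deterministic multistart over log-spaced tau initializations (jittered
    with the configured seed); modes are returned tau-ascending.
    """
    config = config or FitConfig()
    if n_m < 1:
        raise ValueError("n_m must be >= 1")
    if n_m > config.max_modes:
        raise ValueError(f"n_m = {n_m} exceeds configured maximum {config.max_modes}")
    idx = _fit_window_indices(curve, config)
    if idx.size < 10:
        raise ValueError(
            f"multi-exponential fit needs >= 10 usable lags, got {idx.size}"
        )
    t = curve.lags[idx]
    y = curve.values[idx]
    w = _weights(curve, idx, config)
    window = float(t[-1])
    dt = float(curve.lags[1] - curve.lags[0])
    lo, hi = math.log(dt * 1e-3), math.log(1e3 * window)
    rng = np.random.default_rng(config.seed)
    resid = _multiexp_residual_factory(t, y, w, n_m)

    # tau spreads spanning the observed window at several placements
    t_hi = math.log(window)
    t_lo = math.log(max(dt * 0.3, window * 1e-5))
    starts = []
    for frac in (1.0, 0.6, 0.3):
        span_hi = t_lo + frac * (t_hi - t_lo)
        base = np.linspace(t_lo, span_hi, n_m) if n_m > 1 else np.array([0.5 * (t_lo + span_hi)])
        starts.append(base)
        starts.append(base + rng.uniform(-0.3, 0.3, size=n_m))
    amp0 = np.full(n_m - 1, 1.0 / n_m)

    lb = np.concatenate([np.full(n_m, lo), np.zeros(n_m - 1)])
    ub = np.concatenate([np.full(n_m, hi), np.ones(n_m - 1)])
    best = None
    for log_taus0 in starts:
        x0 = np.concatenate([np.clip(log_taus0, lo + 1e-9, hi - 1e-9), amp0])
        sol = least_squares(resid, x0=x0, bounds=(lb, ub), xtol=1e-15, ftol=1e-15, gtol=1e-15)
        if best is None or sol.cost < best.cost - 1e-18:
            best = sol
    log_taus = best.x[:n_m]
    free_amps = best.x[n_m:]
    amps = np.concatenate([free_amps, [1.0 - free_amps.sum()]])
    amps = np.clip(amps, 0.0, None)
    amps = amps / amps.sum()  # exact renormalization after clipping
    taus = np.exp(log_taus)
    order = np.argsort(taus)
    taus, amps = taus[order], amps[order]
    # merge numerically coincident modes so tau-ascending is strict
    merged_t: list[float] = []
    merged_a: list[float] = []
    for tau_i, a_i in zip(taus, amps):
        if merged_t and tau_i <= merged_t[-1] * (1 + 1e-9):
            merged_a[-1] += a_i
            merged_t[-1] = max(merged_t[-1], tau_i * (1 + 1e-12))
        else:
            merged_t.append(float(tau_i))
            merged_a.append(float(a_i))
    model = multiexp_curve(t, np.array(merged_t), np.array(merged_a))
    rms = float(np.sqrt(np.mean((model - y) ** 2)))
    return MultiExpFit(
        modes=tuple(zip(merged_t, merged_a)),
        rms_residual=rms,
        converged=bool(best.success),
    )


def select_num_modes(
    curve: TACFCurve,
    max_modes: int | None = None,
    config: FitConfig | None = None,
) -> tuple[int, MultiExpFit]:
    """Smallest mode count that describes the curve.

    Fits n_m = 1, 2, ... and stops at the smallest n_m for which adding one
    more exponential improves the RMS residual by less than the configured
    relative threshold (or the residual is already at the noiseless floor).
    Ties resolve to fewer modes.
    """
    config = config or FitConfig()
    max_modes = max_modes or config.max_modes
    if max_modes < 1:
        raise ValueError("max_modes must be >= 1")
    noise_floor_rms = 1e-8
    fits: list[MultiExpFit] = []
    for n in range(1, max_modes + 1):
        fits.append(fit_multiexp(curve, n, config))
        if fits[-1].rms_residual < noise_floor_rms:
            return n, fits[-1]
        if n >= 2:
            prev, cur = fits[-2].rms_residual, fits[-1].rms_residual
            improvement = (prev - cur) / prev if prev > 0 else 0.0
            if improvement < config.mode_improvement_threshold:
                return n - 1, fits[-2]
    return max_modes, fits[-1]
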