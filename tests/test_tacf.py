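import numpy as np
import pytest

import ringhet as rh
from conftest import make_curve


def _series_from_vectors(vectors, dt=1.0, molecule_id="m0", kind="end_to_end"):
    return rh.OrientationSeries(molecule_id=molecule_id, vectors=vectors,
                                vector_kind=kind, dt_frame=dt)


def test_frozen_vectors_give_unit_correlation():
    u = np.tile(np.array([0.0, 0.0, 1.0]), (50, 1, 1))
    curve = rh.molecule_tacf(_series_from_vectors(u), max_lag_fraction=1.0)
    np.testing.assert_allclose(curve.values, 1.0, atol=1e-12)


def test_c0_is_exactly_one(rotdiff_run):
    for c in rotdiff_run["curves"][:10]:
        assert c.values[0] == 1.0


def test_direct_sum_matches_brute_force_all_strides():
    rng = np.random.default_rng(8)
    v = rng.normal(size=(40, 3, 3))
    v /= np.linalg.norm(v, axis=2, keepdims=True)
    series = _series_from_vectors(v, dt=0.5, kind="diameter")
    for stride in (1, 3):
        curve = rh.molecule_tacf(series, origin_stride=stride, max_lag_fraction=1.0)
        for i, lag in enumerate(range(curve.n_lags)):
            origins = range(0, 40 - lag, stride)
            dots = [float(v[t0 + lag, k] @ v[t0, k]) for t0 in origins for k in range(3)]
            assert curve.counts[i] == len(dots)
            assert abs(curve.values[i] - np.mean(dots)) < 1e-9


def test_correlate_and_loop_paths_agree():
    rng = np.random.default_rng(9)
    v = rng.normal(size=(400, 2, 3))
    v /= np.linalg.norm(v, axis=2, keepdims=True)
    series = _series_from_vectors(v, kind="diameter")
    full = rh.molecule_tacf(series, max_lag_fraction=0.9)  # correlate path
    short = rh.molecule_tacf(series, max_lag_fraction=0.1)  # sliced-lag path
    np.testing.assert_allclose(full.values[: short.n_lags], short.values, atol=1e-10)


def test_ensemble_identity_and_closed_form_mean():
    t = np.arange(20.0)
    c1 = make_curve(t, np.ones_like(t), scope="molecule", molecule_id="a")
    assert np.array_equal(rh.ensemble_tacf([c1]).values, c1.values)
    c2 = make_curve(t, np.exp(-t), scope="molecule", molecule_id="b")
    mean = rh.ensemble_tacf([c1, c2])
    np.testing.assert_allclose(mean.values, (1 + np.exp(-t)) / 2, atol=1e-12)
    assert mean.scope == "ensemble"


def test_ensemble_of_identical_copies_is_unchanged(rotdiff_run):
    c = rotdiff_run["curves"][0]
    mean = rh.ensemble_tacf([c, c, c])
    np.testing.assert_allclose(mean.values, c.values, atol=1e-12)


def test_mismatched_lag_grids_rejected():
    c1 = make_curve(np.arange(5.0), np.exp(-np.arange(5.0)))
    c2 = make_curve(np.arange(4.0), np.exp(-np.arange(4.0)))
    with pytest.raises(ValueError, match="lag grid"):
        rh.ensemble_tacf([c1, c2])


def test_first_negative_crossing():
    t = np.arange(5.0)
    assert rh.first_negative_crossing(make_curve(t, np.exp(-t))) is None
    curve = make_curve(t, [1.0, 0.5, 0.1, -0.02, 0.01])
    assert rh.first_negative_crossing(curve) == 3.0


def test_first_negative_crossing_matches_scan(mixture_run):
    for curve in mixture_run["curves"][:20]:
        found = None
        for lag, val in zip(curve.lags, curve.values):  # brute-force linear scan
            if val < 0:
                found = lag
                break
        assert rh.first_negative_crossing(curve) == found


def test_tacf_invariant_under_global_rotation():
    spec = rh.RouseChainSpec(topology="ring", n_beads=6, k=5.0, zeta=20.0, dt=0.1,
                             n_steps=400, save_stride=2, seed=21)
    traj = rh.generate_rouse_chain(spec)
    rng = np.random.default_rng(4)
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    rotated = rh.Trajectory(traj.coordinates @ q.T, traj.system)
    mid = traj.system.molecule_ids[0]
    c0 = rh.molecule_tacf(rh.diameter_series(traj, mid))
    c1 = rh.molecule_tacf(rh.diameter_series(rotated, mid))
    np.testing.assert_allclose(c1.values, c0.values, atol=1e-9)


def test_rotational_diffusion_matches_exponential(rotdiff_run):
    """Empirical TACF of the diffusing ensemble tracks exp(-2 D_r t)."""
    spec = rotdiff_run["spec"]
    mean = rh.ensemble_tacf(rotdiff_run["curves"])
    exact = np.exp(-2 * 0.1 * mean.lags)
    # Monte-Carlo tolerance from the tracer count and window length
    n_eff = spec.n_molecules * spec.n_frames * spec.dt / (2 * (1 / (2 * 0.1)))
    tol = 5.0 / np.sqrt(n_eff)
    assert np.abs(mean.values - exact).max() < tol


def test_initial_log_slope_recovers_rate(rotdiff_run):
    mean = rh.ensemble_tacf(rotdiff_run["curves"])
    n = 20  # short-lag window, C still near 1
    slope = np.polyfit(mean.lags[:n], np.log(mean.values[:n]), 1)[0]
    assert slope == pytest.approx(-0.2, rel=0.05)


def test_csv_round_trip(mixture_run):
    curve = mixture_run["curves"][0]
    frame = rh.tacf_to_frame(curve)
    back = rh.tacf_from_frame(frame)
    assert len(back) == 1
    np.testing.assert_allclose(back[0].values, curve.values)
    assert back[0].molecule_id == curve.molecule_id
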