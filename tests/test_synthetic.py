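import numpy as np
import pytest
from scipy.linalg import expm

import ringhet as rh


class TestReproducibility:
    def test_rotational_diffusion_bitwise(self):
        spec = rh.RotDiffSpec(n_molecules=5, D_r=0.2, dt=0.05, n_frames=50, seed=13)
        a = rh.generate_rotational_diffusion(spec)
        b = rh.generate_rotational_diffusion(spec)
        for sa, sb in zip(a, b):
            assert np.array_equal(sa.vectors, sb.vectors)

    def test_rouse_bitwise(self):
        spec = rh.RouseChainSpec(topology="linear", n_beads=5, k=3.0, zeta=12.0,
                                 dt=0.2, n_steps=50, save_stride=5, seed=7)
        assert np.array_equal(rh.generate_rouse_chain(spec).coordinates,
                              rh.generate_rouse_chain(spec).coordinates)

    def test_mixture_bitwise(self):
        spec = rh.MixtureSpec(
            populations=(rh.MixturePopulation(1.0, "exponential", 2.0),),
            n_molecules=4, dt=0.1, n_frames=40, seed=5)
        a, truth_a = rh.generate_mixture_ensemble(spec)
        b, truth_b = rh.generate_mixture_ensemble(spec)
        assert truth_a == truth_b
        for sa, sb in zip(a, b):
            assert np.array_equal(sa.vectors, sb.vectors)


class TestRotationalDiffusion:
    def test_unit_norms(self, rotdiff_run):
        v = rotdiff_run["series"][0].vectors
        assert np.abs(np.linalg.norm(v, axis=2) - 1).max() < 1e-9

    def test_effectively_frozen_limit(self):
        spec = rh.RotDiffSpec(n_molecules=3, D_r=1e-12, dt=0.1, n_frames=200, seed=1)
        series = rh.generate_rotational_diffusion(spec)
        curve = rh.molecule_tacf(series[0], max_lag_fraction=1.0)
        assert curve.values.min() > 1 - 1e-6

    def test_discretization_bound_enforced(self):
        with pytest.raises(ValueError, match="bound"):
            rh.RotDiffSpec(n_molecules=2, D_r=1.0, dt=0.1, n_frames=10, seed=0)

    def test_tacf_matches_analytic_exponential(self, rotdiff_run):
        spec = rotdiff_run["spec"]
        mean = rh.ensemble_tacf(rotdiff_run["curves"])
        exact = np.exp(-2 * 0.1 * mean.lags)
        n_eff = spec.n_molecules * spec.n_frames * spec.dt / (1 / 0.1)
        assert np.abs(mean.values - exact).max() < 5.0 / np.sqrt(n_eff)

    def test_per_molecule_rates(self):
        spec = rh.RotDiffSpec(n_molecules=2, D_r=(0.05, 0.4), dt=0.05, n_frames=4000,
                              seed=23)
        fast, slow = None, None
        series = rh.generate_rotational_diffusion(spec)
        c0 = rh.molecule_tacf(series[0], max_lag_fraction=0.1)
        c1 = rh.molecule_tacf(series[1], max_lag_fraction=0.1)
        # the slower-diffusing molecule keeps orientation memory longer
        assert c0.values[30] > c1.values[30]


class TestRouseChain:
    def test_unstable_dt_cites_bound(self):
        with pytest.raises(ValueError, match="zeta/\\(4k\\)"):
            rh.RouseChainSpec(topology="ring", n_beads=6, k=10.0, zeta=10.0,
                              dt=0.5, n_steps=10, save_stride=1, seed=0)

    def test_linear_bond_equipartition(self):
        # independent bonds: <b^2> = 3 kBT / k
        spec = rh.RouseChainSpec(topology="linear", n_beads=10, k=4.0, zeta=16.0,
                                 dt=0.05, n_steps=40000, save_stride=20, seed=31,
                                 n_molecules=4)
        traj = rh.generate_rouse_chain(spec)
        msq = 0.0
        for mid in traj.system.molecule_ids:
            mol = traj.molecule_coordinates(mid)
            bonds = mol[:, 1:] - mol[:, :-1]
            msq += float((bonds ** 2).sum(axis=2).mean())
        msq /= len(traj.system.molecule_ids)
        assert msq == pytest.approx(3.0 / 4.0, rel=0.05)

    def test_ring_bond_equipartition(self, rouse_ring_run):
        # closure constraint: <b^2> = (3 kBT / k)(1 - 1/N)
        traj = rouse_ring_run["traj"]
        spec = rouse_ring_run["spec"]
        mol = traj.molecule_coordinates(traj.system.molecule_ids[0])
        bonds = np.roll(mol, -1, axis=1) - mol
        expected = 3.0 / spec.k * (1 - 1 / spec.n_beads)
        assert float((bonds ** 2).sum(axis=2).mean()) == pytest.approx(expected, rel=0.05)

    def test_center_of_mass_diffusion(self, rouse_ring_run):
        # free-draining: MSD_com = 6 kBT t / (N zeta)
        traj = rouse_ring_run["traj"]
        spec = rouse_ring_run["spec"]
        com = np.stack([traj.molecule_coordinates(m).mean(axis=1)
                        for m in traj.system.molecule_ids], axis=1)
        lag = 200  # frames
        disp = com[lag:] - com[:-lag]
        msd = float((disp ** 2).sum(axis=2).mean())
        t_lag = lag * traj.system.dt_frame
        expected = 6.0 * t_lag / (spec.n_beads * spec.zeta)
        assert msd == pytest.approx(expected, rel=0.15)

    def test_mode_sum_matches_brute_force_n6(self):
        """Analytic mode spectrum vs matrix-exponential covariance, N = 6."""
        N, k, zeta = 6, 5.0, 20.0
        L = 2 * np.eye(N) - np.roll(np.eye(N), 1, 0) - np.roll(np.eye(N), -1, 0)
        h = N // 2 - 1
        w = np.zeros(N)
        w[h], w[0] = 1.0, -1.0
        evals, V = np.linalg.eigh(L)
        pinv = (V[:, 1:] / evals[1:]) @ V[:, 1:].T / k
        ts = np.linspace(0.0, 10.0, 40)
        brute = np.array([3 * w @ expm(-k * L * t / zeta) @ pinv @ w for t in ts])
        assert brute[0] == pytest.approx(3 * h * (N - h) / (N * k), rel=1e-12)
        rho = rh.ring_diameter_normalized_correlation(ts, N, k, zeta)
        np.testing.assert_allclose(brute / brute[0], rho, atol=1e-12)

    def test_simulated_diameter_tacf_matches_normal_mode_oracle(self, rouse_ring_run):
        """Simulated ring diameter TACF vs the analytic normal-mode curve."""
        spec = rouse_ring_run["spec"]
        mean = rouse_ring_run["ensemble"]
        exact = rh.analytic_ring_diameter_tacf(mean.lags, spec.n_beads, spec.k, spec.zeta)
        mask = exact > 0.02
        # Monte-Carlo tolerance from replica count and observation length
        tau1 = spec.slowest_mode_time
        n_eff = spec.n_molecules * (spec.n_steps * spec.dt) / (2 * tau1) * 2
        tol = 5.0 / np.sqrt(n_eff)
        assert np.abs(mean.values - exact)[mask].max() < tol

    def test_mode_times_follow_dispersion_relation(self):
        taus = rh.ring_relaxation_times(8, 10.0, 40.0)
        p = np.arange(1, 8)
        np.testing.assert_allclose(taus, 40.0 / (4 * 10.0 * np.sin(np.pi * p / 8) ** 2))


class TestMixture:
    def test_homogeneous_population_is_exponential(self):
        spec = rh.MixtureSpec(
            populations=(rh.MixturePopulation(1.0, "exponential", 1.5),),
            n_molecules=60, dt=0.05, n_frames=4000, seed=9, n_tracers=4)
        series, truth = rh.generate_mixture_ensemble(spec)
        mean = rh.ensemble_tacf([rh.molecule_tacf(s, max_lag_fraction=0.1) for s in series])
        fit = rh.fit_kww(mean)
        assert fit.beta > 0.93
        assert fit.tau_kww == pytest.approx(1.5, rel=0.1)

    def test_two_population_linearity(self, mixture_run):
        mean = rh.ensemble_tacf(mixture_run["curves"])
        exact = 0.8 * np.exp(-mean.lags / 1.0) + 0.2 * np.exp(-mean.lags / 2.5)
        assert np.abs(mean.values - exact).max() < 0.02

    def test_ground_truth_matches_assignment_weights(self, mixture_run):
        truth = mixture_run["truth"]
        frac_slow = np.mean([t["population"] == 1 for t in truth])
        assert abs(frac_slow - 0.2) < 2.58 * np.sqrt(0.2 * 0.8 / len(truth))

    def test_mean_tau0_matches_weighted_design(self, mixture_run):
        rel = [rh.tau0_numeric(c) for c in mixture_run["curves"]]
        expected = 0.8 * 1.0 + 0.2 * 2.5
        assert np.mean([r.tau0_numeric for r in rel]) == pytest.approx(expected, rel=0.07)

    def test_kww_surrogate_decays_as_stretched_exponential(self):
        spec = rh.MixtureSpec(
            populations=(rh.MixturePopulation(1.0, "kww", 2.0, beta=0.6),),
            n_molecules=150, dt=0.05, n_frames=3000, seed=27, n_tracers=4)
        series, truth = rh.generate_mixture_ensemble(spec)
        mean = rh.ensemble_tacf([rh.molecule_tacf(s, max_lag_fraction=0.2) for s in series])
        exact = rh.kww_curve(mean.lags, 2.0, 0.6)
        assert np.abs(mean.values - exact).max() < 0.04
        assert truth[0]["tau0_ns"] == pytest.approx(rh.tau0_from_kww(2.0, 0.6))

    def test_beta_decreases_with_population_spread(self):
        """Wider relaxation-time spread depresses the ensemble stretching exponent."""
        betas = []
        for ratio in (1.0, 4.0, 25.0):
            tau_lo = 1.0 / np.sqrt(ratio)
            tau_hi = 1.0 * np.sqrt(ratio)
            pops = (
                (rh.MixturePopulation(1.0, "exponential", 1.0),)
                if ratio == 1.0
                else (rh.MixturePopulation(0.5, "exponential", tau_lo),
                      rh.MixturePopulation(0.5, "exponential", tau_hi))
            )
            spec = rh.MixtureSpec(populations=pops, n_molecules=100, dt=0.02,
                                  n_frames=5000, seed=33, n_tracers=4)
            series, _ = rh.generate_mixture_ensemble(spec)
            mean = rh.ensemble_tacf(
                [rh.molecule_tacf(s, max_lag_fraction=0.25) for s in series])
            betas.append(rh.fit_kww(mean).beta)
        assert betas[0] > betas[1] > betas[2]
        assert betas[0] > 0.9
        assert betas[2] < 0.75
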