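import numpy as np
import pytest

import ringhet as rh


def make_curve(t, y, scope="ensemble", molecule_id=None, counts=None):
    """TACFCurve from tabulated values (unit counts unless given)."""
    t = np.asarray(t, dtype=float)
    counts = np.ones(t.size, dtype=int) if counts is None else counts
    return rh.TACFCurve(t, np.asarray(y, dtype=float), counts, scope, molecule_id)


def log_grid(lo, hi, n):
    """Fit-friendly lag grid: 0 plus n log-spaced points in [lo, hi]."""
    return np.concatenate([[0.0], np.geomspace(lo, hi, n)])


@pytest.fixture(scope="session")
def mixture_run():
    """Designed 80/20 fast/slow exponential mixture with ground truth.

    Slow population sits at 2x the reference time 1.25 ns; designed median
    of normalized times is 0.8; tracer families emulate a ring's diameter
    vectors.
    """
    spec = rh.MixtureSpec(
        populations=(
            rh.MixturePopulation(0.8, "exponential", 1.0),
            rh.MixturePopulation(0.2, "exponential", 2.5),
        ),
        n_molecules=200,
        dt=0.1,
        n_frames=6000,
        seed=42,
        n_tracers=8,
    )
    series, truth = rh.generate_mixture_ensemble(spec)
    curves = [rh.molecule_tacf(s, max_lag_fraction=0.05) for s in series]
    return {"spec": spec, "series": series, "truth": truth, "curves": curves,
            "reference_time": 1.25}


@pytest.fixture(scope="session")
def rotdiff_run():
    """400 diffusing unit vectors, D_r = 0.1/ns: exact TACF exp(-0.2 t)."""
    spec = rh.RotDiffSpec(n_molecules=400, D_r=0.1, dt=0.01, n_frames=3000, seed=3)
    series = rh.generate_rotational_diffusion(spec)
    curves = [rh.molecule_tacf(s, max_lag_fraction=0.5) for s in series]
    return {"spec": spec, "series": series, "curves": curves}


@pytest.fixture(scope="session")
def rouse_ring_run():
    """Eight independent N=8 harmonic rings; slowest mode time ~6.8 ns."""
    spec = rh.RouseChainSpec(
        topology="ring", n_beads=8, k=10.0, zeta=40.0, dt=0.05,
        n_steps=40000, save_stride=10, seed=11, n_molecules=8,
    )
    traj = rh.generate_rouse_chain(spec)
    curves = [
        rh.molecule_tacf(rh.diameter_series(traj, mid), max_lag_fraction=0.25)
        for mid in traj.system.molecule_ids
    ]
    return {"spec": spec, "traj": traj, "curves": curves,
            "ensemble": rh.ensemble_tacf(curves)}


@pytest.fixture()
def small_system():
    """One 4-bead ring plus one 3-bead linear chain, dt 0.5 ns."""
    return rh.SystemSpec(
        molecules=(
            rh.MoleculeRecord("ring0", "ring", 4),
            rh.MoleculeRecord("lin0", "linear", 3),
        ),
        dt_frame=0.5,
    )


@pytest.fixture()
def random_trajectory(small_system):
    rng = np.random.default_rng(7)
    coords = rng.normal(size=(10, small_system.total_beads, 3))
    return rh.Trajectory(coords, small_system)
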