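#!/usr/bin/env python
"""Simulate a ring/linear-blend emulation series and compute its TACFs.

Four mixture ensembles stand in for a composition sweep of a ring melt
blended with linear chains: as the linear fraction grows, a larger share of
rings is (multiply) threaded and relaxes ~3x slower than the free ones.
The threaded weights 5/12/18/20% follow the qualitative progression seen
in unentangled ring-linear blends. Each ensemble is 200 molecules x 8
tracers, 600 ns at 0.1 ns resolution, exponential populations with
tau_free = 1 ns.

Writes: results/blend_series/ensemble_tacfs.csv (log-thinned),
scratch/blend_series/<label>_molecule_tacfs.csv (full per-molecule curves
consumed by the downstream scripts).
"""

import sys
import time
from pathlib import Path

import numpy as np
import pandas as pd

import ringhet as rh

ROOT = Path(__file__).resolve().parents[1]

# composition label -> (emulated linear fraction, threaded/slow weight)
COMPOSITIONS = {
    "melt": (0.0, 0.05),
    "blend_02": (0.2, 0.12),
    "blend_05": (0.5, 0.18),
    "blend_07": (0.7, 0.20),
}
TAU_FREE = 1.0  # ns
SLOWDOWN = 5.0  # multiply-threaded rings relax several-fold slower
BASE_SEED = 2026


def build_spec(label: str) -> rh.MixtureSpec:
    phi, w_slow = COMPOSITIONS[label]
    pops = (
        rh.MixturePopulation(1.0 - w_slow, "exponential", TAU_FREE),
        rh.MixturePopulation(w_slow, "exponential", TAU_FREE * SLOWDOWN),
    )
    offset = list(COMPOSITIONS).index(label)
    return rh.MixtureSpec(populations=pops, n_molecules=200, dt=0.1,
                          n_frames=6000, seed=BASE_SEED + offset, n_tracers=8)


def main() -> None:
    out_results = ROOT / "results" / "blend_series"
    out_scratch = ROOT / "scratch" / "blend_series"
    out_results.mkdir(parents=True, exist_ok=True)
    out_scratch.mkdir(parents=True, exist_ok=True)

    thinned_rows = []
    for label in COMPOSITIONS:
        t0 = time.time()
        spec = build_spec(label)
        series, truth = rh.generate_mixture_ensemble(spec)
        curves = [rh.molecule_tacf(s, max_lag_fraction=0.05) for s in series]
        mean = rh.ensemble_tacf(curves)

        pd.concat([rh.tacf_to_frame(c) for c in curves]).to_csv(
            out_scratch / f"{label}_molecule_tacfs.csv", index=False)
        pd.DataFrame(truth).to_csv(out_scratch / f"{label}_ground_truth.csv", index=False)

        keep = np.unique(np.geomspace(1, mean.n_lags - 1, 50).astype(int))
        keep = np.concatenate([[0], keep])
        df = rh.tacf_to_frame(mean).iloc[keep].assign(composition=label)
        thinned_rows.append(df)
        phi, w = COMPOSITIONS[label]
        print(f"{label}: phi_L~{phi}, threaded weight {w:.2f}, "
              f"C(t) at 5 ns = {mean.values[50]:.3f}  ({time.time() - t0:.1f} s)")

    pd.concat(thinned_rows).to_csv(out_results / "ensemble_tacfs.csv", index=False)
    print(f"wrote {out_results / 'ensemble_tacfs.csv'}")
    print("slower compositions hold orientation memory visibly longer, as the")
    print("growing threaded subpopulation delays ensemble decorrelation")


if __name__ == "__main__":
    sys.exit(main())
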