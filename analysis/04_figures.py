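#!/usr/bin/env python
"""Static figures of the blend-series results: TACF decays and histograms.

Reads the tables written by scripts 01-03 and renders two PNGs under
scratch/figures/: the ensemble TACF decay per composition (log time axis)
and the normalized relaxation-time histograms with their slow tails.
"""

import sys
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results" / "blend_series"
FIGS = ROOT / "scratch" / "figures"


def main() -> int:
    if not RESULTS.exists():
        print("run analysis scripts 01-03 first", file=sys.stderr)
        return 1
    FIGS.mkdir(parents=True, exist_ok=True)

    tacfs = pd.read_csv(RESULTS / "ensemble_tacfs.csv")
    fig, ax = plt.subplots(figsize=(5, 3.5))
    for label, grp in tacfs.groupby("composition", sort=False):
        ax.semilogx(grp["lag_ns"].clip(lower=0.05), grp["value"], label=label)
    ax.set_xlabel("lag time (ns)")
    ax.set_ylabel(r"$\langle u(t)\cdot u(0)\rangle$")
    ax.axhline(0.0, color="k", lw=0.5)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(FIGS / "ensemble_tacfs.png", dpi=150)

    hists = pd.read_csv(RESULTS / "histograms.csv")
    comps = hists["composition"].unique()
    fig, axes = plt.subplots(1, len(comps), figsize=(3 * len(comps), 3), sharey=True)
    for ax, label in zip(axes, comps):
        grp = hists[hists["composition"] == label]
        ax.bar(grp["bin_lo"], grp["probability"],
               width=grp["bin_hi"] - grp["bin_lo"], align="edge")
        ax.axvline(1.0, color="r", ls="--", lw=0.8)
        ax.set_title(label, fontsize=9)
        ax.set_xlabel(r"$\tau_0/\tau_{0,\mathrm{melt}}$")
    axes[0].set_ylabel("probability")
    fig.tight_layout()
    fig.savefig(FIGS / "relaxation_time_histograms.png", dpi=150)
    print(f"figures written to {FIGS}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
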