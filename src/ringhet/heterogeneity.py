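"""Population statistics of per-molecule relaxation times.

Dynamic heterogeneity — fast- and slow-relaxing subpopulations coexisting
in one system — shows up as a broad distribution of per-molecule terminal
times. This module turns an ensemble of per-molecule times into its
quantitative summaries: times normalized by a reference system's mean
relaxation time, probability histograms, the ensemble median, and the
slow-tail fraction (the share of molecules slower than a threshold multiple
of the reference time).

Molecules whose TACF never crossed zero inside the observation window are
kept with their (windowed, hence lower-bound) integrals and carried with a
``truncated`` flag: dropping them would bias exactly the slow tail this
analysis is about.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .decay_fitting import MoleculeRelaxation

__all__ = [
    "RelaxationTimeEnsemble",
    "build_ensemble",
    "tail_fraction",
    "ensemble_median",
    "histogram",
    "ensemble_to_frame",
]


@dataclass(frozen=True)
class RelaxationTimeEnsemble:
    """Per-molecule terminal times normalized by a reference time.

    ``reference_time`` is the mean terminal relaxation time of the designated
    reference system (e.g. the pure ring melt), so ``normalized_times`` are
    the dimensionless tau0 / tau0_ref per molecule.
    """

    entries: tuple[MoleculeRelaxation, ...]
    reference_time: float
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "entries", tuple(self.entries))
        if not self.entries:
            raise ValueError("ensemble needs at least one molecule")
        if self.reference_time <= 0:
            raise ValueError("reference_time must be > 0 ns")

    @property
    def times(self) -> np.ndarray:
        return np.array([e.tau0_numeric for e in self.entries])

    @property
    def normalized_times(self) -> np.ndarray:
        return self.times / self.reference_time

    @property
    def truncated_fraction(self) -> float:
        return float(np.mean([e.truncated for e in self.entries]))


def build_ensemble(
    relaxations: list[MoleculeRelaxation],
    reference_time: float,
    label: str = "",
) -> RelaxationTimeEnsemble:
    """Collect per-molecule relaxations and normalize by a reference time."""
    return RelaxationTimeEnsemble(tuple(relaxations), reference_time, label)


def tail_fraction(ens: RelaxationTimeEnsemble, threshold: float = 1.0) -> float:
    """Fraction of molecules with normalized time strictly above threshold."""
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    return float(np.mean(ens.normalized_times > threshold))


def ensemble_median(ens: RelaxationTimeEnsemble) -> float:
    """Sample median of normalized times (midpoint convention, even counts)."""
    return float(np.median(ens.normalized_times))


def histogram(
    ens: RelaxationTimeEnsemble,
    bin_width: float | None = 0.1,
    bin_count: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Probability-normalized histogram of normalized times.

    With ``bin_width`` (default 0.1), bins run from 0 in fixed steps and the
    range auto-extends to the data maximum; with ``bin_count`` that many
    equal bins span [0, max]. Probabilities sum to 1.
    """
    x = ens.normalized_times
    if bin_count is not None:
        if bin_count < 1:
            raise ValueError("bin_count must be >= 1")
        edges = np.linspace(0.0, max(float(x.max()), 1e-12), bin_count + 1)
    else:
        if bin_width is None or bin_width <= 0:
            raise ValueError("bin_width must be > 0")
        n_bins = max(1, int(np.ceil(x.max() / bin_width + 1e-12)))
        edges = np.arange(n_bins + 1) * bin_width
    counts, edges = np.histogram(x, bins=edges)
    probs = counts / counts.sum()
    return edges, probs


def ensemble_to_frame(ens: RelaxationTimeEnsemble) -> pd.DataFrame:
    """CSV-ready view: molecule_id, tau0_ns, normalized_time, truncated."""
    return pd.DataFrame(
        {
            "molecule_id": [e.molecule_id for e in ens.entries],
            "tau0_ns": [e.tau0_numeric for e in ens.entries],
            "normalized_time": ens.normalized_times,
            "truncated": [e.truncated for e in ens.entries],
        }
    )
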