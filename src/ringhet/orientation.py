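"""Characteristic orientation vectors of polymer molecules.

For a linear chain the orientation tracer is the unit vector along the
end-to-end vector R_ee (last bead minus first bead). For a ring of N beads
(N even) it is the family of diameter vectors R_d: the vectors between bead
pairs that are N/2 - 1 bonds apart along the contour. All N cyclic offsets
are used, pair (i, (i + N/2 - 1) mod N) for i = 0..N-1, each kept as its own
tracer over time so that per-tracer time correlation is well defined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trajectory_io import Trajectory

__all__ = [
    "OrientationSeries",
    "DegenerateVectorError",
    "end_to_end_series",
    "diameter_series",
    "ring_diameter_pairs",
    "orientation_series_for",
]

#: unit-norm tolerance enforced by the OrientationSeries invariant
UNIT_NORM_ATOL = 1e-9

#: raw vectors shorter than this (nm) are treated as degenerate
DEGENERATE_NORM = 1e-12


class DegenerateVectorError(ValueError):
    """A raw orientation vector had (numerically) zero length."""


@dataclass(frozen=True)
class OrientationSeries:
    """Per-molecule time series of unit orientation vectors.

    vectors has shape (n_frames, n_vectors, 3); every vector is unit length.
    ``vector_kind`` is ``"end_to_end"`` (n_vectors == 1) or ``"diameter"``
    (n_vectors == N, one tracer per cyclic offset).
    """

    molecule_id: str
    vectors: np.ndarray
    vector_kind: str
    dt_frame: float

    def __post_init__(self) -> None:
        v = np.asarray(self.vectors, dtype=float)
        object.__setattr__(self, "vectors", v)
        if v.ndim != 3 or v.shape[2] != 3:
            raise ValueError(f"vectors must have shape (frames, tracers, 3), got {v.shape}")
        if self.vector_kind not in ("end_to_end", "diameter"):
            raise ValueError(f"unknown vector_kind {self.vector_kind!r}")
        if self.vector_kind == "end_to_end" and v.shape[1] != 1:
            raise ValueError("end_to_end series must have exactly one tracer")
        if self.dt_frame <= 0:
            raise ValueError("dt_frame must be > 0")
        norms = np.linalg.norm(v, axis=2)
        if not np.allclose(norms, 1.0, atol=UNIT_NORM_ATOL, rtol=0.0):
            worst = float(np.abs(norms - 1.0).max())
            raise ValueError(f"orientation vectors not unit length (max |norm-1| = {worst:.3g})")

    @property
    def n_frames(self) -> int:
        return self.vectors.shape[0]

    @property
    def n_vectors(self) -> int:
        return self.vectors.shape[1]


def _normalize(raw: np.ndarray, molecule_id: str, what: str) -> np.ndarray:
    """Normalize raw (frames, tracers, 3) vectors, rejecting degenerate ones."""
    norms = np.linalg.norm(raw, axis=2)
    bad = norms < DEGENERATE_NORM
    if np.any(bad):
        frame, idx = np.argwhere(bad)[0]
        raise DegenerateVectorError(
            f"molecule {molecule_id!r}: degenerate {what} vector at frame {frame}"
            f" (tracer index {idx})"
        )
    return raw / norms[:, :, None]


def end_to_end_series(traj: Trajectory, molecule_id: str) -> OrientationSeries:
    """Unit end-to-end vector time series of a linear chain.

    Direction is last bead minus first bead in every frame.
    """
    rec = traj.system.record(molecule_id)
    if rec.kind != "linear":
        raise ValueError(f"molecule {molecule_id!r} is a {rec.kind}; end-to-end needs a linear chain")
    coords = traj.molecule_coordinates(molecule_id)
    raw = (coords[:, -1, :] - coords[:, 0, :])[:, None, :]
    return OrientationSeries(
        molecule_id=molecule_id,
        vectors=_normalize(raw, molecule_id, "end-to-end"),
        vector_kind="end_to_end",
        dt_frame=traj.system.dt_frame,
    )


def ring_diameter_pairs(n_beads: int) -> list[tuple[int, int]]:
    """Bead index pairs (i, (i + N/2 - 1) mod N) defining the diameter family.

    The offset is N/2 - 1 bonds along the ring contour; all N cyclic offsets
    are enumerated, giving N directed tracers. N must be even.
    """
    if n_beads % 2 != 0:
        raise ValueError(f"ring diameter vectors require even N, got N = {n_beads}")
    off = n_beads // 2 - 1
    return [(i, (i + off) % n_beads) for i in range(n_beads)]


def diameter_series(traj: Trajectory, molecule_id: str) -> OrientationSeries:
    """Unit diameter-vector family of a ring molecule, one tracer per offset.

    The same bead pair defines each tracer index in every frame, so each
    tracer is a consistent object to correlate over time.
    """
    rec = traj.system.record(molecule_id)
    if rec.kind != "ring":
        raise ValueError(f"molecule {molecule_id!r} is a {rec.kind}; diameter vectors need a ring")
    pairs = ring_diameter_pairs(rec.n_beads)
    coords = traj.molecule_coordinates(molecule_id)
    heads = np.array([j for _, j in pairs])
    tails = np.array([i for i, _ in pairs])
    raw = coords[:, heads, :] - coords[:, tails, :]
    return OrientationSeries(
        molecule_id=molecule_id,
        vectors=_normalize(raw, molecule_id, "diameter"),
        vector_kind="diameter",
        dt_frame=traj.system.dt_frame,
    )


def orientation_series_for(traj: Trajectory, molecule_id: str) -> OrientationSeries:
    """Dispatch on molecule kind: end-to-end for linear, diameter family for ring."""
    kind = traj.system.record(molecule_id).kind
    if kind == "linear":
        return end_to_end_series(traj, molecule_id)
    return diameter_series(traj, molecule_id)
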