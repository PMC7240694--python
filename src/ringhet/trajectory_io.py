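"""Trajectory containers and I/O.

The canonical in-memory objects every downstream stage consumes:

* :class:`SystemSpec` — topology declaration: which molecules exist, whether
  each is a ring or a linear chain, how many beads it has, and the time
  between stored frames.
* :class:`Trajectory` — a dense ``(n_frames, total_beads, 3)`` coordinate
  array in nm plus its :class:`SystemSpec`.

Units are fixed package-wide: **nm** for length, **ns** for time.
Coordinates are assumed already unwrapped (continuous molecule images);
no periodic-box handling is performed anywhere.
"""

from __future__ import annotations

import json
import tomllib
from dataclasses import dataclass

import numpy as np

__all__ = [
    "MoleculeRecord",
    "SystemSpec",
    "Trajectory",
    "TrajectoryFormatError",
    "read_xyz_trajectory",
    "write_xyz_trajectory",
    "save_native_archive",
    "load_native_archive",
    "load_system_toml",
]

#: schema tag written into native archives; bump on layout changes
ARCHIVE_SCHEMA_VERSION = 1

#: decimal places written by the XYZ writer (documented in the frame comment)
XYZ_DECIMALS = 6


class TrajectoryFormatError(ValueError):
    """A trajectory file violates the declared format or topology."""


@dataclass(frozen=True)
class MoleculeRecord:
    molecule_id: str
    kind: str  # "ring" | "linear"
    n_beads: int

    def __post_init__(self) -> None:
        if self.kind not in ("ring", "linear"):
            raise ValueError(f"molecule kind must be 'ring' or 'linear', got {self.kind!r}")
        min_beads = 3 if self.kind == "ring" else 2
        if self.n_beads < min_beads:
            raise ValueError(
                f"{self.kind} molecule {self.molecule_id!r} needs >= {min_beads} beads, "
                f"got {self.n_beads}"
            )


@dataclass(frozen=True)
class SystemSpec:
    """Topology declaration for a trajectory.

    Parameters
    ----------
    molecules
        Ordered molecule records; bead slices in a frame follow this order.
    dt_frame
        Time between stored frames (ns), > 0.
    phi_L
        Optional molar fraction of the linear component (metadata only).
    molar_mass
        Optional molar mass in g/mol (metadata only).
    label
        Free-text label carried into reports.
    """

    molecules: tuple[MoleculeRecord, ...]
    dt_frame: float
    phi_L: float | None = None
    molar_mass: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "molecules", tuple(self.molecules))
        if not self.molecules:
            raise ValueError("SystemSpec needs at least one molecule")
        if self.dt_frame <= 0:
            raise ValueError(f"dt_frame must be > 0 ns, got {self.dt_frame}")
        if self.phi_L is not None and not 0.0 <= self.phi_L <= 1.0:
            raise ValueError(f"phi_L must lie in [0, 1], got {self.phi_L}")
        ids = [m.molecule_id for m in self.molecules]
        if len(set(ids)) != len(ids):
            raise ValueError("molecule_ids must be unique")

    @property
    def total_beads(self) -> int:
        return sum(m.n_beads for m in self.molecules)

    @property
    def molecule_ids(self) -> list[str]:
        return [m.molecule_id for m in self.molecules]

    def record(self, molecule_id: str) -> MoleculeRecord:
        for m in self.molecules:
            if m.molecule_id == molecule_id:
                return m
        raise KeyError(f"unknown molecule_id {molecule_id!r}")

    def bead_slice(self, molecule_id: str) -> slice:
        """Contiguous bead index slice of a molecule within a frame."""
        start = 0
        for m in self.molecules:
            if m.molecule_id == molecule_id:
                return slice(start, start + m.n_beads)
            start += m.n_beads
        raise KeyError(f"unknown molecule_id {molecule_id!r}")

    def to_dict(self) -> dict:
        return {
            "schema": ARCHIVE_SCHEMA_VERSION,
            "molecules": [
                {"molecule_id": m.molecule_id, "kind": m.kind, "n_beads": m.n_beads}
                for m in self.molecules
            ],
            "dt_frame": self.dt_frame,
            "phi_L": self.phi_L,
            "molar_mass": self.molar_mass,
            "label": self.label,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SystemSpec":
        required = {"molecules", "dt_frame"}
        missing = sorted(required - d.keys())
        if missing:
            raise TrajectoryFormatError(f"SystemSpec dict missing fields: {missing}")
        mols = tuple(
            MoleculeRecord(m["molecule_id"], m["kind"], int(m["n_beads"]))
            for m in d["molecules"]
        )
        return cls(
            molecules=mols,
            dt_frame=float(d["dt_frame"]),
            phi_L=d.get("phi_L"),
            molar_mass=d.get("molar_mass"),
            label=d.get("label", ""),
        )


@dataclass(frozen=True)
class Trajectory:
    """Coordinates (n_frames, total_beads, 3) in nm plus topology."""

    coordinates: np.ndarray
    system: SystemSpec

    def __post_init__(self) -> None:
        coords = np.asarray(self.coordinates, dtype=float)
        object.__setattr__(self, "coordinates", coords)
        if coords.ndim != 3 or coords.shape[2] != 3:
            raise ValueError(f"coordinates must have shape (n_frames, beads, 3), got {coords.shape}")
        if coords.shape[0] < 2:
            raise ValueError(f"trajectory needs >= 2 frames, got {coords.shape[0]}")
        if coords.shape[1] != self.system.total_beads:
            raise ValueError(
                f"coordinate bead count {coords.shape[1]} != SystemSpec total {self.system.total_beads}"
            )
        if not np.all(np.isfinite(coords)):
            raise ValueError("coordinates contain non-finite values")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def frame_times(self) -> np.ndarray:
        """Frame times in ns, frame_index * dt_frame."""
        return np.arange(self.n_frames) * self.system.dt_frame

    def molecule_coordinates(self, molecule_id: str) -> np.ndarray:
        """(n_frames, N, 3) view of one molecule's beads."""
        return self.coordinates[:, self.system.bead_slice(molecule_id), :]


def read_xyz_trajectory(path, system: SystemSpec) -> Trajectory:
    """Read a multi-frame XYZ file against a topology declaration.

    Each frame is an atom-count line, a comment line, then one
    ``symbol x y z`` line per bead, in SystemSpec molecule order.
    Coordinates are interpreted as nm.
    """
    expected = system.total_beads
    frames: list[np.ndarray] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    frame_idx = 0
    n_lines = len(lines)
    while i < n_lines:
        if lines[i].strip() == "" and all(l.strip() == "" for l in lines[i:]):
            break  # trailing blank lines
        try:
            count = int(lines[i].split()[0])
        except (ValueError, IndexError):
            raise TrajectoryFormatError(
                f"frame {frame_idx}: expected atom-count line at line {i + 1}, got {lines[i]!r}"
            )
        if count != expected:
            raise TrajectoryFormatError(
                f"frame {frame_idx}: declares {count} atoms but SystemSpec totals {expected}"
            )
        if i + 1 + count >= n_lines + 1:
            raise TrajectoryFormatError(f"frame {frame_idx}: truncated (file ends mid-frame)")
        block = np.empty((count, 3))
        for j in range(count):
            line_no = i + 2 + j
            parts = lines[line_no].split()
            if len(parts) < 4:
                raise TrajectoryFormatError(
                    f"line {line_no + 1}: expected 'symbol x y z', got {lines[line_no]!r}"
                )
            try:
                block[j] = [float(parts[1]), float(parts[2]), float(parts[3])]
            except ValueError:
                raise TrajectoryFormatError(
                    f"line {line_no + 1}: non-numeric coordinate in {lines[line_no]!r}"
                )
        frames.append(block)
        i += 2 + count
        frame_idx += 1
    if len(frames) < 2:
        raise TrajectoryFormatError(f"trajectory needs >= 2 frames, file holds {len(frames)}")
    return Trajectory(np.stack(frames), system)


def write_xyz_trajectory(traj: Trajectory, path) -> None:
    """Write a multi-frame XYZ file (coordinates in nm, fixed precision)."""
    n = traj.system.total_beads
    fmt = f"X {{:.{XYZ_DECIMALS}f}} {{:.{XYZ_DECIMALS}f}} {{:.{XYZ_DECIMALS}f}}\n"
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"{n}\n")
            fh.write(f"frame {f} t_ns {traj.frame_times[f]:.9g} (nm, {XYZ_DECIMALS} decimals)\n")
            for x, y, z in traj.coordinates[f]:
                fh.write(fmt.format(x, y, z))


def save_native_archive(traj: Trajectory, path) -> None:
    """Lossless binary archive of coordinates + SystemSpec (npz container)."""
    np.savez_compressed(
        path,
        schema=np.int64(ARCHIVE_SCHEMA_VERSION),
        coordinates=traj.coordinates,
        system_json=np.array(json.dumps(traj.system.to_dict())),
    )


def load_system_toml(path) -> SystemSpec:
    """Read a SystemSpec from TOML.

    Layout: top-level ``dt_frame_ns`` (required), optional ``phi_L``,
    ``molar_mass``, ``label``, and one or more ``[[molecules]]`` tables with
    keys ``kind``, ``n_beads``, ``count``. Molecule ids are generated as
    ``<kind><index>`` in declaration order.
    """
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    if "dt_frame_ns" not in raw:
        raise TrajectoryFormatError("system TOML missing required key 'dt_frame_ns'")
    if "molecules" not in raw or not raw["molecules"]:
        raise TrajectoryFormatError("system TOML needs at least one [[molecules]] table")
    records: list[MoleculeRecord] = []
    counters: dict[str, int] = {}
    for tbl in raw["molecules"]:
        missing = sorted({"kind", "n_beads"} - tbl.keys())
        if missing:
            raise TrajectoryFormatError(f"[[molecules]] table missing keys: {missing}")
        for _ in range(int(tbl.get("count", 1))):
            idx = counters.get(tbl["kind"], 0)
            counters[tbl["kind"]] = idx + 1
            records.append(MoleculeRecord(f"{tbl['kind']}{idx:03d}", tbl["kind"], int(tbl["n_beads"])))
    return SystemSpec(
        molecules=tuple(records),
        dt_frame=float(raw["dt_frame_ns"]),
        phi_L=raw.get("phi_L"),
        molar_mass=raw.get("molar_mass"),
        label=raw.get("label", ""),
    )


def load_native_archive(path) -> Trajectory:
    with np.load(path, allow_pickle=False) as npz:
        missing = sorted({"schema", "coordinates", "system_json"} - set(npz.files))
        if missing:
            raise TrajectoryFormatError(f"archive missing fields: {missing}")
        schema = int(npz["schema"])
        if schema != ARCHIVE_SCHEMA_VERSION:
            raise TrajectoryFormatError(
                f"archive schema version {schema} != supported {ARCHIVE_SCHEMA_VERSION}"
            )
        sys_dict = json.loads(str(npz["system_json"]))
        missing_sys = sorted(k for k in ("molecules", "dt_frame") if k not in sys_dict)
        if missing_sys:
            raise TrajectoryFormatError(f"archive system record missing fields: {missing_sys}")
        return Trajectory(npz["coordinates"], SystemSpec.from_dict(sys_dict))
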