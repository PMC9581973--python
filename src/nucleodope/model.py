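"""Core domain containers: atoms, frames, trajectories, interaction sites.

All lengths are nanometres and all times picoseconds throughout the package;
readers convert Angstrom-based formats (PDB, XYZ) at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterator, Mapping, Sequence

import numpy as np

from .errors import ConfigError, DataError


class InteractionLabel(str, Enum):
    """Per-base-frame interaction taxonomy.

    TYPE_I: one Alq3 molecule provides both a ring stack and a hydrogen bond
    to the same base (the thymine-like multisite mode).
    TYPE_II: the base hydrogen-bonds to one Alq3 molecule while stacking on a
    different, neighbouring one (the adenine-like multisite mode).
    HBOND_ONLY / PI_ONLY: only one interaction kind present.
    NONE: no contact.
    """

    TYPE_I = "TypeI"
    TYPE_II = "TypeII"
    HBOND_ONLY = "HbondOnly"
    PI_ONLY = "PiOnly"
    NONE = "None"


#: the four counted (non-None) categories in canonical order
COUNTED_LABELS = (
    InteractionLabel.TYPE_I,
    InteractionLabel.TYPE_II,
    InteractionLabel.HBOND_ONLY,
    InteractionLabel.PI_ONLY,
)


@dataclass(frozen=True)
class AtomRecord:
    """A single atom: identity plus position (nm)."""

    atom_id: int
    element: str
    name: str
    residue_name: str
    residue_id: int
    molecule_id: int
    position: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise DataError(f"atom {self.atom_id}: position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)


@dataclass
class Topology:
    """Per-atom identity arrays shared by every frame of a trajectory."""

    names: np.ndarray
    elements: np.ndarray
    residue_names: np.ndarray
    residue_ids: np.ndarray
    molecule_ids: np.ndarray
    atom_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.names = np.asarray(self.names, dtype=object)
        n = len(self.names)
        self.elements = np.asarray(self.elements, dtype=object)
        self.residue_names = np.asarray(self.residue_names, dtype=object)
        self.residue_ids = np.asarray(self.residue_ids, dtype=int)
        self.molecule_ids = np.asarray(self.molecule_ids, dtype=int)
        if self.atom_ids is None:
            self.atom_ids = np.arange(n, dtype=int)
        self.atom_ids = np.asarray(self.atom_ids, dtype=int)
        for arr, label in (
            (self.elements, "elements"),
            (self.residue_names, "residue_names"),
            (self.residue_ids, "residue_ids"),
            (self.molecule_ids, "molecule_ids"),
            (self.atom_ids, "atom_ids"),
        ):
            if len(arr) != n:
                raise DataError(f"topology field {label!r} has length {len(arr)} != {n}")
        keys = set(zip(self.molecule_ids.tolist(), self.atom_ids.tolist()))
        if len(keys) != n:
            raise DataError("(molecule_id, atom_id) pairs must be unique")

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    def residue_atom_indices(self) -> dict[int, np.ndarray]:
        """Global atom indices grouped by residue_id, in residue order."""
        order: dict[int, list[int]] = {}
        for i, rid in enumerate(self.residue_ids.tolist()):
            order.setdefault(rid, []).append(i)
        return {rid: np.asarray(ix, dtype=int) for rid, ix in order.items()}


@dataclass
class Frame:
    """Atomic coordinates (N, 3) in nm at one stored time (ps)."""

    time: float
    positions: np.ndarray
    topology: Topology
    box: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise DataError("positions must have shape (N, 3)")
        if self.positions.shape[0] != self.topology.n_atoms:
            raise DataError(
                f"frame has {self.positions.shape[0]} positions for "
                f"{self.topology.n_atoms} topology atoms"
            )
        if not np.all(np.isfinite(self.positions)):
            raise DataError("frame contains non-finite coordinates")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float).reshape(3)

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[0]

    def atoms(self) -> Iterator[AtomRecord]:
        top = self.topology
        for i in range(self.n_atoms):
            yield AtomRecord(
                atom_id=int(top.atom_ids[i]),
                element=str(top.elements[i]),
                name=str(top.names[i]),
                residue_name=str(top.residue_names[i]),
                residue_id=int(top.residue_ids[i]),
                molecule_id=int(top.molecule_ids[i]),
                position=self.positions[i],
            )


@dataclass
class Trajectory:
    """An ordered sequence of frames with a fixed save interval dt (ps)."""

    frames: list[Frame]
    dt: float

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise DataError("trajectory dt must be > 0")
        if not self.frames:
            raise DataError("trajectory has zero frames")
        times = self.times
        if np.any(np.diff(times) <= 0):
            raise DataError("frame times must be strictly increasing")
        n0 = self.frames[0].n_atoms
        for f in self.frames:
            if f.n_atoms != n0:
                raise DataError("atom count differs across frames")

    @property
    def times(self) -> np.ndarray:
        return np.asarray([f.time for f in self.frames], dtype=float)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def topology(self) -> Topology:
        return self.frames[0].topology

    def select_window(self, start: float, end: float, stride: int = 1) -> "Trajectory":
        """Frames with time in the closed interval [start, end], strided.

        Idempotent and order-preserving.
        """
        if start >= end:
            raise ConfigError("window_start must be < window_end")
        if stride < 1:
            raise ConfigError("stride must be >= 1")
        times = self.times
        keep = [f for f, t in zip(self.frames, times) if start <= t <= end]
        keep = keep[::stride]
        if not keep:
            raise DataError(f"no frames in window [{start}, {end}] ps")
        return Trajectory(frames=keep, dt=self.dt * stride)

    def final_window(self, duration_ps: float, stride: int = 1) -> "Trajectory":
        """The trailing `duration_ps` of the trajectory (closed interval)."""
        t_end = float(self.times[-1])
        return self.select_window(t_end - duration_ps, t_end, stride=stride)


@dataclass
class RingGroup:
    """A named aromatic ring: >=3 atom indices forming one planar unit.

    kind is 'base' (nucleobase ring) or 'quinoline' (one Alq3 ligand treated
    as a single fused-ring plane).
    """

    molecule_id: int
    ring_id: int
    atom_indices: np.ndarray
    kind: str
    residue_id: int

    def __post_init__(self) -> None:
        self.atom_indices = np.asarray(self.atom_indices, dtype=int)
        if self.atom_indices.size < 3:
            raise ConfigError(f"ring {self.ring_id}: needs >= 3 atoms")
        if self.kind not in ("base", "quinoline"):
            raise ConfigError(f"ring {self.ring_id}: unknown kind {self.kind!r}")


@dataclass
class DonorAcceptorSet:
    """Hydrogen-bond participants resolved to global atom indices.

    donors is an (n, 2) array of (D-atom, H-atom) index pairs; acceptors is a
    flat index array. Parallel arrays carry molecule and residue identity.
    """

    donors: np.ndarray
    donor_molecule_ids: np.ndarray
    donor_residue_ids: np.ndarray
    acceptors: np.ndarray
    acceptor_molecule_ids: np.ndarray
    acceptor_residue_ids: np.ndarray

    def __post_init__(self) -> None:
        self.donors = np.asarray(self.donors, dtype=int).reshape(-1, 2)
        self.donor_molecule_ids = np.asarray(self.donor_molecule_ids, dtype=int)
        self.donor_residue_ids = np.asarray(self.donor_residue_ids, dtype=int)
        self.acceptors = np.asarray(self.acceptors, dtype=int)
        self.acceptor_molecule_ids = np.asarray(self.acceptor_molecule_ids, dtype=int)
        self.acceptor_residue_ids = np.asarray(self.acceptor_residue_ids, dtype=int)
        if len(self.donor_molecule_ids) != len(self.donors) or len(
            self.donor_residue_ids
        ) != len(self.donors):
            raise DataError("donor identity arrays must match donor count")
        if len(self.acceptor_molecule_ids) != len(self.acceptors) or len(
            self.acceptor_residue_ids
        ) != len(self.acceptors):
            raise DataError("acceptor identity arrays must match acceptor count")

    def check_donor_hydrogens(self, frame: Frame, max_dh: float = 0.25) -> None:
        """Verify each donor H sits within a covalent-bond distance of its D."""
        if len(self.donors) == 0:
            return
        d = frame.positions[self.donors[:, 0]]
        h = frame.positions[self.donors[:, 1]]
        dist = np.linalg.norm(h - d, axis=1)
        bad = np.nonzero(dist > max_dh)[0]
        if bad.size:
            raise DataError(
                f"donor H not bonded to its D for donor index {int(bad[0])} "
                f"(D-H = {dist[bad[0]]:.3f} nm)"
            )


@dataclass
class AnalysisConfig:
    """Tunable geometric criteria and windowing for contact analysis.

    Defaults follow the analysis conventions of the underlying study: a
    0.45 nm ring-to-ring vertical-separation cutoff for stacking, standard
    0.35 nm / 30 degree hydrogen-bond criteria, a 1.2 nm nonbonded cutoff,
    and an analysis window covering the trailing 10 ns of the trajectory.
    """

    stacking_cutoff: float = 0.45
    lateral_guard: float = 0.3
    hbond_distance_cutoff: float = 0.35
    hbond_angle_cutoff: float = 30.0
    window_start: float | None = None
    window_end: float | None = None
    window_duration: float = 10_000.0  # ps; used when start/end not given
    stride: int = 1
    nonbonded_cutoff: float = 1.2
    temperature: float = 298.15
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "stacking_cutoff",
            "hbond_distance_cutoff",
            "hbond_angle_cutoff",
            "nonbonded_cutoff",
            "temperature",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        if self.lateral_guard < 0:
            raise ConfigError("lateral_guard must be >= 0")
        if self.stride < 1:
            raise ConfigError("stride must be >= 1")
        if (
            self.window_start is not None
            and self.window_end is not None
            and self.window_start >= self.window_end
        ):
            raise ConfigError("window_start must be < window_end")

    @classmethod
    def from_mapping(cls, mapping: Mapping) -> "AnalysisConfig":
        known = {f for f in cls.__dataclass_fields__}  # noqa: C401
        bad = [k for k in mapping if k not in known]
        if bad:
            raise ConfigError(f"unknown analysis config keys: {bad}")
        return cls(**dict(mapping))

    def window(self, trajectory: Trajectory) -> Trajectory:
        """Apply the configured analysis window to a trajectory."""
        if self.window_start is not None and self.window_end is not None:
            return trajectory.select_window(
                self.window_start, self.window_end, stride=self.stride
            )
        duration = min(
            self.window_duration, float(trajectory.times[-1] - trajectory.times[0])
        )
        return trajectory.final_window(duration, stride=self.stride)
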