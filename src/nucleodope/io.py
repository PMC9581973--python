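"""File readers and writers for the standard formats the analyses consume.

Structure and trajectory formats (PDB, GRO, XYZ) are parsed through
MDAnalysis and converted to the package's nm-based containers at the
boundary (MDAnalysis works in Angstrom internally). Two-column numeric
tables (spectra, PMF curves, decay series) and umbrella-window tables are
plain text with '#' comments.

Molecule identity is not stored by GRO/XYZ, so it is reconstructed with a
simple rule: consecutive nucleotide residues form one DNA molecule; every
other residue is its own molecule.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .definitions import NUCLEOTIDE_RESNAMES
from .errors import DataError, ParseError
from .model import Frame, Topology, Trajectory
from .synthetic import UmbrellaWindows

log = logging.getLogger(__name__)

_STRUCTURE_FORMATS = {"PDB", "GRO"}
_A_TO_NM = 0.1

_ELEMENT_GUESS = {"AL": "Al", "CL": "Cl", "NA": "Na", "MG": "Mg"}


def _guess_element(name: str) -> str:
    stripped = name.strip().lstrip("0123456789")
    if not stripped:
        return "X"
    two = stripped[:2].upper()
    if two in _ELEMENT_GUESS:
        return _ELEMENT_GUESS[two]
    return stripped[0].upper()


def _molecule_ids_from_residues(resnames, resids) -> np.ndarray:
    """Group consecutive nucleotide residues into one molecule."""
    mol_of_residue: dict[int, int] = {}
    mol = -1
    prev_rid = None
    prev_was_nt = False
    for rn, rid in zip(resnames, resids):
        if rid == prev_rid:
            continue
        is_nt = str(rn).upper() in NUCLEOTIDE_RESNAMES
        if not (is_nt and prev_was_nt):
            mol += 1
        mol_of_residue[rid] = mol
        prev_rid, prev_was_nt = rid, is_nt
    return np.asarray([mol_of_residue[r] for r in resids], dtype=int)


def _import_mda():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        import MDAnalysis as mda
    return mda


def _topology_from_universe(u) -> Topology:
    atoms = u.atoms
    names = [str(n) for n in atoms.names]
    try:
        resnames = [str(r) for r in atoms.resnames]
    except Exception:
        resnames = ["UNK"] * len(names)
    try:
        resids = np.asarray(atoms.resids, dtype=int)
    except Exception:
        resids = np.zeros(len(names), dtype=int)
    try:
        elements = [str(e) for e in atoms.elements]
    except Exception:
        elements = [_guess_element(n) for n in names]
    return Topology(
        names=names,
        elements=elements,
        residue_names=resnames,
        residue_ids=resids,
        molecule_ids=_molecule_ids_from_residues(resnames, resids),
    )


def read_structure(path, fmt: str | None = None) -> Frame:
    """Read a single-frame structure (PDB or GRO) into a Frame in nm."""
    path = Path(path)
    if not path.exists():
        raise ParseError(f"{path}: file not found")
    fmt = (fmt or path.suffix.lstrip(".")).upper()
    if fmt not in _STRUCTURE_FORMATS:
        raise ParseError(f"unsupported structure format {fmt!r} (use PDB or GRO)")
    if path.stat().st_size == 0:
        raise ParseError(f"{path}: empty file")
    mda = _import_mda()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(path), format=fmt, topology_format=fmt)
    except Exception as exc:
        raise ParseError(f"{path}: failed to parse as {fmt}: {exc}") from exc
    topology = _topology_from_universe(u)
    box = None
    dims = u.dimensions
    if dims is not None and np.all(dims[:3] > 0):
        box = np.asarray(dims[:3], dtype=float) * _A_TO_NM
    return Frame(
        time=0.0,
        positions=u.atoms.positions.astype(float) * _A_TO_NM,
        topology=topology,
        box=box,
    )


def write_structure(frame: Frame, path) -> None:
    """Write a Frame to PDB or GRO (by extension), converting nm back out."""
    path = Path(path)
    mda = _import_mda()
    top = frame.topology
    n_res = len(set(top.residue_ids.tolist()))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(
            frame.n_atoms, n_residues=n_res, atom_resindex=_res_index(top), trajectory=True
        )
        u.add_TopologyAttr("names", [str(n) for n in top.names])
        resnames, resids = _residue_tables(top)
        u.add_TopologyAttr("resnames", resnames)
        u.add_TopologyAttr("resids", resids)
        u.atoms.positions = frame.positions / _A_TO_NM
        if frame.box is not None:
            u.dimensions = np.concatenate([frame.box / _A_TO_NM, [90.0, 90.0, 90.0]])
        u.atoms.write(str(path))


def _res_index(top: Topology) -> np.ndarray:
    uniq = {rid: i for i, rid in enumerate(dict.fromkeys(top.residue_ids.tolist()))}
    return np.asarray([uniq[r] for r in top.residue_ids.tolist()], dtype=int)


def _residue_tables(top: Topology):
    seen: dict[int, str] = {}
    for rn, rid in zip(top.residue_names.tolist(), top.residue_ids.tolist()):
        seen.setdefault(rid, rn)
    return list(seen.values()), [int(r) for r in seen.keys()]


def read_trajectory(
    traj_path,
    topology: "Topology | None" = None,
    top_path=None,
    fmt: str | None = None,
    dt: float = 1.0,
    length_unit: str = "A",
) -> Trajectory:
    """Read a multi-frame trajectory (XYZ text, or any MDAnalysis-readable
    coordinate dialect) into an in-memory Trajectory.

    XYZ stores no time axis, so frame times are assigned as i * dt (ps).
    ``length_unit`` declares the unit of the file ('A' by default, 'nm' for
    nm-valued XYZ). A structure file via ``top_path`` supplies residue and
    molecule identity; otherwise a flat topology is inferred.
    """
    traj_path = Path(traj_path)
    if not traj_path.exists():
        raise ParseError(f"{traj_path}: file not found")
    if traj_path.stat().st_size == 0:
        raise ParseError(f"{traj_path}: empty file")
    if (fmt or traj_path.suffix.lstrip(".")).lower() == "xyz":
        _validate_xyz_frames(traj_path)
    mda = _import_mda()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if top_path is not None:
                u = mda.Universe(str(top_path), str(traj_path), format=fmt)
            else:
                u = mda.Universe(str(traj_path), format=fmt)
    except (ValueError, OSError, EOFError) as exc:
        raise ParseError(f"{traj_path}: failed to parse: {exc}") from exc
    if topology is None:
        topology = _topology_from_universe(u)
    scale = _A_TO_NM if length_unit.upper() in ("A", "ANGSTROM") else 1.0
    frames = []
    try:
        for i, ts in enumerate(u.trajectory):
            frames.append(
                Frame(
                    time=i * dt,
                    positions=ts.positions.astype(float) * scale,
                    topology=topology,
                )
            )
    except (ValueError, EOFError) as exc:
        raise ParseError(
            f"{traj_path}: inconsistent frame structure at frame {len(frames)}: {exc}"
        ) from exc
    if not frames:
        raise ParseError(f"{traj_path}: zero frames")
    return Trajectory(frames=frames, dt=dt)


def _validate_xyz_frames(path: Path) -> None:
    """Require a constant atom count across all frames of an XYZ file."""
    n_atoms = None
    with open(path) as fh:
        lineno = 0
        while True:
            header = fh.readline()
            lineno += 1
            if not header:
                return
            if not header.strip():
                continue
            try:
                n = int(header.split()[0])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad XYZ frame header") from exc
            if n_atoms is None:
                n_atoms = n
            elif n != n_atoms:
                raise ParseError(
                    f"{path}:{lineno}: atom count changed from {n_atoms} to {n}"
                )
            for _ in range(n + 1):
                fh.readline()
                lineno += 1


def write_trajectory_xyz(trajectory: Trajectory, path, length_unit: str = "A") -> None:
    """Write a trajectory as multi-frame XYZ text (element column = atom name)."""
    scale = 1.0 / _A_TO_NM if length_unit.upper() in ("A", "ANGSTROM") else 1.0
    top = trajectory.topology
    with open(path, "w") as fh:
        for frame in trajectory.frames:
            fh.write(f"{frame.n_atoms}\n")
            fh.write(f"t= {frame.time:.4f} ps\n")
            for name, pos in zip(top.names.tolist(), frame.positions * scale):
                fh.write(f"{name} {pos[0]:.6f} {pos[1]:.6f} {pos[2]:.6f}\n")


def read_xy_table(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a two-column numeric table; '#' comments tolerated.

    Rows are sorted ascending in x and duplicate x values are collapsed by
    averaging y. Raises on fewer than 2 distinct points.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"{path}: file not found")
    xs, ys = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            body = line.split("#", 1)[0].strip()
            if not body:
                continue
            parts = body.replace(",", " ").split()
            if len(parts) < 2:
                raise ParseError(f"{path}:{lineno}: expected two numeric columns")
            try:
                xs.append(float(parts[0]))
                ys.append(float(parts[1]))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    if len(xs) < 2:
        raise DataError(f"{path}: fewer than 2 data points")
    df = pd.DataFrame({"x": xs, "y": ys}).groupby("x", sort=True).mean().reset_index()
    if len(df) < 2:
        raise DataError(f"{path}: fewer than 2 distinct x values")
    return df["x"].to_numpy(), df["y"].to_numpy()


def write_xy_table(x, y, path, header: str = "") -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        for xi, yi in zip(np.asarray(x), np.asarray(y)):
            fh.write(f"{xi:.8g} {yi:.8g}\n")


def read_umbrella_windows(path, temperature: float = 298.15) -> UmbrellaWindows:
    """Read umbrella samples from TSV columns: window_id, center, k, sample."""
    df = pd.read_csv(path, sep=r"\s+", comment="#", header=None,
                     names=["window_id", "center", "k", "sample"])
    if df.empty:
        raise DataError(f"{path}: no umbrella samples")
    centers, samples = [], []
    k_values = set()
    for _, grp in df.groupby("window_id", sort=True):
        centers.append(float(grp["center"].iloc[0]))
        k_values.update(grp["k"].unique().tolist())
        samples.append(grp["sample"].to_numpy(dtype=float))
    if len(k_values) != 1:
        raise DataError("per-window force constants must be identical")
    return UmbrellaWindows(
        centers=np.asarray(centers),
        force_constant=float(k_values.pop()),
        samples=samples,
        temperature=temperature,
    )


def write_umbrella_windows(windows: UmbrellaWindows, path) -> None:
    with open(path, "w") as fh:
        fh.write("# window_id center_nm k_kJ_mol_nm2 sample_nm\n")
        for i, (c, s) in enumerate(zip(windows.centers, windows.samples)):
            for z in s:
                fh.write(f"{i} {c:.6g} {windows.force_constant:.6g} {z:.8g}\n")
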