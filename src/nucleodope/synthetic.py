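"""Seeded synthetic inputs with known ground truth for every analysis stage.

Four generators emulate the data the analyses consume:

* :func:`synth_interaction_trajectory` — a cluster of idealized three-ligand
  Alq3-like molecules plus a single-stranded DNA whose bases are placed, per
  frame, in scheduled fractions of the five interaction modes (TypeI, TypeII,
  HbondOnly, PiOnly, None). With zero geometric noise every base-frame
  satisfies exactly its scheduled label under the default analysis criteria.
* :func:`synth_umbrella_samples` — biased reaction-coordinate samples drawn
  exactly (inverse-CDF on a fine grid) from exp(-[U(z) + k/2 (z-z_i)^2]/kT).
* :func:`synth_spectrum` — a sum of Gaussian emission peaks plus noise.
* :func:`synth_waveguide_series` — an exponentially decaying intensity-vs-
  distance series with multiplicative (log-normal) noise.

All randomness comes from ``numpy.random.default_rng`` (PCG64), so a fixed
seed reproduces output bit-identically across platforms.

Molecules are rigid idealized templates (planar hexagons / fused bicycles
with 0.14 nm bonds); the contact analysis consumes only centroids, normals
and donor/acceptor positions, so chemically exact geometry is not attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .constants import KB
from .errors import ConfigError, DataError
from .model import Frame, InteractionLabel, Topology, Trajectory

_BOND = 0.14  # aromatic bond length, nm
_HEX_ANGLES = np.deg2rad(np.arange(30.0, 360.0, 60.0))

#: per-base geometric offsets (nm) shared by the mode constructors
_STACK_SEP = 0.35  # base ring above ligand ring
_HB_DA = 0.29  # donor-acceptor distance
_HB_ANGLE = 10.0  # H-D-A angle, degrees
_ACC_OFFSET = 0.25  # acceptor offset from ligand-ring centroid, in plane
_SITE_SPACING = 4.0  # grid spacing between interaction sites, nm


def _hexagon(center: np.ndarray) -> np.ndarray:
    """Six ring atoms at circumradius = bond length, xy-plane."""
    pts = np.stack(
        [np.cos(_HEX_ANGLES), np.sin(_HEX_ANGLES), np.zeros(6)], axis=1
    ) * _BOND
    return pts + center


def _quinoline_template() -> np.ndarray:
    """Ten-atom fused bicycle in the xy-plane, first ring centred at origin."""
    hex1 = _hexagon(np.zeros(3))
    c2 = np.array([2.0 * _BOND * np.cos(np.pi / 6), 0.0, 0.0])
    hex2 = _hexagon(c2)
    # drop hex2's two shared vertices (angles 150 and 210 degrees)
    deg = np.rad2deg(_HEX_ANGLES)
    keep = [
        i
        for i, a in enumerate(deg)
        if not (np.isclose(a, 150.0) or np.isclose(a, 210.0))
    ]
    return np.vstack([hex1, hex2[keep]])


_QUINOLINE = _quinoline_template()
_LIGAND_CENTROID_LOCAL = _QUINOLINE.mean(axis=0)  # ~ (0.121, 0, 0)
_LIGAND_RADIAL = 0.5  # first-ring centre distance from Al, nm


def _alq3_template() -> tuple[np.ndarray, list[str], list[str]]:
    """Rigid three-ligand template: positions, atom names, elements.

    Ligands A/B/C point along 0/120/240 degrees in the xy-plane; each carries
    a phenolate-like acceptor oxygen at the outer edge of its fused ring.
    """
    positions = [np.zeros(3)]
    names = ["AL"]
    elements = ["Al"]
    for k, lig in enumerate("ABC"):
        theta = np.deg2rad(120.0 * k)
        rot = np.array(
            [
                [np.cos(theta), -np.sin(theta), 0.0],
                [np.sin(theta), np.cos(theta), 0.0],
                [0.0, 0.0, 1.0],
            ]
        )
        u = rot[:, 0]
        ring = (_QUINOLINE @ rot.T) + _LIGAND_RADIAL * u
        positions.extend(ring)
        names.extend(f"{lig}C{i}" for i in range(1, 11))
        elements.extend(["C"] * 10)
        centroid = (rot @ _LIGAND_CENTROID_LOCAL) + _LIGAND_RADIAL * u
        positions.append(centroid + _ACC_OFFSET * u)
        names.append(f"{lig}O")
        elements.append("O")
    return np.asarray(positions), names, elements


_ALQ_POS, _ALQ_NAMES, _ALQ_ELEMENTS = _alq3_template()
#: local centroid of ligand A's fused ring and its acceptor position
_LIG_A_CENTROID = (_LIGAND_CENTROID_LOCAL + np.array([_LIGAND_RADIAL, 0, 0]))
_LIG_A_ACCEPTOR = _LIG_A_CENTROID + np.array([_ACC_OFFSET, 0.0, 0.0])

_BASE_RING_NAMES = [f"C{i}" for i in range(1, 7)]
_LABEL_ORDER = (
    InteractionLabel.TYPE_I,
    InteractionLabel.TYPE_II,
    InteractionLabel.HBOND_ONLY,
    InteractionLabel.PI_ONLY,
    InteractionLabel.NONE,
)


@dataclass
class ScenarioSpec:
    """Study conditions for a synthetic interaction trajectory.

    Defaults mirror the simulated systems the analysis targets: ~100
    Alq3-like molecules with a 20-mer single-stranded DNA, frames saved
    every 2 ps, and a label schedule dominated by plain ring stacking with
    rare multisite events (the thymine-strand regime).
    """

    n_alq3: int = 100
    sequence: str = "T" * 20
    fractions: dict[str, float] = field(
        default_factory=lambda: {
            "TypeI": 0.04,
            "TypeII": 0.02,
            "HbondOnly": 0.06,
            "PiOnly": 0.88,
        }
    )
    noise_sd: float = 0.0
    n_frames: int = 500
    dt: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.sequence or any(b not in "ATGC" for b in self.sequence):
            raise ConfigError("sequence must be a non-empty string over A/T/G/C")
        if self.n_frames < 1 or self.n_alq3 < 2 * len(self.sequence):
            raise ConfigError(
                "need n_frames >= 1 and n_alq3 >= 2 bases (each base uses a "
                "primary and a secondary Alq3 molecule)"
            )
        if self.noise_sd < 0 or self.dt <= 0:
            raise ConfigError("noise_sd must be >= 0 and dt > 0")
        vals = [self.fractions.get(lab.value, 0.0) for lab in _LABEL_ORDER[:4]]
        if any(v < 0 for v in vals) or sum(vals) > 1.0 + 1e-12:
            raise ConfigError("label fractions must be >= 0 and sum to <= 1")

    @property
    def label_probabilities(self) -> np.ndarray:
        p = np.array(
            [self.fractions.get(lab.value, 0.0) for lab in _LABEL_ORDER[:4]], dtype=float
        )
        return np.append(p, max(0.0, 1.0 - p.sum()))


def _site_origin(site: int) -> np.ndarray:
    return _SITE_SPACING * np.array(
        [site % 5, (site // 5) % 5, site // 25], dtype=float
    )


# orientation of the secondary molecule during TypeII frames: ligand-A axis
# -> -y, ring normal -> +x (vertical), so its rings stay outside both the
# vertical-separation and lateral-guard criteria of the stacked base.
_R_SECONDARY = np.array([[0.0, 0.0, 1.0], [-1.0, 0.0, 0.0], [0.0, -1.0, 0.0]])


def _base_atoms(label: InteractionLabel, c0: np.ndarray, a0: np.ndarray):
    """Base atom positions (ring C1..C6, ND, HD, OA) for one scheduled mode.

    c0/a0: primary molecule's ligand-A ring centroid and acceptor position.
    Returns (positions, secondary_acceptor_target or None).
    """
    z = np.array([0.0, 0.0, 1.0])
    x = np.array([1.0, 0.0, 0.0])
    y = np.array([0.0, 1.0, 0.0])
    sin10, cos10 = np.sin(np.deg2rad(_HB_ANGLE)), np.cos(np.deg2rad(_HB_ANGLE))
    sec_target = None
    if label is InteractionLabel.PI_ONLY:
        cb = c0 + _STACK_SEP * z
        ring = _hexagon(cb)
        nd = cb - _ACC_OFFSET * x  # away from the acceptor side
        hd = nd - 0.1 * x
        oa = cb + _ACC_OFFSET * y
    elif label is InteractionLabel.TYPE_I:
        cb = c0 + _STACK_SEP * z
        ring = _hexagon(cb)
        nd = a0 + _HB_DA * z  # D-A along -z, 0.29 nm
        hd = nd + 0.1 * (-cos10 * z + sin10 * x)  # H-D-A = 10 degrees
        oa = cb - _ACC_OFFSET * x
    elif label is InteractionLabel.HBOND_ONLY:
        nd = a0 + _HB_DA * x
        hd = nd + 0.1 * (-cos10 * x + sin10 * z)
        cb = nd + _STACK_SEP * x
        # vertical ring (normal = +x): built in the yz-plane around cb
        ring = np.stack(
            [np.zeros(6), np.cos(_HEX_ANGLES), np.sin(_HEX_ANGLES)], axis=1
        ) * _BOND + cb
        oa = cb + _ACC_OFFSET * y
    elif label is InteractionLabel.TYPE_II:
        cb = c0 + _STACK_SEP * z
        ring = _hexagon(cb)
        nd = cb + _ACC_OFFSET * y  # donor points away from the primary's acceptor
        hd = nd + 0.1 * (cos10 * y + sin10 * z)
        oa = cb - _ACC_OFFSET * y
        sec_target = nd + _HB_DA * y  # secondary molecule's acceptor goes here
    else:  # NONE: parked far above the site
        cb = c0 + 3.0 * z
        ring = _hexagon(cb)
        nd = cb + _ACC_OFFSET * x
        hd = nd + 0.1 * x
        oa = cb - _ACC_OFFSET * x
    return np.vstack([ring, nd, hd, oa]), sec_target


def synth_interaction_trajectory(
    spec: ScenarioSpec,
) -> tuple[Trajectory, pd.DataFrame]:
    """Generate a labeled trajectory; returns (trajectory, ground-truth table).

    The ground-truth table has one row per (frame, base_index) with the
    scheduled label and the Alq3 molecule ids involved. Base b interacts only
    with its two dedicated molecules (primary 2b, secondary 2b+1), each site
    isolated on a 4 nm grid, so with zero noise the scheduled label is exactly
    the label the contact classifier must recover.
    """
    rng = np.random.default_rng(spec.seed)
    n_bases = len(spec.sequence)
    n_alq = spec.n_alq3

    # ---- topology -------------------------------------------------------
    names: list[str] = []
    elements: list[str] = []
    resnames: list[str] = []
    resids: list[int] = []
    molids: list[int] = []
    for m in range(n_alq):
        names.extend(_ALQ_NAMES)
        elements.extend(_ALQ_ELEMENTS)
        resnames.extend(["ALQ"] * len(_ALQ_NAMES))
        resids.extend([m] * len(_ALQ_NAMES))
        molids.extend([m] * len(_ALQ_NAMES))
    base_resids = []
    for b, letter in enumerate(spec.sequence):
        rid = n_alq + b
        base_resids.append(rid)
        names.extend(_BASE_RING_NAMES + ["ND", "HD", "OA"])
        elements.extend(["C"] * 6 + ["N", "H", "O"])
        resnames.extend([f"S{letter}"] * 9)
        resids.extend([rid] * 9)
        molids.extend([n_alq] * 9)  # whole strand is one molecule
    topology = Topology(
        names=names,
        elements=elements,
        residue_names=resnames,
        residue_ids=resids,
        molecule_ids=molids,
    )
    n_atoms_alq = len(_ALQ_NAMES)
    n_atoms = len(names)

    # ---- static molecule poses -----------------------------------------
    base_pos = np.zeros((n_atoms, 3))
    sites = [_site_origin(b) for b in range(n_bases)]
    parked_secondary = [s + np.array([2.0, 2.0, 0.0]) for s in sites]
    for m in range(n_alq):
        if m < 2 * n_bases:
            b, role = divmod(m, 2)
            origin = sites[b] if role == 0 else parked_secondary[b]
        else:
            origin = _site_origin(n_bases + (m - 2 * n_bases))
        base_pos[m * n_atoms_alq : (m + 1) * n_atoms_alq] = _ALQ_POS + origin

    # ---- schedule -------------------------------------------------------
    probs = spec.label_probabilities
    draw = rng.choice(len(_LABEL_ORDER), size=(spec.n_frames, n_bases), p=probs)

    frames: list[Frame] = []
    truth_rows = []
    label_values = [lab for lab in _LABEL_ORDER]
    for fi in range(spec.n_frames):
        pos = base_pos.copy()
        for b in range(n_bases):
            label = label_values[draw[fi, b]]
            primary, secondary = 2 * b, 2 * b + 1
            origin = sites[b]
            c0 = origin + _LIG_A_CENTROID
            a0 = origin + _LIG_A_ACCEPTOR
            atoms, sec_target = _base_atoms(label, c0, a0)
            start = n_alq * n_atoms_alq + b * 9
            pos[start : start + 9] = atoms
            if sec_target is not None:
                # place the secondary molecule so its ligand-A acceptor lands
                # on the target with vertical ring planes
                acc_local = _R_SECONDARY @ _LIG_A_ACCEPTOR
                al2 = sec_target - acc_local
                s0 = secondary * n_atoms_alq
                pos[s0 : s0 + n_atoms_alq] = (_ALQ_POS @ _R_SECONDARY.T) + al2
            stack_partner = {
                InteractionLabel.TYPE_I: primary,
                InteractionLabel.TYPE_II: primary,
                InteractionLabel.PI_ONLY: primary,
            }.get(label)
            hbond_partner = {
                InteractionLabel.TYPE_I: primary,
                InteractionLabel.TYPE_II: secondary,
                InteractionLabel.HBOND_ONLY: primary,
            }.get(label)
            truth_rows.append(
                {
                    "frame": fi,
                    "base_index": b,
                    "base_residue_id": base_resids[b],
                    "label": label.value,
                    "stack_partner": stack_partner,
                    "hbond_partner": hbond_partner,
                }
            )
        if spec.noise_sd > 0:
            pos = pos + rng.normal(0.0, spec.noise_sd, size=pos.shape)
        frames.append(Frame(time=fi * spec.dt, positions=pos, topology=topology))
    truth = pd.DataFrame(truth_rows)
    return Trajectory(frames=frames, dt=spec.dt), truth


# ---------------------------------------------------------------------------
# umbrella sampling
# ---------------------------------------------------------------------------


@dataclass
class UmbrellaWindows:
    """Biased samples per harmonic window along a 1-D reaction coordinate."""

    centers: np.ndarray  # nm
    force_constant: float  # kJ/mol/nm^2
    samples: list[np.ndarray]  # one array per window, nm
    temperature: float = 298.15

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float)
        if len(self.centers) < 1:
            raise DataError("need >= 1 umbrella window")
        if len(self.samples) != len(self.centers):
            raise DataError("one sample array required per window")
        self.samples = [np.asarray(s, dtype=float) for s in self.samples]


def synth_umbrella_samples(
    potential: Callable[[np.ndarray], np.ndarray],
    n_windows: int = 40,
    spacing: float = 0.15,
    force_constant: float = 1000.0,
    n_samples: int = 50_000,
    temperature: float = 298.15,
    z_start: float = 0.5,
    seed: int = 0,
) -> UmbrellaWindows:
    """Draw exact biased samples from each umbrella window.

    Window i is centred at ``z_start + i * spacing``; samples follow the
    density proportional to exp(-[U(z) + k/2 (z - z_i)^2]/kT), drawn by
    inverse-CDF interpolation on a fine grid (no dynamics involved). The
    default window layout (40 windows, 0.15 nm spacing, k = 1000
    kJ mol^-1 nm^-2, 298.15 K) is the pulling protocol the binding-energy
    analysis assumes.
    """
    if n_samples < 1:
        raise DataError("n_samples must be >= 1")
    if n_windows < 2 or spacing <= 0 or force_constant <= 0 or temperature <= 0:
        raise ConfigError("invalid umbrella protocol parameters")
    rng = np.random.default_rng(seed)
    kt = KB * temperature
    centers = z_start + spacing * np.arange(n_windows)
    sigma = np.sqrt(kt / force_constant)
    samples = []
    for zc in centers:
        grid = np.linspace(zc - 8 * sigma, zc + 8 * sigma, 4001)
        u = np.asarray(potential(grid), dtype=float)
        if not np.all(np.isfinite(u)):
            raise DataError(f"potential non-finite inside window at {zc:.3f} nm")
        w = u + 0.5 * force_constant * (grid - zc) ** 2
        logp = -(w - w.min()) / kt
        p = np.exp(logp)
        cdf = np.concatenate([[0.0], np.cumsum((p[1:] + p[:-1]) * 0.5 * np.diff(grid))])
        cdf /= cdf[-1]
        # strictly increasing CDF for interpolation
        uq = rng.uniform(size=n_samples)
        samples.append(np.interp(uq, cdf, grid))
    return UmbrellaWindows(
        centers=centers,
        force_constant=force_constant,
        samples=samples,
        temperature=temperature,
    )


# ---------------------------------------------------------------------------
# photophysics inputs
# ---------------------------------------------------------------------------


def synth_spectrum(
    peaks: Sequence[tuple[float, float, float]],
    noise_sd: float = 0.0,
    grid: np.ndarray | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Sum-of-Gaussians emission spectrum (center nm, sd nm, area) plus noise.

    Returns (wavelength, intensity). Noise is proportional (Gaussian with sd
    = noise_sd x local intensity, e.g. 0.01 for 1% noise), matching the
    roughly intensity-proportional noise of PL detectors at these levels.
    """
    if not peaks:
        raise DataError("peak list is empty")
    for c, s, a in peaks:
        if s <= 0 or a <= 0:
            raise DataError("peak sd and area must be > 0")
    if grid is None:
        grid = np.arange(380.0, 701.0, 1.0)
    grid = np.asarray(grid, dtype=float)
    intensity = np.zeros_like(grid)
    for center, sd, area in peaks:
        amp = area / (sd * np.sqrt(2 * np.pi))
        intensity += amp * np.exp(-0.5 * ((grid - center) / sd) ** 2)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        intensity = intensity * (1.0 + rng.normal(0.0, noise_sd, size=grid.shape))
    return grid, intensity


def synth_waveguide_series(
    i0: float,
    alpha: float,
    distances: Sequence[float],
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Waveguided-emission decay I(d) = I0 exp(-alpha d) with multiplicative noise.

    distances in micrometres, alpha in um^-1; noise_sd is the sd of the
    log-normal multiplicative factor (0.02 for '2% noise').
    """
    d = np.asarray(distances, dtype=float)
    if np.any(d < 0):
        raise DataError("propagation distances must be >= 0")
    if alpha < 0:
        raise DataError("loss coefficient alpha must be >= 0")
    y = i0 * np.exp(-alpha * d)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y * np.exp(rng.normal(0.0, noise_sd, size=d.shape))
    return d, y
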