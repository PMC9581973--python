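"""Group-group nonbonded energies, WHAM, and binding-energy extraction.

The electrostatic sum is a plain cutoff-truncated pairwise Coulomb term (no
Ewald/PME), so absolute values are an approximation to lattice-summed
engine output; Lennard-Jones uses Lorentz-Berthelot combination. WHAM is
the standard self-consistent weighted-histogram iteration over harmonic
umbrella windows; the binding energy of a PMF curve is the span between its
highest and lowest states, reported negative for favourable binding.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .constants import COULOMB_CONSTANT, KB
from .errors import ConfigError, ConvergenceError, DataError
from .synthetic import UmbrellaWindows

log = logging.getLogger(__name__)

_SINGULARITY_R = 0.01  # nm


@dataclass
class NonbondedParams:
    """Per-atom partial charges (e) and LJ parameters (sigma nm, epsilon kJ/mol)."""

    charges: np.ndarray
    sigmas: np.ndarray
    epsilons: np.ndarray
    cutoff: float = 1.2

    def __post_init__(self) -> None:
        self.charges = np.asarray(self.charges, dtype=float)
        self.sigmas = np.asarray(self.sigmas, dtype=float)
        self.epsilons = np.asarray(self.epsilons, dtype=float)
        if np.any(self.sigmas <= 0) or np.any(self.epsilons < 0):
            raise ConfigError("require sigma > 0 and epsilon >= 0")
        if self.cutoff <= 0:
            raise ConfigError("cutoff must be > 0")


def _min_image(diff: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    if box is None:
        return diff
    return diff - box * np.round(diff / box)


def nonbonded_energy(
    positions: np.ndarray,
    group_a: np.ndarray,
    group_b: np.ndarray,
    params: NonbondedParams,
    box: np.ndarray | None = None,
) -> tuple[float, float]:
    """Cutoff-truncated (Coulomb, LJ) cross energy between two atom groups, kJ/mol."""
    group_a = np.asarray(group_a, dtype=int)
    group_b = np.asarray(group_b, dtype=int)
    if np.intersect1d(group_a, group_b).size:
        raise DataError("groups must be disjoint")
    pa, pb = positions[group_a], positions[group_b]
    diff = _min_image(pb[None, :, :] - pa[:, None, :], box)
    r = np.linalg.norm(diff, axis=-1)
    if np.any(r < _SINGULARITY_R):
        raise DataError(f"overlapping atoms (r < {_SINGULARITY_R} nm) in energy sum")
    mask = r <= params.cutoff
    if not np.any(mask):
        return 0.0, 0.0
    rr = r[mask]
    qq = np.outer(params.charges[group_a], params.charges[group_b])[mask]
    coulomb = COULOMB_CONSTANT * float(np.sum(qq / rr))
    sig = 0.5 * (
        params.sigmas[group_a][:, None] + params.sigmas[group_b][None, :]
    )[mask]
    eps = np.sqrt(
        params.epsilons[group_a][:, None] * params.epsilons[group_b][None, :]
    )[mask]
    sr6 = (sig / rr) ** 6
    lj = float(np.sum(4.0 * eps * (sr6**2 - sr6)))
    return coulomb, lj


@dataclass
class PmfCurve:
    """Potential of mean force on a reaction-coordinate grid, minimum at zero."""

    z: np.ndarray  # nm
    w: np.ndarray  # kJ/mol
    converged: bool = True
    n_iterations: int = 0

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.w = np.asarray(self.w, dtype=float)
        if self.z.shape != self.w.shape:
            raise DataError("z and w must have the same shape")
        finite = np.isfinite(self.w)
        if not np.any(finite):
            raise DataError("PMF has no finite values")
        self.w = self.w - np.nanmin(self.w[finite])


def wham(
    windows: UmbrellaWindows,
    bin_width: float = 0.02,
    tolerance: float = 1e-6,
    max_iter: int = 100_000,
    min_counts: int = 25,
) -> PmfCurve:
    """Self-consistent WHAM estimate of the unbiased PMF from umbrella windows.

    Iterates the window free energies f_i until the largest change is below
    ``tolerance`` (kJ/mol); the returned curve is shifted so min W = 0.

    All occupied bins drive the self-consistency, but the reported curve
    drops bins holding fewer than ``min_counts`` samples: -ln of a handful
    of counts carries > kT/5 of noise and such edge-bin spikes would corrupt
    max(W)-based quantities. Raises ConvergenceError with diagnostics if
    windows do not overlap enough to stitch.
    """
    if max_iter < 1 or bin_width <= 0 or tolerance < 0:
        raise ConfigError("require max_iter >= 1, bin_width > 0, tolerance >= 0")
    kt = KB * windows.temperature
    all_samples = np.concatenate(windows.samples)
    if all_samples.size == 0:
        raise DataError("umbrella windows contain no samples")
    lo, hi = all_samples.min(), all_samples.max()
    n_bins = max(int(np.ceil((hi - lo) / bin_width)), 1)
    edges = lo + bin_width * np.arange(n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])

    n_windows = len(windows.centers)
    n_i = np.asarray([len(s) for s in windows.samples], dtype=float)
    counts = np.zeros(n_bins)
    for s in windows.samples:
        counts += np.histogram(s, bins=edges)[0]
    # bias factor exp(-w_i(z_b)/kT), (windows x bins)
    bias = np.exp(
        -0.5
        * windows.force_constant
        * (centers[None, :] - windows.centers[:, None]) ** 2
        / kt
    )
    occupied = counts > 0
    f = np.zeros(n_windows)  # in kT units
    n_it = 0
    converged = False
    for n_it in range(1, max_iter + 1):
        denom = (n_i[:, None] * np.exp(f)[:, None] * bias).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(occupied & (denom > 0), counts / denom, 0.0)
        z_i = bias @ (p * bin_width)
        if np.any(z_i <= 0):
            raise ConvergenceError(
                "a window has zero overlap with the sampled histogram; "
                f"window centers span [{windows.centers.min():.3f}, "
                f"{windows.centers.max():.3f}] nm, samples "
                f"[{lo:.3f}, {hi:.3f}] nm"
            )
        f_new = -np.log(z_i)
        f_new -= f_new[0]
        delta = float(np.max(np.abs(f_new - f)) * kt)
        f = f_new
        if delta < tolerance:
            converged = True
            break
    if not converged:
        log.warning(
            "WHAM not converged after %d iterations (last |df| = %.3g kJ/mol)",
            n_it,
            delta,
        )
    denom = (n_i[:, None] * np.exp(f)[:, None] * bias).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(occupied & (denom > 0), counts / denom, np.nan)
        w = -kt * np.log(p)
    keep = np.isfinite(w) & (counts >= min_counts)
    if not np.any(keep):
        keep = np.isfinite(w)
    return PmfCurve(
        z=centers[keep], w=w[keep], converged=converged, n_iterations=n_it
    )


def boltzmann_inversion(
    samples: np.ndarray,
    bin_width: float = 0.02,
    temperature: float = 298.15,
    min_counts: int = 25,
) -> PmfCurve:
    """Direct -kT ln h(z) estimate from unbiased samples (the one-window limit)."""
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise DataError("no samples")
    lo, hi = samples.min(), samples.max()
    n_bins = max(int(np.ceil((hi - lo) / bin_width)), 1)
    edges = lo + bin_width * np.arange(n_bins + 1)
    counts = np.histogram(samples, bins=edges)[0].astype(float)
    centers = 0.5 * (edges[:-1] + edges[1:])
    keep = counts >= max(min_counts, 1)
    if not np.any(keep):
        keep = counts > 0
    kt = KB * temperature
    w = -kt * np.log(counts[keep])
    return PmfCurve(z=centers[keep], w=w)


@dataclass
class BindingEnergy:
    """Max-minus-min span of PMF curves, negative for favourable binding."""

    delta_g: float  # kJ/mol, <= 0
    replicate_values: np.ndarray
    sd: float
    flagged_flat: bool = False


def binding_energy_from_pmf(
    curves: "PmfCurve | Sequence[PmfCurve]",
) -> BindingEnergy:
    """Binding energy from one or more replicate PMF curves.

    The magnitude per curve is max(W) - min(W); replicates are combined as
    mean +/- sd over replicates (n-1 denominator, as replicate error bars
    are conventionally reported). A constant curve yields 0 with a flag.
    """
    if isinstance(curves, PmfCurve):
        curves = [curves]
    if not curves:
        raise DataError("no PMF curves supplied")
    spans = np.asarray([float(np.max(c.w) - np.min(c.w)) for c in curves])
    flagged = bool(np.all(spans == 0.0))
    if flagged:
        log.warning("PMF curve(s) are constant; binding energy reported as 0")
    return BindingEnergy(
        delta_g=-float(spans.mean()),
        replicate_values=-spans,
        sd=float(spans.std(ddof=1)) if len(spans) > 1 else 0.0,
        flagged_flat=flagged,
    )
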