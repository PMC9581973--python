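"""Spectral and optical reductions: Gaussian deconvolution, emission ratio,
FRET efficiency, waveguide loss fitting, and profile normalization.

The photoluminescence model is a sum of Gaussian emission bands on the
wavelength axis; the doping-degree proxy is the area ratio of the acceptor
band (~572 nm, Cy3) to the donor band (~512 nm, Alq3). Peak areas are
computed analytically as amplitude x sd x sqrt(2 pi).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.optimize import curve_fit
from scipy.signal import find_peaks

from .errors import ConvergenceError, DataError

log = logging.getLogger(__name__)

#: fallback three-band initialization: blue shoulder, Alq3 main band, Cy3 band (nm)
DEFAULT_PEAK_CENTERS = (450.0, 512.0, 572.0)
#: tolerance for matching a fitted peak to a requested band center (nm)
PEAK_MATCH_TOL = 15.0


@dataclass(frozen=True)
class GaussianPeak:
    center: float  # nm
    sd: float  # nm
    area: float

    @property
    def amplitude(self) -> float:
        return self.area / (self.sd * np.sqrt(2 * np.pi))


@dataclass
class GaussianPeakSet:
    """Fitted Gaussian bands, sorted by center, with fit diagnostics."""

    peaks: list[GaussianPeak]
    residual_rms: float
    converged: bool = True

    def __post_init__(self) -> None:
        self.peaks = sorted(self.peaks, key=lambda p: p.center)
        for p in self.peaks:
            if p.sd <= 0 or p.area < 0:
                raise DataError("fitted peak has sd <= 0 or negative area")


def _validate_spectrum(wavelength: np.ndarray, intensity: np.ndarray):
    wavelength = np.asarray(wavelength, dtype=float)
    intensity = np.asarray(intensity, dtype=float)
    if wavelength.ndim != 1 or wavelength.shape != intensity.shape:
        raise DataError("spectrum must be two equal-length 1-D arrays")
    if np.any(np.diff(wavelength) <= 0):
        raise DataError("wavelength grid must be strictly increasing")
    return wavelength, intensity


def _gauss_sum(x: np.ndarray, *params: float) -> np.ndarray:
    y = np.zeros_like(x)
    for i in range(0, len(params), 3):
        amp, center, sd = params[i : i + 3]
        y = y + amp * np.exp(-0.5 * ((x - center) / sd) ** 2)
    return y


def _initial_centers(
    wavelength: np.ndarray, intensity: np.ndarray, n_peaks: int
) -> list[float]:
    """Local maxima of a lightly smoothed spectrum; fall back to the
    standard three-band centers (or grid quantiles for other n_peaks)."""
    smooth = gaussian_filter1d(intensity, sigma=2.0)
    idx, props = find_peaks(smooth, prominence=0.01 * max(smooth.max(), 1e-12))
    centers = [wavelength[i] for i in idx]
    if len(centers) >= n_peaks:
        order = np.argsort(props["prominences"])[::-1][:n_peaks]
        return sorted(float(centers[i]) for i in order)
    if n_peaks == len(DEFAULT_PEAK_CENTERS):
        return list(DEFAULT_PEAK_CENTERS)
    qs = np.linspace(0.15, 0.85, n_peaks)
    return [float(np.quantile(wavelength, q)) for q in qs]


def deconvolve_pl(
    wavelength: np.ndarray,
    intensity: np.ndarray,
    n_peaks: int = 3,
    init_centers: list[float] | None = None,
    init_sd: float = 15.0,
) -> GaussianPeakSet:
    """Nonlinear least-squares fit of a sum of Gaussians to a PL spectrum."""
    wavelength, intensity = _validate_spectrum(wavelength, intensity)
    if wavelength.size < 3 * n_peaks:
        raise DataError(f"need >= {3 * n_peaks} grid points for {n_peaks} peaks")
    if intensity.max() <= 0:
        raise DataError("spectrum carries no positive signal to deconvolve")
    centers = list(init_centers) if init_centers else _initial_centers(
        wavelength, intensity, n_peaks
    )
    if len(centers) != n_peaks:
        raise DataError(f"got {len(centers)} initial centers for {n_peaks} peaks")
    span = float(wavelength[-1] - wavelength[0])
    tried = []
    for sd0 in (init_sd, 0.5 * init_sd, 2.0 * init_sd):
        p0, lower, upper = [], [], []
        for c in centers:
            amp0 = max(float(np.interp(c, wavelength, intensity)), 1e-9)
            p0 += [amp0, float(c), sd0]
            lower += [0.0, float(wavelength[0]), 0.1]
            upper += [np.inf, float(wavelength[-1]), span]
        tried.append(p0)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = curve_fit(
                    _gauss_sum,
                    wavelength,
                    intensity,
                    p0=p0,
                    bounds=(lower, upper),
                    maxfev=20_000,
                )
        except (RuntimeError, ValueError):
            continue
        resid = intensity - _gauss_sum(wavelength, *popt)
        peaks = [
            GaussianPeak(
                center=float(popt[i + 1]),
                sd=float(popt[i + 2]),
                area=float(popt[i] * popt[i + 2] * np.sqrt(2 * np.pi)),
            )
            for i in range(0, len(popt), 3)
        ]
        return GaussianPeakSet(
            peaks=peaks, residual_rms=float(np.sqrt(np.mean(resid**2)))
        )
    raise ConvergenceError(
        f"Gaussian deconvolution failed to converge; initializations tried: {tried}"
    )


def emission_ratio(
    peaks: GaussianPeakSet,
    num_center: float = 572.0,
    den_center: float = 512.0,
    match_tol: float = PEAK_MATCH_TOL,
) -> float:
    """Area ratio A(num)/A(den) of the bands nearest the requested centers."""

    def _match(target: float) -> GaussianPeak:
        best = min(peaks.peaks, key=lambda p: abs(p.center - target))
        if abs(best.center - target) > match_tol:
            raise DataError(
                f"no fitted peak within {match_tol} nm of {target} nm "
                f"(nearest at {best.center:.1f} nm)"
            )
        return best

    num, den = _match(num_center), _match(den_center)
    if den.area <= 0:
        raise DataError("denominator band has zero area")
    return num.area / den.area


def fret_efficiency(i_donor_alone: float, i_donor_with_acceptor: float) -> float:
    """E = 1 - I_DA / I_D from donor-band intensities with and without acceptor.

    Values outside [0, 1] (non-quenched donors) are returned as-is with a
    warning rather than clamped.
    """
    if i_donor_alone <= 0 or i_donor_with_acceptor < 0:
        raise DataError("donor intensities must be positive (I_DA may be 0)")
    e = 1.0 - i_donor_with_acceptor / i_donor_alone
    if not 0.0 <= e <= 1.0:
        warnings.warn(
            f"FRET efficiency {e:.3f} outside [0, 1]; check input ordering",
            stacklevel=2,
        )
    return e


@dataclass
class LossFit:
    """Exponential waveguide-loss fit I(d) = I0 exp(-alpha d)."""

    alpha: float  # um^-1
    i0: float
    flagged_nondecaying: bool = False


def optical_loss_fit(
    distances: np.ndarray,
    intensities: np.ndarray,
    multiplicative: bool = True,
) -> LossFit:
    """Fit the optical loss coefficient alpha from intensity vs distance.

    With ``multiplicative`` (default) residuals are minimised on the log
    scale, matching proportional waveguide noise; this makes the problem an
    exact linear regression of ln I on d. The linear-scale option runs
    nonlinear least squares initialized from the log-linear slope. A
    non-decaying series yields alpha = 0 with a flag.
    """
    d = np.asarray(distances, dtype=float)
    y = np.asarray(intensities, dtype=float)
    if d.ndim != 1 or d.shape != y.shape or d.size < 3:
        raise DataError("need >= 3 (distance, intensity) pairs")
    if np.any(np.diff(d) <= 0):
        raise DataError("distances must be strictly increasing")
    if np.any(y <= 0):
        raise DataError("intensities must be > 0 for exponential fitting")
    slope, intercept = np.polyfit(d, np.log(y), 1)
    alpha, i0 = -float(slope), float(np.exp(intercept))
    if not multiplicative:
        try:
            popt, _ = curve_fit(
                lambda x, a, b: b * np.exp(-a * x),
                d,
                y,
                p0=[max(alpha, 0.0), i0],
                maxfev=10_000,
            )
            alpha, i0 = float(popt[0]), float(popt[1])
        except RuntimeError as exc:
            raise ConvergenceError(f"exponential fit did not converge: {exc}") from exc
    if alpha < 0:
        log.warning("series does not decay (alpha = %.3g); reporting alpha = 0", alpha)
        return LossFit(alpha=0.0, i0=i0, flagged_nondecaying=True)
    return LossFit(alpha=alpha, i0=i0)


def normalize_profile(profile: np.ndarray, reference: float) -> np.ndarray:
    """Pointwise division of an intensity profile by a reference intensity.

    Self-normalization (reference = max of the profile) is idempotent; a
    reference from another profile may yield values above 1, which is
    allowed and flagged with a warning.
    """
    if reference <= 0:
        raise DataError("reference intensity must be > 0")
    out = np.asarray(profile, dtype=float) / reference
    if np.any(out > 1.0 + 1e-12):
        log.warning("normalized profile exceeds 1 (external reference)")
    return out
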