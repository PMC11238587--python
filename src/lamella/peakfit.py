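"""Parametric peak models and least-squares peak fitting.

Shared by the diffraction stage (Pearson VII Bragg peaks) and the FTIR
stage (Lorentzian vibrational bands).  Peaks are parameterised in the
amplitude/FWHM form: ``height`` is the value at ``center`` and ``width``
is the full width at half maximum.  Pearson VII carries an additional
shape exponent ``m``: ``m = 1`` is exactly a Lorentzian and ``m -> inf``
approaches a Gaussian.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import gammaln

from .datatypes import Spectrum1D

__all__ = [
    "PeakModel",
    "PeakFitResult",
    "evaluate_peak",
    "peak_area",
    "fit_peaks",
    "guess_peaks",
]

_SHAPES = ("lorentzian", "gaussian", "pearson7")


@dataclass(frozen=True)
class PeakModel:
    """A single analytic peak.

    Parameters
    ----------
    shape : {"lorentzian", "gaussian", "pearson7"}
    center : float
        Peak position in x-units.
    height : float
        Peak maximum in y-units; must be positive.
    width : float
        Full width at half maximum in x-units; must be positive.
    shape_exponent : float
        Pearson VII exponent ``m`` (ignored for the other shapes).
    """

    shape: str
    center: float
    height: float
    width: float
    shape_exponent: float = 1.0

    def __post_init__(self) -> None:
        if self.shape not in _SHAPES:
            raise ValueError(f"unknown peak shape {self.shape!r}")
        if not (self.height > 0):
            raise ValueError("peak height must be > 0")
        if not (self.width > 0):
            raise ValueError("peak width (FWHM) must be > 0")
        if self.shape == "pearson7" and not (self.shape_exponent > 0.5):
            raise ValueError("Pearson VII exponent must exceed 1/2")


@dataclass
class PeakFitResult:
    """Outcome of a multi-peak least-squares fit."""

    peaks: list[PeakModel]
    baseline: np.ndarray  # polynomial coefficients, highest degree first
    residual_rms: float
    areas: list[float] = field(default_factory=list)
    success: bool = True
    message: str = ""

    def __post_init__(self) -> None:
        if not self.areas:
            self.areas = [peak_area(p) for p in self.peaks]


def evaluate_peak(model: PeakModel, x) -> np.ndarray:
    """Evaluate a peak model on ``x``; the maximum at ``center`` equals ``height``."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("x contains non-finite values")
    u = (x - model.center) / model.width
    if model.shape == "lorentzian":
        return model.height / (1.0 + 4.0 * u * u)
    if model.shape == "gaussian":
        return model.height * np.exp(-4.0 * np.log(2.0) * u * u)
    m = model.shape_exponent
    return model.height * (1.0 + 4.0 * (2.0 ** (1.0 / m) - 1.0) * u * u) ** (-m)


def peak_area(model: PeakModel) -> float:
    """Analytic integral of the peak over the whole real line."""
    h, w = model.height, model.width
    if model.shape == "lorentzian":
        return 0.5 * np.pi * h * w
    if model.shape == "gaussian":
        return 0.5 * h * w * np.sqrt(np.pi / np.log(2.0))
    m = model.shape_exponent
    # Pearson VII: h*w * sqrt(pi) * Gamma(m-1/2) / (2*sqrt(2^(1/m)-1) * Gamma(m))
    lg = gammaln(m - 0.5) - gammaln(m)
    return h * w * np.sqrt(np.pi) * np.exp(lg) / (2.0 * np.sqrt(2.0 ** (1.0 / m) - 1.0))


def guess_peaks(spectrum: Spectrum1D, shape: str = "lorentzian",
                max_peaks: int | None = None) -> list[PeakModel]:
    """Deterministic local-maxima initial guess.

    Maxima must rise more than three median absolute deviations above the
    median to count.  Widths are seeded from the half-maximum crossings.
    """
    from scipy.signal import find_peaks, peak_widths

    x, y = np.asarray(spectrum.x, float), np.asarray(spectrum.y, float)
    mad = np.median(np.abs(y - np.median(y)))
    prominence = max(3.0 * mad, 1e-12)
    idx, _ = find_peaks(y, prominence=prominence)
    if idx.size == 0:
        return []
    widths, _, _, _ = peak_widths(y, idx, rel_height=0.5)
    dx = np.median(np.diff(x)) if x.size > 1 else 1.0
    order = np.argsort(y[idx])[::-1]
    if max_peaks is not None:
        order = order[:max_peaks]
    models = []
    for k in sorted(order, key=lambda k: x[idx[k]]):
        i = idx[k]
        w = max(widths[k] * abs(dx), abs(dx))
        models.append(PeakModel(shape, float(x[i]), float(max(y[i], 1e-12)), float(w)))
    return models


def _pack(peaks: list[PeakModel], nbase: int, base0: np.ndarray) -> np.ndarray:
    p = []
    for pk in peaks:
        p.extend([pk.center, pk.height, pk.width])
        if pk.shape == "pearson7":
            p.append(pk.shape_exponent)
    return np.concatenate([np.asarray(p, float), base0])


def fit_peaks(spectrum: Spectrum1D, initial: list[PeakModel] | None = None,
              window: tuple[float, float] | None = None,
              baseline_order: int = 1,
              merge_tol: float = 1e-3) -> PeakFitResult:
    """Fit a sum of peaks plus a polynomial baseline by bounded least squares.

    Centers are bounded to the fitting window and widths to positive values
    so peaks cannot swap or collapse; two peaks that nevertheless converge
    onto one center (within ``merge_tol`` of the window span) are merged
    with a warning.  Non-convergence is flagged on the result rather than
    raised.
    """
    from scipy.optimize import least_squares

    x = np.asarray(spectrum.x, float)
    y = np.asarray(spectrum.y, float)
    if window is not None:
        lo, hi = min(window), max(window)
        mask = (x >= lo) & (x <= hi)
        x, y = x[mask], y[mask]
    if x.size == 0:
        raise ValueError("empty fitting window")
    lo, hi = float(x.min()), float(x.max())
    span = max(hi - lo, np.finfo(float).tiny)

    if initial is None:
        initial = guess_peaks(Spectrum1D(x, y))
    if not initial:
        base = np.polyfit(x, y, min(baseline_order, x.size - 1))
        resid = y - np.polyval(base, x)
        return PeakFitResult([], base, float(np.sqrt(np.mean(resid**2))), areas=[0.0][:0])

    nfree = sum(3 + (pk.shape == "pearson7") for pk in initial) + baseline_order + 1
    if x.size < 5 * nfree:
        raise ValueError(
            f"window holds {x.size} points for {nfree} free parameters; "
            "need at least 5 per parameter")

    # rescale initial heights to the data range so the starting point (and
    # hence the fit) is equivariant under y-scaling of the spectrum
    yscale = max(float(np.max(y) - np.min(y)), np.finfo(float).tiny)
    init_max = max(sum(evaluate_peak(pk, np.array([pk.center]))[0]
                       for pk in initial), np.finfo(float).tiny)
    hscale = yscale / init_max
    initial = [replace(pk, height=pk.height * hscale) for pk in initial]

    shapes = [pk.shape for pk in initial]
    base0 = np.zeros(baseline_order + 1)
    base0[-1] = float(np.min(y))
    p0, lb, ub = [], [], []
    for pk in initial:
        p0 += [np.clip(pk.center, lo, hi), pk.height, pk.width]
        lb += [lo, 1e-12 * yscale, 1e-6 * span]
        ub += [hi, np.inf, 10.0 * span]
        if pk.shape == "pearson7":
            p0.append(pk.shape_exponent)
            lb.append(0.51)
            ub.append(200.0)
    p0 += list(base0)
    lb += [-np.inf] * base0.size
    ub += [np.inf] * base0.size

    def unpack(p):
        peaks, i = [], 0
        for s in shapes:
            c, h, w = p[i], p[i + 1], p[i + 2]
            i += 3
            m = 1.0
            if s == "pearson7":
                m = p[i]
                i += 1
            peaks.append(PeakModel(s, float(c), float(max(h, 1e-300)),
                                   float(max(w, 1e-300)), float(m)))
        return peaks, p[i:]

    def resid(p):
        peaks, base = unpack(p)
        model = np.polyval(base, x)
        for pk in peaks:
            model = model + evaluate_peak(pk, x)
        return model - y

    sol = least_squares(resid, np.asarray(p0, float), bounds=(lb, ub),
                        xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=20000)
    peaks, base = unpack(sol.x)

    # merge peaks whose centers coincide
    merged: list[PeakModel] = []
    for pk in sorted(peaks, key=lambda p: p.center):
        if merged and abs(pk.center - merged[-1].center) < merge_tol * span:
            prev = merged[-1]
            warnings.warn("two peaks converged to the same center; merged",
                          stacklevel=2)
            merged[-1] = replace(prev, height=prev.height + pk.height)
        else:
            merged.append(pk)

    rms = float(np.sqrt(np.mean(sol.fun**2)))
    msg = "" if sol.success else f"optimizer did not converge: {sol.message}"
    return PeakFitResult(merged, base, rms, success=bool(sol.success), message=msg)
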