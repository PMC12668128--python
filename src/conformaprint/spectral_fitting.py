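"""Lorentzian deconvolution of 1D spectra and state populations.

A processed 1D spectrum (e.g. a 19F titration point) is modelled as a sum of
1-3 Lorentzian peaks plus an optional constant baseline.  Peak areas are the
physically meaningful quantity: the relative populations of the wobble and
anionic (and occasionally a third) state are the ratios of the fitted peak
integrals.

Each Lorentzian is parameterized by (center, fwhm, area):

    L(x) = (area / pi) * (fwhm/2) / ((x - center)**2 + (fwhm/2)**2)

so that the integral over the full line equals ``area`` exactly and the peak
height is ``2*area / (pi*fwhm)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit


class FitConvergenceError(RuntimeError):
    """Nonlinear least squares failed; carries the residual report."""


@dataclass
class Spectrum:
    """1D spectrum on a chemical-shift axis (ppm)."""

    axis: np.ndarray
    intensity: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.axis.shape != self.intensity.shape:
            raise ValueError("axis and intensity must have the same shape")
        d = np.diff(self.axis)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("axis must be strictly monotone")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensities must be finite")


@dataclass
class LorentzianPeak:
    center: float
    fwhm: float
    area: float
    assignment: str = "other"

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise ValueError("fwhm must be > 0")
        if self.area <= 0:
            raise ValueError("area must be > 0")

    @property
    def amplitude(self) -> float:
        """Peak height at the center."""
        return 2.0 * self.area / (math.pi * self.fwhm)


@dataclass
class StatePopulations:
    p_wobble: float
    p_anion: float
    p_other: float = 0.0
    sigma_wobble: float = 0.0
    sigma_anion: float = 0.0
    sigma_other: float = 0.0

    def __post_init__(self) -> None:
        total = self.p_wobble + self.p_anion + self.p_other
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"populations must sum to 1, got {total}")
        for p in (self.p_wobble, self.p_anion, self.p_other):
            if not -1e-12 <= p <= 1 + 1e-12:
                raise ValueError("populations must lie in [0, 1]")


def lorentzian(x: np.ndarray, center: float, fwhm: float, area: float) -> np.ndarray:
    hw = fwhm / 2.0
    return (area / math.pi) * hw / ((x - center) ** 2 + hw**2)


def peak_area(peak: LorentzianPeak) -> float:
    """Closed-form integral of the peak; equals amplitude*pi*fwhm/2."""
    return peak.amplitude * math.pi * peak.fwhm / 2.0


def _model(x: np.ndarray, params: np.ndarray, n_peaks: int, baseline: bool) -> np.ndarray:
    y = np.zeros_like(x)
    for i in range(n_peaks):
        c, w, a = params[3 * i : 3 * i + 3]
        y += lorentzian(x, c, w, a)
    if baseline:
        y += params[-1]
    return y


def median_filter_baseline(intensity: np.ndarray, window: int = 101) -> np.ndarray:
    """Rolling-median baseline estimate (pre-corrector for sloped spectra)."""
    from scipy.ndimage import median_filter

    window = min(window, len(intensity) | 1)
    return median_filter(intensity, size=window, mode="nearest")


def _pick_peaks(spectrum: Spectrum, n_peaks: int) -> list[tuple[float, float, float]]:
    """Deterministic initialization: local maxima above 5x the noise MAD."""
    x, y = spectrum.axis, spectrum.intensity
    noise = 1.4826 * np.median(np.abs(np.diff(y))) / math.sqrt(2)
    from scipy.signal import find_peaks

    span = abs(x[-1] - x[0])
    idx, props = find_peaks(y, height=max(5 * noise, 1e-30))
    order = np.argsort(props["peak_heights"])[::-1]
    idx = idx[order][:n_peaks]
    guesses = []
    for i in idx:
        amp = y[i]
        # half-height width from the nearest crossings
        above = y >= amp / 2
        lo = i
        while lo > 0 and above[lo - 1]:
            lo -= 1
        hi = i
        while hi < len(y) - 1 and above[hi + 1]:
            hi += 1
        fwhm = max(abs(x[hi] - x[lo]), span / len(x))
        guesses.append((x[i], fwhm, amp * math.pi * fwhm / 2))
    # pad with evenly spread guesses if peak picking found too few
    while len(guesses) < n_peaks:
        frac = (len(guesses) + 1) / (n_peaks + 1)
        c = x[0] + frac * (x[-1] - x[0])
        guesses.append((c, span / 20, max(y.max(), 1e-12) * span / 40))
    return guesses


def fit_lorentzians(
    spectrum: Spectrum,
    n_peaks: int,
    init: Sequence[LorentzianPeak] | None = None,
    baseline: bool = False,
) -> tuple[list[LorentzianPeak], np.ndarray]:
    """Fit ``n_peaks`` Lorentzians (plus optional constant baseline).

    Returns the fitted peaks and the parameter covariance matrix, ordered
    (center, fwhm, area) per peak then the baseline term if requested.
    Parameter uncertainties are the square roots of the covariance diagonal.
    """
    if not 1 <= n_peaks <= 3:
        raise ValueError("n_peaks must be in 1..3")
    x, y = spectrum.axis, spectrum.intensity
    if len(x) < 10:
        raise ValueError("spectrum must have at least 10 points")

    if init is not None:
        guesses = [(p.center, p.fwhm, p.area) for p in init]
    else:
        guesses = _pick_peaks(spectrum, n_peaks)
    p0 = [v for g in guesses for v in g]
    if baseline:
        p0.append(float(np.median(y)))

    span = abs(x[-1] - x[0])
    lo, hi = [], []
    for _ in range(n_peaks):
        lo += [min(x[0], x[-1]) - span, 1e-6 * span, 1e-30]
        hi += [max(x[0], x[-1]) + span, 10 * span, np.inf]
    if baseline:
        lo.append(-np.inf)
        hi.append(np.inf)
    p0 = np.clip(p0, lo, hi)

    def f(x, *params):
        return _model(x, np.asarray(params), n_peaks, baseline)

    try:
        popt, pcov = curve_fit(f, x, y, p0=p0, bounds=(lo, hi), maxfev=20000)
    except RuntimeError as exc:
        resid = float(np.sum((y - _model(x, np.asarray(p0), n_peaks, baseline)) ** 2))
        raise FitConvergenceError(
            f"Lorentzian fit did not converge (initial SSR {resid:.3g}): {exc}"
        ) from exc

    peaks = [
        LorentzianPeak(center=popt[3 * i], fwhm=popt[3 * i + 1], area=popt[3 * i + 2])
        for i in range(n_peaks)
    ]
    return peaks, pcov


def populations_from_peaks(
    peaks: Sequence[LorentzianPeak],
    covariance: np.ndarray | None = None,
) -> StatePopulations:
    """Populations as ratios of peak integrals, with first-order errors.

    Peaks must carry ``assignment`` labels; at least one must be "wobble" or
    "anion".  Uncertainties are propagated from the fit covariance of the
    area parameters (indices 3i+2) when given.
    """
    if not any(p.assignment in ("wobble", "anion") for p in peaks):
        raise ValueError("at least one peak must be assigned wobble or anion")
    areas = np.array([p.area for p in peaks], dtype=float)
    total = areas.sum()
    if total <= 0:
        raise ValueError("all peak areas are zero")
    fracs = areas / total

    sigmas = np.zeros(len(peaks))
    if covariance is not None:
        n = len(peaks)
        area_idx = [3 * i + 2 for i in range(n)]
        cov_a = np.asarray(covariance)[np.ix_(area_idx, area_idx)]
        # d p_i / d a_j = (delta_ij - p_i) / total
        jac = (np.eye(n) - fracs[:, None]) / total
        var = np.einsum("ij,jk,ik->i", jac, cov_a, jac)
        sigmas = np.sqrt(np.clip(var, 0, None))

    out = {"wobble": (0.0, 0.0), "anion": (0.0, 0.0), "other": (0.0, 0.0)}
    for p, f_, s in zip(peaks, fracs, sigmas):
        key = p.assignment if p.assignment in out else "other"
        prev = out[key]
        out[key] = (prev[0] + f_, math.hypot(prev[1], s))
    return StatePopulations(
        p_wobble=out["wobble"][0],
        p_anion=out["anion"][0],
        p_other=out["other"][0],
        sigma_wobble=out["wobble"][1],
        sigma_anion=out["anion"][1],
        sigma_other=out["other"][1],
    )


def select_peak_count(
    spectrum: Spectrum, max_peaks: int = 3, baseline: bool = False
) -> tuple[int, bool]:
    """Choose the number of peaks by BIC.

    Returns (count, confident).  The count is the smallest model whose BIC is
    within 2 of the minimum.  ``confident`` is False when no model beats a
    flat (noise-only) description — e.g. pure-noise input, where the returned
    count falls back to 1.
    """
    x, y = spectrum.axis, spectrum.intensity
    n = len(x)
    bics = {}
    for k in range(1, max_peaks + 1):
        try:
            peaks, _ = fit_lorentzians(spectrum, k, baseline=baseline)
        except (FitConvergenceError, ValueError):
            continue
        params = [v for p in peaks for v in (p.center, p.fwhm, p.area)]
        resid = y - _model(x, np.asarray(params), k, False)
        rss = float(np.sum(resid**2))
        n_par = 3 * k + (1 if baseline else 0)
        bics[k] = n * math.log(max(rss, 1e-300) / n) + n_par * math.log(n)
    if not bics:
        raise FitConvergenceError("no peak-count model converged")
    flat_rss = float(np.sum((y - y.mean()) ** 2))
    bic_flat = n * math.log(max(flat_rss, 1e-300) / n) + math.log(n)
    best = min(bics.values())
    chosen = min(k for k, b in bics.items() if b <= best + 2)
    confident = best < bic_flat - 2
    if not confident:
        chosen = 1
    return chosen, confident


def read_xy(path) -> Spectrum:
    """Read a 2-column delimited (x, y) text file with one header line."""
    arr = np.loadtxt(path, skiprows=1, delimiter=None)
    return Spectrum(axis=arr[:, 0], intensity=arr[:, 1])


def write_xy(path, spectrum: Spectrum, header: str = "ppm\tintensity") -> None:
    np.savetxt(
        path,
        np.column_stack([spectrum.axis, spectrum.intensity]),
        header=header,
        comments="",
        delimiter="\t",
    )
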