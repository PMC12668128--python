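"""Two-state UV melting of a non-self-complementary DNA duplex.

Absorbance at 260 nm versus temperature is modelled as a population-weighted
average of two sloped baselines,

    A260(T) = (m_ss*T + b_ss) * p_ss + (m_ds*T + b_ds) * p_ds,

with the single-strand fraction given by the two-state duplex <-> strands
equilibrium

    x    = exp(-(1/Tm - 1/T) * dH / R)
    p_ss = (sqrt(1 + 8x) - 1) / (4x),     p_ds = 1 - p_ss,

where dH is the standard enthalpy of melting (positive) and Tm the melting
temperature (p_ss(Tm) = 1/2 exactly).  Entropy and free energy follow from
dS = dH/Tm - R*ln(C_total/2) and dG(T) = dH - T*dS, with R = 1.987e-3
kcal/mol/K and C_total the total duplex concentration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .titration_pka import R_KCAL

T25_K = 298.15


@dataclass
class MeltingCurve:
    T: np.ndarray  # kelvin, monotone increasing
    A260: np.ndarray
    replicate: str = "rep1"

    def __post_init__(self) -> None:
        self.T = np.asarray(self.T, dtype=float)
        self.A260 = np.asarray(self.A260, dtype=float)
        if len(self.T) < 20:
            raise ValueError("melting curve needs at least 20 points")
        if not np.all(np.diff(self.T) > 0):
            raise ValueError("temperature axis must be strictly increasing")


@dataclass
class MeltingFit:
    Tm: float
    dH: float
    dS: float
    dG25: float
    m_ss: float
    b_ss: float
    m_ds: float
    b_ds: float
    C_total: float
    sigma_Tm: float = 0.0
    sigma_dH: float = 0.0
    sigma_dS: float = 0.0
    sigma_dG25: float = 0.0
    n_replicates: int = 1


def single_strand_fraction(T, Tm: float, dH: float) -> np.ndarray:
    """p_ss(T) from the two-state equilibrium; overflow-guarded."""
    T = np.asarray(T, dtype=float)
    expo = -(1.0 / Tm - 1.0 / T) * dH / R_KCAL
    x = np.exp(np.clip(expo, -700.0, 700.0))
    small = x < 1e-8
    with np.errstate(over="ignore"):
        p = np.where(
            small,
            1.0 - 2.0 * x,  # series limit of the closed form as x -> 0
            (np.sqrt(1.0 + 8.0 * x) - 1.0) / (4.0 * np.where(small, 1.0, x)),
        )
    return p


def melting_model(
    T,
    Tm: float,
    dH: float,
    m_ss: float,
    b_ss: float,
    m_ds: float,
    b_ds: float,
) -> np.ndarray:
    """A260(T) for the two-state model with sloped baselines."""
    T = np.asarray(T, dtype=float)
    p_ss = single_strand_fraction(T, Tm, dH)
    return (m_ss * T + b_ss) * p_ss + (m_ds * T + b_ds) * (1.0 - p_ss)


def entropy_from_tm(
    dH: float, Tm: float, C_total: float, convention: str = "printed"
) -> float:
    """dS (kcal/mol/K) of melting from dH, Tm and total duplex concentration.

    ``convention="printed"`` uses dS = dH/Tm - R*ln(C_total/2).  The
    two-state p_ss model is internally consistent with the opposite sign on
    the concentration term (dS = dH/Tm + R*ln(C_total/2)), available as
    ``convention="model"``; see the methods note for the derivation.
    """
    if dH <= 0 or Tm <= 0 or C_total <= 0:
        raise ValueError("dH, Tm and C_total must be positive")
    term = R_KCAL * math.log(C_total / 2.0)
    if convention == "printed":
        return dH / Tm - term
    if convention == "model":
        return dH / Tm + term
    raise ValueError(f"unknown convention {convention!r}")


def free_energy_at(dH: float, dS: float, T: float = T25_K) -> float:
    """dG(T) = dH - T*dS (kcal/mol); defaults to 25 degC (298.15 K)."""
    return dH - T * dS


def _detect_transition(curve: MeltingCurve) -> float:
    """Tm guess from the peak of the smoothed derivative; raises if absent."""
    T, A = curve.T, curve.A260
    n = len(T)
    k = max(n // 20, 2)
    dA = np.gradient(A, T)
    # moving-average smoothing of the derivative
    kern = np.ones(k) / k
    sm = np.convolve(dA, kern, mode="same")
    interior = slice(k, n - k)
    i = int(np.argmax(np.abs(sm[interior]))) + k
    # baseline slope estimate from the curve ends
    edge_slope = 0.5 * (abs(sm[:k].mean()) + abs(sm[-k:].mean()))
    amp = A.max() - A.min()
    if abs(sm[i]) < 3.0 * edge_slope + 1e-12 or abs(sm[i]) * (T[-1] - T[0]) < 0.1 * amp:
        raise ValueError("no sigmoid melting transition detected")
    return float(T[i])


def fit_melting(
    curve: MeltingCurve, C_total: float = 3e-6, dH_init: float = 70.0
) -> MeltingFit:
    """Nonlinear least squares over (Tm, dH, four baseline coefficients)."""
    T, A = curve.T, curve.A260
    Tm0 = _detect_transition(curve)
    n = len(T)
    k = max(n // 6, 3)
    lo_fit = np.polyfit(T[:k], A[:k], 1)
    hi_fit = np.polyfit(T[-k:], A[-k:], 1)
    p0 = [Tm0, dH_init, hi_fit[0], hi_fit[1], lo_fit[0], lo_fit[1]]
    bounds = (
        [T[0], 1.0, -np.inf, -np.inf, -np.inf, -np.inf],
        [T[-1], 400.0, np.inf, np.inf, np.inf, np.inf],
    )
    popt, _ = curve_fit(melting_model, T, A, p0=p0, bounds=bounds, maxfev=20000)
    Tm, dH, m_ss, b_ss, m_ds, b_ds = popt
    dS = entropy_from_tm(dH, Tm, C_total)
    return MeltingFit(
        Tm=float(Tm), dH=float(dH), dS=float(dS),
        dG25=float(free_energy_at(dH, dS)),
        m_ss=float(m_ss), b_ss=float(b_ss), m_ds=float(m_ds), b_ds=float(b_ds),
        C_total=C_total,
    )


def aggregate_replicates(fits: list[MeltingFit]) -> MeltingFit:
    """Mean +/- SD of (Tm, dH, dS, dG25) across >=1 replicate fits."""
    if not fits:
        raise ValueError("no replicate fits to aggregate")
    tm = np.array([f.Tm for f in fits])
    dh = np.array([f.dH for f in fits])
    ds = np.array([f.dS for f in fits])
    dg = np.array([f.dG25 for f in fits])
    sd = (lambda a: float(a.std(ddof=1)) if len(a) > 1 else 0.0)
    f0 = fits[0]
    return MeltingFit(
        Tm=float(tm.mean()), dH=float(dh.mean()), dS=float(ds.mean()),
        dG25=float(dg.mean()),
        m_ss=f0.m_ss, b_ss=f0.b_ss, m_ds=f0.m_ds, b_ds=f0.b_ds,
        C_total=f0.C_total,
        sigma_Tm=sd(tm), sigma_dH=sd(dh), sigma_dS=sd(ds), sigma_dG25=sd(dg),
        n_replicates=len(fits),
    )


def equilibrium_p_ss_oracle(T: float, Tm: float, dH: float, C_total: float) -> float:
    """Independent mass-action check: duplex <-> 2 strands by root finding.

    Solves p**2 * C / (1 - p) = K_melt(T) with the van 't Hoff constant
    implied by the closed-form model, K_melt(T) = (C/2) * exp((1/Tm - 1/T)
    * dH / R), using Brent's method.  Used only as a test oracle.
    """
    from scipy.optimize import brentq

    K = (C_total / 2.0) * math.exp((1.0 / Tm - 1.0 / T) * dH / R_KCAL)

    def g(p):
        return p * p * C_total / (1.0 - p) - K

    return brentq(g, 1e-16, 1.0 - 1e-16, xtol=1e-15, rtol=8.9e-16)
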