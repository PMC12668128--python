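"""Apparent-pKa analysis of a two-state wobble/anion titration.

The wobble <-> anionic equilibrium of a G.T (or G.5F-dU) mismatch follows the
Henderson-Hasselbalch relation; the pH at which both states are equally
populated defines the apparent pKa of the mismatch in its trinucleotide
context.  This module converts state populations to pKa values and free
energies, quantifies 5'/3' nearest-neighbor additivity via thermodynamic
mutation cycles, tests purine/pyrimidine partitions with an exact rank-sum
test, and regresses one per-context fingerprint against another.

Free energies use R = 1.987e-3 kcal/mol/K and the two-state relation
dG = R*T*ln(10)*(pKa - pH), so dG > 0 when the anion is the minor state.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .contexts import BASES, TripletContext

#: Gas constant in kcal/mol/K.
R_KCAL = 1.987e-3

#: Default temperature: titrations measured at 1 degC.
T_DEFAULT_K = 274.15


@dataclass
class PKaRecord:
    context: TripletContext
    pKa_app: float
    sigma: float = 0.0
    pH_points_used: int = 1

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


@dataclass
class FreeEnergyRecord:
    context: TripletContext
    dG: float
    ddG: float
    sigma: float = 0.0


@dataclass
class AdditivityCycle:
    """One rectangle in the 4x4 (5'-base x 3'-base) table.

    ``reference`` -> ``double`` changes both neighbors; the two ``singles``
    change one each.  Additivity predicts the double perturbation equals the
    sum of the single ones.
    """

    reference: TripletContext
    double: TripletContext
    single_five: TripletContext
    single_three: TripletContext
    predicted: float
    observed: float

    @property
    def deviation(self) -> float:
        return self.observed - self.predicted


def pka_from_population(pH: float, p_anion: float) -> float:
    """pKa_app = pH - log10(p_anion / (1 - p_anion))."""
    if not 0.0 < p_anion < 1.0:
        raise ValueError(
            f"p_anion must be strictly inside (0, 1); got {p_anion} "
            "(titration point out of range)"
        )
    return pH - math.log10(p_anion / (1.0 - p_anion))


def population_at_pH(pKa_app: float, pH: float):
    """Anion fraction p = 1 / (1 + 10**(pKa - pH))."""
    return 1.0 / (1.0 + 10.0 ** (np.asarray(pKa_app) - pH))


def aggregate_pka(
    points: list[tuple[float, float, float]], context: TripletContext | None = None
) -> PKaRecord:
    """Inverse-variance-weighted pKa over multiple (pH, p_anion, sigma_p) points.

    Per-point pKa uncertainties are first-order propagated from sigma_p:
    d pKa / d p = -1 / (ln10 * p * (1-p)).
    """
    values, sigmas = [], []
    for pH, p, sp in points:
        if not 0.0 < p < 1.0:
            continue
        values.append(pka_from_population(pH, p))
        sigmas.append(abs(sp) / (math.log(10) * p * (1 - p)))
    if not values:
        raise ValueError("no usable titration points (all populations at 0 or 1)")
    values = np.asarray(values)
    sigmas = np.asarray(sigmas)
    if np.any(sigmas <= 0):
        # unweighted mean when any point claims zero uncertainty
        mean = float(values.mean())
        sd = float(values.std(ddof=1)) if len(values) > 1 else 0.0
        return PKaRecord(context, mean, sd, len(values))
    w = 1.0 / sigmas**2
    mean = float(np.sum(w * values) / np.sum(w))
    sigma = float(1.0 / math.sqrt(np.sum(w)))
    return PKaRecord(context, mean, sigma, len(values))


def free_energy(pKa_app: float, pH: float, T_kelvin: float = T_DEFAULT_K):
    """dG (kcal/mol) to form the anion at this pH; > 0 when anion is minor."""
    if T_kelvin <= 0:
        raise ValueError("temperature must be positive")
    return R_KCAL * T_kelvin * math.log(10) * (np.asarray(pKa_app) - pH)


def delta_table(
    values: dict[TripletContext, tuple[float, float]],
    reference: TripletContext,
) -> dict[TripletContext, tuple[float, float]]:
    """Per-context deltas vs a reference context, sigma added in quadrature."""
    if reference not in values:
        raise ValueError(f"reference context {reference.label} missing from table")
    ref_v, ref_s = values[reference]
    out = {}
    for ctx, (v, s) in values.items():
        if ctx == reference:
            out[ctx] = (0.0, 0.0)
        else:
            out[ctx] = (v - ref_v, math.hypot(s, ref_s))
    return out


def enumerate_additivity_cycles(
    table: dict[TripletContext, float]
) -> list[AdditivityCycle]:
    """All 72 mutation cycles of a full 4x4 table.

    Every unordered pair of 5' bases crossed with every unordered pair of 3'
    bases gives 36 rectangles; each rectangle is traversed along both
    diagonals (two reference->double orientations), giving 72 cycles.
    """
    missing = [
        (z, w) for z in BASES for w in BASES if TripletContext(z, w) not in table
    ]
    if missing:
        raise ValueError(f"table is missing contexts: {missing}")
    cycles = []
    for z1, z2 in itertools.combinations(BASES, 2):
        for w1, w2 in itertools.combinations(BASES, 2):
            for ref_z, dbl_z, ref_w, dbl_w in (
                (z1, z2, w1, w2),
                (z1, z2, w2, w1),
            ):
                ref = TripletContext(ref_z, ref_w)
                dbl = TripletContext(dbl_z, dbl_w)
                s5 = TripletContext(dbl_z, ref_w)
                s3 = TripletContext(ref_z, dbl_w)
                predicted = (table[s5] - table[ref]) + (table[s3] - table[ref])
                observed = table[dbl] - table[ref]
                cycles.append(AdditivityCycle(ref, dbl, s5, s3, predicted, observed))
    return cycles


def additivity_summary(
    cycles: list[AdditivityCycle],
) -> tuple[float, float, float, float]:
    """(rmsd of deviations, pearson r, OLS slope, intercept) of predicted vs observed."""
    if len(cycles) < 3:
        raise ValueError("need at least 3 cycles")
    pred = np.array([c.predicted for c in cycles])
    obs = np.array([c.observed for c in cycles])
    rmsd = float(np.sqrt(np.mean((obs - pred) ** 2)))
    if np.ptp(pred) == 0 or np.ptp(obs) == 0:
        raise ValueError("degenerate variance: predicted or observed are constant")
    res = stats.linregress(pred, obs)
    return rmsd, float(res.rvalue), float(res.slope), float(res.intercept)


def partition_test(x, y) -> float:
    """Exact two-sided Wilcoxon rank-sum p by exhaustive enumeration.

    All C(n1+n2, n1) group labelings of the pooled sample are enumerated and
    the two-sided p-value is the fraction of labelings whose rank-sum
    deviates from its expectation at least as much as the observed one.
    Ties receive mid-ranks, which the permutation null handles exactly.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n1, n = len(x), len(pooled)
    obs = ranks[:n1].sum()
    mean = n1 * (n + 1) / 2.0
    count = 0
    total = 0
    obs_dev = abs(obs - mean) - 1e-9
    for combo in itertools.combinations(range(n), n1):
        w = ranks[list(combo)].sum()
        if abs(w - mean) >= obs_dev:
            count += 1
        total += 1
    return count / total


def group_by_three_prime_class(
    records: list[PKaRecord],
) -> tuple[list[float], list[float]]:
    """Split pKa values by 3'-neighbor purine (A/G) vs pyrimidine (C/T)."""
    purine = [r.pKa_app for r in records if r.context.three_prime in ("A", "G")]
    pyrimidine = [r.pKa_app for r in records if r.context.three_prime in ("C", "T")]
    return purine, pyrimidine


def compare_fingerprints(x, y, conf_level: float = 0.95) -> dict:
    """OLS of y on x with slope/intercept CIs, Pearson r, and RMSD about y=x.

    This is the regression used to compare one per-context ddG fingerprint
    against an independently measured one.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("fingerprints must share contexts")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 shared contexts")
    res = stats.linregress(x, y)
    tcrit = stats.t.ppf(0.5 + conf_level / 2, n - 2)
    rmsd = float(np.sqrt(np.mean((y - x) ** 2)))
    return {
        "rmsd": rmsd,
        "pearson_r": float(res.rvalue),
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "slope_ci": (
            float(res.slope - tcrit * res.stderr),
            float(res.slope + tcrit * res.stderr),
        ),
        "intercept_ci": (
            float(res.intercept - tcrit * res.intercept_stderr),
            float(res.intercept + tcrit * res.intercept_stderr),
        ),
        "n": n,
    }


def deshear_decomposition(
    ddG_melt_GT: dict[TripletContext, tuple[float, float]],
    ddG_melt_GC: dict[TripletContext, tuple[float, float]],
) -> dict[TripletContext, tuple[float, float]]:
    """Neutral de-shearing cost per context.

    Estimates the sequence-specific cost of moving the wobble base into
    Watson-Crick alignment while still neutral, as the difference between the
    G.T wobble and G-C (Watson-Crick proxy) melting perturbations:
    ddG(de-shear, neutral) = ddG_melt(GT) - ddG_melt(GC), sigmas in quadrature.
    """
    if set(ddG_melt_GT) != set(ddG_melt_GC):
        raise ValueError("context sets of the two tables do not match")
    return {
        ctx: (
            ddG_melt_GT[ctx][0] - ddG_melt_GC[ctx][0],
            math.hypot(ddG_melt_GT[ctx][1], ddG_melt_GC[ctx][1]),
        )
        for ctx in ddG_melt_GT
    }
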