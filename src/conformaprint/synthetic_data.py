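"""Synthetic generators for every pipeline input.

Each generator produces data with the statistical structure the downstream
analysis assumes, so the whole pipeline can be exercised and validated
without experimental data:

* pH series of two-Lorentzian spectra whose peak-area ratio follows the
  Henderson-Hasselbalch titration of a wobble/anion equilibrium;
* 4x4 apparent-pKa tables constructed to be exactly additive plus noise;
* off-resonance R1rho datasets forward-modelled through the Bloch-McConnell
  simulator on a spin-lock power/offset grid mirroring the experimental one
  (powers 500-2000 Hz, offsets spanning +/-3.5x the power, five delays);
* two-state UV melting curves with sloped baselines;
* SBS96 signature catalogs with one planted signature whose chosen
  substitution channel mixes a given fingerprint with Dirichlet noise.

Noise is additive i.i.d. Gaussian throughout; all generators are
bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .contexts import ALL_CONTEXTS, BASES, TripletContext
from .relaxation_dispersion import ExchangeModel, R1rhoPoint, _simulate_batch
from .signature_fingerprinting import (
    CHANNELS_96,
    SUBSTITUTION_CLASSES,
    Fingerprint,
    SignatureMatrix,
)
from .spectral_fitting import Spectrum, lorentzian
from .titration_pka import population_at_pH
from .uv_melting import MeltingCurve, melting_model


@dataclass
class SyntheticTitrationSpec:
    """Two-peak 19F-style titration series.

    Defaults place the wobble and anion resonances 2 ppm apart with 0.15 ppm
    linewidths and sample seven pH points bracketing the pKa, matching the
    regime in which both peaks are quantifiable.
    """

    true_pKa: float = 8.9
    pH_grid: tuple = (7.4, 7.9, 8.4, 8.9, 9.4, 9.9, 10.4)
    wobble_center: float = 0.0  # ppm
    anion_center: float = 2.0  # ppm
    linewidths: tuple = (0.15, 0.15)  # FWHM, ppm
    total_area: float = 1.0
    noise_sd: float = 0.0
    shift_axis: tuple = (-1.5, 3.5, 800)  # (min ppm, max ppm, n points)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.pH_grid) < 2:
            raise ValueError("pH grid must have at least 2 points")
        if not all(b > a for a, b in zip(self.pH_grid, self.pH_grid[1:])):
            raise ValueError("pH grid must be strictly increasing")
        if any(w <= 0 for w in self.linewidths):
            raise ValueError("linewidths must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def gen_titration_series(spec: SyntheticTitrationSpec) -> dict[float, Spectrum]:
    """Map pH -> spectrum; peak-area ratio p_anion/p_wobble = 10**(pH - pKa)."""
    rng = np.random.default_rng(spec.seed)
    lo, hi, n = spec.shift_axis
    axis = np.linspace(lo, hi, int(n))
    out = {}
    for pH in spec.pH_grid:
        p_anion = float(population_at_pH(spec.true_pKa, pH))
        y = lorentzian(
            axis, spec.wobble_center, spec.linewidths[0],
            spec.total_area * (1.0 - p_anion),
        ) + lorentzian(
            axis, spec.anion_center, spec.linewidths[1],
            spec.total_area * p_anion,
        )
        if spec.noise_sd > 0:
            y = y + rng.normal(0.0, spec.noise_sd, size=axis.shape)
        out[pH] = Spectrum(axis=axis, intensity=y, meta={"pH": pH})
    return out


def gen_additive_pka_table(
    base: float = 8.9,
    inc5: tuple = (0.0, -0.15, 0.10, -0.05),
    inc3: tuple = (0.55, -0.35, 0.65, -0.25),
    noise_sd: float = 0.0,
    seed: int = 0,
) -> dict[TripletContext, float]:
    """16-entry pKa table, exactly additive before noise.

    ``inc5``/``inc3`` give the per-base (A, C, G, T order) contribution of
    the 5' and 3' neighbor; defaults echo the dominant 3'-neighbor effect
    (purines raising pKa relative to pyrimidines).
    """
    if len(inc5) != 4 or len(inc3) != 4:
        raise ValueError("need 4 increments per side")
    rng = np.random.default_rng(seed)
    table = {}
    for i, z in enumerate(BASES):
        for j, w in enumerate(BASES):
            noise = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
            table[TripletContext(z, w)] = base + inc5[i] + inc3[j] + noise
    return table


def _default_exchange_model() -> ExchangeModel:
    # sparse tautomer-like ES1 and anion-like ES2, 15N-observable shifts
    return ExchangeModel(
        p_es1=0.004, p_es2=0.010,
        kex_gs_es1=3000.0, kex_gs_es2=2000.0, kex_es1_es2=150.0,
        dw_es1=-3.0, dw_es2=5.0,
        r1=2.0, r2=16.0,
    )


@dataclass
class SyntheticExchangeSpec:
    """R1rho grid mirroring the experimental acquisition.

    Spin-lock powers span 500-2000 Hz with offsets on a uniform grid over
    +/-3.5x the power (20 points per power) and five relaxation delays up to
    120 ms; intensity noise defaults to 1% of the initial intensity.
    """

    true_model: ExchangeModel = field(default_factory=_default_exchange_model)
    spinlock_powers: tuple = (500.0, 1000.0, 2000.0)
    offset_multiples: float = 3.5
    offsets_per_power: int = 20
    delays: tuple = (0.0, 0.03, 0.06, 0.09, 0.12)
    intensity_noise_fraction: float = 0.01
    spectrometer_mhz: float = 70.96
    nucleus: str = "N1"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.spinlock_powers or any(p <= 0 for p in self.spinlock_powers):
            raise ValueError("spin-lock powers must be positive and non-empty")
        if len(self.delays) < 2 or any(d < 0 for d in self.delays):
            raise ValueError("delays must be non-negative")
        if 0.0 not in self.delays:
            raise ValueError("delays must include 0")


def gen_r1rho_dataset(spec: SyntheticExchangeSpec) -> list[R1rhoPoint]:
    """Forward-model intensities I0*exp(-R1rho_sim*t)*(1 + noise) per point."""
    rng = np.random.default_rng(spec.seed)
    delays = np.asarray(spec.delays, dtype=float)
    powers, offsets = [], []
    for pw in spec.spinlock_powers:
        span = spec.offset_multiples * pw
        offs = np.linspace(-span, span, spec.offsets_per_power)
        powers.extend([pw] * len(offs))
        offsets.extend(offs)
    powers = np.asarray(powers)
    offsets = np.asarray(offsets)
    r1rho = _simulate_batch(
        spec.true_model, powers, offsets, delays, spec.spectrometer_mhz
    )
    points = []
    for pw, off, rate in zip(powers, offsets, r1rho):
        signal = np.exp(-rate * delays)
        if spec.intensity_noise_fraction > 0:
            signal = signal * (
                1.0 + rng.normal(0.0, spec.intensity_noise_fraction, size=delays.shape)
            )
        points.append(
            R1rhoPoint(
                spinlock_power=float(pw), offset=float(off),
                delays=delays.copy(), intensities=signal,
                nucleus=spec.nucleus,
            )
        )
    return points


@dataclass
class SyntheticMeltSpec:
    """Two-state melting curve of a ~12-bp duplex at 3 uM total duplex.

    Baselines give ~17% hyperchromicity at the midpoint; the temperature grid
    covers 15-95 degC in 0.5 K steps as in a heating run.
    """

    Tm: float = 330.0  # K
    dH: float = 80.0  # kcal/mol, melting direction (positive)
    m_ss: float = 3.0e-4
    b_ss: float = 0.62
    m_ds: float = 2.0e-4
    b_ds: float = 0.55
    C_total: float = 3.0e-6  # mol/L duplex
    T_grid: tuple = (288.15, 368.15, 161)  # (min K, max K, n points)
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi, _ = self.T_grid
        if not (lo < self.Tm < hi):
            raise ValueError("Tm must lie inside the temperature span")
        if self.dH <= 0:
            raise ValueError("dH must be > 0 (melting direction)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def gen_melting_curve(spec: SyntheticMeltSpec, replicate: str = "rep1") -> MeltingCurve:
    rng = np.random.default_rng(spec.seed)
    lo, hi, n = spec.T_grid
    T = np.linspace(lo, hi, int(n))
    A = melting_model(T, spec.Tm, spec.dH, spec.m_ss, spec.b_ss, spec.m_ds, spec.b_ds)
    if spec.noise_sd > 0:
        A = A + rng.normal(0.0, spec.noise_sd, size=T.shape)
    return MeltingCurve(T=T, A260=A, replicate=replicate)


def _default_fingerprint() -> Fingerprint:
    rng = np.random.default_rng(1234)
    w = rng.dirichlet(np.full(16, 0.8))
    return Fingerprint(state="GT_anion", contexts=ALL_CONTEXTS, weights=w)


@dataclass
class SyntheticCatalogSpec:
    """SBS96 catalog with one planted fingerprint-carrying signature."""

    n_signatures: int = 80
    planted_index: int = 36  # 0-based column of the planted signature
    planted_substitution: str = "C>T"
    planted_fingerprint: Fingerprint = field(default_factory=_default_fingerprint)
    contamination_eps: float = 0.1
    dirichlet_concentration: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.planted_index < self.n_signatures:
            raise ValueError("planted_index out of range")
        if not 0.0 <= self.contamination_eps <= 1.0:
            raise ValueError("contamination_eps must lie in [0, 1]")
        if self.planted_substitution not in SUBSTITUTION_CLASSES:
            raise ValueError("unknown substitution class")
        fp = self.planted_fingerprint
        if len(fp.contexts) != 16:
            raise ValueError("planted fingerprint must cover all 16 contexts")


def gen_signature_catalog(spec: SyntheticCatalogSpec) -> SignatureMatrix:
    """Dirichlet background columns plus one planted channel.

    The planted signature's 16-entry block for ``planted_substitution`` is
    set to (1 - eps) * fingerprint + eps * noise (noise itself Dirichlet)
    before the whole column is renormalized, so restricting and
    renormalizing that channel recovers the mixture exactly.
    """
    rng = np.random.default_rng(spec.seed)
    alpha = np.full(96, spec.dirichlet_concentration)
    cols = {}
    # fingerprint weights in canonical channel order for the planted block
    order = {c: i for i, c in enumerate(spec.planted_fingerprint.contexts)}
    fp_vec = np.array(
        [
            spec.planted_fingerprint.weights[order[c]]
            for c in sorted(spec.planted_fingerprint.contexts)
        ]
    )
    sub_idx = SUBSTITUTION_CLASSES.index(spec.planted_substitution)
    block = slice(16 * sub_idx, 16 * sub_idx + 16)
    for j in range(spec.n_signatures):
        col = rng.dirichlet(alpha)
        if j == spec.planted_index:
            noise16 = rng.dirichlet(np.full(16, spec.dirichlet_concentration))
            mixed = (1.0 - spec.contamination_eps) * fp_vec + (
                spec.contamination_eps * noise16
            )
            col = col.copy()
            col[block] = mixed
            col = col / col.sum()
        cols[f"SBS_SYN{j + 1:02d}"] = col
    df = pd.DataFrame(cols, index=list(CHANNELS_96))
    return SignatureMatrix(df)


def planted_signature_id(spec: SyntheticCatalogSpec) -> str:
    return f"SBS_SYN{spec.planted_index + 1:02d}"
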