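"""Simulate and globally fit off-resonance R1rho dispersion data.

Forward-models a 3-state exchange system (ground state plus two sparse
excited states) on a realistic spin-lock power/offset grid, adds 1%
intensity noise, fits the per-point mono-exponential decays, runs the
shared-parameter Bloch-McConnell fit, and reports Monte-Carlo uncertainties.
"""

import numpy as np

from conformaprint import (
    ExchangeModel,
    SyntheticExchangeSpec,
    fit_exchange,
    gen_r1rho_dataset,
    mc_exchange_uncertainty,
    r2rex_profile,
)
from conformaprint.relaxation_dispersion import fit_decays

truth = ExchangeModel(
    p_es1=0.010, p_es2=0.005,
    kex_gs_es1=2500.0, kex_gs_es2=2000.0, kex_es1_es2=600.0,
    dw_es1=-14.0, dw_es2=10.0, r1=2.0, r2=16.0,
)
spec = SyntheticExchangeSpec(true_model=truth, seed=3, offsets_per_power=12)
points = gen_r1rho_dataset(spec)
fit_decays(points, n_mc=40, seed=3)

fit = fit_exchange(points, spec.spectrometer_mhz)
sigmas = mc_exchange_uncertainty(
    fit, points, spec.spectrometer_mhz, n_iter=50, seed=3
)

m = fit.shared
print("shared exchange parameters (fit +/- MC sigma, truth):")
for name, true_val in [
    ("p_es1", truth.p_es1), ("p_es2", truth.p_es2),
    ("kex_gs_es1", truth.kex_gs_es1), ("kex_gs_es2", truth.kex_gs_es2),
    ("kex_es1_es2", truth.kex_es1_es2),
]:
    print(f"  {name:12s} {getattr(m, name):10.4g} +/- {sigmas[name]:8.3g}"
          f"   (true {true_val:g})")
print(f"chi-square = {2 * fit.cost:.0f} over {len(points)} grid points")

profile = r2rex_profile(points, r1=m.r1)
peak = max((o for o in profile if not o["excluded"]), key=lambda o: o["r2_rex"])
print(f"\nR2+Rex peaks at offset {peak['offset_hz']:+.0f} Hz "
      f"({peak['r2_rex']:.1f} 1/s): the dispersion profile localizes the "
      "excited-state resonances")
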