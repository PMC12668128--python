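# Methods

This note documents the models implemented in `conformaprint`, the defaults
and numerical choices behind them, what the synthetic generators do and do
not emulate, and the known limitations.

## Two-state titration and apparent pKa

A G•T (or G•5F-dU) mismatch exchanges between a neutral wobble conformation
and an anionic Watson–Crick-like conformation whose population grows with
pH. With both states resolved in a 1D spectrum, the anion fraction follows
the Henderson–Hasselbalch relation, and the apparent pKa is

    pKa_app = pH − log10(p_anion / (1 − p_anion)).

`pka_from_population` rejects p ∈ {0, 1}: such points carry no titration
information and typically indicate a pH far outside the transition.
Multi-pH aggregation (`aggregate_pka`) uses an inverse-variance-weighted
mean with per-point pKa uncertainties first-order propagated from the
population uncertainties, σ(pKa) = σ(p)/(ln10 · p(1−p)); when any point
claims zero uncertainty the aggregate falls back to an unweighted mean ± SD.
Weighting by the reciprocal variance is the natural pooling rule when the
per-point estimates are treated as independent Gaussian measurements of a
common pKa.

Free energies use ΔG = R·T·ln10·(pKa − pH) with R = 1.987×10⁻³ kcal/mol/K
and default T = 274.15 K (titrations at 1 °C); ΔG > 0 when the anion is the
minor state. Differences between contexts, ΔΔG = RT·ln10·ΔpKa, are
pH-independent.

### Additivity cycles

For a full 4×4 (5′-base × 3′-base) table, every unordered pair of 5′ bases
crossed with every unordered pair of 3′ bases defines a rectangle (36), each
traversed along its two reference→double diagonals, giving 72 cycles. A
cycle compares the observed double-neighbor perturbation with the sum of the
two single-neighbor perturbations. Note a statistical consequence of the
construction: each cycle's deviation is a ±1 combination of four distinct
table cells, so i.i.d. cell noise of SD σ produces deviations of SD 2σ (the
test suite verifies the factor 2 empirically).

### Partition test

The purine/pyrimidine 3′-neighbor partition is tested with an exact
two-sided Wilcoxon rank-sum p-value computed by full enumeration of all
C(n₁+n₂, n₁) labelings (12 870 at 8+8) with mid-ranks for ties; no normal
approximation is ever used at these sample sizes. Complete separation of
8 vs 8 yields p = 2/12870 ≈ 1.55×10⁻⁴, the smallest attainable two-sided
value at that size.

## Lorentzian deconvolution

Peaks are parameterized by (center, FWHM, area), L(x) = (area/π)·(w/2)/
((x−c)² + (w/2)²), so the fitted area *is* the integral used for
populations. Initialization picks local maxima above 5× a noise MAD
estimate; half-height crossings seed the widths. An optional constant
baseline term and a median-filter pre-corrector cover processed spectra
with residual baseline. Population uncertainties are first-order propagated
from the fit covariance of the areas (Jacobian of pᵢ = aᵢ/Σa). Peak-count
selection fits 1..3 peaks and takes the smallest model within 2 BIC units
of the minimum; when no model beats a flat description by 2 BIC units the
result is flagged low-confidence. Which resonance is wobble and which is
anion is sequence-dependent and must be assigned by the caller — the code
never guesses.

## Bloch–McConnell R1ρ

The 3-state triangular exchange model propagates (x, y, z) magnetization of
each state through a 9×9 evolution matrix: per-state Bloch blocks with
state offsets Ωᵢ = Ω_GS + Δωᵢ, spin-lock ω₁ along x, shared R1/R2 damping,
and first-order exchange blocks with rates k_{i→j} = kex_ij·p_j/(p_i+p_j),
which satisfies detailed balance by construction and reduces to the usual
two-site decomposition. All states share one R1 and one R2.

R1ρ for a grid point is obtained exactly as in the experiment's own
analysis: propagate (via eigendecomposition of the evolution matrix),
project onto the effective-field axis at each delay, and fit the projected
decay to a mono-exponential. The initial magnetization is aligned along the
ground-state effective field unless kex/|Δω| of the major excited state
exceeds 1, in which case the population-average effective field is used;
the threshold of 1 is configurable in spirit (the rule lives in one small
function) and θ is computed from the ground-state offset, matching the
"observed resonance" convention. Offsets are defined as the ground-state
resonance position relative to the carrier; ppm→rad/s conversion always
requires an explicit spectrometer frequency.

Two accuracy remarks. First, the no-exchange identity
R1ρ = R1cos²θ + R2sin²θ is exact on resonance and whenever R1 = R2; off
resonance with R1 ≠ R2 it is the leading-order result and the simulator
agrees with it to ~10⁻⁴ relative at typical effective fields — the residual
is a property of the formula, not of the integrator. Second, in the
fast-exchange regime the simulated Rex matches the algebraic
p_G·p_E·Δω²·kex/(kex² + ω_eff²) approximation within a few percent inside
its validity window.

### Decay fits and noise model

Mono-exponential fits minimize *relative* residuals (y/f − 1), the matched
estimator for the multiplicative intensity noise the generator produces
(and a good model for peak-intensity noise generally); the R1ρ uncertainty
is the SD of refits over noise-resampled replicates. Because a single
5-delay fit estimates its noise level with 3 degrees of freedom, the
per-point estimate is debiased (c4 correction) and — in `fit_decays` —
pooled across all grid points of a nucleus: the spectrometer noise level
does not change from point to point, and pooling turns a ±40% noise
estimate into a ±7% one, which keeps the weighted global fit and its
Monte-Carlo errors calibrated.

### Global fitting strategy

The χ² surface of a 3-state model is multimodal (state-label swaps,
p·kex ridges, runaway ES1↔ES2 exchange), so the global fit is staged:

1. dispersion-profile analysis proposes Δω candidates — R2+Rex peaks across
   all powers map to offsets −Δω·MHz, with an excess-broadening centroid as
   fallback when no peak is resolved;
2. a 2-state fit (ES2 frozen) over a log-spaced kex multistart finds the
   dominant excited state;
3. 3-state starts add the second state at a distinct peak candidate or on
   either side of the dominant Δω (overlapping states merge into one broad
   feature, so both signs must be proposed), over a small kex₂ grid;
4. all starts get cheap trust-region fits; the best few are polished to
   convergence; targeted mode-hop proposals (swap kex roles, swap
   populations, collapse the inter-ES rate) then try to improve the
   incumbent; if the final χ²/n is still poor, a cold-start escalation
   sweep runs every start to full convergence.

Populations and the three kex values are shared across nuclei; Δω, R1, R2
are per nucleus. Monte-Carlo uncertainties resample every R1ρ from
N(value, σ), refit warm-started from the solution, and report both
parameter SDs and the full sample set, from which percentile
(2.5–97.5%) confidence intervals are formed; percentile intervals are
preferred for the skewed rate parameters. The ES1/ES2 labeling is an exact
model symmetry; fits are canonicalized so ES1 carries the smaller Δω on the
first nucleus.

### Synthetic study conditions

The default simulated grid mirrors the experimental acquisition: powers
500–2000 Hz, offsets uniform over ±3.5× the power (20 per power by default;
the validation experiments use 12 to keep 50-replicate runs tractable),
five delays from 0 to 120 ms, 1% relative intensity noise. The
parameter-recovery experiments use a ground truth with two resolved
excited states in the slow–intermediate regime (p = 1.0% and 0.5%,
kex = 2500 and 2000 s⁻¹, Δω = −14 and +10 ppm at 70.96 MHz,
kex(ES1↔ES2) = 600 s⁻¹): in this regime populations, rates and shifts are
separately identifiable from a single nucleus, which is what a coverage
experiment must assume — in the very-slow limit only the product p·kex is
determined and in the fast limit only p·Δω², and no fitting procedure can
resolve the corresponding ridge from one field and one temperature.

## UV melting

The two-state duplex⇌strands model uses
p_ss = (√(1+8x) − 1)/(4x), x = exp(−(1/Tm − 1/T)·ΔH°/R), which satisfies
p_ss(Tm) = 1/2 exactly and agrees with an independent mass-action
equilibrium solver (van 't Hoff K(T), Brent root finding) to better than
10⁻⁶ across the curve; the x → 0 limit is series-guarded. Fits optimize
(Tm, ΔH°) plus four baseline coefficients, initialized from the smoothed
derivative peak and end-segment line fits; curves without a detectable
sigmoid transition are rejected. Replicates are fitted independently and
aggregated as mean ± SD (co-fitting was considered and rejected as the
default because replicate-level scatter is the quantity the SD is meant to
capture).

One convention deserves care. The printed entropy relation
ΔS° = ΔH°/Tm − R·ln(C_total/2) is implemented as the default
(`convention="printed"`), but the p_ss model itself implies the opposite
sign on the concentration term: from the closed form,
K_melt(T) = (C_total/2)·x⁻¹, so at Tm, ΔG°_melt = −R·Tm·ln(C_total/2) and
ΔS° = ΔH°/Tm + R·ln(C_total/2). Both conventions are exposed
(`convention="model"`), outputs are labelled, and per-context *differences*
(the quantities the de-shearing decomposition consumes) are identical under
either choice because the concentration term cancels. ΔG°25 uses exactly
298.15 K. The de-shearing decomposition itself is the elementwise
difference ΔΔG°(de-shear, neutral) = ΔΔG°melt(G•T) − ΔΔG°melt(G-C) with
quadrature uncertainties; a context measured in neither table stays
missing — never imputed.

## Signature fingerprinting

Fingerprints normalize the available per-context propensities to sum 1;
missing contexts are omitted and recorded, and comparisons restrict the
signature channel to the same context set before renormalizing. For the
anionic state the propensity at reference pH (default 7.4) is the
Henderson–Hasselbalch population of the per-context pKa. Fingerprints
measured on the purine strand can be re-expressed on the pyrimidine
(SBS96) strand with `reverse_complement_fingerprint`.

JSD uses base-2 logarithms — H(M) − (H(P)+H(Q))/2 with M the midpoint
mixture and 0·log0 ≡ 0 — so its range is [0, 1]; it is reported as the
divergence, not its square root. The null distribution draws each context's
probability i.i.d. from the pooled multiset of **all** channel
probabilities across all signatures and all six substitution classes
(sorted, so it depends only on the multiset), renormalizes, and scores
against the fingerprint; all-zero draws are redrawn and counted. One shared
null serves every pair in a scan. p-values are left-tail with the add-one
estimator p = (1 + #{null ≤ obs})/(1 + n), which is super-uniform under the
null by construction; FDR is Benjamini–Hochberg across the full scan.
Matches with JSD ≤ 0.090 and both p and FDR < 0.05 carry the strong flag.
The default draw count is 10⁶; validation experiments use 10⁵, which
changes p-value resolution but not the JSD ranking.

The mechanistic state→substitution registry maps G•T⁻ → {C>T, T>C},
A(syn)-T Hoogsteen → {T>A, T>C, T>G}, G(syn)-C⁺ Hoogsteen →
{C>A, C>T, C>G}, and the A-T opened state → {T>A, T>G}; unknown states are
rejected rather than guessed.

## Synthetic generators

All generators take explicit seeds and are bit-reproducible. Noise is
additive i.i.d. Gaussian throughout (relative, for R1ρ intensities); this
matches standard detector-noise assumptions and keeps Monte-Carlo error
analyses honest. The titration generator emits two Lorentzians whose areas
follow the Henderson–Hasselbalch ratio with total area conserved across pH;
the melting generator applies the exact two-state model with sloped
baselines (defaults: Tm 330 K, ΔH 80 kcal/mol, 3 µM duplex, ~17%
hyperchromicity, 15–95 °C at 0.5 K steps); the catalog generator draws
symmetric-Dirichlet background columns (concentration 0.5, sparse like real
signatures) and sets the planted channel to (1−ε)·fingerprint + ε·noise
before renormalizing the column, so restriction-plus-renormalization
recovers the mixture exactly.

What the generators do **not** emulate: solvent-exchange line broadening,
field- or temperature-dependent chemical-shift changes, spectrometer
artifacts (phase errors, baseline roll), heat-capacity effects in melting,
pulse-sequence imperfections in R1ρ, or the correlated channel structure of
real mutational catalogs. Tests passing on synthetic data therefore
demonstrate the correctness and calibration of the *analysis*, not the
fidelity of any instrument model; conclusions about real samples still
require the real measurements.

## Known limitations

- The intensity-noise magnitude of real spectra is instrument-dependent;
  the 1% default is a representative choice, not a measured value.
- The 3-state global fit assumes the data were acquired in a regime where
  the parameters are identifiable (resolved, slow–intermediate excited
  states); outside that regime the fit still converges but individual
  parameters are ridge-degenerate and only products are meaningful.
- Whether the original spectra's Lorentzian fits included a baseline term
  is not documented; both options are provided.
- Reproducing published COSMIC-dependent divergence values requires the
  external COSMIC GRCh37 download and the measured propensity tables; the
  package supports that workflow (`read_signatures` + `make_fingerprint`)
  but ships no COSMIC data.
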