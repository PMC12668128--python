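# conformaprint

Conformational fingerprinting of rare DNA states, and statistical matching of
those fingerprints against trinucleotide (SBS96) mutational signatures.

Watson–Crick DNA transiently visits low-populated, short-lived conformations —
anionic Watson–Crick-like G•T⁻ mismatches, Hoogsteen base pairs, locally
opened pairs — that are candidate intermediates of replication errors and
chemical damage. Their propensities depend strongly on the flanking
Watson–Crick neighbors, so each state carries a sequence-specific
*conformational fingerprint*: a normalized vector of propensities across the
16 NTN triplet contexts. This package implements the full analysis chain that
measures such fingerprints from biophysical data and asks whether they
resemble the sequence preferences of cancer mutational signatures:

- **`spectral_fitting`** — deconvolve 1D spectra (e.g. ¹⁹F titration points)
  into 1–3 Lorentzian peaks and convert peak integrals into state
  populations with propagated uncertainties.
- **`titration_pka`** — Henderson–Hasselbalch analysis: apparent pKa from
  anion populations, pKa\_app = pH − log₁₀(p/(1−p)); free energies
  ΔG = RT·ln10·(pKa − pH); 72-cycle nearest-neighbor additivity tests; exact
  Wilcoxon rank-sum partition tests; fingerprint-vs-fingerprint regression.
- **`relaxation_dispersion`** — off-resonance ¹⁵N R1ρ under a 3-state
  triangular Bloch–McConnell model: simulation on the 9×9 evolution matrix,
  mono-exponential decay fits, shared-parameter global fits across nuclei,
  Monte-Carlo uncertainties, and R2+Rex = (R1ρ − R1cos²θ)/sin²θ profiles.
- **`uv_melting`** — two-state duplex melting: A260(T) with sloped baselines,
  p\_ss = (√(1+8x) − 1)/(4x) with x = exp(−(1/Tm − 1/T)ΔH°/R), and
  ΔS° = ΔH°/Tm − R·ln(C_total/2), ΔG° = ΔH° − TΔS°.
- **`signature_fingerprinting`** — SBS96 catalog I/O (COSMIC dialect),
  base-2 Jensen–Shannon divergence between a fingerprint and each
  signature's renormalized substitution channel, a pooled-probability
  resampled null (default 10⁶ draws), add-one p-values, Benjamini–Hochberg
  FDR, and the strong-similarity rule (JSD ≤ 0.090, p and FDR < 5%).
- **`synthetic_data`** — generators for every input above (titration
  spectra, R1ρ grids, melting curves, signature catalogs with a planted
  fingerprint), so the whole pipeline runs and is tested without any
  external download.

## Worked example

`examples/signature_scan.py` builds a G•T⁻ fingerprint from per-context pKa
values, plants it (with 10% contamination) in the C>T channel of one of 80
synthetic signatures, and scans the catalog:

```
signature substitution      jsd  p_value      fdr  n_contexts  strong
SBS_SYN37          C>T 0.007988  0.00001 0.001600          16    True
SBS_SYN13          T>C 0.161499  0.00919 0.735193          16   False
...
top hit JSD = 0.0080; p = 1.00e-05, FDR = 1.60e-03
```

The planted signature is recovered as the unique strong match: its JSD is
far below the 0.090 threshold while every unplanted pair fails the FDR cut.
The other examples print an apparent-pKa estimate from a simulated titration
(8.900 ± 0.000 vs truth 8.90), melting thermodynamics from three replicates
(Tm 330.06 ± 0.08 K vs truth 330), and a 3-state R1ρ global fit with
Monte-Carlo errors.

Scanning real COSMIC signatures works the same way: pass a GRCh37 SBS96
tab-separated file to `read_signatures` and your measured per-context
propensities to `make_fingerprint`.

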