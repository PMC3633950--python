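# Methods

## Scope

`ptssnmr` models the ¹H→¹³C polarization-transfer experiment used to read out
molecular mobility in stratum corneum (SC): three spectra per sample — DP
(direct polarization), CP (cross polarization, contact time t_CP) and
refocused INEPT (delays τ, τ′) — acquired under magic-angle spinning with
high-power decoupling.  The package covers (i) the forward model from motion
parameters to the three intensities, (ii) the ¹³C assignment table and
signature windows, (iii) the FID→spectrum processing chain, (iv) a synthetic
SC sample generator, and (v) interpretation of spectrum triplets into dynamic
state calls.  It does not do quantum spin-dynamics simulation (no density
matrix / Floquet treatment), chemical-shift-anisotropy relaxation, ¹H–¹H
spin-diffusion during CP (the short 1 ms contact makes it negligible at this
operating point), peak deconvolution, or multidimensional NMR.

## Dynamics model

A C–Hₙ segment reorients according to the two-step correlation function
C(t) = (1 − S²)·exp(−t/τ_c) + S²·exp(−t/τ_s), where |S_CH| is the bond order
parameter, τ_c the fast local correlation time, and τ_s the slow/global time
(default 1 s, i.e. an effectively static residual).  The reduced spectral
density uses the (2/5) convention, so all dipolar prefactors live in one
place, the relaxation-rate expressions.

Relaxation rates are Redfield-style combinations of J(ω) at the usual
heteronuclear/homonuclear frequency sets, with three deliberate departures
from the liquid-state textbook forms, each reflecting the MAS solid-state
setting:

1. **MAS secular averaging.**  Zero-frequency (secular) spectral densities are
   evaluated as ½[J(ω_R) + J(2ω_R)] instead of J(0): spinning converts static
   dephasing into rotor-frequency modulation.  This produces the T₂ minimum at
   τ_c ≈ 1/ω_R (tens of µs at 5 kHz MAS) characteristic of MAS/motion
   interference.
2. **Spin-lock sampling for T₁ρᴴ.**  The rotating-frame rate samples
   J at 2ω₁ ± ω_R and 2ω₁ ± 2ω_R, with ω₁ the ¹H nutation frequency at the
   ramp midpoint (80 kHz).  This places the T₁ρᴴ minimum — and therefore the
   CP efficiency dip — at τ_c ≈ 1/(2ω₁) ≈ 1 µs.
3. **Coherent residual broadening.**  Motionally averaged but non-zero
   dipolar couplings (∝ S·d) dephase transverse magnetization coherently.
   The rate is modeled as √M₂ gated by (M₂/(M₂ + ω_R²))^q: residual couplings
   well below the spinning rate are spun out and refocused (inhomogeneous
   limit), couplings above it broaden homogeneously (rigid limit).  This term
   is what shuts INEPT off for anisotropic segments while leaving truly
   isotropic ones untouched.

Two more ingredients connect the slow-motion and fast-motion regimes:

- **Pre-averaging crossover.**  Local motion only averages a coupling it is
  fast against; the residual order entering CP build-up and coherent
  broadening is S_m² = S² + (1 − S²)·w with w = d·τ_c/(1 + d·τ_c).  A slowly
  tumbling isotropic segment (τ_c ≳ 1/d) therefore still cross-polarizes like
  a solid, as observed.
- **Libration floor.**  Rigid segments retain fast small-angle librations, so
  the relaxation-active variance never vanishes: the residual order is scaled
  by a librational factor 0.9 wherever it enters a relaxation rate.  Without
  it a fully ordered segment would have no τ_c dependence at all, contrary to
  the measured behaviour of rigid solids (T₁ρ minima vs temperature).

CP build-up follows 1/T_CH ∝ n·d²_CH/ω_bath · S_m^α with α = 1.4, an
empirical exponent between the sudden (rate, ∝ S²) and adiabatic-passage
(∝ S) limits for a contact ramped through the n = ±1 Hartmann–Hahn sideband;
ω_bath is the rigid proton-bath width.  The CP amplitude then follows the
standard two-reservoir kinetics (I_CP formula in the README) and INEPT the
refocused product formula with multiplicity factors sin, sin·cos, sin·cos²
for CH, CH₂, CH₃.

### Free constants and their calibration

The cited intensity model's coefficients are not printed anywhere, so three
dimensionless constants are the package's own: the libration factor (0.9),
the CP transfer constant ζ = 0.035 with exponent α = 1.4, and the MAS-gate
exponent q = 3.  They were fixed **once**, against the published regime
thresholds of the efficiency map — CP/INEPT equality near |S_CH| ≈ 0.1 at
τ_c = 1 ns, CP negligible below 0.01 and maximal above 0.5, and a joint
CP+INEPT efficiency minimum near τ_c = 1 µs — and are not tuning knobs.  With
these values the rigid-limit derived quantities are physically sensible:
T_CH ≈ 120 µs and T₂ᴴ ≈ 7 µs for a rigid CH₂, T₂ᴴ ≈ 3 s in extreme narrowing.

### Regime classification

A triplet is classified by per-scheme thresholds (default 5% of the scheme's
theoretical ceiling: γ for CP, γ·|sin(πJτ₂)Fₙ(πJτ₂′)| for INEPT): INEPT-only →
`mobile_isotropic`; both → `mobile_anisotropic`; CP-only → `rigid_slow`;
neither, with DP present → `intermediate`; nothing → `ambiguous`.  An
all-zero triplet is never an error.

## Peak library

The shipped table contains every ¹³C shift quoted in the source assignment
work for intact pig SC (lipid chain markers 14.6/23.3/30.5/32.7/33.4 ppm,
cholesterol 40.4–40.9/42.8/51.8/57.6 ppm, keratin core 40.6 ppm and the
helical C_α envelope, keratin terminal markers 43.7/56.7/62.4 ppm), each
carrying a source tag; the complete supplementary assignment table is not
reproduced, but user CSVs merge with precedence.  Signature windows default
to ±0.3 ppm.  Two windows required a design decision:

- the keratin-core C_α window is set to **[58.0, 60.0] ppm** — the upfield
  part of the helical C_α envelope — so that the three main signature groups
  (lipids, core, terminals) are pairwise disjoint: a wider "around 57 ppm"
  window would swallow the terminal Ser C_α marker at 56.7 ppm and the mobile
  cholesterol C14/C17 line at 57.6 ppm;
- cholesterol windows intrinsically overlap keratin (40.4–40.9 vs 40.6 ppm);
  they are distinguished by scheme (INEPT dots on a CP background), not by
  shift, so no disjointness is claimed for that group.

## Processing chain

Exponential apodization (default 10 Hz), zero-filling (default 1597 → 8192
points), FFT with a descending-ppm axis (carrier at the window centre),
automatic phasing, ALS baseline, optional referencing of the α-glycine
methylene to 43.7 ppm.  The in-house algorithms behind the named processing
steps of the original workflow are not public; the substitutes are pinned and
documented:

- **Phasing**: minimize the Shannon entropy of |d(Re S)/dω| with a quadratic
  penalty on negative intensity, Nelder–Mead from a fixed 12-point φ₀ grid
  (first-order phase optional, off by default since the simulated FIDs have
  no dead time).  Deterministic for identical input.
- **Baseline**: exact least-squares line removal followed by asymmetric least
  squares (Whittaker smoother, λ = 10⁸, p = 10⁻³, 10 iterations).  Offsets
  and ramps are removed to solver precision; a synthetic Lorentzian's height
  survives within 2%.

## Synthetic samples

`sc_sample` encodes the qualitative hydration/temperature phenomenology as a
generator: a rigid all-trans methylene pool (33.4 ppm) that survives
hydration at 32 °C but melts on heating (gone at 60 °C once water ≥ 30 wt%);
a mobile lipid pool (30.5/23.3/14.6 ppm, S = 0.005, ns correlation times)
whose fraction grows smoothly from 0.12 (dry) to 0.54 (99.5% RH) and with
temperature, while its chain-middle τ_c slows with hydration; rigid keratin
core markers at all states; terminal-domain markers that switch abruptly from
rigid to nearly isotropic (S = 0.005) between RH 80 and 85%; and mobile
cholesterol lines only in the 82–88% RH window.  RH maps to water content by
monotone interpolation of the measured pairs (80→24, 85→30, 90→37, 93→46,
96→50 wt%); the NaCl-molality→RH table is interpolated with PCHIP.  The
quantitative pool fractions are synthetic placeholders (the source
observations are qualitative) and are flagged as such in sample metadata.

FIDs are sums of exponentially decaying complex sinusoids — Lorentzian lines
only, no spinning sidebands (weak ¹³C CSA at 5 kHz MAS), no chemical-exchange
lineshapes — with per-segment linewidths 1/(πT₂ᶜ) clipped to 12–100 Hz (the
field-inhomogeneity floor and decoupling-limited ceiling of the real
experiment), identical across the three schemes so that within-window
CP/DP and INEPT/DP ratios are lineshape-independent.  Noise is circular
Gaussian, always explicitly seeded.  **What passing round-trip tests show**:
that the classification logic correctly inverts the forward model at realistic
SNR.  What they do not show: robustness to baseline roll, sidebands, peak
overlap beyond the shipped windows, radiofrequency inhomogeneity, or
assignment errors in real SC spectra.

## Interpretation

Peak areas are trapezoidal integrals over signature windows after a local
linear baseline between window edges (edge level averaged over 3 points);
negative areas are floored at zero with the signed value retained.  CP and
INEPT areas are normalized by the window's DP area, which makes state calls
invariant under uniform rescaling of all three spectra.  A scheme counts as
detected only if its area also exceeds 3× a noise bound estimated from
signal-free windows (default 75–122 ppm, configurable) — without this guard,
near-threshold windows flip on noise.  Windows with no significant DP signal
are `ambiguous`.

Series reports normalize group amplitudes by the full-axis DP integral (the
stable per-scan scale, proportional to total ¹³C), flag monotone trends with
a 5% tolerance, and color-code calls (rigid = blue, mobile = red, matching
the conventional overlay palette).  `detect_transition` returns the first
adjacent RH pair where a group's INEPT amplitude rises from below to above
20% (configurable) of the series maximum, with a 2%-of-DP noise floor so a
signal-free group (keratin core) never reports a spurious step.

## Numerical choices and degenerate inputs

- τ_s may be infinite (no slow process); ω = 0 is handled analytically.
- The CP kinetics singularity T_CH = T₁ρᴴ uses its analytic limit.
- Rates are floored at 10⁻³⁰ s⁻¹ so all time constants stay finite/positive.
- Grids for the efficiency map: τ_c on log₁₀[−12, 0] s, S on log₁₀[−3, 0];
  map arrays are (S × τ_c), rows ascending in S.
- The map export offers per-scheme and joint normalization (the published
  figure's scaling is not stated; per-scheme is the default).
- All stochastic operations require an explicit integer seed; identical
  (config, seed) reproduce byte-identical outputs.

## Problem sizes

The shipped test suite runs the full simulate→process→classify round trip on
100 seeded replicates of 1597-point FIDs (zero-filled to 8192) at SNR 50, and
evaluates the efficiency map on coarse grids; the whole suite completes in
about two minutes on one core.  The acceptance script evaluates only the
deterministic forward model (bisection and grid sweeps over a few hundred
triplet evaluations) and runs in seconds.

## Known limitations

- The relaxation expressions are perturbative closed forms, not stochastic
  Liouville or Floquet simulations; coefficients in the intermediate regime
  are approximate, and the CP exponent α = 1.4 is an empirical interpolation.
- DP is treated as fully quantitative (recycle-delay saturation effects are
  ignored); the optional visibility factor for extremely broad lines is off
  by default.
- The assignment table covers the signature markers, not the full SC
  spectrum; crowded regions (30 ppm amino-acid cluster) are not deconvolved.
- JCAMP-DX import supports AFFN (X++(Y..Y)) tables only, no SQZ/DIF/DUP
  compression.
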