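# Methods

`zymokin` analyses the inter-molecular activation of a trypsin-like
zymogen (proDer p 3, the house-dust-mite group-3 allergen precursor) by
the cysteine protease Der p 1, across the three kinds of measurement such
a study produces: thermal unfolding scans, coupled continuous activity
assays, and time-resolved electrospray mass spectrometry of a
quenched-flow reaction.  Every analysis step has a synthetic counterpart
that generates the corresponding raw data from known ground truth, so the
whole chain is validated by parameter recovery.

## Proteoform bookkeeping

Species are tracked as proteoforms: sequence and/or average neutral mass,
a role (zymogen, truncated zymogen, mature enzyme, propeptide, internal
fragment, internal standard), and the ESI charge states used for
quantification.  Average (isotope-averaged) masses are used rather than
monoisotopic ones because the ~25 kDa species are observed as unresolved
isotope envelopes whose centroid corresponds to the average mass; with
that convention the sequence-derived masses agree with the deconvoluted
values (zymogen 26354 Da, mature enzyme 24987 Da, released propeptide
1385 Da, leucine-enkephalin standard 556 Da) to within a dalton.  m/z of
the z-fold protonated ion is (M + z·1.00728)/z; values are only rounded
at the reporting layer.

Peptide-bond hydrolysis is modelled with exact mass balance: the two
products of a cleavage sum to the parent mass plus one water (18.015 Da).
Proteoforms declared by mass alone (no sequence) are allowed for MS work;
mass-balance checks are then skipped and the omission is logged.

N-terminal truncation catalogs list the forms observed in a purified
preparation with their approximate abundances (which must total 100 ± 1%).
A form is classified *activatable* when its N-terminus lies at or before
the start of the mature protease domain (the IVGG… junction), so that
propeptide removal can still produce the native enzyme; forms beginning
inside the mature domain (e.g. the ALAGE fragment from activation-loop
autolysis) are *non-activatable*; unsequenced entries are *unknown* and
excluded from the activatable fraction.  With this rule the heavily
truncated triple proline-to-alanine preparation is 94% activatable.

Proline-rich motifs are defined as maximal runs of prolines spaced exactly
three residues apart (PxxP period, the polyproline-II-prone arrangement);
runs of at least two prolines are reported.  Adjacent prolines do not
satisfy the period.  The wild-type propeptide NPILPASPQAT carries the
three-proline motif PxxPxxP at positions 2, 5, 8.

## Two-state thermal unfolding

Unfolding monitored by intrinsic fluorescence is fitted with the two-state
van't Hoff model, ΔCp = 0:

    ΔG(T) = ΔH_m (1 − T/T_m),  K = exp(−ΔG/RT),  f_U = K/(1+K)
    y(T) = (y_N + pT)(1 − f_U) + (y_U + qT) f_U

with linear native and unfolded baselines and R = 8.314 J mol⁻¹ K⁻¹.
Because unfolding of an active protease is irreversible (aggregation and
autolysis consume the unfolded state), the fitted T_m is always reported
as *apparent*; no reversibility test is attempted and ΔH_m is treated as
a shape parameter.  Internally all temperatures are Kelvin; I/O and
reports use °C.

Fitting is full six-parameter nonlinear least squares (lmfit,
Levenberg–Marquardt).  Starting values: baselines from the first/last 10%
of points; T_m from the steepest point of a lightly smoothed numerical
derivative; ΔH_m = 300 kJ/mol, a typical unfolding enthalpy for a ~25 kDa
globular protein at ~50 °C.  A curve whose baseline-detrended amplitude
does not exceed six times its point-to-point scatter (or an absolute
floor of 10⁻⁷ of the signal scale) is rejected as transition-free.  A T_m
at or beyond the scanned range sets an edge flag.

The experimental scans emulated by the generator run 20→70 °C at
0.5 °C/min read every 30 s, i.e. 201 points at 0.25 °C spacing, with 0.5%
relative Gaussian noise.  Under those conditions the fit recovers T_m
with ≈0.03 °C replicate scatter and no detectable bias, and ΔH_m within
a few percent.  The study never reports enthalpies, so recovery tests fix
ΔH_m = 300 kJ/mol in simulation and compare only T_m.

## Activation kinetics

**Progress curves.**  When maturation is followed through the activity of
the nascent enzyme on a fluorogenic substrate, the product curve follows
the classical lag/burst equation

    P(t) = v_s t + (v_i − v_s)(1 − e^(−k_obs t))/k_obs

with initial rate v_i, steady-state rate v_s, and pseudo-first-order
maturation constant k_obs; the k_obs → 0 limit P = v_i t is taken
analytically (via expm1 for numerical stability).  Substrate depletion is
neglected: over a 30-min assay of a 10 µM substrate the product remains
far below K_m of the mature enzyme, consistent with the constant-v_s
form.  Fits warn when the assay is shorter than 3/k_obs (poor
identifiability) and when v_s < v_i (no activation).  The emulated assay
is 1800 s at 5 s reads with 1% relative noise, v_i = 0.0005 and
v_s = 0.005 µM/s; 50-replicate means recover the generating k_obs within
well under 5% at both the wild-type (0.0035 s⁻¹) and slow-mutant
(0.0011 s⁻¹) values.

**k_obs vs activator.**  In the regime where the zymogen (12.5 nM) is far
below K_m (µM range), k_obs is linear in activator concentration; an OLS
line with free intercept (basal activity is observed experimentally) is
fitted, and its slope is the apparent specificity constant of activation.
Consistency with the Michaelis–Menten layer is asserted by a test: data
generated from the depletion model in the sub-K_m regime give back
k_cat/K_m as the slope.

**Michaelis–Menten depletion.**  At zymogen concentrations comparable to
K_m (the MS experiment: Z₀ = 16 µM), depletion follows
dZ/dt = −k_cat E₁ Z/(K_m + Z).  Two independent routes are implemented
and must agree to 10⁻⁶ relative: LSODA integration (rtol 10⁻¹⁰) and the
closed-form solution of the integrated Michaelis–Menten relation
K_m ln(Z₀/Z) + (Z₀ − Z) = k_cat E₁ t, evaluated with the Wright omega
function ω (the Lambert W of an exponential argument, overflow-safe):
Z(t) = K_m ω(ln(Z₀/K_m) + (Z₀ − k_cat E₁ t)/K_m).  Optional first-order
sinks model zymogen autolysis (cleavage after the activation-loop lysine,
giving an inactive internal fragment) and self-degradation of the mature
enzyme; with sinks enabled only the ODE route applies.  Propeptide
release tracks total processing 1:1 (mature + degraded mature).

The depletion fit uses the closed form as the model function.  K_m and
k_cat are jointly identifiable only when the course spans both saturated
and sub-K_m regimes; after fitting, a pure exponential alternative is
fitted as well, and if the Michaelis–Menten model does not reduce the
residual sum of squares by at least 5% (or K_m runs beyond 50·Z₀), K_m is
flagged unidentifiable and only k_cat/K_m (from the exponential rate over
E₁) is reported.  Confidence intervals are ±1.96 standard errors from the
least-squares covariance — adequate for the well-conditioned fits here.

**Species network.**  Mutant preparations are mixtures of truncated forms
processed in parallel.  Each form carries activator-proportional specific
rates toward the mature enzyme and/or toward inert truncated products,
plus an optional first-order autolysis rate; mature enzyme may
self-degrade.  The system is linear, so it is propagated exactly through
an eigen-decomposition of the rate matrix (matrix-exponential fallback
when eigenvalues coincide), conserving total protein to machine
precision.  A single processable species reduces to the depletion model
in its first-order limit, which is asserted in tests.

## Quenched-flow ESI-MS quantification

The reaction (16 µM zymogen pool, 0.16 µM activator, 1.8 µM internal
standard) is continuously quenched and electrosprayed; centroid spectra
arrive every 3 s.  The quantification chain is:

1. **XIC**: per declared (species, charge) target m/z — targets are
   computed from the declared mass and charge set, never discovered —
   centroid intensities within ±0.5 Th are summed per scan (tolerance
   configurable; 0.5 Th matches integer-rounded reporting of the
   targets).  Overlapping targets of different species within the summed
   tolerances flag both courses as ambiguous.
2. **Normalization**: each trace is divided scan-by-scan by the internal
   standard's intensity, I_t = I_obs/I_std, cancelling ionization and
   transmission drift.  Scans without the standard are dropped from all
   traces (missing, not zero), with a logged count.
3. **Concentration**: a species' normalized charge-state traces are
   summed and anchored to the known loading: C_t = C₀ · ΣI(t)/I₀, with
   I₀ the summed normalized intensity of the whole zymogen pool (intact
   plus truncated forms, for preparations that start as mixtures) in the
   first retained scan, and C₀ = 16 µM by default.  Sum-then-normalize
   equals normalize-then-sum given the common standard trace; this is
   asserted numerically.
4. **Kinetics**: the zymogen-pool decay is fitted with the integrated
   Michaelis–Menten model above.

Equal ionization response across species is assumed by step 3, as the
anchoring to a single I₀ implies.  The generator exposes per-species
response factors so this assumption can be violated deliberately: the
reconstruction bias is then exactly the response ratio (asserted in a
test and quantified in `analysis/04`).  The propeptide course is
reported but not used in kinetic fitting — it is a small, noisier species
and the protein courses carry the kinetic information.  Unassigned small
fragments from non-specific degradation are outside the declared target
sets and therefore excluded from ΣI.

## Synthetic-data generators

All generators are pure functions of (ground truth, seed), asserted by
determinism tests.  The QFMS generator integrates the species kinetics
(Michaelis–Menten for a single intact zymogen; the linear network for
mixtures), then per scan emits one centroid per (species, charge) at the
theoretical m/z plus Gaussian jitter (σ = 0.05 Th, so tolerance matching
is exercised) with intensity = concentration × response × envelope
weight × 1000 counts/µM, perturbed by relative Gaussian noise truncated
at zero, plus the constant internal-standard centroid.  Charge envelopes
default to the experimentally observed sets (zymogen 10–12+, mature
9–12+, propeptide 1–2+, standard 1+) with uniform weights.  An optional
global linear drift multiplies every centroid in a scan — precisely the
disturbance the internal standard removes, asserted in a test.  The
quenched-flow plumbing is abstracted to "reaction time = scan time"
(configurable dead-time offset, default 0).

The reference scenario uses K_m = 4.5 µM (mid-range of the 3–6 µM the MS
analysis of this system yields) and k_cat = 0.095 s⁻¹, chosen so that
16 µM zymogen is essentially fully depleted by 0.16 µM activator within
the 40-min window, matching the observed time course; 2% relative
centroid noise.  The implied specificity constant, k_cat/K_m ≈
0.021 µM⁻¹ s⁻¹, is what a complete ~40-min depletion under these
concentrations requires; a literature figure of 22–44 µM⁻¹ s⁻¹ for this
system is three orders larger and cannot be reconciled with that time
scale — a units ambiguity is suspected, and this package reports the
constant in µM⁻¹ s⁻¹ without forcing agreement.  All end-to-end checks
are therefore parameter recovery against generator truth, not against
that printed value.

What the generators do *not* emulate: isotopic fine structure, profile
peak shapes and peak picking, detector saturation, chemical background,
correlated drift beyond the global factor, response factors varying with
charge state, and quench-chemistry artefacts.  Passing recovery tests
therefore validates the estimation chain under the stated noise model,
not the instrument physics upstream of centroided spectra.

## Numerical choices and degenerate inputs

- Gas constant 8.314 J mol⁻¹ K⁻¹; proton 1.00728 Da; water 18.01528 Da.
- `fraction_unfolded` evaluates through the logistic function (expit) to
  avoid overflow at extreme arguments; the progress model uses expm1.
- Non-convergent fits raise an explicit error carrying the best iterate.
- Flat melting curves (no transition) are rejected at the initial-guess
  stage with a diagnostic; transitions at the scan edge are clamped and
  flagged.
- Zero-slope fluorimeter calibrations are rejected; negative
  concentrations after calibration are clipped to zero with a warning.
- Depletion courses showing <5% decay warn that kinetics are
  unidentifiable; purely exponential courses report only k_cat/K_m.
- Per-scan conservation of reconstructed total protein holds to machine
  precision on ideal (noise-free, equal-response) data.  Under
  independent per-centroid intensity noise the per-scan total inherits
  roughly the standard's relative noise (~2% at the default settings),
  so single-scan totals scatter accordingly while replicate-median
  kinetic parameters remain accurate; the conservation check is
  therefore defined on ideal data.

## Problem sizes

Replicate counts used by the shipped studies — 50 for progress-curve and
melting recovery and for the QFMS end-to-end medians, 20–25 in the
narrative analysis scripts — give stable means/medians for the stated
tolerances while keeping each study in the seconds-to-minutes range.
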