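# Methods

`rnaexcite` models a hairpin RNA that exchanges between its ground state
(GS) and a sparsely populated excited state (ES) through a base-pair
register shift, and implements the full quantitative chain from raw
relaxation-dispersion observables to the multi-step kinetic picture, plus
the combinatorial design of new hairpins with a predefined ES.

## Two-site exchange models (`rnaexcite.exchange`)

The exchange is two-state: GS ⇌ ES with forward/backward rate constants
k₁ = p_ES·k_ex and k₋₁ = p_GS·k_ex, k_ex = k₁ + k₋₁.  Two observables are
modelled.

**R1ρ (rotating frame).**  The closed form is the Laguerre approximation
of two-site exchange,

    R1ρ = R1 cos²θ + R2 sin²θ +
          sin²θ p_GS p_ES Δω² k_ex /
          { ω_GS²ω_ES²/ω_eff² + k_ex²
            − sin²θ p_GS p_ES Δω² [1 + 2k_ex²(p_GS ω_GS² + p_ES ω_ES²)
                                       /(ω_GS²ω_ES² + ω_eff² k_ex²)] }

with ω_i² = (Ω_i − ω_rf)² + ω_SL², ω_eff² = ΔΩ̄² + ω_SL²,
θ = atan2(ω_SL, ΔΩ̄) and Ω̄ = p_GS Ω_GS + p_ES Ω_ES.  The inner correction
term uses the per-state effective fields (p_GS ω_GS² + p_ES ω_ES²), the
grouping given in the Laguerre-approximation literature.  A non-positive
denominator raises a validity error naming the offending setting; a
random sweep over the physical domain (population ≤ 0.5, any shift,
power, offset) found no such point, so the guard is purely defensive.

The numerical oracle propagates the six-dimensional two-site
Bloch–McConnell magnetisation (x, y, z for each state) under the tilted
spin lock, starting aligned with the average effective field, and
extracts the effective rate by log-linear regression over the delay
grid — the same reduction applied to experimental decays.  Thermal
recovery is omitted (decay toward zero), matching the analysis of decays
from a prepared state.  Over the study regime (p_ES 0.5–10%, k_ex
300–2000 s⁻¹, Δω 0.3–3 ppm ¹⁵N at 60.8 MHz, spin locks 100–500 Hz,
offsets within ±3 powers) the closed form tracks the propagator with a
median relative deviation of ~0.1% and a worst case of ~2–3%, the larger
deviations occurring where Δω/k_ex ≈ 2 (slow-intermediate exchange).
This residual is what limits parameter recovery below (see *Known
systematic*).

**CEST.**  Saturation profiles are simulated as plain two-site
Bloch–McConnell evolution of longitudinal magnetisation under a weak
field at each carrier, normalised by the same simulation with the
carrier at the far off-resonance reference (−12 kHz), so the baseline is
1.  The spin-state-selective (α/β) detail of the TROSY experiment is not
modelled at the density-matrix level; the β component is represented by
the matched no-exchange profile so that the α−β difference isolates the
exchange dips, which is the quantity fitted in practice.

Units: all model math is in rad/s; ppm conversions go through the probe's
Larmor frequency, derived from the spectrometer ¹H frequency and a
gyromagnetic-ratio table (γ(¹⁵N)/γ(¹H) = 0.10136767).  The field is an
explicit input everywhere; nothing assumes 600 vs 800 MHz.

## Dispersion fitting (`rnaexcite.fitting`)

Fitting is two-stage, as in standard RD practice:

1. Each peak-intensity decay is fitted to I(t) = I₀e^(−Rt) by
   least squares (log-linear start, vectorised Gauss–Newton refinement);
   its uncertainty is the SD of the rate over 50 Monte-Carlo refits of
   Gaussian-perturbed intensities.
2. The resulting R1ρ values, weighted by those errors, are fitted to the
   Laguerre form — per probe over (p_ES, k_ex, Δω, R1, R2), or globally
   with (p_ES, k_ex) shared and (Δω, R1, R2) per probe.  k_ex is fitted
   on a log scale.  Bounds: p_ES ∈ (0, 0.5] (the ES is the minor state by
   convention), R1 ∈ [0.1, 10] s⁻¹, R2 ∈ [1, 100] s⁻¹, Δω unbounded
   within ±20 ppm.

The optimiser is multistart trust-region least squares (8 starts over
the sign and magnitude of Δω and two k_ex decades), guarding the known
±Δω and fast/slow-exchange degeneracies.  After the best fit, two
diagnostics run: a no-exchange null fit (Δχ² < 2 flags
`no_exchange_information`) and a sign-flipped refit (a minimum within
Δχ² < 1 with opposite Δω signs flags `ambiguous_dw_sign` and reports the
alternative — the sign is ultimately resolved by external chemical-shift
prediction, not by R1ρ data).

**Monte-Carlo errors** are a parametric bootstrap: each replicate
resamples every R1ρ from a Gaussian centred on the best-fit model with
the measured SD, refits from the best-fit start, and parameter SDs are
taken over replicates (deterministic under a seed; >20% failed refits
invalidates the estimate).  Centring on the model rather than the
measured values is the standard reading of "Monte-Carlo simulation" in
the RD literature; the distinction is second-order at these noise
levels.  "Coverage" in the self-validation experiments means the truth
lies within the fit ± 2 MC SDs — the usual 95% interval (at ±1 SD even a
perfectly calibrated estimator covers only ~68% of replicates).

**CEST fitting** holds (p_ES, k_ex) frozen at the R1ρ-derived values and
fits the ES position plus nuisance R1/R2 of the observed coherence,
multistarting from detected local minima of the profile.  A frozen
p_ES ≤ 0.2% is rejected as unidentifiable; a fitted Δω collapsing onto
the main dip is flagged.  ES shifts are reconstructed as GS + Δω
(downfield-positive).

**Known systematic.**  When decays are drawn from the full
Bloch–McConnell propagator (the generator default) and fitted with the
closed form, the ~0.5–2.7% rate underestimate at the slowest-exchange
probes projects onto the parameters as ≈ −0.2 population points in p_ES
and ≈ +10% in k_ex, with χ²/dof ≈ 1 (the misfit is absorbed by the
nuisance parameters, not visible in residuals).  The recovery experiment
(`experiments.pes_recovery_experiment`) therefore runs in two modes:
`model="laguerre"` (data drawn from the fitted model) measures estimator
calibration — bias ~0.01 points, 2-SD coverage ~19/20 — and `model="bm"`
carries the additional closed-form error — mean bias ≈ −0.2 points.
Fits of real data with the closed form inherit a bias of this order;
it is small against the biological contrasts of interest (populations
differing by factors of 2–12 across constructs) but not zero.

## Thermodynamics (`rnaexcite.thermo`)

Eyring conversions use k = κ(k_B T/h)e^(−ΔG‡/RT) with κ = 1,
R = 1.98720425864×10⁻³ kcal mol⁻¹ K⁻¹ and CODATA-2018 k_B, h.  The
modified van't Hoff fit regresses ln(k_i/T) on (1/T − 1/T_hm), where
T_hm is the harmonic mean of the experimental temperatures: the slope
gives −ΔH‡/R and the intercept gives ΔG‡(T_hm); TΔS‡ = ΔH‡ − ΔG‡ at
T_hm, and net GS→ES quantities are forward − backward.  The fit is
weighted by σ(ln k) ≈ σ_k/k when rate errors are supplied, unweighted
otherwise; two temperatures give an exactly determined fit flagged
`zero_dof`.  Boltzmann populations: p_ES = e^(−ΔΔG/RT)/(1 + e^(−ΔΔG/RT))
with exact inverse.  File readers accept Celsius and convert with the
273.15 offset; the default single-temperature reference is 283.15 K
(10 °C, the temperature of the dispersion experiments).

## Multi-step register-shift kinetics (`rnaexcite.kinetics`)

A register shift proceeding one base pair at a time is a linear chain
GS ⇌ I1 ⇌ … ⇌ ES.  Transition states are stored as absolute free
energies so each pair of forward/backward hops shares one barrier and
detailed balance holds by construction; hop rates are
k = (k_B T/h)e^(−(TS−E_i)/RT) and the stationary distribution is the
Boltzmann distribution of the state energies.

The bundled six-state chain places GS at 0, ES at 1.63 kcal/mol (the
experimental GS–ES gap, taken as a supplied constant) and the four
intermediates 1.27 kcal/mol above the ES — a 10-fold lower abundance at
278.15 K (the default chain temperature), keeping them below the
dispersion-detection floor.  All five transition states start at one
height and are tuned by a uniform additive shift (bisection, tolerance
10⁻⁴ kcal/mol) until the apparent two-state activation free energy
matches a target; a uniform shift rescales every rate by one factor, so
relative spectral properties are tuning-invariant.

The two-state reduction is reported in two conventions:

* **Boltzmann lump**: k_ex,app = −λ₂ (slowest relaxation eigenvalue,
  computed on the π-symmetrised generator), p_ES,app = Boltzmann mass of
  all non-GS states, k₁,app = p_ES,app·k_ex,app, and
  ΔG‡,app = Eyring(k₁,app).  This matches how a two-state fit of the
  relaxation would read the chain.  A spectral gap below 10 between the
  two slowest relaxation modes triggers a warning.
* **Committor-corrected**: k₁ = reactive flux through the GS cut divided
  by the committor-weighted GS population; on a linear chain this equals
  the exact inverse mean first-passage time GS→ES, and it is the
  quantity validated by the Gillespie first-passage oracle (exact
  stochastic simulation, seeded, with standard errors).

The two conventions coincide exactly for a genuine two-state chain but
differ by ~20% on the bundled six-state chain, because the four
intermediates jointly carry ~40% as much population as the ES, blurring
the lump boundary.  Tuned to the experimental apparent barrier of
14.74 kcal/mol under the Boltzmann-lump reading, the largest
single-step barrier comes out at 13.97 kcal/mol — the apparent barrier
exceeds it by roughly RT·ln(number of forward steps), the entropic cost
of needing five consecutive uphill steps.  The hypothetical concerted
transition accumulates the per-step activation costs
Σ(TS_i − E_{i−1}) ≈ 58 kcal/mol for the tuned chain, an unreachable
barrier — the quantitative argument for the multi-step mechanism.  The
per-step barrier values themselves depend on the equal-height reading
and are order-of-magnitude anchors, not measurements.

## Hairpin ES design (`rnaexcite.design`)

A design is a stem of base pairs (ordered loop→terminal, each stored as
5′/3′ bases) beneath an invariant tetraloop, capped below by a
non-canonical mismatch.  Strong pairs are the Watson–Crick pairs plus
G·U wobbles; weak pairs are G·G, U·U, G·A, A·G.  The predefined ES is
the re-pairing after a register shift: +1 (type 1, loop grows
tetraloop→pentaloop and the mismatch 5′ base joins the stem), −1
(type 2, mirrored), +2 (type 3, loop grows by two, recruiting the
dangling 5′ G), or +1 next to a bulge (type 4 — same pair arithmetic
with the bulge base as context).  Shifts conserve nucleotide content and
are invertible on interior pairs.

Enumeration is exhaustive over strong pairs (6^stem_len raw
combinations) under three constraints: all-strong GS; per-nucleotide
base-pair-triplet uniqueness (signature = strand + the pair and both
neighbours, with loop/mismatch context tokens at the termini; a
G/U-only switch restricts the check to imino-bearing nucleotides); and
an ES with at most one weak pair.  Output order is lexicographic.

Scoring is ΔΔG = E(ES) − E(GS) through a pluggable backend.  The bundled
nearest-neighbor backend is additive: hairpin-loop initiation by loop
size (Jacobson–Stockmayer extrapolation beyond the table) plus stacking
free energies between consecutive strong pairs plus a fixed
1.0 kcal/mol penalty per weak pair (whose flanking stacks are skipped).
The ten canonical Watson–Crick stack values are the standard
Turner-style ΔG°37 numbers; wobble-containing stacks and loop penalties
are approximate round values.  The backend is a deterministic,
self-consistent ranking tool — it makes no claim of reproducing any
external folding program's energies, and an adapter slot accepts
externally computed alternative-structure scores.

The filter accepts a candidate iff 0 ≤ ΔΔG ≤ 3 kcal/mol (inclusive; the
threshold corresponds to ≈0.5% ES population at 283.15 K, the practical
dispersion-detection floor) and no scanned alternative scores lower.
ΔΔG < 0 is a GS/ES inversion — the intended ground state is not the
most stable structure — flagged and never accepted.  The bundled
alternative scan covers register shifts of magnitude ≤ 2 in both
directions plus the terminal- and loop-side pair-melted variants; it is
a bounded stand-in for a full structure-ensemble scan.

## Synthetic data (`rnaexcite.synth`)

The raw dispersion data behind the study conditions are not publicly
deposited, so the generators emulate them with known truth:

* **R1ρ**: four ¹⁵N probes sharing one exchange process (defaults
  p_ES = 6.2%, k_ex = 453 s⁻¹, Δω = 1.0/1.5/2.0/2.5 ppm downfield — the
  wobble→Watson-Crick direction — at a 600 MHz spectrometer, R1 = 2,
  R2 = 18 s⁻¹), spin-lock powers {100, 150, 200, 300, 500} Hz, offsets
  at {0, ±0.5, ±1, ±1.5, ±2, ±3}× the power, eight delays over 0–70 ms.
  Decays are Bloch–McConnell-simulated (or closed-form mono-exponentials
  with `model="laguerre"` for inverse-crime round trips) and multiplied
  by Gaussian(1, noise) factors; the stated per-point error is
  noise × model intensity.  Default noise is 2% — not a printed value,
  but chosen so Monte-Carlo population uncertainties land on the
  ±0.1–0.5-point scale reported for this class of experiment.
* **CEST**: α/β component pairs on an 8.5–15.5 ppm grid in 30 Hz steps
  (B1 = 15 Hz, mixing 0.2 s), with ¹H Δω set to one fifth of the ¹⁵N
  values (imino ¹H shifts move much less than ¹⁵N on pairing changes).
* **Rates**: multi-temperature k₁/k₋₁ series from activation truths via
  the modified van't Hoff relation, with multiplicative log-normal noise
  (rates are positive and are fitted in log space).

Every generator is a pure function of (truth, layout, seed) and
reproduces bit-identically; truth records serialise to JSON beside the
data.  What the generators do **not** emulate: peak overlap and
assignment errors, field inhomogeneity and calibration error of the
spin-lock power, temperature miscalibration, spin-state-selective
systematics in CEST, and any non-two-state background dynamics.
Passing recovery tests therefore demonstrate estimator correctness and
calibration under the stated noise model, not robustness to those
experimental artifacts.

## Problem sizes and numerical choices

Self-validation runs 20 four-probe datasets with 50 Monte-Carlo refits
each for the recovery experiment, a 100-point closed-form/propagator
sweep, 100 van't Hoff replicates, and 10,000 Gillespie paths — a few
minutes on one core, chosen as the smallest sizes at which the summary
statistics are stable.  Propagation uses batched eigendecomposition of
the 6×6 generators (condition numbers checked, >10¹² is an error);
degenerate inputs (zero mixing time, p_ES = 0, flat decays, single
temperatures) are exercised in the test suite.  All stochastic routines
take explicit seeds and are bit-reproducible.

## Known limitations

* Two-site exchange only; no ≥3-site models, no off-resonance alignment
  corrections beyond the tilted-frame picture, no pulse-sequence
  simulation.
* The closed-form fitting bias described above (≈ −0.2 population
  points against full Bloch–McConnell truth in the slowest-exchange
  corner of the study regime).
* The energy backend is an approximate ranking device; absolute ΔΔG
  values should not be compared with melting experiments or external
  folding programs.
* The multi-step chain is linear; branched transition networks and
  simulation of trajectory data are out of scope.
* No heat-capacity (ΔCp) term in the van't Hoff analysis; activation
  enthalpies are assumed temperature-independent over 5–20 °C.
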