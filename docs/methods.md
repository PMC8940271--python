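# Methods

`phototrace` implements the derivation chain used to phenotype
light-harvesting (LHCII) mutants of vascular plants from raw biophysical
traces: pulse-amplitude-modulated (PAM) chlorophyll fluorescence,
dual-wavelength electrochromic shift (ECS) absorbance kinetics,
time-correlated single-photon-counting (TCSPC) fluorescence decays, fast
(OJIP) induction pulse trains, pigment extract absorbances, and grana
morphometry tables. This note documents the models, the parameters that
matter, the synthetic data generator, and the numerical choices.

## Quenching analysis (PAM)

From a trace annotated with its light protocol the landmark extractor
reads:

* **Fm** — mean over the first saturating-pulse window, given in darkness;
* **F0** — median of the dark window before that pulse;
* **Fm′** per light step — mean over the step's pulse window;
* **Fs** — mean of the last 5% of samples of the actinic phase preceding
  the pulse ("just before" the pulse, made deterministic);
* **F0′** — minimum inside the far-red window following the step (far-red
  light oxidizes the intersystem chain; the minimum approximates the fully
  oxidized level of the decaying transient).

Pulse levels are *window means*, not window maxima. The pulse window is
the fluorescence plateau of a multiple-turnover saturating pulse, and the
mean of the plateau is an unbiased estimator under additive detector
noise, whereas the window maximum is an order statistic biased upward by
roughly 1.3 standard deviations; at NPQ near 2 that bias alone would
displace NPQ by about −0.06. No smoothing is applied before extraction;
smoothing is an opt-in concern of the caller.

Derived parameters (standard definitions):

* NPQ = (Fm − Fm′)/Fm′
* ΦPSII = (Fm′ − Fs)/Fm′
* 1 − qL = 1 − [(Fm′ − Fs)/(Fm′ − F0′)]·(F0′/Fs)
* qT = (Fm,St1 − Fm,St2)/Fm,St1

The state-transition literature also contains a variant normalization
qT = (Fm′,St1 − Fm′,St2)/Fm′,St2; the first (St1-normalized) form is
implemented. The two differ by the choice of denominator and are not
interchangeable — callers comparing against the variant form should
convert explicitly.

NPQ induction/relaxation kinetics are decomposed operationally, not by
curve fitting: qE (the rapidly reversible, energy-dependent component) is
NPQ at the last pulse in the light minus NPQ at the pulse nearest the
requested relaxation read time (default 300 s after light-off, tolerance
±30 s); the remainder is reported as the slowly reversible residual. No
multi-component relaxation model is fitted.

## ECS analysis

The carotenoid bandshift at 520 nm reports the transmembrane electric
potential linearly; the 546 nm channel carries the non-electrochromic
background and is subtracted point-wise (no resampling unless explicitly
requested, so acquisition faults stay visible). Two primitives follow:

* **One-charge calibration**: the deconvolved amplitude 140 µs after a
  saturating single-turnover flash equals one charge separation per
  photosystem. The amplitude is read by linear interpolation at exactly
  t_flash + 140 µs against a 1 ms pre-flash baseline, making it
  sampling-rate independent.
* **Initial slope**: when actinic light switches off, photochemistry
  stops instantly while ATP-synthase consumption continues, so the
  initial ECS decay slope equals −(electron flow rate)·(one-charge
  amplitude). The slope is an ordinary-least-squares fit over a 5 ms
  window (configurable). The window must stay well below the ATP-synthase
  decay constant τ; for an exponential decay the OLS slope over a window
  w underestimates the initial slope by ≈ w/2τ, i.e. ~1.2% at the
  defaults (w = 5 ms, τ = 200 ms). That truncation bias dominates the
  error budget of the rate pipeline.

Derived quantities: photochemical rate = |slope|/amp_one_charge
(e⁻ s⁻¹ PS⁻¹); PSII/PSI reaction-center ratio
r = (amp_total − amp_PSI-only)/amp_PSI-only from flashes with and without
PSII inhibition (DCMU + hydroxylamine); CEF fraction =
100·rate_far-red/rate_total, far-red light exciting PSI only. The
measurement intensity is metadata carried through — nothing is hard-coded
to a particular µmol m⁻² s⁻¹ value.

## Chlorophyll repartition and antenna size

Three routes to the PSI share of chlorophyll:

1. **Rates + stoichiometry.** Under fixed light, the per-photosystem rate
   is proportional to the per-photosystem absorption cross-section, and
   the PSII pool outnumbers the PSI pool r-fold, so
   PSI/(PSI+PSII) = rate_PSI/(rate_PSI + rate_PSII·r).
2. **FLIM.** TCSPC decays are fitted with three exponentials at *fixed*
   lifetimes (defaults 0.1, 0.9, 2.0 ns), which reduces the fit to
   non-negative linear least squares on the (optionally
   Gaussian-IRF-convolved) basis, weighted by the Poisson uncertainty
   1/√max(count, 1) — far better conditioned than free-lifetime fitting,
   and matching how such decays are analyzed in practice. The fast
   (~100 ps) amplitude a1 reports PSI-associated chlorophyll through
   PSI/(PSI+PSII) = c·a1/(1 − a1 + c·a1), with c a setup-specific
   correction factor taken as an input (default 0.49; its derivation is
   instrument-specific and out of scope). Free-lifetime and per-pixel
   fitting are out of scope.
3. **DCMU induction.** With DCMU blocking Q_A→Q_B transfer, fluorescence
   rise reflects a single stable charge separation, and the reciprocal of
   the complementary area above the normalized induction curve,
   1/∫(1 − V(t))dt, is the maximal initial PSII rate — proportional to
   the functional PSII antenna cross-section. Integration is trapezoidal
   over the trace plus an analytic exponential tail fitted to the last
   10% of samples; the curve must reach 99% of Fm or a coverage error
   with the partial area is raised.

## Fast induction (Vj)

Vj = (F(3 ms) − F0)/(Fm − F0) with F0 read 50 µs after pulse onset (the
first reliable point of fast-induction instruments) and Fm the pulse
maximum. The variable-fluorescence normalization is the default; the
plain F(3 ms)/Fm variant is available behind a flag. Vj against the
dark/far-red interval between pulses is summarized by the OLS slope
versus log10(interval) — the intervals span three orders of magnitude, so
a linear abscissa would let the longest interval dominate — alongside a
LOWESS curve (span 0.75) for display only. The full JIP-test parameter
suite is out of scope.

## Pigments

Chlorophyll quantification uses the multi-wavelength linear system for
Tris-buffered 80% acetone (1 cm pathlength, µg/ml):
chl a = 12.25·A663.6 − 2.55·A646.6, chl b = 20.31·A646.6 − 4.91·A663.6,
after subtracting the 750 nm turbidity reading and scaling by dilution.
The coefficients are module constants so other solvent systems can be
swapped in. Values in [−0.01, 0] µg/ml are clamped to zero; anything more
negative is rejected as spectrally inconsistent. Carotenoid quantification
is out of scope.

## Morphometry statistics

`compare_groups` gates the omnibus test on Shapiro–Wilk normality of the
residuals (values minus group means) at the same α: ANOVA if p ≥ α,
Kruskal–Wallis otherwise; a significant omnibus triggers all pairwise
Student's t-tests, unadjusted by default (Bonferroni/Holm optional).
Stack counts per granum are modeled with a Poisson GLM (log link, IRLS to
1e-8 deviance tolerance, Wald z statistics), widths with ordinary least
squares; both accept genotype-by-covariate interaction formulas. Counts
are modeled as-is even though the generator produces support-≥1 counts —
a known, mild misspecification that keeps the conventional model family;
the intercept-only fit still equals the log sample mean exactly, and the
genotype coefficient estimates the log mean ratio consistently.

## The synthetic data generator

Every simulator is a pure function of (parameters, seed). The generative
parameter set (`SimulationGroundTruth`) defaults to a wild-type-like
plant; `mutant_like()` applies the antenna-mutant offsets: PSII
cross-section −25%, PSII/PSI reaction-center ratio +25% (1.37 → 1.71),
maximal NPQ −30%, state-transition amplitude 0.12 → 0.02, fast FLIM
amplitude raised so the PSI chlorophyll share moves from ≈0.52 to ≈0.60,
and faster, more complete far-red PQ-pool oxidation.

**PAM.** A lake model: Fm′(t) = Fm/(1 + NPQ(t)) with NPQ the sum of a
fast component relaxing first-order toward the Hill steady state
NPQ_ss(I) = NPQ_max·I^h/(I50^h + I^h) (τ_ind = 60 s in light, τ_rel =
90 s in dark; defaults NPQ_max 2.4, I50 400 µmol m⁻² s⁻¹, h 1.3 — at the
1000 µmol m⁻² s⁻¹ induction protocol this drives end-of-light NPQ to
≈1.9) and a slowly reversible zeaxanthin-like component (amplitude 0.3,
τ 2000 s). The closed-center fraction is
C(I) = σ_II·I/(σ_II·I + k_d + σ_I·I/r): PSII excitation against PQ-pool
reoxidation driven by PSI excitation plus a constant dark pathway k_d
(default 100 intensity-equivalent units) — the constant term makes C rise
with intensity and vanish in darkness instead of being intensity-flat.
F0′ follows the Oxborough–Baker relation, and Fs follows the lake-model
relation Fs = Fm′·F0′/(F0′ + (1 − C)(Fm′ − F0′)), under which the derived
1 − qL equals C exactly; with the puddle-model linear Fs the derived
1 − qL would mix NPQ into the closed fraction and invert the
wild-type/mutant contrast at high light. Saturating pulses read Fm′,
far-red windows F0′. The emitted ground truth contains the exact
noiseless landmarks read with the same window conventions as the
extractor, so recovery tests isolate the extraction path. The simulator
also renders the far-red F0′ windows, so the analysis path that reads F0′
from the trace is exercised rather than assumed.

**ECS.** Flash responses step by amp_one_charge·(1 + r) (or ·1 with PSII
inhibited) and decay with τ_ATPase = 200 ms; off-decays start from a
plateau rate·amp·τ so the initial slope is exactly −rate·amp. The 546 nm
channel carries a slow linear drift also added to the 520 nm channel, so
deconvolution is exactly testable. Noise is multiplicative (each sample
scaled by 1 + N(0, sd)), emulating detection noise proportional to
transmitted intensity. Off-decays are sampled at 2 µs, the sampling class
of ECS spectrophotometers, which keeps the OLS slope variance small
relative to the w/2τ truncation bias.

**Other modalities.** DCMU induction is the exact exponential rise with
k = σ_II·I (the unit constant linking cross-section to rate is fixed at
1 — only ratios matter downstream). Vj series follow
V_inf + (V0 − V_inf)·e^(−Δ/τ) with τ_dark = 10 s, τ_far-red = 0.4 s
(0.3 s mutant-like) and plateaus 0.35 (dark) / 0.15 (far-red; 0.10
mutant-like — far-red drains the mutant pool to a more oxidized level,
which is what makes its far-red decline steeper on the fixed interval
grid). TCSPC histograms are multinomial draws of n_photons from the
(optionally IRF-convolved) three-exponential law, so totals are exact.
Grana stack counts are 1 + Poisson(mean − 1) — a granum has at least one
layer — with truncated-normal widths; the downstream GLM still treats
counts as plain Poisson. Pigment absorbances invert the quantification
matrix exactly.

**What the generator does not emulate:** baseline drift and photobleaching
in PAM traces, the ECS b/c-phases and proton-motive-force partitioning,
detector afterpulsing and dead time in TCSPC, biological replicate
variance structure, or any spatial heterogeneity. Passing recovery tests
therefore demonstrate correctness of the derivation chain under the
stated noise models, not robustness to every instrument artifact.

## Numerical choices and degenerate inputs

* Time is seconds everywhere internally; readers convert declared
  ms/µs/ps units at ingest.
* Phase membership uses half-open intervals [start, end); a sample on a
  boundary belongs to the later phase.
* Traces serialize at 17 significant digits, so write∘read round trips
  are exact; reports sort keys and fix float formats, so reruns are
  byte-identical (stage timings are logged to stderr, not serialized).
* Domain violations raise typed exceptions (`DomainError`,
  `CoverageError`, `ResolutionError`, ...); suspicious-but-usable data
  (Fs > Fm′, Fm′ > Fm) produce `QualityWarning` findings and are never
  silently clamped.
* The flash-amplitude ratio is scale invariant; the rate is linear in the
  slope; the FLIM fraction formula and its analytic inverse compose to
  the identity — all asserted as property tests.

## Problem sizes

The test suite and study runner use sizes that keep a full run on one CPU
in well under a minute while leaving the statistical criteria
discriminating: PAM light curves at 10 Hz (100 Hz for the noise-recovery
runs, giving ~60 samples per pulse plateau), 200-seed noise ensembles for
PAM and ECS, 100-seed ensembles at 10⁶ photons for FLIM, 2,000 null
simulations for the type-I-error check, and 240 grana per genotype (200
replicates) for the GLM consistency check.

## Known limitations

* The PAM generative model is a deliberately simple closed-form surrogate;
  it is not a kinetic electron-transport simulator.
* qE is defined by the two-point decomposition, not by fitting relaxation
  components; slowly reversible quenching beyond that split is not
  resolved.
* The FLIM correction factor c and the fixed lifetimes are inputs, not
  estimates; systematic error in either propagates directly to the PSI
  fraction.
* The morphometry GLM treats shifted-Poisson counts as Poisson (see
  above).
* Printed per-study regression values that depend on unavailable raw
  instrument data (e.g. published Vj trend numbers and model z-values)
  are context for interpretation, not reproduction targets.
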