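# Methods

`rloopkin` reimplements, as a tested pipeline over synthetic data, the
quantitative analyses used to characterise how 5′ modifications of a
Cas9 guide RNA change R-loop dynamics, R-loop size and DNA cleavage:
sequential cleavage kinetics on supercoiled plasmid, magnetic-tweezers
(MT) dwell-time analysis, rotation-curve R-loop sizing, and a FRET-ratio
readout of ribonucleoprotein (RNP) loading.

## Cleavage kinetics (`kinetics`)

A Cas9 RNP converts supercoiled plasmid (SC) to an open-circle nicked
intermediate (OC) and then to linear product (LIN). Two first-order
schemes are implemented:

* **two-step** — SC →(k_a) OC →(k_b) LIN. Solved in closed form (the
  Bateman solution for sequential decays); the degenerate branch
  OC(t) = k·t·e^(−kt) is used when |k_a−k_b|/k_a < 1e−9.
* **three-step** — an R-loop formation step precedes the first cut:
  U →(k_formation) R →(k_a) OC →(k_b) LIN. After the assay quench,
  R-loop-bound uncut plasmid co-migrates with SC on a gel, so the
  observed SC column is U + R. Solved with an adaptive ODE integrator
  (LSODA, rtol 1e−8, atol 1e−12), which also handles the stiff
  fast-formation limit.

Fitting minimises the **unweighted** sum of squared residuals over all
three species simultaneously, per replicate; counts are first normalised
to fractions per time point (scintillation counts scale per gel lane, so
per-lane totals carry no kinetic information). Parameters are fitted in
log space (positivity by construction) with three multiplicative starts
(×0.1, ×1, ×10 around the initial guess) to reduce local-minimum risk; a
fit is non-converged, and flagged rather than silently returned, only if
every start fails. Replicate estimates are averaged as mean ± SD (n−1);
a single replicate reports SD = NaN with an explicit flag. An optional
`f_active` ∈ (0, 1] scales the reactive SC pool for assays that do not go
to completion because of low specific activity; it is fixed at 1 unless
explicitly freed. Species are weighted equally because count depths per
lane are similar; no per-species weighting is applied.

The three-step refit supports clamping k_a (e.g. at 0.14 s⁻¹, the mean
first-strand rate of the unmodified-guide conditions) while k_formation
and k_b float — the configuration used to ask whether a slow apparent
first cut is really rate-limited by R-loop formation.

## Trace processing (`traces`)

MT bead traces are 60 Hz extension records of a torsionally constrained
DNA tether. Negative magnet turns favour R-loop formation, positive turns
favour dissociation; both transitions absorb/release ~2 turns of twist
and appear as **upward** extension steps.

* **Smoothing** — 2nd-order Butterworth low-pass (default 2 Hz cutoff),
  applied forward-backward (zero phase), matching the display convention
  for such traces and leaving step positions unbiased.
* **Segmentation** — each sample is labelled with its protocol phase;
  the magnet-transit window at the start of each phase
  (|Δturns| / rotation rate, default 10 turns/s) is flagged and excluded
  from dwell timing. The dwell clock starts when the transit ends,
  since dwell times are defined under constant applied turns.
* **Step detection** — per hold phase, the step height is the late-median
  minus early-median extension level. Holds with step below 25% of the
  expected full step yield a right-censored dwell (the hold duration).
  Otherwise the dwell is the first crossing of
  baseline + threshold_fraction × *measured* step height that persists
  ≥ 0.5 s. The threshold is taken against the measured rather than the
  expected step so that half-size (partial) R-loops — whose steps are
  ~41% of full — are detected by the same rule that classifies them:
  steps between 25% and 75% of the expected full step are flagged
  `complete=False`. The expected step itself comes from calibration
  (extension-per-turn of a no-enzyme rotation curve × full R-loop turns),
  never from a hard-coded constant. Detection is plain threshold-crossing
  with a persistence check — transparent and adequate at the
  signal-to-noise of these traces; change-point methods were considered
  and not needed.

Formation events are asserted (hard) to occur only in negative-turn
phases and dissociation events only in positive-turn phases. Traces in
which the R-loop forms during the magnet transit itself are outside the
detector's model; at the default transit times (≤ 3 s) and dwell scales
this is a small fraction of events.

## Dwell-time statistics (`dwellstats`)

Dwell times are summarised as the empirical survival function
P(T > t) = 1 − rank/N (ties share the maximal rank; right-continuous),
the "inverted cumulative probability" convention of single-molecule
kinetics. Exponential models,

    S(t) = e^(−t/τ)            or
    S(t) = a·e^(−t/τ_slow) + (1−a)·e^(−t/τ_fast),  τ_slow > τ_fast,

are fitted to the survival points by least squares — matching the fits
drawn through such plots — with τ in log space and the amplitude a
through a logit, so amplitudes sum to 1 by construction. Standard errors
come from the Gauss–Newton covariance (delta method back to the natural
scale); a seeded bootstrap is available when covariance SEs are unstable
at small N. A maximum-likelihood backend (closed form for one component,
EM for the mixture) serves as a cross-check. The reported mean time is τ
(one component) or a·τ_slow + (1−a)·τ_fast. Minimum event counts are 10
(single) and 19 (double), the smallest set sizes the fits are used on.

**Model selection** (1 vs 2 components) uses AICc computed from the
raw-dwell log-likelihood at the fitted parameters, not from the
survival-curve RSS: survival residuals are strongly correlated, and an
RSS-based score overstates the improvement of the richer model (in
simulation it selected two components on single-exponential data about
30% of the time at N = 1000; the likelihood-based score brings this to
the nominal AIC level). Ties go to the single component. Censored dwells
are excluded from fitting by default.

Formation-rate concentration dependence is fitted as rate = k·Cⁿ by
linear regression on log–log axes; n ± SE comes from the slope. The
formation pathway shows a second-order dependence on RNP concentration,
which this fit quantifies.

## R-loop sizing (`rloopsize`)

Extension-vs-turns "hat" curves (recorded at 1 turn/s) have linear flanks
past the buckling shoulder. A trapped R-loop unwinds DNA and shifts the
negative flank horizontally by the absorbed turns. Sizing steps:

1. **Flank fit** — OLS line on points with extension < 90% of the plateau
   and ≥ 2 turns beyond the apex (apex = centroid of the top 2% of the
   curve), requiring ≥ 5 points; a region whose slope is not resolvable
   from noise (|slope| ≤ 3 SE) is rejected as flat.
2. **Pairwise shift** — for each (reference, trapped) pair, the shift is
   the difference of the two flank lines' turn positions at the midpoint
   of their overlapping extension range; evaluating at the midpoint
   averages out intercept noise. Pairs whose slopes differ by > 20% are
   invalid and dropped (a hard error if more than half of all pairs are).
   The negative flank is used for sizing, because R-loops are trapped
   under negative torque; the positive flank is supported for symmetry
   checks.
3. **Aggregation** — all N_ref × N_rloop shifts (the study design pairs
   20 references with 22 trapped curves → 440 estimates) give the mean ±
   SD and a cumulative-probability curve.
4. **bp conversion** — bp = 20 × mean_turns / mean(full-length turns),
   calibrated on conditions assumed to form the full 20 bp R-loop. The
   conversion is exactly linear in mean_turns.

Conditions are compared by one-way ANOVA followed by all-pairs Tukey HSD
(statsmodels). The procedure is protected: a pair is called significant
only if the ANOVA rejects *and* its Tukey-adjusted p is below α. The
original analysis names only "a multiple comparison significance test";
ANOVA + Tukey is this package's choice and is recorded as such.

## FRET ratio (`fret`)

(ratio)_A = acceptor emission under donor excitation (530 nm) divided by
acceptor emission under direct acceptor excitation (630 nm). Peaks are
quantified as the mean intensity over ±10 nm around the acceptor emission
maximum located in the 630 nm spectrum (more robust than a single-pixel
maximum). When a donor-only reference is supplied, its scaled
contribution in the acceptor window is subtracted from the sensitized
emission (donor bleed-through correction). This corrected
sensitized/direct ratio is the module's defining convention; it is
invariant to joint rescaling of the two spectra and strictly increasing
in the sensitized amplitude. No conversion to absolute FRET efficiency or
distance is attempted — the ratio is used purely as a loading proxy
(high in the apo state, low once a gRNA is loaded).

Labelling efficiency follows Beer–Lambert arithmetic: dye concentrations
A/ε at 552 nm (Cy3) and 650 nm (Cy5), protein from A280 after
subtracting each dye's fractional 280 nm absorbance (defaults 0.08/0.05),
and dye:protein ratios from the quotients.

## Synthetic data (`synth`)

The generators emulate the statistical structure the analyses assume,
with defaults set to the study conditions: 60 Hz sampling, 10 turns/s
cycling, 1 turn/s sizing curves, a 1.9-turn (20 bp) full R-loop, 20/22
reference/trapped curve sets, ~2000 scintillation counts per gel lane.
Free parameters with no stated value were set once to field-typical
magnitudes: extension change 50 nm/turn (a typical plectoneme slope at
sub-piconewton forces; used only through calibration, never assumed by
analysis code), 10 nm Gaussian tracking noise at 60 Hz (SNR ≈ 9.5 on the
full step), rotation-curve noise 5 nm (≈ 5% of the full-step amplitude),
hold baselines and plateau heights of order 0.5–0.9 µm.

Noise models: white Gaussian on extension (no drift by default), Poisson
on scintillation counts, Gaussian emission bands with FRET-dependent
sensitized acceptor amplitude. Dwells exceeding the hold duration are
recorded as censored and the R-loop state carries across phases. Every
generator returns a machine-readable ground-truth sidecar, and all
randomness derives from the config seed through named streams, so
identical configs give byte-identical CSVs.

What the generators do **not** emulate — bead-tracking artefacts, drift,
torque-dependent dwell broadening, plectoneme mechanics, gel densitometry
nonlinearity, spectral baselines — bounds what passing tests show: the
pipeline recovers the parameters of data generated under its own
assumed models at realistic noise, which validates the estimators, not
the instruments.

## Workflow (`workflow`, `cli`)

`run_pipeline` chains simulate → analyze → fit → report for any subset of
stages {cleavage, dwells, sizing, fret}; every output embeds a manifest
(config hash, seed, package version, timestamp), and reruns with the same
manifest reproduce identical numbers. The default end-to-end study sizes
were chosen so each recovered quantity has a comfortably smaller sampling
error than its check tolerance: 3 cleavage replicates, 20 traces × 10
cycles (~200 dwells per kind), 20 × 22 curve pairs. The `rloopkin` CLI
exposes simulate, fit-cleavage, analyze-traces, fit-dwells, size-rloop,
ratio-a and run as thin wrappers over the library.

## Numerical choices and limitations

* Optimiser tolerances 1e−14 (xtol/ftol/gtol) for all least-squares fits;
  ODE tolerances rtol 1e−8 / atol 1e−12.
* Degenerate inputs are errors, not warnings: empty dwell sets, flat
  flanks, zero-variance groups (flagged), overcorrected A280, protocol /
  trace span mismatches.
* The two-strand cleavage order (which nuclease domain cuts first) is not
  identifiable from these data and is not modelled; k_a and k_b are
  apparent first/second-cut rates.
* Exponential-mixture amplitudes are constrained to sum to 1; fits with
  more than two components are out of scope.
* The half-size R-loop's dissociation behaviour under very long holds
  (hyperstable events) is represented only through the configurable
  mixture dwell laws, not mechanistically.
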