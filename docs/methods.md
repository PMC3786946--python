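# Methods

## Scope

`petrt` quantifies dynamic PET studies of a high-affinity dopamine D2/3
radioligand ([11C]FLB 457-like) acquired after an amphetamine challenge,
and asks the reliability question such studies hinge on: when the same
subject is scanned twice under identical conditions, how reproducible are
the plasma and brain outcome measures, and how large is the challenge
effect relative to that test-retest noise?

The pipeline covers: synthetic study generation with known ground truth,
arterial input processing, two-tissue compartment (2TC) kinetic fitting,
reference-region binding-potential outcomes, and test-retest statistics.
Image reconstruction, motion correction, MR segmentation and ROI
delineation are upstream of this package: its inputs are regional
time-activity curves and arterial sample tables.

## Plasma model

Total plasma activity is metabolite-corrected with a Hill-type parent
fraction

    f(t) = 1 - a t^b / (c + t^b),   0 <= a <= 1, b, c > 0,

fitted to six sparse HPLC measurements by bounded least squares with a
small multistart grid over slope and half-conversion constants. f(0) = 1
and monotone decline are structural. The no-metabolism case (all measured
fractions 1) returns a = 0 with a `degenerate` flag since b and c are then
unidentifiable.

The metabolite-corrected input is total activity x interpolated parent
fraction at each arterial sample. The curve is represented piecewise:
linear interpolation through the measured pre-peak samples (anchored at
(0, 0)), and a sum of up to three decaying exponentials fitted from the
time of the peak parent sample. The exponential fit minimises *relative*
residuals: arterial counting noise is multiplicative, and an unweighted fit
lets the large early samples swamp the small late ones, mis-estimating the
slow component that dominates the tail and hence V_T. Model order (1, 2 or
3 exponentials) is selected by best weighted SSE with ties broken toward
fewer terms, so a truly mono-exponential input recovers a single rate
rather than an arbitrary three-way split. Amplitudes are non-negative
(weighted NNLS inside a variable-projection multistart), keeping the curve
non-negative everywhere.

Clearance is C_L = dose / AUC with the fitted tail integrated to infinity
(the conventional AUC(0, inf)); the pre-peak portion integrates the linear
interpolant exactly. Units: minutes, kBq/mL and MBq internally; C_L
converted to L/h at the boundary (60 x MBq / (kBq/mL x min)). The fraction
of AUC beyond the observed 90 min is reported and a warning raised above
30%, flagging fits whose clearance rests mostly on extrapolation.

## Kinetic model

The 2TC model with rate constants K1 (mL cm^-3 min^-1, delivery), k2
(efflux), k3/k4 (exchange with the specifically bound compartment) has
tissue impulse response

    h(t) = K1/(a2 - a1) [(k3 + k4 - a1) e^{-a1 t} + (a2 - k3 - k4) e^{-a2 t}],

with eigenrates a1,2 = ((k2+k3+k4) -/+ sqrt((k2+k3+k4)^2 - 4 k2 k4))/2, and
total distribution volume V_T = (K1/k2)(1 + k3/k4). Because the input is
piecewise linear plus exponentials, the convolution has a closed form; the
forward model evaluates it exactly and averages each frame with 8-point
Gauss-Legendre quadrature (verified against a stiff LSODA integration to
~1e-10 relative). A repeated eigenvalue (discriminant below 1e-10 relative)
is handled by splitting the eigenrates symmetrically by 1e-7 relative,
numerically indistinguishable from the analytic limit (error O(eps^2 t^2)).

Fitting is weighted nonlinear least squares over (K1, k2, k3, k4) with
frame-duration weights (uniform available), bounds K1 in (0, 2],
k2..k4 in [1e-4, 2] min^-1, and the best of 10 multistarts (one fixed
physiological guess plus log-uniform draws from a seeded generator, so fits
are deterministic). No vascular term is fitted by default (vB = 0,
configurable up to 0.1): the quantification protocol this emulates uses
none, and the synthetic data contain none. Approximate standard errors come
from the Jacobian at the optimum; a flag marks fits with poorly determined
k3/k4 (relative SE > 1) or parameters pinned at bounds. Only V_T is treated
as reliably identified; micro-parameters may trade off.

## Outcomes

With cerebellar V_T estimating the non-displaceable volume V_ND:
BP_P = V_T - V_ND (mL cm^-3) and BP_ND = (V_T - V_ND)/V_ND (unitless),
computed per scan and then summarised — group BP_ND is a mean of per-scan
ratios, which is what the corresponding published tables contain and which
differs from the ratio of group means on heterogeneous data. Negative
binding potentials (possible at high noise) are kept with a warning;
censoring them would bias the reliability statistics. No correction is
applied for the small specific-binding fraction known to exist in the
cerebellar reference.

## Test-retest statistics

Per subject, VAR = 100 |test - retest| / mean(test, retest), summarised as
mean +/- sample SD (ddof 1). Variance components use the one-way
random-effects decomposition with subjects as groups and n = 2 repeats:
WSMSS = SS_within/(N(n-1)), BSMSS = n SS_between/(N-1); WSSD = sqrt(WSMSS);
BSSD is the SD of subject means; both are expressed as CVs against the
grand mean. The reliability coefficient is

    ICC = (BSMSS - WSMSS) / (BSMSS + (n - 1) WSMSS),

ranging from -1 (BSMSS = 0) to +1 (WSMSS = 0); the all-identical table
makes it 0/0 and is returned as NaN with a warning. BSSD/WSSD are not given
estimator definitions in the source protocol; the ANOVA-frame definitions
above are the standard PET test-retest choice and are consistent with the
printed ICC. The challenge effect size is d = |mean dBP_ND| / pooled
variability with pooling sqrt((BASE^2 + POST^2)/2) across the baseline and
post-challenge test-retest studies; d is reported as a magnitude, and
report tables round half away from zero to 2 decimals.

## Synthetic-study generator

The generator is the package's source of fully known ground truth. Defaults
describe one amphetamine test-retest study condition: 10 subjects x 2
sessions, 90-min acquisition in 33 frames (6x10 s, 4x30 s, 5x1 min,
8x4 min, 10x5 min), 35 arterial samples (every 6 s to 2 min, sparser
later), parent fractions at 4/10/20/40/60/80 min, 300 MBq injected dose.
The input curve rises linearly to a peak at 1.5 min (the pre-peak shape is
unconstrained by any fit downstream) and decays triexponentially with rates
0.6/0.08/0.011 min^-1; the true parent fraction is Hill with a = 0.8,
b = 1.5, c = 25. Population rate constants share K1 = 0.30, k2 = 0.12,
k4 = 0.025 across regions, with k3 solved per region so population V_T
equals the published post-amphetamine regional means (cerebellum 3.90,
medial temporal lobe 8.45, ..., temporal cortex 9.64), which makes
simulated summary tables directly comparable to the published ones.

Biological and measurement variation:

* **Between subject** (CV 0.18, mid-range of the published between-subject
  CVs): one log-normal multiplier per subject, applied to K1 *and* k3 —
  subjects differ in both delivery and receptor availability, so V_T, BP_P
  and BP_ND all carry real between-subject spread.
* **Within subject** (CV 0.09, matching the published ~9% session CV of
  V_T): one log-normal multiplier per session applied to K1 only. This
  emulates a scan-level input-function scale error, the dominant
  test-retest error source; it makes true V_T exactly log-normal across
  sessions (so the expected VAR has a closed form usable as a test oracle)
  and cancels in the V_T ratio, reproducing the empirical ordering in which
  BP_ND is the most reproducible outcome.
* **Measurement noise** (scale 0.025): multiplicative log-normal noise on
  plasma and parent-fraction samples; additive Gaussian frame noise with
  SD = scale x value / sqrt(frame duration), the standard count-statistics
  surrogate. The scale is set so that frame-noise-driven V_T estimation
  error stays a minor contributor and the *total* session-to-session V_T
  CV lands at the calibrated ~9%; larger frame noise would overshoot that
  calibration and, amplified by ~(1 + 1/BP_ND) in low-binding regions,
  dominate BP_ND variability. Plasma free fraction and amphetamine levels
  are generated as
  paired scalars with the same between/within CVs.

All multipliers are unit-mean log-normal (positivity-preserving, CV =
SD/mean); every random stream is keyed by (seed, stage, subject, session),
so regeneration is bit-identical and independent of evaluation order.
Injected dose is metadata only — it scales the curve but is not linked to
noise. What the generator does *not* emulate: voxel-level imaging effects
(resolution, partial volume, motion), dispersion/delay in the arterial
line, violations of the 2TC structure, and any systematic test-to-retest
bias (e.g. mass carryover). Passing tests therefore demonstrate estimator
correctness and self-consistency under the stated variance model, not
robustness to those real-data effects.

With these defaults the full pipeline lands close to the published
magnitudes (V_T VAR ~11%, BP_P ~14%, BP_ND ~9%, ICC ~0.7-0.8); exact VAR
levels are checked against the generator's own analytic expectation rather
than the published numbers, which reflect the original human scans.

## Numerical and design choices

* Exponential-fit multistarts are log-spaced over rates scaled to the data
  span; amplitude ties below 1e-9 of the maximum are zeroed.
* The pre-peak segment of a fitted input is pinned to the fitted value at
  the peak so the composed curve is continuous.
* Problem sizes in the analysis drivers (10 subjects, 9 regions, 10
  multistarts) match the emulated study design; the deeper simulation
  tests use 5 multistarts per fit, which the noiseless and calibrated-noise
  regimes do not distinguish from 10.
* Degenerate inputs: all-identical reliability tables return NaN ICC;
  zero pair means exclude a subject from VAR with a warning; a plasma curve
  that never decays raises "no decay phase".
* Known limitations: k3/k4 are weakly identified at 90 min for slow
  tracers (flagged, not prevented); clearance depends on tail extrapolation
  (flagged above 30%); BSSD/WSSD estimator choice is a convention, not a
  printed definition.
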