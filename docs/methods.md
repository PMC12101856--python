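# Methods

`serscal` implements a complete surface-enhanced Raman (SERS) chemometric
calibration study in silico: it synthesizes blood-SERS spectra whose band
intensities respond to growth hormone (GH) and testosterone (TE), reduces
them to principal-component scores, regresses score vectors to concentration
with small feedforward networks trained by resilient backpropagation, and
characterizes the calibration with RMSE, R², and leverage-based detection
limits, alongside a simulated ELISA reference assay.

## Spectrum model

A clean spectrum on the grid 400–1800 cm⁻¹ (step 2 cm⁻¹, 701 channels) is

    I(ν) = Σ_b A_b · [1 + s_b^GH f(C_GH) + s_b^TE f(C_TE)] · L(ν; ν_b, w) + B(ν)

where `L` is a unit-height Lorentzian of HWHM `w` = 8 cm⁻¹, `B` a gentle
quadratic background, and

    f(C) = C / (C + K),   K = 20 ng/ml

a saturating (adsorption-style) concentration response: SERS intensities grow
with analyte coverage of the nanoparticle surface and level off as sites
fill. The saturation is the reason a flexible nonlinear calibration (a neural
network) is preferred over a straight line.

The band table covers the prominent blood bands at 658, 798, 878, 914, 932,
1064, 1190, 1354, 1410 and 1658 cm⁻¹, plus the hormone-discriminating bands
seen in loading plots: GH-sensitive 658, 684, 1042, 1378 and 1596 cm⁻¹;
TE-sensitive 798, 914, 1240 and 1690 cm⁻¹ (a 912 cm⁻¹ TE band is folded into
914 — two centers 2 cm⁻¹ apart are unresolvable at 8 cm⁻¹ HWHM and would
only stack amplitude). Sensitivities default to 0.6 on hormone-specific
bands and 0 elsewhere. Base amplitudes (0.55–1.05) were fixed from a desk
signal-to-noise analysis before any end-to-end run: hormone-sensitive bands
sit at 0.9–1.0 so that, under the default noise, concentration information
survives at the top of the calibrated range, where `f'(C) = K/(C+K)²` is
sixteen times smaller than at zero.

Measurement noise has two parts, applied as
`m·I(ν) + ε(ν)` and clipped at zero:

* multiplicative jitter `m ~ N(1, 0.05)` per spectrum (laser power, focus,
  droplet geometry);
* additive white noise `ε ~ N(0, (0.01·max I)²)` per channel (shot/detector
  noise at peak SNR 100).

Vector normalization removes `m` almost exactly, which is why it is the
default preprocessing step.

### Calibration and in-vivo designs

The calibration series uses 30 log-spaced concentrations from 0.01 to
60 ng/ml with 30 replicates each (900 spectra). Standards emulate spiked
blood, so the off-target hormone sits at its endogenous baseline (TE
2 ng/ml in the GH series, GH 3 ng/ml in the TE series) rather than zero;
calibrating against a hormone-free matrix leaves a measurable bias on
physiological samples.

The in-vivo experiment has four groups (non-injected, GH, TE, GH+TE) of six
rats sampled at 0, 0.5, 2, 4, 8 and 24 h. Concentration time-courses follow
a Bateman (one-compartment, first-order absorption/elimination) profile

    C(t) = baseline + A·(e^{−k_e t} − e^{−k_a t})

with `k_e` = 0.3 h⁻¹ and `k_a`, `A` solved so the maximum equals the peak at
the peak time. Defaults: GH from 3 ng/ml to 44 ng/ml at 0.5 h; TE from
2 ng/ml to 20 ng/ml at 2 h (the TE peak value is a design choice in the
physiological range; the TE peak time follows the reference assay's
narrative). Per-rat lognormal factors (log-SD 0.1) scale the bolus so peaks
vary between animals while baselines stay fixed.

## Dimension reduction and calibration model

Spectra are vector-normalized and mean-centered; a thin SVD provides
loadings and scores. No per-channel variance scaling is applied (channels
share units). Six PC scores feed the networks; the sign convention (largest
|element| of each loading positive) makes fits reproducible.

The two regression networks follow fixed architectures —
6→12:10:10:10:6→1 for GH and 6→10:8:8:8:6→1 for TE — with ReLU hidden
activations and a linear output, trained on full-batch MSE in ng/ml by
Rprop+ (resilient backpropagation with weight backtracking): per-parameter
step sizes grow by η⁺ = 1.2 under stable gradient sign, shrink by η⁻ = 0.5
with the previous update reverted on a sign flip, within [10⁻⁶, 50], initial
step 0.01. Training runs at most 6000 epochs and stops earlier when the loss
has not improved by 10⁻⁸ for 50 consecutive epochs.

Two deliberate choices depart from common recipes, both verified on the
default protocol:

* **No per-feature standardization of the PC scores.** The synthetic signal
  is essentially rank one, so components 2–6 are nearly pure measurement
  noise; z-scoring inflates them to the same scale as the informative first
  component and the network then couples its output to them, roughly
  doubling validation RMSE. Scores therefore enter on their natural scale
  (Rprop's sign-based steps are insensitive to input scaling);
  standardization remains available as a `TrainConfig` option.
* **A committee of three restarts with median aggregation.** Full-batch
  Rprop+ on a deep ReLU stack occasionally settles in a visibly poor basin
  or, rarely, diverges. Three networks are trained from independent
  initializations and predictions are the elementwise median — robust to one
  bad member, neutral when all three are good.

Hold-out validation uses a concentration-stratified 75/25 split (675/225
spectra), so every level appears in both partitions; k-fold cross-validation
(default k = 4, consistent with the split geometry) reuses the same
stratification. Reported RMSE and R² follow the usual definitions; R² is one
minus the residual-to-total sum-of-squares ratio and may be negative for a
poor model.

## Detection limits

Limits of detection and quantification use the multivariate-calibration
form with blank leverages:

    limit = factor · sqrt( σ_b²/S₀² + h₀·σ_b²/S₀² + h₀·σ_ycal² )

with factor 3.3 (LOD) or 10 (LOQ), evaluated at the minimum and maximum
leverage `h₀ = t₀ᵀ(TᵀT)⁻¹t₀` of 30 simulated blank spectra (zero hormone)
projected into the centered calibration score space. `σ_ycal` is the SD of
training residuals in ng/ml. Because the calibration is a nonlinear network,
no separate univariate sensitivity is defined: `σ_b/S₀` is estimated
operationally as the SD of the model's predicted concentration over the
replicate blanks. Both estimators are isolated behind `LODInputs` and can be
swapped. At `h₀ = 0` the expression collapses to the univariate
`3.3·σ_b/S₀`, and LOQ/LOD = 10/3.3 exactly for any input.

## ELISA comparison

The reference assay is simulated from fixed "true" kit curves — a Boltzmann
sigmoid `OD = A₂ + (A₁−A₂)/(1+e^{(x−x₀)/dx})` for GH and an exponential
decay `OD = y₀ + A·e^{−x/t}` for TE — with eight log-spaced standards
(0.05–100 ng/ml) and 1% proportional OD noise. Curves are fitted by
nonlinear least squares from three heuristic starts; the Boltzmann fit is
canonicalized to `dx > 0` (the sigmoid is invariant under swapping plateaus
and negating `dx`). Unknown samples are quantified by closed-form inversion,
refused outside the standards' OD range; sample ODs at the plate rails are
clamped just inside the fitted curve's invertible interval, as kits do.
The comparison reports paired differences, Pearson correlation and per-group
peak times for the network and ELISA time-courses.

## What the generator does and does not emulate

It reproduces: band-level concentration sensitivity with saturation,
replicate noise at realistic SNR, multiplicative intensity jitter, the
calibration and group designs, and rise–peak–return pharmacokinetics. It
does **not** emulate: baseline drift or cosmic-ray artifacts (no correction
is implemented either), matrix heterogeneity between animals beyond the peak
factor, band shifts or width changes, or any electromagnetic-enhancement
physics. Passing tests therefore demonstrate the correctness and internal
consistency of the analysis chain on data with the assumed structure — not
performance on real instrument output.

Two consequences of the synthetic structure are worth stating plainly:

* **Explained variance concentrates in one component.** All GH bands share
  one response `f(C)`, so the signal is rank one: PC1 carries ~69% of the
  total variance of the normalized calibration set and PCs 2–6 sit at the
  noise floor (the remaining ~30% is white channel noise spread over 701
  dimensions). Six components capture roughly 70%, not ~90% as with real
  blood spectra, whose many uncontrolled biochemical sources of variation
  populate several components. The regression is unaffected — virtually all
  concentration information is inside the six scores.
* **Cross-hormone matrix effects are real but bounded.** Each model is
  calibrated with the other hormone fixed at baseline, so predictions are
  accurate for the non-injected group and the model's own group, and biased
  low when the other hormone is strongly elevated (the GH+TE group). This
  mirrors a genuine limitation of single-analyte calibration in a shared
  matrix and is reported, not hidden, by the time-course tables.

## Numerical and degenerate-input conventions

Normalization raises on an all-zero spectrum, naming the offending id.
PCA requires at least two spectra and `k ≤ min(n−1, p)`. Leverage
computation raises on a singular score Gram matrix. Band intensity is a
windowed maximum (default half-window 10 cm⁻¹) because band labels wander a
few cm⁻¹ between figures; loading-peak ties break toward the lower
wavenumber. A stratum with a single replicate goes to the training side of a
split with a warning. Training aborts on a non-finite loss. All randomness
derives from one global seed via named per-stage sub-seeds, so every run is
reproducible from its manifest.

## Problem sizes used by the test suite

The acceptance-style checks run the full default protocol (900 spectra per
hormone, 701 channels, three-restart committees, 6000-epoch cap) — about
15–20 s per hormone on one CPU. Unit and property tests use scaled-down
designs (tens of spectra, tiny networks) chosen to make each oracle exact or
fast. Validation RMSE at the default noise level is seed-sensitive
(roughly 0.3–0.9 ng/ml across data realizations) because the top
concentration levels, where the saturating response is flattest, dominate
the squared error; the methods above are at the information limit of the
simulated noise regime rather than of the optimizer.
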