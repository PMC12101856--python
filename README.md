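# serscal

Chemometric quantification of blood hormone levels from surface-enhanced
Raman spectra (SERS), end to end and fully synthetic: a spectrum generator
with concentration-sensitive Lorentzian bands stands in for the wet lab, and
the analysis chain — normalization, principal-component reduction,
neural-network calibration, detection limits, pharmacokinetic time-course
prediction and an ELISA cross-check — is implemented and tested on top of it.

## Who this is for

Raman/SERS spectroscopists and chemometricians who want a transparent,
reproducible reference implementation of score-based neural calibration:
how PC scores of normalized spectra are regressed to analyte concentration,
how resilient backpropagation (Rprop+) behaves on that problem, and how
multivariate detection limits follow from blank leverages.

## The model in brief

Synthetic blood spectra follow a band-plus-baseline model in which each
band's amplitude responds to growth hormone (GH) and testosterone (TE)
through a saturating term `f(C) = C/(C+K)` (K = 20 ng/ml) — the adsorption
behavior that makes SERS intensity nonlinear in concentration and motivates
a neural calibration. The pipeline is:

1. simulate a calibration series (30 log-spaced levels, 0.01–60 ng/ml,
   30 replicate spectra each);
2. vector-normalize each spectrum; reduce to six PC scores (mean-centered
   SVD);
3. train a ReLU network per hormone (GH: 6→12:10:10:10:6→1, TE:
   6→10:8:8:8:6→1) with full-batch Rprop+ on a stratified 75% split,
   median-aggregated over three restarts;
4. report validation RMSE = √(Σ(P−A)²/N) and R² = 1 − SS_res/SS_tot on the
   held-out 25%, plus limits of detection and quantification

       limit = factor · √( σ_b²/S₀² + h₀·σ_b²/S₀² + h₀·σ_ycal² )

   (factor 3.3 → LOD, 10 → LOQ) from 30 blank spectra and their leverages
   h₀ in score space;
5. predict the four-group (non-injected / GH / TE / GH+TE) 24-hour animal
   time-course and compare against a simulated ELISA standard-curve assay
   (Boltzmann curve for GH, exponential decay for TE).

See `docs/methods.md` for assumptions, defaults and limitations.

## Worked example

```bash
$ serscal calibrate --hormone gh --seed 42 --out-dir out
GH: validation RMSE 0.4720 ng/ml, R^2 0.9989; LOD_min 0.4062 ng/ml

$ serscal report out/gh/report.json
model  rmse_train_ng_ml  rmse_validation_ng_ml  r2_train  r2_validation  lod_min_ng_ml  lod_max_ng_ml  loq_min_ng_ml  loq_max_ng_ml
   gh          0.420126               0.472042  0.999142       0.998931       0.406192       0.416499       1.230884       1.262118
```

Reading the numbers: the GH network recovers held-out concentrations with a
root-mean-squared error of 0.47 ng/ml over the 0.01–60 ng/ml range and
explains 99.9% of the concentration variance (R² 0.9989). The smallest
concentration distinguishable from blank matrix is ~0.41 ng/ml (LOD), and
reliable quantification starts at ~1.23 ng/ml (LOQ = 10/3.3 × LOD by
construction). The same library calls are available in Python:

```python
from serscal import RunConfig, run_calibration, run_timecourse

cfg = RunConfig(seed=42)
calibrations = {h: run_calibration(cfg, h) for h in ("gh", "te")}
timecourse, groups, per_spectrum = run_timecourse(cfg, calibrations)
print(timecourse[(timecourse.hormone == "gh") & (timecourse.group == "GH")])
```

which shows the GH-injected group rising from its 3 ng/ml baseline to a
~43 ng/ml predicted peak at 0.5 h and returning to baseline by 24 h.
`serscal simulate`, `serscal predict` and `serscal elisa-compare` expose the
other stages; every command takes `--seed`, `--config` (YAML) and
`--out-dir`, and all outputs are plain CSV/JSON with a manifest sufficient
to re-run the stage.

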