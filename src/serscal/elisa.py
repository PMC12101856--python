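"""ELISA standard curves and inverse prediction for method comparison.

The plate-reader reference assay fits optical density (OD) against known
standards with one of two forms:

* Boltzmann sigmoid (growth-hormone kit):
  ``OD(x) = A2 + (A1 - A2) / (1 + exp((x - x0)/dx))``
* single exponential decay (testosterone kit, competitive format):
  ``OD(x) = y0 + A * exp(-x / t)``

Both are analytically invertible, so unknown samples are quantified by
closed-form inversion of the fitted curve.  Inversion outside the OD range
spanned by the standards is refused — extrapolating a standard curve is not
meaningful.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import curve_fit

CURVE_FORMS = ("boltzmann", "exp_decay")


def boltzmann(x, a1, a2, x0, dx):
    """Four-parameter sigmoid; ``a1`` and ``a2`` are the two plateaus."""
    x = np.asarray(x, dtype=float)
    return a2 + (a1 - a2) / (1.0 + np.exp((x - x0) / dx))


def exp_decay(x, y0, a, t):
    """Offset exponential decay with time-constant-like scale ``t``."""
    x = np.asarray(x, dtype=float)
    return y0 + a * np.exp(-x / t)


@dataclasses.dataclass
class StandardCurve:
    """A fitted standard curve with its validity range.

    ``parameters`` maps the form's parameter names to fitted values;
    ``valid_od_range`` is the OD interval spanned by the standards, the only
    region where inverse prediction is allowed.
    """

    model_form: str
    parameters: dict[str, float]
    fit_r2: float
    valid_od_range: tuple[float, float]

    def predict_od(self, conc) -> np.ndarray:
        if self.model_form == "boltzmann":
            return boltzmann(conc, *(self.parameters[k] for k in ("a1", "a2", "x0", "dx")))
        return exp_decay(conc, *(self.parameters[k] for k in ("y0", "a", "t")))


_PARAM_NAMES = {"boltzmann": ("a1", "a2", "x0", "dx"), "exp_decay": ("y0", "a", "t")}


def _initial_guesses(conc: np.ndarray, od: np.ndarray, form: str) -> list[np.ndarray]:
    """Three heuristic starts to dodge local minima of the nonlinear fit."""
    order = np.argsort(conc)
    c, o = conc[order], od[order]
    span = c[-1] - c[0]
    if form == "boltzmann":
        base = np.array([o[0], o[-1], float(np.median(c)), max(span / 5.0, 1e-3)])
        return [
            base,
            base * np.array([1.0, 1.0, 0.5, 2.0]),
            np.array([o[-1], o[0], float(np.median(c)), -max(span / 5.0, 1e-3)]),
        ]
    y0 = float(o[-1]) if o[0] > o[-1] else float(o[0])
    a = float(o[0] - y0)
    base = np.array([y0, a if a != 0 else 1.0, max(span / 3.0, 1e-3)])
    return [base, base * np.array([0.5, 1.5, 0.3]), base * np.array([1.0, 1.0, 3.0])]


def fit_standard_curve(concentrations, optical_densities, form: str) -> StandardCurve:
    """Nonlinear least-squares fit of one of the two standard-curve forms.

    Tries three heuristic starting points and keeps the best sum of squared
    residuals.  Requires more distinct standards than parameters.
    """
    if form not in CURVE_FORMS:
        raise ValueError(f"unknown form {form!r}; expected one of {CURVE_FORMS}")
    conc = np.asarray(concentrations, dtype=float)
    od = np.asarray(optical_densities, dtype=float)
    names = _PARAM_NAMES[form]
    if np.unique(conc).size != conc.size:
        raise ValueError("standard concentrations must be distinct")
    if conc.size < len(names) + 1:
        raise ValueError(
            f"{form} fit needs at least {len(names) + 1} standards, got {conc.size}"
        )
    func = boltzmann if form == "boltzmann" else exp_decay
    best_popt, best_ssr = None, np.inf
    for p0 in _initial_guesses(conc, od, form):
        try:
            popt, _ = curve_fit(func, conc, od, p0=p0, maxfev=20000)
        except RuntimeError:
            continue
        ssr = float(np.sum((func(conc, *popt) - od) ** 2))
        if ssr < best_ssr:
            best_popt, best_ssr = popt, ssr
    if best_popt is None:
        raise RuntimeError(
            f"{form} standard-curve fit failed to converge from all starts"
        )
    if form == "exp_decay" and best_popt[2] <= 0:
        raise RuntimeError("exp_decay fit produced a non-positive scale")
    if form == "boltzmann" and best_popt[3] < 0:
        # the sigmoid is invariant under (a1, a2, dx) -> (a2, a1, -dx);
        # canonicalize to dx > 0 so fits are unique and serializable
        best_popt = np.array(
            [best_popt[1], best_popt[0], best_popt[2], -best_popt[3]]
        )
    ss_tot = float(np.sum((od - od.mean()) ** 2))
    r2 = 1.0 - best_ssr / ss_tot if ss_tot > 0 else 1.0
    return StandardCurve(
        model_form=form,
        parameters=dict(zip(names, (float(v) for v in best_popt))),
        fit_r2=r2,
        valid_od_range=(float(od.min()), float(od.max())),
    )


def invert_curve(curve: StandardCurve, od: float) -> float:
    """Concentration (ng/ml) whose curve OD equals ``od``; closed form.

    Refuses ODs outside the standards' range (no extrapolation); results are
    clipped at zero concentration.
    """
    lo, hi = curve.valid_od_range
    tol = 1e-9 * max(abs(lo), abs(hi), 1.0)
    if not (lo - tol <= od <= hi + tol):
        raise ValueError(
            f"OD {od:.4g} outside the standards' range [{lo:.4g}, {hi:.4g}]"
        )
    p = curve.parameters
    if curve.model_form == "boltzmann":
        ratio = (p["a1"] - p["a2"]) / (od - p["a2"]) - 1.0
        if ratio <= 0:
            raise ValueError(f"OD {od:.4g} beyond the sigmoid plateau")
        x = p["x0"] + p["dx"] * np.log(ratio)
    else:
        ratio = (od - p["y0"]) / p["a"]
        if ratio <= 0:
            raise ValueError(f"OD {od:.4g} beyond the exponential plateau")
        x = -p["t"] * np.log(ratio)
    return max(float(x), 0.0)


def clip_to_range(curve: StandardCurve, od) -> np.ndarray:
    """Clamp ODs into the standards' range before inversion (kit practice for
    samples reading at the plate's rails).

    Also keeps values strictly inside the fitted curve's invertible interval:
    a noisy fit can place a sigmoid plateau just inside the standards' OD
    span, and an OD beyond the plateau has no finite inverse.
    """
    lo, hi = curve.valid_od_range
    p = curve.parameters
    if curve.model_form == "boltzmann":
        plat_lo, plat_hi = sorted((p["a1"], p["a2"]))
        margin = 1e-6 * (plat_hi - plat_lo)
        lo = max(lo, plat_lo + margin)
        hi = min(hi, plat_hi - margin)
    else:
        margin = 1e-6 * abs(p["a"])
        if p["a"] > 0:
            lo = max(lo, p["y0"] + margin)
        else:
            hi = min(hi, p["y0"] - margin)
    return np.clip(np.asarray(od, dtype=float), lo, hi)


def compare_methods(
    ann_predictions: pd.DataFrame,
    elisa_predictions: pd.DataFrame,
    keys: tuple[str, ...] = ("group", "time_h"),
) -> tuple[pd.DataFrame, dict]:
    """Pair ANN and ELISA concentration tables on (group, time).

    Both frames need the key columns plus a ``concentration`` column.  Returns
    the paired table with per-time differences and a summary with the Pearson
    correlation, mean difference and per-group peak-time agreement.
    """
    for name, df in (("ann", ann_predictions), ("elisa", elisa_predictions)):
        missing = [c for c in (*keys, "concentration") if c not in df.columns]
        if missing:
            raise KeyError(f"{name} predictions missing columns {missing}")
    merged = ann_predictions.merge(
        elisa_predictions, on=list(keys), suffixes=("_ann", "_elisa"), how="inner"
    )
    if len(merged) != len(ann_predictions) or len(merged) != len(elisa_predictions):
        raise ValueError("ANN and ELISA predictions do not share identical keys")
    merged["difference"] = merged["concentration_ann"] - merged["concentration_elisa"]
    if len(merged) >= 2 and merged["concentration_ann"].std() > 0:
        r, _ = stats.pearsonr(
            merged["concentration_ann"], merged["concentration_elisa"]
        )
    else:
        r = np.nan
    peak_times = {}
    for group, sub in merged.groupby("group"):
        peak_times[group] = {
            "ann": float(sub.loc[sub["concentration_ann"].idxmax(), "time_h"]),
            "elisa": float(sub.loc[sub["concentration_elisa"].idxmax(), "time_h"]),
        }
    summary = {
        "pearson_r": float(r),
        "mean_difference": float(merged["difference"].mean()),
        "max_abs_difference": float(merged["difference"].abs().max()),
        "peak_times": peak_times,
    }
    return merged, summary
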