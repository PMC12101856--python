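"""Calibration figures of merit: RMSE, R², and leverage-based LOD/LOQ.

The detection limits follow the multivariate-calibration form

    limit = factor * sqrt( sb^2/S0^2  +  h0 * sb^2/S0^2  +  h0 * sycal^2 )

with ``factor`` 3.3 for the limit of detection and 10 for the limit of
quantification, ``sb`` the blank-response SD, ``S0`` the sensitivity at
minimum analyte concentration, ``sycal`` the SD of calibration residuals in
concentration units, and ``h0`` the blank leverage — the normalized squared
distance of a blank from the calibration centroid in PC-score space, which
inflates the prediction variance for blanks far from the calibration cloud.
The minimum and maximum limits use the minimum and maximum blank leverages.
At ``h0 = 0`` the expression collapses to the univariate ``3.3 * sb / S0``.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np
import pandas as pd

LOD_FACTOR = 3.3
LOQ_FACTOR = 10.0


def rmse(predicted, actual) -> float:
    """Root mean squared error, sqrt(mean((P - A)^2)), in ng/ml."""
    p = np.asarray(predicted, dtype=float)
    a = np.asarray(actual, dtype=float)
    if p.size == 0:
        raise ValueError("empty prediction set")
    if p.shape != a.shape:
        raise ValueError("predicted and actual differ in shape")
    return float(np.sqrt(np.mean((p - a) ** 2)))


def r_squared(predicted, actual) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot.

    Computed against the residual sum of squares (not a squared correlation),
    so it is negative for models worse than the mean predictor; reported as
    computed.  Undefined when all actual values are equal.
    """
    p = np.asarray(predicted, dtype=float)
    a = np.asarray(actual, dtype=float)
    if p.size < 2:
        raise ValueError("R^2 needs at least two samples")
    ss_tot = float(np.sum((a - a.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("R^2 undefined: all actual values are equal")
    ss_res = float(np.sum((a - p) ** 2))
    return 1.0 - ss_res / ss_tot


def blank_leverage(
    calibration_scores: np.ndarray, blank_scores: np.ndarray
) -> tuple[float, float]:
    """(min, max) leverage of blank samples in calibration score space.

    ``h0 = t0' (T'T)^-1 t0`` with ``T`` the calibration score matrix centered
    on its own mean and ``t0`` a blank score relative to that mean.  Raises if
    ``T'T`` is singular (fewer effective calibration samples than components).
    """
    T = np.atleast_2d(np.asarray(calibration_scores, dtype=float))
    B = np.atleast_2d(np.asarray(blank_scores, dtype=float))
    if B.shape[1] != T.shape[1]:
        raise ValueError("blank scores have a different component count")
    center = T.mean(axis=0)
    Tc = T - center
    Bc = B - center
    gram = Tc.T @ Tc
    try:
        solved = np.linalg.solve(gram, Bc.T)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "singular score Gram matrix: use more calibration samples than components"
        ) from exc
    h0 = np.einsum("ij,ji->i", Bc, solved)
    return float(h0.min()), float(h0.max())


@dataclasses.dataclass
class LODInputs:
    """Ingredients of the leverage-based detection limits.

    ``sigma_b`` and ``s0`` only enter through their ratio (a concentration);
    when the blank SD is estimated directly from model-predicted blank
    concentrations, pass that SD as ``sigma_b`` with ``s0 = 1``.
    """

    sigma_b: float
    s0: float
    sigma_ycal: float
    h0_min: float
    h0_max: float

    def __post_init__(self) -> None:
        if self.s0 == 0:
            raise ValueError("zero sensitivity S0")
        if min(self.sigma_b, self.sigma_ycal, self.h0_min, self.h0_max) < 0:
            raise ValueError("LOD inputs must be non-negative")
        if self.h0_min > self.h0_max:
            raise ValueError("h0_min exceeds h0_max")


def detection_limits(
    inputs: LODInputs, expansion_factor: float = LOD_FACTOR
) -> tuple[float, float]:
    """(limit_min, limit_max) in ng/ml, at h0_min and h0_max respectively."""

    def limit(h0: float) -> float:
        ratio2 = (inputs.sigma_b / inputs.s0) ** 2
        return expansion_factor * float(
            np.sqrt(ratio2 + h0 * ratio2 + h0 * inputs.sigma_ycal**2)
        )

    return limit(inputs.h0_min), limit(inputs.h0_max)


def quantification_limits(inputs: LODInputs) -> tuple[float, float]:
    """LOQ: the same expression with expansion factor 10."""
    return detection_limits(inputs, expansion_factor=LOQ_FACTOR)


@dataclasses.dataclass
class CalibrationReport:
    """Everything a calibrated model reports: errors, fits, limits, folds."""

    hormone: str
    rmse_train: float
    rmse_validation: float
    r2_train: float
    r2_validation: float
    lod_min: float
    lod_max: float
    loq_min: float
    loq_max: float
    n_train: int
    n_validation: int
    fold_metrics: list[dict] | None = None

    def fold_summary(self) -> dict | None:
        """Mean and SD of the fold-level RMSE and R^2."""
        if not self.fold_metrics:
            return None
        r = np.array([f["rmse"] for f in self.fold_metrics])
        q = np.array([f["r2"] for f in self.fold_metrics])
        return {
            "rmse_mean": float(r.mean()),
            "rmse_sd": float(r.std(ddof=1)) if r.size > 1 else 0.0,
            "r2_mean": float(q.mean()),
            "r2_sd": float(q.std(ddof=1)) if q.size > 1 else 0.0,
            "k": len(self.fold_metrics),
        }

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["schema_version"] = 1
        summary = self.fold_summary()
        if summary:
            d["fold_summary"] = summary
        return d

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "CalibrationReport":
        with open(path, encoding="utf-8") as fh:
            d = json.load(fh)
        d.pop("schema_version", None)
        d.pop("fold_summary", None)
        return cls(**d)

    def to_frame(self) -> pd.DataFrame:
        """One-row summary mirroring the validation-metrics table layout."""
        return pd.DataFrame(
            [
                {
                    "model": self.hormone,
                    "rmse_train_ng_ml": self.rmse_train,
                    "rmse_validation_ng_ml": self.rmse_validation,
                    "r2_train": self.r2_train,
                    "r2_validation": self.r2_validation,
                    "lod_min_ng_ml": self.lod_min,
                    "lod_max_ng_ml": self.lod_max,
                    "loq_min_ng_ml": self.loq_min,
                    "loq_max_ng_ml": self.loq_max,
                }
            ]
        )


def build_report(
    hormone: str,
    train_predicted,
    train_actual,
    validation_predicted,
    validation_actual,
    lod_inputs: LODInputs,
    fold_metrics: list[dict] | None = None,
) -> CalibrationReport:
    """Assemble train/validation metrics and detection limits into a report."""
    lod_min, lod_max = detection_limits(lod_inputs)
    loq_min, loq_max = quantification_limits(lod_inputs)
    return CalibrationReport(
        hormone=hormone,
        rmse_train=rmse(train_predicted, train_actual),
        rmse_validation=rmse(validation_predicted, validation_actual),
        r2_train=r_squared(train_predicted, train_actual),
        r2_validation=r_squared(validation_predicted, validation_actual),
        lod_min=lod_min,
        lod_max=lod_max,
        loq_min=loq_min,
        loq_max=loq_max,
        n_train=int(np.asarray(train_actual).size),
        n_validation=int(np.asarray(validation_actual).size),
        fold_metrics=fold_metrics,
    )
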