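"""Spectral preprocessing: normalization, group averaging, band statistics.

The pipeline order is fixed: normalize each replicate, then average.  Vector
(Euclidean) normalization is the default; it removes per-spectrum
multiplicative intensity jitter, the dominant nuisance in SERS replicates.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import SpectrumSet

NORMALIZATION_METHODS = ("vector", "max", "area")


def normalize(spectrum_set: SpectrumSet, method: str = "vector") -> SpectrumSet:
    """Scale each spectrum to unit Euclidean norm, unit maximum or unit area.

    ``area`` uses the trapezoidal integral over the wavenumber grid.  Raises
    on an all-zero spectrum, naming the offending spectrum id.
    """
    X = spectrum_set.intensities
    if method == "vector":
        scale = np.linalg.norm(X, axis=1)
    elif method == "max":
        scale = X.max(axis=1)
    elif method == "area":
        scale = np.trapezoid(X, spectrum_set.wavenumbers, axis=1)
    else:
        raise ValueError(
            f"unknown normalization {method!r}; expected one of {NORMALIZATION_METHODS}"
        )
    zero = np.flatnonzero(scale == 0)
    if zero.size:
        sid = spectrum_set.metadata["spectrum_id"].iloc[zero[0]]
        raise ValueError(f"cannot normalize all-zero spectrum {sid!r}")
    return spectrum_set.with_intensities(X / scale[:, None])


def average_spectra(
    spectrum_set: SpectrumSet, group_keys: Sequence[str] = ("group",)
) -> SpectrumSet:
    """Channel-wise mean spectrum per metadata key combination.

    The result has one spectrum per key combination and records the replicate
    count in an ``n_replicates`` metadata column.  Numeric metadata not in the
    keys is averaged; other columns take the first value of the group.
    """
    group_keys = list(group_keys)
    meta = spectrum_set.metadata
    for key in group_keys:
        if key not in meta.columns:
            raise KeyError(f"metadata has no column {key!r}")
    rows = []
    means = []
    for combo, idx in meta.groupby(group_keys, sort=True).groups.items():
        idx = np.asarray(idx)
        if idx.size == 0:
            raise ValueError(f"empty group {combo!r}")
        combo = combo if isinstance(combo, tuple) else (combo,)
        means.append(spectrum_set.intensities[idx].mean(axis=0))
        row = dict(zip(group_keys, combo))
        sub = meta.iloc[idx]
        row.setdefault("spectrum_id", "mean_" + "_".join(str(c) for c in combo))
        for col in ("time_h", "gh_ng_ml", "te_ng_ml"):
            if col not in row:
                row[col] = float(sub[col].mean())
        if "group" not in row:
            row["group"] = str(sub["group"].iloc[0])
        row["n_replicates"] = int(idx.size)
        rows.append(row)
    return SpectrumSet(spectrum_set.wavenumbers, np.vstack(means), pd.DataFrame(rows))


def band_intensity(
    wavenumbers: np.ndarray,
    intensities: np.ndarray,
    center: float,
    half_window: float = 10.0,
) -> np.ndarray:
    """Maximum intensity within ``center +/- half_window`` (cm^-1).

    A windowed maximum rather than the value at the exact center, because
    band maxima wander by a few cm^-1 between spectra.  Works on a single
    spectrum or a matrix (rows = spectra).
    """
    wavenumbers = np.asarray(wavenumbers)
    step = np.min(np.diff(wavenumbers))
    if half_window < step:
        raise ValueError("half_window must be at least the grid step")
    if not (wavenumbers[0] <= center <= wavenumbers[-1]):
        raise ValueError(f"band center {center} cm^-1 outside the grid")
    lo, hi = center - half_window, center + half_window
    if lo < wavenumbers[0] or hi > wavenumbers[-1]:
        raise ValueError(
            f"window [{lo}, {hi}] cm^-1 extends outside the grid "
            f"[{wavenumbers[0]}, {wavenumbers[-1]}]"
        )
    mask = (wavenumbers >= lo) & (wavenumbers <= hi)
    return np.atleast_2d(intensities)[:, mask].max(axis=1)


@dataclasses.dataclass
class BandStatistics:
    """Descriptive statistics and one-way ANOVA for one band."""

    band_center: float
    group_means: dict[str, float]
    pooled_sd: float
    anova_f: float
    anova_p: float

    @property
    def pooled_variance(self) -> float:
        return self.pooled_sd**2


def band_statistics(
    spectrum_set: SpectrumSet,
    centers: Sequence[float],
    group_key: str = "group",
    half_window: float = 10.0,
) -> list[BandStatistics]:
    """Per-band group means, pooled SD and fixed-effects one-way ANOVA.

    Requires at least two groups with at least two spectra each (otherwise
    the ANOVA is undefined).
    """
    meta = spectrum_set.metadata
    if group_key not in meta.columns:
        raise KeyError(f"metadata has no column {group_key!r}")
    labels = meta[group_key].astype(str)
    groups = sorted(labels.unique())
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least two groups")
    results = []
    for center in centers:
        values = band_intensity(
            spectrum_set.wavenumbers, spectrum_set.intensities, center, half_window
        )
        per_group = [values[(labels == g).to_numpy()] for g in groups]
        if any(v.size < 2 for v in per_group):
            raise ValueError("each group needs at least two spectra")
        f_stat, p_val = stats.f_oneway(*per_group)
        dof = sum(v.size - 1 for v in per_group)
        pooled_var = sum((v.size - 1) * v.var(ddof=1) for v in per_group) / dof
        results.append(
            BandStatistics(
                band_center=float(center),
                group_means={g: float(v.mean()) for g, v in zip(groups, per_group)},
                pooled_sd=float(np.sqrt(pooled_var)),
                anova_f=float(f_stat),
                anova_p=float(p_val),
            )
        )
    return results


def band_statistics_frame(stats_list: list[BandStatistics]) -> pd.DataFrame:
    """Long-format CSV-ready table: one row per (band, group)."""
    rows = []
    for s in stats_list:
        for group, mean in s.group_means.items():
            rows.append(
                {
                    "band_center": s.band_center,
                    "group": group,
                    "mean": mean,
                    "sd": s.pooled_sd,
                    "variance": s.pooled_variance,
                    "F": s.anova_f,
                    "p": s.anova_p,
                }
            )
    return pd.DataFrame(rows)
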