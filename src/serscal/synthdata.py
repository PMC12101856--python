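"""Synthetic blood-SERS spectrum generator and experiment designs.

Real SERS spectra of silver-nanoparticle-mixed rat blood show a stack of
Lorentzian bands over a slowly varying background; growth hormone (GH) and
testosterone (TE) modulate the intensity of hormone-specific bands.  This
module emulates that signal:

* each band is a unit-height Lorentzian scaled by its base amplitude and by a
  saturating concentration response ``f(C) = C / (C + K)`` — band intensity
  grows with analyte adsorption and saturates as nanoparticle surface sites
  fill, which is why a nonlinear (neural) calibration is used downstream;
* a gentle quadratic baseline models the broad fluorescence background;
* instrument noise enters as a per-spectrum multiplicative factor (laser
  power / focus jitter) and additive white Gaussian channel noise.

Experimental designs mirror the animal study the analysis assumes: a
calibration series of ~30 log-spaced concentrations with ~30 replicates each,
and four in-vivo groups (non-injected, GH, TE, GH+TE) sampled at
0, 0.5, 2, 4, 8 and 24 h whose concentrations follow a Bateman
(one-compartment) pharmacokinetic profile.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq

from .dataset import SpectrumSet, concat_spectrum_sets

__all__ = [
    "BandSpec",
    "GeneratorConfig",
    "PKProfile",
    "SpectrumSet",
    "default_band_table",
    "clean_spectrum",
    "simulate_spectrum",
    "simulate_calibration_set",
    "simulate_blank_set",
    "simulate_pk_timecourse",
    "simulate_group_experiment",
    "simulate_elisa_standards",
    "GROUP_LABELS",
    "DEFAULT_TIMES_H",
    "GH_PK_DEFAULTS",
    "TE_PK_DEFAULTS",
]

#: Sampling times (hours) used in the in-vivo design.
DEFAULT_TIMES_H = (0.0, 0.5, 2.0, 4.0, 8.0, 24.0)

#: The four experimental groups.
GROUP_LABELS = ("non-injected", "GH", "TE", "GH+TE")

#: Pharmacokinetic defaults: GH peaks at 44 ng/ml half an hour post-injection
#: from a 3 ng/ml baseline; TE rises more slowly from 2 ng/ml.
GH_PK_DEFAULTS = {"baseline": 3.0, "peak": 44.0, "t_peak": 0.5}
TE_PK_DEFAULTS = {"baseline": 2.0, "peak": 20.0, "t_peak": 2.0}


@dataclasses.dataclass(frozen=True)
class BandSpec:
    """One Raman band.

    ``center`` and ``width`` (half-width at half-maximum) are in cm^-1;
    ``base_amplitude`` is the band height at zero analyte; the sensitivities
    scale the saturating concentration response of each hormone.
    """

    center: float
    width: float
    base_amplitude: float
    gh_sensitivity: float = 0.0
    te_sensitivity: float = 0.0

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("band width must be positive")
        if self.base_amplitude < 0:
            raise ValueError("base amplitude must be non-negative")


def default_band_table() -> tuple[BandSpec, ...]:
    """Band table emulating blood SERS spectra.

    Ten prominent blood bands (658, 798, 878, 914, 932, 1064, 1190, 1354,
    1410, 1658 cm^-1) plus the hormone-discriminating bands seen in loading
    plots: GH-sensitive 658, 684, 1042, 1378, 1596; TE-sensitive 798, 914,
    1240, 1690.  A 912 cm^-1 TE band is folded into 914 (unresolvable at the
    default 8 cm^-1 HWHM).  Sensitivity 0.6 on hormone-specific bands.
    """
    w = 8.0
    s = 0.6
    return (
        BandSpec(658.0, w, 1.00, gh_sensitivity=s),
        BandSpec(684.0, w, 0.90, gh_sensitivity=s),
        BandSpec(798.0, w, 1.00, te_sensitivity=s),
        BandSpec(878.0, w, 0.75),
        BandSpec(914.0, w, 1.00, te_sensitivity=s),
        BandSpec(932.0, w, 0.70),
        BandSpec(1042.0, w, 0.90, gh_sensitivity=s),
        BandSpec(1064.0, w, 0.65),
        BandSpec(1190.0, w, 0.55),
        BandSpec(1240.0, w, 0.90, te_sensitivity=s),
        BandSpec(1354.0, w, 1.00),
        BandSpec(1378.0, w, 0.90, gh_sensitivity=s),
        BandSpec(1410.0, w, 0.80),
        BandSpec(1596.0, w, 0.90, gh_sensitivity=s),
        BandSpec(1658.0, w, 1.05),
        BandSpec(1690.0, w, 0.90, te_sensitivity=s),
    )


@dataclasses.dataclass
class GeneratorConfig:
    """Everything needed to synthesize one spectrum.

    ``baseline_coefficients`` are polynomial coefficients (constant first) in
    the scaled coordinate ``u = (nu - grid_min) / (grid_max - grid_min)``.
    ``saturation_k`` is the half-saturation concentration K (ng/ml) of the
    band response ``f(C) = C / (C + K)``.  ``additive_noise_sd`` is a fraction
    of the spectrum's maximum clean intensity; ``multiplicative_jitter_sd`` is
    the SD of the per-spectrum scale factor around 1.
    """

    grid_min: float = 400.0
    grid_max: float = 1800.0
    grid_step: float = 2.0
    bands: tuple[BandSpec, ...] = dataclasses.field(default_factory=default_band_table)
    saturation_k: float = 20.0
    additive_noise_sd: float = 0.01
    multiplicative_jitter_sd: float = 0.05
    baseline_coefficients: tuple[float, ...] = (0.15, 0.20, -0.20)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_min >= self.grid_max:
            raise ValueError("grid_min must be below grid_max")
        if self.grid_step <= 0:
            raise ValueError("grid_step must be positive")
        if self.saturation_k <= 0:
            raise ValueError("saturation constant K must be positive")
        if self.additive_noise_sd < 0 or self.multiplicative_jitter_sd < 0:
            raise ValueError("noise parameters must be non-negative")
        if not self.bands:
            raise ValueError("band table is empty")
        self.bands = tuple(self.bands)
        for band in self.bands:
            if not (self.grid_min <= band.center <= self.grid_max):
                raise ValueError(
                    f"band center {band.center} cm^-1 outside grid range"
                )

    def grid(self) -> np.ndarray:
        """The shared wavenumber grid in cm^-1."""
        return np.arange(self.grid_min, self.grid_max + 0.5 * self.grid_step,
                         self.grid_step)

    # ------------------------------------------------------------- YAML I/O

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["bands"] = [dataclasses.asdict(b) for b in self.bands]
        d["baseline_coefficients"] = list(self.baseline_coefficients)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        if "bands" in d:
            d["bands"] = tuple(BandSpec(**b) for b in d["bands"])
        if "baseline_coefficients" in d:
            d["baseline_coefficients"] = tuple(d["baseline_coefficients"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------- spectra


def _lorentzian(nu: np.ndarray, center: float, width: float) -> np.ndarray:
    """Unit-height Lorentzian with HWHM ``width``."""
    return width**2 / (width**2 + (nu - center) ** 2)


def baseline_profile(config: GeneratorConfig, nu: np.ndarray | None = None) -> np.ndarray:
    """Polynomial background evaluated on the grid."""
    if nu is None:
        nu = config.grid()
    u = (nu - config.grid_min) / (config.grid_max - config.grid_min)
    return sum(c * u**k for k, c in enumerate(config.baseline_coefficients))


def saturating_response(conc: float, k: float) -> float:
    """Adsorption-style response f(C) = C / (C + K), in [0, 1)."""
    return conc / (conc + k)


def clean_spectrum(config: GeneratorConfig, gh_conc: float, te_conc: float) -> np.ndarray:
    """Noise-free band-plus-baseline profile; the generator's ground truth."""
    if gh_conc < 0 or te_conc < 0:
        raise ValueError("concentrations must be non-negative")
    nu = config.grid()
    fg = saturating_response(gh_conc, config.saturation_k)
    ft = saturating_response(te_conc, config.saturation_k)
    signal = baseline_profile(config, nu)
    for band in config.bands:
        amp = band.base_amplitude * (
            1.0 + band.gh_sensitivity * fg + band.te_sensitivity * ft
        )
        signal = signal + amp * _lorentzian(nu, band.center, band.width)
    return signal


def simulate_spectrum(
    config: GeneratorConfig,
    gh_conc: float,
    te_conc: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One noisy spectrum: multiplicative jitter then additive channel noise.

    ``intensity = m * clean(nu) + eps`` with ``m ~ N(1, jitter_sd)`` and
    ``eps ~ N(0, additive_sd * max(clean))`` i.i.d. per channel, clipped at 0.
    """
    clean = clean_spectrum(config, gh_conc, te_conc)
    m = 1.0 + config.multiplicative_jitter_sd * rng.standard_normal()
    eps_sd = config.additive_noise_sd * clean.max()
    noisy = m * clean + eps_sd * rng.standard_normal(clean.size)
    return np.clip(noisy, 0.0, None)


def _hormone_concentrations(
    hormone: str, level: float, other_conc: float | None
) -> tuple[float, float]:
    hormone = hormone.lower()
    if hormone == "gh":
        other = TE_PK_DEFAULTS["baseline"] if other_conc is None else other_conc
        return level, other
    if hormone == "te":
        other = GH_PK_DEFAULTS["baseline"] if other_conc is None else other_conc
        return other, level
    raise ValueError(f"unknown hormone {hormone!r}; expected 'gh' or 'te'")


def simulate_calibration_set(
    config: GeneratorConfig,
    hormone: str = "gh",
    n_concentrations: int = 30,
    conc_min: float = 0.01,
    conc_max: float = 60.0,
    n_replicates: int = 30,
    seed: int | None = None,
    other_conc: float | None = None,
) -> SpectrumSet:
    """Calibration series: log-spaced levels, ``n_replicates`` spectra each.

    Defaults reproduce the study design: 30 concentrations from 0.01 to
    60 ng/ml with 30 replicates, i.e. 900 spectra.  Calibration standards are
    spiked blood, so the *other* hormone sits at its endogenous baseline
    (``other_conc=None``; pass an explicit value, e.g. 0, to override) —
    otherwise predictions on physiological samples inherit a matrix bias.
    Fully reproducible from ``seed``.
    """
    if n_concentrations < 2:
        raise ValueError("need at least two concentration levels")
    if conc_min <= 0:
        raise ValueError("conc_min must be positive (levels are log-spaced)")
    if conc_min >= conc_max:
        raise ValueError("conc_min must be below conc_max")
    if n_replicates < 1:
        raise ValueError("need at least one replicate per level")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    levels = np.geomspace(conc_min, conc_max, n_concentrations)
    grid = config.grid()
    hormone = hormone.lower()
    intensities = np.empty((n_concentrations * n_replicates, grid.size))
    rows = []
    i = 0
    for li, level in enumerate(levels):
        gh, te = _hormone_concentrations(hormone, level, other_conc)
        for rep in range(n_replicates):
            intensities[i] = simulate_spectrum(config, gh, te, rng)
            rows.append(
                {
                    "spectrum_id": f"{hormone}_cal_L{li:02d}_r{rep:02d}",
                    "group": f"{hormone.upper()}-calibration",
                    "time_h": 0.0,
                    "gh_ng_ml": gh,
                    "te_ng_ml": te,
                }
            )
            i += 1
    return SpectrumSet(grid, intensities, pd.DataFrame(rows))


def simulate_blank_set(
    config: GeneratorConfig, n_blanks: int = 30, seed: int | None = None
) -> SpectrumSet:
    """Blank matrix spectra (zero hormone concentration) for detection limits."""
    if n_blanks < 2:
        raise ValueError("need at least two blanks to estimate a blank SD")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    grid = config.grid()
    intensities = np.vstack(
        [simulate_spectrum(config, 0.0, 0.0, rng) for _ in range(n_blanks)]
    )
    meta = pd.DataFrame(
        {
            "spectrum_id": [f"blank_{i:02d}" for i in range(n_blanks)],
            "group": "blank",
            "time_h": 0.0,
            "gh_ng_ml": 0.0,
            "te_ng_ml": 0.0,
        }
    )
    return SpectrumSet(grid, intensities, meta)


# -------------------------------------------------------------- PK profiles


@dataclasses.dataclass
class PKProfile:
    """A Bateman (one-compartment) concentration time-course.

    ``C(t) = baseline + A * (exp(-k_e t) - exp(-k_a t))`` with absorption rate
    ``k_a`` > elimination rate ``k_e``; ``A`` scales the bolus so that the
    maximum equals ``peak`` at ``t_peak``.  Constant profiles (non-injected
    controls) have ``amplitude = 0``.
    """

    times: np.ndarray
    concentrations: np.ndarray
    baseline: float
    peak: float
    absorption_rate: float
    elimination_rate: float
    amplitude: float

    def concentration(self, t) -> np.ndarray:
        """Evaluate the profile at arbitrary times (hours)."""
        t = np.asarray(t, dtype=float)
        if self.amplitude == 0.0:
            return np.full_like(t, self.baseline, dtype=float)
        return self.baseline + self.amplitude * (
            np.exp(-self.elimination_rate * t) - np.exp(-self.absorption_rate * t)
        )


def bateman_peak_time(k_a: float, k_e: float) -> float:
    """Closed-form argmax of the Bateman term: ln(k_a/k_e) / (k_a - k_e)."""
    if k_a <= k_e:
        raise ValueError("absorption rate must exceed elimination rate")
    return float(np.log(k_a / k_e) / (k_a - k_e))


def simulate_pk_timecourse(
    group: str,
    times: Sequence[float] = DEFAULT_TIMES_H,
    baseline: float = 3.0,
    peak: float = 44.0,
    t_peak: float = 0.5,
    elimination_rate: float = 0.3,
) -> PKProfile:
    """Bateman profile with its maximum at (t_peak, peak).

    Given ``elimination_rate`` (k_e, 1/h) and the requested peak time, the
    absorption rate k_a is solved from ``t_peak = ln(k_a/k_e)/(k_a - k_e)``
    and the amplitude from the peak value.  A ``group`` of ``non-injected``
    yields a constant profile at baseline.  Raises if the profile has not
    returned to within 10% of baseline by 24 h.
    """
    times = np.asarray(times, dtype=float)
    if group == "non-injected":
        return PKProfile(
            times, np.full(times.shape, float(baseline)), float(baseline),
            float(baseline), 0.0, 0.0, 0.0,
        )
    if peak < baseline:
        raise ValueError("peak concentration must be at least the baseline")
    if t_peak <= 0:
        raise ValueError("t_peak must be positive")
    if elimination_rate * t_peak >= 1:
        raise ValueError("elimination_rate * t_peak must be < 1 for a Bateman peak")
    k_e = float(elimination_rate)

    def peak_time_error(k_a: float) -> float:
        return np.log(k_a / k_e) - t_peak * (k_a - k_e)

    k_a = brentq(peak_time_error, k_e * (1 + 1e-9), 1e6)
    amplitude = (peak - baseline) / (
        np.exp(-k_e * t_peak) - np.exp(-k_a * t_peak)
    )
    profile = PKProfile(
        times, np.empty_like(times), float(baseline), float(peak),
        float(k_a), k_e, float(amplitude),
    )
    profile.concentrations = profile.concentration(times)
    residual = profile.concentration(24.0) - baseline
    if abs(residual) > 0.10 * baseline:
        raise ValueError(
            f"profile has not returned to baseline by 24 h (residual {residual:.3g} "
            f"ng/ml); increase elimination_rate"
        )
    return profile


def group_pk_profiles(
    group: str, times: Sequence[float] = DEFAULT_TIMES_H
) -> tuple[PKProfile, PKProfile]:
    """(GH profile, TE profile) for one experimental group."""
    if group not in GROUP_LABELS:
        raise ValueError(f"unknown group {group!r}")
    gh_injected = group in ("GH", "GH+TE")
    te_injected = group in ("TE", "GH+TE")
    gh = simulate_pk_timecourse(
        "injected" if gh_injected else "non-injected", times, **GH_PK_DEFAULTS
    )
    te = simulate_pk_timecourse(
        "injected" if te_injected else "non-injected", times, **TE_PK_DEFAULTS
    )
    return gh, te


def simulate_group_experiment(
    config: GeneratorConfig,
    n_rats_per_group: int = 6,
    times: Sequence[float] = DEFAULT_TIMES_H,
    rat_variation_sd: float = 0.1,
    seed: int | None = None,
) -> SpectrumSet:
    """In-vivo design: four groups x rats x sampling times, one spectrum each.

    Each rat carries a lognormal factor (log-SD ``rat_variation_sd``) applied
    to the bolus part of its group profile, so peaks vary between animals
    while baselines stay physiological.
    """
    if n_rats_per_group < 1:
        raise ValueError("need at least one rat per group")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    times = np.asarray(times, dtype=float)
    grid = config.grid()
    sets = []
    for group in GROUP_LABELS:
        gh_prof, te_prof = group_pk_profiles(group, times)
        for rat in range(n_rats_per_group):
            gh_factor = float(np.exp(rat_variation_sd * rng.standard_normal()))
            te_factor = float(np.exp(rat_variation_sd * rng.standard_normal()))
            gh_t = gh_prof.baseline + gh_factor * (
                gh_prof.concentration(times) - gh_prof.baseline
            )
            te_t = te_prof.baseline + te_factor * (
                te_prof.concentration(times) - te_prof.baseline
            )
            intensities = np.vstack(
                [
                    simulate_spectrum(config, g, t, rng)
                    for g, t in zip(gh_t, te_t)
                ]
            )
            meta = pd.DataFrame(
                {
                    "spectrum_id": [
                        f"{group}_rat{rat:02d}_t{t:g}h" for t in times
                    ],
                    "group": group,
                    "time_h": times,
                    "gh_ng_ml": gh_t,
                    "te_ng_ml": te_t,
                    "rat": f"{group}_rat{rat:02d}",
                }
            )
            sets.append(SpectrumSet(grid, intensities, meta))
    return concat_spectrum_sets(sets)


# ---------------------------------------------------------------- ELISA ODs


def simulate_elisa_standards(
    curve: Callable[[np.ndarray], np.ndarray],
    concentrations: Sequence[float],
    od_noise_fraction: float = 0.01,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Plate-reader standards: true curve plus proportional OD noise.

    ``curve`` maps concentration (ng/ml) to optical density; the returned
    frame has columns ``conc_ng_ml`` and ``od``.
    """
    rng = np.random.default_rng() if rng is None else rng
    conc = np.asarray(concentrations, dtype=float)
    od = np.asarray(curve(conc), dtype=float)
    od = od * (1.0 + od_noise_fraction * rng.standard_normal(od.size))
    return pd.DataFrame({"conc_ng_ml": conc, "od": od})
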